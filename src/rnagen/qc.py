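"""Sequence-quality filters, the non-canonical base-pair statistic, and a
greedy identity-clustering train/test split.

The filter battery removes, in order: (1) sequences with too many ambiguous
residues, (2) sequences covering too little of the consensus columns,
(3) unusually long sequences (length z-score), and (4) sequences breaking
too many consensus base pairs (z-score) — the last filter targets likely
pseudogenes. Z-score statistics are computed over the sequences surviving
the previous filters, with population SD (ddof=0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .sequence_io import AlignedFamily, NucleotideSequence, PairList

CANONICAL_PAIRS = {"GC", "CG", "AU", "UA", "GU", "UG"}


@dataclass
class QCParams:
    max_ambiguity_fraction: float = 0.05
    min_consensus_coverage: float = 0.85  # 0.90 for the broad multi-family mode
    length_sd_multiplier: float = 2.0  # 1.0 for 16S/23S rRNA
    bp_fraction_sd_multiplier: float = 2.0

    def __post_init__(self):
        if not 0 <= self.max_ambiguity_fraction <= 1:
            raise ValueError("max_ambiguity_fraction must be in [0,1]")
        if not 0 < self.min_consensus_coverage <= 1:
            raise ValueError("min_consensus_coverage must be in (0,1]")
        if self.length_sd_multiplier <= 0 or self.bp_fraction_sd_multiplier <= 0:
            raise ValueError("SD multipliers must be positive")

    @classmethod
    def rrna_mode(cls) -> "QCParams":
        return cls(min_consensus_coverage=0.85, length_sd_multiplier=1.0)

    @classmethod
    def rfam228_mode(cls) -> "QCParams":
        return cls(min_consensus_coverage=0.90, length_sd_multiplier=2.0)


@dataclass
class QCReport:
    records: list[dict] = field(default_factory=list)
    stats: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def passed_ids(self) -> list[str]:
        return [r["id"] for r in self.records if r["passed"]]


def noncanonical_bp_fraction(row: str, pairs: PairList) -> tuple[float, int]:
    """Fraction of scorable consensus pairs that are non-canonical.

    A pair is scorable when neither position is a gap or N. Returns
    (fraction, n_scorable); fraction is 0.0 when nothing is scorable.
    """
    scorable = 0
    noncanonical = 0
    for i, j in pairs:
        if i >= len(row) or j >= len(row):
            raise IndexError(f"pair ({i},{j}) out of range for row of length {len(row)}")
        a, b = row[i], row[j]
        if a in "-N" or b in "-N":
            continue
        scorable += 1
        if a + b not in CANONICAL_PAIRS:
            noncanonical += 1
    if scorable == 0:
        return 0.0, 0
    return noncanonical / scorable, scorable


def _consensus_coverage(seq: str, mask: list[bool] | None) -> float:
    cols = range(len(seq)) if mask is None else [c for c, m in enumerate(mask) if m]
    cols = list(cols)
    if not cols:
        return 0.0
    return sum(1 for c in cols if seq[c] != "-") / len(cols)


def apply_garnet_filters(
    family: AlignedFamily,
    pairs: PairList,
    params: QCParams | None = None,
    frozen_stats: dict | None = None,
) -> tuple[AlignedFamily, QCReport]:
    """Apply the four quality filters in order with running statistics.

    Each z-score filter computes its mean/SD over the sequences that
    survived the preceding filters (population SD). Passing
    ``frozen_stats`` from a previous report re-uses those means/SDs
    instead, which makes the filter idempotent on its own output.
    """
    if family.n_rows == 0:
        raise ValueError("cannot filter an empty family")
    params = params or QCParams()
    report = QCReport()

    recs = {}
    for rid, seq in family.rows:
        n_resid = sum(1 for c in seq if c != "-")
        n_amb = sum(1 for c in seq if c == "N")
        frac_amb = n_amb / n_resid if n_resid else 0.0
        bp_frac, n_scorable = noncanonical_bp_fraction(seq, pairs)
        recs[rid] = {
            "id": rid,
            "ambiguity_fraction": frac_amb,
            "consensus_coverage": _consensus_coverage(seq, family.consensus_mask),
            "length": n_resid,
            "noncanonical_bp_fraction": bp_frac,
            "scorable_pairs": n_scorable,
            "failed_filters": [],
        }

    # filter 1: ambiguity; filter 2: consensus coverage
    for r in recs.values():
        if r["ambiguity_fraction"] > params.max_ambiguity_fraction:
            r["failed_filters"].append("ambiguity")
        elif r["consensus_coverage"] < params.min_consensus_coverage:
            r["failed_filters"].append("coverage")

    def _z_filter(name: str, key: str, mult: float) -> None:
        survivors = [r for r in recs.values() if not r["failed_filters"]]
        if frozen_stats and name in frozen_stats:
            mean, sd = frozen_stats[name]
        elif len(survivors) < 2:
            report.notes.append(f"{name}: SD undefined for <2 survivors; filter skipped")
            report.stats[name] = (float("nan"), float("nan"))
            return
        else:
            vals = np.array([r[key] for r in survivors], dtype=float)
            mean, sd = float(vals.mean()), float(vals.std(ddof=0))
        report.stats[name] = (mean, sd)
        if sd == 0:
            return
        for r in survivors:
            if r[key] > mean + mult * sd:
                r["failed_filters"].append(name)

    _z_filter("length", "length", params.length_sd_multiplier)
    _z_filter("bp_fraction", "noncanonical_bp_fraction", params.bp_fraction_sd_multiplier)

    for r in recs.values():
        r["passed"] = not r["failed_filters"]
    report.records = list(recs.values())

    kept_ids = {r["id"] for r in recs.values() if r["passed"]}
    rows = [(rid, seq) for rid, seq in family.rows if rid in kept_ids]
    labels = None
    if family.labels:
        labels = {k: v for k, v in family.labels.items() if k in kept_ids}
    filtered = AlignedFamily(
        rows=rows,
        ss_cons=family.ss_cons,
        consensus_mask=family.consensus_mask,
        labels=labels,
    )
    return filtered, report


def pairwise_identity(a: str, b: str) -> float:
    """Fractional identity between two unaligned sequences.

    Computed from the global (Needleman-Wunsch) edit distance as
    1 - d / max(len); deterministic and symmetric.
    """
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def aligned_identity(a: str, b: str) -> float:
    """Identity over shared (both non-gap) MSA columns."""
    shared = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not shared:
        return 0.0
    return sum(1 for x, y in shared if x == y) / len(shared)


def greedy_cluster(
    sequences: list[NucleotideSequence], identity_threshold: float
) -> list[list[int]]:
    """Greedy centroid clustering, longest sequence first.

    Each sequence joins the first existing centroid with identity >=
    threshold, else founds a new cluster. Returns clusters as lists of
    indices into the input list.
    """
    if not 0 < identity_threshold < 1:
        raise ValueError("identity threshold must be in (0,1)")
    order = sorted(
        range(len(sequences)),
        key=lambda i: (-len(sequences[i]), sequences[i].id),
    )
    centroids: list[int] = []
    clusters: list[list[int]] = []
    for idx in order:
        placed = False
        for ci, cidx in enumerate(centroids):
            ident = pairwise_identity(
                sequences[idx].residues, sequences[cidx].residues
            )
            if ident >= identity_threshold:
                clusters[ci].append(idx)
                placed = True
                break
        if not placed:
            centroids.append(idx)
            clusters.append([idx])
    return clusters


def greedy_identity_split(
    sequences: list[NucleotideSequence],
    identity_threshold: float,
    test_token_fraction: float,
    rng_seed: int = 0,
) -> tuple[list[NucleotideSequence], list[NucleotideSequence], pd.DataFrame]:
    """Cluster at the identity threshold, then deal whole clusters to the
    test set (seeded shuffle) until it holds >= the requested nucleotide
    fraction; everything else is training data. No cluster is split.
    """
    if not sequences:
        return [], [], pd.DataFrame(columns=["id", "cluster", "split"])
    clusters = greedy_cluster(sequences, identity_threshold)
    total_tokens = sum(len(s) for s in sequences)
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(clusters))

    test_clusters: set[int] = set()
    test_tokens = 0
    for ci in order:
        if test_tokens >= test_token_fraction * total_tokens:
            break
        test_clusters.add(int(ci))
        test_tokens += sum(len(sequences[i]) for i in clusters[ci])

    rows = []
    train, test = [], []
    for ci, members in enumerate(clusters):
        split = "test" if ci in test_clusters else "train"
        for i in members:
            rows.append({"id": sequences[i].id, "cluster": ci, "split": split})
            (test if split == "test" else train).append(sequences[i])
    return train, test, pd.DataFrame(rows)


def diversity_curve(
    sequences: list[NucleotideSequence], thresholds: list[float]
) -> pd.DataFrame:
    """Cluster counts across identity thresholds (a redundancy curve)."""
    rows = [
        {"threshold": t, "n_clusters": len(greedy_cluster(sequences, t))}
        for t in thresholds
    ]
    return pd.DataFrame(rows)
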