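"""Finetuned-vs-pretrained mutation discovery statistics.

Two complementary interrogations of a pretrained (PT) and a finetuned (FT)
generative model:

* a per-column Jensen-Shannon divergence scan between the nucleotide
  frequency profiles of PT-generated and FT-generated sequence sets,
  masking seed columns and low-occupancy columns;
* whole-sequence likelihood scoring of candidate mutations,
  ddlogp = (logP_FT(mut) - logP_PT(mut)) - (logP_FT(wt) - logP_PT(wt)),
  with a reference distribution over all single-nucleotide mutants to
  place a candidate on a percentile scale.

A positive ddlogp means the finetuned model supports the mutant better
than the pretrained model does, relative to wild type. JSD uses base-2
logarithms, so values live in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequence_io import AlignedFamily, NucleotideSequence

NTS = "ACGU"
_NT_IDX = {c: i for i, c in enumerate(NTS)}


@dataclass
class ColumnDivergence:
    column: int  # 0-based reference coordinate
    jsd: float
    occupancy_pt: float
    occupancy_ft: float
    masked: bool
    mask_reason: str | None  # "seed" | "low_occupancy" | None
    rank: int | None  # 1-based among unmasked columns


@dataclass
class MutationSpec:
    """Substitutions (1-based position, from, to); no indels."""

    substitutions: list[tuple[int, str, str]]

    def __post_init__(self):
        positions = [p for p, _, _ in self.substitutions]
        if len(set(positions)) != len(positions):
            raise ValueError("mutation positions must be distinct")

    @property
    def name(self) -> str:
        if not self.substitutions:
            return "WT"
        return "-".join(f"{f}{p}{t}" for p, f, t in sorted(self.substitutions))

    def apply(self, wt: str) -> str:
        chars = list(wt)
        for pos, from_nt, to_nt in self.substitutions:
            i = pos - 1
            if i < 0 or i >= len(wt):
                raise ValueError(f"position {pos} outside the sequence")
            if chars[i] != from_nt:
                raise ValueError(
                    f"wild type has {chars[i]} at position {pos}, not {from_nt}"
                )
            chars[i] = to_nt
        return "".join(chars)


@dataclass
class MutationScore:
    spec: MutationSpec
    logp_ft_mut: float
    logp_pt_mut: float
    logp_ft_wt: float
    logp_pt_wt: float
    percentile: float | None = None

    @property
    def ddlogp(self) -> float:
        return (self.logp_ft_mut - self.logp_pt_mut) - (
            self.logp_ft_wt - self.logp_pt_wt
        )


def column_frequencies(
    family: AlignedFamily | list[str], column: int
) -> tuple[np.ndarray, bool]:
    """Nucleotide distribution over {A,C,G,U} at one alignment column.

    Gaps and N are excluded from the denominator. Returns (freqs, defined);
    `defined` is False for columns with no scorable residue."""
    rows = family.rows if isinstance(family, AlignedFamily) else [(None, r) for r in family]
    counts = np.zeros(4)
    for _, seq in rows:
        if column >= len(seq):
            raise IndexError(f"column {column} out of range")
        c = seq[column]
        if c in _NT_IDX:
            counts[_NT_IDX[c]] += 1
    total = counts.sum()
    if total == 0:
        return counts, False
    return counts / total, True


def _entropy2(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence, base 2: H((p+q)/2) - (H(p)+H(q))/2."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must share a support")
    if abs(p.sum() - 1) > 1e-6 or abs(q.sum() - 1) > 1e-6:
        raise ValueError("inputs must be normalized distributions")
    m = 0.5 * (p + q)
    return _entropy2(m) - 0.5 * (_entropy2(p) + _entropy2(q))


def jsd_scan(
    pt_family: AlignedFamily | list[str],
    ft_family: AlignedFamily | list[str],
    seed_mask_length: int,
    occupancy_min: float = 0.5,
) -> list[ColumnDivergence]:
    """Per-column JSD between PT- and FT-generated sets, with masking.

    Columns with index < seed_mask_length are masked (generation seed);
    columns under the occupancy threshold in either set are masked.
    Remaining columns are ranked by descending JSD, ties by lower index."""
    pt_rows = [r for _, r in pt_family.rows] if isinstance(pt_family, AlignedFamily) else list(pt_family)
    ft_rows = [r for _, r in ft_family.rows] if isinstance(ft_family, AlignedFamily) else list(ft_family)
    widths = {len(r) for r in pt_rows} | {len(r) for r in ft_rows}
    if len(widths) != 1:
        raise ValueError("PT and FT sets must be in the same fixed-width coordinates")
    W = widths.pop()

    def occ(rows: list[str], c: int) -> float:
        return sum(1 for r in rows if r[c] in _NT_IDX) / len(rows)

    out: list[ColumnDivergence] = []
    for c in range(W):
        o_pt, o_ft = occ(pt_rows, c), occ(ft_rows, c)
        reason = None
        if c < seed_mask_length:
            reason = "seed"
        elif o_pt < occupancy_min or o_ft < occupancy_min:
            reason = "low_occupancy"
        value = 0.0
        if reason is None:
            p, p_ok = column_frequencies(pt_rows, c)
            q, q_ok = column_frequencies(ft_rows, c)
            value = jsd(p, q) if (p_ok and q_ok) else 0.0
        out.append(
            ColumnDivergence(column=c, jsd=value, occupancy_pt=o_pt,
                             occupancy_ft=o_ft, masked=reason is not None,
                             mask_reason=reason, rank=None)
        )
    unmasked = [d for d in out if not d.masked]
    unmasked.sort(key=lambda d: (-d.jsd, d.column))
    for rank, d in enumerate(unmasked, start=1):
        d.rank = rank
    return out


def scan_table(divergences: list[ColumnDivergence]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"position": d.column + 1, "jsd": d.jsd,
             "occupancy_pt": d.occupancy_pt, "occupancy_ft": d.occupancy_ft,
             "masked": d.masked, "mask_reason": d.mask_reason, "rank": d.rank}
            for d in divergences
        ]
    )


def top_columns(divergences: list[ColumnDivergence], top_n: int) -> list[int]:
    ranked = sorted(
        (d for d in divergences if not d.masked), key=lambda d: d.rank
    )
    return [d.column for d in ranked[:top_n]]


def overlap_matrix(
    rankings: list[list[int]], top_n: int = 200
) -> tuple[np.ndarray, bool]:
    """Pairwise |top_n(a) & top_n(b)|; diagonal = effective top_n.

    If any ranking is shorter than top_n its full length is used and the
    returned flag is set."""
    if len(rankings) < 2:
        raise ValueError("need at least two rankings")
    truncated = any(len(r) < top_n for r in rankings)
    tops = [set(r[:top_n]) for r in rankings]
    m = len(tops)
    M = np.zeros((m, m), dtype=int)
    for a in range(m):
        for b in range(m):
            M[a, b] = len(tops[a] & tops[b])
    return M, truncated


def ddlogp(
    ft_model,
    pt_model,
    wt: NucleotideSequence | str,
    spec: MutationSpec,
    logprob_fn=None,
) -> MutationScore:
    """Score one mutation set by FT/PT whole-sequence log likelihoods.

    `logprob_fn(model, sequence_str) -> float` defaults to the language
    model scorer; pass a wrapper around the structure-conditioned model's
    scorer to evaluate alignment-coordinate models."""
    scores = ddlogp_batch(ft_model, pt_model, wt, [spec], logprob_fn)
    return scores[0]


def _default_logprob_batch(model, seqs: list[str]) -> list[float]:
    from .lm import sequence_log_probabilities

    return [r.logp for r in sequence_log_probabilities(model, seqs)]


def ddlogp_batch(
    ft_model,
    pt_model,
    wt: NucleotideSequence | str,
    specs: list[MutationSpec],
    logprob_fn=None,
    batch_logprob_fn=None,
) -> list[MutationScore]:
    wt_str = wt.residues if isinstance(wt, NucleotideSequence) else wt
    if batch_logprob_fn is None:
        if logprob_fn is None:
            batch_fn = _default_logprob_batch
        else:
            def batch_fn(model, seqs):
                return [logprob_fn(model, s) for s in seqs]
    else:
        batch_fn = batch_logprob_fn
    mutants = [spec.apply(wt_str) for spec in specs]
    ft_wt, pt_wt = batch_fn(ft_model, [wt_str])[0], batch_fn(pt_model, [wt_str])[0]
    ft_mut = batch_fn(ft_model, mutants)
    pt_mut = batch_fn(pt_model, mutants)
    return [
        MutationScore(spec=spec, logp_ft_mut=fm, logp_pt_mut=pm,
                      logp_ft_wt=ft_wt, logp_pt_wt=pt_wt)
        for spec, fm, pm in zip(specs, ft_mut, pt_mut)
    ]


@dataclass
class SingleMutantReference:
    """ddlogp values of every single-nucleotide mutant of the wild type."""

    scores: list[MutationScore]
    values: np.ndarray = field(init=False)

    def __post_init__(self):
        self.values = np.array([s.ddlogp for s in self.scores])

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=0))

    def percentile(self, x: float) -> float:
        """100 x the fraction of reference values strictly below x."""
        return float(100.0 * (self.values < x).mean())


def single_mutant_reference(
    ft_model,
    pt_model,
    wt: NucleotideSequence | str,
    logprob_fn=None,
    batch_logprob_fn=None,
    chunk_size: int = 96,
) -> SingleMutantReference:
    """ddlogp for all 3L single mutants, evaluated in chunks."""
    wt_str = wt.residues if isinstance(wt, NucleotideSequence) else wt
    specs = [
        MutationSpec([(pos + 1, wt_str[pos], alt)])
        for pos in range(len(wt_str))
        for alt in NTS
        if alt != wt_str[pos]
    ]
    scores: list[MutationScore] = []
    for s in range(0, len(specs), chunk_size):
        scores.extend(
            ddlogp_batch(ft_model, pt_model, wt_str, specs[s : s + chunk_size],
                         logprob_fn, batch_logprob_fn)
        )
    return SingleMutantReference(scores=scores)


def mutation_table(scores: list[MutationScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"name": s.spec.name, "logp_ft_mut": s.logp_ft_mut,
             "logp_pt_mut": s.logp_pt_mut, "logp_ft_wt": s.logp_ft_wt,
             "logp_pt_wt": s.logp_pt_wt, "ddlogp": s.ddlogp,
             "percentile": s.percentile}
            for s in scores
        ]
    )
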