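"""Synthetic RNA families with planted thermophile signal.

The generator emulates the situation the mutation-discovery pipeline is
built for: an alignment of a structured RNA family in which a subpopulation
of rows comes from hyperthermophiles (optimal growth temperature >= 60 C).
A family consensus is drawn once (paired columns jointly from canonical
pair frequencies, unpaired columns from background frequencies); rows are
i.i.d. copies of the consensus with per-position mutation noise. Planted
columns carry the thermophile signal: thermophile rows emit the "to"
nucleotide with probability delta, mesophile rows keep the consensus
nucleotide. Thermophile rows additionally re-draw each helix pair towards
G-C with a small probability, mimicking the GC-enrichment of thermophile
helices. A toy distance matrix consistent with the helix topology is
provided for structure-conditioned models: backbone neighbors sit at 6 A,
paired partners at 5 A, and all other distances are weighted shortest-path
lengths through that graph.

Rows are independent given their condition; real families' phylogenetic
correlation and indel structure are deliberately not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .sequence_io import AlignedFamily, PairList
from .structure import DistanceMatrix

NTS = "ACGU"
_NT_IDX = {c: i for i, c in enumerate(NTS)}

#: canonical pair frequencies: GC-rich stems with some wobble
DEFAULT_PAIR_FREQS = {
    "GC": 0.28, "CG": 0.28, "AU": 0.16, "UA": 0.16, "GU": 0.06, "UG": 0.06,
}
#: slightly A/U-rich loops, as in ribosomal RNA
DEFAULT_BACKGROUND = {"A": 0.30, "C": 0.20, "G": 0.22, "U": 0.28}


def hairpin(start: int, stem: int, loop: int) -> list[tuple[int, int]]:
    """Base pairs of a hairpin whose 5' side begins at `start`."""
    span = 2 * stem + loop
    return [(start + t, start + span - 1 - t) for t in range(stem)]


@dataclass
class SyntheticFamilySpec:
    length: int = 200
    helices: PairList = None
    background_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND))
    pair_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_FREQS))
    mutation_rate: float = 0.02
    planted_columns: list[tuple[int, str, str, float]] = field(default_factory=list)
    thermophile_fraction: float = 0.2
    gc_shift_thermo: float = 0.05
    ogt_mesophile: float = 37.0
    ogt_thermophile: float = 75.0
    gap_injection_rate: float = 0.0
    n_sequences: int = 500
    rng_seed: int = 0

    def __post_init__(self):
        if self.helices is None:
            self.helices = PairList([])
        paired = {c for p in self.helices for c in p}
        cols = [c for c, *_ in self.planted_columns]
        if len(set(cols)) != len(cols):
            raise ValueError("planted columns must be distinct")
        for col, from_nt, to_nt, delta in self.planted_columns:
            if col in paired:
                raise ValueError(f"planted column {col} lies inside a helix")
            if not 0 <= delta <= 1:
                raise ValueError("shift probability delta must be in [0,1]")
            if from_nt not in NTS or to_nt not in NTS:
                raise ValueError("planted nucleotides must be in ACGU")
        for freqs in (self.background_freqs, self.pair_freqs):
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError("frequency tables must sum to 1")

    @classmethod
    def default(
        cls,
        length: int = 200,
        n_sequences: int = 500,
        delta: float = 0.9,
        thermophile_fraction: float = 0.2,
        rng_seed: int = 0,
        **kwargs,
    ) -> "SyntheticFamilySpec":
        """A family with four hairpins and five planted unpaired columns
        (all U->C, echoing thermostabilizing loop mutations). The canonical
        layout is defined on 200 columns and scaled to other lengths;
        planted columns snap to the nearest unpaired position."""
        if length < 50:
            raise ValueError("default layout needs length >= 50")
        s = length / 200.0
        pairs = []
        for start, stem, loop in ((30, 8, 6), (70, 10, 8), (120, 8, 6), (160, 9, 6)):
            pairs += hairpin(int(start * s), max(2, int(stem * s)),
                             max(3, int(loop * s)))
        paired = {c for p in pairs for c in p}
        planted, used = [], set()
        for col in (40, 55, 83, 110, 130):
            c = int(col * s)
            while c in paired or c in used or c >= length:
                c += 1
            planted.append((c, "U", "C", delta))
            used.add(c)
        return cls(
            length=length,
            helices=PairList(sorted(pairs)),
            planted_columns=planted,
            thermophile_fraction=thermophile_fraction,
            n_sequences=n_sequences,
            rng_seed=rng_seed,
            **kwargs,
        )


@dataclass
class FamilySample:
    family: AlignedFamily
    consensus: str
    truth: dict
    distance: DistanceMatrix
    spec: SyntheticFamilySpec


def _draw_consensus(spec: SyntheticFamilySpec, rng: np.random.Generator) -> list[str]:
    cons = [""] * spec.length
    bg_nts = list(spec.background_freqs)
    bg_p = np.array([spec.background_freqs[c] for c in bg_nts])
    pair_kinds = list(spec.pair_freqs)
    pair_p = np.array([spec.pair_freqs[k] for k in pair_kinds])
    paired_cols = {c for p in spec.helices for c in p}
    for i, j in spec.helices:
        kind = pair_kinds[rng.choice(len(pair_kinds), p=pair_p)]
        cons[i], cons[j] = kind[0], kind[1]
    for c in range(spec.length):
        if c not in paired_cols:
            cons[c] = bg_nts[rng.choice(len(bg_nts), p=bg_p)]
    for col, from_nt, _, _ in spec.planted_columns:
        cons[col] = from_nt
    return cons


def sample_family(
    spec: SyntheticFamilySpec, rng: np.random.Generator | int | None = None
) -> FamilySample:
    """Draw a full family sample; bit-reproducible given spec.rng_seed."""
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    elif isinstance(rng, int):
        rng = np.random.default_rng(rng)

    consensus = _draw_consensus(spec, rng)
    planted = {col: (f, t, d) for col, f, t, d in spec.planted_columns}

    rows: list[tuple[str, str]] = []
    labels: dict[str, float] = {}
    n_thermo = 0
    for r in range(spec.n_sequences):
        is_thermo = rng.random() < spec.thermophile_fraction
        chars = list(consensus)
        if is_thermo:
            # GC reweighting of helix pairs
            for i, j in spec.helices:
                if rng.random() < spec.gc_shift_thermo:
                    kind = ("GC", "CG")[rng.integers(2)]
                    chars[i], chars[j] = kind[0], kind[1]
            for col, (from_nt, to_nt, delta) in planted.items():
                chars[col] = to_nt if rng.random() < delta else from_nt
        # mutation noise: replace with a uniform nucleotide
        noise = rng.random(spec.length) < spec.mutation_rate
        for c in np.flatnonzero(noise):
            chars[c] = NTS[rng.integers(4)]
        if spec.gap_injection_rate > 0:
            gaps = rng.random(spec.length) < spec.gap_injection_rate
            for c in np.flatnonzero(gaps):
                chars[c] = "-"
        if is_thermo:
            n_thermo += 1
            rid = f"thermo_{n_thermo:05d}"
            ogt = max(60.0, rng.normal(spec.ogt_thermophile, 5.0))
        else:
            rid = f"meso_{r + 1 - n_thermo:05d}"
            ogt = rng.normal(spec.ogt_mesophile, 5.0)
        rows.append((rid, "".join(chars)))
        labels[rid] = float(ogt)

    ss = _wuss_from_pairs(spec.helices, spec.length)
    family = AlignedFamily(rows=rows, ss_cons=ss,
                           consensus_mask=[True] * spec.length, labels=labels)
    return FamilySample(
        family=family,
        consensus="".join(consensus),
        truth=planted_truth(spec),
        distance=synthetic_distance_matrix(spec),
        spec=spec,
    )


def _wuss_from_pairs(pairs: PairList, length: int) -> str:
    chars = ["."] * length
    for i, j in pairs:
        chars[i], chars[j] = "<", ">"
    return "".join(chars)


def synthetic_distance_matrix(spec: SyntheticFamilySpec) -> DistanceMatrix:
    """Path-metric toy distances: backbone edges 6 A, pair edges 5 A,
    everything else the weighted shortest path through that graph."""
    n = spec.length
    rows, cols, w = [], [], []
    for i in range(n - 1):
        rows += [i, i + 1]
        cols += [i + 1, i]
        w += [6.0, 6.0]
    for i, j in spec.helices:
        rows += [i, j]
        cols += [j, i]
        w += [5.0, 5.0]
    graph = csr_matrix((w, (rows, cols)), shape=(n, n))
    D = shortest_path(graph, method="D", directed=False)
    return DistanceMatrix(D=D, labels=[str(i + 1) for i in range(n)],
                          mask=np.ones(n, dtype=bool))


def _emission_table(base: dict[str, float], mutation_rate: float) -> np.ndarray:
    """Post-noise emission distribution over ACGU for a pre-noise table."""
    p0 = np.array([base.get(c, 0.0) for c in NTS])
    return (1.0 - mutation_rate) * p0 + mutation_rate / 4.0


def planted_truth(spec: SyntheticFamilySpec) -> dict:
    """Ground truth for scan recovery: per planted column, the expected
    nucleotide distributions of the whole family (the pretraining
    population) and of the thermophile subpopulation (the finetuning
    population), plus the expected-positive substitution."""
    tf = spec.thermophile_fraction
    out = {}
    for col, from_nt, to_nt, delta in spec.planted_columns:
        ft_base = {from_nt: 1.0 - delta, to_nt: delta}
        pt_base = {from_nt: 1.0 - tf * delta, to_nt: tf * delta}
        out[col] = {
            "from": from_nt,
            "to": to_nt,
            "delta": delta,
            "pt_freqs": _emission_table(pt_base, spec.mutation_rate),
            "ft_freqs": _emission_table(ft_base, spec.mutation_rate),
            "mutation": (col + 1, from_nt, to_nt),  # 1-based for reports
        }
    return out
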