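"""Reading, writing and projecting RNA sequences and alignments.

Sequences are canonicalized to the RNA alphabet {A,C,G,U,N} on input:
T becomes U, lowercase is upcased, and IUPAC ambiguity codes collapse to N.
Alignments carry an optional consensus secondary structure (WUSS notation,
from a Stockholm ``#=GC SS_cons`` line) plus a per-column consensus mask.

Coordinates are 0-based half-open everywhere in the library; the CLI and
report writers convert to 1-based nucleotide numbering for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL = set("ACGUN")
_IUPAC_AMBIGUOUS = set("RYSWKMBDHVN")
GAP_CHARS = set(".-")

# WUSS bracket pairs; pseudoknot letters (Aa, Bb, ...) are treated as unpaired
_OPEN = {"<": ">", "(": ")", "[": "]", "{": "}"}
_CLOSE = {v: k for k, v in _OPEN.items()}


class ParseError(ValueError):
    """Malformed input file or structure string."""


def canonicalize_residues(raw: str, allow_gap: bool = False) -> str:
    """Map a raw residue string onto {A,C,G,U,N} (plus '-' if allow_gap)."""
    out = []
    for ch in raw:
        up = ch.upper()
        if up == "T":
            up = "U"
        if up in "ACGU":
            out.append(up)
        elif up in _IUPAC_AMBIGUOUS:
            out.append("N")
        elif allow_gap and ch in GAP_CHARS:
            out.append("-")
        else:
            raise ParseError(f"unexpected residue character {ch!r}")
    return "".join(out)


def ambiguity_fraction(raw: str) -> float:
    """Fraction of non-gap residues that are IUPAC-ambiguous (pre-collapse)."""
    residues = [c for c in raw if c not in GAP_CHARS]
    if not residues:
        return 0.0
    n_amb = sum(1 for c in residues if c.upper() not in "ACGUT")
    return n_amb / len(residues)


@dataclass
class NucleotideSequence:
    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - CANONICAL
        if bad:
            raise ValueError(f"sequence {self.id!r} has non-canonical residues {bad}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class PairList:
    """Base-paired column index pairs (i, j), i < j, 0-based."""

    pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        seen: set[int] = set()
        for i, j in self.pairs:
            if not i < j:
                raise ValueError(f"pair ({i},{j}) not ordered i < j")
            if i in seen or j in seen:
                raise ValueError(f"column in more than one pair: ({i},{j})")
            seen.update((i, j))

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


@dataclass
class AlignedFamily:
    """An MSA over {A,C,G,U,N,-} with optional structure and OGT labels."""

    rows: list[tuple[str, str]]
    ss_cons: str | None = None
    consensus_mask: list[bool] | None = None
    labels: dict[str, float] | None = None  # per-row OGT in deg C

    def __post_init__(self):
        widths = {len(seq) for _, seq in self.rows}
        if len(widths) > 1:
            raise ValueError(f"ragged alignment: row widths {sorted(widths)}")
        if self.ss_cons is not None and self.rows:
            if len(self.ss_cons) != self.n_columns:
                raise ValueError("SS_cons length does not match alignment width")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, row_id: str) -> str:
        for rid, seq in self.rows:
            if rid == row_id:
                return seq
        raise KeyError(f"row {row_id!r} not in family")

    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def ungapped(self) -> list[NucleotideSequence]:
        return [
            NucleotideSequence(rid, seq.replace("-", ""))
            for rid, seq in self.rows
            if seq.replace("-", "")
        ]


def read_fasta(path) -> list[NucleotideSequence]:
    """Read a FASTA file, canonicalizing residues; record order preserved."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            residues = canonicalize_residues(str(rec.seq))
        except ParseError as exc:
            raise ParseError(f"record {rec.id!r}: {exc}") from exc
        out.append(NucleotideSequence(rec.id, residues, rec.description))
    return out


def write_fasta(path, sequences: list[NucleotideSequence]) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description or "")
        for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def read_stockholm(path) -> AlignedFamily:
    """Read a Stockholm 1.0 alignment with an optional #=GC SS_cons line.

    '.' and '-' are both read as gaps. Columns where SS_cons/RF annotation
    marks an insert state (lowercase residue columns / '.' in RF) are
    flagged non-consensus; without annotation, a column is consensus when
    any residue in it is uppercase in the raw file.
    """
    try:
        aln = AlignIO.read(str(path), "stockholm")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    raw_rows = [(rec.id, str(rec.seq)) for rec in aln]
    n_cols = aln.get_alignment_length()

    col_ann = getattr(aln, "column_annotations", {}) or {}
    ss_raw = col_ann.get("secondary_structure")
    rf = col_ann.get("reference_annotation")
    if rf is not None:
        consensus = [c not in ".~" for c in rf]
    else:
        consensus = [
            any(seq[c].isupper() for _, seq in raw_rows) for c in range(n_cols)
        ]

    rows = [(rid, canonicalize_residues(seq, allow_gap=True)) for rid, seq in raw_rows]
    family = AlignedFamily(rows=rows, ss_cons=ss_raw, consensus_mask=consensus)
    if ss_raw is not None:
        pairs_from_wuss(ss_raw)  # validates bracket balance
    return family


def write_stockholm(path, family: AlignedFamily) -> None:
    with open(str(path), "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        width = max([len("#=GC SS_cons")] + [len(rid) for rid, _ in family.rows]) + 2
        for rid, seq in family.rows:
            fh.write(f"{rid:<{width}}{seq}\n")
        if family.ss_cons is not None:
            fh.write(f"{'#=GC SS_cons':<{width}}{family.ss_cons}\n")
        fh.write("//\n")


def pairs_from_wuss(ss: str) -> PairList:
    """Extract nested base pairs from a WUSS secondary-structure string.

    Matching is innermost-first per bracket family (<>, (), [], {});
    every other character, including pseudoknot letters, is unpaired.
    """
    stacks: dict[str, list[int]] = {b: [] for b in _OPEN}
    pairs: list[tuple[int, int]] = []
    for col, ch in enumerate(ss):
        if ch in _OPEN:
            stacks[ch].append(col)
        elif ch in _CLOSE:
            opener = _CLOSE[ch]
            if not stacks[opener]:
                raise ParseError(f"unbalanced {ch!r} at column {col}")
            pairs.append((stacks[opener].pop(), col))
    for opener, stack in stacks.items():
        if stack:
            raise ParseError(f"unbalanced {opener!r} at column {stack[-1]}")
    return PairList(sorted(pairs))


def project_pairs(pairs: PairList, column_map: dict[int, int]) -> PairList:
    """Re-index pairs through a column map, dropping pairs with lost ends."""
    kept = [
        (column_map[i], column_map[j])
        for i, j in pairs
        if i in column_map and j in column_map
    ]
    return PairList(sorted(kept))


def project_to_reference(
    family: AlignedFamily, ref_row_id: str
) -> tuple[AlignedFamily, dict[int, int]]:
    """Keep exactly the columns where the reference row is non-gap.

    Returns the projected family and the old->new column map. SS_cons is
    re-derived so that pairs losing an endpoint become unpaired ('.').
    """
    ref = family.row(ref_row_id)
    keep = [c for c, ch in enumerate(ref) if ch != "-"]
    if not keep:
        raise ValueError(f"reference row {ref_row_id!r} is all-gap")
    column_map = {old: new for new, old in enumerate(keep)}

    rows = [(rid, "".join(seq[c] for c in keep)) for rid, seq in family.rows]
    ss = None
    if family.ss_cons is not None:
        kept_pairs = project_pairs(pairs_from_wuss(family.ss_cons), column_map)
        chars = ["."] * len(keep)
        for i, j in kept_pairs:
            chars[i], chars[j] = "<", ">"
        ss = "".join(chars)
    mask = None
    if family.consensus_mask is not None:
        mask = [family.consensus_mask[c] for c in keep]
    labels = dict(family.labels) if family.labels else None
    return AlignedFamily(rows=rows, ss_cons=ss, consensus_mask=mask, labels=labels), column_map


def write_column_map(path, column_map: dict[int, int]) -> None:
    """Export an old->new column map as TSV (1-based positions)."""
    with open(str(path), "w") as fh:
        fh.write("alignment_column\treference_position\n")
        for old in sorted(column_map):
            fh.write(f"{old + 1}\t{column_map[old] + 1}\n")


def column_occupancy(family: AlignedFamily):
    """Per-column fraction of non-gap residues (N counts as occupied)."""
    import numpy as np

    if family.n_rows == 0:
        raise ValueError("empty family")
    counts = np.zeros(family.n_columns, dtype=np.int64)
    for _, seq in family.rows:
        counts += np.frombuffer(seq.encode(), dtype=np.uint8) != ord("-")
    return counts / family.n_rows
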