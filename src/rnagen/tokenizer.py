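"""Overlapping n-gram tokenization of RNA sequences.

A sequence of L nucleotides becomes L - n + 1 body tokens: the n-mer
starting at every position, stepping one nucleotide at a time, flanked by
BOS and EOS. Because the step is 1, each predicted token reveals exactly
one new nucleotide, so per-token perplexity is directly comparable across
n = 1, 2, 3 and equals the per-nucleotide perplexity.

There is no UNK token: the model alphabet is exactly the four nucleotides,
and sequences containing N must be removed by QC before encoding.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

from .sequence_io import NucleotideSequence

NUCLEOTIDES = "ACGU"
SPECIALS = ("<bos>", "<eos>", "<pad>")


@dataclass(frozen=True)
class TokenizerSpec:
    """Vocabulary for overlapping n-gram tokenization (n in {1,2,3})."""

    n: int
    vocab: dict[str, int] = field(compare=False)
    step: int = 1

    @property
    def vocab_size(self) -> int:
        return len(self.vocab)

    @property
    def bos_id(self) -> int:
        return self.vocab["<bos>"]

    @property
    def eos_id(self) -> int:
        return self.vocab["<eos>"]

    @property
    def pad_id(self) -> int:
        return self.vocab["<pad>"]

    def id_to_token(self) -> dict[int, str]:
        return {i: t for t, i in self.vocab.items()}

    def to_json(self) -> str:
        return json.dumps({"n": self.n, "step": self.step, "vocab": self.vocab})

    @classmethod
    def from_json(cls, text: str) -> "TokenizerSpec":
        obj = json.loads(text)
        return cls(n=obj["n"], vocab=obj["vocab"], step=obj["step"])


@dataclass
class TokenSequence:
    ids: list[int]
    source_length: int


def build_vocab(n: int) -> TokenizerSpec:
    """Lexicographic ids for all 4^n n-grams, then BOS/EOS/PAD."""
    if n not in (1, 2, 3):
        raise ValueError(f"n-gram size must be 1, 2 or 3, got {n}")
    grams = ["".join(g) for g in itertools.product(NUCLEOTIDES, repeat=n)]
    vocab = {g: i for i, g in enumerate(grams)}
    for s in SPECIALS:
        vocab[s] = len(vocab)
    return TokenizerSpec(n=n, vocab=vocab)


def encode(seq: NucleotideSequence | str, spec: TokenizerSpec) -> TokenSequence:
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    if "N" in residues:
        raise ValueError(
            "sequence contains N; ambiguous sequences must be removed by QC "
            "before tokenization"
        )
    n = spec.n
    if len(residues) < n:
        raise ValueError(f"sequence length {len(residues)} < n-gram size {n}")
    body = [spec.vocab[residues[i : i + n]] for i in range(len(residues) - n + 1)]
    return TokenSequence(ids=[spec.bos_id] + body + [spec.eos_id],
                         source_length=len(residues))


def decode(tokens: TokenSequence | list[int], spec: TokenizerSpec) -> tuple[str, int]:
    """Invert `encode`; returns (sequence, overlap inconsistency count).

    The sequence is rebuilt from the first character of each body token plus
    the trailing n-1 characters of the last one. Adjacent body tokens whose
    (n-1)-overlap disagrees are counted; the first-character policy above
    decides which nucleotide wins.
    """
    ids = tokens.ids if isinstance(tokens, TokenSequence) else list(tokens)
    if not ids or ids[0] != spec.bos_id:
        raise ValueError("token sequence must begin with BOS")
    body_ids = []
    for tid in ids[1:]:
        if tid == spec.eos_id:
            break
        if tid == spec.pad_id:
            raise ValueError("PAD inside token body")
        body_ids.append(tid)
    if not body_ids:
        return "", 0
    rev = spec.id_to_token()
    grams = [rev[t] for t in body_ids]
    inconsistencies = sum(
        1 for a, b in zip(grams, grams[1:]) if a[1:] != b[:-1]
    )
    seq = "".join(g[0] for g in grams) + grams[-1][1:]
    return seq, inconsistencies


def perplexity_from_nll(mean_nll_per_token: float) -> float:
    """exp(mean NLL); with step-1 tokenization this is per-nucleotide too."""
    if mean_nll_per_token < 0:
        raise ValueError("mean negative log-likelihood cannot be negative")
    return math.exp(mean_nll_per_token)
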