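"""Sequence primitives shared across the pipeline.

Mature miRNAs are stored as RNA (5'->3'), 3'UTRs as sense-strand DNA
(5'->3', 0-based half-open coordinates internally).  All cross-alphabet
comparisons go through the explicit converters below; T and U are
equivalent everywhere.
"""
from __future__ import annotations

from dataclasses import dataclass

_DNA_ALPHABET = set("ACGTN")
_RNA_ALPHABET = set("ACGUN")
_DNA_COMP = str.maketrans("ACGTN", "TGCAN")

#: seed anchor: first seed nucleotide is mature position 2 (1-based)
SEED_START = 2
SEED_LENGTHS = (6, 7, 8)


def as_dna(seq: str) -> str:
    """Uppercase and map U->T."""
    return seq.upper().replace("U", "T")


def as_rna(seq: str) -> str:
    """Uppercase and map T->U."""
    return seq.upper().replace("T", "U")


def revcomp_dna(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return as_dna(seq).translate(_DNA_COMP)[::-1]


@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature miRNA sequence with derived seed subsequences.

    The seed of length L covers mature positions 2..L+1 (1-based), i.e.
    seeds of length 6/7/8 span positions 2-7, 2-8 and 2-9.
    """

    name: str
    sequence: str  # RNA, 5'->3'

    def __post_init__(self) -> None:
        seq = as_rna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if not set(seq) <= _RNA_ALPHABET:
            raise ValueError(f"miRNA {self.name!r}: non-RNA characters in sequence")
        if len(seq) < 9:
            raise ValueError(
                f"miRNA {self.name!r}: length {len(seq)} < 9, seeds 6-8 undefined"
            )

    def seed(self, seed_len: int, seed_start: int = SEED_START) -> str:
        """Seed subsequence of the given length anchored at ``seed_start``."""
        i = seed_start - 1
        return self.sequence[i : i + seed_len]

    @property
    def seeds(self) -> dict[int, str]:
        return {n: self.seed(n) for n in SEED_LENGTHS}

    @property
    def sequence_dna(self) -> str:
        return as_dna(self.sequence)


@dataclass
class UTRSequence:
    """A 3'UTR sense-strand DNA sequence."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = as_dna(self.sequence)
        if not set(self.sequence) <= _DNA_ALPHABET:
            raise ValueError(f"UTR {self.gene_id!r}: non-DNA characters in sequence")

    def __len__(self) -> int:
        return len(self.sequence)
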