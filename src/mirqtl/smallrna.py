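"""Small-RNA read processing: adapter trimming, length filtering,
isomiR-tolerant annotation against a mature reference, and collapsing of
sequence variants into per-miRNA counts.

Annotation accepts an ungapped alignment with at most 2 substitutions
after allowing up to 2 additional or missing bases at either read end;
all end-shifted/substituted variants of a miRNA are counted under its
canonical name.  Reads tying between distinct miRNAs at the best score
are dropped as ambiguous.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import pandas as pd

from .sequences import MatureMiRNA, as_dna

DEFAULT_ADAPTER = "GCCTTGGCACCCGAGAATTCCA"
DEFAULT_MIN_LEN = 16
DEFAULT_MAX_LEN = 28
DEFAULT_MIN_OVERLAP = 6


@dataclass
class SmallRnaRead:
    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        self.sequence = as_dna(self.sequence)


class Assignment(NamedTuple):
    """One read assigned to a canonical miRNA.

    ``shift5``/``shift3``: signed extra (+) or missing (-) bases of the
    read relative to the reference at the 5'/3' end.
    """

    mirna: str
    shift5: int
    shift3: int
    n_mismatch: int


def trim_adapter(
    read: SmallRnaRead, adapter: str = DEFAULT_ADAPTER, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> SmallRnaRead:
    """Remove the 3' sequencing adapter from a read.

    The read prefix preceding the leftmost full adapter occurrence is
    kept; failing that, a >= ``min_overlap`` nt prefix of the adapter at
    the read's 3' end is removed.  A read with no occurrence is returned
    unchanged.  N bases never match adapter bases (exact string
    comparison), so trimming is conservative around them.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    adapter = as_dna(adapter)
    seq = read.sequence
    i = seq.find(adapter)
    if i < 0:
        # partial adapter at the 3' end: longest prefix wins (leftmost cut)
        for k in range(min(len(adapter) - 1, len(seq)), min_overlap - 1, -1):
            if seq.endswith(adapter[:k]):
                i = len(seq) - k
                break
    if i < 0:
        return read
    qual = read.quality[:i] if read.quality is not None else None
    return SmallRnaRead(read.id, seq[:i], qual)


def filter_reads(
    reads: Iterable[SmallRnaRead],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[SmallRnaRead]:
    """Keep reads whose trimmed length is in [min_len, max_len] with no N."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [
        r for r in reads
        if min_len <= len(r.sequence) <= max_len and "N" not in r.sequence
    ]


def _alignments(read_seq: str, ref_seq: str, max_mismatch: int, max_shift: int):
    """Enumerate ungapped alignments of read vs reference with bounded
    end shifts; yield (n_mismatch, total_shift, a, b) for admissible ones.

    ``a`` is the read index where the reference 5' end sits (a > 0: the
    read carries ``a`` extra upstream bases; a < 0: ``-a`` reference
    bases are missing from the read).  ``b`` is the analogous signed 3'
    difference, b = len(read) - len(ref) - a.
    """
    nr, nf = len(read_seq), len(ref_seq)
    for a in range(-max_shift, max_shift + 1):
        b = nr - nf - a
        if abs(b) > max_shift:
            continue
        lo = max(0, a)
        hi = min(nr, nf + a)
        if hi <= lo:
            continue
        mm = 0
        for i in range(lo, hi):
            if read_seq[i] != ref_seq[i - a]:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            yield (mm, abs(a) + abs(b), a, b)


def annotate_read(
    read: SmallRnaRead,
    reference: list[MatureMiRNA],
    max_mismatch: int = 2,
    max_shift: int = 2,
) -> tuple[Assignment | None, str]:
    """Assign a trimmed read to its best-matching reference miRNA.

    Best = fewest mismatches, then smallest total end shift.  Returns
    ``(assignment, status)`` with status in ``assigned`` / ``ambiguous``
    (distinct miRNAs tie at the identical best score) / ``unassigned``.
    """
    seq = read.sequence
    best_key = None
    best: list[tuple[str, int, int]] = []  # (name, a, b) at the best key
    for ref in reference:
        for mm, shift, a, b in _alignments(seq, ref.sequence_dna, max_mismatch, max_shift):
            key = (mm, shift)
            if best_key is None or key < best_key:
                best_key = key
                best = [(ref.name, a, b)]
            elif key == best_key:
                best.append((ref.name, a, b))
    if best_key is None:
        return (None, "unassigned")
    names = {name for name, _, _ in best}
    if len(names) > 1:
        return (None, "ambiguous")
    name, a, b = best[0]
    return (Assignment(name, shift5=a, shift3=b, n_mismatch=best_key[0]), "assigned")


def annotate_reads(
    reads: Iterable[SmallRnaRead],
    reference: list[MatureMiRNA],
    max_mismatch: int = 2,
    max_shift: int = 2,
) -> tuple[list[Assignment], dict[str, int]]:
    """Annotate a batch of reads; returns assignments plus a status tally.

    An exact-sequence dictionary short-circuits the (common) unshifted
    perfect matches before the full shifted-alignment search.
    """
    exact: dict[str, str | None] = {}
    for ref in reference:
        d = ref.sequence_dna
        exact[d] = None if d in exact else ref.name  # None marks a duplicate
    assignments: list[Assignment] = []
    tally = {"assigned": 0, "ambiguous": 0, "unassigned": 0}
    for read in reads:
        hit = exact.get(read.sequence, "")
        if hit:  # unique exact match
            assignments.append(Assignment(hit, 0, 0, 0))
            tally["assigned"] += 1
            continue
        asg, status = annotate_read(read, reference, max_mismatch, max_shift)
        tally[status] += 1
        if asg is not None:
            assignments.append(asg)
    return assignments, tally


def collapse_isomirs(
    assignments: Iterable[Assignment],
    sample_label: str,
    reference: list[MatureMiRNA],
) -> pd.Series:
    """Sum reads over all variants of each canonical miRNA.

    Returns one count-matrix column indexed by every reference miRNA
    (zeros included), named after the sample.
    """
    names = [m.name for m in reference]
    counts = pd.Series(0, index=pd.Index(names, name="mirna"), name=sample_label)
    for asg in assignments:
        if asg.mirna not in counts.index:
            raise KeyError(f"assignment references unknown miRNA {asg.mirna!r}")
        counts[asg.mirna] += 1
    return counts


def quantify_sample(
    reads: Iterable[SmallRnaRead],
    reference: list[MatureMiRNA],
    sample_label: str,
    adapter: str = DEFAULT_ADAPTER,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[pd.Series, dict[str, int]]:
    """Trim, filter, annotate and collapse one sample's reads."""
    trimmed = [trim_adapter(r, adapter, min_overlap) for r in reads]
    kept = filter_reads(trimmed, min_len, max_len)
    assignments, tally = annotate_reads(kept, reference)
    tally["total"] = len(trimmed)
    tally["filtered_out"] = len(trimmed) - len(kept)
    return collapse_isomirs(assignments, sample_label, reference), tally
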