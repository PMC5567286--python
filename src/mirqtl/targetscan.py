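"""Detection of miRNA seed-binding sites (MRESS) in 3'UTRs.

The scanner pairs a miRNA seed (anchored at mature position 2) against
UTR windows antiparallel, classifying each base pair as Watson-Crick,
G:U wobble, or mismatch, and admits a window under length-specific
allowances:

======  ===========  =============
length  G:U wobbles  mismatches
======  ===========  =============
6       0            0
7       <= 1         0
8       <= 1         <= 1
======  ===========  =============

No gaps/loops are ever allowed.  Each reported site carries the free
energy of the seed-anchored duplex extended 3'-ward along the miRNA
(nearest-neighbor stacking model; see :func:`duplex_energy`), and a flag
for the -15 kcal/mol hybridization threshold.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

from .sequences import SEED_START, MatureMiRNA, UTRSequence, as_rna

DEFAULT_ENERGY_CUTOFF = -15.0

# Watson-Crick pairs (miRNA base, target base), RNA alphabet
_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
# G:U wobble: seed G with target U, or seed U with target G
_WOBBLE = {("G", "U"), ("U", "G")}

PAIR_WC = "wc"
PAIR_WOBBLE = "wobble"
PAIR_MISMATCH = "mismatch"


class EnergyTableError(KeyError):
    """A required nearest-neighbor stack is missing from the energy table."""


def classify_pair(seed_base: str, target_base: str) -> str:
    """Classify one (miRNA base, target base as RNA) pair."""
    p = (seed_base, target_base)
    if p in _WC:
        return PAIR_WC
    if p in _WOBBLE:
        return PAIR_WOBBLE
    return PAIR_MISMATCH


@dataclass(frozen=True)
class SeedRuleSet:
    """Admission rules for one seed length."""

    seed_len: int
    seed_start: int = SEED_START
    max_wobble: int = 0
    max_mismatch: int = 0
    allow_gaps: bool = False  # fixed: no loop is ever allowed

    def __post_init__(self) -> None:
        if self.seed_len not in (6, 7, 8):
            raise ValueError(f"seed_len must be 6, 7 or 8, got {self.seed_len}")
        if self.allow_gaps:
            raise ValueError("gapped seeds are not supported")


#: the published scanning parameters: 6-mers exact, 7-mers tolerate one
#: wobble, 8-mers tolerate one wobble and one mismatch.
DEFAULT_RULES: dict[int, SeedRuleSet] = {
    6: SeedRuleSet(6, max_wobble=0, max_mismatch=0),
    7: SeedRuleSet(7, max_wobble=1, max_mismatch=0),
    8: SeedRuleSet(8, max_wobble=1, max_mismatch=1),
}


@dataclass
class SeedSite:
    """A located seed match on a UTR (0-based half-open interval)."""

    mirna: str
    gene_id: str
    start: int
    end: int
    seed_len: int
    n_wobble: int
    n_mismatch: int
    duplex_energy: float = field(default=float("nan"))
    passes_energy: bool = field(default=False)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def seed_match(seed: str, window: str, rules: SeedRuleSet):
    """Test one seed against one UTR window.

    The seed (RNA, 5'->3') pairs the window (DNA sense strand, 5'->3')
    antiparallel: seed position i pairs window position len-1-i.

    Returns ``(matched, n_wobble, n_mismatch)``.  Windows containing N
    never match.
    """
    if len(seed) != rules.seed_len or len(window) != rules.seed_len:
        raise ValueError(
            f"seed/window length must equal rules.seed_len={rules.seed_len}; "
            f"got {len(seed)} and {len(window)}"
        )
    w = as_rna(window)
    if "N" in w or "N" in seed:
        return (False, 0, 0)
    n_wob = n_mm = 0
    L = rules.seed_len
    for i in range(L):
        kind = classify_pair(seed[i], w[L - 1 - i])
        if kind == PAIR_WOBBLE:
            n_wob += 1
        elif kind == PAIR_MISMATCH:
            n_mm += 1
    matched = n_wob <= rules.max_wobble and n_mm <= rules.max_mismatch
    return (matched, n_wob, n_mm)


@lru_cache(maxsize=1)
def load_energy_table(resource: str = "stack_energies.tsv") -> dict[str, float]:
    """Load the nearest-neighbor stack table shipped with the package."""
    text = (
        importlib.resources.files("mirqtl.resources").joinpath(resource).read_text()
    )
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("stack\t"):
            continue
        key, val = line.split("\t")
        table[key] = float(val)
    if "INIT" not in table:
        raise EnergyTableError("energy table lacks the INIT duplex-initiation term")
    return table


def duplex_energy(
    mirna: MatureMiRNA,
    utr: UTRSequence,
    site_start: int,
    seed_len: int,
    energy_table: dict[str, float] | None = None,
    seed_start: int = SEED_START,
) -> float:
    """Free energy (kcal/mol) of the seed-anchored duplex at a site.

    The seed region (mature positions ``seed_start``..``seed_start+L-1``)
    pairs the window ``[site_start, site_start+L)``; pairing is then
    extended 3'-ward along the miRNA, one gapless base per step toward
    the UTR 5' side, for as long as pairs stay Watson-Crick or wobble.
    The total is the duplex-initiation term plus one stack term per
    adjacent pair of paired positions; a mismatch inside an 8-mer seed
    contributes no stack, and the 3'-ward extension stops at the first
    non-pairing position.
    """
    table = energy_table if energy_table is not None else load_energy_table()
    m = mirna.sequence
    u = as_rna(utr.sequence)

    # paired[j] for mature 1-based position j -> UTR index, or None if mismatched
    pairs: list[tuple[int, int] | None] = []  # (mature pos, utr index) or None
    for i in range(seed_len):
        j = seed_start + i  # mature position, 1-based
        t = site_start + seed_len - 1 - i
        kind = classify_pair(m[j - 1], u[t])
        pairs.append((j, t) if kind != PAIR_MISMATCH else None)
    # 3'-ward extension: mature seed_start+seed_len, ... pairing utr
    # positions site_start-1, site_start-2, ...
    j = seed_start + seed_len
    t = site_start - 1
    while j <= len(m) and t >= 0:
        if u[t] == "N" or classify_pair(m[j - 1], u[t]) == PAIR_MISMATCH:
            break
        pairs.append((j, t))
        j += 1
        t -= 1

    energy = table["INIT"]
    for a, b in zip(pairs, pairs[1:]):
        if a is None or b is None:
            continue
        (j1, t1), (j2, t2) = a, b
        key = f"{m[j1 - 1]}{m[j2 - 1]}/{u[t1]}{u[t2]}"
        try:
            energy += table[key]
        except KeyError:
            raise EnergyTableError(
                f"no stack entry {key!r} in energy table"
            ) from None
    return energy


def scan_sites(
    mirna: MatureMiRNA,
    utr: UTRSequence,
    rules: dict[int, SeedRuleSet] | None = None,
    energy_cutoff: float = DEFAULT_ENERGY_CUTOFF,
    energy_table: dict[str, float] | None = None,
    start_range: tuple[int, int] | None = None,
) -> list[SeedSite]:
    """Scan every window of every seed length; report sites sorted by start.

    At a given start position, only the longest matching seed length is
    reported (an 8-mer match subsumes the 7- and 6-mer calls at the same
    start).  ``start_range`` restricts the window starts considered
    (half-open, clipped to the UTR), used by the SNP classifier.
    """
    rules = rules if rules is not None else DEFAULT_RULES
    seq = utr.sequence
    n = len(seq)
    lengths = sorted(rules, reverse=True)
    seeds = {L: mirna.seed(L, rules[L].seed_start) for L in lengths}
    lo, hi = (0, n) if start_range is None else (max(0, start_range[0]), min(n, start_range[1]))
    sites: list[SeedSite] = []
    for s in range(lo, hi):
        for L in lengths:
            if s + L > n:
                continue
            matched, n_wob, n_mm = seed_match(seeds[L], seq[s : s + L], rules[L])
            if matched:
                e = duplex_energy(
                    mirna, utr, s, L, energy_table=energy_table,
                    seed_start=rules[L].seed_start,
                )
                sites.append(
                    SeedSite(
                        mirna=mirna.name,
                        gene_id=utr.gene_id,
                        start=s,
                        end=s + L,
                        seed_len=L,
                        n_wobble=n_wob,
                        n_mismatch=n_mm,
                        duplex_energy=e,
                        passes_energy=e <= energy_cutoff,
                    )
                )
                break  # longest match wins at this start
    return sites


def intersect_site_lists(
    lists: list[list[SeedSite]], slack: int = 5
) -> list[SeedSite]:
    """Consensus sites across independent predictors.

    A site from the first list is consensus iff every other list holds a
    site for the same (miRNA, gene) whose interval midpoint lies within
    ``slack`` nucleotides of its own.
    """
    if len(lists) < 2:
        raise ValueError("need at least two site lists to intersect")
    keyed: list[dict[tuple[str, str], list[SeedSite]]] = []
    for lst in lists[1:]:
        d: dict[tuple[str, str], list[SeedSite]] = {}
        for s in lst:
            d.setdefault((s.mirna, s.gene_id), []).append(s)
        keyed.append(d)
    consensus = []
    for site in lists[0]:
        ok = True
        for d in keyed:
            near = d.get((site.mirna, site.gene_id), [])
            if not any(abs(o.midpoint - site.midpoint) <= slack for o in near):
                ok = False
                break
        if ok:
            consensus.append(site)
    return consensus
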