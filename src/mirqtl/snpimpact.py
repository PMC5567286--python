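"""Classification of 3'UTR SNPs as destroying or creating miRNA seed
sites, and screening of pooled allele counts for high-vs-low family
imbalance.

A SNP *destroys* a site when the genomic (UTR) allele carries a seed
match overlapping the SNP and the other allele does not; it *creates* a
novel illegitimate site in the symmetric case.  Classification is a
function of the UTR sequence and the two alleles, so swapping which
allele is labelled REF in the variant table changes nothing.

The imbalance screen applies the pooled-variant filters (total reads
> 10, minor allele count > 4, MAF > 0.05) and flags SNPs whose
effect-allele frequency ratio between high- and low-ranked families is
>= 2.0 (amplification) or <= 0.5 (loss of heterozygosity).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .sequences import MatureMiRNA, UTRSequence
from .targetscan import DEFAULT_RULES, SeedRuleSet, SeedSite, scan_sites

CLASS_DESTROYED = "destroyed"
CLASS_CREATED = "created"
CLASS_NONE = "none"

FLAG_AMPLIFICATION = "amplification"
FLAG_LOH = "LOH"
FLAG_NONE = "none"

MIN_READS = 10
MIN_MINOR = 4
MIN_MAF = 0.05
RATIO_HIGH = 2.0
RATIO_LOW = 0.5


@dataclass
class SNPRecord:
    """A biallelic UTR SNP with pooled per-group allele depths.

    ``position`` is 1-based on the UTR sense strand; ``depths`` maps
    group label -> (ref reads, alt reads).
    """

    snp_id: str
    gene_id: str
    position: int
    ref_allele: str
    alt_allele: str
    depths: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ref_allele = self.ref_allele.upper()
        self.alt_allele = self.alt_allele.upper()
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.snp_id}: ref and alt alleles are identical")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(f"{self.snp_id}: alleles must be single bases")
        for g, (r, a) in self.depths.items():
            if r < 0 or a < 0:
                raise ValueError(f"{self.snp_id}: negative depth in group {g!r}")


@dataclass
class SnpImpact:
    snp_id: str
    mirna: str
    classification: str
    effect_allele: str | None = None
    site_before: SeedSite | None = None
    site_after: SeedSite | None = None


@dataclass
class PooledAlleleRecord:
    snp_id: str
    freq_alt: dict[str, float | None]  # per group; None when the group has no reads
    total_reads: dict[str, int]
    minor_allele_count: int
    maf: float
    filter_reason: str | None = None
    ratio_high_low: float | None = None
    flag: str = FLAG_NONE
    ratio_repr: str | None = None  # "0.5/0"-style sentinel for zero denominators

    @property
    def passes(self) -> bool:
        return self.filter_reason is None


def apply_allele(utr: UTRSequence, snp: SNPRecord, allele: str) -> UTRSequence:
    """Return the UTR sequence with the SNP base substituted."""
    pos0 = snp.position - 1
    if not 0 <= pos0 < len(utr.sequence):
        raise IndexError(
            f"{snp.snp_id}: position {snp.position} outside UTR {utr.gene_id} "
            f"(length {len(utr.sequence)})"
        )
    base = utr.sequence[pos0]
    if base not in (snp.ref_allele, snp.alt_allele):
        raise ValueError(
            f"{snp.snp_id}: UTR base {base!r} at position {snp.position} matches "
            f"neither allele [{snp.ref_allele}/{snp.alt_allele}]"
        )
    allele = allele.upper()
    if allele not in (snp.ref_allele, snp.alt_allele):
        raise ValueError(f"{snp.snp_id}: {allele!r} is not one of this SNP's alleles")
    return UTRSequence(utr.gene_id, utr.sequence[:pos0] + allele + utr.sequence[pos0 + 1 :])


def _overlapping_sites(
    mirna: MatureMiRNA,
    utr: UTRSequence,
    pos0: int,
    rules: dict[int, SeedRuleSet],
    energy_cutoff: float | None,
) -> list[SeedSite]:
    max_len = max(rules)
    sites = scan_sites(
        mirna, utr, rules=rules,
        energy_cutoff=energy_cutoff if energy_cutoff is not None else 0.0,
        start_range=(pos0 - max_len + 1, pos0 + 1),
    )
    sites = [s for s in sites if s.start <= pos0 < s.end]
    if energy_cutoff is not None:
        sites = [s for s in sites if s.passes_energy]
    return sites


def classify_snp(
    snp: SNPRecord,
    utr: UTRSequence,
    mirnas: list[MatureMiRNA],
    rules: dict[int, SeedRuleSet] | None = None,
    energy_cutoff: float | None = None,
) -> list[SnpImpact]:
    """Compare seed-site calls under the two alleles, per miRNA.

    Only windows overlapping the SNP are scanned (classification is
    local by construction).  When ``energy_cutoff`` is given, a site
    only counts if its duplex energy passes it; by default presence is
    judged on the seed rules alone.
    """
    rules = rules if rules is not None else DEFAULT_RULES
    pos0 = snp.position - 1
    genome_allele = utr.sequence[pos0]
    if genome_allele not in (snp.ref_allele, snp.alt_allele):
        raise ValueError(
            f"{snp.snp_id}: UTR base {genome_allele!r} matches neither allele"
        )
    other_allele = (
        snp.alt_allele if genome_allele == snp.ref_allele else snp.ref_allele
    )
    utr_other = apply_allele(utr, snp, other_allele)
    impacts = []
    for m in mirnas:
        sites_g = _overlapping_sites(m, utr, pos0, rules, energy_cutoff)
        sites_o = _overlapping_sites(m, utr_other, pos0, rules, energy_cutoff)
        if sites_g and not sites_o:
            impacts.append(
                SnpImpact(snp.snp_id, m.name, CLASS_DESTROYED,
                          effect_allele=other_allele,
                          site_before=sites_g[0], site_after=None)
            )
        elif sites_o and not sites_g:
            impacts.append(
                SnpImpact(snp.snp_id, m.name, CLASS_CREATED,
                          effect_allele=other_allele,
                          site_before=None, site_after=sites_o[0])
            )
        else:
            impacts.append(SnpImpact(snp.snp_id, m.name, CLASS_NONE))
    return impacts


def allele_frequencies(
    snp: SNPRecord,
    min_reads: int = MIN_READS,
    min_minor: int = MIN_MINOR,
    min_maf: float = MIN_MAF,
) -> PooledAlleleRecord:
    """Derive pooled frequencies and apply the variant filters.

    Filters use strict inequalities on the depths pooled over groups:
    total reads > ``min_reads``, minor allele count > ``min_minor``,
    MAF > ``min_maf``.  The returned record carries ``filter_reason``
    (None when the record passes).
    """
    total_ref = sum(r for r, _ in snp.depths.values())
    total_alt = sum(a for _, a in snp.depths.values())
    total = total_ref + total_alt
    freq_alt = {
        g: (a / (r + a) if (r + a) > 0 else None) for g, (r, a) in snp.depths.items()
    }
    totals = {g: r + a for g, (r, a) in snp.depths.items()}
    minor = min(total_ref, total_alt)
    maf = minor / total if total else 0.0
    if total == 0:
        reason = "no coverage"
    elif total <= min_reads:
        reason = f"total reads {total} not > {min_reads}"
    elif minor <= min_minor:
        reason = f"minor allele count {minor} not > {min_minor}"
    elif maf <= min_maf:
        reason = f"MAF {maf:.4f} not > {min_maf}"
    else:
        reason = None
    return PooledAlleleRecord(
        snp_id=snp.snp_id,
        freq_alt=freq_alt,
        total_reads=totals,
        minor_allele_count=minor,
        maf=maf,
        filter_reason=reason,
    )


def imbalance_ratio(
    freq_high: float,
    freq_low: float,
    ratio_high: float = RATIO_HIGH,
    ratio_low: float = RATIO_LOW,
    strict: bool = False,
) -> tuple[float | None, str]:
    """Effect-allele frequency ratio (high/low) and its imbalance flag.

    ``strict=False`` uses the inclusive thresholds (>= 2.0 amplification,
    <= 0.5 LOH); ``strict=True`` the exclusive variants.  A zero
    denominator with a nonzero numerator flags amplification with an
    infinite ratio; both zero is undefined and never flagged.
    """
    for f in (freq_high, freq_low):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"frequency {f} outside [0, 1]")
    if freq_low == 0.0:
        if freq_high == 0.0:
            return (None, FLAG_NONE)
        return (math.inf, FLAG_AMPLIFICATION)
    ratio = freq_high / freq_low
    if (ratio > ratio_high) if strict else (ratio >= ratio_high):
        return (ratio, FLAG_AMPLIFICATION)
    if (ratio < ratio_low) if strict else (ratio <= ratio_low):
        return (ratio, FLAG_LOH)
    return (ratio, FLAG_NONE)


def flag_imbalance(
    record: PooledAlleleRecord,
    high_group: str,
    low_group: str,
    effect_is_alt: bool = True,
    strict: bool = False,
) -> PooledAlleleRecord:
    """Attach the high/low ratio and flag for one contrast.

    The ratio is taken on the putative effect allele (ALT by default;
    set ``effect_is_alt=False`` to use the reference allele).
    """
    fh, fl = record.freq_alt.get(high_group), record.freq_alt.get(low_group)
    if fh is None or fl is None:
        return replace(record, ratio_high_low=None, flag=FLAG_NONE, ratio_repr=None)
    if not effect_is_alt:
        fh, fl = 1.0 - fh, 1.0 - fl
    ratio, flag = imbalance_ratio(fh, fl, strict=strict)
    repr_ = f"{fh:g}/0" if (fl == 0.0 and fh > 0.0) else None
    return replace(record, ratio_high_low=ratio, flag=flag, ratio_repr=repr_)


def screen_candidates(
    impacts: list[SnpImpact],
    records: list[PooledAlleleRecord],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Join impact classes with imbalance flags into the candidate table.

    Candidates are SNPs with a non-``none`` classification for some
    miRNA AND an imbalance flag.  Records failing the variant filters
    never become candidates.  Returns (table, summary); the summary
    counts impact classes, flags, candidates and unmatched keys.
    """
    by_snp: dict[str, PooledAlleleRecord] = {r.snp_id: r for r in records}
    rows = []
    unmatched = 0
    seen = set()
    for imp in impacts:
        seen.add(imp.snp_id)
        rec = by_snp.get(imp.snp_id)
        if rec is None:
            unmatched += 1
            continue
        if imp.classification == CLASS_NONE:
            continue
        site = imp.site_before or imp.site_after
        rows.append(
            {
                "snp_id": imp.snp_id,
                "mirna": imp.mirna,
                "classification": imp.classification,
                "effect_allele": imp.effect_allele,
                "seed_len": site.seed_len if site else None,
                "passes_filters": rec.passes,
                "filter_reason": rec.filter_reason or "",
                "ratio_high_low": rec.ratio_high_low,
                "ratio_repr": rec.ratio_repr or "",
                "flag": rec.flag,
                "is_candidate": rec.passes and rec.flag != FLAG_NONE,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "snp_id", "mirna", "classification", "effect_allele", "seed_len",
            "passes_filters", "filter_reason", "ratio_high_low", "ratio_repr",
            "flag", "is_candidate",
        ],
    )
    impacted = table["snp_id"].nunique() if len(table) else 0
    cand = table[table["is_candidate"]] if len(table) else table
    summary = {
        "n_snps_seen": len(seen),
        "n_unmatched": unmatched,
        "n_destroyed": int((table["classification"] == CLASS_DESTROYED).sum()) if len(table) else 0,
        "n_created": int((table["classification"] == CLASS_CREATED).sum()) if len(table) else 0,
        "n_snps_impacting": impacted,
        "n_candidates": int(cand["snp_id"].nunique()) if len(table) else 0,
    }
    return table, summary


def mirna_snp_scan(snps: list[SNPRecord], mirna_ids: set[str]) -> list[str]:
    """Report provided variants that fall on mature miRNA sequences.

    The pipeline does not call variants; this is a bookkeeping scan of a
    supplied variant table against miRNA identifiers (by gene_id).
    """
    return [s.snp_id for s in snps if s.gene_id in mirna_ids]
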