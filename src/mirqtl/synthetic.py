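"""Synthetic cohort generator with planted ground truth.

Emulates the study design the pipeline targets: a growth-selected
rainbow-trout line of ~98 full-sib families (~5 fish each), with small
RNA sequenced from pooled libraries of the phenotypically highest- and
lowest-ranked families, pooled allele depths at 3'UTR SNPs for the same
contrast, and per-fish phenotype / genotype / qPCR tables for the
association stage.

Ground truth is planted at every stage: seed sites whose presence a SNP
allele toggles (destroy / create / neutral), miRNA fold changes between
the pools, per-group allele frequencies, and per-predictor fractions of
phenotypic variance.  Each planted SNP is verified by re-running the
impact classifier before it is accepted (bounded retries), so class
recovery downstream is exact by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import snpimpact
from .sequences import MatureMiRNA, UTRSequence, revcomp_dna
from .snpimpact import CLASS_CREATED, CLASS_DESTROYED, CLASS_NONE, SNPRecord
from .targetscan import DEFAULT_RULES

_BASES_DNA = "ACGT"
_BASES_RNA = "ACGU"

#: DNA bases whose RNA reading neither Watson-Crick-pairs nor wobbles
#: with the given miRNA (RNA) base.
_HARD_MISMATCH = {
    "A": ("A", "C", "G"),   # A pairs T only
    "C": ("A", "C", "T"),   # C pairs G only
    "G": ("A", "G"),        # G pairs C, wobbles with T
    "U": ("C", "T"),        # U pairs A, wobbles with G
}

MAX_PLACEMENT_TRIES = 1000


class GenerationError(RuntimeError):
    pass


@dataclass
class PlantedSite:
    mirna: str
    gene_id: str
    interval: tuple[int, int]  # 0-based half-open on the UTR
    seed_len: int


@dataclass
class PlantedSnp:
    snp_id: str
    gene_id: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    intended_class: str
    effect_allele: str | None
    mirna: str | None


@dataclass
class TruthBundle:
    """Everything the pipeline's inputs were generated from."""

    mirna_set: list[MatureMiRNA]
    utr_set: list[UTRSequence]
    planted_sites: list[PlantedSite] = field(default_factory=list)
    planted_snps: list[PlantedSnp] = field(default_factory=list)
    de_truth: dict[str, float] = field(default_factory=dict)
    imbalance_truth: dict[str, dict[str, float]] = field(default_factory=dict)
    effect_truth: dict[str, dict[str, float]] = field(default_factory=dict)

    def snp_records(self) -> list[SNPRecord]:
        return [
            SNPRecord(s.snp_id, s.gene_id, s.position, s.ref_allele, s.alt_allele)
            for s in self.planted_snps
        ]


def _rng(rng_seed) -> np.random.Generator:
    return rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)


def gen_mirnas(n: int, length: tuple[int, int] = (20, 24), rng_seed=0) -> list[MatureMiRNA]:
    """Random mature miRNA sequences with unique names and unique 8-nt seeds.

    Lengths are drawn uniformly from ``length`` (inclusive), centred on
    the ~22 nt typical of mature miRNAs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length
    if lo < 18 or hi > 26 or lo > hi:
        raise ValueError("length range must lie within [18, 26]")
    rng = _rng(rng_seed)
    out: list[MatureMiRNA] = []
    seeds_seen: set[str] = set()
    tries = 0
    while len(out) < n:
        if tries > MAX_PLACEMENT_TRIES * max(n, 1):
            raise GenerationError("could not draw n miRNAs with distinct 8-nt seeds")
        tries += 1
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(_BASES_RNA), size=L))
        seed8 = seq[1:9]
        if seed8 in seeds_seen:
            continue
        seeds_seen.add(seed8)
        out.append(MatureMiRNA(name=f"syn-mir-{len(out) + 1:03d}", sequence=seq))
    return out


def gen_utrs(n: int, length: int = 400, rng_seed=0) -> list[UTRSequence]:
    """Random 3'UTR background sequences."""
    rng = _rng(rng_seed)
    return [
        UTRSequence(f"gene{i + 1:03d}", "".join(rng.choice(list(_BASES_DNA), size=length)))
        for i in range(n)
    ]


def _planted_region(mirna: MatureMiRNA, rng: np.random.Generator) -> tuple[str, int]:
    """Target DNA for one plantable site and its core offset map.

    The region complements mature positions 2..9 (8 nt) except that the
    base pairing position 9 is replaced by a hard (non-wobble) mismatch.
    This pre-consumes the in-register 8-mer window's mismatch budget so
    that a single core substitution later removes the 6-, 7- and 8-mer
    calls at once.  Returns (region, p_offset_of_core) where the core
    positions eligible for a SNP are region indices 2..6 (pairing seed
    positions 7..3).
    """
    t = list(revcomp_dna(mirna.sequence[1:9]))  # pairs positions 2..9; t[0] pairs pos 9
    pos9 = mirna.sequence[8]
    choices = _HARD_MISMATCH[pos9]
    t[0] = choices[int(rng.integers(len(choices)))]
    return "".join(t), 0


def _verify_snp(
    snp: SNPRecord, utr: UTRSequence, mirnas: list[MatureMiRNA],
    intended_class: str, intended_mirna: str | None,
) -> bool:
    """A planted SNP is accepted only if the classifier reproduces its
    intended class for its intended miRNA and calls nothing else."""
    impacts = snpimpact.classify_snp(snp, utr, mirnas, rules=DEFAULT_RULES)
    for imp in impacts:
        if imp.mirna == intended_mirna:
            if imp.classification != intended_class:
                return False
        elif imp.classification != CLASS_NONE:
            return False
    if intended_class == CLASS_NONE and intended_mirna is None:
        return all(i.classification == CLASS_NONE for i in impacts)
    return True


def plant_sites_and_snps(
    utrs: list[UTRSequence],
    mirnas: list[MatureMiRNA],
    n_destroy: int,
    n_create: int,
    n_neutral: int,
    rng_seed=0,
    margin: int = 12,
) -> TruthBundle:
    """Plant seed sites and destroy/create/neutral SNPs into the UTRs.

    Placements are non-overlapping with a guard ``margin`` so later
    plantings cannot disturb verified earlier ones (classification is
    local to +/-7 nt of a SNP).  Every SNP is self-verified through the
    impact classifier; an infeasible request fails after bounded retries.
    """
    for c, label in ((n_destroy, "n_destroy"), (n_create, "n_create"), (n_neutral, "n_neutral")):
        if c < 0:
            raise ValueError(f"{label} must be >= 0")
    rng = _rng(rng_seed)
    seqs = {u.gene_id: list(u.sequence) for u in utrs}
    occupied: dict[str, list[tuple[int, int]]] = {u.gene_id: [] for u in utrs}
    gene_ids = [u.gene_id for u in utrs]

    def free(gene: str, start: int, end: int) -> bool:
        return all(
            end + margin <= s or e + margin <= start for s, e in occupied[gene]
        )

    def current_utr(gene: str) -> UTRSequence:
        return UTRSequence(gene, "".join(seqs[gene]))

    bundle = TruthBundle(mirna_set=mirnas, utr_set=[])
    snp_no = 0
    plan = (
        [(CLASS_DESTROYED, None)] * n_destroy
        + [(CLASS_CREATED, None)] * n_create
        + [(CLASS_NONE, None)] * n_neutral
    )
    for intended, _ in plan:
        snp_no += 1
        snp_id = f"snp{snp_no:04d}"
        placed = False
        for _attempt in range(MAX_PLACEMENT_TRIES):
            gene = gene_ids[int(rng.integers(len(gene_ids)))]
            n = len(seqs[gene])
            if intended == CLASS_NONE:
                pos0 = int(rng.integers(margin, n - margin))
                if not free(gene, pos0, pos0 + 1):
                    continue
                ref = seqs[gene][pos0]
                alt = rng.choice([b for b in _BASES_DNA if b != ref])
                snp = SNPRecord(snp_id, gene, pos0 + 1, ref, alt)
                if not _verify_snp(snp, current_utr(gene), mirnas, CLASS_NONE, None):
                    continue
                occupied[gene].append((pos0, pos0 + 1))
                bundle.planted_snps.append(
                    PlantedSnp(snp_id, gene, pos0 + 1, ref, alt, CLASS_NONE, None, None)
                )
                placed = True
                break

            mirna = mirnas[int(rng.integers(len(mirnas)))]
            region, _ = _planted_region(mirna, rng)
            R = len(region)  # 8
            if n < R + 2 * margin:
                raise GenerationError(
                    f"UTR {gene} too short ({n} nt) to host a planted site"
                )
            p = int(rng.integers(margin, n - R - margin))
            if not free(gene, p, p + R):
                continue
            # core SNP position pairs seed position j in {3..7}: q = p + 9 - j
            j = int(rng.integers(3, 8))
            q = p + 9 - j
            complement_base = region[q - p]
            seed_base = mirna.sequence[j - 1]
            mm_choices = [b for b in _HARD_MISMATCH[seed_base] if b != complement_base]
            mm_base = mm_choices[int(rng.integers(len(mm_choices)))]
            planted = list(region)
            if intended == CLASS_DESTROYED:
                ref, alt = complement_base, mm_base
            else:  # CREATED: genome carries the broken site, alt restores it
                planted[q - p] = mm_base
                ref, alt = mm_base, complement_base
            seqs[gene][p : p + R] = planted
            snp = SNPRecord(snp_id, gene, q + 1, ref, alt)
            if not _verify_snp(snp, current_utr(gene), mirnas, intended, mirna.name):
                # undo and retry elsewhere
                seqs[gene][p : p + R] = list(
                    "".join(rng.choice(list(_BASES_DNA), size=R))
                )
                continue
            occupied[gene].append((p, p + R))
            bundle.planted_snps.append(
                PlantedSnp(snp_id, gene, q + 1, ref, alt, intended, alt, mirna.name)
            )
            if intended == CLASS_DESTROYED:
                # the in-register 7-mer the reference sequence carries
                bundle.planted_sites.append(
                    PlantedSite(mirna.name, gene, (p + 1, p + 8), 7)
                )
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place {intended} SNP {snp_id} after "
                f"{MAX_PLACEMENT_TRIES} attempts (UTR space/miRNA cross-talk)"
            )
    bundle.utr_set = [UTRSequence(g, "".join(seqs[g])) for g in gene_ids]
    return bundle


def simulate_counts(
    mirnas: list[MatureMiRNA],
    groups: tuple[str, str] = ("high", "low"),
    depth: int = 20000,
    de_truth: dict[str, float] | None = None,
    dispersion: float = 0.1,
    rng_seed=0,
    weights=None,
) -> pd.DataFrame:
    """Negative-binomial pooled counts per miRNA per group library.

    Counts have mean mu and variance mu + d*mu^2 (d = ``dispersion``;
    d = 0 is Poisson).  The low group's expected counts split ``depth``
    by lognormal abundance weights (or caller-fixed ``weights``); the
    high group's means are scaled by the per-miRNA true fold change, so
    the expected ratio of group means equals ``de_truth``.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = _rng(rng_seed)
    names = [m.name for m in mirnas]
    de_truth = de_truth or {}
    w = (
        np.asarray(weights, dtype=float)
        if weights is not None
        else np.exp(rng.normal(0.0, 1.0, size=len(names)))
    )
    mu_low = depth * w / w.sum()
    fc = np.array([de_truth.get(n, 1.0) for n in names], dtype=float)
    if np.any(fc <= 0):
        raise ValueError("true fold changes must be positive")
    mu_high = mu_low * fc

    def draw(mu: np.ndarray) -> np.ndarray:
        if depth == 0:
            return np.zeros(len(mu), dtype=int)
        if dispersion == 0:
            return rng.poisson(mu)
        r = 1.0 / dispersion
        return rng.negative_binomial(r, r / (r + mu))

    data = {groups[0]: draw(mu_high), groups[1]: draw(mu_low)}
    return pd.DataFrame(data, index=pd.Index(names, name="mirna"))


def simulate_pooled_alleles(
    snps: list[SNPRecord] | list[PlantedSnp],
    freq_by_group: dict[str, dict[str, float]],
    depth_range: tuple[int, int] = (80, 200),
    rng_seed=0,
) -> list[SNPRecord]:
    """Binomial pooled allele depths per group.

    ``freq_by_group``: snp_id -> {group: ALT-allele frequency}.  Returns
    new SNPRecords with ``depths`` filled; the empirical frequencies
    converge to the truth as depth grows.
    """
    rng = _rng(rng_seed)
    out = []
    for s in snps:
        freqs = freq_by_group[s.snp_id]
        depths = {}
        for group, f in freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{s.snp_id}: frequency {f} outside [0, 1]")
            n = int(rng.integers(depth_range[0], depth_range[1] + 1))
            alt = int(rng.binomial(n, f))
            depths[group] = (n - alt, alt)
        out.append(
            SNPRecord(s.snp_id, s.gene_id, s.position,
                      getattr(s, "ref_allele"), getattr(s, "alt_allele"), depths)
        )
    return out


#: trait scales used for the simulated cohort (mean, SD in trait units);
#: chosen to match a ~13-month growth-selected line: WBW in grams,
#: muscle yield / crude fat as percentages, shear force in gf/g,
#: whiteness on the colorimeter-derived index scale.
TRAIT_PARAMS: dict[str, tuple[float, float]] = {
    "WBW": (860.0, 190.0),
    "muscle_yield": (47.0, 3.0),
    "crude_fat": (7.0, 2.2),
    "shear_force": (420.0, 90.0),
    "whiteness": (43.0, 1.5),
}
TRAITS = list(TRAIT_PARAMS)


def simulate_phenotypes(
    n_families: int = 98,
    fish_per_family: int = 5,
    genotype_effects: dict[str, dict[str, float]] | None = None,
    expression_effects: dict[str, dict[str, float]] | None = None,
    family_sd: float = 0.5,
    residual_sd: float = 0.866,
    rng_seed=0,
    maf: float = 0.3,
    extra_null_snps: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Family-structured phenotypes with planted predictor effects.

    Each trait is built on a standardized latent scale as
    ``family effect + sum(beta_k * z_k) + residual`` with
    ``beta_k^2 = f_k * V_total`` for planted variance fraction ``f_k``
    (``V_total = (family_sd^2 + residual_sd^2) / (1 - sum f)``), then
    mapped to trait units.  Genotypes are biallelic Hardy-Weinberg
    dosages 0/1/2 at allele frequency ``maf``; expression enters through
    a per-fish qPCR delta-Ct that is a fixed monotone map of the latent
    expression score.  Returns (phenotypes, genotypes, ct_table).
    """
    if family_sd < 0 or residual_sd < 0:
        raise ValueError("variance components must be non-negative")
    genotype_effects = genotype_effects or {}
    expression_effects = expression_effects or {}
    frac_by_trait: dict[str, float] = {t: 0.0 for t in TRAITS}
    for eff in (genotype_effects, expression_effects):
        for _, per_trait in eff.items():
            for t, f in per_trait.items():
                if t not in frac_by_trait:
                    raise ValueError(f"unknown trait {t!r}")
                if not 0.0 <= f < 1.0:
                    raise ValueError(f"variance fraction {f} outside [0, 1)")
                frac_by_trait[t] += f
    for t, tot in frac_by_trait.items():
        if tot >= 1.0:
            raise ValueError(f"planted variance fractions for {t} sum to {tot} >= 1")

    rng = _rng(rng_seed)
    n = n_families * fish_per_family
    fam_ids = [f"F{i + 1:03d}" for i in range(n_families)]
    family = np.repeat(fam_ids, fish_per_family)
    fish_ids = [f"{f}-{k + 1}" for f in fam_ids for k in range(fish_per_family)]

    # predictors
    dosages: dict[str, np.ndarray] = {}
    for snp_id in genotype_effects:
        dosages[snp_id] = rng.binomial(2, maf, size=n).astype(float)
    for i in range(extra_null_snps):
        dosages[f"null{i + 1:04d}"] = rng.binomial(2, maf, size=n).astype(float)
    expr_latent: dict[str, np.ndarray] = {
        mid: rng.normal(0.0, 1.0, size=n) for mid in expression_effects
    }

    v_base = family_sd**2 + residual_sd**2
    pheno = pd.DataFrame({"fish_id": fish_ids, "family_id": family})
    for trait in TRAITS:
        v_total = v_base / (1.0 - frac_by_trait[trait])
        fam_eff = rng.normal(0.0, family_sd, size=n_families)
        y = np.repeat(fam_eff, fish_per_family) + rng.normal(0.0, residual_sd, size=n)
        for snp_id, per_trait in genotype_effects.items():
            f = per_trait.get(trait, 0.0)
            if f:
                g = dosages[snp_id]
                z = (g - 2 * maf) / np.sqrt(2 * maf * (1 - maf))
                y = y + np.sqrt(f * v_total) * z
        for mid, per_trait in expression_effects.items():
            f = per_trait.get(trait, 0.0)
            if f:
                y = y + np.sqrt(f * v_total) * expr_latent[mid]
        mean_t, sd_t = TRAIT_PARAMS[trait]
        pheno[trait] = mean_t + sd_t * y / np.sqrt(v_total)

    # colorimeter readings consistent with the whiteness column
    a = rng.normal(2.5, 0.5, size=n)
    b = rng.normal(8.0, 1.0, size=n)
    w = pheno["whiteness"].to_numpy()
    pheno["L"] = 100.0 - np.sqrt(np.maximum((100.0 - w) ** 2 - a**2 - b**2, 0.0))
    pheno["a"] = a
    pheno["b"] = b
    pheno = pheno[
        ["fish_id", "family_id", "WBW", "muscle_yield", "crude_fat",
         "shear_force", "L", "a", "b", "whiteness"]
    ]

    geno = pd.DataFrame(dosages, index=pd.Index(fish_ids, name="fish_id"))
    ct_rows = []
    for mid, e in expr_latent.items():
        dct = 5.0 - 1.5 * e  # lower delta-Ct = higher expression
        for fid, d in zip(fish_ids, dct):
            ct_rows.append(
                {"fish_id": fid, "target": mid,
                 "ct_target": 20.0 + d, "ct_reference": 20.0}
            )
    ct = pd.DataFrame(ct_rows, columns=["fish_id", "target", "ct_target", "ct_reference"])
    return pheno, geno, ct


def reads_for_pool(
    counts: pd.Series,
    mirnas: list[MatureMiRNA],
    pool_label: str,
    adapter: str,
    read_length: int = 36,
    isomir_fraction: float = 0.15,
    rng_seed=0,
):
    """Expand a count column into adapter-carrying FASTQ-style reads.

    Most reads are the exact mature sequence; ``isomir_fraction`` of
    them carry a 1-nt end extension/truncation or one substitution,
    exercising the tolerant annotation downstream.  Each insert is
    padded with the 3' adapter and clipped to ``read_length`` cycles.
    """
    from .smallrna import SmallRnaRead  # local import to avoid a cycle

    rng = _rng(rng_seed)
    by_name = {m.name: m.sequence_dna for m in mirnas}
    reads = []
    i = 0
    for name, c in counts.items():
        seq0 = by_name[name]
        for _ in range(int(c)):
            i += 1
            insert = seq0
            if rng.random() < isomir_fraction:
                mode = int(rng.integers(3))
                if mode == 0:  # 3' extension by one templated-looking base
                    insert = insert + _BASES_DNA[int(rng.integers(4))]
                elif mode == 1:  # 3' truncation
                    insert = insert[:-1]
                else:  # one internal substitution
                    k = int(rng.integers(len(insert)))
                    sub = _BASES_DNA[(int(_BASES_DNA.index(insert[k])) + 1 + int(rng.integers(3))) % 4]
                    insert = insert[:k] + sub + insert[k + 1 :]
            full = (insert + adapter)[:read_length]
            reads.append(
                SmallRnaRead(f"{pool_label}:{name}:{i}", full, "I" * len(full))
            )
    return reads
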