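"""End-to-end orchestration: simulate -> quantify -> DE -> scan ->
snp-impact/screen -> associate, with per-stage TSV outputs, stderr
logging and a machine-readable JSON summary.

Fully deterministic for a fixed ``rng_seed``: per-stage generators are
spawned from one seed sequence, iteration orders are sorted, and the
summary contains no timestamps.
"""
from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, diffexp, smallrna, snpimpact, synthetic
from . import io as mio
from .io import PipelineConfig
from .sequences import MatureMiRNA, UTRSequence
from .targetscan import DEFAULT_RULES, scan_sites

log = logging.getLogger("mirqtl")


def _setup_logging() -> None:
    if not log.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
        log.addHandler(h)
        log.setLevel(logging.INFO)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception:
                log.error("stage %s: FAILED", name)
                raise
            log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("simulate")
def stage_simulate(config: PipelineConfig, outdir: Path) -> dict:
    seeds = np.random.SeedSequence(config.rng_seed).spawn(6)
    rngs = [np.random.default_rng(s) for s in seeds]
    mirnas = synthetic.gen_mirnas(config.n_mirnas, rng_seed=rngs[0])
    utrs = synthetic.gen_utrs(config.n_utrs, config.utr_length, rng_seed=rngs[0])
    bundle = synthetic.plant_sites_and_snps(
        utrs, mirnas, config.n_destroy, config.n_create, config.n_neutral,
        rng_seed=rngs[1],
    )

    # expression truth: first miRNAs up/down at the stated fold change
    names = [m.name for m in mirnas]
    de_truth = {}
    for n in names[: config.n_de_up]:
        de_truth[n] = config.de_fold_change
    for n in names[config.n_de_up : config.n_de_up + config.n_de_down]:
        de_truth[n] = 1.0 / config.de_fold_change
    bundle.de_truth = {n: de_truth.get(n, 1.0) for n in names}
    counts_truth = synthetic.simulate_counts(
        mirnas, config.groups, config.read_depth, bundle.de_truth,
        config.dispersion, rng_seed=rngs[2],
    )

    # pooled allele-frequency truth: planted effect SNPs are imbalanced
    high, low = config.groups
    freq = {}
    for i, s in enumerate(bundle.planted_snps):
        if s.intended_class == snpimpact.CLASS_NONE:
            freq[s.snp_id] = {high: 0.4, low: 0.4}
        elif i % 2 == 0:
            freq[s.snp_id] = {high: 0.7, low: 0.1}  # amplification truth
        else:
            freq[s.snp_id] = {high: 0.1, low: 0.7}  # LOH truth
    bundle.imbalance_truth = freq
    snps = synthetic.simulate_pooled_alleles(
        bundle.planted_snps, freq, rng_seed=rngs[3]
    )

    # phenotype truth: two effect SNPs and two effect miRNAs at 5%
    eff_snps = [s.snp_id for s in bundle.planted_snps
                if s.intended_class != snpimpact.CLASS_NONE][:2]
    genotype_effects = {sid: {"WBW": 0.05, "muscle_yield": 0.05} for sid in eff_snps}
    expression_effects = {n: {"WBW": 0.05} for n in names[:2]}
    bundle.effect_truth = {**genotype_effects, **expression_effects}
    pheno, geno, ct = synthetic.simulate_phenotypes(
        config.n_families, config.fish_per_family,
        genotype_effects, expression_effects,
        rng_seed=rngs[4], extra_null_snps=8,
    )

    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    mio.write_fasta([(m.name, m.sequence) for m in mirnas], inputs / "mirnas.fa")
    mio.write_fasta([(u.gene_id, u.sequence) for u in bundle.utr_set], inputs / "utrs.fa")
    groups = {}
    for g in config.groups:
        reads = synthetic.reads_for_pool(
            counts_truth[g], mirnas, f"{g}_pool", config.adapter, rng_seed=rngs[5]
        )
        mio.write_fastq(reads, inputs / f"reads_{g}.fastq")
        groups[f"{g}_pool"] = g
    mio.write_design(groups, inputs / "design.tsv")
    snps_pooled = []
    for s in snps:
        s.depths = {f"{g}_pool": s.depths[g] for g in config.groups}
        snps_pooled.append(s)
    mio.write_vcf_pooled(snps_pooled, inputs / "snps.vcf", samples=sorted(groups))
    mio.write_tsv(pheno.set_index("fish_id"), inputs / "phenotypes.tsv")
    mio.write_tsv(geno, inputs / "genotypes.tsv")
    mio.write_tsv(ct.set_index("fish_id"), inputs / "ct.tsv")

    truth_dir = outdir / "truth"
    truth_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {"snp_id": s.snp_id, "gene_id": s.gene_id, "position": s.position,
             "ref": s.ref_allele, "alt": s.alt_allele, "class": s.intended_class,
             "effect_allele": s.effect_allele or "", "mirna": s.mirna or ""}
            for s in bundle.planted_snps
        ]
    ).to_csv(truth_dir / "snps.tsv", sep="\t", index=False)
    pd.Series(bundle.de_truth, name="fold_change").rename_axis("mirna").to_csv(
        truth_dir / "de.tsv", sep="\t"
    )

    log.info("simulate: %d miRNAs, %d UTRs, %d SNPs, %d fish",
             len(mirnas), len(bundle.utr_set), len(bundle.planted_snps), len(pheno))
    return {
        "bundle": bundle,
        "n_mirnas": len(mirnas),
        "n_snps": len(bundle.planted_snps),
        "truth_classes": {
            c: sum(1 for s in bundle.planted_snps if s.intended_class == c)
            for c in (snpimpact.CLASS_DESTROYED, snpimpact.CLASS_CREATED, snpimpact.CLASS_NONE)
        },
    }


@_stage("quantify")
def stage_quantify(config: PipelineConfig, outdir: Path) -> dict:
    inputs = outdir / "inputs"
    mirnas = mio.read_mirna_fasta(inputs / "mirnas.fa")
    design = mio.read_design(inputs / "design.tsv")
    columns = {}
    tallies = {}
    for sample in sorted(design):
        group = design[sample]
        reads = mio.read_fastq(inputs / f"reads_{group}.fastq")
        col, tally = smallrna.quantify_sample(
            reads, mirnas, sample,
            adapter=config.adapter, min_len=config.min_len, max_len=config.max_len,
        )
        columns[sample] = col
        tallies[sample] = tally
        log.info("quantify %s: %d reads, %d assigned", sample,
                 tally["total"], tally["assigned"])
    counts = pd.DataFrame(columns)
    mio.write_counts(counts, outdir / "counts.tsv")
    return {"tallies": tallies, "n_mirnas": int(counts.shape[0])}


@_stage("de")
def stage_de(config: PipelineConfig, outdir: Path) -> dict:
    counts = mio.read_counts(outdir / "counts.tsv")
    design = mio.read_design(outdir / "inputs" / "design.tsv")
    table = diffexp.de_test(
        counts, design, config.groups, fc_cut=config.fc_cut, q_cut=config.q_cut
    )
    mio.write_tsv(table, outdir / "de.tsv")
    summary = diffexp.de_summary(table)
    log.info("de: %d tested, %d DE (%d up / %d down)",
             summary["n_tested"], summary["n_de"], summary["n_up"], summary["n_down"])
    return summary


@_stage("scan")
def stage_scan(config: PipelineConfig, outdir: Path) -> dict:
    inputs = outdir / "inputs"
    mirnas = mio.read_mirna_fasta(inputs / "mirnas.fa")
    utrs = mio.read_utr_fasta(inputs / "utrs.fa")
    sites = []
    for m in mirnas:
        for u in utrs:
            sites.extend(scan_sites(m, u, energy_cutoff=config.energy_cutoff))
    mio.write_sites(sites, outdir / "sites.tsv")
    n_pass = sum(1 for s in sites if s.passes_energy)
    log.info("scan: %d seed sites, %d pass %.0f kcal/mol",
             len(sites), n_pass, config.energy_cutoff)
    return {"n_sites": len(sites), "n_pass_energy": n_pass}


@_stage("snp_impact")
def stage_snp_impact(config: PipelineConfig, outdir: Path) -> dict:
    inputs = outdir / "inputs"
    mirnas = mio.read_mirna_fasta(inputs / "mirnas.fa")
    utrs = {u.gene_id: u for u in mio.read_utr_fasta(inputs / "utrs.fa")}
    design = mio.read_design(inputs / "design.tsv")
    snps, vcf_tally = mio.read_vcf_pooled(inputs / "snps.vcf", design)
    high, low = config.groups

    impacts = []
    records = []
    for snp in snps:
        impacts.extend(snpimpact.classify_snp(snp, utrs[snp.gene_id], mirnas))
        rec = snpimpact.allele_frequencies(
            snp, config.min_reads, config.min_minor, config.min_maf
        )
        records.append(
            snpimpact.flag_imbalance(rec, high, low, strict=config.strict_ratio)
        )
    table, summary = snpimpact.screen_candidates(impacts, records)
    mio.write_tsv(table, outdir / "candidates.tsv", index=False)
    class_by_snp = {}
    for imp in impacts:
        if imp.classification != snpimpact.CLASS_NONE:
            class_by_snp.setdefault(imp.snp_id, imp.classification)
    n_dest = sum(1 for c in class_by_snp.values() if c == snpimpact.CLASS_DESTROYED)
    n_crea = sum(1 for c in class_by_snp.values() if c == snpimpact.CLASS_CREATED)
    summary.update(
        {
            "vcf": vcf_tally,
            "snp_classes": {
                snpimpact.CLASS_DESTROYED: n_dest,
                snpimpact.CLASS_CREATED: n_crea,
                snpimpact.CLASS_NONE: len(snps) - len(class_by_snp),
            },
        }
    )
    log.info("snp_impact: %d SNPs -> %d destroyed, %d created, %d candidates",
             len(snps), n_dest, n_crea, summary["n_candidates"])
    return summary


@_stage("associate")
def stage_associate(config: PipelineConfig, outdir: Path) -> dict:
    inputs = outdir / "inputs"
    pheno = mio.read_tsv(inputs / "phenotypes.tsv")
    geno = mio.read_tsv(inputs / "genotypes.tsv")
    ct = pd.read_csv(inputs / "ct.tsv", sep="\t")
    geno = geno.loc[pheno.index]

    traits = synthetic.TRAITS
    n_sig = {}
    for trait in traits:
        table = assoc.association_panel(geno, pheno[trait], trait, kind="snp")
        mio.write_tsv(table, outdir / f"assoc_snp_{trait}.tsv", index=False)
        n_sig[trait] = int((table["q"] < config.q_cut).sum())

    ct["dct"] = ct["ct_target"] - ct["ct_reference"]
    dct = ct.pivot(index="fish_id", columns="target", values="dct").loc[pheno.index]
    n_sig_expr = {}
    for trait in traits:
        table = assoc.association_panel(dct, pheno[trait], trait, kind="expression")
        mio.write_tsv(table, outdir / f"assoc_expr_{trait}.tsv", index=False)
        n_sig_expr[trait] = int((table["q"] < config.q_cut).sum())

    corr = assoc.pairwise_trait_correlation(pheno, traits)
    mio.write_tsv(corr["signed_r2"], outdir / "trait_correlations.tsv")

    # stratification diagnostic on a family subsample (MDS is O(n^2))
    sub = geno.iloc[: min(len(geno), 200)]
    coords = assoc.ibs_mds(sub, k=2)
    mio.write_tsv(coords, outdir / "mds.tsv")

    log.info("associate: significant SNPs per trait %s", n_sig)
    return {"n_significant_snp": n_sig, "n_significant_expr": n_sig_expr}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns (and writes) the summary."""
    _setup_logging()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not config.simulate:
        required = [config.mirna_fasta, config.utr_fasta, config.vcf]
        if any(p is None or not Path(p).exists() for p in required):
            raise FileNotFoundError(
                "simulate=False requires existing mirna_fasta, utr_fasta and vcf paths"
            )

    summary: dict = {"seed": config.rng_seed}
    if config.simulate:
        sim = stage_simulate(config, outdir)
        summary["simulate"] = {k: v for k, v in sim.items() if k != "bundle"}
    summary["quantify"] = stage_quantify(config, outdir)
    summary["de"] = stage_de(config, outdir)
    summary["scan"] = stage_scan(config, outdir)
    summary["snp_impact"] = stage_snp_impact(config, outdir)
    summary["associate"] = stage_associate(config, outdir)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
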