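"""Generator contracts: determinism, planted-truth self-consistency,
distributional behavior of the simulators."""
import numpy as np
import pandas as pd
import pytest

from mirqtl import synthetic
from mirqtl.sequences import MatureMiRNA
from mirqtl.snpimpact import CLASS_NONE
from mirqtl.synthetic import (
    GenerationError, gen_mirnas, gen_utrs, plant_sites_and_snps,
    simulate_counts, simulate_phenotypes, simulate_pooled_alleles,
)


def test_gen_mirnas_length_and_uniqueness():
    out = gen_mirnas(1, length=(22, 22), rng_seed=7)
    assert len(out) == 1 and len(out[0].sequence) == 22
    many = gen_mirnas(100, rng_seed=1)
    assert len({m.name for m in many}) == 100
    assert len({m.seed(8) for m in many}) == 100
    with pytest.raises(ValueError):
        gen_mirnas(0)
    with pytest.raises(ValueError):
        gen_mirnas(5, length=(10, 30))


def test_gen_mirnas_deterministic():
    a = gen_mirnas(5, rng_seed=7)
    b = gen_mirnas(5, rng_seed=7)
    assert [(m.name, m.sequence) for m in a] == [(m.name, m.sequence) for m in b]


def test_plant_deterministic_and_empty_case():
    mirnas = gen_mirnas(8, rng_seed=2)
    utrs = gen_utrs(6, 300, rng_seed=3)
    b1 = plant_sites_and_snps(utrs, mirnas, 5, 5, 3, rng_seed=4)
    b2 = plant_sites_and_snps(utrs, mirnas, 5, 5, 3, rng_seed=4)
    assert [u.sequence for u in b1.utr_set] == [u.sequence for u in b2.utr_set]
    assert b1.planted_snps == b2.planted_snps
    empty = plant_sites_and_snps(utrs, mirnas, 0, 0, 0, rng_seed=4)
    assert empty.planted_snps == [] and len(empty.utr_set) == 6


def test_plant_intervals_inside_utrs(small_bundle):
    lens = {u.gene_id: len(u.sequence) for u in small_bundle.utr_set}
    for site in small_bundle.planted_sites:
        lo, hi = site.interval
        assert 0 <= lo < hi <= lens[site.gene_id]
    for s in small_bundle.planted_snps:
        assert 1 <= s.position <= lens[s.gene_id]


def test_plant_destroy_snps_sit_inside_planted_sites(small_bundle):
    sites_by_mirna_gene = {}
    for site in small_bundle.planted_sites:
        sites_by_mirna_gene.setdefault((site.mirna, site.gene_id), []).append(site)
    destroys = [s for s in small_bundle.planted_snps if s.intended_class == "destroyed"]
    assert destroys
    for s in destroys:
        hosts = sites_by_mirna_gene[(s.mirna, s.gene_id)]
        assert any(lo <= s.position - 1 < hi for (lo, hi) in (h.interval for h in hosts))


def test_plant_infeasible_request_fails_loudly():
    mirnas = gen_mirnas(3, rng_seed=1)
    tiny = gen_utrs(1, 40, rng_seed=1)
    with pytest.raises(GenerationError):
        plant_sites_and_snps(tiny, mirnas, 30, 0, 0, rng_seed=1)


def test_counts_null_ratio_concentrates_at_one():
    mirnas = gen_mirnas(300, rng_seed=5)
    c = simulate_counts(mirnas, depth=200_000, dispersion=0.0, rng_seed=6)
    total_ratio = c["high"].sum() / c["low"].sum()
    assert total_ratio == pytest.approx(1.0, abs=0.02)
    kept = c[(c["high"] > 50) & (c["low"] > 50)]
    ratios = kept["high"] / kept["low"]
    # per-miRNA ratio centred on 1 within Monte-Carlo error
    assert ratios.mean() == pytest.approx(1.0, abs=3 * ratios.std() / np.sqrt(len(kept)))


def test_counts_poisson_limit_and_degenerate_depth():
    mirnas = gen_mirnas(4, rng_seed=1)
    w = np.array([1.0, 2.0, 4.0, 8.0])
    reps = np.array(
        [simulate_counts(mirnas, depth=4000, dispersion=0.0, rng_seed=s,
                         weights=w)["low"].to_numpy()
         for s in range(400)]
    )
    mean, var = reps.mean(axis=0), reps.var(axis=0)
    assert np.all(np.abs(var / mean - 1.0) < 0.3)  # variance ~ mean
    zero = simulate_counts(mirnas, depth=0, rng_seed=1)
    assert (zero.to_numpy() == 0).all()


def test_counts_overdispersed_variance_matches_nb():
    mirnas = gen_mirnas(3, rng_seed=2)
    d = 0.2
    w = np.array([1.0, 2.0, 5.0])
    reps = np.array(
        [simulate_counts(mirnas, depth=3000, dispersion=d, rng_seed=s,
                         weights=w)["low"].to_numpy()
         for s in range(1500)]
    )
    mean, var = reps.mean(axis=0), reps.var(axis=0)
    expected = mean + d * mean**2
    assert np.all(np.abs(var / expected - 1.0) < 0.25)


def test_counts_expected_fold_change():
    mirnas = gen_mirnas(20, rng_seed=3)
    fc = {mirnas[0].name: 4.0}
    reps = np.array(
        [simulate_counts(mirnas, depth=50_000, de_truth=fc, dispersion=0.0, rng_seed=s,
                         weights=np.ones(20)).loc[mirnas[0].name].to_numpy()
         for s in range(200)]
    )
    assert reps[:, 0].mean() / reps[:, 1].mean() == pytest.approx(4.0, rel=0.05)


def test_pooled_alleles_concentration_and_bounds(small_bundle):
    snps = small_bundle.planted_snps[:4]
    freq = {s.snp_id: {"high": 0.5, "low": 0.5} for s in snps}
    recs = simulate_pooled_alleles(snps, freq, depth_range=(100_000, 100_000), rng_seed=1)
    for r in recs:
        fh = r.depths["high"][1] / sum(r.depths["high"])
        fl = r.depths["low"][1] / sum(r.depths["low"])
        assert 0.97 <= fh / fl <= 1.03
    zero = simulate_pooled_alleles(snps, {s.snp_id: {"high": 0.0} for s in snps},
                                   rng_seed=2)
    assert all(r.depths["high"][1] == 0 for r in zero)
    with pytest.raises(ValueError):
        simulate_pooled_alleles(snps, {s.snp_id: {"high": 1.5} for s in snps})


def test_phenotypes_shape_and_variance_decomposition():
    pheno, geno, ct = simulate_phenotypes(98, 5, rng_seed=8)
    assert len(pheno) == 490
    assert pheno["family_id"].nunique() == 98
    # no planted effects: standardized variance ~ family_sd^2 + residual_sd^2
    mean_t, sd_t = synthetic.TRAIT_PARAMS["WBW"]
    z = (pheno["WBW"] - mean_t) / sd_t
    assert z.var() == pytest.approx(1.0, abs=0.15)
    # whiteness column is consistent with its colorimeter readings
    from mirqtl.assoc import whiteness_index
    w = whiteness_index(pheno["L"], pheno["a"], pheno["b"])
    assert np.allclose(w, pheno["whiteness"], atol=1e-9)


def test_phenotypes_effect_fraction_validation():
    with pytest.raises(ValueError):
        simulate_phenotypes(10, 5, genotype_effects={"s": {"WBW": 0.6},
                                                     "t": {"WBW": 0.5}})
    with pytest.raises(ValueError):
        simulate_phenotypes(10, 5, genotype_effects={"s": {"nope": 0.1}})


def test_phenotypes_expression_effect_recoverable():
    eff = {"mir-1": {"WBW": 0.10}}
    pheno, _, ct = simulate_phenotypes(131, 6, expression_effects=eff, rng_seed=21)
    from mirqtl.assoc import regress_expression_phenotype
    dct = ct[ct["target"] == "mir-1"].set_index("fish_id")["ct_target"] - 20.0
    res = regress_expression_phenotype(
        dct.loc[pheno["fish_id"]].to_numpy(), pheno["WBW"].to_numpy()
    )
    assert 0.04 <= abs(res.signed_r2) <= 0.16
    assert res.signed_r2 < 0  # higher delta-Ct = lower expression = lower trait
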