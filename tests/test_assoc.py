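"""Phenotype derivations, rank transform, association and stratification."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirqtl import synthetic
from mirqtl.assoc import (
    association_panel, combined_variance, conditional_association,
    correlate_expression_pairs, ddct_fold_change, group_compare, ibs_distance,
    ibs_mds, pairwise_trait_correlation, rank_inverse_normal,
    regress_expression_phenotype, snp_association, tpm, whiteness_index,
)


def test_whiteness_closed_form():
    assert whiteness_index(100, 0, 0) == pytest.approx(100.0)
    assert whiteness_index(50, 3, 4) == pytest.approx(100 - np.sqrt(2525), abs=1e-9)
    rng = np.random.default_rng(1)
    L, a, b = rng.uniform(30, 60, 100), rng.uniform(-5, 5, 100), rng.uniform(0, 15, 100)
    assert np.allclose(
        whiteness_index(L, a, b), 100 - np.sqrt((100 - L) ** 2 + a**2 + b**2),
        atol=1e-9,
    )


def test_whiteness_decreases_with_redness():
    vals = [whiteness_index(50, a, 4) for a in (0, 1, 2, 5)]
    assert all(x > y for x, y in zip(vals, vals[1:]))


@pytest.mark.parametrize("case,ctrl,expect", [(5, 6, 2.0), (6, 6, 1.0), (8, 6, 0.25)])
def test_ddct_fold_change(case, ctrl, expect):
    assert ddct_fold_change(case, ctrl) == pytest.approx(expect)


def test_rank_inverse_normal_small_n_values():
    # Blom scores at n=3: Phi^-1 of (0.1923, 0.5, 0.8077)
    out = rank_inverse_normal([10.0, 20.0, 30.0])
    assert out == pytest.approx([-0.8694, 0.0, 0.8694], abs=1e-3)


def test_rank_inverse_normal_monotone_invariance(rng):
    x = rng.normal(size=50)
    assert np.allclose(rank_inverse_normal(x), rank_inverse_normal(np.exp(3 * x)))
    assert abs(rank_inverse_normal(x).mean()) < 1e-12
    with pytest.raises(ValueError):
        rank_inverse_normal(np.ones(10))


def test_rank_inverse_normal_output_passes_normality_screens(rng):
    z = rank_inverse_normal(rng.exponential(size=400))
    assert stats.shapiro(z).pvalue > 0.05
    assert stats.kstest(z, "norm").pvalue > 0.05


def test_regression_perfect_line():
    x = np.arange(10, dtype=float)
    res = regress_expression_phenotype(x, 2 * x)
    assert res.signed_r2 == pytest.approx(1.0)
    assert res.p < 1e-12
    down = regress_expression_phenotype(x, -2 * x)
    assert down.signed_r2 == pytest.approx(-1.0)


def test_regression_zero_variance_is_untestable():
    assert regress_expression_phenotype(np.ones(10), np.arange(10)).untestable


def test_snp_association_planted_variance_recovery():
    eff = {"snpA": {"WBW": 0.05}}
    pheno, geno, _ = synthetic.simulate_phenotypes(
        131, 6, genotype_effects=eff, rng_seed=42
    )
    res = snp_association(geno["snpA"], pheno["WBW"], transform=True)
    assert res.n == 786
    assert 0.03 <= abs(res.signed_r2) <= 0.07
    assert res.signed_r2 > 0  # planted effect is positive on dosage


def test_snp_association_monomorphic_untestable():
    res = snp_association(np.zeros(50), np.random.default_rng(0).normal(size=50))
    assert res.untestable


def test_snp_association_null_calibration_small():
    rng = np.random.default_rng(9)
    n, reps, alpha = 300, 600, 0.05
    rej = 0
    for _ in range(reps):
        g = rng.binomial(2, 0.3, size=n).astype(float)
        y = rng.normal(size=n)
        res = snp_association(g, y)
        rej += res.p < alpha
    assert 0.03 <= rej / reps <= 0.07


def test_association_panel_bh_within_trait():
    eff = {"snpA": {"WBW": 0.08}}
    pheno, geno, _ = synthetic.simulate_phenotypes(
        98, 5, genotype_effects=eff, extra_null_snps=10, rng_seed=7
    )
    table = association_panel(geno, pheno["WBW"], "WBW")
    hit = table[table["predictor"] == "snpA"].iloc[0]
    assert hit["q"] < 0.05


def test_combined_variance_reduction_and_nesting(rng):
    n = 400
    x1, x2 = rng.normal(size=n), rng.normal(size=n)
    y = 0.3 * x1 + 0.3 * x2 + rng.normal(size=n)
    X1 = pd.DataFrame({"x1": x1})
    X12 = pd.DataFrame({"x1": x1, "x2": x2})
    r2_single, _ = combined_variance(X1, y)
    single = regress_expression_phenotype(x1, y)
    assert r2_single == pytest.approx(abs(single.signed_r2), abs=1e-12)
    r2_both, kept = combined_variance(X12, y)
    assert r2_both >= r2_single
    assert kept == ["x1", "x2"]


def test_combined_variance_drops_collinear(rng):
    n = 100
    x = rng.normal(size=n)
    X = pd.DataFrame({"x1": x, "x2": 2 * x})
    with pytest.warns(UserWarning, match="collinear"):
        r2, kept = combined_variance(X, x + rng.normal(size=n))
    assert kept == ["x1"]


def test_pairwise_trait_correlation_structure():
    pheno, _, _ = synthetic.simulate_phenotypes(98, 5, rng_seed=3)
    out = pairwise_trait_correlation(pheno, synthetic.TRAITS)
    r2 = out["signed_r2"]
    assert np.allclose(np.diag(r2), 1.0)
    assert np.allclose(r2, r2.T)
    assert (out["n"].to_numpy() == 490).all()


def test_conditional_association_independent_and_mediated(rng):
    n = 500
    g1 = rng.binomial(2, 0.3, n).astype(float)
    g2 = rng.binomial(2, 0.3, n).astype(float)
    y = 0.4 * g1 + rng.normal(size=n)
    p_adj, indep = conditional_association(g1, pd.DataFrame({"g2": g2}), y)
    assert indep
    marginal = snp_association(g1, y).p
    assert np.log10(p_adj) == pytest.approx(np.log10(marginal), abs=1.0)
    # focal fully mediated: focal IS the covariate
    with pytest.warns(UserWarning, match="collinear"):
        _, indep2 = conditional_association(g1, pd.DataFrame({"dup": g1}), y)
    assert indep2  # duplicate covariate dropped, effect stands


def test_conditional_association_mediated_effect_not_independent(rng):
    n = 500
    g = rng.binomial(2, 0.3, n).astype(float)
    proxy = g + rng.normal(scale=0.05, size=n)  # near-duplicate tag
    y = 0.4 * proxy + rng.normal(size=n)
    _, indep = conditional_association(g, pd.DataFrame({"proxy": proxy}), y)
    assert not indep


def test_ibs_distance_identity_and_symmetry():
    G = pd.DataFrame([[0, 1, 2], [0, 1, 2], [2, 1, 0]], dtype=float)
    D = ibs_distance(G)
    assert D.iloc[0, 1] == 0.0
    assert D.iloc[0, 2] == pytest.approx((2 + 0 + 2) / 3 / 2)
    assert np.allclose(D, D.T)
    assert np.allclose(np.diag(D), 0.0)


def test_ibs_mds_separates_planted_subpopulations(rng):
    n, m = 60, 120
    f1, f2 = 0.1, 0.8
    G = np.vstack(
        [rng.binomial(2, f1, size=(n // 2, m)), rng.binomial(2, f2, size=(n // 2, m))]
    ).astype(float)
    coords = ibs_mds(pd.DataFrame(G), k=2)
    c1 = coords["C1"].to_numpy()
    labels = np.array([0] * (n // 2) + [1] * (n // 2))
    # silhouette on the first coordinate
    from sklearn.metrics import silhouette_score
    assert silhouette_score(c1.reshape(-1, 1), labels) > 0.5


def test_group_compare_welch():
    rng = np.random.default_rng(2)
    h = rng.normal(10, 1, 4) * 0 + np.array([9.5, 10.2, 10.1, 10.4])
    l = np.array([19.5, 20.2, 20.1, 20.4])
    out = group_compare(l, h)
    assert out["p"] < 0.01
    sym = group_compare(h, l)
    assert sym["p"] == pytest.approx(out["p"])
    same = group_compare([5.0, 5.0], [5.0, 5.0])
    assert same["p"] == 1.0
    single = group_compare([5.0], [4.0, 6.0])
    assert single["p"] is None


def test_tpm_and_expression_pair_screen(rng):
    samples = [f"s{i}" for i in range(8)]
    base = rng.normal(size=8)
    mirna = pd.DataFrame(
        {s: [base[i] + 10, rng.normal() + 10] for i, s in enumerate(samples)},
        index=["mir-1", "mir-2"],
    )
    genes = pd.DataFrame(
        {s: [2 * base[i] + 50, -3 * base[i] + 50, 50.0] for i, s in enumerate(samples)},
        index=["gA", "gB", "gC"],
    )
    pairs = [("mir-1", "gA"), ("mir-1", "gB"), ("mir-2", "gC")]
    table, tally = correlate_expression_pairs(mirna, genes, pairs)
    assert list(table["gene"]) == ["gA"]  # positive and strong only
    assert tally["skipped_zero_variance"] == 1
    counts = pd.DataFrame({"s1": [100, 100]}, index=["gA", "gB"])
    t = tpm(counts, pd.Series([1000.0, 2000.0], index=["gA", "gB"]))
    assert t["s1"].sum() == pytest.approx(1e6)
    assert t.loc["gA", "s1"] == pytest.approx(2 * t.loc["gB", "s1"])
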