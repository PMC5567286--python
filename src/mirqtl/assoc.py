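"""Phenotype derivations and association statistics.

Covers the whiteness index, qPCR delta-Ct quantities, rank-based inverse
normal transformation, single- and multi-predictor regressions of traits
on miRNA expression or SNP dosage, pairwise trait correlations, an
identity-by-state MDS stratification diagnostic, and expression
co-correlation screening.

Sign convention: tables report signed r-squared, sign(slope) * r^2, so a
negative entry means the predictor decreases the trait.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .diffexp import bh_fdr

DEFAULT_ALPHA = 0.05


@dataclass
class AssociationResult:
    predictor: str
    trait: str
    n: int
    signed_r2: float
    r: float
    p: float
    q: float | None = None
    untestable: bool = False


def whiteness_index(L, a, b):
    """Fillet whiteness from colorimeter L* (lightness), a* (redness),
    b* (yellowness): 100 - sqrt((100-L)^2 + a^2 + b^2)."""
    L, a, b = (np.asarray(x, dtype=float) for x in (L, a, b))
    out = 100.0 - np.sqrt((100.0 - L) ** 2 + a**2 + b**2)
    return float(out) if out.ndim == 0 else out


def ddct_fold_change(dct_case: float, dct_control: float) -> float:
    """Relative expression by the delta-delta-Ct method: 2^-(dCt_case - dCt_control)."""
    return float(2.0 ** (-(dct_case - dct_control)))


def rank_inverse_normal(values) -> np.ndarray:
    """Blom rank-based inverse normal transform.

    Maps value of rank r (ties averaged) to Phi^-1((r - 3/8)/(n + 1/4)).
    The output depends on the input only through its ranks, so any
    strictly monotone transform of the input leaves it unchanged.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values to rank-transform")
    if np.unique(x).size == 1:
        raise ValueError("constant input: ranks are undefined up to ties")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 3.0 / 8.0) / (x.size + 1.0 / 4.0))


def _simple_regression(x: np.ndarray, y: np.ndarray, predictor: str, trait: str) -> AssociationResult:
    n = len(x)
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return AssociationResult(predictor, trait, n, np.nan, np.nan, np.nan, untestable=True)
    fit = stats.linregress(x, y)
    r = fit.rvalue
    return AssociationResult(
        predictor, trait, n,
        signed_r2=float(np.sign(fit.slope) * r**2),
        r=float(r),
        p=float(fit.pvalue),
    )


def regress_expression_phenotype(
    dct, trait_values, predictor: str = "mirna", trait: str = "trait"
) -> AssociationResult:
    """OLS of a trait on per-fish qPCR delta-Ct (Ct_target - Ct_U6).

    Note that a lower delta-Ct means higher expression, so a positive
    slope on delta-Ct is a *negative* association with expression.
    """
    x = np.asarray(dct, dtype=float)
    y = np.asarray(trait_values, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    return _simple_regression(x[keep], y[keep], predictor, trait)


def snp_association(
    genotypes,
    trait_values,
    predictor: str = "snp",
    trait: str = "trait",
    transform: bool = True,
) -> AssociationResult:
    """OLS of a (rank-transformed) trait on additive genotype dosage 0/1/2."""
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(trait_values, dtype=float)
    keep = ~(np.isnan(g) | np.isnan(y))
    g, y = g[keep], y[keep]
    if np.unique(g).size < 2:
        return AssociationResult(predictor, trait, len(g), np.nan, np.nan, np.nan, untestable=True)
    if transform:
        y = rank_inverse_normal(y)
    return _simple_regression(g, y, predictor, trait)


def association_panel(
    predictors: pd.DataFrame,
    trait_values: pd.Series,
    trait: str,
    kind: str = "snp",
    transform: bool = True,
) -> pd.DataFrame:
    """Run one trait against a panel of predictors and BH-adjust within it.

    ``predictors``: fish x predictor matrix (dosages or delta-Ct),
    aligned on index with ``trait_values``.
    """
    results = []
    y = trait_values
    for name in predictors.columns:
        x = predictors[name]
        if kind == "snp":
            res = snp_association(x, y, predictor=name, trait=trait, transform=transform)
        else:
            res = regress_expression_phenotype(x, y, predictor=name, trait=trait)
        results.append(res)
    df = pd.DataFrame(
        {
            "predictor": [r.predictor for r in results],
            "trait": trait,
            "n": [r.n for r in results],
            "signed_r2": [r.signed_r2 for r in results],
            "r": [r.r for r in results],
            "p": [r.p for r in results],
            "untestable": [r.untestable for r in results],
        }
    )
    testable = ~df["untestable"]
    q = np.full(len(df), np.nan)
    if testable.any():
        q[testable.to_numpy()] = bh_fdr(df.loc[testable, "p"].to_numpy())
    df["q"] = q
    return df


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    """Greedily drop columns that do not increase the design-matrix rank."""
    keep: list[str] = []
    dropped: list[str] = []
    for col in X.columns:
        trial = X[keep + [col]].to_numpy(dtype=float)
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(trial)), trial])) == len(keep) + 2:
            keep.append(col)
        else:
            dropped.append(col)
    if dropped:
        warnings.warn(f"dropped collinear predictor(s): {', '.join(dropped)}", stacklevel=3)
    return X[keep]


def combined_variance(predictors: pd.DataFrame, trait_values) -> tuple[float, list[str]]:
    """Multiple-regression R^2 of a trait on several predictors jointly.

    Collinear predictors are dropped with a warning; returns
    (R^2, retained predictor names).
    """
    y = np.asarray(trait_values, dtype=float)
    X = predictors.dropna(axis=0)
    y = y[predictors.notna().all(axis=1).to_numpy()]
    if len(X) <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    X = _drop_collinear(X)
    model = sm.OLS(y, sm.add_constant(X.to_numpy(dtype=float))).fit()
    return float(model.rsquared), list(X.columns)


def pairwise_trait_correlation(
    phenotypes: pd.DataFrame, traits: list[str] | None = None
) -> dict[str, pd.DataFrame]:
    """All-pairs trait correlation with pairwise deletion of missing data.

    Returns ``{"signed_r2": ..., "p": ..., "n": ...}`` square frames.
    """
    traits = traits if traits is not None else list(phenotypes.columns)
    k = len(traits)
    r2 = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    pv = pd.DataFrame(np.zeros((k, k)), index=traits, columns=traits)
    nn = pd.DataFrame(0, index=traits, columns=traits)
    for i, t1 in enumerate(traits):
        nn.loc[t1, t1] = int(phenotypes[t1].notna().sum())
        for t2 in traits[i + 1 :]:
            pair = phenotypes[[t1, t2]].dropna()
            n = len(pair)
            nn.loc[t1, t2] = nn.loc[t2, t1] = n
            if n < 3 or pair[t1].std() == 0 or pair[t2].std() == 0:
                r2.loc[t1, t2] = r2.loc[t2, t1] = np.nan
                pv.loc[t1, t2] = pv.loc[t2, t1] = np.nan
                continue
            r, p = stats.pearsonr(pair[t1], pair[t2])
            s = float(np.sign(r) * r**2)
            r2.loc[t1, t2] = r2.loc[t2, t1] = s
            pv.loc[t1, t2] = pv.loc[t2, t1] = float(p)
    return {"signed_r2": r2, "p": pv, "n": nn}


def conditional_association(
    focal, covariates: pd.DataFrame, trait_values, alpha: float = DEFAULT_ALPHA,
    transform: bool = True,
) -> tuple[float, bool]:
    """Test whether a focal SNP's effect survives adjustment for others.

    Regresses the (rank-transformed) trait on the focal dosage with the
    covariate dosages included; collinear covariates are dropped with a
    warning.  Returns (adjusted p of the focal term, independent?).
    """
    g = np.asarray(focal, dtype=float)
    y = np.asarray(trait_values, dtype=float)
    if transform:
        y = rank_inverse_normal(y)
    X = pd.DataFrame({"focal": g})
    for c in covariates.columns:
        X[c] = covariates[c].to_numpy(dtype=float)
    X = pd.concat([X[["focal"]], _drop_collinear_against(X)], axis=1)
    model = sm.OLS(y, sm.add_constant(X.to_numpy(dtype=float))).fit()
    p_focal = float(model.pvalues[1])
    return p_focal, p_focal < alpha


def _drop_collinear_against(X: pd.DataFrame) -> pd.DataFrame:
    """Covariate columns of X (all but 'focal') that add rank beyond the focal term."""
    base = ["focal"]
    keep: list[str] = []
    dropped: list[str] = []
    for col in [c for c in X.columns if c != "focal"]:
        trial = X[base + keep + [col]].to_numpy(dtype=float)
        want = len(keep) + 3  # const + focal + kept + candidate
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(trial)), trial])) == want:
            keep.append(col)
        else:
            dropped.append(col)
    if dropped:
        warnings.warn(f"dropped collinear covariate(s): {', '.join(dropped)}", stacklevel=3)
    return X[keep]


def ibs_distance(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Pairwise identity-by-state distance, 1 - (mean shared alleles)/2.

    ``genotypes``: fish x SNP dosage matrix (0/1/2, NaN allowed); shared
    alleles between dosages g1, g2 at one locus = 2 - |g1 - g2|, averaged
    over loci where both are non-missing.
    """
    G = genotypes.to_numpy(dtype=float)
    n = G.shape[0]
    D = np.zeros((n, n))
    mask = ~np.isnan(G)
    for i in range(n):
        diff = np.abs(G[i] - G)  # (n, m)
        both = mask[i] & mask
        with np.errstate(invalid="ignore"):
            shared = np.where(both, 2.0 - diff, np.nan)
        cnt = both.sum(axis=1)
        if np.any(cnt == 0):
            raise ValueError("a pair of individuals shares no genotyped locus")
        D[i] = 1.0 - np.nansum(shared, axis=1) / cnt / 2.0
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=genotypes.index, columns=genotypes.index)


def ibs_mds(genotypes: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS of the IBS distance matrix.

    Double-centers the squared distances and returns the top-``k``
    positive-eigenvalue coordinates; ``k`` is reduced with a warning if
    the matrix has fewer positive dimensions.
    """
    if len(genotypes) < k + 1:
        raise ValueError("need at least k+1 individuals")
    D = ibs_distance(genotypes).to_numpy()
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = int((vals > 1e-10).sum())
    if pos < k:
        warnings.warn(f"distance matrix supports only {pos} MDS dimensions, not {k}")
        k = pos
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    return pd.DataFrame(
        coords, index=genotypes.index, columns=[f"C{i+1}" for i in range(k)]
    )


def group_compare(high_values, low_values) -> dict:
    """Welch two-sample comparison of a phenotype between family groups."""
    h = np.asarray(high_values, dtype=float)
    l = np.asarray(low_values, dtype=float)
    out = {
        "mean_high": float(np.mean(h)),
        "sd_high": float(np.std(h, ddof=1)) if len(h) > 1 else np.nan,
        "mean_low": float(np.mean(l)),
        "sd_low": float(np.std(l, ddof=1)) if len(l) > 1 else np.nan,
        "n_high": len(h),
        "n_low": len(l),
        "p": None,
    }
    if len(h) < 2 or len(l) < 2:
        return out  # descriptive only
    if np.std(h) == 0 and np.std(l) == 0:
        out["p"] = 1.0 if np.mean(h) == np.mean(l) else 0.0
        return out
    out["p"] = float(stats.ttest_ind(h, l, equal_var=False).pvalue)
    return out


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from gene counts and effective lengths."""
    rate = counts.div(lengths, axis=0)
    return rate * 1e6 / rate.sum(axis=0)


def correlate_expression_pairs(
    mirna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    pairs: list[tuple[str, str]],
    threshold: float = 0.70,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Screen (miRNA, target gene) pairs for strong positive co-expression.

    Pearson r over shared sample columns; a pair is retained when
    r^2 > ``threshold`` and r > 0.  Zero-variance series are skipped.
    """
    shared = [c for c in mirna_expr.columns if c in gene_expr.columns]
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples")
    rows = []
    tally = {"tested": 0, "skipped_zero_variance": 0, "retained": 0}
    for mirna, gene in pairs:
        x = mirna_expr.loc[mirna, shared].to_numpy(dtype=float)
        y = gene_expr.loc[gene, shared].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            tally["skipped_zero_variance"] += 1
            continue
        tally["tested"] += 1
        r, p = stats.pearsonr(x, y)
        if r > 0 and r**2 > threshold:
            tally["retained"] += 1
            rows.append({"mirna": mirna, "gene": gene, "r": float(r),
                         "r2": float(r**2), "p": float(p)})
    return pd.DataFrame(rows, columns=["mirna", "gene", "r", "r2", "p"]), tally
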