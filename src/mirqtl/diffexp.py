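"""Differential expression of miRNAs between divergent family pools.

With one pooled library per group there is no replication to estimate a
dispersion from, so the test is the conditional exact binomial: given
the total count of a miRNA across the two pools, its split is
Binomial(total, lib_a/(lib_a+lib_b)) under the null of equal relative
abundance.  A miRNA is called DE when FDR-q < 0.05 and the signed fold
change exceeds 2 in magnitude.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_FC_CUT = 2.0
DEFAULT_Q_CUT = 0.05
ZERO_PSEUDOCOUNT = 0.5


@dataclass
class DEResult:
    mirna: str
    mean_high: float
    mean_low: float
    fold_change: float
    p: float
    q: float
    is_de: bool
    untestable: bool = False


def normalize_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million library-size normalization (per column)."""
    sums = counts.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"zero library size in column(s): {', '.join(map(str, zero.index))}")
    return counts * 1e6 / sums


def exact_count_test(count_a: int, count_b: int, lib_a: int, lib_b: int) -> float:
    """Two-sided exact binomial test of a count split between two pools.

    Tests ``count_a ~ Binomial(count_a+count_b, lib_a/(lib_a+lib_b))``
    (minimum-likelihood two-sided p).  Both counts zero carries no
    evidence: p = 1.
    """
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be positive")
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    n = count_a + count_b
    if n == 0:
        return 1.0
    p0 = lib_a / (lib_a + lib_b)
    return stats.binomtest(count_a, n, p0, alternative="two-sided").pvalue


def fold_change(
    mean_high: float, mean_low: float, pseudocount: float = ZERO_PSEUDOCOUNT
) -> float:
    """Signed fold change between group means.

    The ratio r = mean_high/mean_low is reported as r when r >= 1 and as
    -1/r otherwise, so "down 4-fold" prints -4.  The pseudocount is
    added to *both* means only when either is zero, keeping ratios of
    well-covered miRNAs exact.
    """
    if mean_high < 0 or mean_low < 0:
        raise ValueError("means must be non-negative")
    if pseudocount and (mean_high == 0 or mean_low == 0):
        mean_high += pseudocount
        mean_low += pseudocount
    if mean_low == 0:
        return float("inf") if mean_high > 0 else 1.0
    r = mean_high / mean_low
    if r == 0:
        return float("-inf")
    return r if r >= 1 else -1.0 / r


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(
    counts: pd.DataFrame,
    groups: dict[str, str],
    contrast: tuple[str, str],
    fc_cut: float = DEFAULT_FC_CUT,
    q_cut: float = DEFAULT_Q_CUT,
) -> pd.DataFrame:
    """Run the exact test for one high-vs-low contrast.

    ``groups`` maps sample column -> group label; samples of the same
    group are pooled (counts and library sizes summed).  Returns a table
    with one row per miRNA: mean_high/mean_low (CPM), fold_change, p, q,
    is_de, untestable.
    """
    high, low = contrast
    cols_h = [c for c in counts.columns if groups.get(c) == high]
    cols_l = [c for c in counts.columns if groups.get(c) == low]
    if not cols_h or not cols_l:
        raise ValueError(f"contrast {high}:{low} has an empty group in the design")
    ch = counts[cols_h].sum(axis=1)
    cl = counts[cols_l].sum(axis=1)
    lib_h, lib_l = int(ch.sum()), int(cl.sum())
    cpm = normalize_cpm(pd.DataFrame({"high": ch, "low": cl}))
    pvals = np.array(
        [exact_count_test(int(a), int(b), lib_h, lib_l) for a, b in zip(ch, cl)]
    )
    out = pd.DataFrame(
        {
            "mirna": counts.index,
            "mean_high": cpm["high"].to_numpy(),
            "mean_low": cpm["low"].to_numpy(),
            "fold_change": [
                fold_change(mh, ml)
                for mh, ml in zip(cpm["high"].to_numpy(), cpm["low"].to_numpy())
            ],
            "p": pvals,
            "q": bh_fdr(pvals),
            "untestable": [(a + b) == 0 for a, b in zip(ch, cl)],
        }
    ).set_index("mirna")
    return call_de(out, fc_cut=fc_cut, q_cut=q_cut)


def call_de(results: pd.DataFrame, fc_cut: float = DEFAULT_FC_CUT, q_cut: float = DEFAULT_Q_CUT) -> pd.DataFrame:
    """Apply the significance thresholds; adds/overwrites ``is_de``."""
    results = results.copy()
    results["is_de"] = (results["q"] < q_cut) & (results["fold_change"].abs() > fc_cut)
    return results


def de_summary(results: pd.DataFrame) -> dict[str, int]:
    de = results[results["is_de"]]
    return {
        "n_tested": int((~results["untestable"]).sum()),
        "n_de": int(len(de)),
        "n_up": int((de["fold_change"] > 0).sum()),
        "n_down": int((de["fold_change"] < 0).sum()),
    }
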