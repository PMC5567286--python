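#!/usr/bin/env python
"""Associate SNP genotypes and miRNA expression with the muscle traits.

Rank-inverse-normal transforms each trait, regresses it on additive SNP
dosage and on per-fish qPCR delta-Ct, BH-adjusts within each trait
panel, computes the all-pairs trait correlation matrix, and runs the
identity-by-state MDS stratification diagnostic.  Writes the per-trait
association tables, trait_correlations.tsv and mds.tsv under
results/analysis/.
"""
import argparse
from pathlib import Path

import pandas as pd

from mirqtl.io import PipelineConfig
from mirqtl.pipeline import _setup_logging, stage_associate


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    _setup_logging()
    summary = stage_associate(PipelineConfig(outdir=str(args.out)), args.out)
    print("significant SNP associations per trait (FDR < 0.05):")
    for trait, n in summary["n_significant_snp"].items():
        print(f"  {trait}: {n}")
    print("significant expression associations per trait:")
    for trait, n in summary["n_significant_expr"].items():
        print(f"  {trait}: {n}")
    wbw = pd.read_csv(args.out / "assoc_snp_WBW.tsv", sep="\t")
    top = wbw.sort_values("p").head(3)
    print("top WBW SNP associations (predictor, signed_r2, q):")
    for _, r in top.iterrows():
        print(f"  {r['predictor']}: {r['signed_r2']:+.4f} (q={r['q']:.3g})")


if __name__ == "__main__":
    main()
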