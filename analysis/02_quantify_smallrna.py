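#!/usr/bin/env python
"""Quantify the pooled small-RNA libraries.

Trims the 3' sequencing adapter, drops reads outside 16-28 nt or with N
bases, annotates reads against the mature reference (<=2 substitutions,
<=2 shifted end bases), and sums isomiR variants into per-miRNA counts.
Writes results/analysis/counts.tsv.
"""
import argparse
from pathlib import Path

from mirqtl.io import PipelineConfig
from mirqtl.pipeline import _setup_logging, stage_quantify


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    _setup_logging()
    info = stage_quantify(PipelineConfig(outdir=str(args.out)), args.out)
    for sample, tally in info["tallies"].items():
        pct = 100.0 * tally["assigned"] / max(tally["total"], 1)
        print(f"{sample}: {tally['total']} reads, {tally['assigned']} assigned "
              f"({pct:.1f}%), {tally['ambiguous']} ambiguous, "
              f"{tally['filtered_out']} filtered")


if __name__ == "__main__":
    main()
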