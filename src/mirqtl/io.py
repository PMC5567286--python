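"""Readers and writers for the pipeline's file formats.

FASTA/FASTQ go through Biopython, VCF reading through cyvcf2; all
tabular outputs are single-header tab-separated files ('#' comments
allowed).  Emitted coordinates are 1-based closed (the VCF convention);
internal arithmetic is 0-based half-open.
"""
from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .sequences import MatureMiRNA, UTRSequence, as_rna
from .smallrna import SmallRnaRead
from .snpimpact import SNPRecord
from .targetscan import SeedSite


def _open_maybe_gz(path, mode="rt"):
    path = str(path)
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA into (id, sequence) pairs; duplicate ids are rejected."""
    records = []
    seen = set()
    with _open_maybe_gz(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append((rec.id, str(rec.seq).upper()))
    if not records:
        warnings.warn(f"FASTA file {path} contains no records")
    return records


def write_fasta(records: list[tuple[str, str]], path, width: int = 70) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_mirna_fasta(path) -> list[MatureMiRNA]:
    return [MatureMiRNA(name, as_rna(seq)) for name, seq in read_fasta(path)]


def read_utr_fasta(path) -> list[UTRSequence]:
    return [UTRSequence(name, seq) for name, seq in read_fasta(path)]


def read_fastq(path) -> list[SmallRnaRead]:
    with _open_maybe_gz(path) as fh:
        return [
            SmallRnaRead(
                rec.id, str(rec.seq),
                "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]),
            )
            for rec in SeqIO.parse(fh, "fastq")
        ]


def write_fastq(reads: list[SmallRnaRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality if r.quality is not None else "I" * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


# -- variant tables -----------------------------------------------------------

VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depth per allele">
"""


def write_vcf_pooled(snps: list[SNPRecord], path, samples: list[str] | None = None) -> None:
    """Write SNPs as VCF 4.2 with per-pool GT:AD fields.

    One sample column per pool; ``samples`` fixes the column order
    (default: sorted union of the groups seen in the records).
    """
    if samples is None:
        samples = sorted({g for s in snps for g in s.depths})
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        contigs = sorted({s.gene_id for s in snps})
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for s in sorted(snps, key=lambda x: (x.gene_id, x.position, x.snp_id)):
            cells = []
            for g in samples:
                r, a = s.depths.get(g, (0, 0))
                cells.append(f"./.:{r},{a}")
            fh.write(
                f"{s.gene_id}\t{s.position}\t{s.snp_id}\t{s.ref_allele}\t"
                f"{s.alt_allele}\t.\tPASS\t.\tGT:AD\t" + "\t".join(cells) + "\n"
            )


def read_vcf_pooled(path, design: dict[str, str]) -> tuple[list[SNPRecord], dict[str, int]]:
    """Read a VCF with per-sample AD fields into pooled SNP records.

    ``design`` maps sample name -> group; depths of samples in the same
    group are summed.  Indels and multiallelic records are skipped with
    a tally.
    """
    vcf = VCF(str(path))
    for s in vcf.samples:
        if s not in design:
            raise ValueError(f"VCF sample {s!r} missing from the design")
    tally = {"snps": 0, "skipped_indel": 0, "skipped_multiallelic": 0}
    records = []
    for var in vcf:
        if len(var.ALT) != 1:
            tally["skipped_multiallelic"] += 1
            continue
        if len(var.REF) != 1 or len(var.ALT[0]) != 1:
            tally["skipped_indel"] += 1
            continue
        ad = var.format("AD")
        if ad is None:
            raise ValueError(f"record {var.ID or var.POS} lacks the AD format field")
        depths: dict[str, list[int]] = {}
        for sample, row in zip(vcf.samples, ad):
            group = design[sample]
            d = depths.setdefault(group, [0, 0])
            d[0] += max(int(row[0]), 0)
            d[1] += max(int(row[1]), 0)
        records.append(
            SNPRecord(
                snp_id=var.ID or f"{var.CHROM}:{var.POS}",
                gene_id=var.CHROM,
                position=var.POS,
                ref_allele=var.REF,
                alt_allele=var.ALT[0],
                depths={g: (r, a) for g, (r, a) in depths.items()},
            )
        )
        tally["snps"] += 1
    return records, tally


# -- tab-separated tables -----------------------------------------------------

def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")


def write_counts(counts: pd.DataFrame, path) -> None:
    write_tsv(counts, path)


def read_counts(path) -> pd.DataFrame:
    return read_tsv(path)


def write_design(groups: dict[str, str], path) -> None:
    pd.DataFrame(
        {"sample": list(groups), "group": list(groups.values())}
    ).to_csv(path, sep="\t", index=False)


def read_design(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["sample"], df["group"]))


def sites_to_frame(sites: list[SeedSite]) -> pd.DataFrame:
    """Site list as a BED-like table (1-based closed coordinates)."""
    return pd.DataFrame(
        {
            "gene": [s.gene_id for s in sites],
            "start": [s.start + 1 for s in sites],
            "end": [s.end for s in sites],
            "mirna": [s.mirna for s in sites],
            "seed_len": [s.seed_len for s in sites],
            "wobble": [s.n_wobble for s in sites],
            "mismatch": [s.n_mismatch for s in sites],
            "energy": [s.duplex_energy for s in sites],
            "passes_energy": [s.passes_energy for s in sites],
        }
    )


def frame_to_sites(df: pd.DataFrame) -> list[SeedSite]:
    return [
        SeedSite(
            mirna=row["mirna"], gene_id=row["gene"],
            start=int(row["start"]) - 1, end=int(row["end"]),
            seed_len=int(row["seed_len"]), n_wobble=int(row["wobble"]),
            n_mismatch=int(row["mismatch"]),
            duplex_energy=float(row.get("energy", float("nan"))),
            passes_energy=bool(row.get("passes_energy", False)),
        )
        for _, row in df.iterrows()
    ]


def read_sites(path) -> list[SeedSite]:
    return frame_to_sites(pd.read_csv(path, sep="\t", comment="#"))


def write_sites(sites: list[SeedSite], path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False, float_format="%.4f")


# -- configuration ------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Paths and thresholds for an end-to-end run."""

    outdir: str = "results/pipeline"
    rng_seed: int = 0
    simulate: bool = True
    # simulation scale
    n_mirnas: int = 15
    n_utrs: int = 30
    utr_length: int = 400
    n_destroy: int = 10
    n_create: int = 10
    n_neutral: int = 10
    read_depth: int = 20000
    dispersion: float = 0.1
    n_de_up: int = 2
    n_de_down: int = 2
    de_fold_change: float = 4.0
    n_families: int = 98
    fish_per_family: int = 5
    groups: tuple[str, str] = ("high", "low")
    # analysis thresholds
    adapter: str = "GCCTTGGCACCCGAGAATTCCA"
    min_len: int = 16
    max_len: int = 28
    energy_cutoff: float = -15.0
    fc_cut: float = 2.0
    q_cut: float = 0.05
    min_reads: int = 10
    min_minor: int = 4
    min_maf: float = 0.05
    strict_ratio: bool = False
    # user-supplied inputs (used when simulate is False)
    mirna_fasta: str | None = None
    utr_fasta: str | None = None
    reads_by_sample: dict[str, str] = field(default_factory=dict)
    vcf: str | None = None
    design: dict[str, str] = field(default_factory=dict)
    phenotypes: str | None = None
    genotypes: str | None = None

    def __post_init__(self) -> None:
        for name in ("fc_cut", "q_cut", "min_reads", "min_minor", "min_maf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "groups" in data:
            data["groups"] = tuple(data["groups"])
        return cls(**data)
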