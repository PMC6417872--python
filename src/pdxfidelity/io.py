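"""File format adapters.

Coordinate conventions: VCF positions are 1-based inclusive; all internal
tables and BED files are 0-based half-open. SEG tables carry absolute copy
number in the segment-mean column.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd

SEG_COLUMNS = ["sample", "chrom", "start", "end", "seg_mean"]
PILEUP_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "depth", "alt_reads"]
BED_COLUMNS = ["chrom", "start", "end", "name"]


def read_seg(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SEG file {path} missing columns: {sorted(missing)}")
    return df[SEG_COLUMNS].astype({"start": int, "end": int, "seg_mean": float})


def write_seg(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[SEG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a 3+ column BED (0-based half-open); 4th column is the name."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"BED file {path} has fewer than 3 columns")
    if df.shape[1] == 3:
        df[3] = [f"region_{i}" for i in range(len(df))]
    df = df.iloc[:, :4]
    df.columns = BED_COLUMNS
    df = df.astype({"start": int, "end": int})
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"BED file {path} has empty or inverted intervals")
    return df


def write_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[BED_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_pileup(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup file {path} missing columns: {sorted(missing)}")
    return df[PILEUP_COLUMNS].astype({"pos": int, "depth": int, "alt_reads": int})


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """One identifier per line; blank lines and '#' comments skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    """Genes x samples TSV with gene ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"duplicate gene ids in {path}")
    return df


def write_expression(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


_VCF_HEADER = """##fileformat=VCFv4.2
##source=pdxfidelity
{contigs}##INFO=<ID=CLONE,Number=1,Type=String,Description="Originating clone id (simulation ground truth)">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref, alt)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf(
    records: Iterable[dict],
    sample: str,
    path: str | os.PathLike,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write single-sample VCF records with DP/AD genotype fields.

    Each record dict needs chrom, pos (1-based), ref, alt, depth, alt_reads;
    optional clone id goes in INFO. Records are written sorted.
    """
    contig_lines = ""
    if contigs:
        contig_lines = "".join(
            f"##contig=<ID={c},length={ln}>\n" for c, ln in contigs.items()
        )
    recs = sorted(records, key=lambda r: (str(r["chrom"]), int(r["pos"])))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contig_lines, sample=sample))
        for r in recs:
            depth = int(r["depth"])
            alt = int(r["alt_reads"])
            info = f"CLONE={r['clone']}" if "clone" in r else "."
            gt = "0/1" if alt > 0 else "0/0"
            fh.write(
                f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t.\tPASS\t"
                f"{info}\tGT:DP:AD\t{gt}:{depth}:{depth - alt},{alt}\n"
            )


def read_vcf_observations(path: str | os.PathLike, sample: str | None = None) -> pd.DataFrame:
    """Read a single-sample VCF into a pileup-style observation table.

    Uses cyvcf2; requires per-sample DP and AD fields. Multi-allelic sites
    are decomposed to one biallelic row per alternate allele. Positions
    are converted from VCF 1-based to the internal 0-based convention.
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    if sample is None:
        if len(vcf.samples) != 1:
            raise ValueError(f"{path} has {len(vcf.samples)} samples; specify one")
        sample = vcf.samples[0]
    sidx = vcf.samples.index(sample)
    rows = []
    for var in vcf:
        depths = var.format("DP")
        ads = var.format("AD")
        if depths is None or ads is None:
            raise ValueError(f"{path}: record at {var.CHROM}:{var.POS} lacks DP/AD")
        depth = int(depths[sidx][0])
        for ai, alt in enumerate(var.ALT):
            rows.append(
                {
                    "sample": sample,
                    "chrom": var.CHROM,
                    "pos": var.POS - 1,  # internal tables are 0-based
                    "ref": var.REF,
                    "alt": alt,
                    "depth": depth,
                    "alt_reads": int(ads[sidx][ai + 1]),
                }
            )
    vcf.close()
    return pd.DataFrame(rows, columns=PILEUP_COLUMNS)
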