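"""Readers and writers for the plain-text formats the pipeline consumes.

Coverage windows travel as BED-like TSV (0-based half-open), counts and
metadata as TSV, similarity scores as 12-column BLAST outfmt-6 tables,
variants as VCF 4.2 (monomorphic records retained, read back through
cyvcf2) and annotation as GFF3 (1-based inclusive, per the format).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .popgen import GenotypeMatrix
from .simulate import BLAST6_COLUMNS

__all__ = [
    "read_coverage",
    "write_coverage",
    "read_counts",
    "write_counts",
    "read_meta",
    "write_meta",
    "read_blast6",
    "write_blast6",
    "read_vcf",
    "write_vcf",
    "write_bed",
    "read_bed",
    "write_gene_gff3",
    "read_gene_map",
]

_COVERAGE_COLUMNS = ["contig", "start", "end", "sample", "sex", "count"]


def write_coverage(cov: pd.DataFrame, path) -> None:
    cols = _COVERAGE_COLUMNS + [
        c for c in ("rpkm", "norm", "truncated") if c in cov.columns
    ]
    cov[cols].to_csv(path, sep="\t", index=False)


def read_coverage(path) -> pd.DataFrame:
    cov = pd.read_csv(path, sep="\t")
    missing = set(_COVERAGE_COLUMNS) - set(cov.columns)
    if missing:
        raise ValueError(f"coverage table missing columns: {sorted(missing)}")
    return cov


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = {"sample", "species", "sex", "tissue", "replicate"} - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta


def write_blast6(scores: pd.DataFrame, path) -> None:
    scores[BLAST6_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_blast6(path) -> pd.DataFrame:
    """Parse a 12-column tabular similarity file, naming the bad line on error."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                rows.append(
                    (
                        fields[0], fields[1], float(fields[2]), int(fields[3]),
                        int(fields[4]), int(fields[5]), int(fields[6]),
                        int(fields[7]), int(fields[8]), int(fields[9]),
                        float(fields[10]), float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return pd.DataFrame(rows, columns=BLAST6_COLUMNS)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2; monomorphic records keep ALT '.'."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig, length in g.contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        gt = g.genotypes
        for i, row in g.sites.iterrows():
            alt = row["alt"]
            alt = "." if alt is None or (isinstance(alt, float) and np.isnan(alt)) else alt
            calls = []
            for s in range(len(g.samples)):
                a, b = gt[i, 2 * s], gt[i, 2 * s + 1]
                calls.append(
                    f"{'.' if a < 0 else a}/{'.' if b < 0 else b}"
                )
            fh.write(
                f"{row['contig']}\t{row['pos']}\t.\t{row['ref']}\t{alt}\t"
                f"{row['qual']:g}\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Load a VCF into a GenotypeMatrix via cyvcf2 (plain or bgzipped)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    contig_lengths = dict(zip(vcf.seqnames, vcf.seqlens)) if vcf.seqlens else {}
    site_rows, gt_rows = [], []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else None
        qual = var.QUAL if var.QUAL is not None else 0.0
        depth = var.INFO.get("DP")
        site_rows.append((var.CHROM, var.POS, var.REF, alt, qual, depth))
        row = np.full(2 * len(samples), -1, dtype=np.int8)
        for s, call in enumerate(var.genotypes):
            a, b = call[0], call[1]
            row[2 * s] = a if a >= 0 else -1
            row[2 * s + 1] = b if b >= 0 else -1
        gt_rows.append(row)
    sites = pd.DataFrame(
        site_rows, columns=["contig", "pos", "ref", "alt", "qual", "depth"]
    )
    if sites["depth"].isna().all():
        sites = sites.drop(columns="depth")
    genotypes = (
        np.vstack(gt_rows) if gt_rows else np.zeros((0, 2 * len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(sites, genotypes, samples, contig_lengths)


def write_bed(intervals: pd.DataFrame, path) -> None:
    intervals[["contig", "start", "end"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["contig", "start", "end"],
    )
    return bed


def write_gene_gff3(genes: pd.DataFrame, path) -> None:
    """Write a one-exon-per-gene GFF3 from a gene table.

    ``genes`` needs columns ``gene_id, chromosome`` and optionally
    ``start, end, strand`` (1-based inclusive; defaults tile genes
    side by side along each chromosome).
    """
    genes = genes.copy()
    if "start" not in genes.columns:
        genes["start"] = 0
        for chrom, grp in genes.groupby("chromosome"):
            genes.loc[grp.index, "start"] = 1 + 2000 * np.arange(len(grp))
        genes["end"] = genes["start"] + 999
    if "strand" not in genes.columns:
        genes["strand"] = "+"
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in genes.iterrows():
            base = f"{r['chromosome']}\tlampyrid\t"
            coords = f"{int(r['start'])}\t{int(r['end'])}\t.\t{r['strand']}\t.\t"
            fh.write(base + "gene\t" + coords + f"ID={r['gene_id']}\n")
            fh.write(
                base + "exon\t" + coords
                + f"ID={r['gene_id']}.e1;Parent={r['gene_id']}\n"
            )


def read_gene_map(gff_path) -> pd.DataFrame:
    """gene_id -> chromosome table from a GFF3 annotation."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = [(g.id, g.seqid) for g in db.features_of_type("gene")]
    return pd.DataFrame(rows, columns=["gene_id", "chromosome"])
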