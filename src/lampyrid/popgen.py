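"""Nucleotide diversity (pi) and Tajima's D over annotated genomic regions.

Implements the population-genetic half of the pipeline: site filtering of
variant tables (quality, biallelic-SNP, missingness, depth, repeat
overlap), per-region and per-window pi and Tajima's D, strand-aware
extraction of exon/intron/promoter intervals from GFF3 annotation, and
rank-sum contrasts of diversity between expression-bias classes.

Coordinate conventions: variant positions are 1-based (VCF); intervals
(regions, repeats, windows) are 0-based half-open (BED). A variant at
1-based position p occupies 0-based coordinate p - 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import rank_sum_test

__all__ = [
    "GenotypeMatrix",
    "PiWindow",
    "TajimaConstants",
    "filter_sites",
    "pi_region",
    "region_stats",
    "windows_pi",
    "tajima_constants",
    "tajimas_d",
    "build_regions",
    "gene_pi",
    "compare_bias_classes",
]

#: required columns of the per-site table
SITE_COLUMNS = ("contig", "pos", "ref", "alt", "qual")


@dataclass
class GenotypeMatrix:
    """Haplotype-resolved genotype calls at a set of sites.

    Parameters
    ----------
    sites
        One row per record with columns ``contig, pos, ref, alt, qual``
        (1-based positions, strictly increasing per contig). Monomorphic
        records carry ``alt = None`` (written/read as '.' in VCF) and are
        retained for length accounting. An optional ``depth`` column
        holds per-site mean depth.
    genotypes
        ``(n_sites, n_haplotypes)`` int8 array of allele indices
        (0 = ref, 1 = alt, -1 = missing). Haplotypes ``2i`` and
        ``2i + 1`` belong to diploid sample ``i``.
    samples
        Diploid sample names, ``len(samples) * 2 == n_haplotypes``.
    contig_lengths
        Total length in bp of each contig, used for per-bp normalization.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    samples: list[str]
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if len(self.sites) != self.genotypes.shape[0]:
            raise ValueError("sites and genotypes row counts differ")
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != 2 * len(self.samples):
            raise ValueError("genotypes must be (n_sites, 2 * n_samples)")
        for col in SITE_COLUMNS:
            if col not in self.sites.columns:
                raise ValueError(f"sites table missing column {col!r}")

    @property
    def n_haplotypes(self) -> int:
        return self.genotypes.shape[1]

    @property
    def is_monomorphic(self) -> np.ndarray:
        alt = self.sites["alt"]
        return (alt.isna() | (alt == ".") | (alt == "")).to_numpy()

    def subset(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.sites.loc[np.asarray(mask)].reset_index(drop=True),
            self.genotypes[np.asarray(mask)],
            list(self.samples),
            dict(self.contig_lengths),
        )


@dataclass
class PiWindow:
    """Diversity summary of one region or window."""

    region_id: str
    contig: str
    start: int
    end: int
    length: int
    n_haplotypes: int
    n_segregating: int
    pi: float  # per-bp
    theta_w: float  # per-bp Watterson estimator
    tajimas_d: float | None  # None when S = 0


# ---------------------------------------------------------------------------
# site filtering
# ---------------------------------------------------------------------------

def _repeat_mask(sites: pd.DataFrame, repeats) -> np.ndarray:
    """True where a site falls inside a repeat interval.

    Intervals are half-open; a site is excluded iff
    ``start <= pos < end`` with the record position compared directly
    against the interval bounds, so a site whose position equals an
    interval's end coordinate is retained.
    """
    if repeats is None:
        return np.zeros(len(sites), dtype=bool)
    rep = pd.DataFrame(repeats, columns=["contig", "start", "end"]) if not isinstance(
        repeats, pd.DataFrame
    ) else repeats
    hit = np.zeros(len(sites), dtype=bool)
    for contig, grp in rep.groupby("contig"):
        sel = sites["contig"] == contig
        if not sel.any():
            continue
        pos = sites.loc[sel, "pos"].to_numpy()
        inside = np.zeros(pos.size, dtype=bool)
        for s, e in zip(grp["start"].to_numpy(), grp["end"].to_numpy()):
            inside |= (pos >= s) & (pos < e)
        hit[sel.to_numpy()] = inside
    return hit


def filter_sites(
    g: GenotypeMatrix,
    repeats=None,
    qual_min: float = 30.0,
    max_missing: float = 0.25,
    depth_bounds: tuple[float, float] | None = None,
    snps_only: bool = True,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply hard site filters and report per-filter removal counts.

    Variant records are dropped if they are indels (ref or alt longer
    than 1 bp), multiallelic, have ``QUAL <= qual_min``, exceed the
    missing-genotype fraction, fall outside the depth bounds (when a
    depth column is present), or overlap a repeat interval. Monomorphic
    records are exempt from the SNP-only, QUAL and missingness rules
    (they exist only for length accounting) but are removed inside
    repeats. Each record is charged to the first rule it fails, in the
    order indel, multiallelic, qual, missing, depth, repeat.
    """
    sites = g.sites
    n = len(sites)
    mono = g.is_monomorphic
    alt = sites["alt"].fillna(".").astype(str)
    ref = sites["ref"].astype(str)

    removed = np.zeros(n, dtype=bool)
    ledger = {"indel": 0, "multiallelic": 0, "qual": 0, "missing": 0, "depth": 0, "repeat": 0}

    def charge(rule: str, mask: np.ndarray) -> None:
        fresh = mask & ~removed
        ledger[rule] += int(fresh.sum())
        removed[fresh] = True

    if snps_only:
        multi = alt.str.contains(",")
        is_indel = ((ref.str.len() > 1) | (~multi & (alt.str.len() > 1))) & ~mono
        charge("indel", is_indel.to_numpy())
        charge("multiallelic", (multi & ~mono).to_numpy())
    charge("qual", (sites["qual"].to_numpy(dtype=float) <= qual_min) & ~mono)

    miss_frac = (g.genotypes < 0).mean(axis=1)
    charge("missing", (miss_frac > max_missing) & ~mono)

    if depth_bounds is not None and "depth" in sites.columns:
        lo, hi = depth_bounds
        depth = sites["depth"].to_numpy(dtype=float)
        ok = np.isnan(depth) | ((depth >= lo) & (depth <= hi))
        charge("depth", ~ok & ~mono)

    charge("repeat", _repeat_mask(sites, repeats))
    return g.subset(~removed), ledger


# ---------------------------------------------------------------------------
# diversity statistics
# ---------------------------------------------------------------------------

def _site_pi_terms(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (pi contribution, called-allele count, derived count).

    For a site with j derived alleles among n called ones, the mean
    pairwise difference over all n(n-1)/2 haplotype pairs is
    2 j (n - j) / (n (n - 1)). Sites with fewer than two called alleles
    contribute nothing.
    """
    called = gt >= 0
    n_called = called.sum(axis=1)
    j = ((gt == 1) & called).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            n_called >= 2,
            2.0 * j * (n_called - j) / (n_called * (n_called - 1.0)),
            0.0,
        )
    return terms, n_called, j


def _region_site_mask(g: GenotypeMatrix, contig: str, start: int, end: int) -> np.ndarray:
    pos0 = g.sites["pos"].to_numpy() - 1
    return (g.sites["contig"] == contig).to_numpy() & (pos0 >= start) & (pos0 < end)


def pi_region(
    g: GenotypeMatrix,
    contig: str,
    start: int | None = None,
    end: int | None = None,
    length: int | None = None,
) -> float:
    """Per-bp nucleotide diversity over a region (0-based half-open).

    The denominator is the full region length in bp, i.e. invariant
    positions dilute pi; this matches variant tables that retain
    monomorphic records for length accounting.
    """
    if start is None:
        start = 0
    if end is None:
        end = g.contig_lengths.get(contig, 0)
        if end == 0:
            raise ValueError(f"no length known for contig {contig!r}")
    L = length if length is not None else end - start
    if L <= 0:
        raise ValueError("region length must be positive")
    mask = _region_site_mask(g, contig, start, end)
    terms, _, _ = _site_pi_terms(g.genotypes[mask])
    return float(terms.sum() / L)


@dataclass(frozen=True)
class TajimaConstants:
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Standard normalizing constants of Tajima's D for n haplotypes."""
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(a1, a2, b1, b2, c1, c2, e1, e2)


def tajimas_d(pi_total: float, n_segregating: int, n: int) -> float | None:
    """Tajima's D from the region pi sum, segregating-site count and n.

    ``pi_total`` is the summed per-site pi over the region (not per-bp).
    Returns None when S = 0 (the statistic is undefined, not zero).
    """
    S = int(n_segregating)
    if S == 0:
        return None
    if n < 4:
        raise ValueError("Tajima's D requires at least 4 haplotypes")
    k = tajima_constants(n)
    var = k.e1 * S + k.e2 * S * (S - 1.0)
    return float((pi_total - S / k.a1) / math.sqrt(var))


def region_stats(
    g: GenotypeMatrix,
    contig: str,
    start: int,
    end: int,
    region_id: str | None = None,
    length: int | None = None,
) -> PiWindow:
    """Full diversity summary (S, pi, theta_W, Tajima's D) for a region."""
    L = length if length is not None else end - start
    if L <= 0:
        raise ValueError("region length must be positive")
    mask = _region_site_mask(g, contig, start, end)
    terms, n_called, j = _site_pi_terms(g.genotypes[mask])
    seg = (j > 0) & (j < n_called)
    S = int(seg.sum())
    n = g.n_haplotypes
    pi_total = float(terms.sum())
    k = tajima_constants(n)
    return PiWindow(
        region_id=region_id or f"{contig}:{start}-{end}",
        contig=contig,
        start=start,
        end=end,
        length=L,
        n_haplotypes=n,
        n_segregating=S,
        pi=pi_total / L,
        theta_w=S / k.a1 / L,
        tajimas_d=tajimas_d(pi_total, S, n) if n >= 4 else None,
    )


def windows_pi(
    g: GenotypeMatrix,
    contig: str,
    window: int = 10000,
    step: int | None = None,
) -> pd.DataFrame:
    """Diversity in windows along a contig (non-overlapping by default).

    ``step`` defaults to the window size; a smaller step yields
    overlapping sliding windows. Terminal windows are truncated at the
    contig end and normalized by their true length.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    step = step or window
    length = g.contig_lengths.get(contig)
    if length is None:
        raise ValueError(f"no length known for contig {contig!r}")
    rows = []
    for start in range(0, length, step):
        end = min(start + window, length)
        rows.append(region_stats(g, contig, start, end))
        if end == length:
            break
    return pd.DataFrame([vars(w) for w in rows])


# ---------------------------------------------------------------------------
# region extraction from annotation
# ---------------------------------------------------------------------------

def build_regions(
    annotation,
    promoter_len: int = 2000,
    contig_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Exon / intron / promoter intervals per gene from GFF3 annotation.

    ``annotation`` is a GFF3 file path or an already-open
    :mod:`gffutils` FeatureDB. Output intervals are 0-based half-open
    with columns ``contig, start, end, strand, gene_id, region_type``.
    Introns are the gene span minus its exons; the promoter is
    ``promoter_len`` bp upstream of the strand-aware TSS, truncated at
    contig edges and at neighboring gene spans.
    """
    import gffutils

    if isinstance(annotation, gffutils.FeatureDB):
        db = annotation
    else:
        db = gffutils.create_db(
            str(annotation),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    contig_lengths = dict(contig_lengths or {})

    genes = []
    for gene in db.features_of_type("gene"):
        exons = []
        for ex in db.children(gene, featuretype="exon"):
            if ex.start < gene.start or ex.end > gene.end:
                raise ValueError(f"exon outside gene span for {gene.id}")
            exons.append((ex.start - 1, ex.end))  # to 0-based half-open
        if not exons:
            raise ValueError(f"gene {gene.id} has no exons")
        genes.append(
            {
                "gene_id": gene.id,
                "contig": gene.seqid,
                "start": gene.start - 1,
                "end": gene.end,
                "strand": gene.strand,
                "exons": sorted(exons),
            }
        )

    by_contig: dict[str, list[dict]] = {}
    for grec in genes:
        by_contig.setdefault(grec["contig"], []).append(grec)
    for recs in by_contig.values():
        recs.sort(key=lambda r: (r["start"], r["end"]))

    rows = []
    for contig, recs in by_contig.items():
        for i, grec in enumerate(recs):
            gid, strand = grec["gene_id"], grec["strand"]
            for s, e in grec["exons"]:
                rows.append((contig, s, e, strand, gid, "exon"))
            # introns: gaps between consecutive exons inside the gene span
            cursor = grec["start"]
            for s, e in grec["exons"]:
                if s > cursor:
                    rows.append((contig, cursor, s, strand, gid, "intron"))
                cursor = max(cursor, e)
            if cursor < grec["end"]:
                rows.append((contig, cursor, grec["end"], strand, gid, "intron"))
            # promoter upstream of the TSS, clipped to neighbors and edges
            if strand == "-":
                p_start = grec["end"]
                p_end = grec["end"] + promoter_len
                if i + 1 < len(recs):
                    p_end = min(p_end, recs[i + 1]["start"])
                clen = contig_lengths.get(contig)
                if clen is not None:
                    p_end = min(p_end, clen)
            else:
                p_start = max(0, grec["start"] - promoter_len)
                p_end = grec["start"]
                if i > 0:
                    p_start = max(p_start, recs[i - 1]["end"])
            if p_end > p_start:
                rows.append((contig, p_start, p_end, strand, gid, "promoter"))
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "strand", "gene_id", "region_type"]
    )


def gene_pi(
    g: GenotypeMatrix,
    regions: pd.DataFrame,
    region_types: Sequence[str] = ("exon", "intron", "promoter"),
) -> pd.DataFrame:
    """Length-weighted per-gene pi for each region class.

    Returns one row per (gene_id, region_type) with the pooled pi over
    that gene's intervals of the class (sum of per-site pi divided by
    summed interval length).
    """
    rows = []
    for (gid, rtype), grp in regions.groupby(["gene_id", "region_type"]):
        if rtype not in region_types:
            continue
        pi_total = 0.0
        length = 0
        for _, r in grp.iterrows():
            mask = _region_site_mask(g, r["contig"], r["start"], r["end"])
            terms, _, _ = _site_pi_terms(g.genotypes[mask])
            pi_total += float(terms.sum())
            length += int(r["end"] - r["start"])
        if length > 0:
            rows.append((gid, rtype, length, pi_total / length))
    return pd.DataFrame(rows, columns=["gene_id", "region_type", "length", "pi"])


_SIG_THRESHOLDS = (1e-4, 1e-3, 1e-2)
_SIG_LABELS = ("****", "***", "**")


def compare_bias_classes(
    pi_table: pd.DataFrame,
    baseline: str = "unbiased",
    groups: Sequence[str] = ("female-biased", "male-biased"),
) -> pd.DataFrame:
    """Rank-sum contrasts of pi between expression-bias classes.

    ``pi_table`` has columns ``status``, ``region_type`` and ``pi``.
    For each region class, the baseline (unbiased) distribution is
    compared two-sided against each bias class. Significance labels:
    '****' p < 0.0001, '***' p < 0.001, '**' p < 0.01, else 'ns';
    an empty group is reported as 'ns (empty)'.
    """
    rows = []
    for rtype, grp in pi_table.groupby("region_type"):
        base = grp.loc[grp["status"] == baseline, "pi"].to_numpy()
        for other in groups:
            vals = grp.loc[grp["status"] == other, "pi"].to_numpy()
            if base.size == 0 or vals.size == 0:
                rows.append((rtype, other, np.nan, "ns (empty)", base.size, vals.size))
                continue
            p = rank_sum_test(base, vals)
            label = "ns"
            for t, lab in zip(_SIG_THRESHOLDS, _SIG_LABELS):
                if p < t:
                    label = lab
                    break
            rows.append((rtype, other, p, label, base.size, vals.size))
    return pd.DataFrame(
        rows,
        columns=["region_type", "comparison", "pvalue", "label", "n_baseline", "n_group"],
    )
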