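"""X-chromosome dosage-compensation statistics from expression counts.

Two complementary views of compensation status:

* per-chromosome distributions of the per-gene female:male (f:m) CPM
  ratio — full compensation predicts a median near 1 on the X;
* the X:A ratio — median per-gene expression of X-linked genes over the
  autosomal median within one sex, with a percentile bootstrap CI
  (genes resampled with replacement, X and autosomes independently),
  plus a rank-sum test for over-/under-expression of the X.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .stats import rank_sum_test

__all__ = [
    "cpm",
    "expressed_genes",
    "fm_ratios",
    "summarize_fm_by_chromosome",
    "xa_ratio",
    "overcompensation_test",
    "DosageEstimate",
]


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: each column scaled to sum to 1e6."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].to_list()
        raise ValueError(f"samples with zero total counts: {bad}")
    return counts * 1e6 / totals


def _chrom_map(annotation) -> pd.Series:
    """Normalize an annotation (DataFrame / Series / dict) to gene -> chromosome."""
    if isinstance(annotation, pd.DataFrame):
        return annotation.set_index("gene_id")["chromosome"]
    if isinstance(annotation, pd.Series):
        return annotation
    return pd.Series(dict(annotation))


def _tissue_samples(meta: pd.DataFrame, tissue: str, sex: str | None = None) -> list[str]:
    sel = meta["tissue"] == tissue
    if sex is not None:
        sel &= meta["sex"] == sex
    return meta.loc[sel, "sample"].to_list()


def expressed_genes(
    cpm_tab: pd.DataFrame,
    meta: pd.DataFrame,
    tissue: str,
    min_cpm: float = 1.0,
    min_frac: float = 0.5,
) -> pd.Index:
    """Genes with CPM >= min_cpm in >= min_frac of replicates of a sex.

    Meeting the threshold in either sex suffices, so sex-specific genes
    (expressed in one sex only) are retained.
    """
    if tissue not in set(meta["tissue"]):
        raise ValueError(f"tissue {tissue!r} absent from metadata")
    keep = pd.Series(False, index=cpm_tab.index)
    for sex in ("female", "male"):
        cols = _tissue_samples(meta, tissue, sex)
        if not cols:
            continue
        frac = (cpm_tab[cols] >= min_cpm).mean(axis=1)
        keep |= frac >= min_frac
    return cpm_tab.index[keep]


def fm_ratios(
    cpm_tab: pd.DataFrame,
    meta: pd.DataFrame,
    annotation,
    tissue: str,
    pseudocount: float = 0.25,
    expressed: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-gene f:m CPM ratio for expressed genes of a tissue.

    ratio = (mean female CPM + eps) / (mean male CPM + eps) with
    eps = ``pseudocount`` guarding division by zero. Returns columns
    ``gene_id, chromosome, fm_ratio, log2_fm``.
    """
    chrom = _chrom_map(annotation)
    if expressed is None:
        expressed = expressed_genes(cpm_tab, meta, tissue)
    sub = cpm_tab.loc[list(expressed)]
    mean_f = sub[_tissue_samples(meta, tissue, "female")].mean(axis=1)
    mean_m = sub[_tissue_samples(meta, tissue, "male")].mean(axis=1)
    ratio = (mean_f + pseudocount) / (mean_m + pseudocount)
    return pd.DataFrame(
        {
            "gene_id": sub.index,
            "chromosome": chrom.reindex(sub.index).to_numpy(),
            "fm_ratio": ratio.to_numpy(),
            "log2_fm": np.log2(ratio.to_numpy()),
        }
    )


def summarize_fm_by_chromosome(ratios: pd.DataFrame) -> pd.DataFrame:
    """Median and log2-scale quartiles of the f:m ratio per chromosome."""
    import warnings

    rows = []
    for chrom, grp in ratios.groupby("chromosome", dropna=False):
        if len(grp) == 0:
            warnings.warn(f"chromosome {chrom} has no expressed genes; omitted")
            continue
        lg = grp["log2_fm"].to_numpy()
        rows.append(
            (chrom, len(grp), float(grp["fm_ratio"].median()),
             float(np.quantile(lg, 0.25)), float(np.median(lg)),
             float(np.quantile(lg, 0.75)))
        )
    return pd.DataFrame(
        rows,
        columns=["chromosome", "n_genes", "median_fm_ratio",
                 "log2_q1", "log2_median", "log2_q3"],
    )


@dataclass
class DosageEstimate:
    """X:A ratio with percentile-bootstrap confidence interval."""

    sex: str
    tissue: str
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_x_genes: int
    n_autosomal_genes: int


def _gene_means(
    cpm_tab: pd.DataFrame,
    meta: pd.DataFrame,
    annotation,
    sex: str,
    tissue: str,
    x_chrom: str,
    expressed: Iterable[str] | None,
) -> tuple[np.ndarray, np.ndarray]:
    chrom = _chrom_map(annotation)
    if expressed is None:
        expressed = expressed_genes(cpm_tab, meta, tissue)
    sub = cpm_tab.loc[list(expressed)]
    cols = _tissue_samples(meta, tissue, sex)
    if not cols:
        raise ValueError(f"no {sex} samples for tissue {tissue!r}")
    means = sub[cols].mean(axis=1)
    on_x = chrom.reindex(sub.index) == x_chrom
    return means[on_x.to_numpy()].to_numpy(), means[(~on_x).to_numpy()].to_numpy()


def xa_ratio(
    cpm_tab: pd.DataFrame,
    meta: pd.DataFrame,
    annotation,
    sex: str,
    tissue: str,
    n_boot: int = 10000,
    seed: int | None = None,
    x_chrom: str = "X",
    expressed: Iterable[str] | None = None,
    ci: float = 0.95,
) -> DosageEstimate:
    """X:A expression ratio within one sex with bootstrap 95% CI.

    Point estimate: median per-gene mean CPM of X-linked genes divided
    by the autosomal median. The CI takes the 2.5/97.5 percentiles of
    the statistic over ``n_boot`` resamples drawing X genes and
    autosomal genes independently with replacement.
    """
    x_vals, a_vals = _gene_means(
        cpm_tab, meta, annotation, sex, tissue, x_chrom, expressed
    )
    if x_vals.size < 10 or a_vals.size < 10:
        raise ValueError(
            f"need >= 10 expressed genes per class, got {x_vals.size} X "
            f"and {a_vals.size} autosomal"
        )
    med_a = np.median(a_vals)
    if med_a == 0:
        raise ValueError("autosomal median expression is zero")
    point = float(np.median(x_vals) / med_a)

    rng = np.random.default_rng(seed)
    stat = np.empty(n_boot)
    chunk = max(1, int(2e6 // max(x_vals.size, a_vals.size)))
    for i in range(0, n_boot, chunk):
        k = min(chunk, n_boot - i)
        xi = rng.integers(0, x_vals.size, size=(k, x_vals.size))
        ai = rng.integers(0, a_vals.size, size=(k, a_vals.size))
        stat[i:i + k] = np.median(x_vals[xi], axis=1) / np.median(a_vals[ai], axis=1)
    lo, hi = np.quantile(stat, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return DosageEstimate(
        sex=sex, tissue=tissue, point=point,
        ci_low=float(lo), ci_high=float(hi), n_boot=n_boot,
        n_x_genes=int(x_vals.size), n_autosomal_genes=int(a_vals.size),
    )


def overcompensation_test(
    cpm_tab: pd.DataFrame,
    meta: pd.DataFrame,
    annotation,
    sex: str,
    tissue: str,
    x_chrom: str = "X",
    pseudocount: float = 0.25,
    expressed: Iterable[str] | None = None,
) -> dict:
    """Rank-sum test of X vs autosomal per-gene expression within a sex.

    Compares log2(mean CPM + eps) of X-linked genes against autosomal
    genes, two-sided; the direction reports which median is higher.
    """
    x_vals, a_vals = _gene_means(
        cpm_tab, meta, annotation, sex, tissue, x_chrom, expressed
    )
    lx = np.log2(x_vals + pseudocount)
    la = np.log2(a_vals + pseudocount)
    p = rank_sum_test(lx, la)
    direction = "X > A" if np.median(lx) > np.median(la) else "X < A"
    if np.median(lx) == np.median(la):
        direction = "X = A"
    return {
        "sex": sex,
        "tissue": tissue,
        "pvalue": p,
        "direction": direction,
        "median_log2_x": float(np.median(lx)),
        "median_log2_a": float(np.median(la)),
    }
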