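"""Coverage-based X-chromosome identification.

In an XO system males carry a single X, so the male:female (m:f)
sequencing-depth ratio is expected near 0.5 on X-linked contigs and
near 1 on autosomes. The pipeline: RPKM-normalize per-window read
counts, pick reference autosomal contigs (largest contigs with
preliminary m:f ratio within 1 +/- 0.1), divide every window by the
per-sample mean over the reference contigs, then per contig test male
vs female window values with a two-sided Wilcoxon rank-sum test,
Bonferroni-correct over tested contigs, and call X any significant
contig whose m:f ratio falls in the [0.4, 0.6] band.

Coverage tables are long DataFrames with one row per (contig, window,
sample): columns ``contig, start, end, sample, sex, count`` plus the
derived ``rpkm`` and ``norm`` columns. Windows are 0-based half-open.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .stats import bonferroni, rank_sum_test

__all__ = [
    "rpkm_normalize",
    "select_reference_contigs",
    "normalize_by_reference",
    "classify_contigs",
    "identify_x",
]


def rpkm_normalize(cov: pd.DataFrame) -> pd.DataFrame:
    """Add an ``rpkm`` column: count / (window kb x sample Mreads).

    Per-sample totals are computed over all windows of that sample, so
    RPKM is invariant to uniform rescaling of a sample's counts.
    """
    cov = cov.copy()
    lengths = cov["end"] - cov["start"]
    if (lengths <= 0).any():
        raise ValueError("zero- or negative-length window")
    totals = cov.groupby("sample")["count"].transform("sum")
    if (totals <= 0).any():
        raise ValueError("a sample has zero total mapped reads")
    cov["rpkm"] = cov["count"] / (lengths / 1e3 * totals / 1e6)
    return cov


def _contig_summary(cov: pd.DataFrame, value: str) -> pd.DataFrame:
    """Per-contig length, window count and per-sex mean of ``value``."""
    per_sex = cov.groupby(["contig", "sex"])[value].mean().unstack("sex")
    missing = [s for s in ("female", "male") if s not in per_sex.columns]
    if missing:
        raise ValueError(f"coverage table has no {missing[0]} samples")
    geom = cov.groupby("contig").agg(
        length=("end", "max"),
        n_windows=("start", "nunique"),
    )
    out = geom.join(per_sex)
    out["mf_ratio"] = out["male"] / out["female"]
    return out


def select_reference_contigs(
    cov: pd.DataFrame, k: int = 5, tol: float = 0.1
) -> list[str]:
    """The k longest contigs with preliminary m:f RPKM ratio in 1 +/- tol.

    The preliminary ratio is (mean RPKM over male samples) / (mean over
    female samples) per contig. Length ties break on lexicographic
    contig id. Raises if fewer than k contigs qualify.
    """
    summ = _contig_summary(cov, "rpkm")
    ok = summ[(summ["mf_ratio"] >= 1 - tol) & (summ["mf_ratio"] <= 1 + tol)]
    if len(ok) < k:
        raise ValueError(
            f"only {len(ok)} contigs have m:f ratio within 1 +/- {tol}, need {k}"
        )
    ordered = ok.sort_values(
        ["length", "contig"], ascending=[False, True], kind="mergesort"
    )
    return ordered.index[:k].to_list()


def normalize_by_reference(cov: pd.DataFrame, refs: Sequence[str]) -> pd.DataFrame:
    """Add a ``norm`` column: RPKM / per-sample mean RPKM over ``refs``.

    After normalization the reference windows of each sample average to
    1, removing residual per-sample depth differences.
    """
    if len(refs) == 0:
        raise ValueError("reference contig list is empty")
    cov = cov.copy()
    ref_mean = (
        cov[cov["contig"].isin(refs)].groupby("sample")["rpkm"].mean()
    )
    if (ref_mean <= 0).any() or ref_mean.isna().any():
        raise ValueError("reference mean RPKM is zero for some sample")
    cov["norm"] = cov["rpkm"] / cov["sample"].map(ref_mean)
    return cov


def classify_contigs(
    cov: pd.DataFrame,
    min_len: int = 30000,
    min_windows: int = 3,
    band: tuple[float, float] = (0.4, 0.6),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-contig rank-sum test and m:f-ratio banding.

    Contigs shorter than ``min_len`` or with fewer than ``min_windows``
    windows are labeled ``filtered`` and excluded from the Bonferroni
    denominator. For tested contigs, window values are pooled across
    same-sex samples and compared two-sided (male vs female). The m:f
    ratio (mean male / mean female normalized coverage) is reported
    only for contigs significant after correction; classes:
    significant and in band -> ``X``; significant outside band ->
    ``undetermined``; non-significant -> ``autosome``.
    """
    if "norm" not in cov.columns:
        raise ValueError("run rpkm_normalize and normalize_by_reference first")
    summ = _contig_summary(cov, "norm")
    tested = summ[(summ["length"] >= min_len) & (summ["n_windows"] >= min_windows)]
    n_tested = len(tested)

    rows = []
    grouped = {c: grp for c, grp in cov.groupby("contig")}
    for contig, info in summ.iterrows():
        filtered = contig not in tested.index
        if filtered:
            rows.append(
                (contig, int(info["length"]), int(info["n_windows"]),
                 info["female"], info["male"], np.nan, np.nan, np.nan, "filtered")
            )
            continue
        grp = grouped[contig]
        male = grp.loc[grp["sex"] == "male", "norm"].to_numpy()
        female = grp.loc[grp["sex"] == "female", "norm"].to_numpy()
        if male.size == 0 or female.size == 0:
            raise ValueError(f"contig {contig!r} has windows from one sex only")
        p = rank_sum_test(male, female)
        p_adj = float(bonferroni(p, n_tested))
        significant = p_adj < alpha
        ratio = info["mf_ratio"] if significant else np.nan
        if not significant:
            cls = "autosome"
        elif band[0] <= info["mf_ratio"] <= band[1]:
            cls = "X"
        else:
            cls = "undetermined"
        rows.append(
            (contig, int(info["length"]), int(info["n_windows"]),
             info["female"], info["male"], ratio, p, p_adj, cls)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "length", "n_windows", "mean_norm_female",
            "mean_norm_male", "mf_ratio", "pvalue", "p_bonferroni",
            "classification",
        ],
    )


def identify_x(
    cov_raw: pd.DataFrame,
    k_ref: int = 5,
    ref_tol: float = 0.1,
    min_len: int = 30000,
    min_windows: int = 3,
    band: tuple[float, float] = (0.4, 0.6),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full pipeline from raw window counts to contig classifications."""
    cov = rpkm_normalize(cov_raw)
    refs = select_reference_contigs(cov, k=k_ref, tol=ref_tol)
    cov = normalize_by_reference(cov, refs)
    return classify_contigs(
        cov, min_len=min_len, min_windows=min_windows, band=band, alpha=alpha
    )
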