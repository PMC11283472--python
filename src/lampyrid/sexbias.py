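"""Sex-biased gene calling and three-tier effect-size categorization.

A gene is sex-biased when its female:male log2 fold change exceeds the
cutoff (|logFC| > 2 by default) at FDR < 0.05. Called genes of each
stratum (direction within a species x tissue dataset) are then split
into three tiers by |logFC| relative to the stratum's third quartile
Q3 and maximum: weak (< Q3), intermediate ([Q3, (Q3 + max)/2)) and
sex-specific (>= (Q3 + max)/2).

The built-in differential-expression engine is a Welch t-test on
log2(CPM + 0.25) with a variance floor — a deliberately simple
replacement for a negative-binomial GLM; published DE tables (gene,
logFC, FDR) can be imported instead via :func:`import_de_table`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dosage import cpm as _cpm
from .stats import bh_adjust

__all__ = [
    "welch_rows",
    "differential_expression",
    "call_sex_bias",
    "categorize_bias",
    "import_de_table",
    "CategoryThresholds",
]

STATUSES = ("female-biased", "male-biased", "unbiased")
TIERS = ("weak", "intermediate", "sex-specific")


def welch_rows(
    a: np.ndarray, b: np.ndarray, var_floor: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided Welch t-test of ``a`` (g x n1) vs ``b`` (g x n2).

    Sample variances are floored at ``var_floor`` so rows with zero
    within-group variance still yield a finite statistic. Returns
    (t, p).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("Welch test needs >= 2 replicates per group")
    v1 = np.maximum(a.var(axis=1, ddof=1), var_floor)
    v2 = np.maximum(b.var(axis=1, ddof=1), var_floor)
    se2 = v1 / n1 + v2 / n2
    t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(se2)
    df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, p


def differential_expression(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    tissue: str,
    species: str | None = None,
    pseudocount: float = 0.25,
    var_floor: float = 1e-8,
) -> pd.DataFrame:
    """Female-vs-male DE for one tissue (one-factor design).

    logFC = log2((mean female CPM + eps) / (mean male CPM + eps));
    p-values from the row-wise Welch test on log2(CPM + eps); FDR by
    Benjamini-Hochberg over all tested genes of the tissue. Returns
    columns ``gene_id, logFC, pvalue, fdr, mean_cpm_female,
    mean_cpm_male``.
    """
    sel = meta["tissue"] == tissue
    if species is not None:
        sel &= meta["species"] == species
    sub_meta = meta[sel]
    cols_f = sub_meta.loc[sub_meta["sex"] == "female", "sample"].to_list()
    cols_m = sub_meta.loc[sub_meta["sex"] == "male", "sample"].to_list()
    if len(cols_f) < 2 or len(cols_m) < 2:
        raise ValueError(
            f"need >= 2 replicates per sex, got {len(cols_f)} female / "
            f"{len(cols_m)} male"
        )
    cpm_tab = _cpm(counts[cols_f + cols_m])
    log_f = np.log2(cpm_tab[cols_f].to_numpy() + pseudocount)
    log_m = np.log2(cpm_tab[cols_m].to_numpy() + pseudocount)
    mean_f = cpm_tab[cols_f].mean(axis=1)
    mean_m = cpm_tab[cols_m].mean(axis=1)
    logfc = np.log2((mean_f + pseudocount) / (mean_m + pseudocount))
    _, p = welch_rows(log_f, log_m, var_floor=var_floor)
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "logFC": logfc.to_numpy(),
            "pvalue": p,
            "fdr": bh_adjust(p),
            "mean_cpm_female": mean_f.to_numpy(),
            "mean_cpm_male": mean_m.to_numpy(),
        }
    )


def import_de_table(path, gene_col="gene_id", lfc_col="logFC", fdr_col="FDR") -> pd.DataFrame:
    """Load an externally produced DE table (e.g. from a NB GLM fit)."""
    de = pd.read_csv(path, sep="\t")
    out = de.rename(columns={gene_col: "gene_id", lfc_col: "logFC", fdr_col: "fdr"})
    missing = {"gene_id", "logFC", "fdr"} - set(out.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    return out


def call_sex_bias(
    de: pd.DataFrame, fdr: float = 0.05, lfc: float = 2.0
) -> pd.DataFrame:
    """Assign bias status from a DE table (strict inequalities).

    female-biased iff FDR < ``fdr`` and logFC > ``lfc``; male-biased
    iff FDR < ``fdr`` and logFC < -``lfc``; otherwise unbiased. A gene
    sitting exactly on a cutoff is unbiased.
    """
    if len(de) == 0:
        raise ValueError("empty DE table")
    sig = de["fdr"].to_numpy() < fdr
    lf = de["logFC"].to_numpy()
    status = np.full(len(de), "unbiased", dtype=object)
    status[sig & (lf > lfc)] = "female-biased"
    status[sig & (lf < -lfc)] = "male-biased"
    return pd.DataFrame({"gene_id": de["gene_id"].to_numpy(), "status": status})


@dataclass
class CategoryThresholds:
    """Quantile boundaries defining the tiers of one stratum."""

    stratum: str
    n_called: int
    q1: float
    q3: float
    max: float
    boundary: float  # (q3 + max) / 2
    flagged: bool  # True when < 4 called genes forced the all-weak fallback


def categorize_bias(
    calls: pd.DataFrame,
    de: pd.DataFrame,
    stratum_prefix: str = "",
) -> tuple[pd.DataFrame, list[CategoryThresholds]]:
    """Assign weak / intermediate / sex-specific tiers per direction.

    Within each direction stratum, Q1, Q3 and max of |logFC| over the
    called genes (linear-interpolation quantiles) define the tier
    boundaries: weak |logFC| < Q3; intermediate Q3 <= |logFC| < B;
    sex-specific |logFC| >= B with B = (Q3 + max)/2. Boundary ties go
    to the higher tier, so a degenerate stratum (all equal |logFC|)
    is entirely sex-specific. Strata with fewer than 4 called genes
    fall back to all-weak and are flagged. Unbiased genes get tier
    'none'.
    """
    merged = calls.merge(de[["gene_id", "logFC"]], on="gene_id", how="left")
    tier = pd.Series("none", index=merged.index, dtype=object)
    thresholds = []
    for direction in ("female-biased", "male-biased"):
        idx = merged.index[merged["status"] == direction]
        if len(idx) == 0:
            continue
        abs_lfc = merged.loc[idx, "logFC"].abs().to_numpy()
        name = f"{stratum_prefix}{direction}"
        if len(idx) < 4:
            tier.loc[idx] = "weak"
            thresholds.append(
                CategoryThresholds(
                    stratum=name, n_called=len(idx),
                    q1=float(np.min(abs_lfc)), q3=float(np.max(abs_lfc)),
                    max=float(np.max(abs_lfc)),
                    boundary=float(np.max(abs_lfc)), flagged=True,
                )
            )
            warnings.warn(
                f"stratum {name}: fewer than 4 called genes; all tiers set to weak"
            )
            continue
        q1, q3 = np.quantile(abs_lfc, [0.25, 0.75])
        mx = float(np.max(abs_lfc))
        boundary = (q3 + mx) / 2.0
        t = np.where(
            abs_lfc >= boundary, "sex-specific",
            np.where(abs_lfc >= q3, "intermediate", "weak"),
        )
        tier.loc[idx] = t
        thresholds.append(
            CategoryThresholds(
                stratum=name, n_called=len(idx), q1=float(q1), q3=float(q3),
                max=mx, boundary=float(boundary), flagged=False,
            )
        )
    out = merged[["gene_id", "status"]].copy()
    out["tier"] = tier.to_numpy()
    return out, thresholds
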