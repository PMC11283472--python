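"""Cross-species ortholog congruence and chromosomal enrichment.

Orthologs are inferred by reciprocal best hit (RBH) over directed
similarity-score tables; each ortholog pair's joint bias status is
classified as congruent (same direction in both species), incongruent
(opposite directions), transition (biased in exactly one species) or
both-unbiased. A one-proportion Z-test asks whether transitions favor
one sex; per-chromosome Fisher exact tests assess enrichment of bias
classes; and a binary logistic regression models the probability of
having a cross-species hit as a function of bias status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, star_label

__all__ = [
    "reciprocal_best_hits",
    "congruence_classify",
    "congruence_summary",
    "transition_ztest",
    "chromosome_enrichment",
    "hit_probability_model",
    "HitModelResult",
]

CLASSES = ("congruent", "incongruent", "transition", "both-unbiased")


def _best_unique(scores: pd.DataFrame) -> pd.Series:
    """query -> unique top-scoring subject; queries with a top-score tie
    across distinct subjects are dropped as ambiguous."""
    required = {"query", "subject", "bitscore"}
    if not required <= set(scores.columns):
        raise ValueError(f"score table needs columns {sorted(required)}")
    best = {}
    for query, grp in scores.groupby("query"):
        top = grp["bitscore"].max()
        subjects = grp.loc[grp["bitscore"] == top, "subject"].unique()
        if len(subjects) == 1:
            best[query] = subjects[0]
    return pd.Series(best, dtype=object)


def reciprocal_best_hits(
    scores_ab: pd.DataFrame, scores_ba: pd.DataFrame
) -> pd.DataFrame:
    """One-to-one ortholog pairs where each gene is the other's unique best hit.

    Returns columns ``gene_a, gene_b, score_ab, score_ba``.
    """
    best_ab = _best_unique(scores_ab)
    best_ba = _best_unique(scores_ba)
    rows = []
    for a, b in best_ab.items():
        if best_ba.get(b) == a:
            s_ab = scores_ab.loc[
                (scores_ab["query"] == a) & (scores_ab["subject"] == b), "bitscore"
            ].max()
            s_ba = scores_ba.loc[
                (scores_ba["query"] == b) & (scores_ba["subject"] == a), "bitscore"
            ].max()
            rows.append((a, b, float(s_ab), float(s_ba)))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score_ab", "score_ba"])


def _status_lookup(calls: pd.DataFrame) -> pd.Series:
    return calls.set_index("gene_id")["status"]


def congruence_classify(
    orthologs: pd.DataFrame,
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
) -> pd.DataFrame:
    """Joint bias class per ortholog pair.

    Genes absent from a call table are treated as unbiased, counted
    and reported through a warning. Returns ``gene_a, gene_b,
    status_a, status_b, congruence_class``.
    """
    lut_a, lut_b = _status_lookup(calls_a), _status_lookup(calls_b)
    missing = 0
    rows = []
    for a, b in zip(orthologs["gene_a"], orthologs["gene_b"]):
        sa = lut_a.get(a)
        sb = lut_b.get(b)
        if sa is None:
            sa = "unbiased"
            missing += 1
        if sb is None:
            sb = "unbiased"
            missing += 1
        a_biased = sa != "unbiased"
        b_biased = sb != "unbiased"
        if a_biased and b_biased:
            cls = "congruent" if sa == sb else "incongruent"
        elif a_biased or b_biased:
            cls = "transition"
        else:
            cls = "both-unbiased"
        rows.append((a, b, sa, sb, cls))
    if missing:
        warnings.warn(f"{missing} ortholog members missing from calls; treated unbiased")
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "status_a", "status_b", "congruence_class"]
    )


def congruence_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Class counts with percentages under every plausible denominator.

    Denominators reported: all pairs, pairs with >= 1 biased member,
    and each species' biased genes among the pairs.
    """
    counts = table["congruence_class"].value_counts()
    n_pairs = len(table)
    n_any_biased = int((table["congruence_class"] != "both-unbiased").sum())
    n_biased_a = int((table["status_a"] != "unbiased").sum())
    n_biased_b = int((table["status_b"] != "unbiased").sum())
    rows = []
    for cls in CLASSES:
        c = int(counts.get(cls, 0))
        rows.append(
            (
                cls, c,
                100.0 * c / n_pairs if n_pairs else np.nan,
                100.0 * c / n_any_biased if n_any_biased else np.nan,
                100.0 * c / n_biased_a if n_biased_a else np.nan,
                100.0 * c / n_biased_b if n_biased_b else np.nan,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "congruence_class", "count", "pct_of_pairs", "pct_of_any_biased",
            "pct_of_biased_a", "pct_of_biased_b",
        ],
    )


def transition_ztest(table: pd.DataFrame) -> tuple[float, float]:
    """One-proportion Z-test that transitions favor neither sex.

    Among the n transition pairs, x go toward female bias (the biased
    member is female-biased); z = (x/n - 0.5) / sqrt(0.25/n) and
    p = 2 (1 - Phi(|z|)).
    """
    trans = table[table["congruence_class"] == "transition"]
    n = len(trans)
    if n == 0:
        raise ValueError("no transition pairs")
    biased_side = np.where(
        trans["status_a"] != "unbiased", trans["status_a"], trans["status_b"]
    )
    x = int((biased_side == "female-biased").sum())
    z = (x / n - 0.5) / np.sqrt(0.25 / n)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def chromosome_enrichment(
    calls: pd.DataFrame,
    annotation,
    directions: tuple[str, ...] = ("female-biased", "male-biased"),
    alternative: str = "greater",
) -> pd.DataFrame:
    """Fisher exact test of bias-class enrichment per chromosome.

    For each chromosome and direction, the 2x2 table contrasts genes
    biased in that direction on vs off the chromosome against all
    remaining genes. One-sided (enrichment) by default. Star labels
    follow the raw p (thresholds 0.0001/0.001/0.01); BH-adjusted
    p-values across all tests are emitted alongside.
    """
    if isinstance(annotation, pd.DataFrame):
        chrom = annotation.set_index("gene_id")["chromosome"]
    else:
        chrom = pd.Series(dict(annotation))
    gene_chrom = chrom.reindex(calls["gene_id"])
    if gene_chrom.isna().any():
        bad = calls["gene_id"][gene_chrom.isna().to_numpy()].to_list()
        raise ValueError(f"genes missing from annotation: {bad[:5]}")
    status = calls["status"].to_numpy()
    chrom_arr = gene_chrom.to_numpy()
    rows = []
    for chromosome in pd.unique(chrom_arr):
        on = chrom_arr == chromosome
        for direction in directions:
            biased = status == direction
            a = int((biased & on).sum())
            b = int((biased & ~on).sum())
            c = int((~biased & on).sum())
            d = int((~biased & ~on).sum())
            odds, p = sps.fisher_exact([[a, b], [c, d]], alternative=alternative)
            rows.append((chromosome, direction, a, b, c, d, float(odds), float(p)))
    out = pd.DataFrame(
        rows,
        columns=[
            "chromosome", "direction", "biased_on", "biased_off",
            "other_on", "other_off", "odds_ratio", "pvalue",
        ],
    )
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    out["stars"] = [star_label(p) for p in out["pvalue"]]
    return out


@dataclass
class HitModelResult:
    coefficient: float
    pvalue: float | None
    intercept: float
    separated: bool


def hit_probability_model(genes: pd.DataFrame) -> HitModelResult:
    """Logistic regression of cross-species hit presence on bias status.

    ``genes`` needs boolean columns ``is_sex_biased`` and ``has_hit``.
    The slope is the log-odds difference of having a hit for sex-biased
    vs unbiased genes with a Wald p-value. Perfect separation (a bias
    group whose outcome is constant) is flagged and no Wald p is
    returned; the coefficient is then the (infinite) log odds ratio.
    """
    import statsmodels.api as sm

    y = genes["has_hit"].astype(int).to_numpy()
    x = genes["is_sex_biased"].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        # outcome constant overall: trivially separated
        return HitModelResult(np.nan, None, np.nan, True)
    tab = pd.crosstab(x, y).reindex(index=[0, 1], columns=[0, 1], fill_value=0)
    if (tab.to_numpy() == 0).any():
        a, b = tab.loc[0, 0], tab.loc[0, 1]
        c, d = tab.loc[1, 0], tab.loc[1, 1]
        with np.errstate(divide="ignore"):
            coef = np.log(d * a) - np.log(c * b) if min(a, b, c, d) >= 0 else np.nan
        return HitModelResult(float(coef), None, np.nan, True)
    X = sm.add_constant(x.astype(float))
    fit = sm.Logit(y, X).fit(disp=0)
    return HitModelResult(
        coefficient=float(fit.params[1]),
        pvalue=float(fit.pvalues[1]),
        intercept=float(fit.params[0]),
        separated=False,
    )
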