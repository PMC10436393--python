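"""Gene Expression Classifier: count-of-activated-genes prognosis scoring.

Each sample is scored by the number of panel biomarkers ON in its tumour
(expression strictly above the gene's cohort-calibrated threshold).  With a
panel of K genes, counts 0-1 define the favourable ("low") group and
counts >= 2 the unfavourable ("high") group; counts 0 and >= K-1 define the
GEC- / GEC+ extremes used by the extreme-group differential-expression
filter.  Evaluation couples a low-vs-high logrank test with Cox models
(univariate on the count, multivariate with age / molecular subtype /
stage) and subtype-stratified analyses.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .activation import call_activation_matrix
from .survival import bh_adjust, cox_fit, logrank_test

__all__ = [
    "gec_score",
    "score_cohort",
    "evaluate_gec",
    "multivariate_cox",
    "subtype_stratified_evaluation",
    "de_extreme_groups",
]

logger = logging.getLogger(__name__)

SUBTYPE_ORDER = ("luminal_A", "luminal_B", "HER2", "basal")


def _classify(counts: pd.Series, k: int) -> pd.DataFrame:
    out = pd.DataFrame({"activated_count": counts.astype(int)})
    out["group"] = np.where(out["activated_count"] <= 1, "low", "high")
    out["extreme"] = np.select(
        [out["activated_count"] == 0, out["activated_count"] >= k - 1],
        ["GEC-", "GEC+"], default="intermediate")
    out.index.name = "sample_id"
    return out


def score_cohort(expression: pd.DataFrame, panel_thresholds: pd.Series,
                 samples: list[str] | None = None) -> pd.DataFrame:
    """Score every sample of a cohort against the panel thresholds.

    ``panel_thresholds`` maps each panel gene to its threshold in this
    cohort (already propagated).  Missing expression values contribute OFF.
    Returns per-sample activated_count, low/high group and GEC-/GEC+
    extreme label.
    """
    if samples is not None:
        expression = expression[samples]
    missing = [g for g in panel_thresholds.index if g not in expression.index]
    if missing:
        raise ValueError(f"panel genes absent from expression matrix: {missing}")
    on = call_activation_matrix(expression, panel_thresholds)
    counts = on.sum(axis=0)
    return _classify(counts, k=len(panel_thresholds))


def gec_score(sample_values: pd.Series, panel_thresholds: pd.Series) -> dict:
    """Score a single sample; returns count, group and extreme label."""
    frame = score_cohort(sample_values.to_frame("sample"), panel_thresholds)
    row = frame.iloc[0]
    return {"activated_count": int(row["activated_count"]),
            "group": str(row["group"]), "extreme": str(row["extreme"])}


def evaluate_gec(scores: pd.DataFrame, survival: pd.DataFrame) -> dict:
    """Low-vs-high logrank plus univariate Cox on the activated count.

    Returns logrank_p, cox_p, cox_hr (HR per additional activated gene)
    and the group sizes; degenerate grouping (an empty arm or no events)
    yields a flagged result with NaN statistics.
    """
    df = scores.join(survival, how="inner")
    low = df[df["group"] == "low"]
    high = df[df["group"] == "high"]
    out = {"n_low": len(low), "n_high": len(high), "degenerate": False,
           "logrank_p": float("nan"), "cox_p": float("nan"), "cox_hr": float("nan")}
    if low.empty or high.empty or df["dfs_event"].sum() < 1:
        logger.warning("evaluate_gec: degenerate grouping (%d low / %d high)",
                       len(low), len(high))
        out["degenerate"] = True
        return out
    lr = logrank_test(low["dfs_time"], low["dfs_event"],
                      high["dfs_time"], high["dfs_event"])
    out["logrank_p"] = lr.p_value
    if df["activated_count"].nunique() > 1:
        fit = cox_fit(df.rename(columns={"activated_count": "gec_count"}),
                      ["gec_count"])
        out["cox_p"] = float(fit.loc["gec_count", "p"])
        out["cox_hr"] = float(fit.loc["gec_count", "hazard_ratio"])
    return out


def multivariate_cox(scores: pd.DataFrame, survival: pd.DataFrame,
                     clinical: pd.DataFrame,
                     covariates: tuple[str, ...] = ("gec_count", "age", "subtype", "stage"),
                     subtype_encoding: str = "ordinal") -> pd.DataFrame:
    """Joint Cox fit of the GEC count with clinical risk factors.

    Subtype enters either as a single ordered numeric covariate (default,
    ordered by ``SUBTYPE_ORDER``) or as dummy indicators
    (``subtype_encoding='dummy'``); stage is ordinal.  Covariates missing
    from the cohort are dropped.
    """
    df = scores.join(survival, how="inner")
    df = df.rename(columns={"activated_count": "gec_count"})
    ann = clinical.set_index("sample_id")
    cols: list[str] = []
    for cov in covariates:
        if cov == "gec_count":
            cols.append(cov)
        elif cov == "subtype":
            if "subtype" not in ann.columns:
                continue
            sub = ann.loc[df.index, "subtype"].replace("", np.nan)
            if subtype_encoding == "ordinal":
                order = {s: i for i, s in enumerate(SUBTYPE_ORDER)}
                df["subtype"] = sub.map(order)
                cols.append("subtype")
            elif subtype_encoding == "dummy":
                dummies = pd.get_dummies(sub, prefix="subtype", drop_first=True,
                                         dtype=float)
                for c in dummies.columns:
                    df[c] = dummies[c]
                    cols.append(c)
            else:
                raise ValueError(f"unknown subtype_encoding {subtype_encoding!r}")
        else:
            if cov not in ann.columns:
                continue
            df[cov] = pd.to_numeric(ann.loc[df.index, cov], errors="coerce")
            cols.append(cov)
    return cox_fit(df, cols)


def subtype_stratified_evaluation(scores: pd.DataFrame, survival: pd.DataFrame,
                                  clinical: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Per-subtype GEC-count distribution and low-vs-high survival tests.

    Cohorts may be pooled upstream (scores are cohort-calibrated counts).
    Returns one row per subtype with the count-fraction columns
    ``frac_0..frac_K`` (summing to 1), group fractions, and the logrank /
    Cox results; subtypes with a degenerate grouping are flagged
    non-evaluable.
    """
    ann = clinical.set_index("sample_id")
    df = scores.join(survival, how="inner")
    df["subtype"] = ann.loc[df.index, "subtype"].replace("", np.nan)
    df = df.dropna(subset=["subtype"])
    rows = []
    for subtype, sub in df.groupby("subtype", sort=True):
        row: dict = {"subtype": subtype, "n": len(sub)}
        counts = sub["activated_count"].value_counts(normalize=True)
        for c in range(k + 1):
            row[f"frac_{c}"] = float(counts.get(c, 0.0))
        row["frac_low"] = float((sub["group"] == "low").mean())
        row["frac_high"] = float((sub["group"] == "high").mean())
        res = evaluate_gec(sub[["activated_count", "group", "extreme"]],
                           sub[["dfs_time", "dfs_event"]])
        row["evaluable"] = not res["degenerate"]
        row["logrank_p"] = res["logrank_p"]
        row["cox_p"] = res["cox_p"]
        row["cox_hr"] = res["cox_hr"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("subtype")


def de_extreme_groups(expression: pd.DataFrame, scores: pd.DataFrame,
                      alpha: float = 0.05, min_ratio: float = 1.5,
                      min_group: int = 3) -> pd.DataFrame:
    """Differential expression between the GEC+ and GEC- extremes.

    Intermediate samples are excluded.  Per gene: two-sided Mann-Whitney
    p between groups, BH-adjusted across all tested genes, and the
    linear-scale fold ratio of group means (values back-transformed from
    log2).  Selected iff adjusted p < ``alpha`` and ratio > ``min_ratio``
    or < 1/``min_ratio``; direction labels regulation in GEC+.
    """
    pos = scores.index[scores["extreme"] == "GEC+"]
    neg = scores.index[scores["extreme"] == "GEC-"]
    pos = [s for s in pos if s in expression.columns]
    neg = [s for s in neg if s in expression.columns]
    if len(pos) < min_group or len(neg) < min_group:
        raise ValueError(
            f"extreme groups too small: {len(pos)} GEC+ / {len(neg)} GEC- "
            f"(need >= {min_group} each)")
    xp = expression[pos].to_numpy(dtype=float)
    xn = expression[neg].to_numpy(dtype=float)
    res = stats.mannwhitneyu(xp, xn, axis=1, alternative="two-sided")
    p_adj = bh_adjust(res.pvalue)
    mean_pos = (2.0 ** xp).mean(axis=1)
    mean_neg = (2.0 ** xn).mean(axis=1)
    ratio = mean_pos / mean_neg
    out = pd.DataFrame({
        "p": res.pvalue,
        "p_adj": p_adj,
        "ratio": ratio,
        "direction": np.where(ratio >= 1.0, "up", "down"),
    }, index=expression.index.copy())
    out["selected"] = (out["p_adj"] < alpha) & \
        ((out["ratio"] > min_ratio) | (out["ratio"] < 1.0 / min_ratio))
    return out
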