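"""Ectopic-activation calling: per-gene ON/OFF thresholds and frequencies.

For each candidate gene the activation threshold is the mean + 2 standard
deviations (sample sd, ddof=1) of its log2 expression in non-tumour
samples; a tumour sample is ON when its value is strictly above the
threshold.  Genes are retained for survival screening when they are
activated in strictly more than 10% of tumour samples.  Each threshold also
carries its percentile rank in the tumour-expression distribution of the
cohort where it was defined, so it can be propagated to other cohorts by
rank rather than absolute value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ActivationModel",
    "fit_activation_threshold",
    "fit_activation_models",
    "call_activation",
    "call_activation_matrix",
    "activation_frequency",
    "filter_frequent",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ActivationModel:
    gene: str
    threshold_value: float
    source: str = "nontumour_mean2sd"    # or "percentile_propagated"
    percentile_rank: float = float("nan")  # fraction of tumour samples <= threshold


def fit_activation_threshold(gene: str, nontumour_values: np.ndarray,
                             tumour_values: np.ndarray | None = None,
                             ) -> ActivationModel:
    """Threshold = mean + 2 * sample sd of the non-tumour log2 signal.

    When the cohort's tumour values are supplied the threshold's percentile
    rank (fraction of tumour samples at or below it) is recorded for later
    cross-cohort propagation.
    """
    vals = np.asarray(nontumour_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise ValueError(
            f"gene {gene}: need >= 2 non-tumour samples, got {vals.size}")
    thr = float(vals.mean() + 2.0 * vals.std(ddof=1))
    rank = float("nan")
    if tumour_values is not None:
        tv = np.asarray(tumour_values, dtype=float)
        tv = tv[~np.isnan(tv)]
        if tv.size:
            rank = float(np.mean(tv <= thr))
    return ActivationModel(gene=gene, threshold_value=thr, percentile_rank=rank)


def call_activation(value: float, model: ActivationModel) -> bool:
    """ON iff strictly above the threshold; missing values are OFF."""
    if value is None or np.isnan(value):
        return False
    return bool(value > model.threshold_value)


def call_activation_matrix(expression: pd.DataFrame,
                           thresholds: pd.Series) -> pd.DataFrame:
    """Genes x samples boolean ON matrix; NaN cells are OFF (logged)."""
    sub = expression.loc[thresholds.index]
    n_missing = int(sub.isna().to_numpy().sum())
    if n_missing:
        logger.info("call_activation_matrix: %d missing value(s) treated as OFF",
                    n_missing)
    return sub.gt(thresholds, axis=0).fillna(False)


def activation_frequency(gene: str, tumour_values: np.ndarray,
                         model: ActivationModel) -> float:
    """Fraction of non-missing tumour samples strictly above the threshold."""
    vals = np.asarray(tumour_values, dtype=float)
    if vals.size == 0:
        raise ValueError(f"gene {gene}: no tumour samples")
    ok = ~np.isnan(vals)
    if not ok.any():
        logger.warning("gene %s: zero usable tumour values, frequency undefined", gene)
        return float("nan")
    return float(np.mean(vals[ok] > model.threshold_value))


def fit_activation_models(expression: pd.DataFrame, clinical: pd.DataFrame,
                          genes: list[str] | None = None) -> pd.DataFrame:
    """Fit thresholds and activation frequencies for a whole cohort.

    ``clinical`` must carry sample_id and sample_type ('tumour' /
    'non-tumour') for every expression column.  Returns a per-gene table
    with threshold, percentile_rank and frequency.
    """
    ann = clinical.set_index("sample_id")
    missing = [s for s in expression.columns if s not in ann.index]
    if missing:
        raise ValueError(f"samples without clinical annotation: {missing}")
    types = ann.loc[list(expression.columns), "sample_type"]
    tum_cols = list(types.index[types == "tumour"])
    non_cols = list(types.index[types == "non-tumour"])
    if len(non_cols) < 2:
        raise ValueError("need >= 2 non-tumour samples to fit thresholds")
    if not tum_cols:
        raise ValueError("cohort has no tumour samples")
    if genes is None:
        genes = list(expression.index)

    sub_n = expression.loc[genes, non_cols].to_numpy(dtype=float)
    sub_t = expression.loc[genes, tum_cols].to_numpy(dtype=float)
    thr = np.nanmean(sub_n, axis=1) + 2.0 * np.nanstd(sub_n, axis=1, ddof=1)
    with np.errstate(invalid="ignore"):
        rank = np.nanmean(sub_t <= thr[:, None], axis=1)
        freq = np.nanmean(sub_t > thr[:, None], axis=1)
    return pd.DataFrame({
        "threshold": thr,
        "percentile_rank": rank,
        "frequency": freq,
        "source": "nontumour_mean2sd",
    }, index=pd.Index(genes, name="gene"))


def filter_frequent(frequencies: pd.Series, min_frequency: float = 0.10) -> list[str]:
    """Genes activated in strictly more than ``min_frequency`` of tumours."""
    freq = frequencies.dropna()
    return list(freq.index[freq > min_frequency])
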