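"""Threshold-scanning cross-validated survival screen.

For each candidate gene the screen tests every expression threshold on a
percentile grid (15th to 85th percentile of tumour expression, half-
percentile steps) as an ON/OFF split of the training cohort, scoring each
split with the two-group logrank test on the full cohort and on random
cross-validation subsets (threefold, repeated five times).  Full-set
p-values are Benjamini-Hochberg adjusted across the whole gene x threshold
family.  A threshold is significant when logrank p < 0.05, FDR < 0.2 and
the ON-vs-OFF hazard ratio (univariate Cox on the ON indicator) exceeds 1;
among significant thresholds the reference threshold is the one most stable
across the cross-validation subsets.  Reference thresholds travel to other
cohorts as percentile ranks, and a gene is validated when it is significant
(p < 0.05, HR > 1) in at least two of three validation cohorts with
p < 0.1 in the remaining one.

The scan evaluates on the order of 10^5 gene x threshold x subset splits,
so the logrank statistic and the one-parameter Cox partial likelihood are
computed here with vectorized count-based formulas (all thresholds of a
gene at once).  Because the scanned covariate is binary, the Efron-tie
partial likelihood reduces to risk-set counts already produced for the
logrank statistic.  ``lifelines`` remains the general Cox/Kaplan-Meier
engine for everything that is not the inner scan loop, and serves as an
independent cross-check of the fast paths in the test-suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LogrankResult",
    "BiomarkerCandidate",
    "km_estimator",
    "logrank_test",
    "cox_fit",
    "bh_adjust",
    "threshold_grid",
    "cv_partitions",
    "survival_from_clinical",
    "scan_cohort",
    "select_reference_threshold",
    "select_candidates",
    "propagate_threshold",
    "validation_decision",
    "validate_genes",
]

logger = logging.getLogger(__name__)

GRID_LOW = 15.0
GRID_HIGH = 85.0
GRID_STEP = 0.5
MIN_GROUP_FRAC = 0.15   # smallest allowed arm, as a fraction of tumour samples


# ---------------------------------------------------------------------------
# survival table plumbing

def survival_from_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Extract the tumour survival table (index sample_id; dfs_time, dfs_event).

    Validates the survival invariants: positive times, 0/1 events, unique
    samples.
    """
    df = clinical.loc[clinical["sample_type"] == "tumour",
                      ["sample_id", "dfs_time", "dfs_event"]].dropna()
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicated samples in survival table: {dup}")
    if (df["dfs_time"] <= 0).any():
        raise ValueError("survival times must be > 0")
    ev = df["dfs_event"].to_numpy()
    if not np.isin(ev, (0, 1)).all():
        raise ValueError("event indicator must be 0 or 1")
    out = df.set_index("sample_id")
    out["dfs_event"] = out["dfs_event"].astype(int)
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier and general Cox (lifelines-backed)

def km_estimator(times, events) -> KaplanMeierFitter:
    """Product-limit survival estimate (right-continuous, starts at 1)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("km_estimator requires at least one sample")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    return kmf


def cox_fit(table: pd.DataFrame, covariates: list[str],
            duration_col: str = "dfs_time", event_col: str = "dfs_event",
            ) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron tie handling via lifelines).

    Constant covariates are dropped with a warning; returns a per-covariate
    table with coef, hazard_ratio and Wald p.
    """
    cols = []
    for c in covariates:
        if table[c].nunique(dropna=True) < 2:
            logger.warning("cox_fit: dropping constant covariate %r", c)
            continue
        cols.append(c)
    if not cols:
        raise ValueError("no non-constant covariates to fit")
    df = table[[duration_col, event_col] + cols].dropna()
    if df[event_col].sum() < 1:
        raise ValueError("cox_fit requires at least one event")
    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    out = pd.DataFrame({
        "coef": cph.params_,
        "hazard_ratio": np.exp(cph.params_),
        "p": cph.summary["p"],
    })
    out.index.name = "covariate"
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# fast count-based logrank / binary Cox

@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float


class _SortedSurv:
    """Time-sorted survival arrays with distinct-event-time segments."""

    def __init__(self, times: np.ndarray, events: np.ndarray):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=np.int64)
        order = np.argsort(times, kind="stable")
        t = times[order]
        e = events[order]
        starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
        d_all = np.add.reduceat(e, starts)
        keep = d_all > 0
        self.order = order
        self.n = times.size
        self.e_sorted = e
        self.starts = starts
        self.keep = keep
        self.d = d_all[keep].astype(float)
        self.N = (self.n - starts[keep]).astype(float)

    def group_counts(self, on_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-split at-risk (R1) and event (d1) counts in the ON group.

        ``on_matrix`` is (splits, n) boolean in original sample order.
        Returns R1, d1 of shape (splits, n_event_times).
        """
        ind = on_matrix[:, self.order].astype(np.int64)
        suffix = np.cumsum(ind[:, ::-1], axis=1)[:, ::-1]
        r1 = suffix[:, self.starts[self.keep]].astype(float)
        d1 = np.add.reduceat(ind * self.e_sorted, self.starts, axis=1)
        return r1, d1[:, self.keep].astype(float)


def _logrank_counts(N, d, R1, d1) -> tuple[np.ndarray, np.ndarray]:
    """Chi-square statistic and p for many splits from risk-set counts."""
    frac = R1 / N
    o_minus_e = (d1 - d * frac).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_terms = d * frac * (1.0 - frac) * (N - d) / (N - 1.0)
    v_terms = np.where(N > 1, v_terms, 0.0)
    var = v_terms.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(var > 0, o_minus_e ** 2 / var, 0.0)
    p = stats.chi2.sf(chi2, df=1)
    return chi2, p


def _cox_binary_counts(N, d, R1, d1, max_iter: int = 40,
                       tol: float = 1e-9) -> np.ndarray:
    """Hazard ratios of many binary ON/OFF splits (Efron tie handling).

    Newton iteration on the one-parameter partial likelihood expressed in
    risk-set counts.  Splits where the likelihood is flat (no information)
    yield NaN; diverging estimates are clipped at |log HR| = 15.
    """
    n_splits = R1.shape[0]
    beta = np.zeros(n_splits)
    n0 = N - R1
    dd0 = d - d1
    dmax = int(d.max()) if d.size else 1
    dsum = d1.sum(axis=1)
    active = np.ones(n_splits, dtype=bool)
    for _ in range(max_iter):
        w = np.exp(beta)[:, None]
        s0 = n0 + R1 * w
        s1 = R1 * w
        s0d = dd0 + d1 * w
        s1d = d1 * w
        g = np.zeros(n_splits)
        h = np.zeros(n_splits)
        for el in range(dmax):
            mask = el < d
            if not mask.any():
                break
            a = np.where(mask, el / d, 0.0)
            s0l = s0 - a * s0d
            s1l = s1 - a * s1d
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where(s0l > 0, s1l / s0l, 0.0)
            g += (r * mask).sum(axis=1)
            h += ((r - r * r) * mask).sum(axis=1)
        grad = dsum - g
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(h > 1e-12, grad / h, 0.0)
        step = np.clip(step, -2.0, 2.0)
        beta = np.where(active, np.clip(beta + step, -15.0, 15.0), beta)
        active = active & (np.abs(step) > tol) & (np.abs(beta) < 15.0)
        if not active.any():
            break
    flat = ~np.isfinite(beta)
    no_info = (R1.sum(axis=1) == 0) | (n0.sum(axis=1) == 0)
    beta = np.where(no_info | flat, np.nan, beta)
    return np.exp(beta)


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Two-group logrank test: chi-square with 1 df, upper-tail p."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() < 1:
        raise ValueError("logrank test requires at least one event")
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    on = np.zeros((1, times.size), dtype=bool)
    on[0, : ta.size] = True
    ss = _SortedSurv(times, events)
    r1, d1 = ss.group_counts(on)
    chi2, p = _logrank_counts(ss.N, ss.d, r1, d1)
    return LogrankResult(statistic=float(chi2[0]), p_value=float(p[0]))


# ---------------------------------------------------------------------------
# threshold grid and cross-validation subsets

def threshold_grid(tumour_values, low: float = GRID_LOW, high: float = GRID_HIGH,
                   step: float = GRID_STEP) -> pd.DataFrame:
    """Percentile grid of candidate thresholds over tumour expression.

    Linear-interpolation quantiles from ``low`` to ``high`` percent in
    ``step`` increments (141 points at the defaults); duplicate threshold
    values are collapsed keeping the lowest percentile.  Constant
    expression yields an empty grid.
    """
    vals = np.asarray(tumour_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 10:
        raise ValueError(f"threshold_grid requires >= 10 tumour samples, got {vals.size}")
    cols = ["percentile", "value"]
    if vals.max() == vals.min():
        return pd.DataFrame(columns=cols)
    n_points = int(round((high - low) / step)) + 1
    pcts = low + step * np.arange(n_points)
    values = np.percentile(vals, pcts)  # linear interpolation between order stats
    _, first = np.unique(values, return_index=True)
    first.sort()
    return pd.DataFrame({"percentile": pcts[first], "value": values[first]})


def cv_partitions(n_samples: int, k: int = 3, repeats: int = 5,
                  seed: int | np.random.Generator = 0,
                  mode: str = "held_in") -> list[np.ndarray]:
    """Random k-fold partitions; returns the evaluated subsets.

    ``mode='held_in'`` yields the k complements of the folds per repeat
    (each of size ~(k-1)/k * n; 15 subsets at the defaults), which
    preserves event counts for the subset logrank tests; ``'held_out'``
    yields the folds themselves.
    """
    if n_samples < 3 * k:
        raise ValueError(f"need at least {3 * k} samples for {k}-fold partitions")
    if mode not in ("held_in", "held_out"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    subsets: list[np.ndarray] = []
    for _ in range(repeats):
        perm = rng.permutation(n_samples)
        folds = np.array_split(perm, k)
        for f in folds:
            sub = np.setdiff1d(perm, f) if mode == "held_in" else np.sort(f)
            subsets.append(sub)
    return subsets


# ---------------------------------------------------------------------------
# the screen

@dataclass(frozen=True)
class BiomarkerCandidate:
    gene: str
    percentile: float
    threshold_value: float
    logrank_p: float
    fdr: float
    hazard_ratio: float
    stability: float


def scan_cohort(expression: pd.DataFrame, survival: pd.DataFrame,
                genes: list[str], seed: int = 0, grid_step: float = GRID_STEP,
                k: int = 3, repeats: int = 5, subset_mode: str = "held_in",
                min_group_frac: float = MIN_GROUP_FRAC,
                alpha: float = 0.05) -> pd.DataFrame:
    """Scan every gene x threshold split of the training cohort.

    Returns one record per retained threshold with the full-set logrank p,
    ON-vs-OFF hazard ratio, cross-validation stability (fraction of subsets
    with subset logrank p < ``alpha``) and the BH-adjusted p (``fdr``)
    computed across the entire gene x threshold family.  Thresholds leaving
    either arm below ``min_group_frac`` of the cohort are skipped; genes
    whose thresholds are all skipped are absent from the output.
    """
    samples = list(survival.index)
    missing = [s for s in samples if s not in expression.columns]
    if missing:
        raise ValueError(f"survival samples missing from expression: {missing}")
    times = survival["dfs_time"].to_numpy(dtype=float)
    events = survival["dfs_event"].to_numpy(dtype=int)
    n = len(samples)
    min_arm = max(1, int(math.ceil(min_group_frac * n)))
    subset_idx = cv_partitions(n, k=k, repeats=repeats,
                               seed=np.random.default_rng(seed), mode=subset_mode)
    full = _SortedSurv(times, events)
    subs = [_SortedSurv(times[ix], events[ix]) for ix in subset_idx]

    frames = []
    expr_t = expression.loc[genes, samples]
    for gene in genes:
        vals = expr_t.loc[gene].to_numpy(dtype=float)
        grid = threshold_grid(vals, step=grid_step)
        if grid.empty:
            logger.info("scan_cohort: gene %s has a degenerate grid, skipped", gene)
            continue
        on = vals[None, :] > grid["value"].to_numpy()[:, None]
        n_on = on.sum(axis=1)
        ok = (n_on >= min_arm) & (n - n_on >= min_arm)
        if not ok.any():
            logger.info("scan_cohort: gene %s has no admissible threshold", gene)
            continue
        grid = grid.loc[ok].reset_index(drop=True)
        on = on[ok]
        n_on = n_on[ok]

        r1, d1 = full.group_counts(on)
        chi2, p = _logrank_counts(full.N, full.d, r1, d1)
        hr = _cox_binary_counts(full.N, full.d, r1, d1)

        stab = np.zeros(on.shape[0])
        for ss, ix in zip(subs, subset_idx):
            r1s, d1s = ss.group_counts(on[:, ix])
            _, ps = _logrank_counts(ss.N, ss.d, r1s, d1s)
            stab += (ps < alpha)
        stab /= len(subs)

        frames.append(pd.DataFrame({
            "gene": gene,
            "percentile": grid["percentile"].to_numpy(),
            "threshold": grid["value"].to_numpy(),
            "logrank_p": p,
            "hazard_ratio": hr,
            "stability": stab,
            "n_on": n_on,
            "n_off": n - n_on,
        }))
    if not frames:
        return pd.DataFrame(columns=["gene", "percentile", "threshold", "logrank_p",
                                     "hazard_ratio", "stability", "n_on", "n_off",
                                     "fdr"])
    records = pd.concat(frames, ignore_index=True)
    records["fdr"] = bh_adjust(records["logrank_p"].to_numpy())
    return records


def select_reference_threshold(records: pd.DataFrame, alpha: float = 0.05,
                               fdr_max: float = 0.2) -> BiomarkerCandidate | None:
    """Most-stable significant threshold of one gene's scan records.

    Significance: logrank p < 0.05, FDR < 0.2 and HR > 1.  Ties on
    stability break by lower full-set p, then lower percentile.
    """
    genes = records["gene"].unique()
    if len(genes) != 1:
        raise ValueError("select_reference_threshold expects records of one gene")
    sig = records[(records["logrank_p"] < alpha) & (records["fdr"] < fdr_max)
                  & (records["hazard_ratio"] > 1.0)]
    if sig.empty:
        return None
    best = sig.sort_values(["stability", "logrank_p", "percentile"],
                           ascending=[False, True, True]).iloc[0]
    return BiomarkerCandidate(
        gene=str(best["gene"]), percentile=float(best["percentile"]),
        threshold_value=float(best["threshold"]), logrank_p=float(best["logrank_p"]),
        fdr=float(best["fdr"]), hazard_ratio=float(best["hazard_ratio"]),
        stability=float(best["stability"]))


def select_candidates(records: pd.DataFrame, alpha: float = 0.05,
                      fdr_max: float = 0.2) -> pd.DataFrame:
    """Reference thresholds of all genes with a significant threshold."""
    rows = []
    for gene, sub in records.groupby("gene", sort=True):
        cand = select_reference_threshold(sub, alpha=alpha, fdr_max=fdr_max)
        if cand is not None:
            rows.append(vars(cand))
    cols = ["gene", "percentile", "threshold_value", "logrank_p", "fdr",
            "hazard_ratio", "stability"]
    if not rows:
        return pd.DataFrame(columns=cols).set_index("gene")
    return pd.DataFrame(rows, columns=cols).set_index("gene")


def propagate_threshold(percentile: float, target_tumour_values) -> float:
    """Target-cohort tumour quantile at the reference percentile rank."""
    vals = np.asarray(target_tumour_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("target cohort has no tumour samples")
    return float(np.percentile(vals, percentile))


def _cohort_gene_test(expr: pd.DataFrame, surv: pd.DataFrame, gene: str,
                      percentile: float) -> tuple[float, float, float]:
    """Logrank p, HR and propagated threshold for one gene in one cohort."""
    samples = list(surv.index)
    vals = expr.loc[gene, samples].to_numpy(dtype=float)
    thr = propagate_threshold(percentile, vals)
    on = vals > thr
    if on.all() or not on.any():
        return float("nan"), float("nan"), thr
    times = surv["dfs_time"].to_numpy(dtype=float)
    events = surv["dfs_event"].to_numpy(dtype=int)
    ss = _SortedSurv(times, events)
    r1, d1 = ss.group_counts(on[None, :])
    _, p = _logrank_counts(ss.N, ss.d, r1, d1)
    hr = _cox_binary_counts(ss.N, ss.d, r1, d1)
    return float(p[0]), float(hr[0]), thr


def validation_decision(p_values, hazard_ratios, alpha: float = 0.05,
                        weak_alpha: float = 0.1) -> bool:
    """The 2-of-3 validation rule, generalized to m cohorts.

    Validated iff significant (p < ``alpha`` with HR > 1) in at least
    ceil(2m/3) cohorts and p < ``weak_alpha`` in every remaining cohort.
    NaN entries (degenerate splits) always fail.
    """
    p = np.asarray(p_values, dtype=float)
    hr = np.asarray(hazard_ratios, dtype=float)
    if p.size == 0 or p.size != hr.size:
        raise ValueError("need matching non-empty p-value and HR vectors")
    sig = np.isfinite(p) & (p < alpha) & np.isfinite(hr) & (hr > 1.0)
    weak = np.isfinite(p) & (p < weak_alpha)
    need = math.ceil(2 * p.size / 3)
    return bool(sig.sum() >= need and np.all(sig | weak))


def validate_genes(candidates: pd.DataFrame,
                   validation_cohorts: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
                   alpha: float = 0.05, weak_alpha: float = 0.1) -> pd.DataFrame:
    """Test candidate genes in independent cohorts at propagated thresholds.

    A cohort counts a gene significant when logrank p < ``alpha`` with
    HR > 1 at the percentile-propagated threshold.  With m usable cohorts a
    gene is validated when significant in at least ceil(2m/3) of them and
    p < ``weak_alpha`` in every remaining cohort (the 2-of-3 rule at
    m = 3).  Cohorts with zero events are excluded with a warning.
    """
    usable: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for name, (expr, surv) in validation_cohorts.items():
        if surv["dfs_event"].sum() < 1:
            logger.warning("validate_genes: cohort %s has zero events, excluded", name)
            continue
        usable[name] = (expr, surv)
    if not usable:
        raise ValueError("no usable validation cohorts")
    rows = []
    for gene, cand in candidates.iterrows():
        row: dict = {"gene": gene}
        pvals, hrs = [], []
        for name, (expr, surv) in usable.items():
            p, hr, thr = _cohort_gene_test(expr, surv, gene, cand["percentile"])
            row[f"p_{name}"] = p
            row[f"hr_{name}"] = hr
            row[f"threshold_{name}"] = thr
            pvals.append(p)
            hrs.append(hr)
        row["n_significant"] = int(sum(
            np.isfinite(p) and p < alpha and np.isfinite(h) and h > 1.0
            for p, h in zip(pvals, hrs)))
        row["validated"] = validation_decision(pvals, hrs, alpha=alpha,
                                               weak_alpha=weak_alpha)
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.set_index("gene")
    return out
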