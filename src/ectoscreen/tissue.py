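"""Tissue-predominant gene identification from a normal-tissue panel.

A gene is called predominant in a tissue when that tissue's mean expression
is an outlier of the gene's cross-tissue profile, measured by the Z-score
(x - mean) / std computed over non-foetal tissue means.  The cutoff is 60%
of the maximum attainable Z-score, 0.6 * (N - 1) / sqrt(N) for N tissues.
The population standard deviation (divide by N) is used: with that
convention the maximum attainable Z of a profile concentrated in one tissue
is exactly (N - 1) / sqrt(N), which is the quantity the threshold scales.

Predominance is assessed at two granularities — the detailed tissue list
and the pooled tissue groups — and a gene becomes a screening candidate if
it passes at either granularity in a target tissue (testis, placenta or
embryonic stem cells) while remaining lowly expressed in breast (linear
breast mean strictly below one tenth of the predominant tissue's linear
mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TissuePanel",
    "PredominanceCall",
    "compute_tissue_means",
    "zscore_threshold",
    "zscore_matrix",
    "zscore_profile",
    "call_predominance",
    "call_all_genes",
    "select_candidate_genes",
]

logger = logging.getLogger(__name__)

GRANULARITIES = ("detailed", "grouped")


@dataclass(frozen=True)
class TissuePanel:
    """Per-gene per-tissue mean log2 expression at both granularities."""
    means: pd.DataFrame          # genes x tissues (detailed)
    group_means: pd.DataFrame    # genes x tissue groups (pooled samples)
    foetal_tissues: tuple[str, ...]
    foetal_groups: tuple[str, ...]
    tissue_to_group: dict[str, str]

    def columns(self, granularity: str) -> pd.DataFrame:
        if granularity == "detailed":
            return self.means
        if granularity == "grouped":
            return self.group_means
        raise ValueError(f"unknown granularity {granularity!r}")

    def foetal(self, granularity: str) -> tuple[str, ...]:
        return self.foetal_tissues if granularity == "detailed" else self.foetal_groups

    def n_tissues(self, granularity: str) -> int:
        """Number of non-foetal tissues (or groups) entering the Z computation."""
        cols = self.columns(granularity).columns
        return len([c for c in cols if c not in set(self.foetal(granularity))])


@dataclass(frozen=True)
class PredominanceCall:
    gene: str
    predominant_tissue: str
    granularity: str
    z_score: float
    threshold: float
    passed: bool
    scorable: bool = True


def compute_tissue_means(expression: pd.DataFrame,
                         samples: pd.DataFrame) -> TissuePanel:
    """Average log2 expression per tissue and per pooled tissue group.

    ``samples`` must carry columns sample_id, tissue, tissue_group and
    is_foetal covering every column of ``expression``.  Grouped means pool
    the raw samples of each group (weighted by sample count), not the
    per-tissue means.
    """
    ann = samples.set_index("sample_id")
    missing = [s for s in expression.columns if s not in ann.index]
    if missing:
        raise ValueError(f"samples without tissue label: {missing}")
    ann = ann.loc[list(expression.columns)]
    multi = ann.groupby("tissue")["tissue_group"].nunique()
    bad = multi[multi > 1]
    if len(bad):
        raise ValueError(f"tissues mapping to multiple groups: {list(bad.index)}")

    means = expression.T.groupby(ann["tissue"]).mean().T
    group_means = expression.T.groupby(ann["tissue_group"]).mean().T
    foet_t = tuple(sorted(ann.loc[ann["is_foetal"], "tissue"].unique()))
    foet_g = tuple(sorted(ann.loc[ann["is_foetal"], "tissue_group"].unique()))
    t2g = dict(ann.groupby("tissue")["tissue_group"].first())
    return TissuePanel(means=means, group_means=group_means,
                       foetal_tissues=foet_t, foetal_groups=foet_g,
                       tissue_to_group=t2g)


def zscore_threshold(n_tissues: int) -> float:
    """Predominance cutoff 0.6 * (N - 1) / sqrt(N), 60% of the maximum Z."""
    if n_tissues < 2:
        raise ValueError(f"zscore_threshold requires N >= 2, got {n_tissues}")
    return 0.6 * (n_tissues - 1) / np.sqrt(n_tissues)


def zscore_matrix(panel: TissuePanel, granularity: str = "detailed",
                  ) -> tuple[pd.DataFrame, pd.Series]:
    """Z-scores over non-foetal tissues for all genes at once.

    Returns the genes x non-foetal-tissues Z matrix and a boolean
    scorability mask; genes with zero cross-tissue variance are
    non-scorable and get NaN rows.
    """
    cols = panel.columns(granularity)
    foet = set(panel.foetal(granularity))
    nonf = cols[[c for c in cols.columns if c not in foet]]
    if nonf.shape[1] < 3:
        raise ValueError("need at least 3 non-foetal tissues for Z-scores")
    mu = nonf.mean(axis=1)
    sd = nonf.std(axis=1, ddof=0)  # population std: max Z is (N-1)/sqrt(N)
    scorable = sd > 0
    z = nonf.sub(mu, axis=0).div(sd.where(scorable), axis=0)
    return z, scorable


def zscore_profile(panel: TissuePanel, gene: str,
                   granularity: str = "detailed") -> pd.Series:
    """Per-tissue Z profile of one gene; all-NaN when non-scorable."""
    z, _ = zscore_matrix(panel, granularity)
    return z.loc[gene]


def call_predominance(panel: TissuePanel, gene: str,
                      granularity: str = "detailed") -> PredominanceCall:
    """Call the single maximal-Z tissue for one gene."""
    z, scorable = zscore_matrix(panel, granularity)
    thr = zscore_threshold(panel.n_tissues(granularity))
    if not scorable.loc[gene]:
        return PredominanceCall(gene, "", granularity, float("nan"), thr,
                                passed=False, scorable=False)
    prof = z.loc[gene]
    best = prof.idxmax()
    zmax = float(prof.loc[best])
    return PredominanceCall(gene, str(best), granularity, zmax, thr,
                            passed=zmax > thr)


def call_all_genes(panel: TissuePanel, granularity: str = "detailed") -> pd.DataFrame:
    """Vectorized predominance calls; one row per scorable gene.

    Non-scorable (zero-variance) genes are dropped with a logged count.
    """
    z, scorable = zscore_matrix(panel, granularity)
    n_drop = int((~scorable).sum())
    if n_drop:
        logger.info("%s granularity: dropped %d non-scorable gene(s)",
                    granularity, n_drop)
    z = z.loc[scorable]
    thr = zscore_threshold(panel.n_tissues(granularity))
    out = pd.DataFrame({
        "predominant_tissue": z.idxmax(axis=1),
        "z_score": z.max(axis=1),
    })
    out["threshold"] = thr
    out["granularity"] = granularity
    out["passed"] = out["z_score"] > thr
    out.index.name = "gene"
    return out


def select_candidate_genes(calls_detailed: pd.DataFrame,
                           calls_grouped: pd.DataFrame,
                           panel: TissuePanel,
                           target_tissues: tuple[str, ...] = ("testis", "placenta", "esc"),
                           breast_tissue: str = "breast",
                           breast_ratio: float = 10.0) -> pd.DataFrame:
    """Union of target-tissue predominance calls, filtered by the breast rule.

    A gene qualifies through a granularity when it passes there with its
    predominant tissue in the target set and its linear-scale breast mean is
    strictly below 1/``breast_ratio`` of the linear-scale mean in the
    predominant tissue (means back-transformed from log2).  The returned
    table has one row per gene with the qualifying granularities.
    """
    if breast_tissue not in panel.means.columns:
        raise ValueError(f"breast tissue {breast_tissue!r} absent from panel")
    target_groups = {panel.tissue_to_group.get(t, t) for t in target_tissues}
    breast_group = panel.tissue_to_group.get(breast_tissue, breast_tissue)

    selected: dict[str, dict] = {}
    for calls, granularity, targets, breast_col in (
            (calls_detailed, "detailed", set(target_tissues), breast_tissue),
            (calls_grouped, "grouped", target_groups, breast_group)):
        cols = panel.columns(granularity)
        passing = calls[calls["passed"] & calls["predominant_tissue"].isin(targets)]
        for gene, row in passing.iterrows():
            pred_lin = float(2.0 ** cols.loc[gene, row["predominant_tissue"]])
            breast_lin = float(2.0 ** cols.loc[gene, breast_col])
            if not breast_lin * breast_ratio < pred_lin:
                continue
            rec = selected.setdefault(gene, {
                "gene": gene, "predominant_tissue": row["predominant_tissue"],
                "granularities": [], "z_detailed": np.nan, "z_grouped": np.nan})
            rec["granularities"].append(granularity)
            rec[f"z_{granularity}"] = float(row["z_score"])
    if not selected:
        return pd.DataFrame(
            columns=["predominant_tissue", "granularities", "z_detailed", "z_grouped"],
        ).rename_axis("gene")
    out = pd.DataFrame(list(selected.values())).set_index("gene")
    out["granularities"] = out["granularities"].map(lambda g: "+".join(g))
    return out.sort_index()
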