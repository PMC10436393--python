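"""Synthetic multi-tissue panels and tumour cohorts with planted signal.

The generator emulates the statistical structure of a biomarker-discovery
study: a normal-tissue expression panel containing genes predominantly
expressed in testis, placenta or embryonic stem cells (ESC) while silent in
breast; and several heterogeneous breast-tumour cohorts in which a subset of
those genes is ectopically activated, with disease-free survival generated
under a proportional-hazards model tied to the number of activated
prognostic genes.

All expression values are on the log2 scale with additive Gaussian noise.
Event times are exponential (the simplest proportional-hazards-compatible
family, giving closed-form oracles); censoring is an independent exponential
time plus an administrative follow-up cap.  Inter-cohort heterogeneity is an
additive per-cohort log2 offset, mimicking platform shifts that
percentile-rank threshold propagation is designed to absorb.

Every generated dataset carries a planted-truth manifest (which genes are
predominant / activatable / prognostic, and per-sample activation
indicators) so downstream recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "PanelData",
    "CohortData",
    "generate_normal_panel",
    "generate_cohort",
    "generate_cohorts",
]

TARGET_CLASSES = ("testis", "placenta", "esc")
SUBTYPES = ("luminal_A", "luminal_B", "HER2", "basal")
#: Molecular-subtype composition of the simulated cohorts (training-cohort-like
#: mix dominated by luminal-A).
SUBTYPE_PROBS = (0.534, 0.198, 0.080, 0.188)
STAGE_LEVELS = (1, 2, 3)
STAGE_PROBS = (0.3, 0.5, 0.2)


def _check(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid SimulationConfig.{fieldname}: {msg}")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe the reference study conditions: a 20-adult-tissue
    normal panel (plus 2 foetal tissues), 125 genes of which 30 are planted
    tissue-predominant (10 per target class), 25 of the planted genes are
    tumour-activatable and 5 of those are prognostic; four cohorts (one
    training-sized, three validation-sized).  Prognostic genes carry
    per-activation hazard ratios spanning 2.5-3 and activation frequencies
    spanning 0.25-0.35; other activatable genes activate at frequency 0.30
    with no survival effect.

    Expression units are log2 signal; time units are years.
    """

    seed: int = 0
    # --- normal panel ---
    n_tissues: int = 20            # adult (non-foetal) tissues, incl. targets + breast
    n_foetal_tissues: int = 2
    samples_per_tissue: int = 3
    n_genes: int = 125
    n_predominant: int = 10        # planted predominant genes per target class
    baseline_mean: float = 1.0     # log2 units
    baseline_sd: float = 0.5       # log2 units
    predominance_shift: float = 6.0  # log2 units added in the predominant tissue
    # --- tumour cohorts ---
    n_cohorts: int = 4
    n_tumour: int | tuple[int, ...] = (600, 250, 250, 250)
    n_nontumour: int | tuple[int, ...] = (100, 50, 50, 50)
    n_activatable: int = 25        # planted genes that can turn ON in tumours
    n_prognostic: int = 5          # activatable genes tied to survival
    activation_frequency: float | None = None   # scalar override; None = study defaults
    activation_shift: float = 4.0  # log2 units added when a gene is ON
    log_hazard_per_activation: float | None = None  # scalar override; None = HR 2.5-3 span
    baseline_hazard: float = 0.08  # events / year for zero activations
    censoring_rate: float = 0.04   # events / year, independent
    follow_up_cap: float = 10.0    # years
    cohort_shift_sd: float = 0.5   # log2 units, per-cohort additive offset

    def __post_init__(self) -> None:
        _check(self.n_tissues >= 4, "n_tissues",
               "need at least testis, placenta, esc and breast")
        _check(self.n_foetal_tissues >= 1, "n_foetal_tissues", "must be >= 1")
        _check(self.samples_per_tissue >= 1, "samples_per_tissue", "must be >= 1")
        _check(self.n_genes >= 1, "n_genes", "must be >= 1")
        _check(self.n_predominant >= 1, "n_predominant", "must be >= 1")
        _check(3 * self.n_predominant <= self.n_genes, "n_predominant",
               "3 * n_predominant must not exceed n_genes")
        _check(self.baseline_sd > 0, "baseline_sd", "must be > 0")
        _check(self.n_cohorts >= 1, "n_cohorts", "must be >= 1")
        for name in ("n_tumour", "n_nontumour"):
            val = getattr(self, name)
            sizes = (val,) if isinstance(val, int) else tuple(val)
            _check(all(s >= 1 for s in sizes), name, "all counts must be >= 1")
            if not isinstance(val, int):
                _check(len(sizes) == self.n_cohorts, name,
                       f"needs {self.n_cohorts} entries (one per cohort)")
        _check(0 <= self.n_activatable <= 3 * self.n_predominant, "n_activatable",
               "must be a subset of the planted predominant genes")
        _check(0 <= self.n_prognostic <= self.n_activatable, "n_prognostic",
               "prognostic genes must be a subset of activatable genes")
        if self.activation_frequency is not None:
            _check(0.0 <= self.activation_frequency <= 1.0,
                   "activation_frequency", "must be in [0, 1]")
        _check(self.baseline_hazard > 0, "baseline_hazard", "must be > 0")
        _check(self.censoring_rate >= 0, "censoring_rate", "must be >= 0")
        _check(self.follow_up_cap > 0, "follow_up_cap", "must be > 0")
        _check(self.cohort_shift_sd >= 0, "cohort_shift_sd", "must be >= 0")

    # ------------------------------------------------------------------
    # derived, deterministic bookkeeping

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    @property
    def planted_genes(self) -> dict[str, str]:
        """Mapping gene -> target tissue class for planted predominant genes."""
        out: dict[str, str] = {}
        genes = self.gene_ids
        for c, cls in enumerate(TARGET_CLASSES):
            for j in range(self.n_predominant):
                out[genes[c * self.n_predominant + j]] = cls
        return out

    @property
    def activatable_genes(self) -> list[str]:
        return list(self.planted_genes)[: self.n_activatable]

    @property
    def prognostic_genes(self) -> list[str]:
        return self.activatable_genes[: self.n_prognostic]

    def gene_activation_frequencies(self) -> pd.Series:
        """Per-activatable-gene tumour activation probability."""
        act = self.activatable_genes
        freqs = pd.Series(
            self.activation_frequency if self.activation_frequency is not None else 0.30,
            index=act, dtype=float)
        if self.activation_frequency is None and self.n_prognostic > 0:
            freqs[self.prognostic_genes] = np.linspace(
                0.25, 0.35, self.n_prognostic)
        return freqs

    def gene_log_hazards(self) -> pd.Series:
        """Per-prognostic-gene additive log hazard when the gene is ON."""
        prog = self.prognostic_genes
        if self.log_hazard_per_activation is not None:
            return pd.Series(self.log_hazard_per_activation, index=prog, dtype=float)
        if not prog:
            return pd.Series(dtype=float)
        return pd.Series(
            np.linspace(math.log(2.5), math.log(3.0), len(prog)), index=prog)

    @property
    def tissue_names(self) -> list[str]:
        generic = [f"tissue_{i + 1:02d}" for i in range(self.n_tissues - 4)]
        return ["testis", "placenta", "esc", "breast"] + generic

    @property
    def foetal_tissue_names(self) -> list[str]:
        return [f"foetal_{i + 1:02d}" for i in range(self.n_foetal_tissues)]

    def tissue_annotation(self) -> pd.DataFrame:
        """Tissue -> (group, foetal flag) table at the coarse granularity.

        The target tissues and breast keep their own group; generic adult
        tissues are pooled pairwise; foetal tissues fall into per-pair
        foetal groups.
        """
        rows = []
        for t in self.tissue_names:
            if t in ("testis", "placenta", "esc", "breast"):
                grp = t
            else:
                idx = int(t.split("_")[1]) - 1
                grp = f"group_{idx // 2 + 1:02d}"
            rows.append((t, grp, False))
        for t in self.foetal_tissue_names:
            idx = int(t.split("_")[1]) - 1
            rows.append((t, f"foetal_group_{idx // 2 + 1:02d}", True))
        return pd.DataFrame(rows, columns=["tissue", "tissue_group", "is_foetal"])

    def truth_manifest(self) -> pd.DataFrame:
        planted = self.planted_genes
        act = set(self.activatable_genes)
        prog = set(self.prognostic_genes)
        freqs = self.gene_activation_frequencies()
        loghr = self.gene_log_hazards()
        rows = []
        for g in self.gene_ids:
            rows.append({
                "gene": g,
                "is_predominant": g in planted,
                "predominant_tissue": planted.get(g, ""),
                "is_activatable": g in act,
                "is_prognostic": g in prog,
                "activation_frequency": float(freqs.get(g, 0.0)),
                "log_hazard": float(loghr.get(g, 0.0)),
            })
        return pd.DataFrame(rows).set_index("gene")


@dataclass(frozen=True)
class PanelData:
    """Normal-tissue panel: genes x samples log2 expression plus annotations."""
    expression: pd.DataFrame
    samples: pd.DataFrame      # sample_id, tissue, tissue_group, is_foetal
    truth: pd.DataFrame


@dataclass(frozen=True)
class CohortData:
    """One tumour cohort: expression, clinical table and planted truth."""
    cohort_id: str
    expression: pd.DataFrame
    clinical: pd.DataFrame     # sample_id, sample_type, dfs_time, dfs_event, age, subtype, stage
    activation_truth: pd.DataFrame  # genes x tumour samples, boolean
    cohort_offset: float


def _cohort_size(val: int | tuple[int, ...], idx: int) -> int:
    return val if isinstance(val, int) else val[idx]


def generate_normal_panel(config: SimulationConfig) -> PanelData:
    """Simulate the multi-tissue normal expression panel.

    Planted predominant genes are elevated by ``predominance_shift`` in
    exactly their designated target tissue and stay at baseline everywhere
    else, including breast and foetal tissues; all other genes are
    ubiquitous at baseline.
    """
    rng = np.random.default_rng([config.seed, 0])
    tissues = config.tissue_annotation()
    genes = config.gene_ids
    planted = config.planted_genes

    sample_rows = []
    for _, trow in tissues.iterrows():
        for s in range(config.samples_per_tissue):
            sample_rows.append((
                f"{trow.tissue}_s{s + 1:02d}", trow.tissue,
                trow.tissue_group, bool(trow.is_foetal)))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "tissue", "tissue_group", "is_foetal"])

    mean = np.full((len(genes), len(samples)), config.baseline_mean)
    tissue_of_sample = samples["tissue"].to_numpy()
    for gi, g in enumerate(genes):
        cls = planted.get(g)
        if cls is not None:
            mean[gi, tissue_of_sample == cls] += config.predominance_shift
    values = mean + rng.normal(0.0, config.baseline_sd, size=mean.shape)
    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                        columns=samples["sample_id"].to_list())
    return PanelData(expression=expr, samples=samples, truth=config.truth_manifest())


def generate_cohort(config: SimulationConfig, cohort_index: int) -> CohortData:
    """Simulate one tumour cohort with planted ectopic activations.

    Non-tumour samples keep every gene at the silent baseline.  Each tumour
    sample independently activates each activatable gene with its planted
    probability, adding ``activation_shift`` log2 units.  Disease-free
    survival is min(event, censoring, cap) with an exponential event time at
    hazard ``baseline_hazard * exp(sum of log hazards of activated
    prognostic genes)`` and independent exponential censoring.  A single
    cohort-level offset drawn with sd ``cohort_shift_sd`` is added to all
    expression values.
    """
    if not 0 <= cohort_index < config.n_cohorts:
        raise ValueError(
            f"cohort_index {cohort_index} out of range for n_cohorts={config.n_cohorts}")
    rng = np.random.default_rng([config.seed, 1 + cohort_index])
    genes = config.gene_ids
    n_t = _cohort_size(config.n_tumour, cohort_index)
    n_n = _cohort_size(config.n_nontumour, cohort_index)
    cid = f"cohort_{cohort_index + 1:02d}"
    tumour_ids = [f"{cid}_t{i + 1:04d}" for i in range(n_t)]
    normal_ids = [f"{cid}_n{i + 1:04d}" for i in range(n_n)]
    sample_ids = tumour_ids + normal_ids

    offset = float(rng.normal(0.0, config.cohort_shift_sd)) if config.cohort_shift_sd else 0.0

    values = rng.normal(config.baseline_mean, config.baseline_sd,
                        size=(len(genes), n_t + n_n))

    freqs = config.gene_activation_frequencies()
    act_genes = config.activatable_genes
    gene_pos = {g: i for i, g in enumerate(genes)}
    activated = np.zeros((len(act_genes), n_t), dtype=bool)
    for k, g in enumerate(act_genes):
        on = rng.random(n_t) < freqs[g]
        activated[k] = on
        values[gene_pos[g], :n_t][on] += config.activation_shift
    values += offset

    loghr = config.gene_log_hazards()
    lin_pred = np.zeros(n_t)
    for k, g in enumerate(act_genes):
        if g in loghr.index:
            lin_pred += loghr[g] * activated[k]
    hazard = config.baseline_hazard * np.exp(lin_pred)
    event_time = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        cens_time = rng.exponential(1.0 / config.censoring_rate, size=n_t)
    else:
        cens_time = np.full(n_t, np.inf)
    cens_time = np.minimum(cens_time, config.follow_up_cap)
    dfs_time = np.minimum(event_time, cens_time)
    dfs_event = (event_time <= cens_time).astype(int)

    subtype = rng.choice(SUBTYPES, size=n_t, p=SUBTYPE_PROBS)
    age = rng.uniform(30.0, 80.0, size=n_t)
    stage = rng.choice(STAGE_LEVELS, size=n_t, p=STAGE_PROBS)

    clinical = pd.DataFrame({
        "sample_id": sample_ids,
        "sample_type": ["tumour"] * n_t + ["non-tumour"] * n_n,
        "dfs_time": np.concatenate([dfs_time, np.full(n_n, np.nan)]),
        "dfs_event": np.concatenate([dfs_event.astype(float), np.full(n_n, np.nan)]),
        "age": np.concatenate([age, np.full(n_n, np.nan)]),
        "subtype": list(subtype) + [""] * n_n,
        "stage": np.concatenate([stage.astype(float), np.full(n_n, np.nan)]),
    })
    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=sample_ids)
    truth = pd.DataFrame(activated, index=pd.Index(act_genes, name="gene"),
                         columns=tumour_ids)
    return CohortData(cohort_id=cid, expression=expr, clinical=clinical,
                      activation_truth=truth, cohort_offset=offset)


def generate_cohorts(config: SimulationConfig) -> list[CohortData]:
    """All cohorts of the configured study, in index order."""
    return [generate_cohort(config, i) for i in range(config.n_cohorts)]
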