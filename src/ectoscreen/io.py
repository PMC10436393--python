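"""Readers, writers and the end-to-end training/validation/test pipeline.

One fixed table dialect is used throughout so that reruns are byte-
identical: expression matrices are tab-separated text with genes as rows
(first column the gene identifier, header row of sample identifiers,
UTF-8, '.' decimal, no quoting); annotation and manifest tables are
comma-separated with a header.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import activation as _activation
from . import gec as _gec
from . import survival as _survival
from . import tissue as _tissue

__all__ = [
    "read_expression",
    "write_expression",
    "read_table",
    "write_table",
    "log_transform",
    "PipelineCohort",
    "read_manifest",
    "PipelineResult",
    "run_pipeline",
    "load_cohorts",
]

logger = logging.getLogger(__name__)

ROLES = ("training", "validation", "test")


# ---------------------------------------------------------------------------
# format plumbing

def read_expression(path: str | Path) -> pd.DataFrame:
    """Parse a genes x samples TSV expression matrix.

    Rejects ragged rows, non-numeric cells and duplicated gene
    identifiers, reporting the offending line number or gene.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    n_cols = len(header)
    samples = header[1:]
    genes: list[str] = []
    data: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != n_cols:
            raise ValueError(
                f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {n_cols})")
        genes.append(parts[0])
        try:
            data.append([float(x) for x in parts[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    seen: set[str] = set()
    for g in genes:
        if g in seen:
            raise ValueError(f"{path}: duplicated gene identifier {g!r}")
        seen.add(g)
    return pd.DataFrame(np.asarray(data, dtype=float),
                        index=pd.Index(genes, name="gene"), columns=samples)


def write_expression(expression: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = expression.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_table(path: str | Path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


def write_table(df: pd.DataFrame, path: str | Path, sep: str = ",",
                index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=index, lineterminator="\n")


def log_transform(values, mode: str = "fpkm") -> np.ndarray:
    """log2(1 + v) elementwise; values must be non-negative linear signal."""
    if mode not in ("fpkm", "counts_rpkm"):
        raise ValueError(f"unknown mode {mode!r}")
    arr = np.asarray(values, dtype=float)
    if np.nanmin(arr) < 0:
        raise ValueError("log_transform requires non-negative values")
    return np.log2(1.0 + arr)


# ---------------------------------------------------------------------------
# cohort manifest

@dataclass
class PipelineCohort:
    cohort_id: str
    role: str
    expression: pd.DataFrame
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"cohort {self.cohort_id}: unknown role {self.role!r}")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Cohort manifest CSV: cohort_id, role, expression, clinical paths."""
    df = read_table(path)
    required = {"cohort_id", "role", "expression", "clinical"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    bad = df.loc[~df["role"].isin(ROLES), "role"].unique()
    if len(bad):
        raise ValueError(f"manifest has unknown roles: {list(bad)}")
    return df


def load_cohorts(manifest: pd.DataFrame, base_dir: str | Path | None = None,
                 ) -> list[PipelineCohort]:
    base = Path(base_dir) if base_dir is not None else Path(".")
    cohorts = []
    for _, row in manifest.iterrows():
        cohorts.append(PipelineCohort(
            cohort_id=str(row["cohort_id"]), role=str(row["role"]),
            expression=read_expression(base / row["expression"]),
            clinical=read_table(base / row["clinical"])))
    return cohorts


# ---------------------------------------------------------------------------
# the end-to-end pipeline

@dataclass
class PipelineResult:
    tissue_candidates: pd.DataFrame | None
    activation_models: pd.DataFrame
    frequent_genes: list[str]
    scan_records: pd.DataFrame
    screen_candidates: pd.DataFrame
    validation: pd.DataFrame
    panel: list[str]
    gec_scores: dict[str, pd.DataFrame] = field(default_factory=dict)
    gec_evaluation: pd.DataFrame = field(default_factory=pd.DataFrame)
    subtype_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    de_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    run_log: dict = field(default_factory=dict)


def _config_hash(params: dict) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cohorts: list[PipelineCohort], seed: int,
                 normal_panel_expression: pd.DataFrame | None = None,
                 normal_panel_samples: pd.DataFrame | None = None,
                 target_tissues: tuple[str, ...] = ("testis", "placenta", "esc"),
                 breast_tissue: str = "breast",
                 min_frequency: float = 0.10,
                 grid_step: float = _survival.GRID_STEP,
                 panel_size: int = 5,
                 subtype_encoding: str = "ordinal",
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run specificity -> activation -> screen -> validation -> GEC -> DE.

    Requires exactly one training cohort and at least one validation
    cohort; test cohorts are optional (GEC evaluation then reports on
    validation + training cohorts only for information).  When a normal
    panel is supplied, candidate genes come from the tissue-predominance
    caller; otherwise all genes of the training matrix are screened.
    All randomness (cross-validation subsets) flows from ``seed``.
    """
    training = [c for c in cohorts if c.role == "training"]
    validations = [c for c in cohorts if c.role == "validation"]
    tests = [c for c in cohorts if c.role == "test"]
    if len(training) != 1:
        raise ValueError(f"need exactly one training cohort, got {len(training)}")
    if not validations:
        raise ValueError("need at least one validation cohort to run the screen")
    train = training[0]

    # 1. tissue specificity (optional)
    tissue_candidates = None
    if normal_panel_expression is not None:
        if normal_panel_samples is None:
            raise ValueError("normal panel requires a sample annotation table")
        panel = _tissue.compute_tissue_means(normal_panel_expression,
                                             normal_panel_samples)
        calls_d = _tissue.call_all_genes(panel, "detailed")
        calls_g = _tissue.call_all_genes(panel, "grouped")
        tissue_candidates = _tissue.select_candidate_genes(
            calls_d, calls_g, panel, target_tissues, breast_tissue)
        genes = [g for g in tissue_candidates.index if g in train.expression.index]
    else:
        genes = list(train.expression.index)
    if not genes:
        raise ValueError("stage tissue_specificity: no candidate genes")

    # 2. activation thresholds and frequency filter on the training cohort
    models = _activation.fit_activation_models(train.expression, train.clinical,
                                               genes=genes)
    frequent = _activation.filter_frequent(models["frequency"], min_frequency)
    if not frequent:
        raise ValueError("stage ectopic_activation: no frequently activated genes")

    # 3. threshold-scanning survival screen on the training cohort
    surv_train = _survival.survival_from_clinical(train.clinical)
    records = _survival.scan_cohort(train.expression, surv_train, frequent,
                                    seed=seed, grid_step=grid_step)
    candidates = _survival.select_candidates(records)

    # 4. validation by percentile propagation
    val_map = {c.cohort_id: (c.expression, _survival.survival_from_clinical(c.clinical))
               for c in validations}
    if candidates.empty:
        validation = pd.DataFrame()
        panel_genes: list[str] = []
    else:
        validation = _survival.validate_genes(candidates, val_map)
        validated = validation.index[validation["validated"]]
        ordered = candidates.loc[validated].sort_values("logrank_p")
        panel_genes = list(ordered.index[:panel_size])

    result = PipelineResult(
        tissue_candidates=tissue_candidates, activation_models=models,
        frequent_genes=frequent, scan_records=records,
        screen_candidates=candidates, validation=validation, panel=panel_genes)

    # 5. GEC scoring and evaluation
    eval_rows = []
    if panel_genes:
        eval_cohorts = tests if tests else (validations + training)
        pooled_scores = []
        pooled_surv = []
        pooled_clin = []
        for c in eval_cohorts:
            surv = _survival.survival_from_clinical(c.clinical)
            thresholds = pd.Series({
                g: _survival.propagate_threshold(
                    candidates.loc[g, "percentile"],
                    c.expression.loc[g, surv.index])
                for g in panel_genes})
            scores = _gec.score_cohort(c.expression, thresholds,
                                       samples=list(surv.index))
            result.gec_scores[c.cohort_id] = scores
            res = _gec.evaluate_gec(scores, surv)
            res["cohort_id"] = c.cohort_id
            eval_rows.append(res)
            pooled_scores.append(scores)
            pooled_surv.append(surv)
            pooled_clin.append(c.clinical)
            try:
                result.de_tables[c.cohort_id] = _gec.de_extreme_groups(
                    c.expression[list(surv.index)], scores)
            except ValueError as exc:
                logger.info("de skipped for cohort %s: %s", c.cohort_id, exc)
        result.gec_evaluation = pd.DataFrame(eval_rows).set_index("cohort_id")
        result.subtype_table = _gec.subtype_stratified_evaluation(
            pd.concat(pooled_scores), pd.concat(pooled_surv),
            pd.concat(pooled_clin, ignore_index=True), k=len(panel_genes))

    # 6. run log
    params = {"seed": seed, "min_frequency": min_frequency,
              "grid_step": grid_step, "panel_size": panel_size,
              "target_tissues": list(target_tissues),
              "breast_tissue": breast_tissue,
              "subtype_encoding": subtype_encoding}
    from . import __version__
    result.run_log = {
        "seed": seed,
        "config_hash": _config_hash(params),
        "params": params,
        "version": __version__,
        "counts": {
            "candidate_genes": len(genes),
            "frequent_genes": len(frequent),
            "screen_candidates": int(len(candidates)),
            "validated_genes": int(validation["validated"].sum()) if len(validation) else 0,
            "panel_size": len(panel_genes),
        },
    }

    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if result.tissue_candidates is not None:
        write_table(result.tissue_candidates.reset_index(),
                    out_dir / "tissue_candidates.tsv", sep="\t")
    write_table(result.activation_models.reset_index(),
                out_dir / "activation_models.tsv", sep="\t")
    write_table(result.scan_records, out_dir / "scan_records.tsv", sep="\t")
    write_table(result.screen_candidates.reset_index(),
                out_dir / "screen_candidates.tsv", sep="\t")
    if len(result.validation):
        write_table(result.validation.reset_index(),
                    out_dir / "validation.tsv", sep="\t")
    for cid, scores in result.gec_scores.items():
        write_table(scores.reset_index(), out_dir / f"gec_scores_{cid}.tsv", sep="\t")
    if len(result.gec_evaluation):
        write_table(result.gec_evaluation.reset_index(),
                    out_dir / "gec_evaluation.tsv", sep="\t")
    if len(result.subtype_table):
        write_table(result.subtype_table.reset_index(),
                    out_dir / "subtype_evaluation.tsv", sep="\t")
    for cid, table in result.de_tables.items():
        write_table(table.reset_index(), out_dir / f"de_{cid}.tsv", sep="\t")
    (out_dir / "run_log.json").write_text(
        json.dumps(result.run_log, indent=2, sort_keys=True) + "\n")
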