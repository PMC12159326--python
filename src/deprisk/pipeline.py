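"""End-to-end study pipeline: generate or ingest a cohort, code phenotypes,
run the exclusion cascade, externally validate a fixed-coefficient risk
model, recalibrate its intercept, refit it by penalized maximum likelihood,
cross-evaluate every model variant against both incident outcomes, estimate
per-predictor associations, and compute reporter agreement — with full
provenance in a serialized run bundle.

Model updating targets incident MDD only; the updated models are
additionally evaluated against the increased-DS outcome (generalisability
check), but no DS-specific model is fit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .metrics import MetricDelta, ValidationReport, compare_reports, validation_report
from .phenotypes import (
    AgreementTable,
    CascadeReport,
    REPORTERS,
    apply_exclusion_cascade,
    code_cohort,
    cohen_kappa,
)
from .risk import RiskModel, score_cohort
from .synthetic import SyntheticConfig, default_true_model, read_cohort_csv, simulate
from .updating import RefitOptions, recalibrate_intercept, refit_model
from .associations import AssociationResult, association_frame, association_table

log = logging.getLogger("deprisk")

OUTCOMES = ("incident_mdd", "increased_ds")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    synthetic_config: Optional[SyntheticConfig] = None
    cohort_csv: Optional[str] = None
    model_path: Optional[str] = None  # None -> packaged synthetic truth
    reporter: str = "youth"
    outcomes: tuple[str, ...] = OUTCOMES
    include_interactions: bool = True
    n_boot: int = 1000
    penalty: Optional[float] = None
    criterion: str = "aic"
    group_col: str = "site_id"
    out_dir: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.reporter not in REPORTERS:
            raise PipelineError(f"unknown reporter {self.reporter!r}")
        unknown = set(self.outcomes) - set(OUTCOMES)
        if unknown:
            raise PipelineError(f"unknown outcomes {sorted(unknown)}")
        if self.synthetic_config is None and self.cohort_csv is None:
            self.synthetic_config = SyntheticConfig(seed=self.seed)
        if self.cohort_csv is not None and not Path(self.cohort_csv).exists():
            raise PipelineError(f"cohort CSV not found: {self.cohort_csv}")
        if self.model_path is not None and not Path(self.model_path).exists():
            raise PipelineError(f"model file not found: {self.model_path}")

    def to_dict(self) -> dict:
        return {
            "synthetic_config": (
                self.synthetic_config.to_dict() if self.synthetic_config else None
            ),
            "cohort_csv": self.cohort_csv,
            "model_path": self.model_path,
            "reporter": self.reporter,
            "outcomes": list(self.outcomes),
            "include_interactions": self.include_interactions,
            "n_boot": self.n_boot,
            "penalty": self.penalty,
            "criterion": self.criterion,
            "group_col": self.group_col,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic_config"):
            d["synthetic_config"] = SyntheticConfig.from_dict(d["synthetic_config"])
        if d.get("outcomes"):
            d["outcomes"] = tuple(d["outcomes"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunBundle:
    cascade: CascadeReport
    reports: dict[str, ValidationReport]  # key "provenance:outcome"
    deltas: list[MetricDelta]
    associations: dict[str, list[AssociationResult]]
    agreement: dict[str, dict]
    manifest: dict = field(default_factory=dict)

    def report(self, provenance: str, outcome: str) -> ValidationReport:
        return self.reports[f"{provenance}:{outcome}"]

    def to_dict(self) -> dict:
        return {
            "cascade": self.cascade.to_dict(),
            "reports": {k: v.to_dict() for k, v in self.reports.items()},
            "deltas": [d.to_dict() for d in self.deltas],
            "associations": {
                k: [r.to_dict() for r in v] for k, v in self.associations.items()
            },
            "agreement": self.agreement,
            "manifest": self.manifest,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunBundle":
        from .phenotypes import CascadeStage

        cascade = CascadeReport(
            stages=[CascadeStage(**s) for s in d["cascade"]["stages"]]
        )
        reports = {k: ValidationReport.from_dict(v) for k, v in d["reports"].items()}
        deltas = [
            MetricDelta(
                outcome_label=x["outcome_label"],
                from_provenance=x["from"],
                to_provenance=x["to"],
                auc_points=x["delta_auc_points"],
                brier=x["delta_brier"],
                citl=x["delta_calibration_in_the_large"],
                slope=x["delta_calibration_slope"],
            )
            for x in d["deltas"]
        ]
        associations = {
            k: [
                AssociationResult(
                    predictor=r["predictor"],
                    level=r["level"],
                    reference=r["reference"],
                    odds_ratio=r["odds_ratio"],
                    ci=(
                        r["ci_low"] if r["ci_low"] is not None else 0.0,
                        r["ci_high"] if r["ci_high"] is not None else float("inf"),
                    ),
                    p=r["p"],
                    p_fdr=r["p_fdr"],
                    significant_fdr=r["significant_fdr"],
                )
                for r in v
            ]
            for k, v in d["associations"].items()
        }
        return cls(
            cascade=cascade,
            reports=reports,
            deltas=deltas,
            associations=associations,
            agreement=d["agreement"],
            manifest=d["manifest"],
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunBundle":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def summary_table(self) -> pd.DataFrame:
        """Human-readable metric grid (AUC as %, 1 dp; others 2–3 dp)."""
        rows = []
        for key, rep in self.reports.items():
            prov, outcome = key.split(":")
            lo, hi = rep.auc_ci
            rows.append(
                {
                    "model": prov,
                    "outcome": outcome,
                    "AUC": f"{100 * rep.auc:.1f}% ({100 * lo:.1f}%-{100 * hi:.1f}%)",
                    "Brier": f"{rep.brier:.3f}",
                    "Calibration-in-the-large": f"{rep.citl:.2f}",
                    "Calibration slope": f"{rep.slope:.2f}",
                    "cases": rep.n_cases,
                    "controls": rep.n_controls,
                }
            )
        return pd.DataFrame(rows)


def reporter_agreement(
    analytic: pd.DataFrame, outcome_label: str
) -> tuple[AgreementTable, float]:
    """Youth×parent 2×2 for one outcome on the analytic sample, plus κ."""
    ycol, pcol = f"{outcome_label}_youth", f"{outcome_label}_parent"
    for col in (ycol, pcol):
        if col not in analytic.columns:
            raise PipelineError(f"reporter column {col!r} absent")
    y = analytic[ycol].astype(bool).to_numpy()
    p = analytic[pcol].astype(bool).to_numpy()
    table = AgreementTable(
        both_pos=int((y & p).sum()),
        row_only=int((y & ~p).sum()),
        col_only=int((~y & p).sum()),
        both_neg=int((~y & ~p).sum()),
    )
    return table, cohen_kappa(table)


def _outcome_column(outcome: str, reporter: str) -> str:
    return f"{outcome}_{reporter}"


def run_pipeline(config: PipelineConfig) -> RunBundle:
    """Execute all stages in order; any stage error aborts with the stage
    name while artifacts written so far are preserved."""
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        stream=sys.stderr,
        format="%(levelname)s %(name)s: %(message)s",
    )
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(out_dir / "run.log")
        fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        log.addHandler(fh)

    stage = "input"
    try:
        if config.cohort_csv:
            log.info("loading cohort from %s", config.cohort_csv)
            cohort = read_cohort_csv(config.cohort_csv)
        else:
            log.info("simulating synthetic cohort (seed=%d)", config.synthetic_config.seed)
            cohort = simulate(config.synthetic_config)

        stage = "phenotype coding"
        coded = code_cohort(cohort)

        stage = "exclusion cascade"
        analytic, cascade = apply_exclusion_cascade(
            coded, seed=config.seed, reporter=config.reporter
        )
        log.info("analytic sample n=%d", len(analytic))
        if out_dir:
            cascade.to_json(out_dir / "cascade.json")
            (out_dir / "cascade_stard.txt").write_text(cascade.stard_text())

        stage = "external model"
        external = (
            RiskModel.from_json(config.model_path)
            if config.model_path
            else default_true_model()
        )

        stage = "agreement"
        agreement = {}
        for outcome in config.outcomes:
            table, kappa = reporter_agreement(analytic, outcome)
            agreement[outcome] = {
                "both_pos": table.both_pos,
                "youth_only": table.row_only,
                "parent_only": table.col_only,
                "both_neg": table.both_neg,
                "kappa": kappa,
            }
            log.info("reporter agreement for %s: kappa=%.3f", outcome, kappa)

        models: dict[str, RiskModel] = {"external": external}

        stage = "recalibration"
        mdd_col = _outcome_column("incident_mdd", config.reporter)
        if "incident_mdd" in config.outcomes:
            models["recalibrated"] = recalibrate_intercept(
                external, analytic, mdd_col
            )
            if out_dir:
                models["recalibrated"].to_json(out_dir / "model_recalibrated.json")

        stage = "refitting"
        if "incident_mdd" in config.outcomes:
            refitted, selection = refit_model(
                analytic,
                mdd_col,
                RefitOptions(
                    include_interactions=config.include_interactions,
                    n_boot=config.n_boot,
                    seed=config.seed,
                    criterion=config.criterion,
                    penalty=config.penalty,
                ),
            )
            refitted.outcome_label = "incident_mdd"
            models["refitted"] = refitted
            log.info("refit penalty=%.4g", refitted.penalty)
            if out_dir:
                refitted.to_json(out_dir / "model_refitted.json")
                if selection is not None:
                    selection.to_json(out_dir / "penalty_selection.json")

        stage = "validation"
        reports: dict[str, ValidationReport] = {}
        for prov, model in models.items():
            scored = score_cohort(model, analytic)
            if out_dir:
                scored.to_csv(out_dir / f"predictions_{prov}.csv", index=False)
            for outcome in config.outcomes:
                y = analytic[_outcome_column(outcome, config.reporter)]
                rep = validation_report(
                    scored["p"].to_numpy(),
                    y.to_numpy(),
                    outcome,
                    prov,
                    linear_predictors=scored["coef_sum"].to_numpy(),
                )
                reports[f"{prov}:{outcome}"] = rep
                if out_dir:
                    rep.to_json(out_dir / f"report_{prov}_{outcome}.json")
                    rep.curve_frame().to_csv(
                        out_dir / f"calibration_curve_{prov}_{outcome}.csv", index=False
                    )

        stage = "deltas"
        deltas = []
        for outcome in config.outcomes:
            for prov in ("recalibrated", "refitted"):
                key = f"{prov}:{outcome}"
                if key in reports:
                    deltas.append(
                        compare_reports(reports[f"external:{outcome}"], reports[key])
                    )

        stage = "associations"
        associations = {}
        for outcome in config.outcomes:
            results = association_table(
                analytic,
                _outcome_column(outcome, config.reporter),
                group_col=config.group_col,
            )
            associations[outcome] = results
            if out_dir:
                association_frame(results).to_csv(
                    out_dir / f"associations_{outcome}.csv", index=False
                )
    except Exception as exc:
        raise PipelineError(f"pipeline failed at stage '{stage}': {exc}") from exc

    bundle = RunBundle(
        cascade=cascade,
        reports=reports,
        deltas=deltas,
        associations=associations,
        agreement=agreement,
        manifest={
            "config_hash": config.config_hash(),
            "deprisk_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "seed": config.seed,
            "reporter": config.reporter,
        },
    )
    if out_dir:
        bundle.to_json(out_dir / "bundle.json")
        bundle.summary_table().to_csv(out_dir / "metric_grid.csv", index=False)
    return bundle
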