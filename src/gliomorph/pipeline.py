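"""End-to-end orchestration: measure masks, merge covariates, analyze.

The pipeline mirrors a study inclusion flowchart: every case is measured
if possible, cases failing the inclusion rules (empty or multifocal
masks, unreadable files) are logged with a reason and skipped, and the
analysis stage runs on whatever survives.  Each run writes the fully
resolved configuration beside its outputs so results are reproducible
from the sidecar alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mask_io import Connectivity, MaskRole, read_mask
from .morphometry import (
    MorphometryConfig,
    MorphometryError,
    morphometry_pipeline,
)
from .survival_analysis import AnalysisConfig, AnalysisError, analysis_report

logger = logging.getLogger(__name__)

__all__ = ["CaseSpec", "PipelineConfig", "run_pipeline", "load_pipeline_config"]

MORPHOMETRY_COLUMNS = [
    "case_id", "volume_ml", "tsa_cm2", "csa_cm2", "si", "av_per_cm",
    "dural_fraction", "eor_percent", "eor_category",
]


@dataclass(frozen=True)
class CaseSpec:
    case_id: str
    pre: str
    post: Optional[str] = None
    brain: Optional[str] = None
    contact: Optional[str] = None  # NIfTI with nonzero on dura-adjacent voxels


@dataclass(frozen=True)
class PipelineConfig:
    cases: tuple = ()
    covariates_csv: Optional[str] = None
    output_dir: str = "gliomorph-out"
    contact_tolerance_mm: float = 1.0
    connectivity: str = Connectivity.FACE_EDGE_VERTEX.value
    smoothing_sigma: float = 0.0
    surface_estimator: str = "mesh"
    split_day: float = 300.0
    ties: str = "efron"
    min_n_for_analysis: int = 30
    seed: int = 0
    version: str = __version__

    def morphometry_config(self) -> MorphometryConfig:
        return MorphometryConfig(
            contact_tolerance_mm=self.contact_tolerance_mm,
            connectivity=Connectivity(self.connectivity),
            smoothing_sigma=self.smoothing_sigma,
            surface_estimator=self.surface_estimator,
        )

    def analysis_config(self) -> AnalysisConfig:
        return AnalysisConfig(split_day=self.split_day, ties=self.ties)


def load_pipeline_config(path) -> PipelineConfig:
    """Read a YAML pipeline config; case entries become :class:`CaseSpec`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cases = tuple(CaseSpec(**c) for c in raw.pop("cases", []))
    ids = [c.case_id for c in cases]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate case ids: {sorted(dupes)}")
    return PipelineConfig(cases=cases, **raw)


def _measure_case(case: CaseSpec, config: PipelineConfig):
    import nibabel as nib

    pre = read_mask(case.pre, MaskRole.TUMOR_PRE)
    post = read_mask(case.post, MaskRole.TUMOR_POST) if case.post else None
    brain = read_mask(case.brain, MaskRole.BRAIN) if case.brain else None
    contact_voxels = None
    if case.contact:
        contact_voxels = np.asanyarray(nib.load(case.contact).dataobj) != 0
    morph, resection = morphometry_pipeline(
        pre, post=post, brain=brain, config=config.morphometry_config(),
        contact_voxels=contact_voxels,
    )
    row = {
        "case_id": case.case_id,
        "volume_ml": morph.volume_ml,
        "tsa_cm2": morph.tsa_cm2,
        "csa_cm2": morph.csa_cm2,
        "si": morph.si,
        "av_per_cm": morph.av_per_cm,
        "dural_fraction": morph.dural_fraction,
        "eor_percent": resection.eor_percent if resection else np.nan,
        "eor_category": resection.category.value if resection else "",
    }
    return row


def run_pipeline(config: PipelineConfig) -> dict:
    """Measure all cases, log exclusions, and analyze if data allow.

    Returns a summary dict with counts and output paths.  Per-case
    failures never abort the run; only configuration problems do.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    ids = [c.case_id for c in config.cases]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate case ids: {sorted(dupes)}")

    rows, exclusions = [], []
    for case in config.cases:
        try:
            rows.append(_measure_case(case, config))
        except (MorphometryError, FileNotFoundError, ValueError) as exc:
            reason = str(exc)
            logger.warning("case %s excluded: %s", case.case_id, reason)
            exclusions.append({"case_id": case.case_id, "reason": reason})

    morph_df = pd.DataFrame(rows, columns=MORPHOMETRY_COLUMNS)
    morph_df = morph_df.sort_values("case_id", kind="stable").reset_index(drop=True)
    excl_df = pd.DataFrame(exclusions, columns=["case_id", "reason"])
    morph_path = out / "morphometry.csv"
    excl_path = out / "exclusions.csv"
    morph_df.to_csv(morph_path, index=False)
    excl_df.to_csv(excl_path, index=False)

    analysis_status = "skipped: no covariate table"
    report_path = None
    if config.covariates_csv:
        cov = pd.read_csv(config.covariates_csv)
        cohort = cov.merge(
            morph_df.drop(columns=["eor_percent", "eor_category"]),
            on="case_id", how="inner",
        )
        cohort_path = out / "cohort.csv"
        cohort.to_csv(cohort_path, index=False)
        if len(cohort) >= config.min_n_for_analysis:
            try:
                report = analysis_report(cohort, config.analysis_config())
                report_path = out / "report"
                _write_report(report, report_path)
                analysis_status = "ok"
            except AnalysisError as exc:
                analysis_status = f"failed: {exc}"
        else:
            analysis_status = (
                f"skipped: {len(cohort)} cases < min_n_for_analysis "
                f"({config.min_n_for_analysis})"
            )

    resolved = dataclasses.asdict(config)
    resolved["cases"] = [dataclasses.asdict(c) for c in config.cases]
    summary = {
        "n_cases": len(config.cases),
        "n_measured": len(morph_df),
        "n_excluded": len(excl_df),
        "analysis": analysis_status,
        "outputs": {
            "morphometry": str(morph_path),
            "exclusions": str(excl_path),
            "report": str(report_path) if report_path else None,
        },
    }
    with open(out / "config.resolved.json", "w") as fh:
        json.dump({"config": resolved, "summary": summary}, fh, indent=2)
    return summary


def _write_report(report: dict, report_dir: Path) -> None:
    report_dir.mkdir(parents=True, exist_ok=True)
    report["spearman"].to_csv(report_dir / "spearman.csv", index=False)
    report["group_tests"].to_csv(report_dir / "group_tests.csv", index=False)
    report["univariable_cox"].to_csv(report_dir / "univariable_cox.csv")
    for name, fit in report["multivariable"].items():
        fit.table.to_csv(report_dir / f"{name}.csv")
    summary = {
        "descriptive": report["descriptive"],
        "n": report["n"],
        "n_events": report["n_events"],
        "multivariable": {
            name: {
                "c_index": fit.c_index,
                "aic": fit.aic,
                "n_used": fit.n_used,
                "n_events": fit.n_events,
            }
            for name, fit in report["multivariable"].items()
        },
        "km_logrank_p": {
            key: (val["logrank_p"] if val else None)
            for key, val in report["km"].items()
        },
        "config": report["config"],
    }
    with open(report_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
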