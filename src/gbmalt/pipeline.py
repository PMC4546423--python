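"""End-to-end driver: cohort → maps → screen → features → diagnostics.

A single seed governs all randomness through per-patient sub-seeds, so a
cohort is bit-reproducible and any one patient can be regenerated alone.
Stages log their counts as they complete, mirroring the accrual cascade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .config import CohortConfig, save_config
from .diagnostics import (BONFERRONI_ALPHA, DiagnosticReport, evaluate_cohort)
from .errors import GbmaltError
from .features import extract_features
from .io import save_json
from .maps import compute_adc, compute_iauc_map, compute_ncbv
from .screen import (DEFAULT_NIL_FRACTION_CUTOFF, AccrualReport,
                     apply_accrual_filters, flag_signal_loss)
from .synthetic import PatientRecord, generate_cohort, generate_study

logger = logging.getLogger("gbmalt")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs: cohort, filters, statistics, seed, output."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    nil_fraction_cutoff: float = DEFAULT_NIL_FRACTION_CUTOFF
    alpha: float = BONFERRONI_ALPHA
    combined_threshold: str = "youden"
    screen_dsc_maps: bool = True
    output_dir: Optional[str] = None


@dataclass
class PipelineResult:
    records: List[PatientRecord]
    kept: List[PatientRecord]
    accrual: AccrualReport
    screen_table: pd.DataFrame
    features: pd.DataFrame
    report: DiagnosticReport


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except GbmaltError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis once and (optionally) write its artifacts."""
    records, _ = generate_cohort(config.cohort, config.seed)
    logger.info("generated cohort of %d records (seed %d)",
                len(records), config.seed)

    kept, accrual = _stage("screen")(apply_accrual_filters)(records)
    logger.info("accrual: %d/%d with both modalities interpretable, "
                "%d final", accrual.n_both_interpretable, accrual.n_input,
                accrual.n_final)

    kept_ids = {r.id for r in kept}
    screen_rows = []
    feature_rows = []
    for record in records:
        if not (config.screen_dsc_maps or record.id in kept_ids):
            continue
        study = _stage("simulate")(generate_study)(record, config.cohort)
        if config.screen_dsc_maps:
            ncbv = _stage("maps")(compute_ncbv)(study.dsc, study.nawm_mask)
            verdict = _stage("screen")(flag_signal_loss)(
                ncbv, study.lesion_mask_reader1, config.nil_fraction_cutoff)
            screen_rows.append({
                "patient": record.id, "label": record.label,
                "dsc_artifact_cause": record.artifact_cause,
                "dsc_nil_fraction": verdict.nil_fraction,
                "dsc_interpretable": verdict.interpretable,
                "dwi_interpretable": record.dwi_interpretable,
                "dce_interpretable": record.dce_interpretable,
            })
        if record.id not in kept_ids:
            continue
        adc_map = _stage("maps")(compute_adc)(study.dwi)
        iauc_map = _stage("maps")(compute_iauc_map)(
            study.dce, lesion_mask=study.lesion_mask_reader1)
        for reader, mask in (("1", study.lesion_mask_reader1),
                             ("2", study.lesion_mask_reader2)):
            fs = _stage("features")(extract_features)(
                adc_map, iauc_map, mask, reader=reader,
                patient=record.id, label=record.label)
            feature_rows.append({
                "patient": fs.patient, "reader": fs.reader,
                "label": fs.label, "adc10": fs.adc10,
                "iauc90": fs.iauc90, "n_voxels": fs.n_voxels})
    screen_table = pd.DataFrame(screen_rows)
    features = pd.DataFrame(feature_rows).sort_values(
        ["reader", "patient"], ignore_index=True)
    logger.info("extracted %d feature sets from %d patients",
                len(features), len(kept))

    report = _stage("evaluate")(evaluate_cohort)(
        features, alpha=config.alpha, threshold=config.combined_threshold)
    result = PipelineResult(records=records, kept=kept, accrual=accrual,
                            screen_table=screen_table, features=features,
                            report=report)
    if config.output_dir is not None:
        write_artifacts(result, config)
    return result


def write_artifacts(result: PipelineResult, config: PipelineConfig) -> None:
    """Write accrual, screening, feature and diagnostic artifacts.

    Outputs are byte-deterministic for a fixed seed (no timestamps).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_json(result.accrual.to_dict(), out / "accrual.json")
    if len(result.screen_table):
        result.screen_table.to_csv(out / "dsc_screen.csv", index=False)
    result.features.to_csv(out / "features.csv", index=False)
    save_json(result.report.to_dict(), out / "diagnostics.json")
    with open(out / "report.txt", "w") as fh:
        fh.write(result.accrual.to_text())
        fh.write("\n\n")
        fh.write(result.report.to_text())
        fh.write("\n")
    save_config(config.cohort, out / "cohort_config.yaml")
    logger.info("wrote artifacts to %s", out)
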