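"""Interpretability screening and accrual filtering.

A study is uninterpretable for a modality when signal loss wipes out the
contrast-enhancing lesion on that modality's parameter map. The accrual
filter reproduces the study-selection cascade: keep patients with both
fallback modalities (DWI and DCE) interpretable, then exclude steroid use
at imaging and missing follow-up reference imaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, NamedTuple, Tuple

from .core import ParameterMap
from .errors import DomainError, InputError
from .synthetic import PatientRecord

import numpy as np

#: A lesion with at least this fraction of nil voxels is uninterpretable.
DEFAULT_NIL_FRACTION_CUTOFF = 0.25


class SignalLossResult(NamedTuple):
    interpretable: bool
    nil_fraction: float


def flag_signal_loss(pmap: ParameterMap, lesion: np.ndarray,
                     nil_fraction_cutoff: float = DEFAULT_NIL_FRACTION_CUTOFF
                     ) -> SignalLossResult:
    """Fraction of lesion voxels with no defined map value, and the verdict.

    Operationalizes the qualitative "marked image degradation" call: the
    study is interpretable when fewer than ``nil_fraction_cutoff`` of the
    lesion's voxels are nil (signal loss).
    """
    lesion = np.asarray(lesion, dtype=bool)
    if lesion.shape != pmap.grid_shape:
        raise InputError("lesion mask must share the map grid")
    n = int(lesion.sum())
    if n == 0:
        raise DomainError("lesion mask is empty")
    nil_fraction = float((pmap.nil_mask & lesion).sum()) / n
    return SignalLossResult(nil_fraction < nil_fraction_cutoff, nil_fraction)


@dataclass(frozen=True)
class AccrualReport:
    """Stage counts of the accrual cascade."""

    n_input: int
    n_dsc_uninterpretable_hemorrhage: int
    n_dsc_uninterpretable_skull_base: int
    n_dwi_interpretable: int
    n_dce_interpretable: int
    n_both_interpretable: int
    n_steroid_excluded: int
    n_no_followup: int
    n_final: int

    def __post_init__(self) -> None:
        if self.n_final != (self.n_both_interpretable - self.n_steroid_excluded
                            - self.n_no_followup):
            raise InputError("final count inconsistent with exclusions")
        if self.n_both_interpretable > min(self.n_dwi_interpretable,
                                           self.n_dce_interpretable):
            raise InputError("joint interpretability exceeds a marginal count")

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def to_text(self) -> str:
        frac = lambda k: f"{100.0 * k / self.n_input:.1f}%" if self.n_input else "-"
        lines = [
            "Accrual cascade",
            f"  uninterpretable DSC studies          {self.n_input}",
            f"    cause: hemorrhage                  "
            f"{self.n_dsc_uninterpretable_hemorrhage} "
            f"({frac(self.n_dsc_uninterpretable_hemorrhage)})",
            f"    cause: skull-base proximity        "
            f"{self.n_dsc_uninterpretable_skull_base} "
            f"({frac(self.n_dsc_uninterpretable_skull_base)})",
            f"  interpretable DWI                    "
            f"{self.n_dwi_interpretable} ({frac(self.n_dwi_interpretable)})",
            f"  interpretable DCE                    "
            f"{self.n_dce_interpretable} ({frac(self.n_dce_interpretable)})",
            f"  interpretable DWI and DCE            "
            f"{self.n_both_interpretable} ({frac(self.n_both_interpretable)})",
            f"  excluded: steroids at imaging        {self.n_steroid_excluded}",
            f"  excluded: no follow-up reference     {self.n_no_followup}",
            f"  final analyzable patients            {self.n_final}",
        ]
        return "\n".join(lines)


def apply_accrual_filters(cohort: Iterable[PatientRecord]
                          ) -> Tuple[List[PatientRecord], AccrualReport]:
    """Keep patients with both modalities interpretable, no steroids, and
    follow-up available; count every stage. Idempotent."""
    records = list(cohort)
    both = [r for r in records if r.dwi_interpretable and r.dce_interpretable]
    steroid = [r for r in both if r.steroid]
    remaining = [r for r in both if not r.steroid]
    nofu = [r for r in remaining if not r.followup_available]
    kept = [r for r in remaining if r.followup_available]
    report = AccrualReport(
        n_input=len(records),
        n_dsc_uninterpretable_hemorrhage=sum(
            r.artifact_cause == "hemorrhage" for r in records),
        n_dsc_uninterpretable_skull_base=sum(
            r.artifact_cause == "skull_base" for r in records),
        n_dwi_interpretable=sum(r.dwi_interpretable for r in records),
        n_dce_interpretable=sum(r.dce_interpretable for r in records),
        n_both_interpretable=len(both),
        n_steroid_excluded=len(steroid),
        n_no_followup=len(nofu),
        n_final=len(kept),
    )
    return kept, report
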