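"""Lesion histogram features: cumulative-percentile cutoffs ADC10 and IAUC90.

Percentile cutoffs of the lesion-volume histogram are used instead of the
minimum/maximum because they are far less sensitive to random fluctuation:
the 10th percentile of ADC captures the densest (most cellular) tumor
component, the 90th percentile of IAUC the most permeable one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import ParameterMap
from .errors import FeatureUndefinedError, InputError, ParameterError


def cumulative_percentile(values: np.ndarray, q: float) -> float:
    """Linear-interpolation percentile of a multiset (q=0 → min, 100 → max)."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise FeatureUndefinedError("no values left after nil exclusion")
    if not 0.0 <= q <= 100.0:
        raise ParameterError("q must lie in [0, 100]")
    return float(np.percentile(values, q, method="linear"))


@dataclass(frozen=True)
class FeatureSet:
    """Per-patient, per-reader histogram features of one lesion."""

    patient: str
    reader: str
    adc10: float         # 10⁻³ mm²/s
    iauc90: float        # a.u.
    n_voxels: int
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_voxels <= 0:
            raise InputError("feature set needs at least one voxel")


def extract_features(adc_map: ParameterMap, iauc_map: ParameterMap,
                     lesion: np.ndarray, reader: str,
                     patient: str = "", label: Optional[str] = None
                     ) -> FeatureSet:
    """ADC10 and IAUC90 over a reader's lesion mask, excluding nil voxels.

    Voxels that are nil on either map (signal loss on either modality) are
    dropped from both histograms so the two features describe the same
    voxel population.
    """
    if adc_map.kind != "ADC":
        raise InputError(f"expected an ADC map, got {adc_map.kind}")
    if iauc_map.kind != "IAUC":
        raise InputError(f"expected an IAUC map, got {iauc_map.kind}")
    lesion = np.asarray(lesion, dtype=bool)
    if (lesion.shape != adc_map.grid_shape
            or lesion.shape != iauc_map.grid_shape):
        raise InputError("maps and lesion mask must share one grid")
    valid = lesion & ~adc_map.nil_mask & ~iauc_map.nil_mask
    n = int(valid.sum())
    if n == 0:
        raise FeatureUndefinedError(
            f"lesion of patient {patient!r} is fully nil; features undefined")
    return FeatureSet(
        patient=patient, reader=reader, label=label,
        adc10=cumulative_percentile(adc_map.values[valid], 10.0),
        iauc90=cumulative_percentile(iauc_map.values[valid], 90.0),
        n_voxels=n)
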