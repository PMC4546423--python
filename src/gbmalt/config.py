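"""Acquisition, class-distribution and cohort configuration.

The defaults encode the study conditions the pipeline is calibrated to: a
3 T dynamic contrast-enhanced (DCE) acquisition with 120 dynamics at 3.22 s
temporal resolution and 10 pre-contrast baseline dynamics, diffusion imaging
at b = 0 and 1000 s/mm², a dynamic susceptibility contrast (DSC) acquisition
with TE = 40 ms, and a 71-patient accrual structure in which every patient
has an uninterpretable DSC study (hemorrhage or skull-base signal loss) and
diffusion/permeability imaging serve as the fallback markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

import yaml

from .errors import ConfigurationError


@dataclass(frozen=True)
class AcquisitionConfig:
    """Timing and geometry of the dynamic and diffusion acquisitions.

    ``n_dynamics``/``n_baseline``/``dt`` describe the DCE series; the DSC
    series has its own (shorter, faster) dynamic sampling and an echo time
    ``te_dsc`` used to convert signal to ΔR2*.
    """

    n_dynamics: int = 120
    n_baseline: int = 10
    dt: float = 3.22                    # seconds per DCE dynamic
    te_dsc: float = 0.040               # seconds (gradient-echo EPI)
    b_values: Tuple[float, float] = (0.0, 1000.0)   # s/mm²
    grid_shape: Tuple[int, int, int] = (32, 32, 8)
    n_dynamics_dsc: int = 60
    n_baseline_dsc: int = 10
    dt_dsc: float = 1.808               # seconds per DSC dynamic

    def __post_init__(self) -> None:
        if self.n_dynamics <= 0 or self.dt <= 0:
            raise ConfigurationError("n_dynamics and dt must be positive")
        if not (0 < self.n_baseline < self.n_dynamics):
            raise ConfigurationError("need 0 < n_baseline < n_dynamics")
        if self.te_dsc <= 0:
            raise ConfigurationError("te_dsc must be positive")
        bv = sorted(self.b_values)
        if len(bv) != 2 or bv[0] != 0 or bv[1] <= 0:
            raise ConfigurationError("b_values must contain 0 and one positive value")
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ConfigurationError("grid_shape must be three positive extents")
        if self.n_dynamics_dsc <= 0 or self.dt_dsc <= 0:
            raise ConfigurationError("DSC dynamics and dt must be positive")
        if not (0 < self.n_baseline_dsc < self.n_dynamics_dsc):
            raise ConfigurationError("need 0 < n_baseline_dsc < n_dynamics_dsc")

    @property
    def b(self) -> float:
        """The non-zero diffusion weighting (s/mm²)."""
        return float(max(self.b_values))


@dataclass(frozen=True)
class ClassParams:
    """Gaussian feature model of one diagnostic class.

    ``iauc90`` in arbitrary units of normalized-SI·seconds; ``adc10`` in
    10⁻³ mm²/s. ``feature_correlation`` is the correlation between the two
    features within the class (0 = independent).
    """

    iauc90_mean: float
    iauc90_sd: float
    adc10_mean: float
    adc10_sd: float
    feature_correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.iauc90_sd <= 0 or self.adc10_sd <= 0:
            raise ConfigurationError("class SDs must be positive")
        if not -1.0 <= self.feature_correlation <= 1.0:
            raise ConfigurationError("feature_correlation must lie in [-1, 1]")


# Per-reader group calibration (cohort means ± SDs of lesion ADC10 and
# IAUC90 for tumor recurrence vs post-treatment effect). Reader 1 is the
# generator default; reader 2 is used by the cross-validation surrogates.
READER1_RECURRENCE = ClassParams(iauc90_mean=8.64, iauc90_sd=3.96,
                                 adc10_mean=0.96, adc10_sd=0.14)
READER1_POST_TREATMENT = ClassParams(iauc90_mean=5.84, iauc90_sd=2.63,
                                     adc10_mean=0.99, adc10_sd=0.19)
READER2_RECURRENCE = ClassParams(iauc90_mean=8.81, iauc90_sd=3.84,
                                 adc10_mean=0.96, adc10_sd=0.15)
READER2_POST_TREATMENT = ClassParams(iauc90_mean=5.95, iauc90_sd=2.62,
                                     adc10_mean=0.99, adc10_sd=0.21)


@dataclass(frozen=True)
class CohortConfig:
    """Counts and noise levels defining a synthetic accrual cohort.

    The default structure: 71 patients, all with uninterpretable DSC (54
    from intralesional hemorrhage, 17 from skull-base signal loss); 20 with
    uninterpretable DWI (14 from skull-base proximity, 6 from hemorrhage);
    12 with uninterpretable DCE, all of whom carry macro-hemorrhage and are
    a subset of the DWI-uninterpretable patients; 3 steroid exclusions and
    3 without follow-up among the 51 with both fallback modalities
    interpretable; 20 recurrence / 25 post-treatment among the final 45.
    """

    n_total: int = 71
    n_dsc_hemorrhage: int = 54
    n_dsc_skull_base: int = 17
    n_dwi_uninterp_skull_base: int = 14
    n_dwi_uninterp_hemorrhage: int = 6
    n_dce_uninterp: int = 12
    n_steroid: int = 3
    n_no_followup: int = 3
    n_recurrence_final: int = 20
    n_post_treatment_final: int = 25

    recurrence: ClassParams = READER1_RECURRENCE
    post_treatment: ClassParams = READER1_POST_TREATMENT

    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)

    # phantom geometry / noise
    lesion_radius_xy: float = 4.5       # voxels
    lesion_radius_z: float = 2.5
    artifact_lesion_fraction: float = 0.6
    dce_baseline: float = 100.0
    dce_noise_sd: float = 1.0           # a.u. on SI
    dwi_s0: float = 1000.0
    dwi_noise_sd: float = 7.0
    dsc_baseline: float = 600.0
    dsc_noise_sd: float = 3.0
    background_adc: float = 0.78        # 10⁻³ mm²/s, normal white matter
    reader_flip_prob: float = 0.1       # boundary-voxel flip probability

    def __post_init__(self) -> None:
        counts = (self.n_total, self.n_dsc_hemorrhage, self.n_dsc_skull_base,
                  self.n_dwi_uninterp_skull_base, self.n_dwi_uninterp_hemorrhage,
                  self.n_dce_uninterp, self.n_steroid, self.n_no_followup,
                  self.n_recurrence_final, self.n_post_treatment_final)
        if any(c < 0 for c in counts):
            raise ConfigurationError("cohort counts must be non-negative")
        if self.n_dsc_hemorrhage + self.n_dsc_skull_base != self.n_total:
            raise ConfigurationError("DSC artifact causes must partition the cohort")
        n_dwi_un = self.n_dwi_uninterp_skull_base + self.n_dwi_uninterp_hemorrhage
        if n_dwi_un > self.n_total:
            raise ConfigurationError("more DWI-uninterpretable patients than patients")
        # DCE-uninterpretable patients are nested inside the DWI-uninterpretable
        # set, and every one carries macro-hemorrhage.
        if self.n_dce_uninterp > n_dwi_un:
            raise ConfigurationError(
                "DCE-uninterpretable set must nest inside the DWI-uninterpretable set")
        if self.n_dce_uninterp < self.n_dwi_uninterp_hemorrhage:
            raise ConfigurationError(
                "hemorrhage-caused DWI losses must be DCE-uninterpretable too")
        if (self.n_dce_uninterp - self.n_dwi_uninterp_hemorrhage
                > self.n_dwi_uninterp_skull_base):
            raise ConfigurationError("not enough DWI-uninterpretable patients to "
                                     "carry the required macro-hemorrhages")
        if self.n_dwi_uninterp_hemorrhage > self.n_dsc_hemorrhage:
            raise ConfigurationError("hemorrhage DWI losses exceed hemorrhage patients")
        n_both = self.n_total - n_dwi_un
        n_final = n_both - self.n_steroid - self.n_no_followup
        if n_final < 0:
            raise ConfigurationError("exclusions exceed interpretable patients")
        if self.n_recurrence_final + self.n_post_treatment_final != n_final:
            raise ConfigurationError(
                f"final labels ({self.n_recurrence_final}+{self.n_post_treatment_final}) "
                f"must sum to the analyzable count {n_final}")
        if not 0 <= self.reader_flip_prob < 0.5:
            raise ConfigurationError("reader_flip_prob must lie in [0, 0.5)")

    @property
    def n_dwi_uninterpretable(self) -> int:
        return self.n_dwi_uninterp_skull_base + self.n_dwi_uninterp_hemorrhage

    @property
    def n_both_interpretable(self) -> int:
        return self.n_total - self.n_dwi_uninterpretable

    @property
    def n_final(self) -> int:
        return self.n_both_interpretable - self.n_steroid - self.n_no_followup


def _to_plain(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(config, path) -> None:
    """Write a config dataclass as a plain-text key/value (YAML) file."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)


def load_cohort_config(path) -> CohortConfig:
    """Read a :class:`CohortConfig` written by :func:`save_config`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "acquisition" in raw:
        acq = raw.pop("acquisition")
        for key in ("b_values", "grid_shape"):
            if key in acq and isinstance(acq[key], list):
                acq[key] = tuple(acq[key])
        raw["acquisition"] = AcquisitionConfig(**acq)
    for key in ("recurrence", "post_treatment"):
        if key in raw and isinstance(raw[key], dict):
            raw[key] = ClassParams(**raw[key])
    return CohortConfig(**raw)
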