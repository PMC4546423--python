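"""Seeded digital phantoms and whole accrual cohorts.

This module stands in for the raw clinical data: post-treatment glioblastoma
patients whose DSC perfusion study is uninterpretable (intralesional
hemorrhage or skull-base susceptibility signal loss) and who therefore rely
on diffusion (ADC10) and model-free permeability (IAUC90) markers. Class
separation is injected at the feature scale — each patient receives target
lesion IAUC90/ADC10 values drawn from the per-class Gaussian calibration —
and the voxelwise images are constructed so the map pipeline recovers those
targets on clean data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import AcquisitionConfig, ClassParams, CohortConfig
from .core import DiffusionPair, DynamicSeries
from .errors import BoundsError, ConfigurationError, DomainError, InputError
from .maps import compute_iauc, detect_arrival

RECURRENCE = "recurrence"
POST_TREATMENT = "post_treatment"

#: Gamma-variate wash-in shape for DCE enhancement: (s/tp)^α exp(α(1 − s/tp)),
#: unit peak at s = tp seconds after onset.
DCE_GAMMA_ALPHA = 1.5
DCE_GAMMA_TPEAK = 40.0
#: First-pass bolus shape for DSC (narrower, earlier peak) and a smaller,
#: delayed recirculation bump.
DSC_GAMMA_ALPHA = 3.0
DSC_GAMMA_TPEAK = 6.0
DSC_RECIRC_DELAY = 20.0
DSC_RECIRC_AMPLITUDE = 0.25
DSC_RECIRC_TPEAK = 12.0
DSC_PEAK_DR2 = 10.0        # s⁻¹ at unit relative blood volume
ARTIFACT_SI_FRACTION = 0.01


def gamma_variate(t: np.ndarray, t0: float, alpha: float,
                  t_peak: float) -> np.ndarray:
    """Unit-peak gamma-variate wash-in starting at ``t0``."""
    s = (np.asarray(t, dtype=float) - t0) / t_peak
    out = np.zeros_like(s)
    pos = s > 0
    out[pos] = s[pos] ** alpha * np.exp(alpha * (1.0 - s[pos]))
    return out


# ---------------------------------------------------------------------------
# records and studies

@dataclass
class PatientRecord:
    """Per-patient labels, artifact causes and interpretability flags.

    ``artifact_cause`` is the cause of the (always uninterpretable) DSC
    study; ``dwi_artifact_cause`` separately records what degraded DWI when
    it is uninterpretable — a skull-base lesion can lose DWI to proximity
    artifact while its DSC loss (and its DCE loss) stems from hemorrhage.
    """

    id: str
    label: str
    artifact_cause: str                  # hemorrhage | skull_base | none
    dwi_interpretable: bool
    dce_interpretable: bool
    steroid: bool
    followup_available: bool
    seed: int
    dwi_artifact_cause: str = "none"
    target_iauc90: float = float("nan")  # a.u., generator ground truth
    target_adc10: float = float("nan")   # 10⁻³ mm²/s

    def __post_init__(self) -> None:
        if self.label not in (RECURRENCE, POST_TREATMENT):
            raise InputError(f"unknown label {self.label!r}")
        if self.artifact_cause not in ("hemorrhage", "skull_base", "none"):
            raise InputError(f"unknown artifact cause {self.artifact_cause!r}")
        if self.artifact_cause == "skull_base" and not self.dce_interpretable:
            raise ConfigurationError(
                "DCE loss requires hemorrhage, not skull-base-only artifact")
        if self.dwi_interpretable and not self.dce_interpretable:
            raise ConfigurationError(
                "interpretable DWI implies interpretable DCE")


@dataclass
class PhantomStudy:
    """One patient's synthetic MR session plus masks and provenance."""

    dce: DynamicSeries
    dwi: DiffusionPair
    dsc: DynamicSeries
    lesion_mask_reader1: np.ndarray
    lesion_mask_reader2: np.ndarray
    nawm_mask: np.ndarray
    record: PatientRecord
    lesion_mask_true: np.ndarray = None
    artifact_region: np.ndarray = None

    def __post_init__(self) -> None:
        grid = self.dce.grid_shape
        for name in ("lesion_mask_reader1", "lesion_mask_reader2", "nawm_mask"):
            arr = np.asarray(getattr(self, name), dtype=bool)
            setattr(self, name, arr)
            if arr.shape != grid:
                raise InputError(f"{name} does not share the study grid")
        if self.dwi.grid_shape != grid or self.dsc.grid_shape != grid:
            raise InputError("all volumes must share one grid")
        for name in ("lesion_mask_reader1", "lesion_mask_reader2", "nawm_mask"):
            if not getattr(self, name).any():
                raise InputError(f"{name} is empty")
        for name in ("lesion_mask_reader1", "lesion_mask_reader2"):
            if (getattr(self, name) & self.nawm_mask).any():
                raise InputError("lesion and NAWM masks must be disjoint")


# ---------------------------------------------------------------------------
# curve / volume generators

def _unit_enhancement(acquisition: AcquisitionConfig) -> Tuple[np.ndarray, int, float]:
    """Sampled unit gamma-variate enhancement, its detected arrival sample,
    and its 30 s IAUC (used to calibrate amplitudes).

    Onset sits at the last baseline sample, so the first ``n_baseline``
    samples are exactly baseline and arrival detection fires at index
    ``n_baseline`` on clean data.
    """
    t = np.arange(acquisition.n_dynamics) * acquisition.dt
    t0 = (acquisition.n_baseline - 1) * acquisition.dt
    g = gamma_variate(t, t0, DCE_GAMMA_ALPHA, DCE_GAMMA_TPEAK)
    arrival = detect_arrival(g, acquisition.dt, acquisition.n_baseline)
    unit_iauc = compute_iauc(g, arrival, acquisition.dt, window_s=30.0)
    return g, arrival, unit_iauc


def generate_si_curve(class_amplitude: float, acquisition: AcquisitionConfig,
                      noise_sd: float, seed: Optional[int] = None,
                      baseline: float = 100.0) -> np.ndarray:
    """One DCE time–SI curve: flat baseline, gamma-variate wash-in, noise.

    The wash-in is scaled so that the noiseless baseline-normalized curve
    has a 30 s initial area of exactly ``class_amplitude`` under the
    package's own arrival/integration conventions.
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be non-negative")
    if class_amplitude < 0:
        raise DomainError("class_amplitude must be non-negative")
    g, _, unit_iauc = _unit_enhancement(acquisition)
    amp = class_amplitude / unit_iauc if class_amplitude > 0 else 0.0
    si = baseline * (1.0 + amp * g)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        si = si + rng.normal(0.0, noise_sd, si.shape)
    return np.maximum(si, 0.0)


def generate_dce_volume(amplitude_field: np.ndarray,
                        acquisition: AcquisitionConfig, noise_sd: float,
                        seed: Optional[int] = None,
                        baseline: float = 100.0) -> DynamicSeries:
    """4D DCE series whose voxel at amplitude a yields a noiseless IAUC of a."""
    amplitude_field = np.asarray(amplitude_field, dtype=float)
    if np.any(amplitude_field < 0):
        raise DomainError("enhancement amplitudes must be non-negative")
    g, _, unit_iauc = _unit_enhancement(acquisition)
    si = baseline * (1.0 + amplitude_field[..., None] / unit_iauc * g)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        si = si + rng.normal(0.0, noise_sd, si.shape)
    return DynamicSeries(np.maximum(si, 0.0), dt=acquisition.dt,
                         n_baseline=acquisition.n_baseline)


def generate_dwi_pair(adc_field: np.ndarray, s0: float = 1000.0,
                      b: float = 1000.0, noise_sd: float = 0.0,
                      seed: Optional[int] = None) -> DiffusionPair:
    """Invert the mono-exponential decay: S_b = S₀·exp(−b·ADC) + noise.

    ``adc_field`` is in 10⁻³ mm²/s. The same receiver noise sd applies to
    both volumes.
    """
    adc_field = np.asarray(adc_field, dtype=float)
    if np.any(adc_field < 0):
        raise DomainError("ADC must be non-negative everywhere")
    if s0 <= 0:
        raise DomainError("s0 must be positive")
    if noise_sd < 0:
        raise DomainError("noise_sd must be non-negative")
    vol0 = np.full(adc_field.shape, float(s0))
    volb = s0 * np.exp(-b * adc_field * 1e-3)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol0 = vol0 + rng.normal(0.0, noise_sd, vol0.shape)
        volb = volb + rng.normal(0.0, noise_sd, volb.shape)
    return DiffusionPair(np.maximum(vol0, 0.0), np.maximum(volb, 0.0), b=b)


def _dsc_shape(acquisition: AcquisitionConfig,
               recirculation: bool = True) -> np.ndarray:
    t = np.arange(acquisition.n_dynamics_dsc) * acquisition.dt_dsc
    t0 = (acquisition.n_baseline_dsc - 1) * acquisition.dt_dsc
    shape = gamma_variate(t, t0, DSC_GAMMA_ALPHA, DSC_GAMMA_TPEAK)
    if recirculation:
        shape = shape + DSC_RECIRC_AMPLITUDE * gamma_variate(
            t, t0 + DSC_RECIRC_DELAY, DSC_GAMMA_ALPHA, DSC_RECIRC_TPEAK)
    return shape


def generate_dsc_series(acquisition: AcquisitionConfig, artifact_cause: str,
                        artifact_region: np.ndarray,
                        seed: Optional[int] = None, *,
                        cbv_field: Optional[np.ndarray] = None,
                        baseline: float = 600.0, noise_sd: float = 0.0,
                        recirculation: bool = True) -> DynamicSeries:
    """4D DSC series with a first-pass bolus dip and signal-loss regions.

    Voxels in ``artifact_region`` (hemorrhage or skull-base susceptibility)
    hold near-zero SI in every dynamic — below the nil-baseline threshold —
    so downstream nCBV maps flag them nil. Elsewhere the bolus passage
    produces a transient ΔR2* rise (SI dip) proportional to ``cbv_field``.
    """
    grid = tuple(acquisition.grid_shape)
    artifact_region = np.asarray(artifact_region, dtype=bool)
    if artifact_region.shape != grid:
        raise BoundsError("artifact region does not match the acquisition grid")
    if artifact_cause == "none" and artifact_region.any():
        raise ConfigurationError("artifact_cause 'none' requires an empty region")
    if cbv_field is None:
        cbv_field = np.ones(grid)
    else:
        cbv_field = np.asarray(cbv_field, dtype=float)
        if cbv_field.shape != grid:
            raise InputError("cbv_field must match the acquisition grid")
    shape = _dsc_shape(acquisition, recirculation)
    dr2 = DSC_PEAK_DR2 * cbv_field[..., None] * shape
    si = baseline * np.exp(-acquisition.te_dsc * dr2)
    si[artifact_region] = ARTIFACT_SI_FRACTION * baseline
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, si.shape)
        noise[artifact_region] = 0.0     # dead voxels stay below the nil floor
        si = si + noise
    return DynamicSeries(np.maximum(si, 0.0), dt=acquisition.dt_dsc,
                         n_baseline=acquisition.n_baseline_dsc,
                         te=acquisition.te_dsc)


def simulate_reader_mask(mask: np.ndarray, boundary_flip_prob: float,
                         seed: Optional[int] = None) -> np.ndarray:
    """A reader's lesion segmentation: independent flips of boundary voxels.

    Stands in for human inter-reader variability in contrast-enhancing
    lesion segmentation; interior and far-exterior voxels are untouched.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DomainError("cannot perturb an empty mask")
    if not 0.0 <= boundary_flip_prob < 0.5:
        raise DomainError("boundary_flip_prob must lie in [0, 0.5)")
    if boundary_flip_prob == 0.0:
        return mask.copy()
    inner = mask & ~ndimage.binary_erosion(mask)
    outer = ndimage.binary_dilation(mask) & ~mask
    boundary = inner | outer
    rng = np.random.default_rng(seed)
    flips = boundary & (rng.random(mask.shape) < boundary_flip_prob)
    out = mask ^ flips
    if not out.any():        # degenerate tiny mask: keep at least the input core
        return mask.copy()
    return out


# ---------------------------------------------------------------------------
# geometry helpers

def ellipsoid_mask(grid: Tuple[int, int, int], center: Tuple[float, float, float],
                   radii: Tuple[float, float, float]) -> np.ndarray:
    idx = np.indices(grid, dtype=float)
    d = sum(((idx[i] - center[i]) / radii[i]) ** 2 for i in range(3))
    return d <= 1.0


def box_mask(grid: Tuple[int, int, int], lo: Tuple[int, int, int],
             hi: Tuple[int, int, int]) -> np.ndarray:
    out = np.zeros(grid, dtype=bool)
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return out


def artifact_subregion(lesion: np.ndarray, fraction: float,
                       cause: str) -> np.ndarray:
    """Subset of the lesion covering ``fraction`` of its voxels.

    Hemorrhage grows outward from the lesion centroid; skull-base loss
    grows inward from the low-x face (the face nearest the skull base).
    """
    coords = np.argwhere(lesion)
    n = coords.shape[0]
    k = int(round(fraction * n))
    region = np.zeros(lesion.shape, dtype=bool)
    if k == 0:
        return region
    if cause == "skull_base":
        order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
    else:
        centroid = coords.mean(axis=0)
        order = np.argsort(((coords - centroid) ** 2).sum(axis=1), kind="stable")
    chosen = coords[order[:k]]
    region[tuple(chosen.T)] = True
    return region


# ---------------------------------------------------------------------------
# cohort generation

def _draw_targets(rng: np.random.Generator, params: ClassParams,
                  n: int) -> Tuple[np.ndarray, np.ndarray]:
    """Correlated per-patient (IAUC90, ADC10) targets for one class."""
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    rho = params.feature_correlation
    iauc = params.iauc90_mean + params.iauc90_sd * z1
    adc = params.adc10_mean + params.adc10_sd * (
        rho * z1 + np.sqrt(max(0.0, 1.0 - rho ** 2)) * z2)
    return iauc, adc


def generate_cohort(config: CohortConfig, seed: int,
                    with_images: bool = False):
    """Generate a full accrual cohort.

    Returns ``(patients, accrual_table)`` where patients are
    :class:`PatientRecord` (or :class:`PhantomStudy` when ``with_images``)
    and the table counts each accrual stage. The default configuration
    yields 71 patients, 51 with both fallback modalities interpretable, and
    45 analyzable after steroid and follow-up exclusions (20 recurrence,
    25 post-treatment).
    """
    rng = np.random.default_rng(seed)
    n = config.n_total
    n_hem = config.n_dsc_hemorrhage

    # DSC artifact causes partition the cohort: [0, n_hem) hemorrhage,
    # the rest skull base.
    cause = np.array(["hemorrhage"] * n_hem
                     + ["skull_base"] * config.n_dsc_skull_base)
    dwi_cause = np.array(["none"] * n, dtype=object)
    dwi_ok = np.ones(n, dtype=bool)
    dce_ok = np.ones(n, dtype=bool)

    # DWI losses: n_dwi_uninterp_hemorrhage hemorrhage-caused (drawn from the
    # hemorrhage patients) plus n_dwi_uninterp_skull_base skull-base-caused.
    # Of the skull-base-caused DWI losses, enough are drawn from hemorrhage
    # patients that every DCE-uninterpretable case carries macro-hemorrhage
    # while remaining nested inside the DWI-uninterpretable set.
    hem_idx = rng.permutation(n_hem)
    sb_idx = n_hem + rng.permutation(config.n_dsc_skull_base)
    n_c = config.n_dwi_uninterp_hemorrhage
    n_b = config.n_dce_uninterp - n_c          # skull-base DWI loss + hemorrhage
    n_a = config.n_dwi_uninterp_skull_base - n_b
    grp_c = hem_idx[:n_c]
    grp_b = hem_idx[n_c:n_c + n_b]
    grp_a = sb_idx[:n_a]
    dwi_cause[grp_c] = "hemorrhage"
    dwi_cause[np.concatenate([grp_b, grp_a]).astype(int)] = "skull_base"
    dwi_ok[np.concatenate([grp_a, grp_b, grp_c]).astype(int)] = False
    dce_ok[np.concatenate([grp_b, grp_c]).astype(int)] = False

    steroid = np.zeros(n, dtype=bool)
    followup = np.ones(n, dtype=bool)
    both = np.flatnonzero(dwi_ok & dce_ok)
    both = rng.permutation(both)
    steroid[both[:config.n_steroid]] = True
    stop = config.n_steroid + config.n_no_followup
    followup[both[config.n_steroid:stop]] = False
    final = both[stop:]

    labels = np.array([POST_TREATMENT] * n, dtype=object)
    final_labels = np.array([RECURRENCE] * config.n_recurrence_final
                            + [POST_TREATMENT] * config.n_post_treatment_final,
                            dtype=object)
    labels[final] = rng.permutation(final_labels)
    excluded = np.setdiff1d(np.arange(n), final)
    if excluded.size and (config.n_recurrence_final
                          + config.n_post_treatment_final) > 0:
        p_rec = config.n_recurrence_final / max(config.n_final, 1)
        labels[excluded] = np.where(rng.random(excluded.size) < p_rec,
                                    RECURRENCE, POST_TREATMENT)

    # feature targets by class
    iauc = np.empty(n)
    adc = np.empty(n)
    for lab, params in ((RECURRENCE, config.recurrence),
                        (POST_TREATMENT, config.post_treatment)):
        sel = labels == lab
        iauc[sel], adc[sel] = _draw_targets(rng, params, int(sel.sum()))

    seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    order = rng.permutation(n)
    records: List[PatientRecord] = []
    for rank, i in enumerate(order):
        records.append(PatientRecord(
            id=f"P{rank + 1:03d}", label=str(labels[i]),
            artifact_cause=str(cause[i]), dwi_artifact_cause=str(dwi_cause[i]),
            dwi_interpretable=bool(dwi_ok[i]), dce_interpretable=bool(dce_ok[i]),
            steroid=bool(steroid[i]), followup_available=bool(followup[i]),
            seed=int(seeds[i]),
            target_iauc90=float(iauc[i]), target_adc10=float(adc[i])))

    accrual = cohort_accrual_table(records)
    if with_images:
        studies = [generate_study(rec, config) for rec in records]
        return studies, accrual
    return records, accrual


def cohort_accrual_table(records: List[PatientRecord]) -> pd.DataFrame:
    """Stage-by-stage accrual counts for a list of records."""
    n = len(records)
    dwi_ok = sum(r.dwi_interpretable for r in records)
    dce_ok = sum(r.dce_interpretable for r in records)
    both = sum(r.dwi_interpretable and r.dce_interpretable for r in records)
    steroid = sum(r.steroid for r in records
                  if r.dwi_interpretable and r.dce_interpretable)
    nofu = sum(not r.followup_available for r in records
               if r.dwi_interpretable and r.dce_interpretable and not r.steroid)
    final = both - steroid - nofu
    rows = [
        ("patients with uninterpretable DSC", n),
        ("DSC loss from hemorrhage",
         sum(r.artifact_cause == "hemorrhage" for r in records)),
        ("DSC loss from skull-base proximity",
         sum(r.artifact_cause == "skull_base" for r in records)),
        ("interpretable DWI", dwi_ok),
        ("interpretable DCE", dce_ok),
        ("interpretable DWI and DCE", both),
        ("excluded: steroid at imaging", steroid),
        ("excluded: no follow-up reference", nofu),
        ("final analyzable patients", final),
    ]
    return pd.DataFrame(rows, columns=["stage", "count"])


def generate_study(record: PatientRecord, config: CohortConfig) -> PhantomStudy:
    """Materialize one patient's phantom volumes from their record."""
    acq = config.acquisition
    grid = tuple(acq.grid_shape)
    rng = np.random.default_rng(record.seed)
    sub = rng.integers(0, 2 ** 31 - 1, size=6)

    near_edge = (record.artifact_cause == "skull_base"
                 or record.dwi_artifact_cause == "skull_base")
    cx = config.lesion_radius_xy + 1.0 if near_edge else grid[0] / 2.0
    center = (cx, grid[1] / 2.0, (grid[2] - 1) / 2.0)
    radii = (config.lesion_radius_xy, config.lesion_radius_xy,
             config.lesion_radius_z)
    lesion = ellipsoid_mask(grid, center, radii)
    nawm = box_mask(grid, (grid[0] - 6, grid[1] // 2 - 3, 2),
                    (grid[0] - 1, grid[1] // 2 + 3, grid[2] - 2))
    if (lesion & nawm).any():
        raise ConfigurationError("lesion and NAWM geometry overlap; "
                                 "shrink the lesion radius or the grid")

    n_les = int(lesion.sum())
    target_iauc = max(record.target_iauc90, 0.1)
    target_adc = max(record.target_adc10, 0.2)

    # amplitude profiles normalized so the lesion percentile hits the target
    prof = rng.uniform(0.4, 1.1, n_les)
    prof /= np.percentile(prof, 90)
    amp = np.zeros(grid)
    amp[lesion] = target_iauc * prof

    adc_prof = rng.uniform(1.0, 1.6, n_les)
    adc_prof /= np.percentile(adc_prof, 10)
    adc_field = np.full(grid, config.background_adc)
    adc_field += rng.uniform(-0.04, 0.04, grid)
    # enhancing lesions sit inside a rim of vasogenic edema (elevated ADC),
    # so boundary voxels a reader includes by mistake do not drag the 10th
    # percentile toward white matter
    edema = ndimage.binary_dilation(lesion, iterations=2) & ~lesion
    adc_field[edema] = rng.uniform(1.15, 1.45, int(edema.sum()))
    adc_field[lesion] = target_adc * adc_prof

    artifact = artifact_subregion(lesion, config.artifact_lesion_fraction,
                                  record.artifact_cause)

    dce = generate_dce_volume(amp, acq, config.dce_noise_sd, seed=int(sub[0]),
                              baseline=config.dce_baseline)
    if not record.dce_interpretable:
        dce.si[artifact] = ARTIFACT_SI_FRACTION * config.dce_baseline

    dwi = generate_dwi_pair(adc_field, s0=config.dwi_s0, b=acq.b,
                            noise_sd=config.dwi_noise_sd, seed=int(sub[1]))
    if not record.dwi_interpretable:
        dwi.s0[artifact] = ARTIFACT_SI_FRACTION * config.dwi_s0
        dwi.sb[artifact] = ARTIFACT_SI_FRACTION * config.dwi_s0

    cbv = np.ones(grid)
    cbv[lesion] = 1.5 if record.label == RECURRENCE else 1.1
    dsc = generate_dsc_series(acq, record.artifact_cause, artifact,
                              seed=int(sub[2]), cbv_field=cbv,
                              baseline=config.dsc_baseline,
                              noise_sd=config.dsc_noise_sd)

    r1 = simulate_reader_mask(lesion, config.reader_flip_prob, seed=int(sub[3]))
    r2 = simulate_reader_mask(lesion, config.reader_flip_prob, seed=int(sub[4]))
    r1 &= ~nawm
    r2 &= ~nawm

    return PhantomStudy(dce=dce, dwi=dwi, dsc=dsc,
                        lesion_mask_reader1=r1, lesion_mask_reader2=r2,
                        nawm_mask=nawm, record=record,
                        lesion_mask_true=lesion, artifact_region=artifact)
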