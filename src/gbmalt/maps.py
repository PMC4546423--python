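"""Voxelwise parameter maps: model-free IAUC, ADC, and leakage-corrected nCBV.

The DCE analysis is model-free: each voxel's time–signal-intensity curve is
low-pass smoothed, normalized to its pre-contrast baseline (baseline set to
zero), and integrated over the first 30 s after contrast arrival (IAUC).
ADC comes from the mono-exponential decay between the b=0 and b=1000 s/mm²
volumes. DSC relative CBV integrates ΔR2*(t) = −ln(S/S₀)/TE over the first
pass after a two-parameter linear leakage correction, and is normalized to
contralateral normal-appearing white matter (NAWM).
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .core import DiffusionPair, DynamicSeries, ParameterMap
from .errors import (ConfigurationError, InputError, NilVoxelError,
                     ParameterError, TruncationError)

#: Baseline SI below this fraction of the within-brain median baseline marks
#: a signal-loss (nil) voxel.
NIL_BASELINE_FRACTION = 0.05


# ---------------------------------------------------------------------------
# temporal smoothing

def smooth_lowpass(curve: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average along the last axis with edge replication.

    Reduces noise and spikes in dynamic SI curves without shifting the
    curve. At the default window of 3 the replicated edges make the filter
    exactly mass-conserving (output mean equals input mean).
    """
    curve = np.asarray(curve, dtype=float)
    if window <= 0 or window % 2 == 0:
        raise ParameterError("window must be a positive odd integer")
    if window > curve.shape[-1]:
        raise ParameterError("window exceeds the curve length")
    if window == 1:
        return curve.copy()
    k = window // 2
    pad_lo = np.repeat(curve[..., :1], k, axis=-1)
    pad_hi = np.repeat(curve[..., -1:], k, axis=-1)
    padded = np.concatenate([pad_lo, curve, pad_hi], axis=-1)
    zeros = np.zeros(padded.shape[:-1] + (1,))
    cs = np.concatenate([zeros, np.cumsum(padded, axis=-1)], axis=-1)
    return (cs[..., window:] - cs[..., :-window]) / window


# ---------------------------------------------------------------------------
# baseline normalization

def _normalize_nd(curves: np.ndarray, n_baseline: int,
                  baseline_floor: float = 0.0) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized baseline normalization; returns (normalized, nil_mask)."""
    base = curves[..., :n_baseline].mean(axis=-1)
    nil = base <= max(baseline_floor, 0.0)
    safe = np.where(nil, 1.0, base)
    norm = (curves - base[..., None]) / safe[..., None]
    norm[nil] = 0.0
    return norm, nil


def normalize_baseline(curve: np.ndarray, n_baseline: int) -> np.ndarray:
    """Normalize one SI curve to its pre-contrast baseline.

    Output is (SI − baseline)/baseline, so the baseline sits at zero and
    enhancement is a fraction of the pre-contrast signal. A non-positive
    baseline mean marks a signal-loss voxel and raises :class:`NilVoxelError`.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 1:
        raise InputError("normalize_baseline expects a single 1-D curve")
    if not 2 <= n_baseline <= curve.shape[-1]:
        raise ParameterError("n_baseline must lie in [2, len(curve)]")
    base = curve[:n_baseline].mean()
    if base <= 0:
        raise NilVoxelError("non-positive baseline mean: signal-loss voxel")
    return (curve - base) / base


# ---------------------------------------------------------------------------
# contrast arrival

def _detect_arrival_nd(curves: np.ndarray, n_baseline: int,
                       k_sd: float = 3.0) -> np.ndarray:
    """Smallest post-baseline index whose value exceeds baseline mean +
    k·SD for two consecutive points; falls back to ``n_baseline``."""
    base = curves[..., :n_baseline]
    thresh = base.mean(axis=-1) + k_sd * base.std(axis=-1)
    exceed = curves > thresh[..., None]
    two = exceed[..., :-1] & exceed[..., 1:]
    two[..., :n_baseline] = False
    found = two.any(axis=-1)
    idx = np.argmax(two, axis=-1)
    return np.where(found, idx, n_baseline)


def detect_arrival(curve: np.ndarray, dt: float, n_baseline: int,
                   k_sd: float = 3.0) -> int:
    """Detect the contrast-arrival sample of a baseline-normalized curve."""
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 1:
        raise InputError("detect_arrival expects a single 1-D curve")
    if dt <= 0:
        raise ParameterError("dt must be positive")
    return int(_detect_arrival_nd(curve, n_baseline, k_sd))


# ---------------------------------------------------------------------------
# initial area under the curve

def _iauc_nd(curves: np.ndarray, arrivals: np.ndarray, dt: float,
             window_s: float, method: str) -> np.ndarray:
    """IAUC over ``window_s`` seconds from per-voxel arrival samples.

    Trapezoidal (default) or rectangular summation; the 30 s boundary
    rarely falls on a sample, so the final partial interval is handled by
    linear interpolation between the bracketing samples (the last sample is
    replicated if the boundary extends one interpolation step beyond it).
    """
    if method not in ("trapezoid", "rectangle"):
        raise ParameterError(f"unknown integration method {method!r}")
    n_t = curves.shape[-1]
    n_span = window_s / dt
    n_full = int(np.floor(n_span + 1e-12))
    frac = n_span - n_full
    if frac < 1e-12:
        frac = 0.0
    arrivals = np.asarray(arrivals)
    if np.any(arrivals + n_full > n_t - 1):
        raise TruncationError(
            f"{window_s} s window from arrival extends beyond the acquisition")
    n_pts = n_full + (2 if frac > 0 else 1)
    idx = arrivals[..., None] + np.arange(n_pts)
    np.clip(idx, 0, n_t - 1, out=idx)    # only the interpolation helper sample
    vals = np.take_along_axis(curves, idx, axis=-1)
    if method == "trapezoid":
        full = np.trapezoid(vals[..., :n_full + 1], dx=dt, axis=-1)
        if frac > 0:
            v0 = vals[..., n_full]
            v1 = vals[..., n_full + 1]
            v_end = v0 + frac * (v1 - v0)
            full = full + 0.5 * (v0 + v_end) * frac * dt
        return full
    total = vals[..., :n_full].sum(axis=-1) * dt
    if frac > 0:
        total = total + vals[..., n_full] * frac * dt
    return total


def compute_iauc(curve: np.ndarray, arrival: int, dt: float,
                 window_s: float = 30.0, method: str = "trapezoid") -> float:
    """Initial area under one baseline-normalized curve (normalized-SI·s)."""
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 1:
        raise InputError("compute_iauc expects a single 1-D curve")
    if dt <= 0 or window_s <= 0:
        raise ParameterError("dt and window_s must be positive")
    return float(_iauc_nd(curve, np.asarray(arrival), dt, window_s, method))


def compute_iauc_map(series: DynamicSeries, *,
                     lesion_mask: Optional[np.ndarray] = None,
                     arrival: Optional[int] = None,
                     smooth_window: int = 3,
                     k_sd: float = 3.0,
                     window_s: float = 30.0,
                     method: str = "trapezoid",
                     per_voxel_arrival: bool = False) -> ParameterMap:
    """Voxelwise IAUC map from a DCE series.

    Arrival is estimated once from the mean normalized curve over
    ``lesion_mask`` (or over all non-nil voxels) unless an explicit sample
    index is given: bolus arrival is a global event, and a single high-SNR
    estimate avoids the late-detection bias that per-voxel thresholding
    shows in weakly enhancing voxels. Set ``per_voxel_arrival`` to detect
    independently per voxel instead.
    """
    shape = series.grid_shape
    flat = series.si.reshape(-1, series.n_dynamics)
    smoothed = smooth_lowpass(flat, smooth_window)
    base = smoothed[:, :series.n_baseline].mean(axis=1)
    positive = base[base > 0]
    floor = NIL_BASELINE_FRACTION * np.median(positive) if positive.size else 0.0
    norm, nil = _normalize_nd(smoothed, series.n_baseline, baseline_floor=floor)

    if arrival is not None:
        arrivals = np.full(norm.shape[0], int(arrival))
    elif per_voxel_arrival:
        arrivals = _detect_arrival_nd(norm, series.n_baseline, k_sd)
    else:
        if lesion_mask is not None:
            ref_sel = np.asarray(lesion_mask, bool).reshape(-1) & ~nil
        else:
            ref_sel = ~nil
        if ref_sel.any():
            ref_curve = norm[ref_sel].mean(axis=0)
            global_arrival = int(_detect_arrival_nd(ref_curve,
                                                    series.n_baseline, k_sd))
        else:
            global_arrival = series.n_baseline
        arrivals = np.full(norm.shape[0], global_arrival)

    values = _iauc_nd(norm, arrivals, series.dt, window_s, method)
    values[nil] = 0.0
    return ParameterMap(values.reshape(shape), kind="IAUC",
                        nil_mask=nil.reshape(shape))


# ---------------------------------------------------------------------------
# apparent diffusion coefficient

def compute_adc(pair: DiffusionPair) -> ParameterMap:
    """Mono-exponential ADC map in 10⁻³ mm²/s: ADC = ln(S₀/S_b)/b.

    Voxels with non-positive signal, S_b above S₀ (negative ADC), or b=0
    signal under the signal-loss floor are flagged nil.
    """
    s0, sb, b = pair.s0, pair.sb, pair.b
    positive = s0[s0 > 0]
    floor = NIL_BASELINE_FRACTION * np.median(positive) if positive.size else 0.0
    nil = (s0 <= 0) | (sb <= 0) | (sb > s0) | (s0 < floor)
    values = np.zeros(s0.shape)
    ok = ~nil
    values[ok] = np.log(s0[ok] / sb[ok]) / b * 1e3
    return ParameterMap(values, kind="ADC", nil_mask=nil)


# ---------------------------------------------------------------------------
# DSC relative CBV with recirculation elimination and leakage correction

def _first_pass_window(ref: np.ndarray, n_baseline: int,
                       cut: float = 0.1) -> slice:
    """Contiguous first-pass window around the bolus peak of a reference
    ΔR2* curve, cut where the curve drops below ``cut``×peak; this excludes
    recirculation bumps separated from the first pass."""
    n_t = ref.shape[0]
    post = ref[n_baseline:]
    if post.size == 0 or np.max(post) <= 0:
        return slice(n_baseline, n_t)
    peak = int(np.argmax(post)) + n_baseline
    level = cut * ref[peak]
    lo = peak
    while lo > 0 and ref[lo - 1] >= level:
        lo -= 1
    hi = peak
    while hi < n_t - 1 and ref[hi + 1] >= level:
        hi += 1
    return slice(max(lo - 1, 0), min(hi + 1, n_t - 1) + 1)


def compute_ncbv(dsc: DynamicSeries, nawm_mask: np.ndarray, *,
                 brain_mask: Optional[np.ndarray] = None,
                 leakage_correction: bool = True,
                 recirculation_cut: float = 0.1,
                 nil_fraction: float = NIL_BASELINE_FRACTION) -> ParameterMap:
    """Leakage-corrected relative CBV normalized to NAWM.

    Per voxel, ΔR2*(t) = −ln(S(t)/S_baseline)/TE. The whole-brain mean
    ΔR2* curve serves as the non-leaky reference; recirculation is
    eliminated by integrating only over the contiguous first-pass window of
    that reference. Leakage is corrected with the standard two-parameter
    linear model — each voxel's curve is regressed on the reference curve
    and its running integral, ΔR2*_v(t) ≈ K1·R(t) − K2·∫R — and the
    corrected blood volume is K1·∫R. The map is divided by its mean over
    ``nawm_mask`` so NAWM averages exactly 1.
    """
    if dsc.te is None or dsc.te <= 0:
        raise ConfigurationError("DSC series needs a positive echo time te")
    nawm_mask = np.asarray(nawm_mask, dtype=bool)
    if nawm_mask.shape != dsc.grid_shape:
        raise InputError("NAWM mask must share the series grid")
    if not nawm_mask.any():
        raise ConfigurationError("NAWM mask is empty")
    if brain_mask is None:
        brain = np.ones(dsc.grid_shape, dtype=bool)
    else:
        brain = np.asarray(brain_mask, dtype=bool)
        if brain.shape != dsc.grid_shape:
            raise InputError("brain mask must share the series grid")

    n_b = dsc.n_baseline
    flat = dsc.si.reshape(-1, dsc.n_dynamics)
    base = flat[:, :n_b].mean(axis=1)
    brain_flat = brain.reshape(-1)
    positive = base[brain_flat & (base > 0)]
    floor = nil_fraction * np.median(positive) if positive.size else 0.0
    nil = (base <= max(floor, 0.0))

    safe_base = np.where(nil, 1.0, base)
    eps = np.finfo(float).tiny
    dr2 = -np.log(np.maximum(flat, eps) / safe_base[:, None]) / dsc.te
    dr2[nil] = 0.0

    ok = brain_flat & ~nil
    if not ok.any():
        raise ConfigurationError("no usable voxels inside the brain mask")
    ref = dr2[ok].mean(axis=0)
    win = _first_pass_window(ref, n_b, recirculation_cut)
    r = ref[win]
    dx = dsc.dt
    ref_integral = np.trapezoid(r, dx=dx)

    if leakage_correction and ref_integral > 0:
        c = cumulative_trapezoid(r, dx=dx, initial=0.0)
        y = dr2[:, win]
        g11 = float(r @ r)
        g12 = float(r @ c)
        g22 = float(c @ c)
        det = g11 * g22 - g12 * g12
        b1 = y @ r
        b2 = y @ c
        if det > 1e-12 * max(g11 * g22, 1e-300):
            k1 = (g22 * b1 - g12 * b2) / det
        else:                         # degenerate basis: plain projection
            k1 = b1 / g11 if g11 > 0 else np.zeros(y.shape[0])
        rcbv = k1 * ref_integral
    else:
        rcbv = np.trapezoid(dr2[:, win], dx=dx, axis=1)
    rcbv = np.maximum(rcbv, 0.0)
    rcbv[nil] = 0.0

    nawm_ok = nawm_mask.reshape(-1) & ~nil
    if not nawm_ok.any():
        raise ConfigurationError("NAWM mask contains only signal-loss voxels")
    denom = rcbv[nawm_ok].mean()
    if denom <= 0:
        raise ConfigurationError("NAWM mean rCBV is non-positive")
    ncbv = rcbv / denom
    shape = dsc.grid_shape
    return ParameterMap(ncbv.reshape(shape), kind="nCBV",
                        nil_mask=nil.reshape(shape))
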