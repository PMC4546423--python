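"""In-memory containers for dynamic series, diffusion pairs and parameter maps."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigurationError, InputError

#: Units reported in sidecars and headers, by map kind.
MAP_UNITS = {
    "ADC": "1e-3 mm^2/s",
    "IAUC": "a.u. (normalized SI * s)",
    "rCBV": "a.u.",
    "nCBV": "ratio (NAWM = 1)",
}


@dataclass
class DynamicSeries:
    """A 4D dynamic signal-intensity stack with temporal metadata.

    ``si`` is (x, y, z, t) in arbitrary units; ``dt`` the dynamic interval in
    seconds; ``n_baseline`` the number of pre-contrast dynamics; ``te`` the
    echo time in seconds (needed for DSC ΔR2* conversion only).
    """

    si: np.ndarray
    dt: float
    n_baseline: int
    te: Optional[float] = None

    def __post_init__(self) -> None:
        self.si = np.asarray(self.si, dtype=float)
        if self.si.ndim != 4:
            raise InputError("si must be a 4D (x, y, z, t) array")
        if not np.all(np.isfinite(self.si)) or np.any(self.si < 0):
            raise InputError("all SI values must be finite and non-negative")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.n_baseline < 2:
            raise ConfigurationError("need at least 2 baseline dynamics")
        if self.n_baseline >= self.si.shape[-1]:
            raise ConfigurationError("n_baseline must be below n_dynamics")

    @property
    def grid_shape(self):
        return self.si.shape[:3]

    @property
    def n_dynamics(self) -> int:
        return self.si.shape[-1]


@dataclass
class DiffusionPair:
    """Co-registered b=0 and b>0 diffusion volumes."""

    s0: np.ndarray
    sb: np.ndarray
    b: float

    def __post_init__(self) -> None:
        self.s0 = np.asarray(self.s0, dtype=float)
        self.sb = np.asarray(self.sb, dtype=float)
        if self.s0.shape != self.sb.shape:
            raise InputError("b=0 and diffusion-weighted volumes must share a grid")
        if self.b <= 0:
            raise InputError("diffusion weighting b must be positive")

    @property
    def grid_shape(self):
        return self.s0.shape


@dataclass
class ParameterMap:
    """A 3D scalar map plus a nil mask of voxels with no defined value.

    ``kind`` is one of ``ADC`` (10⁻³ mm²/s), ``IAUC`` (a.u.), ``rCBV``
    (a.u.) or ``nCBV`` (ratio to normal-appearing white matter). Nil voxels
    (signal loss, undefined logs) hold 0 in ``values`` and are excluded from
    every downstream histogram.
    """

    values: np.ndarray
    kind: str
    nil_mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InputError("parameter map must be 3D")
        if self.kind not in MAP_UNITS:
            raise InputError(f"unknown map kind {self.kind!r}")
        if self.nil_mask is None:
            self.nil_mask = np.zeros(self.values.shape, dtype=bool)
        self.nil_mask = np.asarray(self.nil_mask, dtype=bool)
        if self.nil_mask.shape != self.values.shape:
            raise InputError("nil_mask must share the map grid")

    @property
    def units(self) -> str:
        return MAP_UNITS[self.kind]

    @property
    def grid_shape(self):
        return self.values.shape

    def valid_values(self, mask: Optional[np.ndarray] = None) -> np.ndarray:
        """Non-nil values, optionally restricted to a boolean mask."""
        keep = ~self.nil_mask
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.values.shape:
                raise InputError("mask must share the map grid")
            keep &= mask
        return self.values[keep]
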