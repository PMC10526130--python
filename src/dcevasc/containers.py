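"""In-memory containers shared by all pipeline stages.

Axis convention: image arrays are indexed (x, y, z) and dynamic series
(x, y, z, t).  ``frame_times`` are seconds from the start of the dynamic
series; ``voxel_spacing`` is millimetres per axis.  World coordinates are
never used by the algorithms, only voxel indices and spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "DCESeries",
    "ConcentrationSeries",
    "VolumeImage",
    "AIF",
    "TumorMask",
    "ParamMaps",
    "SemiQuantMaps",
    "FractalMap",
    "NO_ONSET",
]

#: Sentinel for voxels/curves in which no contrast arrival was detected.
NO_ONSET: float = -1.0

VOLUME_ROLES = (
    "breast_coil_T1w",
    "body_coil_T1w",
    "mask",
    "parameter_map",
    "subtraction",
)


def _check_times(frame_times: np.ndarray, n_frames: int) -> np.ndarray:
    t = np.asarray(frame_times, dtype=float)
    if t.ndim != 1 or t.size != n_frames:
        raise ValueError(
            f"frame_times must be 1-D with length {n_frames}, got shape {t.shape}"
        )
    if not np.all(np.diff(t) > 0):
        raise ValueError("frame_times must be strictly increasing")
    return t


def _check_spacing(spacing) -> tuple[float, float, float]:
    s = tuple(float(v) for v in spacing)
    if len(s) != 3 or any(v <= 0 for v in s):
        raise ValueError(f"voxel_spacing must be three positive values, got {spacing}")
    return s


@dataclass
class DCESeries:
    """4-D dynamic series in scanner signal units.

    data : ndarray, shape (x, y, z, t)
    frame_times : seconds from the start of the acquisition
    voxel_spacing : mm per axis
    meta : free-form provenance (subject id, arm, timepoint, settings)
    """

    data: np.ndarray
    frame_times: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.5)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"DCESeries data must be 4-D, got {self.data.ndim}-D")
        self.frame_times = _check_times(self.frame_times, self.data.shape[3])
        self.voxel_spacing = _check_spacing(self.voxel_spacing)

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def with_data(self, data: np.ndarray) -> "DCESeries":
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class ConcentrationSeries(DCESeries):
    """4-D tracer-concentration series in mM (mmol/L).

    Same geometry as the :class:`DCESeries` it was derived from; the
    pre-injection frames are ~0 after a correct signal conversion.
    """


@dataclass
class VolumeImage:
    """A single 3-D volume with an explicit role (mask, subtraction, ...)."""

    data: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.5)
    role: str = "parameter_map"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VolumeImage data must be 3-D, got {self.data.ndim}-D")
        if self.role not in VOLUME_ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {VOLUME_ROLES}")
        if self.role == "mask":
            self.data = self.data.astype(bool)
        else:
            self.data = self.data.astype(float)
            if not np.all(np.isfinite(self.data)):
                raise ValueError("VolumeImage data must be finite")
        self.voxel_spacing = _check_spacing(self.voxel_spacing)


@dataclass
class AIF:
    """Arterial input function: plasma tracer concentration vs. time.

    cp is in mM, times in seconds.  ``hematocrit_used`` records whether the
    blood→plasma correction cp = cb/(1-Hct) was applied; ``n_subjects`` is
    the number of curves averaged into a population AIF.
    """

    times: np.ndarray
    cp: np.ndarray
    hematocrit_used: Optional[float] = None
    n_subjects: int = 1

    def __post_init__(self):
        self.cp = np.asarray(self.cp, dtype=float)
        self.times = _check_times(self.times, self.cp.size)
        if np.any(self.cp < -1e-9):
            raise ValueError("AIF concentration must be nonnegative")
        self.cp = np.clip(self.cp, 0.0, None)

    def resample(self, times: np.ndarray) -> "AIF":
        """Linearly interpolate onto a new time grid (zero outside support)."""
        times = np.asarray(times, dtype=float)
        cp = np.interp(times, self.times, self.cp, left=0.0, right=self.cp[-1])
        return AIF(times=times, cp=cp,
                   hematocrit_used=self.hematocrit_used, n_subjects=self.n_subjects)


@dataclass
class TumorMask:
    """Binary tumor mask plus optional necrosis exclusion on the same grid."""

    data: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.5)
    provenance: str = "auto"  # auto | adjusted
    exclusion_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("TumorMask data must be 3-D")
        self.voxel_spacing = _check_spacing(self.voxel_spacing)
        if self.provenance not in ("auto", "adjusted"):
            raise ValueError("provenance must be 'auto' or 'adjusted'")
        if self.exclusion_mask is not None:
            self.exclusion_mask = np.asarray(self.exclusion_mask).astype(bool)
            if self.exclusion_mask.shape != self.data.shape:
                raise ValueError("exclusion mask grid does not match tumor mask")
            # excluded voxels can never be tumor voxels
            self.data = self.data & ~self.exclusion_mask

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class ParamMaps:
    """Voxel-wise extended Tofts parameter maps with fit diagnostics.

    ktrans, kep are /min; ve, vp are fractions; ve = ktrans/kep holds
    exactly wherever kep > 0 because ve is derived, not fitted.
    """

    ktrans: np.ndarray
    kep: np.ndarray
    ve: np.ndarray
    vp: np.ndarray
    rss: np.ndarray
    converged: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.5)
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"ktrans": self.ktrans, "kep": self.kep,
                "ve": self.ve, "vp": self.vp}


@dataclass
class SemiQuantMaps:
    """Time-to-peak and initial-area-under-the-curve maps.

    ttp is seconds (onset-relative by default; ``ttp_absolute`` keeps the
    series-time convention), auc90 is concentration·s, onset is seconds.
    Voxels without detectable enhancement carry the NO_ONSET sentinel.
    """

    ttp: np.ndarray
    auc90: np.ndarray
    onset: np.ndarray
    ttp_absolute: Optional[np.ndarray] = None
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.5)
    meta: dict = field(default_factory=dict)


@dataclass
class FractalMap:
    """Local blanket-method fractal-dimension map.

    fd is unitless in [2, 3]; NaN where the sliding window does not fit.
    tumor_fd is the eroded-mask median summary (NaN when erosion empties
    the mask).
    """

    fd: np.ndarray
    n_blankets: int = 44
    window: int = 3
    tumor_fd: float = float("nan")
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.5)
    meta: dict = field(default_factory=dict)
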