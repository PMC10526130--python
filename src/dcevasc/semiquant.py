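"""Semi-quantitative enhancement-curve metrics: time-to-peak (TTP) and the
initial area under the contrast curve (AUC over the first 90 s of
enhancement), computed voxel-wise over a mask."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .containers import NO_ONSET, ConcentrationSeries, SemiQuantMaps
from .preprocessing import detect_onset

__all__ = ["compute_ttp", "compute_auc", "compute_semiquant"]


def _onset_map(conc: ConcentrationSeries, mask: np.ndarray,
               baseline_frames: int, k: float) -> np.ndarray:
    onset = np.full(conc.grid_shape, NO_ONSET)
    t = conc.frame_times
    for (i, j, kk) in np.argwhere(mask):
        onset[i, j, kk] = detect_onset(conc.data[i, j, kk, :], t,
                                       baseline_frames=baseline_frames, k=k)
    return onset


def compute_ttp(
    conc: ConcentrationSeries,
    mask: Optional[np.ndarray] = None,
    onset: Optional[np.ndarray] = None,
    baseline_frames: int = 5,
    k: float = 3.0,
    relative_to_onset: bool = True,
) -> np.ndarray:
    """Time at which each voxel's curve reaches its global maximum.

    Reported in seconds, onset-relative by default (set
    ``relative_to_onset=False`` for absolute series time).  Ties take the
    earliest frame; voxels without a detected onset carry NO_ONSET.
    """
    mask = _default_mask(conc, mask)
    if onset is None:
        onset = _onset_map(conc, mask, baseline_frames, k)
    t = conc.frame_times
    ttp = np.full(conc.grid_shape, NO_ONSET)
    for (i, j, kk) in np.argwhere(mask):
        if onset[i, j, kk] < 0:
            continue
        peak = int(np.argmax(conc.data[i, j, kk, :]))  # argmax: earliest tie
        ttp[i, j, kk] = t[peak] - (onset[i, j, kk] if relative_to_onset else 0.0)
    return ttp


def compute_auc(
    conc: ConcentrationSeries,
    mask: Optional[np.ndarray] = None,
    onset: Optional[np.ndarray] = None,
    window: float = 90.0,
    baseline_frames: int = 5,
    k: float = 3.0,
) -> np.ndarray:
    """Trapezoidal integral of each voxel curve from onset to onset+window.

    The window edge is handled by linear interpolation of the curve; if the
    series ends before onset+window the integral runs to the series end
    (NaN is *not* used — the voxel is still reported, matching the
    pairwise-deletion philosophy downstream).  Units: curve units × s.
    """
    mask = _default_mask(conc, mask)
    if onset is None:
        onset = _onset_map(conc, mask, baseline_frames, k)
    t = conc.frame_times
    auc = np.full(conc.grid_shape, NO_ONSET)
    for (i, j, kk) in np.argwhere(mask):
        t0 = onset[i, j, kk]
        if t0 < 0:
            continue
        t1 = min(t0 + window, t[-1])
        # dense grid over [t0, t1] including the exact edge points
        grid = np.unique(np.concatenate([[t0, t1], t[(t >= t0) & (t <= t1)]]))
        curve = np.interp(grid, t, conc.data[i, j, kk, :])
        auc[i, j, kk] = np.trapezoid(curve, grid)
    return auc


def _default_mask(conc: ConcentrationSeries, mask) -> np.ndarray:
    if mask is None:
        return np.ones(conc.grid_shape, dtype=bool)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != conc.grid_shape:
        raise ValueError("mask grid does not match series")
    return mask


def compute_semiquant(
    conc: ConcentrationSeries,
    mask: Optional[np.ndarray] = None,
    window: float = 90.0,
    baseline_frames: int = 5,
    k: float = 3.0,
) -> SemiQuantMaps:
    """TTP and AUC maps sharing one onset detection pass."""
    mask = _default_mask(conc, mask)
    onset = _onset_map(conc, mask, baseline_frames, k)
    ttp = compute_ttp(conc, mask, onset=onset)
    ttp_abs = compute_ttp(conc, mask, onset=onset, relative_to_onset=False)
    auc = compute_auc(conc, mask, onset=onset, window=window)
    return SemiQuantMaps(ttp=ttp, auc90=auc, onset=onset, ttp_absolute=ttp_abs,
                         voxel_spacing=conc.voxel_spacing,
                         meta={"window_s": window, "units": conc.meta.get("mode",
                               "concentration")})
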