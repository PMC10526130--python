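"""Signal preprocessing: B1 ratio correction, SPGR signal→concentration
conversion with fixed pre-contrast T1, subtraction images and bolus-arrival
detection.

The spoiled-gradient-echo (SPGR) steady-state signal is

    S = M0 sin(a) (1 - E1) / (1 - cos(a) E1),   E1 = exp(-TR/T1)

and the contrast agent shortens T1 according to 1/T1(t) = 1/T10 + r1*C(t).
The conversion inverts this relation voxel-wise using the pre-injection
signal S0 as the T1 = T10 anchor, so no M0 estimate is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .containers import NO_ONSET, ConcentrationSeries, DCESeries, VolumeImage

__all__ = [
    "ConversionSettings",
    "spgr_signal",
    "b1_correct",
    "signal_to_concentration",
    "subtraction_image",
    "detect_onset",
]


@dataclass
class ConversionSettings:
    """Constants of the SPGR signal→concentration conversion.

    t10_tissue / t10_blood : pre-contrast T1 in ms (tissue 900, blood 1200)
    r1 : contrast-agent relaxivity, L·mmol⁻¹·s⁻¹
    tr : repetition time, ms
    flip_angle : degrees
    mode : 'spgr_inversion' (physical units) or 'relative_enhancement'
           ((S-S0)/S0 fallback when the SPGR inversion is not wanted)
    """

    t10_tissue: float = 900.0
    t10_blood: float = 1200.0
    r1: float = 5.0
    tr: float = 5.46
    flip_angle: float = 12.0
    mode: str = "spgr_inversion"

    def __post_init__(self):
        for name in ("t10_tissue", "t10_blood", "r1", "tr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.flip_angle <= 90:
            raise ValueError("flip_angle must be in (0, 90] degrees")
        if self.mode not in ("spgr_inversion", "relative_enhancement"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def as_meta(self) -> dict:
        return {"t10_tissue_ms": self.t10_tissue, "t10_blood_ms": self.t10_blood,
                "r1_L_per_mmol_s": self.r1, "tr_ms": self.tr,
                "flip_angle_deg": self.flip_angle, "mode": self.mode}


def spgr_signal(t1_ms: np.ndarray, m0: Union[float, np.ndarray],
                tr_ms: float, flip_deg: float) -> np.ndarray:
    """SPGR steady-state signal for a given T1 (ms)."""
    t1 = np.asarray(t1_ms, dtype=float)
    e1 = np.exp(-tr_ms / t1)
    a = np.deg2rad(flip_deg)
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1)


def b1_correct(
    dce: DCESeries,
    breast_coil: VolumeImage,
    body_coil: VolumeImage,
    direction: str = "body_over_breast",
) -> DCESeries:
    """Remove coil-sensitivity shading using the two T1-weighted volumes.

    Every frame is multiplied voxel-wise by the coil-image ratio.  The
    breast-coil volume carries the same multiplicative bias b(x) as the
    dynamic series, the body-coil volume does not, so the default
    ``body_over_breast`` ratio (body/breast = 1/b) removes the bias.  The
    ``breast_over_body`` direction applies the ratio the other way round,
    which squares the shading instead of cancelling it; it is provided for
    protocol compatibility.  Voxels with a zero denominator are zeroed out
    and counted in ``meta['b1_zero_denominator']``.
    """
    if direction not in ("body_over_breast", "breast_over_body"):
        raise ValueError(f"unknown direction {direction!r}")
    for img in (breast_coil, body_coil):
        if img.data.shape != dce.grid_shape:
            raise ValueError(
                f"coil image grid {img.data.shape} does not match series "
                f"grid {dce.grid_shape}")
        if tuple(np.round(img.voxel_spacing, 6)) != tuple(np.round(dce.voxel_spacing, 6)):
            raise ValueError("coil image spacing does not match series spacing")
    if direction == "body_over_breast":
        num, den = body_coil.data, breast_coil.data
    else:
        num, den = breast_coil.data, body_coil.data
    bad = den == 0
    ratio = np.where(bad, 0.0, num / np.where(bad, 1.0, den))
    out = dce.data * ratio[..., None]
    meta = dict(dce.meta)
    meta["b1_direction"] = direction
    meta["b1_zero_denominator"] = int(bad.sum())
    return DCESeries(data=out, frame_times=dce.frame_times,
                     voxel_spacing=dce.voxel_spacing, meta=meta)


def signal_to_concentration(
    dce: DCESeries,
    settings: ConversionSettings = ConversionSettings(),
    t10_map_or_constant: Union[float, np.ndarray, None] = None,
    n_pre_frames: int = 5,
) -> ConcentrationSeries:
    """Convert the dynamic signal to tracer concentration (mM).

    The pre-contrast signal S0 is the mean of the first ``n_pre_frames``
    frames; the SPGR equation is inverted per voxel per frame using the
    fixed pre-contrast T1 (``t10_map_or_constant`` in ms; defaults to
    ``settings.t10_tissue``; pass a 3-D map to give blood voxels their
    1200 ms value).  Signal ratios outside the invertible range are clamped
    and the voxel is flagged (count in ``meta['n_clamped']``).
    ``mode='relative_enhancement'`` returns (S-S0)/S0 instead.
    """
    if dce.n_frames <= n_pre_frames:
        raise ValueError(
            f"series has {dce.n_frames} frames; need more than "
            f"{n_pre_frames} baseline frames")
    s0 = dce.data[..., :n_pre_frames].mean(axis=3)
    meta = dict(dce.meta)
    meta.update(settings.as_meta())
    meta["n_pre_frames"] = n_pre_frames

    if settings.mode == "relative_enhancement":
        safe = np.where(s0 == 0, 1.0, s0)
        enh = np.where((s0 == 0)[..., None], 0.0,
                       (dce.data - s0[..., None]) / safe[..., None])
        return ConcentrationSeries(data=enh, frame_times=dce.frame_times,
                                   voxel_spacing=dce.voxel_spacing, meta=meta)

    if t10_map_or_constant is None:
        t10 = np.full(dce.grid_shape, settings.t10_tissue)
    else:
        t10 = np.broadcast_to(np.asarray(t10_map_or_constant, dtype=float),
                              dce.grid_shape).copy()
    cos_a = np.cos(np.deg2rad(settings.flip_angle))
    e10 = np.exp(-settings.tr / t10)

    safe_s0 = np.where(s0 == 0, 1.0, s0)
    ratio = np.where((s0 == 0)[..., None], 1.0, dce.data / safe_s0[..., None])
    # S/S0 = [(1-E1)(1-cos a E10)] / [(1-E10)(1-cos a E1)]
    b = ratio * ((1.0 - e10) / (1.0 - cos_a * e10))[..., None]
    e1 = (1.0 - b) / (1.0 - cos_a * b)
    bad = ~((e1 > 0.0) & (e1 < 1.0))
    n_clamped = int(bad.sum())
    e1 = np.clip(e1, 1e-9, 1.0 - 1e-9)
    t1 = -settings.tr / np.log(e1)  # ms
    # rates in 1/s: R1 = 1000/T1[ms]
    conc = (1000.0 / t1 - (1000.0 / t10)[..., None]) / settings.r1
    meta["n_clamped"] = n_clamped
    return ConcentrationSeries(data=conc, frame_times=dce.frame_times,
                               voxel_spacing=dce.voxel_spacing, meta=meta)


def subtraction_image(
    series: DCESeries,
    post_time: float = 238.0,
    n_pre: int = 5,
    injection_time: float | None = None,
) -> VolumeImage:
    """Late-enhancement subtraction image.

    Subtracts the mean of the ``n_pre`` pre-injection frames from the frame
    nearest to ``injection_time + post_time`` (ties round up to the later
    frame).  ``injection_time`` defaults to the time of the first
    post-baseline frame, frame_times[n_pre].
    """
    if series.n_frames <= n_pre:
        raise ValueError("series shorter than the requested baseline")
    t = series.frame_times
    if injection_time is None:
        injection_time = float(t[n_pre])
    target = injection_time + post_time
    if t[-1] < target:
        raise ValueError(
            f"series ends at {t[-1]:.1f} s but {target:.1f} s "
            f"(injection + {post_time:.0f} s) is required")
    diffs = np.abs(t - target)
    idx = int(np.max(np.flatnonzero(diffs == diffs.min())))  # half-up
    baseline = series.data[..., :n_pre].mean(axis=3)
    sub = series.data[..., idx] - baseline
    return VolumeImage(data=sub, voxel_spacing=series.voxel_spacing,
                       role="subtraction",
                       meta={**series.meta, "post_frame_index": idx,
                             "post_frame_time_s": float(t[idx]),
                             "injection_time_s": injection_time,
                             "n_pre": n_pre})


def detect_onset(
    curve: np.ndarray,
    frame_times: np.ndarray,
    baseline_frames: int = 5,
    k: float = 3.0,
    min_consecutive: int = 2,
) -> float:
    """Bolus-arrival time of a single enhancement curve.

    Returns the time of the first frame exceeding baseline mean + k·SD and
    staying above for at least ``min_consecutive`` frames; the NO_ONSET
    sentinel (-1.0) when no such frame exists.  With a noiseless baseline
    (SD = 0) any strict rise above the baseline mean counts.
    """
    curve = np.asarray(curve, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    if baseline_frames < 3:
        raise ValueError("need at least 3 baseline frames")
    if curve.size <= baseline_frames:
        return NO_ONSET
    base = curve[:baseline_frames]
    thr = base.mean() + k * base.std()
    above = curve > thr
    for i in range(baseline_frames, curve.size):
        run = above[i: i + min_consecutive]
        if run.size == min_consecutive and run.all():
            return float(frame_times[i])
    return NO_ONSET
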