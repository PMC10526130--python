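"""Extended Tofts pharmacokinetic modelling.

The extended Tofts model (ETM) describes the tissue tracer concentration as

    Ct(t) = vp * Cp(t) + Ktrans * (exp(-kep*t) * Cp)(t)

where ``*`` is causal convolution, Cp is the arterial input function (plasma
concentration), Ktrans [/min] the plasma→EES transfer constant, kep [/min]
the efflux rate, vp the plasma volume fraction and ve = Ktrans/kep the
EES volume fraction.

The convolution is evaluated with an exact recursion for piecewise-linear
Cp, which is numerically stable for any kep and avoids fine-grid
oversampling during fitting.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .containers import AIF, ConcentrationSeries, ParamMaps
from .preprocessing import detect_onset

__all__ = [
    "convolve_exp",
    "etm_curve",
    "build_population_aif",
    "fit_etm",
    "DEFAULT_BOUNDS",
    "DEFAULT_STARTS",
]

# (Ktrans /min, kep /min, vp) box bounds and fixed multi-start points
DEFAULT_BOUNDS = ((0.0, 5.0), (0.0, 10.0), (0.0, 1.0))
DEFAULT_STARTS = (
    (0.1, 0.5, 0.05),
    (0.5, 2.0, 0.02),
    (0.02, 0.1, 0.10),
)


def _exp_conv(times_s: np.ndarray, cp: np.ndarray, rate_per_s: float) -> np.ndarray:
    """Causal convolution of cp with exp(-rate*t) on a (possibly non-uniform)
    grid, exact for piecewise-linear cp.

    Returns y(t_n) = \\int_0^{t_n} exp(-rate (t_n - s)) cp(s) ds  [units: cp*s].
    """
    t = np.asarray(times_s, dtype=float)
    c = np.asarray(cp, dtype=float)
    y = np.zeros_like(c)
    k = float(rate_per_s)
    dt = np.diff(t)
    a = c[:-1]
    b = np.diff(c) / dt
    if k < 1e-12:
        # kernel == 1: cumulative trapezoid
        incr = 0.5 * (c[:-1] + c[1:]) * dt
        y[1:] = np.cumsum(incr)
        return y
    E = np.exp(-k * dt)
    # \int_0^dt e^{-k u} du  and  \int_0^dt u e^{-k u} du  (u measured back
    # from the right endpoint)
    i0 = (1.0 - E) / k
    i1 = (1.0 - E * (1.0 + k * dt)) / (k * k)
    incr = a * i0 + b * (dt * i0 - i1)
    if np.allclose(dt, dt[0]):
        # uniform grid: the recursion y_n = E*y_{n-1} + incr_{n-1} is an
        # IIR filter
        from scipy.signal import lfilter
        y[1:] = lfilter([1.0], [1.0, -E[0]], incr)
    else:
        for n in range(1, t.size):
            y[n] = y[n - 1] * E[n - 1] + incr[n - 1]
    return y


def convolve_exp(aif: AIF, kep: float, frame_times: np.ndarray) -> np.ndarray:
    """Convolve the AIF with exp(-kep*t), kep in /min, times in seconds.

    Returns the convolution integral in units of cp·min so that multiplying
    by Ktrans [/min] yields a concentration.  kep = 0 degenerates to the
    running integral of Cp.
    """
    if kep < 0:
        raise ValueError("kep must be nonnegative")
    frame_times = np.asarray(frame_times, dtype=float)
    cp = aif.resample(frame_times).cp if not np.array_equal(aif.times, frame_times) else aif.cp
    return _exp_conv(frame_times, cp, kep / 60.0) / 60.0


def etm_curve(
    cp: np.ndarray,
    times_s: np.ndarray,
    ktrans: float,
    kep: float,
    vp: float,
) -> np.ndarray:
    """Forward extended Tofts curve on the given time grid (rates in /min)."""
    conv = _exp_conv(times_s, cp, kep / 60.0)
    return vp * cp + (ktrans / 60.0) * conv


def build_population_aif(
    lv_curves: Sequence[tuple[np.ndarray, np.ndarray]],
    hematocrit: Optional[float] = None,
    baseline_frames: int = 5,
) -> AIF:
    """Average left-ventricle blood curves into a population AIF.

    Each element of ``lv_curves`` is a ``(times_s, cb)`` pair of blood
    concentration vs. time.  Curves are aligned on bolus arrival by
    cross-correlating first differences against the first usable curve,
    interpolated onto that curve's grid and averaged point-wise.  Curves
    without a detectable bolus are excluded (reported in the result meta
    via ``n_subjects``).  With a configured hematocrit the blood
    concentration is converted to plasma: cp = cb / (1 - Hct).
    """
    if not lv_curves:
        raise ValueError("need at least one left-ventricle curve")
    usable = []
    for times, cb in lv_curves:
        times = np.asarray(times, dtype=float)
        cb = np.asarray(cb, dtype=float)
        onset = detect_onset(cb, times, baseline_frames=baseline_frames)
        if onset < 0:
            continue  # no detectable bolus: exclude
        usable.append((times, cb))
    if not usable:
        raise ValueError("no curve had a detectable bolus")

    ref_t, ref_c = usable[0]
    aligned = [ref_c]
    ref_d = np.diff(ref_c)
    for times, cb in usable[1:]:
        cb_on_ref = np.interp(ref_t, times, cb, left=0.0, right=cb[-1])
        d = np.diff(cb_on_ref)

        def _corr(lag: int) -> float:
            # correlation of ref_d with d delayed by `lag` frames, no wrap
            if abs(lag) >= d.size:
                return -np.inf
            if lag >= 0:
                return float(np.dot(ref_d[lag:], d[: d.size - lag]))
            return float(np.dot(ref_d[: d.size + lag], d[-lag:]))

        best = max(range(-5, 6), key=_corr)
        # a curve delayed by one frame gives best = -1; shifting its time
        # axis by best*dt advances it back onto the reference
        dt_med = float(np.median(np.diff(ref_t)))
        shifted = np.interp(ref_t, times + best * dt_med, cb, left=0.0, right=cb[-1])
        aligned.append(shifted)
    mean_cb = np.mean(aligned, axis=0)
    if hematocrit:
        if not 0 <= hematocrit < 1:
            raise ValueError("hematocrit must be in [0, 1)")
        cp = mean_cb / (1.0 - hematocrit)
    else:
        cp = mean_cb
    cp = np.clip(cp, 0.0, None)
    return AIF(times=ref_t, cp=cp, hematocrit_used=hematocrit or None,
               n_subjects=len(usable))


def _fit_voxel(
    ct: np.ndarray,
    cp: np.ndarray,
    times_s: np.ndarray,
    bounds,
    starts,
    fit_ve: bool,
) -> tuple[float, float, float, float, bool]:
    """Fit a single voxel curve; returns (ktrans, kep, vp, rss, converged)."""

    if fit_ve:
        def residual(p):
            ktrans, ve, vp = p
            kep = ktrans / ve if ve > 1e-12 else 0.0
            return etm_curve(cp, times_s, ktrans, kep, vp) - ct
    else:
        def residual(p):
            ktrans, kep, vp = p
            return etm_curve(cp, times_s, ktrans, kep, vp) - ct

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    best = None
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)
        try:
            sol = least_squares(residual, x0, bounds=(lo, hi),
                                method="trf", xtol=1e-10, ftol=1e-10)
        except Exception:
            continue
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[1]:
            best = (sol, rss)
    if best is None:
        return 0.0, 0.0, 0.0, float(np.sum(ct ** 2)), False
    sol, rss = best
    if fit_ve:
        ktrans, ve, vp = sol.x
        kep = ktrans / ve if ve > 1e-12 else 0.0
    else:
        ktrans, kep, vp = sol.x
    return float(ktrans), float(kep), float(vp), rss, bool(sol.status > 0)


def fit_etm(
    conc: ConcentrationSeries,
    aif: AIF,
    mask: Optional[np.ndarray] = None,
    bounds=DEFAULT_BOUNDS,
    starts=DEFAULT_STARTS,
    parameterization: str = "ktrans_kep_vp",
) -> ParamMaps:
    """Voxel-wise extended Tofts fit over a mask.

    Nonlinear least squares over (Ktrans, kep, vp) from 3 fixed starting
    points per voxel; ve is derived as Ktrans/kep so the identity
    ve·kep = Ktrans is exact in the output.  The alternative
    ``parameterization='ktrans_ve_vp'`` fits ve directly and derives kep.
    Voxels whose curve is identically zero are assigned zero parameters and
    converged=False.  Voxels where the derived fraction exceeds 1 are
    clipped (ve=1, ktrans=kep) and counted in ``meta['n_clipped']``.
    """
    if not np.all(np.isfinite(conc.data)):
        raise ValueError("concentration series contains non-finite values")
    if parameterization not in ("ktrans_kep_vp", "ktrans_ve_vp"):
        raise ValueError(f"unknown parameterization {parameterization!r}")
    fit_ve = parameterization == "ktrans_ve_vp"
    if fit_ve:
        bounds = (bounds[0], (0.0, 1.0), bounds[2])

    shape = conc.grid_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != shape:
        raise ValueError("mask grid does not match series")

    times = conc.frame_times
    cp = aif.resample(times).cp

    maps = {k: np.zeros(shape) for k in ("ktrans", "kep", "ve", "vp", "rss")}
    converged = np.zeros(shape, dtype=bool)
    n_clipped = 0
    idx = np.argwhere(mask)
    for (i, j, k) in idx:
        ct = conc.data[i, j, k, :]
        if not np.any(np.abs(ct) > 1e-12):
            continue  # all-zero: parameters 0, converged False
        ktrans, kep, vp, rss, ok = _fit_voxel(ct, cp, times, bounds, starts, fit_ve)
        ve = ktrans / kep if kep > 1e-12 else 0.0
        if ve > 1.0:
            ve = 1.0
            ktrans = kep  # keep ve*kep == ktrans exact
            n_clipped += 1
        if vp > 1.0:
            vp = 1.0
            n_clipped += 1
        maps["ktrans"][i, j, k] = ktrans
        maps["kep"][i, j, k] = kep
        maps["ve"][i, j, k] = ve
        maps["vp"][i, j, k] = vp
        maps["rss"][i, j, k] = rss
        converged[i, j, k] = ok
    return ParamMaps(
        ktrans=maps["ktrans"], kep=maps["kep"], ve=maps["ve"], vp=maps["vp"],
        rss=maps["rss"], converged=converged, voxel_spacing=conc.voxel_spacing,
        meta={"n_clipped": n_clipped, "parameterization": parameterization,
              "bounds": bounds, "starts": tuple(starts)},
    )
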