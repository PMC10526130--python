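"""Synthetic DCE-MRI phantoms and two-arm longitudinal cohorts.

Every downstream stage of the pipeline is validated against phantoms with
known ground truth: ellipsoidal heterogeneous tumors with per-voxel
(Ktrans, kep, ve, vp) fields, a left-ventricle blood pool carrying the
arterial input function, SPGR signal generation with a fixed pre-contrast
T1, a smooth multiplicative coil-sensitivity bias field and configurable
noise.  The acquisition geometry emulates a clinical breast protocol:
13 s temporal resolution, 1.0 x 1.0 x 1.5 mm voxels, five pre-injection
frames, coverage beyond 300 s.

The cohort generator produces a two-arm (chemotherapy vs. chemotherapy +
bevacizumab), four-timepoint design with arm-specific multiplicative
parameter reductions and lognormal subject-level heterogeneity, together
with a ground-truth table in the cohort-statistics schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import gamma as gamma_fn, gammainc

from .containers import AIF, ConcentrationSeries, DCESeries, VolumeImage
from .preprocessing import ConversionSettings, spgr_signal
from .pk import etm_curve

__all__ = [
    "AIFParams",
    "PhantomSpec",
    "CohortSpec",
    "Phantom",
    "generate_aif",
    "aif_integral",
    "forward_etm",
    "generate_phantom",
    "generate_cohort",
    "sigma_for_snr",
    "DEFAULT_ARM_EFFECTS",
]


@dataclass(frozen=True)
class AIFParams:
    """Parametric population-like AIF: delayed gamma-variate bolus plus a
    difference-of-exponentials washout/recirculation tail.

    Cp(t) = 0 for t < t0; with tau = t - t0:
        bolus(tau)   = peak * (tau/(alpha*beta))**alpha * exp(alpha - tau/beta)
        washout(tau) = tail * (exp(-m1*tau) - exp(-m2*tau)),  m2 > m1

    The bolus peaks at tau = alpha*beta with amplitude ``peak`` [mM]; both
    terms are causal and closed-form integrable.
    """

    t0: float = 65.0          # injection/arrival time, s
    peak: float = 6.0         # bolus peak plasma concentration, mM
    alpha: float = 3.0        # gamma-variate shape
    beta: float = 12.0        # gamma-variate time scale, s
    tail: float = 1.0         # washout amplitude, mM
    m1: float = 0.005         # slow washout rate, 1/s
    m2: float = 0.05          # fast uptake rate, 1/s

    def __post_init__(self):
        if self.m2 <= self.m1:
            raise ValueError("washout rates must satisfy m2 > m1")
        if min(self.peak, self.alpha, self.beta, self.m1) <= 0 or self.tail < 0:
            raise ValueError("AIF parameters must be positive")

    def evaluate(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        tau = t - self.t0
        pos = tau > 0
        cp = np.zeros_like(t)
        tp = tau[pos]
        bolus = self.peak * (tp / (self.alpha * self.beta)) ** self.alpha \
            * np.exp(self.alpha - tp / self.beta)
        washout = self.tail * (np.exp(-self.m1 * tp) - np.exp(-self.m2 * tp))
        cp[pos] = bolus + washout
        return cp


def aif_integral(params: AIFParams, t_end: float) -> float:
    """Closed-form integral of the parametric AIF from 0 to t_end [mM·s]."""
    tau = t_end - params.t0
    if tau <= 0:
        return 0.0
    a, b = params.alpha, params.beta
    # \int_0^tau (s/(ab))^a e^{a - s/b} ds = e^a b /(a^a) * gamma_lower(a+1, tau/b)
    bolus = params.peak * np.exp(a) * b / a ** a \
        * gammainc(a + 1.0, tau / b) * gamma_fn(a + 1.0)
    washout = params.tail * ((1.0 - np.exp(-params.m1 * tau)) / params.m1
                             - (1.0 - np.exp(-params.m2 * tau)) / params.m2)
    return float(bolus + washout)


def generate_aif(aif_params: AIFParams, frame_times: np.ndarray) -> AIF:
    """Sample the parametric AIF on a time grid.

    The returned curve is causal (exactly zero before the injection time)
    and nonnegative, with a single bolus peak after injection.
    """
    t = np.asarray(frame_times, dtype=float)
    if t.ndim != 1 or t.size < 2 or not np.all(np.diff(t) > 0):
        raise ValueError("frame_times must be strictly increasing")
    return AIF(times=t, cp=aif_params.evaluate(t))


def forward_etm(
    aif: AIF,
    ktrans: float,
    kep: float,
    vp: float,
    frame_times: np.ndarray,
) -> np.ndarray:
    """Extended Tofts tissue curve Ct(t) = vp·Cp + Ktrans·(e^(-kep t) ∗ Cp).

    ktrans, kep in /min; times in s.  Raises on negative rates or vp
    outside [0, 1].
    """
    if ktrans < 0 or kep < 0:
        raise ValueError("ktrans and kep must be nonnegative")
    if not 0 <= vp <= 1:
        raise ValueError("vp must be in [0, 1]")
    frame_times = np.asarray(frame_times, dtype=float)
    cp = aif.resample(frame_times).cp
    return etm_curve(cp, frame_times, ktrans, kep, vp)


@dataclass
class PhantomSpec:
    """Full description of one synthetic DCE acquisition.

    Tumor geometry is given in mm (ellipsoid center relative to the grid
    origin, semi-axes); ``ktrans0``/``ve0``/``vp0`` are the tumor-median
    ground-truth parameters, modulated spatially by ``heterogeneity``
    (fractional amplitude of a smooth random field).  kep is always derived
    as Ktrans/ve.  ``bias_field_strength`` scales a smooth multiplicative
    coil-sensitivity field; ``noise_sigma`` is the SD of additive Gaussian
    noise in signal units (the baseline tissue signal is ~``m0``/10, so
    noise_sigma = baseline/SNR; see :func:`sigma_for_snr`).
    """

    grid_shape: tuple[int, int, int] = (24, 24, 10)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.5)
    frame_interval: float = 13.0
    n_pre_frames: int = 5
    total_duration: float = 364.0
    tumor_center: Optional[tuple[float, float, float]] = None  # mm; default grid center
    tumor_axes: tuple[float, float, float] = (8.0, 7.0, 6.0)   # semi-axes, mm
    ktrans0: float = 0.13   # /min
    ve0: float = 0.2364     # fraction (= ktrans0 / kep0 with kep0 = 0.55)
    vp0: float = 0.094      # fraction
    heterogeneity: float = 0.3
    aif_params: AIFParams = field(default_factory=AIFParams)
    bias_field_strength: float = 0.3
    noise_sigma: float = 0.0
    noise_model: str = "gaussian"  # gaussian | rician
    m0: float = 1000.0
    conversion: ConversionSettings = field(default_factory=ConversionSettings)
    seed: int = 0

    def __post_init__(self):
        if self.n_pre_frames < 5:
            raise ValueError("need at least 5 pre-injection frames")
        if self.total_duration < 300:
            raise ValueError("total_duration must cover at least 300 s")
        if self.n_pre_frames * self.frame_interval > self.aif_params.t0:
            raise ValueError(
                "pre-injection frames extend past the injection time")
        if not 0 < self.ve0 <= 1 or not 0 <= self.vp0 <= 1:
            raise ValueError("ve0 and vp0 must be fractions")
        if self.ve0 + self.vp0 > 1:
            raise ValueError("ve0 + vp0 must not exceed 1")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def frame_times(self) -> np.ndarray:
        n = int(np.floor(self.total_duration / self.frame_interval)) + 1
        return np.arange(n) * self.frame_interval

    @property
    def kep0(self) -> float:
        return self.ktrans0 / self.ve0


@dataclass
class Phantom:
    """Everything :func:`generate_phantom` knows about one acquisition."""

    dce: DCESeries
    breast_coil: VolumeImage
    body_coil: VolumeImage
    tumor_mask: VolumeImage
    lv_mask: VolumeImage
    conc_truth: ConcentrationSeries
    truth_maps: dict            # ktrans, kep, ve, vp 3-D arrays
    bias_field: np.ndarray
    aif: AIF
    spec: PhantomSpec


def sigma_for_snr(spec: PhantomSpec, snr: float) -> float:
    """Noise SD giving the requested baseline-signal SNR in tissue."""
    s0 = spgr_signal(spec.conversion.t10_tissue, spec.m0,
                     spec.conversion.tr, spec.conversion.flip_angle)
    return float(s0 / snr)


def _smooth_field(shape, rng, n_modes: int = 3) -> np.ndarray:
    """Smooth random field in [-1, 1]: a few low-frequency cosine modes."""
    nx, ny, nz = shape
    x, y, z = np.meshgrid(np.linspace(0, 1, nx), np.linspace(0, 1, ny),
                          np.linspace(0, 1, nz), indexing="ij")
    out = np.zeros(shape)
    for _ in range(n_modes):
        fx, fy, fz = rng.uniform(0.5, 1.5, size=3)
        px, py, pz = rng.uniform(0, 2 * np.pi, size=3)
        out += rng.uniform(0.3, 1.0) * (
            np.cos(2 * np.pi * fx * x + px)
            * np.cos(2 * np.pi * fy * y + py)
            * np.cos(2 * np.pi * fz * z + pz))
    m = np.abs(out).max()
    return out / m if m > 0 else out


def _ellipsoid_mask(spec: PhantomSpec, center_mm, axes_mm) -> np.ndarray:
    shape = spec.grid_shape
    sp = spec.voxel_spacing
    coords = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, sp)],
                         indexing="ij")
    r2 = sum(((c - c0) / a) ** 2 for c, c0, a in zip(coords, center_mm, axes_mm))
    return r2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build one 4-D phantom acquisition from its spec.

    The ground-truth concentration field is pushed through the SPGR signal
    model (fixed pre-contrast T1: 1200 ms in the left-ventricle blood pool,
    900 ms elsewhere), multiplied by the smooth coil bias field and
    degraded by noise.  Matched breast-coil (biased) and body-coil
    (unbiased) T1-weighted volumes are produced for B1 correction.  The
    output is a pure function of the spec (identical seed, identical
    arrays).
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    times = spec.frame_times
    extent = [n * s for n, s in zip(shape, spec.voxel_spacing)]
    center = spec.tumor_center or tuple(e / 2 for e in extent)
    for c, a, e in zip(center, spec.tumor_axes, extent):
        if c - a < 0 or c + a > e:
            raise ValueError(
                f"tumor (center {center} mm, axes {spec.tumor_axes} mm) "
                f"exceeds the {extent} mm grid")
    tumor = _ellipsoid_mask(spec, center, spec.tumor_axes)

    # left-ventricle blood pool: a small sphere in the grid corner
    lv_center = [0.15 * e for e in extent[:2]] + [extent[2] / 2]
    lv_radius = max(2.0 * min(spec.voxel_spacing), 0.08 * min(extent))
    lv = _ellipsoid_mask(
        spec, lv_center, (lv_radius,) * 3) & ~tumor

    # heterogeneous ground-truth parameter fields inside the tumor
    h = spec.heterogeneity
    f_kt = _smooth_field(shape, rng)
    f_ve = _smooth_field(shape, rng)
    f_vp = _smooth_field(shape, rng)
    ktrans = np.where(tumor, spec.ktrans0 * (1 + h * f_kt), 0.0)
    ve = np.where(tumor, np.clip(spec.ve0 * (1 + h * f_ve), 0.01, 0.9), 0.0)
    vp = np.where(tumor, np.clip(spec.vp0 * (1 + h * f_vp), 0.001, 0.5), 0.0)
    # enforce ve + vp <= 1
    over = (ve + vp) > 1.0
    ve[over] = 1.0 - vp[over]
    ktrans = np.clip(ktrans, 0.0, None)
    kep = np.where(ve > 0, ktrans / np.where(ve > 0, ve, 1.0), 0.0)

    aif = generate_aif(spec.aif_params, times)

    conc = np.zeros(shape + (times.size,))
    idx = np.argwhere(tumor)
    for (i, j, k) in idx:
        conc[i, j, k, :] = etm_curve(aif.cp, times, ktrans[i, j, k],
                                     kep[i, j, k], vp[i, j, k])
    conc[lv, :] = aif.cp  # blood pool carries the AIF (Hct correction off)

    cs = spec.conversion
    t10 = np.where(lv, cs.t10_blood, cs.t10_tissue)
    r1_rate = 1000.0 / t10[..., None] + cs.r1 * conc   # 1/s
    t1_ms = 1000.0 / r1_rate
    signal = spgr_signal(t1_ms, spec.m0, cs.tr, cs.flip_angle)

    if spec.bias_field_strength > 0:
        bias = 1.0 + spec.bias_field_strength * _smooth_field(shape, rng)
        bias = np.clip(bias, 0.05, None)
    else:
        bias = np.ones(shape)

    dce_data = signal * bias[..., None]
    t1w = spgr_signal(t10, spec.m0, cs.tr, cs.flip_angle)
    breast = t1w * bias
    body = t1w.copy()
    if spec.noise_sigma > 0:
        if spec.noise_model == "rician":
            n1 = rng.normal(0, spec.noise_sigma, dce_data.shape)
            n2 = rng.normal(0, spec.noise_sigma, dce_data.shape)
            dce_data = np.sqrt((dce_data + n1) ** 2 + n2 ** 2)
        else:
            dce_data = dce_data + rng.normal(0, spec.noise_sigma, dce_data.shape)
        breast = breast + rng.normal(0, spec.noise_sigma, shape)
        body = body + rng.normal(0, spec.noise_sigma, shape)

    meta = {"seed": spec.seed, "injection_time_s": spec.aif_params.t0,
            "n_pre_frames": spec.n_pre_frames}
    return Phantom(
        dce=DCESeries(dce_data, times, spec.voxel_spacing, meta=dict(meta)),
        breast_coil=VolumeImage(breast, spec.voxel_spacing, "breast_coil_T1w"),
        body_coil=VolumeImage(body, spec.voxel_spacing, "body_coil_T1w"),
        tumor_mask=VolumeImage(tumor, spec.voxel_spacing, "mask"),
        lv_mask=VolumeImage(lv, spec.voxel_spacing, "mask"),
        conc_truth=ConcentrationSeries(conc, times, spec.voxel_spacing,
                                       meta=dict(meta)),
        truth_maps={"ktrans": ktrans, "kep": kep, "ve": ve, "vp": vp},
        bias_field=bias,
        aif=aif,
        spec=spec,
    )


# Arm-specific multiplicative changes relative to baseline; the values are
# the observed clinical effect sizes for the two neoadjuvant regimens
# (relative median changes in Ktrans, kep, vp and tumor volume).  ve is not
# listed: it is derived as Ktrans/kep throughout.
DEFAULT_ARM_EFFECTS = {
    "chemo": {
        "baseline": {"ktrans": 1.0, "kep": 1.0, "vp": 1.0, "volume": 1.0},
        "1w": {"ktrans": 0.997, "kep": 0.813, "vp": 0.790, "volume": 1.192},
        "12w": {"ktrans": 0.686, "kep": 0.588, "vp": 0.711, "volume": 0.340},
        "25w": {"ktrans": 0.606, "kep": 0.563, "vp": 0.713, "volume": 0.115},
    },
    "chemo+bev": {
        "baseline": {"ktrans": 1.0, "kep": 1.0, "vp": 1.0, "volume": 1.0},
        "1w": {"ktrans": 0.702, "kep": 0.556, "vp": 0.463, "volume": 1.044},
        "12w": {"ktrans": 0.457, "kep": 0.493, "vp": 0.528, "volume": 0.222},
        "25w": {"ktrans": 0.395, "kep": 0.411, "vp": 0.540, "volume": 0.102},
    },
}

TIMEPOINTS = ("baseline", "1w", "12w", "25w")


@dataclass
class CohortSpec:
    """Two-arm longitudinal cohort design with known ground truth.

    ``arm_effects[arm][timepoint][param]`` are multiplicative changes
    relative to baseline (baseline multipliers must be 1).  Subject-level
    heterogeneity is a lognormal factor with coefficient of variation
    ``inter_subject_cv`` drawn independently per subject, timepoint and
    parameter (mean 1, so the arm multiplier is the expected change).
    """

    n_per_arm: int = 15
    timepoints: tuple[str, ...] = TIMEPOINTS
    arm_effects: dict = field(default_factory=lambda: DEFAULT_ARM_EFFECTS)
    inter_subject_cv: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if self.inter_subject_cv < 0:
            raise ValueError("inter_subject_cv must be nonnegative")
        for arm, effects in self.arm_effects.items():
            for tp, mult in effects.items():
                if any(m <= 0 for m in mult.values()):
                    raise ValueError(f"multiplier <= 0 for {arm}/{tp}")
            base = effects.get("baseline")
            if base is not None and any(m != 1.0 for m in base.values()):
                raise ValueError(f"baseline multipliers must be 1 for {arm}")


def _lognormal_factor(rng, cv: float, size=None):
    if cv == 0:
        return np.ones(size) if size else 1.0
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=size)


def generate_cohort(cohort: CohortSpec, base: PhantomSpec):
    """Expand the cohort design into per-subject, per-timepoint phantom
    specs plus a ground-truth table.

    Returns ``(truth_table, specs)`` where ``truth_table`` is a pandas
    DataFrame in the (subject, arm, timepoint, metric, value) schema with
    metrics ktrans, kep, ve, vp (tumor-median ground truth) and
    volume_cm3, and ``specs[(subject, timepoint)]`` is the
    :class:`PhantomSpec` that materializes that acquisition via
    :func:`generate_phantom`.  Tumor volume changes are realized by
    scaling the ellipsoid axes by the cube root of the volume multiplier.
    """
    import pandas as pd

    rng = np.random.default_rng(cohort.seed)
    rows = []
    specs = {}
    subject_idx = 0
    base_vol_cm3 = (4.0 / 3.0 * np.pi * np.prod(base.tumor_axes)) / 1000.0
    for arm in cohort.arm_effects:
        for _ in range(cohort.n_per_arm):
            subject = f"{arm}-{subject_idx:03d}"
            subject_idx += 1
            for tp in cohort.timepoints:
                mult = cohort.arm_effects[arm][tp]
                fac = {p: mult.get(p, 1.0) * _lognormal_factor(rng, cohort.inter_subject_cv)
                       for p in ("ktrans", "kep", "vp", "volume")}
                ktrans = base.ktrans0 * fac["ktrans"]
                kep = base.kep0 * fac["kep"]
                ve = min(ktrans / kep, 0.95) if kep > 0 else 0.0
                vp = min(base.vp0 * fac["vp"], 1.0 - ve)
                vol_scale = fac["volume"] ** (1.0 / 3.0)
                axes = tuple(a * vol_scale for a in base.tumor_axes)
                spec = replace(
                    base,
                    tumor_axes=axes,
                    ktrans0=ktrans, ve0=ve, vp0=vp,
                    seed=int(rng.integers(0, 2 ** 31 - 1)),
                )
                specs[(subject, tp)] = spec
                truth = {"ktrans": ktrans, "kep": kep, "ve": ve, "vp": vp,
                         "volume_cm3": base_vol_cm3 * fac["volume"]}
                for metric, value in truth.items():
                    rows.append({"subject": subject, "arm": arm,
                                 "timepoint": tp, "metric": metric,
                                 "value": value})
    return pd.DataFrame(rows), specs
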