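# dcevasc

Tumor-vascularity analysis of dynamic contrast-enhanced (DCE) breast MRI:
from a 4-D acquisition to voxel-wise semi-quantitative maps (time-to-peak,
AUC90), extended Tofts pharmacokinetic maps (Ktrans, kep, ve, vp),
blanket-method fractal-dimension texture maps, semi-automatic tumor
volumetry, and two-arm longitudinal treatment-effect statistics.

The package targets researchers quantifying anti-angiogenic treatment
response (e.g. bevacizumab added to neoadjuvant chemotherapy): each patient
is imaged at several visits, per-tumor median metrics are reduced to
percentage changes from baseline, and the treatment arms are compared with
nonparametric tests. Because clinical DCE datasets are rarely shareable,
the package ships a synthetic phantom generator with full ground truth —
every analysis stage is validated against phantoms, and a complete
simulated two-arm study runs end to end from one config and one seed.

## The models

**Extended Tofts.** Tissue tracer concentration responds to the arterial
input function Cp(t) as

    Ct(t) = vp·Cp(t) + Ktrans·(e^(−kep·t) ∗ Cp)(t),    kep = Ktrans/ve

with Ktrans [/min] the plasma↔interstitium transfer constant, vp and ve the
plasma and extravascular-extracellular volume fractions. Fitting is
bounded nonlinear least squares per voxel over (Ktrans, kep, vp) with ve
derived, so ve·kep = Ktrans holds exactly in every output map. The
convolution uses an exact recursion for piecewise-linear Cp. A population
AIF is built from left-ventricle curves aligned on bolus arrival, and
signal is converted to concentration by inverting the SPGR signal equation
with fixed pre-contrast T1 (blood 1200 ms, tissue 900 ms) after B1
coil-shading correction.

**Semi-quantitative.** TTP is the time from enhancement onset to the curve
maximum; AUC90 the trapezoidal integral over the first 90 s of enhancement.

**Fractal texture.** On the late subtraction image (238 s post-injection
minus the 5-frame pre-injection mean), upper/lower blanket surfaces grown
over 44 iterations give a scale-dependent area A(ε); the local fractal
dimension is 2 − slope of log A vs log ε in a 3×3 sliding window (2 = flat
surface, →3 = space-filling texture), summarized per tumor as the median
over border-eroded voxels.

**Statistics.** Per-subject percentage changes from baseline, pairwise
deletion for missing visits, two-sided Mann–Whitney U (exact for small
samples) at p < 0.05, voxel-value probability densities, and bootstrap
median CIs. No multiple-testing correction (documented in
`docs/methods.md`).

## Worked example

Phantom → B1 correction → concentration → extended Tofts fit
(`examples/02_fit_pk_maps.py`):

```text
param      truth median   fit median  rel err %
ktrans           0.1302       0.1302   9.83e-12
kep              0.5425       0.5425   5.73e-13
ve               0.2402       0.2402   3.70e-13
vp               0.0942       0.0942   1.18e-12
converged voxels: 205 of 205
ve*kep == ktrans identity: True
```

On noiseless data the full measurement chain returns the ground-truth
medians to numerical precision — Ktrans/kep in /min, ve/vp as fractions.
At SNR 20 the median absolute relative error of Ktrans and kep stays in
the few-percent range (see `scripts/acceptance.py` output).

A simulated two-arm cohort (`examples/05_cohort_stats.py`, n = 15/arm)
prints the ground-truth median changes and the arm comparisons:

```text
  1w   ktrans      U= 173.0 p=0.0128* (asymptotic)
  1w   vp          U= 208.0 p=0.0001* (asymptotic)
  1w   volume_cm3  U= 126.0 p=0.5897  (asymptotic)
```

— the bevacizumab-like arm separates on Ktrans and vp already at one week
while tumor volume does not, the signature of early vascular shutdown
preceding shrinkage.

The other scripts in `examples/` cover phantom generation, TTP/AUC maps,
fractal-dimension maps and the full pipeline. The `dcevasc` CLI mirrors
the stages (`simulate`, `preprocess`, `segment`, `semiquant`, `fit-etm`,
`fractal`, `stats`, `run-all`); `dcevasc run-all --seed 12 --out dir/`
runs the built-in demo cohort end to end, deterministically in the seed.

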