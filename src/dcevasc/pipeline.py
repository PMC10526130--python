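"""End-to-end orchestration: simulate a cohort, preprocess, segment,
compute semi-quantitative, pharmacokinetic and fractal metrics per
subject/timepoint, and produce the cohort statistics report.

Everything is driven by a YAML-able config dict and a single seed; the
same config and seed produce bit-identical output tables.  Every written
table gets a ``<name>.provenance.json`` companion recording the config
hash, package version and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import AIF
from .io import save_config, write_aif, write_table
from .pk import build_population_aif, fit_etm
from .preprocessing import (ConversionSettings, b1_correct,
                            signal_to_concentration, subtraction_image)
from .fractal import fd_map_3d, tumor_fd_summary
from .segmentation import segment_tumor, tumor_volume
from .semiquant import compute_semiquant
from .stats import pipeline_report
from .synthetic import (AIFParams, CohortSpec, PhantomSpec, generate_cohort,
                        generate_phantom, sigma_for_snr)

__all__ = ["PipelineError", "demo_config", "run_all"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and subject."""


def demo_config() -> dict:
    """Small two-arm demo that runs end to end in a couple of minutes."""
    return {
        "seed": 0,
        "cohort": {
            "n_per_arm": 4,
            "timepoints": ["baseline", "1w"],
            "inter_subject_cv": 0.15,
        },
        "phantom": {
            "grid_shape": [12, 12, 4],
            "voxel_spacing": [1.0, 1.0, 1.5],
            "tumor_axes": [3.5, 3.5, 2.2],
            "heterogeneity": 0.2,
            "snr": 40,
            "bias_field_strength": 0.3,
        },
        "preprocess": {
            "direction": "body_over_breast",
            "mode": "spgr_inversion",
            "t10_tissue": 900.0,
            "t10_blood": 1200.0,
            "r1": 5.0,
            "tr": 5.46,
            "flip_angle": 12.0,
        },
        "aif": {"source": "population"},
        "semiquant": {"window": 90.0},
        "segment": {"voi_pad": 2},
        "fractal": {"window": 3, "blankets": 44, "post_time": 238.0},
        "stats": {"n_boot": 2000},
    }


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _build_specs(config: dict) -> tuple[CohortSpec, PhantomSpec]:
    ph = dict(config.get("phantom", {}))
    pre = config.get("preprocess", {})
    conv = ConversionSettings(
        t10_tissue=pre.get("t10_tissue", 900.0),
        t10_blood=pre.get("t10_blood", 1200.0),
        r1=pre.get("r1", 5.0), tr=pre.get("tr", 5.46),
        flip_angle=pre.get("flip_angle", 12.0),
        mode=pre.get("mode", "spgr_inversion"))
    snr = ph.pop("snr", None)
    base = PhantomSpec(
        grid_shape=tuple(ph.get("grid_shape", (24, 24, 10))),
        voxel_spacing=tuple(ph.get("voxel_spacing", (1.0, 1.0, 1.5))),
        tumor_axes=tuple(ph.get("tumor_axes", (8.0, 7.0, 6.0))),
        heterogeneity=ph.get("heterogeneity", 0.3),
        bias_field_strength=ph.get("bias_field_strength", 0.3),
        noise_sigma=ph.get("noise_sigma", 0.0),
        aif_params=AIFParams(**ph.get("aif_params", {})),
        conversion=conv,
        seed=int(config.get("seed", 0)),
    )
    if snr is not None:
        base = dataclasses.replace(base, noise_sigma=sigma_for_snr(base, snr))
    co = config.get("cohort", {})
    cohort = CohortSpec(
        n_per_arm=int(co.get("n_per_arm", 4)),
        timepoints=tuple(co.get("timepoints", ("baseline", "1w"))),
        inter_subject_cv=float(co.get("inter_subject_cv", 0.15)),
        seed=int(config.get("seed", 0)),
    )
    if "arm_effects" in co:
        cohort = dataclasses.replace(cohort, arm_effects=co["arm_effects"])
    return cohort, base


def _tumor_voi(tumor_mask: np.ndarray, pad: int) -> np.ndarray:
    """Padded bounding box of the true tumor, standing in for the
    radiologist-drawn VOI."""
    voi = np.zeros_like(tumor_mask)
    idx = np.argwhere(tumor_mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, tumor_mask.shape)
    voi[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return voi


def _subject_metrics(phantom, aif: AIF, config: dict) -> dict:
    """All per-tumor metrics for one acquisition."""
    pre = config.get("preprocess", {})
    spec = phantom.spec
    corrected = b1_correct(phantom.dce, phantom.breast_coil, phantom.body_coil,
                           direction=pre.get("direction", "body_over_breast"))
    t10_map = np.where(phantom.lv_mask.data, spec.conversion.t10_blood,
                       spec.conversion.t10_tissue)
    conc = signal_to_concentration(corrected, spec.conversion, t10_map,
                                   n_pre_frames=spec.n_pre_frames)
    fr = config.get("fractal", {})
    sub = subtraction_image(conc, post_time=fr.get("post_time", 238.0),
                            n_pre=spec.n_pre_frames,
                            injection_time=spec.aif_params.t0)
    voi = _tumor_voi(phantom.tumor_mask.data,
                     int(config.get("segment", {}).get("voi_pad", 2)))
    mask = segment_tumor(sub, voi)
    if mask.n_voxels == 0:  # fall back to the simulated VOI itself
        raise PipelineError("segmentation produced an empty tumor mask")
    metrics = {"volume_cm3": tumor_volume(mask)}

    sq = compute_semiquant(conc, mask.data,
                           window=config.get("semiquant", {}).get("window", 90.0),
                           baseline_frames=spec.n_pre_frames)
    ttp = sq.ttp[mask.data]
    auc = sq.auc90[mask.data]
    metrics["ttp_s"] = float(np.median(ttp[ttp >= 0])) if np.any(ttp >= 0) else np.nan
    metrics["auc90"] = float(np.median(auc[auc >= 0])) if np.any(auc >= 0) else np.nan

    pk = fit_etm(conc, aif, mask.data)
    for name, arr in pk.as_dict().items():
        metrics[name] = float(np.median(arr[mask.data]))

    fd = fd_map_3d(sub, window=fr.get("window", 3),
                   n_blankets=fr.get("blankets", 44))
    metrics["fd"] = tumor_fd_summary(fd, mask)
    return metrics


def _lv_curve(phantom, config: dict):
    """Blood concentration curve from the left-ventricle ROI."""
    pre = config.get("preprocess", {})
    spec = phantom.spec
    corrected = b1_correct(phantom.dce, phantom.breast_coil, phantom.body_coil,
                           direction=pre.get("direction", "body_over_breast"))
    conc = signal_to_concentration(corrected, spec.conversion,
                                   spec.conversion.t10_blood,
                                   n_pre_frames=spec.n_pre_frames)
    curve = conc.data[phantom.lv_mask.data].mean(axis=0)
    return conc.frame_times, curve


def run_all(config: dict, out_dir, seed: int | None = None) -> Path:
    """Run simulate → preprocess → segment → semiquant → fit → fractal →
    stats on a config dict; returns the artifact directory.

    Deterministic given the seed; any stage failure raises
    :class:`PipelineError` naming the stage and subject/timepoint.
    """
    config = dict(config)
    if seed is not None:
        config["seed"] = int(seed)
    if "aif" not in config:
        raise PipelineError("config lacks the 'aif' section "
                            "(expected {'source': 'population'|'parametric'})")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": _config_hash(config),
                  "version": __version__, "seed": config.get("seed", 0)}
    save_config(config, out / "config.yaml")

    cohort, base = _build_specs(config)
    truth, specs = generate_cohort(cohort, base)
    _write_with_provenance(truth, out / "truth_table.csv", provenance)

    # population AIF from the baseline left-ventricle curves
    source = config["aif"].get("source", "population")
    if source == "population":
        curves = []
        for (subject, tp), spec in specs.items():
            if tp != cohort.timepoints[0]:
                continue
            try:
                curves.append(_lv_curve(generate_phantom(spec), config))
            except Exception as exc:
                raise PipelineError(
                    f"stage aif failed for {subject}/{tp}: {exc}") from exc
        aif = build_population_aif(curves, baseline_frames=base.n_pre_frames)
    elif source == "parametric":
        from .synthetic import generate_aif
        aif = generate_aif(base.aif_params, base.frame_times)
    else:
        raise PipelineError(f"unknown aif source {source!r}")
    write_aif(aif, out / "population_aif.csv")

    rows = []
    for (subject, tp), spec in specs.items():
        try:
            phantom = generate_phantom(spec)
            metrics = _subject_metrics(phantom, aif, config)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(
                f"stage analysis failed for {subject}/{tp}: {exc}") from exc
        arm = subject.rsplit("-", 1)[0]
        for metric, value in metrics.items():
            if np.isfinite(value):
                rows.append({"subject": subject, "arm": arm, "timepoint": tp,
                             "metric": metric, "value": float(value)})
    table = pd.DataFrame(rows)
    _write_with_provenance(table, out / "cohort_table.csv", provenance)

    report = pipeline_report(table, seed=int(config.get("seed", 0)),
                             out_dir=out / "figures")
    _write_with_provenance(report["summary"], out / "summary.csv", provenance)
    _write_with_provenance(report["tests"], out / "arm_tests.csv", provenance)
    (out / "arm_tests.json").write_text(json.dumps(
        {"provenance": provenance,
         "tests": report["tests"].to_dict(orient="records")}, indent=1))
    return out


def _write_with_provenance(table: pd.DataFrame, path: Path, provenance: dict):
    if {"subject", "arm", "timepoint", "metric", "value"}.issubset(table.columns):
        write_table(table, path)
    else:
        table.to_csv(path, index=False, float_format="%.17g")
    path.with_suffix(".provenance.json").write_text(
        json.dumps(provenance, indent=1))
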