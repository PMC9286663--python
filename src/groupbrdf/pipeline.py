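"""End-to-end workflows: model estimation (fit), application, assessment.

The model sidecar JSON is the only interface between estimation and
application: it stores bin edges, per-bin coefficients, kernel choice and
constants, per-line topographic fits, the sampling seed and the resolved
reference solar zenith, so a fit can be re-applied to new lines
bit-identically.  Running single-line corrections is the same code path
with a one-line file list.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np

from . import __version__
from . import assess as assess_mod
from . import brdf, envi, solar, topo
from .config import RunConfig
from .errors import DataError

log = logging.getLogger(__name__)


def load_lines(cfg: RunConfig):
    """Read (name, cube, obs) for every configured flightline."""
    cfg.validate_files()
    out = []
    for line in cfg.lines:
        cube = envi.read_cube(line.reflectance, scale_divisor=cfg.scale_divisor)
        obs = envi.read_observation(line.observation, band_map=cfg.obs_band_map)
        if obs.shape != (cube.header.n_rows, cube.header.n_cols):
            raise DataError(f"line {line.name}: observation grid does not match cube")
        out.append((line.name, cube, obs))
    return out


def _topo_correct(cfg: RunConfig, name, cube, obs, stored_fit=None):
    if not cfg.topo_enabled:
        return cube, None
    if stored_fit is not None:
        fit = topo.TopoFit.from_dict(stored_fit)
    else:
        sample = topo.select_fit_sample(
            cube, obs, min_sample=cfg.topo_min_sample, seed=cfg.topo_seed,
            ndvi_threshold=cfg.bins.lower_mask)
        fit = topo.fit_c_factor(cube, obs, sample, b_threshold=cfg.topo_b_threshold)
    log.info("line %s: SCS+C fit over %d pixels", name, fit.fit_sample_size)
    return topo.apply_scs_c(cube, obs, fit), fit


def fit_group(cfg: RunConfig):
    """Estimation workflow: topo -> NDVI -> bins -> sample -> fit -> theta_ref.

    Returns (table, topo_fits, manifest).
    """
    lines = load_lines(cfg)
    prepared = []
    topo_fits = {}
    for name, cube, obs in lines:
        cube_t, fit = _topo_correct(cfg, name, cube, obs)
        if fit is not None:
            topo_fits[name] = fit.to_dict()
        ndvi = brdf.compute_ndvi(cube_t)
        prepared.append((name, cube_t, obs, ndvi))

    pooled = np.concatenate([
        ndvi[cube_t.valid_mask & obs.valid_mask & np.isfinite(ndvi)]
        for _, cube_t, obs, ndvi in prepared
    ])
    bins = brdf.build_bins(pooled, cfg.bins)
    log.info("bins (%s): %s", bins.mode, np.array2string(bins.edges, precision=3))

    samples = brdf.stratified_group_sample(
        [(cube_t, obs, ndvi) for _, cube_t, obs, ndvi in prepared],
        bins, per_bin=cfg.per_bin, seed=cfg.sampling_seed)
    log.info("stratified sample: %d pixels across %d bins",
             samples.n_samples, bins.n_bins)

    theta_ref = solar.resolve_reference_zenith(
        cfg.solar_reference, [obs for _, _, obs, _ in prepared])
    table = brdf.fit_brdf_coefficients(
        samples, bins, choice=cfg.kernel_choice, constants=cfg.kernel_constants,
        smoothing=cfg.smoothing, smoothing_range=cfg.smoothing_range,
        reference_zenith=theta_ref,
        wavelengths=prepared[0][1].header.wavelengths)
    manifest = {
        "tool": "groupbrdf",
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "sampling_seed": cfg.sampling_seed,
        "topo_seed": cfg.topo_seed,
        "reference_zenith": theta_ref,
        "n_lines": len(lines),
        "bins_fitted": int(table.fitted.sum()),
    }
    return table, topo_fits, manifest


def write_model(cfg: RunConfig, table, topo_fits, manifest, model_path=None):
    os.makedirs(cfg.output_dir, exist_ok=True)
    model_path = model_path or os.path.join(cfg.output_dir, "model.json")
    brdf.save_model(table, model_path, extra={"topo_fits": topo_fits})
    with open(os.path.join(cfg.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return model_path


def corrected_path(cfg: RunConfig, name):
    return os.path.join(cfg.output_dir, f"{name}_corrected")


def apply_group(cfg: RunConfig, model_path):
    """Application workflow: re-apply a stored model to the configured lines."""
    table, extra = brdf.load_model(model_path)
    topo_fits = (extra or {}).get("topo_fits", {})
    os.makedirs(cfg.output_dir, exist_ok=True)
    outputs = []
    for name, cube, obs in load_lines(cfg):
        if table.wavelengths is not None and cube.header.wavelengths is not None:
            if table.wavelengths.size != cube.header.wavelengths.size or \
               not np.allclose(table.wavelengths, cube.header.wavelengths):
                raise DataError(
                    f"line {name}: wavelength grid does not match the model")
        stored = topo_fits.get(name)
        if cfg.topo_enabled and stored is None:
            raise DataError(
                f"line {name}: model sidecar holds no topographic fit for it")
        cube_t, _ = _topo_correct(cfg, name, cube, obs, stored_fit=stored)
        ndvi = brdf.compute_ndvi(cube_t)
        corrected = brdf.apply_brdf_correction(cube_t, obs, ndvi, table)
        path = corrected_path(cfg, name)
        envi.write_cube(corrected, path)
        outputs.append(path)
        log.info("line %s: corrected cube -> %s", name, path)
    return outputs


def _pairs(headers):
    pairs = []
    for i in range(len(headers)):
        for j in range(i + 1, len(headers)):
            name_i, hdr_i = headers[i]
            name_j, hdr_j = headers[j]
            pair = assess_mod.find_overlap(hdr_i, hdr_j, name_i, name_j)
            if pair.n_pairs:
                pairs.append(pair)
    return pairs


def assess_set(cfg: RunConfig, paths_and_names, tag):
    """Overlap reports for one set of cubes; returns (reports, group_mean)."""
    cubes = {name: envi.read_cube(path, scale_divisor=scale)
             for name, path, scale in paths_and_names}
    headers = [(name, cube.header) for name, cube in cubes.items()]
    pairs = _pairs(headers)
    if not pairs:
        raise DataError("no overlapping flightline pairs found")
    band_idx = None
    wl = next(iter(cubes.values())).header.wavelengths
    if cfg.band_subset and wl is not None:
        band_idx = assess_mod.band_subset(wl, cfg.band_subset)
    reports = [
        assess_mod.overlap_statistics(cubes[p.line_a], cubes[p.line_b], p, band_idx)
        for p in pairs
    ]
    group = assess_mod.group_average(reports)
    os.makedirs(cfg.output_dir, exist_ok=True)
    assess_mod.write_reports(
        reports,
        csv_path=os.path.join(cfg.output_dir, f"assessment_{tag}.csv"),
        json_path=os.path.join(cfg.output_dir, f"assessment_{tag}.json"),
        group=group)
    return reports, group


def assess_group(cfg: RunConfig, corrected_dir=None):
    """Reports for the uncorrected inputs and, when present, the corrected
    outputs."""
    cfg.validate_files()
    if len(cfg.lines) < 2:
        raise DataError("assessment needs at least 2 flightlines")
    uncorrected = [(l.name, l.reflectance, cfg.scale_divisor) for l in cfg.lines]
    results = {"uncorrected": assess_set(cfg, uncorrected, "uncorrected")}
    corrected_dir = corrected_dir or cfg.output_dir
    corrected = []
    for l in cfg.lines:
        path = os.path.join(corrected_dir, f"{l.name}_corrected")
        if os.path.exists(path):
            corrected.append((l.name, path, 1.0))
    if len(corrected) == len(cfg.lines):
        results["corrected"] = assess_set(cfg, corrected, "corrected")
    return results
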