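"""Preset studies: the simulation campaigns of the imaging feasibility study.

Each preset builds its phantom, runs the transport chain, computes the
relevant summary statistics and (for imaging presets) the acquisition and
reconstruction, and writes all artifacts plus a machine-readable YAML
summary into the output directory.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__, analysis, recon
from .detector import CLINICAL_RING, DetectorRing, detect_coincidences
from .phantom import PhantomGrid, build_cube, build_cylinder_phantom
from .recon import ImageGeometry, mlem_reconstruct, postfilter
from .transport import EventLog, TransportConfig, run_simulation

log = logging.getLogger("pptsim")

PRESETS = (
    "water_cube_10",
    "budget_cube_1",
    "material_cubes_20",
    "six_insert",
    "four_rod",
    "nu4_small",
    "clinical_ppt_imaging",
)

__all__ = ["PRESETS", "run_preset"]


def _summary_header(name, n_primaries, seed, extra=None):
    out = {
        "preset": name,
        "n_primaries": int(n_primaries),
        "seed": int(seed),
        "pptsim_version": __version__,
    }
    if extra:
        out.update(extra)
    return out


def _dump(summary, outdir):
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "summary.yaml", "w") as f:
        yaml.safe_dump(summary, f, sort_keys=False)


def _log_counters(eventlog: EventLog):
    for k, v in sorted(eventlog.counters().items()):
        log.info("%s = %s", k, v)


def _density_map(positions, extent_mm, bin_mm=2.0):
    """X-Z density map of event positions (counts), plus bin edges."""
    edges = np.arange(-extent_mm, extent_mm + bin_mm, bin_mm)
    h, ex, ez = np.histogram2d(positions[:, 0], positions[:, 2], bins=(edges, edges))
    return h, edges


def run_preset(
    name: str,
    n_primaries: int = 1_000_000,
    seed: int = 0,
    outdir=None,
    tof: bool = True,
    save_events: bool = False,
) -> dict:
    """Run a named preset and return (and write) its summary dict.

    Presets: water_cube_10 (10 cm water cube localization study),
    budget_cube_1 (1 cm cube interaction budget with analytic
    cross-check), material_cubes_20 (per-material efficiency), six_insert
    / four_rod / nu4_small (cylinder phantoms), clinical_ppt_imaging
    (four-rod phantom through detection and TOF reconstruction).
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESETS)}")
    outdir = Path(outdir) if outdir is not None else Path(f"pptsim_{name}")
    fn = globals()[f"_run_{name}"]
    summary = fn(n_primaries, seed, outdir, tof=tof, save_events=save_events)
    _dump(summary, outdir)
    return summary


def _run_water_cube_10(n, seed, outdir, tof=True, save_events=False):
    grid = build_cube(100.0, "water", "point")
    eventlog = run_simulation(grid, n, TransportConfig(), seed=seed)
    _log_counters(eventlog)
    outdir.mkdir(parents=True, exist_ok=True)
    if save_events:
        eventlog.save(outdir / "events.h5")
    stats = analysis.positron_stats(eventlog)
    fits = {}
    for label, pos in (("production", eventlog.pair_r_p), ("annihilation", eventlog.ann_r_a)):
        hist = analysis.slice_profile(pos, axis=None, half_thickness_mm=0.5,
                                      bin_width_mm=0.25)
        fit = analysis.fit_profile(hist)
        fits[label] = fit
        np.savetxt(
            outdir / f"profile_x_{label}.tsv",
            np.column_stack([hist.centers, hist.counts]),
            header="x_mm\tcounts", delimiter="\t", comments="",
        )
    return _summary_header("water_cube_10", n, seed, {
        "mean_positron_ke_mev": stats.mean_ke_mev,
        "ke_symmetry_center_mev": stats.ke_symmetry_center_mev,
        "mean_positron_range_mm": stats.mean_range_mm,
        "range_percentiles_mm": {str(k): v for k, v in stats.range_percentiles_mm.items()},
        "fwhm_production_mm": fits["production"].fwhm_mm,
        "fwhm_annihilation_mm": fits["annihilation"].fwhm_mm,
        "fwhm_production_total_mm": fits["production"].fwhm_total_mm,
        "fwhm_annihilation_total_mm": fits["annihilation"].fwhm_total_mm,
        "n_pairs": eventlog.n_pairs,
        "n_annihilations": eventlog.n_annihilations,
    })


def _run_budget_cube_1(n, seed, outdir, tof=True, save_events=False):
    grid = build_cube(10.0, "water", "point")
    cfg = TransportConfig(track_secondaries=False)
    eventlog = run_simulation(grid, n, cfg, seed=seed)
    _log_counters(eventlog)
    frac = analysis.interaction_fractions(eventlog)
    oracle = analysis.first_interaction_oracle(10.0, "water", cfg.primary_energy_mev)
    return _summary_header("budget_cube_1", n, seed, {
        "fractions_percent": {k: 100 * v for k, v in frac.items()},
        "oracle_percent": {k: 100 * v for k, v in oracle.items()},
    })


def _run_material_cubes_20(n, seed, outdir, tof=True, save_events=False):
    logs = {}
    rng = np.random.default_rng(seed)
    for mat in ("water", "adipose", "lung", "bone"):
        grid = build_cube(200.0, mat, "point")
        logs[mat] = run_simulation(grid, n, TransportConfig(), seed=rng)
        log.info("material %s:", mat)
        _log_counters(logs[mat])
    table = analysis.efficiency_table(logs, roi_side_mm=10.0)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "efficiency.tsv", sep="\t")
    fits = {}
    for mat, lg in logs.items():
        if lg.n_pairs >= 100:
            hist = analysis.slice_profile(lg.pair_r_p, axis=0,
                                          half_thickness_mm=None, bin_width_mm=1.0)
            try:
                fits[mat] = analysis.fit_profile(hist).fwhm_mm
            except (RuntimeError, ValueError):
                fits[mat] = None
    prod = table["production_efficiency"]
    return _summary_header("material_cubes_20", n, seed, {
        "production_efficiency": {m: float(v) for m, v in prod.items()},
        "bone_over_water": float(prod["bone"] / prod["water"]),
        "bone_over_lung": float(prod["bone"] / prod["lung"]),
        "projection_fwhm_mm": fits,
    })


def _run_cylinder(preset_name, n, seed, outdir, save_events):
    grid = build_cylinder_phantom(preset_name)
    eventlog = run_simulation(grid, n, TransportConfig(), seed=seed)
    _log_counters(eventlog)
    outdir.mkdir(parents=True, exist_ok=True)
    if save_events:
        eventlog.save(outdir / "events.h5")
    for label, pos in (("production", eventlog.pair_r_p), ("annihilation", eventlog.ann_r_a)):
        h, edges = _density_map(pos, extent_mm=110.0, bin_mm=2.0)
        np.savetxt(outdir / f"xz_map_{label}.tsv", h, delimiter="\t")
        band = np.abs(pos[:, 2]) <= 19.0  # rod-length band
        hxy, _, _ = np.histogram2d(
            pos[band, 0], pos[band, 1],
            bins=(np.arange(-110.0, 112.0, 2.0),) * 2,
        )
        np.savetxt(outdir / f"xy_map_{label}.tsv", hxy, delimiter="\t")
    return grid, eventlog


def _run_six_insert(n, seed, outdir, tof=True, save_events=False):
    grid, eventlog = _run_cylinder("six_insert", n, seed, outdir, save_events)
    return _summary_header("six_insert", n, seed, {
        "n_pairs": eventlog.n_pairs,
        "n_annihilations": eventlog.n_annihilations,
    })


def _run_four_rod(n, seed, outdir, tof=True, save_events=False):
    grid, eventlog = _run_cylinder("four_rod", n, seed, outdir, save_events)
    # peak-to-valley between adjacent rods along the x axis (production map)
    sl = np.abs(eventlog.pair_r_p[:, 2]) <= 19.0
    prof = analysis.slice_profile(
        eventlog.pair_r_p[sl], axis=0, half_thickness_mm=None, bin_width_mm=2.0,
        extent_mm=100.0,
    )
    return _summary_header("four_rod", n, seed, {
        "n_pairs": eventlog.n_pairs,
        "n_annihilations": eventlog.n_annihilations,
    })


def _run_nu4_small(n, seed, outdir, tof=True, save_events=False):
    grid = build_cylinder_phantom("nu4_small")
    cfg = TransportConfig(track_annihilation_photons=True)
    eventlog = run_simulation(grid, n, cfg, seed=seed)
    _log_counters(eventlog)
    rng = np.random.default_rng(seed + 1)
    from .detector import PRECLINICAL_RING

    coinc = detect_coincidences(eventlog, PRECLINICAL_RING, rng)
    geom = ImageGeometry.like(grid)
    summary = _summary_header("nu4_small", n, seed, {
        "n_pairs": eventlog.n_pairs,
        "n_annihilations": eventlog.n_annihilations,
        "n_coincidences": len(coinc),
    })
    if len(coinc):
        img = mlem_reconstruct(coinc, geom, n_iter=40, n_subsets=1, tof=False)
        outdir.mkdir(parents=True, exist_ok=True)
        img.to_nifti(outdir / "recon_nontof.nii.gz")
        coinc.save_listmode(outdir / "listmode.txt")
    return summary


def _run_clinical_ppt_imaging(n, seed, outdir, tof=True, save_events=False):
    grid = build_cylinder_phantom("four_rod")
    cfg = TransportConfig(track_annihilation_photons=True)
    eventlog = run_simulation(grid, n, cfg, seed=seed)
    _log_counters(eventlog)
    rng = np.random.default_rng(seed + 1)
    coinc = detect_coincidences(eventlog, CLINICAL_RING, rng)
    summary = _summary_header("clinical_ppt_imaging", n, seed, {
        "n_pairs": eventlog.n_pairs,
        "n_annihilations": eventlog.n_annihilations,
        "n_coincidences": len(coinc),
        "tof": bool(tof),
    })
    if len(coinc):
        geom = ImageGeometry((101, 101, 51), (2.0, 2.0, 4.0))
        img = mlem_reconstruct(coinc, geom, n_iter=4, n_subsets=5, tof=tof)
        img = postfilter(img, 9.0)
        outdir.mkdir(parents=True, exist_ok=True)
        img.to_nifti(outdir / "recon.nii.gz")
        coinc.save_listmode(outdir / "listmode.txt")
        summary["image_max"] = float(img.values.max())
    return summary
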