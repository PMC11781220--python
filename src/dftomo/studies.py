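"""Reproduction harness: the simulation studies, at desk scale.

Each driver reproduces one simulation study end to end — generate Born-ratio
data on an independent mesh, reconstruct in two stages, evaluate the error
metrics — and returns the per-run metric reports.  All randomness (mesh
jitter, noise draws) derives from a single integer seed.

Problem sizes: the studies run on ~16k-node forward meshes with a ~2.5k-node
inversion mesh (the original studies used 28k-64k-node meshes with a ~6.5k
inversion mesh).  Data-generation and reconstruction meshes are independent
random lattice realizations of equal density: at these resolutions a denser
data mesh would no longer share the reconstruction mesh's O(h^2) dispersion
bias, and the resulting systematic Born-ratio mismatch (~2% of the data
norm) dominates the partition selection; equal-density independent meshes
cancel the shared bias while still avoiding the inverse crime (no element,
node or matrix of the data mesh appears in the reconstruction).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .evaluation import MetricsReport
from .fem import OpticalField, green_set
from .forward import jacobian
from .mesh import build_box_mesh
from .phantom import (
    Scenario,
    default_scenario,
    gt_mu_af,
    scenario_optics,
    simulate_measurements,
    twelve_fiber_scenario,
)
from .pipeline import ReconstructionSetup, run_two_stage

__all__ = [
    "StudyConfig",
    "default_family",
    "radius_sweep",
    "contrast_sweep",
    "noise_study",
    "cutoff_study",
    "optics_mismatch_study",
    "gt_sphere_volume_cm3",
]

RADII_MM = (3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
CONTRAST_LEVELS = (0.050, 0.075, 0.100, 0.125)
LOW_CONTRAST = 0.025
NOISE_AMPLITUDES = (0.01, 0.02)
CUTOFF_LEVELS = (0.015, 0.030, 0.045, 0.060, 0.075, 0.090)


@dataclass
class StudyConfig:
    mesh_nodes: int = 16000
    recon_nodes: int = 2500
    seed: int = 1


@dataclass
class StudyFamily:
    """Shared data-side and reconstruction-side state for one scenario family."""

    scenario: Scenario
    data_mesh: object
    data_greens: object
    setup: ReconstructionSetup


def _mesh_seed(seed: int, k: int) -> int:
    return (int(seed) * 101 + k) % (2**31 - 1)


def default_family(seed: int = 1, cfg: StudyConfig | None = None) -> StudyFamily:
    """13-fiber single-sphere scenario family with shared Green's functions."""
    cfg = cfg or StudyConfig()
    sc = default_scenario(data_mesh_nodes=cfg.mesh_nodes)
    data_mesh = build_box_mesh(
        sc.extent, sc.fibers, cfg.mesh_nodes, seed=_mesh_seed(seed, 0)
    )
    data_greens = green_set(data_mesh, scenario_optics(data_mesh, sc), sc.fibers)
    setup = ReconstructionSetup.build(
        sc,
        fwd_mesh_nodes=cfg.mesh_nodes,
        recon_mesh_nodes=cfg.recon_nodes,
        mesh_seed=_mesh_seed(seed, 1),
    )
    return StudyFamily(sc, data_mesh, data_greens, setup)


def _run_variant(family: StudyFamily, sc: Scenario, noise_seed=None, matched=False) -> MetricsReport:
    if matched:
        out = simulate_measurements(
            sc, mesh=family.setup.fwd_mesh, greens=family.setup.greens, noise_seed=noise_seed
        )
    else:
        out = simulate_measurements(
            sc, mesh=family.data_mesh, greens=family.data_greens, noise_seed=noise_seed
        )
    res = run_two_stage(
        family.setup,
        out.measurements,
        mu_af_gt_on_fwd=gt_mu_af(family.setup.fwd_mesh, sc),
        scenario=sc,
    )
    return res.metrics


def radius_sweep(
    seed: int = 1,
    radii=RADII_MM,
    family: StudyFamily | None = None,
    cfg: StudyConfig | None = None,
) -> dict:
    """Inclusion-size sweep of the default scenario (noiseless, dual meshes)."""
    family = family or default_family(seed, cfg)
    reports = {}
    for r in radii:
        sc = replace(family.scenario, gt=dict(family.scenario.gt, radius=float(r)))
        reports[float(r)] = _run_variant(family, sc)
    return reports


def contrast_sweep(
    seed: int = 1,
    levels=CONTRAST_LEVELS,
    family: StudyFamily | None = None,
    cfg: StudyConfig | None = None,
) -> dict:
    """Fluorophore-contrast sweep at fixed R = 6.7 mm."""
    family = family or default_family(seed, cfg)
    reports = {}
    for mui in levels:
        sc = replace(
            family.scenario, gt=dict(family.scenario.gt, mu_af_inclusion=float(mui))
        )
        reports[float(mui)] = _run_variant(family, sc)
    return reports


def noise_study(
    seed: int = 1,
    amplitudes=NOISE_AMPLITUDES,
    n_repeats: int = 5,
    family: StudyFamily | None = None,
    cfg: StudyConfig | None = None,
) -> dict:
    """Measurement-noise study on matched data/reconstruction meshes.

    Returns {amplitude: {"runs": [MetricsReport...], "mean_abs": {...}}} with
    seed-averaged absolute metric values per amplitude.
    """
    family = family or default_family(seed, cfg)
    out = {}
    for amp in amplitudes:
        runs = []
        for k in range(n_repeats):
            sc = replace(family.scenario, noise_amplitude=float(amp))
            runs.append(
                _run_variant(family, sc, noise_seed=_mesh_seed(seed, 100 + k), matched=True)
            )
        out[float(amp)] = {
            "runs": runs,
            "mean_abs": {
                "dV_i": float(np.mean([abs(m.dV_i) for m in runs])),
                "d_mu_af_i": float(np.mean([abs(m.d_mu_af_i) for m in runs])),
                "d_mu_af_bg": float(np.mean([abs(m.d_mu_af_bg) for m in runs])),
                "mean_abs_rel_err_s2": float(
                    np.mean([m.mean_abs_rel_err_s2 for m in runs])
                ),
                "mean_abs_rel_err_s1": float(
                    np.mean([m.mean_abs_rel_err_s1 for m in runs])
                ),
            },
        }
    return out


def cutoff_study(
    seed: int = 1,
    levels=CUTOFF_LEVELS,
    cfg: StudyConfig | None = None,
) -> dict:
    """Detector cut-off study: 12 fibers, zero-background fluorophore.

    The absolute power calibration is fixed at the lowest-concentration
    scenario (weakest signal at 1e-11 W) and reused across levels, so higher
    concentrations keep more source-detector pairs, as in a real session.
    Returns per-level reports plus the recovered volume fraction (%).
    """
    cfg = cfg or StudyConfig()
    sc0 = twelve_fiber_scenario()
    data_mesh = build_box_mesh(
        sc0.extent, sc0.fibers, cfg.mesh_nodes, seed=_mesh_seed(seed, 2)
    )
    data_greens = green_set(data_mesh, scenario_optics(data_mesh, sc0), sc0.fibers)
    setup = ReconstructionSetup.build(
        sc0,
        fwd_mesh_nodes=cfg.mesh_nodes,
        recon_mesh_nodes=cfg.recon_nodes,
        mesh_seed=_mesh_seed(seed, 3),
    )
    family = StudyFamily(sc0, data_mesh, data_greens, setup)

    ref = replace(sc0, gt=dict(sc0.gt, mu_af_inclusion=min(levels)), p_cut=0.0)
    kappa = simulate_measurements(ref, mesh=data_mesh, greens=data_greens).power_calibration

    v_gt = gt_sphere_volume_cm3(sc0.gt["radius"])
    reports = {}
    for mui in levels:
        sc = replace(
            sc0, gt=dict(sc0.gt, mu_af_inclusion=float(mui)), power_calibration=kappa
        )
        m = _run_variant(family, sc)
        reports[float(mui)] = {
            "metrics": m,
            "volume_fraction_pct": m.volume_recon_cm3 / v_gt * 100.0,
        }
    return reports


#: Table-4-style optics rows: ((mu_a, mu_s') actual, (mu_a, mu_s') given)
OPTICS_MISMATCH_ROWS = (
    ((0.30, 8.7), (0.30, 8.7)),
    ((0.30, 8.7), (0.50, 8.7)),
    ((0.50, 8.7), (0.30, 8.7)),
    ((0.50, 8.7), (0.50, 8.7)),
    ((0.50, 7.3), (0.50, 7.3)),
    ((0.50, 7.3), (0.50, 8.7)),
    ((0.50, 8.7), (0.50, 7.3)),
)


def optics_mismatch_study(seed: int = 1, cfg: StudyConfig | None = None) -> list:
    """Background-optics mismatch study on a single matched mesh.

    Data are generated with the 'actual' background optics and reconstructed
    assuming the 'given' ones; mild mismatches around the default properties.
    Returns [(actual, given, MetricsReport), ...].
    """
    cfg = cfg or StudyConfig()
    sc0 = default_scenario()
    mesh = build_box_mesh(sc0.extent, sc0.fibers, cfg.mesh_nodes, seed=_mesh_seed(seed, 4))
    rec = build_box_mesh(sc0.extent, sc0.fibers, cfg.recon_nodes, seed=_mesh_seed(seed, 5))
    needed = {opt for row in OPTICS_MISMATCH_ROWS for opt in row}
    greens = {}
    for mua, musp in needed:
        g = green_set(mesh, OpticalField.homogeneous(mesh, mua, musp), sc0.fibers)
        greens[(mua, musp)] = (g, jacobian(g, mesh.nodal_volume))
    gt_field = gt_mu_af(mesh, sc0)
    results = []
    for actual, given in OPTICS_MISMATCH_ROWS:
        g_act, _ = greens[actual]
        g_giv, J_giv = greens[given]
        sc = replace(sc0, mu_a=actual[0], mu_s_prime=actual[1])
        out = simulate_measurements(sc, mesh=mesh, greens=g_act)
        setup = ReconstructionSetup(sc0, mesh, rec, g_giv, J_giv)
        res = run_two_stage(setup, out.measurements, mu_af_gt_on_fwd=gt_field, scenario=sc0)
        results.append((actual, given, res.metrics))
    return results


def gt_sphere_volume_cm3(radius_mm: float) -> float:
    """Analytic ground-truth sphere volume (cm^3)."""
    return 4.0 / 3.0 * np.pi * (radius_mm / 10.0) ** 3
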