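"""Synthetic phantom scenarios: ground-truth fields, noisy data, detector cut-off.

The simulator is the in-silico counterpart of an interstitial fluorescence
measurement: a box medium with known background optics, a single fluorescent
inclusion (step-profile sphere or radial Gaussian), a set of interstitial
fiber tips, and a measurement model producing per-pair detected powers at the
excitation and fluorescence wavelengths.  Corruptions modeled:

* multiplicative Gaussian noise — each detected power is scaled by
  (1 + a Z) with Z ~ N(0, 1), independently per pair and wavelength, so the
  noise standard deviation equals the clean signal times the amplitude
  factor a;
* an absolute detection cut-off — fluorescence powers below P_cut are
  discarded (Born ratios are calibration-free, but the cut-off needs an
  absolute power scale, see :func:`calibrate_power`);
* uniform random perturbations of the fiber-tip coordinates, emulating
  needle-placement uncertainty.

Default scenario values: background fluorophore absorption 0.01 cm^-1,
inclusion 0.10 cm^-1, mu_a = 0.50 cm^-1, mu_s' = 8.7 cm^-1, a sphere of
radius 6.7 mm centered at (19, 25, 18) mm, and the 13-fiber clinical
configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .fem import GreenSet, OpticalField, green_set
from .forward import BornMeasurementSet, YieldField, jacobian, pair_table
from .mesh import FiberConfig, TetMesh, build_box_mesh, table2_fibers, table3_fibers

__all__ = [
    "Scenario",
    "NoiseModel",
    "SimulationOutput",
    "default_scenario",
    "twelve_fiber_scenario",
    "gt_field_sphere",
    "gt_field_gaussian",
    "gt_mu_af",
    "add_noise",
    "apply_cutoff",
    "perturb_fibers",
    "calibrate_power",
    "simulate_measurements",
]

log = logging.getLogger(__name__)

#: weakest detected fluorescence power the simulated instrument is calibrated
#: to produce (W); chosen so that per-pair signals straddle the default
#: detection cut-off and the weakest pairs are pruned, as in a real session.
WEAKEST_POWER_W = 1e-11
DEFAULT_P_CUT_W = 4.5e-11


@dataclass
class NoiseModel:
    """Multiplicative Gaussian noise with std = amplitude_factor * signal."""

    amplitude_factor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_factor < 0:
            raise ValueError("noise amplitude factor must be >= 0")


@dataclass
class Scenario:
    """Complete description of a synthetic measurement study."""

    extent: tuple = (52.0, 57.0, 40.0)  # mm
    fibers: FiberConfig = None
    mu_a: float = 0.50  # background absorption, cm^-1
    mu_s_prime: float = 8.7  # background reduced scattering, cm^-1
    inclusion_mu_a: float | None = None  # optional distinct inclusion optics
    inclusion_mu_s_prime: float | None = None
    gt: dict = field(
        default_factory=lambda: {
            "kind": "sphere",
            "center": (19.0, 25.0, 18.0),  # mm
            "radius": 6.7,  # mm
            "mu_af_inclusion": 0.10,  # cm^-1
            "mu_af_background": 0.01,  # cm^-1
        }
    )
    gamma: float = 0.1
    noise_amplitude: float = 0.0
    p_cut: float = 0.0  # W; 0 disables the cut-off
    power_calibration: float | None = None  # W per unit Born numerator; None -> auto
    data_mesh_nodes: int = 8000
    seed: int = 0
    fresnel_A: float = 1.0

    def __post_init__(self) -> None:
        if self.fibers is None:
            self.fibers = table2_fibers()
        g = self.gt
        if g["kind"] in ("sphere", "gaussian"):
            c = np.asarray(g["center"], float)
            if np.any(c - g["radius"] < 0) or np.any(
                c + g["radius"] > np.asarray(self.extent)
            ):
                if g["kind"] == "sphere":
                    raise ValueError("inclusion sphere must lie fully inside the box")
        if g.get("mu_af_background", 0.0) > g.get(
            "mu_af_inclusion", g.get("mu_af_peak", np.inf)
        ):
            raise ValueError("inclusion fluorophore absorption must be >= background")


def default_scenario(**overrides) -> Scenario:
    """Single-sphere default study: 13 fibers, R = 6.7 mm, contrast 10."""
    return replace(Scenario(), **overrides) if overrides else Scenario()


def twelve_fiber_scenario(**overrides) -> Scenario:
    """Cut-off study scenario: 12 fibers, R = 5.5 mm sphere at (22.5, 27.5, 20) mm,
    background optics 0.24/8.3 cm^-1, inclusion optics 0.20/15.7 cm^-1, zero
    background fluorophore."""
    sc = Scenario(
        extent=(50.0, 50.0, 40.0),
        fibers=table3_fibers(),
        mu_a=0.24,
        mu_s_prime=8.3,
        inclusion_mu_a=0.20,
        inclusion_mu_s_prime=15.7,
        gt={
            "kind": "sphere",
            "center": (22.5, 27.5, 20.0),
            "radius": 5.5,
            "mu_af_inclusion": 0.015,
            "mu_af_background": 0.0,
        },
        p_cut=DEFAULT_P_CUT_W,
    )
    return replace(sc, **overrides) if overrides else sc


# ---------------------------------------------------------------------------
# ground-truth fields
# ---------------------------------------------------------------------------


def gt_field_sphere(mesh: TetMesh, center, radius: float, mu_af_in: float, mu_af_bg: float) -> np.ndarray:
    """Step-profile sphere: mu_af_in inside radius (mm), mu_af_bg outside."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    r = np.linalg.norm(mesh.node_coords - np.asarray(center, float), axis=1)
    return np.where(r <= radius, mu_af_in, mu_af_bg)


def gt_field_gaussian(mesh: TetMesh, center, radius: float, mu_af_peak: float, mu_af_bg: float) -> np.ndarray:
    """Radial Gaussian profile inside radius R, background outside:

    mu_af(r) = peak * exp(-ln(peak/bg) r^2 / R^2), continuous at r = R.
    """
    if mu_af_bg <= 0:
        raise ValueError("background mu_af must be positive (log contrast undefined)")
    if mu_af_peak <= mu_af_bg:
        raise ValueError("peak must exceed background")
    r = np.linalg.norm(mesh.node_coords - np.asarray(center, float), axis=1)
    prof = mu_af_peak * np.exp(-np.log(mu_af_peak / mu_af_bg) * r**2 / radius**2)
    return np.where(r < radius, prof, mu_af_bg)


def gt_mu_af(mesh: TetMesh, scenario: Scenario) -> np.ndarray:
    g = scenario.gt
    if g["kind"] == "sphere":
        return gt_field_sphere(
            mesh, g["center"], g["radius"], g["mu_af_inclusion"], g["mu_af_background"]
        )
    if g["kind"] == "gaussian":
        return gt_field_gaussian(
            mesh, g["center"], g["radius"],
            g.get("mu_af_peak", g.get("mu_af_inclusion")), g["mu_af_background"],
        )
    raise ValueError(f"unknown ground-truth kind {g['kind']!r}")


def scenario_optics(mesh: TetMesh, scenario: Scenario) -> OpticalField:
    """Nodal optical-property field (heterogeneous if inclusion optics given)."""
    n = mesh.n_nodes
    mua = np.full(n, scenario.mu_a)
    musp = np.full(n, scenario.mu_s_prime)
    if scenario.inclusion_mu_a is not None or scenario.inclusion_mu_s_prime is not None:
        g = scenario.gt
        r = np.linalg.norm(mesh.node_coords - np.asarray(g["center"], float), axis=1)
        inside = r <= g["radius"]
        if scenario.inclusion_mu_a is not None:
            mua[inside] = scenario.inclusion_mu_a
        if scenario.inclusion_mu_s_prime is not None:
            musp[inside] = scenario.inclusion_mu_s_prime
    return OpticalField({"x": mua}, {"x": musp}, scenario.fresnel_A)


# ---------------------------------------------------------------------------
# corruption models
# ---------------------------------------------------------------------------


def add_noise(signals: np.ndarray, model: NoiseModel, rng: np.random.Generator | None = None) -> np.ndarray:
    """Multiplicative Gaussian noise, s' = s (1 + a Z); results that would go
    negative are floored at 1e-3 of the clean signal (Born ratios must stay
    positive)."""
    s = np.asarray(signals, dtype=float)
    if np.any(s < 0):
        raise ValueError("signals must be nonnegative")
    if model.amplitude_factor == 0:
        return s.copy()
    if rng is None:
        rng = np.random.default_rng(model.seed)
    noisy = s * (1.0 + model.amplitude_factor * rng.standard_normal(s.shape))
    floor = 1e-3 * s
    n_clip = int(np.sum(noisy < floor))
    if n_clip:
        log.info("floored %d noisy signal(s) at 1e-3 of the clean value", n_clip)
    return np.maximum(noisy, floor)


def apply_cutoff(raw_fluorescence: np.ndarray, p_cut: float) -> np.ndarray:
    """Keep pairs whose detected fluorescence power is >= p_cut (W)."""
    if p_cut < 0:
        raise ValueError("p_cut must be >= 0")
    mask = np.asarray(raw_fluorescence, dtype=float) >= p_cut
    if not mask.any():
        raise ValueError("cut-off removed every measurement pair")
    return mask


def perturb_fibers(
    cfg: FiberConfig,
    dx_range=(-0.5, 0.5),
    dy_range=(-0.5, 0.5),
    dz_range=(-1.0, 1.0),
    seed: int = 0,
    extent=None,
) -> FiberConfig:
    """Offset each tip coordinate by a uniform draw from its interval (mm)."""
    rng = np.random.default_rng(seed)
    n = cfg.n_fibers
    offs = np.column_stack(
        [
            rng.uniform(lo, hi, n) if hi > lo else np.full(n, lo)
            for lo, hi in (dx_range, dy_range, dz_range)
        ]
    )
    tips = cfg.tip_coords + offs
    if extent is not None and (np.any(tips <= 0) or np.any(tips >= np.asarray(extent))):
        raise ValueError("perturbed fiber tip left the mesh box")
    return FiberConfig(tips)


# ---------------------------------------------------------------------------
# measurement simulation
# ---------------------------------------------------------------------------


def calibrate_power(clean_fluorescence_numerator: np.ndarray) -> float:
    """Power calibration (source power x coupling) for simulated signals.

    The Born ratio is calibration-free; only the absolute cut-off needs a
    scale.  The constant is chosen so that the weakest clean fluorescence
    power equals 1e-11 W, placing the low tail of the per-pair signals below
    the default cut-off of 4.5e-11 W — so the cut-off prunes a substantial
    minority of pairs, as in a real acquisition.  In sweep studies the
    calibration is fixed at the reference (lowest-signal) scenario and reused
    for the other levels, mimicking a fixed instrument.
    """
    weakest = float(np.min(clean_fluorescence_numerator))
    if weakest <= 0:
        raise ValueError("cannot calibrate: nonpositive fluorescence signal")
    return WEAKEST_POWER_W / weakest


@dataclass
class SimulationOutput:
    measurements: BornMeasurementSet
    mesh: TetMesh
    greens: GreenSet
    mu_af_gt: np.ndarray
    eta_gt: np.ndarray
    power_calibration: float


def simulate_measurements(
    scenario: Scenario,
    mesh: TetMesh | None = None,
    greens: GreenSet | None = None,
    noise_seed: int | None = None,
) -> SimulationOutput:
    """Simulate per-pair detected powers and Born ratios for a scenario.

    A mesh and/or Green's-function set may be supplied to reuse across
    scenario variants (e.g. a radius sweep shares one mesh and one solve set).
    By default the data mesh is built at ``scenario.data_mesh_nodes``, denser
    than a typical reconstruction forward mesh so reconstruction never runs
    on the exact discretization that generated the data.
    """
    if mesh is None:
        mesh = build_box_mesh(
            scenario.extent,
            scenario.fibers,
            target_nodes=scenario.data_mesh_nodes,
            seed=scenario.seed,
        )
    if greens is None:
        greens = green_set(mesh, scenario_optics(mesh, scenario), scenario.fibers)

    mu_af = gt_mu_af(mesh, scenario)
    yf = YieldField.from_mu_af(mu_af, scenario.gamma)
    J = jacobian(greens, mesh.nodal_volume)
    born_clean = J @ yf.eta

    pairs = pair_table(scenario.fibers.n_fibers)
    gx_tip = greens.tip["x"][pairs[:, 0], pairs[:, 1]]
    kappa = scenario.power_calibration
    numerator = born_clean * gx_tip  # unscaled fluorescence detection
    if kappa is None:
        kappa = calibrate_power(numerator)
    exc_clean = kappa * gx_tip
    flu_clean = kappa * numerator

    seed = scenario.seed if noise_seed is None else noise_seed
    rng = np.random.default_rng(seed)
    model = NoiseModel(scenario.noise_amplitude, seed)
    exc = add_noise(exc_clean, model, rng)
    flu = add_noise(flu_clean, model, rng)

    mask = apply_cutoff(flu, scenario.p_cut) if scenario.p_cut > 0 else np.ones(len(flu), bool)
    born = flu / exc

    measurements = BornMeasurementSet(
        n_fibers=scenario.fibers.n_fibers,
        born=born,
        mask=mask,
        raw_excitation=exc,
        raw_fluorescence=flu,
        p_cut=scenario.p_cut,
        seed=seed,
    )
    return SimulationOutput(
        measurements=measurements,
        mesh=mesh,
        greens=greens,
        mu_af_gt=mu_af,
        eta_gt=yf.eta,
        power_calibration=kappa,
    )
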