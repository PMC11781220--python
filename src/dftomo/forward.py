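"""Normalized-Born fluorescence forward model and measurement Jacobian.

With n interstitial fibers, every ordered source-detector pair (s, d), s != d,
yields one Born ratio: the detected fluorescence power divided by the detected
excitation power for the same pair.  The ratio cancels source power and fiber
coupling, leaving a model linear in the nodal fluorescent yield eta = gamma *
mu_af:

    F_{s,d}(eta) = sum_i Gx(r_i, r_s) Gm(r_i, r_d) eta_i dV_i / Gx(r_d, r_s).

The measurement index is the bijection f(s, d) = d - 1 + (n-1)(s-1) + p(s, d)
(1-based; p = 0 for s < d, 1 for s > d) onto 1..n(n-1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fem import GreenSet

__all__ = [
    "YieldField",
    "BornMeasurementSet",
    "pair_index",
    "pair_table",
    "born_forward",
    "jacobian",
    "residual",
    "read_measurement_csv",
    "write_measurement_csv",
]


@dataclass
class YieldField:
    """Nodal fluorescent yield eta = gamma * mu_af (cm^-1)."""

    eta: np.ndarray
    gamma: float = 0.1

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=float)
        if not 0 < self.gamma <= 1:
            raise ValueError("quantum yield gamma must be in (0, 1]")

    @property
    def mu_af(self) -> np.ndarray:
        return self.eta / self.gamma

    @classmethod
    def from_mu_af(cls, mu_af, gamma: float = 0.1) -> "YieldField":
        return cls(np.asarray(mu_af, dtype=float) * gamma, gamma)


def pair_index(s: int, d: int, n: int) -> int:
    """1-based measurement index of ordered pair (s, d) among n fibers."""
    if not (1 <= s <= n and 1 <= d <= n):
        raise ValueError(f"fiber indices must be in 1..{n}")
    if s == d:
        raise ValueError("no self-measurement: source and detector must differ")
    p = 0 if s < d else 1
    return d - 1 + (n - 1) * (s - 1) + p


def pair_table(n: int) -> np.ndarray:
    """(Nm, 2) array of 0-based (source, detector) pairs ordered by pair_index."""
    nm = n * (n - 1)
    out = np.empty((nm, 2), dtype=np.int64)
    for s in range(1, n + 1):
        for d in range(1, n + 1):
            if s == d:
                continue
            out[pair_index(s, d, n) - 1] = (s - 1, d - 1)
    return out


@dataclass
class BornMeasurementSet:
    """Born ratios for all ordered pairs, with the detector cut-off mask.

    ``born``, ``raw_excitation``, ``raw_fluorescence`` have full length
    Nm = n(n-1); discarded pairs stay in the arrays but are masked out.
    """

    n_fibers: int
    born: np.ndarray
    mask: np.ndarray = None
    raw_excitation: np.ndarray = None
    raw_fluorescence: np.ndarray = None
    p_cut: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.born = np.asarray(self.born, dtype=float)
        if self.mask is None:
            self.mask = np.ones(len(self.born), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.born) != self.nm or len(self.mask) != self.nm:
            raise ValueError(f"expected {self.nm} = n(n-1) measurement slots")
        kept = self.born[self.mask]
        if np.any(~np.isfinite(kept)) or np.any(kept <= 0):
            raise ValueError("surviving Born ratios must be finite and positive")

    @property
    def nm(self) -> int:
        return self.n_fibers * (self.n_fibers - 1)

    @property
    def nm_prime(self) -> int:
        return int(self.mask.sum())

    @property
    def kept_born(self) -> np.ndarray:
        return self.born[self.mask]


def jacobian(greens: GreenSet, nodal_volume: np.ndarray, mask=None) -> np.ndarray:
    """Sensitivity matrix J with J[f(s,d), i] = Gx(i,s) Gm(i,d) dV_i / Gx(d,s).

    The Born model is linear in eta, so J is constant and ``J @ eta`` equals
    the forward vector exactly.  Rows follow pair_index order, restricted to
    the surviving pairs when a mask is given.
    """
    n = greens.n_fibers
    pairs = pair_table(n)
    if mask is not None:
        pairs = pairs[np.asarray(mask, dtype=bool)]
    gx, gm = greens.g["x"], greens.g["m"]
    norm = greens.tip["x"][pairs[:, 0], pairs[:, 1]]
    if np.any(norm <= 0):
        raise ValueError("nonpositive excitation normalizer Gx(r_d, r_s)")
    dv = np.asarray(nodal_volume, dtype=float)
    return gx[pairs[:, 0]] * gm[pairs[:, 1]] * dv[None, :] / norm[:, None]


def born_forward(
    greens: GreenSet, yields: YieldField, nodal_volume: np.ndarray, mask=None
) -> np.ndarray:
    """Forward Born-ratio vector F(eta) over the surviving pairs."""
    return jacobian(greens, nodal_volume, mask) @ yields.eta


def residual(measured: BornMeasurementSet, forward: np.ndarray):
    """Error vector delta = M - F(eta) over surviving pairs, and its 2-norm."""
    m = measured.kept_born
    forward = np.asarray(forward, dtype=float)
    if len(forward) != len(m):
        raise ValueError(
            f"forward vector has {len(forward)} entries, expected {len(m)} surviving pairs"
        )
    delta = m - forward
    return delta, float(np.linalg.norm(delta))


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def write_measurement_csv(measured: BornMeasurementSet, path) -> None:
    pairs = pair_table(measured.n_fibers) + 1
    nan = np.full(measured.nm, np.nan)
    df = pd.DataFrame(
        {
            "source": pairs[:, 0],
            "detector": pairs[:, 1],
            "excitation_W": measured.raw_excitation
            if measured.raw_excitation is not None
            else nan,
            "fluorescence_W": measured.raw_fluorescence
            if measured.raw_fluorescence is not None
            else nan,
            "born_ratio": measured.born,
            "kept": measured.mask.astype(int),
        }
    )
    df.to_csv(path, index=False)
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "n_fibers": measured.n_fibers,
                "p_cut": measured.p_cut,
                "seed": measured.seed,
            },
            fh,
        )


def read_measurement_csv(path) -> BornMeasurementSet:
    df = pd.read_csv(path)
    n = int(df["source"].max())
    meta = {}
    try:
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        pass
    exc = df["excitation_W"].to_numpy(float)
    flu = df["fluorescence_W"].to_numpy(float)
    return BornMeasurementSet(
        n_fibers=meta.get("n_fibers", n),
        born=df["born_ratio"].to_numpy(float),
        mask=df["kept"].to_numpy(bool),
        raw_excitation=None if np.all(np.isnan(exc)) else exc,
        raw_fluorescence=None if np.all(np.isnan(flu)) else flu,
        p_cut=meta.get("p_cut", 0.0),
        seed=meta.get("seed"),
    )
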