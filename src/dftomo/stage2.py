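"""Stage-2 reconstruction: adaptive-threshold region growing and hard-prior refit.

The stage-1 image is smoother than the true fluorophore map, but its maxima
locate the inclusions.  Stage 2 segments the stage-1 field into a few
homogeneous regions, collapses the unknowns to one value per region through a
binary Nn x Nr transition matrix T (eta_nodal = T eta_regions, J2 = J T), and
refits the region values by unregularized Gauss-Newton — a single step
reaches the least-squares optimum since the Born model is linear.  The
segmentation is repeated over a grid of threshold fractions and the
regionalization with the smallest residual norm ||delta|| wins.

Region growing (peak threshold t_p, background threshold t_b):

1. Seed region r at the unassigned node with the largest value; its reference
   is the mean of the seed and all its mesh neighbors.
2. Absorb any unassigned neighbor of the region whose value is at least
   t_p * reference; repeat until no candidate remains.
3. If the largest remaining value is at least t_b * (region 1's reference),
   seed the next region; otherwise all remaining nodes become background.

Ties at the maximum break to the lowest node index, making the procedure
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix

from .fem import GreenSet
from .forward import BornMeasurementSet, jacobian, residual
from .stage1 import S1Result

__all__ = [
    "RegionPartition",
    "S2Result",
    "grow_regions",
    "threshold_candidates",
    "reduce_jacobian",
    "fit_regions",
    "reconstruct_s2",
]


@dataclass
class RegionPartition:
    """Node labels 1..Nr (background, when present, is region Nr)."""

    labels: np.ndarray
    n_regions: int
    t_p: float
    t_b: float
    has_background: bool = True

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.min() < 1 or self.labels.max() > self.n_regions:
            raise ValueError("labels must partition nodes into 1..Nr")

    @property
    def transition_matrix(self) -> csr_matrix:
        """Binary Nn x Nr matrix with T[i, j] = 1 iff node i is in region j+1."""
        n = len(self.labels)
        return csr_matrix(
            (np.ones(n), (np.arange(n), self.labels - 1)),
            shape=(n, self.n_regions),
        )

    def region_nodes(self, region_id: int) -> np.ndarray:
        return np.where(self.labels == region_id)[0]


@dataclass
class S2Result:
    eta_regions: np.ndarray  # fitted yield per region (cm^-1)
    eta_field: np.ndarray  # piecewise-constant nodal field T @ eta_regions
    partition: RegionPartition
    residual_norm: float
    candidates: list = field(default_factory=list)  # (t_p, t_b, Nr, ||delta||)


def grow_regions(mu_af_s1: np.ndarray, adjacency, t_p: float, t_b: float) -> RegionPartition:
    """Adaptive-threshold region growing on the mesh adjacency graph."""
    v = np.asarray(mu_af_s1, dtype=float)
    if v.size == 0:
        raise ValueError("empty mesh")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values in the stage-1 field")
    if not (0 < t_p < 1 and 0 < t_b < 1):
        raise ValueError("threshold fractions must be in (0, 1)")
    adjacency = csr_matrix(adjacency, dtype=bool)

    n = len(v)
    labels = np.zeros(n, dtype=np.int64)
    unassigned = np.ones(n, dtype=bool)
    ref1 = None
    region = 0
    while unassigned.any():
        # seed: largest unassigned value (argmax ties -> lowest index)
        masked = np.where(unassigned, v, -np.inf)
        seed = int(np.argmax(masked))
        if ref1 is not None and v[seed] < t_b * ref1:
            break  # everything left is background
        region += 1
        nbr = adjacency.indices[adjacency.indptr[seed] : adjacency.indptr[seed + 1]]
        ref_r = float(np.mean(np.append(v[nbr], v[seed])))
        if ref1 is None:
            ref1 = ref_r
        members = np.zeros(n, dtype=bool)
        members[seed] = True
        while True:
            reach = (adjacency @ members.astype(np.float64)) > 0
            frontier = reach & unassigned & ~members
            cand = frontier & (v >= t_p * ref_r)
            if not cand.any():
                break
            members |= cand
        labels[members] = region
        unassigned &= ~members

    if unassigned.any():
        region += 1
        labels[unassigned] = region
        has_bg = True
    else:
        has_bg = False
    return RegionPartition(labels, region, t_p, t_b, has_background=has_bg)


def threshold_candidates(mode: str = "equal") -> list[tuple[float, float]]:
    """Candidate (t_p, t_b) grids: nine equidistant fractions spanning 0.33-0.87.

    ``equal`` pairs each fraction with itself (9 candidates); ``ordered``
    allows independent peak/background fractions with t_b <= t_p (45).
    """
    grid = np.linspace(0.33, 0.87, 9)
    if mode == "equal":
        return [(float(t), float(t)) for t in grid]
    if mode == "ordered":
        return [
            (float(tp), float(tb)) for tp in grid for tb in grid if tb <= tp + 1e-12
        ]
    raise ValueError(f"unknown threshold mode {mode!r}")


def reduce_jacobian(J_full: np.ndarray, T: csr_matrix) -> np.ndarray:
    """Hard-prior reduction J2 = J T (region column = sum of member columns)."""
    counts = np.asarray(T.sum(axis=0)).ravel()
    if np.any(counts == 0):
        raise ValueError("transition matrix has an empty region column")
    return np.asarray(J_full @ T)


def fit_regions(
    measured: BornMeasurementSet,
    greens: GreenSet,
    partition: RegionPartition,
    eta_s1: np.ndarray,
    nodal_volume: np.ndarray | None = None,
    J_full: np.ndarray | None = None,
    max_iter: int = 20,
    rel_decrease_stop: float = 0.02,
) -> S2Result:
    """Gauss-Newton refit of per-region yields for one fixed partition.

    Starts from the region means of the stage-1 field; since the model is
    linear in eta, the first step already attains the least-squares optimum
    (the loop is kept for contract symmetry with stage 1).
    """
    if J_full is None:
        dv = greens.mesh.nodal_volume if nodal_volume is None else nodal_volume
        J_full = jacobian(greens, dv, measured.mask)
    T = partition.transition_matrix
    J2 = reduce_jacobian(J_full, T)
    if partition.n_regions > measured.nm_prime:
        raise ValueError("more regions than surviving measurements (underdetermined)")

    counts = np.asarray(T.sum(axis=0)).ravel()
    eta2 = np.asarray(T.T @ np.asarray(eta_s1, dtype=float)).ravel() / counts

    h = J2.T @ J2
    rank = np.linalg.matrix_rank(h)
    if rank < partition.n_regions:
        raise np.linalg.LinAlgError(
            f"indistinguishable regions: J2^T J2 has rank {rank} < {partition.n_regions}"
        )
    m = measured.kept_born
    prev = None
    for _ in range(max_iter):
        delta, norm = residual(measured, J2 @ eta2)
        if prev is not None and (prev - norm) / max(prev, 1e-300) < rel_decrease_stop:
            break
        prev = norm
        eta2 = eta2 + np.linalg.solve(h, J2.T @ delta)
    _, norm = residual(measured, J2 @ eta2)
    return S2Result(
        eta_regions=eta2,
        eta_field=np.asarray(T @ eta2),
        partition=partition,
        residual_norm=norm,
    )


def reconstruct_s2(
    measured: BornMeasurementSet,
    greens: GreenSet,
    s1: S1Result,
    mode: str = "equal",
    nodal_volume: np.ndarray | None = None,
    J_full: np.ndarray | None = None,
    adjacency=None,
) -> S2Result:
    """Full stage 2: grow regions for every threshold candidate, refit, select.

    Negative stage-1 lobes are clamped to zero before region growing so that
    spurious negative peaks cannot seed regions.  Candidates whose partitions
    coincide are fitted once.  Returns the minimal-residual candidate with the
    complete candidate table (t_p, t_b, Nr, residual norm).
    """
    if J_full is None:
        dv = greens.mesh.nodal_volume if nodal_volume is None else nodal_volume
        J_full = jacobian(greens, dv, measured.mask)
    if adjacency is None:
        adjacency = greens.mesh.node_adjacency
    field_s1 = np.clip(np.asarray(s1.eta_s1, dtype=float), 0.0, None)

    best: S2Result | None = None
    candidates = []
    cache: dict[bytes, S2Result] = {}
    for t_p, t_b in threshold_candidates(mode):
        part = grow_regions(field_s1, adjacency, t_p, t_b)
        key = part.labels.tobytes()
        if key in cache:
            fit = cache[key]
        else:
            try:
                fit = fit_regions(
                    measured, greens, part, field_s1, J_full=J_full
                )
            except (np.linalg.LinAlgError, ValueError):
                candidates.append((t_p, t_b, part.n_regions, np.inf))
                continue
            cache[key] = fit
        candidates.append((t_p, t_b, part.n_regions, fit.residual_norm))
        if best is None or fit.residual_norm < best.residual_norm:
            best = S2Result(
                eta_regions=fit.eta_regions,
                eta_field=fit.eta_field,
                partition=RegionPartition(
                    part.labels, part.n_regions, t_p, t_b, part.has_background
                ),
                residual_norm=fit.residual_norm,
            )
    if best is None:
        raise ValueError("all threshold candidates produced degenerate partitions")
    best.candidates = candidates
    return best
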