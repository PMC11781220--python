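"""Stage-1 nodal reconstruction: damped (Levenberg-Marquardt) Tikhonov inversion.

The Tikhonov objective is

    Omega(eta) = ||M - F(eta)||^2 + lambda ||L (eta - eta0)||^2,

minimized by the modified Levenberg-Marquardt iteration

    eta_{i+1} = eta_i + (J^T J + lambda_i L^T L)^{-1} J^T delta(eta_i),

with the damping initialized to the largest diagonal entry of the Hessian
J^T J and decayed geometrically, lambda_i = max diag(J^T J) * 10^(-i/4).
Iteration stops when the residual norm ||delta|| decreases by less than 2%
relative, or after max_iter (default 20) updates.

The update runs on a coarser reconstruction mesh: with P the barycentric
prolongation matrix from reconstruction nodes to forward nodes, the effective
Jacobian is J P and the updated coarse field is prolonged back after every
iteration.  For the identity regularizer the damped normal equations are
solved through the measurement-space (Woodbury) form, which is exact and
avoids forming the Nn x Nn Hessian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy.sparse import csr_matrix, identity, issparse

from .fem import GreenSet
from .forward import BornMeasurementSet, jacobian
from .mesh import TetMesh, interpolation_matrix

__all__ = [
    "RegularizationSpec",
    "S1Result",
    "soft_prior_matrix",
    "lambda_schedule",
    "lm_update",
    "reconstruct_s1",
]


@dataclass
class RegularizationSpec:
    """Regularization matrix, damping schedule and stopping rule for stage 1."""

    L: object = None  # None -> identity
    lambda0: float | None = None  # None -> max diag(J^T J)
    eta0: np.ndarray | float | None = None
    max_iter: int = 20
    rel_decrease_stop: float = 0.02
    include_prior_term: bool = False  # full update with -lambda L^T L (eta - eta0)


@dataclass
class S1Result:
    eta_s1: np.ndarray  # nodal yields on the forward mesh
    residual_trace: list = field(default_factory=list)
    lambda_trace: list = field(default_factory=list)
    n_iter: int = 0
    eta_recon: np.ndarray = None  # coarse-mesh solution


def soft_prior_matrix(labels) -> csr_matrix:
    """Soft-prior regularization matrix: unit diagonal, -1/N_R off-diagonals
    for node pairs sharing a region, zero otherwise."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label set")
    n = len(labels)
    rows, cols, vals = [np.arange(n)], [np.arange(n)], [np.ones(n)]
    for lab in np.unique(labels):
        members = np.where(labels == lab)[0]
        nr = len(members)
        if nr < 2:
            continue
        r = np.repeat(members, nr)
        c = np.tile(members, nr)
        off = r != c
        rows.append(r[off])
        cols.append(c[off])
        vals.append(np.full(off.sum(), -1.0 / nr))
    return csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )


def lambda_schedule(hessian_diag_max: float, i: int) -> float:
    """Damping at iteration i: max diag(J^T J) * 10^(-i/4)."""
    if hessian_diag_max <= 0:
        raise ValueError("hessian_diag_max must be positive")
    return float(hessian_diag_max) * 10.0 ** (-i / 4.0)


def lm_update(
    eta_i: np.ndarray,
    J: np.ndarray,
    delta: np.ndarray,
    lambda_i: float,
    L=None,
    eta0=None,
    include_prior_term: bool = False,
) -> np.ndarray:
    """One damped-normal-equations update.

    With ``include_prior_term`` the full Tikhonov gradient step
    ``(J^T J + lam L^T L)^{-1} (J^T delta - lam L^T L (eta - eta0))`` is taken;
    the default drops the prior-pull term (modified Levenberg-Marquardt).
    """
    eta_i = np.asarray(eta_i, dtype=float)
    n = len(eta_i)
    if L is None and not include_prior_term and n > len(delta):
        # identity regularizer: solve in measurement space (exact Woodbury form)
        m = J @ J.T
        m[np.diag_indices_from(m)] += lambda_i
        try:
            cf = sla.cho_factor(m)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "singular damped system; increase lambda or coarsen the reconstruction mesh"
            ) from err
        return eta_i + J.T @ sla.cho_solve(cf, delta)

    Lmat = identity(n, format="csr") if L is None else L
    ltl = (Lmat.T @ Lmat).toarray() if issparse(Lmat) else np.asarray(Lmat).T @ np.asarray(Lmat)
    h = J.T @ J + lambda_i * ltl
    rhs = J.T @ delta
    if include_prior_term:
        e0 = np.zeros(n) if eta0 is None else np.broadcast_to(np.asarray(eta0, float), (n,))
        rhs = rhs - lambda_i * (ltl @ (eta_i - e0))
    try:
        cf = sla.cho_factor(h)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular damped system; increase lambda or coarsen the reconstruction mesh"
        ) from err
    return eta_i + sla.cho_solve(cf, rhs)


def reconstruct_s1(
    measured: BornMeasurementSet,
    greens: GreenSet,
    fwd_mesh: TetMesh,
    recon_mesh: TetMesh | None = None,
    reg: RegularizationSpec | None = None,
    J_fwd: np.ndarray | None = None,
) -> S1Result:
    """Levenberg-Marquardt stage-1 reconstruction on the dual-mesh system.

    ``recon_mesh=None`` (or the forward mesh itself) solves directly on the
    forward mesh.  A precomputed forward-mesh Jacobian may be passed to avoid
    recomputation across repeated reconstructions.
    """
    if measured.nm_prime == 0:
        raise ValueError("no surviving measurements")
    reg = reg or RegularizationSpec()
    if J_fwd is None:
        J_fwd = jacobian(greens, fwd_mesh.nodal_volume, measured.mask)

    matched = recon_mesh is None or recon_mesh is fwd_mesh
    if matched:
        P = None
        J = J_fwd
        n_rec = fwd_mesh.n_nodes
    else:
        P = interpolation_matrix(recon_mesh, fwd_mesh.node_coords)  # (Nfwd, Nrec)
        J = np.asarray(J_fwd @ P)
        n_rec = recon_mesh.n_nodes

    m = measured.kept_born
    scale = float(np.max(np.abs(m))) if np.max(np.abs(m)) > 0 else 1.0
    # default initial guess: small uniform positive field, 1e-4 of the data scale
    if reg.eta0 is None:
        eta = np.full(n_rec, 1e-4 * scale / max(np.max(J.sum(axis=1)), 1e-300))
    elif np.isscalar(reg.eta0):
        eta = np.full(n_rec, float(reg.eta0))
    else:
        eta0 = np.asarray(reg.eta0, dtype=float)
        if len(eta0) == n_rec:
            eta = eta0.copy()
        elif not matched and len(eta0) == fwd_mesh.n_nodes:
            R = interpolation_matrix(fwd_mesh, recon_mesh.node_coords)
            eta = R @ eta0
        else:
            raise ValueError("eta0 length matches neither mesh")
    eta_start = eta.copy()

    lam0 = reg.lambda0
    if lam0 is None:
        lam0 = float(np.max(np.einsum("mi,mi->i", J, J)))  # max diag(J^T J)

    res_trace: list[float] = []
    lam_trace: list[float] = []
    prev = None
    for i in range(reg.max_iter):
        delta = m - J @ eta
        norm = float(np.linalg.norm(delta))
        if prev is not None:
            if norm > prev:
                eta = eta_prev  # reject the step that increased the residual
                break
            res_trace.append(norm)
            if prev == 0.0 or (prev - norm) / prev < reg.rel_decrease_stop:
                prev = norm
                break
        else:
            res_trace.append(norm)
            if norm == 0.0:
                break
        prev = norm
        lam = lambda_schedule(lam0, i)
        lam_trace.append(lam)
        eta_prev = eta
        eta = lm_update(
            eta, J, delta, lam, reg.L,
            eta0=eta_start if reg.include_prior_term else None,
            include_prior_term=reg.include_prior_term,
        )

    eta_fwd = eta if matched else P @ eta
    return S1Result(
        eta_s1=np.asarray(eta_fwd),
        residual_trace=res_trace,
        lambda_trace=lam_trace,
        n_iter=len(lam_trace),
        eta_recon=np.asarray(eta),
    )
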