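"""Galerkin finite-element solver for the continuous-wave diffusion equation.

The steady-state diffusion approximation for light transport in a highly
scattering medium (mu_a << mu_s') reads

    (-div D(r) grad + mu_a(r)) Phi(r) = q0(r),      D = 1 / (3 mu_s'),

with a Robin boundary condition parameterized by the effective Fresnel
coefficient A.  On a linear-tetrahedron mesh the Galerkin discretization
yields the sparse symmetric system

    (K + C + B / (2A)) Phi = Q,

with K the diffusion stiffness matrix, C the absorption mass matrix and B the
boundary mass matrix; all element integrals are evaluated in closed form for
element-constant coefficients (mean of the four nodal values).  Units are cm
throughout this module (mesh coordinates are converted from mm on assembly).

Green's functions for every fiber tip are obtained by placing a unit point
source at the tip and reusing a single sparse factorization across fibers;
by reciprocity of the symmetric operator the solution sampled at another tip
equals the detector-side Green's function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import splu

from .mesh import FiberConfig, TetMesh, interpolation_matrix

__all__ = [
    "OpticalField",
    "SystemMatrix",
    "GreenSet",
    "assemble",
    "source_vector",
    "solve_fluence",
    "analytic_green_infinite",
    "green_set",
]

MM_PER_CM = 10.0


@dataclass
class OpticalField:
    """Per-node absorption and reduced scattering (cm^-1) per wavelength tag.

    Tags are ``"x"`` (excitation) and ``"m"`` (fluorescence emission).  A tag
    missing from the dictionaries falls back to ``"x"`` — interstitial
    photosensitizer imaging typically assumes the two wavelengths propagate
    identically.
    """

    mu_a: dict
    mu_s_prime: dict
    fresnel_A: float = 1.0

    @classmethod
    def homogeneous(
        cls,
        mesh: TetMesh,
        mu_a: float,
        mu_s_prime: float,
        fresnel_A: float = 1.0,
        mu_a_m: float | None = None,
        mu_s_prime_m: float | None = None,
    ) -> "OpticalField":
        n = mesh.n_nodes
        mua = {"x": np.full(n, float(mu_a))}
        musp = {"x": np.full(n, float(mu_s_prime))}
        if mu_a_m is not None:
            mua["m"] = np.full(n, float(mu_a_m))
        if mu_s_prime_m is not None:
            musp["m"] = np.full(n, float(mu_s_prime_m))
        return cls(mua, musp, fresnel_A)

    def __post_init__(self) -> None:
        for d in (self.mu_a, self.mu_s_prime):
            for k, v in d.items():
                d[k] = np.asarray(v, dtype=float)
                if np.any(d[k] <= 0):
                    raise ValueError(f"optical coefficient '{k}' must be positive")
        for tag in self.mu_a:
            mua, musp = self.mu_a[tag], self.absorption_partner(tag)
            if np.any(mua > 0.1 * musp):
                warnings.warn(
                    "mu_a exceeds 0.1*mu_s'; the diffusion approximation is strained",
                    stacklevel=2,
                )

    def absorption_partner(self, tag: str) -> np.ndarray:
        return self.mu_s_prime.get(tag, self.mu_s_prime["x"])

    def absorption(self, tag: str) -> np.ndarray:
        return self.mu_a.get(tag, self.mu_a["x"])

    def scattering(self, tag: str) -> np.ndarray:
        return self.mu_s_prime.get(tag, self.mu_s_prime["x"])

    def diffusion(self, tag: str) -> np.ndarray:
        return 1.0 / (3.0 * self.scattering(tag))

    def mu_eff(self, tag: str) -> np.ndarray:
        return np.sqrt(3.0 * self.absorption(tag) * self.scattering(tag))

    def same_at_both_wavelengths(self) -> bool:
        return (
            np.array_equal(self.absorption("x"), self.absorption("m"))
            and np.array_equal(self.scattering("x"), self.scattering("m"))
        )


@dataclass
class SystemMatrix:
    """Assembled FEM operator ``A = K + C + B/(2A_fresnel)`` (units cm)."""

    K: csr_matrix
    C: csr_matrix
    B: csr_matrix
    fresnel_A: float
    _lu: object = field(default=None, repr=False)

    @property
    def A(self) -> csr_matrix:
        return (self.K + self.C + self.B / (2.0 * self.fresnel_A)).tocsr()

    def factorize(self):
        if self._lu is None:
            self._lu = splu(self.A.tocsc())
        return self._lu


def assemble(mesh: TetMesh, optics: OpticalField, wavelength: str = "x") -> SystemMatrix:
    """Assemble stiffness, absorption-mass and boundary-mass matrices.

    Element coefficients are the arithmetic means of the four nodal values.
    Closed-form linear-tet integrals: mass matrix ``V (1+delta_ij)/20``,
    boundary-triangle mass ``area (1+delta_ij)/12``.
    """
    coords = mesh.node_coords / MM_PER_CM  # cm
    tets = mesh.elements
    p = coords[tets]
    m = p[:, 1:] - p[:, :1]  # (Ne,3,3)
    det = np.linalg.det(m)
    vol = np.abs(det) / 6.0
    if np.any(vol <= 0):
        bad = int(np.argmin(vol))
        raise ValueError(f"degenerate element {bad} (zero volume)")

    inv = np.linalg.inv(m)  # rows of inv.T are gradients of barycentric coords 1..3
    g = np.empty((len(tets), 4, 3))
    g[:, 1:, :] = np.transpose(inv, (0, 2, 1))
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)

    d_e = optics.diffusion(wavelength)[tets].mean(axis=1)
    mua_e = optics.absorption(wavelength)[tets].mean(axis=1)

    ke = np.einsum("eia,eja->eij", g, g) * (d_e * vol)[:, None, None]
    mass = (np.ones((4, 4)) + np.eye(4)) / 20.0
    ce = mass[None, :, :] * (mua_e * vol)[:, None, None]

    rows = np.repeat(tets, 4, axis=1).ravel()
    cols = np.tile(tets, (1, 4)).ravel()
    n = mesh.n_nodes
    K = coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    C = coo_matrix((ce.ravel(), (rows, cols)), shape=(n, n)).tocsr()

    faces = mesh.boundary_faces
    q = coords[faces]
    area = 0.5 * np.linalg.norm(
        np.cross(q[:, 1] - q[:, 0], q[:, 2] - q[:, 0]), axis=1
    )
    tmass = (np.ones((3, 3)) + np.eye(3)) / 12.0
    be = tmass[None, :, :] * area[:, None, None]
    brows = np.repeat(faces, 3, axis=1).ravel()
    bcols = np.tile(faces, (1, 3)).ravel()
    B = coo_matrix((be.ravel(), (brows, bcols)), shape=(n, n)).tocsr()

    return SystemMatrix(K, C, B, optics.fresnel_A)


def source_vector(mesh: TetMesh, position_mm) -> np.ndarray:
    """Unit point source distributed to the containing element's nodes.

    The entries are the barycentric weights of the source position, so they
    sum to the source strength (1) exactly.
    """
    from .mesh import locate_point

    e, w = locate_point(mesh, position_mm)
    q = np.zeros(mesh.n_nodes)
    q[mesh.elements[e]] = w
    return q


def solve_fluence(sys: SystemMatrix, q: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Solve ``A Phi = Q`` by sparse LU; verifies the relative residual."""
    lu = sys.factorize()
    phi = lu.solve(q)
    if not np.all(np.isfinite(phi)):
        raise np.linalg.LinAlgError(
            "singular or indefinite diffusion system (is mu_a zero everywhere?)"
        )
    qn = np.linalg.norm(q)
    if qn > 0:
        res = np.linalg.norm(sys.A @ phi - q) / qn
        if res > rtol:
            raise np.linalg.LinAlgError(f"solver residual {res:.2e} exceeds {rtol:.0e}")
    return phi


def analytic_green_infinite(dist_cm, mu_a: float, mu_s_prime: float):
    """Infinite-medium CW Green's function exp(-mu_eff d) / (4 pi D d).

    ``dist_cm`` may be scalar or array (cm); returns fluence per unit source
    power (cm^-2).
    """
    d = np.asarray(dist_cm, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance must be positive (point-source singularity at 0)")
    diff = 1.0 / (3.0 * mu_s_prime)
    mu_eff = np.sqrt(mu_a / diff)
    out = np.exp(-mu_eff * d) / (4.0 * np.pi * diff * d)
    return float(out) if np.isscalar(dist_cm) else out


@dataclass
class GreenSet:
    """Nodal Green's functions for every fiber at both wavelength tags.

    ``g[tag]`` has shape (n_fibers, Nn): row f is the fluence everywhere for a
    unit source at fiber tip f.  ``tip[tag][s, d]`` is the fluence at tip d
    for a source at tip s (symmetric up to solver tolerance, by reciprocity).
    """

    g: dict
    tip: dict
    fibers: FiberConfig
    mesh: TetMesh

    @property
    def n_fibers(self) -> int:
        return self.fibers.n_fibers


def green_set(mesh: TetMesh, optics: OpticalField, fibers: FiberConfig) -> GreenSet:
    """One diffusion solve per fiber per distinct wavelength, shared factorization."""
    sample = interpolation_matrix(mesh, fibers.tip_coords)  # (nf, Nn)
    sources = np.column_stack([source_vector(mesh, t) for t in fibers.tip_coords])

    tags = ["x"] if optics.same_at_both_wavelengths() else ["x", "m"]
    g: dict[str, np.ndarray] = {}
    for tag in tags:
        sys = assemble(mesh, optics, tag)
        lu = sys.factorize()
        sol = lu.solve(sources)  # (Nn, nf)
        g[tag] = np.clip(sol.T, 0.0, None)
    if "m" not in g:
        g["m"] = g["x"]
    tip = {tag: np.asarray(sample @ g[tag].T).T for tag in ("x", "m")}
    return GreenSet(g=g, tip=tip, fibers=fibers, mesh=mesh)
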