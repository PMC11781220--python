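"""Reconstruction quality metrics and slice export.

Metrics (all signed percentages unless noted):

* ``dV_i`` — relative error of the reconstructed inclusion volume against the
  analytic ground-truth sphere volume;
* ``d_mu_af_i`` / ``d_mu_af_bg`` — relative errors of the fitted region
  fluorophore absorption against the ground-truth inclusion / background
  values;
* ``mean_abs_rel_err`` (<|e|>) — node-averaged absolute relative error of the
  reconstructed fluorophore absorption over the whole medium; defined after
  both stages and the primary witness of the two-stage benefit.

The inclusion region is identified as the fitted region with the highest
fluorophore absorption; the background as the region holding the most nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TetMesh, interpolation_matrix
from .stage2 import RegionPartition, S2Result

__all__ = [
    "MetricsReport",
    "region_volume",
    "identify_regions",
    "relative_errors",
    "mean_abs_rel_err",
    "export_slice",
]


@dataclass
class MetricsReport:
    dV_i: float
    d_mu_af_i: float
    d_mu_af_bg: float | None
    mean_abs_rel_err_s2: float | None
    mean_abs_rel_err_s1: float | None
    n_regions: int
    inclusion_region: int
    background_region: int
    volume_recon_cm3: float
    bg_metric_is_scaled_absolute: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def region_volume(partition: RegionPartition, nodal_volume: np.ndarray, region_id: int) -> float:
    """Summed lumped nodal volume (cm^3) of a region."""
    if not 1 <= region_id <= partition.n_regions:
        raise ValueError(f"unknown region id {region_id}")
    nodes = partition.region_nodes(region_id)
    return float(np.asarray(nodal_volume)[nodes].sum())


def identify_regions(s2: S2Result) -> tuple[int, int]:
    """(inclusion, background) region ids: highest fitted value / most nodes."""
    values = np.asarray(s2.eta_regions)
    inclusion = int(np.argmax(values)) + 1
    counts = np.bincount(s2.partition.labels, minlength=s2.partition.n_regions + 1)[1:]
    background = int(np.argmax(counts)) + 1
    return inclusion, background


def mean_abs_rel_err(recon_field, gt_field, zero_ref: float | None = None) -> float:
    """Node-averaged absolute relative error, percent: mean |recon-gt|/gt * 100.

    Nodes where the ground truth is zero are normalized by ``zero_ref``
    (default: the ground-truth maximum) — relevant only for zero-background
    studies, where the paper reports region metrics instead.
    """
    recon = np.asarray(recon_field, dtype=float)
    gt = np.asarray(gt_field, dtype=float)
    if np.all(gt == 0):
        raise ValueError("metric undefined for an all-zero ground truth")
    denom = gt.copy()
    if np.any(gt == 0):
        denom[gt == 0] = zero_ref if zero_ref is not None else gt.max()
    return float(np.mean(np.abs(recon - gt) / denom) * 100.0)


def relative_errors(
    s2: S2Result,
    gt_field: np.ndarray,
    gt_sphere: dict,
    nodal_volume: np.ndarray,
    gamma: float = 0.1,
    s1_field: np.ndarray | None = None,
) -> MetricsReport:
    """Region-level and node-level error report for a stage-2 result.

    ``gt_sphere`` needs keys ``radius`` (mm), ``mu_af_inclusion`` and
    ``mu_af_background`` (cm^-1).  Fields are fluorescent-yield fields (eta);
    relative errors are invariant to the gamma scaling.
    """
    inc, bg = identify_regions(s2)
    v_gt = 4.0 / 3.0 * np.pi * (gt_sphere["radius"] / 10.0) ** 3  # cm^3
    v_rec = region_volume(s2.partition, nodal_volume, inc)
    dv = (v_rec - v_gt) / v_gt * 100.0

    mu_rec = np.asarray(s2.eta_regions) / gamma
    mu_i_gt = gt_sphere["mu_af_inclusion"]
    mu_bg_gt = gt_sphere["mu_af_background"]
    d_i = (mu_rec[inc - 1] - mu_i_gt) / mu_i_gt * 100.0

    scaled_abs = False
    if mu_bg_gt > 0:
        d_bg = (mu_rec[bg - 1] - mu_bg_gt) / mu_bg_gt * 100.0
    else:
        # zero-background study: absolute error scaled by the GT inclusion value
        d_bg = mu_rec[bg - 1] / mu_i_gt * 100.0
        scaled_abs = True

    gt = np.asarray(gt_field, dtype=float)
    zero_ref = gt.max()
    e2 = mean_abs_rel_err(s2.eta_field, gt, zero_ref)
    e1 = mean_abs_rel_err(s1_field, gt, zero_ref) if s1_field is not None else None

    return MetricsReport(
        dV_i=float(dv),
        d_mu_af_i=float(d_i),
        d_mu_af_bg=float(d_bg),
        mean_abs_rel_err_s2=e2,
        mean_abs_rel_err_s1=e1,
        n_regions=s2.partition.n_regions,
        inclusion_region=inc,
        background_region=bg,
        volume_recon_cm3=v_rec,
        bg_metric_is_scaled_absolute=scaled_abs,
    )


def export_slice(field, mesh: TetMesh, z_mm: float, nx: int = 80, ny: int = 80):
    """Sample a nodal field on a regular xy grid at height z (mm).

    Returns (x, y, raster) with raster shape (ny, nx); values outside the
    mesh hull take the nearest-node value, matching the interpolation rule.
    """
    lo, hi = mesh.bounding_box()
    if not lo[2] - 1e-9 <= z_mm <= hi[2] + 1e-9:
        raise ValueError(f"slice height {z_mm} mm outside the mesh")
    x = np.linspace(lo[0], hi[0], nx)
    y = np.linspace(lo[1], hi[1], ny)
    xx, yy = np.meshgrid(x, y)
    pts = np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, z_mm)])
    vals = interpolation_matrix(mesh, pts) @ np.asarray(field, dtype=float)
    return x, y, vals.reshape(ny, nx)
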