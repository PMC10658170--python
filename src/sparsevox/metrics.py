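"""Segmentation-mask evaluation: DSC, reconstruction error, implant
extraction, border DSC and HD95.

Conventions for degenerate inputs (both masks empty -> DSC 1, HD95 0) are
chosen so tests on empty grids are well-defined; every convention is recorded
in the report itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .voxgrid import VoxelGrid

logger = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class MetricReport:
    """All evaluation quantities for one prediction/ground-truth pair."""

    dsc: float
    re_percent: float
    misclassified: int
    total: int
    bdsc: float | None = None
    band_radius: int | None = None
    hd95: float | None = None
    conventions: str = "both-empty: dsc=1, hd95=0; re over all grid voxels"

    def as_dict(self) -> dict:
        return asdict(self)


def dsc(pred: VoxelGrid, gt: VoxelGrid) -> float:
    """Dice similarity coefficient 2|P∩G| / (|P|+|G|); 1 if both are empty."""
    p, g = pred.data.astype(bool), gt.data.astype(bool)
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        logger.info("DSC of two empty masks: 1 by convention")
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def reconstruction_error(pred: VoxelGrid, gt: VoxelGrid) -> tuple[float, int]:
    """Percentage of misclassified voxels and their count (|P △ G|)."""
    mis = int((pred.data.astype(bool) ^ gt.data.astype(bool)).sum())
    total = pred.data.size
    return 100.0 * mis / total, mis


def misclassified_from_re(re_percent: float, total_voxels: int) -> int:
    """Back-compute the misclassified-voxel count from a printed RE percentage.

    Truncation (floor) convention on the product RE * total / 100.
    """
    return int(re_percent * total_voxels / 100.0)


def extract_implant(
    completed: VoxelGrid, defective: VoxelGrid, cleanup: bool = True
) -> VoxelGrid:
    """The implant is the completed skull minus the defective input.

    ``cleanup`` keeps only the largest 26-connected component of the
    difference (on for reports; off when exact set identities are asserted).
    """
    diff = completed.data.astype(bool) & ~defective.data.astype(bool)
    if cleanup and diff.any():
        lab, num = ndimage.label(diff, structure=_CONN26)
        if num > 1:
            sizes = ndimage.sum_labels(diff, lab, index=np.arange(1, num + 1))
            diff = lab == (1 + int(np.argmax(sizes)))
    return VoxelGrid(diff.astype(np.uint8), completed.spacing, completed.origin)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels: occupied voxels with at least one 6-neighbour outside."""
    if not mask.any():
        return mask
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(3, 1))
    return mask & ~eroded


def hd95(pred: VoxelGrid, gt: VoxelGrid, spacing=None) -> float:
    """95th percentile of the pooled symmetric surface distances.

    Distances are between boundary voxel sets, scaled by the per-axis physical
    spacing.  Empty masks: 0 if both empty, otherwise the grid diagonal as a
    defined worst-case sentinel (logged).
    """
    p = pred.data.astype(bool)
    g = gt.data.astype(bool)
    if spacing is None:
        spacing = pred.spacing
    sp = np.asarray(spacing, dtype=np.float64)
    if not p.any() and not g.any():
        return 0.0
    if not p.any() or not g.any():
        diag = float(np.linalg.norm(np.asarray(pred.shape) * sp))
        logger.warning("hd95 with one empty mask: returning grid diagonal %.3f", diag)
        return diag
    pb = np.argwhere(_boundary(p)) * sp
    gb = np.argwhere(_boundary(g)) * sp
    d_pg = cKDTree(gb).query(pb, k=1)[0]
    d_gp = cKDTree(pb).query(gb, k=1)[0]
    return float(np.percentile(np.concatenate([d_pg, d_gp]), 95))


def border_dsc(
    pred_implant: VoxelGrid,
    gt_implant: VoxelGrid,
    band_radius: int = 2,
) -> float:
    """DSC restricted to a Chebyshev band around the ground-truth implant border.

    The band is the morphological dilation (cubic structuring element of
    half-width ``band_radius``) of the ground-truth implant's boundary
    surface; this emphasises rim fit, the clinically critical region.
    """
    g = gt_implant.data.astype(bool)
    p = pred_implant.data.astype(bool)
    if not g.any():
        return 1.0 if not p.any() else 0.0
    border = _boundary(g)
    size = 2 * band_radius + 1
    band = ndimage.binary_dilation(border, structure=np.ones((size, size, size), dtype=bool))
    return dsc(
        VoxelGrid((p & band).astype(np.uint8)),
        VoxelGrid((g & band).astype(np.uint8)),
    )


def evaluate(
    pred: VoxelGrid,
    gt: VoxelGrid,
    defective: VoxelGrid | None = None,
    band_radius: int = 2,
    with_hd95: bool = True,
) -> MetricReport:
    """Full report for a prediction/ground-truth pair.

    When ``defective`` is given, border DSC is computed between the implants
    extracted from prediction and ground truth.
    """
    re, mis = reconstruction_error(pred, gt)
    report = MetricReport(
        dsc=dsc(pred, gt),
        re_percent=re,
        misclassified=mis,
        total=pred.data.size,
    )
    if with_hd95:
        report.hd95 = hd95(pred, gt)
    if defective is not None:
        pred_imp = extract_implant(pred, defective, cleanup=True)
        gt_imp = extract_implant(gt, defective, cleanup=False)
        report.bdsc = border_dsc(pred_imp, gt_imp, band_radius)
        report.band_radius = band_radius
    return report
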