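"""Equidistant laminar segmentation of the cortical ribbon.

The cortical grey matter (GM) ribbon is bounded by the pial surface
(GM-CSF interface) and the white-matter surface (GM-WM interface).  Each
GM voxel is assigned a normalized cortical depth

    d = D_pial / (D_pial + D_wm)

where ``D_pial`` and ``D_wm`` are Euclidean distances (in mm) to the two
boundary voxel sets; binning ``d`` into K equal-width bins yields K
equidistant laminae.  With the default K = 8 the innermost and outermost
laminae are discarded (they are dominated by partial-volume voxels) and
the six retained laminae are relabelled I-VI, I being the pial-most.

The same machinery applies to 2D histological sections, where the two
boundaries arrive as hand-drawn polylines instead of masks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "LabelVolume",
    "extract_boundaries",
    "compute_depth",
    "assign_laminae",
    "retain_layers",
    "parcel_thickness_qc",
    "layering_2d",
    "rasterize_polyline",
]

#: number of laminae the ribbon is divided into before exclusion
DEFAULT_K = 8


@dataclass
class LabelVolume:
    """An integer label grid (2D or 3D) with physical voxel spacing.

    Houses GM/WM masks, ROI parcellations, lamina labels.  ``affine`` is
    an optional NIfTI-style voxel-to-world matrix kept for round-trips.
    """

    values: np.ndarray
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer) and not (
            self.values.dtype == bool
        ):
            raise TypeError("LabelVolume requires an integer or boolean array")
        if self.values.min() < 0:
            raise ValueError("labels must be non-negative")
        vs = tuple(float(v) for v in self.voxel_size_mm)[: self.values.ndim]
        if any(v <= 0 for v in vs):
            raise ValueError("voxel spacing must be positive")
        self.voxel_size_mm = vs

    @property
    def mask(self) -> np.ndarray:
        return self.values > 0


def _face_structure(ndim: int) -> np.ndarray:
    """Face-connected structuring element (6-conn in 3D, 4-conn in 2D)."""
    return ndimage.generate_binary_structure(ndim, 1)


def extract_boundaries(gm_mask: np.ndarray, wm_mask: np.ndarray):
    """Locate pial- and WM-surface voxels of the GM ribbon.

    The WM boundary is the set of GM voxels face-adjacent to WM; the pial
    boundary is the set of GM voxels face-adjacent to anything that is
    neither GM nor WM (CSF / background).  Both are subsets of GM, found
    by dilating the neighbouring compartment by one voxel and
    intersecting with the GM mask.

    Returns ``(pial_boundary, wm_boundary)`` as boolean arrays.
    """
    gm = np.asarray(gm_mask, dtype=bool)
    wm = np.asarray(wm_mask, dtype=bool)
    if gm.shape != wm.shape:
        raise ValueError("GM and WM masks must share a grid")
    if (gm & wm).any():
        raise ValueError("GM and WM masks overlap")
    if not gm.any():
        warnings.warn("empty GM mask: boundary sets are empty", stacklevel=2)
        return np.zeros_like(gm), np.zeros_like(gm)

    structure = _face_structure(gm.ndim)
    outside = ~(gm | wm)  # CSF + background
    wm_boundary = gm & ndimage.binary_dilation(wm, structure=structure)
    pial_boundary = gm & ndimage.binary_dilation(outside, structure=structure)
    return pial_boundary, wm_boundary


def _edt_to_set(target: np.ndarray, sampling) -> np.ndarray:
    """Euclidean distance (mm) from every voxel to the nearest True voxel."""
    return ndimage.distance_transform_edt(~target, sampling=sampling)


def compute_depth(
    gm_mask: np.ndarray,
    pial_boundary: np.ndarray,
    wm_boundary: np.ndarray,
    voxel_size_mm=(1.0, 1.0, 1.0),
    return_distances: bool = False,
):
    """Normalized equidistant cortical depth on the GM mask.

    ``d = D_pial / (D_pial + D_wm)`` with distances in mm; 0 at the pial
    surface, 1 at the WM surface.  Voxels belonging to both boundary sets
    (one-voxel ribbons) get d = 0.5.  Non-GM voxels are NaN.

    With ``return_distances`` the raw distance maps are returned too,
    which `parcel_thickness_qc` reuses as its thickness estimate.
    """
    gm = np.asarray(gm_mask, dtype=bool)
    pial = np.asarray(pial_boundary, dtype=bool)
    wm_b = np.asarray(wm_boundary, dtype=bool)
    if not pial.any() or not wm_b.any():
        raise ValueError(
            "both boundary sets must be non-empty (open ribbon?): "
            f"pial={int(pial.sum())} wm={int(wm_b.sum())} voxels"
        )
    sampling = tuple(voxel_size_mm)[: gm.ndim]

    d_pial = _edt_to_set(pial, sampling)
    d_wm = _edt_to_set(wm_b, sampling)

    depth = np.full(gm.shape, np.nan)
    denom = d_pial + d_wm
    both = pial & wm_b & gm
    with np.errstate(invalid="ignore", divide="ignore"):
        depth[gm] = d_pial[gm] / denom[gm]
    depth[both] = 0.5  # one-voxel ribbon: equidistant by convention
    if both.any():
        logger.info("%d voxels adjacent to both surfaces set to d=0.5", both.sum())
    if return_distances:
        return depth, d_pial, d_wm
    return depth


def assign_laminae(depth: np.ndarray, K: int = DEFAULT_K) -> np.ndarray:
    """Bin depth into K equidistant laminae, 1 (pial-most) .. K (WM-most).

    Rule: ``lamina = min(floor(d*K) + 1, K)``; the clamp puts d = 1 in
    lamina K, and ties at bin edges fall to the deeper lamina.
    Non-finite depth (outside GM) maps to 0.
    """
    if K < 3:
        raise ValueError("K must be >= 3")
    depth = np.asarray(depth, dtype=float)
    finite = np.isfinite(depth)
    if finite.any() and ((depth[finite] < 0) | (depth[finite] > 1)).any():
        raise ValueError("depth values outside [0, 1]")
    laminae = np.zeros(depth.shape, dtype=np.int32)
    laminae[finite] = np.minimum(np.floor(depth[finite] * K).astype(np.int32) + 1, K)
    return laminae


def retain_layers(laminae: np.ndarray, K: int = DEFAULT_K) -> np.ndarray:
    """Drop laminae 1 and K, relabel 2..K-1 as layers 1..K-2 (I..VI for K=8).

    The outermost lamina hugs the pial surface and the innermost hugs
    WM; both are dominated by partial-volume voxels and are excluded.
    Layer 1 (I) is the pial-most retained layer.  Dropped voxels get 0.
    """
    if K < 3:
        raise ValueError("K must be >= 3")
    laminae = np.asarray(laminae)
    out = np.zeros(laminae.shape, dtype=np.int32)
    inner = (laminae >= 2) & (laminae <= K - 1)
    out[inner] = laminae[inner] - 1
    return out


def parcel_thickness_qc(
    gm_mask: np.ndarray,
    d_pial: np.ndarray,
    d_wm: np.ndarray,
    roi_atlas: np.ndarray,
    reference_thickness_mm: dict,
    tol_mm: float = 0.5,
):
    """Retain parcels whose estimated thickness matches a reference.

    Parcel thickness is the mean of ``D_pial + D_wm`` over its GM voxels;
    parcels with ``|thickness - reference| < tol_mm`` (default 0.5 mm)
    pass QC.  Returns ``(retained_roi_ids, report)`` where the report is
    a list of dicts (roi, thickness_mm, reference_mm, retained).
    """
    gm = np.asarray(gm_mask, dtype=bool)
    atlas = np.asarray(roi_atlas)
    rois = [int(r) for r in np.unique(atlas) if r > 0]
    missing = [r for r in rois if r not in reference_thickness_mm]
    if missing:
        raise KeyError(f"reference thickness missing for ROIs {missing}")

    total = d_pial + d_wm
    retained, report = [], []
    for roi in rois:
        cell = gm & (atlas == roi)
        if not cell.any():
            warnings.warn(f"ROI {roi} has no GM voxels; excluded", stacklevel=2)
            report.append(
                {"roi": roi, "thickness_mm": np.nan,
                 "reference_mm": float(reference_thickness_mm[roi]), "retained": False}
            )
            continue
        thick = float(total[cell].mean())
        ref = float(reference_thickness_mm[roi])
        keep = abs(thick - ref) < tol_mm
        if keep:
            retained.append(roi)
        report.append(
            {"roi": roi, "thickness_mm": thick, "reference_mm": ref, "retained": keep}
        )
    return retained, report


def rasterize_polyline(vertices: np.ndarray, shape) -> np.ndarray:
    """Rasterize an (N, 2) polyline of (row, col) vertices to a boolean mask."""
    from skimage.draw import line

    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 2:
        raise ValueError("polyline must be an (N>=2, 2) array of (row, col)")
    mask = np.zeros(shape, dtype=bool)
    v = np.round(verts).astype(int)
    for (r0, c0), (r1, c1) in zip(v[:-1], v[1:]):
        rr, cc = line(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        mask[rr[keep], cc[keep]] = True
    return mask


def _polylines_intersect(a: np.ndarray, b: np.ndarray) -> bool:
    from shapely.geometry import LineString

    return LineString(np.asarray(a, float)).intersects(LineString(np.asarray(b, float)))


def layering_2d(
    region_mask: np.ndarray,
    pial_polyline: np.ndarray,
    wm_polyline: np.ndarray,
    K: int = DEFAULT_K,
    pixel_size_mm=(1.0, 1.0),
):
    """Laminar segmentation of a 2D histology band between two polylines.

    The CSF-GM and WM-GM boundary polylines are rasterized onto the image
    grid and the same equidistant depth / binning / exclusion machinery
    as in 3D is applied.  Returns ``(retained_layers, depth)``.
    """
    region = np.asarray(region_mask, dtype=bool)
    if not region.any():
        raise ValueError("empty band between boundaries")
    if _polylines_intersect(pial_polyline, wm_polyline):
        raise ValueError("pial and WM polylines intersect")

    pial = rasterize_polyline(pial_polyline, region.shape)
    wm = rasterize_polyline(wm_polyline, region.shape)
    depth = compute_depth(region, pial, wm, voxel_size_mm=pixel_size_mm)
    laminae = assign_laminae(depth, K=K)
    return retain_layers(laminae, K=K), depth
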