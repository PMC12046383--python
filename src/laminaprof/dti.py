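"""Diffusion tensor fitting and layer/ROI metric profiling.

The monoexponential tensor model relates the diffusion-weighted signal
to a symmetric positive tensor D (mm^2/s):

    S(g, b) = S0 * exp(-b * g' D g)

Taking logs makes the fit linear; per voxel an ordinary least-squares
regression of ln S on the 7-column design

    [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]

yields ln S0 and the six unique tensor components.  Eigenvalues
(sorted lambda1 >= lambda2 >= lambda3) give the scalar maps

    MD = (l1 + l2 + l3) / 3        AD = l1        RD = (l2 + l3) / 2
    FA = sqrt(3/2) * sqrt(sum (li - MD)^2) / sqrt(sum li^2)

and each map is optionally normalized by its mean over the cortex mask
(mFA, mMD, ...) to remove between-subject global scaling before laminar
profiling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DwiDataset",
    "TensorField",
    "MetricMaps",
    "design_matrix",
    "fit_tensor",
    "tensor_metrics",
    "normalize_metric",
    "layer_roi_profile",
    "LAYER_NAMES",
]

#: roman numerals for the six retained layers, pial-most first
LAYER_NAMES = ("I", "II", "III", "IV", "V", "VI")

_LOG_EPS = 1e-6  # floor applied to non-positive signals before log


@dataclass
class DwiDataset:
    """4D diffusion-weighted signal with its acquisition protocol.

    ``signal`` is (x, y, z, volumes); ``bvals`` in s/mm^2 per volume;
    ``bvecs`` an (N, 3) array of unit gradient directions (zero rows
    allowed for b=0 volumes).
    """

    signal: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape == (3, len(self.bvals)) and self.bvecs.shape[0] == 3:
            if self.bvecs.shape != (len(self.bvals), 3):
                self.bvecs = self.bvecs.T
        n_vol = self.signal.shape[-1]
        if not (n_vol == len(self.bvals) == len(self.bvecs)):
            raise ValueError(
                f"volume count {n_vol} != bvals {len(self.bvals)} / "
                f"bvecs {len(self.bvecs)}"
            )
        dwi = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dwi], axis=1)
        if dwi.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("gradient directions must be unit-norm")
        if not (~dwi).any():
            raise ValueError("at least one b=0 volume required")
        if dwi.sum() < 6:
            raise ValueError("at least 6 diffusion-weighted directions required")

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[-1]


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors on a grid.

    ``components`` is (..., 6) ordered (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) in
    mm^2/s; ``log_s0`` the fitted ln S0; ``mask`` where the fit is valid;
    ``flagged`` marks voxels with clipped signals or degenerate fits.
    """

    components: np.ndarray
    log_s0: np.ndarray
    mask: np.ndarray
    flagged: np.ndarray

    def as_matrices(self) -> np.ndarray:
        """Expand to (..., 3, 3) symmetric matrices."""
        c = self.components
        out = np.empty(c.shape[:-1] + (3, 3))
        out[..., 0, 0] = c[..., 0]
        out[..., 1, 1] = c[..., 1]
        out[..., 2, 2] = c[..., 2]
        out[..., 0, 1] = out[..., 1, 0] = c[..., 3]
        out[..., 0, 2] = out[..., 2, 0] = c[..., 4]
        out[..., 1, 2] = out[..., 2, 1] = c[..., 5]
        return out


@dataclass
class MetricMaps:
    """Scalar tensor-derived maps; NaN outside the fitted mask."""

    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray

    def as_dict(self, normalized: bool = False) -> dict:
        prefix = "m" if normalized else ""
        return {
            prefix + "FA": self.fa, prefix + "MD": self.md,
            prefix + "AD": self.ad, prefix + "RD": self.rd,
        }


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Log-linear tensor design: columns [1, -b gx^2, ..., -2b gy gz]."""
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx**2, -b * gy**2, -b * gz**2,
            -2 * b * gx * gy, -2 * b * gx * gz, -2 * b * gy * gz,
        ]
    )


def fit_tensor(dwi: DwiDataset, mask: np.ndarray | None = None) -> TensorField:
    """Ordinary least-squares log-linear tensor fit per masked voxel.

    Signals <= 0 are clipped to a small epsilon before the log and the
    voxel flagged; all-zero voxels are flagged and excluded from the
    fitted mask.  Raises on a rank-deficient (collinear) direction set.
    """
    if mask is None:
        mask = np.ones(dwi.signal.shape[:-1], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.signal.shape[:-1]:
        raise ValueError("mask does not match the DWI grid")
    if dwi.n_volumes < 7:
        raise ValueError("need at least 7 volumes to fit 7 parameters")

    X = design_matrix(dwi.bvals, dwi.bvecs)
    rank = np.linalg.matrix_rank(X)
    if rank < 7:
        raise np.linalg.LinAlgError(
            f"rank-deficient tensor design (rank {rank} < 7): "
            "diffusion directions are collinear or too few"
        )

    sig = dwi.signal[mask]  # (n_voxels, n_volumes)
    if not np.isfinite(sig).all():
        raise ValueError("non-finite signal values inside the mask")
    dead = ~(sig > 0).any(axis=1)
    clipped = (sig <= 0).any(axis=1)
    logs = np.log(np.where(sig > 0, sig, _LOG_EPS))  # only non-positive replaced

    pinv = np.linalg.pinv(X)
    beta = logs @ pinv.T  # (n_voxels, 7)

    shape = mask.shape
    components = np.full(shape + (6,), np.nan)
    log_s0 = np.full(shape, np.nan)
    flagged = np.zeros(shape, dtype=bool)

    fitted = mask.copy()
    idx = np.flatnonzero(mask.ravel())
    comp_flat = components.reshape(-1, 6)
    comp_flat[idx] = beta[:, 1:]
    log_s0.ravel()[idx] = beta[:, 0]
    flagged.ravel()[idx] = clipped
    # all-zero voxels: no usable signal at all
    dead_idx = idx[dead]
    comp_flat[dead_idx] = np.nan
    log_s0.ravel()[dead_idx] = np.nan
    fitted.ravel()[dead_idx] = False
    if clipped.any():
        logger.info("%d voxels had non-positive signals clipped", int(clipped.sum()))

    return TensorField(components=components, log_s0=log_s0, mask=fitted, flagged=flagged)


def tensor_metrics(tensors: TensorField) -> MetricMaps:
    """FA/MD/AD/RD maps from the eigen-decomposition of each tensor.

    Eigenvalues are sorted descending; negative eigenvalues from noisy
    fits enter the arithmetic unclipped (the voxel is already flagged).
    FA of the zero tensor is defined as 0.
    """
    shape = tensors.mask.shape
    fa = np.full(shape, np.nan)
    md = np.full(shape, np.nan)
    ad = np.full(shape, np.nan)
    rd = np.full(shape, np.nan)

    m = tensors.mask & np.isfinite(tensors.components).all(axis=-1)
    if not m.any():
        return MetricMaps(fa, md, ad, rd)
    mats = tensors.as_matrices()[m]
    evals = np.linalg.eigvalsh(mats)[:, ::-1]  # descending

    mean = evals.mean(axis=1)
    num = np.sqrt(((evals - mean[:, None]) ** 2).sum(axis=1))
    den = np.sqrt((evals**2).sum(axis=1))
    fa_v = np.zeros(len(evals))
    nz = den > 0
    fa_v[nz] = np.sqrt(1.5) * num[nz] / den[nz]

    fa[m] = fa_v
    md[m] = mean
    ad[m] = evals[:, 0]
    rd[m] = evals[:, 1:].mean(axis=1)
    return MetricMaps(fa, md, ad, rd)


def normalize_metric(metric_map: np.ndarray, cortex_mask: np.ndarray) -> np.ndarray:
    """Divide a map by its mean over the cortex mask (mFA, mMD, ...).

    The normalized map has mean exactly 1 over the mask, removing
    between-subject global scaling.
    """
    mask = np.asarray(cortex_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cortex mask")
    vals = np.asarray(metric_map, dtype=float)[mask]
    if not np.isfinite(vals).all():
        raise ValueError("non-finite metric values inside the cortex mask")
    mean = vals.mean()
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError(f"cortex mean must be positive and finite, got {mean}")
    return np.asarray(metric_map, dtype=float) / mean


def layer_roi_profile(
    maps: dict,
    layers: np.ndarray,
    roi_atlas: np.ndarray,
    subject_id: str,
) -> pd.DataFrame:
    """Reduce metric maps to a (subject, roi, layer, metric) mean table.

    ``maps`` is ``{metric_name: array}``; ``layers`` the retained-layer
    labels (1..6, 0 outside); ``roi_atlas`` integer parcels.  Cells with
    no finite voxels are emitted with NaN value and n_voxels = 0 rather
    than silently dropped.
    """
    layers = np.asarray(layers)
    atlas = np.asarray(roi_atlas)
    if layers.shape != atlas.shape:
        raise ValueError("layer and ROI grids do not match")
    for name, arr in maps.items():
        if np.asarray(arr).shape != layers.shape:
            raise ValueError(f"metric map {name!r} does not match the label grid")

    rois = [int(r) for r in np.unique(atlas) if r > 0]
    layer_ids = [int(l) for l in np.unique(layers) if l > 0]
    rows = []
    for roi in rois:
        roi_mask = atlas == roi
        for lay in layer_ids:
            cell = roi_mask & (layers == lay)
            for name, arr in maps.items():
                vals = np.asarray(arr, dtype=float)[cell]
                vals = vals[np.isfinite(vals)]
                rows.append(
                    {
                        "subject": subject_id,
                        "roi": roi,
                        "layer": LAYER_NAMES[lay - 1] if lay <= 6 else str(lay),
                        "metric": name,
                        "value": vals.mean() if len(vals) else np.nan,
                        "n_voxels": int(len(vals)),
                    }
                )
    df = pd.DataFrame(rows)
    n_empty = int((df["n_voxels"] == 0).sum())
    if n_empty:
        logger.info("%d empty (roi, layer) cells for subject %s", n_empty, subject_id)
    return df
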