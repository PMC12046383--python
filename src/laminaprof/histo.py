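"""Stained-slide quantification: stain unmixing, thresholding, layer density.

Brightfield immunohistochemistry obeys the Beer-Lambert law: a pixel's
optical density ``OD_c = -log10(I_c / I0)`` in each RGB channel is the
sum of the contributions of the stains present, each stain having a
characteristic unit OD direction.  Stacking those directions as rows of
a stain matrix M, the per-stain densities are recovered by inverting M
(Ruifrok-Johnston color deconvolution).

A deconvolved stain channel is binarized with Tsai's moment-preserving
threshold: the bilevel image whose two representative grey levels and
mixing fraction preserve the channel's first three moments; the
threshold is the grey level at the below-fraction fractile, and pixels
at or above it are "positive".  The positive-pixel fraction within each
retained cortical layer band is the laminar density of that stain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dti import LAYER_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "StainImage",
    "STAIN_PRESETS",
    "stain_matrix",
    "color_deconvolve",
    "moment_threshold",
    "layer_density",
]

#: unit optical-density vectors (R, G, B rows) for common stains.
#: H and E from the standard brightfield deconvolution literature; DAB
#: likewise; the LFB vector is an approximate blue-absorber direction
#: (myelin stains blue, absorbing red and green).
_RAW_PRESETS = {
    "hematoxylin": (0.650, 0.704, 0.286),
    "eosin": (0.072, 0.990, 0.105),
    "dab": (0.268, 0.570, 0.776),
    "lfb": (0.740, 0.650, 0.175),
}

STAIN_PRESETS = {
    name: tuple(np.asarray(v) / np.linalg.norm(v)) for name, v in _RAW_PRESETS.items()
}


def _orthogonal_complement(rows: np.ndarray) -> np.ndarray:
    """Unit vector orthogonal to two stain rows (third residual channel)."""
    v = np.cross(rows[0], rows[1])
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("stain vectors are collinear; cannot complete the matrix")
    return v / n


def stain_matrix(stains) -> tuple[np.ndarray, list[str]]:
    """Build a 3x3 unit-row OD matrix from stain names or (name, vector) pairs.

    One or two stains are completed to a full basis: a missing third row
    is the orthogonal complement; a single stain gets two arbitrary
    orthogonal residual rows.
    """
    names, rows = [], []
    for s in stains:
        if isinstance(s, str):
            if s not in STAIN_PRESETS:
                raise KeyError(f"unknown stain preset {s!r}; have {sorted(STAIN_PRESETS)}")
            names.append(s)
            rows.append(np.asarray(STAIN_PRESETS[s]))
        else:
            name, vec = s
            vec = np.asarray(vec, dtype=float)
            n = np.linalg.norm(vec)
            if n <= 0:
                raise ValueError(f"zero-norm stain vector for {name!r}")
            names.append(name)
            rows.append(vec / n)
    if not 1 <= len(rows) <= 3:
        raise ValueError("need between 1 and 3 stains")
    if len(rows) == 1:
        # complete with any orthonormal pair
        a = rows[0]
        b = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(b) < 1e-6:
            b = np.cross(a, [0.0, 1.0, 0.0])
        b = b / np.linalg.norm(b)
        rows += [b, _orthogonal_complement(np.array([a, b]))]
        names += ["residual1", "residual2"]
    elif len(rows) == 2:
        rows.append(_orthogonal_complement(np.array(rows)))
        names.append("residual")
    M = np.array(rows)
    if abs(np.linalg.det(M)) < 1e-8:
        raise ValueError("singular stain matrix (collinear stain vectors)")
    return M, names


@dataclass
class StainImage:
    """An RGB brightfield slide with its stain basis.

    ``rgb`` is (H, W, 3) with intensities in [0, I0]; ``stains`` the
    stain names matching the rows of ``matrix``.
    """

    rgb: np.ndarray
    stains: list = field(default_factory=lambda: ["hematoxylin", "dab"])
    i0: float = 255.0
    matrix: np.ndarray | None = None

    def __post_init__(self):
        self.rgb = np.asarray(self.rgb, dtype=float)
        if self.rgb.ndim != 3 or self.rgb.shape[-1] != 3:
            raise ValueError("rgb must be (H, W, 3)")
        if self.rgb.min() < 0 or self.rgb.max() > self.i0:
            raise ValueError(f"intensities must lie in [0, {self.i0}]")
        if self.matrix is None:
            self.matrix, self.stains = stain_matrix(self.stains)
        else:
            self.matrix = np.asarray(self.matrix, dtype=float)
            norms = np.linalg.norm(self.matrix, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("stain matrix rows must be unit-norm")


def color_deconvolve(img: StainImage) -> dict[str, np.ndarray]:
    """Unmix an RGB slide into per-stain density channels.

    ``OD = -log10(max(I, 1) / I0)`` per channel, then densities =
    OD @ inv(M).  Returns ``{stain_name: (H, W) density array}`` in
    stain order, including completed residual channels.
    """
    M = img.matrix
    if abs(np.linalg.det(M)) < 1e-8:
        raise ValueError("singular stain matrix")
    od = -np.log10(np.maximum(img.rgb, 1.0) / img.i0)
    dens = od @ np.linalg.inv(M)
    return {name: dens[..., i] for i, name in enumerate(img.stains)}


def _moment_split(hist: np.ndarray) -> int:
    """Best moment-preserving split index of a grey-level histogram.

    For each candidate split t (below class = levels < t) with below
    fraction p0 in (0, 1), the unique representative pair z0 <= z1
    preserving the first and second moments is solved in closed form
    (a quadratic in z1); the split minimizing the residual third-moment
    mismatch |p0 z0^3 + p1 z1^3 - m3| is returned, the lowest split on
    ties.  Since m0..m2 are preserved exactly, this is the bilevel image
    closest to preserving the channel's first three moments.
    """
    p = hist / hist.sum()
    levels = np.arange(len(hist), dtype=float)
    m1 = float(np.sum(p * levels))
    m2 = float(np.sum(p * levels**2))
    m3 = float(np.sum(p * levels**3))
    if m2 - m1 * m1 <= 0:
        raise ValueError("degenerate histogram (zero variance)")

    cum = np.cumsum(p)
    p0 = cum[:-1]  # below fraction of split t = 1..n-1
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = 1.0 - p0
        a = p1 * p1 / p0 + p1
        b = -2.0 * p1 * m1 / p0
        c = m1 * m1 / p0 - m2
        disc = b * b - 4.0 * a * c
        z1 = (-b + np.sqrt(disc)) / (2.0 * a)  # larger root -> z1 >= z0
        z0 = (m1 - p1 * z1) / p0
        err = np.abs(p0 * z0**3 + p1 * z1**3 - m3)
    err[~((p0 > 0) & (p0 < 1) & (disc >= 0))] = np.inf
    if not np.isfinite(err).any():
        raise ValueError("no valid split")
    return int(np.argmin(err)) + 1


def moment_threshold(channel: np.ndarray, n_bins: int = 256):
    """Tsai-style moment-preserving threshold of a 2D stain channel.

    The channel is quantized to ``n_bins`` grey levels (the method is
    histogram-based) and split into below/above classes whose two-level
    representative image preserves the channel's first three grey-level
    moments as closely as possible (the first two exactly; the split is
    the one minimizing the third-moment residual, which coincides with
    the classical p0-fractile rule away from discretization ties).
    Pixels at or above the threshold are positive.

    Returns ``(threshold, binary_mask)`` with the threshold expressed on
    the channel's original scale.  A constant channel yields an
    all-negative mask with a warning.
    """
    ch = np.asarray(channel, dtype=float)
    if not np.isfinite(ch).all():
        raise ValueError("non-finite values in channel")
    lo, hi = float(ch.min()), float(ch.max())
    if hi == lo:
        warnings.warn("constant channel: empty positive mask", stacklevel=2)
        return np.inf, np.zeros(ch.shape, dtype=bool)

    scale = (n_bins - 1) / (hi - lo)
    q = np.round((ch - lo) * scale).astype(np.int64)
    hist = np.bincount(q.ravel(), minlength=n_bins).astype(float)
    if np.count_nonzero(hist) < 2:
        warnings.warn("constant quantized channel: empty positive mask", stacklevel=2)
        return np.inf, np.zeros(ch.shape, dtype=bool)

    t_bin = _moment_split(hist)
    threshold = lo + t_bin / scale
    mask = q >= t_bin
    return threshold, mask


def layer_density(
    binary_mask: np.ndarray,
    layers2d: np.ndarray,
    stain: str,
    slide_id: str,
) -> pd.DataFrame:
    """Positive-pixel fraction per retained cortical layer band.

    Returns a DensityProfile table with one row per layer present in
    ``layers2d``: (slide, stain, layer, positive_fraction, n_pixels).
    Layers with zero pixels are logged and skipped.
    """
    mask = np.asarray(binary_mask, dtype=bool)
    layers = np.asarray(layers2d)
    if mask.shape != layers.shape:
        raise ValueError("mask and layer grids do not match")
    rows = []
    for lay in range(1, 7):
        band = layers == lay
        n = int(band.sum())
        if n == 0:
            logger.info("slide %s: layer %s has no pixels", slide_id, LAYER_NAMES[lay - 1])
            continue
        rows.append(
            {
                "slide": slide_id,
                "stain": stain,
                "layer": LAYER_NAMES[lay - 1],
                "positive_fraction": float(mask[band].sum()) / n,
                "n_pixels": n,
            }
        )
    return pd.DataFrame(rows)
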