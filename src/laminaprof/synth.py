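"""Synthetic ground-truth data: DWI phantoms, cohorts, and stained slides.

Real ex vivo specimens with paired dMRI and histology are rarely shared;
this module builds stand-ins with known ground truth so that every stage
of the laminar pipeline can be validated end to end.

Three generators:

* :func:`make_phantom` — a cortical ribbon (spherical shell or slab)
  whose per-voxel diffusion tensors are radially oriented and realize a
  prescribed per-layer MD/FA profile (FA rising and diffusivity falling
  from the pial surface toward white matter, the canonical laminar
  pattern in fixed cortex).
* :func:`make_cohort` — a case-control cohort (healthy controls, primary
  age-related tauopathy, and amyloid-positive cases) with realistic
  covariates and a configurable multiplicative MD elevation injected
  into chosen layers of the amyloid-positive group.
* :func:`render_slide` — a layered brightfield histology image whose
  per-layer positive-stain fraction is known exactly, synthesized by
  Beer-Lambert forward mixing through a stain OD matrix.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import laminar
from .dti import LAYER_NAMES, DwiDataset, TensorField
from .histo import stain_matrix
from .laminar import LabelVolume

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "Protocol",
    "CohortSpec",
    "SlideSpec",
    "default_directions",
    "default_protocol",
    "make_phantom",
    "axially_symmetric_eigenvalues",
    "synthesize_dwi",
    "make_cohort",
    "render_slide",
    "REFERENCE_COHORT",
]

# Default laminar profiles for fixed ex vivo cortex, pial-most layer
# first.  MD in mm^2/s falls roughly linearly with depth; FA rises
# nonlinearly toward the heavily myelinated deep layers.
DEFAULT_LAYER_MD = (0.40e-3, 0.37e-3, 0.34e-3, 0.31e-3, 0.28e-3, 0.25e-3)
DEFAULT_LAYER_FA = (0.10, 0.14, 0.18, 0.24, 0.30, 0.38)

_WM_MD = 0.23e-3
_WM_FA = 0.45


@dataclass
class PhantomSpec:
    """Geometry and laminar tensor profile of a cortical-ribbon phantom."""

    geometry: str = "spherical_shell"  # or "slab"
    inner_radius_mm: float = 20.0
    outer_radius_mm: float = 23.0
    thickness_mm: float = 3.0  # slab only
    extent_mm: tuple = (20.0, 20.0)  # slab in-plane size
    voxel_size_mm: tuple = (0.5, 0.5, 0.5)
    n_laminae: int = 8
    layer_md_profile: tuple = DEFAULT_LAYER_MD
    layer_fa_profile: tuple = DEFAULT_LAYER_FA
    roi_count: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.geometry not in ("spherical_shell", "slab"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.geometry == "spherical_shell" and not (
            self.outer_radius_mm > self.inner_radius_mm > 0
        ):
            raise ValueError("need outer_radius > inner_radius > 0")
        if self.geometry == "slab" and self.thickness_mm <= 0:
            raise ValueError("slab thickness must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel size must be positive")
        md = np.asarray(self.layer_md_profile, dtype=float)
        fa = np.asarray(self.layer_fa_profile, dtype=float)
        n_layers = self.n_laminae - 2
        if len(md) != n_layers or len(fa) != n_layers:
            raise ValueError(
                f"layer profiles must have {n_layers} entries for "
                f"n_laminae={self.n_laminae}"
            )
        if (md <= 0).any():
            raise ValueError("MD profile must be positive")
        if ((fa < 0) | (fa >= 1)).any():
            raise ValueError("FA profile must lie in [0, 1)")
        if self.roi_count < 1:
            raise ValueError("roi_count must be >= 1")
        thickness = (
            self.outer_radius_mm - self.inner_radius_mm
            if self.geometry == "spherical_shell"
            else self.thickness_mm
        )
        if thickness < 2 * min(self.voxel_size_mm):
            raise ValueError(
                f"ribbon thickness {thickness} mm under 2 voxels: laminae unresolvable"
            )

    @property
    def ribbon_thickness_mm(self) -> float:
        if self.geometry == "spherical_shell":
            return self.outer_radius_mm - self.inner_radius_mm
        return self.thickness_mm


def default_directions(n: int = 60) -> np.ndarray:
    """Deterministic well-spread unit directions (spherical Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(np.maximum(0.0, 1 - z**2))
    g = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return g / np.linalg.norm(g, axis=1, keepdims=True)


@dataclass
class Protocol:
    """Diffusion acquisition protocol: b0 count, directions, b-value, noise.

    Defaults mirror a high-b ex vivo protocol: 20 b=0 images plus 60
    non-collinear directions at b = 6000 s/mm^2.  SNR is defined as
    S0 / sigma on the complex-channel noise; ``snr=inf`` is noiseless.
    Magnitude data gets Rician noise by default.
    """

    b0_count: int = 20
    dwi_directions: np.ndarray = field(default_factory=default_directions)
    b_value: float = 6000.0
    snr: float = 30.0
    noise_model: str = "rician"

    def __post_init__(self):
        self.dwi_directions = np.atleast_2d(np.asarray(self.dwi_directions, float))
        norms = np.linalg.norm(self.dwi_directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("direction vectors must be unit-norm (tol 1e-8)")
        if self.b_value <= 0:
            raise ValueError("b_value must be positive")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.snr <= 0:
            raise ValueError("snr must be positive (use inf for noiseless)")

    @property
    def bvals(self) -> np.ndarray:
        return np.concatenate(
            [np.zeros(self.b0_count), np.full(len(self.dwi_directions), self.b_value)]
        )

    @property
    def bvecs(self) -> np.ndarray:
        return np.vstack([np.zeros((self.b0_count, 3)), self.dwi_directions])


def default_protocol(snr: float = 30.0, noise_model: str = "rician") -> Protocol:
    return Protocol(snr=snr, noise_model=noise_model)


def axially_symmetric_eigenvalues(md: float, fa: float):
    """Closed-form (lambda_par, lambda_perp) realizing given MD and FA.

    For a prolate axially symmetric tensor with eigenvalues
    (l_par, l_perp, l_perp), write delta = l_par - l_perp.  Then
    MD = (l_par + 2 l_perp)/3 and

        FA^2 = delta^2 / (3 MD^2 + (2/3) delta^2)

    which inverts to delta = sqrt(3) MD FA / sqrt(1 - (2/3) FA^2), and
    l_par = MD + 2 delta / 3,  l_perp = MD - delta / 3.
    """
    fa2 = fa * fa
    delta = np.sqrt(3.0) * md * fa / np.sqrt(1.0 - (2.0 / 3.0) * fa2)
    lam_par = md + 2.0 * delta / 3.0
    lam_perp = md - delta / 3.0
    return lam_par, lam_perp


def _lamina_to_layer_index(lamina: np.ndarray, K: int) -> np.ndarray:
    """Map lamina 1..K to a retained-layer profile index 0..K-3.

    Excluded laminae 1 and K borrow the nearest retained layer's values.
    """
    return np.clip(lamina - 2, 0, K - 3)


def make_phantom(spec: PhantomSpec):
    """Build a cortical-ribbon phantom with known laminar tensors.

    Returns ``(gm, wm, roi_atlas, tensor_field, truth)`` where the first
    three are :class:`LabelVolume`; ``truth`` is a dict with the exact
    per-voxel ``depth``, the ``lamina`` (1..K) and retained ``layers``
    labels, and a ``table`` DataFrame of the per-(ROI, layer) MD/FA the
    tensors realize.  Every GM tensor's principal eigenvector is the
    local surface normal.
    """
    vs = np.asarray(spec.voxel_size_mm, dtype=float)
    K = spec.n_laminae
    md_prof = np.asarray(spec.layer_md_profile, float)
    fa_prof = np.asarray(spec.layer_fa_profile, float)

    if spec.geometry == "spherical_shell":
        half = spec.outer_radius_mm + 2 * float(vs.max())
        shape = tuple(int(np.ceil(2 * half / v)) for v in vs)
        center = (np.asarray(shape) - 1) / 2.0
        idx = np.indices(shape, dtype=float)
        coords = (idx - center.reshape(3, 1, 1, 1)) * vs.reshape(3, 1, 1, 1)
        r = np.sqrt((coords**2).sum(axis=0))
        wm = r < spec.inner_radius_mm
        gm = (r >= spec.inner_radius_mm) & (r <= spec.outer_radius_mm)
        depth = np.full(shape, np.nan)
        # pial surface is the outer shell: depth 0 there, 1 at the WM core.
        # The scale runs between boundary-voxel centres (half a voxel in
        # from each surface), matching what equidistant depth means on a
        # sampled grid.
        v = float(vs.mean())
        r_pial = spec.outer_radius_mm - 0.5 * v
        r_wm = spec.inner_radius_mm + 0.5 * v
        depth[gm] = (r_pial - r[gm]) / (r_pial - r_wm)
        with np.errstate(invalid="ignore", divide="ignore"):
            normal = np.where(r > 0, coords / r, 0.0)
        azimuth = np.arctan2(coords[1], coords[0])  # (-pi, pi]
        sector = np.floor((azimuth + np.pi) / (2 * np.pi) * spec.roi_count)
        sector = np.clip(sector, 0, spec.roi_count - 1).astype(np.int32)
    else:  # slab: depth along axis 0, pial at low index
        n_gm = int(round(spec.thickness_mm / vs[0]))
        n_pad = 3
        shape = (
            n_gm + 2 * n_pad,
            int(np.ceil(spec.extent_mm[0] / vs[1])),
            int(np.ceil(spec.extent_mm[1] / vs[2])),
        )
        gm = np.zeros(shape, dtype=bool)
        wm = np.zeros(shape, dtype=bool)
        gm[n_pad : n_pad + n_gm] = True
        wm[n_pad + n_gm :] = True
        depth = np.full(shape, np.nan)
        rows = np.arange(shape[0], dtype=float)
        # voxel-centre depth: row i of the ribbon sits at fraction i/(n_gm-1)
        frac = np.clip((rows - n_pad) / max(n_gm - 1, 1), 0, 1)
        depth[gm] = np.broadcast_to(frac.reshape(-1, 1, 1), shape)[gm]
        normal = np.zeros((3,) + shape)
        normal[0] = 1.0
        cols = np.indices(shape)[1]
        sector = np.floor(cols / shape[1] * spec.roi_count)
        sector = np.clip(sector, 0, spec.roi_count - 1).astype(np.int32)

    depth = np.where(gm, np.clip(depth, 0.0, 1.0), np.nan)
    lamina = laminar.assign_laminae(depth, K=K)
    layers = laminar.retain_layers(lamina, K=K)
    roi_atlas = np.where(gm, sector + 1, 0).astype(np.int32)

    # per-voxel tensors: D = l_perp I + (l_par - l_perp) n n'
    layer_ix = _lamina_to_layer_index(lamina, K)
    md_vox = np.where(gm, md_prof[layer_ix], np.nan)
    fa_vox = np.where(gm, fa_prof[layer_ix], np.nan)
    md_vox = np.where(wm, _WM_MD, md_vox)
    fa_vox = np.where(wm, _WM_FA, fa_vox)

    tissue = gm | wm
    lam_par, lam_perp = axially_symmetric_eigenvalues(
        np.where(tissue, md_vox, 1.0), np.where(tissue, fa_vox, 0.0)
    )
    diff = lam_par - lam_perp
    nx, ny, nz = normal[0], normal[1], normal[2]
    comp = np.zeros(gm.shape + (6,))
    comp[..., 0] = lam_perp + diff * nx * nx
    comp[..., 1] = lam_perp + diff * ny * ny
    comp[..., 2] = lam_perp + diff * nz * nz
    comp[..., 3] = diff * nx * ny
    comp[..., 4] = diff * nx * nz
    comp[..., 5] = diff * ny * nz
    comp[~tissue] = 0.0

    tensor_field = TensorField(
        components=comp,
        log_s0=np.zeros(gm.shape),
        mask=tissue,
        flagged=np.zeros(gm.shape, dtype=bool),
    )

    rows = []
    for roi in range(1, spec.roi_count + 1):
        for li, name in enumerate(LAYER_NAMES[: K - 2]):
            rows.append({"roi": roi, "layer": name, "metric": "MD", "value": md_prof[li]})
            rows.append({"roi": roi, "layer": name, "metric": "FA", "value": fa_prof[li]})
    truth = {
        "depth": depth,
        "lamina": lamina,
        "layers": layers,
        "table": pd.DataFrame(rows),
    }
    mk = lambda arr: LabelVolume(arr.astype(np.int32), tuple(vs))
    return (
        mk(gm),
        mk(wm),
        LabelVolume(roi_atlas, tuple(vs)),
        tensor_field,
        truth,
    )


def synthesize_dwi(
    tensor_field: TensorField,
    s0_map: np.ndarray | float,
    protocol: Protocol,
    seed: int = 0,
    voxel_size_mm=(0.5, 0.5, 0.5),
) -> DwiDataset:
    """Forward-simulate DWI from a tensor field under a protocol.

    Noiseless signal ``S(g, b) = S0 exp(-b g' D g)`` per voxel and
    volume; Gaussian or Rician noise of scale ``sigma = S0_ref / snr``
    is then added (``S0_ref`` is the mean S0 over the tensor mask).
    """
    mask = tensor_field.mask
    comp = tensor_field.components
    if not np.isfinite(comp[mask]).all():
        raise ValueError("non-finite tensor entries inside the mask")
    s0 = np.broadcast_to(np.asarray(s0_map, dtype=float), mask.shape)

    bvals, bvecs = protocol.bvals, protocol.bvecs
    g = bvecs
    # g' D g for the 6-component layout (xx, yy, zz, xy, xz, yz)
    quad = np.stack(
        [
            g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
        ],
        axis=1,
    )  # (n_vol, 6)
    c = comp[mask]  # (n_vox, 6)
    atten = np.exp(-(c @ quad.T) * bvals[None, :])  # (n_vox, n_vol)
    signal = np.zeros(mask.shape + (len(bvals),))
    signal[mask] = s0[mask][:, None] * atten

    if np.isfinite(protocol.snr):
        rng = np.random.default_rng(seed)
        s0_ref = float(s0[mask].mean()) if mask.any() else 1.0
        sigma = s0_ref / protocol.snr
        if protocol.noise_model == "gaussian":
            signal = signal + rng.normal(0.0, sigma, signal.shape)
        else:  # rician: magnitude of complex Gaussian noise around the signal
            n1 = rng.normal(0.0, sigma, signal.shape)
            n2 = rng.normal(0.0, sigma, signal.shape)
            signal = np.sqrt((signal + n1) ** 2 + n2**2)
    return DwiDataset(
        signal=signal, bvals=bvals, bvecs=bvecs, voxel_size_mm=tuple(voxel_size_mm)
    )


# ---------------------------------------------------------------------------
# cohort generation

# Reference case table for the default 4 HC + 3 PART + 8 amyloid-positive
# cohort: age (years), sex, post-mortem interval (minutes), fixation time
# (days), Braak stage, Amyloid (Thal) stage.
_REFERENCE_COHORT_CSV = """\
subject,group,age,sex,pmi_min,ft_days,braak,amyloid
HC1,HC,58,M,1075,77,0,0
HC2,HC,64,M,372,32,0,0
HC3,HC,54,M,298,42,0,0
HC4,HC,48,F,669,36,0,0
PART1,PART,89,M,885,40,1,0
PART2,PART,74,M,161,39,2,0
PART3,PART,63,M,967,58,4,0
ad1,AbPos,54,M,351,38,0,1
ad2,AbPos,66,M,660,45,0,1
ad3,AbPos,65,M,469,56,1,1
ad4,AbPos,80,M,353,35,2,1
ad5,AbPos,73,M,264,31,3,2
ad6,AbPos,70,M,294,32,2,2
ad7,AbPos,73,M,331,40,3,2
ad8,AbPos,80,M,702,32,1,1
"""

REFERENCE_COHORT = pd.read_csv(_io.StringIO(_REFERENCE_COHORT_CSV))

GROUPS = ("HC", "PART", "AbPos")

# per-group sampling distributions used when the requested sizes differ
# from the reference table (means/sds estimated from it)
_COV_DIST = {
    "HC": {"age": (56.0, 7.0), "p_male": 0.75, "braak": (0,), "amyloid": (0,)},
    "PART": {"age": (75.0, 13.0), "p_male": 1.0, "braak": (1, 2, 4), "amyloid": (0,)},
    "AbPos": {"age": (70.0, 9.0), "p_male": 0.9, "braak": (0, 1, 2, 3),
              "amyloid": (1, 2)},
}
_PMI_MEAN_SD = (550.0, 260.0)
_FT_MEAN_SD = (42.0, 12.0)
# mean cortical thickness (mm), identical across groups by default so
# that group labels are exchangeable under the no-effect null; a
# group gap can be injected via CohortSpec.thickness_gap_mm
_THICK_MEAN_SD = (2.85, 0.15)


@dataclass
class CohortSpec:
    """Cohort composition, covariate model, and injected laminar effect.

    ``effect_spec`` maps ``(group, layer)`` or ``(group, layer, roi)`` to
    a multiplicative MD factor applied to that cell of affected
    subjects' profiles; the default elevates MD by 10% in layers II and
    III of the amyloid-positive group.  ``subject_sd`` is the
    between-subject multiplicative scatter and ``cell_noise_sd`` the
    residual per-cell noise, both lognormal.
    """

    n_hc: int = 4
    n_part: int = 3
    n_abpos: int = 8
    effect_spec: dict = field(
        default_factory=lambda: {("AbPos", "II"): 1.10, ("AbPos", "III"): 1.10}
    )
    subject_sd: float = 0.05
    cell_noise_sd: float = 0.03
    roi_sd: float = 0.02
    thickness_gap_mm: float = 0.0  # amyloid-positive thinning, if any
    seed: int = 0

    def __post_init__(self):
        if min(self.n_hc, self.n_part, self.n_abpos) < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_hc + self.n_part + self.n_abpos == 0:
            raise ValueError("empty cohort")
        for key, f in self.effect_spec.items():
            if f <= 0:
                raise ValueError(f"multiplicative shift for {key} must be > 0")
            if key[0] in ("HC", "PART") and key[1] and f != 1.0:
                # amyloid stage 0 groups carry no amyloid-driven effect by
                # construction, but user-specified shifts are allowed
                logger.info("effect injected into amyloid-negative group %s", key[0])

    @property
    def sizes(self) -> dict:
        return {"HC": self.n_hc, "PART": self.n_part, "AbPos": self.n_abpos}


def _sample_covariates(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    sizes = spec.sizes
    if (sizes["HC"], sizes["PART"], sizes["AbPos"]) == (4, 3, 8):
        df = REFERENCE_COHORT.copy()
    else:
        rows = []
        for grp in GROUPS:
            dist = _COV_DIST[grp]
            for i in range(sizes[grp]):
                age = float(np.clip(rng.normal(*dist["age"]), 40, 95))
                rows.append(
                    {
                        "subject": f"{grp}{i + 1}",
                        "group": grp,
                        "age": round(age),
                        "sex": "M" if rng.random() < dist["p_male"] else "F",
                        "pmi_min": round(float(np.clip(rng.normal(*_PMI_MEAN_SD), 120, 1500))),
                        "ft_days": round(float(np.clip(rng.normal(*_FT_MEAN_SD), 20, 90))),
                        "braak": int(rng.choice(dist["braak"])),
                        "amyloid": int(rng.choice(dist["amyloid"])),
                    }
                )
        df = pd.DataFrame(rows)
    thick = rng.normal(*_THICK_MEAN_SD, size=len(df))
    thick = np.where(df["group"] == "AbPos", thick - spec.thickness_gap_mm, thick)
    df["thickness_mm"] = np.round(np.clip(thick, 1.8, 4.0), 3)
    df["ab_status"] = np.where(df["amyloid"] >= 1, "positive", "negative")
    return df


def _effect_factor(effect_spec: dict, group: str, layer: str, roi: int) -> float:
    if (group, layer, roi) in effect_spec:
        return float(effect_spec[(group, layer, roi)])
    if (group, layer) in effect_spec:
        return float(effect_spec[(group, layer)])
    return 1.0


def make_cohort(
    cohort: CohortSpec,
    phantom: PhantomSpec | None = None,
    protocol: Protocol | None = None,
    mode: str = "profile",
):
    """Generate a cohort with a known laminar group effect.

    In the default fast ``profile`` mode each subject's (ROI x layer)
    MD/FA table is drawn directly from the phantom's laminar profiles
    with lognormal subject, ROI, and cell variability, and the
    ``effect_spec`` multiplier applied to affected cells.  In
    ``imaging`` mode a full phantom + noisy DWI volume is synthesized
    per subject (slow; intended for small grids).

    Returns a dict with ``covariates`` (CohortTable), ``profiles``
    (stacked LayerProfile rows), ``effect_table`` (ground-truth
    multiplicative factors per (group, roi, layer)), and in imaging mode
    ``datasets`` (subject -> (DwiDataset, labels dict)).
    """
    if mode not in ("profile", "imaging"):
        raise ValueError(f"unknown mode {mode!r}")
    phantom = phantom or PhantomSpec()
    protocol = protocol or default_protocol()
    rng = np.random.default_rng(cohort.seed)
    cov = _sample_covariates(cohort, rng)

    md_prof = np.asarray(phantom.layer_md_profile, float)
    fa_prof = np.asarray(phantom.layer_fa_profile, float)
    n_layers = len(md_prof)
    layer_names = LAYER_NAMES[:n_layers]
    rois = list(range(1, phantom.roi_count + 1))

    # fixed per-ROI multiplicative offsets (regional heterogeneity)
    roi_factor = np.exp(rng.normal(0.0, cohort.roi_sd, size=len(rois)))

    effect_rows = []
    for grp in GROUPS:
        for roi in rois:
            for lay in layer_names:
                effect_rows.append(
                    {
                        "group": grp,
                        "roi": roi,
                        "layer": lay,
                        "md_factor": _effect_factor(cohort.effect_spec, grp, lay, roi),
                    }
                )
    effect_table = pd.DataFrame(effect_rows)

    profiles = []
    datasets = {}
    for _, row in cov.iterrows():
        subj_f = np.exp(rng.normal(0.0, cohort.subject_sd))
        factors = np.array(
            [
                [_effect_factor(cohort.effect_spec, row["group"], lay, roi)
                 for lay in layer_names]
                for roi in rois
            ]
        )  # (roi, layer)
        if mode == "imaging":
            md_subject = md_prof * subj_f * factors.mean(axis=0)
            sub_phantom = PhantomSpec(
                geometry=phantom.geometry,
                inner_radius_mm=phantom.inner_radius_mm,
                outer_radius_mm=phantom.outer_radius_mm,
                thickness_mm=phantom.thickness_mm,
                extent_mm=phantom.extent_mm,
                voxel_size_mm=phantom.voxel_size_mm,
                n_laminae=phantom.n_laminae,
                layer_md_profile=tuple(md_subject),
                layer_fa_profile=phantom.layer_fa_profile,
                roi_count=phantom.roi_count,
                seed=phantom.seed,
            )
            gm, wm, atlas, tensors, truth = make_phantom(sub_phantom)
            dwi = synthesize_dwi(
                tensors, 1.0, protocol,
                seed=int(rng.integers(2**31)),
                voxel_size_mm=phantom.voxel_size_mm,
            )
            datasets[row["subject"]] = (
                dwi,
                {"gm": gm, "wm": wm, "roi_atlas": atlas, "truth": truth},
            )
        else:
            noise = np.exp(
                rng.normal(0.0, cohort.cell_noise_sd, size=(len(rois), n_layers, 2))
            )
            for ri, roi in enumerate(rois):
                for li, lay in enumerate(layer_names):
                    md = md_prof[li] * subj_f * roi_factor[ri] * factors[ri, li]
                    fa = fa_prof[li] * noise[ri, li, 1]
                    profiles.append(
                        {
                            "subject": row["subject"], "roi": roi, "layer": lay,
                            "metric": "MD", "value": md * noise[ri, li, 0],
                            "n_voxels": 1000,
                        }
                    )
                    profiles.append(
                        {
                            "subject": row["subject"], "roi": roi, "layer": lay,
                            "metric": "FA", "value": min(fa, 0.999),
                            "n_voxels": 1000,
                        }
                    )

    out = {
        "covariates": cov,
        "effect_table": effect_table,
        "profiles": pd.DataFrame(profiles) if profiles else None,
    }
    if mode == "imaging":
        out["datasets"] = datasets
    return out


# ---------------------------------------------------------------------------
# slide rendering


@dataclass
class SlideSpec:
    """Layout and targets of a synthetic stained section.

    One target stain per slide (each stain is a separate preparation in
    practice); ``layer_targets`` are the positive-pixel fractions of the
    six retained layers, pial-most first.  ``counterstain_density``
    spreads a light second stain over the whole band so that unmixing is
    non-trivial.
    """

    height: int = 400
    width: int = 300
    band_top_row: int = 40
    band_bottom_row: int = 360
    stain: str = "dab"
    counterstain: str = "hematoxylin"
    layer_targets: tuple = (0.02, 0.05, 0.10, 0.15, 0.15, 0.12)
    blob_radius_px: float = 3.0
    counterstain_density: float = 0.15
    i0: float = 255.0
    n_laminae: int = 8
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.layer_targets, float)
        if ((t < 0) | (t > 1)).any():
            raise ValueError("layer targets must lie in [0, 1]")
        if len(t) != self.n_laminae - 2:
            raise ValueError(
                f"need {self.n_laminae - 2} layer targets for n_laminae={self.n_laminae}"
            )
        if not 0 < self.band_top_row < self.band_bottom_row < self.height:
            raise ValueError("band rows must satisfy 0 < top < bottom < height")
        if (t > 0.95).any():
            raise ValueError("target fraction exceeds packable density")


def _fill_band_to_count(
    band_mask: np.ndarray, target_count: int, radius: float, rng
) -> np.ndarray:
    """Random blobs inside a band, trimmed/padded to an exact pixel count."""
    from skimage.draw import disk

    out = np.zeros(band_mask.shape, dtype=bool)
    if target_count == 0:
        return out
    rows, cols = np.nonzero(band_mask)
    n_band = len(rows)
    for _ in range(50 * max(1, int(np.ceil(target_count / (np.pi * radius**2))))):
        if out.sum() >= target_count:
            break
        j = rng.integers(n_band)
        r = max(1.0, rng.normal(radius, radius / 3))
        rr, cc = disk((rows[j], cols[j]), r, shape=band_mask.shape)
        keep = band_mask[rr, cc]
        out[rr[keep], cc[keep]] = True
    # exact adjustment: trim random positives or add random negatives
    excess = int(out.sum()) - target_count
    if excess > 0:
        pos = np.flatnonzero(out.ravel())
        drop = rng.choice(pos, size=excess, replace=False)
        out.ravel()[drop] = False
    elif excess < 0:
        neg = np.flatnonzero(band_mask.ravel() & ~out.ravel())
        add = rng.choice(neg, size=-excess, replace=False)
        out.ravel()[add] = True
    return out


def render_slide(spec: SlideSpec):
    """Render a layered brightfield slide with exact per-layer fractions.

    The GM band between two horizontal boundary polylines is split into
    equidistant laminae (same machinery as the imaging pipeline); stain
    blobs are placed in each retained layer until its positive-pixel
    count matches the target exactly; RGB is synthesized by Beer-Lambert
    mixing (target stain density 1 on positive pixels, a light uniform
    counterstain over the band) and quantized to 8 bits.

    Returns ``(rgb_uint8, truth_table, polylines)`` where ``truth_table``
    has the realized per-layer fractions counted on the ground-truth
    mask and ``polylines`` is ``{"pial": (N,2), "wm": (N,2)}``.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    top, bot = spec.band_top_row, spec.band_bottom_row

    pial = np.array([[top, 0], [top, W - 1]], dtype=float)
    wm = np.array([[bot, 0], [bot, W - 1]], dtype=float)
    region = np.zeros((H, W), dtype=bool)
    region[top : bot + 1, :] = True
    layers, _ = laminar.layering_2d(region, pial, wm, K=spec.n_laminae)

    truth_mask = np.zeros((H, W), dtype=bool)
    rows = []
    for li, name in enumerate(LAYER_NAMES[: spec.n_laminae - 2]):
        band = layers == li + 1
        n = int(band.sum())
        target = int(round(spec.layer_targets[li] * n))
        blob = _fill_band_to_count(band, target, spec.blob_radius_px, rng)
        truth_mask |= blob
        rows.append(
            {
                "layer": name,
                "target_fraction": float(spec.layer_targets[li]),
                "realized_fraction": float(blob.sum()) / n,
                "n_pixels": n,
            }
        )
    truth_table = pd.DataFrame(rows)

    M, names = stain_matrix([spec.stain, spec.counterstain])
    density = np.zeros((H, W, 3))
    density[..., 0] = truth_mask.astype(float)  # target stain
    density[..., 1] = np.where(region, spec.counterstain_density, 0.0)
    od = density @ M
    rgb = spec.i0 * np.power(10.0, -od)
    rgb_u8 = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    return rgb_u8, truth_table, {"pial": pial, "wm": wm}
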