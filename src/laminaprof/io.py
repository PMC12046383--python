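"""File formats, run configuration, and the end-to-end pipeline driver.

Volumes travel as NIfTI (.nii/.nii.gz), diffusion protocols as FSL-style
whitespace-delimited ``bvals``/``bvecs`` text files, tables as CSV, and
configuration as YAML.  :func:`run_pipeline` glues the stages together:

    simulate -> layer -> dti -> histo -> stats

writing every product plus a provenance log into one output directory;
a rerun with the same configuration and seeds is byte-identical for all
label and CSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__, dti, histo, laminar, stats, synth
from .laminar import LabelVolume

logger = logging.getLogger(__name__)

__all__ = [
    "read_nifti",
    "write_nifti",
    "read_bval_bvec",
    "write_bval_bvec",
    "read_dwi",
    "write_dwi",
    "RunConfig",
    "run_pipeline",
]

#: b-values under this (s/mm^2) count as b=0 volumes
B0_THRESHOLD = 50.0


def _affine_from_spacing(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    for i, v in enumerate(voxel_size_mm[:3]):
        aff[i, i] = v
    return aff


def write_nifti(path, data, voxel_size_mm=(1.0, 1.0, 1.0), affine=None):
    """Write an array or LabelVolume to NIfTI; integers stay integral."""
    if isinstance(data, LabelVolume):
        arr = data.values
        voxel_size_mm = data.voxel_size_mm + (1.0,) * (3 - len(data.voxel_size_mm))
        affine = data.affine if data.affine is not None else affine
    else:
        arr = np.asarray(data)
    if any(v <= 0 for v in voxel_size_mm[:3]):
        raise ValueError("voxel spacing must be positive")
    if affine is None:
        affine = _affine_from_spacing(voxel_size_mm)
    if np.issubdtype(arr.dtype, np.integer) or arr.dtype == bool:
        arr = arr.astype(np.int32)
    else:
        arr = arr.astype(np.float64)
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms(tuple(voxel_size_mm[: arr.ndim])[:3] + (1.0,) * max(0, arr.ndim - 3))
    nib.save(img, str(path))
    return Path(path)


def read_nifti(path, as_label: bool = False):
    """Read a NIfTI file.

    Returns ``(array, voxel_size_mm, affine)``, or a :class:`LabelVolume`
    when ``as_label`` (data cast to int32 after an integrality check).
    """
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: non-positive voxel spacing {zooms}")
    if as_label:
        if not np.allclose(arr, np.round(arr)):
            raise ValueError(f"{path}: non-integer values in a label volume")
        return LabelVolume(arr.astype(np.int32), zooms, affine=img.affine)
    return arr, zooms, img.affine


def _parse_numeric_table(path) -> np.ndarray:
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        vals = []
        for col, tok in enumerate(line.split(), start=1):
            try:
                vals.append(float(tok))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric token {tok!r} at line {ln}, column {col}"
                ) from None
        rows.append(vals)
    if not rows or len({len(r) for r in rows}) != 1:
        raise ValueError(f"{path}: empty or ragged numeric table")
    return np.array(rows)


def read_bval_bvec(bval_path, bvec_path, n_volumes: int | None = None):
    """Read FSL-dialect bvals/bvecs text files.

    bvecs are canonically 3 rows x N columns; a transposed N x 3 layout
    is auto-detected and accepted with a warning.  Gradient rows of
    b-weighted volumes must be unit-norm.  Returns ``(bvals, bvecs)``
    with bvecs shaped (N, 3).
    """
    bvals = _parse_numeric_table(bval_path).ravel()
    bvecs = _parse_numeric_table(bvec_path)
    if bvecs.shape[0] == 3 and (bvecs.shape[1] != 3 or len(bvals) == bvecs.shape[1]):
        bvecs = bvecs.T
    elif bvecs.shape[1] == 3:
        logger.warning("%s: transposed (N x 3) bvec layout accepted", bvec_path)
    else:
        raise ValueError(f"{bvec_path}: bvecs must be 3 x N or N x 3")
    if len(bvals) != len(bvecs):
        raise ValueError(
            f"bvals ({len(bvals)}) and bvecs ({len(bvecs)}) length mismatch"
        )
    if n_volumes is not None and len(bvals) != n_volumes:
        raise ValueError(
            f"protocol length {len(bvals)} does not match {n_volumes} volumes"
        )
    dwi = bvals >= B0_THRESHOLD
    norms = np.linalg.norm(bvecs[dwi], axis=1)
    if dwi.any() and not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError(f"{bvec_path}: gradient rows are not unit-norm (tol 1e-6)")
    return bvals, bvecs


def write_bval_bvec(bvals, bvecs, bval_path, bvec_path):
    bvals = np.asarray(bvals, float).ravel()
    bvecs = np.asarray(bvecs, float)
    if bvecs.shape != (len(bvals), 3):
        raise ValueError("bvecs must be (N, 3)")
    Path(bval_path).write_text(" ".join(f"{b:g}" for b in bvals) + "\n")
    lines = [" ".join(f"{v:.8f}" for v in bvecs[:, i]) for i in range(3)]
    Path(bvec_path).write_text("\n".join(lines) + "\n")


def write_dwi(dataset: dti.DwiDataset, stem: Path):
    """Write a DWI dataset as <stem>.nii.gz + <stem>.bvals/.bvecs."""
    stem = Path(stem)
    write_nifti(stem.with_suffix(".nii.gz"), dataset.signal, dataset.voxel_size_mm)
    write_bval_bvec(
        dataset.bvals, dataset.bvecs,
        stem.parent / (stem.name + ".bvals"), stem.parent / (stem.name + ".bvecs"),
    )


def read_dwi(nifti_path, bval_path, bvec_path) -> dti.DwiDataset:
    arr, zooms, affine = read_nifti(nifti_path)
    if arr.ndim != 4:
        raise ValueError(f"{nifti_path}: DWI must be 4-D, got {arr.ndim}-D")
    bvals, bvecs = read_bval_bvec(bval_path, bvec_path, n_volumes=arr.shape[-1])
    return dti.DwiDataset(arr, bvals, bvecs, zooms, affine=affine)


# ---------------------------------------------------------------------------
# configuration


def _from_dict(cls, d: dict, where: str):
    """Construct a dataclass from a mapping, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise KeyError(f"unknown config keys in {where}: {sorted(unknown)}")
    return cls(**d)


@dataclass
class SlideConfig:
    stain: str = "dab"
    layer_targets: tuple = (0.02, 0.05, 0.10, 0.15, 0.15, 0.12)
    seed: int = 0


@dataclass
class StatsConfig:
    metric: str = "MD"
    alpha: float = 0.05
    pairs: dict = field(default_factory=dict)  # case -> matched control


@dataclass
class RunConfig:
    """Full pipeline configuration; every random stage carries a seed."""

    stages: tuple = ("simulate", "histo", "stats")
    phantom: synth.PhantomSpec = field(default_factory=synth.PhantomSpec)
    protocol: synth.Protocol = field(default_factory=synth.default_protocol)
    cohort: synth.CohortSpec = field(default_factory=synth.CohortSpec)
    slides: tuple = (SlideConfig(),)
    stats: StatsConfig = field(default_factory=StatsConfig)
    n_laminae: int = 8

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sub = {
            "phantom": synth.PhantomSpec,
            "cohort": synth.CohortSpec,
            "stats": StatsConfig,
        }
        kwargs = {}
        for key, klass in sub.items():
            if key in d:
                section = d.pop(key)
                kwargs[key] = _from_dict(klass, section, key)
        if "protocol" in d:
            kwargs["protocol"] = _from_dict(synth.Protocol, d.pop("protocol"), "protocol")
        if "slides" in d:
            kwargs["slides"] = tuple(
                _from_dict(SlideConfig, s, "slides") for s in d.pop("slides")
            )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(d)
        if "stats" in kwargs and kwargs["stats"].pairs:
            kwargs["stats"].pairs = dict(kwargs["stats"].pairs)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _jsonable(o):
    if isinstance(o, dict):
        return {str(k): _jsonable(v) for k, v in o.items()}
    if isinstance(o, (list, tuple)):
        return [_jsonable(v) for v in o]
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    if dataclasses.is_dataclass(o):
        return {f.name: _jsonable(getattr(o, f.name)) for f in dataclasses.fields(o)}
    return o


def _config_digest(config: RunConfig) -> str:
    blob = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


# ---------------------------------------------------------------------------
# pipeline


def _default_pairs(cov: pd.DataFrame) -> dict:
    """Age-ordered case-control pairing when none is configured."""
    cases = cov[cov["group"] != "HC"].sort_values("age")
    hcs = cov[cov["group"] == "HC"].sort_values("age")
    if hcs.empty or cases.empty:
        return {}
    pairs = {}
    for _, case in cases.iterrows():
        j = (hcs["age"] - case["age"]).abs().idxmin()
        pairs[case["subject"]] = hcs.loc[j, "subject"]
    return pairs


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the configured stages and write an output tree.

    Products: ``covariates.csv``, ``profiles.csv`` and
    ``effect_table.csv`` (simulate); per-stain ``slide_*.png`` and
    ``density.csv`` (histo); ``stat_result.csv``, ``lmm.csv``,
    ``delta.csv`` and ``summary.md`` (stats); plus ``provenance.json``.
    Raises if a stage's inputs are missing; a ``.partial`` marker is
    present while the run is incomplete.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / ".partial"
    marker.write_text("run in progress\n")
    t0 = time.time()
    products: dict = {}

    stages = tuple(config.stages)
    unknown = set(stages) - {"simulate", "layer", "dti", "histo", "stats"}
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    if "simulate" in stages:
        cohort_out = synth.make_cohort(config.cohort, config.phantom, config.protocol)
        cohort_out["covariates"].to_csv(out / "covariates.csv", index=False)
        cohort_out["profiles"].to_csv(out / "profiles.csv", index=False)
        cohort_out["effect_table"].to_csv(out / "effect_table.csv", index=False)
        products["cohort"] = cohort_out

    if "histo" in stages:
        from PIL import Image

        densities = []
        for sc in config.slides:
            spec = synth.SlideSpec(
                stain=sc.stain, layer_targets=tuple(sc.layer_targets), seed=sc.seed
            )
            rgb, truth, lines = synth.render_slide(spec)
            Image.fromarray(rgb).save(out / f"slide_{sc.stain}.png")
            for name, poly in lines.items():
                pd.DataFrame(poly, columns=["row", "col"]).to_csv(
                    out / f"slide_{sc.stain}_{name}.csv", index=False
                )
            img = histo.StainImage(rgb.astype(float), stains=[sc.stain, "hematoxylin"]
                                   if sc.stain != "hematoxylin" else ["hematoxylin", "eosin"])
            chans = histo.color_deconvolve(img)
            region = np.zeros(rgb.shape[:2], dtype=bool)
            region[spec.band_top_row : spec.band_bottom_row + 1] = True
            layers2d, _ = laminar.layering_2d(
                region, lines["pial"], lines["wm"], K=spec.n_laminae
            )
            _, mask = histo.moment_threshold(chans[sc.stain])
            densities.append(
                histo.layer_density(mask, layers2d, sc.stain, f"slide_{sc.stain}")
            )
            truth.to_csv(out / f"slide_{sc.stain}_truth.csv", index=False)
        density = pd.concat(densities, ignore_index=True)
        density.to_csv(out / "density.csv", index=False)
        products["density"] = density

    if "stats" in stages:
        if "cohort" not in products:
            prof_path = out / "profiles.csv"
            if not prof_path.exists():
                raise FileNotFoundError(
                    "stats stage requires profiles from the simulate stage "
                    "(profiles.csv not found)"
                )
            profiles = pd.read_csv(prof_path)
            cov = pd.read_csv(out / "covariates.csv")
        else:
            profiles = products["cohort"]["profiles"]
            cov = products["cohort"]["covariates"]
        sc = config.stats
        result = stats.group_ttest(profiles, cov, metric=sc.metric)
        cellwise = result[result["roi"] != "pooled"].copy()
        q, sig = stats.fdr_bh(cellwise["p"].to_numpy(), alpha=sc.alpha)
        cellwise["q"], cellwise["significant"] = q, sig
        pooled = result[result["roi"] == "pooled"].copy()
        stat_result = pd.concat([cellwise, pooled], ignore_index=True)
        stat_result.to_csv(out / "stat_result.csv", index=False)

        lmm = stats.fit_stage_lmm(profiles, cov, metric=sc.metric)
        lmm.to_csv(out / "lmm.csv", index=False)

        pairs = dict(sc.pairs) or _default_pairs(cov)
        delta = stats.delta_profile(profiles, pairs, metric=sc.metric) if pairs else pd.DataFrame()
        delta.to_csv(out / "delta.csv", index=False)

        n_cells = int((cellwise["roi"] != "pooled").sum())
        summary = [
            "# Laminar statistics summary",
            "",
            f"- metric: {sc.metric}",
            f"- ROI x layer comparisons: {n_cells}",
            f"- BH-significant cells at alpha={sc.alpha}: {int(cellwise['significant'].sum())}",
            "",
            "Pooled per-layer t-tests (amyloid-negative minus amyloid-positive):",
            "",
            pooled[["layer", "t", "p"]].to_string(index=False),
            "",
        ]
        (out / "summary.md").write_text("\n".join(summary))
        products["stat_result"] = stat_result
        products["lmm"] = lmm
        products["delta"] = delta

    log = {
        "version": __version__,
        "config_sha256": _config_digest(config),
        "stages": list(stages),
        "elapsed_s": round(time.time() - t0, 3),
        "outputs": sorted(p.name for p in out.iterdir() if p.name != ".partial"),
    }
    (out / "provenance.json").write_text(json.dumps(log, indent=2) + "\n")
    marker.unlink()
    return products
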