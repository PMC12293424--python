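"""Readers/writers for the formats the pipeline touches, and run configuration.

Formats: NIfTI-1 volumes (nibabel), FSL-dialect gradient tables (one-row
.bval, three-row .bvec, transposed tables auto-detected), TSV for ROI
definitions / annotation grids / ALPS results / stats reports, JSON summaries
and a YAML config file.  Floats in tabular outputs print at 6 significant
digits so repeated runs are byte-comparable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .dwi_synth import B0_MAX, DwiVolume, GradientScheme, PhantomSpec, TensorVolume

logger = logging.getLogger("alpsim")

FLOAT_FMT = "%.6g"


def write_gradient_table(scheme: GradientScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.9f")


def read_gradient_table(bval_path, bvec_path) -> GradientScheme:
    """Read an FSL-style bval/bvec pair.

    Accepts both the canonical 3 x n_volumes bvec layout and the transposed
    n_volumes x 3 one (detected by shape).  Directions with a norm slightly
    off 1 are renormalized with a logged warning; b=0 rows keep the zero
    vector.
    """
    bvals = np.atleast_1d(np.loadtxt(bval_path).ravel())
    bvecs = np.atleast_2d(np.loadtxt(bvec_path))
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] != 3:
        if bvecs.shape[0] == 3:  # ambiguous 3x3 resolved as canonical layout
            bvecs = bvecs.T
        else:
            raise ValueError(f"bvec table must have a 3-long axis, got {bvecs.shape}")
    if bvecs.shape[0] != bvals.shape[0]:
        raise ValueError(
            f"gradient table mismatch: {bvals.shape[0]} b-values vs "
            f"{bvecs.shape[0]} directions"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    weighted = bvals >= B0_MAX
    off = weighted & (np.abs(norms - 1.0) > 1e-9)
    if np.any(off & (np.abs(norms - 1.0) > 1e-2)):
        raise ValueError("weighted directions deviate too far from unit norm")
    if np.any(off):
        logger.warning("renormalizing %d off-unit gradient directions", off.sum())
        bvecs[off] /= norms[off, None]
    bvecs[~weighted] = 0.0
    return GradientScheme(bvals, bvecs)


def write_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine)), str(path))


def read_volume(path) -> tuple:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def write_dwi(dwi: DwiVolume, stem) -> None:
    """Write a DWI acquisition as <stem>.nii.gz + <stem>.bval/.bvec."""
    stem = str(stem)
    write_volume(dwi.signal, dwi.affine, stem + ".nii.gz")
    write_gradient_table(dwi.scheme, stem + ".bval", stem + ".bvec")


def read_dwi(stem, subject="sub-01", time_label="awake") -> DwiVolume:
    stem = str(stem)
    data, affine = read_volume(stem + ".nii.gz")
    scheme = read_gradient_table(stem + ".bval", stem + ".bvec")
    if data.ndim != 4 or data.shape[3] != scheme.n_volumes:
        raise ValueError(
            f"volume has {data.shape[3] if data.ndim == 4 else 'no'} frames but "
            f"the gradient table defines {scheme.n_volumes}"
        )
    return DwiVolume(data, scheme, affine, subject, time_label)


TENSOR_ORDER = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


def write_tensor(tv: TensorVolume, path) -> None:
    write_volume(tv.elements, tv.affine, path)


def read_tensor(path) -> TensorVolume:
    data, affine = read_volume(path)
    flags = ~np.all(np.isfinite(data), axis=-1)
    return TensorVolume(np.nan_to_num(data, nan=np.nan), affine, flags=flags)


def write_roi_table(pairs: list, path) -> None:
    rows = []
    for p in pairs:
        for role, c in (("proj", p.proj_center), ("assoc", p.assoc_center)):
            rows.append(
                {
                    "pair_id": p.pair_id,
                    "role": role,
                    "x_mm": c[0],
                    "y_mm": c[1],
                    "z_mm": c[2],
                    "edge_mm": p.refined_edge,
                    "status": p.status,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_alps_table(cohort: list, path) -> None:
    """One row per subject x time x pair with the quad and the index."""
    from .alps_core import alps_index

    rows = []
    for series in cohort:
        for pid, quads in sorted(series.quads.items()):
            for t, q in zip(series.times, quads):
                rows.append(
                    {
                        "subject": series.subject,
                        "time_min": t,
                        "pair_id": pid,
                        "Dxx_proj": q.dxx_proj,
                        "Dxx_assoc": q.dxx_assoc,
                        "Dyy_proj": q.dyy_proj,
                        "Dzz_assoc": q.dzz_assoc,
                        "alps_index": alps_index(q),
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_alps_table(path) -> list:
    from .alps_core import AlpsSeries, DiffusivityQuad

    df = pd.read_csv(path, sep="\t")
    cohort = []
    for sub, block in df.groupby("subject", sort=True):
        times = ["awake"] + sorted(
            float(t) for t in block["time_min"].unique() if t != "awake"
        )
        quads = {}
        for pid, pblock in block.groupby("pair_id", sort=True):
            by_time = {str(r.time_min): r for r in pblock.itertuples()}
            quads[pid] = [
                DiffusivityQuad(
                    by_time[str(t)].Dxx_proj,
                    by_time[str(t)].Dxx_assoc,
                    by_time[str(t)].Dyy_proj,
                    by_time[str(t)].Dzz_assoc,
                )
                for t in times
            ]
        cohort.append(AlpsSeries(str(sub), times, quads))
    return cohort


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


@dataclass
class PipelineConfig:
    """One config file drives the whole pipeline; the seed is mandatory."""

    seed: int
    outdir: str = "alpsim_out"
    phantom: dict = field(default_factory=dict)
    scheme: dict = field(
        default_factory=lambda: {
            "n_dirs_per_shell": 30,
            "shell_bvals": [800.0, 2800.0],
            "n_b0": 8,
        }
    )
    cohort: dict = field(
        default_factory=lambda: {"n_subjects": 9, "between_subject_cv": 0.03}
    )
    fit: dict = field(default_factory=lambda: {"b_target": 800.0, "method": "wls"})
    rois: str = "standard"
    hemisphere: str = "left"
    stats: dict = field(default_factory=lambda: {"alpha": 0.05, "method": "chi2"})

    def __post_init__(self) -> None:
        alpha = self.stats.get("alpha", 0.05)
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def phantom_spec(self) -> PhantomSpec:
        kw = dict(self.phantom)
        for key in ("shape", "origin", "time_labels"):
            if key in kw:
                kw[key] = tuple(kw[key])
        if "trajectory" in kw:
            kw["trajectory"] = tuple(tuple(ab) for ab in kw["trajectory"])
        kw.setdefault("seed", self.seed)
        return PhantomSpec(**kw)


def load_config(path, seed_override: int | None = None) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if seed_override is not None:
        raw["seed"] = int(seed_override)
    if "seed" not in raw:
        raise ValueError("config must define a seed")
    return PipelineConfig(**raw)
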