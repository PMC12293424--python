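"""ROI geometry and the ALPS (diffusion along the perivascular space) index.

The ALPS index quantifies excess left-right (x) diffusivity where deep
medullary veins — and the perivascular spaces around them — run perpendicular
to both the z-oriented projection fibers (superior corona radiata) and the
y-oriented association fibers (superior longitudinal fasciculus):

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

Nine standard pairs of small ROIs tile this region in the left hemisphere of
template space; each pair holds one projection ROI and one association ROI
sharing y and z.  ROIs are voxelized into native space through the template
affine, refined by a deterministic +/-1 mm in-plane search that maximises
agreement between the primary eigenvector and the expected fiber axis, and
excluded when alignment stays poor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dwi_synth import TensorVolume
from .tensor_fit import EigenMap

__all__ = [
    "RoiPair",
    "DiffusivityQuad",
    "AlpsSeries",
    "standard_roi_pairs",
    "roi_voxels",
    "map_rois_to_native",
    "refine_and_validate",
    "extract_quad",
    "alps_index",
    "percent_change_series",
    "decompose_components",
    "process_scan_series",
]

AXIS_X, AXIS_Y, AXIS_Z = 0, 1, 2

NOMINAL_EDGE_MM = 3.0
REFINED_EDGE_MM = 2.0
ALIGNMENT_THRESHOLD = 0.5

# template-space ROI layout: projection/association x, the three (y, z)-plane
# pair positions, and the three axial slices
_PROJ_X, _ASSOC_X = -26.0, -37.0
_PAIR_YS = (-17.0, -27.0, -29.0)
_SLICE_ZS = (29.0, 30.0, 31.0)


@dataclass
class RoiPair:
    """One projection + association ROI pair in template-space mm."""

    pair_id: str
    proj_center: tuple
    assoc_center: tuple
    nominal_edge: float = NOMINAL_EDGE_MM
    refined_edge: float = REFINED_EDGE_MM
    proj_axis: int = AXIS_Z
    assoc_axis: int = AXIS_Y
    status: str = "active"
    proj_shift: tuple = (0.0, 0.0)
    assoc_shift: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.proj_center[1:] != self.assoc_center[1:]:
            raise ValueError("projection and association ROIs must share y and z")
        if self.nominal_edge < self.refined_edge:
            raise ValueError("nominal edge must be >= refined edge")

    @property
    def active(self) -> bool:
        return not self.status.startswith("excluded")


def standard_roi_pairs(hemisphere: str = "left") -> list:
    """The nine standard template-space ROI pairs (3 (x,y) pairings x 3 slices).

    ``hemisphere``: ``"left"`` (default; the right hemisphere is typically
    unusable under EEG-gel susceptibility artifacts), ``"right"`` (mirrored
    x), or ``"both"`` (18 pairs).
    """
    if hemisphere not in ("left", "right", "both"):
        raise ValueError(f"unknown hemisphere {hemisphere!r}")
    sides = {"left": [1.0], "right": [-1.0], "both": [1.0, -1.0]}[hemisphere]
    pairs = []
    for sgn in sides:
        tag = "L" if sgn > 0 else "R"
        for z in _SLICE_ZS:
            for y in _PAIR_YS:
                pairs.append(
                    RoiPair(
                        pair_id=f"{tag}_y{y:+.0f}_z{z:.0f}",
                        proj_center=(sgn * _PROJ_X, y, z),
                        assoc_center=(sgn * _ASSOC_X, y, z),
                    )
                )
    return pairs


def roi_voxels(
    center_mm, edge_mm: float, affine: np.ndarray, shape: tuple
) -> np.ndarray:
    """Voxel indices (n, 3) whose centers fall inside the axis-aligned cube
    [c - e/2, c + e/2) (half-open, template mm space) around ``center_mm``.

    The half-open convention makes edge = voxel size unambiguous: a cube
    centered on a voxel center contains exactly that voxel.
    """
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError("affine must be invertible")
    center = np.asarray(center_mm, dtype=float)
    idx = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    mm = idx @ affine[:3, :3].T + affine[:3, 3]
    half = edge_mm / 2.0
    inside = np.all((mm >= center - half) & (mm < center + half), axis=1)
    return idx[inside]


def map_rois_to_native(pairs: list, affine: np.ndarray, shape: tuple) -> dict:
    """Voxelize every ROI of every pair; pairs losing an ROI are excluded.

    Returns ``{pair_id: {"proj": (n,3) indices, "assoc": ...}}`` for pairs
    that retain at least one voxel per ROI; the others get status
    ``excluded(out_of_grid)`` (mutated in place on the pair list).
    """
    out = {}
    for i, pair in enumerate(pairs):
        proj = roi_voxels(
            _shifted(pair.proj_center, pair.proj_shift),
            pair.refined_edge,
            affine,
            shape,
        )
        assoc = roi_voxels(
            _shifted(pair.assoc_center, pair.assoc_shift),
            pair.refined_edge,
            affine,
            shape,
        )
        if len(proj) == 0 or len(assoc) == 0:
            pairs[i] = replace(pair, status="excluded(out_of_grid)")
            continue
        out[pair.pair_id] = {"proj": proj, "assoc": assoc}
    return out


def _shifted(center, shift) -> tuple:
    return (center[0] + shift[0], center[1] + shift[1], center[2])


def _alignment_score(
    center_mm, edge_mm: float, axis: int, eigenmap: EigenMap
) -> float:
    vox = roi_voxels(center_mm, edge_mm, eigenmap.affine, eigenmap.eigvals.shape[:3])
    if len(vox) == 0:
        return -1.0
    dom = eigenmap.dominant_axis()[vox[:, 0], vox[:, 1], vox[:, 2]]
    ok = ~eigenmap.flags[vox[:, 0], vox[:, 1], vox[:, 2]]
    if not np.any(ok):
        return -1.0
    return float(np.mean(dom[ok] == axis))


def refine_and_validate(pair: RoiPair, eigenmap: EigenMap) -> RoiPair:
    """Deterministic stand-in for visual ROI QC: search the nine in-plane
    shifts {-1, 0, +1} mm^2 for the placement whose voxels' V1 dominant axis
    best matches the expected fiber axis.

    Each ROI of the pair is refined independently.  Ties break toward the
    smallest shift norm, then lexicographically (x before y).  If either
    ROI's best alignment score is below 0.5 the pair is excluded
    (``excluded(misaligned)``).
    """
    shifts = [(float(dx), float(dy)) for dx in (-1, 0, 1) for dy in (-1, 0, 1)]

    def best(center, axis):
        scored = [
            (
                -_alignment_score(_shifted(center, s), pair.refined_edge, axis, eigenmap),
                s[0] ** 2 + s[1] ** 2,
                s[0],
                s[1],
                s,
            )
            for s in shifts
        ]
        scored.sort(key=lambda t: t[:4])
        return -scored[0][0], scored[0][4]

    p_score, p_shift = best(pair.proj_center, pair.proj_axis)
    a_score, a_shift = best(pair.assoc_center, pair.assoc_axis)
    if p_score < ALIGNMENT_THRESHOLD or a_score < ALIGNMENT_THRESHOLD:
        return replace(pair, status="excluded(misaligned)")
    status = "active" if p_shift == (0.0, 0.0) and a_shift == (0.0, 0.0) else (
        f"adjusted({p_shift[0]:+.0f}{p_shift[1]:+.0f}/"
        f"{a_shift[0]:+.0f}{a_shift[1]:+.0f})"
    )
    return replace(pair, status=status, proj_shift=p_shift, assoc_shift=a_shift)


@dataclass
class DiffusivityQuad:
    """ROI-mean diffusivities entering the ALPS ratio (mm^2/s)."""

    dxx_proj: float
    dxx_assoc: float
    dyy_proj: float
    dzz_assoc: float
    counts: tuple = (0, 0)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.dxx_proj, self.dxx_assoc, self.dyy_proj, self.dzz_assoc]
        )


def extract_quad(tensors: TensorVolume, pair: RoiPair) -> DiffusivityQuad:
    """Mean Dxx over both ROIs, Dyy over the projection ROI and Dzz over the
    association ROI, excluding flagged voxels."""
    if not pair.active:
        raise ValueError(f"pair {pair.pair_id} is not active ({pair.status})")
    vox = map_rois_to_native([pair], tensors.affine, tensors.shape)
    if pair.pair_id not in vox:
        raise ValueError(f"empty_roi: pair {pair.pair_id} maps outside the grid")
    proj, assoc = vox[pair.pair_id]["proj"], vox[pair.pair_id]["assoc"]

    def mean_of(vx, element):
        vals = tensors.elements[vx[:, 0], vx[:, 1], vx[:, 2], element]
        ok = ~tensors.flags[vx[:, 0], vx[:, 1], vx[:, 2]] & np.isfinite(vals)
        if not np.any(ok):
            raise ValueError(f"empty_roi: all voxels flagged in pair {pair.pair_id}")
        return float(np.mean(vals[ok])), int(ok.sum())

    dxx_p, n_p = mean_of(proj, 0)
    dxx_a, n_a = mean_of(assoc, 0)
    dyy_p, _ = mean_of(proj, 1)
    dzz_a, _ = mean_of(assoc, 2)
    return DiffusivityQuad(dxx_p, dxx_a, dyy_p, dzz_a, (n_p, n_a))


def alps_index(quad: DiffusivityQuad) -> float:
    """ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)."""
    num = 0.5 * (quad.dxx_proj + quad.dxx_assoc)
    den = 0.5 * (quad.dyy_proj + quad.dzz_assoc)
    if den <= 0:
        raise ValueError("non-positive perpendicular diffusivity mean")
    return num / den


@dataclass
class AlpsSeries:
    """One subject's per-time-point diffusivity quads across ROI pairs.

    ``times`` starts with ``'awake'`` followed by minutes since sleep
    notification; ``quads`` maps pair id to the time-ordered quad list.
    """

    subject: str
    times: list
    quads: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.times or self.times[0] != "awake":
            raise ValueError("series must start with the awake time point")
        for pid, qs in self.quads.items():
            if len(qs) != len(self.times):
                raise ValueError(f"pair {pid}: quad count != time count")

    def indices(self, pair_id: str) -> np.ndarray:
        return np.array([alps_index(q) for q in self.quads[pair_id]])


def percent_change_series(series: AlpsSeries, pair_id: str) -> pd.Series:
    """Fractional index change vs awake for each sleep time point."""
    idx = series.indices(pair_id)
    return pd.Series(
        (idx[1:] - idx[0]) / idx[0], index=pd.Index(series.times[1:], name="time")
    )


def decompose_components(quads: list, times: list) -> pd.DataFrame:
    """Split the index change into numerator and denominator contributions.

    For each sleep time point, reports the fractional change vs awake of
    mean(Dxx_proj, Dxx_assoc) (``delta_num``), of mean(Dyy_proj, Dzz_assoc)
    (``delta_den``), and of the index itself (``delta_index``).  These are
    tied by construction: (1 + delta_index) = (1 + delta_num)/(1 + delta_den).
    """
    if not times or times[0] != "awake":
        raise ValueError("decomposition requires the awake entry first")
    if len(quads) != len(times):
        raise ValueError("quads and times must align")
    arr = np.array([q.as_array() for q in quads])
    num = arr[:, :2].mean(axis=1)
    den = arr[:, 2:].mean(axis=1)
    d_num = num[1:] / num[0] - 1.0
    d_den = den[1:] / den[0] - 1.0
    d_idx = (num[1:] / den[1:]) / (num[0] / den[0]) - 1.0
    return pd.DataFrame(
        {"delta_num": d_num, "delta_den": d_den, "delta_index": d_idx},
        index=pd.Index(times[1:], name="time"),
    )


def process_scan_series(
    scans_by_time: dict,
    pairs: list | None = None,
    b_target: float = 800.0,
    fit_method: str = "wls",
) -> AlpsSeries:
    """Run one subject's scans through shell selection, tensor fit, ROI
    refinement (on the awake scan) and quad extraction.

    ``scans_by_time`` maps time label -> DwiVolume and must contain 'awake'.
    ROI refinement uses the awake eigenvector map and the refined placement
    is then held fixed across the sleep scans, so index changes reflect
    diffusivity, not ROI drift.
    """
    from .tensor_fit import eigen_decompose, fit_tensor, select_shell

    if "awake" not in scans_by_time:
        raise ValueError("scan series must contain the awake scan")
    if pairs is None:
        pairs = standard_roi_pairs()
    times = ["awake"] + [t for t in scans_by_time if t != "awake"]

    tensors_by_time = {}
    for t in times:
        sub = select_shell(scans_by_time[t], b_target)
        tensors_by_time[t] = fit_tensor(sub, method=fit_method)
    emap = eigen_decompose(tensors_by_time["awake"])
    refined = [refine_and_validate(p, emap) for p in pairs]
    active = [p for p in refined if p.active]
    if not active:
        raise ValueError("all ROI pairs excluded by alignment validation")

    subject = scans_by_time["awake"].subject
    quads = {
        p.pair_id: [extract_quad(tensors_by_time[t], p) for t in times]
        for p in active
    }
    series = AlpsSeries(subject, times, quads)
    series.pairs = refined  # refined statuses kept for reporting
    return series
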