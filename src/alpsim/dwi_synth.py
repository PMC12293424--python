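"""Synthetic diffusion-MRI cohorts with sleep-state modulation.

This module builds everything needed to exercise the ALPS analysis without
scanner data: a two-shell gradient scheme, a tensor phantom containing a
z-oriented projection-fiber block and a y-oriented association-fiber block
(both carrying an extra x-direction "perivascular" diffusivity), per-time-point
modulation of the x and perpendicular components, a monoexponential forward
model with Rician noise, and a multi-subject cohort generator that also emits
the sleep-annotation grid consumed by the inclusion filter.

Units: diffusivities are in mm^2/s, b-values in s/mm^2, coordinates in mm.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "B0_MAX",
    "GradientScheme",
    "PhantomSpec",
    "TensorVolume",
    "DwiVolume",
    "CohortScans",
    "build_gradient_scheme",
    "build_phantom",
    "apply_state_modulation",
    "synthesize_dwi",
    "simulate_cohort",
    "simulate_quad_cohort",
    "DEFAULT_TRAJECTORY",
    "DEFAULT_TIME_LABELS",
]

#: b-values below this (s/mm^2) are treated as unweighted (b=0) volumes.
B0_MAX = 50.0

#: Sleep time-point labels, minutes since sleep notification.
DEFAULT_TIME_LABELS = (14.46, 19.46, 25.46, 31.45, 37.45, 43.45)

#: Per-time-point fractional change applied to the x diffusivities (a_t) and
#: to the perpendicular diffusivities (b_t): Dyy in the projection block and
#: Dzz in the association block.  One entry per sleep time point.
DEFAULT_TRAJECTORY = (
    (0.0633, -0.1105),
    (0.0351, -0.1432),
    (0.1057, -0.0804),
    (0.0594, -0.0335),
    (0.0639, 0.0174),
    (0.0451, -0.0953),
)


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion acquisition scheme: per-volume b-value and unit direction.

    ``bvals`` has shape (n,), ``bvecs`` shape (n, 3).  Directions of weighted
    volumes are unit vectors; unweighted volumes carry the zero vector.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must have shape (n, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"bvals ({bvals.shape[0]}) and bvecs ({bvecs.shape[0]}) "
                "must have one entry per volume"
            )
        norms = np.linalg.norm(bvecs, axis=1)
        weighted = bvals >= B0_MAX
        if np.any(np.abs(norms[weighted] - 1.0) > 1e-6):
            raise ValueError("weighted-volume directions must be unit vectors")
        if np.any(norms[~weighted] > 1e-12):
            raise ValueError("b=0 volumes must carry the zero direction")
        if not np.any(~weighted):
            raise ValueError("scheme needs at least one b=0 volume")

    @property
    def n_volumes(self) -> int:
        return int(self.bvals.shape[0])

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals < B0_MAX

    def subset(self, mask: np.ndarray) -> "GradientScheme":
        mask = np.asarray(mask)
        return GradientScheme(self.bvals[mask], self.bvecs[mask])


def _repulsion_directions(n: int, seed: int, n_iter: int = 600) -> np.ndarray:
    """Spread ``n`` directions on the half-sphere by antipodal Coulomb repulsion.

    Each direction and its antipode repel all others; projected gradient
    descent with a decaying step.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    p = rng.normal(size=(n, 3))
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    step = 0.1
    eye = np.eye(n, dtype=bool)
    for _ in range(n_iter):
        force = np.zeros_like(p)
        for sign in (1.0, -1.0):
            diff = p[:, None, :] - sign * p[None, :, :]
            dist = np.linalg.norm(diff, axis=-1)
            if sign > 0:
                dist[eye] = np.inf
            else:
                # antipode of self is at distance 2; keep its (radial) term out
                dist[eye] = np.inf
            force += (diff / dist[..., None] ** 3).sum(axis=1)
        # tangential component only
        force -= (force * p).sum(axis=1, keepdims=True) * p
        fmax = np.linalg.norm(force, axis=1).max()
        if fmax > 0:
            p = p + step * force / fmax
            p /= np.linalg.norm(p, axis=1, keepdims=True)
        step *= 0.99
    return p


def build_gradient_scheme(
    n_dirs_per_shell: int,
    shell_bvals: Sequence[float],
    n_b0: int = 8,
    seed: int = 0,
) -> GradientScheme:
    """Build a multi-shell scheme with repulsion-optimised directions.

    The b=0 volumes come first, then each shell in the given order; the same
    optimised direction set is reused on every shell (common acquisition
    practice for repeated two-shell protocols).

    Parameters
    ----------
    n_dirs_per_shell : number of weighted directions per shell (>= 6, else the
        tensor is under-determined).
    shell_bvals : positive b-value of each shell, s/mm^2.
    n_b0 : number of unweighted volumes (>= 1).
    seed : seed for the (deterministic) direction optimisation.
    """
    if n_dirs_per_shell < 6:
        raise ValueError(
            "at least 6 directions per shell are required to determine the tensor"
        )
    if n_b0 < 1:
        raise ValueError("at least one b=0 volume is required")
    shell_bvals = [float(b) for b in shell_bvals]
    if any(b <= 0 for b in shell_bvals):
        raise ValueError("shell b-values must be positive")
    dirs = _repulsion_directions(n_dirs_per_shell, seed)
    bvals = [0.0] * n_b0
    bvecs = [np.zeros(3)] * n_b0
    for b in shell_bvals:
        bvals.extend([b] * n_dirs_per_shell)
        bvecs.extend(dirs)
    return GradientScheme(np.array(bvals), np.array(bvecs))


def _block(x: tuple, y: tuple, z: tuple) -> np.ndarray:
    return np.array([x, y, z], dtype=float)


@dataclass
class PhantomSpec:
    """Geometry, diffusivities and study conditions of the synthetic phantom.

    The grid is deliberately small (48 x 48 x 12 voxels at 2 mm): the analysis
    is driven by the ROI geometry, not by whole-brain realism.  The template
    affine is chosen so the standard template-space ROI coordinates
    (x = -26/-37 mm, y in {-17,-27,-29} mm, z in {29,30,31} mm) fall inside
    the two fiber blocks.

    Baseline tensors are axially symmetric per block with an additional
    x-direction increment standing in for perivascular water: in both blocks
    Dxx = lambda_perp + perivascular_dxx, so the awake ALPS ratio equals
    (lambda_perp + perivascular_dxx) / lambda_perp (1.000e-3 / 0.699e-3 =
    1.431 with the defaults, matching a typical awake index of ~1.43).
    """

    shape: tuple = (48, 48, 12)
    voxel_size: float = 2.0
    origin: tuple = (-80.0, -70.0, 20.0)
    proj_block: np.ndarray = field(
        default_factory=lambda: _block((-31, -21), (-35, -11), (23, 37))
    )
    assoc_block: np.ndarray = field(
        default_factory=lambda: _block((-43, -33), (-35, -11), (23, 37))
    )
    lambda_parallel: float = 1.7e-3
    lambda_perp: float = 0.699e-3
    perivascular_dxx: float = 0.301e-3
    d_background: float = 0.8e-3
    trajectory: tuple = DEFAULT_TRAJECTORY
    time_labels: tuple = DEFAULT_TIME_LABELS
    S0: float = 1000.0
    snr: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lambda_parallel", "lambda_perp", "d_background"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.perivascular_dxx < 0:
            raise ValueError("perivascular_dxx must be non-negative")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if len(self.trajectory) != len(self.time_labels):
            raise ValueError("trajectory needs one (a_t, b_t) entry per time label")
        for a, b in self.trajectory:
            if 1 + a <= 0 or 1 + b <= 0:
                raise ValueError("state multipliers must keep diffusivities positive")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = self.origin
        return aff

    @property
    def awake_ratio(self) -> float:
        """Ground-truth awake ALPS index of the phantom."""
        return (self.lambda_perp + self.perivascular_dxx) / self.lambda_perp


# region labels in TensorVolume.labels
BACKGROUND, PROJECTION, ASSOCIATION = 0, 1, 2


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensor field.

    ``elements`` has shape (nx, ny, nz, 6) ordered Dxx, Dyy, Dzz, Dxy, Dxz,
    Dyz (mm^2/s).  ``flags`` marks voxels whose fit failed or needed
    eigenvalue clamping; flagged voxels are excluded from ROI means.
    """

    elements: np.ndarray
    affine: np.ndarray
    labels: np.ndarray | None = None
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=float)
        if self.elements.ndim != 4 or self.elements.shape[-1] != 6:
            raise ValueError("elements must have shape (nx, ny, nz, 6)")
        self.affine = np.asarray(self.affine, dtype=float)
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.flags is None:
            self.flags = np.zeros(self.elements.shape[:3], dtype=bool)

    @property
    def shape(self) -> tuple:
        return self.elements.shape[:3]

    def as_matrices(self) -> np.ndarray:
        """Return the field as full (..., 3, 3) symmetric matrices."""
        e = self.elements
        m = np.empty(e.shape[:3] + (3, 3))
        m[..., 0, 0] = e[..., 0]
        m[..., 1, 1] = e[..., 1]
        m[..., 2, 2] = e[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = e[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = e[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = e[..., 5]
        return m

    def copy(self) -> "TensorVolume":
        return TensorVolume(
            self.elements.copy(),
            self.affine.copy(),
            None if self.labels is None else self.labels.copy(),
            self.flags.copy(),
        )


@dataclass
class DwiVolume:
    """One 4D diffusion-weighted acquisition with its scheme and provenance."""

    signal: np.ndarray
    scheme: GradientScheme
    affine: np.ndarray
    subject: str = "sub-01"
    time_label: object = "awake"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, volume)")
        if self.signal.shape[3] != self.scheme.n_volumes:
            raise ValueError(
                f"signal has {self.signal.shape[3]} volumes but the scheme "
                f"defines {self.scheme.n_volumes}"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")


def _voxel_centers_mm(shape: tuple, affine: np.ndarray) -> np.ndarray:
    """mm coordinates of all voxel centers, shape (nx, ny, nz, 3)."""
    idx = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).astype(float)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def _in_block(centers: np.ndarray, block: np.ndarray) -> np.ndarray:
    return np.all((centers >= block[:, 0]) & (centers <= block[:, 1]), axis=-1)


def build_phantom(spec: PhantomSpec) -> TensorVolume:
    """Construct the noiseless awake-state tensor field of the phantom.

    Projection-block tensors are diag(lambda_perp + perivascular_dxx,
    lambda_perp, lambda_parallel) — principal axis z; association-block
    tensors diag(lambda_perp + perivascular_dxx, lambda_parallel,
    lambda_perp) — principal axis y; the background is isotropic.

    Raises if any of the nine standard ROI pairs (nominal 3 mm cube plus the
    1 mm refinement margin) does not fit inside its block.
    """
    from .alps_core import standard_roi_pairs  # local import: no cycle at load

    centers = _voxel_centers_mm(spec.shape, spec.affine)
    labels = np.zeros(spec.shape, dtype=np.int8)
    labels[_in_block(centers, spec.proj_block)] = PROJECTION
    labels[_in_block(centers, spec.assoc_block)] = ASSOCIATION

    margin = 3.0 / 2 + 1.0  # nominal half-edge + refinement shift
    for pair in standard_roi_pairs():
        for center, block, name in (
            (pair.proj_center, spec.proj_block, f"{pair.pair_id}/projection"),
            (pair.assoc_center, spec.assoc_block, f"{pair.pair_id}/association"),
        ):
            c = np.asarray(center, dtype=float)
            if np.any(c - margin < block[:, 0]) or np.any(c + margin > block[:, 1]):
                raise ValueError(f"ROI {name} does not fit inside its fiber block")

    elements = np.zeros(spec.shape + (6,))
    elements[..., :3] = spec.d_background
    dxx = spec.lambda_perp + spec.perivascular_dxx
    elements[labels == PROJECTION, 0] = dxx
    elements[labels == PROJECTION, 1] = spec.lambda_perp
    elements[labels == PROJECTION, 2] = spec.lambda_parallel
    elements[labels == ASSOCIATION, 0] = dxx
    elements[labels == ASSOCIATION, 1] = spec.lambda_parallel
    elements[labels == ASSOCIATION, 2] = spec.lambda_perp
    return TensorVolume(elements, spec.affine, labels=labels)


def apply_state_modulation(
    tensors: TensorVolume, a_t: float, b_t: float
) -> TensorVolume:
    """Apply one sleep time point's fractional diffusivity changes.

    Within both fiber blocks the x diagonal element is scaled by (1 + a_t);
    the perpendicular element of interest — Dyy in the projection block, Dzz
    in the association block — by (1 + b_t).  All other elements and the
    background are untouched; the input is not mutated.
    """
    if 1 + a_t <= 0 or 1 + b_t <= 0:
        raise ValueError("modulation must keep diffusivities positive")
    if tensors.labels is None:
        raise ValueError("tensor volume carries no region labels")
    out = tensors.copy()
    fib = (out.labels == PROJECTION) | (out.labels == ASSOCIATION)
    out.elements[fib, 0] *= 1 + a_t
    out.elements[out.labels == PROJECTION, 1] *= 1 + b_t
    out.elements[out.labels == ASSOCIATION, 2] *= 1 + b_t
    return out


def synthesize_dwi(
    tensors: TensorVolume,
    scheme: GradientScheme,
    S0: float = 1000.0,
    snr: float = 30.0,
    seed: int = 0,
    noise: str = "rician",
    subject: str = "sub-01",
    time_label: object = "awake",
) -> DwiVolume:
    """Forward-simulate the DWI signal S = S0 exp(-b g^T D g), plus noise.

    Noise models: ``"rician"`` (magnitude MRI: sqrt((S + n1)^2 + n2^2) with
    n1, n2 ~ N(0, (S0/snr)^2)), ``"gaussian"`` (S + n1, clipped at 0, for
    oracle tests) or ``"none"``.  ``snr = inf`` disables noise.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    g = scheme.bvecs
    b = scheme.bvals
    # g^T D g expanded over the 6 unique elements
    quad = (
        np.einsum("...i,vi->...v", tensors.elements[..., :3], g**2)
        + 2 * tensors.elements[..., 3, None] * (g[:, 0] * g[:, 1])
        + 2 * tensors.elements[..., 4, None] * (g[:, 0] * g[:, 2])
        + 2 * tensors.elements[..., 5, None] * (g[:, 1] * g[:, 2])
    )
    with np.errstate(over="ignore"):
        signal = S0 * np.exp(-b * quad)
    if not np.all(np.isfinite(signal)):
        raise FloatingPointError("non-finite synthetic signal (tensor overflow)")
    if noise != "none" and np.isfinite(snr):
        sigma = S0 / snr
        rng = np.random.default_rng(seed)
        n1 = rng.normal(0.0, sigma, size=signal.shape)
        if noise == "rician":
            n2 = rng.normal(0.0, sigma, size=signal.shape)
            signal = np.sqrt((signal + n1) ** 2 + n2**2)
        elif noise == "gaussian":
            signal = np.clip(signal + n1, 0.0, None)
        else:
            raise ValueError(f"unknown noise model {noise!r}")
    return DwiVolume(signal, scheme, tensors.affine, subject, time_label)


@dataclass
class CohortScans:
    """A simulated cohort: per-subject DWI time series plus the annotation grid."""

    subjects: list  # subject ids
    time_labels: list  # 'awake' first, then minutes since sleep notification
    scans: dict  # (subject, time_label) -> DwiVolume
    grid: "object"  # AnnotationGrid (sleep_annotation)
    truth: dict  # ground-truth per-time (a_t, b_t) and awake ratio


def _subject_factors(rng: np.random.Generator, cv: float) -> np.ndarray:
    """Four log-normal multiplicative factors (mean 1, coefficient of
    variation ``cv``) perturbing Dxx_proj, Dxx_assoc, Dyy_proj, Dzz_assoc."""
    if cv == 0:
        return np.ones(4)
    s = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * s**2, s, size=4))


def simulate_cohort(
    spec: PhantomSpec,
    n_subjects: int = 9,
    between_subject_cv: float = 0.03,
    seed: int | None = None,
    scheme: GradientScheme | None = None,
    noise: str = "rician",
    annotation_mode: str = "all_included",
    dtype: type = np.float32,
) -> CohortScans:
    """Simulate a sleep-study cohort: one awake scan plus one scan per
    trajectory entry for every subject.

    Subject-to-subject variability is a log-normal multiplicative
    perturbation (coefficient of variation ``between_subject_cv``) applied to
    the four ALPS diffusivity components of the baseline phantom; the state
    trajectory then multiplies on top, so each subject's fractional index
    change is preserved.  Deterministic and bit-identical given the seed.

    ``annotation_mode``: ``"all_included"`` emits an awake-then-asleep grid
    for every subject; ``"table1"`` (requires 12 subjects) emits the packaged
    12-subject fixture grid with awake / sleep / unreadable epochs, for
    exercising the inclusion filter.
    """
    from .sleep_annotation import AnnotationGrid, N_EPOCHS, table1_grid

    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    if seed is None:
        seed = spec.seed
    if scheme is None:
        scheme = build_gradient_scheme(30, [800.0, 2800.0], n_b0=8, seed=seed)
    base = build_phantom(spec)
    subjects = [f"sub-{i + 1:02d}" for i in range(n_subjects)]
    time_labels = ["awake"] + list(spec.time_labels)

    root = np.random.SeedSequence(seed)
    scans: dict = {}
    for si, (sub, ss) in enumerate(zip(subjects, root.spawn(n_subjects))):
        rng = np.random.default_rng(ss)
        f = _subject_factors(rng, between_subject_cv)
        subj_base = base.copy()
        proj = subj_base.labels == PROJECTION
        asso = subj_base.labels == ASSOCIATION
        subj_base.elements[proj, 0] *= f[0]
        subj_base.elements[asso, 0] *= f[1]
        subj_base.elements[proj, 1] *= f[2]
        subj_base.elements[asso, 2] *= f[3]
        noise_seeds = rng.integers(0, 2**31 - 1, size=len(time_labels))
        for ti, label in enumerate(time_labels):
            tensors = (
                subj_base
                if label == "awake"
                else apply_state_modulation(subj_base, *spec.trajectory[ti - 1])
            )
            dwi = synthesize_dwi(
                tensors,
                scheme,
                S0=spec.S0,
                snr=spec.snr,
                seed=int(noise_seeds[ti]),
                noise=noise,
                subject=sub,
                time_label=label,
            )
            dwi.signal = dwi.signal.astype(dtype)
            scans[(sub, label)] = dwi

    if annotation_mode == "table1":
        grid = table1_grid()
        if n_subjects != len(grid.subjects):
            raise ValueError(
                f"annotation_mode='table1' requires {len(grid.subjects)} subjects"
            )
        grid = AnnotationGrid(list(subjects), grid.labels.copy())
    elif annotation_mode == "all_included":
        labels = np.full((n_subjects, N_EPOCHS), "1", dtype="U1")
        labels[:, 0] = "0"
        grid = AnnotationGrid(list(subjects), labels)
    else:
        raise ValueError(f"unknown annotation_mode {annotation_mode!r}")

    truth = {
        "awake_ratio": spec.awake_ratio,
        "trajectory": {
            t: ab for t, ab in zip(spec.time_labels, spec.trajectory)
        },
    }
    return CohortScans(list(subjects), time_labels, scans, grid, truth)


def simulate_quad_cohort(
    spec: PhantomSpec,
    n_subjects: int = 9,
    between_subject_cv: float = 0.03,
    measurement_cv: float = 0.02,
    seed: int = 0,
    n_pairs: int = 9,
    null: bool = False,
):
    """Fast quad-level cohort: ALPS diffusivity quads drawn directly, without
    image synthesis and tensor fitting.

    Emulates the imaging pipeline's output for statistics-level studies: each
    subject gets baseline quads perturbed between subjects (log-normal, CV
    ``between_subject_cv``), the trajectory modulation (suppressed when
    ``null`` is true), and per-scan log-normal measurement noise of CV
    ``measurement_cv`` on each of the four components.

    Returns a list of :class:`alpsim.alps_core.AlpsSeries`, one per subject,
    each covering ``n_pairs`` ROI pairs.
    """
    from .alps_core import AlpsSeries, DiffusivityQuad, standard_roi_pairs

    pairs = [p.pair_id for p in standard_roi_pairs()[:n_pairs]]
    time_labels = ["awake"] + list(spec.time_labels)
    dxx = spec.lambda_perp + spec.perivascular_dxx
    base = np.array([dxx, dxx, spec.lambda_perp, spec.lambda_perp])
    root = np.random.SeedSequence(seed)
    series = []
    for i, ss in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(ss)
        subj = base * _subject_factors(rng, between_subject_cv)
        quads: dict = {p: [] for p in pairs}
        for ti, label in enumerate(time_labels):
            q_t = subj.copy()
            if label != "awake" and not null:
                a, b = spec.trajectory[ti - 1]
                q_t *= np.array([1 + a, 1 + a, 1 + b, 1 + b])
            for p in pairs:
                noisy = q_t * _subject_factors(rng, measurement_cv)[:4] if (
                    measurement_cv > 0
                ) else q_t
                quads[p].append(
                    DiffusivityQuad(noisy[0], noisy[1], noisy[2], noisy[3], (1, 1))
                )
        series.append(AlpsSeries(f"sub-{i + 1:02d}", time_labels, quads))
    return series
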