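"""Per-voxel diffusion-tensor estimation from a single shell plus b=0 volumes.

The analysis deliberately restricts the fit to the low-b shell (b = 800
s/mm^2 by default): low b-values weight the slow/fast ADC regime that tracks
perivascular water better than the full two-shell fit would.  Under the
noiseless monoexponential model the fitted diagonal diffusivities are
identical whichever shell is used; the restriction is a configuration choice,
not a different model.

Estimator: log-linear weighted least squares.  ln S = ln S0 - b g^T D g is
linear in (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz); an OLS pass provides
predicted signals whose squares serve as weights for one reweighting pass
(the standard WLS correction for the log transform's noise distortion).
S0 is estimated jointly as a regression coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dwi_synth import B0_MAX, DwiVolume, GradientScheme, TensorVolume

__all__ = ["EigenMap", "select_shell", "design_matrix", "fit_tensor", "eigen_decompose"]


@dataclass
class EigenMap:
    """Sorted eigenvalues and primary eigenvector of a tensor field.

    ``eigvals`` has shape (nx, ny, nz, 3) sorted descending (clamped at 0);
    ``v1`` holds the unit primary eigenvector with its sign fixed so the
    largest-magnitude component is non-negative.  ``flags`` marks voxels that
    were masked upstream or needed negative-eigenvalue clamping.
    """

    eigvals: np.ndarray
    v1: np.ndarray
    affine: np.ndarray
    flags: np.ndarray

    def dominant_axis(self) -> np.ndarray:
        """Index (0=x, 1=y, 2=z) of V1's largest absolute component.

        Exact ties resolve to the lowest axis index (x before y before z).
        """
        return np.argmax(np.abs(self.v1), axis=-1)


def select_shell(dwi: DwiVolume, b_target: float, tol: float = 50.0) -> DwiVolume:
    """Keep the b=0 volumes plus the shell with |b - b_target| <= tol."""
    b = dwi.scheme.bvals
    mask = (b < B0_MAX) | (np.abs(b - b_target) <= tol)
    sub = dwi.scheme.subset(mask)
    weighted = sub.bvals >= B0_MAX
    n_distinct = np.unique(np.round(sub.bvecs[weighted], 9), axis=0).shape[0]
    if sub.n_volumes < 7 or n_distinct < 6:
        raise ValueError(
            f"shell selection at b={b_target} leaves {sub.n_volumes} volumes "
            f"with {n_distinct} distinct directions; tensor under-determined"
        )
    return DwiVolume(
        dwi.signal[..., mask], sub, dwi.affine, dwi.subject, dwi.time_label
    )


def design_matrix(scheme: GradientScheme) -> np.ndarray:
    """(n_volumes, 7) design for ln S = X @ (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)."""
    b, g = scheme.bvals, scheme.bvecs
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )


def fit_tensor(dwi: DwiVolume, method: str = "wls") -> TensorVolume:
    """Fit the diffusion tensor at every voxel of a shell-selected acquisition.

    ``method``: ``"wls"`` (default; OLS followed by one reweighting pass with
    weights = squared predicted signal) or ``"ols"`` (single log-linear pass,
    kept for oracle comparisons).  Voxels containing any non-positive signal
    are masked (flagged, elements NaN), not fatal.
    """
    if method not in ("wls", "ols"):
        raise ValueError(f"unknown method {method!r}")
    X = design_matrix(dwi.scheme)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("rank-deficient design: directions do not span the tensor")
    shape = dwi.signal.shape[:3]
    S = dwi.signal.reshape(-1, dwi.scheme.n_volumes).astype(float)
    good = np.all(S > 0, axis=1) & np.all(np.isfinite(S), axis=1)
    y = np.log(S[good])

    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)  # (7, n_good)
    if method == "wls":
        w = np.exp(2.0 * (X @ beta)).T  # squared predicted signal, (n_good, nvol)
        A = np.einsum("nv,vi,vj->nij", w, X, X)
        rhs = np.einsum("nv,vi,nv->ni", w, X, y)
        beta = np.linalg.solve(A, rhs[..., None])[..., 0].T

    elements = np.full((S.shape[0], 6), np.nan)
    elements[good] = beta[1:].T
    flags = ~good
    return TensorVolume(
        elements.reshape(shape + (6,)),
        dwi.affine,
        flags=flags.reshape(shape),
    )


def eigen_decompose(tensors: TensorVolume) -> EigenMap:
    """Eigen-decompose the tensor field into sorted eigenvalues and V1.

    Negative eigenvalues are clamped to zero and the voxel flagged (they are
    non-physical, a finite-noise artifact).  V1's sign is fixed so its
    largest-magnitude component is non-negative; for degenerate (isotropic)
    tensors any eigenvector of the top eigenvalue may be returned.
    """
    mats = tensors.as_matrices()
    bad = ~np.all(np.isfinite(mats), axis=(-2, -1))
    safe = np.where(bad[..., None, None], np.eye(3), mats)
    vals, vecs = np.linalg.eigh(safe)  # ascending
    vals = vals[..., ::-1]
    v1 = vecs[..., :, 2]
    clamped = np.any(vals < 0, axis=-1)
    vals = np.clip(vals, 0.0, None)
    dom = np.argmax(np.abs(v1), axis=-1, keepdims=True)
    sign = np.sign(np.take_along_axis(v1, dom, axis=-1))
    sign[sign == 0] = 1.0
    v1 = v1 * sign
    norm = np.linalg.norm(v1, axis=-1, keepdims=True)
    v1 = np.divide(v1, norm, out=np.zeros_like(v1), where=norm > 0)
    vals[bad] = np.nan
    flags = tensors.flags | clamped | bad
    return EigenMap(vals, v1, tensors.affine, flags)
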