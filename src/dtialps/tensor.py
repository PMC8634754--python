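"""Per-voxel diffusion tensor estimation and derived maps.

Fits the log-linearized monoexponential model ln S = ln S0 − b gᵀDg by
ordinary or (one-iteration) weighted linear least squares over the six unique
tensor components plus ln S0 — a seven-parameter design per voxel. Derived
quantities: eigenvalues/eigenvectors, fractional anisotropy, and the
direction-encoded color FA map (red = x/right–left, green = y/anterior–
posterior, blue = z/inferior–superior) used for ROI placement.
"""

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .gradients import GradientTable, _b_design

__all__ = [
    "DWIVolume",
    "TensorField",
    "design_matrix",
    "fit_tensor",
    "eigensystem",
    "fractional_anisotropy",
    "color_fa",
]

CLAMP_FRACTION = 1e-6       # signal floor, relative to the voxel's b0 level
QC_CLAMP_LIMIT = 0.25       # flag voxels with more clamped volumes than this


@dataclass(frozen=True)
class DWIVolume:
    """A 4D diffusion-weighted series with its voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"DWI data must be 4D, got shape {data.shape}")
        if np.any(data < 0):
            raise ValueError("DWI data must be nonnegative")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class TensorField:
    """Fitted tensors with eigensystem, FA and QC flags.

    ``lower_triangular`` stores (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz) per voxel in
    mm²/s; ``Dxx``/``Dyy``/``Dzz`` are the tensor diagonal in the image frame
    — the directional diffusivities the ALPS index is built from. Eigenvalues
    are sorted descending; negative eigenvalues (possible under noise) are
    kept as-is and recorded in ``negative_eval_mask``. ``flag_mask`` marks
    voxels whose fit is unusable or dominated by clamped (non-positive)
    signals.
    """

    lower_triangular: np.ndarray   # (x, y, z, 6)
    evals: np.ndarray              # (x, y, z, 3) descending
    evecs: np.ndarray              # (x, y, z, 3, 3) columns e1,e2,e3
    fa: np.ndarray                 # (x, y, z)
    s0: np.ndarray                 # (x, y, z)
    affine: np.ndarray
    flag_mask: np.ndarray          # (x, y, z) bool: null/low-quality fits
    negative_eval_mask: np.ndarray

    @property
    def Dxx(self):
        return self.lower_triangular[..., 0]

    @property
    def Dyy(self):
        return self.lower_triangular[..., 3]

    @property
    def Dzz(self):
        return self.lower_triangular[..., 5]

    @property
    def e1(self):
        return self.evecs[..., 0]

    def as_matrices(self) -> np.ndarray:
        """Full symmetric 3×3 tensors, shape (x, y, z, 3, 3)."""
        t = self.lower_triangular
        M = np.empty(t.shape[:-1] + (3, 3))
        M[..., 0, 0] = t[..., 0]
        M[..., 0, 1] = M[..., 1, 0] = t[..., 1]
        M[..., 0, 2] = M[..., 2, 0] = t[..., 2]
        M[..., 1, 1] = t[..., 3]
        M[..., 1, 2] = M[..., 2, 1] = t[..., 4]
        M[..., 2, 2] = t[..., 5]
        return M


def design_matrix(gtab: GradientTable) -> np.ndarray:
    """(N, 7) design: six tensor-component columns plus a ln S0 column."""
    X = np.column_stack([_b_design(gtab.bvals, gtab.bvecs), np.ones(len(gtab))])
    return X


def _check_affine_alignment(affine):
    R = affine[:3, :3]
    scales = np.linalg.norm(R, axis=0)
    R_unit = R / scales
    off = np.abs(R_unit) - np.eye(3) * np.abs(np.diag(R_unit))
    # angle of the worst column from its nearest axis
    cosang = np.max(np.abs(R_unit), axis=0)
    worst = math.degrees(math.acos(min(1.0, cosang.min())))
    if worst > 5.0:
        warnings.warn(
            f"image axes deviate {worst:.1f} deg from scanner axes; bvecs are "
            "interpreted in the image frame and no reorientation is performed",
            stacklevel=3,
        )


def fit_tensor(dwi: DWIVolume, gtab: GradientTable, method: str = "ols",
               mask: np.ndarray | None = None, s0_mode: str = "joint") -> TensorField:
    """Fit the diffusion tensor in every (masked) voxel.

    Parameters
    ----------
    method : {'ols', 'wls'}
        Ordinary least squares on log signals, or one iteration of weighted
        least squares with weights equal to the squared OLS-predicted signal.
    mask : bool array, optional
        Voxels to fit; others yield flagged null tensors.
    s0_mode : {'joint', 'mean_b0'}
        Estimate ln S0 as the seventh design parameter (default) or fix S0 to
        the mean b = 0 signal per voxel.

    Non-positive signals are clamped to 1e-6 of the voxel's b0 level before
    the log; voxels with more than 25% clamped volumes, or with no b0 signal,
    are flagged.
    """
    if method not in ("ols", "wls"):
        raise ValueError(f"unknown method {method!r}")
    if s0_mode not in ("joint", "mean_b0"):
        raise ValueError(f"unknown s0_mode {s0_mode!r}")
    if dwi.n_volumes != len(gtab):
        raise ValueError(
            f"DWI has {dwi.n_volumes} volumes but gradient table has {len(gtab)}"
        )
    if len(gtab) < 7:
        raise ValueError("need at least 7 volumes (6 directions + b0)")
    _check_affine_alignment(dwi.affine)

    shape = dwi.data.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    X = design_matrix(gtab)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError(
            "rank-deficient design: gradient directions do not span the six "
            "tensor components (collinear scheme)"
        )

    S = dwi.data[mask]                       # (V, N)
    b0 = S[:, gtab.b0_mask].mean(axis=1)     # (V,)
    usable = b0 > 0
    floor = np.where(usable, CLAMP_FRACTION * np.where(b0 > 0, b0, 1.0), 1.0)
    clamped = S <= 0
    S_cl = np.where(clamped, floor[:, None], S)
    frac_clamped = clamped.mean(axis=1)

    if s0_mode == "joint":
        y = np.log(S_cl)
        beta = _solve(X, y, method)
    else:
        y = np.log(S_cl) - np.log(np.where(usable, b0, 1.0))[:, None]
        beta6 = _solve(X[:, :6], y, method)
        beta = np.column_stack([beta6, np.log(np.where(usable, b0, 1.0))])

    lt_flat = beta[:, :6]
    s0_flat = np.exp(beta[:, 6])
    flag_flat = (~usable) | (frac_clamped > QC_CLAMP_LIMIT)
    lt_flat[~usable] = 0.0
    s0_flat[~usable] = 0.0

    lt = np.zeros(shape + (6,))
    s0 = np.zeros(shape)
    flags = np.ones(shape, dtype=bool)
    lt[mask] = lt_flat
    s0[mask] = s0_flat
    flags[mask] = flag_flat

    evals, evecs = eigensystem(lt)
    fa = fractional_anisotropy(evals)
    neg = np.any(evals < 0, axis=-1) & ~flags
    return TensorField(
        lower_triangular=lt, evals=evals, evecs=evecs, fa=fa, s0=s0,
        affine=np.asarray(dwi.affine, dtype=float), flag_mask=flags,
        negative_eval_mask=neg,
    )


def _solve(X, y, method):
    """Least-squares solve of X beta = y for every voxel (rows of y)."""
    beta = np.linalg.lstsq(X, y.T, rcond=None)[0].T
    if method == "wls":
        # one reweighting pass: weights = squared predicted signal
        w = np.exp(2.0 * (beta @ X.T))
        if X.shape[1] == 6:
            # mean-b0 mode: y already normalized; predicted ln S relative
            w = np.exp(2.0 * (beta @ X.T))
        A = np.einsum("ni,vn,nj->vij", X, w, X)
        rhs = np.einsum("ni,vn->vi", X, w * y)
        beta = np.linalg.solve(A, rhs[..., None])[..., 0]
    return beta


def eigensystem(lower_triangular: np.ndarray):
    """Eigenvalues (descending) and eigenvectors of symmetric tensors.

    Accepts (..., 6) lower-triangular components or a single 3×3 matrix.
    Eigenvector columns are ordered to match the eigenvalues and sign-fixed so
    each vector's first nonzero component is nonnegative.
    """
    lt = np.asarray(lower_triangular, dtype=float)
    if not np.all(np.isfinite(lt)):
        raise ValueError("non-finite tensor components")
    if lt.shape[-2:] == (3, 3):
        M = (lt + np.swapaxes(lt, -1, -2)) / 2.0
        if not np.allclose(lt, np.swapaxes(lt, -1, -2), atol=1e-10):
            raise ValueError("tensor must be symmetric")
    else:
        if lt.shape[-1] != 6:
            raise ValueError("expected (..., 6) components or (..., 3, 3) matrices")
        M = np.empty(lt.shape[:-1] + (3, 3))
        M[..., 0, 0] = lt[..., 0]
        M[..., 0, 1] = M[..., 1, 0] = lt[..., 1]
        M[..., 0, 2] = M[..., 2, 0] = lt[..., 2]
        M[..., 1, 1] = lt[..., 3]
        M[..., 1, 2] = M[..., 2, 1] = lt[..., 4]
        M[..., 2, 2] = lt[..., 5]
    if not np.all(np.isfinite(M)):
        raise ValueError("non-finite tensor components")
    w, v = np.linalg.eigh(M)            # ascending
    w = w[..., ::-1]
    v = v[..., ::-1]
    # sign convention: first nonzero component of each eigenvector >= 0
    for k in range(3):
        vk = v[..., k]
        first = np.where(
            np.abs(vk[..., 0]) > 1e-12,
            vk[..., 0],
            np.where(np.abs(vk[..., 1]) > 1e-12, vk[..., 1], vk[..., 2]),
        )
        flip = first < 0
        v[..., k] = np.where(flip[..., None], -vk, vk)
    return w, v


def fractional_anisotropy(evals: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2)·||λ − λ̄||/||λ||, clipped to [0, 1]; 0 for null tensors."""
    ev = np.asarray(evals, dtype=float)
    mean = ev.mean(axis=-1, keepdims=True)
    num = np.sum((ev - mean) ** 2, axis=-1)
    den = np.sum(ev**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def color_fa(tf: TensorField) -> np.ndarray:
    """Direction-encoded color map: RGB = FA·(|e1_x|, |e1_y|, |e1_z|).

    Voxels whose principal axis runs right–left render red, anterior–
    posterior green, inferior–superior blue; isotropic voxels are black.
    """
    rgb = tf.fa[..., None] * np.abs(tf.e1)
    return np.clip(rgb, 0.0, 1.0)
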