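"""Gradient tables for diffusion acquisitions.

A gradient table pairs each acquired volume with its b-value (s/mm²) and unit
diffusion-sensitizing direction, expressed in the image coordinate frame.
"""

from dataclasses import dataclass, field

import numpy as np

UNIT_NORM_TOL = 1e-3


def _b_design(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Per-volume design rows for the six unique tensor components.

    Component order is (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz); each row is the
    coefficient of ln(S/S0) = -b gᵀ D g expanded in those components.
    """
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    b = bvals
    return np.column_stack(
        [
            -b * gx * gx,
            -2.0 * b * gx * gy,
            -2.0 * b * gx * gz,
            -b * gy * gy,
            -2.0 * b * gy * gz,
            -b * gz * gz,
        ]
    )


@dataclass(frozen=True)
class GradientTable:
    """b-values and unit gradient directions defining the acquisition.

    Parameters
    ----------
    bvals : (N,) array
        b-values in s/mm²; at least one must be 0.
    bvecs : (N, 3) array
        Gradient directions, unit norm (tolerance 1e-3) wherever b > 0.
        Directions for b = 0 volumes are ignored.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (N, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"bvals has {bvals.shape[0]} entries but bvecs has {bvecs.shape[0]}"
            )
        if np.any(bvals < 0):
            raise ValueError("negative b-values are not physical")
        if not np.any(bvals == 0):
            raise ValueError("gradient table needs at least one b = 0 volume")
        dw = bvals > 0
        if dw.sum() < 6:
            raise ValueError("at least 6 diffusion-weighted directions are required")
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > UNIT_NORM_TOL):
            raise ValueError(
                "bvecs must have unit norm (tol 1e-3) where b > 0; "
                f"worst deviation {np.abs(norms - 1.0).max():.3g}"
            )
        # Non-collinearity: the 6-component tensor design must have full rank.
        if np.linalg.matrix_rank(_b_design(bvals[dw], bvecs[dw])) < 6:
            raise ValueError(
                "diffusion directions are collinear/degenerate: the tensor "
                "design matrix is rank-deficient (< 6)"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0


def dispersed_directions(n: int, seed: int = 0, iterations: int = 500) -> np.ndarray:
    """Spread ``n`` unit vectors on the sphere by antipodal electrostatic repulsion.

    Points start from a seeded random draw and relax under pairwise Coulomb
    forces between each point and every other point *and its antipode* (gradient
    directions are sign-symmetric), re-projected to the sphere each step.
    Deterministic for a given (n, seed, iterations).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(0x67726164,)))
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    step = 0.05
    for _ in range(iterations):
        force = np.zeros_like(pts)
        for sign in (1.0, -1.0):
            diff = pts[:, None, :] - sign * pts[None, :, :]
            dist2 = np.sum(diff * diff, axis=-1)
            np.fill_diagonal(dist2, np.inf)
            if sign < 0:
                # the own antipode only pushes radially; keep it but it cancels
                np.fill_diagonal(dist2, np.inf)
            force += np.sum(diff / (dist2[..., None] ** 1.5 + 1e-12), axis=1)
        pts = pts + step * force
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        step *= 0.99
    return pts


def default_gradient_table(n_directions: int = 31, bval: float = 1000.0, seed: int = 0) -> GradientTable:
    """One b = 0 volume plus ``n_directions`` dispersed directions at ``bval`` s/mm²."""
    dirs = dispersed_directions(n_directions, seed=seed)
    bvals = np.concatenate([[0.0], np.full(n_directions, float(bval))])
    bvecs = np.vstack([[0.0, 0.0, 0.0], dirs])
    return GradientTable(bvals, bvecs)
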