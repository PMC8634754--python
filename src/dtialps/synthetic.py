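"""Synthetic DWI phantoms and cohort simulation with known ground truth.

The phantom emulates the periventricular geometry seen on an axial color-FA
map at the level of the lateral-ventricle body: a midline CSF-filled
ventricle slab, a band of projection fibers (principal axis inferior–superior,
z) lateral to it, a band of association fibers (anterior–posterior, y) lateral
to that, and a subcortical band (right–left, x) further out, embedded in an
isotropic background. Every voxel carries a known diffusion tensor, so the
phantom's ALPS index has a closed-form ground truth.

The cohort simulator draws three groups (normal controls, early-stage and
late-stage Parkinson's disease) with calibrated ALPS means/SDs, demographic
and clinical covariates, and conditional effects of cognition, perivascular
space burden and age on the ALPS index, so that regression-recovery tests
have known true slopes.
"""

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .gradients import GradientTable

__all__ = [
    "RegionTensor",
    "PhantomSpec",
    "Phantom",
    "GroupParams",
    "CohortSimParams",
    "DEFAULT_REGION_TENSORS",
    "REGION_LABELS",
    "signal_from_tensor",
    "add_rician_noise",
    "make_phantom",
    "region_map",
    "analytic_alps",
    "simulate_cohort",
]

# Physiological range for water diffusivity eigenvalues at body temperature.
EVAL_MIN = 1e-5
EVAL_MAX = 4e-3

REGION_LABELS = {
    "background": 0,
    "ventricle": 1,
    "projection": 2,
    "association": 3,
    "subcortical": 4,
}


@dataclass(frozen=True)
class RegionTensor:
    """A named tissue region with its ground-truth diffusion tensor.

    ``D`` is a symmetric positive-definite 3×3 tensor in mm²/s with
    eigenvalues inside the physiological water range [1e-5, 4e-3].
    """

    label: str
    D: np.ndarray

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float)
        if D.shape != (3, 3):
            raise ValueError("D must be 3x3")
        if not np.allclose(D, D.T, atol=1e-15):
            raise ValueError("D must be symmetric")
        evals = np.linalg.eigvalsh(D)
        if np.any(evals < EVAL_MIN) or np.any(evals > EVAL_MAX):
            raise ValueError(
                f"region '{self.label}': eigenvalues {evals} outside "
                f"physiological range [{EVAL_MIN}, {EVAL_MAX}] mm^2/s"
            )
        object.__setattr__(self, "D", D)

    @property
    def lower_triangular(self) -> np.ndarray:
        """Components in (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz) order."""
        D = self.D
        return np.array([D[0, 0], D[0, 1], D[0, 2], D[1, 1], D[1, 2], D[2, 2]])


def _diag_tensor(label, dxx, dyy, dzz):
    return RegionTensor(label, np.diag([dxx, dyy, dzz]))


# Principal axes follow the color-FA conventions: projection fibers along z
# (blue), association fibers along y (green), subcortical fibers along x (red);
# ventricle is free water, background is mildly diffusive isotropic tissue.
DEFAULT_REGION_TENSORS = {
    "ventricle": _diag_tensor("ventricle", 3.0e-3, 3.0e-3, 3.0e-3),
    "projection": _diag_tensor("projection", 0.60e-3, 0.45e-3, 1.40e-3),
    "association": _diag_tensor("association", 0.55e-3, 1.30e-3, 0.40e-3),
    "subcortical": _diag_tensor("subcortical", 1.40e-3, 0.45e-3, 0.45e-3),
    "background": _diag_tensor("background", 0.8e-3, 0.8e-3, 0.8e-3),
}


def _rotated_tensors(tensors, angle_deg):
    """Rotate every region tensor in the axial (x-y) plane by ``angle_deg``."""
    if angle_deg == 0:
        return dict(tensors)
    a = math.radians(angle_deg)
    R = np.array(
        [[math.cos(a), -math.sin(a), 0.0], [math.sin(a), math.cos(a), 0.0], [0.0, 0.0, 1.0]]
    )
    return {
        name: RegionTensor(rt.label, R @ rt.D @ R.T) for name, rt in tensors.items()
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, region tensors and noise level of the synthetic phantom.

    Defaults follow a 24 cm axial field of view at matrix 64 (1.875 mm
    in-plane) with 3 mm slices; the ventricle-body slice sits mid-stack.
    Band widths are in mm so the geometry is grid-independent; each fiber
    band must be wide enough to hold a full 5-mm spherical ROI.
    """

    grid_shape: tuple = (64, 64, 40)
    voxel_size: tuple = (1.875, 1.875, 3.0)
    S0: float = 1000.0
    snr: float = math.inf
    seed: int = 0
    ventricle_half_width_mm: float = 5.625
    band_width_mm: float = 11.25
    ventricle_body_slice: int = 20
    region_tensors: dict = field(default_factory=lambda: dict(DEFAULT_REGION_TENSORS))
    rotation_deg: float = 0.0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(s) < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be 3 strictly positive lengths (mm)")
        if not (0 <= self.ventricle_body_slice < self.grid_shape[2]):
            raise ValueError("ventricle_body_slice outside the grid")
        if self.snr <= 0:
            raise ValueError("snr must be positive (inf = noiseless)")
        if self.S0 <= 0:
            raise ValueError("S0 must be positive")
        missing = set(REGION_LABELS) - set(self.region_tensors)
        if missing:
            raise ValueError(f"region_tensors missing regions: {sorted(missing)}")

    @property
    def affine(self) -> np.ndarray:
        """RAS+ voxel-to-world map with the world origin at the grid center."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        for i in range(3):
            aff[i, 3] = -self.voxel_size[i] * (self.grid_shape[i] - 1) / 2.0
        return aff

    @property
    def effective_tensors(self) -> dict:
        return _rotated_tensors(self.region_tensors, self.rotation_deg)

    @property
    def sigma(self) -> float:
        """Rician noise SD implied by SNR on the b0 signal."""
        return 0.0 if math.isinf(self.snr) else self.S0 / self.snr


def region_map(spec: PhantomSpec) -> np.ndarray:
    """Assign every voxel a region label from its world x coordinate.

    Mirror-symmetric about the midline (world x = 0): ventricle slab in the
    middle, then projection, association and subcortical bands moving
    laterally, background beyond. Raises if the grid cannot hold a full 5-mm
    sphere in each fiber band.
    """
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.voxel_size
    roi_d = 5.0
    if spec.band_width_mm < roi_d:
        raise ValueError(
            f"band_width_mm={spec.band_width_mm} cannot contain a {roi_d}-mm sphere"
        )
    if ny * dy < roi_d + 2 * dy or nz * dz < roi_d + 2 * dz:
        raise ValueError("grid too small in y/z for a full 5-mm spherical ROI")
    lateral_extent = spec.ventricle_half_width_mm + 3 * spec.band_width_mm
    half_fov_x = nx * dx / 2.0
    if lateral_extent > half_fov_x:
        raise ValueError(
            f"grid too small in x: bands need {lateral_extent:.1f} mm half-width, "
            f"grid provides {half_fov_x:.1f} mm"
        )
    x_world = spec.affine[0, 0] * np.arange(nx) + spec.affine[0, 3]
    ax = np.abs(x_world)
    v = spec.ventricle_half_width_mm
    w = spec.band_width_mm
    col = np.full(nx, REGION_LABELS["background"], dtype=np.int16)
    col[ax <= v] = REGION_LABELS["ventricle"]
    col[(ax > v) & (ax <= v + w)] = REGION_LABELS["projection"]
    col[(ax > v + w) & (ax <= v + 2 * w)] = REGION_LABELS["association"]
    col[(ax > v + 2 * w) & (ax <= v + 3 * w)] = REGION_LABELS["subcortical"]
    return np.broadcast_to(col[:, None, None], (nx, ny, nz)).copy()


def signal_from_tensor(D, bval, gvec, S0=1.0):
    """Monoexponential diffusion signal S = S0·exp(−b·gᵀDg).

    ``D`` is a symmetric positive-semidefinite tensor (mm²/s), ``bval`` in
    s/mm², ``gvec`` a unit vector when bval > 0. Returns S0 exactly at b = 0.
    """
    D = np.asarray(D, dtype=float)
    g = np.asarray(gvec, dtype=float)
    if bval < 0:
        raise ValueError("bval must be >= 0")
    if np.linalg.eigvalsh((D + D.T) / 2).min() < -1e-15:
        raise ValueError("tensor is not positive semi-definite")
    if bval == 0:
        return float(S0)
    if abs(np.linalg.norm(g) - 1.0) > 1e-3:
        raise ValueError("gvec must have unit norm when bval > 0")
    return float(S0 * math.exp(-bval * (g @ D @ g)))


def add_rician_noise(signal, sigma, rng=None, seed=None):
    """Corrupt a noise-free magnitude signal with Rician noise.

    Returns sqrt((S + n1)² + n2²) with n1, n2 ~ N(0, σ²) — the magnitude of a
    complex Gaussian perturbation, the standard model for magnitude MR images.
    ``sigma = 0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


@dataclass(frozen=True)
class Phantom:
    """A generated phantom: DWI data plus per-voxel ground truth."""

    dwi: np.ndarray            # (x, y, z, volume)
    labels: np.ndarray         # (x, y, z) int region codes
    tensors: np.ndarray        # (x, y, z, 6) ground-truth lower-triangular tensors
    affine: np.ndarray
    spec: PhantomSpec
    gtab: GradientTable


def make_phantom(spec: PhantomSpec, gtab: GradientTable) -> Phantom:
    """Simulate the 4D DWI acquisition of the phantom.

    Each voxel's noise-free signal follows the monoexponential tensor model
    for its region; Rician noise is added at ``spec.snr`` (σ = S0/snr on the
    b0 signal). Deterministic given ``spec.seed``.
    """
    labels = region_map(spec)
    tensors = spec.effective_tensors
    nvol = len(gtab)
    dwi = np.empty(spec.grid_shape + (nvol,), dtype=float)
    tens6 = np.empty(spec.grid_shape + (6,), dtype=float)
    for name, code in REGION_LABELS.items():
        rt = tensors[name]
        sig = np.array(
            [
                signal_from_tensor(rt.D, b, g, spec.S0)
                for b, g in zip(gtab.bvals, gtab.bvecs)
            ]
        )
        where = labels == code
        dwi[where] = sig
        tens6[where] = rt.lower_triangular
    if spec.sigma > 0:
        rng = substream(spec.seed, "noise")
        dwi = add_rician_noise(dwi, spec.sigma, rng=rng)
    return Phantom(dwi=dwi, labels=labels, tensors=tens6, affine=spec.affine, spec=spec, gtab=gtab)


def analytic_alps(spec: PhantomSpec) -> float:
    """Ground-truth ALPS index of the phantom's region tensors.

    mean(Dxx_projection, Dxx_association) / mean(Dyy_projection, Dzz_association),
    computed directly from the generating tensors — the reference value every
    pipeline-recovery test compares against.
    """
    tensors = spec.effective_tensors
    proj = tensors["projection"].D
    assoc = tensors["association"].D
    num = (proj[0, 0] + assoc[0, 0]) / 2.0
    den = (proj[1, 1] + assoc[2, 2]) / 2.0
    if den == 0:
        raise ZeroDivisionError("denominator diffusivities sum to zero")
    return float(num / den)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _draw_bounded(rng, n, mean, sd, lo=0.0, hi=math.inf):
    """Draw a bounded clinical score with exact target mean and SD.

    Uses a moment-matched gamma: right-skewed above the lower bound for
    scores like disease duration or motor ratings, reflected (left-skewed)
    below the upper bound for ceiling-limited scores like MMSE. The gamma
    family attains any mean/SD pair on a one-sided support, which a truncated
    normal cannot (e.g. MMSE 27.86 ± 2.20 with a ceiling at 30).
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    if math.isfinite(hi):
        gap = hi - mean
        if gap <= 0:
            raise ValueError(f"mean {mean} must lie below the upper bound {hi}")
        x = hi - rng.gamma((gap / sd) ** 2, sd**2 / gap, size=n)
        # residual mass below lo is astronomically small for realistic scores
        return np.clip(x, lo, hi)
    gap = mean - lo
    if gap <= 0:
        raise ValueError(f"mean {mean} must lie above the lower bound {lo}")
    return lo + rng.gamma((gap / sd) ** 2, sd**2 / gap, size=n)


@dataclass(frozen=True)
class GroupParams:
    """Calibration of one diagnostic group."""

    n: int
    alps_mean: float
    alps_sd: float
    age_mean: float
    age_sd: float
    mmse_mean: float
    mmse_sd: float
    edu_mean: float
    edu_sd: float
    male_frac: float
    dur_mean: float | None = None
    dur_sd: float | None = None
    updrs_means: tuple | None = None     # parts I..V; total is their sum
    updrs_sds: tuple | None = None
    hy_stages: tuple | None = None
    hy_probs: tuple | None = None
    pvwmh_probs: tuple = (0.2, 0.4, 0.3, 0.1)

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        for name in ("alps_sd", "age_sd", "mmse_sd", "edu_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.male_frac <= 1:
            raise ValueError("male_frac must be in [0, 1]")
        if abs(sum(self.pvwmh_probs) - 1.0) > 1e-9 or len(self.pvwmh_probs) != 4:
            raise ValueError("pvwmh_probs must be 4 probabilities summing to 1")


# Table-1-style calibration: controls and two Parkinson's subgroups split by
# Hoehn–Yahr stage (early: HY 1–2; late: HY 2.5–4).
_NC_DEFAULT = GroupParams(
    n=36, alps_mean=1.53, alps_sd=0.16, age_mean=62.00, age_sd=6.24,
    mmse_mean=27.86, mmse_sd=2.20, edu_mean=10.44, edu_sd=3.18,
    male_frac=18 / 36, pvwmh_probs=(0.2, 0.4, 0.3, 0.1),
)
_EARLY_DEFAULT = GroupParams(
    n=35, alps_mean=1.46, alps_sd=0.15, age_mean=63.57, age_sd=8.93,
    mmse_mean=28.09, mmse_sd=2.47, edu_mean=12.91, edu_sd=3.48,
    male_frac=17 / 35, dur_mean=6.86, dur_sd=4.02,
    updrs_means=(2.80, 10.40, 26.31, 2.14, 0.97),
    updrs_sds=(2.13, 4.31, 9.80, 2.35, 1.04),
    hy_stages=(1.0, 1.5, 2.0), hy_probs=(1 / 3, 1 / 3, 1 / 3),
    pvwmh_probs=(0.2, 0.4, 0.3, 0.1),
)
_LATE_DEFAULT = GroupParams(
    n=36, alps_mean=1.42, alps_sd=0.18, age_mean=65.75, age_sd=7.23,
    mmse_mean=27.97, mmse_sd=1.83, edu_mean=12.94, edu_sd=3.16,
    male_frac=14 / 36, dur_mean=9.86, dur_sd=4.06,
    updrs_means=(3.28, 15.11, 35.39, 3.19, 1.14),
    updrs_sds=(1.72, 4.40, 11.54, 2.49, 0.87),
    hy_stages=(2.5, 3.0, 3.5, 4.0), hy_probs=(0.35, 0.35, 0.2, 0.1),
    pvwmh_probs=(0.0, 0.25, 0.5, 0.25),
)


@dataclass(frozen=True)
class CohortSimParams:
    """Three-group cohort calibration plus conditional-effect slopes.

    The conditional model applies slopes around group covariate means, so the
    marginal group ALPS mean stays at the calibration intercept:

    * early group: ALPS gains ``beta_mmse_early`` per MMSE point and
      ``beta_epvs_early`` per EPVS grade;
    * late group: ALPS changes by ``beta_age_late`` per year of age;
    * EPVS itself is an ordinal discretization of a latent Gaussian with
      slope ``beta_epvs_age`` (latent units per year of age).
    """

    nc: GroupParams = _NC_DEFAULT
    early: GroupParams = _EARLY_DEFAULT
    late: GroupParams = _LATE_DEFAULT
    beta_mmse_early: float = 0.021
    beta_epvs_early: float = -0.050
    beta_age_late: float = -0.012
    beta_epvs_age: float = 0.056
    epvs_ref_age: float = 64.0
    epvs_thresholds: tuple = (-0.5, 0.8, 1.8, 2.6)
    seed: int = 0

    def __post_init__(self):
        if list(self.epvs_thresholds) != sorted(self.epvs_thresholds) or len(self.epvs_thresholds) != 4:
            raise ValueError("epvs_thresholds must be 4 increasing cut points")
        for g, name in ((self.early, "early"), (self.late, "late")):
            if g.hy_stages is None or g.dur_mean is None or g.updrs_means is None:
                raise ValueError(f"{name} group needs duration, UPDRS and HY parameters")
        if any(h > 2 for h in self.early.hy_stages):
            raise ValueError("early-group HY stages must be <= 2")
        if any(h < 2.5 for h in self.late.hy_stages):
            raise ValueError("late-group HY stages must be >= 2.5")


def _epvs_from_age(rng, age, params):
    latent = params.beta_epvs_age * (age - params.epvs_ref_age) + rng.normal(size=age.shape)
    return np.digitize(latent, params.epvs_thresholds).astype(int)  # 0..4


def _residual_sd(target_sd, linear_part, context):
    var = target_sd**2 - np.var(linear_part)
    if var <= 0:
        raise ValueError(
            f"{context}: conditional slopes explain variance "
            f"{np.var(linear_part):.4g} >= target marginal variance "
            f"{target_sd**2:.4g}; reduce the slopes or raise the SD"
        )
    return math.sqrt(var)


def _simulate_group(rng, name, g, params):
    n = g.n
    cols = {}
    cols["group"] = [name] * n
    age = rng.normal(g.age_mean, g.age_sd, size=n)
    cols["age"] = age
    cols["sex"] = np.where(rng.random(n) < g.male_frac, "M", "F")
    cols["education_y"] = _draw_bounded(rng, n, g.edu_mean, g.edu_sd, lo=0.0)
    mmse = _draw_bounded(rng, n, g.mmse_mean, g.mmse_sd, lo=0.0, hi=30.0)
    cols["mmse"] = mmse
    epvs = _epvs_from_age(rng, age, params)
    cols["epvs"] = epvs
    cols["pvwmh"] = rng.choice(4, size=n, p=g.pvwmh_probs)

    if g.dur_mean is not None:
        cols["duration_y"] = _draw_bounded(rng, n, g.dur_mean, g.dur_sd, lo=0.0)
        parts = [
            _draw_bounded(rng, n, m, s, lo=0.0)
            for m, s in zip(g.updrs_means, g.updrs_sds)
        ]
        for i, p in enumerate(parts, start=1):
            cols[f"updrs{i}"] = p
        cols["updrs_total"] = np.sum(parts, axis=0)
        cols["hy"] = rng.choice(np.asarray(g.hy_stages, dtype=float), size=n, p=g.hy_probs)
    else:
        cols["duration_y"] = np.full(n, np.nan)
        for i in range(1, 6):
            cols[f"updrs{i}"] = np.full(n, np.nan)
        cols["updrs_total"] = np.full(n, np.nan)
        cols["hy"] = np.full(n, np.nan)

    if name == "ePD":
        lin = params.beta_mmse_early * (mmse - mmse.mean()) + params.beta_epvs_early * (
            epvs - epvs.mean()
        )
    elif name == "lPD":
        lin = params.beta_age_late * (age - age.mean())
    else:
        lin = np.zeros(n)
    sd_eps = _residual_sd(g.alps_sd, lin, f"group {name}") if np.any(lin) else g.alps_sd
    cols["alps"] = g.alps_mean + lin + rng.normal(0.0, sd_eps, size=n)
    return pd.DataFrame(cols)


COHORT_COLUMNS = [
    "subject_id", "group", "age", "sex", "education_y", "mmse", "duration_y",
    "updrs1", "updrs2", "updrs3", "updrs4", "updrs5", "updrs_total",
    "hy", "epvs", "pvwmh", "alps",
]


def simulate_cohort(params: CohortSimParams = CohortSimParams()) -> pd.DataFrame:
    """Draw a three-group cohort table; deterministic given ``params.seed``.

    Returns a DataFrame with one row per subject and the fixed column order
    ``COHORT_COLUMNS``. Group marginal ALPS mean/SD match the calibration;
    within-group conditional effects follow the stated slopes.
    """
    rng = substream(params.seed, "cohort")
    frames = [
        _simulate_group(rng, "NC", params.nc, params),
        _simulate_group(rng, "ePD", params.early, params),
        _simulate_group(rng, "lPD", params.late, params),
    ]
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "subject_id", [f"S{i:05d}" for i in range(len(df))])
    return df[COHORT_COLUMNS]
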