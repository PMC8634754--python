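"""ALPS index: spherical ROI placement, directional diffusivities, and the ratio.

The ALPS (analysis along the perivascular space) index compares water
diffusivity along the right–left (x) axis — the direction of the perivascular
spaces at the lateral-ventricle body — with diffusivity perpendicular to both
the perivascular spaces and the local fiber bundles:

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

where the two 5-mm spherical ROIs sit in the projection-fiber area (fibers
along z, so Dyy is the perpendicular diffusivity) and the association-fiber
area (fibers along y, so Dzz is perpendicular). A higher index means more
diffusivity along the perivascular direction.
"""

import json
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy import ndimage

from .gradients import GradientTable
from .synthetic import REGION_LABELS
from .tensor import DWIVolume, TensorField, fit_tensor, color_fa

__all__ = [
    "RoiSpec",
    "AlpsResult",
    "sphere_roi_mask",
    "roi_mean_diffusivities",
    "alps_index",
    "auto_place_rois",
    "compute_alps",
]

MIN_COMPONENT_VOXELS = 10
ROI_USABLE_WARN_FRACTION = 0.5
FA_DOMINANCE_THRESHOLD = 0.1   # only visibly anisotropic voxels count as colored


@dataclass(frozen=True)
class RoiSpec:
    """A spherical region of interest in world coordinates (mm)."""

    center: tuple
    diameter: float = 5.0
    target: str = ""    # 'projection' or 'association'

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")
        if len(self.center) != 3:
            raise ValueError("center must be a 3-vector (mm, world coordinates)")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))


def _voxel_centers_world(shape, affine):
    idx = np.indices(shape).reshape(3, -1)
    world = affine[:3, :3] @ idx + affine[:3, 3:4]
    return world.T.reshape(shape + (3,))


def sphere_roi_mask(center, diameter, shape, affine) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within the sphere.

    A voxel belongs to the ROI iff its center is within ``diameter/2`` mm
    (Euclidean, world coordinates) of ``center``. The sphere must lie fully
    inside the volume bounds; an empty mask raises with advice to enlarge the
    diameter.
    """
    center = np.asarray(center, dtype=float)
    radius = float(diameter) / 2.0
    if radius <= 0:
        raise ValueError("diameter must be > 0")
    affine = np.asarray(affine, dtype=float)
    shape = tuple(shape)
    corners = np.array(
        [[i, j, k] for i in (-0.5, shape[0] - 0.5)
         for j in (-0.5, shape[1] - 0.5) for k in (-0.5, shape[2] - 0.5)]
    )
    world_corners = corners @ affine[:3, :3].T + affine[:3, 3]
    lo, hi = world_corners.min(axis=0), world_corners.max(axis=0)
    if np.any(center - radius < lo) or np.any(center + radius > hi):
        raise ValueError(
            f"sphere (center {tuple(center)}, d={diameter} mm) extends outside "
            "the volume bounds"
        )
    world = _voxel_centers_world(shape, affine)
    dist2 = np.sum((world - center) ** 2, axis=-1)
    mask = dist2 <= radius**2
    if not mask.any():
        raise ValueError(
            "spherical ROI contains no voxel centers; use a larger diameter "
            "(sphere smaller than the voxel grid spacing)"
        )
    return mask


def roi_mean_diffusivities(tf: TensorField, mask: np.ndarray):
    """Mean (Dxx, Dyy, Dzz) over unflagged voxels of the mask.

    Returns ``(dxx, dyy, dzz, n_used, n_flagged)``; raises if every masked
    voxel is flagged.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    good = mask & ~tf.flag_mask
    n_flagged = int(mask.sum() - good.sum())
    if not good.any():
        raise ValueError("all ROI voxels are flagged as unusable fits")
    dxx = float(tf.Dxx[good].mean())
    dyy = float(tf.Dyy[good].mean())
    dzz = float(tf.Dzz[good].mean())
    return dxx, dyy, dzz, int(good.sum()), n_flagged


def alps_index(dxx_proj, dxx_assoc, dyy_proj, dzz_assoc) -> float:
    """mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)."""
    vals = [dxx_proj, dxx_assoc, dyy_proj, dzz_assoc]
    if not all(np.isfinite(vals)):
        raise ValueError("non-finite diffusivity input")
    den = dyy_proj + dzz_assoc
    if den <= 0:
        raise ValueError(
            f"denominator mean(Dyy_proj, Dzz_assoc) = {den / 2:.3g} is not "
            "positive (noisy/negative diagonal components); refusing to "
            "compute an ALPS index"
        )
    return float((dxx_proj + dxx_assoc) / den)


def _hemisphere_mask(shape, affine, laterality):
    world_x = _voxel_centers_world(shape, affine)[..., 0]
    if laterality == "left":
        return world_x < 0     # RAS+: left hemisphere has negative x
    if laterality == "right":
        return world_x > 0
    raise ValueError("laterality must be 'left' or 'right'")


def _centroid_world(mask, affine):
    idx = np.argwhere(mask).mean(axis=0)
    return tuple(affine[:3, :3] @ idx + affine[:3, 3])


def auto_place_rois(*, labels=None, tensorfield=None, affine=None, slice_index,
                    laterality="left", diameter=5.0):
    """Place the projection and association ROIs on the ventricle-body slice.

    Label mode (``labels`` given): each ROI centers on the centroid of its
    region label restricted to the axial slice and hemisphere.

    Heuristic mode (``tensorfield`` given): mimics manual placement on a
    color-FA map — the projection ROI centers on the largest connected
    component of blue-dominant (z-axis) voxels in the slice/hemisphere, the
    association ROI on the largest green-dominant (y-axis) component, which
    must lie lateral to the projection component.
    """
    if (labels is None) == (tensorfield is None):
        raise ValueError("provide exactly one of labels= or tensorfield=")
    if labels is not None:
        if affine is None:
            raise ValueError("label mode requires affine=")
        shape = labels.shape
        hemi = _hemisphere_mask(shape, affine, laterality)
        sl = np.zeros(shape, dtype=bool)
        sl[:, :, slice_index] = True
        centers = {}
        for target in ("projection", "association"):
            m = (labels == REGION_LABELS[target]) & hemi & sl
            if not m.any():
                raise ValueError(
                    f"no '{target}' label voxels on slice {slice_index} in the "
                    f"{laterality} hemisphere"
                )
            centers[target] = _centroid_world(m, affine)
        aff = affine
    else:
        aff = tensorfield.affine
        shape = tensorfield.fa.shape
        rgb = color_fa(tensorfield)
        hemi = _hemisphere_mask(shape, aff, laterality)[:, :, slice_index]
        r, g, b = (rgb[:, :, slice_index, c] for c in range(3))
        vivid = tensorfield.fa[:, :, slice_index] > FA_DOMINANCE_THRESHOLD
        centers = {}
        for target, dom in (("projection", (b > r) & (b > g) & vivid),
                            ("association", (g > r) & (g > b) & vivid)):
            m2d = dom & hemi
            lbl, n = ndimage.label(m2d)
            if n == 0:
                raise ValueError(
                    f"no {target}-dominant voxels on slice {slice_index}; "
                    "place the ROI manually"
                )
            sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, index=range(1, n + 1))
            best = int(np.argmax(sizes)) + 1
            if sizes[best - 1] < MIN_COMPONENT_VOXELS:
                raise ValueError(
                    f"largest {target}-dominant component has "
                    f"{int(sizes[best - 1])} voxels (< {MIN_COMPONENT_VOXELS}); "
                    "place the ROI manually"
                )
            comp3d = np.zeros(shape, dtype=bool)
            comp3d[:, :, slice_index] = lbl == best
            centers[target] = _centroid_world(comp3d, aff)
        if abs(centers["association"][0]) < abs(centers["projection"][0]):
            raise ValueError(
                "association component is medial to the projection component; "
                "check the slice or place ROIs manually"
            )
    return (
        RoiSpec(center=centers["projection"], diameter=diameter, target="projection"),
        RoiSpec(center=centers["association"], diameter=diameter, target="association"),
    )


@dataclass(frozen=True)
class AlpsResult:
    """The four diffusivities entering the ALPS ratio, the index, and provenance."""

    alps_index: float
    Dxx_proj: float
    Dyy_proj: float
    Dzz_proj: float
    Dxx_assoc: float
    Dyy_assoc: float
    Dzz_assoc: float
    n_voxels_proj: int
    n_voxels_assoc: int
    n_flagged_proj: int
    n_flagged_assoc: int
    roi_proj: RoiSpec
    roi_assoc: RoiSpec
    method: str
    software_version: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roi_proj"] = asdict(self.roi_proj)
        d["roi_assoc"] = asdict(self.roi_assoc)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)


def compute_alps_bilateral(dwi, gtab, **kwargs) -> float:
    """Average of the left- and right-hemisphere ALPS indices (auto-placed ROIs).

    The standard index is computed in the left hemisphere only; this optional
    mode averages both sides for symmetry-sensitivity checks.
    """
    kwargs.pop("laterality", None)
    left = compute_alps(dwi, gtab, laterality="left", **kwargs)
    right = compute_alps(dwi, gtab, laterality="right", **kwargs)
    return (left.alps_index + right.alps_index) / 2.0


def compute_alps(dwi: DWIVolume, gtab: GradientTable, rois=None, *,
                 labels=None, slice_index=None, laterality="left",
                 method="ols", mask=None) -> AlpsResult:
    """End-to-end ALPS: tensor fit → ROI diffusivities → index.

    ``rois`` may be a (projection RoiSpec, association RoiSpec) pair; when
    omitted the ROIs are auto-placed on ``slice_index`` — from a region-label
    volume if ``labels`` is given, else heuristically from the color-FA map.
    """
    from . import __version__

    tf = fit_tensor(dwi, gtab, method=method, mask=mask)
    if rois is None:
        if slice_index is None:
            raise ValueError("auto placement requires slice_index")
        if labels is not None:
            roi_p, roi_a = auto_place_rois(
                labels=labels, affine=dwi.affine, slice_index=slice_index,
                laterality=laterality,
            )
        else:
            roi_p, roi_a = auto_place_rois(
                tensorfield=tf, slice_index=slice_index, laterality=laterality
            )
    else:
        roi_p, roi_a = rois

    shape = tf.fa.shape
    mask_p = sphere_roi_mask(roi_p.center, roi_p.diameter, shape, tf.affine)
    mask_a = sphere_roi_mask(roi_a.center, roi_a.diameter, shape, tf.affine)
    dxx_p, dyy_p, dzz_p, n_p, nf_p = roi_mean_diffusivities(tf, mask_p)
    dxx_a, dyy_a, dzz_a, n_a, nf_a = roi_mean_diffusivities(tf, mask_a)
    idx = alps_index(dxx_p, dxx_a, dyy_p, dzz_a)
    return AlpsResult(
        alps_index=idx,
        Dxx_proj=dxx_p, Dyy_proj=dyy_p, Dzz_proj=dzz_p,
        Dxx_assoc=dxx_a, Dyy_assoc=dyy_a, Dzz_assoc=dzz_a,
        n_voxels_proj=n_p, n_voxels_assoc=n_a,
        n_flagged_proj=nf_p, n_flagged_assoc=nf_a,
        roi_proj=roi_p, roi_assoc=roi_a, method=method,
        software_version=__version__,
    )
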