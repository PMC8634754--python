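"""Pipeline configuration: a single strict YAML/JSON document.

Unknown keys are rejected so typos fail loudly; command-line flags override
file values. The configuration round-trips losslessly through
``to_dict``/``from_dict``.
"""

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

import yaml

from .synthetic import (
    PhantomSpec, CohortSimParams, GroupParams, RegionTensor,
    DEFAULT_REGION_TENSORS,
)

__all__ = ["PipelineConfig", "load_config", "config_hash"]

_PHANTOM_KEYS = {
    "grid_shape", "voxel_size", "S0", "snr", "ventricle_half_width_mm",
    "band_width_mm", "ventricle_body_slice", "rotation_deg", "region_diffusivities",
}
_COHORT_GROUP_KEYS = {
    "n", "alps_mean", "alps_sd", "age_mean", "age_sd", "mmse_mean", "mmse_sd",
    "edu_mean", "edu_sd", "male_frac", "dur_mean", "dur_sd", "updrs_means",
    "updrs_sds", "hy_stages", "hy_probs", "pvwmh_probs",
}
_COHORT_KEYS = {
    "nc", "early", "late", "beta_mmse_early", "beta_epvs_early",
    "beta_age_late", "beta_epvs_age", "epvs_ref_age", "epvs_thresholds",
}
_FIT_KEYS = {"method", "s0_mode"}
_ROI_KEYS = {"mode", "proj_center", "assoc_center", "slice_index", "laterality", "diameter"}
_STATS_KEYS = {"ttest", "posthoc", "regression_covariates"}
_TOP_KEYS = {"phantom", "cohort", "fit", "roi", "stats", "seed", "out_dir", "log_level"}


def _check_keys(block: dict, allowed: set, where: str):
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Validated parameters for the full simulate → fit → ALPS → stats run."""

    phantom: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    fit: dict = field(default_factory=lambda: {"method": "ols"})
    roi: dict = field(default_factory=lambda: {"mode": "label", "laterality": "left"})
    stats: dict = field(default_factory=lambda: {"ttest": "welch", "posthoc": "tukey"})
    seed: int = 0
    out_dir: str = "dtialps_out"
    log_level: str = "INFO"

    def __post_init__(self):
        _check_keys(self.phantom, _PHANTOM_KEYS, "phantom")
        _check_keys(self.cohort, _COHORT_KEYS, "cohort")
        for grp in ("nc", "early", "late"):
            if grp in self.cohort:
                _check_keys(self.cohort[grp], _COHORT_GROUP_KEYS, f"cohort.{grp}")
        _check_keys(self.fit, _FIT_KEYS, "fit")
        _check_keys(self.roi, _ROI_KEYS, "roi")
        _check_keys(self.stats, _STATS_KEYS, "stats")
        if self.fit.get("method", "ols") not in ("ols", "wls"):
            raise ValueError("fit.method must be 'ols' or 'wls'")
        if self.roi.get("mode", "label") not in ("label", "heuristic", "manual"):
            raise ValueError("roi.mode must be label, heuristic or manual")
        if self.roi.get("mode") == "manual":
            for k in ("proj_center", "assoc_center"):
                if k not in self.roi:
                    raise ValueError(f"roi.mode=manual requires roi.{k}")

    # -- construction of stage parameter objects -------------------------

    def phantom_spec(self) -> PhantomSpec:
        kw = dict(self.phantom)
        diffs = kw.pop("region_diffusivities", None)
        if diffs is not None:
            tensors = dict(DEFAULT_REGION_TENSORS)
            for name, d in diffs.items():
                import numpy as np
                tensors[name] = RegionTensor(name, np.diag([float(x) for x in d]))
            kw["region_tensors"] = tensors
        for key in ("grid_shape", "voxel_size"):
            if key in kw:
                kw[key] = tuple(kw[key])
        if kw.get("snr") in ("inf", None):
            kw.pop("snr", None)
        return PhantomSpec(seed=self.seed, **kw)

    def cohort_params(self) -> CohortSimParams:
        kw = dict(self.cohort)
        for grp in ("nc", "early", "late"):
            if grp in kw:
                gkw = dict(kw[grp])
                for tup in ("updrs_means", "updrs_sds", "hy_stages", "hy_probs",
                            "pvwmh_probs"):
                    if tup in gkw:
                        gkw[tup] = tuple(gkw[tup])
                base = getattr(CohortSimParams(), grp)
                kw[grp] = dataclasses.replace(base, **gkw)
        if "epvs_thresholds" in kw:
            kw["epvs_thresholds"] = tuple(kw["epvs_thresholds"])
        return CohortSimParams(seed=self.seed, **kw)

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        _check_keys(d, _TOP_KEYS, "top level")
        return cls(**d)


def load_config(path) -> PipelineConfig:
    """Load a YAML (or JSON — a YAML subset) configuration file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return PipelineConfig.from_dict(doc)


def config_hash(cfg: PipelineConfig) -> str:
    """Stable SHA-256 of the canonical JSON form (provenance stamping)."""
    canonical = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
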