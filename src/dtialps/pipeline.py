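"""The umbrella pipeline: simulate → fit → ALPS → cohort statistics.

Every run logs its seed, configuration hash, per-stage wall time and ROI
geometry, and stamps outputs with provenance so that a re-run with the same
configuration is bit-identical for every deterministic stage. A failing stage
raises a stage-named error and moves partial outputs under ``failed/``.
"""

import json
import logging
import os
import shutil
import time

from . import __version__
from .alps import compute_alps
from .config import PipelineConfig, config_hash
from .gradients import default_gradient_table
from .io import write_cohort_csv, write_phantom
from .stats import linear_regression, one_way_anova_posthoc, summarize_cohort
from .synthetic import make_phantom, analytic_alps, simulate_cohort
from .tensor import DWIVolume

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("dtialps")

DEFAULT_REGRESSION_COVARIATES = [
    "age", "sex", "duration_y", "mmse", "epvs", "updrs3", "updrs_total", "hy",
]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage, cause):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(name, exc) from exc
            log.info("stage %-16s %.2f s", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> dict:
    """Run the full pipeline described by ``cfg``; returns the result bundle.

    Writes ``phantom/`` (DWI + ground truth), ``alps_result.json``,
    ``cohort.csv``, ``cohort_summary.csv``, ``anova.json`` and
    ``regressions.json`` under the output directory. On failure, whatever was
    produced is moved under ``failed/`` and a stage-named error is raised.
    """
    out_dir = out_dir or cfg.out_dir
    os.makedirs(out_dir, exist_ok=True)
    chash = config_hash(cfg)
    log.info("pipeline start: seed=%d config_hash=%s version=%s",
             cfg.seed, chash, __version__)
    provenance = {"config_hash": chash, "seed": cfg.seed, "version": __version__}

    try:
        spec = cfg.phantom_spec()
        gtab = default_gradient_table(seed=cfg.seed)
        phantom = _stage("simulate_phantom")(make_phantom)(spec, gtab)
        _stage("write_phantom")(write_phantom)(phantom, os.path.join(out_dir, "phantom"))

        dwi = DWIVolume(data=phantom.dwi, affine=phantom.affine)
        roi_mode = cfg.roi.get("mode", "label")
        kwargs = dict(method=cfg.fit.get("method", "ols"))
        if roi_mode == "manual":
            from .alps import RoiSpec
            kwargs["rois"] = (
                RoiSpec(tuple(cfg.roi["proj_center"]), cfg.roi.get("diameter", 5.0), "projection"),
                RoiSpec(tuple(cfg.roi["assoc_center"]), cfg.roi.get("diameter", 5.0), "association"),
            )
        else:
            kwargs["slice_index"] = cfg.roi.get("slice_index", spec.ventricle_body_slice)
            kwargs["laterality"] = cfg.roi.get("laterality", "left")
            if roi_mode == "label":
                kwargs["labels"] = phantom.labels
        result = _stage("compute_alps")(compute_alps)(dwi, gtab, **kwargs)
        log.info("ALPS ROI proj center=%s assoc center=%s voxels=(%d, %d)",
                 result.roi_proj.center, result.roi_assoc.center,
                 result.n_voxels_proj, result.n_voxels_assoc)

        alps_doc = {
            "provenance": provenance,
            "analytic_alps": analytic_alps(spec),
            "result": result.to_dict(),
        }
        with open(os.path.join(out_dir, "alps_result.json"), "w") as fh:
            json.dump(alps_doc, fh, indent=2, sort_keys=True)

        params = cfg.cohort_params()
        cohort = _stage("simulate_cohort")(simulate_cohort)(params)
        write_cohort_csv(cohort, os.path.join(out_dir, "cohort.csv"))

        summary = _stage("cohort_summary")(summarize_cohort)(
            cohort, ttest_variant=cfg.stats.get("ttest", "welch")
        )
        summary.to_csv(os.path.join(out_dir, "cohort_summary.csv"), index=False)

        by_group = [cohort.loc[cohort["group"] == g, "alps"] for g in ("NC", "ePD", "lPD")]
        F, dfs, p, pairwise = _stage("anova")(one_way_anova_posthoc)(
            by_group, posthoc=cfg.stats.get("posthoc", "tukey"),
            labels=["NC", "ePD", "lPD"],
        )
        with open(os.path.join(out_dir, "anova.json"), "w") as fh:
            json.dump({"provenance": provenance, "F": F, "df": list(dfs), "p": p,
                       "pairwise": pairwise.to_dict(orient="records")},
                      fh, indent=2, sort_keys=True)

        covs = cfg.stats.get("regression_covariates", DEFAULT_REGRESSION_COVARIATES)
        regs = {}
        for grp in ("ePD", "lPD"):
            res = _stage(f"regression_{grp}")(linear_regression)(
                cohort, response="alps", covariates=covs, subset=grp
            )
            regs[grp] = {
                "beta": res.beta, "se": res.se, "p": res.p,
                "n": res.n, "r_squared": res.r_squared,
            }
        with open(os.path.join(out_dir, "regressions.json"), "w") as fh:
            json.dump({"provenance": provenance, "fits": regs}, fh,
                      indent=2, sort_keys=True)
    except PipelineError:
        failed = os.path.join(out_dir, "failed")
        os.makedirs(failed, exist_ok=True)
        for name in os.listdir(out_dir):
            if name != "failed":
                shutil.move(os.path.join(out_dir, name), os.path.join(failed, name))
        raise

    return {
        "provenance": provenance,
        "alps": alps_doc,
        "cohort": cohort,
        "summary": summary,
        "regressions": regs,
    }
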