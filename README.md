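# dtialps

**Diffusion tensor image analysis along the perivascular space (DTI-ALPS),
end to end** — from diffusion-weighted volumes through per-voxel tensor
fitting and ROI-based directional diffusivities to the ALPS index, plus the
cohort-level statistics used in clinical glymphatic-imaging studies, and
synthetic phantoms/cohorts with known ground truth to validate all of it.

The ALPS index is a non-invasive MRI proxy for glymphatic (perivascular
fluid-clearance) function. At the level of the lateral-ventricle body, the
perivascular spaces run right–left (x), perpendicular to both the projection
fibers (z) and association fibers (y). With D·· the mean diagonal tensor
components inside two 5-mm spherical ROIs placed on a color-FA map,

```
ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)
```

Higher values indicate more water diffusivity along the perivascular
direction; indices near 1 indicate none. The index has been applied in
Alzheimer's disease, normal-pressure hydrocephalus and Parkinson's disease,
where patients show lower values than controls.

Who this is for: neuroimaging researchers who want a transparent,
fully-testable ALPS implementation (most published values come from manual
ROI work in GUI tools), and methodologists who want calibrated synthetic
cohorts to study the index's statistical behavior.

## Worked example

Run the complete demonstration pipeline (synthetic phantom → tensor fit →
ALPS → simulated cohort → statistics):

```
$ dtialps run --seed 3 --out demo/
{
  "config_hash": "94e9e799858b687b",
  "seed": 3,
  "version": "0.1.0"
}
ALPS index = 1.3529 (analytic 1.3529)
```

The printed index, computed by fitting tensors to the simulated acquisition
and averaging diagonal diffusivities in auto-placed 5-mm ROIs, matches the
value implied analytically by the phantom's ground-truth region tensors
(mean(0.60, 0.55)/mean(0.45, 0.40)×10⁻³ = 1.3529) — the pipeline recovers
known truth exactly on noiseless data. `demo/` then contains the phantom
(NIfTI + FSL bval/bvec), `alps_result.json` with the six ROI diffusivities
and provenance, a simulated three-group cohort (`cohort.csv`), a
demographics table with group tests (`cohort_summary.csv`), ANOVA + Tukey
post hoc results, and within-group regressions of ALPS on clinical
covariates. A second run with the same seed is bit-identical.

The same stages are available individually (`simulate-phantom`,
`simulate-cohort`, `fit-tensor`, `compute-alps`, `cohort-stats`, `regress`)
and as library functions:

```python
import dtialps

res = dtialps.t_test_from_summary(36, 62.00, 6.24, 71, 64.68, 8.12)
# (t=-1.89, df=88.3, p=0.062) — Welch test straight from printed summaries
```

See `docs/methods.md` for the model, the phantom and cohort-simulator
design, and numerical conventions.

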