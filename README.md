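# attnspot

Attention-spotlight analysis of retinotopic fMRI: background (residual)
connectivity profiles under focal vs diffused spatial attention, bilinear
dynamic causal modeling (DCM) with variational-Laplace inversion and
random-effects Bayesian model selection, and stimulus-field center/size
estimation — plus a synthetic BOLD generator so the entire pipeline can be
exercised end to end without real MRI data.

## What it does

Given per-subject V1 vertex time series and downstream-area (V2/V3/V4)
series acquired under two attention conditions (focal attention on a
parafoveal stimulus array vs diffused attention across the field), the
pipeline:

1. **Residualizes** each run: optional high-pass (DCT basis), nuisance GLM,
   and exact removal of the mean evoked response with a finite-impulse-response
   (FIR) basis spanning each stimulus+fixation cycle (`attnspot.residualize`).
2. **Maps ROIs**: a localizer GLM defines the stimulated V1 subregion; the
   remaining vertices are binned by eccentricity (stim, 4–6°, 6–8°, 8–10°)
   along the horizontal meridian (`attnspot.retinomap`).
3. **Profiles background connectivity**: per-run Pearson correlations
   between V1 vertices and each downstream area on the residuals, Fisher
   z-transformed and averaged; tested with repeated-measures ANOVA
   (Huynh–Feldt corrected), paired t-tests, and FDR adjustment
   (`attnspot.bgconn`).
4. **Fits DCMs**: three candidate modulation structures (feedforward,
   feedback, recurrent) on V1_S / V1_NS / extrastriate node time series;
   bilinear neuronal dynamics plus balloon hemodynamics, inverted by
   variational Laplace; structures compared by random-effects Bayesian model
   selection; modulatory parameters tested at the group level
   (`attnspot.dcm_engine`).
5. **Estimates the stimulus field**: eccentricity response profiles are
   truncated at zero, normalized to a distribution, and summarized by their
   mean (field center) and 2×SD (field size) (`attnspot.attnfield`).

`attnspot.synthgen` generates cohorts with known ground truth (connectivity
gain profiles per eccentricity bin and condition, or DCM coupling matrices),
and `attnspot.pipeline_io` handles HDF5 datasets, NIfTI/GIFTI import, YAML
configuration, and the one-call `run_pipeline`.

## Quick start

```python
import attnspot as ats

# simulate a small cohort with an attention-dependent connectivity gradient
cohort = ats.synthgen.make_cohort(
    8, "weak_crowding", seed=1,
    design=ats.DesignSpec(n_runs_per_condition=4, n_cycles=6),
    n_vertices=150, snr=1.0,
)
profiles = ats.pipeline_io.cohort_profiles(cohort)     # tidy z per bin/condition
anova, ttests = ats.pipeline_io.cohort_stats(profiles)  # rm-ANOVA + paired t
```

Command line:

```bash
attnspot simulate --scenario weak_crowding --subjects 8 --seed 1 --out sims/
attnspot rois --in sims/sub-00.h5 --out rois.tsv
attnspot run config.yaml --out results/   # full pipeline from a YAML config
```

DCM model comparison:

```python
import numpy as np
from attnspot import dcm_engine as de, synthgen
from attnspot.core import DesignSpec

design = DesignSpec(n_runs_per_condition=2, n_cycles=10)
cohort, run_conds = synthgen.make_dcm_cohort(8, "recurrent", design, seed=42)
models = {s: de.specify_model(s, design, run_conds, nodes=de.NODES_3)
          for s in de.STRUCTURES}
F = np.array([[de.invert(models[s], y).free_energy for s in de.STRUCTURES]
              for y, _ in cohort])
print(de.rfx_bms(F).exceedance_prob)
```

## Testing

```bash
pytest -q                       # unit + acceptance suite
python scripts/acceptance.py --seed 0 --out report.json   # JSON metrics
```

The acceptance tests check FIR exactness, recovery of the
connectivity-gradient interaction, null calibration of the statistics, DCM
structure selection and parameter recovery, closed-form forward-model
oracles, and the field estimator against quadrature. See `docs/methods.md`
for the statistical details and the problem-size scaling used in CI.

## Layout

- `src/attnspot/core.py` — design/timing, geometry, dataset containers
- `src/attnspot/synthgen.py` — synthetic cohorts with ground truth
- `src/attnspot/residualize.py` — DCT high-pass, nuisance GLM, FIR removal
- `src/attnspot/retinomap.py` — localizer contrast, ROI assignment
- `src/attnspot/bgconn.py` — connectivity maps, profiles, statistics
- `src/attnspot/dcm_engine/` — model specification, forward model,
  variational-Laplace inversion, BMS, group statistics
- `src/attnspot/attnfield.py` — stimulus-field center/size estimation
- `src/attnspot/pipeline_io.py` — HDF5/NIfTI/GIFTI/YAML I/O, full pipeline
- `src/attnspot/cli.py` — `attnspot` command-line interface
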