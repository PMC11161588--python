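# Methods

This note records the statistical and numerical conventions used by
`attnspot`, and the problem-size scaling applied in the test suite.

## Synthetic data generator (`synthgen`)

Vertices get polar retinotopic coordinates (eccentricity 0–12°, uniform in
area; polar angle uniform). The stimulus is a disc of radius 1.5° centered
at 2.5° eccentricity on the horizontal meridian; `is_stimulated_truth`
marks vertices whose visual-field position falls inside the disc.

Per run, each vertex's BOLD is

```
bold = evoked + gain(bin, condition) * latent + nuisance + noise
```

- **evoked**: stimulus boxcar convolved with a double-gamma HRF in steady
  state (periodic convolution), identical across conditions, so the evoked
  component is exactly cycle-locked from the first volume.
- **latent**: a shared low-pass-filtered (Butterworth, 0.1 Hz) Gaussian
  fluctuation per run; the same latent series drives the downstream-area
  series, so the per-bin coupling *gain* sets the background correlation.
  Scenario profiles (`SCENARIO_PROFILES`) define gain(bin, condition);
  `weak_crowding` has a focal > diffused gain at the stim bin and the
  reverse at 4–6° and 6–8°; `null` uses identical gains for both
  conditions.
- **nuisance**: random linear combinations of 8 realistic regressors
  (drifts, motion-like series); the mixing weights are returned with the
  dataset so the analysis can regress them out.
- **noise**: iid Gaussian scaled so that SD(signal)/SD(noise) = `snr`
  (`snr=inf` disables it).

Per-subject seeds derive from the cohort master seed via
`np.random.SeedSequence(master, spawn_key=(i,))`, so cohorts are
reproducible and subjects are independent.

DCM cohorts (`make_dcm_cohort`) integrate the bilinear forward model from a
ground-truth parameter vector (`dcm_truth_params`) with per-subject Gaussian
jitter on A and B. Before integrating, the generator verifies that
`A + Σ_j u_j B_j` has eigenvalues with negative real part for every input
combination realized in the design; destabilizing jitter draws are redrawn
(deterministically, from the subject's stream).

## Residualization (`residualize`)

Per run, a single joint GLM contains the DCT drift regressors (optional
high-pass, cutoff 100 s), the nuisance matrix, and — when evoked removal is
requested — an FIR basis of one indicator per TR position within the
stimulus+fixation cycle. Fitting everything jointly makes the residuals
exactly orthogonal to every regressor set; sequential regression (nuisance
first, FIR second) would leak the nuisance-projection of the evoked
response back into the residuals. The FIR columns span all cycle-locked
signals, so a purely cycle-locked input is annihilated to machine
precision — the property checked by acceptance criterion 1. Residual
variance after projection on a rank-p design over T volumes shrinks by
(T−p)/T; the df-accounting check verifies this within 2%. The standalone
`remove_evoked` helper still operates on pre-cleaned runs (and warns
otherwise).

## Background connectivity (`bgconn`)

Pearson correlations between each V1 vertex and each downstream-area
series, computed per run on residuals, Fisher z-transformed (atanh), and
averaged across a condition's runs (`per_run_z_mean`; a `concatenated`
variant exists for comparison). Profiles average z within eccentricity
bins.

Statistics:

- **Repeated-measures two-way ANOVA** on the subject × factor-A × factor-B
  cell table, with each effect tested against its subject-interaction error
  term. Reported F and df are the classical (uncorrected) values; p-values
  carry the **Huynh–Feldt** sphericity correction: epsilon is first
  estimated à la Greenhouse–Geisser from the covariance of orthonormalized
  within-subject contrasts (clipped to [1/df1, 1]), then Huynh–Feldt
  bias-corrected (clipped to [GG, 1]). Without any correction the
  interaction test involving the 4-level visual-field factor is
  anticonservative (empirical null rejection ≈ 0.07 at nominal 0.05);
  the raw GG correction over-corrects at 8 subjects (≈ 0.033); Huynh–Feldt
  restores ≈ 0.055.
- **Paired and one-sample t tests**, with exact zero-difference handled as
  t=0, p=1, and constant non-zero differences rejected as undefined.
- **Benjamini–Hochberg FDR** adjustment across each result family.

## DCM engine (`dcm_engine`)

Nodes are V1_S (stimulated subregion), V1_NS (non-stimulated, 6–8°), and
either one pooled extrastriate node (3-node preset) or V2/V3/V4 (5-node).
Inputs: u1 = stimulus boxcar (drives V1_S only), u2 = attention indicator
(1 during focal runs). The three candidate structures free the attention
modulation (B2) on feedforward V1→extrastriate links, feedback
extrastriate→V1 links, or both ("recurrent"); the lateral V1_S↔V1_NS pair
is always free.

- **Forward model**: bilinear neuronal dynamics
  dz/dt = (A + Σ_j u_j B_j) z + C u, with self-connections parameterized as
  −0.5·exp(θ) (log scale, guaranteeing negativity), coupled to the balloon
  hemodynamic model integrated in log-space so flow, volume, and
  deoxyhemoglobin stay positive. RK4 at dt = TR/16, numba-compiled, batched
  over parameter vectors. Linear-regime trajectories match the piecewise
  matrix-exponential closed form to < 1e−5 (criterion 5).
- **Inversion**: variational Laplace with Gaussian priors, central
  finite-difference Jacobians, Levenberg-damped Gauss–Newton M-steps, and
  per-run mean removal (one df per run deducted in the noise-precision
  update). The free energy includes the standard accuracy, complexity, and
  trace terms.
- **Model comparison**: random-effects BMS — variational Dirichlet update
  on per-subject free energies; exceedance probabilities by Monte Carlo on
  the fitted Dirichlet (1e6 draws).
- **Group statistics**: per-pathway S-vs-NS paired t tests, one-sample
  tests vs 0, and a visual-field × area rm-ANOVA where ≥2 areas carry free
  modulation; FDR-adjusted.

## Stimulus field (`attnfield`)

Eccentricity response profiles (stimulus-vs-fixation GLM betas averaged in
1° bins) are truncated at zero and normalized to a probability
distribution. Field center = mean of that distribution; field size =
2×SD. Against a continuous Gaussian profile (center 2.5°, SD 1°)
discretized to 1° bins, the estimator agrees with the quadrature oracle
within half a bin (center) and 0.3° (size).

## Problem-size scaling in the test suite

The study-scale design (8 runs per condition, 10 cycles per run, 300+
vertices, 5-node DCM) is too slow for a single-CPU CI budget. The suite
scales *sizes*, never thresholds or test logic:

| Criterion | Scaled size | Study scale |
|---|---|---|
| 1 FIR exactness | 150 vertices, 2 runs/cond, 4 cycles | identical property at any size |
| 2 gradient recovery | 8 subjects, 150 vertices, 6 runs/cond, 8 cycles, snr 1, 100 cohorts | 8 runs/cond, 10 cycles, 300 vertices |
| 3 null calibration | 8 subjects, 100 vertices, 2 runs/cond, 6 cycles, 1000 reps | 8 runs/cond, 10 cycles, 300 vertices |
| 4 DCM selection | 8 subjects, 3-node preset, 2 runs/cond, 10 cycles, snr 2 | 5-node, 8 runs/cond |
| 5 forward oracles | 3-node, 1 run/cond, 3 cycles | n/a (exact identities) |
| 6 field estimator | 10 one-degree bins | same |

Statistics pooled for acceptance use the per-subject mean z across
downstream areas ("pooled" profile), so each criterion tests one ANOVA
rather than three.

All randomness is seeded; `scripts/acceptance.py --seed N` offsets every
seed range by N, so reported rates are honest re-draws rather than a
memorized batch.
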