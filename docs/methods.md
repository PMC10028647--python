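# Methods

## Model and procedure

The quantity at the center of this package is the **temporal clustering
coefficient** of a binary multilayer network: for node i with adjacency
a_ij(t) over W layers,

    C_i = (1/(W−1)) Σ_{t=1}^{W−1}
          Σ_j a_ij(t) a_ij(t+1) / sqrt( Σ_j a_ij(t) · Σ_j a_ij(t+1) ).

Each term is the overlap of node i's neighbor sets in consecutive layers,
normalized by the geometric mean of its two degrees, so by Cauchy–Schwarz
every term — and hence C_i — lies in [0, 1]. C_i = 1 exactly when the
neighbor set is nonempty and constant across every consecutive pair;
white-noise layers give values near the thresholding density.

The multilayer network is built per run by sliding-window Pearson
correlation followed by proportional thresholding, and the coefficient is
summarized at three scopes (nodal; unweighted subnetwork means; unweighted
global mean), at every density of a sweep. Reliability across repeated
runs is quantified by ICC(3,1) per density and summarized by the
density-averaged overall ICC; demographic effects are tested on
run-averaged metrics.

### Numerical conventions

* **Denominator square root.** The normalization uses the geometric mean
  sqrt(deg_t · deg_{t+1}). Without the radical the ratio can exceed 1,
  contradicting the metric's defined range.
* **Isolated nodes (0/0).** If node i has degree 0 in layer t or t+1, that
  transition contributes 0 and the divisor remains W−1. This keeps C_i
  defined at very low densities and matches the common toolbox behavior of
  treating an absent neighborhood as zero overlap. It is a convention, not
  a mathematical necessity.
* **Edge-count rounding.** k_edges = round(density · N(N−1)/2) with
  round-half-away-from-zero — symmetric and platform-independent.
* **Edge ranking.** "Strongest" means largest *signed* correlation by
  default, conventional for data without global-signal regression where
  strong edges are predominantly positive; `rank_by="absolute"` is
  available. Negative correlations may therefore enter at high densities.
* **Ties.** Edges tied at the cutoff are kept in ascending (i, j)
  lexicographic order, making thresholding deterministic. Thresholding
  depends only on the rank order of the weights (invariant to strictly
  increasing transforms).
* **Windows.** Rectangular (no taper), half-open [s, s+width), starts at
  multiples of the step; trailing timepoints that do not fill a window are
  discarded, giving exactly ⌊(T − width)/step⌋ + 1 windows.
* **ICC(3,1).** Two-way ANOVA with subjects random and scan fixed:
  BMS from between-subject sums of squares, EMS the residual after
  removing the scan main effect — which makes the estimate exactly
  invariant to a pure per-scan shift (the property test asserts this).
  Negative estimates are reported as computed; an all-identical panel
  yields NaN with a warning. A panel with any missing cell is rejected
  rather than imputed. Optional confidence intervals use the standard
  F-distribution interval for ICC(3,1).
* **Classification boundary.** The published four-level criterion assigns
  [0.6, 0.75) to "good" and (0.75, ∞) to "excellent", leaving exactly 0.75
  unassigned; we map 0.75 to "good" (conservative, measure-zero case).
* **Sex contrast.** In a balanced split-plot design the between-subject
  stratum is exactly the analysis of subject means over the within-factor
  (density) levels, so the sex F is computed by OLS ANCOVA on each
  subject's density mean with age, education and mean framewise
  displacement as covariates. This reproduces the repeated-measures
  between-subject F without modeling the density main effect or
  sphericity. Constant covariates are dropped; rank-deficient designs are
  rejected with the collinear columns named. A numerically perfect fit
  returns F = 0, p = 1 (or F = ∞ when the sex coefficient is genuinely
  nonzero).
* **Age association.** Partial Spearman: mid-ranks for ties, metric and
  age ranks residualized on covariate ranks, t-approximation with
  n − 2 − #covariates degrees of freedom. With degenerate covariates this
  reduces exactly to the plain Spearman correlation.
* **Bonferroni families.** 2 tests at the global level and 2 × 9 = 18 at
  the subnetwork level by default; family sizes are arguments, not
  constants.

## The synthetic cohort generator

The generator emulates the *statistical* structure the analyses assume,
not fMRI physics. Each run is a regime-switching Gaussian factor model:

* A **regime** assigns each of the nine subnetworks to one of
  `n_modules = 3` latent modules; every node's signal is
  `coupling · f_module + sqrt(1 − coupling²) · ε` with standard-normal
  factors and noise, plus isotropic observation noise (`noise_sd`).
  Within a regime the strongest correlations therefore sit inside modules;
  at a regime switch the module pattern is redrawn and the strong-edge set
  changes.
* Regime durations are geometric with mean **dwell** λ timepoints
  (memoryless; a single interpretable parameter). Long dwell ⇒ windowed
  networks persist across consecutive windows ⇒ high temporal clustering.
  λ is clipped at 2 to avoid single-sample regimes.
* Per run, λ = base_dwell + sex_effect·1[female] + age_slope·(age − mean
  age) + b_subject + e_run, with b_subject ~ N(0, σ_subject²) shared
  across a subject's runs and e_run ~ N(0, σ_run²). b_subject is what
  ICC(3,1) on any dwell-driven metric should recover; sex_effect and
  age_slope are what the group statistics should detect.
* Covariates: sex Bernoulli(0.5); age uniform on 22–37 years; education
  N(15, 2²) years; mean framewise displacement log-normal
  (median ≈ 0.2 mm). All draws flow from one seeded generator, so a spec
  and seed reproduce the cohort exactly.

### Default study conditions and why

| parameter | default | rationale |
|---|---|---|
| n_subjects × k_runs | 40 × 2 | enough subjects for group stats; ≥ 2 runs for reliability |
| n_nodes, t_points, TR | 20, 300, 0.72 s | desk-scale stand-in for a 90-node, 1200-timepoint run; 9 subnetworks keep 2–3 nodes each |
| window width, step | 20, 10 TRs | width ≈ half the base dwell keeps the dwell→persistence mapping in its sensitive range (it saturates once dwell ≫ width) |
| density grid (reduced) | 5–50% step 5% | spans the same range as the full 1–50% sweep at a tenth of the cost |
| base_dwell | 40 timepoints | ~2 windows' worth: regimes survive some transitions and not others |
| σ_subject, σ_run | 8, 4 | modest trait variance plus run noise |
| coupling, noise_sd | 0.9, 0.3 | within-module correlations ≈ 0.7 after noise, typical of strong functional edges |
| sex_effect (calibrated) | +35 timepoints | calibrated once so the n = 40+40 power study reaches its ≥ 80% design target; null cohorts use 0 |

The full-scale geometry (1200 timepoints, width 139, step 8 → 133 windows;
densities 1–50% at 1%) is exercised by the window/threshold arithmetic
itself, which is size-independent; the simulation studies use the reduced
conditions above so the power and type-I studies (50 and 200 cohorts)
finish in minutes.

### What the generator does *not* emulate

Hemodynamic autocorrelation and filtering, realistic fMRI noise spectra
(1/f, physiological), motion artifacts and their correlation with
demographics, spatial autocorrelation within subnetworks, and
heavy-tailed or skewed metric distributions. Passing tests therefore show
that the *estimators* behave correctly when their assumptions hold — not
that those assumptions hold in real resting-state data. In particular the
type-I error check validates the ANCOVA under Gaussian subject effects;
real cohorts with confounded motion or non-normal metrics may need the
rank-based route throughout.

On the default cohort the overall ICC of global temporal clustering is
low (≈ 0.1): with σ_subject = 8 on the dwell scale the trait signal is
small relative to windowed-estimation noise. The ICC recovery tests use
injected panels with known variance components instead, which is the
direct validation of the estimator; cohorts simulated with larger
σ_subject show correspondingly higher network-level ICCs.

## Design choices that were genuinely open

* **Persistence mechanism.** Dwell-time regime switching rather than
  autocorrelated edge weights: it maps directly onto "connections persist
  over consecutive windows" and provides a scalar ground truth per run.
* **Geometric dwell.** Memoryless, one parameter, easy closed-form
  reasoning.
* **Covariate effects on the timepoint scale.** Additive on λ, so effect
  sizes are in interpretable units (timepoints of persistence).
* **Static metrics via networkx.** The comparator metrics are standard
  graph quantities; tests check them against hand-derived values and a
  literal BFS oracle. The temporal clustering coefficient and ICC are
  implemented here and cross-checked against independent oracles
  (triple-loop brute force; pingouin's ICC(C,1)).
* **Balanced power-study cohorts.** The power/type-I studies fix exactly
  n females and n males per cohort (the effect enters the female half's
  dwell) so power is not diluted by random group-size imbalance.

## Limitations

* The temporal clustering coefficient is defined for binary networks only;
  no weighted or tapered variant is provided.
* Reliability requires complete, balanced panels — no imputation.
* The repeated-measures ANCOVA reports only the between-subject sex
  effect; density-by-sex interactions and sphericity corrections are out
  of scope.
* Sex is modeled as a two-level category (a simplification inherited from
  the study design this mirrors).
* The ICC confidence interval is the standard F interval, stated as an
  assumption rather than a reproduction of any published choice.
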