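# Methods

## Model and procedure

The pipeline treats a subject as a multivariate signal `X ∈ R^{n×N}`
(n regions, N timepoints, sampling interval TR in seconds) and proceeds:

**Windowed signed connectivity.** For window length `w` (default 50
timepoints — 36 s at the TR = 0.72 s typical of fast multiband fMRI) and
step 1, each window yields the n×n Pearson correlation matrix of the
windowed segments. Positive and negative correlations are both kept; the
diagonal is stored as 0 because self-edges never enter a triangle. No
tapering or regularization is applied — the weights are plain sample
correlations. With `N` timepoints this gives `T = ⌊(N − w)/step⌋ + 1`
matrices; when a recording concatenates several runs, `run_boundaries`
confines windows within runs (the default lets windows span joints, which
is the appropriate choice when the concatenated series has been
continuously preprocessed; both behaviors are supported because neither is
canonical).

**Triad classification and energy.** Every triple of regions i<j<k is a
triangle with edge weights (S_ij, S_ik, S_jk). The sign multiset assigns
one of four configurations `+++`, `+-+`, `-+-`, `---`; under strong
structural balance, `+++` and `-+-` (positive sign product) are balanced,
`+-+` and `---` imbalanced. The continuous companion measure is the triad
energy

    E = −sign(p)·|p|^{1/3},   p = S_ij · S_ik · S_jk,

i.e. minus the *signed* cube root of the edge-weight product. The cube
root is defined explicitly through sign and magnitude because raising a
negative base to the power 1/3 is undefined (or complex) in IEEE float
semantics. For correlation weights, E ∈ [−1, 1]; E < 0 for balanced,
E > 0 for imbalanced, E = 0 iff some edge weight is 0 (or the product
underflows). Exact-zero weights are classified as positive — a
measure-zero event for continuous correlations, fixed deterministically so
that classification is total.

**Episodes.** Per triangle, the per-window state sequence is split into
maximal same-state runs. Each run is an episode with a *lifetime* (number
of windows) and an *absolute peak energy* (max |E| within the run).
Lifetimes partition the window axis, so for every state
`occurrence[s] = Σ lifetimes of s-episodes` holds exactly — the identity
that links prevalence to dwell time and transition inflow. The first and
last episodes of every triangle are flagged left-/right-censored (their
true lifetimes are truncated by the observation window); they are included
in the per-state means by default, with `include_censored=False` available
as a sensitivity analysis. Per-state subject means are episode-weighted
(every episode counts once, across all triangles); a state with no
episodes carries `None`, never a silent 0. Triangles are processed as a
stream, so memory stays at one triangle's tracks regardless of n.

**Transitions and occurrence.** Adjacent episode pairs give a 4×4 directed
transition count matrix (zero diagonal by construction). Proportions are
reported under two normalizations — global (all transitions sum to 1) and
row/outflow — because "proportion of state changes" is denominator-
ambiguous; both are emitted. Group-level matrices average per-subject
proportion matrices so subjects weigh equally regardless of how many
transitions they produced.

**Surrogate null.** Classic Theiler phase randomization per region:
forward real FFT, magnitudes kept, phases of the free positive-frequency
bins replaced by i.i.d. U[0, 2π) draws (independent across regions by
default — destroying cross-regional coupling is the point of the null),
DC kept unchanged, and at even length the Nyquist bin kept real with a
random sign flip (its phase is constrained to {0, π}; randomizing the sign
treats it like every other bin as far as a real inverse transform allows).
The inverse transform is real by construction of the conjugate symmetry.
Amplitude-adjusted variants (AAFT/IAAFT) are unnecessary here because the
pipeline's inputs are standardized, approximately Gaussian signals.
Realization r draws from the substream (seed, r), so any single
realization is reproducible in isolation. The null summary runs the full
windows→triads pipeline on each of `n_realizations` surrogates (default
10) and averages the per-state means; states absent from a realization are
excluded from that realization's contribution and counted in
`realization_counts`.

**Group statistics.** All tests are two-sided paired Wilcoxon signed-rank
tests across subjects (zero differences dropped; ≥ 5 non-zero pairs
required; exact null for n ≤ 25 — the exact method also handles tied
midranks — normal approximation with continuity correction beyond). Effect
sizes are Cliff's delta, `(#{x_i > y_j} − #{x_i < y_j})/(n_x n_y)`.
FDR correction is Benjamini–Hochberg within each family: the 6 state pairs
per metric for within-subject comparisons, and the 4 per-state tests for
real-versus-surrogate lifetimes. The balanced-minus-imbalanced lifetime
gap (mean of `+++`, `-+-` minus mean of `+-+`, `---`, per subject) is
tested real-versus-surrogate as a single additional paired test; a
subject-level sign-flip permutation test (`permutation_gap_test`) is
provided as a sensitivity check because "nonparametric p-value" can denote
either procedure. Subjects missing a state are dropped (state-pair family)
or excluded pairwise (real-vs-null family), with counts logged.

## Synthetic generator

The generator emulates exactly the features the analysis consumes:

- **Signed covariance structure** via block correlation matrices — unit
  diagonal, `within_r` inside blocks, `between_r` across — repaired to PSD
  by eigenvalue clipping at zero followed by re-normalization to unit
  diagonal (a deliberately simple, reproducible repair; nearest-
  correlation-matrix iterations are out of scope). The repair reports
  whether it moved any entry by more than 1e-6.
- **Temporal autocorrelation** via an AR(1) filter applied after mixing,
  with the same coefficient for every region, so lag-0 cross-correlations
  are preserved by the filtering while each signal gains realistic
  smoothness. The AR state carries across regime boundaries (no seams).
- **Regime switches**: piecewise-stationary segments whose covariances
  differ; standardization to zero mean / unit sample variance is applied
  over the *full* series, so switches manifest as covariance changes, not
  variance jumps.
- **Determinism**: one global seed; each region draws innovations from its
  own spawned substream, so outputs are bit-identical across runs.
  Series shorter than 100 timepoints (2× the field-standard 50-timepoint
  window) trigger a warning rather than an error.

The study-condition cohort used by the recovery tests: 10 subjects,
12 regions in two 6-blocks, `within_r = 0.3`, `between_r` alternating
−0.4 / +0.4 over six 150-timepoint regimes, AR(1) = 0.3, TR = 0.72 s,
window 50 / step 1, 10 surrogate realizations. The parameters were chosen
from feasibility and regime logic: |between_r| is bounded by the PSD
constraint `1 + 5·within_r ≥ 6·|between_r|`, and the deliberately weak
within-block correlation lets windowed within-block edges occasionally
flicker negative, so all four configurations — including the otherwise
unreachable `---` — occur in every subject while remaining transient.
Anti-correlated regimes plant persistent `-+-`/`+++` structure; regime
flips and sampling flicker generate the short-lived imbalanced episodes.
Cohort sizes (10–12 regions, 600–900 timepoints) keep the full suite in
tens of seconds while exercising every stage at realistic window counts.

What the generator does **not** emulate: hemodynamic response shapes,
scanner noise spectra, head motion, spatial autocorrelation of parcels, or
non-Gaussian amplitude distributions. Gaussian AR(1) is an assumption of
convenience — passing recovery tests shows the pipeline recovers planted
signed-covariance dynamics, not that real cortical signals satisfy the
model.

## Numerical choices and degenerate inputs

- Window correlations are clipped to [−1, 1] and symmetrized to remove
  float round-off; the energy routine tolerates |w| ≤ 1 + 1e-9.
- A zero-variance region inside a window makes the correlation undefined;
  the default is a loud error naming window and region (silent NaNs would
  corrupt episode extraction), with `on_degenerate="zero"` zeroing and
  flagging the affected entries instead.
- Surrogate spectra are preserved to ~1e-8 relative by construction; the
  imaginary residue of the inverse transform is below 1e-8 and discarded
  by the real inverse FFT.
- BH q-values come from the step-up transform (monotone, capped at 1,
  input order preserved). Episode means use float accumulation; lifetimes
  and occurrences are exact integers.

## Known limitations

- Lifetimes are right/left-censored at the observation edges; the default
  includes censored episodes, which biases mean lifetimes downward for
  very persistent states. The `include_censored` flag quantifies the
  effect but no survival-analysis correction is attempted.
- Overlapping windows (step 1) make consecutive network frames strongly
  dependent; lifetimes are therefore meaningful comparatively (state A vs
  state B, real vs surrogate) rather than as absolute dwell times.
- The phase-randomized null preserves each region's marginal spectrum but
  no spatial or modular constraints beyond it.
- The energy-vs-lifetime OLS fits (linear for imbalanced, quadratic for
  balanced states) are descriptive summaries of the joint distribution;
  their coefficients are data-dependent and carry no inferential weight.
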