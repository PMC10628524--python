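# Methods

`megsw` reimplements, as a tested pipeline over synthetic data, a resting-state
MEG functional-network analysis: phase-lag-index (PLI) connectivity between 68
cortical regions per frequency band, binary small-world graph metrics
normalised by degree-preserving rewired nulls, an eyes-open/eyes-closed (EO/EC)
reactivity statistic, and a mixed-model/regression layer relating
small-worldness to disease status (Alzheimer's disease vs. control), age and
delayed recall. This note records the model, the numerical choices, what the
synthetic data do and do not emulate, and the problem sizes the test suite and
the acceptance script use.

## Signal layer

**Input.** One samples x channels matrix per subject and eyes state (68
Desikan–Killiany regions by convention), with sampling rate and ROI labels in
a JSON sidecar. The pipeline assumes source reconstruction and artifact
removal happened upstream; synthetic inputs are clean by construction.

**Preprocessing.** Polyphase resampling to 500 Hz, IIR notch filters at 60,
120 and 180 Hz (quality factor 30), optional broadband Butterworth band-pass
0.5–200 Hz. All filters are applied forward–backward (zero phase), so phases
downstream are not biased by group delay. With `target_fs == fs`, no notch
frequencies and `broadband=None` the stage is an exact identity — useful for
worked examples.

**Epoching and bands.** Recordings are cut into non-overlapping 5-s epochs
(trailing remainder discarded) *before* band-filtering. Canonical bands:
delta 2–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–60 Hz. Band-pass is a
4th-order Butterworth (applied twice via `sosfiltfilt`); order and transition
behaviour are the usual trade-off between pass-band flatness and epoch-edge
ringing at 5-s epochs.

**PLI.** Per epoch and channel pair,

    PLI_ij = | (1/N) * sum_k sign(delta_phi_ij(t_k)) |,

where `delta_phi` is the wrapped Hilbert-phase difference. The absolute value
makes PLI lie in [0, 1]; the per-sample `sign(0)` counts as 0, which is a
measure-zero event for continuous phases but deterministic for constructed
test vectors. The sign of the wrapped difference is evaluated as
`sign(sin(phi_i - phi_j))`, identical everywhere except at a difference of
exactly pi. PLI is insensitive to zero-lag synchrony, which is the reason the
measure is used at all: field spread between reconstructed sources produces
zero-lag correlations that a lag-sensitive measure would mistake for coupling.

Because the analytic signal is distorted near epoch edges, the first and last
5% of samples of each epoch are excluded from the PLI sum by default
(`edge_trim`, settable to 0 for exact worked examples). Per-epoch PLI matrices
are averaged element-wise per subject, condition and band.

## Graph layer

**Binarization.** Proportional threshold kappa: the `floor(kappa * n(n-1)/2)`
strongest weights become edges (kappa = 0.2 on 68 nodes keeps exactly 455).
Flooring never exceeds the stated proportion. Ties at the threshold weight are
broken by weight descending, then (row, column) ascending — deterministic,
which matters because short synthetic epochs do produce tied PLI values.
Zero-weight pairs are never edges.

**Metrics.** Mean clustering coefficient `C` with `C_i = 0` for nodes of
degree < 2; characteristic path length `L` as the mean shortest-path length
over ordered pairs with finite distance, excluding disconnected pairs from
numerator and denominator (equivalent to unordered averaging by symmetry).
Both are computed on dense numpy adjacency (triangle counts via `diag(A^3)`,
distances via BFS) and are tested against brute-force enumeration on an
exhaustive small-graph battery.

**Null normalisation.** `SW = (C/C_rand)/(L/L_rand)` with null means over an
ensemble of Maslov–Sneppen rewirings of the observed graph: repeated
double-edge swaps with four distinct endpoints, rejecting self-loops and
duplicate edges, preserving the degree sequence exactly. The convention for
"rewiring iterations" is ambiguous in the literature, so both are provided:
`per_edge` mode (default) accepts `10 * n_edges` swaps per null graph, enough
to decorrelate from the seed topology; `total` mode accepts exactly 1000 swaps
per null regardless of size. The mode and swap count are recorded in the
ensemble provenance. The study protocol's ensemble size is 1000 nulls per
graph; calibration tests use 200 (the standard error of `C_rand` is already
well under 1% at 200 nulls for the 68-node, kappa = 0.2 regime).

**Reactivity.** `(SW_EO - SW_EC) / (SW_EO + SW_EC)`, one value per subject and
band; undefined (and skipped with a warning) when the denominator is zero,
which only occurs for degenerate triangle-free graphs far below study scale.

## Inference layer

**Mixed model.** Per band, `sw ~ disease + condition + age` with
subject-specific random intercepts, fitted by maximum likelihood
(statsmodels `MixedLM`; REML switchable). Coding: control = 0 / AD = 1,
EC = 0 / EO = 1. Reported standard errors are cluster-by-subject sandwich
estimates computed from the ML variance components: with
`V_i = sigma^2 I + tau^2 J` per subject, the bread is
`A = sum_i X_i' V_i^{-1} X_i`, the meat stacks per-subject scores
`X_i' V_i^{-1} (y_i - X_i b)`, and the covariance is `A^{-1} B A^{-1}`
scaled by the conventional `G/(G-1)` small-cluster factor. Model-based SEs
(`A^{-1}` alone) are retained as a switch and agree with the sandwich within
15% on homoscedastic data at 200+ subjects (a tested invariant). Wald z tests;
alpha = 0.05. When the estimated between-subject variance share (ICC) falls
below 1% the fit is flagged `boundary_random_effect`; below 1e-6 the sandwich
is computed at the boundary exactly, where the estimator coincides with pooled
OLS plus a cluster sandwich.

**Recall and reactivity regressions.** Robust (HC1) OLS with t tests on the
residual df, per group x condition (outcome SW) or per group (outcome
reactivity); alpha = 0.025, reflecting the study's policy of correcting only
across the two disease groups and deliberately not across frequency bands or
eyes states. Significance is strict (`p < alpha`). The published analysis
chose robust SEs after a manual residual inspection; since that step is
inherently manual, the default here is always-robust (switchable to
model-based), which is conservative and removes an unreproducible judgement
call. An all-constant outcome returns zero slopes flagged
`degenerate_constant_outcome` instead of dividing by zero.

**Effect sizes.** The mixed model reports standardized coefficients
(`b * sd(x)/sd(y)`); the OLS fits report per-term partial eta squared
approximated as `t^2/(t^2 + df_resid)`. Published effect-size columns for
these analyses carry no stated definition, so no equivalence is claimed and
those columns are not used as quantitative anchors.

**Demographics.** Pooled-variance two-sample t (df `n1+n2-2`) from group
summary statistics, and Pearson chi-square without continuity correction on
the 2x2 sex table. The published cohort summaries (24 controls / 18 AD) are
shipped in `megsw.datasets` and fully determine these statistics, which is
why they are exactly recomputable while the MEG-derived regression
coefficients are not.

## Synthetic data: what it emulates, and what it does not

**Oscillators.** Channels coupled in a cluster share one common band-limited
phase process: the instantaneous frequency follows the band midpoint plus a
smoothed Gaussian wander squashed (tanh) to stay inside the band, and the
phase is its running integral. Each channel mixes
`cos(common_phase + lag_offset)` with weight equal to its coupling strength
and an independent oscillator with the complementary weight, plus optional
white noise. Phase noise enters the shared process *before* the deterministic
lag, so the sign of the pairwise phase difference — the quantity PLI measures
— is controlled by the antisymmetric lag matrix. Full coupling with a fixed
non-zero lag yields PLI = 1 after the whole signal chain; zero lag with full
coupling yields identical signals and PLI = 0 (the field-spread suppression
property); uncoupled pairs sit at the chance level.

That chance level deserves a number: for a band-limited process, per-epoch
signs are autocorrelated on the ~0.2 s timescale of the phase-difference
drift, so a 5-s epoch contains only ~25 effective sign samples and the
per-epoch `|mean sign|` of an uncoupled pair is O(0.15), not O(1/sqrt(2500)).
Averaging PLI (an absolute value) over epochs does not shrink it. The
Monte-Carlo null for the default alpha-band generator is ~0.18 with a
seed-to-seed SD of ~0.02 for 100-epoch averages; the corresponding test bound
is frozen at 0.25. This is a property of any band-limited signal at this epoch
length, not of this generator specifically.

**Subject tables.** Long-format tables with one row per subject x condition x
band; `sw` follows a linear model with configurable disease, condition, age
and recall coefficients, subject random intercepts (drawn independently per
band, matching the per-band model), and residual noise whose SD may scale
with standardized age (`hetero_factor`) to exercise the robust SEs. Age and
recall are drawn per group from the published cohort means/SDs. True
coefficients are recorded in `DataFrame.attrs["truth"]`. A companion
generator produces one reactivity value per subject x band from the analogous
linear model.

**Not emulated:** MEG sensor physics, head models, source leakage,
artifacts (blinks, cardiac), 1/f background spectra, cross-band coupling, or
any genuine disease physiology. Passing tests therefore demonstrate that the
*pipeline* is correct and calibrated — that known coupling produces the
expected PLI, known graph structure the expected metrics, and known
coefficients are recovered with the stated error rates — not that the
published biological findings replicate.

## Calibration designs and problem sizes

Chosen once as the package's validation design:

- **Null-model calibration:** 20 Erdos–Renyi graphs (68 nodes, density 0.2,
  i.e. degree-matched to the kappa = 0.2 study graphs), 200 nulls each; the
  ensemble-mean SW must lie in [0.9, 1.1]. One Watts–Strogatz graph
  (n = 68, k = 13, p = 0.1) must give SW > 1.
- **Type-I error:** mixed model at 200 subjects x 2 conditions, 1200
  replicates, acceptance band 0.05 ± 0.02; robust OLS at n = 100 per slice,
  2000 replicates, band 0.025 ± 0.02. Null simulations run in the asymptotic
  regime because they calibrate the estimator, not the small-sample study; at
  the study's 42 subjects the cluster sandwich is mildly anticonservative
  (a known small-G property), which is documented rather than corrected.
- **Recovery:** simulation truths set to published-magnitude effects
  (disease -0.132 and age 0.011 for the gamma-band mixed model, recall slope
  -0.013 for the alpha-band AD regression, -0.006 for the alpha-band
  reactivity regression); 200 replicates at n = 500 subjects (mixed) or
  n = 100 per slice (OLS); mean bias must stay under 10% of the truth and
  mixed-model 95% CI coverage within [0.90, 0.98].
- **End-to-end smoke:** 4 subjects x 2 conditions x 10 s x 68 channels with
  40 rewired nulls per graph; must produce exactly 40 metric rows and
  byte-identical output on re-run under the same master seed.

## Known limitations

- The rewiring null assumes the observed graph is connected enough to swap;
  star-like graphs (no two node-disjoint edges) are rejected.
- Cluster-robust z tests are anticonservative for few clusters; no
  small-sample dof correction (e.g. Satterthwaite) is implemented.
- The epoch-level PLI chance floor means weak true couplings (PLI below
  ~0.2 at 5-s epochs) are not distinguishable from noise without many epochs.
- `eta^2` and standardized-coefficient effect sizes are pragmatic
  approximations, labelled as such.
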