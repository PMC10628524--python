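# megsw

Phase-lag-index connectivity and small-world network statistics for
parcellated MEG source time series, with the full statistical layer of a
resting-state Alzheimer's-disease (AD) study — reimplemented as a tested,
reusable pipeline and exercised end-to-end on synthetic data with known
ground truth.

## The problem

Resting-state MEG studies of AD ask whether the brain's functional network —
nodes are cortical regions, edges are statistical dependencies between their
band-limited signals — loses its "small-world" organisation, and whether that
loss tracks memory impairment. The analysis chain is long: source time series
per region, per-band phase synchrony, thresholded binary graphs, graph metrics
normalised against random rewirings, and regressions over a few dozen
subjects. Each stage has conventions and pitfalls (zero-lag leakage,
threshold choice, null-model ambiguity, robust-vs-model-based errors). This
package implements that chain with every convention explicit and every stage
testable against an oracle.

## The model

For each subject, eyes state (eyes-open EO / eyes-closed EC) and frequency
band (δ 2–4, θ 4–8, α 8–13, β 13–30, γ 30–60 Hz):

1. **PLI.** Recordings are cut into 5-s epochs, band-passed, and per-channel
   instantaneous phases φ(t) extracted by Hilbert transform. For channels
   *i, j*:

       PLI_ij = | (1/N) Σ_k sign(Δφ_ij(t_k)) |  ∈ [0, 1]

   PLI ignores zero-lag synchrony, suppressing field-spread artefacts between
   reconstructed sources. Epoch matrices are averaged per subject.
2. **Binary graph.** The strongest κ = 0.2 fraction of possible edges is kept
   (455 edges on 68 nodes).
3. **Small-worldness.** With mean clustering C, characteristic path length L
   (connected pairs only), and C_rand, L_rand averaged over degree-preserving
   Maslov–Sneppen rewirings of the same graph:

       SW = (C / C_rand) / (L / L_rand)

   SW ≈ 1 for random graphs, > 1 in the small-world regime.
4. **Reactivity.** (SW_EO − SW_EC) / (SW_EO + SW_EC) per subject and band.
5. **Inference.** Per band: a random-intercept mixed model
   `SW ~ disease + condition + age` with cluster-robust z tests (α = 0.05);
   robust OLS `SW ~ delayed_recall + age` per group × condition and
   `reactivity ~ delayed_recall + age` per group (α = 0.025); pooled-variance
   t and Pearson χ² for cohort demographics.

No MEG recordings were deposited by the study this pipeline emulates, so the
`megsw.simulate` module generates every input with known ground truth:
band-limited oscillators with controllable pairwise phase-lag coupling,
benchmark graphs, and subject tables drawn from a known linear model. See
`docs/methods.md` for the full model description and design choices.

## Worked example

```sh
python analysis/01_simulate_study.py     # 10 subjects, 30 s signals (demo scale)
python analysis/02_connectivity_metrics.py --n-null 100
python analysis/03_fit_models.py
python analysis/04_demographics.py
```

`04_demographics.py` recomputes the published cohort's between-group
statistics from its printed summary table and prints:

```
                    variable statistic_type  statistic  p_value  df
                         age              t    -1.6493   0.1069  40
                        mmse              t     8.9228   0.0000  40
         wmsr_delayed_recall              t    10.6448   0.0000  40
                         sex           chi2     0.0084   0.9269   1
```

(excerpt) — e.g. the MMSE row: controls 28.8 (0.9, n = 24) vs AD 22.0
(3.6, n = 18) give a pooled-variance t of 8.92 on 40 df, matching the
published 8.93 to input rounding. `02_connectivity_metrics.py` prints the
mean small-worldness per band and eyes state of the synthetic cohort, and
`03_fit_models.py` the mixed-model coefficient table (coefficient, robust SE,
z, p, significance at the two-tier α policy).

The same pipeline is scriptable via the `megsw` CLI
(`megsw simulate | connectivity | analyze | all`), whose defaults reproduce
the study protocol: five canonical bands, 5-s epochs, κ = 0.2, 1000 rewired
nulls, α = 0.05/0.025.

## Layout

- `src/megsw/` — library: `core` (containers), `simulate`, `connectivity`,
  `graphs`, `stats`, `datasets`, `validation`, `io`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — pytest suite, including brute-force graph-metric oracles,
  property tests and the acceptance layer.
- `docs/methods.md` — model, numerical choices, calibration designs,
  limitations.
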