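"""Simulation studies that calibrate the pipeline against known ground truth.

These helpers run the actual package code on synthetic inputs whose generating
parameters are known, and summarise how well the estimators behave:

- :func:`er_smallworldness` — small-worldness of Erdos-Renyi graphs under the
  rewired-null normalisation (should sit at ~1: the self-normalisation check);
- :func:`ws_smallworldness` — Watts-Strogatz graphs in the small-world regime
  (should exceed 1);
- :func:`mixed_model_type_i_error` / :func:`ols_type_i_error` — empirical
  rejection rates under null data at the study's alpha thresholds;
- :func:`recover_mixed_coefficients` / :func:`recover_recall_slope` /
  :func:`recover_reactivity_slope` — mean recovered coefficients when the
  simulation truth is set to published-magnitude effects.

Every function is a pure function of its seed.
"""

from __future__ import annotations

import numpy as np

from .core import ConnectivityMatrix, band_by_name
from .graphs import binarize_proportional, graph_metrics
from .simulate import SubjectTableSpec, generate_benchmark_graph, generate_reactivity_table, generate_subject_table
from .stats import (
    ALPHA_MIXED,
    ALPHA_REGRESSION,
    fit_reactivity_regression,
    fit_recall_regression,
    fit_sw_mixed_model,
)

__all__ = [
    "er_smallworldness",
    "ws_smallworldness",
    "mixed_model_type_i_error",
    "ols_type_i_error",
    "reactivity_type_i_error",
    "recover_mixed_coefficients",
    "recover_recall_slope",
    "recover_reactivity_slope",
]


def _er_connectivity(n: int, density: float, rng: np.random.Generator) -> ConnectivityMatrix:
    """Random symmetric weights; proportional threshold keeps a uniform-random
    edge set, i.e. a G(n, m) graph with m = floor(density * n(n-1)/2)."""
    w = rng.random((n, n))
    w = np.triu(w, k=1)
    w = w + w.T
    return ConnectivityMatrix(weights=w * 0.999, band=band_by_name("alpha"))


def er_smallworldness(
    n: int = 68,
    density: float = 0.2,
    n_seeds: int = 20,
    n_null: int = 200,
    seed: int = 0,
) -> float:
    """Mean SW of degree-matched ER graphs over ``n_seeds`` realisations."""
    rng = np.random.default_rng(seed)
    sws = []
    for i in range(n_seeds):
        G = binarize_proportional(_er_connectivity(n, density, rng), kappa=density)
        res = graph_metrics(G, n_null=n_null, seed=int(rng.integers(0, 2**31)))
        sws.append(res.SW)
    return float(np.mean(sws))


def ws_smallworldness(
    n: int = 68, k: int = 13, p: float = 0.1, n_null: int = 200, seed: int = 0
) -> float:
    """SW of one connected Watts-Strogatz graph in the small-world regime."""
    G = generate_benchmark_graph("smallworld", n=n, k=k, p=p, seed=seed)
    return graph_metrics(G, n_null=n_null, seed=seed + 1).SW


def mixed_model_type_i_error(
    n_reps: int = 1000,
    n_per_group: tuple[int, int] = (120, 80),
    sigma_subject: float = 0.1,
    sigma_resid: float = 0.1,
    seed: int = 0,
    term: str = "disease",
) -> float:
    """Rejection rate of the mixed-model z test at alpha=0.05 under the null.

    Data are generated with every fixed effect zero; the calibration sample
    (200 subjects by default) sits in the asymptotic regime where the cluster
    sandwich is expected to be well calibrated.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        spec = SubjectTableSpec(
            n_per_group=n_per_group,
            sigma_subject=sigma_subject,
            sigma_resid=sigma_resid,
            bands=("gamma",),
            seed=int(rng.integers(0, 2**31)),
        )
        res = fit_sw_mixed_model(generate_subject_table(spec), "gamma")
        if res.term(term)["p_value"] < ALPHA_MIXED:
            rejections += 1
    return rejections / n_reps


def ols_type_i_error(
    n_reps: int = 2000,
    n_per_group: tuple[int, int] = (100, 100),
    sigma_resid: float = 0.1,
    hetero_factor: float = 0.0,
    seed: int = 0,
    term: str = "delayed_recall",
) -> float:
    """Rejection rate of the robust-OLS t test at alpha=0.025 under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        spec = SubjectTableSpec(
            n_per_group=n_per_group,
            sigma_subject=0.0,
            sigma_resid=sigma_resid,
            hetero_factor=hetero_factor,
            bands=("alpha",),
            conditions=("EO",),
            seed=int(rng.integers(0, 2**31)),
        )
        res = fit_recall_regression(generate_subject_table(spec), "alpha", "control", "EO")
        if res.term(term)["p_value"] < ALPHA_REGRESSION:
            rejections += 1
    return rejections / n_reps


def reactivity_type_i_error(
    n_reps: int = 2000,
    n_per_group: tuple[int, int] = (100, 100),
    sigma_resid: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the reactivity regression at alpha=0.025 under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        spec = SubjectTableSpec(
            n_per_group=n_per_group,
            intercept=0.0,
            sigma_resid=sigma_resid,
            bands=("alpha",),
            seed=int(rng.integers(0, 2**31)),
        )
        res = fit_reactivity_regression(generate_reactivity_table(spec), "alpha", "control")
        if res.term("delayed_recall")["p_value"] < ALPHA_REGRESSION:
            rejections += 1
    return rejections / n_reps


def recover_mixed_coefficients(
    beta_disease: float = -0.132,
    beta_age: float = 0.011,
    beta_condition: float = 0.018,
    n_reps: int = 200,
    n_subjects: int = 500,
    sigma_subject: float = 0.15,
    sigma_resid: float = 0.1,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Mean recovered mixed-model coefficients and CI coverage over replicates.

    Truth values default to published gamma-band magnitudes. Returns, per
    term, the mean estimate, the truth, and the 95% confidence-interval
    coverage across replicates.
    """
    rng = np.random.default_rng(seed)
    n_ctrl = round(n_subjects * 24 / 42)
    truths = {"disease": beta_disease, "condition": beta_condition, "age": beta_age}
    est = {t: [] for t in truths}
    cover = {t: 0 for t in truths}
    for _ in range(n_reps):
        spec = SubjectTableSpec(
            n_per_group=(n_ctrl, n_subjects - n_ctrl),
            beta_disease=beta_disease,
            beta_condition=beta_condition,
            beta_age=beta_age,
            sigma_subject=sigma_subject,
            sigma_resid=sigma_resid,
            bands=("gamma",),
            seed=int(rng.integers(0, 2**31)),
        )
        res = fit_sw_mixed_model(generate_subject_table(spec), "gamma")
        for t, truth in truths.items():
            row = res.term(t)
            est[t].append(row["coefficient"])
            half = 1.959963984540054 * row["robust_se"]
            if abs(row["coefficient"] - truth) <= half:
                cover[t] += 1
    return {
        t: {
            "mean_estimate": float(np.mean(est[t])),
            "truth": truths[t],
            "coverage_95": cover[t] / n_reps,
        }
        for t in truths
    }


def recover_recall_slope(
    beta_recall: float = -0.013,
    beta_age: float = 0.032,
    n_reps: int = 200,
    n: int = 100,
    sigma_resid: float = 0.1,
    seed: int = 0,
) -> dict[str, float]:
    """Mean recovered delayed-recall slope from the robust OLS regression.

    Truth defaults to the published alpha-band AD-group magnitude.
    """
    rng = np.random.default_rng(seed)
    est = []
    for _ in range(n_reps):
        spec = SubjectTableSpec(
            n_per_group=(4, n),  # fit on the AD slice of size n
            beta_recall=beta_recall,
            beta_age=beta_age,
            sigma_subject=0.0,
            sigma_resid=sigma_resid,
            bands=("alpha",),
            conditions=("EO",),
            seed=int(rng.integers(0, 2**31)),
        )
        res = fit_recall_regression(generate_subject_table(spec), "alpha", "AD", "EO")
        est.append(res.term("delayed_recall")["coefficient"])
    return {"mean_estimate": float(np.mean(est)), "truth": beta_recall}


def recover_reactivity_slope(
    beta_recall: float = -0.006,
    beta_age: float = 0.011,
    n_reps: int = 200,
    n: int = 100,
    sigma_resid: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Mean recovered recall slope from the reactivity regression.

    Truth defaults to the published alpha-band magnitude.
    """
    rng = np.random.default_rng(seed)
    est = []
    for _ in range(n_reps):
        spec = SubjectTableSpec(
            n_per_group=(4, n),
            intercept=0.0,
            beta_recall=beta_recall,
            beta_age=beta_age,
            sigma_resid=sigma_resid,
            bands=("alpha",),
            seed=int(rng.integers(0, 2**31)),
        )
        res = fit_reactivity_regression(generate_reactivity_table(spec), "alpha", "AD")
        est.append(res.term("delayed_recall")["coefficient"])
    return {"mean_estimate": float(np.mean(est)), "truth": beta_recall}
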