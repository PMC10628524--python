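"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators, all pure functions of their spec (identical seeds give
bit-identical output):

- :func:`generate_coupled_oscillators` — band-limited oscillatory ROI signals
  with controllable pairwise phase-lag synchrony. Coupled channels share a
  common stochastic band-limited phase process; each channel mixes
  ``cos(common phase + its lag offset)`` with an independent oscillator in
  proportion ``(1 - coupling)`` plus additive white noise. Phase noise enters
  the common process *before* the deterministic lag is added, so the sign of
  the pairwise phase difference — and hence the PLI — is controlled by the lag
  matrix.
- :func:`generate_subject_table` — long-format subject tables whose per-band
  small-worldness values are drawn from a known linear model (disease,
  condition, age and delayed-recall effects, subject random intercepts,
  optionally heteroscedastic residuals), so the inference layer can be tested
  by parameter recovery.
- :func:`generate_benchmark_graph` — graph families (lattice, random,
  small-world, complete, star, path) with known metric values for the graph
  layer.

Default scales mirror the emulated study: 68 ROIs sampled at 500 Hz, and
42 subjects (24 control / 18 AD) recorded for 2 minutes under each eyes state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import (
    BAND_NAMES,
    BandDefinition,
    BinaryGraph,
    RoiTimeSeries,
    ValidationError,
)

__all__ = [
    "OscillatorSpec",
    "SubjectTableSpec",
    "generate_coupled_oscillators",
    "generate_subject_table",
    "generate_reactivity_table",
    "generate_benchmark_graph",
    "default_roi_labels",
]

#: Default study scale: analysed sample of the emulated study.
DEFAULT_N_CONTROL = 24
DEFAULT_N_AD = 18


def default_roi_labels(n: int = 68) -> list[str]:
    """Placeholder ROI names (``roi01`` ...) for synthetic recordings."""
    width = len(str(n))
    return [f"roi{i + 1:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Oscillator signals
# ---------------------------------------------------------------------------


@dataclass
class OscillatorSpec:
    """Parameters of a synthetic multichannel band-limited recording.

    ``coupling`` is a symmetric matrix in [0, 1] with unit diagonal giving the
    target phase-locking strength per channel pair; ``lag`` is an antisymmetric
    matrix (radians, zero diagonal) of pairwise phase offsets. Channels joined
    by positive coupling form clusters driven by one common phase process.
    """

    n_channels: int = 68
    band: tuple[float, float] = (8.0, 13.0)
    coupling: np.ndarray | None = None
    lag: np.ndarray | None = None
    noise_sd: float = 0.0
    duration_s: float = 120.0
    fs: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.n_channels
        if n < 1:
            raise ValidationError(f"n_channels: must be >= 1, got {n}")
        if self.coupling is None:
            self.coupling = np.eye(n)
        if self.lag is None:
            self.lag = np.zeros((n, n))
        self.coupling = np.asarray(self.coupling, dtype=float)
        self.lag = np.asarray(self.lag, dtype=float)
        if self.coupling.shape != (n, n):
            raise ValidationError(f"coupling: expected shape ({n}, {n}), got {self.coupling.shape}")
        if self.lag.shape != (n, n):
            raise ValidationError(f"lag: expected shape ({n}, {n}), got {self.lag.shape}")
        if not np.allclose(self.coupling, self.coupling.T, atol=1e-12):
            raise ValidationError("coupling: matrix must be symmetric")
        if not np.allclose(np.diag(self.coupling), 1.0, atol=1e-12):
            raise ValidationError("coupling: diagonal must be 1")
        if np.any(self.coupling < -1e-12) or np.any(self.coupling > 1 + 1e-12):
            raise ValidationError("coupling: entries must lie in [0, 1]")
        if not np.allclose(self.lag, -self.lag.T, atol=1e-12):
            raise ValidationError("lag: matrix must be antisymmetric")
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ValidationError(f"band: need 0 < f_lo < f_hi, got ({lo}, {hi})")
        if self.fs <= 2 * hi:
            raise ValidationError(
                f"fs: {self.fs} Hz must exceed twice the band upper edge ({2 * hi} Hz)"
            )
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd: must be >= 0, got {self.noise_sd}")
        if self.duration_s <= 0:
            raise ValidationError(f"duration_s: must be positive, got {self.duration_s}")


def _band_limited_phase(
    rng: np.random.Generator, n_samples: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """A stochastic phase whose instantaneous frequency wanders inside the band.

    The frequency follows the band midpoint plus a smoothed (low-passed)
    Gaussian wander squashed by tanh so it never leaves the band; the phase is
    its running integral with a uniform random start.
    """
    f_lo, f_hi = band
    f0 = 0.5 * (f_lo + f_hi)
    half_bw = 0.5 * (f_hi - f_lo)
    wander_cut = max(min((f_hi - f_lo) / 4.0, fs / 4.0), 0.05)
    sos = sps.butter(2, wander_cut, btype="low", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n_samples))
    sd = x.std()
    if sd > 0:
        x = x / sd
    f_inst = f0 + 0.8 * half_bw * np.tanh(x)
    phase0 = rng.uniform(0, 2 * np.pi)
    return phase0 + 2 * np.pi * np.cumsum(f_inst) / fs


def _coupling_clusters(coupling: np.ndarray) -> list[np.ndarray]:
    """Connected components of the off-diagonal coupling > 0 graph."""
    n = coupling.shape[0]
    off = coupling.copy()
    np.fill_diagonal(off, 0.0)
    g = nx.from_numpy_array((off > 0).astype(int))
    return [np.array(sorted(comp)) for comp in nx.connected_components(g)]


def generate_coupled_oscillators(spec: OscillatorSpec) -> RoiTimeSeries:
    """Synthesize a samples x channels recording with known phase structure.

    Channel pairs with coupling -> 1 and a fixed non-zero lag produce PLI -> 1
    in the spec band; uncoupled pairs have independent phases and PLI at chance
    level (shrinking as epochs accumulate).
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.duration_s * spec.fs))
    n = spec.n_channels
    data = np.empty((n_samples, n))
    for cluster in _coupling_clusters(spec.coupling):
        root = int(cluster[0])
        common = _band_limited_phase(rng, n_samples, spec.fs, spec.band) if len(cluster) > 1 else None
        for ch in cluster:
            ch = int(ch)
            if len(cluster) > 1:
                strengths = [spec.coupling[ch, j] for j in cluster if j != ch]
                c = float(max(strengths))
            else:
                c = 0.0
            own = _band_limited_phase(rng, n_samples, spec.fs, spec.band)
            if common is not None and c > 0:
                shifted = common + spec.lag[ch, root]
                data[:, ch] = c * np.cos(shifted) + (1.0 - c) * np.cos(own)
            else:
                data[:, ch] = np.cos(own)
    if spec.noise_sd > 0:
        data = data + spec.noise_sd * rng.standard_normal(data.shape)
    return RoiTimeSeries(
        data=data,
        fs=spec.fs,
        labels=default_roi_labels(n),
    )


# ---------------------------------------------------------------------------
# Subject tables
# ---------------------------------------------------------------------------


def _per_band(value: float | Mapping[str, float], band: str) -> float:
    if isinstance(value, Mapping):
        return float(value.get(band, 0.0))
    return float(value)


@dataclass
class SubjectTableSpec:
    """Generative model for per-subject covariates and per-band outcomes.

    Outcomes follow, per band,

        sw = intercept + beta_disease * AD + beta_condition * EO
             + beta_age * age + beta_recall * recall + u_subject + eps

    with ``u_subject ~ N(0, sigma_subject^2)`` drawn independently per subject
    and band, and ``eps ~ N(0, sigma_i^2)`` where
    ``sigma_i = sigma_resid * (1 + hetero_factor * z(age_i))`` (floored at 5%
    of ``sigma_resid``) so a positive ``hetero_factor`` yields the
    heteroscedasticity that robust standard errors exist to handle.

    Coefficients may be scalars (applied to every band) or dicts keyed by band
    name. Age and recall distributions are (mean, sd) pairs per group.
    """

    n_per_group: tuple[int, int] = (DEFAULT_N_CONTROL, DEFAULT_N_AD)  # (control, AD)
    intercept: float = 1.0
    beta_disease: float | Mapping[str, float] = 0.0
    beta_condition: float | Mapping[str, float] = 0.0
    beta_age: float | Mapping[str, float] = 0.0
    beta_recall: float | Mapping[str, float] = 0.0
    sigma_subject: float = 0.1
    sigma_resid: float = 0.1
    hetero_factor: float = 0.0
    age_dist: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"control": (68.4, 6.9), "AD": (71.8, 6.2)}
    )
    recall_dist: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"control": (98.8, 11.7), "AD": (60.8, 11.1)}
    )
    bands: tuple[str, ...] = BAND_NAMES
    conditions: tuple[str, ...] = ("EO", "EC")
    male_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"control": 15 / 24, "AD": 11 / 18}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        n_control, n_ad = self.n_per_group
        if n_control < 2 or n_ad < 2:
            raise ValidationError(f"n_per_group: group sizes must be >= 2, got {self.n_per_group}")
        for name in ("sigma_subject", "sigma_resid"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name}: must be >= 0, got {getattr(self, name)}")
        for grp in ("control", "AD"):
            for dist_name in ("age_dist", "recall_dist"):
                mean, sd = getattr(self, dist_name)[grp]
                if sd < 0:
                    raise ValidationError(f"{dist_name}[{grp!r}]: sd must be >= 0, got {sd}")
        unknown = set(self.bands) - set(BAND_NAMES)
        if unknown:
            raise ValidationError(f"bands: unknown band names {sorted(unknown)}")


def _draw_subjects(spec: SubjectTableSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    idx = 0
    for grp, n in zip(("control", "AD"), spec.n_per_group):
        a_mean, a_sd = spec.age_dist[grp]
        r_mean, r_sd = spec.recall_dist[grp]
        for _ in range(n):
            idx += 1
            rows.append(
                {
                    "subject_id": f"sub{idx:03d}",
                    "group": grp,
                    "age": rng.normal(a_mean, a_sd),
                    "delayed_recall": rng.normal(r_mean, r_sd),
                    "sex": "M" if rng.random() < spec.male_fraction[grp] else "F",
                }
            )
    return pd.DataFrame(rows)


def _residual_sd(spec: SubjectTableSpec, ages: np.ndarray) -> np.ndarray:
    z = (ages - ages.mean()) / (ages.std() if ages.std() > 0 else 1.0)
    sd = spec.sigma_resid * (1.0 + spec.hetero_factor * z)
    return np.maximum(sd, 0.05 * spec.sigma_resid)


def generate_subject_table(spec: SubjectTableSpec) -> pd.DataFrame:
    """Long-format table: one row per subject x condition x band.

    Columns: ``subject_id, group, condition, age, delayed_recall, sex, band,
    sw``. The true generating coefficients are recorded in
    ``DataFrame.attrs["truth"]``.
    """
    rng = np.random.default_rng(spec.seed)
    subjects = _draw_subjects(spec, rng)
    resid_sd = _residual_sd(spec, subjects["age"].to_numpy())
    rows = []
    for band in spec.bands:
        b_dis = _per_band(spec.beta_disease, band)
        b_cond = _per_band(spec.beta_condition, band)
        b_age = _per_band(spec.beta_age, band)
        b_rec = _per_band(spec.beta_recall, band)
        u = rng.normal(0.0, spec.sigma_subject, size=len(subjects))
        for i, subj in subjects.iterrows():
            base = (
                spec.intercept
                + b_dis * (subj["group"] == "AD")
                + b_age * subj["age"]
                + b_rec * subj["delayed_recall"]
                + u[i]
            )
            for cond in spec.conditions:
                eps = rng.normal(0.0, resid_sd[i])
                rows.append(
                    {
                        "subject_id": subj["subject_id"],
                        "group": subj["group"],
                        "condition": cond,
                        "age": subj["age"],
                        "delayed_recall": subj["delayed_recall"],
                        "sex": subj["sex"],
                        "band": band,
                        "sw": base + b_cond * (cond == "EO") + eps,
                    }
                )
    table = pd.DataFrame(rows)
    table.attrs["truth"] = {
        "intercept": spec.intercept,
        "beta_disease": {b: _per_band(spec.beta_disease, b) for b in spec.bands},
        "beta_condition": {b: _per_band(spec.beta_condition, b) for b in spec.bands},
        "beta_age": {b: _per_band(spec.beta_age, b) for b in spec.bands},
        "beta_recall": {b: _per_band(spec.beta_recall, b) for b in spec.bands},
        "sigma_subject": spec.sigma_subject,
        "sigma_resid": spec.sigma_resid,
        "hetero_factor": spec.hetero_factor,
        "seed": spec.seed,
    }
    return table


def generate_reactivity_table(spec: SubjectTableSpec) -> pd.DataFrame:
    """One reactivity value per subject x band from a known linear model.

    ``reactivity = beta_recall * recall + beta_age * age + eps`` with the
    spec's intercept interpreted as the reactivity intercept (use 0 for a
    centred outcome); ``sigma_subject`` is irrelevant here (one row per
    subject) and ignored.
    """
    rng = np.random.default_rng(spec.seed)
    subjects = _draw_subjects(spec, rng)
    resid_sd = _residual_sd(spec, subjects["age"].to_numpy())
    rows = []
    for band in spec.bands:
        b_age = _per_band(spec.beta_age, band)
        b_rec = _per_band(spec.beta_recall, band)
        for i, subj in subjects.iterrows():
            rows.append(
                {
                    "subject_id": subj["subject_id"],
                    "group": subj["group"],
                    "age": subj["age"],
                    "delayed_recall": subj["delayed_recall"],
                    "sex": subj["sex"],
                    "band": band,
                    "reactivity": spec.intercept
                    + b_rec * subj["delayed_recall"]
                    + b_age * subj["age"]
                    + rng.normal(0.0, resid_sd[i]),
                }
            )
    table = pd.DataFrame(rows)
    table.attrs["truth"] = {
        "intercept": spec.intercept,
        "beta_age": {b: _per_band(spec.beta_age, b) for b in spec.bands},
        "beta_recall": {b: _per_band(spec.beta_recall, b) for b in spec.bands},
        "seed": spec.seed,
    }
    return table


# ---------------------------------------------------------------------------
# Benchmark graphs
# ---------------------------------------------------------------------------


def generate_benchmark_graph(
    kind: str,
    n: int,
    k: int = 0,
    p: float = 0.1,
    seed: int = 0,
) -> BinaryGraph:
    """Connected benchmark graphs with known metric behaviour.

    Kinds: ``lattice`` (ring lattice, k even), ``random`` (connected G(n, m)
    with m = n*k/2), ``smallworld`` (connected Watts-Strogatz), ``complete``,
    ``star``, ``path``.
    """
    if n < 3:
        raise ValidationError(f"n: need >= 3 nodes, got {n}")
    if kind in ("lattice", "random", "smallworld"):
        if not (0 < k < n):
            raise ValidationError(f"k: mean degree must satisfy 0 < k < n, got {k}")
    if kind == "lattice":
        if k % 2:
            raise ValidationError(f"k: ring lattice needs even k, got {k}")
        g = nx.watts_strogatz_graph(n, k, 0.0)
    elif kind == "smallworld":
        g = nx.connected_watts_strogatz_graph(n, k, p, tries=200, seed=seed)
    elif kind == "random":
        m = n * k // 2
        rng = np.random.default_rng(seed)
        for _ in range(200):
            g = nx.gnm_random_graph(n, m, seed=int(rng.integers(0, 2**31)))
            if nx.is_connected(g):
                break
        else:
            raise ValidationError(f"random: no connected G({n}, {m}) found in 200 draws")
    elif kind == "complete":
        g = nx.complete_graph(n)
    elif kind == "star":
        g = nx.star_graph(n - 1)
    elif kind == "path":
        g = nx.path_graph(n)
    else:
        raise ValidationError(
            f"kind: expected lattice|random|smallworld|complete|star|path, got {kind!r}"
        )
    adj = nx.to_numpy_array(g, nodelist=range(n), dtype=np.int8)
    return BinaryGraph(adjacency=adj, kappa=0.0, source=f"benchmark:{kind}")
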