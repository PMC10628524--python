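"""Shared containers for the MEG small-world pipeline.

The pipeline operates on parcellated source-space signals (68 Desikan-Killiany
regions by convention, though nothing below hard-codes that count): multichannel
time series are band-pass filtered per canonical frequency band, converted to
instantaneous phases, summarised as phase-lag-index (PLI) connectivity matrices,
thresholded into binary graphs, and reduced to small-world statistics that feed
the regression layer.

Every container validates its own invariants on construction and raises
:class:`ValidationError` naming the offending field, so malformed inputs fail
at the boundary rather than deep inside a filter or a graph routine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class ValidationError(ValueError):
    """An input violates a documented precondition or container invariant."""


# ---------------------------------------------------------------------------
# Frequency bands
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValidationError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got ({self.f_lo}, {self.f_hi})"
            )

    def validate_for_fs(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ValidationError(
                f"band {self.name!r}: f_hi={self.f_hi} Hz is not below Nyquist ({fs / 2} Hz)"
            )


#: The canonical five resting-state bands used throughout the pipeline.
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 2.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 60.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)


def band_by_name(name: str) -> BandDefinition:
    for b in CANONICAL_BANDS:
        if b.name == name:
            return b
    raise ValidationError(f"unknown band name {name!r}; canonical bands are {BAND_NAMES}")


# ---------------------------------------------------------------------------
# Signals and phases
# ---------------------------------------------------------------------------


@dataclass
class RoiTimeSeries:
    """A samples x channels source-space signal with sampling metadata.

    Parameters
    ----------
    data:
        Real matrix, one column per ROI, arbitrary amplitude units.
    fs:
        Sampling rate in Hz.
    labels:
        Unique ROI names, one per column.
    subject_id, condition:
        Provenance carried through the pipeline; ``condition`` is ``"EO"``
        (eyes open) or ``"EC"`` (eyes closed) in study data but is not
        restricted here so fixtures can use other tags.
    """

    data: np.ndarray
    fs: float
    labels: Sequence[str]
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data: expected a 2-D samples x channels matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data: contains non-finite values")
        if self.fs <= 0:
            raise ValidationError(f"fs: must be positive, got {self.fs}")
        self.labels = list(self.labels)
        if len(self.labels) != self.data.shape[1]:
            raise ValidationError(
                f"labels: {len(self.labels)} names for {self.data.shape[1]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("labels: ROI names must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class PhaseEpoch:
    """Instantaneous phases (radians, wrapped to (-pi, pi]) for one epoch."""

    phases: np.ndarray
    band: BandDefinition
    epoch_index: int = 0
    fs: float = 0.0
    labels: Sequence[str] = field(default_factory=list)
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 2:
            raise ValidationError("phases: expected a 2-D samples x channels matrix")
        if not np.all(np.isfinite(self.phases)):
            raise ValidationError("phases: contains non-finite values")
        if np.any(self.phases <= -np.pi - 1e-12) or np.any(self.phases > np.pi + 1e-12):
            raise ValidationError("phases: values must be wrapped to (-pi, pi]")


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------


@dataclass
class ConnectivityMatrix:
    """Symmetric channels x channels PLI weights in [0, 1], zero diagonal."""

    weights: np.ndarray
    band: BandDefinition
    subject_id: str = ""
    condition: str = ""
    n_epochs_averaged: int = 1
    labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError("weights: expected a square matrix")
        if not np.all(np.isfinite(w)):
            raise ValidationError("weights: contains non-finite values")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValidationError("weights: matrix must be symmetric")
        if np.any(np.abs(np.diag(w)) > 1e-12):
            raise ValidationError("weights: diagonal must be zero")
        if np.any(w < -1e-12) or np.any(w > 1 + 1e-12):
            raise ValidationError("weights: entries must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]


# ---------------------------------------------------------------------------
# Graphs and graph metrics
# ---------------------------------------------------------------------------


@dataclass
class BinaryGraph:
    """Undirected simple graph as a dense 0/1 adjacency matrix.

    ``kappa`` records the proportional threshold used to build the graph
    (0 when constructed directly, e.g. benchmark fixtures).
    """

    adjacency: np.ndarray
    kappa: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError("adjacency: expected a square matrix")
        if not np.all((a == 0) | (a == 1)):
            raise ValidationError("adjacency: entries must be 0 or 1")
        a = a.astype(np.int8)
        if not np.array_equal(a, a.T):
            raise ValidationError("adjacency: matrix must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValidationError("adjacency: diagonal must be zero (no self-loops)")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


@dataclass
class GraphMetricsResult:
    """Clustering, path length, rewired-null means and small-worldness."""

    C: float
    L: float
    C_rand: float
    L_rand: float
    n_null: int
    null_seed: int
    subject_id: str = ""
    condition: str = ""
    band: str = ""
    kappa: float = 0.0
    rewire_mode: str = "per_edge"

    def __post_init__(self) -> None:
        for name in ("C", "L", "C_rand", "L_rand"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValidationError(f"{name}: must be finite, got {v}")
        if not (0 <= self.C <= 1):
            raise ValidationError(f"C: mean clustering must lie in [0,1], got {self.C}")
        if self.C_rand <= 0 or self.L_rand <= 0:
            raise ValidationError("C_rand/L_rand: null means must be positive")

    @property
    def C_norm(self) -> float:
        return self.C / self.C_rand

    @property
    def L_norm(self) -> float:
        return self.L / self.L_rand

    @property
    def SW(self) -> float:
        return self.C_norm / self.L_norm


@dataclass
class ReactivityValue:
    """Relative eyes-open/eyes-closed change, (SW_EO - SW_EC)/(SW_EO + SW_EC)."""

    value: float
    band: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValidationError(f"value: must be finite, got {self.value}")


# ---------------------------------------------------------------------------
# Statistical results
# ---------------------------------------------------------------------------


@dataclass
class ModelResult:
    """A fitted regression / mixed-model summary, one row per term."""

    outcome: str
    terms: list[str]
    coefficients: np.ndarray
    robust_se: np.ndarray
    statistic: np.ndarray
    p_value: np.ndarray
    effect_size: np.ndarray
    n_obs: int
    n_subjects: int
    se_flavor: str
    alpha_threshold: float
    statistic_name: str = "z"
    flags: list[str] = field(default_factory=list)
    significant: np.ndarray | None = None

    def __post_init__(self) -> None:
        k = len(self.terms)
        for name in ("coefficients", "robust_se", "statistic", "p_value", "effect_size"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (k,):
                raise ValidationError(f"{name}: expected {k} entries, got shape {arr.shape}")
            setattr(self, name, arr)
        ok = np.isfinite(self.p_value)
        if np.any(self.p_value[ok] < 0) or np.any(self.p_value[ok] > 1):
            raise ValidationError("p_value: values must lie in [0, 1]")

    def term(self, name: str) -> dict:
        """All quantities for one named term, as a plain dict."""
        i = self.terms.index(name)
        return {
            "coefficient": float(self.coefficients[i]),
            "robust_se": float(self.robust_se[i]),
            "statistic": float(self.statistic[i]),
            "p_value": float(self.p_value[i]),
            "effect_size": float(self.effect_size[i]),
        }


@dataclass
class GroupComparison:
    """A two-group demographic test: Student t or Pearson chi-square."""

    variable: str
    statistic_type: str  # "t" | "chi2"
    statistic: float
    p_value: float
    df: float

    def __post_init__(self) -> None:
        if self.statistic_type not in ("t", "chi2"):
            raise ValidationError(f"statistic_type: must be 't' or 'chi2', got {self.statistic_type!r}")
        if self.statistic_type == "chi2" and self.statistic < 0:
            raise ValidationError("statistic: chi-square must be non-negative")
        if self.df < 1:
            raise ValidationError(f"df: must be >= 1, got {self.df}")
        if not (0 <= self.p_value <= 1):
            raise ValidationError(f"p_value: must lie in [0, 1], got {self.p_value}")


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(phi)))
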