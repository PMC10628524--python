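"""End-to-end pipeline stages: simulate -> connectivity -> analyze.

Each stage is a plain function over a :class:`PipelineConfig`; the click CLI
and the numbered analysis scripts are thin wrappers around these. A single
``master_seed`` fans out deterministically to every stage and subject via
:func:`derive_seed` (CRC-32 of the token tuple, reduced below 2^31), so
identical configs reproduce identical outputs bit-for-bit and partial reruns
stay consistent.

Every run writes a JSON manifest (config snapshot, package version, record
counts, seeds, timestamps) next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import CANONICAL_BANDS, BandDefinition, ValidationError, band_by_name
from .connectivity import band_connectivity, preprocess
from .graphs import binarize_proportional, graph_metrics, reactivity
from .io import read_signal, read_table, write_signal, write_table
from .simulate import (
    OscillatorSpec,
    SubjectTableSpec,
    generate_coupled_oscillators,
    generate_subject_table,
)
from .stats import (
    chi_square_2x2,
    fit_reactivity_regression,
    fit_recall_regression,
    fit_sw_mixed_model,
    significance_policy,
    two_sample_t_from_summary,
)

logger = logging.getLogger("megsw")

__all__ = [
    "PipelineConfig",
    "derive_seed",
    "run_simulate",
    "run_connectivity",
    "run_analyze",
    "run_all",
]


@dataclass
class PipelineConfig:
    """Resolved pipeline settings; the defaults reproduce the study protocol.

    Five canonical bands, 5-s epochs, proportional threshold kappa = 0.2,
    1000 rewired nulls, alpha = 0.05 (mixed family) / 0.025 (regression and
    reactivity families), robust standard errors.
    """

    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS
    epoch_s: float = 5.0
    kappa: float = 0.2
    n_null: int = 1000
    master_seed: int = 0
    se_flavor: str = "robust"
    alpha_mixed: float = 0.05
    alpha_regression: float = 0.025
    edge_trim_fraction: float = 0.05
    rewire_mode: str = "per_edge"
    iter_per_edge: int = 10
    target_fs: float = 500.0
    notch_freqs: tuple[float, ...] = (60.0, 120.0, 180.0)
    broadband: tuple[float, float] | None = (0.5, 200.0)
    input_dir: str = "data"
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValidationError("bands: band subset must be non-empty")
        self.bands = tuple(
            band_by_name(b) if isinstance(b, str) else b for b in self.bands
        )
        if not (0 < self.kappa <= 1):
            raise ValidationError(f"kappa: must lie in (0, 1], got {self.kappa}")
        if self.n_null < 1:
            raise ValidationError(f"n_null: must be >= 1, got {self.n_null}")
        if self.epoch_s <= 0:
            raise ValidationError(f"epoch_s: must be positive, got {self.epoch_s}")
        for name in ("alpha_mixed", "alpha_regression"):
            a = getattr(self, name)
            if not (0 < a < 1):
                raise ValidationError(f"{name}: must lie in (0, 1), got {a}")

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = [(b.name, b.f_lo, b.f_hi) for b in self.bands]
        return d

    @classmethod
    def from_json(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "bands" in d:
            d["bands"] = tuple(
                BandDefinition(*b) if isinstance(b, (list, tuple)) else band_by_name(b)
                for b in d["bands"]
            )
        for key in ("notch_freqs", "broadband"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"config: unknown fields {sorted(unknown)}")
        return cls(**d)


def derive_seed(master_seed: int, *tokens) -> int:
    """Deterministic stage/subject seed below 2^31 from a master seed."""
    key = repr((int(master_seed),) + tuple(str(t) for t in tokens)).encode()
    return zlib.crc32(key) % (2**31)


def _write_manifest(out_dir: Path, stage: str, config: PipelineConfig, records: dict) -> Path:
    manifest = {
        "stage": stage,
        "version": __version__,
        "config": config.to_json(),
        "records": records,
        "timestamp": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def run_simulate(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    n_controls: int = 24,
    n_ad: int = 18,
    duration_s: float = 120.0,
    n_channels: int = 68,
    n_coupled: int = 16,
    noise_sd: float = 0.3,
) -> Path:
    """Write a full synthetic study: per subject x condition signals + subjects.csv.

    Each subject/condition recording contains a cluster of ``n_coupled``
    phase-coupled channels with subject-specific coupling strength; eyes-closed
    recordings get a mildly stronger synchrony than eyes-open (the classic
    eyes-closed alpha-synchrony increase), AD subjects a mildly weaker one.
    The remaining channels are independent oscillators. Signals are broadband
    mixtures over the configured bands.
    """
    out = Path(out_dir if out_dir is not None else config.input_dir)
    out.mkdir(parents=True, exist_ok=True)
    table_spec = SubjectTableSpec(
        n_per_group=(n_controls, n_ad), seed=derive_seed(config.master_seed, "subjects")
    )
    subjects = generate_subject_table(table_spec)
    covars = subjects.drop_duplicates("subject_id")[
        ["subject_id", "group", "age", "delayed_recall", "sex"]
    ].reset_index(drop=True)
    write_table(covars, out / "subjects.csv")

    n_signals = 0
    for _, subj in covars.iterrows():
        for cond in ("EO", "EC"):
            seed = derive_seed(config.master_seed, "signal", subj["subject_id"], cond)
            rng = np.random.default_rng(seed)
            base = 0.55 if cond == "EC" else 0.45
            if subj["group"] == "AD":
                base -= 0.10
            strength = float(np.clip(base + 0.05 * rng.standard_normal(), 0.05, 0.95))
            coupling = np.eye(n_channels)
            idx = np.arange(min(n_coupled, n_channels))
            for a in idx:
                for b in idx:
                    if a != b:
                        coupling[a, b] = strength
            lag = np.zeros((n_channels, n_channels))
            offsets = rng.uniform(0.3, 1.2, size=n_channels)
            for a in idx:
                for b in idx:
                    if a < b:
                        lag[a, b] = offsets[a] - offsets[b]
                        lag[b, a] = -lag[a, b]
            # mix one coupled narrowband process per configured band
            data = None
            for band in config.bands:
                spec = OscillatorSpec(
                    n_channels=n_channels,
                    band=(band.f_lo, band.f_hi),
                    coupling=coupling,
                    lag=lag,
                    noise_sd=0.0,
                    duration_s=duration_s,
                    fs=config.target_fs,
                    seed=derive_seed(seed, band.name),
                )
                ts = generate_coupled_oscillators(spec)
                data = ts.data if data is None else data + ts.data
            data = data + noise_sd * rng.standard_normal(data.shape)
            sig = ts.__class__(
                data=data, fs=config.target_fs, labels=ts.labels,
                subject_id=subj["subject_id"], condition=cond,
            )
            write_signal(sig, out / f"{subj['subject_id']}_{cond}")
            n_signals += 1
            logger.info("simulate: wrote %s %s (%.0f s)", subj["subject_id"], cond, duration_s)
    _write_manifest(out, "simulate", config, {"subjects": len(covars), "signals": n_signals})
    return out


# ---------------------------------------------------------------------------
# connectivity + graph metrics
# ---------------------------------------------------------------------------


def run_connectivity(
    config: PipelineConfig,
    in_dir: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> Path:
    """Signals -> per-band epoch-average PLI -> graph metrics + reactivity CSVs.

    Produces ``metrics.csv`` (one row per subject x condition x band) and
    ``reactivity.csv`` (one row per subject x band; subjects missing one
    condition are skipped with a logged warning).
    """
    src = Path(in_dir if in_dir is not None else config.input_dir)
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    signal_files = sorted(src.glob("*_*.tsv"))
    if not signal_files:
        raise ValidationError(f"{src}: no signal files (*_EO.tsv / *_EC.tsv) found")

    per_subject: dict[str, dict[str, dict[str, object]]] = {}
    for f in signal_files:
        ts = read_signal(f)
        ts = preprocess(
            ts,
            target_fs=config.target_fs,
            notch_freqs=config.notch_freqs,
            broadband=config.broadband,
        )
        mats = band_connectivity(
            ts, config.bands, epoch_s=config.epoch_s, edge_trim=config.edge_trim_fraction
        )
        per_subject.setdefault(ts.subject_id, {})[ts.condition] = mats
        logger.info("connectivity: %s %s done (%d bands)", ts.subject_id, ts.condition, len(mats))

    metric_rows, react_rows = [], []
    for subject_id in sorted(per_subject):
        conds = per_subject[subject_id]
        if {"EO", "EC"} - set(conds):
            missing = sorted({"EO", "EC"} - set(conds))
            logger.warning("connectivity: subject %s missing condition(s) %s; skipped",
                           subject_id, missing)
            continue
        for band in config.bands:
            seed = derive_seed(config.master_seed, "null", subject_id, band.name)
            results = {}
            for cond in ("EO", "EC"):
                g = binarize_proportional(conds[cond][band.name], kappa=config.kappa)
                results[cond] = graph_metrics(
                    g,
                    n_null=config.n_null,
                    iter_per_edge=config.iter_per_edge,
                    seed=seed,
                    mode=config.rewire_mode,
                    subject_id=subject_id,
                    condition=cond,
                    band=band.name,
                )
            for res in results.values():
                metric_rows.append(
                    {
                        "subject_id": subject_id,
                        "condition": res.condition,
                        "band": band.name,
                        "C": res.C,
                        "L": res.L,
                        "C_rand": res.C_rand,
                        "L_rand": res.L_rand,
                        "C_norm": res.C_norm,
                        "L_norm": res.L_norm,
                        "sw": res.SW,
                        "kappa": config.kappa,
                        "n_null": config.n_null,
                        "seed": seed,
                    }
                )
            try:
                react = reactivity(
                    results["EO"].SW, results["EC"].SW, band=band.name, subject_id=subject_id
                )
            except ValidationError as exc:
                logger.warning(
                    "connectivity: reactivity undefined for %s band %s: %s",
                    subject_id, band.name, exc,
                )
                continue
            react_rows.append(
                {"subject_id": subject_id, "band": band.name, "reactivity": react.value}
            )
    metrics = pd.DataFrame(metric_rows)
    write_table(metrics, out / "metrics.csv")
    write_table(pd.DataFrame(react_rows), out / "reactivity.csv")
    _write_manifest(
        out, "connectivity", config,
        {"metric_rows": len(metric_rows), "reactivity_rows": len(react_rows)},
    )
    return out


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------


def _model_rows(result, band: str, extra: dict) -> list[dict]:
    rows = []
    sig = result.significant
    for i, term in enumerate(result.terms):
        if term == "intercept":
            continue
        rows.append(
            {
                **extra,
                "band": band,
                "term": term,
                "coefficient": result.coefficients[i],
                "robust_se": result.robust_se[i],
                "statistic": result.statistic[i],
                "statistic_name": result.statistic_name,
                "p_value": result.p_value[i],
                "effect_size": result.effect_size[i],
                "significant": bool(sig[i]) if sig is not None else None,
                "n_obs": result.n_obs,
                "flags": ";".join(result.flags),
            }
        )
    return rows


def run_analyze(
    config: PipelineConfig,
    metrics_csv: str | Path,
    subjects_csv: str | Path,
    reactivity_csv: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> Path:
    """Join metrics with covariates and fit the full statistical layer.

    Writes ``mixed_models.csv`` (SW ~ disease + condition + age, per band),
    ``recall_regressions.csv`` (SW ~ recall + age per group x condition x
    band), ``reactivity_regressions.csv`` (reactivity ~ recall + age per group
    x band) and ``demographics.csv``. Slices too small to fit are skipped with
    a logged warning (miniature smoke fixtures).
    """
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    metrics = read_table(metrics_csv)
    subjects = read_table(subjects_csv)
    orphans = sorted(set(metrics["subject_id"]) - set(subjects["subject_id"]))
    if orphans:
        raise ValidationError(f"join: metric rows with no covariates for subjects {orphans}")
    table = metrics.merge(subjects, on="subject_id", how="left")

    mixed_results, mixed_rows = [], []
    for band in config.bands:
        try:
            res = fit_sw_mixed_model(table, band.name)
        except (ValidationError, np.linalg.LinAlgError) as exc:
            logger.warning("analyze: mixed model failed for band %s: %s", band.name, exc)
            continue
        mixed_results.append((band.name, res))
    significance_policy([r for _, r in mixed_results], "mixed")
    for band_name, res in mixed_results:
        mixed_rows.extend(_model_rows(res, band_name, {"outcome": "sw"}))
    write_table(pd.DataFrame(mixed_rows), out / "mixed_models.csv")

    recall_rows, recall_results = [], []
    for band in config.bands:
        for group in ("AD", "control"):
            for cond in ("EO", "EC"):
                try:
                    res = fit_recall_regression(table, band.name, group, cond)
                except ValidationError as exc:
                    logger.warning(
                        "analyze: recall regression skipped (%s/%s/%s): %s",
                        group, cond, band.name, exc,
                    )
                    continue
                recall_results.append((band.name, group, cond, res))
    significance_policy([r for *_, r in recall_results], "regression")
    for band_name, group, cond, res in recall_results:
        recall_rows.extend(
            _model_rows(res, band_name, {"outcome": "sw", "group": group, "condition": cond})
        )
    write_table(pd.DataFrame(recall_rows), out / "recall_regressions.csv")

    react_rows_out, react_results = [], []
    if reactivity_csv is not None and Path(reactivity_csv).exists():
        react = read_table(reactivity_csv).merge(subjects, on="subject_id", how="left")
        for band in config.bands:
            for group in ("AD", "control"):
                try:
                    res = fit_reactivity_regression(react, band.name, group)
                except ValidationError as exc:
                    logger.warning(
                        "analyze: reactivity regression skipped (%s/%s): %s",
                        group, band.name, exc,
                    )
                    continue
                react_results.append((band.name, group, res))
        significance_policy([r for *_, r in react_results], "reactivity")
        for band_name, group, res in react_results:
            react_rows_out.extend(
                _model_rows(res, band_name, {"outcome": "reactivity", "group": group})
            )
    write_table(pd.DataFrame(react_rows_out), out / "reactivity_regressions.csv")

    demo_rows = []
    ctrl = subjects[subjects["group"] == "control"]
    ad = subjects[subjects["group"] == "AD"]
    for col in ("age", "delayed_recall"):
        if col in subjects.columns and len(ctrl) >= 2 and len(ad) >= 2:
            cmp = two_sample_t_from_summary(
                ctrl[col].mean(), ctrl[col].std(ddof=1), len(ctrl),
                ad[col].mean(), ad[col].std(ddof=1), len(ad), variable=col,
            )
            demo_rows.append(dataclasses.asdict(cmp))
    if "sex" in subjects.columns:
        a = int((ctrl["sex"] == "M").sum())
        b = int((ctrl["sex"] == "F").sum())
        c = int((ad["sex"] == "M").sum())
        d = int((ad["sex"] == "F").sum())
        try:
            demo_rows.append(dataclasses.asdict(chi_square_2x2(a, b, c, d, variable="sex")))
        except ValidationError as exc:
            logger.warning("analyze: sex chi-square skipped: %s", exc)
    write_table(pd.DataFrame(demo_rows), out / "demographics.csv")

    _write_manifest(
        out, "analyze", config,
        {
            "mixed_rows": len(mixed_rows),
            "recall_rows": len(recall_rows),
            "reactivity_rows": len(react_rows_out),
            "demographic_rows": len(demo_rows),
        },
    )
    return out


def run_all(
    config: PipelineConfig,
    work_dir: str | Path,
    n_controls: int = 24,
    n_ad: int = 18,
    duration_s: float = 120.0,
    n_channels: int = 68,
) -> Path:
    """simulate -> connectivity -> analyze under one working directory."""
    work = Path(work_dir)
    data = run_simulate(
        config, out_dir=work / "data",
        n_controls=n_controls, n_ad=n_ad, duration_s=duration_s, n_channels=n_channels,
    )
    derived = run_connectivity(config, in_dir=data, out_dir=work / "derived")
    return run_analyze(
        config,
        metrics_csv=derived / "metrics.csv",
        subjects_csv=data / "subjects.csv",
        reactivity_csv=derived / "reactivity.csv",
        out_dir=work / "stats",
    )
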