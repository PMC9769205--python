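"""Pipeline orchestration: trial-log IO, configuration, reporting, DOT export.

Runs the full analysis: read or generate trials -> RT filter -> outcome
encoding -> pooled per-environment transition tables (orders 0-2) ->
prior-state and cofactor ANOVAs -> order assignment -> JSON-serialisable
report.  Deterministic given the seed; every stage logs its record counts so
the filter/window arithmetic can be audited from logs alone.

Trial logs are interchanged as CSV with the documented header (no standard
exists for behavioural trial logs); externally produced CSVs can be adapted
through a column-mapping dictionary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import synthetic_data as sd
from . import preprocess, markov_chain, rt_stats

__all__ = [
    "PipelineError",
    "PipelineConfig",
    "AnalysisReport",
    "read_trials",
    "write_trials",
    "read_profiles",
    "write_profiles",
    "run_pipeline",
    "export_chain_dot",
]

logger = logging.getLogger("gogomarkov")

_REQUIRED = set(sd.TRIAL_COLUMNS)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# trial-log IO
# ---------------------------------------------------------------------------


def read_trials(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a trial-log CSV (header-driven, not positional).

    ``column_map`` renames external columns to the documented schema, e.g.
    ``{"subject": "participant_id"}``.  Validation is row-addressed: the first
    offending row is named in the error.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = _REQUIRED - set(df.columns)
    if missing:
        raise preprocess.DataError(f"{path}: missing columns {sorted(missing)}")
    df = df[sd.TRIAL_COLUMNS]

    bad = ~df["correct"].isin((0, 1))
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise preprocess.DataError(f"{path}: non-binary 'correct'={df['correct'].iloc[i]!r} at data row {i}")
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad = ~(rt > 0)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise preprocess.DataError(f"{path}: nonpositive rt_ms={df['rt_ms'].iloc[i]!r} at data row {i}")
    df["correct"] = df["correct"].astype(int)
    df["trial_index"] = df["trial_index"].astype(int)
    df["block_index"] = df["block_index"].astype(int)
    df["rt_ms"] = rt.astype(float)
    df["isi_s"] = df["isi_s"].astype(float)
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    trials[sd.TRIAL_COLUMNS].to_csv(path, index=False)


def write_profiles(profiles: Sequence[sd.ParticipantProfile], path) -> None:
    pd.DataFrame([asdict(p) for p in profiles]).to_csv(path, index=False, float_format="%.17g")


def read_profiles(path) -> list[sd.ParticipantProfile]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        sd.ParticipantProfile(
            participant_id=str(r.participant_id),
            gender=str(r.gender),
            coffee=bool(r.coffee),
            mood=int(r.mood),
            rt_offset_ms=float(r.rt_offset_ms),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# configuration and report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run settings.

    When ``input_csv`` is None, a synthetic cohort is generated from
    ``generator``/``kernels``/``rt_model`` (defaulting to the study
    conditions with this config's seed).
    """

    seed: int = 0
    input_csv: str | None = None
    profiles_csv: str | None = None
    column_map: Mapping[str, str] | None = None
    generator: sd.GeneratorConfig | None = None
    kernels: Mapping[str, sd.AccuracyKernel] | None = None
    rt_model: sd.RTModel | None = None
    window_length: int = 3
    orders: tuple[int, ...] = (0, 1, 2)
    alpha: float = 0.05
    threshold_ms: float = 200.0
    add_one_smoothing: bool = False
    break_at_gaps: bool = False

    def __post_init__(self) -> None:
        if not set(self.orders) <= {0, 1, 2}:
            raise ValueError(f"orders must be a subset of {{0, 1, 2}}, got {self.orders}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Build a config from a YAML file mirroring the generator fields.

        Recognised keys: seed, input_csv, profiles_csv, column_map,
        window_length, orders, alpha, threshold_ms, add_one_smoothing,
        break_at_gaps, plus a ``generator`` block (GeneratorConfig fields),
        a ``kernels`` block (environment -> {order, probs keyed by 'F'/'V'
        strings}), and an ``rt_model`` block (RTModel fields; shift tables
        keyed by 'F'/'V' strings).
        """
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", None)
        kernels = raw.pop("kernels", None)
        rt = raw.pop("rt_model", None)
        kwargs = dict(raw)
        if gen:
            if "environments" in gen:
                gen["environments"] = tuple(gen["environments"])
            if "isi_range_s" in gen:
                gen["isi_range_s"] = tuple(gen["isi_range_s"])
            kwargs["generator"] = sd.GeneratorConfig(**gen)
        if kernels:
            kwargs["kernels"] = {
                env: sd.AccuracyKernel(
                    order=int(spec["order"]),
                    probs={_label_key(k): float(v) for k, v in spec["probs"].items()},
                )
                for env, spec in kernels.items()
            }
        if rt:
            if "history_shift_ms" in rt:
                rt["history_shift_ms"] = {
                    env: {_label_key(k): float(v) for k, v in table.items()}
                    for env, table in rt["history_shift_ms"].items()
                }
            if "anticipatory_range_ms" in rt:
                rt["anticipatory_range_ms"] = tuple(rt["anticipatory_range_ms"])
            kwargs["rt_model"] = sd.RTModel(**rt)
        if "orders" in kwargs:
            kwargs["orders"] = tuple(kwargs["orders"])
        return cls(**kwargs)

    def canonical_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "input_csv": self.input_csv,
            "profiles_csv": self.profiles_csv,
            "column_map": dict(self.column_map) if self.column_map else None,
            "window_length": self.window_length,
            "orders": list(self.orders),
            "alpha": self.alpha,
            "threshold_ms": self.threshold_ms,
            "add_one_smoothing": self.add_one_smoothing,
            "break_at_gaps": self.break_at_gaps,
            "generator": _jsonify(asdict(self.generator)) if self.generator else None,
            "kernels": {
                env: {"order": k.order, "probs": {markov_chain.history_label(h): p for h, p in k.probs.items()}}
                for env, k in (self.kernels or {}).items()
            } or None,
            "rt_model": _jsonify(asdict(self.rt_model)) if self.rt_model else None,
        }
        return d

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.canonical_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _label_key(key) -> tuple[int, ...]:
    if isinstance(key, str):
        return markov_chain._parse_history_label(key)
    return tuple(int(x) for x in key)


def _jsonify(obj):
    """Make tuple-keyed/typed structures JSON-serialisable, deterministically."""
    if isinstance(obj, dict):
        return {
            (markov_chain.history_label(k) if isinstance(k, tuple) else str(k)): _jsonify(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class AnalysisReport:
    """Assembled stage outputs; every number equals the stage API output."""

    filter_report: dict
    normality_pooled: list[dict]
    normality_by_group: list[dict]
    transition_tables: dict  # env -> {order -> TransitionTable.to_dict()}
    prior_state_anova: dict  # env -> {m -> [row dicts]}
    cofactor_anova: list[dict]
    order_assignment: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "filter_report": self.filter_report,
            "normality_pooled": self.normality_pooled,
            "normality_by_group": self.normality_by_group,
            "transition_tables": self.transition_tables,
            "prior_state_anova": self.prior_state_anova,
            "cofactor_anova": self.cofactor_anova,
            "order_assignment": self.order_assignment,
            "provenance": self.provenance,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _stage(name):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, f"{type(exc).__name__}: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute all stages and assemble the report (deterministic given seed)."""
    with _stage("load"):
        if config.input_csv is not None:
            trials = read_trials(config.input_csv, column_map=config.column_map)
            profiles = read_profiles(config.profiles_csv) if config.profiles_csv else None
        else:
            gen, kernels, rt_model = sd.study_defaults(seed=config.seed)
            gen = config.generator or gen
            kernels = config.kernels or kernels
            rt_model = config.rt_model or rt_model
            trials, profiles = sd.generate_cohort(gen, kernels, rt_model)
        environments = list(pd.unique(trials["environment"]))
        logger.info("loaded %d trials across environments %s", len(trials), environments)

    with _stage("filter"):
        kept, report = preprocess.filter_rt(trials, threshold_ms=config.threshold_ms)
        logger.info("filter: kept %d / removed %d of %d", report.n_kept, report.n_removed, report.n_input)

    with _stage("normality"):
        pooled = []
        for env in environments:
            rts = kept.loc[kept["environment"] == env, "rt_ms"].to_numpy()
            try:
                w, p = preprocess.check_normality(rts, group=env)
                pooled.append({"environment": env, "n": int(rts.size), "W": w, "p": p, "degenerate": False})
            except preprocess.DegenerateSampleError:
                pooled.append({"environment": env, "n": int(rts.size),
                               "W": None, "p": None, "degenerate": True})
        by_group = preprocess.normality_by_group(kept)
        by_group_records = json.loads(by_group.to_json(orient="records"))

    with _stage("chains"):
        sequences = markov_chain.encode_outcomes(kept)
        smoothing = "add_one" if config.add_one_smoothing else None
        tables: dict[str, dict[str, dict]] = {}
        for env in environments:
            env_seqs = [s for s in sequences if s.environment == env]
            tables[env] = {}
            for order in config.orders:
                table = markov_chain.pool_cohort(
                    env_seqs, environment=env, order=order,
                    break_at_gaps=config.break_at_gaps, smoothing=smoothing,
                )
                tables[env][str(order)] = table.to_dict()
                logger.info("chains: %s order %d over %d windows", env, order, table.n_windows)

    with _stage("anova"):
        anova: dict[str, dict[str, list[dict]]] = {}
        suites = {}
        for env in environments:
            suite = rt_stats.prior_state_anova_suite(kept, env)
            suites[env] = suite
            anova[env] = {
                str(m): [
                    {"model_states": r.model_states, "level": r.level, "F": r.F, "p": r.p}
                    for r in rows
                ]
                for m, rows in suite.items()
            }
        cof_rows = []
        if profiles is not None:
            cof_rows = [
                {"environment": r.environment, "factor": r.factor,
                 "F": None if np.isnan(r.F) else r.F,
                 "p": None if np.isnan(r.p) else r.p,
                 "estimable": r.estimable}
                for r in rt_stats.cofactor_anova(kept, profiles)
            ]

    with _stage("order-assignment"):
        orders = {env: rt_stats.assign_markov_order(suites[env], alpha=config.alpha) for env in environments}
        assignment = rt_stats.OrderAssignment(orders=orders, alpha=config.alpha)
        logger.info("assigned orders: %s", orders)

    with _stage("report"):
        from . import __version__

        return AnalysisReport(
            filter_report=report.to_dict(),
            normality_pooled=pooled,
            normality_by_group=by_group_records,
            transition_tables=tables,
            prior_state_anova=anova,
            cofactor_anova=cof_rows,
            order_assignment=assignment.to_dict(),
            provenance={"config_hash": config.hash(), "seed": config.seed, "version": __version__},
        )


# ---------------------------------------------------------------------------
# DOT export
# ---------------------------------------------------------------------------


def export_chain_dot(table: markov_chain.TransitionTable, path=None) -> str:
    """Chain diagram in DOT format: one node per history, edges labelled with
    3-decimal probabilities.  Undefined rows are omitted with a warning."""
    lines = ["digraph markov_chain {", "  rankdir=LR;"]
    for h in table.histories:
        lines.append(f'  "{markov_chain.history_label(h)}";')
    for h in table.histories:
        pv = table.p_correct(h)
        if pv is None:
            logger.warning("DOT export: history %s has no observations; edges omitted",
                           markov_chain.history_label(h))
            continue
        for outcome, prob in ((1, pv), (0, 1.0 - pv)):
            succ = (h + (outcome,))[1:] if table.order else ()
            label = "V" if outcome else "F"
            lines.append(
                f'  "{markov_chain.history_label(h)}" -> "{markov_chain.history_label(succ)}"'
                f' [label="{label} {prob:.3f}"];'
            )
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
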