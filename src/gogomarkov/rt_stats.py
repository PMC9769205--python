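"""Prior-state and cofactor ANOVAs on reaction times, and the order rule.

The prior-state analysis asks how deep the trial-history dependence of RT
reaches.  For a model of m "states", trial-level RT is regressed on m binary
correctness factors: level 0 is the current trial's outcome, level 1 the
previous trial's, level 2 the outcome two trials back.  Each level gets one
F statistic (fixed effects, main effects only, Type II sums of squares —
robust to the mild imbalance of history cells).

The order-assignment rule turns the significance pattern into a Markov order
per environment: the assigned order is m* - 1 where m* is the smallest model
size whose levels 0..m*-1 are ALL significant at alpha; if no model
qualifies the environment is "undetermined".

Cofactors (answer V/F, coffee, mood, gender) are tested per environment.
Answer varies within participants and is tested on trial-level RTs; coffee,
mood and gender are between-subject and are tested on participant-mean RTs,
which keeps the type-I rate honest under participant-to-participant RT
heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

__all__ = [
    "DegenerateDesignError",
    "AnovaRow",
    "CofactorRow",
    "OrderAssignment",
    "UNDETERMINED",
    "factorial_anova",
    "history_factors",
    "prior_state_anova",
    "prior_state_anova_suite",
    "cofactor_anova",
    "assign_markov_order",
    "assign_orders",
    "REFERENCE_PRIOR_STATE_TABLE",
    "reference_prior_state_rows",
]

COFACTORS = ("answer", "coffee", "mood", "gender")
UNDETERMINED = "undetermined"


class DegenerateDesignError(ValueError):
    """Raised when a factor cell is empty and the ANOVA design collapses."""


@dataclass(frozen=True)
class AnovaRow:
    """One level of one prior-state model: F and p for that correctness lag."""

    model_states: int
    level: int
    F: float
    p: float
    environment: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.level < self.model_states:
            raise ValueError(f"level {self.level} outside model with {self.model_states} states")


@dataclass(frozen=True)
class CofactorRow:
    environment: str
    factor: str
    F: float
    p: float
    estimable: bool = True


@dataclass(frozen=True)
class OrderAssignment:
    """Markov order per environment under the significance-pattern rule."""

    orders: Mapping[str, int | str]
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "orders": dict(self.orders)}


# ---------------------------------------------------------------------------
# ANOVA machinery
# ---------------------------------------------------------------------------


def factorial_anova(data: pd.DataFrame, response: str, factors: Sequence[str]) -> list[tuple[str, float, float]]:
    """Fixed-effects, main-effects-only factorial ANOVA (Type II SS).

    Returns (factor, F, p) per factor in the given order.  Every factor must
    take at least two values in ``data``.
    """
    for f in factors:
        if data[f].nunique() < 2:
            raise DegenerateDesignError(f"factor {f!r} has an empty cell (single observed level)")
    formula = f"{response} ~ " + " + ".join(f"C({f})" for f in factors)
    fit = ols(formula, data=data).fit()
    table = anova_lm(fit, typ=2)
    out = []
    for f in factors:
        row = table.loc[f"C({f})"]
        out.append((f, float(row["F"]), float(row["PR(>F)"])))
    return out


def history_factors(trials: pd.DataFrame, model_states: int) -> pd.DataFrame:
    """Attach lagged correctness columns lag0..lag{m-1} within each block.

    lag0 is the current trial's outcome; lag j the outcome j trials back.
    Trials lacking m - 1 predecessors within their block (the first trials of
    each block) are dropped, mirroring the sliding-window construction.
    """
    m = int(model_states)
    if m < 1:
        raise ValueError("model_states must be >= 1")
    df = trials.sort_values(["participant_id", "environment", "trial_index"]).copy()
    grouped = df.groupby(["participant_id", "environment"], sort=False)["correct"]
    df["lag0"] = df["correct"]
    for j in range(1, m):
        df[f"lag{j}"] = grouped.shift(j)
    lag_cols = [f"lag{j}" for j in range(m)]
    df = df.dropna(subset=lag_cols).copy()
    df[lag_cols] = df[lag_cols].astype(int)
    return df


def prior_state_anova(
    trials: pd.DataFrame,
    environment: str,
    model_states: int,
    include_participant: bool = False,
) -> list[AnovaRow]:
    """Prior-state ANOVA of trial-level RT for one environment.

    ``model_states`` = m fits RT on the m correctness levels 0..m-1 and
    returns one row per level.  ``include_participant`` adds participant as a
    fixed factor (off by default: the reference analysis reports one F per
    level and nothing more).
    """
    env_trials = trials[trials["environment"] == environment]
    if env_trials.empty:
        raise DegenerateDesignError(f"no trials for environment {environment!r}")
    df = history_factors(env_trials, model_states)
    factors = [f"lag{j}" for j in range(model_states)]
    if include_participant:
        factors = factors + ["participant_id"]
    result = factorial_anova(df, "rt_ms", factors)
    rows = []
    for j in range(model_states):
        _, F, p = result[j]
        rows.append(AnovaRow(model_states=model_states, level=j, F=F, p=p, environment=environment))
    return rows


def prior_state_anova_suite(
    trials: pd.DataFrame,
    environment: str,
    model_sizes: Sequence[int] = (1, 2, 3),
    include_participant: bool = False,
) -> dict[int, list[AnovaRow]]:
    """All prior-state models (default m = 1, 2, 3) for one environment."""
    return {
        m: prior_state_anova(trials, environment, m, include_participant=include_participant)
        for m in model_sizes
    }


def cofactor_anova(trials: pd.DataFrame, profiles) -> list[CofactorRow]:
    """Per-environment one-way ANOVAs of RT on answer, coffee, mood, gender.

    Profiles must cover every participant appearing in the trials.  A factor
    with a single observed level is flagged not estimable (F, p = NaN) rather
    than silently dropped.
    """
    prof = pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in profiles],
            "gender": [p.gender for p in profiles],
            "coffee": [p.coffee for p in profiles],
            "mood": [p.mood for p in profiles],
        }
    )
    missing = set(trials["participant_id"]) - set(prof["participant_id"])
    if missing:
        raise DegenerateDesignError(f"profiles missing for participants {sorted(missing)}")
    merged = trials.merge(prof, on="participant_id", how="left")

    rows: list[CofactorRow] = []
    for env in pd.unique(trials["environment"]):
        env_trials = merged[merged["environment"] == env]
        # answer (V/F): within-subject, trial level
        rows.append(_one_way(env, "answer", env_trials, "correct", env_trials["rt_ms"]))
        # between-subject factors: participant-mean RTs
        means = (
            env_trials.groupby(["participant_id", "gender", "coffee", "mood"], as_index=False)["rt_ms"].mean()
        )
        for factor in ("coffee", "mood", "gender"):
            rows.append(_one_way(env, factor, means, factor, means["rt_ms"]))
    return rows


def _one_way(environment, factor_name, data, column, response) -> CofactorRow:
    groups = [response[data[column] == level].to_numpy(dtype=float) for level in sorted(data[column].unique())]
    if len(groups) < 2:
        return CofactorRow(environment=str(environment), factor=factor_name,
                           F=float("nan"), p=float("nan"), estimable=False)
    F, p = stats.f_oneway(*groups)
    return CofactorRow(environment=str(environment), factor=factor_name, F=float(F), p=float(p))


# ---------------------------------------------------------------------------
# order-assignment rule
# ---------------------------------------------------------------------------


def assign_markov_order(
    rows_by_model: Mapping[int, Sequence[AnovaRow]],
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> int | str:
    """Markov order from the significance pattern of nested prior-state models.

    order = m* - 1 for the smallest model size m* whose levels 0..m*-1 all
    have p < alpha; ``UNDETERMINED`` when no model qualifies.  Models 1, 2 and
    3 must all be supplied.  ``bonferroni`` divides alpha by the number of
    levels within each model (off by default; the reference analysis applies
    no correction).
    """
    for m in (1, 2, 3):
        if m not in rows_by_model:
            raise ValueError(f"missing prior-state model with {m} states")
    for m in sorted(rows_by_model):
        rows = rows_by_model[m]
        if sorted(r.level for r in rows) != list(range(m)):
            raise ValueError(f"model {m} must carry exactly levels 0..{m - 1}")
        threshold = alpha / m if bonferroni else alpha
        if all(r.p < threshold for r in rows):
            return m - 1
    return UNDETERMINED


def assign_orders(
    trials: pd.DataFrame,
    alpha: float = 0.05,
    environments: Sequence[str] | None = None,
    include_participant: bool = False,
    bonferroni: bool = False,
) -> OrderAssignment:
    """Run the three prior-state models and the rule for each environment."""
    envs = list(environments) if environments is not None else list(pd.unique(trials["environment"]))
    orders = {}
    for env in envs:
        suite = prior_state_anova_suite(trials, env, include_participant=include_participant)
        orders[env] = assign_markov_order(suite, alpha=alpha, bonferroni=bonferroni)
    return OrderAssignment(orders=orders, alpha=alpha)


# ---------------------------------------------------------------------------
# published reference table
# ---------------------------------------------------------------------------

#: Prior-state ANOVA summary (F, p per level) published for the original
#: 22-participant Go-Go study in 2D, 3D and AR.  The worked example for
#: :func:`assign_markov_order`: the rule maps it to orders {2D: 0, 3D: 1,
#: AR: 2}.  Keys: environment -> model size m -> list of (level, F, p).
REFERENCE_PRIOR_STATE_TABLE: dict[str, dict[int, list[tuple[int, float, float]]]] = {
    "2D": {
        1: [(0, 6.2, 0.0169)],
        2: [(0, 46.3, 0.0), (1, 36.3, 0.0)],
        3: [(0, 57.0, 0.0), (1, 72.0, 0.0), (2, 71.7, 0.0)],
    },
    "3D": {
        1: [(0, 1.7, 0.1940)],
        2: [(0, 49.8, 0.0), (1, 36.1, 0.0)],
        3: [(0, 103.5, 0.0), (1, 88.6, 0.0), (2, 117.7, 0.0)],
    },
    "AR": {
        1: [(0, 2.8, 0.1034)],
        2: [(0, 19.4, 0.0), (1, 3.3, 0.0716)],
        3: [(0, 13.1, 0.0004), (1, 6.6, 0.0110), (2, 59.8, 0.0)],
    },
}


def reference_prior_state_rows(environment: str) -> dict[int, list[AnovaRow]]:
    """The reference table as :class:`AnovaRow` objects for one environment."""
    return {
        m: [AnovaRow(model_states=m, level=lv, F=F, p=p, environment=environment) for lv, F, p in rows]
        for m, rows in REFERENCE_PRIOR_STATE_TABLE[environment].items()
    }
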