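"""Synthetic Go-Go cohort generator.

Emulates a two-alternative speeded directional task ("Go-Go": every stimulus
requires a response) played in three environments (2D, 3D, AR).  Each
participant sees one block of arrows per environment; each arrow points left
or right and the participant presses the matching button.  The generator
produces trial-level logs with known, configurable sequential structure so the
downstream Markov-chain and ANOVA machinery can be validated by parameter
recovery:

* correctness follows an order-k Markov process (:class:`AccuracyKernel`),
* reaction times are Gaussian around an environment baseline with additive
  shifts that depend on the recent correctness window (:class:`RTModel`),
* a small rate of anticipatory (<200 ms) responses contaminates the logs to
  exercise the RT filter.

Randomness is drawn from streams derived per (seed, participant, environment),
so cohorts are reproducible element-for-element and invariant to the order in
which blocks are generated.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "ConfigurationError",
    "GeneratorConfig",
    "AccuracyKernel",
    "RTModel",
    "ParticipantProfile",
    "generate_block",
    "generate_profiles",
    "generate_cohort",
    "window_joint",
    "window_covariance",
    "masked_history_shift",
    "study_defaults",
]

#: Canonical column order of a trial log.
TRIAL_COLUMNS = [
    "participant_id",
    "environment",
    "block_index",
    "trial_index",
    "stimulus_direction",
    "response_direction",
    "correct",
    "rt_ms",
    "isi_s",
]

# Sub-stream tag for the profile RNG, outside the crc32 range used for blocks.
_PROFILE_STREAM = 2**33


class ConfigurationError(ValueError):
    """Raised when generator settings are inconsistent or incomplete."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level settings.

    Defaults reproduce the study conditions: 22 participants (six women),
    three environment blocks of 120 stimuli each (360 per session), arrow
    shown ~1 s, inter-stimulus interval uniform on 0.7-1.3 s.
    """

    n_participants: int = 22
    n_female: int = 6
    environments: tuple[str, ...] = ("2D", "3D", "AR")
    trials_per_block: int = 120
    isi_range_s: tuple[float, float] = (0.7, 1.3)
    arrow_duration_s: float = 1.0
    seed: int = 0
    #: how correctness histories shorter than the kernel order are handled at
    #: block start: "correct" pads with 1s, "burnin" simulates and discards a
    #: short warm-up run.
    history_padding: str = "correct"

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be >= 0")
        if not 0 <= self.n_female <= self.n_participants:
            raise ConfigurationError(
                f"n_female={self.n_female} must lie in [0, n_participants={self.n_participants}]"
            )
        if self.trials_per_block < 1:
            raise ConfigurationError("trials_per_block must be >= 1")
        lo, hi = self.isi_range_s
        if not (0 < lo <= hi):
            raise ConfigurationError(f"isi_range_s must satisfy 0 < low <= high, got {self.isi_range_s}")
        if len(set(self.environments)) != len(self.environments):
            raise ConfigurationError("environment labels must be unique")
        if self.history_padding not in ("correct", "burnin"):
            raise ConfigurationError("history_padding must be 'correct' or 'burnin'")
        if not 0 <= int(self.seed) < 2**31:
            raise ConfigurationError("seed must be a non-negative integer below 2**31")


@dataclass(frozen=True)
class AccuracyKernel:
    """Order-k Markov law for trial correctness.

    ``probs`` maps every binary history of length ``order`` (oldest outcome
    first) to the probability that the next response is correct.  Order 0 is
    an i.i.d. Bernoulli process keyed by the empty tuple.
    """

    order: int
    probs: Mapping[tuple[int, ...], float]

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ConfigurationError("kernel order must be >= 0")
        expected = set(itertools.product((0, 1), repeat=self.order))
        got = {tuple(k) for k in self.probs}
        if got != expected:
            missing = sorted(expected - got)
            raise ConfigurationError(
                f"incomplete order-{self.order} kernel: missing histories {missing}" if missing
                else f"order-{self.order} kernel has unexpected histories {sorted(got - expected)}"
            )
        for h, p in self.probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"P(correct|{h})={p} outside [0, 1]")
        object.__setattr__(self, "probs", {tuple(k): float(v) for k, v in self.probs.items()})

    @classmethod
    def constant(cls, p: float) -> "AccuracyKernel":
        """Order-0 kernel with fixed accuracy ``p``."""
        return cls(order=0, probs={(): p})

    def p_correct(self, history: Sequence[int]) -> float:
        if self.order == 0:
            return self.probs[()]
        return self.probs[tuple(history[-self.order:])]


@dataclass(frozen=True)
class RTModel:
    """Generative reaction-time model.

    RT = baseline(environment) + history shift + participant offset
         + gender shift (women) + Gaussian noise, truncated at 1 ms,
    replaced with an anticipatory uniform draw with probability
    ``anticipatory_rate``.

    ``history_shift_ms`` maps an environment to a shift table keyed by windows
    of consecutive correctness values *ending at the current trial* (oldest
    first); the window length sets how deep the RT's trial-history dependence
    reaches.  All keys within one environment must share a length.
    """

    baseline_mean_ms: Mapping[str, float]
    sd_ms: float = 70.0
    history_shift_ms: Mapping[str, Mapping[tuple[int, ...], float]] = field(default_factory=dict)
    gender_shift_ms: Mapping[str, float] = field(default_factory=dict)
    participant_offset_sd_ms: float = 20.0
    anticipatory_rate: float = 0.02
    anticipatory_range_ms: tuple[float, float] = (100.0, 200.0)

    def __post_init__(self) -> None:
        if self.sd_ms <= 0:
            raise ConfigurationError("sd_ms must be > 0")
        if self.participant_offset_sd_ms < 0:
            raise ConfigurationError("participant_offset_sd_ms must be >= 0")
        if not 0.0 <= self.anticipatory_rate <= 1.0:
            raise ConfigurationError("anticipatory_rate must lie in [0, 1]")
        lo, hi = self.anticipatory_range_ms
        if not (0 < lo <= hi):
            raise ConfigurationError("anticipatory_range_ms must satisfy 0 < low <= high")
        for env, table in self.history_shift_ms.items():
            lengths = {len(k) for k in table}
            if len(lengths) > 1:
                raise ConfigurationError(f"history shift windows for {env!r} have mixed lengths {lengths}")
            expected = set(itertools.product((0, 1), repeat=lengths.pop())) if table else set()
            if expected and {tuple(k) for k in table} != expected:
                raise ConfigurationError(f"history shift table for {env!r} does not cover all windows")

    def shift_table(self, environment: str) -> Mapping[tuple[int, ...], float]:
        return self.history_shift_ms.get(environment, {})


@dataclass(frozen=True)
class ParticipantProfile:
    """Between-subject covariates: gender, coffee intake, mood (3-point
    ordinal placeholder) and an idiosyncratic RT offset."""

    participant_id: str
    gender: str  # "female" | "male"
    coffee: bool
    mood: int  # 0, 1, 2
    rt_offset_ms: float


# ---------------------------------------------------------------------------
# stationary law of a kernel (used to design masked RT shift tables)
# ---------------------------------------------------------------------------


def window_joint(kernel: AccuracyKernel, length: int) -> dict[tuple[int, ...], float]:
    """Stationary joint distribution of ``length`` consecutive outcomes.

    Windows are oldest-first.  Computed from the stationary distribution of
    the kernel's history chain, extended forward one outcome at a time.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    k = max(kernel.order, 1)
    states = list(itertools.product((0, 1), repeat=k))
    index = {s: i for i, s in enumerate(states)}
    m = np.zeros((len(states), len(states)))
    for s in states:
        p1 = kernel.p_correct(s)
        for x, px in ((1, p1), (0, 1.0 - p1)):
            m[index[s], index[s[1:] + (x,)]] += px
    # stationary row vector: left eigenvector of m for eigenvalue 1
    w, v = np.linalg.eig(m.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi) / np.abs(pi).sum()

    joint = {s: float(pi[index[s]]) for s in states}
    cur_len = k
    while cur_len < length:
        nxt: dict[tuple[int, ...], float] = {}
        for win, p in joint.items():
            p1 = kernel.p_correct(win)
            for x, px in ((1, p1), (0, 1.0 - p1)):
                nxt[win + (x,)] = nxt.get(win + (x,), 0.0) + p * px
        joint = nxt
        cur_len += 1
    if cur_len > length:  # marginalise the oldest outcomes away
        short: dict[tuple[int, ...], float] = {}
        for win, p in joint.items():
            key = win[cur_len - length:]
            short[key] = short.get(key, 0.0) + p
        joint = short
    return joint


def window_covariance(kernel: AccuracyKernel, length: int) -> np.ndarray:
    """Stationary covariance matrix of (x_n, x_{n-1}, ..., x_{n-length+1}).

    Index j corresponds to lag j (0 = current outcome).
    """
    joint = window_joint(kernel, length)
    wins = np.array(list(joint.keys()), dtype=float)  # oldest first
    probs = np.array(list(joint.values()))
    # reorder columns so index j = lag j
    x = wins[:, ::-1]
    mean = probs @ x
    centred = x - mean
    return (centred * probs[:, None]).T @ centred


def masked_history_shift(kernel: AccuracyKernel, order: int, effect_ms: float) -> dict[tuple[int, ...], float]:
    """Design an RT shift table whose true depth is exactly ``order``.

    Returns additive mean shifts on windows of the last ``order + 1`` outcomes
    (oldest first, current trial last) with linear coefficients c_j on lag j
    solved so that every lag < ``order`` has *zero marginal* (omitted-variable)
    association with RT under the kernel's stationary law, while all partial
    effects in the full (order+1)-factor model are nonzero.  Nested sub-models
    of the prior-state ANOVA therefore show no fully significant pattern, and
    the (order+1)-state model is the smallest one that does — the signature
    the order-assignment rule keys on.

    Coefficients are scaled so the smallest |c_j| equals ``effect_ms`` and
    signed so that a correct answer at the deepest lag speeds responses.
    """
    if order < 0:
        raise ConfigurationError("order must be >= 0")
    if order == 0:
        c = np.array([1.0])
    else:
        sigma = window_covariance(kernel, order + 1)
        rhs = np.zeros(order + 1)
        rhs[-1] = 1.0
        c = np.linalg.solve(sigma, rhs)
    c = c * (float(effect_ms) / np.min(np.abs(c)))
    if c[-1] > 0:
        c = -c
    table: dict[tuple[int, ...], float] = {}
    for win in itertools.product((0, 1), repeat=order + 1):
        # window is oldest-first, so lag j sits at index order - j
        table[win] = float(sum(c[j] * win[order - j] for j in range(order + 1)))
    return table


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _block_rng(seed: int, participant_id: str, environment: str) -> np.random.Generator:
    """Stream derived from (seed, participant, environment) only."""
    tag = zlib.crc32(f"{participant_id}|{environment}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def generate_block(
    config: GeneratorConfig,
    profile: ParticipantProfile,
    kernel: AccuracyKernel,
    rt_model: RTModel,
    environment: str,
) -> pd.DataFrame:
    """Simulate one participant x environment block of trials.

    Returns exactly ``config.trials_per_block`` rows in :data:`TRIAL_COLUMNS`
    order.  Stimulus directions are Bernoulli(0.5); correctness of trial n is
    drawn from the kernel applied to the preceding correctness values (padded
    or burnt in per ``config.history_padding``); RTs follow ``rt_model``.
    """
    if environment not in config.environments:
        raise ConfigurationError(f"unknown environment label {environment!r}")
    if environment not in rt_model.baseline_mean_ms:
        raise ConfigurationError(f"no RT baseline configured for environment {environment!r}")

    shift = rt_model.shift_table(environment)
    shift_len = len(next(iter(shift))) if shift else 0
    depth = max(kernel.order, max(shift_len - 1, 0))

    rng = _block_rng(config.seed, profile.participant_id, environment)
    history: list[int] = [1] * depth
    if config.history_padding == "burnin" and depth:
        for _ in range(depth):
            history.append(int(rng.random() < kernel.p_correct(history)))
        history = history[-depth:]

    baseline = float(rt_model.baseline_mean_ms[environment])
    gender_shift = float(rt_model.gender_shift_ms.get(environment, 0.0)) if profile.gender == "female" else 0.0
    lo, hi = config.isi_range_s
    alo, ahi = rt_model.anticipatory_range_ms

    rows = []
    block_index = config.environments.index(environment) + 1
    for n in range(1, config.trials_per_block + 1):
        stimulus = "L" if rng.random() < 0.5 else "R"
        correct = int(rng.random() < kernel.p_correct(history))
        response = stimulus if correct else ("R" if stimulus == "L" else "L")
        h_shift = 0.0
        if shift:
            window = tuple(history[len(history) - (shift_len - 1):]) + (correct,) if shift_len > 1 else (correct,)
            h_shift = shift[window]
        rt = baseline + h_shift + profile.rt_offset_ms + gender_shift + rng.normal(0.0, rt_model.sd_ms)
        rt = max(rt, 1.0)
        if rng.random() < rt_model.anticipatory_rate:
            rt = rng.uniform(alo, ahi)
        rows.append(
            (
                profile.participant_id,
                environment,
                block_index,
                n,
                stimulus,
                response,
                correct,
                float(rt),
                float(rng.uniform(lo, hi)),
            )
        )
        history.append(correct)

    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def generate_profiles(config: GeneratorConfig, rt_model: RTModel) -> list[ParticipantProfile]:
    """Draw the cohort's participant profiles (deterministic in the seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), _PROFILE_STREAM]))
    female = np.zeros(config.n_participants, dtype=bool)
    if config.n_participants:
        female[rng.choice(config.n_participants, size=config.n_female, replace=False)] = True
    width = max(2, len(str(max(config.n_participants, 1))))
    profiles = []
    for i in range(config.n_participants):
        profiles.append(
            ParticipantProfile(
                participant_id=f"p{i + 1:0{width}d}",
                gender="female" if female[i] else "male",
                coffee=bool(rng.random() < 0.5),
                mood=int(rng.integers(0, 3)),
                rt_offset_ms=float(rng.normal(0.0, rt_model.participant_offset_sd_ms)),
            )
        )
    return profiles


def generate_cohort(
    config: GeneratorConfig,
    kernels: Mapping[str, AccuracyKernel],
    rt_model: RTModel,
) -> tuple[pd.DataFrame, list[ParticipantProfile]]:
    """Simulate the full cohort: one block per participant x environment.

    Fully reproducible from ``config.seed``; block RNG streams depend only on
    (seed, participant, environment), never on generation order.
    """
    missing = [e for e in config.environments if e not in kernels]
    if missing:
        raise ConfigurationError(f"no accuracy kernel for environments {missing}")
    profiles = generate_profiles(config, rt_model)
    blocks = [
        generate_block(config, profile, kernels[env], rt_model, env)
        for profile in profiles
        for env in config.environments
    ]
    if blocks:
        trials = pd.concat(blocks, ignore_index=True)
    else:
        trials = pd.DataFrame(columns=TRIAL_COLUMNS)
    return trials, profiles


# ---------------------------------------------------------------------------
# study defaults
# ---------------------------------------------------------------------------


def study_defaults(
    seed: int = 0,
    anticipatory_rate: float = 0.02,
) -> tuple[GeneratorConfig, dict[str, AccuracyKernel], RTModel]:
    """Default study conditions: per-environment true Markov orders 0, 1, 2.

    * 2D — order 0: i.i.d. correctness at 0.93; wrong answers slow the
      current RT (a plain "answer" effect, depth 0).
    * 3D — order 1: error-contingent accuracy (more careful after an error)
      and a masked depth-1 RT shift (post-error slowing whose marginal
      association with the current outcome cancels).
    * AR — order 2: genuinely second-order accuracy kernel and a masked
      depth-2 RT shift.

    Women respond faster in 3D by 40 ms (the one injected gender effect);
    coffee and mood carry no effect.  Kernel probabilities are set well below
    ceiling so error histories occur often enough at 22 x 120 trials for the
    transition tables and ANOVAs to be estimable.
    """
    config = GeneratorConfig(seed=seed)
    kernels = {
        "2D": AccuracyKernel.constant(0.93),
        "3D": AccuracyKernel(order=1, probs={(0,): 0.95, (1,): 0.78}),
        "AR": AccuracyKernel(order=2, probs={(0, 0): 0.95, (0, 1): 0.80, (1, 0): 0.88, (1, 1): 0.68}),
    }
    rt_model = RTModel(
        baseline_mean_ms={"2D": 450.0, "3D": 520.0, "AR": 620.0},
        sd_ms=70.0,
        history_shift_ms={
            "2D": masked_history_shift(kernels["2D"], 0, 35.0),
            "3D": masked_history_shift(kernels["3D"], 1, 16.0),
            "AR": masked_history_shift(kernels["AR"], 2, 20.0),
        },
        gender_shift_ms={"3D": -40.0},
        participant_offset_sd_ms=20.0,
        anticipatory_rate=anticipatory_rate,
    )
    return config, kernels, rt_model
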