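"""Empirical Markov-chain estimation over binary correct/incorrect sequences.

The core computation: each participant x environment block becomes an ordered
binary outcome sequence (1 = correct "V", 0 = wrong "F"); sliding windows of
``w`` consecutive outcomes form the matrix of state chains (a 120-trial block
yields 118 windows at w = 3); windows are coded in base 10 with the oldest
trial as the most significant bit; and order-k conditional transition
probabilities P(next outcome | k-history) are estimated by raw maximum
likelihood, pooled across participants per environment by summing counts.

Windows never span participants or blocks.  Estimates use no smoothing by
default, so empirical 0%/100% cells survive; optional add-one smoothing is
available for downstream modelling.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import DataError

__all__ = [
    "SequenceTooShortError",
    "OutcomeSequence",
    "StateMatrix",
    "TransitionTable",
    "history_label",
    "encode_outcomes",
    "build_state_matrix",
    "encode_base10",
    "decode_base10",
    "count_state_occurrences",
    "estimate_transitions",
    "pool_cohort",
]


class SequenceTooShortError(ValueError):
    """Raised when a sequence is shorter than the requested window."""


def history_label(history: tuple[int, ...]) -> str:
    """Human-readable history label, oldest trial first ('' order-0 -> '-')."""
    return "".join("V" if x else "F" for x in history) or "-"


def _parse_history_label(label: str) -> tuple[int, ...]:
    if label == "-":
        return ()
    return tuple(1 if ch == "V" else 0 for ch in label)


@dataclass(frozen=True)
class OutcomeSequence:
    """Ordered binary outcomes of one participant-block (after RT filtering).

    ``trial_indices`` preserves the original 1-based trial numbers so that
    gaps left by filtered trials can optionally break the chain.
    """

    participant_id: str
    environment: str
    outcomes: np.ndarray
    trial_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        out = np.asarray(self.outcomes, dtype=np.int8)
        if out.ndim != 1:
            raise DataError("outcomes must be one-dimensional")
        if out.size and not np.isin(out, (0, 1)).all():
            raise DataError("outcomes must be binary (0 = F wrong, 1 = V correct)")
        object.__setattr__(self, "outcomes", out)
        if self.trial_indices is not None:
            idx = np.asarray(self.trial_indices, dtype=np.int64)
            if idx.shape != out.shape:
                raise DataError("trial_indices must align with outcomes")
            object.__setattr__(self, "trial_indices", idx)

    def __len__(self) -> int:
        return int(self.outcomes.size)

    def segments(self, break_at_gaps: bool = False) -> list[np.ndarray]:
        """Outcome runs; contiguous-trial runs when ``break_at_gaps``."""
        if not break_at_gaps or self.trial_indices is None or len(self) == 0:
            return [self.outcomes] if len(self) else []
        cut = np.flatnonzero(np.diff(self.trial_indices) != 1) + 1
        return np.split(self.outcomes, cut)


@dataclass(frozen=True)
class StateMatrix:
    """All length-w windows of one sequence at stride 1 (the chains of states)."""

    window_length: int
    rows: np.ndarray  # shape (n_windows, window_length)

    @property
    def n_rows(self) -> int:
        return int(self.rows.shape[0])


def encode_outcomes(trials: pd.DataFrame) -> list[OutcomeSequence]:
    """One outcome sequence per participant x environment block.

    Correct responses map to 1, wrong to 0; within-block trial order is
    preserved.  Duplicate (participant, environment, trial_index) rows are a
    data error.
    """
    dup = trials.duplicated(subset=["participant_id", "environment", "trial_index"])
    if dup.any():
        row = trials.loc[dup.idxmax()]
        raise DataError(
            f"duplicate trial: participant {row['participant_id']!r}, "
            f"environment {row['environment']!r}, trial_index {row['trial_index']}"
        )
    bad = ~trials["correct"].isin((0, 1))
    if bad.any():
        raise DataError(f"non-binary 'correct' value at row {int(bad.idxmax())}")
    sequences = []
    for (pid, env), grp in trials.groupby(["participant_id", "environment"], sort=True):
        grp = grp.sort_values("trial_index")
        sequences.append(
            OutcomeSequence(
                participant_id=str(pid),
                environment=str(env),
                outcomes=grp["correct"].to_numpy(dtype=np.int8),
                trial_indices=grp["trial_index"].to_numpy(dtype=np.int64),
            )
        )
    return sequences


def build_state_matrix(
    seq: OutcomeSequence,
    window_length: int = 3,
    break_at_gaps: bool = False,
) -> StateMatrix:
    """Sliding length-w windows at stride 1; len(seq) - w + 1 rows.

    A sequence shorter than the window raises :class:`SequenceTooShortError`
    rather than returning an empty matrix, to surface data problems.
    """
    w = int(window_length)
    if w < 1:
        raise ValueError("window_length must be >= 1")
    if len(seq) < w:
        raise SequenceTooShortError(
            f"sequence of length {len(seq)} is shorter than window {w} "
            f"(participant {seq.participant_id!r}, environment {seq.environment!r})"
        )
    parts = [
        np.lib.stride_tricks.sliding_window_view(segment, w)
        for segment in seq.segments(break_at_gaps)
        if segment.size >= w
    ]
    rows = np.vstack(parts) if parts else np.empty((0, w), dtype=np.int8)
    return StateMatrix(window_length=w, rows=rows)


def encode_base10(row) -> int:
    """Base-10 code of a binary window, oldest trial as most significant bit."""
    bits = np.asarray(row, dtype=np.int64)
    if bits.size == 0 or not np.isin(bits, (0, 1)).all():
        raise ValueError(f"window must be nonempty binary, got {tuple(row)}")
    return int(bits @ (1 << np.arange(bits.size - 1, -1, -1)))


def decode_base10(code: int, window_length: int) -> tuple[int, ...]:
    """Inverse of :func:`encode_base10`."""
    if not 0 <= code < 2**window_length:
        raise ValueError(f"code {code} outside [0, {2**window_length - 1}]")
    return tuple((code >> i) & 1 for i in range(window_length - 1, -1, -1))


def count_state_occurrences(matrix: StateMatrix) -> dict[int, int]:
    """Occurrences of every base-10 state code, absent codes reported as 0."""
    if matrix.n_rows == 0:
        raise DataError("cannot count occurrences of an empty state matrix")
    codes = matrix.rows @ (1 << np.arange(matrix.window_length - 1, -1, -1))
    counts = {code: 0 for code in range(2**matrix.window_length)}
    values, tallies = np.unique(codes, return_counts=True)
    for v, t in zip(values, tallies):
        counts[int(v)] = int(t)
    return counts


@dataclass(frozen=True)
class TransitionTable:
    """Order-k conditional distribution P(next outcome | k-history) with raw counts.

    ``count_f``/``count_v`` tally the outcome following each history; rows
    with zero total are flagged undefined rather than invented.  ``smoothing``
    records whether add-one smoothing was applied to the probabilities (the
    raw counts always stay raw).
    """

    order: int
    count_f: dict[tuple[int, ...], int]
    count_v: dict[tuple[int, ...], int]
    environment: str | None = None
    smoothing: str | None = None  # None or "add_one"

    @property
    def histories(self) -> list[tuple[int, ...]]:
        return list(itertools.product((0, 1), repeat=self.order))

    @property
    def n_windows(self) -> int:
        return sum(self.count_f.values()) + sum(self.count_v.values())

    def defined(self, history: tuple[int, ...]) -> bool:
        if self.smoothing == "add_one":
            return True
        return (self.count_f.get(history, 0) + self.count_v.get(history, 0)) > 0

    def p_correct(self, history: tuple[int, ...]) -> float | None:
        """P(V | history); None when the history was never observed (unsmoothed)."""
        f = self.count_f.get(history, 0)
        v = self.count_v.get(history, 0)
        if self.smoothing == "add_one":
            return (v + 1) / (f + v + 2)
        if f + v == 0:
            return None
        return v / (f + v)

    def p(self, history: tuple[int, ...], outcome: int) -> float | None:
        pv = self.p_correct(history)
        if pv is None:
            return None
        return pv if outcome == 1 else 1.0 - pv

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for h in self.histories:
            pv = self.p_correct(h)
            rows.append(
                {
                    "history": history_label(h),
                    "count_F": self.count_f.get(h, 0),
                    "count_V": self.count_v.get(h, 0),
                    "p_F": float("nan") if pv is None else 1.0 - pv,
                    "p_V": float("nan") if pv is None else pv,
                }
            )
        return pd.DataFrame(rows, columns=["history", "count_F", "count_V", "p_F", "p_V"])

    def to_dict(self) -> dict:
        table = {}
        for h in self.histories:
            pv = self.p_correct(h)
            table[history_label(h)] = {
                "count_F": self.count_f.get(h, 0),
                "count_V": self.count_v.get(h, 0),
                "p_F": None if pv is None else 1.0 - pv,
                "p_V": None if pv is None else pv,
            }
        return {
            "order": self.order,
            "environment": self.environment,
            "smoothing": self.smoothing,
            "n_windows": self.n_windows,
            "transitions": table,
        }


def estimate_transitions(
    sequences,
    order: int,
    environment: str | None = None,
    break_at_gaps: bool = False,
    smoothing: str | None = None,
) -> TransitionTable:
    """Raw maximum-likelihood order-k transition estimates.

    Accepts one :class:`OutcomeSequence` or a list (counts are pooled by
    summation — windows never cross sequence boundaries).  Every contributing
    sequence must have length >= order + 1.
    """
    k = int(order)
    if k < 0:
        raise ValueError("order must be >= 0")
    if smoothing not in (None, "add_one"):
        raise ValueError("smoothing must be None or 'add_one'")
    if isinstance(sequences, OutcomeSequence):
        sequences = [sequences]
    sequences = list(sequences)
    if not sequences:
        raise DataError("cannot estimate transitions from an empty collection of sequences")

    count_f: dict[tuple[int, ...], int] = {h: 0 for h in itertools.product((0, 1), repeat=k)}
    count_v = {h: 0 for h in count_f}
    for seq in sequences:
        if len(seq) < k + 1:
            raise SequenceTooShortError(
                f"sequence of length {len(seq)} cannot contribute order-{k} transitions "
                f"(participant {seq.participant_id!r}, environment {seq.environment!r})"
            )
        for segment in seq.segments(break_at_gaps):
            x = segment.astype(np.int64)
            for n in range(k, x.size):
                h = tuple(x[n - k:n])
                if x[n]:
                    count_v[h] += 1
                else:
                    count_f[h] += 1
    return TransitionTable(
        order=k,
        count_f=count_f,
        count_v=count_v,
        environment=environment,
        smoothing=smoothing,
    )


def pool_cohort(
    sequences,
    environment: str,
    order: int,
    break_at_gaps: bool = False,
    smoothing: str | None = None,
) -> TransitionTable:
    """Pool one environment's sequences across participants by summing counts.

    All sequences must carry the given environment label; an empty cohort or a
    mixed-environment collection is an error.
    """
    sequences = list(sequences)
    if not sequences:
        raise DataError(f"empty cohort for environment {environment!r}")
    mixed = sorted({s.environment for s in sequences} - {environment})
    if mixed:
        raise DataError(f"sequences from environments {mixed} cannot pool into {environment!r}")
    return estimate_transitions(
        sequences, order=order, environment=environment,
        break_at_gaps=break_at_gaps, smoothing=smoothing,
    )
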