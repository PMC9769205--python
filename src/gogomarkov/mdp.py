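"""Learning-augmented Markov decision processes over behavioural states.

Implements the proposed extension of the trial-history analysis to decision
processes: a Bellman optimality backup carrying an extra learning term mu on
the successor value,

    V(s) = max_a  sum_{s'} T(s, a, s') [ R(s, a, s') + (gamma + mu) V(s') ],

i.e. the learning term acts as an additional discount-like weight on the
successor value, so the solver contracts iff gamma + mu < 1 (enforced at
construction).  mu = gamma**2 recovers the truncated n-step special case, and
mu = 0 is classical value iteration.  History-conditioned policies
pi(a | s_n, s_{n-1}, ...) are obtained by augmenting the state space with
h-tuples of recent states and running the same solver.

The backup interpretation is isolated in :func:`_backup` so alternative
readings can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping

__all__ = [
    "MDPValidationError",
    "NonContractionError",
    "MDPSpec",
    "value_iterate",
    "greedy_policy",
    "evaluate_policy",
    "augment_history",
]

State = Hashable
Action = Hashable


class MDPValidationError(ValueError):
    """Raised when the transition kernel or spec fields are malformed."""


class NonContractionError(ValueError):
    """Raised when gamma + mu >= 1 and the backup is not a contraction."""


@dataclass(frozen=True)
class MDPSpec:
    """Finite MDP with discount gamma and learning term mu.

    ``transitions[(s, a)]`` maps successor states to probabilities (each row
    sums to 1); ``rewards[(s, a, s')]`` defaults to 0 when absent.
    """

    states: tuple[State, ...]
    actions: Mapping[State, tuple[Action, ...]]
    transitions: Mapping[tuple[State, Action], Mapping[State, float]]
    rewards: Mapping[tuple[State, Action, State], float] = field(default_factory=dict)
    gamma: float = 0.9
    mu: float = 0.0

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states) or not self.states:
            raise MDPValidationError("states must be a nonempty collection of unique labels")
        if not 0.0 <= self.gamma < 1.0:
            raise MDPValidationError(f"gamma={self.gamma} must lie in [0, 1)")
        if self.mu < 0.0:
            raise MDPValidationError(f"mu={self.mu} must be >= 0")
        if self.gamma + self.mu >= 1.0:
            raise NonContractionError(
                f"gamma + mu = {self.gamma + self.mu} >= 1: the learning-augmented backup does not contract"
            )
        state_set = set(self.states)
        for s in self.states:
            acts = self.actions.get(s, ())
            if not acts:
                raise MDPValidationError(f"state {s!r} has no actions")
            for a in acts:
                row = self.transitions.get((s, a))
                if row is None:
                    raise MDPValidationError(f"missing transition row for (state={s!r}, action={a!r})")
                if not row or abs(sum(row.values()) - 1.0) > 1e-9 or any(p < 0 for p in row.values()):
                    raise MDPValidationError(
                        f"transition row for (state={s!r}, action={a!r}) is not a probability distribution"
                    )
                unknown = set(row) - state_set
                if unknown:
                    raise MDPValidationError(f"transition from (state={s!r}, action={a!r}) to unknown states {unknown}")

    @property
    def effective_discount(self) -> float:
        return self.gamma + self.mu

    def reward(self, s: State, a: Action, s2: State) -> float:
        return float(self.rewards.get((s, a, s2), 0.0))


def _backup(spec: MDPSpec, s: State, a: Action, values: Mapping[State, float]) -> float:
    """Expected one-step return of (s, a): E[R + (gamma + mu) V(s')]."""
    beta = spec.effective_discount
    return sum(p * (spec.reward(s, a, s2) + beta * values[s2]) for s2, p in spec.transitions[(s, a)].items())


def value_iterate(spec: MDPSpec, tolerance: float = 1e-8, max_sweeps: int = 1_000_000) -> dict[State, float]:
    """Optimal values to sup-norm ``tolerance`` of the true fixed point.

    Deterministic sweep order over sorted state labels; stops when the
    contraction bound beta * delta / (1 - beta) falls below tolerance.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    order = sorted(spec.states, key=repr)
    values = {s: 0.0 for s in spec.states}
    beta = spec.effective_discount
    for _ in range(max_sweeps):
        delta = 0.0
        new = dict(values)
        for s in order:
            new[s] = max(_backup(spec, s, a, values) for a in spec.actions[s])
            delta = max(delta, abs(new[s] - values[s]))
        values = new
        if beta == 0.0 or beta * delta / (1.0 - beta) < tolerance:
            return values
    raise RuntimeError(f"value iteration did not converge within {max_sweeps} sweeps")


def greedy_policy(spec: MDPSpec, values: Mapping[State, float]) -> dict[State, Action]:
    """Greedy action per state; ties broken by lowest action index."""
    policy = {}
    for s in spec.states:
        best_a, best_q = None, None
        for a in spec.actions[s]:  # first best kept -> lowest index wins ties
            q = _backup(spec, s, a, values)
            if best_q is None or q > best_q:
                best_a, best_q = a, q
        policy[s] = best_a
    return policy


def evaluate_policy(
    spec: MDPSpec, policy: Mapping[State, Action], tolerance: float = 1e-10, max_sweeps: int = 1_000_000
) -> dict[State, float]:
    """Fixed-point value of a stationary deterministic policy."""
    values = {s: 0.0 for s in spec.states}
    beta = spec.effective_discount
    order = sorted(spec.states, key=repr)
    for _ in range(max_sweeps):
        delta = 0.0
        new = dict(values)
        for s in order:
            new[s] = _backup(spec, s, policy[s], values)
            delta = max(delta, abs(new[s] - values[s]))
        values = new
        if beta == 0.0 or beta * delta / (1.0 - beta) < tolerance:
            return values
    raise RuntimeError(f"policy evaluation did not converge within {max_sweeps} sweeps")


def augment_history(spec: MDPSpec, order: int) -> MDPSpec:
    """Equivalent MDP over h-tuples of states (most recent state last).

    Standard value iteration on the augmented spec yields the optimum among
    history-conditioned policies pi(a | s_n, s_{n-1}, ..., s_{n-h+1}).  The
    augmented state set is the full tuple product, size |S|**h.
    """
    h = int(order)
    if h < 1:
        raise ValueError("history order must be >= 1")
    import itertools

    aug_states = tuple(itertools.product(spec.states, repeat=h))
    actions = {t: tuple(spec.actions[t[-1]]) for t in aug_states}
    transitions = {}
    rewards = {}
    for t in aug_states:
        last = t[-1]
        for a in spec.actions[last]:
            row = {}
            for s2, p in spec.transitions[(last, a)].items():
                t2 = t[1:] + (s2,)
                row[t2] = row.get(t2, 0.0) + p
                r = spec.reward(last, a, s2)
                if r:
                    rewards[(t, a, t2)] = r
            transitions[(t, a)] = row
    return MDPSpec(
        states=aug_states,
        actions=actions,
        transitions=transitions,
        rewards=rewards,
        gamma=spec.gamma,
        mu=spec.mu,
    )
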