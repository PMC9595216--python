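"""Stationary (null-space) families of two-state transition tables.

For a target marginal probability of pain ``pi``, the stationarity
constraint ``pi = pi * a + (1 - pi) * b`` (with ``a = p(pain|pain)`` and
``b = p(pain|pain_free)``) has a one-parameter family of solutions — a line
of transition tables that leave ``pi`` unchanged in the long run.  Chains
built from this family relax back to ``pi`` from any initial prior, at a
geometric rate set by the second eigenvalue ``a - b``; this is the
treatment-resistance mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beliefs import ConditionalTable, PseudocountDistribution
from .chain_model import (
    HIDDEN_LABELS,
    UNOBSERVED,
    ChainModel,
    ObservationSchedule,
    build_model,
)

__all__ = [
    "StationaryFamily",
    "stationary_family",
    "sample_transition",
    "stationarity_residual",
    "convergence_time",
]


@dataclass(frozen=True)
class StationaryFamily:
    """The line of two-state transitions stationary for a target marginal."""

    target_marginal: float
    valid_interval: tuple[float, float]

    def b(self, a: float) -> float:
        """Slope map: p(pain|pain_free) as a function of a = p(pain|pain)."""
        pi = self.target_marginal
        return pi * (1.0 - a) / (1.0 - pi)

    def second_eigenvalue(self, a: float) -> float:
        """Eigenvalue a - b(a) = (a - pi) / (1 - pi); controls relaxation rate."""
        return a - self.b(a)

    def contains(self, a: float, atol: float = 1e-12) -> bool:
        lo, hi = self.valid_interval
        if not (lo - atol <= a <= hi + atol):
            return False
        b = self.b(a)
        return -atol <= b <= 1.0 + atol

    def member(self, a: float, nu: float = 100.0) -> ConditionalTable:
        """Build the transition table for a given self-transition a."""
        if not self.contains(a):
            raise ValueError(f"a={a} outside the admissible interval {self.valid_interval}")
        b = self.b(a)
        return ConditionalTable(
            HIDDEN_LABELS,
            (
                PseudocountDistribution(HIDDEN_LABELS, (a, 1.0 - a), nu),
                PseudocountDistribution(HIDDEN_LABELS, (b, 1.0 - b), nu),
            ),
        )


def stationary_family(target_marginal: float) -> StationaryFamily:
    """Construct the family for a marginal strictly inside (0, 1).

    The admissible self-transition interval is ``[max(0, (2*pi-1)/pi), 1]``:
    below the lower bound the slope map would require b > 1.
    """
    pi = float(target_marginal)
    if not 0.0 < pi < 1.0:
        raise ValueError("target marginal must lie strictly between 0 and 1")
    lower = max(0.0, (2.0 * pi - 1.0) / pi)
    return StationaryFamily(target_marginal=pi, valid_interval=(lower, 1.0))


def sample_transition(
    family: StationaryFamily,
    seed: int | np.random.Generator,
    max_second_eigenvalue: float = 0.8,
    nu: float = 100.0,
) -> ConditionalTable:
    """Draw a family member uniformly, capping the second-eigenvalue magnitude.

    The cap excludes the degenerate endpoint a=1 (the identity transition,
    which never relaxes); ``|a - b(a)| <= max_second_eigenvalue`` translates
    into a sub-interval of self-transitions around the target marginal.
    """
    if not 0.0 <= max_second_eigenvalue < 1.0:
        raise ValueError("max_second_eigenvalue must lie in [0, 1)")
    pi = family.target_marginal
    # |a - b| = |a - pi| / (1 - pi)
    half_width = max_second_eigenvalue * (1.0 - pi)
    lo = max(family.valid_interval[0], pi - half_width)
    hi = min(family.valid_interval[1], pi + half_width)
    if lo > hi:
        raise ValueError("no admissible self-transition under the eigenvalue cap")
    rng = np.random.default_rng(seed)
    a = rng.uniform(lo, hi)
    return family.member(a, nu=nu)


def stationarity_residual(transition: ConditionalTable, marginal) -> float:
    """Max-norm residual ||pi T - pi|| using the transition means."""
    t = transition.mean_matrix()
    if t.shape != (2, 2):
        raise ValueError("stationarity residual is defined for two-state tables")
    pi = np.asarray(marginal, dtype=float)
    return float(np.max(np.abs(pi @ t - pi)))


def _unobserved_model(
    transition: ConditionalTable, initial_prior, n_steps: int
) -> tuple[ChainModel, ObservationSchedule]:
    prior = PseudocountDistribution(HIDDEN_LABELS, initial_prior, 100.0)
    # likelihood never enters: all nodes unobserved
    uniform_row = PseudocountDistribution(("noxious", "harmless"), (0.5, 0.5), 100.0)
    likelihood = ConditionalTable(HIDDEN_LABELS, (uniform_row, uniform_row))
    model = build_model(prior, transition, likelihood, n_steps)
    return model, ObservationSchedule((UNOBSERVED,) * n_steps)


def convergence_time(
    transition: ConditionalTable,
    initial_prior,
    target: float,
    tolerance: float,
    n_steps: int = 20,
) -> int | None:
    """Steps until the unobserved-chain pain marginal is within tolerance of target.

    Runs exact sum-product on an ``n_steps`` chain with no observations, so
    the marginal at step t+1 deviates from the target by a factor ``a - b``
    per transition.  Returns the smallest number of transitions after which
    ``|q(pain) - target| < tolerance``, or ``None`` if never within the
    chain length (0 if the initial prior already satisfies the tolerance).
    """
    from .inference import propagate

    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    model, schedule = _unobserved_model(transition, initial_prior, n_steps)
    q_pain = propagate(model, schedule, parameterization="mean").q_pain()
    within = np.abs(q_pain - float(target)) < tolerance
    hits = np.flatnonzero(within)
    return int(hits[0]) if hits.size else None
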