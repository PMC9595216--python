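"""Batch free-energy learning: sweep -> expected counts -> pseudocount update.

Parameters are updated once per trial, after a full time series has been
inferred (retrospective consolidation).  Each sweep contributes unit-weight
expected counts: the prior absorbs q(H1), each transition row absorbs the
summed pairwise marginals, and each likelihood row absorbs the singleton
marginal mass of the observed symbol at observed nodes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chain_model import UNOBSERVED, ChainModel, ObservationSchedule
from .inference import PosteriorSweep, propagate

__all__ = [
    "CountSet",
    "LearningRun",
    "expected_counts",
    "path_counts",
    "batch_update",
    "run_learning",
]


@dataclass(frozen=True)
class CountSet:
    """Expected sufficient statistics extracted from one posterior sweep."""

    prior_counts: np.ndarray = field(repr=False)  # (K,)
    transition_counts: np.ndarray = field(repr=False)  # (K, K)
    likelihood_counts: np.ndarray = field(repr=False)  # (K, M)

    def __post_init__(self) -> None:
        for name in ("prior_counts", "transition_counts", "likelihood_counts"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
            object.__setattr__(self, name, arr)

    @classmethod
    def zeros(cls, n_hidden: int = 2, n_obs: int = 2) -> "CountSet":
        return cls(
            np.zeros(n_hidden), np.zeros((n_hidden, n_hidden)), np.zeros((n_hidden, n_obs))
        )


def expected_counts(
    model: ChainModel, sweep: PosteriorSweep, obs: ObservationSchedule
) -> CountSet:
    """Posterior-expected counts for one sweep.

    The prior contributes one datum (q(H1) sums to 1), the transitions N-1,
    and the likelihood one per observed node; unobserved nodes add nothing
    to the likelihood counts.
    """
    if sweep.n_steps != len(obs) or sweep.n_steps != model.n_steps:
        raise ValueError("sweep, schedule and model lengths must agree")
    k = len(model.hidden_labels)
    m = len(model.obs_labels)
    lik_counts = np.zeros((k, m))
    for t, entry in enumerate(obs.entries):
        if entry != UNOBSERVED:
            lik_counts[:, model.obs_labels.index(entry)] += sweep.singleton[t]
    return CountSet(
        prior_counts=sweep.singleton[0].copy(),
        transition_counts=sweep.pairwise.sum(axis=0) if sweep.n_steps > 1 else np.zeros((k, k)),
        likelihood_counts=lik_counts,
    )


def path_counts(
    model: ChainModel, hidden_path: tuple[str, ...], obs: ObservationSchedule
) -> CountSet:
    """Exact indicator counts when the hidden path is known (supervised case).

    Used for parameter-recovery checks on generated sequences, where the
    sampler reveals the hidden states alongside the observations.
    """
    if len(hidden_path) != model.n_steps or len(obs) != model.n_steps:
        raise ValueError("path, schedule and model lengths must agree")
    k = len(model.hidden_labels)
    m = len(model.obs_labels)
    h_idx = [model.hidden_labels.index(h) for h in hidden_path]
    prior = np.zeros(k)
    prior[h_idx[0]] = 1.0
    trans = np.zeros((k, k))
    for a, b in zip(h_idx[:-1], h_idx[1:]):
        trans[a, b] += 1.0
    lik = np.zeros((k, m))
    for h, entry in zip(h_idx, obs.entries):
        if entry != UNOBSERVED:
            lik[h, model.obs_labels.index(entry)] += 1.0
    return CountSet(prior, trans, lik)


def batch_update(model: ChainModel, counts: CountSet) -> ChainModel:
    """Absorb one sweep's counts into prior, transition and likelihood."""
    k = len(model.hidden_labels)
    m = len(model.obs_labels)
    if counts.prior_counts.shape != (k,):
        raise ValueError("prior_counts shape does not match the hidden alphabet")
    if counts.transition_counts.shape != (k, k):
        raise ValueError("transition_counts shape does not match the hidden alphabet")
    if counts.likelihood_counts.shape != (k, m):
        raise ValueError("likelihood_counts shape does not match the alphabets")
    return model.replace(
        prior=model.prior.absorb_counts(counts.prior_counts),
        transition=model.transition.absorb_counts(counts.transition_counts),
        likelihood=model.likelihood.absorb_counts(counts.likelihood_counts),
    )


@dataclass(frozen=True)
class LearningRun:
    """Trajectories and free energies across learning trials."""

    trajectories: np.ndarray = field(repr=False)  # (n_trials, n_steps) of q(pain)
    free_energies: np.ndarray = field(repr=False)  # (n_trials,)
    final_model: ChainModel
    n_trials: int
    n_steps: int
    seed: int | None = None

    def __post_init__(self) -> None:
        traj = np.asarray(self.trajectories, dtype=float)
        fes = np.asarray(self.free_energies, dtype=float)
        if traj.shape != (self.n_trials, self.n_steps):
            raise ValueError("trajectory array shape must be (n_trials, n_steps)")
        if fes.shape != (self.n_trials,):
            raise ValueError("free_energies must have one entry per trial")
        if np.any(traj < -1e-12) or np.any(traj > 1 + 1e-12):
            raise ValueError("stored marginals must lie in [0, 1]")
        object.__setattr__(self, "trajectories", np.clip(traj, 0.0, 1.0))
        object.__setattr__(self, "free_energies", fes)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: trial, time_step (both 1-based), q_pain, free_energy."""
        trials, steps = np.meshgrid(
            np.arange(1, self.n_trials + 1), np.arange(1, self.n_steps + 1), indexing="ij"
        )
        return pd.DataFrame(
            {
                "trial": trials.ravel(),
                "time_step": steps.ravel(),
                "q_pain": self.trajectories.ravel(),
                "free_energy": np.repeat(self.free_energies, self.n_steps),
            }
        )


def run_learning(
    model: ChainModel,
    schedules: list[ObservationSchedule],
    seed: int | None = None,
    parameterization: str = "mean",
    learn: bool = True,
) -> LearningRun:
    """Infer, record and batch-update once per trial, in schedule order.

    Deterministic given its inputs; ``seed`` is recorded for provenance
    (randomness lives in schedule/model generators, not here).  Set
    ``learn=False`` to record trajectories without parameter updates.
    """
    if not schedules:
        raise ValueError("need at least one schedule")
    for sched in schedules:
        if len(sched) != model.n_steps:
            raise ValueError("every schedule must match the model's n_steps")
    n_trials = len(schedules)
    traj = np.empty((n_trials, model.n_steps))
    fes = np.empty(n_trials)
    current = model
    for i, sched in enumerate(schedules):
        sweep = propagate(current, sched, parameterization=parameterization)
        traj[i] = sweep.q_pain()
        fes[i] = sweep.free_energy
        if learn:
            current = batch_update(current, expected_counts(current, sweep, sched))
    return LearningRun(
        trajectories=traj,
        free_energies=fes,
        final_model=current,
        n_trials=n_trials,
        n_steps=model.n_steps,
        seed=seed,
    )
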