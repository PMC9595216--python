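"""Exact sum-product inference on the chain, with an enumeration oracle.

The chain is singly connected, so one forward and one backward pass of
normalized messages yields exact singleton and adjacent pairwise marginals.
Unobserved nodes contribute uniform evidence messages.  Messages can be
built either from mean probabilities (``parameterization="mean"``) or from
geometric-mean Dirichlet weights (``"geometric"``); the free energy is
minus the log of the accumulated normalizers, which for exact inference
equals the variational functional E_q[log q - log p~].

Time steps are 1-based in all documentation; arrays are 0-indexed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .chain_model import UNOBSERVED, ChainModel, ObservationSchedule

__all__ = [
    "PosteriorSweep",
    "ImpossibleEvidenceError",
    "propagate",
    "brute_force_posterior",
    "free_energy",
]

_BRUTE_FORCE_MAX_STEPS = 16


class ImpossibleEvidenceError(ValueError):
    """All messages vanished: the schedule has probability zero under the model."""


@dataclass(frozen=True)
class PosteriorSweep:
    """Per-step singleton marginals, adjacent pairwise marginals, free energy."""

    singleton: np.ndarray = field(repr=False)  # (N, K)
    pairwise: np.ndarray = field(repr=False)  # (N-1, K, K)
    free_energy: float

    def __post_init__(self) -> None:
        singleton = np.asarray(self.singleton, dtype=float)
        pairwise = np.asarray(self.pairwise, dtype=float)
        n, k = singleton.shape
        if pairwise.shape != (max(n - 1, 0), k, k):
            raise ValueError("pairwise shape inconsistent with singleton shape")
        object.__setattr__(self, "singleton", singleton)
        object.__setattr__(self, "pairwise", pairwise)
        object.__setattr__(self, "free_energy", float(self.free_energy))

    @property
    def n_steps(self) -> int:
        return self.singleton.shape[0]

    def q_pain(self) -> np.ndarray:
        """Marginal probability of the first hidden label (pain) per step."""
        return self.singleton[:, 0]

    def validate(self, atol: float = 1e-10) -> None:
        assert np.all(np.isfinite(self.singleton))
        assert np.allclose(self.singleton.sum(axis=1), 1.0, atol=atol)
        if self.n_steps > 1:
            assert np.allclose(self.pairwise.sum(axis=(1, 2)), 1.0, atol=atol)
            assert np.allclose(self.pairwise.sum(axis=2), self.singleton[:-1], atol=atol)
            assert np.allclose(self.pairwise.sum(axis=1), self.singleton[1:], atol=atol)
        assert np.isfinite(self.free_energy)


def _check_schedule(model: ChainModel, obs: ObservationSchedule) -> None:
    if len(obs) != model.n_steps:
        raise ValueError(
            f"schedule length {len(obs)} does not match model n_steps {model.n_steps}"
        )


def _evidence_matrix(
    model: ChainModel, obs: ObservationSchedule, parameterization: str
) -> np.ndarray:
    """Per-step evidence message over hidden states; uniform when unobserved."""
    lik = model.likelihood.matrix(parameterization)
    k = len(model.hidden_labels)
    ev = np.ones((model.n_steps, k))
    for t, entry in enumerate(obs.entries):
        if entry != UNOBSERVED:
            ev[t] = lik[:, model.obs_labels.index(entry)]
    return ev


def propagate(
    model: ChainModel,
    obs: ObservationSchedule,
    parameterization: str = "mean",
) -> PosteriorSweep:
    """Forward-backward sweep; exact marginals and free energy.

    Messages are renormalized after every multiplication; the marginals are
    invariant to that scaling and the forward log-normalizers accumulate to
    the free energy -log(evidence).
    """
    _check_schedule(model, obs)
    n = model.n_steps
    prior = model.prior.parameters(parameterization)
    trans = model.transition.matrix(parameterization)
    ev = _evidence_matrix(model, obs, parameterization)

    # forward pass with per-step normalizers
    fwd = np.empty((n, prior.size))
    log_z = 0.0
    msg = prior * ev[0]
    for t in range(n):
        if t > 0:
            msg = (fwd[t - 1] @ trans) * ev[t]
        c = msg.sum()
        if c <= 0.0:
            raise ImpossibleEvidenceError(
                f"evidence message vanished at time step {t + 1}"
            )
        fwd[t] = msg / c
        log_z += np.log(c)

    # backward pass (scaled; scale cancels in the marginals)
    bwd = np.empty_like(fwd)
    bwd[-1] = 1.0
    for t in range(n - 2, -1, -1):
        msg = trans @ (ev[t + 1] * bwd[t + 1])
        s = msg.sum()
        if s <= 0.0:
            raise ImpossibleEvidenceError(
                f"backward message vanished at time step {t + 1}"
            )
        bwd[t] = msg / s

    single = fwd * bwd
    single /= single.sum(axis=1, keepdims=True)

    pair = np.empty((max(n - 1, 0), prior.size, prior.size))
    for t in range(n - 1):
        joint = fwd[t][:, None] * trans * (ev[t + 1] * bwd[t + 1])[None, :]
        pair[t] = joint / joint.sum()

    return PosteriorSweep(singleton=single, pairwise=pair, free_energy=-log_z)


def brute_force_posterior(
    model: ChainModel,
    obs: ObservationSchedule,
    parameterization: str = "mean",
) -> PosteriorSweep:
    """Oracle: enumerate all K^N hidden paths and marginalize exhaustively.

    Guarded to ``N <= 16``; intended for testing ``propagate`` only.
    """
    _check_schedule(model, obs)
    n = model.n_steps
    if n > _BRUTE_FORCE_MAX_STEPS:
        raise ValueError(f"brute force limited to N <= {_BRUTE_FORCE_MAX_STEPS}")
    prior = model.prior.parameters(parameterization)
    trans = model.transition.matrix(parameterization)
    ev = _evidence_matrix(model, obs, parameterization)
    k = prior.size

    paths = np.array(list(itertools.product(range(k), repeat=n)), dtype=int)
    weights = prior[paths[:, 0]] * ev[0][paths[:, 0]]
    for t in range(1, n):
        weights = weights * trans[paths[:, t - 1], paths[:, t]] * ev[t][paths[:, t]]
    evidence = weights.sum()
    if evidence <= 0.0:
        raise ImpossibleEvidenceError("all hidden paths have zero probability")

    post = weights / evidence
    single = np.zeros((n, k))
    for t in range(n):
        np.add.at(single[t], paths[:, t], post)
    pair = np.zeros((max(n - 1, 0), k, k))
    for t in range(n - 1):
        np.add.at(pair[t], (paths[:, t], paths[:, t + 1]), post)

    return PosteriorSweep(singleton=single, pairwise=pair, free_energy=-np.log(evidence))


def _xlogy(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    from scipy.special import xlogy

    return xlogy(x, y)


def free_energy(
    model: ChainModel,
    obs: ObservationSchedule,
    sweep: PosteriorSweep,
    parameterization: str = "mean",
) -> float:
    """Evaluate E_q[log q - log p~] for a sweep produced on (model, obs).

    ``p~`` is the (possibly sub-normalized) chain measure built from the
    chosen message parameters.  For a sweep computed by exact sum-product
    this equals the sweep's stored free energy, i.e. -log(evidence).
    """
    _check_schedule(model, obs)
    if sweep.n_steps != model.n_steps:
        raise ValueError("sweep does not match the model's n_steps")
    prior = model.prior.parameters(parameterization)
    trans = model.transition.matrix(parameterization)
    ev = _evidence_matrix(model, obs, parameterization)

    q1 = sweep.singleton
    qp = sweep.pairwise
    n = sweep.n_steps

    # entropy term: chain posterior factorizes over cliques
    e_log_q = _xlogy(q1[0], q1[0]).sum()
    for t in range(n - 1):
        cond = _xlogy(qp[t], qp[t]).sum() - _xlogy(q1[t], q1[t]).sum()
        e_log_q += cond

    e_log_p = _xlogy(q1[0], prior).sum()
    for t in range(n - 1):
        e_log_p += _xlogy(qp[t], trans).sum()
    for t in range(n):
        e_log_p += _xlogy(q1[t], ev[t]).sum()

    return float(e_log_q - e_log_p)
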