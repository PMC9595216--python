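"""Construction of the N-step two-state hidden chain and the observer presets.

The hidden alphabet is the ordered pair ``("pain", "pain_free")`` and the
observation alphabet is ``("noxious", "harmless")``; index 0 is pain /
noxious throughout.  Two named presets ("healthy" and "chronic") carry the
published parameter values; transition entries that are not printed are
completed by requiring the prior to be the stationary distribution of the
transition means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .beliefs import ConditionalTable, PseudocountDistribution

__all__ = [
    "HIDDEN_LABELS",
    "OBS_LABELS",
    "UNOBSERVED",
    "ChainModel",
    "ObservationSchedule",
    "build_model",
    "preset_observer",
    "stationary_complement",
    "sample_generative",
    "model_from_config",
]

HIDDEN_LABELS: tuple[str, str] = ("pain", "pain_free")
OBS_LABELS: tuple[str, str] = ("noxious", "harmless")
UNOBSERVED = "unobserved"

#: Entries allowed in an observation schedule.
SCHEDULE_ALPHABET = frozenset(OBS_LABELS) | {UNOBSERVED}


@dataclass(frozen=True)
class ChainModel:
    """An N-step hidden Markov chain over two pain states.

    ``prior`` is the belief over the first hidden node, ``transition`` the
    table p(H_t | H_{t-1}) and ``likelihood`` the emission table
    p(S_t | H_t).  Construction performs no inference.
    """

    n_steps: int
    prior: PseudocountDistribution
    transition: ConditionalTable
    likelihood: ConditionalTable
    hidden_labels: tuple[str, str] = HIDDEN_LABELS
    obs_labels: tuple[str, str] = OBS_LABELS

    def __post_init__(self) -> None:
        if int(self.n_steps) < 1:
            raise ValueError("n_steps must be at least 1")
        object.__setattr__(self, "n_steps", int(self.n_steps))
        if self.prior.labels != self.hidden_labels:
            raise ValueError("prior alphabet must equal the hidden labels")
        if self.transition.parent_labels != self.hidden_labels:
            raise ValueError("transition parent alphabet must equal the hidden labels")
        if self.transition.child_labels != self.hidden_labels:
            raise ValueError("transition child alphabet must equal the hidden labels")
        if self.likelihood.parent_labels != self.hidden_labels:
            raise ValueError("likelihood parent alphabet must equal the hidden labels")
        if self.likelihood.child_labels != self.obs_labels:
            raise ValueError("likelihood child alphabet must equal the observation labels")

    def replace(self, **changes) -> "ChainModel":
        from dataclasses import replace as _replace

        return _replace(self, **changes)


@dataclass(frozen=True)
class ObservationSchedule:
    """Per-time-step observations: one of noxious / harmless / unobserved."""

    entries: tuple[str, ...]

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        if not entries:
            raise ValueError("schedule must have at least one entry")
        bad = [e for e in entries if e not in SCHEDULE_ALPHABET]
        if bad:
            raise ValueError(f"invalid schedule entries: {bad!r}")
        object.__setattr__(self, "entries", entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_observed(self) -> int:
        return sum(e != UNOBSERVED for e in self.entries)


def build_model(
    prior: PseudocountDistribution,
    transition: ConditionalTable,
    likelihood: ConditionalTable,
    n_steps: int,
) -> ChainModel:
    """Validate and assemble a :class:`ChainModel`."""
    return ChainModel(
        n_steps=n_steps, prior=prior, transition=transition, likelihood=likelihood
    )


def stationary_complement(pi_pain: float, known: float, known_row: str) -> float:
    """Complete a two-state transition table from the stationarity constraint.

    Given the target marginal probability of pain ``pi_pain`` and one known
    entry — either ``a = p(pain | pain)`` (``known_row="pain"``) or
    ``b = p(pain | pain_free)`` (``known_row="pain_free"``) — solve
    ``pi = pi * a + (1 - pi) * b`` for the missing entry.
    """
    pi = float(pi_pain)
    if not 0 < pi < 1:
        raise ValueError("pi_pain must lie strictly between 0 and 1")
    if known_row == "pain":
        return (pi - pi * float(known)) / (1.0 - pi)
    if known_row == "pain_free":
        return (pi - (1.0 - pi) * float(known)) / pi
    raise ValueError(f"unknown row {known_row!r}")


def _hidden_dist(p_pain: float, nu: float) -> PseudocountDistribution:
    return PseudocountDistribution(HIDDEN_LABELS, (p_pain, 1.0 - p_pain), nu)


def _transition_table(a: float, b: float, nu: float) -> ConditionalTable:
    """Transition table with a = p(pain|pain), b = p(pain|pain_free)."""
    return ConditionalTable(
        HIDDEN_LABELS,
        (
            PseudocountDistribution(HIDDEN_LABELS, (a, 1.0 - a), nu),
            PseudocountDistribution(HIDDEN_LABELS, (b, 1.0 - b), nu),
        ),
    )


def _likelihood_table(
    p_nox_pain: float, p_nox_painfree: float, nu: float
) -> ConditionalTable:
    return ConditionalTable(
        HIDDEN_LABELS,
        (
            PseudocountDistribution(OBS_LABELS, (p_nox_pain, 1.0 - p_nox_pain), nu),
            PseudocountDistribution(
                OBS_LABELS, (p_nox_painfree, 1.0 - p_nox_painfree), nu
            ),
        ),
    )


def preset_observer(name: str, n_steps: int = 20) -> ChainModel:
    """Return one of the two published observer presets as a 20-step model.

    ``"healthy"``: low precise prior p(pain)=0.2 (nu=100), accurate likelihood
    (0.8/0.2 and 0.1/0.9, nu=100), transition p(pain_free|pain)=0.7 with the
    remaining entry p(pain|pain_free)=0.175 fixed by stationarity of the prior.

    ``"chronic"``: high prior p(pain)=0.9 (nu=100), ambiguous imprecise
    likelihood (0.6/0.4 in both rows, nu=20), transition p(pain|pain_free)=0.7
    with p(pain|pain)=0.83/0.9 fixed by stationarity of the prior.
    """
    if name == "healthy":
        pi = 0.2
        a = 0.3  # p(pain|pain) = 1 - p(pain_free|pain) = 1 - 0.7
        b = stationary_complement(pi, a, known_row="pain")  # 0.175
        return build_model(
            prior=_hidden_dist(pi, 100.0),
            transition=_transition_table(a, b, 100.0),
            likelihood=_likelihood_table(0.8, 0.1, 100.0),
            n_steps=n_steps,
        )
    if name == "chronic":
        pi = 0.9
        b = 0.7  # p(pain|pain_free)
        a = stationary_complement(pi, b, known_row="pain_free")  # 0.83/0.9
        return build_model(
            prior=_hidden_dist(pi, 100.0),
            transition=_transition_table(a, b, 100.0),
            likelihood=_likelihood_table(0.6, 0.6, 20.0),
            n_steps=n_steps,
        )
    raise ValueError(f"unknown observer preset {name!r}")


def sample_generative(
    model: ChainModel, seed: int | np.random.Generator, n_sequences: int
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """Sample (hidden path, observation sequence) pairs from the model means.

    Hidden paths are drawn from the prior and transition mean probabilities,
    observations from the likelihood means.  Reproducible for a fixed seed.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be at least 1")
    rng = np.random.default_rng(seed)
    prior = model.prior.mean_probabilities()
    trans = model.transition.mean_matrix()
    lik = model.likelihood.mean_matrix()
    n, k_obs = model.n_steps, len(model.obs_labels)
    out = []
    for _ in range(n_sequences):
        hidden = np.empty(n, dtype=int)
        hidden[0] = rng.choice(2, p=prior)
        for t in range(1, n):
            hidden[t] = rng.choice(2, p=trans[hidden[t - 1]])
        obs_idx = np.array(
            [rng.choice(k_obs, p=lik[h]) for h in hidden], dtype=int
        )
        out.append(
            (
                tuple(model.hidden_labels[h] for h in hidden),
                tuple(model.obs_labels[o] for o in obs_idx),
            )
        )
    return out


def _dist_from_config(spec: dict, labels: tuple[str, ...]) -> PseudocountDistribution:
    return PseudocountDistribution(labels, spec["lam"], spec["nu"])


def model_from_config(path, base: str | None = None, n_steps: int | None = None) -> ChainModel:
    """Load a model from a YAML/plain-text config, optionally over a preset.

    The config mirrors the model fields: top-level keys ``prior``,
    ``transition`` and ``likelihood``, each holding ``lam`` (a vector for the
    prior, a row-per-parent matrix for the tables) and ``nu`` (a scalar, or a
    per-row list for the tables).  Omitted keys fall back to the ``base``
    preset (required when any key is omitted).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    base_model = preset_observer(base) if base is not None else None
    missing = [k for k in ("prior", "transition", "likelihood") if k not in cfg]
    if missing and base_model is None:
        raise ValueError(f"config omits {missing} and no base preset was given")

    if "prior" in cfg:
        prior = _dist_from_config(cfg["prior"], HIDDEN_LABELS)
    else:
        prior = base_model.prior

    def table(key: str, child: tuple[str, ...], fallback: ConditionalTable):
        if key not in cfg:
            return fallback
        spec = cfg[key]
        lam_rows = spec["lam"]
        nus = spec["nu"]
        if np.isscalar(nus):
            nus = [nus] * len(lam_rows)
        rows = tuple(
            PseudocountDistribution(child, lam, nu) for lam, nu in zip(lam_rows, nus)
        )
        return ConditionalTable(HIDDEN_LABELS, rows)

    transition = table("transition", HIDDEN_LABELS, base_model.transition if base_model else None)
    likelihood = table("likelihood", OBS_LABELS, base_model.likelihood if base_model else None)
    steps = n_steps if n_steps is not None else cfg.get("n_steps", base_model.n_steps if base_model else 20)
    return build_model(prior, transition, likelihood, steps)
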