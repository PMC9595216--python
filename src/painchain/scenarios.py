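"""Named, seeded reproductions of the four simulation experiments.

``mixed`` and the two ``prolonged_*`` scenarios run an observer preset
through 40 learning trials of a fixed schedule.  ``treatment_resistance``
draws, per trial, a fresh transition from the stationary family of the
target marginal together with a uniform-random initial prior, and records
the unobserved-chain relaxation.  The two ``therapy_*`` scenarios place ten
single-step harmless exposures in a 50-step chain whose transitions come
from the same family, differing only in the likelihood model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .beliefs import ConditionalTable, PseudocountDistribution
from .chain_model import (
    HIDDEN_LABELS,
    OBS_LABELS,
    UNOBSERVED,
    ChainModel,
    ObservationSchedule,
    build_model,
    preset_observer,
)
from .learning import LearningRun, run_learning
from .inference import propagate
from .null_space import sample_transition, stationary_family

__all__ = [
    "SCENARIOS",
    "ScenarioResult",
    "observation_schedule",
    "run_scenario",
    "write_result",
    "read_result",
    "rerun_from_provenance",
]

SCENARIOS = (
    "mixed",
    "prolonged_noxious",
    "prolonged_harmless",
    "treatment_resistance",
    "therapy_ambiguous",
    "therapy_accurate",
)

#: Scenarios whose observer is fixed by the scenario itself.
_SELF_CONTAINED = {"treatment_resistance", "therapy_ambiguous", "therapy_accurate"}


def observation_schedule(
    name: str,
    n_steps: int,
    therapy_sessions: int | None = None,
) -> ObservationSchedule:
    """Build one of the named schedules (time steps are 1-based).

    ``mixed``: noxious at steps 1-5, harmless at steps 12-18 (both ranges
    inclusive), unobserved elsewhere; requires at least 18 steps.
    ``all_noxious`` / ``all_harmless``: homogeneous.
    ``therapy``: harmless at evenly spaced session steps (every
    ``n_steps // sessions``-th step), unobserved elsewhere.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be positive")
    if name == "mixed":
        if n_steps < 18:
            raise ValueError("mixed schedule requires n_steps >= 18")
        entries = [UNOBSERVED] * n_steps
        for t in range(1, 6):
            entries[t - 1] = "noxious"
        for t in range(12, 19):
            entries[t - 1] = "harmless"
        return ObservationSchedule(tuple(entries))
    if name == "all_noxious":
        return ObservationSchedule(("noxious",) * n_steps)
    if name == "all_harmless":
        return ObservationSchedule(("harmless",) * n_steps)
    if name == "therapy":
        sessions = 10 if therapy_sessions is None else int(therapy_sessions)
        if not 1 <= sessions <= n_steps:
            raise ValueError("therapy session count must be in [1, n_steps]")
        spacing = n_steps // sessions
        entries = [UNOBSERVED] * n_steps
        for k in range(1, sessions + 1):
            entries[k * spacing - 1] = "harmless"
        return ObservationSchedule(tuple(entries))
    raise ValueError(f"unknown schedule name {name!r}")


@dataclass(frozen=True)
class ScenarioResult:
    """A learning run together with the provenance that reproduces it."""

    scenario: str
    observer: str
    run: LearningRun
    provenance: dict = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        frame = self.run.to_frame()
        frame.insert(0, "scenario", self.scenario)
        return frame


def _ambiguous_likelihood() -> ConditionalTable:
    row = PseudocountDistribution(OBS_LABELS, (0.6, 0.4), 20.0)
    return ConditionalTable(HIDDEN_LABELS, (row, row))


def _accurate_likelihood() -> ConditionalTable:
    return ConditionalTable(
        HIDDEN_LABELS,
        (
            PseudocountDistribution(OBS_LABELS, (0.8, 0.2), 100.0),
            PseudocountDistribution(OBS_LABELS, (0.1, 0.9), 100.0),
        ),
    )


def _resolve_observer(observer: str | ChainModel | None, n_steps: int) -> tuple[ChainModel, str]:
    if observer is None:
        observer = "healthy"
    if isinstance(observer, ChainModel):
        return observer.replace(n_steps=n_steps), "custom"
    model = preset_observer(observer, n_steps=n_steps)
    return model, observer


def _treatment_resistance(
    n_trials: int,
    n_steps: int,
    seed: int,
    target_marginal: float,
    max_second_eigenvalue: float,
    parameterization: str,
) -> LearningRun:
    """Per-trial fresh family member + uniform prior; no learning carries over."""
    family = stationary_family(target_marginal)
    rng = np.random.default_rng(seed)
    schedule = ObservationSchedule((UNOBSERVED,) * n_steps)
    traj = np.empty((n_trials, n_steps))
    fes = np.empty(n_trials)
    model = None
    for i in range(n_trials):
        transition = sample_transition(family, rng, max_second_eigenvalue)
        p_pain = rng.uniform(0.0, 1.0)
        p_pain = min(max(p_pain, 1e-9), 1.0 - 1e-9)
        prior = PseudocountDistribution(HIDDEN_LABELS, (p_pain, 1.0 - p_pain), 100.0)
        model = build_model(prior, transition, _ambiguous_likelihood(), n_steps)
        sweep = propagate(model, schedule, parameterization=parameterization)
        traj[i] = sweep.q_pain()
        fes[i] = sweep.free_energy
    return LearningRun(
        trajectories=traj,
        free_energies=fes,
        final_model=model,
        n_trials=n_trials,
        n_steps=n_steps,
        seed=seed,
    )


def run_scenario(
    name: str,
    observer: str | ChainModel | None = None,
    n_trials: int = 40,
    seed: int = 0,
    n_steps: int | None = None,
    target_marginal: float = 0.7,
    max_second_eigenvalue: float = 0.8,
    therapy_sessions: int = 10,
    parameterization: str = "mean",
    learn: bool = True,
) -> ScenarioResult:
    """Run one of the named scenarios and return run + provenance.

    Defaults: 20 steps and 40 trials for the learning scenarios, 50 steps
    for therapy.  ``therapy_ambiguous`` uses the flat 0.6/0.4 likelihood at
    pseudocount 20, ``therapy_accurate`` the 0.8/0.2, 0.1/0.9 likelihood at
    pseudocount 100; both start from a prior p(pain) equal to the target
    marginal and a transition sampled from its stationary family.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}")
    if n_trials < 1:
        raise ValueError("n_trials must be positive")
    provenance: dict = {
        "scenario": name,
        "seed": int(seed),
        "n_trials": int(n_trials),
        "parameterization": parameterization,
    }

    if name == "treatment_resistance":
        steps = 20 if n_steps is None else int(n_steps)
        run = _treatment_resistance(
            n_trials, steps, seed, target_marginal, max_second_eigenvalue, parameterization
        )
        provenance.update(
            n_steps=steps,
            target_marginal=target_marginal,
            max_second_eigenvalue=max_second_eigenvalue,
            schedule="unobserved",
        )
        return ScenarioResult(name, "null_space", run, provenance)

    if name in ("therapy_ambiguous", "therapy_accurate"):
        steps = 50 if n_steps is None else int(n_steps)
        family = stationary_family(target_marginal)
        transition = sample_transition(family, seed, max_second_eigenvalue)
        likelihood = (
            _ambiguous_likelihood() if name == "therapy_ambiguous" else _accurate_likelihood()
        )
        prior = PseudocountDistribution(
            HIDDEN_LABELS, (target_marginal, 1.0 - target_marginal), 100.0
        )
        model = build_model(prior, transition, likelihood, steps)
        schedule = observation_schedule("therapy", steps, therapy_sessions)
        run = run_learning(
            model, [schedule] * n_trials, seed=seed, parameterization=parameterization, learn=learn
        )
        provenance.update(
            n_steps=steps,
            target_marginal=target_marginal,
            max_second_eigenvalue=max_second_eigenvalue,
            therapy_sessions=therapy_sessions,
            schedule="therapy",
            learn=learn,
        )
        return ScenarioResult(name, name.split("_", 1)[1], run, provenance)

    # preset-observer learning scenarios
    steps = 20 if n_steps is None else int(n_steps)
    model, observer_name = _resolve_observer(observer, steps)
    schedule_name = {
        "mixed": "mixed",
        "prolonged_noxious": "all_noxious",
        "prolonged_harmless": "all_harmless",
    }[name]
    schedule = observation_schedule(schedule_name, steps)
    run = run_learning(
        model, [schedule] * n_trials, seed=seed, parameterization=parameterization, learn=learn
    )
    provenance.update(
        n_steps=steps, observer=observer_name, schedule=schedule_name, learn=learn
    )
    return ScenarioResult(name, observer_name, run, provenance)


def _model_to_dict(model: ChainModel) -> dict:
    return {
        "n_steps": model.n_steps,
        "prior": {"lam": model.prior.lam.tolist(), "nu": model.prior.nu},
        "transition": {
            "lam": model.transition.mean_matrix().tolist(),
            "nu": [r.nu for r in model.transition.rows],
        },
        "likelihood": {
            "lam": model.likelihood.mean_matrix().tolist(),
            "nu": [r.nu for r in model.likelihood.rows],
        },
    }


def write_result(result: ScenarioResult, path, format: str = "csv") -> None:
    """Write a scenario result as a tidy CSV or a JSON document with provenance."""
    path = Path(path)
    try:
        if format == "csv":
            result.to_frame().to_csv(path, index=False)
        elif format == "json":
            doc = {
                "scenario": result.scenario,
                "observer": result.observer,
                "provenance": result.provenance,
                "free_energies": result.run.free_energies.tolist(),
                "trajectories": result.run.trajectories.tolist(),
                "final_model": _model_to_dict(result.run.final_model),
            }
            path.write_text(json.dumps(doc, indent=2))
        else:
            raise ValueError(f"unknown format {format!r}")
    except OSError as exc:
        raise OSError(f"could not write result to {path}: {exc}") from exc


def read_result(path, format: str | None = None):
    """Read back a written result: a DataFrame for CSV, a dict for JSON."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "csv"
    if format == "csv":
        return pd.read_csv(path)
    if format == "json":
        return json.loads(path.read_text())
    raise ValueError(f"unknown format {format!r}")


def rerun_from_provenance(provenance: dict) -> ScenarioResult:
    """Re-execute a scenario from a stored provenance block (determinism check)."""
    prov = dict(provenance)
    name = prov.pop("scenario")
    prov.pop("schedule", None)
    return run_scenario(name, **prov)
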