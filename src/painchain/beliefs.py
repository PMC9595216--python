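"""Categorical beliefs parameterized by sufficient statistics and pseudocounts.

A belief over ``K`` categories is stored as a probability vector ``lam``
(the sufficient statistics) together with a positive pseudocount ``nu``
that plays the role of a precision: the effective Dirichlet counts are
``alpha_k = nu * lam_k``.  Absorbing (possibly fractional) counts is the
learning primitive used by the batch updater.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma

__all__ = ["PseudocountDistribution", "ConditionalTable"]

_ATOL = 1e-12


def _as_prob_vector(values, size: int | None = None) -> np.ndarray:
    vec = np.asarray(values, dtype=float)
    if vec.ndim != 1:
        raise ValueError(f"expected a 1-D probability vector, got shape {vec.shape}")
    if size is not None and vec.size != size:
        raise ValueError(f"expected {size} entries, got {vec.size}")
    if np.any(vec < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(vec.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {vec.sum()!r}")
    return vec / vec.sum()


@dataclass(frozen=True)
class PseudocountDistribution:
    """A categorical belief with sufficient statistics ``lam`` and pseudocount ``nu``.

    Parameters
    ----------
    labels
        Ordered category names, at least two.
    lam
        Probability vector over the categories (sums to one).
    nu
        Positive pseudocount; ``nu * lam`` are the effective Dirichlet counts.
    """

    labels: tuple[str, ...]
    lam: np.ndarray = field(repr=False)
    nu: float

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        if len(labels) < 2:
            raise ValueError("need at least two categories")
        if len(set(labels)) != len(labels):
            raise ValueError("category labels must be unique")
        object.__setattr__(self, "labels", labels)
        lam = _as_prob_vector(self.lam, size=len(labels))
        lam.setflags(write=False)
        object.__setattr__(self, "lam", lam)
        nu = float(self.nu)
        if not np.isfinite(nu) or nu <= 0:
            raise ValueError(f"pseudocount nu must be positive and finite, got {nu}")
        object.__setattr__(self, "nu", nu)

    @property
    def n_categories(self) -> int:
        return len(self.labels)

    @property
    def alpha(self) -> np.ndarray:
        """Effective Dirichlet counts ``nu * lam``."""
        return self.nu * self.lam

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def mean_probabilities(self) -> np.ndarray:
        """Normalized effective counts; equals ``lam`` by construction."""
        alpha = self.alpha
        return alpha / alpha.sum()

    def message_parameters(self) -> np.ndarray:
        """Geometric-mean weights ``exp(psi(alpha_k) - psi(sum alpha))``.

        These are the natural parameters substituted into sum-product
        messages under a variational treatment of the Dirichlet belief.
        They are positive and sub-normalized (their sum is at most one).

        Raises
        ------
        ValueError
            If any effective count is zero: a degenerate belief has no
            finite expected log probability.
        """
        alpha = self.alpha
        if np.any(alpha <= 0):
            raise ValueError("message parameters undefined for zero effective counts")
        return np.exp(digamma(alpha) - digamma(alpha.sum()))

    def parameters(self, parameterization: str = "mean") -> np.ndarray:
        """Dispatch between ``"mean"`` and ``"geometric"`` parameterizations."""
        if parameterization == "mean":
            return self.mean_probabilities()
        if parameterization == "geometric":
            return self.message_parameters()
        raise ValueError(f"unknown parameterization {parameterization!r}")

    def absorb_counts(self, counts) -> "PseudocountDistribution":
        """Return a new belief with ``counts`` added to the effective counts.

        Counts may be fractional (expected counts from a posterior sweep).
        The original belief is unchanged.
        """
        counts = np.asarray(counts, dtype=float)
        if counts.shape != (self.n_categories,):
            raise ValueError(
                f"counts must have shape ({self.n_categories},), got {counts.shape}"
            )
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        alpha_new = self.alpha + counts
        nu_new = self.nu + counts.sum()
        return PseudocountDistribution(self.labels, alpha_new / nu_new, nu_new)

    def validate(self) -> None:
        """Re-check the type invariants (useful after numerical round trips)."""
        assert np.all(self.lam >= 0)
        assert abs(self.lam.sum() - 1.0) <= _ATOL
        assert self.nu > 0
        assert abs(self.alpha.sum() - self.nu) <= _ATOL * max(1.0, self.nu)


@dataclass(frozen=True)
class ConditionalTable:
    """One pseudocount belief per parent state, sharing a child alphabet.

    Houses both the emission table p(observation | hidden) and the
    transition table p(hidden_t | hidden_{t-1}); each row is its own
    Dirichlet belief and is updated independently.
    """

    parent_labels: tuple[str, ...]
    rows: tuple[PseudocountDistribution, ...]

    def __post_init__(self) -> None:
        parents = tuple(self.parent_labels)
        rows = tuple(self.rows)
        if len(rows) != len(parents):
            raise ValueError("need exactly one row per parent state")
        if len(set(parents)) != len(parents):
            raise ValueError("parent labels must be unique")
        child = rows[0].labels
        for row in rows[1:]:
            if row.labels != child:
                raise ValueError("all rows must share an identical child alphabet")
        object.__setattr__(self, "parent_labels", parents)
        object.__setattr__(self, "rows", rows)

    @property
    def child_labels(self) -> tuple[str, ...]:
        return self.rows[0].labels

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.parent_labels), len(self.child_labels))

    def row(self, parent: str) -> PseudocountDistribution:
        return self.rows[self.parent_labels.index(parent)]

    def mean_matrix(self) -> np.ndarray:
        """Row-stochastic matrix of mean probabilities."""
        return np.stack([r.mean_probabilities() for r in self.rows])

    def message_matrix(self) -> np.ndarray:
        return np.stack([r.message_parameters() for r in self.rows])

    def matrix(self, parameterization: str = "mean") -> np.ndarray:
        return np.stack([r.parameters(parameterization) for r in self.rows])

    def absorb_counts(self, counts) -> "ConditionalTable":
        """Absorb a (parent, child) count table row by row."""
        counts = np.asarray(counts, dtype=float)
        if counts.shape != self.shape:
            raise ValueError(f"counts must have shape {self.shape}, got {counts.shape}")
        return ConditionalTable(
            self.parent_labels,
            tuple(row.absorb_counts(c) for row, c in zip(self.rows, counts)),
        )
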