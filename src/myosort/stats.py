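"""Shared statistics: directional-flux estimates and half-sample bootstrap."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed, ``None`` or a Generator into a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def bootstrap_sem(values, B: int = 1000, rng=None) -> float:
    """Half-sample bootstrap standard error of the mean.

    Draws ``B`` subsets of size ``floor(N/2)`` without replacement (no element
    appears twice within a subset), averages each subset, and returns the
    standard deviation of those ``B`` subset means.

    Raises
    ------
    ValueError
        If fewer than two values are supplied.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("bootstrap_sem requires at least two values")
    rng = as_rng(rng)
    n = values.size
    half = n // 2
    means = np.empty(B)
    for j in range(B):
        idx = rng.choice(n, size=half, replace=False)
        means[j] = values[idx].mean()
    return float(means.std(ddof=0))


@dataclass(frozen=True)
class FluxEstimate:
    """Directional flux ``phi_out = n_plus / (n_plus + n_minus)`` with SEM.

    ``n_plus`` counts plus-end / outward outcomes (the stronger motor winning,
    or a trajectory classified outward); ``n_minus`` the opposite.  ``sem`` is
    the binomial standard error; ``sem_bootstrap`` the half-sample bootstrap
    estimate on the 0/1 outcome indicators (``None`` when not computed).
    """

    n_plus: int
    n_minus: int
    phi_out: float
    sem: float
    sem_bootstrap: float | None = None

    @property
    def n(self) -> int:
        return self.n_plus + self.n_minus


def make_flux_estimate(n_plus: int, n_minus: int, *, bootstrap: bool = False,
                       B: int = 1000, rng=None) -> FluxEstimate:
    """Build a :class:`FluxEstimate` from outcome counts."""
    total = n_plus + n_minus
    if total < 1:
        raise ValueError("need at least one classified outcome")
    p = n_plus / total
    sem = float(np.sqrt(p * (1.0 - p) / total))
    sem_boot = None
    if bootstrap:
        indicator = np.concatenate([np.ones(n_plus), np.zeros(n_minus)])
        sem_boot = bootstrap_sem(indicator, B=B, rng=rng)
    return FluxEstimate(n_plus=n_plus, n_minus=n_minus, phi_out=p,
                        sem=sem, sem_bootstrap=sem_boot)
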