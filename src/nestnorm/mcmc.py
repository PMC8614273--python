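"""Component-wise random-walk Metropolis-Hastings with uniform priors.

Credible intervals for the thermal reaction norms are obtained by
sampling the posterior under box-uniform priors.  Parameters are
updated one at a time with Gaussian proposals; any proposal that leaves
its prior support is rejected outright, which under a uniform prior is
exactly the Metropolis rule.  Proposal scales are tuned during burn-in
toward a 0.2-0.5 acceptance rate and then frozen, so the retained chain
is a valid (non-adaptive) Markov chain.  Every run is reproducible from
its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["MCMCConfig", "PosteriorChain", "mh_sample", "credible_interval", "batch_means_se"]


@dataclass
class MCMCConfig:
    """Settings for one Metropolis-Hastings run.

    ``n_iter`` counts retained sweeps (after burn-in, before thinning);
    ``proposal_scales`` defaults to a tenth of each prior width and is
    adapted during burn-in unless ``adapt`` is False.
    """

    n_iter: int = 40_000
    burn_in: int = 10_000
    thin: int = 1
    proposal_scales: Sequence[float] | None = None
    adapt: bool = True
    seed: int = 0


@dataclass
class PosteriorChain:
    """Retained posterior draws plus sampling diagnostics."""

    draws: np.ndarray  # (n_retained, n_params)
    param_names: list[str]
    acceptance_rate: np.ndarray  # per parameter, over the retained phase
    proposal_scales: np.ndarray
    config: MCMCConfig = field(repr=False, default=None)

    def __len__(self) -> int:
        return self.draws.shape[0]

    def param(self, name_or_index) -> np.ndarray:
        if isinstance(name_or_index, str):
            name_or_index = self.param_names.index(name_or_index)
        return self.draws[:, name_or_index]

    def map_derived(self, fn: Callable[[np.ndarray], float | np.ndarray]) -> np.ndarray:
        """Apply ``fn`` to every retained draw (rowwise)."""
        return np.array([fn(row) for row in self.draws])


def mh_sample(
    negloglik: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    init: Sequence[float],
    config: MCMCConfig | None = None,
    param_names: Sequence[str] | None = None,
) -> PosteriorChain:
    """Sample -negloglik(theta) under independent uniform priors.

    ``bounds`` give the prior support per parameter; ``init`` must lie
    strictly inside it with a finite negloglik.
    """
    config = config or MCMCConfig()
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if np.any(hi <= lo):
        raise ValueError("each prior bound must satisfy lo < hi")
    theta = np.asarray(init, dtype=float).copy()
    k = theta.size
    if bounds.shape != (k, 2):
        raise ValueError("bounds must be one (lo, hi) pair per parameter")
    if np.any(theta < lo) or np.any(theta > hi):
        raise ValueError("initial point outside the prior support")
    current = float(negloglik(theta))
    if not np.isfinite(current):
        raise ValueError("negloglik is not finite at the initial point")

    if config.proposal_scales is None:
        scales = 0.1 * (hi - lo)
    else:
        scales = np.asarray(config.proposal_scales, dtype=float).copy()
        if scales.shape != (k,):
            raise ValueError("need one proposal scale per parameter")
    rng = np.random.default_rng(config.seed)

    names = list(param_names) if param_names is not None else [f"p{i}" for i in range(k)]

    def sweep(n_sweeps: int, adapt: bool) -> np.ndarray:
        nonlocal theta, current
        accepted = np.zeros(k)
        window = np.zeros(k)
        window_n = 0
        out = np.empty((n_sweeps, k))
        for it in range(n_sweeps):
            for j in range(k):
                prop = theta[j] + scales[j] * rng.standard_normal()
                if prop < lo[j] or prop > hi[j]:
                    continue  # outside support: reject
                theta_prop = theta.copy()
                theta_prop[j] = prop
                nll = float(negloglik(theta_prop))
                if np.isfinite(nll) and np.log(rng.uniform()) < current - nll:
                    theta, current = theta_prop, nll
                    accepted[j] += 1
                    window[j] += 1
            out[it] = theta
            window_n += 1
            if adapt and window_n == 200:
                rate = window / window_n
                scales[rate < 0.2] *= 0.8
                scales[rate > 0.5] *= 1.25
                window[:] = 0.0
                window_n = 0
        return out, accepted / max(n_sweeps, 1)

    if config.burn_in > 0:
        sweep(config.burn_in, adapt=config.adapt)
    draws, acc = sweep(config.n_iter, adapt=False)
    if config.thin > 1:
        draws = draws[:: config.thin]
    return PosteriorChain(
        draws=draws,
        param_names=names,
        acceptance_rate=acc,
        proposal_scales=scales,
        config=config,
    )


def credible_interval(
    draws: np.ndarray | PosteriorChain,
    param: str | int | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Equal-tailed credible interval from retained draws."""
    if isinstance(draws, PosteriorChain):
        x = draws.param(param if param is not None else 0)
    else:
        x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise ValueError("empty chain")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def batch_means_se(x: np.ndarray, n_batches: int = 50) -> float:
    """Monte-Carlo standard error of a chain mean by batch means.

    Robust to autocorrelation: the chain is cut into ``n_batches``
    contiguous batches and the SE of the batch means is reported.
    """
    x = np.asarray(x, dtype=float)
    n = x.size // n_batches
    if n < 2:
        raise ValueError("chain too short for the requested batch count")
    means = x[: n * n_batches].reshape(n_batches, n).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))
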