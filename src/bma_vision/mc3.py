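"""Markov-chain Monte Carlo model composition (MC3).

A Metropolis-Hastings random walk on the inclusion hypercube: each step
proposes flipping one uniformly chosen covariate in or out of the model
and accepts with probability min(1, marginal-likelihood ratio) under the
uniform model prior (the single-bit proposal is symmetric). Post
burn-in visit frequencies estimate posterior model probabilities; on
spaces small enough to enumerate they serve as a cross-check of the
exact answer, and beyond the enumeration cap they are the only
estimate available.

Marginal likelihoods are memoised by inclusion pattern, since a mixing
chain revisits the same few models most of the time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .core import ModelIndex, _Gram, _fit_from_gram
from .data import StudyTable
from .errors import ConfigError
from .priors import PriorSettings

__all__ = ["SamplerSettings", "SamplerTrace", "mc3_run", "convergence_report"]


@dataclass(frozen=True)
class SamplerSettings:
    """Chain length, burn-in and seed for one MC3 run."""

    n_iter: int = 100_000
    burn_in: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter <= 0:
            raise ConfigError(f"n_iter must be positive, got {self.n_iter}")
        if self.burn_in < 0 or self.burn_in >= self.n_iter:
            raise ConfigError(
                f"burn_in ({self.burn_in}) must be in [0, n_iter={self.n_iter})"
            )


@dataclass(frozen=True)
class SamplerTrace:
    """Visit statistics of one chain.

    ``visit_counts`` maps each visited model to its post-burn-in count;
    ``pmp_mcmc`` holds the normalised frequencies. ``half_counts`` splits
    the kept iterations into first and second half for split-half
    mixing diagnostics.
    """

    visit_counts: dict[ModelIndex, int]
    acceptance_rate: float
    n_kept: int
    pmp_mcmc: dict[ModelIndex, float]
    half_counts: tuple[dict[ModelIndex, int], dict[ModelIndex, int]]

    def pmp_vector(self, models: Sequence[ModelIndex]) -> np.ndarray:
        """Frequency estimates aligned with an enumerated model list."""
        return np.array([self.pmp_mcmc.get(m, 0.0) for m in models])


def _mc3_kernel(
    log_ml: Callable[[tuple[int, ...]], float],
    s: int,
    settings: SamplerSettings,
) -> SamplerTrace:
    """Metropolis-Hastings over inclusion patterns given a log-ML oracle.

    ``log_ml`` takes a sorted tuple of included covariate indices. The
    kernel only ever uses *differences* of log marginal likelihoods, so
    any model-independent additive constant leaves the chain unchanged.
    """
    rng = np.random.default_rng(settings.seed)
    # pre-drawn randomness keeps the Python loop cheap and the run
    # reproducible bit-for-bit for a fixed seed
    flips = rng.integers(0, s, size=settings.n_iter)
    log_u = np.log(rng.random(size=settings.n_iter))

    state = np.zeros(s, dtype=bool)  # start from the null model
    key = ()
    cache: dict[tuple[int, ...], float] = {key: log_ml(key)}
    current_lm = cache[key]

    counts: dict[tuple[int, ...], int] = {}
    first_half: dict[tuple[int, ...], int] = {}
    second_half: dict[tuple[int, ...], int] = {}
    n_kept = settings.n_iter - settings.burn_in
    mid = settings.burn_in + n_kept // 2
    accepted = 0

    for it in range(settings.n_iter):
        j = flips[it]
        state[j] = ~state[j]
        prop_key = tuple(np.flatnonzero(state))
        prop_lm = cache.get(prop_key)
        if prop_lm is None:
            prop_lm = log_ml(prop_key)
            cache[prop_key] = prop_lm
        if log_u[it] < prop_lm - current_lm:
            key = prop_key
            current_lm = prop_lm
            accepted += 1
        else:
            state[j] = ~state[j]  # reject: restore
        if it >= settings.burn_in:
            counts[key] = counts.get(key, 0) + 1
            half = first_half if it < mid else second_half
            half[key] = half.get(key, 0) + 1

    visit_counts = {ModelIndex(k): c for k, c in counts.items()}
    pmp_mcmc = {m: c / n_kept for m, c in visit_counts.items()}
    return SamplerTrace(
        visit_counts=visit_counts,
        acceptance_rate=accepted / settings.n_iter,
        n_kept=n_kept,
        pmp_mcmc=pmp_mcmc,
        half_counts=(
            {ModelIndex(k): c for k, c in first_half.items()},
            {ModelIndex(k): c for k, c in second_half.items()},
        ),
    )


def mc3_run(
    centered: StudyTable, prior: PriorSettings, settings: SamplerSettings
) -> SamplerTrace:
    """Run MC3 on a centered study table.

    Marginal likelihoods come from the same closed form the exact
    enumeration uses, memoised by inclusion pattern.
    """
    gram = _Gram(centered)
    g = prior.resolve_g(gram.n, gram.s)

    def log_ml(included: tuple[int, ...]) -> float:
        return _fit_from_gram(gram, ModelIndex(included), g).log_marginal

    return _mc3_kernel(log_ml, centered.s, settings)


def convergence_report(
    trace: SamplerTrace,
    models: Sequence[ModelIndex] | None = None,
    exact_pmp: np.ndarray | None = None,
) -> dict[str, float]:
    """Mixing diagnostics for one chain.

    With an exact reference distribution: total-variation distance over
    the full model list plus the Pearson correlation between exact and
    frequency estimates over visited models. Without one: the
    correlation between first- and second-half visit frequencies.
    """
    if exact_pmp is not None:
        if models is None:
            raise ConfigError("exact_pmp requires the aligned model list")
        exact_pmp = np.asarray(exact_pmp, dtype=float)
        freq = trace.pmp_vector(models)
        tv = 0.5 * float(np.abs(freq - exact_pmp).sum())
        visited = freq > 0
        if visited.sum() >= 2 and np.std(exact_pmp[visited]) > 0:
            corr = float(np.corrcoef(freq[visited], exact_pmp[visited])[0, 1])
        else:
            corr = float("nan")
        return {"tv_distance": tv, "correlation": corr}

    first, second = trace.half_counts
    support = sorted(set(first) | set(second))
    if len(support) < 2:
        return {"split_half_correlation": float("nan")}
    f = np.array([first.get(m, 0) for m in support], dtype=float)
    g_ = np.array([second.get(m, 0) for m in support], dtype=float)
    f /= max(f.sum(), 1.0)
    g_ /= max(g_.sum(), 1.0)
    if np.std(f) == 0 or np.std(g_) == 0:
        return {"split_half_correlation": float("nan")}
    return {"split_half_correlation": float(np.corrcoef(f, g_)[0, 1])}
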