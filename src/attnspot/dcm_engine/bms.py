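"""Random-effects Bayesian model selection over subject-wise free energies.

The generating model is treated as a random effect across subjects with a
Dirichlet prior over model frequencies (alpha0 = 1 per model). Variational
updates alternate subject-wise model posteriors with Dirichlet counts; the
exceedance probability of each model — the posterior probability that it is
more frequent in the population than every competitor — is estimated by
Monte Carlo sampling from the fitted Dirichlet.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, logsumexp


@dataclass
class BMSResult:
    dirichlet_alpha: np.ndarray  # per model
    expected_frequency: np.ndarray
    exceedance_prob: np.ndarray
    subject_posteriors: np.ndarray  # (subjects, models)


def dirichlet_exceedance(alpha: np.ndarray, n_draws: int = 1_000_000, seed: int = 0) -> np.ndarray:
    """Monte Carlo exceedance probabilities of a Dirichlet distribution."""
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=int(n_draws))
    winners = np.argmax(draws, axis=1)
    return np.bincount(winners, minlength=alpha.size) / float(n_draws)


def rfx_bms(
    F: np.ndarray,
    alpha0: float = 1.0,
    n_draws: int = 1_000_000,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1.0e-8,
) -> BMSResult:
    """RFX model comparison from a (subjects, models) free-energy matrix."""
    F = np.asarray(F, float)
    if F.ndim != 2 or F.shape[0] < 2 or F.shape[1] < 2:
        raise ValueError("need a (subjects >= 2, models >= 2) free-energy matrix")
    if not np.all(np.isfinite(F)):
        raise ValueError("free energies must be finite")
    n_sub, n_mod = F.shape
    alpha = np.full(n_mod, alpha0)
    g = np.full((n_sub, n_mod), 1.0 / n_mod)
    for _ in range(max_iter):
        logu = F + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        g = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    xp = dirichlet_exceedance(alpha, n_draws=n_draws, seed=seed)
    return BMSResult(
        dirichlet_alpha=alpha,
        expected_frequency=alpha / alpha.sum(),
        exceedance_prob=xp,
        subject_posteriors=g,
    )
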