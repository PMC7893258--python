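"""Adaptive Metropolis-within-Gibbs sampling.

Both Bayesian models in this package (the glide-hydrodynamics fit and the
latent body-density fusion model) have posteriors with a modest number of
hyperparameters plus, in the fusion case, one conditionally independent
latent variable per whale.  A componentwise random-walk Metropolis sampler
with per-coordinate step-size adaptation during burn-in handles both well:
hyperparameters are updated one at a time against the full posterior, and
the latent block is updated elementwise in a single vectorized sweep, which
is valid because the latents are mutually independent given the
hyperparameters.

Step sizes adapt toward ~44% acceptance (the optimal rate for
one-dimensional Gaussian targets) in batches during burn-in and are frozen
afterwards, so the post-burn-in chain is a valid Markov chain.  Everything
is driven by a single numpy Generator, so runs are reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

TARGET_ACCEPT = 0.44
ADAPT_BATCH = 50


@dataclass
class McmcConfig:
    """Chain settings: 3 chains of 20 000 iterations, 50% burn-in by default."""

    n_iter: int = 20_000
    burn_frac: float = 0.5
    n_chains: int = 3
    thin: int = 1
    rhat_threshold: float = 1.05

    @property
    def n_burn(self) -> int:
        return int(self.n_iter * self.burn_frac)


@dataclass
class McmcResult:
    """Posterior draws with convergence diagnostics.

    ``draws`` has shape (n_chains, n_kept, dim).  ``rhat`` and ``ess`` are
    per-dimension; ``converged`` is the max-R-hat test at the configured
    threshold.
    """

    draws: np.ndarray
    names: list
    rhat: np.ndarray
    ess: np.ndarray
    accept_rate: np.ndarray
    rhat_threshold: float

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    @property
    def converged(self) -> bool:
        finite = self.rhat[np.isfinite(self.rhat)]
        return bool(finite.size == 0 or np.max(finite) < self.rhat_threshold)


def _split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction factor per dimension."""
    c, n, d = chains.shape
    half = n // 2
    x = chains[:, : 2 * half].reshape(c * 2, half, d)
    m, nn = x.shape[0], x.shape[1]
    chain_means = x.mean(axis=1)
    chain_vars = x.var(axis=1, ddof=1)
    w = chain_vars.mean(axis=0)
    b = nn * chain_means.var(axis=0, ddof=1)
    var_plus = (nn - 1) / nn * w + b / nn
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / w)
    # constant dimensions (e.g. fixed parameters) are trivially converged
    rhat[w <= 1e-300] = 1.0
    return rhat


def _ess(chains: np.ndarray) -> np.ndarray:
    """Crude effective sample size from lag-autocorrelation (per dimension)."""
    c, n, d = chains.shape
    out = np.empty(d)
    for j in range(d):
        x = chains[:, :, j]
        x = x - x.mean(axis=1, keepdims=True)
        var = x.var(axis=1).mean()
        if var <= 1e-300:
            out[j] = c * n
            continue
        rho_sum = 0.0
        for lag in range(1, min(n - 1, 200)):
            acov = np.mean(x[:, :-lag] * x[:, lag:])
            rho = acov / var
            if rho < 0.05:
                break
            rho_sum += rho
        out[j] = c * n / (1.0 + 2.0 * rho_sum)
    return out


def summarize(result: "McmcResult") -> "pd.DataFrame":
    """Posterior mean, sd, 95% credible interval, ESS and R-hat per parameter."""
    import pandas as pd

    flat = result.flat
    lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "parameter": result.names,
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1),
            "ci_lo": lo,
            "ci_hi": hi,
            "ess": result.ess,
            "rhat": result.rhat,
        }
    )


def run_mwg(
    logpost: Callable[[np.ndarray], float],
    x0: np.ndarray,
    *,
    rng: np.random.Generator,
    config: McmcConfig | None = None,
    step0: np.ndarray | None = None,
    lower: np.ndarray | None = None,
    upper: np.ndarray | None = None,
    names: list | None = None,
    latent_slice: slice | None = None,
    latent_logdens: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    block_slice: slice | None = None,
    jitter: float = 0.1,
) -> McmcResult:
    """Sample a posterior with componentwise adaptive random-walk Metropolis.

    Parameters
    ----------
    logpost : callable
        Full log posterior density of the flat parameter vector; may return
        -inf outside the support.
    x0 : array
        Initial point (must have finite log posterior).
    latent_slice, latent_logdens : optional
        If given, coordinates in ``latent_slice`` are treated as a block of
        mutually conditionally independent latents: ``latent_logdens(x, v)``
        must return the vector of per-latent conditional log densities when
        the latent block is set to ``v``.  They are then proposed and
        accepted elementwise in one vectorized sweep per iteration.
    block_slice : optional
        Coordinates proposed jointly (in addition to their componentwise
        updates) from a multivariate normal whose covariance is adapted to
        the burn-in draws -- the standard remedy when a few coordinates
        (e.g. collinear regression coefficients) are strongly correlated.
    jitter : float
        Relative overdispersion of chain starting points (scaled by step0).
    """
    cfg = config or McmcConfig()
    x0 = np.asarray(x0, dtype=float)
    dim = x0.size
    if step0 is None:
        step0 = np.maximum(np.abs(x0) * 0.1, 1e-3)
    step0 = np.broadcast_to(np.asarray(step0, dtype=float), (dim,)).copy()
    lo = np.full(dim, -np.inf) if lower is None else np.asarray(lower, dtype=float)
    hi = np.full(dim, np.inf) if upper is None else np.asarray(upper, dtype=float)

    if not np.isfinite(logpost(x0)):
        raise ValueError("initial point has non-finite log posterior")

    lat_idx = np.arange(dim)[latent_slice] if latent_slice is not None else np.array([], int)
    hyper_idx = np.setdiff1d(np.arange(dim), lat_idx)

    n_keep = (cfg.n_iter - cfg.n_burn) // cfg.thin
    draws = np.empty((cfg.n_chains, n_keep, dim))
    acc_all = np.zeros((cfg.n_chains, dim))

    for chain in range(cfg.n_chains):
        x = x0 + jitter * step0 * rng.standard_normal(dim)
        bad = (x <= lo) | (x >= hi)
        x[bad] = x0[bad]
        lp = logpost(x)
        if not np.isfinite(lp):
            x = x0.copy()
            lp = logpost(x)
        step = step0.copy()
        log_step = np.log(step)
        acc_batch = np.zeros(dim)
        acc_total = np.zeros(dim)
        n_total = 0
        kept = 0
        blk_idx = np.arange(dim)[block_slice] if block_slice is not None else np.array([], int)
        if blk_idx.size:
            blk_hist = np.empty((cfg.n_burn, blk_idx.size))
            blk_chol = np.diag(step0[blk_idx])
            blk_logscale = np.log(2.38 / np.sqrt(blk_idx.size))
            blk_acc_batch = 0
        for it in range(cfg.n_iter):
            # hyperparameters: one-at-a-time random walk
            for i in hyper_idx:
                prop = x[i] + step[i] * rng.standard_normal()
                if prop <= lo[i] or prop >= hi[i]:
                    continue
                x_new = x.copy()
                x_new[i] = prop
                lp_new = logpost(x_new)
                if np.log(rng.random()) < lp_new - lp:
                    x, lp = x_new, lp_new
                    acc_batch[i] += 1
                    acc_total[i] += 1
            # correlated block: joint adaptive-covariance Metropolis move
            if blk_idx.size:
                prop = x.copy()
                prop[blk_idx] = x[blk_idx] + np.exp(blk_logscale) * (
                    blk_chol @ rng.standard_normal(blk_idx.size)
                )
                if np.all(prop[blk_idx] > lo[blk_idx]) and np.all(prop[blk_idx] < hi[blk_idx]):
                    lp_new = logpost(prop)
                    if np.log(rng.random()) < lp_new - lp:
                        x, lp = prop, lp_new
                        blk_acc_batch += 1
                if it < cfg.n_burn:
                    blk_hist[it] = x[blk_idx]
                    if (it + 1) % ADAPT_BATCH == 0:
                        rate = blk_acc_batch / ADAPT_BATCH
                        delta = min(0.25, 2.0 / np.sqrt((it + 1) / ADAPT_BATCH))
                        blk_logscale += delta * np.sign(rate - 0.23)
                        blk_acc_batch = 0
                        if it + 1 >= 10 * blk_idx.size:
                            cov = np.cov(blk_hist[it // 2 : it + 1].T)
                            cov += 1e-12 * np.eye(blk_idx.size)
                            try:
                                blk_chol = np.linalg.cholesky(cov)
                            except np.linalg.LinAlgError:
                                pass
            # latent block: vectorized elementwise Metropolis
            if lat_idx.size:
                cur = x[lat_idx]
                prop = cur + step[lat_idx] * rng.standard_normal(lat_idx.size)
                ok = (prop > lo[lat_idx]) & (prop < hi[lat_idx])
                prop = np.where(ok, prop, cur)
                ld_cur = latent_logdens(x, cur)
                ld_new = latent_logdens(x, prop)
                accept = ok & (np.log(rng.random(lat_idx.size)) < ld_new - ld_cur)
                if np.any(accept):
                    cur = np.where(accept, prop, cur)
                    x[lat_idx] = cur
                    lp = logpost(x)
                acc_batch[lat_idx] += accept
                acc_total[lat_idx] += accept
            n_total += 1
            # step adaptation during burn-in only
            if it < cfg.n_burn and (it + 1) % ADAPT_BATCH == 0:
                rate = acc_batch / ADAPT_BATCH
                delta = min(0.25, 2.0 / np.sqrt((it + 1) / ADAPT_BATCH))
                log_step += delta * np.sign(rate - TARGET_ACCEPT)
                step = np.exp(log_step)
                acc_batch[:] = 0.0
            if it >= cfg.n_burn and (it - cfg.n_burn) % cfg.thin == 0 and kept < n_keep:
                draws[chain, kept] = x
                kept += 1
        acc_all[chain] = acc_total / max(n_total, 1)

    rhat = _split_rhat(draws)
    ess = _ess(draws)
    return McmcResult(
        draws=draws,
        names=list(names) if names is not None else [f"x{i}" for i in range(dim)],
        rhat=rhat,
        ess=ess,
        accept_rate=acc_all.mean(axis=0),
        rhat_threshold=cfg.rhat_threshold,
    )
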