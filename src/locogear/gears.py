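"""Gear (mode-of-motion) decomposition of the log max-SD distribution.

Exploring rats show a bimodal distribution of episode maximal speeds on the
log10 scale: a slow "first gear" centered near 0.71 (~5.1 cm/s) and a fast
"second gear" near 1.24 (~17.4 cm/s).  A two-component Gaussian mixture is
fitted to characterize the modes; gear *assignment*, however, uses the fixed
10 cm/s (log10 = 1) threshold, because mixture fits become unstable when the
second mode flattens (as it does after dopaminergic lesioning).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde, norm

from .io import PipelineConfig
from .segment import MotionEpisode

__all__ = ["GearModel", "log_max_sd_density", "fit_gear_mixture", "assign_gears"]


@dataclass
class GearModel:
    """Two-component Gaussian mixture over log max-SD values."""

    weights: tuple
    means: tuple
    sds: tuple
    log_likelihood: float
    converged: bool
    n_values: int
    separation_log: float = 1.0

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")


def log_max_sd_density(values, bandwidth: float | None = None, grid=None,
                       config: PipelineConfig | None = None, n_grid: int = 512):
    """Kernel-smoothed density of log max-SD values on a fixed grid.

    The grid spans [log10(vnoise), log10(vmax)] by default and the curve is
    renormalized to integrate to 1 (trapezoid) on that grid.  Bandwidth
    defaults to Silverman's rule; an explicit ``bandwidth`` is interpreted in
    data units (log10 cm/s).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for a density estimate")
    if grid is None:
        cfg = config or PipelineConfig()
        grid = np.linspace(np.log10(cfg.vnoise_cms), np.log10(cfg.vmax_cms), n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
    if bandwidth is None:
        kde = gaussian_kde(values, bw_method="silverman")
    else:
        sd = values.std(ddof=1)
        if sd == 0:
            # all values equal: fall back to a normal bump of the given width
            dens = norm.pdf(grid, loc=values[0], scale=bandwidth)
            dens /= np.trapezoid(dens, grid)
            return grid, dens
        kde = gaussian_kde(values, bw_method=bandwidth / sd)
    dens = kde(grid)
    area = np.trapezoid(dens, grid)
    if area <= 0:
        raise ValueError("density integrates to zero on the requested grid")
    return grid, dens / area


def _em_once(x: np.ndarray, mu: np.ndarray, sd: np.ndarray, w: np.ndarray,
             tol: float, max_iter: int, min_sd: float = 1e-4):
    """One EM run; returns (params, ll, converged) or None if degenerate."""
    n = x.size
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        # E step in log space
        logp = np.log(w)[:, None] + norm.logpdf(x[None, :], mu[:, None], sd[:, None])
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        ll = float(lse.sum())
        r = np.exp(logp - lse)  # responsibilities, shape (k, n)
        # M step
        nk = r.sum(axis=1)
        if np.any(nk < 1e-12):
            return None
        w = nk / n
        mu = (r @ x) / nk
        var = (r @ (x**2)) / nk - mu**2
        sd = np.sqrt(np.maximum(var, 0.0))
        if np.any(sd < min_sd):
            return None
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            converged = True
            break
        ll_old = ll
    return (w, mu, sd), ll, converged


def fit_gear_mixture(log_values, n_components: int = 2, n_starts: int = 10,
                     tol: float = 1e-8, max_iter: int = 500, seed: int = 0) -> GearModel:
    """Fit a Gaussian mixture to log max-SD values by EM with restarts.

    The best log-likelihood over ``n_starts`` random initializations is kept;
    components are reported in ascending mean order.  Runs whose component
    standard deviation collapses below 1e-4 are discarded as degenerate; if
    every restart degenerates or fails to converge, a moment-matched result
    flagged ``converged=False`` is returned (no exception), mirroring the
    instability seen on flattened post-lesion distributions.
    """
    x = np.asarray(log_values, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 values to fit a gear mixture")
    rng = np.random.default_rng(seed)
    gsd = max(float(x.std(ddof=1)), 1e-3)
    best = None
    best_ll = -np.inf
    any_converged = False
    for _ in range(n_starts):
        mu0 = rng.choice(x, size=n_components, replace=False) + rng.normal(0, 0.05 * gsd, n_components)
        sd0 = np.full(n_components, gsd * rng.uniform(0.3, 1.0))
        w0 = np.full(n_components, 1.0 / n_components)
        res = _em_once(x, mu0.astype(float), sd0, w0, tol, max_iter)
        if res is None:
            continue
        (w, mu, sd), ll, conv = res
        any_converged = any_converged or conv
        if ll > best_ll:
            best_ll = ll
            best = (w, mu, sd)
    if best is None:
        # all restarts degenerate: moment-matched fallback, flagged
        m, s = float(x.mean()), float(max(x.std(ddof=1), 1e-3))
        return GearModel(weights=(0.5, 0.5), means=(m, m), sds=(s, s),
                         log_likelihood=float("nan"), converged=False, n_values=int(x.size))
    w, mu, sd = best
    order = np.argsort(mu)
    return GearModel(
        weights=tuple(float(v) for v in w[order]),
        means=tuple(float(v) for v in mu[order]),
        sds=tuple(float(v) for v in sd[order]),
        log_likelihood=best_ll,
        converged=bool(any_converged),
        n_values=int(x.size),
    )


def assign_gears(episodes: list[MotionEpisode], config: PipelineConfig) -> list[MotionEpisode]:
    """Label each episode: gear 2 iff max speed >= threshold (inclusive), else 1.

    The mixture model is characterization-only; assignment is always this
    deterministic threshold.
    """
    out = []
    for e in episodes:
        g = 2 if e.max_speed_cms >= config.gear_threshold_cms else 1
        out.append(MotionEpisode(**{**e.__dict__, "gear": g}))
    return out
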