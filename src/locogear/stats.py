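"""Group comparisons, FDR control and bootstrap correlation analysis.

The descriptive family is 48 Wilcoxon rank-sum comparisons (2 groups x 6
endpoints x 4 session contrasts); the regression family is 55 bootstrap
correlations over the 10 variables {SNc count, VTA count, LI, weight
reduction, 6 endpoints} (all unordered pairs including self-pairs, i.e. the
lower triangle of the 10 x 10 matrix).  Benjamini-Hochberg adjustment is
applied within each family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "BootstrapResult",
    "rank_sum_test",
    "bh_fdr",
    "bootstrap_correlation",
    "comparison_family",
    "SESSIONS",
    "CONTRASTS",
    "ENDPOINT_NAMES",
    "REGRESSION_VARS",
]

SESSIONS = ("pre", "post12", "post28")

# session contrasts: pre vs pooled post, pre vs each post, early vs late post
CONTRASTS = (
    ("pre_vs_post", ("pre",), ("post12", "post28")),
    ("pre_vs_post12", ("pre",), ("post12",)),
    ("pre_vs_post28", ("pre",), ("post28",)),
    ("post12_vs_post28", ("post12",), ("post28",)),
)

ENDPOINT_NAMES = (
    "incidence2_pct",
    "distance_m",
    "mean_max_speed_cms",
    "mean_dwell_s",
    "mean_spread_cm",
    "mean_curvature_pct",
)

REGRESSION_VARS = ("snc", "vta", "li", "weight_reduction_pct") + ENDPOINT_NAMES


@dataclass
class ComparisonResult:
    label: str
    statistic: float  # rank sum of the first sample (midranks)
    p_raw: float
    p_fdr: float | None
    n1: int
    n2: int
    method: str = ""


@dataclass
class BootstrapResult:
    label: str
    r_observed: float
    p_boot: float
    n_iter: int
    seed: int
    n: int
    ci_low: float
    ci_high: float
    p_fdr: float | None = None


def rank_sum_test(sample_a, sample_b, alternative: str = "two-sided") -> ComparisonResult:
    """Wilcoxon rank-sum test with midranks for ties.

    The exact null distribution is used when n1 + n2 <= 12 and there are no
    ties; otherwise the normal approximation with tie and continuity
    correction.  The reported statistic is the rank sum of ``sample_a``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= 12 and not has_ties:
        method = "exact"
        res = sps.mannwhitneyu(a, b, alternative=alternative, method="exact")
    else:
        method = "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative=alternative, method="asymptotic",
                               use_continuity=True)
    return ComparisonResult(label="", statistic=w, p_raw=float(res.pvalue),
                            p_fdr=None, n1=int(a.size), n2=int(b.size), method=method)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bootstrap_correlation(x, y, n_iter: int = 5000, seed: int = 0,
                          statistic: str = "correlation") -> BootstrapResult:
    """Bootstrap significance of a product-moment correlation (or slope).

    Pairs are resampled with replacement ``n_iter`` times; the two-sided
    p value is the sign-crossing rule 2 * min(frac(r* <= 0), frac(r* >= 0)),
    capped at 1.  Degenerate resamples (zero variance in either coordinate)
    are redrawn.  A 95% percentile interval is reported alongside.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in input")
    if statistic not in ("correlation", "slope"):
        raise ValueError("statistic must be 'correlation' or 'slope'")

    def _stat(xi, yi):
        if statistic == "correlation":
            return float(np.corrcoef(xi, yi)[0, 1])
        return float(np.cov(xi, yi, ddof=1)[0, 1] / np.var(xi, ddof=1))

    def _stat_rows(xs, ys):
        sx = xs.sum(axis=1)
        sy = ys.sum(axis=1)
        sxx = (xs * xs).sum(axis=1)
        syy = (ys * ys).sum(axis=1)
        sxy = (xs * ys).sum(axis=1)
        vx = n * sxx - sx * sx
        vy = n * syy - sy * sy
        cov = n * sxy - sx * sy
        with np.errstate(invalid="ignore", divide="ignore"):
            if statistic == "correlation":
                return cov / np.sqrt(vx * vy), (vx <= 0) | (vy <= 0)
            return cov / vx, (vx <= 0) | (vy <= 0)

    r_obs = _stat(x, y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, (n_iter, n))
    rstars, bad = _stat_rows(x[idx], y[idx])
    while bad.any():  # degenerate resamples are redrawn
        idx = rng.integers(0, n, (int(bad.sum()), n))
        rstars[bad], bad[bad] = _stat_rows(x[idx], y[idx])
    p = 2.0 * min(float(np.mean(rstars <= 0)), float(np.mean(rstars >= 0)))
    lo, hi = np.percentile(rstars, [2.5, 97.5])
    return BootstrapResult(label="", r_observed=r_obs, p_boot=min(p, 1.0),
                           n_iter=n_iter, seed=seed, n=n,
                           ci_low=float(lo), ci_high=float(hi))


def _expected_family_sizes(n_groups: int, n_endpoints: int, n_vars: int):
    return n_groups * n_endpoints * len(CONTRASTS), n_vars * (n_vars + 1) // 2


def comparison_family(endpoint_table: pd.DataFrame,
                      regression_table: pd.DataFrame | None = None,
                      endpoints=ENDPOINT_NAMES,
                      regression_vars=REGRESSION_VARS,
                      n_iter: int = 5000, seed: int = 0,
                      drop_self_pairs: bool = False):
    """Build the study's two statistical families with within-family FDR.

    ``endpoint_table``: long per-recording table with columns ``animal``,
    ``group``, ``session`` (pre/post12/post28) and one column per endpoint.
    ``regression_table``: one row per lesioned animal with the 10 regression
    variables.  Family sizes are derived from the design and asserted: the
    default design yields 48 comparisons and 55 regressions (self-pairs make
    up the matrix diagonal and are degenerate by construction; set
    ``drop_self_pairs=True`` for the 45 off-diagonal pairs only).

    Returns a dict with ``comparisons`` and (if requested) ``regressions``
    DataFrames carrying raw and FDR-adjusted p values.
    """
    required = {"animal", "group", "session"} | set(endpoints)
    missing = required - set(endpoint_table.columns)
    if missing:
        raise ValueError(f"endpoint table missing columns: {sorted(missing)}")
    bad = set(endpoint_table["session"]) - set(SESSIONS)
    if bad:
        raise ValueError(f"unknown session labels: {sorted(bad)}")
    groups = sorted(set(endpoint_table["group"]))

    rows = []
    for group in groups:
        sub = endpoint_table[endpoint_table["group"] == group]
        for ep in endpoints:
            for cname, sess_a, sess_b in CONTRASTS:
                va = sub[sub["session"].isin(sess_a)][ep].dropna().to_numpy()
                vb = sub[sub["session"].isin(sess_b)][ep].dropna().to_numpy()
                res = rank_sum_test(va, vb)
                res.label = f"{group}:{ep}:{cname}"
                rows.append(res)
    n_expected, _ = _expected_family_sizes(len(groups), len(endpoints), len(regression_vars))
    if len(rows) != n_expected:
        raise AssertionError(f"built {len(rows)} comparisons, expected {n_expected}")
    comp = pd.DataFrame({
        "label": [r.label for r in rows],
        "statistic": [r.statistic for r in rows],
        "p_raw": [r.p_raw for r in rows],
        "n1": [r.n1 for r in rows],
        "n2": [r.n2 for r in rows],
        "method": [r.method for r in rows],
    })
    comp["p_fdr"] = bh_fdr(comp["p_raw"].to_numpy())
    out = {"comparisons": comp}

    if regression_table is not None:
        missing = set(regression_vars) - set(regression_table.columns)
        if missing:
            raise ValueError(f"regression table missing columns: {sorted(missing)}")
        pairs = list(itertools.combinations_with_replacement(regression_vars, 2))
        _, n_reg_expected = _expected_family_sizes(len(groups), len(endpoints), len(regression_vars))
        if len(pairs) != n_reg_expected:
            raise AssertionError(f"built {len(pairs)} regressions, expected {n_reg_expected}")
        if drop_self_pairs:
            pairs = [(u, v) for u, v in pairs if u != v]
        regs = []
        for k, (u, v) in enumerate(pairs):
            xa = regression_table[u].to_numpy(dtype=float)
            ya = regression_table[v].to_numpy(dtype=float)
            ok = ~(np.isnan(xa) | np.isnan(ya))
            res = bootstrap_correlation(xa[ok], ya[ok], n_iter=n_iter, seed=seed + k)
            res.label = f"{u}~{v}"
            regs.append(res)
        reg = pd.DataFrame({
            "label": [r.label for r in regs],
            "r": [r.r_observed for r in regs],
            "p_raw": [r.p_boot for r in regs],
            "n": [r.n for r in regs],
            "ci_low": [r.ci_low for r in regs],
            "ci_high": [r.ci_high for r in regs],
            "self_pair": [r.label.split("~")[0] == r.label.split("~")[1] for r in regs],
        })
        reg["p_fdr"] = bh_fdr(reg["p_raw"].to_numpy())
        out["regressions"] = reg
    return out
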