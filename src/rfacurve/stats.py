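"""Statistical battery for per-sample performance indices.

Covers the analyses applied to the ex vivo cohort: Shapiro-Wilk normality
and Levene (Brown-Forsythe) homogeneity checks, one-way ANOVA across the
five study arms with Tukey HSD post hoc comparisons, a 2x2 two-way ANOVA
(solution type x temperature level, radiofrequency-only control excluded
from the factorial and reported as a standalone reference level),
bias-corrected and accelerated (BCa) bootstrap confidence intervals,
Spearman rank correlation between indices and ablation volume, Tukey-fence
outlier flagging, and estimated marginal means with parametric or
bootstrap intervals.

Alpha is 0.05 throughout unless a caller overrides it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps

from .errors import DegenerateInputError

__all__ = [
    "TestResult",
    "BootstrapCI",
    "shapiro_wilk",
    "levene",
    "one_way_anova",
    "two_way_anova",
    "tukey_hsd",
    "bca_bootstrap_ci",
    "spearman_correlation",
    "flag_outliers",
    "marginal_means",
]

FACTORIAL_GROUPS = ("SALINE23", "SALINE5", "DEI23", "DEI5")


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")


@dataclass
class BootstrapCI:
    estimate: float
    ci_low: float
    ci_high: float
    method: str = "bca"  # "percentile" after a degenerate fallback
    degenerate: bool = False


def _clean(values) -> np.ndarray:
    a = np.asarray(values, dtype=float).ravel()
    if np.any(np.isnan(a)):
        raise DegenerateInputError("input contains NaN")
    return a


def shapiro_wilk(values) -> TestResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000, non-constant input)."""
    a = _clean(values)
    if not (3 <= len(a) <= 5000):
        raise DegenerateInputError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {len(a)}")
    if np.ptp(a) == 0:
        raise DegenerateInputError("constant sample: normality test undefined")
    w, p = sps.shapiro(a)
    return TestResult("shapiro_wilk", float(w), float(p), {"n": len(a)})


def levene(groups, center: str = "median") -> TestResult:
    """Levene homogeneity-of-variance test.

    Default centering is the median (Brown-Forsythe variant), the default
    of the standard R routine the study used.
    """
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    gs = [_clean(g) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise DegenerateInputError("Levene needs >= 2 groups with >= 2 values each")
    if all(np.ptp(g) == 0 for g in gs):
        raise DegenerateInputError("all groups constant: spread test undefined")
    stat, p = sps.levene(*gs, center=center)
    return TestResult(
        "levene", float(stat), float(p), {"center": center, "k": len(gs)}
    )


def one_way_anova(values, group) -> TestResult:
    """Classical one-way ANOVA via the between/within sum-of-squares
    decomposition."""
    a = _clean(values)
    g = np.asarray(group)
    if a.shape != g.shape:
        raise ValueError("values and group must align")
    levels, inverse = np.unique(g, return_inverse=True)
    k = len(levels)
    n = len(a)
    if k < 2:
        raise DegenerateInputError("one-way ANOVA needs >= 2 levels")
    if n <= k:
        raise DegenerateInputError("one-way ANOVA needs n > number of levels")
    counts = np.bincount(inverse)
    if np.any(counts == 0):
        raise DegenerateInputError("empty level after filtering")
    grand = a.mean()
    means = np.array([a[inverse == i].mean() for i in range(k)])
    ss_between = float(np.sum(counts * (means - grand) ** 2))
    ss_within = float(np.sum((a - means[inverse]) ** 2))
    df_b, df_w = k - 1, n - k
    if ss_within == 0:
        raise DegenerateInputError("zero within-group variance")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return TestResult(
        "one_way_anova",
        float(f),
        p,
        {
            "df_between": df_b,
            "df_within": df_w,
            "ss_between": ss_between,
            "ss_within": ss_within,
            "levels": [str(x) for x in levels],
            "group_sizes": counts.tolist(),
        },
    )


def two_way_anova(values, solution, temperature) -> dict[str, TestResult]:
    """Two-factor ANOVA with interaction on the 2x2 crossed design.

    Intended for the four treated arms (saline/deionized x ambient/
    refrigerated); rows whose factor level is ``"none"`` (the
    radiofrequency-only control, which has neither a solution nor a
    solution temperature) are excluded before fitting.  Balanced designs
    use the classical sequential sum-of-squares decomposition, which
    coincides with every ANOVA type when cell sizes are equal.
    """
    a = _clean(values)
    sol = np.asarray(solution).astype(str)
    temp = np.asarray(temperature).astype(str)
    keep = (sol != "none") & (temp != "none")
    a, sol, temp = a[keep], sol[keep], temp[keep]
    sol_levels, si = np.unique(sol, return_inverse=True)
    temp_levels, ti = np.unique(temp, return_inverse=True)
    if len(sol_levels) != 2 or len(temp_levels) != 2:
        raise DegenerateInputError("two-way ANOVA expects 2 levels per factor")
    cell_n = np.zeros((2, 2), dtype=int)
    for i, j in zip(si, ti):
        cell_n[i, j] += 1
    if np.any(cell_n == 0):
        raise DegenerateInputError("empty cell in the 2x2 design")

    n = len(a)
    grand = a.mean()
    cell_mean = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            cell_mean[i, j] = a[(si == i) & (ti == j)].mean()
    sol_mean = np.array([a[si == i].mean() for i in range(2)])
    temp_mean = np.array([a[ti == j].mean() for j in range(2)])

    n_sol = np.array([np.sum(si == i) for i in range(2)])
    n_temp = np.array([np.sum(ti == j) for j in range(2)])
    ss_sol = float(np.sum(n_sol * (sol_mean - grand) ** 2))
    ss_temp = float(np.sum(n_temp * (temp_mean - grand) ** 2))
    ss_cells = float(np.sum(cell_n * (cell_mean - grand) ** 2))
    ss_inter = ss_cells - ss_sol - ss_temp
    ss_err = float(np.sum((a - cell_mean[si, ti]) ** 2))
    df_err = n - 4
    if df_err <= 0 or ss_err == 0:
        raise DegenerateInputError("no residual degrees of freedom")
    mse = ss_err / df_err

    out = {}
    for name, ss, df in (
        ("solution", ss_sol, 1),
        ("temperature", ss_temp, 1),
        ("interaction", ss_inter, 1),
    ):
        f = max(ss, 0.0) / df / mse
        out[name] = TestResult(
            f"two_way_anova_{name}",
            float(f),
            float(sps.f.sf(f, df, df_err)),
            {"ss": ss, "df": df, "df_error": df_err, "mse": mse},
        )
    return out


def tukey_hsd(values, group, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise mean comparisons with studentized-range adjustment.

    Returns rows ``(level_a, level_b, mean_diff, adjusted_p, ci_low,
    ci_high)`` with simultaneous confidence level ``1 - alpha``.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    one_way_anova(values, group)  # shared preconditions
    a = _clean(values)
    g = np.asarray(group)
    levels = [str(x) for x in np.unique(g)]
    samples = [a[g == lv] for lv in np.unique(g)]
    res = sps.tukey_hsd(*samples)
    ci = res.confidence_interval(confidence_level=1.0 - alpha)
    rows = []
    for i, j in itertools.combinations(range(len(levels)), 2):
        rows.append(
            {
                "level_a": levels[i],
                "level_b": levels[j],
                "mean_diff": float(samples[i].mean() - samples[j].mean()),
                "adjusted_p": float(res.pvalue[i, j]),
                "ci_low": float(ci.low[i, j]),
                "ci_high": float(ci.high[i, j]),
            }
        )
    return pd.DataFrame(rows)


def _bootstrap_statistics(rng, a, statistic, B):
    idx = rng.integers(0, len(a), size=(B, len(a)))
    try:
        return np.asarray(statistic(a[idx], axis=1), dtype=float)
    except TypeError:
        return np.array([float(statistic(a[row])) for row in idx])


def bca_bootstrap_ci(
    values,
    statistic=np.mean,
    B: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> BootstrapCI:
    """Bias-corrected and accelerated (BCa) bootstrap confidence interval.

    The bias term z0 comes from the fraction of bootstrap replicates below
    the point estimate; the acceleration from the jackknife skewness of
    the statistic.  When the bootstrap distribution is degenerate (zero
    spread) the interval falls back to the percentile method and is
    flagged.  Reproducible for a fixed seed.
    """
    a = _clean(values)
    if len(a) < 5:
        raise DegenerateInputError("bootstrap needs n >= 5")
    if B < 200:
        raise ValueError("B must be >= 200")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    est = float(statistic(a))
    boot = _bootstrap_statistics(rng, a, statistic, B)
    alpha = 1.0 - level
    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)

    prop_below = np.mean(boot < est) + 0.5 * np.mean(boot == est)
    if np.ptp(boot) == 0 or prop_below <= 0.0 or prop_below >= 1.0:
        lo, hi = np.percentile(boot, [lo_q, hi_q])
        return BootstrapCI(est, float(lo), float(hi), "percentile", True)

    z0 = sps.norm.ppf(prop_below)
    n = len(a)
    jack = np.array(
        [float(statistic(np.delete(a, i))) for i in range(n)]
    )
    d = jack.mean() - jack
    denom = np.sum(d**2) ** 1.5
    accel = np.sum(d**3) / (6.0 * denom) if denom > 0 else 0.0

    z_lo, z_hi = sps.norm.ppf([alpha / 2, 1 - alpha / 2])
    a1 = sps.norm.cdf(z0 + (z0 + z_lo) / (1 - accel * (z0 + z_lo)))
    a2 = sps.norm.cdf(z0 + (z0 + z_hi) / (1 - accel * (z0 + z_hi)))
    lo, hi = np.percentile(boot, [100 * a1, 100 * a2])
    return BootstrapCI(est, float(lo), float(hi), "bca", False)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx_c = rx - rx.mean()
    denom_x = np.sqrt(np.sum(rx_c**2))
    perms = np.array(list(itertools.permutations(ry)))
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom_y = np.sqrt(np.sum(pc[0] ** 2))
    rhos = pc @ rx_c / (denom_x * denom_y)
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    The two-sided p-value uses the t approximation except for n <= 9,
    where the exact permutation distribution is enumerated.
    """
    xa, ya = _clean(x), _clean(y)
    if len(xa) != len(ya):
        raise ValueError("x and y must be paired")
    if len(xa) < 4:
        raise DegenerateInputError("Spearman needs n >= 4")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DegenerateInputError("constant vector: correlation undefined")
    rho, p = sps.spearmanr(xa, ya)
    rho = float(rho)
    if len(xa) <= 9:
        p = _spearman_exact_p(xa, ya, rho)
    elif abs(rho) == 1.0:
        p = 0.0
    return rho, float(p)


def flag_outliers(values) -> np.ndarray:
    """Tukey-fence outlier mask: outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation; with IQR = 0 the fences collapse
    onto the common value and nothing is flagged.
    """
    a = _clean(values)
    if len(a) < 4:
        raise DegenerateInputError("outlier fencing needs n >= 4")
    q1, q3 = np.percentile(a, [25, 75])
    iqr = q3 - q1
    return (a < q1 - 1.5 * iqr) | (a > q3 + 1.5 * iqr)


def marginal_means(
    samples: pd.DataFrame,
    grouping: str = "group",
    value_col: str = "value",
    ci_method: str = "parametric",
    level: float = 0.95,
    B: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-level means with 95% (by default) confidence intervals.

    ``grouping`` is ``"group"``, ``"solution"`` or ``"temperature"``.  In
    factor-wise summaries the radiofrequency-only control (factor level
    ``"none"``) is always reported as its own ``PURERF`` reference level
    rather than folded into a factor it does not possess.  ``ci_method``
    is ``"parametric"`` (t interval) or ``"bca_bootstrap"``.
    """
    if grouping not in ("group", "solution", "temperature"):
        raise ValueError("grouping must be group, solution or temperature")
    if ci_method not in ("parametric", "bca_bootstrap"):
        raise ValueError("ci_method must be parametric or bca_bootstrap")
    labels = samples[grouping].astype(str).replace({"none": "PURERF"})
    rows = []
    for i, lv in enumerate(sorted(labels.unique())):
        vals = _clean(samples.loc[labels == lv, value_col])
        n = len(vals)
        if n < 2:
            raise DegenerateInputError(f"level {lv!r} has n < 2")
        mean = float(vals.mean())
        if ci_method == "parametric":
            se = vals.std(ddof=1) / np.sqrt(n)
            tq = sps.t.ppf(0.5 + level / 2, n - 1)
            lo, hi = mean - tq * se, mean + tq * se
        else:
            ci = bca_bootstrap_ci(
                vals, np.mean, B=B, level=level,
                seed=None if seed is None else seed + i,
            )
            lo, hi = ci.ci_low, ci.ci_high
        rows.append(
            {
                "level": lv,
                "mean": mean,
                "ci_low": float(min(lo, mean)),
                "ci_high": float(max(hi, mean)),
                "n": n,
                "method": ci_method,
            }
        )
    return pd.DataFrame(rows)
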