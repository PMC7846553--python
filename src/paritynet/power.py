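"""Power and critical-value calibration for the study's test battery.

Covers the four calibration computations the pipeline relies on: Welch
t-test power via the noncentral t distribution, the smallest Pearson
correlation detectable by a Fisher r-to-z test at a given power, a
Monte-Carlo power estimate for the Wilcoxon rank-sum test, and a
Shapiro-Wilk normality screen over a dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ExpressionDataset


@dataclass(frozen=True)
class PowerSpec:
    alpha: float = 0.05
    power_target: float = 0.8
    n1: int = 42
    n2: int = 71
    sided: str = "two"  # "one" or "two"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power_target < 1:
            raise ValueError("power_target must be in (0, 1)")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("group sizes must be positive")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")


def welch_df(sd1: float, sd2: float, n1: int, n2: int) -> float:
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    return (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))


def t_test_power(spec: PowerSpec, sd1: float, sd2: float, delta: float) -> float:
    """Power of the Welch two-sample t-test for a true mean difference
    ``delta``, via the noncentral t with Welch-Satterthwaite df."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    se = np.sqrt(sd1**2 / spec.n1 + sd2**2 / spec.n2)
    ncp = delta / se
    df = welch_df(sd1, sd2, spec.n1, spec.n2)
    if spec.sided == "two":
        tcrit = stats.t.ppf(1 - spec.alpha / 2, df)
        upper = stats.nct.sf(tcrit, df, ncp)
        lower = stats.nct.cdf(-tcrit, df, ncp)
        # scipy's noncentral t underflows to NaN in the far tail
        if not np.isfinite(lower):
            lower = 0.0
        if not np.isfinite(upper):
            upper = 1.0 if ncp > tcrit else 0.0
        return float(min(upper + lower, 1.0))
    tcrit = stats.t.ppf(1 - spec.alpha, df)
    return float(stats.nct.sf(tcrit, df, ncp))


def detectable_difference_coverage(
    ds: ExpressionDataset,
    relative_difference: float = 0.10,
    spec: PowerSpec | None = None,
) -> pd.DataFrame:
    """Per-probe Welch power to detect a mean shift of ``relative_difference``
    times the probe's reference-group mean, and the fraction of probes
    reaching the target power.

    Returns a frame with per-probe power plus a ``covered`` flag; the overall
    coverage is ``frame["covered"].mean()``.
    """
    if spec is None:
        spec = PowerSpec(n1=ds.group_size(ds.group1), n2=ds.group_size(ds.group2))
    a = ds.group_values(ds.group1)
    b = ds.group_values(ds.group2)
    sd1 = a.std(axis=1, ddof=1)
    sd2 = b.std(axis=1, ddof=1)
    delta = np.abs(a.mean(axis=1)) * relative_difference
    power = np.array(
        [
            t_test_power(spec, s1, s2, d) if s1 > 0 and s2 > 0 else np.nan
            for s1, s2, d in zip(sd1, sd2, delta)
        ]
    )
    return pd.DataFrame(
        {"power": power, "covered": power >= spec.power_target}, index=ds.probe_ids
    )


def fisher_z_power(rho: float, n: int, alpha: float, sided: str = "one") -> float:
    """Power of the Fisher-z test of H0: rho = 0 against true ``rho``."""
    if n <= 3:
        raise ValueError("need n > 3")
    z = np.arctanh(rho) * np.sqrt(n - 3)
    if sided == "one":
        return float(stats.norm.sf(stats.norm.ppf(1 - alpha) - z))
    za = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.sf(za - z) + stats.norm.cdf(-za - z))


def correlation_critical_value(
    n: int,
    alpha: float = 0.05,
    power: float = 0.8,
    sided: str = "one",
    denominator: str = "n-3",
) -> float:
    """Smallest correlation magnitude detectable by a Fisher-z test of zero
    correlation at the given level and power:

        rho* = tanh((z_alpha + z_power) / sqrt(n - 3)).

    ``denominator`` selects the variance convention: the standard ``"n-3"``
    or the cruder ``"n"``; they differ in the third decimal at these sample
    sizes.  One-sided is the default for this operation.
    """
    if n <= 3:
        raise ValueError("need n > 3")
    if denominator not in ("n-3", "n"):
        raise ValueError("denominator must be 'n-3' or 'n'")
    za = stats.norm.ppf(1 - alpha) if sided == "one" else stats.norm.ppf(1 - alpha / 2)
    zp = stats.norm.ppf(power)
    denom = np.sqrt(n - 3 if denominator == "n-3" else n)
    return float(np.tanh((za + zp) / denom))


_DISTRIBUTIONS = {
    "normal": lambda rng, p, size: rng.normal(p[0], p[1], size=size),
    "uniform": lambda rng, p, size: rng.uniform(p[0], p[1], size=size),
}


def wilcoxon_power_sim(
    dist1: tuple,
    dist2: tuple,
    n1: int,
    n2: int,
    alpha: float = 0.05,
    n_sims: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the two-sided Wilcoxon rank-sum test.

    ``dist1``/``dist2`` are ``("normal", mean, sd)`` or
    ``("uniform", low, high)`` specs.  Uses the normal approximation of the
    rank-sum statistic (midranks for ties), vectorized over simulations.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be at least 100")
    for d in (dist1, dist2):
        if d[0] not in _DISTRIBUTIONS or len(d) != 3:
            raise ValueError(f"invalid distribution spec {d!r}")
    rng = np.random.default_rng(seed)
    x = _DISTRIBUTIONS[dist1[0]](rng, dist1[1:], (n_sims, n1))
    y = _DISTRIBUTIONS[dist2[0]](rng, dist2[1:], (n_sims, n2))
    combined = np.concatenate([x, y], axis=1)
    ranks = stats.rankdata(combined, axis=1)
    w = ranks[:, :n1].sum(axis=1)
    n = n1 + n2
    mean_w = n1 * (n + 1) / 2
    # tie correction per simulation
    sorted_c = np.sort(combined, axis=1)
    ties = sorted_c[:, 1:] == sorted_c[:, :-1]
    # without heavy per-row tie bookkeeping, continuous inputs have no ties
    var_w = np.full(n_sims, n1 * n2 * (n + 1) / 12.0)
    if ties.any():
        for i in np.nonzero(ties.any(axis=1))[0]:
            _, counts = np.unique(sorted_c[i], return_counts=True)
            correction = (counts**3 - counts).sum() / (n * (n - 1))
            var_w[i] = n1 * n2 / 12.0 * (n + 1 - correction)
    z = (w - mean_w) / np.sqrt(var_w)
    pvals = 2 * stats.norm.sf(np.abs(z))
    return float((pvals < alpha).mean())


def normality_screen(ds: ExpressionDataset, alpha: float = 0.05) -> dict:
    """Shapiro-Wilk test per probe per group; reports the fraction of series
    not rejecting normality at ``alpha``.  Constant series are excluded and
    counted separately."""
    results = []
    excluded = 0
    for group in ds.group_order:
        m = ds.group_values(group)
        for row in m:
            if row.size < 3 or np.ptp(row) == 0:
                excluded += 1
                continue
            results.append(stats.shapiro(row).pvalue)
    pvals = np.array(results)
    return {
        "n_series": int(pvals.size),
        "n_excluded": excluded,
        "fraction_normal": float((pvals >= alpha).mean()) if pvals.size else np.nan,
    }
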