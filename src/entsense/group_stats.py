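"""Group comparisons with variance-gated test selection and effect sizes.

The comparison protocol for a (transgenic, control) pair of groups:

1. Brown–Forsythe (median-centered Levene) test of variance equality at
   alpha = 0.05.
2. Equal variances  -> two-sided Student t test; unequal -> two-sided
   Mann–Whitney U test (midrank tie handling).
3. Effect size: Cohen's d from the pooled SD, reported with the Hedges
   small-sample correction as g, when variances are equal; Glass's Δ
   (control-group SD in the denominator) when unequal.
4. 95% CI: noncentral-t inversion for d/g; seeded percentile bootstrap
   (10,000 resamples) for Glass's Δ.

Sign convention: effect = (mean_control − mean_transgenic)/SD, i.e.
negative when the transgenic group has the larger mean — matching the
negative confidence intervals reported for transgenic-vs-control
tangle and linear entropy.

Paired region comparisons (cortex vs hippocampus within a strain) use
the exact-distribution Wilcoxon signed-rank test, dropping zero
differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.optimize import brentq

__all__ = [
    "GroupComparison",
    "variance_gate",
    "effect_size",
    "hedges_correction",
    "effect_ci",
    "run_comparison",
    "region_paired_test",
    "significance_stars",
]

ALPHA_VARIANCE = 0.05


def _validate(a, b, min_n: int = 3):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < min_n or b.size < min_n:
        raise ValueError(f"each group needs at least {min_n} observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups must be finite")
    return a, b


def variance_gate(group_a, group_b, alpha: float = ALPHA_VARIANCE,
                  center: str = "median") -> tuple[str, float, float]:
    """Choose the comparison test from a variance-equality pretest.

    Returns ``(test_name, levene_stat, levene_p)`` where ``test_name``
    is ``"t-test"`` when the Brown–Forsythe p-value is >= alpha (or both
    groups are degenerate), else ``"mann-whitney"``.
    """
    a, b = _validate(group_a, group_b)
    if np.var(a) == 0 and np.var(b) == 0:
        # degenerate: declared equal variances
        return "t-test", 0.0, 1.0
    stat, p = sps.levene(a, b, center=center)
    return ("t-test" if p >= alpha else "mann-whitney"), float(stat), float(p)


def hedges_correction(n_a: int, n_b: int) -> float:
    """Small-sample correction J = 1 − 3/(4·df − 1), df = n_a + n_b − 2."""
    df = n_a + n_b - 2
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def effect_size(group_a, group_b, equal_variance: bool = True) -> tuple[str, float]:
    """Standardized effect size for transgenic (a) vs control (b).

    Equal variances: Cohen's d from the pooled SD with the Hedges
    correction, reported as ("hedges_g", g).  Unequal: Glass's Δ using
    the control-group SD, reported as ("glass_delta", Δ).  The sign is
    sign(mean_b − mean_a).
    """
    a, b = _validate(group_a, group_b)
    diff = b.mean() - a.mean()
    if equal_variance:
        na, nb = a.size, b.size
        pooled = np.sqrt(
            ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        )
        if pooled == 0:
            if diff == 0:
                return "hedges_g", 0.0
            raise ValueError("zero pooled SD with unequal means")
        return "hedges_g", float(diff / pooled * hedges_correction(na, nb))
    sd_control = b.std(ddof=1)
    if sd_control == 0:
        raise ValueError("Glass's delta requires a nonzero control-group SD")
    return "glass_delta", float(diff / sd_control)


def cohens_d(group_a, group_b) -> float:
    """Uncorrected Cohen's d with the pooled SD, sign(mean_b − mean_a)."""
    a, b = _validate(group_a, group_b)
    na, nb = a.size, b.size
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        if b.mean() == a.mean():
            return 0.0
        raise ValueError("zero pooled SD with unequal means")
    return float((b.mean() - a.mean()) / pooled)


def _nct_ci_for_d(d: float, n_a: int, n_b: int, level: float) -> tuple[float, float]:
    """CI for a standardized two-sample difference via noncentral-t inversion."""
    df = n_a + n_b - 2
    scale = np.sqrt(n_a * n_b / (n_a + n_b))
    t_obs = d * scale
    tail = (1.0 - level) / 2.0
    span = abs(t_obs) + 10.0 + 10.0 * np.sqrt(df)

    def cdf(nc: float) -> float:
        val = sps.nct.cdf(t_obs, df, nc)
        if np.isnan(val):  # deep-tail overflow: limits are known
            return 0.0 if nc > t_obs else 1.0
        return float(val)

    def solve(target_cdf: float) -> float:
        f = lambda nc: cdf(nc) - target_cdf
        lo, hi = t_obs - span, t_obs + span
        # nct.cdf decreases in nc, so f is monotone decreasing
        return brentq(f, lo, hi, xtol=1e-10)

    return solve(1.0 - tail) / scale, solve(tail) / scale


def effect_ci(
    group_a,
    group_b,
    effect_name: str,
    level: float = 0.95,
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Confidence interval for the effect size.

    For ``hedges_g`` (and Cohen's d) the CI comes from inverting the
    noncentral-t distribution of the observed t statistic; the bounds
    are scaled by the Hedges correction.  For ``glass_delta`` a seeded
    percentile bootstrap is used.
    """
    a, b = _validate(group_a, group_b)
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if effect_name in ("hedges_g", "cohens_d"):
        d = cohens_d(a, b)
        lo, hi = _nct_ci_for_d(d, a.size, b.size, level)
        if effect_name == "hedges_g":
            j = hedges_correction(a.size, b.size)
            lo, hi = lo * j, hi * j
        return float(lo), float(hi)
    if effect_name == "glass_delta":
        rng = np.random.default_rng(seed)
        vals = np.empty(n_boot)
        for i in range(n_boot):
            ra = rng.choice(a, size=a.size, replace=True)
            rb = rng.choice(b, size=b.size, replace=True)
            sd = rb.std(ddof=1)
            vals[i] = (rb.mean() - ra.mean()) / sd if sd > 0 else np.nan
        vals = vals[np.isfinite(vals)]
        tail = 100.0 * (1.0 - level) / 2.0
        return (
            float(np.percentile(vals, tail)),
            float(np.percentile(vals, 100.0 - tail)),
        )
    raise ValueError(f"unknown effect size {effect_name!r}")


@dataclass
class GroupComparison:
    """Full comparison record for one feature and one group pair."""

    feature: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    levene_stat: float
    levene_p: float
    chosen_test: str
    test_stat: float
    p_value: float
    effect_name: str
    effect: float
    ci_low: float
    ci_high: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def run_comparison(
    group_a,
    group_b,
    feature: str = "",
    name_a: str = "transgenic",
    name_b: str = "control",
    alpha: float = ALPHA_VARIANCE,
    ci_seed: int = 0,
) -> GroupComparison:
    """Run the full gated comparison of two groups of measurements."""
    a, b = _validate(group_a, group_b)
    chosen, lev_stat, lev_p = variance_gate(a, b, alpha=alpha)
    if chosen == "t-test":
        if np.array_equal(np.sort(a), np.sort(b)) and a.var() == 0 and b.var() == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.ttest_ind(a, b, equal_var=True)
        effect_name, effect = effect_size(a, b, equal_variance=True)
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        effect_name, effect = effect_size(a, b, equal_variance=False)
    lo, hi = effect_ci(a, b, effect_name, seed=ci_seed)
    return GroupComparison(
        feature=feature,
        group_a=name_a,
        group_b=name_b,
        n_a=a.size,
        n_b=b.size,
        levene_stat=lev_stat,
        levene_p=lev_p,
        chosen_test=chosen,
        test_stat=float(stat),
        p_value=float(p),
        effect_name=effect_name,
        effect=float(effect),
        ci_low=float(lo),
        ci_high=float(hi),
    )


def region_paired_test(region_a_means, region_b_means) -> tuple[float, float]:
    """Exact Wilcoxon signed-rank test of paired per-sample region means.

    Pairs one mean per sample for each region (e.g. cortex vs
    hippocampus).  Zero differences are dropped; with n <= 25 the exact
    null distribution is used.  Returns (statistic, two-sided p).
    """
    a = np.asarray(region_a_means, dtype=float)
    b = np.asarray(region_b_means, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 4:
        raise ValueError("need at least 4 pairs")
    diffs = a - b
    if np.all(diffs == 0):
        raise ValueError("all paired differences are zero")
    method = "exact" if np.count_nonzero(diffs) <= 25 else "auto"
    res = sps.wilcoxon(a, b, zero_method="wilcox", method=method)
    return float(res.statistic), float(res.pvalue)
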