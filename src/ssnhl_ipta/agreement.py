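"""Method-comparison statistics for recovery measures.

Bland-Altman agreement between PTA4 and iPTA recovery (with iPTA as the
designated reference method and the difference regressed on the *reference*
value rather than the pair mean), Welch/Student group comparisons of the two
measures within subgroups, and a one-way ANOVA of per-frequency recovery with
Tukey HSD follow-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BlandAltmanResult",
    "GroupComparison",
    "AnovaResult",
    "bland_altman",
    "compare_measures_in_subgroup",
    "per_frequency_recovery_anova",
]


@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    slope: Optional[float]
    intercept: Optional[float]
    slope_ci: tuple[float, float] | None
    slope_p: Optional[float]
    mode: str  # difference regressed on "reference" value or pair "mean"

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_difference": self.mean_difference,
            "sd_difference": self.sd_difference,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_ci": list(self.slope_ci) if self.slope_ci else None,
            "slope_p": self.slope_p,
            "mode": self.mode,
        }


@dataclass(frozen=True)
class GroupComparison:
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    mean_difference: float
    t: float
    df: float
    p: float
    flavor: str  # "welch" | "student"


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    group_means: dict
    posthoc: pd.DataFrame  # Tukey HSD pairwise table


def bland_altman(
    reference: Sequence[float],
    test: Sequence[float],
    mode: str = "reference",
) -> BlandAltmanResult:
    """Bland-Altman agreement of ``test`` against ``reference``.

    Differences are test - reference.  Limits of agreement are
    mean +/- 1.96 * SD (n-1 denominator).  An OLS regression of the
    difference on the reference value (``mode="reference"``) quantifies
    proportional bias; ``mode="mean"`` regresses on the pair mean, the
    conventional variant.  With a degenerate abscissa the slope is undefined
    and reported as None.
    """
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if ref.shape != tst.shape or ref.ndim != 1:
        raise ValueError("reference and test must be equal-length 1-d vectors")
    n = ref.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    diff = tst - ref
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    loa_low = mean_diff - 1.96 * sd_diff
    loa_high = mean_diff + 1.96 * sd_diff

    if mode == "reference":
        x = ref
    elif mode == "mean":
        x = (ref + tst) / 2.0
    else:
        raise ValueError(f"unknown mode: {mode!r}")

    slope = intercept = slope_p = None
    slope_ci = None
    if np.ptp(x) > 0:
        res = stats.linregress(x, diff)
        slope, intercept, slope_p = float(res.slope), float(res.intercept), float(res.pvalue)
        tcrit = stats.t.ppf(0.975, n - 2)
        slope_ci = (slope - tcrit * res.stderr, slope + tcrit * res.stderr)
    return BlandAltmanResult(
        n=n,
        mean_difference=mean_diff,
        sd_difference=sd_diff,
        loa_low=loa_low,
        loa_high=loa_high,
        slope=slope,
        intercept=intercept,
        slope_ci=slope_ci,
        slope_p=slope_p,
        mode=mode,
    )


def bland_altman_plot(result: BlandAltmanResult, reference, test, path):
    """Scatter of differences vs the reference with mean/LoA/regression lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = np.asarray(reference, dtype=float)
    diff = np.asarray(test, dtype=float) - ref
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(ref, diff, s=12, alpha=0.5, edgecolors="none")
    ax.axhline(result.mean_difference, color="red", label="mean difference")
    ax.axhline(result.loa_low, color="black", ls="--", label="95% limits of agreement")
    ax.axhline(result.loa_high, color="black", ls="--")
    if result.slope is not None:
        xs = np.linspace(ref.min(), ref.max(), 50)
        ax.plot(xs, result.intercept + result.slope * xs, color="tab:blue",
                label=f"regression (B = {result.slope:.2f})")
    ax.set_xlabel("iPTA recovery (dB)" if result.mode == "reference" else "pair mean (dB)")
    ax.set_ylabel("PTA4 - iPTA recovery (dB)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def compare_measures_in_subgroup(
    values_a: Sequence[float],
    values_b: Sequence[float],
    flavor: str = "welch",
) -> GroupComparison:
    """Unpaired t-test between two recovery-value vectors (e.g. iPTA vs PTA4
    recovery within the frequency-range-specific subgroup).

    Welch's unequal-variance test is the default; ``flavor="student"`` pools
    variances.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    equal_var = flavor == "student"
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = a.size + b.size - 2
    else:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return GroupComparison(
        n_a=a.size,
        n_b=b.size,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        mean_difference=float(a.mean() - b.mean()),
        t=float(t),
        df=float(df),
        p=float(p),
        flavor=flavor,
    )


def per_frequency_recovery_anova(
    table: pd.DataFrame,
    frequency_col: str = "frequency",
    recovery_col: str = "recovery_db",
    alpha: float = 0.05,
) -> AnovaResult:
    """One-way ANOVA of mean hearing recovery per affected frequency.

    ``table`` holds one row per (patient, affected frequency) with the
    per-frequency recovery in dB; each frequency group contains only patients
    for whom that frequency was affected.  Tukey HSD provides the pairwise
    post-hoc comparisons, flagged at ``alpha``.
    """
    groups = {
        f: g[recovery_col].to_numpy(dtype=float)
        for f, g in table.groupby(frequency_col)
    }
    usable = {f: v for f, v in groups.items() if v.size >= 2}
    if len(usable) < 2:
        raise ValueError("need at least 2 frequency groups with >= 2 observations")
    f_stat, p = stats.f_oneway(*usable.values())
    if math.isnan(f_stat):  # all groups constant and identical
        f_stat, p = 0.0, 1.0
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    sub = table[table[frequency_col].isin(usable)]
    tk = pairwise_tukeyhsd(
        sub[recovery_col].to_numpy(dtype=float),
        sub[frequency_col].to_numpy(),
        alpha=alpha,
    )
    posthoc = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    means = {f: float(v.mean()) for f, v in usable.items()}
    return AnovaResult(f=float(f_stat), p=float(p), group_means=means, posthoc=posthoc)
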