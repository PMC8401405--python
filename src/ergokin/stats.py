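"""Group-level comparison statistics for paired exposure measures.

The comparison machinery mirrors common practice in occupational
exposure method-comparison studies: a normality gate (Shapiro-Wilk, or a
moment fallback accepting skewness below 2.0 and kurtosis below 6.0,
since the paired t-test is robust to mild non-normality), a paired t-test
or Wilcoxon signed-rank test on the within-subject differences at
alpha = 0.01, Pearson correlation, ordinary and zero-intercept linear
fits, Bland-Altman limits of agreement, and the chaining of
zero-intercept conversion slopes between velocity conventions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

ALPHA_SIGNIFICANCE = 0.01
SHAPIRO_ALPHA = 0.05
SKEWNESS_BOUND = 2.0
KURTOSIS_BOUND = 6.0   # non-excess (Pearson) kurtosis; normal = 3


@dataclass
class NormalityResult:
    sufficiently_normal: bool
    shapiro_p: float | None
    skewness: float
    kurtosis: float
    flags: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.sufficiently_normal


def normality_gate(values, shapiro_alpha: float = SHAPIRO_ALPHA) -> NormalityResult:
    """Decide whether a sample is sufficiently normal for a paired t-test.

    True if the Shapiro-Wilk test does not reject at ``shapiro_alpha`` OR
    the moment fallback holds (|skewness| < 2.0 and kurtosis < 6.0).
    Constant samples leave Shapiro-Wilk undefined; the gate then returns
    True with a flag.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("normality gate needs at least 3 values")
    if np.ptp(x) == 0:
        return NormalityResult(True, None, 0.0, 0.0, flags=["constant_input"])
    skew = float(sps.skew(x))
    kurt = float(sps.kurtosis(x, fisher=False))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        shapiro_p = float(sps.shapiro(x).pvalue)
    ok = (shapiro_p > shapiro_alpha) or (
        abs(skew) < SKEWNESS_BOUND and kurt < KURTOSIS_BOUND
    )
    return NormalityResult(ok, shapiro_p, skew, kurt)


@dataclass
class PairedComparison:
    """Within-subject difference statistics for one paired measure."""

    label: str
    n: int
    mean_diff: float
    sd_diff: float
    test: str                 # "paired_t" | "wilcoxon"
    statistic: float
    p_value: float
    significant: bool
    flags: list[str] = field(default_factory=list)


def paired_compare(a, b, label: str = "",
                   alpha: float = ALPHA_SIGNIFICANCE) -> PairedComparison:
    """Compare paired measures: t-test if differences gate normal, else Wilcoxon.

    Two-sided p-value; significance at the stricter ``alpha`` = 0.01 used
    in place of an explicit multiple-testing correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-d paired arrays")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean_diff = float(a.mean() - b.mean())
    sd_diff = float(d.std(ddof=1))
    if np.allclose(d, 0.0):
        return PairedComparison(label, a.size, mean_diff, sd_diff,
                                "paired_t", 0.0, 1.0, False,
                                flags=["all_zero_differences"])
    gate = normality_gate(d) if d.size >= 3 else NormalityResult(True, None, 0, 0)
    if gate:
        res = sps.ttest_rel(a, b)
        test, stat, p = "paired_t", float(res.statistic), float(res.pvalue)
    else:
        method = "exact" if d.size < 15 else "approx"
        res = sps.wilcoxon(a, b, zero_method="wilcox", method=method)
        test, stat, p = "wilcoxon", float(res.statistic), float(res.pvalue)
    return PairedComparison(label, a.size, mean_diff, sd_diff, test, stat, p,
                            bool(p < alpha), flags=gate.flags)


@dataclass
class AgreementModel:
    """Correlation, calibration fit and Bland-Altman agreement for a pair."""

    label: str
    n: int
    r: float
    slope: float
    intercept: float
    bias: float              # Bland-Altman mean difference, a - b
    sd_diff: float
    loa_low: float           # bias - 1.96 sd
    loa_high: float          # bias + 1.96 sd
    flags: list[str] = field(default_factory=list)


def fit_agreement(a, b, zero_intercept: bool = False,
                  label: str = "") -> AgreementModel:
    """Pearson r, (zero-intercept) linear fit of b on a, and Bland-Altman.

    The zero-intercept slope is the closed form ``sum(a*b) / sum(a*a)``
    (appropriate for velocity measures, which vanish together); the free
    fit uses ordinary least squares.  Bland-Altman statistics are computed
    on the differences ``a - b`` against the means ``(a + b) / 2``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need at least 3 equal-length pairs")
    flags: list[str] = []
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        r = np.nan
        flags.append("zero_variance")
    else:
        r = float(sps.pearsonr(a, b).statistic)
    if zero_intercept:
        slope = float(a @ b / (a @ a))
        intercept = 0.0
    elif "zero_variance" in flags:
        slope = intercept = np.nan
    else:
        fit = sm.OLS(b, sm.add_constant(a)).fit()
        intercept, slope = (float(v) for v in fit.params)
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementModel(label, a.size, r, slope, intercept, bias, sd,
                          bias - 1.96 * sd, bias + 1.96 * sd, flags)


def conversion_chain(s1: float, s2: float) -> float:
    """Total conversion factor from chained per-step slopes, 2 decimals.

    E.g. fused-inclination -> acc-inclination (s1) chained with
    acc-inclination -> acc-generalized (s2) gives the one-step
    fused-inclination -> acc-generalized factor.
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("conversion slopes must be positive")
    return round(s1 * s2, 2)


def plot_agreement(model: AgreementModel, a, b, path) -> None:
    """Render side-by-side correlation and Bland-Altman panels to a file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.scatter(a, b, s=18)
    lim = [0, max(a.max(), b.max()) * 1.05]
    ax1.plot(lim, lim, "k--", lw=1, label="unity")
    xs = np.linspace(lim[0], lim[1], 2)
    ax1.plot(xs, model.intercept + model.slope * xs, "-",
             label=f"fit (slope {model.slope:.2f})")
    ax1.set_xlabel("a")
    ax1.set_ylabel("b")
    ax1.legend(frameon=False)
    ax2.scatter((a + b) / 2, a - b, s=18)
    for y, style in ((model.bias, "-"), (model.loa_low, "--"), (model.loa_high, "--")):
        ax2.axhline(y, ls=style[-1] if "-" in style else "-", color="C1")
    ax2.set_xlabel("mean of pair")
    ax2.set_ylabel("difference (a - b)")
    fig.suptitle(model.label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
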