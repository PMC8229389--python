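"""Paired-rater agreement and equivalence statistics.

This module compares two raters (e.g. an automated and a manual
segmentation) over the same patients:

* categorical features via paired contingency tables — concordance,
  McNemar's exact test (2 classes), and the paired-rating chi-square for
  ordinal ratings from two related raters (the Friedman statistic for
  two treatments, which reduces to the sign chi-square on the discordant
  pairs),
* continuous features via the Wilcoxon signed-rank test, one-way
  random-effects ICC, Bland-Altman bias and limits of agreement, and the
  Pearson correlation with Fisher-z confidence interval,
* equivalence via two one-sided tests (TOST) against pre-specified
  smallest effect sizes of interest.

Every routine returns an :class:`AgreementSummary`; undefined quantities
are NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, ValidationError


@dataclass(frozen=True)
class EquivalenceBounds:
    """Smallest effect sizes of interest for equivalence testing."""

    proportions: float = 0.10
    volumes_ml: float = 2.0
    foci: float = 1.0
    resectability_index: float = 0.1

    def __post_init__(self) -> None:
        for name in ("proportions", "volumes_ml", "foci", "resectability_index"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} bound must be strictly positive")


@dataclass
class AgreementSummary:
    """One statistical result: point estimate, interval, test statistic,
    p-value.  ``extra`` carries method-specific values (limits of
    agreement, secondary one-sided statistics...)."""

    method: str
    estimate: float
    ci_low: float
    ci_high: float
    statistic: float
    p_value: float
    n: int
    extra: dict[str, float] = field(default_factory=dict)


@dataclass
class PairedContingency:
    """k x k counts of paired categorical ratings over the same patients:
    rows index rater A's class, columns rater B's class, in the order of
    ``classes``."""

    classes: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValidationError(
                f"counts must be {k}x{k} for {k} classes, got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def transposed(self) -> "PairedContingency":
        return PairedContingency(classes=list(self.classes), counts=self.counts.T.copy())


def build_contingency(
    labels_a: Sequence, labels_b: Sequence, classes: Sequence
) -> PairedContingency:
    """Tally paired labels into a k x k table (rows = rater A)."""
    if len(labels_a) != len(labels_b):
        raise ValidationError("paired label sequences must have equal length")
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for a, b in zip(labels_a, labels_b):
        if a not in index or b not in index:
            raise ValidationError(f"label pair ({a!r}, {b!r}) outside classes")
        counts[index[a], index[b]] += 1
    return PairedContingency(classes=classes, counts=counts)


def expand_contingency(table: PairedContingency) -> tuple[list, list]:
    """Inverse of :func:`build_contingency`: emit the paired label
    sequences in deterministic row-major cell order."""
    labels_a: list = []
    labels_b: list = []
    for i, a in enumerate(table.classes):
        for j, b in enumerate(table.classes):
            c = int(table.counts[i, j])
            labels_a.extend([a] * c)
            labels_b.extend([b] * c)
    return labels_a, labels_b


def concordance(table: PairedContingency) -> float:
    """Fraction of patients rated identically by both raters:
    trace / total."""
    if table.total == 0:
        raise DomainError("empty contingency table")
    return float(np.trace(table.counts)) / table.total


def mcnemar_test(table: PairedContingency) -> AgreementSummary:
    """Exact McNemar test on a 2x2 paired table.

    With discordant cells b = counts[A=class0, B=class1] and
    c = counts[A=class1, B=class0], the odds ratio is b / c with an exact
    95% CI obtained from the Clopper-Pearson interval on b / (b + c)
    mapped through p -> p / (1 - p); the p-value is the exact binomial
    two-sided test of b successes in b + c trials at 1/2.  The exact form
    is used because discordant counts range from a handful to hundreds
    across features.
    """
    if len(table.classes) != 2:
        raise ValidationError("McNemar's test requires a 2x2 table")
    b = int(table.counts[0, 1])
    c = int(table.counts[1, 0])
    n_disc = b + c
    if n_disc == 0:
        return AgreementSummary(
            method="mcnemar_exact",
            estimate=math.nan,
            ci_low=math.nan,
            ci_high=math.nan,
            statistic=math.nan,
            p_value=1.0,
            n=table.total,
            extra={"b": float(b), "c": float(c)},
        )
    res = stats.binomtest(b, n_disc, 0.5)
    ci = res.proportion_ci(confidence_level=0.95, method="exact")

    def _odds(p: float) -> float:
        if p >= 1.0:
            return math.inf
        return p / (1.0 - p)

    odds = b / c if c > 0 else math.inf
    return AgreementSummary(
        method="mcnemar_exact",
        estimate=odds,
        ci_low=_odds(ci.low),
        ci_high=_odds(ci.high),
        statistic=float(b),
        p_value=float(res.pvalue),
        n=table.total,
        extra={"b": float(b), "c": float(c)},
    )


def paired_rating_chi2(table: PairedContingency) -> AgreementSummary:
    """Friedman-type chi-square for ordinal ratings from two related
    raters.

    With two treatments the Friedman rank statistic collapses to the
    sign chi-square on the discordant pairs: chi2 = (P - N)^2 / (P + N)
    with df = 1, where P = #pairs with A > B and N = #pairs with A < B
    (class order taken from ``classes``; ties excluded).
    """
    k = len(table.classes)
    p_cnt = n_cnt = 0
    for i in range(k):
        for j in range(k):
            if i > j:
                p_cnt += int(table.counts[i, j])
            elif i < j:
                n_cnt += int(table.counts[i, j])
    disc = p_cnt + n_cnt
    if disc == 0:
        return AgreementSummary(
            method="paired_rating_chi2",
            estimate=0.0,
            ci_low=math.nan,
            ci_high=math.nan,
            statistic=0.0,
            p_value=1.0,
            n=table.total,
            extra={"n_greater": 0.0, "n_less": 0.0},
        )
    chi2 = (p_cnt - n_cnt) ** 2 / disc
    p = float(stats.chi2.sf(chi2, df=1))
    return AgreementSummary(
        method="paired_rating_chi2",
        estimate=(p_cnt - n_cnt) / table.total,
        ci_low=math.nan,
        ci_high=math.nan,
        statistic=float(chi2),
        p_value=p,
        n=table.total,
        extra={"n_greater": float(p_cnt), "n_less": float(n_cnt)},
    )


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> AgreementSummary:
    """Wilcoxon signed-rank test on paired samples (zeros dropped,
    average ranks; exact for small n without ties, tie-corrected normal
    approximation otherwise)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("need equal-length paired sequences, n >= 2")
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        return AgreementSummary(
            method="wilcoxon_signed_rank",
            estimate=0.0,
            ci_low=math.nan,
            ci_high=math.nan,
            statistic=0.0,
            p_value=1.0,
            n=int(x.size),
        )
    res = stats.wilcoxon(x, y, zero_method="wilcox", method="auto")
    return AgreementSummary(
        method="wilcoxon_signed_rank",
        estimate=float(np.median(d)),
        ci_low=math.nan,
        ci_high=math.nan,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def tost_proportions(
    k_a: int, k_b: int, n: int, bound: float
) -> AgreementSummary:
    """Two one-sided Z tests for equivalence of two proportions observed
    on the same n patients.

    The difference d = k_a/n - k_b/n is tested against +-bound using the
    normal standard error from the two marginal proportions.  The
    interval reported is the 90% CI d +- 1.6449 SE: equivalence at
    alpha = 0.05 holds exactly when that interval lies inside
    (-bound, +bound).
    """
    if n <= 0:
        raise DomainError("n must be positive")
    if not (0 <= k_a <= n and 0 <= k_b <= n):
        raise DomainError("counts must lie in [0, n]")
    if bound <= 0:
        raise DomainError("bound must be positive")
    p_a, p_b = k_a / n, k_b / n
    d = p_a - p_b
    se = math.sqrt(p_a * (1 - p_a) / n + p_b * (1 - p_b) / n)
    if se == 0:
        # both proportions degenerate: difference known exactly
        equivalent = abs(d) < bound
        return AgreementSummary(
            method="tost_proportions",
            estimate=d,
            ci_low=d,
            ci_high=d,
            statistic=-math.inf if equivalent else math.inf,
            p_value=0.0 if equivalent else 1.0,
            n=n,
        )
    z_upper = (d - bound) / se
    z_lower = (d + bound) / se
    p_upper = float(stats.norm.cdf(z_upper))  # H1: d < bound
    p_lower = float(stats.norm.sf(z_lower))  # H1: d > -bound
    z_crit = float(stats.norm.ppf(0.95))
    return AgreementSummary(
        method="tost_proportions",
        estimate=d,
        ci_low=d - z_crit * se,
        ci_high=d + z_crit * se,
        statistic=z_upper,
        p_value=max(p_upper, p_lower),
        n=n,
        extra={"z_lower": z_lower, "se": se},
    )


def tost_means(diffs: Sequence[float], bound: float) -> AgreementSummary:
    """Two one-sided t tests for equivalence of a mean paired difference
    within +-bound.

    t_upper = (mean - bound) / (sd / sqrt(n)) with df = n - 1, and
    symmetrically for the lower bound; the TOST p-value is the larger of
    the two one-sided p's.  Zero-variance input degenerates to an exact
    comparison of the mean with the bounds.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValidationError("need at least 2 paired differences")
    if bound <= 0:
        raise DomainError("bound must be positive")
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0:
        inside = abs(mean) < bound
        t_upper = -math.inf if mean < bound else math.inf
        return AgreementSummary(
            method="tost_means",
            estimate=mean,
            ci_low=mean,
            ci_high=mean,
            statistic=t_upper,
            p_value=0.0 if inside else 1.0,
            n=n,
            extra={"t_lower": math.inf if mean > -bound else -math.inf, "df": float(df)},
        )
    se = sd / math.sqrt(n)
    t_upper = (mean - bound) / se
    t_lower = (mean + bound) / se
    p_upper = float(stats.t.cdf(t_upper, df))
    p_lower = float(stats.t.sf(t_lower, df))
    t_crit = float(stats.t.ppf(0.95, df))
    return AgreementSummary(
        method="tost_means",
        estimate=mean,
        ci_low=mean - t_crit * se,
        ci_high=mean + t_crit * se,
        statistic=t_upper,
        p_value=max(p_upper, p_lower),
        n=n,
        extra={"t_lower": t_lower, "df": float(df)},
    )


def icc_oneway(x: Sequence[float], y: Sequence[float]) -> AgreementSummary:
    """One-way random-effects intraclass correlation (absolute
    agreement) for two measurements per subject.

    ICC(1) = (MSB - MSW) / (MSB + (k-1) MSW) with k = 2; the 95% CI comes
    from F-distribution bounds on MSB / MSW.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("need equal-length paired sequences, n >= 3")
    n = x.size
    k = 2
    data = np.stack([x, y], axis=1)
    grand = data.mean()
    subject_means = data.mean(axis=1)
    msb = k * float(np.sum((subject_means - grand) ** 2)) / (n - 1)
    msw = float(np.sum((data - subject_means[:, None]) ** 2)) / (n * (k - 1))
    if msb + msw == 0:
        return AgreementSummary(
            method="icc_oneway",
            estimate=math.nan,
            ci_low=math.nan,
            ci_high=math.nan,
            statistic=math.nan,
            p_value=math.nan,
            n=n,
        )
    icc = (msb - msw) / (msb + (k - 1) * msw)
    if msw == 0:
        return AgreementSummary(
            method="icc_oneway",
            estimate=icc,
            ci_low=math.nan,
            ci_high=math.nan,
            statistic=math.inf,
            p_value=0.0,
            n=n,
        )
    f_obs = msb / msw
    df1, df2 = n - 1, n * (k - 1)
    f_l = f_obs / stats.f.ppf(0.975, df1, df2)
    f_u = f_obs * stats.f.ppf(0.975, df2, df1)
    ci_low = (f_l - 1) / (f_l + k - 1)
    ci_high = (f_u - 1) / (f_u + k - 1)
    p = float(stats.f.sf(f_obs, df1, df2))
    return AgreementSummary(
        method="icc_oneway",
        estimate=float(icc),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        statistic=float(f_obs),
        p_value=p,
        n=n,
    )


def bland_altman(x: Sequence[float], y: Sequence[float]) -> AgreementSummary:
    """Bland-Altman agreement: bias = mean(x - y) with its 95% CI, and
    95% limits of agreement bias +- 1.96 sd(x - y) in ``extra``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("need equal-length paired sequences, n >= 2")
    d = x - y
    n = d.size
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / math.sqrt(n)
    return AgreementSummary(
        method="bland_altman",
        estimate=bias,
        ci_low=bias - 1.96 * se,
        ci_high=bias + 1.96 * se,
        statistic=math.nan,
        p_value=math.nan,
        n=n,
        extra={"loa_low": bias - 1.96 * sd, "loa_high": bias + 1.96 * sd, "sd": sd},
    )


def pearson_ci(x: Sequence[float], y: Sequence[float]) -> AgreementSummary:
    """Pearson product-moment correlation with a 95% Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValidationError("need equal-length paired sequences, n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return AgreementSummary(
            method="pearson",
            estimate=math.nan,
            ci_low=math.nan,
            ci_high=math.nan,
            statistic=math.nan,
            p_value=math.nan,
            n=int(x.size),
        )
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    n = x.size
    if abs(r) >= 1.0:
        lo = hi = r
    else:
        z = math.atanh(r)
        se = 1.0 / math.sqrt(n - 3)
        zc = float(stats.norm.ppf(0.975))
        lo, hi = math.tanh(z - zc * se), math.tanh(z + zc * se)
    return AgreementSummary(
        method="pearson",
        estimate=r,
        ci_low=lo,
        ci_high=hi,
        statistic=r,
        p_value=float(res.pvalue),
        n=int(n),
    )
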