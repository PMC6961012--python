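"""Agreement statistics between gold-standard and algorithm class totals.

Per participant and class, the error of the algorithm's total time against
the observer's total time is expressed as a percentage error

    PE  = 100 · (T_gold − T_algo) / T_gold        (positive = underestimate)
    APE = |PE|

PE cancels over- and underestimation across a group; APE does not, so it
reflects individual-level error.  Group values are summarized as the median
with a distribution-free 95% confidence interval.  Inter-observer
reliability uses Bland–Altman limits of agreement and ICC(2,1) — two-way
random effects, absolute agreement, single measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import ActivityLabel

#: Half-width of the acceptability band on percentage error: agreement
#: between 90% and 110% of the gold standard (inclusive) is acceptable.
ACCEPTABLE_APE_PERCENT = 10.0


class UndefinedErrorDenominator(ValueError):
    """Gold-standard total time is zero; percentage error is undefined."""


def percentage_error(gold_seconds: float, predicted_seconds: float) -> float:
    """Signed percentage error; positive when the algorithm underestimates."""
    if gold_seconds <= 0:
        raise UndefinedErrorDenominator(
            f"gold-standard time must be > 0 s, got {gold_seconds}"
        )
    return 100.0 * (gold_seconds - predicted_seconds) / gold_seconds


def absolute_percentage_error(
    gold_seconds: float, predicted_seconds: float
) -> float:
    """Magnitude of the percentage error (individual-level error measure)."""
    return abs(percentage_error(gold_seconds, predicted_seconds))


def is_within_acceptable_limits(pe: float) -> bool:
    """True when agreement lies in the closed 90–110% band (|PE| ≤ 10)."""
    if not np.isfinite(pe):
        raise ValueError("percentage error must be finite")
    return abs(pe) <= ACCEPTABLE_APE_PERCENT


def group_summary(
    values, confidence: float = 0.95
) -> tuple[float, float, float]:
    """Sample median with a distribution-free confidence interval.

    The CI uses binomial order statistics: the interval between the l-th and
    (n+1−l)-th order statistics, with l the largest rank whose two-sided
    binomial(n, 1/2) coverage is at least ``confidence``.  This is
    conservative (true coverage ≥ the nominal level) and assumption-free.
    For n too small for the exact method (n < 6 at 95%), the full data range
    is returned with a warning.
    """
    v = np.sort(np.asarray(list(values), dtype=float))
    n = v.size
    if n < 3:
        raise ValueError(f"need at least 3 values, got {n}")
    median = float(np.median(v))
    alpha = 1.0 - confidence
    # largest l with P(X <= l-1) <= alpha/2 for X ~ Binomial(n, 1/2)
    l = int(stats.binom.ppf(alpha / 2.0, n, 0.5))
    if l < 1:
        warnings.warn(
            f"n={n} too small for an exact {confidence:.0%} median CI; "
            "returning the data range",
            stacklevel=2,
        )
        return median, float(v[0]), float(v[-1])
    return median, float(v[l - 1]), float(v[n - l])


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference and limits of agreement between two paired methods."""

    mean_difference: float
    loa_lower: float
    loa_upper: float
    n: int


def bland_altman(pairs) -> BlandAltmanResult:
    """Limits of agreement: mean difference ± 1.96 × SD of the differences.

    ``pairs`` is a sequence of (value_a, value_b); differences are a − b.
    The SD uses the n−1 denominator.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (a, b) values")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    d = arr[:, 0] - arr[:, 1]
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        mean_difference=mean,
        loa_lower=mean - 1.96 * sd,
        loa_upper=mean + 1.96 * sd,
        n=arr.shape[0],
    )


def icc_two_way_random_absolute(ratings) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``ratings`` is an n_subjects × k_raters matrix with no missing cells.
    Computed from the two-way ANOVA mean squares as

        (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

    where MSR, MSC and MSE are the row (subject), column (rater) and
    residual mean squares.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings contain missing or non-finite cells")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        # all cells identical: perfect agreement by convention
        return 1.0
    return float((msr - mse) / denom)


@dataclass(frozen=True)
class ClassSummary:
    """Group-level PE/APE summary for one activity class."""

    label: ActivityLabel
    n: int
    median_pe: float
    pe_ci: tuple[float, float]
    median_ape: float
    ape_ci: tuple[float, float]

    @property
    def acceptable(self) -> bool:
        return is_within_acceptable_limits(self.median_ape)


@dataclass(frozen=True)
class ParticipantAgreement:
    """Per-participant, per-class error row."""

    subject_id: str
    label: ActivityLabel
    gold_seconds: float
    predicted_seconds: float
    pe_percent: float

    @property
    def ape_percent(self) -> float:
        return abs(self.pe_percent)


@dataclass
class AgreementReport:
    """Per-participant errors plus group medians and acceptability flags."""

    per_participant: list[ParticipantAgreement] = field(default_factory=list)
    group: dict[ActivityLabel, ClassSummary] = field(default_factory=dict)

    @property
    def acceptable(self) -> dict[ActivityLabel, bool]:
        return {label: s.acceptable for label, s in self.group.items()}


def compute_agreement(totals_by_participant) -> AgreementReport:
    """Build an agreement report from per-participant class totals.

    ``totals_by_participant`` is a sequence of
    ``(subject_id, gold_totals, predicted_totals)`` where both totals map
    :class:`ActivityLabel` to seconds.  Classes with zero gold time for a
    participant are skipped for that participant with a warning (the error
    denominator is undefined).
    """
    rows: list[ParticipantAgreement] = []
    for subject_id, gold, pred in totals_by_participant:
        for label in ActivityLabel:
            g = float(gold.get(label, 0.0))
            p = float(pred.get(label, 0.0))
            if g <= 0:
                warnings.warn(
                    f"subject {subject_id!r}: zero gold time for "
                    f"{label.value}; class skipped",
                    stacklevel=2,
                )
                continue
            rows.append(
                ParticipantAgreement(
                    subject_id=str(subject_id),
                    label=label,
                    gold_seconds=g,
                    predicted_seconds=p,
                    pe_percent=percentage_error(g, p),
                )
            )
    group: dict[ActivityLabel, ClassSummary] = {}
    for label in ActivityLabel:
        pes = [r.pe_percent for r in rows if r.label is label]
        if len(pes) < 3:
            continue
        apes = [abs(pe) for pe in pes]
        med_pe, pe_lo, pe_hi = group_summary(pes)
        med_ape, ape_lo, ape_hi = group_summary(apes)
        group[label] = ClassSummary(
            label=label,
            n=len(pes),
            median_pe=med_pe,
            pe_ci=(pe_lo, pe_hi),
            median_ape=med_ape,
            ape_ci=(ape_lo, ape_hi),
        )
    return AgreementReport(per_participant=rows, group=group)
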