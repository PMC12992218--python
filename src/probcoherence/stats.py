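"""Group comparisons between cohorts of coherence scores.

Implements the inferential layer used to contrast two cohorts (e.g. a noisy
sampler cohort against a coherent or quantum cohort): paired and Welch t
tests on the six core coherence metrics, the Pearson coupling between
participant-level conjunction- and disjunction-fallacy means, and a combined
report.  All p values are two-sided and uncorrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "DegenerateVarianceError",
    "TTestResult",
    "CohortComparison",
    "ComparisonReport",
    "CORE_METRICS",
    "paired_t",
    "welch_t",
    "fallacy_coupling",
    "compare_cohorts",
]

#: The six per-participant coherence metrics compared between cohorts.
CORE_METRICS = ("marginal_comp", "joint_comp", "cf_mean", "dcf_mean", "df_mean", "ddf_mean")


class DegenerateVarianceError(ValueError):
    """Raised when a t statistic is undefined because variance is zero."""


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float


def paired_t(x, y) -> TTestResult:
    """Paired-samples t test on matched vectors.

    ``t = mean(d) / (sd(d) / sqrt(n))`` with ``d = x - y`` and ``df = n - 1``.
    A zero-variance difference vector (e.g. ``x = y + c``) makes the
    statistic degenerate and raises :class:`DegenerateVarianceError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired t requires equal-length 1-d vectors")
    n = len(x)
    if n < 2:
        raise ValueError("paired t requires at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateVarianceError("difference vector has zero variance")
    t = float(d.mean() / (sd / math.sqrt(n)))
    df = n - 1
    p = float(2.0 * _sps.t.sf(abs(t), df))
    return TTestResult(t=t, df=float(df), p=p)


def welch_t(x, y) -> TTestResult:
    """Welch's unequal-variance t test with Welch-Satterthwaite df.

    The df is fractional in general; with equal variances and equal sample
    sizes it reduces to the pooled two-sample t.  One group may be constant
    (the other group's variance carries the test); both constant raises
    :class:`DegenerateVarianceError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch t requires at least 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    if vx == 0.0 and vy == 0.0:
        raise DegenerateVarianceError("both groups have zero variance")
    se2 = vx / nx + vy / ny
    t = float((x.mean() - y.mean()) / math.sqrt(se2))
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = float(2.0 * _sps.t.sf(abs(t), df))
    return TTestResult(t=t, df=float(df), p=p)


def fallacy_coupling(scores: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation between participant CF and DF means.

    A strong positive coupling is the signature of a single sequential
    mechanism driving both fallacy families; independent noise sources
    predict near-zero correlation.  Requires at least 3 participants with
    both means defined; zero variance in either column raises
    :class:`DegenerateVarianceError`.
    """
    sub = scores[["cf_mean", "df_mean"]].dropna()
    if len(sub) < 3:
        raise ValueError("fallacy coupling requires at least 3 participants")
    cf, df = sub["cf_mean"].to_numpy(), sub["df_mean"].to_numpy()
    if cf.std(ddof=1) == 0.0 or df.std(ddof=1) == 0.0:
        raise DegenerateVarianceError("a fallacy-mean column has zero variance")
    r, p = _sps.pearsonr(cf, df)
    return float(r), float(p)


@dataclass(frozen=True)
class CohortComparison:
    """One metric's between-cohort contrast."""

    metric: str
    paired: bool
    t: float
    df: float
    p: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    note: str = ""


@dataclass
class ComparisonReport:
    """Six metric contrasts plus per-cohort prevalence/split summaries."""

    comparisons: list[CohortComparison]
    summary_a: dict
    summary_b: dict

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.comparisons]).set_index("metric")

    def to_text(self) -> str:
        lines = ["Cohort comparison (A vs B)", "=" * 28]
        for c in self.comparisons:
            if c.note:
                lines.append(f"{c.metric:>14}: {c.note} "
                             f"(A {c.mean_a:.4f} +/- {c.sd_a:.4f}, B {c.mean_b:.4f} +/- {c.sd_b:.4f})")
            else:
                lines.append(
                    f"{c.metric:>14}: t({c.df:.2f}) = {c.t:.3f}, p = {c.p:.3g} "
                    f"(A {c.mean_a:.4f} +/- {c.sd_a:.4f}, B {c.mean_b:.4f} +/- {c.sd_b:.4f})"
                )
        for name, summary in (("A", self.summary_a), ("B", self.summary_b)):
            lines.append(f"-- cohort {name} --")
            for k, v in summary.items():
                lines.append(f"  {k}: {v:.4f}" if isinstance(v, float) else f"  {k}: {v}")
        return "\n".join(lines)


def compare_cohorts(a: pd.DataFrame, b: pd.DataFrame, paired: bool = True) -> ComparisonReport:
    """Contrast two score tables on the six core coherence metrics.

    Under ``paired=True`` the tables must be persona-matched: identical
    persona_id sets, compared in aligned order (mismatches raise, listing the
    offending ids).  Metrics whose t statistic is degenerate (zero variance,
    e.g. a cohort compared with itself) are reported with a note instead of
    aborting the report.  Prevalence and single/double-split summaries for
    each cohort come from :func:`probcoherence.scoring.cohort_summary`.
    """
    from .scoring import cohort_summary

    if paired:
        ids_a, ids_b = set(a["persona_id"]), set(b["persona_id"])
        if ids_a != ids_b:
            mismatched = sorted(ids_a.symmetric_difference(ids_b))
            raise ValueError(f"paired comparison with mismatched personas: {mismatched}")
        a = a.sort_values("persona_id").reset_index(drop=True)
        b = b.sort_values("persona_id").reset_index(drop=True)

    comparisons = []
    for metric in CORE_METRICS:
        xa, xb = a[metric].to_numpy(dtype=float), b[metric].to_numpy(dtype=float)
        stats_kwargs = dict(
            mean_a=float(np.nanmean(xa)),
            sd_a=float(np.nanstd(xa, ddof=1)),
            mean_b=float(np.nanmean(xb)),
            sd_b=float(np.nanstd(xb, ddof=1)),
        )
        try:
            res = paired_t(xa, xb) if paired else welch_t(xa, xb)
            comparisons.append(CohortComparison(metric=metric, paired=paired,
                                                t=res.t, df=res.df, p=res.p, **stats_kwargs))
        except DegenerateVarianceError as err:
            comparisons.append(
                CohortComparison(metric=metric, paired=paired,
                                 t=float("nan"), df=float("nan"), p=float("nan"),
                                 note=f"degenerate variance: {err}", **stats_kwargs)
            )
    return ComparisonReport(
        comparisons=comparisons,
        summary_a=cohort_summary(a),
        summary_b=cohort_summary(b),
    )
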