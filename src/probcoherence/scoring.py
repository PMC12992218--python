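"""Coherence scoring for probability-judgment response sets.

Given a participant's answers to the 78-item battery, this module quantifies
departures from the classical probability axioms:

* **Conjunction fallacy (CF)** — the judged probability of "A and B" exceeds
  a constituent:  ``CF = max(P(A&B) - P(A), 0) + max(P(A&B) - P(B), 0)``.
  The *double* variant (DCF) requires exceeding both constituents:
  ``DCF = max(P(A&B) - max(P(A), P(B)), 0)``.
* **Disjunction fallacy (DF)** — the judged probability of "A or B" falls
  below a constituent:  ``DF = max(P(A) - P(AvB), 0) + max(P(B) - P(AvB), 0)``,
  with the double variant ``DDF = max(min(P(A), P(B)) - P(AvB), 0)``.
* **Binary complementarity** — ``P(A) + P(not A) = 1`` for each state's two
  marginals; the joint extension requires the four sign-combination
  conjunctions over a state pair to sum to 1.

All scores are computed on the normalized [0, 1] scale.  Violations are
strict: an exact tie (e.g. integer responses 50 and 50) scores zero.  Each
ordered composite item (reversed and unreversed presentations both count) is
scored independently against the marginals of its two atoms, giving 24
conjunction and 24 disjunction scored items per participant.  Conditionals
are elicited but carry no coherence rule and are not scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .battery import Battery, Candidate, EventAtom, ItemKind

__all__ = [
    "ResponseSet",
    "CoherenceScores",
    "CoverageError",
    "conjunction_scores",
    "disjunction_scores",
    "marginal_complementarity",
    "joint_complementarity",
    "score_participant",
    "score_cohort",
    "cohort_summary",
    "political_sensitivity",
]


class CoverageError(ValueError):
    """Raised when a response set is missing too many scoreable items."""


@dataclass
class ResponseSet:
    """One participant's mapping from battery item to judged probability.

    ``values`` are normalized to [0, 1]; ``raw`` optionally retains the
    elicited 0-100 integers.  ``flagged`` lists item ids that were skipped or
    unanswerable (e.g. a conditional on a zero-probability event, or a parse
    failure in a live session).
    """

    persona_id: str
    triplet: str
    values: dict[str, float]
    raw: Optional[dict[str, int]] = None
    flagged: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for item_id, v in self.values.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"response for {item_id!r} out of [0, 1]: {v}")

    @classmethod
    def from_raw(cls, persona_id: str, triplet: str, raw: Mapping[str, int],
                 flagged: Iterable[str] = ()) -> "ResponseSet":
        values = {k: v / 100.0 for k, v in raw.items()}
        return cls(persona_id=persona_id, triplet=triplet, values=values,
                   raw=dict(raw), flagged=set(flagged))


@dataclass
class CoherenceScores:
    """Per-participant coherence summary.

    Fallacy means average over the eligible ordered items (at most 24 each
    for conjunctions and disjunctions); prevalences are the fraction of those
    items with a strictly positive score.  Among violated items,
    ``*_single_share`` / ``*_double_share`` split single violations (double
    score = 0) from double violations; both are NaN when no item is violated.
    """

    persona_id: str
    marginal_comp: float
    joint_comp: float
    cf_mean: float
    dcf_mean: float
    df_mean: float
    ddf_mean: float
    cf_prevalence: float
    dcf_prevalence: float
    df_prevalence: float
    ddf_prevalence: float
    cf_single_share: float
    cf_double_share: float
    df_single_share: float
    df_double_share: float
    n_conjunction_items: int
    n_disjunction_items: int
    n_cf_violations: int
    n_dcf_violations: int
    n_df_violations: int
    n_ddf_violations: int
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["flags"] = ";".join(self.flags)
        return d


def _check_unit(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} out of [0, 1]: {value}")


def conjunction_scores(p_a: float, p_b: float, p_ab: float) -> tuple[float, float]:
    """Conjunction-fallacy magnitudes (CF, DCF) for one item.

    CF sums the excesses of the conjunction over each constituent; DCF is the
    excess over the larger constituent.  ``CF >= DCF`` always, and both are 0
    when no constituent is strictly exceeded.
    """
    _check_unit("P(A)", p_a)
    _check_unit("P(B)", p_b)
    _check_unit("P(A&B)", p_ab)
    cf = max(p_ab - p_a, 0.0) + max(p_ab - p_b, 0.0)
    dcf = max(p_ab - max(p_a, p_b), 0.0)
    return cf, dcf


def disjunction_scores(p_a: float, p_b: float, p_avb: float) -> tuple[float, float]:
    """Disjunction-fallacy magnitudes (DF, DDF) for one item.

    DF sums the shortfalls of the disjunction below each constituent; DDF is
    the shortfall below the smaller constituent.
    """
    _check_unit("P(A)", p_a)
    _check_unit("P(B)", p_b)
    _check_unit("P(AvB)", p_avb)
    df = max(p_a - p_avb, 0.0) + max(p_b - p_avb, 0.0)
    ddf = max(min(p_a, p_b) - p_avb, 0.0)
    return df, ddf


def _marginal_values(rs: ResponseSet, battery: Battery) -> dict[EventAtom, float]:
    out = {}
    for atom, item_id in battery.marginal_ids().items():
        if item_id in rs.values:
            out[atom] = rs.values[item_id]
    return out


def marginal_complementarity(rs: ResponseSet, battery: Battery) -> float:
    """Mean absolute deviation of P(A wins s) + P(B wins s) from 1.

    Averaged over the three states of the participant's triplet.  A state
    with a missing marginal is excluded; if all three are incomplete a
    :class:`CoverageError` is raised.
    """
    marg = _marginal_values(rs, battery)
    deviations = []
    for state in battery.states:
        pa = marg.get(EventAtom(Candidate.A, state))
        pb = marg.get(EventAtom(Candidate.B, state))
        if pa is None or pb is None:
            continue
        deviations.append(abs(math.fsum([pa, pb, -1.0])))
    if not deviations:
        raise CoverageError("no state has both marginals answered")
    return float(np.mean(deviations))


def joint_complementarity(rs: ResponseSet, battery: Battery) -> float:
    """Mean absolute deviation of four-term conjunction sums from 1.

    For each of the 3 state pairs x 2 presentation orders (6 configurations),
    the four sign-combination conjunction responses should sum to 1 under
    classical additivity.  Incomplete configurations are excluded; if all are
    incomplete a :class:`CoverageError` is raised.
    """
    groups: dict[tuple[frozenset, bool], list[float]] = {}
    for item in battery.items_of_kind(ItemKind.CONJUNCTION):
        key = (frozenset({item.first.state, item.second.state}), item.reversed)
        if item.item_id in rs.values:
            groups.setdefault(key, []).append(rs.values[item.item_id])
    deviations = [abs(math.fsum(vals) - 1.0) for vals in groups.values() if len(vals) == 4]
    if not deviations:
        raise CoverageError("no complete four-conjunction configuration answered")
    return float(np.mean(deviations))


def _share(numer: int, denom: int) -> float:
    return numer / denom if denom else float("nan")


def score_participant(rs: ResponseSet, battery: Battery,
                      min_coverage: float = 0.9) -> CoherenceScores:
    """Assemble the full coherence summary for one participant.

    Scoreable items are the 6 marginals plus the 24 ordered conjunctions and
    24 ordered disjunctions.  Metrics average over the available items;
    coverage below ``min_coverage`` raises :class:`CoverageError` listing the
    missing items rather than silently imputing.
    """
    marg = _marginal_values(rs, battery)
    scoreable = battery.items_of_kind(ItemKind.MARGINAL) \
        + battery.items_of_kind(ItemKind.CONJUNCTION) \
        + battery.items_of_kind(ItemKind.DISJUNCTION)
    missing = [it.item_id for it in scoreable if it.item_id not in rs.values]
    coverage = 1.0 - len(missing) / len(scoreable)
    if coverage < min_coverage:
        raise CoverageError(
            f"coverage {coverage:.2f} below {min_coverage:.2f}; missing items: {missing}"
        )

    flags = list(sorted(rs.flagged))
    cf_items, dcf_items, df_items, ddf_items = [], [], [], []
    for item in battery.items_of_kind(ItemKind.CONJUNCTION):
        pa, pb = marg.get(item.first), marg.get(item.second)
        pab = rs.values.get(item.item_id)
        if pa is None or pb is None or pab is None:
            flags.append(f"unscored:{item.item_id}")
            continue
        cf, dcf = conjunction_scores(pa, pb, pab)
        cf_items.append(cf)
        dcf_items.append(dcf)
    for item in battery.items_of_kind(ItemKind.DISJUNCTION):
        pa, pb = marg.get(item.first), marg.get(item.second)
        pavb = rs.values.get(item.item_id)
        if pa is None or pb is None or pavb is None:
            flags.append(f"unscored:{item.item_id}")
            continue
        df, ddf = disjunction_scores(pa, pb, pavb)
        df_items.append(df)
        ddf_items.append(ddf)

    n_cf = sum(1 for v in cf_items if v > 0)
    n_dcf = sum(1 for v in dcf_items if v > 0)
    n_df = sum(1 for v in df_items if v > 0)
    n_ddf = sum(1 for v in ddf_items if v > 0)
    n_conj, n_disj = len(cf_items), len(df_items)

    return CoherenceScores(
        persona_id=rs.persona_id,
        marginal_comp=marginal_complementarity(rs, battery),
        joint_comp=joint_complementarity(rs, battery),
        cf_mean=float(np.mean(cf_items)) if n_conj else float("nan"),
        dcf_mean=float(np.mean(dcf_items)) if n_conj else float("nan"),
        df_mean=float(np.mean(df_items)) if n_disj else float("nan"),
        ddf_mean=float(np.mean(ddf_items)) if n_disj else float("nan"),
        cf_prevalence=_share(n_cf, n_conj),
        dcf_prevalence=_share(n_dcf, n_conj),
        df_prevalence=_share(n_df, n_disj),
        ddf_prevalence=_share(n_ddf, n_disj),
        cf_single_share=_share(n_cf - n_dcf, n_cf),
        cf_double_share=_share(n_dcf, n_cf),
        df_single_share=_share(n_df - n_ddf, n_df),
        df_double_share=_share(n_ddf, n_df),
        n_conjunction_items=n_conj,
        n_disjunction_items=n_disj,
        n_cf_violations=n_cf,
        n_dcf_violations=n_dcf,
        n_df_violations=n_df,
        n_ddf_violations=n_ddf,
        flags=tuple(flags),
    )


def score_cohort(pairs: Iterable[tuple[ResponseSet, Battery]],
                 min_coverage: float = 0.9) -> pd.DataFrame:
    """Score every (response set, battery) pair; one row per participant."""
    rows = [score_participant(rs, bat, min_coverage=min_coverage).to_dict()
            for rs, bat in pairs]
    return pd.DataFrame(rows)


# The study reports violation prevalences; whether those pool items across
# participants or average participant-level rates is ambiguous, so both are
# emitted under explicit names.
def cohort_summary(scores: pd.DataFrame) -> dict:
    """Cohort-level summary: metric means/SDs plus both prevalence readings."""

    def pooled(viol_col: str, n_col: str) -> float:
        denom = scores[n_col].sum()
        return float(scores[viol_col].sum() / denom) if denom else float("nan")

    summary = {"n_participants": int(len(scores))}
    for metric in ("marginal_comp", "joint_comp", "cf_mean", "dcf_mean", "df_mean", "ddf_mean"):
        summary[f"{metric}_mean"] = float(scores[metric].mean())
        summary[f"{metric}_sd"] = float(scores[metric].std(ddof=1)) if len(scores) > 1 else float("nan")
    for fam, n_col in (("cf", "n_conjunction_items"), ("df", "n_disjunction_items")):
        summary[f"{fam}_prevalence_participant_mean"] = float(scores[f"{fam}_prevalence"].mean())
        summary[f"{fam}_prevalence_pooled"] = pooled(f"n_{fam}_violations", n_col)
        double_col = f"n_d{fam}_violations"
        n_viol = scores[f"n_{fam}_violations"].sum()
        summary[f"{fam}_single_share_pooled"] = (
            float((n_viol - scores[double_col].sum()) / n_viol) if n_viol else float("nan")
        )
        summary[f"{fam}_double_share_pooled"] = (
            float(scores[double_col].sum() / n_viol) if n_viol else float("nan")
        )
    return summary


def political_sensitivity(pairs: Sequence[tuple[ResponseSet, Battery]]) -> pd.DataFrame:
    """Per-state candidate asymmetry of marginal judgments across a cohort.

    For every state covered by the cohort, pairs each participant's raw 0-100
    marginal for candidate A (first label, e.g. Trump) with their marginal for
    candidate B, and reports the mean difference (A - B; positive favours A),
    the paired t statistic with ``df = n - 1``, and the two-sided p value.  A
    state with zero difference variance is flagged (t and p undefined).
    """
    per_state: dict[str, list[tuple[float, float]]] = {}
    for rs, battery in pairs:
        marg_ids = battery.marginal_ids()
        raw = rs.raw if rs.raw is not None else {k: v * 100.0 for k, v in rs.values.items()}
        for state in battery.states:
            ia = marg_ids.get(EventAtom(Candidate.A, state))
            ib = marg_ids.get(EventAtom(Candidate.B, state))
            if ia in raw and ib in raw:
                per_state.setdefault(state, []).append((float(raw[ia]), float(raw[ib])))

    rows = []
    for state, vals in per_state.items():
        if len(vals) < 2:
            raise ValueError(f"state {state!r} has fewer than 2 paired observations")
        a = np.array([v[0] for v in vals])
        b = np.array([v[1] for v in vals])
        d = a - b
        n = len(d)
        sd = d.std(ddof=1)
        if sd == 0.0:
            t = p = float("nan")
            degenerate = True
        else:
            t = float(d.mean() / (sd / math.sqrt(n)))
            p = float(2.0 * _sps.t.sf(abs(t), n - 1))
            degenerate = False
        rows.append(
            {
                "state": state,
                "mean_difference": float(d.mean()),
                "t": t,
                "df": n - 1,
                "p": p,
                "n": n,
                "degenerate_variance": degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("state")
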