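import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from probcoherence.battery import Candidate, EventAtom, ItemKind
from probcoherence.responders import (
    bayesian_sampler_respond,
    coherent_respond,
    make_persona_worlds,
    random_world,
    sampler_responder,
    uniform_world,
)
from probcoherence.responders import SamplerConfig
from probcoherence.scoring import (
    CoverageError,
    ResponseSet,
    cohort_summary,
    conjunction_scores,
    disjunction_scores,
    joint_complementarity,
    marginal_complementarity,
    political_sensitivity,
    score_cohort,
    score_participant,
)

from _oracles import brute_force_scores

unit = st.floats(0.0, 1.0, allow_nan=False)


class TestItemScores:
    @pytest.mark.parametrize("pa,pb,pab,cf,dcf", [
        (0.6, 0.4, 0.3, 0.0, 0.0),     # coherent triple
        (0.4, 0.7, 0.8, 0.5, 0.1),     # single + double excess
        (0.5, 0.5, 0.5, 0.0, 0.0),     # exact tie scores zero
        (0.2, 0.9, 0.95, 0.8, 0.05),
    ])
    def test_conjunction(self, pa, pb, pab, cf, dcf):
        got_cf, got_dcf = conjunction_scores(pa, pb, pab)
        assert got_cf == pytest.approx(cf) and got_dcf == pytest.approx(dcf)

    @pytest.mark.parametrize("pa,pb,pavb,df,ddf", [
        (0.3, 0.6, 0.7, 0.0, 0.0),
        (0.6, 0.4, 0.3, 0.4, 0.1),
        (0.2, 0.9, 0.2, 0.7, 0.0),     # tie with smaller constituent
    ])
    def test_disjunction(self, pa, pb, pavb, df, ddf):
        got_df, got_ddf = disjunction_scores(pa, pb, pavb)
        assert got_df == pytest.approx(df) and got_ddf == pytest.approx(ddf)

    @pytest.mark.parametrize("args", [(1.2, 0.5, 0.5), (0.5, -0.1, 0.5), (0.5, 0.5, 2.0)])
    def test_out_of_range_rejected(self, args):
        with pytest.raises(ValueError):
            conjunction_scores(*args)
        with pytest.raises(ValueError):
            disjunction_scores(*args)

    @given(pa=unit, pb=unit, pab=unit)
    def test_single_dominates_double(self, pa, pb, pab):
        cf, dcf = conjunction_scores(pa, pb, pab)
        df, ddf = disjunction_scores(pa, pb, pab)
        assert 0.0 <= dcf <= cf <= 2.0 and dcf <= 1.0
        assert 0.0 <= ddf <= df <= 2.0 and ddf <= 1.0

    @given(pa=unit, pb=unit, pab=unit, c=st.floats(0.01, 1.0))
    def test_scale_equivariance(self, pa, pb, pab, c):
        """Scores are linear: scoring on a shrunken scale shrinks scores."""
        cf, dcf = conjunction_scores(pa, pb, pab)
        cf_c, dcf_c = conjunction_scores(c * pa, c * pb, c * pab)
        assert cf_c == pytest.approx(c * cf, abs=1e-12)
        assert dcf_c == pytest.approx(c * dcf, abs=1e-12)


def response_set_from(battery, marginals=None, conj=None, disj=None, default=0.5):
    """Hand-build a complete ResponseSet with per-kind overrides."""
    values = {}
    for item in battery.items:
        if item.kind is ItemKind.MARGINAL:
            v = (marginals or {}).get((item.first.candidate, item.first.state), default)
        elif item.kind is ItemKind.CONJUNCTION:
            v = conj if conj is not None else default
        elif item.kind is ItemKind.DISJUNCTION:
            v = disj if disj is not None else default
        else:
            v = default
        values[item.item_id] = v
    return ResponseSet("hand", battery.triplet, values)


class TestComplementarity:
    def test_perfect_marginals(self, battery_t1):
        rs = response_set_from(battery_t1)
        assert marginal_complementarity(rs, battery_t1) == 0.0

    def test_direct_evaluation(self, battery_t1):
        per_state = {"Ohio": (0.6, 0.3), "Missouri": (0.5, 0.5), "Michigan": (0.8, 0.4)}
        marginals = {}
        for state, (pa, pb) in per_state.items():
            marginals[(Candidate.A, state)] = pa
            marginals[(Candidate.B, state)] = pb
        rs = response_set_from(battery_t1, marginals=marginals)
        assert marginal_complementarity(rs, battery_t1) == pytest.approx((0.1 + 0.0 + 0.2) / 3)

    def test_maximal_deviation(self, battery_t1):
        marginals = {(c, s): 1.0 for s in battery_t1.states for c in Candidate}
        rs = response_set_from(battery_t1, marginals=marginals)
        assert marginal_complementarity(rs, battery_t1) == pytest.approx(1.0)

    def test_joint_uniform_coherent(self, battery_t1):
        rs = response_set_from(battery_t1, conj=0.25)
        assert joint_complementarity(rs, battery_t1) == 0.0

    def test_joint_inflated(self, battery_t1):
        rs = response_set_from(battery_t1, conj=0.5)
        assert joint_complementarity(rs, battery_t1) == pytest.approx(1.0)

    def test_missing_marginal_excludes_state(self, battery_t1):
        rs = response_set_from(battery_t1)
        ohio_a = battery_t1.marginal_ids()[EventAtom(Candidate.A, "Ohio")]
        del rs.values[ohio_a]
        assert marginal_complementarity(rs, battery_t1) == 0.0  # other 2 states remain

    def test_all_marginals_missing_errors(self, battery_t1):
        rs = response_set_from(battery_t1)
        for item_id in battery_t1.marginal_ids().values():
            del rs.values[item_id]
        with pytest.raises(CoverageError):
            marginal_complementarity(rs, battery_t1)


class TestScoreParticipant:
    def test_coherent_baseline_is_zero(self, battery_t1, world_t1_uniform):
        s = score_participant(coherent_respond(world_t1_uniform, battery_t1), battery_t1)
        for name in ("marginal_comp", "joint_comp", "cf_mean", "dcf_mean",
                     "df_mean", "ddf_mean", "cf_prevalence", "df_prevalence"):
            assert getattr(s, name) == 0.0

    def test_single_planted_violation(self, battery_t1, world_t1_uniform):
        rs = coherent_respond(world_t1_uniform, battery_t1)
        target = battery_t1.items_of_kind(ItemKind.CONJUNCTION)[0]
        rs.values[target.item_id] = 0.8  # inflated above both 0.5 marginals
        s = score_participant(rs, battery_t1)
        assert s.cf_prevalence == pytest.approx(1 / 24)
        assert s.df_prevalence == 0.0
        assert s.n_conjunction_items == 24 and s.n_disjunction_items == 24

    def test_item_counts_include_both_presentation_orders(self, battery_t1, world_t1_uniform):
        s = score_participant(coherent_respond(world_t1_uniform, battery_t1), battery_t1)
        assert s.n_conjunction_items == 24
        assert s.n_disjunction_items == 24

    def test_low_coverage_raises_with_missing_ids(self, battery_t1, world_t1_uniform):
        rs = coherent_respond(world_t1_uniform, battery_t1)
        conj_ids = [it.item_id for it in battery_t1.items_of_kind(ItemKind.CONJUNCTION)]
        for item_id in conj_ids[:8]:  # drop 8/54 scoreable items -> coverage < 0.9
            del rs.values[item_id]
        with pytest.raises(CoverageError, match=conj_ids[0].replace("|", r"\|")):
            score_participant(rs, battery_t1)

    def test_matches_brute_force_oracle(self, battery_t1):
        rng = np.random.default_rng(42)
        item_ids = [it.item_id for it in battery_t1.items]
        for _ in range(200):
            values = {i: float(v) for i, v in zip(item_ids, rng.uniform(size=78))}
            rs = ResponseSet("r", "T1", values)
            got = score_participant(rs, battery_t1)
            expected = brute_force_scores(values, battery_t1)
            for name, ref in expected.items():
                assert abs(getattr(got, name) - ref) <= 1e-12, name

    def test_sampler_cohort_breaks_every_axiom(self, battery_t1):
        """Finite-sample cohorts show CF, DF and both complementarity failures."""
        worlds = make_persona_worlds(range(40), uniform_world("T1"), 1.0, seed=9)
        pairs = [
            (bayesian_sampler_respond(w, battery_t1, SamplerConfig(seed=i), persona_id=f"p{i}"),
             battery_t1)
            for i, w in enumerate(worlds)
        ]
        scores = score_cohort(pairs)
        assert (scores[["cf_mean", "df_mean", "marginal_comp", "joint_comp"]].mean() > 0).all()
        summary = cohort_summary(scores)
        assert 0 < summary["cf_prevalence_pooled"] <= 1
        assert summary["cf_single_share_pooled"] + summary["cf_double_share_pooled"] == pytest.approx(1.0)


class TestPoliticalSensitivity:
    def test_degenerate_variance_flagged(self, battery_t1):
        pairs = []
        for i in range(5):
            marginals = {(c, s): (0.6 if c is Candidate.A else 0.4)
                         for s in battery_t1.states for c in Candidate}
            rs = response_set_from(battery_t1, marginals=marginals)
            rs.persona_id = f"p{i}"
            pairs.append((rs, battery_t1))
        table = political_sensitivity(pairs)
        assert table["mean_difference"].tolist() == pytest.approx([20.0] * 3)
        assert table["degenerate_variance"].all()
        assert np.isnan(table["t"]).all()

    def test_antisymmetric_cohort_cancels(self, battery_t1):
        pairs = []
        for i, (pa, pb) in enumerate([(0.6, 0.5), (0.4, 0.5)] * 3):
            marginals = {(c, s): (pa if c is Candidate.A else pb)
                         for s in battery_t1.states for c in Candidate}
            rs = response_set_from(battery_t1, marginals=marginals)
            rs.persona_id = f"p{i}"
            pairs.append((rs, battery_t1))
        table = political_sensitivity(pairs)
        assert table["mean_difference"].tolist() == pytest.approx([0.0] * 3)
        assert (table["df"] == 5).all()

    def test_ground_truth_asymmetry_recovered(self, battery_t1):
        """A cohort whose latent beliefs favour candidate A shows positive diffs."""
        from test_responders import independent_world

        world = independent_world("T1", {"Ohio": 0.9, "Missouri": 0.9, "Michigan": 0.9})
        pairs = []
        for i in range(30):
            rs = bayesian_sampler_respond(world, battery_t1,
                                          SamplerConfig(seed=200 + i), persona_id=f"p{i}")
            pairs.append((rs, battery_t1))
        table = political_sensitivity(pairs)
        assert (table["mean_difference"] > 0).all()
        assert (table["p"] < 0.001).all()

    def test_too_few_observations(self, battery_t1):
        rs = response_set_from(battery_t1)
        with pytest.raises(ValueError):
            political_sensitivity([(rs, battery_t1)])
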