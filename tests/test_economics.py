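"""Cost/utility accrual, ICERs, currency conversion, classification."""

import numpy as np
import pytest

from cbescreen import (
    NaturalHistoryModel,
    State,
    classify_cost_effectiveness,
    compute_icer,
    cost_per_diagnosis,
    run_cea,
    run_cohort,
    vnd_to_usd,
)
from cbescreen.economics import accrue_costs, one_off_cost, qalys
from cbescreen.engine import life_years
from cbescreen.params import ParameterError, get_path, set_path
from conftest import quiet_params


class TestCostPerDiagnosis:
    def test_published_columns(self, params):
        c = params.costs
        assert cost_per_diagnosis(c.healthcare_sector.cbe_per_person, c.detection_rate) \
            == pytest.approx(55.0)
        assert cost_per_diagnosis(c.patient.cbe_per_person, c.detection_rate) \
            == pytest.approx(11.0)
        assert cost_per_diagnosis(c.public_payer.cbe_per_person, c.detection_rate) \
            == pytest.approx(44.0)

    def test_unit_rate_is_identity(self):
        assert cost_per_diagnosis(0.7, 1.0) == 0.7

    def test_zero_rate_rejected(self):
        with pytest.raises(ParameterError):
            cost_per_diagnosis(0.033, 0.0)


class TestCurrency:
    @pytest.mark.parametrize("vnd,usd", [(41.0, 1801), (54.2, 2381), (95.1, 4179), (0.0, 0)])
    def test_published_conversions(self, vnd, usd):
        assert vnd_to_usd(vnd, 22759.0) == usd

    def test_half_up_rounding(self):
        # 22759 * 0.5 / 1e6 million VND converts to exactly 0.5 USD
        assert vnd_to_usd(22759.0 * 0.5 / 1e6, 22759.0) == 1


class TestClassification:
    @pytest.mark.parametrize(
        "icer,expected",
        [
            (54.2, "highly_cost_effective"),
            (63.2, "highly_cost_effective"),
            (95.1, "cost_effective"),
            (189.6, "cost_effective"),
            (1000.0, "not_cost_effective"),
        ],
    )
    def test_thresholds(self, icer, expected):
        assert classify_cost_effectiveness(icer) == expected


class TestICER:
    def test_arithmetic(self):
        frag = compute_icer(46.2, 1.1, 1.3)
        assert frag.icer_per_qaly == pytest.approx(42.0)
        assert not frag.dominant and not frag.undefined

    def test_zero_cost_difference(self):
        assert compute_icer(0.0, 1.1, 1.3).icer_per_qaly == 0.0

    def test_dominance_flag(self):
        frag = compute_icer(-10.0, 1.0, 1.0)
        assert frag.dominant

    def test_zero_effect_is_undefined_not_a_crash(self):
        frag = compute_icer(5.0, 0.0, 0.0)
        assert frag.undefined and frag.icer_per_qaly is None


class TestQALYs:
    def test_unit_utilities_equal_life_years(self, params, space):
        p = params.copy()
        for group in ("on_treatment", "off_treatment", "mbc"):
            for band in ("under40", "age40_49", "age50_59", "age60plus", "pooled"):
                p = set_path(p, f"utilities.{group}.{band}", 1.0)
        trace = run_cohort(space.start_distribution(0.9), NaturalHistoryModel(p),
                           240, start_age=44.0)
        assert qalys(trace, p.utilities, 0.0) == pytest.approx(
            life_years(trace, 0.0), abs=1e-12
        )
        # and discounting commutes identically
        assert qalys(trace, p.utilities, 0.015) == pytest.approx(
            life_years(trace, 0.015), abs=1e-12
        )

    def test_zero_utilities_give_zero(self, params, space):
        p = params.copy()
        for group in ("on_treatment", "off_treatment", "mbc"):
            for band in ("under40", "age40_49", "age50_59", "age60plus"):
                p = set_path(p, f"utilities.{group}.{band}", 0.0)
        trace = run_cohort(space.start_distribution(0.9), NaturalHistoryModel(p),
                           24, start_age=44.0)
        assert qalys(trace, p.utilities, 0.0) == 0.0

    def test_mbc_age_band_value(self, params, space):
        """A cohort held in mBC at age 44 for a year accrues the 40-49 band utility."""
        p = quiet_params(params, mbc_death=0.0)
        trace = run_cohort(space.start_distribution(0.0), NaturalHistoryModel(p),
                           12, start_age=44.0)
        assert qalys(trace, p.utilities, 0.0) == pytest.approx(0.7044, abs=1e-12)


class TestCostAccrual:
    def test_all_dead_accrues_one_off_only(self, params, space):
        start = np.zeros(space.n_states)
        start[space.index(State.DEAD)] = 1.0
        trace = run_cohort(start, NaturalHistoryModel(params), 12, start_age=44.0)
        c = params.costs.healthcare_sector
        expected = c.diagnosis + 55.0
        assert accrue_costs(trace, params, "healthcare_sector", "screening") \
            == pytest.approx(expected)
        assert accrue_costs(trace, params, "healthcare_sector", "no_screening") \
            == pytest.approx(c.diagnosis)

    def test_year_on_targeted_therapy(self, params, space):
        """12 undiscounted months fully on targeted therapy cost 12 x 84.7."""
        from cbescreen.engine import CohortTrace

        p = quiet_params(params)
        p.settings.discount_rate = 0.0
        occ = np.zeros((13, space.n_states))
        occ[:, space.index(State.DFS_ON, 1)] = 1.0  # held on treatment throughout
        trace = CohortTrace(occupancy=occ, space=space, start_age=44.0)
        cost = accrue_costs(trace, p, "healthcare_sector", "no_screening")
        assert cost - p.costs.healthcare_sector.diagnosis == pytest.approx(12 * 84.7)

    def test_perspective_additivity(self, params, space):
        trace = run_cohort(space.start_distribution(0.9), NaturalHistoryModel(params),
                           360, start_age=44.0)
        for scenario in ("screening", "no_screening"):
            pat = accrue_costs(trace, params, "patient", scenario)
            pay = accrue_costs(trace, params, "public_payer", scenario)
            tot = accrue_costs(trace, params, "healthcare_sector", scenario)
            assert pat + pay == pytest.approx(tot, abs=1e-9)

    def test_unknown_perspective_rejected(self, params, space):
        trace = run_cohort(space.start_distribution(0.9), NaturalHistoryModel(params),
                           12, start_age=44.0)
        with pytest.raises(ParameterError, match="perspective"):
            accrue_costs(trace, params, "societal", "screening")

    def test_one_off_not_discounted_or_corrected(self, params):
        c = params.costs.healthcare_sector
        assert one_off_cost(c, params.costs.detection_rate, "screening") \
            == pytest.approx(c.diagnosis + 55.0)


@pytest.fixture(scope="module")
def result(params):
    return run_cea(params)


class TestRunCEA:

    def test_downstaging_gap_in_percentage_points(self, params):
        gap = 100 * (params.start_dfs_screening - params.start_dfs_no_screening)
        assert gap == pytest.approx(9.1)

    def test_screening_gains_qalys_and_lys(self, result):
        for p in ("patient", "public_payer", "healthcare_sector"):
            r = result[p]
            assert r.qaly_screening > r.qaly_no_screening
            assert r.ly_screening > r.ly_no_screening
            assert r.cost_screening > r.cost_no_screening

    def test_effects_identical_across_perspectives(self, result):
        rs = [result[p] for p in ("patient", "public_payer", "healthcare_sector")]
        assert len({r.qaly_screening for r in rs}) == 1
        assert len({r.ly_screening for r in rs}) == 1

    def test_healthcare_delta_cost_is_sum_of_components(self, result):
        assert result["healthcare_sector"].icer.delta_cost == pytest.approx(
            result["patient"].icer.delta_cost + result["public_payer"].icer.delta_cost,
            abs=1e-9,
        )

    def test_null_downstaging_leaves_only_screening_one_off(self, params):
        p = params.copy()
        p.start_dfs_screening = p.start_dfs_no_screening
        res = run_cea(p, horizon=240)
        frag = res["healthcare_sector"].icer
        assert frag.undefined
        assert frag.delta_cost == pytest.approx(55.0)

    def test_summary_frame_has_three_perspective_blocks(self, result):
        df = result.summary_frame()
        assert len(df) == 9
        assert set(df.perspective) == {"patient", "public_payer", "healthcare_sector"}

    def test_increasing_detection_rate_lowers_icer(self, params):
        low = run_cea(set_path(params, "costs.detection_rate", 0.0004), horizon=360)
        high = run_cea(set_path(params, "costs.detection_rate", 0.0008), horizon=360)
        assert high["public_payer"].icer.icer_per_qaly \
            < low["public_payer"].icer.icer_per_qaly


def test_delta_qaly_positive_under_random_downstaging(params):
    """More DFS mass at entry always gains QALYs, all else shared."""
    rng = np.random.default_rng(7)
    for _ in range(3):
        lo, hi = np.sort(rng.uniform(0.5, 0.99, size=2))
        if hi - lo < 0.01:
            hi = min(lo + 0.05, 1.0)
        p = params.copy()
        p.start_dfs_no_screening = float(lo)
        p.start_dfs_screening = float(hi)
        res = run_cea(p, horizon=240)
        assert res["healthcare_sector"].icer.delta_qaly > 0
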