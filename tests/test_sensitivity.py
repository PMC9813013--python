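"""DSA tornado, distribution fitting, PSA, CEAC, CE plane."""

import numpy as np
import pytest
from scipy import stats

from cbescreen import (
    DSAParameterRange,
    PSADistribution,
    ce_plane_export,
    ceac,
    fit_beta,
    fit_lognormal,
    run_cea,
    run_dsa,
    run_psa,
)
from cbescreen.params import ParameterError, set_path
from cbescreen.sensitivity import PSAResult
import pandas as pd

H = 240  # shortened horizon keeps one-way reruns fast; directions are unaffected


def _icer(params, perspective="public_payer", horizon=None):
    return run_cea(params, horizon=horizon)[perspective].icer.icer_per_qaly


class TestDSA:
    def test_empty_ranges_give_empty_table(self, params):
        tt = run_dsa(params, [])
        assert len(tt.table) == 0
        assert tt.base_icer == pytest.approx(_icer(params))

    def test_degenerate_range_has_zero_width(self, params):
        base = params.dfs.mbc_split
        tt = run_dsa(params, [DSAParameterRange("dfs.mbc_split", base, base)])
        row = tt.table.iloc[0]
        assert row.width == 0.0
        assert row.icer_low == pytest.approx(tt.base_icer)

    def test_base_outside_range_rejected(self, params):
        with pytest.raises(ParameterError, match="outside"):
            run_dsa(params, [DSAParameterRange("dfs.mbc_split", 0.1, 0.2)])

    def test_unknown_path_named_in_error(self, params):
        with pytest.raises(ParameterError, match="no_such"):
            run_dsa(params, [DSAParameterRange("dfs.no_such", 0.0, 1.0)])

    def test_sorted_by_width(self, params):
        ranges = [
            DSAParameterRange("start_dfs_no_screening", 0.724, 0.874, "ci95"),
            DSAParameterRange("dfs.mbc_split", 0.576, 0.864, "ci95"),
            DSAParameterRange("remission_to_mbc", 0.0061, 0.0091, "ci95"),
        ]
        tt = run_dsa(params, ranges)
        widths = tt.table.width.to_numpy()
        assert np.all(np.diff(widths) <= 0)

    def test_narrowing_downstaging_increases_icer(self, params):
        """A higher no-screening DFS start (smaller downstaging gap) raises the ICER."""
        base = _icer(params, horizon=H)
        shrunk = _icer(set_path(params, "start_dfs_no_screening", 0.874), horizon=H)
        widened = _icer(set_path(params, "start_dfs_no_screening", 0.724), horizon=H)
        assert shrunk > base > widened

    def test_lower_detection_rate_increases_icer(self, params):
        base = _icer(params, horizon=H)
        worse = _icer(set_path(params, "costs.detection_rate", 0.0004), horizon=H)
        assert worse > base

    def test_higher_cbe_cost_increases_icer(self, params):
        p = set_path(params, "costs.public_payer.cbe_per_person", 0.0264 * 1.2)
        assert _icer(p, horizon=H) > _icer(params, horizon=H)


class TestFitBeta:
    def test_symmetric_ci_gives_equal_shapes(self):
        a, b = fit_beta(0.5, 0.3, 0.7)
        assert a == pytest.approx(b, rel=1e-6)

    def test_mean_matched_exactly(self):
        a, b = fit_beta(0.72, 0.576, 0.864)
        assert a / (a + b) == pytest.approx(0.72, abs=1e-9)

    def test_quantiles_near_targets(self):
        a, b = fit_beta(0.5, 0.3, 0.7)
        q = stats.beta.ppf([0.025, 0.975], a, b)
        assert q[0] == pytest.approx(0.3, abs=0.01)
        assert q[1] == pytest.approx(0.7, abs=0.01)

    def test_sampling_recovers_mean(self):
        a, b = fit_beta(0.72, 0.576, 0.864)
        x = np.random.default_rng(0).beta(a, b, size=100_000)
        se = x.std(ddof=1) / np.sqrt(x.size)
        assert abs(x.mean() - 0.72) < 3 * se

    def test_non_bracketing_ci_rejected(self):
        with pytest.raises(ParameterError, match="bracket"):
            fit_beta(0.9, 0.1, 0.5)


class TestFitLognormal:
    def test_mean_matched_exactly(self):
        mu, sigma = fit_lognormal(84.7, 67.8, 101.6)
        assert np.exp(mu + sigma**2 / 2) == pytest.approx(84.7, rel=1e-9)

    def test_degenerate_ci_collapses_dispersion(self):
        mu, sigma = fit_lognormal(10.0, 10.0, 10.0)
        assert sigma < 1e-6

    def test_samples_positive(self):
        mu, sigma = fit_lognormal(5.0, 4.0, 6.0)
        x = np.random.default_rng(1).lognormal(mu, sigma, size=1000)
        assert np.all(x > 0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ParameterError):
            fit_lognormal(-1.0, 0.5, 2.0)


class TestPSA:
    def test_determinism(self, params):
        a = run_psa(params, n_iterations=5, seed=42, horizon=H)
        b = run_psa(params, n_iterations=5, seed=42, horizon=H)
        pd.testing.assert_frame_equal(a.iterations, b.iterations)
        c = run_psa(params, n_iterations=5, seed=43, horizon=H)
        assert not a.iterations.equals(c.iterations)

    def test_degenerate_distributions_reproduce_base_case(self, params):
        # dispersionless costs: every iteration equals the deterministic result
        dists = [
            PSADistribution.lognormal_from_ci(
                "costs.public_payer.monthly_targeted", 34.4, 34.4, 34.4
            )
        ]
        res = run_psa(params, distributions=dists, n_iterations=3, seed=0, horizon=H)
        base = run_cea(params, horizon=H)["public_payer"].icer
        np.testing.assert_allclose(res.iterations.delta_qaly, base.delta_qaly, rtol=1e-9)
        np.testing.assert_allclose(res.iterations.delta_cost, base.delta_cost, rtol=1e-4)

    def test_iteration_count_as_configured(self, params):
        res = run_psa(params, n_iterations=7, seed=0, horizon=H)
        assert res.n_iterations == 7 and len(res.iterations) == 7

    def test_northeast_quadrant(self, params):
        """Screening costs more and gains more in every draw of the default PSA."""
        res = run_psa(params, n_iterations=40, seed=3, horizon=H)
        assert (res.iterations.delta_cost > 0).all()
        assert (res.iterations.delta_qaly > 0).all()

    def test_mean_converges_to_base_as_dispersion_shrinks(self, params):
        from cbescreen.sensitivity import default_psa_distributions

        base = run_cea(params, horizon=H)["public_payer"].icer

        def spread(width):
            dists = []
            for path, mean in (
                ("costs.public_payer.monthly_targeted", 34.4),
                ("costs.public_payer.cbe_per_person", 0.0264),
            ):
                dists.append(PSADistribution.lognormal_from_ci(
                    path, mean, mean * (1 - width), mean * (1 + width)))
            res = run_psa(params, distributions=dists, n_iterations=60, seed=5, horizon=H)
            return abs(res.iterations.delta_cost.mean() - base.delta_cost)

        assert spread(0.02) < spread(0.4)


def _toy_psa(dc, dq):
    df = pd.DataFrame({"delta_cost": dc, "delta_qaly": dq, "delta_ly": dq})
    return PSAResult(iterations=df, seed=0, n_iterations=len(df),
                     perspective="public_payer", wtp_highly=63.2,
                     wtp_cost_effective=189.6)


class TestCEAC:
    def test_zero_wtp_with_positive_costs_gives_zero(self):
        res = _toy_psa([10.0, 20.0], [1.0, 2.0])
        table = ceac(res, wtp_grid=[0.0])
        assert table.probability_cost_effective.iloc[0] == 0.0

    def test_large_wtp_with_positive_qalys_gives_one(self):
        res = _toy_psa([10.0, 20.0], [1.0, 2.0])
        table = ceac(res, wtp_grid=[1e9])
        assert table.probability_cost_effective.iloc[0] == 1.0

    def test_monotone_when_all_gains_positive(self):
        rng = np.random.default_rng(0)
        res = _toy_psa(rng.uniform(10, 100, 200), rng.uniform(0.1, 2.0, 200))
        table = ceac(res, wtp_grid=np.linspace(0, 400, 81))
        p = table.probability_cost_effective.to_numpy()
        assert np.all(np.diff(p) >= 0)
        assert np.all((p >= 0) & (p <= 1))

    def test_strict_nmb_rule_ties_not_cost_effective(self):
        res = _toy_psa([10.0], [1.0])
        table = ceac(res, wtp_grid=[10.0])  # NMB exactly zero
        assert table.probability_cost_effective.iloc[0] == 0.0


class TestCEPlane:
    def test_row_count_and_quadrants(self):
        res = _toy_psa([10.0, -5.0, 3.0], [1.0, 0.5, -0.2])
        df = ce_plane_export(res)
        assert len(df) == 3
        assert list(df.quadrant) == ["NE", "SE", "NW"]
        assert df.attrs["thresholds"] == (63.2, 189.6)

    def test_single_degenerate_iteration(self, params):
        dists = []
        res = run_psa(params, distributions=dists, n_iterations=1, seed=0, horizon=H)
        df = ce_plane_export(res)
        base = run_cea(params, horizon=H)["public_payer"].icer
        assert df.delta_cost.iloc[0] == pytest.approx(base.delta_cost)
        assert df.delta_qaly.iloc[0] == pytest.approx(base.delta_qaly)
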