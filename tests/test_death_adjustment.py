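"""Misclassification correction: bridging, ratio draws, combination,
rescaling, and the Poisson stochastic-variation layer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tenamericas.deaths import (
    MisclassificationRatio,
    apply_and_rescale,
    bridge_multirace_deaths,
    combine_ratio_dimensions,
    draw_ratios_lognormal,
    poisson_perturb,
)
from tenamericas.synthetic import apply_misreporting, derive_misclassification_ratios

RACES = ("AIAN", "Asian", "Black", "Latino", "White")


def _deaths(rows):
    return pd.DataFrame(rows, columns=["year", "county_id", "age_group", "sex",
                                       "race", "value"])


class TestBridgeMultiraceDeaths:
    def test_no_multirace_is_identity(self):
        df = _deaths([(2021, "C0", "40-44", "f", "White", 10.0)])
        out = bridge_multirace_deaths(df)
        pd.testing.assert_frame_equal(out, df)

    def test_proportional_allocation(self):
        df = _deaths([
            (2021, "C0", "40-44", "f", "A", 0.0),
            (2021, "C0", "40-44", "f", "B", 0.0),
            (2021, "C0", "40-44", "f", "C", 0.0),
            (2021, "C0", "40-44", "f", "Multiple", 100.0),
        ])
        comp = pd.DataFrame({
            "year": 2021, "county_id": "C0", "age_group": "40-44", "sex": "f",
            "race": ["A", "B", "C"], "share": [0.5, 0.3, 0.2],
        })
        out = bridge_multirace_deaths(df, composition=comp).set_index("race")["value"]
        assert out["A"] == pytest.approx(50.0)
        assert out["B"] == pytest.approx(30.0)
        assert out["C"] == pytest.approx(20.0)

    def test_grand_total_conserved(self, vitals):
        comp = vitals.population_true.rename(columns={"value": "share"})
        out = bridge_multirace_deaths(vitals.deaths, composition=comp)
        assert out["value"].sum() == pytest.approx(vitals.deaths["value"].sum())
        assert "Multiple" not in set(out["race"])

    def test_all_zero_composition_rejected(self):
        df = _deaths([
            (2021, "C0", "40-44", "f", "A", 0.0),
            (2021, "C0", "40-44", "f", "Multiple", 5.0),
        ])
        comp = pd.DataFrame({
            "year": 2021, "county_id": "C0", "age_group": "40-44", "sex": "f",
            "race": ["A"], "share": [0.0],
        })
        with pytest.raises(ValueError, match="composition"):
            bridge_multirace_deaths(df, composition=comp)


class TestLognormalDraws:
    def test_zero_se_is_degenerate_at_mean(self):
        draws = draw_ratios_lognormal(1.3, 0.0, n_sims=50, seed=1)
        assert np.all(draws == pytest.approx(1.3))
        draws = draw_ratios_lognormal(1.0, 0.0, n_sims=50, seed=1)
        assert np.all(draws == 1.0)

    def test_arithmetic_moment_matching(self):
        draws = draw_ratios_lognormal(1.2, 0.1, n_sims=100_000, seed=2)
        assert draws.mean() == pytest.approx(1.2, abs=0.002)
        assert draws.std(ddof=1) == pytest.approx(0.1, abs=0.002)

    def test_strict_positivity(self):
        draws = draw_ratios_lognormal(0.5, 2.0, n_sims=10_000, seed=3)
        assert (draws > 0).all()

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            draw_ratios_lognormal(0.0, 0.1, n_sims=10, seed=1)
        with pytest.raises(ValueError):
            MisclassificationRatio("AIAN", "overall", "all", mean=-1.0, se=0.1)


class TestCombineDimensions:
    def test_no_deviation_returns_overall(self):
        overall = np.array([1.1, 0.9, 1.3])
        combined = combine_ratio_dimensions(
            overall, {"age_sex": overall, "region": overall})
        assert np.allclose(combined, overall)

    def test_single_active_dimension(self):
        overall = np.full(4, 1.0)
        combined = combine_ratio_dimensions(
            overall, {"age_sex": np.full(4, 1.2), "region": overall})
        assert np.allclose(combined, 1.2)

    def test_general_multiplicative_deviations(self):
        overall = np.array([1.1])
        combined = combine_ratio_dimensions(
            overall, {"age_sex": np.array([1.21]), "region": np.array([1.0])})
        assert combined[0] == pytest.approx(1.1 * (1.21 / 1.1) * (1.0 / 1.1))

    def test_misaligned_component_rejected(self):
        with pytest.raises(ValueError, match="align"):
            combine_ratio_dimensions(np.ones(3), {"region": np.ones(4)})


class TestApplyAndRescale:
    def test_unit_ratios_are_identity(self):
        raw = np.array([3.0, 7.0, 11.0])
        out = apply_and_rescale(raw, np.ones((3, 5)), np.zeros(3, dtype=int))
        assert np.allclose(out, raw[:, None])

    def test_hand_worked_example(self):
        # raw (10, 90), ratios (1.2, 1.0): corrected (12, 90) rescaled by
        # 100/102 -> (11.7647, 88.2353)
        raw = np.array([10.0, 90.0])
        ratios = np.array([[1.2], [1.0]])
        out = apply_and_rescale(raw, ratios, np.zeros(2, dtype=int))
        assert out[:, 0] == pytest.approx([11.7647, 88.2353], abs=1e-4)
        assert out[:, 0].sum() == pytest.approx(100.0, rel=1e-12)

    def test_single_race_stratum_is_fixed_point(self):
        raw = np.array([42.0])
        ratios = np.array([[1.7, 0.4, 2.2]])
        out = apply_and_rescale(raw, ratios, np.zeros(1, dtype=int))
        assert np.allclose(out, 42.0)

    @given(st.lists(st.floats(0.0, 1e4), min_size=2, max_size=8),
           st.integers(0, 2**31 - 1))
    def test_stratum_totals_conserved(self, raw, seed):
        raw = np.asarray(raw)
        if raw.sum() == 0:
            return
        rng = np.random.default_rng(seed)
        ratios = rng.lognormal(0.0, 0.3, size=(len(raw), 6))
        ids = rng.integers(0, 2, size=len(raw))
        out = apply_and_rescale(raw, ratios, ids)
        for stratum in (0, 1):
            mask = ids == stratum
            if mask.any():
                np.testing.assert_allclose(
                    out[mask].sum(axis=0), raw[mask].sum(), rtol=1e-9)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            apply_and_rescale(np.ones(2), np.zeros((2, 1)), np.zeros(2, dtype=int))


class TestPoissonPerturb:
    def test_zero_rate_gives_zero(self):
        out = poisson_perturb(np.zeros((4, 3)), seed=1)
        assert np.all(out == 0)

    def test_moments_at_rate_50(self):
        rates = np.full((1000, 100), 50.0)
        out = poisson_perturb(rates, seed=2)
        assert 49.9 <= out.mean() <= 50.1
        assert 49.3 <= out.var(ddof=1) <= 50.7

    def test_reproducible_under_fixed_seed(self):
        rates = np.random.default_rng(0).uniform(0, 20, size=(50, 8))
        assert np.array_equal(poisson_perturb(rates, seed=7),
                              poisson_perturb(rates, seed=7))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            poisson_perturb(np.array([[-1.0]]), seed=1)

    def test_mean_zero_noise_recovers_expectation(self):
        # averaging over simulations recovers the pre-Poisson rates within
        # a CLT bound: se of the mean at rate 40 with 1000 sims ~ 0.2
        rates = np.full((20, 1000), 40.0)
        out = poisson_perturb(rates, seed=3)
        assert np.abs(out.mean(axis=1) - 40.0).max() < 4 * np.sqrt(40 / 1000)


class TestBiasReduction:
    def test_correction_beats_no_correction_in_most_scenarios(self):
        """With >= 1e4 deaths per race and a known misreporting flow, the
        corrected race totals are closer to truth than uncorrected ones in
        at least 95% of scenarios."""
        p = 0.2
        m = np.eye(5)
        m[0, 0], m[0, 4] = 1 - p, p
        attrs = pd.DataFrame({"county_id": ["C0"], "region": ["South"],
                              "density_tercile_AIAN": ["T2"],
                              "density_tercile_Latino": ["T1"]})
        wins = 0
        n_scen = 20
        for seed in range(n_scen):
            deaths = pd.DataFrame({
                "year": 2020, "county_id": "C0", "age_group": "40-44",
                "sex": "female", "race": list(RACES),
                "value": [20_000, 15_000, 30_000, 25_000, 60_000],
            })
            recs = apply_misreporting(deaths, m, RACES, seed=seed)
            ratios = derive_misclassification_ratios(recs, attrs,
                                                     dimensions=())
            rec = recs.set_index("race")["deaths_recorded"].reindex(RACES).to_numpy(float)
            true = recs.set_index("race")["deaths_true"].reindex(RACES).to_numpy(float)
            r = ratios.set_index("race")["ratio"].reindex(RACES).to_numpy(float)
            draws = apply_and_rescale(rec, np.tile(r[:, None], (1, 1)),
                                      np.zeros(5, dtype=int))
            corrected = draws[:, 0]
            if np.abs(corrected[0] - true[0]) < np.abs(rec[0] - true[0]):
                wins += 1
        assert wins >= int(0.95 * n_scen)
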