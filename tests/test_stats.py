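"""Remoteness index, 2-SD standardisation and the Poisson GLM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emoc_access import (build_glm_dataset, fertile_women_remote, fit_poisson_glm,
                         gen_mortality, remoteness_index, scenario_report,
                         standardize_2sd)


def pat_of(rows):
    from emoc_access.travel_time import ZONE_LABELS, zone_of_minutes
    df = pd.DataFrame(rows, columns=["zone", "minutes", "persons"])
    df["zone_label"] = [ZONE_LABELS[int(c)] for c in zone_of_minutes(df["minutes"])]
    return df


class TestRemotenessIndex:
    def test_strict_threshold_arithmetic(self):
        rt = remoteness_index(pat_of([(1, 100.0, 70.0), (1, 130.0, 30.0)]))
        assert rt.loc[rt["zone"] == 1, "remoteness"].item() == pytest.approx(0.30)

    def test_everyone_within_reach_gives_zero(self):
        rt = remoteness_index(pat_of([(1, 120.0, 50.0), (1, 10.0, 50.0)]))
        assert rt["remoteness"].item() == 0.0  # exactly 120 min is NOT remote

    def test_all_unreachable_gives_one(self):
        rt = remoteness_index(pat_of([(1, np.inf, 80.0)]))
        assert rt["remoteness"].item() == 1.0

    def test_zero_population_zone_flagged_undefined(self):
        rt = remoteness_index(pat_of([(1, 50.0, 10.0)]), zones=[1, 2])
        row = rt.loc[rt["zone"] == 2]
        assert not row["defined"].item()
        assert np.isnan(row["remoteness"].item())

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 500), st.floats(0.1, 100)), min_size=1, max_size=20))
    def test_index_always_in_unit_interval(self, cells):
        rt = remoteness_index(pat_of([(1, m, p) for m, p in cells]))
        assert 0.0 <= rt["remoteness"].item() <= 1.0


class TestFertileWomen:
    def test_product_of_fractions(self):
        rt = pd.DataFrame({"zone": [1], "persons_remote": [10_000.0],
                           "persons_total": [20_000.0], "remoteness": [0.5],
                           "defined": [True]})
        census = pd.DataFrame({"zone": [1], "population": [20_000],
                               "female_fraction": [0.5], "fertile_fraction": [0.43]})
        out = fertile_women_remote(rt, census)
        assert out["fertile_women_remote"].item() == pytest.approx(2150.0)

    def test_zero_fertile_fraction(self):
        rt = pd.DataFrame({"zone": [1], "persons_remote": [10_000.0]})
        census = pd.DataFrame({"zone": [1], "female_fraction": [0.5],
                               "fertile_fraction": [0.0]})
        assert fertile_women_remote(rt, census)["fertile_women_remote"].item() == 0.0


class TestStandardize2SD:
    def test_closed_form_two_points(self):
        z, mean, sd = standardize_2sd([0.0, 1.0])
        assert mean == pytest.approx(0.5)
        assert sd == pytest.approx(np.sqrt(0.5))
        assert z == pytest.approx([-0.35355339, 0.35355339])

    def test_result_has_sd_half_and_round_trips(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 50)
        z, mean, sd = standardize_2sd(x)
        assert z.std(ddof=1) == pytest.approx(0.5)
        assert np.allclose(z * 2 * sd + mean, x)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            standardize_2sd(np.ones(10))


class TestPoissonGLM:
    def test_intercept_only_is_log_mean(self):
        data = pd.DataFrame({"mmr": [1.0, 2.0, 3.0]})
        # pad to satisfy minimum rows
        data = pd.concat([data, pd.DataFrame({"mmr": [2.0]})], ignore_index=True)
        fit = fit_poisson_glm(data, response_mode="mmr", covariates=())
        assert fit.coef("intercept") == pytest.approx(np.log(2.0), abs=1e-10)

    def test_deaths_offset_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(1)
        n = 40
        r = rng.uniform(0, 1, n)
        s = rng.integers(0, 2, n).astype(float)
        births = rng.integers(2000, 20000, n)
        mu = births * np.exp(5.0 + 0.8 * r - 0.3 * s) / 1e5
        deaths = rng.poisson(mu)
        data = pd.DataFrame({"remoteness": r, "season": s, "deaths": deaths,
                             "births": births, "mmr": 1e5 * deaths / births})
        fit = fit_poisson_glm(data, response_mode="deaths_offset", standardize=False)
        X = sm.add_constant(np.column_stack([r, s]))
        ref = sm.GLM(deaths, X, family=sm.families.Poisson(),
                     offset=np.log(births / 1e5)).fit()
        assert np.allclose(fit.beta, ref.params, atol=1e-8)
        assert np.allclose(fit.se, ref.bse, rtol=1e-6)

    def test_standardized_and_raw_scales_consistent(self):
        rng = np.random.default_rng(2)
        n = 30
        r = rng.uniform(0, 1, n)
        s = rng.integers(0, 2, n).astype(float)
        mmr = np.exp(5.0 + 0.5 * r + 0.1 * s)
        data = pd.DataFrame({"remoteness": r, "season": s, "mmr": mmr})
        std = fit_poisson_glm(data, standardize=True)
        raw = fit_poisson_glm(data, standardize=False)
        # beta_std = beta_raw * 2 sd(r); raw-scale coefficients agree
        assert std.coef("remoteness") == pytest.approx(
            raw.coef("remoteness") * 2 * r.std(ddof=1), rel=1e-6)
        assert np.allclose(std.beta_raw, raw.beta, rtol=1e-6)

    def test_mmr_and_offset_agree_with_constant_births(self):
        rng = np.random.default_rng(3)
        n = 32
        r = rng.uniform(0, 1, n)
        s = np.repeat([0.0, 1.0], n // 2)
        births = np.full(n, 10_000)
        deaths = rng.poisson(births * np.exp(5.2 + 0.6 * r + 0.2 * s) / 1e5)
        data = pd.DataFrame({"remoteness": r, "season": s, "deaths": deaths,
                             "births": births, "mmr": 1e5 * deaths / births})
        a = fit_poisson_glm(data, response_mode="mmr")
        b = fit_poisson_glm(data, response_mode="deaths_offset")
        assert np.allclose(a.beta, b.beta, atol=1e-7)

    def test_rank_deficiency_rejected(self):
        data = pd.DataFrame({"remoteness": [0.1, 0.2, 0.3, 0.4],
                             "season": [0.0, 0.0, 0.0, 0.0],  # constant binary
                             "mmr": [100.0, 110.0, 120.0, 130.0]})
        # constant season column makes [intercept, season] collinear
        with pytest.raises(ValueError, match="rank"):
            fit_poisson_glm(data)

    def test_too_few_rows_rejected(self):
        data = pd.DataFrame({"remoteness": [0.1, 0.9], "season": [0, 1],
                             "mmr": [100.0, 200.0]})
        with pytest.raises(ValueError, match="rows"):
            fit_poisson_glm(data)


class TestGLMDataset:
    def test_mean_of_yearly_ratios_and_shared_mmr(self):
        mort = pd.DataFrame({
            "zone": [1, 1, 2, 2], "year": [0, 1, 0, 1],
            "deaths": [1, 3, 0, 2], "births": [1000, 1000, 500, 500],
        })
        rt = pd.DataFrame({"zone": [1, 1, 2, 2], "season": [0, 1, 0, 1],
                           "remoteness": [0.2, 0.1, 0.8, 0.6]})
        data = build_glm_dataset(rt, mort)
        assert len(data) == 4  # two rows per zone, shared MMR across seasons
        z1 = data.loc[data["zone"] == 1, "mmr"].unique()
        assert z1.item() == pytest.approx(np.mean([100.0, 300.0]) * 1000 / 1000)

    def test_zero_birth_years_dropped_with_warning(self):
        mort = pd.DataFrame({"zone": [1, 1], "year": [0, 1],
                             "deaths": [0, 2], "births": [0, 1000]})
        rt = pd.DataFrame({"zone": [1, 1], "season": [0, 1], "remoteness": [0.5, 0.4]})
        with pytest.warns(UserWarning, match="zero births"):
            data = build_glm_dataset(rt, mort)
        assert data["mmr"].unique().item() == pytest.approx(200.0)

    def test_pooled_vs_mean_of_ratios(self):
        # yearly ratios 100 and 300; pooled (1+3)/(1000+3000) differs
        mort = pd.DataFrame({"zone": [1, 1], "year": [0, 1],
                             "deaths": [1, 9], "births": [1000, 3000]})
        rt = pd.DataFrame({"zone": [1, 1], "season": [0, 1], "remoteness": [0.5, 0.4]})
        pooled = build_glm_dataset(rt, mort, pool_years=True)
        assert pooled["mmr"].unique().item() == pytest.approx(1e5 * 10 / 4000)
        unpooled = build_glm_dataset(rt, mort)
        assert unpooled["mmr"].unique().item() == pytest.approx((100.0 + 300.0) / 2)


class TestScenarioReport:
    def test_shares_sum_to_one(self):
        pats = {
            "car_dry": pat_of([(1, 20.0, 10.0), (1, 100.0, 30.0), (2, 150.0, 60.0)]),
            "bus_wet": pat_of([(1, 20.0, 50.0), (2, np.inf, 50.0)]),
        }
        rep = scenario_report(pats)
        assert np.allclose(rep.sum(axis=1), 1.0, atol=1e-9)
        assert rep.loc["bus_wet", ">120"] == pytest.approx(0.5)


def test_parameter_recovery_smoke():
    """The generator/fitter pair round-trips coefficients at moderate n."""
    rng_seed = 7
    r = np.random.default_rng(rng_seed).uniform(0, 1, 32)
    births = np.full(32, 20_000)
    truth = (np.log(250.0), 0.8, 0.3)
    parts = []
    for s in (0, 1):
        tab, _ = gen_mortality(r, s, births, truth, years=5, seed=rng_seed + s)
        parts.append(tab)
    mort = pd.concat(parts)
    rt = pd.DataFrame({"zone": np.tile(np.arange(1, 33), 2),
                       "season": np.repeat([0, 1], 32),
                       "remoteness": np.tile(r, 2)})
    data = build_glm_dataset(rt, mort)
    fit = fit_poisson_glm(data, response_mode="deaths_offset", standardize=False)
    assert fit.coef("intercept") == pytest.approx(truth[0], abs=0.1)
    assert fit.coef("remoteness") == pytest.approx(truth[1], abs=0.15)
    assert fit.coef("season") == pytest.approx(truth[2], abs=0.1)
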