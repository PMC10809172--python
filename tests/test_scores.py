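"""Diet-score construction: quantile binning, index ranges, standardization."""
import numpy as np
import pandas as pd
import pytest

from dietewas import scores as ds


def oracle_quantile_bin(values, n_bins, reverse=False, low=1):
    """Independent rank-then-bin oracle: average ranks by counting, bins by
    right-closed empirical quantile boundaries."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    ranks = np.empty(n)
    for i, xi in enumerate(x):
        less = np.sum(x < xi)
        ties = np.sum(x == xi)
        ranks[i] = less + (ties + 1) / 2.0
    edges = np.quantile(ranks, [k / n_bins for k in range(1, n_bins)])
    out = np.empty(n, dtype=int)
    for i, r in enumerate(ranks):
        b = sum(r > e for e in edges)
        if reverse:
            b = (n_bins - 1) - b
        out[i] = low + b
    return out


def _intake_table(n, rng, sex=None):
    from dietewas.config import FOOD_GROUPS
    table = pd.DataFrame({g: rng.lognormal(0.5, 0.6, n) for g in FOOD_GROUPS})
    table["sodium_mg"] = rng.lognormal(7.8, 0.4, n)
    table["participant_id"] = [f"p{i}" for i in range(n)]
    table["sex"] = sex if sex is not None else rng.choice(["F", "M"], n)
    table["energy"] = rng.normal(2000, 300, n)
    return table


class TestQuantileScores:
    @pytest.mark.parametrize("n_bins,low", [(5, 1), (4, 0)])
    def test_matches_rank_bin_oracle(self, rng, n_bins, low):
        x = rng.lognormal(0, 1, 500)
        x[::7] = x[0]  # inject ties
        for reverse in (False, True):
            got = ds.quantile_scores(x, n_bins, reverse=reverse, low=low)
            want = oracle_quantile_bin(x, n_bins, reverse=reverse, low=low)
            np.testing.assert_array_equal(got, want)

    def test_invariant_to_monotone_transform(self, rng):
        x = rng.lognormal(0, 1, 300)
        base = ds.quantile_scores(x, 5)
        np.testing.assert_array_equal(ds.quantile_scores(np.exp(x), 5), base)
        np.testing.assert_array_equal(ds.quantile_scores(3 * x - 7, 5), base)

    def test_constant_component_gets_midpoint(self):
        with pytest.warns(UserWarning, match="constant"):
            out = ds.quantile_scores(np.ones(50), 5)
        assert set(out) == {3}

    def test_own_score_monotone_in_intake(self, rng):
        # raising one participant's intake (distinct values) never lowers
        # that participant's component score
        x = rng.permutation(np.arange(100, dtype=float))
        before = ds.quantile_scores(x, 5)
        for i in (0, 17, 99):
            bumped = x.copy()
            bumped[i] += 37.5
            after = ds.quantile_scores(bumped, 5)
            assert after[i] >= before[i]


class TestEnergyFilter:
    def test_all_inside_bounds_unchanged(self, one_cohort):
        wide = {"F": (1.0, 1e6), "M": (1.0, 1e6)}
        out = ds.filter_implausible_energy(one_cohort, wide)
        assert len(out) == len(one_cohort)

    def test_forced_bounds(self):
        table = pd.DataFrame({"energy": [400.0, 2000.0, 5000.0],
                              "sex": ["F", "F", "F"]})
        out = ds.filter_implausible_energy(table, {"F": (500, 3500)})
        assert list(out["energy"]) == [2000.0]

    def test_missing_energy_removed_with_warning(self):
        table = pd.DataFrame({"energy": [np.nan, 2000.0], "sex": ["F", "F"]})
        with pytest.warns(UserWarning, match="missing energy"):
            out = ds.filter_implausible_energy(table, {"F": (500, 3500)})
        assert len(out) == 1

    def test_matches_row_scan_oracle(self, one_cohort):
        bounds = {"F": (1200.0, 2800.0), "M": (1400.0, 3200.0)}
        out = ds.filter_implausible_energy(one_cohort, bounds)
        kept = sum(
            bounds[row.sex][0] <= row.energy <= bounds[row.sex][1]
            for row in one_cohort.itertuples())
        assert len(out) == kept
        assert 0 < len(out) < len(one_cohort)

    def test_invalid_bounds_rejected(self, one_cohort):
        with pytest.raises(ValueError):
            ds.filter_implausible_energy(one_cohort, {"F": (3000.0, 500.0)})


class TestDash:
    def test_extremes(self, rng):
        table = _intake_table(100, rng)
        # participant 0: top of every positive, bottom of every negative
        for c in ("fruits", "vegetables", "nuts", "legumes", "dairy_lowfat",
                  "whole_grains"):
            table.loc[0, c] = table[c].max() * 10
            table.loc[1, c] = 0.0
        for c in ("sodium_mg", "ssb", "red_processed_meat"):
            table.loc[0, c] = 0.0
            table.loc[1, c] = table[c].max() * 10
        out = ds.compute_dash(table)
        assert out.iloc[0] == 40
        assert out.iloc[1] == 8

    def test_matches_component_oracle(self, rng):
        table = _intake_table(1000, rng)
        got = ds.compute_dash(table)
        want = np.zeros(len(table), dtype=int)
        for c in ("fruits", "vegetables", "dairy_lowfat", "whole_grains"):
            want += oracle_quantile_bin(table[c], 5)
        want += oracle_quantile_bin(table["nuts"] + table["legumes"], 5)
        for c in ("sodium_mg", "ssb", "red_processed_meat"):
            want += oracle_quantile_bin(table[c], 5, reverse=True)
        np.testing.assert_array_equal(got.to_numpy(), want)

    def test_range_and_integrality(self, one_cohort):
        out = ds.compute_dash(one_cohort).dropna()
        assert out.between(8, 40).all()
        assert (out == out.astype(int)).all()

    def test_missing_intake_excludes_participant(self, rng):
        table = _intake_table(50, rng)
        table.loc[3, "fruits"] = np.nan
        out = ds.compute_dash(table)
        assert np.isnan(out.iloc[3]) and out.drop(index=3).notna().all()


class TestHpdi:
    def test_extremes(self, rng):
        table = _intake_table(100, rng)
        for c in ds.HPDI_HEALTHY_PLANT:
            table.loc[0, c] = table[c].max() * 10
            table.loc[1, c] = 0.0
        for c in ds.HPDI_UNHEALTHY_PLANT + ds.HPDI_ANIMAL:
            table.loc[0, c] = 0.0
            table.loc[1, c] = table[c].max() * 10
        out = ds.compute_hpdi(table)
        assert out.iloc[0] == 90
        assert out.iloc[1] == 18

    def test_matches_component_oracle(self, rng):
        table = _intake_table(800, rng)
        got = ds.compute_hpdi(table)
        want = np.zeros(len(table), dtype=int)
        for c in ds.HPDI_HEALTHY_PLANT:
            want += oracle_quantile_bin(table[c], 5)
        for c in ds.HPDI_UNHEALTHY_PLANT + ds.HPDI_ANIMAL:
            want += oracle_quantile_bin(table[c], 5, reverse=True)
        np.testing.assert_array_equal(got.to_numpy(), want)

    def test_range(self, one_cohort):
        out = ds.compute_hpdi(one_cohort).dropna()
        assert out.between(18, 90).all()


class TestMmds:
    def test_extremes_with_alcohol_window(self, rng):
        table = _intake_table(100, rng, sex="F")
        for c in ("vegetables", "fruits", "nuts", "legumes", "whole_grains",
                  "fish", "mufa_g"):
            table.loc[0, c] = table[c].max() * 10
            table.loc[1, c] = 0.001
        table.loc[0, "sfa_g"] = 0.001           # maximal MUFA:SFA ratio
        table.loc[1, "sfa_g"] = table["sfa_g"].max() * 10
        table.loc[0, "red_processed_meat"] = 0.0
        table.loc[1, "red_processed_meat"] = table["red_processed_meat"].max() * 10
        table.loc[0, "alcohol_g"] = 15.0        # inside the female window
        table.loc[1, "alcohol_g"] = 0.0
        out = ds.compute_mmds(table)
        assert out.iloc[0] == 27
        assert out.iloc[1] == 0

    def test_sfa_zero_uses_capped_ratio(self, rng):
        table = _intake_table(200, rng)
        table.loc[5, "sfa_g"] = 0.0
        out = ds.compute_mmds(table)
        assert out.notna().all()

    def test_matches_component_oracle(self, rng):
        table = _intake_table(600, rng, sex="M")
        got = ds.compute_mmds(table)
        ratio = np.minimum(table["mufa_g"] / table["sfa_g"],
                           np.quantile(table["mufa_g"] / table["sfa_g"], 0.99))
        want = np.zeros(len(table), dtype=int)
        for c in ("vegetables", "fruits", "nuts", "legumes", "whole_grains",
                  "fish"):
            want += oracle_quantile_bin(table[c], 4, low=0)
        want += oracle_quantile_bin(ratio, 4, low=0)
        want += oracle_quantile_bin(table["red_processed_meat"], 4, low=0,
                                    reverse=True)
        want += np.where((table["alcohol_g"] >= 10) & (table["alcohol_g"] <= 50),
                         3, 0)
        np.testing.assert_array_equal(got.to_numpy(), want)

    def test_range(self, one_cohort):
        out = ds.compute_mmds(one_cohort).dropna()
        assert out.between(0, 27).all()


class TestStandardize:
    def test_two_values(self):
        scores = pd.DataFrame({"dash_raw": [10.0, 14.0]})
        z = ds.standardize_scores(scores)["dash_z"]
        np.testing.assert_allclose(z.to_numpy(),
                                   [-1 / np.sqrt(2), 1 / np.sqrt(2)],
                                   atol=1e-12)

    def test_mean_zero_sd_one(self, one_cohort):
        raw = ds.compute_all_scores(one_cohort)
        z = ds.standardize_scores(raw)
        for col in ("mmds_z", "dash_z", "hpdi_z"):
            assert abs(z[col].mean()) < 1e-10
            assert abs(z[col].std(ddof=1) - 1) < 1e-10

    def test_per_cohort_groupwise(self, rng):
        # two cohorts with shifted scores: per-cohort means 0, global not
        a = pd.DataFrame({"dash_raw": rng.integers(8, 25, 100).astype(float)})
        b = pd.DataFrame({"dash_raw": rng.integers
                          (25, 41, 80).astype(float)})
        scores = pd.concat([a, b], ignore_index=True)
        cohort = pd.Series(["a"] * 100 + ["b"] * 80)
        z = ds.standardize_scores(scores, cohort)["dash_z"]
        for name in ("a", "b"):
            grp = z[cohort == name]
            assert abs(grp.mean()) < 1e-10
            assert abs(grp.std(ddof=1) - 1) < 1e-10
        raw_means = scores.groupby(cohort)["dash_raw"].mean()
        assert abs(raw_means["a"] - raw_means["b"]) > 1  # cohorts do differ

    def test_constant_score_raises(self):
        scores = pd.DataFrame({"dash_raw": [20.0, 20.0, 20.0]})
        with pytest.raises(ValueError, match="dash_raw"):
            ds.standardize_scores(scores)


class TestCorrelations:
    def test_duplicated_score_r_one(self, one_cohort):
        raw = ds.compute_all_scores(one_cohort)
        raw["hpdi_raw"] = raw["dash_raw"]
        corr = ds.score_correlations(raw)
        assert corr.loc["dash_raw", "hpdi_raw"] == pytest.approx(1.0)

    def test_matches_pearson_formula(self, one_cohort):
        raw = ds.compute_all_scores(one_cohort).dropna()
        corr = ds.score_correlations(raw)
        x = raw["mmds_raw"].to_numpy()
        y = raw["dash_raw"].to_numpy()
        manual = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert corr.loc["mmds_raw", "dash_raw"] == pytest.approx(manual, abs=1e-12)

    def test_symmetry_unit_diagonal(self, one_cohort):
        corr = ds.score_correlations(ds.compute_all_scores(one_cohort))
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T)
        np.testing.assert_allclose(np.diag(corr), 1.0)
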