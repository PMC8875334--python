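"""Outlier removal, rank and parametric group tests, linear and mixed models."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from deciquant.stats import (
    anova_tukey,
    fit_density_band_mixed,
    fit_site_adjusted_linear,
    kruskal_dunn,
    rout_outliers,
)


class TestRoutOutliers:
    def test_gross_outlier_flagged(self):
        values = list(np.linspace(0.1, 1.0, 10)) + [50.0]
        _, flagged = rout_outliers(values, Q=0.01)
        assert list(flagged) == [10]

    def test_identical_values_flag_nothing(self):
        kept, flagged = rout_outliers([3.0] * 8)
        assert flagged.size == 0
        assert kept.size == 8

    def test_minimum_sample_size_enforced(self):
        with pytest.raises(ValueError):
            rout_outliers([1.0, 2.0, 3.0, 4.0])

    def test_q_range_enforced(self):
        with pytest.raises(ValueError):
            rout_outliers(np.arange(10.0), Q=0.5)

    def test_null_flag_rate_small(self):
        rng = np.random.default_rng(42)
        total_flags = total_points = 0
        for _ in range(200):
            x = rng.standard_normal(100)
            _, flagged = rout_outliers(x, Q=0.01)
            total_flags += flagged.size
            total_points += x.size
        assert total_flags / total_points <= 0.02

    def test_fifty_mad_outlier_always_flagged(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.standard_normal(30)
            med = np.median(x)
            mad = np.median(np.abs(x - med)) * 1.4826
            x = np.append(x, med + 50 * mad)
            _, flagged = rout_outliers(x, Q=0.01)
            assert x.size - 1 in flagged


class TestKruskalDunn:
    def test_exact_p_equals_bruteforce_permutation(self):
        groups = [np.array([1.0, 2.0, 3.0]), np.array([10.0, 11.0, 12.0])]
        res = kruskal_dunn(groups, method="exact")
        pooled = np.concatenate(groups)
        h_obs = sps.kruskal(*groups).statistic
        count = total = 0
        for combo in itertools.combinations(range(6), 3):
            rest = [i for i in range(6) if i not in combo]
            h = sps.kruskal(pooled[list(combo)], pooled[rest]).statistic
            total += 1
            count += h >= h_obs - 1e-9
        assert res.omnibus_p == pytest.approx(count / total)

    def test_exact_p_with_ties_and_three_groups(self):
        groups = [np.array([1.0, 2.0]), np.array([2.0, 5.0, 7.0]), np.array([7.0, 9.0])]
        res = kruskal_dunn(groups, method="exact")
        pooled = np.concatenate(groups)
        h_obs = sps.kruskal(*groups).statistic
        count = total = 0
        idx = range(7)
        for g1 in itertools.combinations(idx, 2):
            rest1 = [i for i in idx if i not in g1]
            for g2 in itertools.combinations(rest1, 3):
                g3 = [i for i in rest1 if i not in g2]
                h = sps.kruskal(pooled[list(g1)], pooled[list(g2)], pooled[g3]).statistic
                total += 1
                count += h >= h_obs - 1e-9
        assert res.omnibus_p == pytest.approx(count / total)

    def test_dunn_z_matches_hand_formula(self):
        groups = {"a": np.array([1.0, 2, 3, 4]), "b": np.array([5.0, 6, 7]),
                  "c": np.array([8.0, 9, 10, 11])}
        res = kruskal_dunn(groups, method="asymptotic")
        # independent computation, no ties: var term n(n+1)/12
        pooled = np.concatenate(list(groups.values()))
        ranks = sps.rankdata(pooled)
        rbar = {"a": ranks[:4].mean(), "b": ranks[4:7].mean(), "c": ranks[7:].mean()}
        n = 11
        se_ab = np.sqrt(n * (n + 1) / 12 * (1 / 4 + 1 / 3))
        z_ab = (rbar["a"] - rbar["b"]) / se_ab
        row = res.pairwise[res.pairwise.contrast == "a vs b"].iloc[0]
        assert row.z == pytest.approx(z_ab)
        assert row.p_raw == pytest.approx(2 * sps.norm.sf(abs(z_ab)))
        assert row.p_adj == pytest.approx(min(1.0, 3 * row.p_raw))

    def test_power_under_large_shift(self):
        rng = np.random.default_rng(1)
        hits = 0
        n_sim = 100
        for _ in range(n_sim):
            g1 = rng.standard_normal(30)
            g2 = rng.standard_normal(30)
            g3 = rng.standard_normal(30) + 3.0
            res = kruskal_dunn([g1, g2, g3], method="asymptotic")
            hits += res.omnibus_p < 0.05
        assert hits / n_sim >= 0.9

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kruskal_dunn([np.array([1.0, 2.0])])
        with pytest.raises(ValueError):
            kruskal_dunn([np.array([1.0, 2.0]), np.array([3.0])])


class TestAnovaTukey:
    def test_identical_groups_give_f_zero_p_one(self):
        res = anova_tukey([np.array([1.0, 2, 3]), np.array([1.0, 2, 3])])
        assert res.f == pytest.approx(0.0)
        assert res.omnibus_p == pytest.approx(1.0)

    def test_all_constant_input_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey([np.array([5.0, 5.0]), np.array([5.0, 5.0])])

    def test_tukey_selects_only_shifted_group(self):
        rng = np.random.default_rng(3)
        selective = 0
        n_sim = 50
        for _ in range(n_sim):
            groups = {
                "a": rng.standard_normal(20),
                "b": rng.standard_normal(20),
                "c": rng.standard_normal(20) + 2.5,
            }
            res = anova_tukey(groups)
            sig = res.pairwise[res.pairwise.p_adj < 0.05].contrast.tolist()
            ok = all("c" in s for s in sig) and len(sig) == 2
            selective += ok
        assert selective / n_sim >= 0.9


class TestSiteAdjustedLinear:
    def test_intercept_only_equals_sample_mean(self):
        res = fit_site_adjusted_linear([1.0, 2.0, 3.0, 4.0], ["g"] * 4, ["a"] * 4)
        assert res.estimated_means.iloc[0]["mean"] == pytest.approx(2.5)

    def test_null_site_coefficient_stays_small(self):
        rng = np.random.default_rng(10)
        ok = 0
        n_sim = 100
        for _ in range(n_sim):
            n = 30
            group = ["normal"] * n + ["pe"] * n
            site = list(np.where(rng.random(2 * n) < 0.5, "A", "B"))
            y = np.r_[rng.normal(100, 5, n), rng.normal(108, 5, n)]
            res = fit_site_adjusted_linear(y, group, site)
            est, se = next(
                v for k, v in res.fixed_effects.items() if k.startswith("C(site")
            )
            ok += abs(est) < 3 * se
        assert ok / n_sim >= 0.95

    def test_group_effect_recovered_unbiased(self):
        rng = np.random.default_rng(11)
        estimates = []
        for _ in range(200):
            n = 30
            group = ["normal"] * n + ["pe"] * n
            site = (["A", "B"] * n)[: 2 * n]
            site_eff = {"A": 0.0, "B": 4.0}
            y = np.array(
                [
                    rng.normal(100 + (10 if g == "pe" else 0) + site_eff[s], 8)
                    for g, s in zip(group, site)
                ]
            )
            res = fit_site_adjusted_linear(y, group, site)
            diff = res.pairwise.iloc[0].estimate
            estimates.append(abs(diff))
        assert np.mean(estimates) == pytest.approx(10.0, abs=2.0)

    def test_confounded_design_raises_naming_columns(self):
        values = [1.0, 2.0, 3.0, 4.0]
        group = ["normal", "normal", "pe", "pe"]
        site = ["A", "A", "B", "B"]  # site == group, collinear
        with pytest.raises(ValueError, match="collinear"):
            fit_site_adjusted_linear(values, group, site)


def _band_data(rng, n_per_group=20, group_eff=8.0, subject_sd=5.0, resid_sd=5.0):
    rows = []
    for grp, eff in [("normal", 0.0), ("pe", group_eff)]:
        for s in range(n_per_group):
            b0 = rng.normal(0, subject_sd)
            for band, bshift in [("low", 0.0), ("high", -10.0)]:
                rows.append(
                    {
                        "subject": f"{grp}{s}",
                        "group": grp,
                        "site": "A" if s % 2 else "B",
                        "band": band,
                        "value": 100 + eff + bshift + b0 + rng.normal(0, resid_sd),
                    }
                )
    return pd.DataFrame(rows)


class TestDensityBandMixed:
    def test_group_effect_recovered(self):
        rng = np.random.default_rng(20)
        df = _band_data(rng, n_per_group=25)
        res = fit_density_band_mixed(df)
        assert res.extra["used_mixed"]
        low = res.pairwise[(res.pairwise.band == "low")].iloc[0]
        assert abs(low.estimate) == pytest.approx(8.0, abs=3.5)
        assert res.extra["random_intercept_var"] > 0

    def test_estimated_means_invariant_to_subject_relabeling(self):
        rng = np.random.default_rng(21)
        df = _band_data(rng)
        res_a = fit_density_band_mixed(df)
        shuffled = df.sample(frac=1.0, random_state=3).copy()
        mapping = {s: f"x{i}" for i, s in enumerate(df.subject.unique())}
        shuffled["subject"] = shuffled["subject"].map(mapping)
        res_b = fit_density_band_mixed(shuffled)
        a = res_a.estimated_means.sort_values(["group", "band"]).reset_index(drop=True)
        b = res_b.estimated_means.sort_values(["group", "band"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, rtol=1e-6)

    def test_duplicate_observations_match_dedup_fixed_effects(self):
        rng = np.random.default_rng(22)
        df = _band_data(rng)
        low_only = df[df.band == "low"]
        with pytest.warns(UserWarning, match="fixed-effects-only"):
            dedup = fit_density_band_mixed(low_only, bands=("low",))
        dup = pd.concat([low_only, low_only], ignore_index=True)
        res_dup = fit_density_band_mixed(dup, bands=("low",))
        for name, (est, _) in dedup.fixed_effects.items():
            assert res_dup.fixed_effects[name][0] == pytest.approx(est, abs=1e-4)

    def test_constant_site_dropped_without_changing_group_estimates(self):
        rng = np.random.default_rng(23)
        df = _band_data(rng)
        df["site"] = "A"
        res = fit_density_band_mixed(df)
        assert not any(k.startswith("C(site") for k in res.fixed_effects)
        assert len(res.estimated_means) == 4

    def test_zero_subject_variance_estimated_near_zero(self):
        rng = np.random.default_rng(24)
        near_zero = 0
        n_sim = 30
        for _ in range(n_sim):
            df = _band_data(rng, n_per_group=15, subject_sd=0.0, resid_sd=5.0)
            res = fit_density_band_mixed(df)
            resid_var = 25.0
            # upper bound consistent with zero between-subject variance
            near_zero += res.extra["random_intercept_var"] <= resid_var
        assert near_zero / n_sim >= 0.9

    def test_restricts_to_trophoblast_bands(self):
        rng = np.random.default_rng(25)
        df = _band_data(rng)
        extra = df.iloc[:4].copy()
        extra["band"] = "maternal"
        res = fit_density_band_mixed(pd.concat([df, extra], ignore_index=True))
        assert set(res.estimated_means.band) == {"low", "high"}
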