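"""The synthetic survey generator: construction options, seed determinism,
Monte-Carlo agreement of labels and counts with their stated distributions,
and consistency of the exported truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stagedist import synthetic as syn
from stagedist.gam import ztp_mean
from stagedist.hurdle import sample_ztp
from stagedist.io_core import REGIONS, validate_hauls, validate_lengths, \
    validate_smalks


class TestEnvironment:
    def test_flat_bathymetry_zero_slope(self):
        from scipy import ndimage
        env = syn.generate_environment(3, (12, 12), bathymetry="flat")
        # restrict to cells whose whole 3x3 neighbourhood is sea (coastal
        # cells legitimately see the land step)
        inner = ndimage.binary_erosion(env.sea_mask(),
                                       structure=np.ones((3, 3)))
        assert np.allclose(env.layers["slope"].values[inner], 0.0)

    def test_monotone_depth_in_longitude(self):
        env = syn.generate_environment(4, (15, 20), bathymetry="monotone")
        depth = env.layers["depth"].values
        for r in range(depth.shape[0]):
            row = depth[r][np.isfinite(depth[r])]
            if len(row) > 2:
                rho = stats.spearmanr(row, -np.arange(len(row))).statistic
                assert rho == 1.0        # deepens strictly westward

    def test_same_seed_identical_stack(self):
        a = syn.generate_environment(7, (12, 14))
        b = syn.generate_environment(7, (12, 14))
        for key in a.layers:
            np.testing.assert_array_equal(a.layers[key].values,
                                          b.layers[key].values)

    def test_distinct_seeds_differ(self):
        a = syn.generate_environment(7, (12, 14))
        b = syn.generate_environment(8, (12, 14))
        assert not np.allclose(a.layers["depth"].values,
                               b.layers["depth"].values, equal_nan=True)

    def test_too_small_grid_fatal(self):
        with pytest.raises(ValueError, match="10"):
            syn.generate_environment(1, (5, 30))

    def test_sediment_classes_and_land_mask(self, env):
        sed = env.layers["sediment"].values
        sea = env.sea_mask()
        assert set(np.unique(sed[sea])) <= {0.0, 1.0, 2.0, 3.0, 4.0}
        assert np.all(np.isnan(sed[~sea]))


class TestHauls:
    def test_counts_and_durations_by_survey(self, env):
        hauls = syn.generate_hauls(env, 10, (2011, 2012), "OCT_NOV", 1)
        counts = hauls.groupby("survey").size()
        assert counts["SWC_IBTS"] == 20 and counts["NIGFS"] == 20
        dur = hauls.groupby("survey")["duration"].unique()
        assert list(dur["SWC_IBTS"]) == [30] and list(dur["NIGFS"]) == [60]

    def test_all_hauls_on_sea_cells(self, env):
        hauls = syn.generate_hauls(env, 50, (2011,), "OCT_NOV", 2)
        template = env.template
        r, c = template.cell_index(hauls["lon"].to_numpy(),
                                   hauls["lat"].to_numpy())
        assert env.sea_mask()[r, c].all()

    def test_haul_density_uniform_over_zone_cells(self, env):
        """Chi-square goodness of fit of cell occupancy at n = 5000."""
        hauls = syn.generate_hauls(env, {"SWC_IBTS": 5000, "NIGFS": 0},
                                   (2011,), "OCT_NOV", 3)
        sub = hauls[hauls["survey"] == "SWC_IBTS"]
        template = env.template
        r, c = template.cell_index(sub["lon"].to_numpy(),
                                   sub["lat"].to_numpy())
        counts = pd.Series(zip(r, c)).value_counts()
        k = len(counts)
        observed = np.concatenate([counts.to_numpy(),
                                   np.zeros(0 if k else 1)])
        chi2, p = stats.chisquare(observed)
        assert p > 0.01

    def test_generated_tables_satisfy_io_invariants(self, env, truth):
        hauls = syn.generate_hauls(env, 15, (2011,), "OCT_NOV", 4)
        assert validate_hauls(hauls)[1].n_rejected == 0
        catches = syn.generate_catches(env, hauls, truth, 5)
        assert validate_lengths(catches, hauls["haul_id"])[1].n_rejected == 0
        smalks = syn.generate_smalks(truth, 20, (2011,), "OCT_NOV", 6)
        assert validate_smalks(smalks)[1].n_rejected == 0


class TestSmalks:
    def test_label_probability_matches_logistic_truth(self, truth):
        """Empirical P(age 0 | length bin) stays inside the binomial CI of
        the true logistic at n = 10000 for one region/sex/year."""
        sm = syn.generate_smalks(truth, 10000, (2011,), "OCT_NOV", 11)
        sub = sm[(sm.region == "N-O") & (sm.sex == "F")]
        bins = np.floor(sub["length"])
        for b, grp in sub.groupby(bins):
            if len(grp) < 50:
                continue
            p_true = truth.stage_prob("AGE0", "N-O", "F", 2011, b + 0.5)
            p_hat = (grp["age"] == 0).mean()
            se = np.sqrt(max(p_true * (1 - p_true), 1e-6) / len(grp))
            assert abs(p_hat - p_true) < 4 * se + 0.05

    def test_degenerate_steep_slope_splits_at_l50(self, env):
        truth = syn.default_truth(2, env)
        # near-degenerate logistic: extremely steep slope at the base L50
        for key in list(truth.stage_logit):
            if key[0] == "AGE0":
                l50 = truth.true_l50(*key)
                truth.stage_logit[key] = (50.0 * l50, -50.0)
        sm = syn.generate_smalks(truth, 500, (2011,), "OCT_NOV", 12)
        young = sm[sm["age"] == 0]
        old = sm[sm["age"] > 0]
        margin = 0.3
        l50s = {(r, s): truth.true_l50("AGE0", r, s, 2011)
                for r in REGIONS for s in "FM"}
        lo = min(l50s.values())
        assert (young["length"] < max(l50s.values()) + margin).all()
        assert (old["length"] > lo - margin).all()

    def test_same_seed_identical(self, truth):
        a = syn.generate_smalks(truth, 30, (2011,), "FEB_MAR", 9)
        b = syn.generate_smalks(truth, 30, (2011,), "FEB_MAR", 9)
        pd.testing.assert_frame_equal(a, b)

    def test_mature_implies_age_at_least_one(self, truth):
        sm = syn.generate_smalks(truth, 200, (2011,), "OCT_NOV", 13)
        assert not ((sm["mature"]) & (sm["age"] < 1)).any()


class TestCatches:
    def test_absent_presence_gives_no_rows(self, env, autumn_hauls):
        truth = syn.default_truth(1, env)
        truth.gear_presence = {k: -50.0 for k in truth.gear_presence}
        nullish = syn.TruthSpec(1, truth.regions, truth.stage_logit, "null",
                                gear_presence={k: -50.0 for k in
                                               truth.gear_presence},
                                gear_count=truth.gear_count)
        catches = syn.generate_catches(env, autumn_hauls.head(50), nullish, 3)
        assert len(catches) == 0

    def test_ztp_sampler_matches_closed_form_mean(self, rng):
        lam = 2.0
        draws = sample_ztp(rng, lam, size=10000)
        mu = ztp_mean(np.array([lam]))[0]
        var = mu * (1 + lam - mu)
        se = np.sqrt(var / 10000)
        assert np.all(draws >= 1)
        assert abs(draws.mean() - mu) < 3 * se

    def test_zero_fraction_matches_presence_probability(self, env, truth,
                                                        autumn_hauls):
        """Fraction of empty hauls tracks mean(1 - p) within Monte-Carlo
        error across seeds."""
        hauls = autumn_hauls.head(400).reset_index(drop=True)
        cov = syn.haul_covariates(env, hauls)
        c = {k: cov[k].to_numpy() for k in cov.columns}
        eta = truth.eta_presence("AGE0", c) + np.array(
            [truth.gear_presence[s] for s in hauls["survey"]])
        p = 1 / (1 + np.exp(-eta))
        catches = syn.generate_catches(env, hauls, truth, 21)
        n_empty = len(hauls) - catches["haul_id"].nunique()
        expected = np.sum(1 - p)
        se = np.sqrt(np.sum(p * (1 - p)))
        assert abs(n_empty - expected) < 3 * se + 1

    def test_standardisation_recovers_generated_counts(self, env, truth,
                                                       autumn_hauls):
        """Raw counts scale with tow duration so a 30-minute
        standardisation reproduces the generated standardized totals."""
        from stagedist.life_stages import standardise_cpue
        hauls = autumn_hauls.head(100)
        catches = syn.generate_catches(env, hauls, truth, 22)
        merged = catches.merge(hauls[["haul_id", "duration"]], on="haul_id")
        std = standardise_cpue(merged["count"].to_numpy(),
                               merged["duration"].to_numpy())
        assert np.all(std * merged["duration"] / 30 == merged["count"])


class TestTruthExport:
    def test_l50_is_minus_alpha_over_beta(self, truth, env):
        l50, _ = syn.export_truth(truth, env)
        for row in l50.sample(20, random_state=0).itertuples():
            alpha, beta = truth.logit_params(row.stage, row.region, row.sex,
                                             row.year)
            assert row.L50_cm == pytest.approx(-alpha / beta)

    def test_combined_surface_is_p_times_truncated_mean(self, truth, env):
        _, grids = syn.export_truth(truth, env)
        year = truth.years_autumn[0]
        p = grids[("AGE0", year, "p")].values
        lam = grids[("AGE0", year, "lambda")].values
        comb = grids[("AGE0", year, "cpue")].values
        ok = np.isfinite(comb)
        np.testing.assert_allclose(comb[ok],
                                   (p * ztp_mean(lam))[ok], rtol=1e-12)

    def test_truth_grids_share_stack_shape(self, truth, env):
        _, grids = syn.export_truth(truth, env)
        assert all(g.shape == env.shape for g in grids.values())
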