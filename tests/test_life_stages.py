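"""Life-stage models: CPUE standardisation arithmetic, closed-form logistic
evaluations, L50 algebra and recovery against the generator's truth,
likelihood-ratio elimination behaviour, and the CPUE decomposition."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from stagedist import life_stages as ls
from stagedist import synthetic as syn


@pytest.mark.parametrize("count, duration, expected", [
    (41, 60, 20),            # 41 * 0.5 = 20.5, floored
    (7, 30, 7),              # identity at the standard tow
    (0, 60, 0),
    (100, 120, 25),
])
def test_standardise_cpue_floors_to_thirty_minutes(count, duration, expected):
    assert ls.standardise_cpue(count, duration) == expected


def test_standardise_cpue_rejects_bad_inputs():
    with pytest.raises(ValueError, match="duration"):
        ls.standardise_cpue(5, 0)
    with pytest.raises(ValueError, match="non-negative"):
        ls.standardise_cpue(-1, 30)


def _simple_smalks(rng, n=2000, alpha=4.0, beta=-0.2, survey="SWC_IBTS"):
    length = rng.uniform(0, 45, n)
    p = special.expit(alpha + beta * length)
    age = np.where(rng.random(n) < p, 0, 1)
    mature = (age >= 1) & (rng.random(n) < special.expit(0.3 * (length - 25)))
    return pd.DataFrame({
        "length": length, "sex": rng.choice(["F", "M"], n), "age": age,
        "mature": mature, "region": rng.choice(["N-O", "Cl"], n),
        "year": rng.choice([2011, 2012], n), "survey": survey})


class TestFitAndPredict:
    def test_probability_closed_form(self, rng):
        """A length-only fit evaluated by hand: expit(alpha + beta L)."""
        df = _simple_smalks(rng, 4000)
        model = ls.fit_stage_model(df, "AGE0", "SWC_IBTS",
                                   mains=("length",), interactions=(),
                                   select=False)
        res = model.result
        a = res.params["Intercept"]
        b = res.params["length"]
        p = ls.stage_probability(model, 10.0, "F", "N-O", 2011)[0]
        assert p == pytest.approx(special.expit(a + b * 10.0), abs=1e-10)
        # and the generating curve is recovered: expit(4 - 0.2*10) ~ 0.8808
        assert p == pytest.approx(special.expit(2.0), abs=0.05)

    def test_lrt_statistic_is_twice_loglik_difference(self, rng):
        df = _simple_smalks(rng)
        full = ls.fit_stage_model(df, "AGE0", "SWC_IBTS",
                                  mains=("length", "sex"), interactions=(),
                                  select=False)
        red = ls.fit_stage_model(df, "AGE0", "SWC_IBTS",
                                 mains=("length",), interactions=(),
                                 select=False)
        lr = 2 * (full.loglik - red.loglik)
        assert lr >= -1e-8
        p = stats.chi2.sf(lr, 1)
        assert 0 <= p <= 1

    def test_unseen_level_fatal(self, rng):
        df = _simple_smalks(rng, 500)
        model = ls.fit_stage_model(df, "AGE0", "SWC_IBTS", interactions=(),
                                   select=False)
        with pytest.raises(ValueError, match="unseen region"):
            ls.stage_probability(model, 20.0, "F", "SE-IS", 2011)

    def test_mature_training_set_is_age_one_plus(self, rng):
        df = _simple_smalks(rng, 1000)
        model = ls.fit_stage_model(df, "MATURE", "SWC_IBTS",
                                   mains=("length",), interactions=(),
                                   select=False)
        assert model.n == int((df["age"] >= 1).sum())


class TestL50:
    def test_analytic_l50_no_interactions(self, rng):
        # alpha = 4, beta = -0.2 -> L50 = 20
        df = _simple_smalks(rng, 20000, alpha=4.0, beta=-0.2)
        model = ls.fit_stage_model(df, "AGE0", "SWC_IBTS",
                                   mains=("length",), interactions=(),
                                   select=False)
        assert ls.compute_L50(model, "F", "N-O", 2011) == pytest.approx(
            20.0, abs=0.5)

    def test_region_offset_shifts_l50_by_ratio(self):
        """Two regions differing by +5 in intercept at shared slope -0.2
        must differ by 25 cm in L50."""
        rng = np.random.default_rng(3)
        n = 30000
        length = rng.uniform(0, 80, n)
        region = rng.choice(["N-O", "Cl"], n)
        alpha = np.where(region == "N-O", 4.0, 9.0)
        p = special.expit(alpha - 0.2 * length)
        df = pd.DataFrame({
            "length": length, "sex": "F", "age": np.where(
                rng.random(n) < p, 0, 1),
            "mature": False, "region": region, "year": 2011,
            "survey": "SWC_IBTS"})
        df["mature"] = df["age"] >= 1
        model = ls.fit_stage_model(df, "AGE0", "SWC_IBTS",
                                   mains=("length", "region"),
                                   interactions=(), select=False)
        d = (ls.compute_L50(model, "F", "Cl", 2011)
             - ls.compute_L50(model, "F", "N-O", 2011))
        assert d == pytest.approx(25.0, abs=1.0)

    def test_recovery_against_truth_export(self, env):
        truth = syn.default_truth(5, env)
        sm = syn.generate_smalks(truth, 2000, (2011,), "OCT_NOV", 6)
        model = ls.fit_stage_model(sm, "AGE0", "SWC_IBTS", interactions=(),
                                   select=False)
        for region in ("N-O", "S-M", "Cl"):
            for sex in ("F", "M"):
                est = ls.compute_L50(model, sex, region, 2011)
                true = truth.true_l50("AGE0", region, sex, 2011)
                assert est == pytest.approx(true, abs=0.5)


class TestElimination:
    def test_null_sex_effect_eliminated_signal_kept(self, env):
        truth = syn.default_truth(4, env, sex_effect_cm=0.0)
        sm = syn.generate_smalks(truth, 600, (2011, 2012), "OCT_NOV", 7)
        model = ls.fit_stage_model(sm, "AGE0", "SWC_IBTS", interactions=())
        assert "length" in model.mains and "region" in model.mains

    def test_hierarchy_never_drops_main_under_interaction(self, rng):
        """With a strong length x region interaction the length and region
        mains must survive even if their own p-values are large."""
        n = 6000
        length = rng.uniform(5, 45, n)
        region = rng.choice(["N-O", "Cl"], n)
        beta = np.where(region == "N-O", -0.6, -0.25)   # slope differs
        p = special.expit(np.where(region == "N-O", 10.0, 5.0)
                          + beta * length)
        df = pd.DataFrame({
            "length": length, "sex": rng.choice(["F", "M"], n),
            "age": np.where(rng.random(n) < p, 0, 1),
            "mature": False, "region": region, "year": 2011,
            "survey": "SWC_IBTS"})
        df["mature"] = df["age"] >= 1
        model = ls.fit_stage_model(
            df, "AGE0", "SWC_IBTS", mains=("length", "region", "sex"),
            interactions=(("length", "region"),))
        if ("length", "region") in model.interactions:
            assert "length" in model.mains and "region" in model.mains


class TestDecomposition:
    def _haul_frame(self):
        return pd.DataFrame({
            "haul_id": ["h1"], "survey": ["SWC_IBTS"], "gear": ["GOV"],
            "year": [2011], "season": ["OCT_NOV"], "lon": [-8.0],
            "lat": [57.0], "duration": [30]})

    def _models(self, rng, alpha, beta):
        df = _simple_smalks(rng, 4000, alpha=alpha, beta=beta)
        m = ls.fit_stage_model(df, "AGE0", "SWC_IBTS", mains=("length",),
                               interactions=(), select=False)
        return df, {("AGE0", "SWC_IBTS"): m, ("AGE0", "NIGFS"): m}

    def test_two_class_hand_computation(self, rng, truth):
        """Counts (10, 20) at probabilities ~(0.9, 0.1) combine to ~11."""
        df, models = self._models(rng, alpha=0.0, beta=0.0)
        hauls = self._haul_frame()
        lengths = pd.DataFrame({
            "haul_id": ["h1", "h1"], "length_class": [10, 30],
            "sex": ["U", "U"], "count": [10.0, 20.0]})
        m = models[("AGE0", "SWC_IBTS")]
        p1 = m.predict(10.5, "F", "N-O", 2011)[0]
        p2 = m.predict(30.5, "F", "N-O", 2011)[0]
        out = ls.decompose_cpue(lengths, hauls, models,
                                truth.regions.region_of, df)
        assert out["cpue_age0"].iloc[0] == pytest.approx(10 * p1 + 20 * p2,
                                                         rel=1e-6)

    def test_certain_probability_returns_class_count(self, rng, truth):
        df, models = self._models(rng, alpha=8.0, beta=-0.4)  # p ~ 1 low L
        hauls = self._haul_frame()
        lengths = pd.DataFrame({"haul_id": ["h1"], "length_class": [5],
                                "sex": ["U"], "count": [17.0]})
        out = ls.decompose_cpue(lengths, hauls, models,
                                truth.regions.region_of, df)
        assert out["cpue_age0"].iloc[0] == pytest.approx(17.0, rel=2e-2)

    def test_zero_probability_gives_zero_cpue(self, rng, truth):
        df, models = self._models(rng, alpha=4.0, beta=-0.3)
        hauls = self._haul_frame()
        # p(40.5 cm) = expit(4 - 12.15) ~ 3e-4: essentially no age-0 mass
        lengths = pd.DataFrame({"haul_id": ["h1"], "length_class": [40],
                                "sex": ["U"], "count": [9.0]})
        out = ls.decompose_cpue(lengths, hauls, models,
                                truth.regions.region_of, df)
        assert out["cpue_age0"].iloc[0] == pytest.approx(0.0, abs=0.05)

    def test_out_of_season_stage_is_nan(self, rng, truth):
        df, models = self._models(rng, 4.0, -0.2)
        hauls = self._haul_frame()                      # autumn haul
        lengths = pd.DataFrame({"haul_id": ["h1"], "length_class": [12],
                                "sex": ["U"], "count": [4.0]})
        out = ls.decompose_cpue(lengths, hauls, models,
                                truth.regions.region_of, df)
        assert np.isnan(out["cpue_age1"].iloc[0])
        assert np.isnan(out["cpue_mature"].iloc[0])

    def test_stage_cpue_bounded_by_total_count(self, env, truth,
                                               autumn_hauls):
        hauls = autumn_hauls.head(60).reset_index(drop=True)
        catches = syn.generate_catches(env, hauls, truth, 31)
        sm = syn.generate_smalks(truth, 300, (2011, 2012), "OCT_NOV", 32)
        models = {("AGE0", s): ls.fit_stage_model(sm, "AGE0", s,
                                                  interactions=(),
                                                  select=False)
                  for s in ("SWC_IBTS", "NIGFS")}
        out = ls.decompose_cpue(catches, hauls, models,
                                truth.regions.region_of, sm)
        merged = catches.merge(hauls[["haul_id", "duration"]], on="haul_id")
        merged["std"] = ls.standardise_cpue(merged["count"].to_numpy(),
                                            merged["duration"].to_numpy())
        totals = merged.groupby("haul_id")["std"].sum()
        for row in out.itertuples():
            total = totals.get(row.haul_id, 0)
            assert row.cpue_age0 <= total + 1e-9
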