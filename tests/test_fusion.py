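"""Latent body-density fusion model: links, contrasts, prediction."""

import numpy as np
import pandas as pd
import pytest

from whalebody.datasets import tagged_whale_records
from whalebody.fusion import (
    UtbdModel,
    WhaleRecord,
    correlate_channels,
    predict_missing,
    season_day,
)
from whalebody.synthetic import PopulationSimConfig, simulate_population


@pytest.fixture(scope="module")
def small_population():
    cfg = PopulationSimConfig(n=40, n_tbd=26, n_lssai=24, n_both=10)
    return simulate_population(cfg, seed=21)


@pytest.fixture(scope="module")
def small_fit(small_population):
    records, truth = small_population
    model = UtbdModel(n_iter=6000, seed=4).fit(records)
    return records, truth, model


class TestSeasonDay:
    def test_summer_date_is_julian_day(self):
        assert season_day("2017-06-23") == 174.0

    def test_midwinter_shifted_into_previous_season(self):
        assert season_day("2017-01-22") == 22.0 + 365.0

    def test_november_not_shifted(self):
        assert season_day("2016-11-15") == 320.0


class TestWhaleRecordInvariants:
    def test_flags_require_female(self):
        with pytest.raises(ValueError, match="female"):
            WhaleRecord("w", "Canada", 180.0, sex="male", pregnant=True,
                        tbd_obs=[(1036.0, 2.0)])

    def test_at_least_one_channel(self):
        with pytest.raises(ValueError, match="channel"):
            WhaleRecord("w", "Canada", 180.0)

    def test_positive_obs_sd(self):
        with pytest.raises(ValueError):
            WhaleRecord("w", "Canada", 180.0, tbd_obs=[(1036.0, 0.0)])


class TestCorrelateChannels:
    def test_published_table_correlation(self):
        r, p = correlate_channels(tagged_whale_records())
        assert r == pytest.approx(-0.48, abs=0.005)
        assert p < 0.05

    def test_perfect_correlation(self):
        recs = [
            WhaleRecord(f"w{i}", "Canada", 150.0,
                        tbd_obs=[(1030.0 + i, 1.0)], lssai_obs=0.06 + 0.001 * i)
            for i in range(5)
        ]
        r, _ = correlate_channels(recs)
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        recs = [
            WhaleRecord(f"w{i}", "Canada", 150.0,
                        tbd_obs=[(1030.0 + i, 1.0)], lssai_obs=0.09 - 0.001 * i)
            for i in range(5)
        ]
        r, _ = correlate_channels(recs)
        assert r == pytest.approx(-1.0)

    def test_too_few_pairs_rejected(self):
        recs = [
            WhaleRecord("a", "Canada", 150.0, tbd_obs=[(1030.0, 1.0)], lssai_obs=0.07),
            WhaleRecord("b", "Canada", 150.0, tbd_obs=[(1031.0, 1.0)], lssai_obs=0.08),
        ]
        with pytest.raises(ValueError):
            correlate_channels(recs)


class TestFitProperties:
    def test_latents_positive_and_converged(self, small_fit):
        _, _, model = small_fit
        u_cols = [i for i, n in enumerate(model.result_.names) if n.startswith("utbd")]
        assert np.all(model.result_.flat[:, u_cols] > 0)
        assert (model.utbd_["utbd_mean"] > 1000).all()

    def test_link_slope_recovers_generated_value(self, small_fit):
        # 10 dual-channel whales: the slope posterior should lean negative
        # and cover the generating value
        _, truth, model = small_fit
        s = model.summary_.set_index("parameter")
        assert model.gamma_ < 0
        assert s.loc["gamma", "ci_lo"] < truth["link"]["gamma"] < s.loc["gamma", "ci_hi"]

    def test_effects_on_response_scale_match_exact_contrast(self, small_fit):
        # effect = exp(b0 + beta) - exp(b0) per draw, not mu_ref * beta
        _, _, model = small_fit
        flat = model.result_.flat
        lay = model._layout
        betas = flat[:, : lay["n_beta"]]
        b0 = betas[:, 0] - betas[:, 1:] @ lay["col_means"]
        j = model.terms_.index("pregnant") + 1
        exact = (np.exp(b0 + betas[:, j]) - np.exp(b0)).mean()
        reported = model.effects_.set_index("effect").loc["pregnant", "mean"]
        assert reported == pytest.approx(exact, rel=1e-3)

    def test_day_shift_changes_nothing_given_internal_anchoring(self, small_population):
        # season-day enters as (day - first sampling day): a constant shift
        # of every date leaves the fitted model identical draw for draw
        records, _ = small_population
        shifted = [
            WhaleRecord(
                r.whale_id, r.location, r.season_day + 50.0, r.sex, r.pregnant,
                r.lactating, r.immature, r.tbd_obs, r.lssai_obs,
            )
            for r in records
        ]
        m1 = UtbdModel(n_iter=1200, seed=4).fit(records)
        m2 = UtbdModel(n_iter=1200, seed=4).fit(shifted)
        assert np.array_equal(m1.result_.draws, m2.result_.draws)

    def test_null_link_slope_covered(self):
        cfg = PopulationSimConfig(
            n=40, n_tbd=26, n_lssai=24, n_both=10, link_gamma=0.0
        )
        records, _ = simulate_population(cfg, seed=5)
        model = UtbdModel(n_iter=5000, seed=2).fit(records)
        s = model.summary_.set_index("parameter")
        assert s.loc["gamma", "ci_lo"] < 0 < s.loc["gamma", "ci_hi"]

    def test_single_channel_whale_less_certain(self, small_fit):
        records, _, model = small_fit
        u = model.utbd_.set_index("whale_id")["utbd_sd"]
        dual = [r.whale_id for r in records if r.tbd_obs and r.lssai_obs is not None]
        lssai_only = [r.whale_id for r in records if not r.tbd_obs]
        assert u[lssai_only].mean() > u[dual].mean()

    def test_rare_factor_level_dropped_with_warning(self):
        records = [
            WhaleRecord(f"w{i}", "Canada", 150.0 + i, sex="female",
                        tbd_obs=[(1035.0 + i % 5, 2.0)])
            for i in range(12)
        ]
        with pytest.warns(UserWarning, match="fixed at 0"):
            model = UtbdModel(n_iter=600, seed=1).fit(records)
        assert "pregnant" not in model.terms_
        assert "norway" not in model.terms_

    def test_no_lssai_anywhere_drops_link(self):
        records = [
            WhaleRecord(f"w{i}", "Canada", 150.0 + 5 * i, sex="female",
                        tbd_obs=[(1034.0 + (i % 7), 2.0)])
            for i in range(15)
        ]
        with pytest.warns(UserWarning):
            model = UtbdModel(n_iter=600, seed=1).fit(records)
        assert not model.has_lssai_
        assert "gamma" not in list(model.summary_["parameter"])

    def test_seed_determinism(self, small_population):
        records, _ = small_population
        m1 = UtbdModel(n_iter=800, seed=9).fit(records)
        m2 = UtbdModel(n_iter=800, seed=9).fit(records)
        assert np.array_equal(m1.result_.draws, m2.result_.draws)


class TestTbdOnlyAgreesWithGammaGlm:
    def test_coefficients_near_glm_when_obs_error_tiny(self):
        # with a near-noiseless TBD channel and no LSSAI the model is a
        # Gamma regression; statsmodels GLM is the independent route
        import statsmodels.api as sm

        cfg = PopulationSimConfig(
            n=60, n_tbd=60, n_lssai=1, n_both=1,
            tbd_sd_range=(0.01, 0.02), p_canada=1.0,
        )
        records, truth = simulate_population(cfg, seed=13)
        for r in records:
            r.lssai_obs = None  # TBD channel only
        model = UtbdModel(n_iter=5000, seed=3).fit(records)

        day0 = min(r.season_day for r in records)
        y = np.array([r.tbd_obs[0][0] for r in records])
        X = pd.DataFrame(
            {
                "day100": [(r.season_day - day0) / 100.0 for r in records],
                "male": [float(r.sex == "male") for r in records],
                "sex_unknown": [float(r.sex == "unknown") for r in records],
                "pregnant": [float(r.pregnant) for r in records],
                "lactating": [float(r.lactating) for r in records],
                "immature": [float(r.immature) for r in records],
            }
        )
        X = X[[t for t in model.terms_]]
        glm = sm.GLM(
            y, sm.add_constant(X),
            family=sm.families.Gamma(link=sm.families.links.Log()),
        ).fit()
        post = model.summary_.set_index("parameter")
        for term in model.terms_:
            mean = post.loc[f"b_{term}", "mean"]
            sd = post.loc[f"b_{term}", "sd"]
            assert abs(mean - glm.params[term]) < 3 * max(sd, glm.bse[term])


class TestPredictMissing:
    def test_lssai_only_whale_gets_plausible_tbd(self, small_fit):
        records, _, model = small_fit
        target = next(r for r in records if not r.tbd_obs)
        pred = predict_missing(model, target)
        assert 1000.0 < pred.tbd_mean.iloc[0] < 1070.0
        assert pred.tbd_lo.iloc[0] < pred.tbd_mean.iloc[0] < pred.tbd_hi.iloc[0]

    def test_unseen_whale_predicted_from_covariates(self, small_fit):
        _, _, model = small_fit
        new = WhaleRecord("fresh", "Canada", 200.0, sex="female",
                          tbd_obs=[(1036.0, 2.0)])
        pred = model.predict([new])
        assert 1020.0 < pred.tbd_mean.iloc[0] < 1055.0

    def test_held_out_channel_covered(self, small_fit):
        # dual-channel whales: the LSSAI predictive interval should usually
        # cover the observed LSSAI
        records, _, model = small_fit
        dual = [r for r in records if r.tbd_obs and r.lssai_obs is not None]
        pred = model.predict(dual).set_index("whale_id")
        covered = sum(
            pred.loc[r.whale_id, "lssai_lo"]
            <= r.lssai_obs
            <= pred.loc[r.whale_id, "lssai_hi"]
            for r in dual
        )
        assert covered >= 0.9 * len(dual)

    def test_unfitted_model_rejected(self):
        with pytest.raises(RuntimeError):
            UtbdModel().predict()
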