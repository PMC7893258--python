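"""Bayesian glide fit: parameter recovery, DIC selection, grid oracle."""

import numpy as np
import pytest

from whalebody.density import (
    ModelStructure,
    TissueDensityModel,
    fit_hydro_model,
    grid_oracle,
    select_structure,
)
from whalebody.hydro import HydroParams
from whalebody.synthetic import GlideSimConfig, simulate_glides

FAST = dict(n_iter=3000, n_chains=3)


def one_whale_glides(noise=0.01, n=200, seed=11, rho=1036.0):
    cfg = GlideSimConfig(
        params={"w0": HydroParams(rho, 12e-6, 3.73e-5)},
        n_glides=n, noise_sd=noise,
    )
    return simulate_glides(cfg, seed=seed)


@pytest.fixture(scope="module")
def standard_fit():
    glides, truth = one_whale_glides()
    model = TissueDensityModel(structure=ModelStructure(), seed=5, **FAST).fit(glides)
    return glides, truth, model


class TestRecovery:
    def test_density_recovered_within_one_kgm3(self, standard_fit):
        _, truth, model = standard_fit
        row = model.tissue_density_.iloc[0]
        rho_true = truth["params"]["w0"]["tissue_density"]
        assert abs(row.rho_tissue_mean - rho_true) < 1.0
        assert row.ci_lo <= rho_true <= row.ci_hi
        assert model.converged_

    def test_noise_free_posterior_concentrates(self):
        glides, truth = one_whale_glides(noise=0.0, n=100, seed=2)
        model = TissueDensityModel(structure=ModelStructure(), seed=1, **FAST).fit(glides)
        row = model.tissue_density_.iloc[0]
        assert row.ci_hi - row.ci_lo < 0.2
        assert abs(row.rho_tissue_mean - 1036.0) < 0.1

    def test_three_whales_rank_ordered(self):
        cfg = GlideSimConfig(
            params={
                "a": HydroParams(1030.0, 12e-6, 3.73e-5),
                "b": HydroParams(1037.0, 12e-6, 3.73e-5),
                "c": HydroParams(1044.0, 12e-6, 3.73e-5),
            },
            n_glides=80,
        )
        glides, _ = simulate_glides(cfg, seed=3)
        model = TissueDensityModel(
            structure=ModelStructure(tissue_scope="individual"), seed=2, **FAST
        ).fit(glides)
        t = model.tissue_density_.set_index("whale_id")
        assert (
            t.loc["a", "rho_tissue_mean"]
            < t.loc["b", "rho_tissue_mean"]
            < t.loc["c", "rho_tissue_mean"]
        )

    def test_reordering_invariance(self, standard_fit):
        glides, _, model = standard_fit
        rng = np.random.default_rng(0)
        shuffled = [glides[i] for i in rng.permutation(len(glides))]
        model2 = TissueDensityModel(structure=ModelStructure(), seed=5, **FAST).fit(shuffled)
        assert model2.tissue_density_.iloc[0].rho_tissue_mean == pytest.approx(
            model.tissue_density_.iloc[0].rho_tissue_mean, abs=0.2
        )

    def test_inflated_errors_widen_interval(self, standard_fit):
        glides, _, model = standard_fit
        inflated = [
            type(g)(
                whale_id=g.whale_id, dive_id=g.dive_id, depth=g.depth,
                pitch=g.pitch, speed=g.speed, rho_sw=g.rho_sw, accel=g.accel,
                accel_se=g.accel_se * 10.0,
            )
            for g in glides
        ]
        wide = TissueDensityModel(structure=ModelStructure(), seed=5, **FAST).fit(inflated)
        w0 = model.tissue_density_.iloc[0]
        w1 = wide.tissue_density_.iloc[0]
        assert (w1.ci_hi - w1.ci_lo) > (w0.ci_hi - w0.ci_lo)

    def test_seed_determinism(self):
        glides, _ = one_whale_glides(n=50, seed=9)
        fits = [
            TissueDensityModel(structure=ModelStructure(), seed=7, n_iter=800).fit(glides)
            for _ in range(2)
        ]
        assert np.array_equal(fits[0].result_.draws, fits[1].result_.draws)

    def test_near_horizontal_glides_warn(self):
        cfg = GlideSimConfig(n_glides=30, pitch_mean_deg=4.0, pitch_sd_deg=1.0)
        glides, _ = simulate_glides(cfg, seed=4)
        with pytest.warns(UserWarning, match="near-horizontal"):
            TissueDensityModel(structure=ModelStructure(), seed=1, n_iter=500).fit(glides)


class TestGridOracle:
    def test_noiseless_truth_on_grid_recovered(self):
        glides, _ = one_whale_glides(noise=0.0, n=60, seed=6)
        out = grid_oracle(
            glides,
            rho_grid=np.arange(1030.0, 1042.5, 0.5),
            drag_grid=np.arange(8e-6, 16.5e-6, 0.5e-6),
            air_per_mass=3.73e-5,
        )
        assert out["rho_tissue"] == pytest.approx(1036.0)
        assert out["drag_term"] == pytest.approx(12e-6)
        assert out["sse"] == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_mcmc_within_one_cell(self, standard_fit):
        # condition the brute-force search on the fitted air volume so both
        # routes optimize the same two free parameters
        glides, _, model = standard_fit
        vair_post = model.summary_.set_index("parameter").loc["vair", "mean"]
        rho_step, drag_step = 0.25, 0.5e-6
        out = grid_oracle(
            glides,
            rho_grid=np.arange(1030.0, 1042.0 + rho_step, rho_step),
            drag_grid=np.arange(5e-6, 20e-6, drag_step),
            air_per_mass=float(vair_post),
        )
        post = model.tissue_density_.iloc[0].rho_tissue_mean
        assert abs(out["rho_tissue"] - post) <= rho_step
        drag_post = model.summary_.set_index("parameter").loc["drag_term", "mean"]
        assert abs(out["drag_term"] - drag_post) <= drag_step

    def test_empty_glides_rejected(self):
        with pytest.raises(ValueError):
            grid_oracle([], np.array([1036.0]), np.array([1e-5]), 0.0)


class TestStructureSelection:
    def test_planted_heterogeneity_prefers_individual(self):
        cfg = GlideSimConfig(
            params={
                "a": HydroParams(1028.0, 12e-6, 3.73e-5),
                "b": HydroParams(1046.0, 12e-6, 3.73e-5),
            },
            n_glides=60,
        )
        glides, _ = simulate_glides(cfg, seed=8)
        best, table = select_structure(
            glides,
            [
                ModelStructure(tissue_scope="individual"),
                ModelStructure(tissue_scope="global"),
            ],
            seed=1, n_iter=2000,
        )
        assert best.structure.tissue_scope == "individual"
        assert table.shape[0] == 2

    def test_planted_homogeneity_global_competitive(self):
        cfg = GlideSimConfig(
            params={
                "a": HydroParams(1036.0, 12e-6, 3.73e-5),
                "b": HydroParams(1036.0, 12e-6, 3.73e-5),
            },
            n_glides=60,
        )
        glides, _ = simulate_glides(cfg, seed=9)
        best, table = select_structure(
            glides,
            [
                ModelStructure(tissue_scope="individual"),
                ModelStructure(tissue_scope="global"),
            ],
            seed=1, n_iter=2000,
        )
        dic = table.set_index("structure")["dic"]
        ind = [s for s in dic.index if "individual" in s][0]
        glo = [s for s in dic.index if "tissue=global" in s][0]
        assert best.structure.tissue_scope == "global" or dic[glo] - dic[ind] < 2.0

    def test_single_candidate_returned(self):
        glides, _ = one_whale_glides(n=40, seed=10)
        best, table = select_structure(
            glides, [ModelStructure()], seed=1, n_iter=800
        )
        assert table.shape[0] == 1

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_structure([], [])


def test_functional_wrapper_matches_estimator():
    glides, _ = one_whale_glides(n=40, seed=12)
    fit = fit_hydro_model(glides, ModelStructure(), seed=3, n_iter=800)
    model = TissueDensityModel(structure=ModelStructure(), seed=3, n_iter=800).fit(glides)
    assert fit.dic == pytest.approx(model.dic_)
    assert np.array_equal(fit.mcmc.draws, model.result_.draws)
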