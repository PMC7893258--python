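"""Bayesian estimation of tissue body density from glide observations.

The hydrodynamic glide model predicts along-path acceleration from tissue
density, the combined drag term and the diving air volume; comparing the
prediction with the acceleration measured over many 5 s glides yields a
posterior for those unknowns.  Parameters can be individual (one value per
whale), global (shared), or -- for the air volume -- per dive with a
hierarchical mean; alternative structures are compared by DIC.

The front door is :class:`TissueDensityModel`, a scikit-learn style
estimator (``fit`` on a list of glide observations, fitted attributes with
trailing underscores); :func:`fit_hydro_model` and :func:`select_structure`
are thin functional wrappers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .hydro import (
    HydroParams,
    PhysicalConstants,
    DEFAULT_COMPRESSIBILITY,
    drag_prior_default,
)
from .kinematics import GlideObservation, frame_to_glides
from .mcmc import McmcConfig, McmcResult, run_mwg, summarize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelStructure:
    """Which parameters are individual vs shared.

    tissue_scope, drag_scope: 'individual' or 'global'; air_scope: 'global'
    or 'per_dive' (per-dive volumes share a hierarchical mean);
    error_model: 'per_glide' (use each segment's regression SE) or
    'estimated' (one global sigma_a, added in quadrature to the SEs).
    """

    tissue_scope: str = "global"
    drag_scope: str = "global"
    air_scope: str = "global"
    error_model: str = "per_glide"

    def __post_init__(self):
        if self.tissue_scope not in ("individual", "global"):
            raise ValueError("tissue_scope must be 'individual' or 'global'")
        if self.drag_scope not in ("individual", "global"):
            raise ValueError("drag_scope must be 'individual' or 'global'")
        if self.air_scope not in ("per_dive", "global"):
            raise ValueError("air_scope must be 'per_dive' or 'global'")
        if self.error_model not in ("per_glide", "estimated"):
            raise ValueError("error_model must be 'per_glide' or 'estimated'")

    @property
    def label(self) -> str:
        return (
            f"tissue={self.tissue_scope},drag={self.drag_scope},"
            f"air={self.air_scope},err={self.error_model}"
        )


DEFAULT_STRUCTURES = (
    ModelStructure(tissue_scope="individual", drag_scope="global"),
    ModelStructure(tissue_scope="global", drag_scope="global"),
)


@dataclass
class FitResult:
    """Posterior fit of one model structure."""

    structure: ModelStructure
    summaries: pd.DataFrame
    dic: float
    tissue_density: pd.DataFrame  # one row per whale: mean, sd, ci
    mcmc: McmcResult
    n_parameters: int
    converged: bool


def _as_glide_arrays(glides) -> dict:
    if isinstance(glides, pd.DataFrame):
        glides = frame_to_glides(glides)
    glides = list(glides)
    if not glides:
        raise ValueError("no glide observations")
    whales = sorted({g.whale_id for g in glides})
    dives = sorted({(g.whale_id, g.dive_id) for g in glides})
    w_index = {w: i for i, w in enumerate(whales)}
    d_index = {d: i for i, d in enumerate(dives)}
    return dict(
        depth=np.array([g.depth for g in glides]),
        pitch=np.array([g.pitch for g in glides]),
        speed=np.array([g.speed for g in glides]),
        rho_sw=np.array([g.rho_sw for g in glides]),
        accel=np.array([g.accel for g in glides]),
        se=np.array([g.accel_se for g in glides]),
        whale_idx=np.array([w_index[g.whale_id] for g in glides]),
        dive_idx=np.array([d_index[(g.whale_id, g.dive_id)] for g in glides]),
        whales=whales,
        dives=dives,
    )


class TissueDensityModel(BaseEstimator):
    """Bayesian hydrodynamic glide fit (scikit-learn style estimator).

    Parameters
    ----------
    structure : ModelStructure, optional
        Parameter scoping; default individual tissue density, global drag,
        global air volume, per-glide observation error.
    n_iter, burn_frac, n_chains, thin : MCMC settings (3 chains of 20 000
        iterations with 50% burn-in by default).
    seed : int
        Seed for the sampler; identical seed and settings give identical draws.
    rho_bounds : (float, float)
        Uniform prior support for tissue density, kg m^-3.
    drag_prior_sd : float
        SD of the truncated-normal drag prior (mean 11e-6 m^2 kg^-1).
    vair_max : float
        Upper bound of the uniform air-volume prior, m^3 kg^-1.
    sigma_scale : float
        Half-normal scale of the estimated global error sigma_a, m s^-2.
    se_floor : float
        Lower floor on per-glide acceleration SEs, m s^-2 (guards the
        noise-free limit).

    Attributes (after ``fit``)
    ----------
    result_ : McmcResult           raw draws and diagnostics
    summary_ : DataFrame           per-parameter posterior summaries
    dic_ : float                   deviance information criterion
    tissue_density_ : DataFrame    per-whale posterior mean/sd/CI, kg m^-3
    converged_ : bool              max split-R-hat below threshold
    """

    def __init__(
        self,
        structure: ModelStructure | None = None,
        n_iter: int = 20_000,
        burn_frac: float = 0.5,
        n_chains: int = 3,
        thin: int = 1,
        seed: int = 0,
        rho_bounds: tuple = (800.0, 1200.0),
        drag_prior_sd: float = 5e-6,
        vair_max: float = 2e-4,
        sigma_scale: float = 0.1,
        sigma_vair_scale: float = 2e-5,
        se_floor: float = 1e-4,
        compressibility: float = DEFAULT_COMPRESSIBILITY,
        constants: PhysicalConstants = PhysicalConstants(),
        rhat_threshold: float = 1.05,
    ):
        self.structure = structure
        self.n_iter = n_iter
        self.burn_frac = burn_frac
        self.n_chains = n_chains
        self.thin = thin
        self.seed = seed
        self.rho_bounds = rho_bounds
        self.drag_prior_sd = drag_prior_sd
        self.vair_max = vair_max
        self.sigma_scale = sigma_scale
        self.sigma_vair_scale = sigma_vair_scale
        self.se_floor = se_floor
        self.compressibility = compressibility
        self.constants = constants
        self.rhat_threshold = rhat_threshold

    # ---- parameter vector layout ------------------------------------
    def _layout(self, structure, n_whales, n_dives):
        names, lower, upper, step0, init = [], [], [], [], []

        n_rho = n_whales if structure.tissue_scope == "individual" else 1
        for i in range(n_rho):
            names.append(f"rho_tissue[{i}]" if n_rho > 1 else "rho_tissue")
            lower.append(self.rho_bounds[0])
            upper.append(self.rho_bounds[1])
            step0.append(0.5)
            init.append(1037.0)
        n_drag = n_whales if structure.drag_scope == "individual" else 1
        for i in range(n_drag):
            names.append(f"drag_term[{i}]" if n_drag > 1 else "drag_term")
            lower.append(0.0)
            upper.append(np.inf)
            step0.append(1e-6)
            init.append(11e-6)
        if structure.air_scope == "per_dive":
            names += ["vair_mu", "vair_sigma"]
            lower += [0.0, 0.0]
            upper += [self.vair_max, np.inf]
            step0 += [2e-6, 2e-6]
            init += [4e-5, 5e-6]
            for i in range(n_dives):
                names.append(f"vair[{i}]")
                lower.append(0.0)
                upper.append(self.vair_max)
                step0.append(2e-6)
                init.append(4e-5)
        else:
            names.append("vair")
            lower.append(0.0)
            upper.append(self.vair_max)
            step0.append(2e-6)
            init.append(4e-5)
        if structure.error_model == "estimated":
            names.append("sigma_a")
            lower.append(0.0)
            upper.append(np.inf)
            step0.append(0.005)
            init.append(0.05)
        return (
            names,
            np.array(lower),
            np.array(upper),
            np.array(step0),
            np.array(init),
        )

    def _predict_from_vector(self, x, structure, arr):
        n_w = len(arr["whales"])
        n_d = len(arr["dives"])
        pos = 0
        n_rho = n_w if structure.tissue_scope == "individual" else 1
        rho = x[pos : pos + n_rho]
        pos += n_rho
        n_drag = n_w if structure.drag_scope == "individual" else 1
        drag = x[pos : pos + n_drag]
        pos += n_drag
        if structure.air_scope == "per_dive":
            vair_mu, vair_sigma = x[pos], x[pos + 1]
            pos += 2
            vair = x[pos : pos + n_d]
            pos += n_d
            vair_obs = vair[arr["dive_idx"]]
        else:
            vair_mu = vair_sigma = None
            vair = x[pos : pos + 1]
            pos += 1
            vair_obs = vair[0]
        sigma_a = x[pos] if structure.error_model == "estimated" else 0.0

        rho_obs = rho[arr["whale_idx"]] if n_rho > 1 else rho[0]
        drag_obs = drag[arr["whale_idx"]] if n_drag > 1 else drag[0]

        c = self.constants
        press_pa = (1.0 + 0.1 * arr["depth"]) * c.atmosphere_pa
        rho_t = rho_obs / (1.0 - self.compressibility * press_pa)
        sinp = np.sin(arr["pitch"])
        press_atm = 1.0 + 0.1 * arr["depth"]
        pred = (
            -0.5 * drag_obs * arr["rho_sw"] * arr["speed"] ** 2
            + (arr["rho_sw"] / rho_t - 1.0) * c.g * sinp
            + vair_obs * c.g * sinp
            * (arr["rho_sw"] - c.rho_air * press_atm) / press_atm
        )
        return pred, dict(
            rho=rho, drag=drag, vair=vair, vair_mu=vair_mu,
            vair_sigma=vair_sigma, sigma_a=sigma_a,
        )

    # ---- fitting ------------------------------------------------------
    def fit(self, X, y=None):
        """Fit the posterior to glide observations.

        X : sequence of GlideObservation or equivalent DataFrame.
        """
        structure = self.structure or ModelStructure(tissue_scope="individual")
        arr = _as_glide_arrays(X)
        n_w, n_d = len(arr["whales"]), len(arr["dives"])

        # near-horizontal glides carry no buoyancy signal
        for w in range(n_w):
            m = arr["whale_idx"] == w
            if np.all(np.abs(arr["pitch"][m]) < np.deg2rad(10.0)):
                warnings.warn(
                    f"whale {arr['whales'][w]}: all glides near-horizontal; "
                    "tissue density is weakly identified",
                    stacklevel=2,
                )

        names, lower, upper, step0, init = self._layout(structure, n_w, n_d)
        se_obs = np.maximum(arr["se"], self.se_floor)
        drag_prior = drag_prior_default(self.drag_prior_sd)
        sigma_scale = self.sigma_scale
        sigma_vair_scale = self.sigma_vair_scale

        def loglik(x):
            pred, parts = self._predict_from_vector(x, structure, arr)
            sd = np.sqrt(se_obs**2 + parts["sigma_a"] ** 2)
            resid = arr["accel"] - pred
            return float(
                -0.5 * np.sum((resid / sd) ** 2) - np.sum(np.log(sd))
            )

        def logpost(x):
            _, parts = self._predict_from_vector(x, structure, arr)
            lp = float(np.sum(drag_prior.logpdf(parts["drag"])))
            if structure.air_scope == "per_dive":
                mu, sg = parts["vair_mu"], parts["vair_sigma"]
                if sg <= 0:
                    return -np.inf
                lp += -0.5 * (sg / sigma_vair_scale) ** 2
                lp += float(
                    -0.5 * np.sum(((parts["vair"] - mu) / sg) ** 2)
                    - parts["vair"].size * np.log(sg)
                )
            if structure.error_model == "estimated":
                lp += -0.5 * (parts["sigma_a"] / sigma_scale) ** 2
            if not np.isfinite(lp):
                return -np.inf
            return lp + loglik(x)

        rng = np.random.default_rng(self.seed)
        cfg = McmcConfig(
            n_iter=self.n_iter,
            burn_frac=self.burn_frac,
            n_chains=self.n_chains,
            thin=self.thin,
            rhat_threshold=self.rhat_threshold,
        )
        res = run_mwg(
            logpost, init, rng=rng, config=cfg,
            step0=step0, lower=lower, upper=upper, names=names,
        )
        self.result_ = res
        self.structure_ = structure
        self.summary_ = summarize(res)
        self.whales_ = arr["whales"]
        self.dives_ = arr["dives"]
        self.converged_ = res.converged
        if not res.converged:
            warnings.warn(
                f"MCMC not converged for structure [{structure.label}]: "
                f"max R-hat {np.nanmax(res.rhat):.3f}",
                stacklevel=2,
            )

        # DIC = Dbar + pD, pD = Dbar - D(posterior mean)
        flat = res.flat
        take = flat[:: max(1, flat.shape[0] // 500)]
        dev = np.array([-2.0 * loglik(x) for x in take])
        d_hat = -2.0 * loglik(flat.mean(axis=0))
        p_d = dev.mean() - d_hat
        self.dic_ = float(dev.mean() + p_d)
        self.n_parameters_ = len(names)

        # per-whale tissue density table
        rows = []
        for i, w in enumerate(arr["whales"]):
            name = f"rho_tissue[{i}]" if structure.tissue_scope == "individual" else "rho_tissue"
            j = names.index(name)
            col = flat[:, j]
            lo_, hi_ = np.percentile(col, [2.5, 97.5])
            rows.append(
                dict(
                    whale_id=w,
                    rho_tissue_mean=col.mean(),
                    rho_tissue_sd=col.std(ddof=1),
                    ci_lo=lo_,
                    ci_hi=hi_,
                    n_glides=int(np.sum(arr["whale_idx"] == i)),
                )
            )
        self.tissue_density_ = pd.DataFrame(rows)
        self._arrays = arr
        self._loglik = loglik
        return self

    def predict(self, X):
        """Predicted along-path acceleration at the posterior-mean parameters."""
        if not hasattr(self, "result_"):
            raise RuntimeError("fit the model first")
        arr = _as_glide_arrays(X)
        if arr["whales"] != self.whales_ or arr["dives"] != self.dives_:
            # map onto the fitted whale/dive indexing
            try:
                w_map = {w: self.whales_.index(w) for w in arr["whales"]}
                d_map = {d: self.dives_.index(d) for d in arr["dives"]}
            except ValueError as err:
                raise ValueError("prediction requires whales/dives seen in fit") from err
            arr["whale_idx"] = np.array(
                [w_map[arr["whales"][i]] for i in arr["whale_idx"]]
            )
            arr["dive_idx"] = np.array(
                [d_map[arr["dives"][i]] for i in arr["dive_idx"]]
            )
        pred, _ = self._predict_from_vector(
            self.result_.flat.mean(axis=0), self.structure_, arr
        )
        return pred


def fit_hydro_model(
    glides: Sequence[GlideObservation],
    structure: ModelStructure | None = None,
    seed: int = 0,
    **kwargs,
) -> FitResult:
    """Functional wrapper: fit one structure, return a :class:`FitResult`."""
    model = TissueDensityModel(structure=structure, seed=seed, **kwargs).fit(glides)
    return FitResult(
        structure=model.structure_,
        summaries=model.summary_,
        dic=model.dic_,
        tissue_density=model.tissue_density_,
        mcmc=model.result_,
        n_parameters=model.n_parameters_,
        converged=model.converged_,
    )


def select_structure(
    glides: Sequence[GlideObservation],
    structures: Sequence[ModelStructure] = DEFAULT_STRUCTURES,
    seed: int = 0,
    **kwargs,
) -> tuple[FitResult, pd.DataFrame]:
    """Fit all candidate structures; return the minimum-DIC fit and a DIC table.

    Non-converged candidates are excluded (with a warning); exact DIC ties
    are broken toward fewer parameters.  A single candidate is returned
    unchanged.
    """
    structures = list(structures)
    if not structures:
        raise ValueError("need at least one candidate structure")
    fits = [fit_hydro_model(glides, s, seed=seed, **kwargs) for s in structures]
    table = pd.DataFrame(
        {
            "structure": [f.structure.label for f in fits],
            "dic": [f.dic for f in fits],
            "n_parameters": [f.n_parameters for f in fits],
            "converged": [f.converged for f in fits],
        }
    ).sort_values(["dic", "n_parameters"]).reset_index(drop=True)
    usable = [f for f in fits if f.converged]
    if not usable:
        warnings.warn("no candidate converged; selecting among all", stacklevel=2)
        usable = fits
    elif len(usable) < len(fits):
        warnings.warn(
            f"excluded {len(fits) - len(usable)} non-converged candidates",
            stacklevel=2,
        )
    best = min(usable, key=lambda f: (f.dic, f.n_parameters))
    return best, table


def grid_oracle(
    glides: Sequence[GlideObservation],
    rho_grid: np.ndarray,
    drag_grid: np.ndarray,
    air_per_mass: float,
    compressibility: float = DEFAULT_COMPRESSIBILITY,
    constants: PhysicalConstants = PhysicalConstants(),
) -> dict:
    """Brute-force least-squares optimum over a (rho, drag) grid.

    Independent check of the MCMC: with the air volume fixed, evaluates the
    sum of squared acceleration residuals at every grid point and returns
    the minimizing pair and the SSE surface.
    """
    glides = list(glides)
    if not glides:
        raise ValueError("no glide observations")
    rho_grid = np.asarray(rho_grid, dtype=float)
    drag_grid = np.asarray(drag_grid, dtype=float)
    arr = _as_glide_arrays(glides)
    press_pa = (1.0 + 0.1 * arr["depth"]) * constants.atmosphere_pa
    press_atm = 1.0 + 0.1 * arr["depth"]
    sinp = np.sin(arr["pitch"])
    air = (
        air_per_mass * constants.g * sinp
        * (arr["rho_sw"] - constants.rho_air * press_atm) / press_atm
    )
    # sse[i, j] over rho_grid[i] x drag_grid[j]
    rho_t = rho_grid[:, None] / (1.0 - compressibility * press_pa)[None, :]
    tissue = (arr["rho_sw"] / rho_t - 1.0) * constants.g * sinp  # (n_rho, n_obs)
    drag = -0.5 * drag_grid[:, None] * (arr["rho_sw"] * arr["speed"] ** 2)  # (n_drag, n_obs)
    resid = (
        arr["accel"][None, None, :]
        - tissue[:, None, :]
        - drag[None, :, :]
        - air[None, None, :]
    )
    sse = np.sum(resid**2, axis=2)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    return dict(
        rho_tissue=float(rho_grid[i]),
        drag_term=float(drag_grid[j]),
        sse=float(sse[i, j]),
        sse_surface=sse,
        rho_grid=rho_grid,
        drag_grid=drag_grid,
    )
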