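"""Synthetic data with the statistical structure the analysis assumes.

Every stage of the pipeline can be exercised without field data: glide
observations are drawn from the hydrodynamic forward model with Gaussian
acceleration noise; tag time series are built with alternating stroke and
glide phases and kinematically consistent depth/pitch/speed; outlines are
humpback-like width profiles scaled to a target LSSAI; and whale
populations follow the log-linear Gamma regression with two observation
channels and study-like missingness.

Each generator takes a seed (or Generator) and returns the synthetic data
together with a machine-readable truth record, so recovery tests never
peek at anything but the declared truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats

from .hydro import HydroParams, PhysicalConstants, glide_acceleration
from .kinematics import CtdProfile, GlideObservation, TagTimeSeries
from .photogrammetry import N_BOUNDARIES, FrameScore, WhaleOutline, lssai
from .fusion import CENTER, WhaleRecord


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ----------------------------------------------------------------------
# CTD profiles
# ----------------------------------------------------------------------

def simulate_ctd(
    surface_density: float = 1025.0,
    gradient: float = 0.01,
    max_depth: float = 200.0,
    n_points: int = 41,
) -> CtdProfile:
    """Monotone seawater-density profile: linear in depth, clipped to the
    physical range [1000, 1035] kg m^-3.

    gradient in kg m^-3 per metre (>= 0; 0 gives a constant profile).
    """
    depth = np.linspace(0.0, max_depth, n_points)
    density = np.clip(surface_density + gradient * depth, 1000.0, 1035.0)
    return CtdProfile(depth=depth, density=density)


# ----------------------------------------------------------------------
# Glide observations from the forward model
# ----------------------------------------------------------------------

@dataclass
class GlideSimConfig:
    """Study conditions of the glide testbed.

    Defaults emulate humpback feeding dives: glide depths uniform on
    10-120 m, |pitch| normal with mean 49.1 deg and sd 13.7 deg (the
    observed glide pitch statistics), speed lognormal around 1.5 m s^-1,
    acceleration noise sd 0.01 m s^-2.
    """

    params: dict = field(
        default_factory=lambda: {
            "w0": HydroParams(
                tissue_density=1036.0, drag_term=12e-6, air_per_mass=3.73e-5
            )
        }
    )
    n_glides: int = 200
    depth_range: tuple = (10.0, 120.0)
    pitch_mean_deg: float = 49.1
    pitch_sd_deg: float = 13.7
    speed_logmean: float = float(np.log(1.5))
    speed_logsd: float = 0.2
    noise_sd: float = 0.01
    glides_per_dive: int = 20
    ctd: CtdProfile = field(default_factory=simulate_ctd)
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_glides < 1:
            raise ValueError("n_glides must be >= 1")


def _sample_pitch(rng: np.random.Generator, n: int, mean_deg: float, sd_deg: float):
    """|pitch| truncated-normal on (0, 90) deg, sign equiprobable."""
    a = (0.0 - mean_deg) / sd_deg
    b = (90.0 - mean_deg) / sd_deg
    mag = stats.truncnorm.rvs(a, b, loc=mean_deg, scale=sd_deg, size=n, random_state=rng)
    sign = rng.choice([-1.0, 1.0], size=n)
    return np.deg2rad(mag * sign)


def simulate_glides(config: GlideSimConfig | None = None, seed=0):
    """Draw glide observations from the hydrodynamic forward model.

    Returns (list of GlideObservation, truth dict).  Acceleration is the
    forward-model value plus N(0, noise_sd); each observation's accel_se is
    set to the noise sd (the generator's analogue of the regression SE).
    """
    cfg = config or GlideSimConfig()
    rng = _rng(seed)
    glides: list[GlideObservation] = []
    for whale_id, params in cfg.params.items():
        d = rng.uniform(*cfg.depth_range, size=cfg.n_glides)
        p = _sample_pitch(rng, cfg.n_glides, cfg.pitch_mean_deg, cfg.pitch_sd_deg)
        v = rng.lognormal(cfg.speed_logmean, cfg.speed_logsd, size=cfg.n_glides)
        rho_sw = cfg.ctd.density_at(d)
        a = glide_acceleration(params, d, p, v, rho_sw, cfg.constants)
        a = a + cfg.noise_sd * rng.standard_normal(cfg.n_glides)
        for i in range(cfg.n_glides):
            glides.append(
                GlideObservation(
                    whale_id=whale_id,
                    dive_id=i // cfg.glides_per_dive,
                    depth=float(d[i]),
                    pitch=float(p[i]),
                    speed=float(v[i]),
                    rho_sw=float(rho_sw[i]),
                    accel=float(a[i]),
                    accel_se=cfg.noise_sd,
                )
            )
    truth = {
        "params": {w: asdict(p) for w, p in cfg.params.items()},
        "noise_sd": cfg.noise_sd,
    }
    return glides, truth


# ----------------------------------------------------------------------
# Tag time series with planted glide windows
# ----------------------------------------------------------------------

@dataclass
class TimeSeriesSimConfig:
    """Dive-shaped tag record: V-shaped descent/ascent phases with stroke
    oscillations, and stroke-free glide windows planted at known times."""

    fs: float = 5.0  # Hz
    duration: float = 600.0  # s
    phase_duration: float = 60.0  # s per descent/ascent leg
    stroke_freq: float = 0.4  # Hz
    stroke_amp: float = 1.0  # m s^-2
    accel_noise: float = 0.02  # m s^-2 on the dorsoventral channel
    base_speed: float = 1.5  # m s^-1 during stroking
    pitch_deg: float = 49.1
    start_depth: float = 5.0
    glide_windows: Sequence[tuple] = ()  # (start s, end s), within one phase
    params: HydroParams = field(
        default_factory=lambda: HydroParams(
            tissue_density=1036.0, drag_term=12e-6, air_per_mass=0.0,
            compressibility=0.0,
        )
    )
    ctd: CtdProfile = field(default_factory=lambda: simulate_ctd(gradient=0.0))
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    whale_id: str = "w0"

    def __post_init__(self):
        if self.fs < 5.0:
            raise ValueError("sampling rate must be >= 5 Hz")


def simulate_timeseries(config: TimeSeriesSimConfig | None = None, seed=0):
    """Build a tag record with known glide windows.

    Pitch alternates between descent (-pitch_deg) and ascent (+pitch_deg)
    legs; depth integrates dz/dt = -v sin(p) sample by sample; the
    dorsoventral channel carries a stroke-frequency sinusoid except inside
    the planted windows.  During each planted glide the speed follows a
    linear ramp whose slope is the forward-model acceleration evaluated at
    the window-centre conditions (quasi-static approximation).

    Returns (TagTimeSeries, truth dict with the planted windows and their
    planted accelerations).
    """
    cfg = config or TimeSeriesSimConfig()
    rng = _rng(seed)
    n = int(round(cfg.duration * cfg.fs)) + 1
    t = np.arange(n) / cfg.fs
    pitch0 = np.deg2rad(cfg.pitch_deg)

    # alternating descent/ascent legs
    leg = (t // cfg.phase_duration).astype(int)
    pitch = np.where(leg % 2 == 0, -pitch0, pitch0)

    for w0, w1 in cfg.glide_windows:
        if not (0 <= w0 < w1 <= cfg.duration):
            raise ValueError(f"window ({w0}, {w1}) outside the record")
        if int(w0 // cfg.phase_duration) != int((w1 - 1e-9) // cfg.phase_duration):
            raise ValueError(f"window ({w0}, {w1}) spans a pitch-phase boundary")

    speed = np.full(n, cfg.base_speed)
    in_glide = np.zeros(n, dtype=bool)
    # first pass: depth with base speed to locate window-centre depths
    dz = -speed * np.sin(pitch) / cfg.fs
    depth = np.maximum(cfg.start_depth + np.concatenate(([0.0], np.cumsum(dz[:-1]))), 0.5)

    planted = []
    for w0, w1 in cfg.glide_windows:
        m = (t >= w0 - 1e-9) & (t <= w1 + 1e-9)
        tc = 0.5 * (w0 + w1)
        ic = np.argmin(np.abs(t - tc))
        d_c, p_c = depth[ic], pitch[ic]
        v_c = cfg.base_speed
        a = float(
            glide_acceleration(
                cfg.params, d_c, p_c, v_c, float(cfg.ctd.density_at(d_c)),
                cfg.constants,
            )
        )
        speed[m] = np.maximum(v_c + a * (t[m] - tc), 0.1)
        in_glide |= m
        planted.append({"start": w0, "end": w1, "accel": a, "pitch": float(p_c)})

    # final depth consistent with the actual speed series (forward Euler)
    dz = -speed * np.sin(pitch) / cfg.fs
    depth = np.maximum(cfg.start_depth + np.concatenate(([0.0], np.cumsum(dz[:-1]))), 0.5)

    accel_dv = cfg.stroke_amp * np.sin(2 * np.pi * cfg.stroke_freq * t)
    accel_dv[in_glide] = 0.0
    accel_dv = accel_dv + cfg.accel_noise * rng.standard_normal(n)

    series = TagTimeSeries(
        time=t, depth=depth, accel_dv=accel_dv, pitch=pitch, speed=speed,
        dive_id=leg // 2, whale_id=cfg.whale_id,
    )
    truth = {
        "windows": [(w["start"], w["end"]) for w in planted],
        "planted": planted,
        "stroke_freq": cfg.stroke_freq,
        "params": asdict(cfg.params),
    }
    return series, truth


# ----------------------------------------------------------------------
# Outlines
# ----------------------------------------------------------------------

#: Humpback-like half-profile: width/length fraction at the 21 section
#: boundaries (rostrum .. fluke notch), peaking mid-body.
OUTLINE_TEMPLATE = np.array(
    [
        0.020, 0.050, 0.080, 0.105, 0.120, 0.130, 0.136, 0.140, 0.142,
        0.142, 0.140, 0.136, 0.130, 0.121, 0.110, 0.096, 0.080, 0.063,
        0.047, 0.032, 0.018,
    ]
)


def simulate_outline(
    target_lssai: float,
    shape_template: np.ndarray | None = None,
    noise: float = 0.0,
    seed=0,
    total_length: float = 1000.0,
    whale_id: str = "w0",
    frame_id: str = "f0",
    score: FrameScore | None = None,
) -> WhaleOutline:
    """Width profile scaled so that lssai(outline) = target (x (1 + noise)).

    ``noise`` perturbs the shape multiplicatively (relative sd per boundary,
    so mid-body widths carry most of the variance) and the achieved index
    (lognormal factor with sd ``noise``).  noise = 0 hits the target exactly.
    """
    if not 0.05 <= target_lssai <= 0.12:
        raise ValueError("target LSSAI outside the plausible range [0.05, 0.12]")
    rng = _rng(seed)
    template = np.asarray(
        OUTLINE_TEMPLATE if shape_template is None else shape_template, dtype=float
    )
    if template.size != N_BOUNDARIES:
        raise ValueError(f"template must have {N_BOUNDARIES} boundary widths")
    w = template * np.exp(noise * rng.standard_normal(N_BOUNDARIES)) if noise else template.copy()
    achieved_target = target_lssai * (np.exp(noise * rng.standard_normal()) if noise else 1.0)
    base = WhaleOutline(
        total_length=total_length,
        boundary_widths=tuple(w * total_length),
        score=score or FrameScore(3, 3, 3),
        whale_id=whale_id,
        frame_id=frame_id,
    )
    scale = achieved_target / lssai(base)  # LSSAI is linear in the widths
    return WhaleOutline(
        total_length=total_length,
        boundary_widths=tuple(w * scale * total_length),
        score=score or FrameScore(3, 3, 3),
        whale_id=whale_id,
        frame_id=frame_id,
    )


# ----------------------------------------------------------------------
# Whale populations for the fusion model
# ----------------------------------------------------------------------

@dataclass
class PopulationSimConfig:
    """Study conditions of the fusion testbed.

    Defaults are calibrated to the humpback study: 93 whales of which 59
    carry the tag (TBD) channel, 55 the photogrammetry (LSSAI) channel and
    21 both; covariate effects of -3.5 (pregnant), +6.0 (lactating) and
    +5.3 (Norway, early season) kg m^-3 and a seasonal slope of -2.7
    kg m^-3 per 100 days; per-whale TBD observation sd uniform on 1-5
    kg m^-3 (the reported range of tag-posterior spreads).
    """

    n: int = 93
    n_tbd: int = 59
    n_lssai: int = 55
    n_both: int = 21
    p_canada: float = 0.55
    canada_days: tuple = (150.0, 270.0)
    norway_early_days: tuple = (120.0, 180.0)
    norway_late_days: tuple = (305.0, 395.0)
    p_norway_late: float = 0.5
    p_male: float = 0.20
    p_sex_unknown: float = 0.20
    p_pregnant_adult_female: float = 0.30
    p_lactating_adult_female: float = 0.12
    p_immature: float = 0.15
    # response-scale truth (kg m^-3 contrasts at the reference whale)
    mu_ref: float = 1038.5
    eff_pregnant: float = -3.5
    eff_lactating: float = 6.0
    eff_norway_early: float = 5.3
    eff_per_100d: float = -2.7
    eff_norway_x_100d: float = -1.3
    eff_immature: float = 2.0
    eff_male: float = -0.2
    eff_sex_unknown: float = 0.0
    gamma_shape: float = 2.7e5
    # LSSAI link truth
    link_alpha: float = 0.0756 + 8.4e-4 * 1037.0
    link_gamma: float = -8.4e-4
    link_sigma: float = 0.0066
    tbd_sd_range: tuple = (1.0, 5.0)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.n_tbd + self.n_lssai - self.n_both != self.n:
            raise ValueError("channel counts must satisfy n_tbd + n_lssai - n_both = n")
        if not 0 <= self.p_canada <= 1:
            raise ValueError("p_canada must be a probability")


def _log_effect(delta_kg: float, mu_ref: float) -> float:
    """Log-scale coefficient giving a ``delta_kg`` contrast at mu_ref."""
    return float(np.log1p(delta_kg / mu_ref))


def simulate_population(config: PopulationSimConfig | None = None, seed=0):
    """Draw a whale population from the latent Gamma regression.

    Returns (list of WhaleRecord, truth dict).  The truth dict carries the
    log-scale coefficients actually used, the response-scale effects they
    encode, the link parameters, and each whale's latent uTBD.
    """
    cfg = config or PopulationSimConfig()
    rng = _rng(seed)
    n = cfg.n

    canada = rng.random(n) < cfg.p_canada
    day = np.empty(n)
    for i in range(n):
        if canada[i]:
            day[i] = rng.uniform(*cfg.canada_days)
        elif rng.random() < cfg.p_norway_late:
            day[i] = rng.uniform(*cfg.norway_late_days)
        else:
            day[i] = rng.uniform(*cfg.norway_early_days)
    u_sex = rng.random(n)
    sex = np.where(
        u_sex < cfg.p_male, "male",
        np.where(u_sex < cfg.p_male + cfg.p_sex_unknown, "unknown", "female"),
    )
    immature = rng.random(n) < cfg.p_immature
    pregnant = np.zeros(n, dtype=bool)
    lactating = np.zeros(n, dtype=bool)
    adult_female = (sex == "female") & ~immature
    u_rep = rng.random(n)
    pregnant = adult_female & (u_rep < cfg.p_pregnant_adult_female)
    lactating = adult_female & ~pregnant & (
        u_rep < cfg.p_pregnant_adult_female + cfg.p_lactating_adult_female
    )

    day0 = float(day.min())
    mu_ref = cfg.mu_ref
    beta = {
        "b0": float(np.log(mu_ref)),
        "norway": _log_effect(cfg.eff_norway_early, mu_ref),
        "day100": _log_effect(cfg.eff_per_100d, mu_ref),
        "norway_x_day100": _log_effect(cfg.eff_norway_x_100d, mu_ref),
        "male": _log_effect(cfg.eff_male, mu_ref),
        "sex_unknown": _log_effect(cfg.eff_sex_unknown, mu_ref),
        "pregnant": _log_effect(cfg.eff_pregnant, mu_ref),
        "lactating": _log_effect(cfg.eff_lactating, mu_ref),
        "immature": _log_effect(cfg.eff_immature, mu_ref),
    }
    day_c = (day - day0) / 100.0
    nor = (~canada).astype(float)
    lp = (
        beta["b0"]
        + beta["norway"] * nor
        + beta["day100"] * day_c
        + beta["norway_x_day100"] * nor * day_c
        + beta["male"] * (sex == "male")
        + beta["sex_unknown"] * (sex == "unknown")
        + beta["pregnant"] * pregnant
        + beta["lactating"] * lactating
        + beta["immature"] * immature
    )
    mu = np.exp(lp)
    u = rng.gamma(shape=cfg.gamma_shape, scale=mu / cfg.gamma_shape)

    # channel assignment: exact study-like counts
    order = rng.permutation(n)
    tbd_only = set(order[: cfg.n_tbd - cfg.n_both])
    both = set(order[cfg.n_tbd - cfg.n_both : cfg.n_tbd])
    has_tbd = tbd_only | both
    # remaining whales are LSSAI-only

    records = []
    tbd_sds = rng.uniform(*cfg.tbd_sd_range, size=n)
    tbd_noise = rng.standard_normal(n)
    lssai_noise = rng.standard_normal(n)
    for i in range(n):
        tbd_obs = None
        lssai_obs = None
        if i in has_tbd:
            tbd_obs = [(float(u[i] + tbd_sds[i] * tbd_noise[i]), float(tbd_sds[i]))]
        if i not in tbd_only:
            lssai_obs = float(
                cfg.link_alpha + cfg.link_gamma * u[i] + cfg.link_sigma * lssai_noise[i]
            )
        records.append(
            WhaleRecord(
                whale_id=f"sim{i:03d}",
                location="Canada" if canada[i] else "Norway",
                season_day=float(day[i]),
                sex=str(sex[i]),
                pregnant=bool(pregnant[i]),
                lactating=bool(lactating[i]),
                immature=bool(immature[i]),
                tbd_obs=tbd_obs,
                lssai_obs=lssai_obs,
            )
        )
    truth = {
        "beta_log": beta,
        "effects_kg": {
            "pregnant": cfg.eff_pregnant,
            "lactating": cfg.eff_lactating,
            "norway_early": cfg.eff_norway_early,
            "per_100_days": cfg.eff_per_100d,
            "norway_x_per_100_days": cfg.eff_norway_x_100d,
            "immature": cfg.eff_immature,
            "male": cfg.eff_male,
            "sex_unknown": cfg.eff_sex_unknown,
            "reference_mean": mu_ref,
        },
        "gamma_shape": cfg.gamma_shape,
        "link": {
            "alpha": cfg.link_alpha,
            "gamma": cfg.link_gamma,
            "sigma_l": cfg.link_sigma,
        },
        "day0": day0,
        "utbd": u.tolist(),
    }
    return records, truth
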