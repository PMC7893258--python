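"""Glide extraction from biologging tag time series.

A tagged whale's record (depth, pitch, high-frequency dorsoventral
acceleration, optionally propeller speed) is scanned for stroke-free
intervals -- glides -- during which hydrodynamic forces alone set the
along-path acceleration.  Each glide is tiled into 5 s segments, and each
segment yields one observation for the hydrodynamic model: mean depth,
pitch, speed and ambient seawater density, plus the acceleration measured
as the ordinary-least-squares slope of speed versus time (with its
standard error).

Stroke detection: the dorsoventral channel is high-pass filtered above a
fraction of the deployment's dominant stroke frequency (found from the
spectral peak), an amplitude envelope is formed by a moving maximum over
one stroke period, and samples where the envelope exceeds a robust
threshold are flagged as stroking.  The threshold is the smaller of
k * MAD of the filtered signal and half the typical peak amplitude, so
detection works whether strokes are rare or dominate the record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

logger = logging.getLogger(__name__)

GRAVITY = 9.8


class PitchBelowFloorError(ValueError):
    """Depth-rate speed is undefined: |pitch| below the configured floor."""


@dataclass
class TagTimeSeries:
    """Uniformly sampled tag record for one deployment.

    time (s, strictly increasing, uniform), depth (m, positive down),
    pitch (rad, positive ascending; may be None if only triaxial
    acceleration is available), accel_dv (m s^-2, high-frequency
    dorsoventral channel), speed (m s^-1, optional propeller channel),
    dive_id (optional per-sample integer labels).
    """

    time: np.ndarray
    depth: np.ndarray
    accel_dv: np.ndarray
    pitch: np.ndarray | None = None
    speed: np.ndarray | None = None
    dive_id: np.ndarray | None = None
    whale_id: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.accel_dv = np.asarray(self.accel_dv, dtype=float)
        n = self.time.size
        for name in ("depth", "accel_dv"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length mismatch")
        dt = np.diff(self.time)
        if n < 2 or np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-6 * dt[0] + 1e-9:
            raise ValueError("non-uniform sampling")
        if dt[0] > 1.0 + 1e-9:
            raise ValueError("sampling rate must be >= 1 Hz")
        if np.any(self.depth < -1e-9):
            raise ValueError("depth must be >= 0")
        if self.pitch is not None:
            self.pitch = np.asarray(self.pitch, dtype=float)
            if self.pitch.size != n:
                raise ValueError("pitch length mismatch")
            if np.any(np.abs(self.pitch) > np.pi / 2 + 1e-9):
                raise ValueError("|pitch| must be <= pi/2")
        if self.speed is not None:
            self.speed = np.asarray(self.speed, dtype=float)
        if self.dive_id is not None:
            self.dive_id = np.asarray(self.dive_id)

    @property
    def fs(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])


@dataclass
class CtdProfile:
    """Seawater density versus depth from a CTD cast near the deployment."""

    depth: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.depth.size != self.density.size or self.depth.size < 1:
            raise ValueError("depth and density grids must match and be non-empty")
        if np.any(np.diff(self.depth) <= 0):
            raise ValueError("depth grid must be increasing")
        if np.any((self.density < 1000.0) | (self.density > 1035.0)):
            raise ValueError("seawater density outside [1000, 1035] kg m^-3")

    def density_at(self, d):
        """Linear interpolation in depth; constant beyond the profile ends."""
        return np.interp(d, self.depth, self.density)


@dataclass(frozen=True)
class GlideObservation:
    """One 5 s glide segment: the unit observation of the hydrodynamic fit."""

    whale_id: str
    dive_id: int
    depth: float
    pitch: float
    speed: float
    rho_sw: float
    accel: float
    accel_se: float

    def __post_init__(self):
        if self.speed <= 0:
            raise ValueError("segment mean speed must be > 0")
        if self.accel_se < 0:
            raise ValueError("accel_se must be >= 0")


@dataclass
class GlideDetectionConfig:
    """Tunable thresholds of glide detection and segmentation."""

    stroke_freq: float | None = None  # Hz; None = spectral peak per deployment
    highpass_factor: float = 0.4  # high-pass cut as fraction of stroke freq
    mad_k: float = 5.0  # MAD multiplier of the stroke threshold
    amplitude_cap_frac: float = 0.5  # cap threshold at this x typical peak
    min_duration: float = 5.0  # s; shortest usable glide
    segment_duration: float = 5.0  # s
    pitch_floor: float = np.deg2rad(30.0)  # rad; depth-rate speed cut-off
    min_speed: float = 0.05  # m s^-1; guard against degenerate segments


def estimate_stroke_frequency(series: TagTimeSeries) -> float:
    """Dominant stroking frequency from the dorsoventral spectral peak."""
    f, pxx = signal.periodogram(series.accel_dv - np.mean(series.accel_dv), fs=series.fs)
    band = f > 0.05
    if not np.any(band):
        raise ValueError("record too short to estimate stroke frequency")
    return float(f[band][np.argmax(pxx[band])])


def detect_glides(
    series: TagTimeSeries, config: GlideDetectionConfig | None = None
) -> list[tuple[float, float]]:
    """Stroke-free windows >= min_duration as (start_time, end_time) pairs."""
    cfg = config or GlideDetectionConfig()
    if series.accel_dv is None:
        raise ValueError("dorsoventral acceleration channel required")
    fs = series.fs
    f_stroke = cfg.stroke_freq or estimate_stroke_frequency(series)
    f_cut = cfg.highpass_factor * f_stroke
    if not 0 < f_cut < fs / 2:
        raise ValueError(f"high-pass cut {f_cut} Hz outside (0, Nyquist)")
    sos = signal.butter(4, f_cut, btype="highpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, series.accel_dv)

    # half a stroke period: |filtered| peaks every half cycle, so a centred
    # moving max of this width bridges zero crossings without over-dilating
    # stroke bouts into adjacent glides
    win = max(3, int(round(fs / (2.0 * f_stroke))))
    envelope = pd.Series(np.abs(filtered)).rolling(win, center=True, min_periods=1).max().to_numpy()

    mad = 1.4826 * np.median(np.abs(filtered - np.median(filtered)))
    typical_peak = np.percentile(envelope, 95)
    threshold = min(cfg.mad_k * mad, cfg.amplitude_cap_frac * typical_peak)
    stroking = envelope > threshold

    windows: list[tuple[float, float]] = []
    quiet = ~stroking
    edges = np.flatnonzero(np.diff(np.concatenate(([False], quiet, [False]))))
    for start, stop in edges.reshape(-1, 2):
        t0, t1 = series.time[start], series.time[stop - 1]
        if t1 - t0 >= cfg.min_duration:
            windows.append((float(t0), float(t1)))
    return windows


def speed_from_depth_rate(depth_rate, pitch, pitch_floor: float = np.deg2rad(30.0)):
    """Swim speed as |depth rate / sin(pitch)|.

    Undefined (raises for scalars, NaN in arrays) when |pitch| is below the
    floor, where the 1/sin error inflation becomes unacceptable.
    """
    scalar = np.isscalar(depth_rate) and np.isscalar(pitch)
    depth_rate = np.asarray(depth_rate, dtype=float)
    pitch = np.asarray(pitch, dtype=float)
    below = np.abs(pitch) < pitch_floor
    if scalar and below:
        raise PitchBelowFloorError(
            f"|pitch| {float(np.abs(pitch)):.3f} rad below floor {pitch_floor:.3f}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.abs(depth_rate / np.sin(pitch))
    v = np.where(below, np.nan, v)
    return float(v) if scalar else v


def _ols_slope(t: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Slope and its standard error of v on t (zero SE for an exact line)."""
    res = stats.linregress(t, v)
    se = res.stderr if np.isfinite(res.stderr) else 0.0
    return float(res.slope), float(se)


def segment_glides(
    windows: Sequence[tuple[float, float]],
    series: TagTimeSeries,
    ctd: CtdProfile,
    config: GlideDetectionConfig | None = None,
) -> list[GlideObservation]:
    """Tile glide windows into 5 s segments and measure each one.

    Per segment: acceleration = OLS slope of speed on time (with SE);
    depth, pitch, speed = segment means; seawater density interpolated from
    the CTD profile at the segment's mean depth.  Segments whose |mean
    pitch| falls below the pitch floor are dropped (and logged) when speed
    must come from the depth rate.
    """
    cfg = config or GlideDetectionConfig()
    if series.pitch is None:
        raise ValueError("pitch channel required (derive it from triaxial accel first)")
    have_propeller = series.speed is not None and np.any(np.isfinite(series.speed))
    depth_rate = np.gradient(series.depth, series.time)

    out: list[GlideObservation] = []
    n_dropped = 0
    for t0, t1 in windows:
        n_seg = int(np.floor((t1 - t0) / cfg.segment_duration))
        for k in range(n_seg):
            s0 = t0 + k * cfg.segment_duration
            s1 = s0 + cfg.segment_duration
            m = (series.time >= s0 - 1e-9) & (series.time <= s1 + 1e-9)
            if m.sum() < 3:
                continue
            t = series.time[m]
            p_mean = float(np.mean(series.pitch[m]))
            if have_propeller:
                v = series.speed[m]
            else:
                if abs(p_mean) < cfg.pitch_floor:
                    n_dropped += 1
                    continue
                v = speed_from_depth_rate(
                    depth_rate[m], series.pitch[m], cfg.pitch_floor
                )
                ok = np.isfinite(v)
                if ok.sum() < 3:
                    n_dropped += 1
                    continue
                t, v = t[ok], v[ok]
            v_mean = float(np.mean(v))
            if v_mean <= cfg.min_speed:
                n_dropped += 1
                continue
            a, se = _ols_slope(t, v)
            d_mean = float(np.mean(series.depth[m]))
            dive = 0
            if series.dive_id is not None:
                dive = int(series.dive_id[m][len(t) // 2] if len(t) else 0)
            out.append(
                GlideObservation(
                    whale_id=series.whale_id,
                    dive_id=dive,
                    depth=d_mean,
                    pitch=p_mean,
                    speed=v_mean,
                    rho_sw=float(ctd.density_at(d_mean)),
                    accel=a,
                    accel_se=se,
                )
            )
    if n_dropped:
        logger.info("segment_glides: dropped %d segments (pitch floor/speed)", n_dropped)
    return out


def pitch_from_triaxial(
    surge_accel: np.ndarray,
    fs: float,
    stroke_freq: float,
    lowpass_factor: float = 0.2,
    g: float = GRAVITY,
) -> np.ndarray:
    """Pitch from the static (gravitational) part of the surge-axis channel.

    Low-pass below a fraction of the stroke frequency isolates the static
    acceleration; pitch = arcsin(static surge / g).
    """
    f_cut = lowpass_factor * stroke_freq
    sos = signal.butter(4, f_cut, btype="lowpass", fs=fs, output="sos")
    static = signal.sosfiltfilt(sos, np.asarray(surge_accel, dtype=float))
    return np.arcsin(np.clip(static / g, -1.0, 1.0))


def filter_whales(
    glides: Sequence[GlideObservation], min_glides: int = 10
) -> tuple[list[GlideObservation], list[str]]:
    """Drop whales with fewer than ``min_glides`` glide segments.

    Returns the retained observations and the list of excluded whale ids
    (also logged).
    """
    if min_glides < 1:
        raise ValueError("min_glides must be >= 1")
    counts: dict[str, int] = {}
    for g in glides:
        counts[g.whale_id] = counts.get(g.whale_id, 0) + 1
    excluded = sorted(w for w, c in counts.items() if c < min_glides)
    if excluded:
        logger.info(
            "filter_whales: excluded %d whales with < %d glides: %s",
            len(excluded), min_glides, ", ".join(excluded),
        )
    kept = [g for g in glides if g.whale_id not in set(excluded)]
    return kept, excluded


def glides_to_frame(glides: Sequence[GlideObservation]) -> pd.DataFrame:
    """Tabular view of glide observations (columns match the glide CSV schema)."""
    return pd.DataFrame(
        {
            "whale_id": [g.whale_id for g in glides],
            "dive_id": [g.dive_id for g in glides],
            "depth_m": [g.depth for g in glides],
            "pitch_rad": [g.pitch for g in glides],
            "speed_ms": [g.speed for g in glides],
            "rho_sw_kgm3": [g.rho_sw for g in glides],
            "accel_ms2": [g.accel for g in glides],
            "accel_se_ms2": [g.accel_se for g in glides],
        }
    )


def frame_to_glides(df: pd.DataFrame) -> list[GlideObservation]:
    return [
        GlideObservation(
            whale_id=str(r.whale_id),
            dive_id=int(r.dive_id),
            depth=float(r.depth_m),
            pitch=float(r.pitch_rad),
            speed=float(r.speed_ms),
            rho_sw=float(r.rho_sw_kgm3),
            accel=float(r.accel_ms2),
            accel_se=float(r.accel_se_ms2),
        )
        for r in df.itertuples(index=False)
    ]
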