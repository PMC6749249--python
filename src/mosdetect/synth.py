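"""Ground-truthed synthetic wearable sessions: GSR, skin temperature, GPS.

The generator emulates the anatomy of a skin-conductance response (SCR) to
an acute stressor and the lab protocol used to calibrate the detector:

* a tonic GSR baseline with slow drift and additive Gaussian sensor noise;
* phasic SCR events with configurable latency (1-5 s), linear rise to peak
  over the rising time (1-5 s), and exponential recovery whose rate is
  solved from the half-recovery time (1-10 s), so the value at
  ``peak + half_recovery`` is exactly half the amplitude;
* a skin-temperature trace that starts a linear decrease a fixed delay
  (default 3 s) after each GSR rise onset, then slowly returns to baseline;
* stimulus schedules with a minimum spacing (default 60 s) so responses do
  not overlap;
* an optional straight-line GPS walk with designated stress zones, used by
  the spatial hotspot tests.

Sessions are fully reproducible from ``SessionSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Polygon

from .errors import ParameterError, SchedulingError
from .traces import GeoTrack, SignalTrace

#: Default wristband sampling rate, Hz.
DEFAULT_RATE = 4.0

#: Mean Earth radius, metres (spherical approximation for short tracks).
_EARTH_R = 6_371_008.8


@dataclass
class SCREventParams:
    """Shape parameters of one injected skin-conductance response.

    Times are seconds from session start; ``stimulus_time`` is the stressor
    onset, the GSR rise begins at ``stimulus_time + latency`` and peaks
    ``rise_time`` later. The skin-temperature decrease of ``st_drop`` °C
    begins ``st_onset_delay`` seconds after the GSR rise onset and lasts
    ``st_drop_duration`` seconds before slowly recovering.
    """

    stimulus_time: float
    latency: float = 3.0
    rise_time: float = 4.0
    half_recovery: float = 5.0
    amplitude: float = 1.0
    st_onset_delay: float = 3.0
    st_drop: float = 0.3
    st_drop_duration: float = 5.0

    def __post_init__(self) -> None:
        if not 1.0 <= self.latency <= 5.0:
            raise ParameterError(f"latency must be in [1, 5] s, got {self.latency}")
        if not 1.0 <= self.rise_time <= 5.0:
            raise ParameterError(f"rise_time must be in [1, 5] s, got {self.rise_time}")
        if not 1.0 <= self.half_recovery <= 10.0:
            raise ParameterError(f"half_recovery must be in [1, 10] s, got {self.half_recovery}")
        if self.amplitude <= 0:
            raise ParameterError("amplitude must be > 0")
        if self.st_drop <= 0:
            raise ParameterError("st_drop must be > 0")
        if self.st_drop_duration < 3.0:
            raise ParameterError("st_drop_duration must be >= 3 s")

    @property
    def onset_time(self) -> float:
        """GSR rise onset (stimulus + latency); the expected detection time."""
        return self.stimulus_time + self.latency

    @property
    def peak_time(self) -> float:
        return self.onset_time + self.rise_time


@dataclass
class SessionSpec:
    """Conditions of one simulated recording session.

    Defaults mirror the calibration protocol: ten stressors per session at
    random times spaced at least 60 s apart, framed by 5-minute rest
    phases, on a wrist with a tonic level of a few microsiemens and a skin
    temperature in the 32-35 °C band.
    """

    duration: float = 1500.0
    n_events: int = 10
    min_spacing: float = 60.0
    baseline_scl: float = 2.0
    baseline_drift: float = 0.01     # uS per minute
    noise_sd_gsr: float = 0.01       # uS per 4 Hz sample
    baseline_st: float = 33.0
    noise_sd_st: float = 0.02        # degC per 4 Hz sample
    amplitude: float = 1.0           # first-event SCR amplitude, uS
    habituation_factor: float = 1.0  # amplitude multiplier per repeated stimulus
    jitter: float = 0.0              # 0 = canonical shapes, 1 = full-range shape jitter
    rate: float = DEFAULT_RATE
    start_time: float = 0.0
    rest_phase: float = 300.0        # stimulus-free margin at both session ends
    stress_zone: tuple[float, float] | None = None  # confine stimuli to this window
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.rate <= 0:
            raise ParameterError("duration and rate must be > 0")
        if self.n_events < 0:
            raise ParameterError("n_events must be >= 0")
        if self.n_events * self.min_spacing >= self.duration:
            raise ParameterError("n_events * min_spacing must be < duration")
        if not 32.0 <= self.baseline_st <= 35.0:
            raise ParameterError("baseline_st must lie in the plausible wrist band [32, 35] degC")
        if not 0.0 < self.habituation_factor <= 1.0:
            raise ParameterError("habituation_factor must be in (0, 1]")
        if not 0.0 <= self.jitter <= 1.0:
            raise ParameterError("jitter must be in [0, 1]")

    def stimulus_window(self) -> tuple[float, float]:
        """Time window in which stimuli may be scheduled."""
        if self.stress_zone is not None:
            lo, hi = self.stress_zone
            return max(lo, 0.0), min(hi, self.duration)
        return self.rest_phase, self.duration - self.rest_phase


@dataclass
class StressZone:
    """A designated stressful stretch of the track: a time window and its polygon."""

    t_start: float
    t_end: float
    polygon: Polygon | None = None


@dataclass
class GroundTruth:
    """What was injected into a session, for evaluating the detector."""

    events: list[SCREventParams]
    expected_mos_times: list[float]
    zones: list[StressZone] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.events) != len(self.expected_mos_times):
            raise ParameterError("one expected MOS time per injected event")
        gaps = np.diff(self.expected_mos_times)
        if gaps.size and np.any(gaps <= 10.0):
            raise ParameterError("expected MOS times must be increasing with gaps > 10 s")


def scr_value(params: SCREventParams, t: np.ndarray) -> np.ndarray:
    """Phasic GSR contribution of one event at times ``t`` (seconds).

    Zero before the rise onset; linear ramp to ``amplitude`` over
    ``rise_time``; exponential decay at rate ln(2)/half_recovery after the
    peak, so the value at ``peak_time + half_recovery`` is amplitude/2.
    """
    t = np.asarray(t, dtype=float)
    onset, peak = params.onset_time, params.peak_time
    y = np.zeros_like(t)
    rising = (t >= onset) & (t <= peak)
    y[rising] = params.amplitude * (t[rising] - onset) / params.rise_time
    fall = t > peak
    k = np.log(2.0) / params.half_recovery
    y[fall] = params.amplitude * np.exp(-k * (t[fall] - peak))
    return y


def st_value(params: SCREventParams, t: np.ndarray,
             recovery_factor: float = 4.0) -> np.ndarray:
    """Skin-temperature deviation (°C, non-positive) of one event at times ``t``.

    Linear drop of ``st_drop`` over ``st_drop_duration`` starting
    ``st_onset_delay`` after the GSR rise onset, then a slow linear return
    over ``recovery_factor`` times the drop duration.
    """
    t = np.asarray(t, dtype=float)
    d0 = params.onset_time + params.st_onset_delay
    d1 = d0 + params.st_drop_duration
    d2 = d1 + recovery_factor * params.st_drop_duration
    y = np.zeros_like(t)
    dropping = (t >= d0) & (t < d1)
    y[dropping] = -params.st_drop * (t[dropping] - d0) / params.st_drop_duration
    recovering = (t >= d1) & (t < d2)
    y[recovering] = -params.st_drop * (1.0 - (t[recovering] - d1) / (d2 - d1))
    return y


def render_scr_waveform(params: SCREventParams, rate: float,
                        duration: float | None = None) -> SignalTrace:
    """Render one SCR event as a standalone GSR trace at ``rate`` Hz."""
    if rate <= 0:
        raise ParameterError("rate must be > 0")
    if duration is None:
        duration = params.peak_time + 8.0 * params.half_recovery
    t = np.arange(0.0, duration, 1.0 / rate)
    return SignalTrace(start_time=0.0, rate=rate, values=scr_value(params, t), kind="gsr")


def schedule_stimuli(spec: SessionSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw stimulus times uniformly over schedules satisfying the spacing rule.

    Construction: with n events in window [a, b] and minimum spacing s, draw
    n sorted uniforms on the slack interval of length (b-a) - (n-1)s and add
    back the mandatory gaps. This samples the uniform distribution over the
    feasible region directly, with no rejection loop.
    """
    if spec.n_events == 0:
        return np.empty(0)
    a, b = spec.stimulus_window()
    slack = (b - a) - (spec.n_events - 1) * spec.min_spacing
    if slack <= 0:
        raise SchedulingError(
            f"cannot place {spec.n_events} stimuli with spacing >= {spec.min_spacing} s "
            f"in window [{a:.0f}, {b:.0f}] s"
        )
    u = np.sort(rng.uniform(0.0, slack, size=spec.n_events))
    return a + u + np.arange(spec.n_events) * spec.min_spacing


def _draw_event(spec: SessionSpec, k: int, stim_t: float,
                rng: np.random.Generator) -> SCREventParams:
    """Event k (0-based) at stimulus time ``stim_t``, with optional shape jitter."""
    j = spec.jitter
    latency = float(np.clip(3.0 + j * rng.uniform(-2.0, 2.0), 1.0, 5.0))
    rise = float(np.clip(4.0 + j * rng.uniform(-1.0, 1.0), 1.0, 5.0))
    half_rec = float(np.clip(5.0 + j * rng.uniform(-2.0, 3.0), 1.0, 10.0))
    amp = spec.amplitude * spec.habituation_factor ** k
    return SCREventParams(
        stimulus_time=float(stim_t),
        latency=latency,
        rise_time=rise,
        half_recovery=half_rec,
        amplitude=amp,
    )


def generate_session(
    spec: SessionSpec,
    zones: list[StressZone] | None = None,
) -> tuple[SignalTrace, SignalTrace, GeoTrack, GroundTruth]:
    """Generate one ground-truthed session: (gsr @ rate, st @ rate, track, truth).

    GSR = baseline + drift + sum of event waveforms + Gaussian noise;
    ST = baseline - sum of event drop ramps + Gaussian noise. The GPS track
    walks a straight line at constant speed with one fix per second; any
    requested stress zones confine the stimuli (via ``spec.stress_zone``)
    and are returned as polygons around the corresponding track stretch.
    """
    rng = np.random.default_rng(spec.seed)
    stim_times = schedule_stimuli(spec, rng)
    events = [_draw_event(spec, k, st_, rng) for k, st_ in enumerate(stim_times)]

    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate

    gsr = np.full(n, spec.baseline_scl) + (spec.baseline_drift / 60.0) * t
    st = np.full(n, spec.baseline_st)
    for ev in events:
        gsr += scr_value(ev, t)
        st += st_value(ev, t)
    if spec.noise_sd_gsr > 0:
        gsr += rng.normal(0.0, spec.noise_sd_gsr, size=n)
    if spec.noise_sd_st > 0:
        st += rng.normal(0.0, spec.noise_sd_st, size=n)

    gsr_trace = SignalTrace(spec.start_time, spec.rate, gsr, kind="gsr")
    st_trace = SignalTrace(spec.start_time, spec.rate, st, kind="st")

    if zones is None and spec.stress_zone is not None:
        zones = [StressZone(*spec.stress_zone)]
    track = generate_track(spec, zones)
    truth = GroundTruth(
        events=events,
        expected_mos_times=[spec.start_time + ev.onset_time for ev in events],
        zones=zones or [],
    )
    return gsr_trace, st_trace, track, truth


def generate_track(spec: SessionSpec, zones: list[StressZone] | None = None,
                   origin: tuple[float, float] = (47.8095, 13.0550),
                   speed: float = 1.4, heading_deg: float = 90.0,
                   zone_buffer: float = 25.0) -> GeoTrack:
    """Straight constant-speed walk with one GPS fix per second.

    ``origin`` is (lat, lon) of the first fix; ``speed`` is m/s along the
    compass ``heading_deg`` (90° = due east). Any ``zones`` get their
    polygons filled in as a ``zone_buffer``-metre buffer around the stretch
    of track walked during the zone's time window, so fixes (and hence
    events) inside the window are inside the polygon by construction.
    """
    n = int(round(spec.duration))
    if n < 1:
        raise ParameterError("track requires a session of at least 1 s")
    t = spec.start_time + np.arange(n, dtype=float)
    lat0, lon0 = origin
    theta = np.deg2rad(heading_deg)
    dist = speed * np.arange(n, dtype=float)
    north, east = dist * np.cos(theta), dist * np.sin(theta)
    lat = lat0 + np.rad2deg(north / _EARTH_R)
    lon = lon0 + np.rad2deg(east / (_EARTH_R * np.cos(np.deg2rad(lat0))))
    track = GeoTrack(t=t, lat=lat, lon=lon)

    if zones:
        m_per_deg_lat = np.deg2rad(1.0) * _EARTH_R
        m_per_deg_lon = m_per_deg_lat * np.cos(np.deg2rad(lat0))
        for zone in zones:
            sel = (t - spec.start_time >= zone.t_start) & (t - spec.start_time <= zone.t_end)
            if sel.sum() < 2:
                raise ParameterError(
                    f"stress zone [{zone.t_start}, {zone.t_end}] covers < 2 fixes"
                )
            seg = LineString(np.column_stack([lon[sel], lat[sel]]))
            # buffer in degrees of longitude; correct latitude anisotropy by scaling
            buf_deg = zone_buffer / m_per_deg_lon
            poly = seg.buffer(buf_deg)
            zone.polygon = poly
    return track
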