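"""Rule-based moment-of-stress (MOS) detection on the per-second bio-geotable.

Five rules, each scored on the ternary scale {0, 0.5, 1} (not / partially /
fully satisfied):

* **R1 — GSR increase**: the second sits at the start of a run of strictly
  positive per-second GSR differences; full score for runs of 2-5 s,
  partial for 5-8 s.
* **R2 — ST decrease**: skin temperature falls for at least 3 consecutive
  seconds starting 3 s after the GSR rise onset (full) or starting
  anywhere 2-6 s after it (partial).
* **R3 — rising time**: onset-to-peak duration of 1-5 s (full) or
  5-15 s (partial).
* **R4 — response slope**: arctan of the conductance rise over the rising
  time, in degrees with the μS and s axes; >= 10° full, >= 8° partial.
* **R5 — refractoriness**: no other MOS accepted within the previous 10 s
  (full or nothing).

Each score is multiplied by its rule's importance weight (the five weights
sum to 100), the weighted scores are summed into the total score
TS ∈ [0, 100], and a MOS is emitted when TS reaches the critical score
(default 75). Detection scans candidate rises in time order so that R5 can
refer to already-accepted events.

The weights the original calibration produced were never published; the
defaults shipped here (25, 20, 10, 30, 15) are package defaults chosen so
that the slope rule — the only rule that sees the response *amplitude* —
is decisive: without it the other four rules sum to 70 < 75, so
zero-amplitude noise wiggles (which satisfy the run-length and rise-time
rules for free) cannot reach the critical score.
:func:`calibrate_weights` is the supported path to study-specific weights.

Rule evaluation runs on the phasic component for run structure (R1/R3) and
on the noise-filtered conductance for the R4 amplitude, matching the
psychophysiological definition of SCR amplitude as peak conductance minus
the pre-stimulus level; R2 uses the 1 Hz skin-temperature trace. All three
column choices are switches on :func:`detect_mos`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError
from .synth import GroundTruth

#: Shipped default importance weights for rules R1..R5.
DEFAULT_WEIGHTS = (25.0, 20.0, 10.0, 30.0, 15.0)
#: Default critical score for accepting a MOS.
DEFAULT_CS = 75.0


@dataclass(frozen=True)
class RuleWeights:
    """Importance weights w1..w5; must be non-negative and sum to 100."""

    w1: float = DEFAULT_WEIGHTS[0]
    w2: float = DEFAULT_WEIGHTS[1]
    w3: float = DEFAULT_WEIGHTS[2]
    w4: float = DEFAULT_WEIGHTS[3]
    w5: float = DEFAULT_WEIGHTS[4]

    def __post_init__(self) -> None:
        w = self.as_tuple()
        if any(x < 0 for x in w):
            raise ConfigurationError(f"rule weights must be non-negative, got {w}")
        if not math.isclose(sum(w), 100.0, abs_tol=1e-9):
            raise ConfigurationError(f"rule weights must sum to 100, got {sum(w)}")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.w1, self.w2, self.w3, self.w4, self.w5)


@dataclass(frozen=True)
class CriticalValues:
    """Score-band edges for the five rules (all overridable).

    ``r1_full`` is the inclusive run-length band for full score; runs up to
    ``r1_partial_max`` score 0.5. ``r2_onset`` is the ST-decrease onset
    delay for full score, ``r2_window`` the inclusive onset window for
    partial score, ``r2_min_run`` the minimum decrease duration.
    ``r3_full``/``r3_partial_max`` bound the rising time, ``r4_full_deg``/
    ``r4_partial_deg`` the response slope, and ``r5_gap`` the refractory
    period in seconds.
    """

    r1_full: tuple[int, int] = (2, 5)
    r1_partial_max: int = 8
    r2_onset: int = 3
    r2_window: tuple[int, int] = (2, 6)
    r2_min_run: int = 3
    r3_full: tuple[float, float] = (1.0, 5.0)
    r3_partial_max: float = 15.0
    r4_full_deg: float = 10.0
    r4_partial_deg: float = 8.0
    r5_gap: float = 10.0

    def __post_init__(self) -> None:
        if not (self.r1_full[0] <= self.r1_full[1] <= self.r1_partial_max):
            raise ConfigurationError("R1 bands must satisfy full_lo <= full_hi <= partial_max")
        if not (self.r2_window[0] <= self.r2_onset <= self.r2_window[1]):
            raise ConfigurationError("R2 partial onset window must bracket the full-score onset")
        if not (self.r3_full[0] <= self.r3_full[1] <= self.r3_partial_max):
            raise ConfigurationError("R3 bands must satisfy full_lo <= full_hi <= partial_max")
        if self.r4_partial_deg > self.r4_full_deg:
            raise ConfigurationError("R4 partial threshold must not exceed the full threshold")
        if self.r5_gap <= 0:
            raise ConfigurationError("R5 refractory gap must be > 0")


DEFAULT_CRITICAL_VALUES = CriticalValues()


@dataclass
class Candidate:
    """A maximal run of strictly increasing per-second GSR: one potential MOS.

    Indices are positions in the 1 Hz series; ``rise_run`` is the run
    length in seconds (peak_i - onset_i).
    """

    onset_i: int
    peak_i: int
    g_onset: float
    g_peak: float

    def __post_init__(self) -> None:
        if self.peak_i <= self.onset_i:
            raise ParameterError("peak must follow onset")
        if self.g_peak < self.g_onset:
            raise ParameterError("peak value must be >= onset value")

    @property
    def rise_run(self) -> int:
        return self.peak_i - self.onset_i

    @property
    def slope_deg(self) -> float:
        """Response slope: arctan(Δg / Δt) in degrees (μS and s axes)."""
        return math.degrees(math.atan((self.g_peak - self.g_onset) / self.rise_run))


@dataclass
class MOSEvent:
    """A detected moment of stress: time, total score, rule scores, location."""

    t: float
    total_score: float
    scores: tuple[float, float, float, float, float]
    lat: float = math.nan
    lon: float = math.nan
    onset_i: int = -1
    peak_i: int = -1


def find_candidates(g: np.ndarray) -> list[Candidate]:
    """One candidate per maximal run of strictly positive first differences.

    The run start is the local minimum (response onset) and the run end the
    local maximum (response peak).
    """
    g = np.asarray(g, dtype=float)
    if g.size < 3:
        return []
    pos = np.diff(g) > 0
    out: list[Candidate] = []
    i = 0
    while i < pos.size:
        if pos[i]:
            j = i
            while j < pos.size and pos[j]:
                j += 1
            out.append(Candidate(onset_i=i, peak_i=j, g_onset=g[i], g_peak=g[j]))
            i = j
        else:
            i += 1
    return out


def score_r1(c: Candidate, cv: CriticalValues = DEFAULT_CRITICAL_VALUES) -> float:
    n = c.rise_run
    lo, hi = cv.r1_full
    if lo <= n <= hi:
        return 1.0
    if hi < n <= cv.r1_partial_max:
        return 0.5
    return 0.0


def _neg_run_starts_at(diffs: np.ndarray, s: int, min_run: int) -> bool:
    """True if first differences are negative for >= min_run seconds from s."""
    if s < 0 or s + min_run > diffs.size:
        return False
    return bool(np.all(diffs[s:s + min_run] < 0))


def score_r2(T: np.ndarray, c: Candidate,
             cv: CriticalValues = DEFAULT_CRITICAL_VALUES) -> float:
    """Skin-temperature decrease following the GSR rise onset.

    Full score when the decrease starts exactly ``cv.r2_onset`` seconds
    after the onset and lasts at least ``cv.r2_min_run`` seconds; partial
    when such a run starts anywhere inside ``cv.r2_window`` after the
    onset. Insufficient ST coverage scores 0 with a warning.
    """
    T = np.asarray(T, dtype=float)
    need = c.onset_i + cv.r2_window[1] + cv.r2_min_run + 1
    if need > T.size:
        warnings.warn(
            f"ST series ends before the R2 window of the candidate at t={c.onset_i}; scoring 0",
            stacklevel=2,
        )
        # fall through: any runs that do fit are still checked
    diffs = np.diff(T)
    if _neg_run_starts_at(diffs, c.onset_i + cv.r2_onset, cv.r2_min_run):
        return 1.0
    for s in range(c.onset_i + cv.r2_window[0], c.onset_i + cv.r2_window[1] + 1):
        if _neg_run_starts_at(diffs, s, cv.r2_min_run):
            return 0.5
    return 0.0


def score_r3(c: Candidate, cv: CriticalValues = DEFAULT_CRITICAL_VALUES) -> float:
    rt = c.peak_i - c.onset_i
    lo, hi = cv.r3_full
    if lo <= rt <= hi:
        return 1.0
    if hi < rt <= cv.r3_partial_max:
        return 0.5
    return 0.0


def slope_degrees(delta_g: float, delta_t: float) -> float:
    """Response slope arctan(Δg / Δt) in degrees, with μS and s axes."""
    return math.degrees(math.atan(delta_g / delta_t))


def _score_slope(slope_deg: float, cv: CriticalValues) -> float:
    if slope_deg >= cv.r4_full_deg:
        return 1.0
    if slope_deg >= cv.r4_partial_deg:
        return 0.5
    return 0.0


def score_r4(c: Candidate, cv: CriticalValues = DEFAULT_CRITICAL_VALUES,
             g_amplitude: np.ndarray | None = None) -> float:
    """Response-slope score; ``g_amplitude`` optionally supplies the series
    the Δg is read from (at the candidate's onset/peak indices), defaulting
    to the candidate's own values."""
    if g_amplitude is not None:
        dg = float(g_amplitude[c.peak_i]) - float(g_amplitude[c.onset_i])
        return _score_slope(slope_degrees(dg, c.rise_run), cv)
    return _score_slope(c.slope_deg, cv)


def score_r5(t: float, previous_mos: list[float],
             cv: CriticalValues = DEFAULT_CRITICAL_VALUES) -> float:
    """1 if no accepted MOS lies within the refractory gap before t, else 0.

    The gap must strictly exceed the refractory period, so an event exactly
    ``r5_gap`` seconds after the previous one still scores 0.
    """
    for tm in reversed(previous_mos):
        if t - cv.r5_gap <= tm <= t:
            return 0.0
        if tm < t - cv.r5_gap:
            break
    return 1.0


def total_score(scores: tuple[float, float, float, float, float],
                weights: RuleWeights) -> float:
    """Weighted sum of the five ternary scores: TS ∈ [0, 100]."""
    for sc in scores:
        if sc not in (0.0, 0.5, 1.0):
            raise ParameterError(f"rule scores must be 0, 0.5 or 1, got {sc}")
    return float(sum(sc * w for sc, w in zip(scores, weights.as_tuple())))


def detect_mos(table: pd.DataFrame,
               weights: RuleWeights | None = None,
               cs: float = DEFAULT_CS,
               cv: CriticalValues = DEFAULT_CRITICAL_VALUES,
               gsr_column: str = "phasic",
               amplitude_column: str | None = "gsr",
               st_column: str = "st") -> list[MOSEvent]:
    """Scan the 1 Hz bio-geotable and emit geolocated moments of stress.

    Candidates (maximal GSR rises, by default on the phasic component) are
    scored in time order; the R4 amplitude is read from
    ``amplitude_column`` (default the noise-filtered conductance; pass
    ``None`` to use ``gsr_column`` itself); R5 consults the
    already-accepted events; a
    candidate is accepted when its total score reaches ``cs`` and it is
    outside the refractory period (R5 = 1). The refractory rule is a hard
    constraint — another detection within 10 s of an accepted one is
    infeasible by definition, whatever the weights — which also makes the
    detection count monotone non-increasing in ``cs``. The event timestamp
    is the candidate's onset second.
    """
    if weights is None:
        weights = RuleWeights()
    if not 0.0 <= cs <= 100.0:
        raise ConfigurationError(f"critical score must be in [0, 100], got {cs}")
    if table.empty:
        return []
    g = table[gsr_column].to_numpy(dtype=float)
    if amplitude_column is not None and amplitude_column in table:
        g_amp = table[amplitude_column].to_numpy(dtype=float)
    else:
        g_amp = None
    T = table[st_column].to_numpy(dtype=float) if st_column in table else np.full(len(table), np.nan)
    t = table["t"].to_numpy(dtype=float)
    events: list[MOSEvent] = []
    accepted_times: list[float] = []
    for c in find_candidates(g):
        scores = (
            score_r1(c, cv),
            score_r2(T, c, cv),
            score_r3(c, cv),
            score_r4(c, cv, g_amplitude=g_amp),
            score_r5(t[c.onset_i], accepted_times, cv),
        )
        ts = total_score(scores, weights)
        if scores[4] == 1.0 and ts >= cs:
            row = table.iloc[c.onset_i]
            events.append(MOSEvent(
                t=float(t[c.onset_i]),
                total_score=ts,
                scores=scores,
                lat=float(row.get("lat", math.nan)),
                lon=float(row.get("lon", math.nan)),
                onset_i=c.onset_i,
                peak_i=c.peak_i,
            ))
            accepted_times.append(float(t[c.onset_i]))
    return events


def evaluate(events: list[MOSEvent], truth: GroundTruth | list[float],
             match_window: float = 10.0) -> dict:
    """Greedy one-to-one matching of detections to injected stimuli.

    Events and truth times are walked in time order; each event matches the
    earliest unmatched truth time within ``match_window`` seconds.
    Accuracy = TP / (TP + FP + FN), defined as 1.0 when all three are zero.
    """
    truth_times = sorted(
        truth.expected_mos_times if isinstance(truth, GroundTruth) else truth
    )
    ev_times = sorted(e.t for e in events)
    matched = [False] * len(truth_times)
    tp = 0
    for te in ev_times:
        best, best_d = -1, match_window
        for i, tt in enumerate(truth_times):
            if matched[i]:
                continue
            d = abs(te - tt)
            if d <= best_d:
                best, best_d = i, d
        if best >= 0:
            matched[best] = True
            tp += 1
    fp = len(ev_times) - tp
    fn = len(truth_times) - tp
    denom = tp + fp + fn
    return {
        "tp": tp, "fp": fp, "fn": fn,
        "accuracy": tp / denom if denom else 1.0,
        "recall": tp / (tp + fn) if (tp + fn) else 1.0,
        "precision": tp / (tp + fp) if (tp + fp) else 1.0,
    }


def calibrate_weights(sessions: list[tuple[pd.DataFrame, GroundTruth]],
                      n_samples: int = 100,
                      cs_grid: tuple[float, ...] = (60.0, 65.0, 70.0, 75.0, 80.0, 85.0),
                      fp_penalty: float = 1.0,
                      cv: CriticalValues = DEFAULT_CRITICAL_VALUES,
                      seed: int = 0) -> tuple[RuleWeights, float, pd.DataFrame]:
    """Search weight vectors and critical scores maximising TP - λ·FP.

    Random weight vectors are drawn uniformly on the simplex (scaled to sum
    100) alongside the shipped defaults, each crossed with every critical
    score in ``cs_grid``; the objective is summed over all ground-truthed
    sessions. Deterministic given ``seed``. Returns the best weights, best
    critical score, and a per-setting report with TP/FP/FN.
    """
    if not sessions:
        raise ConfigurationError("calibration requires at least one ground-truthed session")
    if not cs_grid or n_samples < 0:
        raise ConfigurationError("empty calibration grid")
    rng = np.random.default_rng(seed)
    candidates = [RuleWeights()]
    for _ in range(n_samples):
        w = rng.dirichlet(np.ones(5)) * 100.0
        w[-1] = 100.0 - w[:-1].sum()  # exact sum under float rounding
        candidates.append(RuleWeights(*w))
    rows = []
    best = None
    for w in candidates:
        for cs in cs_grid:
            tp = fp = fn = 0
            for table, truth in sessions:
                res = evaluate(detect_mos(table, w, cs=cs, cv=cv), truth)
                tp += res["tp"]; fp += res["fp"]; fn += res["fn"]
            objective = tp - fp_penalty * fp
            rows.append({"w1": w.w1, "w2": w.w2, "w3": w.w3, "w4": w.w4, "w5": w.w5,
                         "cs": cs, "tp": tp, "fp": fp, "fn": fn, "objective": objective})
            if best is None or objective > best[0]:
                best = (objective, w, cs)
    report = pd.DataFrame(rows)
    assert best is not None
    return best[1], best[2], report
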