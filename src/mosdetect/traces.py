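"""Core in-memory containers: uniformly sampled signal traces and GPS tracks.

A :class:`SignalTrace` is a uniformly sampled physiological series (GSR in
microsiemens or skin temperature in degrees Celsius) with an explicit start
time (UTC epoch seconds), a sample rate in Hz, and a missing-value mask.
All time arithmetic in the package is done on UTC epoch seconds; no
local-time handling exists anywhere.

A :class:`GeoTrack` is an ordered sequence of GPS fixes (t, lat, lon).

The per-second bio-geotable that joins the preprocessed signals with
location is a plain :class:`pandas.DataFrame` with columns
``t, gsr, st, phasic, tonic, st_band, lat, lon`` (see
:func:`mosdetect.preprocess.build_biogeo`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError

#: Physical measurement range of wrist-worn GSR sensors, in microsiemens.
GSR_RANGE_US = (0.01, 100.0)

_UNITS = {"gsr": "uS", "st": "degC"}


@dataclass
class SignalTrace:
    """Uniformly sampled physiological series.

    Parameters
    ----------
    start_time:
        UTC epoch seconds of the first sample.
    rate:
        Sampling rate in Hz (> 0).
    values:
        Sample values; NaNs are treated as missing and reflected in ``missing``.
    kind:
        ``"gsr"`` or ``"st"``.
    missing:
        Boolean mask, True where the sample is missing. Defaults to
        ``~isfinite(values)``.
    """

    start_time: float
    rate: float
    values: np.ndarray
    kind: str = "gsr"
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ParameterError(f"rate must be > 0, got {self.rate}")
        if self.kind not in _UNITS:
            raise ParameterError(f"kind must be one of {sorted(_UNITS)}, got {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ParameterError("values must be a non-empty 1-D sequence")
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.values.shape:
                raise ParameterError("missing mask must match values in shape")
            self.missing = self.missing | ~np.isfinite(self.values)

    @property
    def unit(self) -> str:
        return _UNITS[self.kind]

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Covered time span in seconds (n / rate)."""
        return self.n / self.rate

    def times(self) -> np.ndarray:
        """Per-sample UTC epoch timestamps."""
        return self.start_time + np.arange(self.n) / self.rate

    def with_values(self, values: np.ndarray, *, rate: float | None = None,
                    missing: np.ndarray | None = None) -> "SignalTrace":
        """Copy of this trace with new values (and optionally a new rate)."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            rate=self.rate if rate is None else rate,
            missing=missing,
        )


@dataclass
class GeoTrack:
    """Sequence of GPS fixes: UTC epoch seconds, latitude, longitude (degrees)."""

    t: np.ndarray
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if not (self.t.shape == self.lat.shape == self.lon.shape):
            raise ParameterError("t, lat, lon must have equal length")
        if self.t.size and np.any(np.diff(self.t) < 0):
            raise ParameterError("timestamps must be non-decreasing")
        if self.lat.size and (np.nanmax(np.abs(self.lat)) > 90 or np.nanmax(np.abs(self.lon)) > 180):
            raise ParameterError("latitude/longitude out of range")

    def __len__(self) -> int:
        return self.t.size
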