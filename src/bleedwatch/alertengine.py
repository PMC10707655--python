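"""Low-pass filtering and escalation of the per-frame bleeding confidence.

The raw per-frame confidence emitted by the event-detection branch is noisy;
a causal digital Butterworth low-pass filter (default cutoff 5 Hz) stabilises
it. On top of the filtered signal sits a "parking sensor" escalation: brief
bleeding detections — even at modest confidence — that keep recurring raise
a bounded warning level, because in practice such repeated low-confidence
occurrences over roughly 2.1–2.3 s tend to precede a frank bleeding event.
When the warning level crosses a significance threshold (93–95 % band,
default 94 %), a dichotomic bleeding event (0/1) is recorded with its onset
time.

Escalation law (one first-order update per frame, Δt = 1/fps)::

    detection  := filtered p >= detection_floor
    active(t)  := some detection occurred within the trailing hold window
    w += Δt / escalation_window        while active
    w -= decay_rate * Δt               while inactive
    w  = clip(w, 0, 1)

The rise rate is amplitude-independent above the floor: persistence of
detections, not their confidence, drives escalation, so sustained
detections saturate the warning level in exactly one escalation window.
The hold window (default 300 ms) bridges the gaps between recurring
precursor detections, mirroring how a parking sensor holds its tone
between pings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "ProbabilitySeries",
    "FilterSpec",
    "AlertConfig",
    "AlertTrace",
    "design_butterworth",
    "lowpass_filter",
    "update_warning",
    "detect_events",
    "run_alert_pipeline",
]


@dataclass
class ProbabilitySeries:
    """Uniformly sampled per-frame confidence signal in [0, 1]."""

    values: np.ndarray
    fps: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.values.size and (self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9):
            raise ValueError("values must lie in [0, 1]")

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fps


@dataclass(frozen=True)
class FilterSpec:
    """Designed digital low-pass filter (transfer-function form)."""

    cutoff_hz: float
    order: int
    sample_rate_hz: float
    b: tuple[float, ...]
    a: tuple[float, ...]
    nominal_delay_ms: float

    def magnitude(self, freq_hz: np.ndarray) -> np.ndarray:
        """|H(f)| evaluated at the given frequencies."""
        w = 2 * np.pi * np.asarray(freq_hz, dtype=float) / self.sample_rate_hz
        _, h = sps.freqz(self.b, self.a, worN=w)
        return np.abs(h)


@dataclass(frozen=True)
class AlertConfig:
    """Escalation and thresholding parameters.

    ``escalation_window_ms`` is the horizon over which persistent detections
    saturate the warning level (valid range ≈ 2100–2300 ms);
    ``detection_floor`` is the minimum filtered confidence counted as a
    possible bleeding occurrence; ``significant_threshold`` declares
    significant bleeding (93–95 % band); ``decay_rate`` pulls the level back
    down once detections stop; ``hold_ms`` is how long a single detection
    keeps the escalation active.
    """

    escalation_window_ms: float = 2200.0
    detection_floor: float = 0.30
    significant_threshold: float = 0.94
    decay_rate: float = 0.5
    hold_ms: float = 300.0

    def __post_init__(self) -> None:
        if not 0 < self.detection_floor < self.significant_threshold <= 1:
            raise ValueError("need 0 < detection_floor < significant_threshold <= 1")
        if self.escalation_window_ms <= 0 or self.hold_ms < 0:
            raise ValueError("window and hold must be non-negative")


@dataclass
class AlertTrace:
    """Filtered signal, warning level and dichotomic alert events."""

    filtered: ProbabilitySeries
    warning_level: np.ndarray
    events: list[tuple[float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        onsets = [t for t, _ in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")


def design_butterworth(
    cutoff_hz: float = 5.0, sample_rate_hz: float = 25.0, order: int = 2
) -> FilterSpec:
    """Design a causal digital Butterworth low-pass filter.

    DC gain is 1 and the magnitude response is monotonically non-increasing;
    the −3 dB point sits at ``cutoff_hz``. ``nominal_delay_ms`` is measured
    from the unit-step response (time of the 50 % crossing) rather than
    asserted, since group delay depends on order and sample rate.
    """
    nyquist = sample_rate_hz / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, {nyquist}) Hz")
    if order < 1:
        raise ValueError("order must be >= 1")
    b, a = sps.butter(order, cutoff_hz / nyquist)
    step = sps.lfilter(b, a, np.ones(int(10 * sample_rate_hz / cutoff_hz) + 50))
    crossing = int(np.argmax(step >= 0.5))
    delay_ms = 1000.0 * crossing / sample_rate_hz
    return FilterSpec(
        cutoff_hz=cutoff_hz,
        order=order,
        sample_rate_hz=sample_rate_hz,
        b=tuple(b),
        a=tuple(a),
        nominal_delay_ms=delay_ms,
    )


def lowpass_filter(series: ProbabilitySeries, spec: FilterSpec) -> ProbabilitySeries:
    """Causally filter a confidence series; output clamped back to [0, 1].

    Initial filter state is zero, so prepending zero-confidence samples
    leaves later output unchanged (live-stream semantics).
    """
    if not np.isclose(series.fps, spec.sample_rate_hz):
        raise ValueError(
            f"series fps {series.fps} != filter sample rate {spec.sample_rate_hz}"
        )
    y = sps.lfilter(spec.b, spec.a, series.values)
    return ProbabilitySeries(values=np.clip(y, 0.0, 1.0), fps=series.fps, t0=series.t0)


def update_warning(filtered: ProbabilitySeries, cfg: AlertConfig) -> AlertTrace:
    """Escalate the filtered signal into a bounded warning level.

    Implements the persistence law in the module docstring and records
    dichotomic events at upward crossings of ``significant_threshold``.
    """
    p = filtered.values
    dt = 1.0 / filtered.fps
    hold_n = int(round(cfg.hold_ms / 1000.0 * filtered.fps))
    rise = dt / (cfg.escalation_window_ms / 1000.0)
    w = np.zeros_like(p)
    level = 0.0
    since_detection = hold_n + 1  # no detection yet
    for i, pi in enumerate(p):
        if pi >= cfg.detection_floor:
            since_detection = 0
        else:
            since_detection += 1
        if since_detection <= hold_n:
            level = min(1.0, level + rise)
        else:
            level = max(0.0, level - cfg.decay_rate * dt)
        w[i] = level
    trace = AlertTrace(filtered=filtered, warning_level=w, events=[])
    trace.events = detect_events(trace, cfg)
    return trace


def detect_events(trace: AlertTrace, cfg: AlertConfig) -> list[tuple[float, int]]:
    """Dichotomic bleeding events: one per upward threshold crossing."""
    w = trace.warning_level
    t = trace.filtered.times()
    above = w >= cfg.significant_threshold
    rising = above & ~np.concatenate([[False], above[:-1]])
    return [(float(t[i]), 1) for i in np.flatnonzero(rising)]


def run_alert_pipeline(
    series: ProbabilitySeries,
    filter_spec: FilterSpec | None = None,
    alert_config: AlertConfig | None = None,
) -> AlertTrace:
    """Filter a raw confidence series and escalate it into alerts."""
    if filter_spec is None:
        filter_spec = design_butterworth(sample_rate_hz=series.fps)
    if alert_config is None:
        alert_config = AlertConfig()
    return update_warning(lowpass_filter(series, filter_spec), alert_config)
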