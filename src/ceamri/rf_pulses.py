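"""Transmit waveform synthesis for concurrent excitation and acquisition (CEA) MRI.

All pulses are complex baseband envelopes: the Larmor carrier is never
synthesized, and "frequency" always means offset from the carrier.  Three
families are provided:

* a constant rectangular pulse, used by the calibration feedback loop;
* a linear-sweep chirp with sinusoidally smoothed edges, the workhorse
  imaging pulse;
* the HS8 hyperbolic-secant adiabatic pulse (amplitude ``sech(beta*tau^8)``
  with frequency modulation proportional to the running integral of the
  squared amplitude), used by the fast protocols.

Phase is accumulated by trapezoidal integration of the instantaneous
frequency, because no closed form exists for the HS8 phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RFPulse",
    "make_rect",
    "make_chirp",
    "make_hs8",
    "instantaneous_frequency",
]


@dataclass(frozen=True)
class RFPulse:
    """A complex baseband transmit waveform.

    Attributes
    ----------
    samples : ndarray of complex
        Complex envelope in arbitrary voltage units.
    dt : float
        Sample interval in seconds.
    duration : float
        Pulse duration in seconds (``len(samples) * dt`` within one sample).
    sweep_bandwidth : float
        Total instantaneous-frequency excursion in Hz (0 for rect).
    kind : str
        One of ``{"rect", "chirp", "hs8"}``.
    center_offset : float
        Offset of the sweep center from the carrier, Hz.
    """

    samples: np.ndarray
    dt: float
    duration: float
    sweep_bandwidth: float = 0.0
    kind: str = "rect"
    center_offset: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=complex))

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def t(self) -> np.ndarray:
        """Sample times (s), starting at 0."""
        return np.arange(self.n) * self.dt

    def to_config(self) -> dict:
        """Serializable description of the pulse parameters."""
        cfg = {
            "kind": self.kind,
            "duration_s": self.duration,
            "bandwidth_hz": self.sweep_bandwidth,
            "amplitude": float(np.max(np.abs(self.samples))) if self.n else 0.0,
            "dt_s": self.dt,
        }
        cfg.update(self.meta)
        return cfg


def _check_timing(duration: float, dt: float) -> int:
    if duration <= 0 or dt <= 0:
        raise ValueError(f"duration and dt must be positive, got {duration=}, {dt=}")
    n = int(round(duration / dt))
    if n < 2:
        raise ValueError("pulse must contain at least 2 samples")
    return n


def _phase_from_freq(freq_hz: np.ndarray, dt: float) -> np.ndarray:
    """Accumulated phase (rad) from instantaneous frequency by trapezoidal rule."""
    phase = np.zeros_like(freq_hz)
    phase[1:] = np.cumsum(0.5 * (freq_hz[1:] + freq_hz[:-1])) * dt
    return 2.0 * np.pi * phase


def make_rect(duration: float, amplitude: float, dt: float) -> RFPulse:
    """Constant rectangular pulse with zero phase.

    The calibration sequence transmits a 4 ms rectangular pulse while the
    feedback controller adjusts the canceller; this synthesizes that pulse.
    """
    n = _check_timing(duration, dt)
    samples = np.full(n, amplitude, dtype=complex)
    return RFPulse(samples, dt, duration, 0.0, "rect")


def make_chirp(
    duration: float,
    sweep_bandwidth: float,
    amplitude: float,
    dt: float,
    smooth_fraction: float = 0.1,
    center_offset: float = 0.0,
) -> RFPulse:
    """Linear frequency sweep from -BW/2 to +BW/2 with smoothed edges.

    The envelope is ramped by a quarter-period sine over the first
    ``smooth_fraction`` of the duration and mirrored over the last, to
    avoid the acquisition distortions a hard RF onset would cause.
    """
    if not 0.0 <= smooth_fraction <= 0.5:
        raise ValueError(f"smooth_fraction must be in [0, 0.5], got {smooth_fraction}")
    n = _check_timing(duration, dt)
    t = np.arange(n) * dt
    # instantaneous frequency: linear ramp crossing center at mid-pulse
    freq = center_offset + sweep_bandwidth * (t / duration - 0.5)
    phase = _phase_from_freq(freq, dt)

    env = np.ones(n)
    n_ramp = int(round(smooth_fraction * n))
    if n_ramp > 0:
        ramp = np.sin(0.5 * np.pi * np.arange(n_ramp) / n_ramp)
        env[:n_ramp] = ramp
        env[n - n_ramp:] = ramp[::-1]
    samples = amplitude * env * np.exp(1j * phase)
    return RFPulse(
        samples, dt, duration, sweep_bandwidth, "chirp", center_offset,
        meta={"smooth_fraction": smooth_fraction},
    )


def make_hs8(
    duration: float,
    sweep_bandwidth: float,
    amplitude: float,
    dt: float,
    truncation: float = 0.01,
    center_offset: float = 0.0,
) -> RFPulse:
    """HS8 hyperbolic-secant frequency-swept pulse.

    Amplitude modulation ``AM(tau) = sech(beta * tau**8)`` on tau in [-1, 1],
    with beta fixed by the edge truncation level ``AM(+-1) = truncation``.
    The frequency modulation is proportional to the running integral of
    ``AM**2`` (the standard adiabatic HSn construction), scaled so the total
    excursion equals ``sweep_bandwidth``.
    """
    if not 0.0 < truncation < 1.0:
        raise ValueError(f"truncation must be in (0, 1), got {truncation}")
    n = _check_timing(duration, dt)
    t = np.arange(n) * dt
    # midpoint sampling keeps the envelope exactly even in tau
    tau = 2.0 * (np.arange(n) + 0.5) / n - 1.0
    beta = np.arccosh(1.0 / truncation)  # asech(truncation)
    am = 1.0 / np.cosh(beta * tau**8)

    # FM from the cumulative integral of AM^2, centered and normalized
    cum = np.concatenate(([0.0], np.cumsum(0.5 * (am[1:] ** 2 + am[:-1] ** 2))))
    cum /= cum[-1]
    freq = center_offset + sweep_bandwidth * (cum - 0.5)
    phase = _phase_from_freq(freq, dt)
    samples = amplitude * am * np.exp(1j * phase)
    return RFPulse(
        samples, dt, duration, sweep_bandwidth, "hs8", center_offset,
        meta={"truncation": truncation},
    )


def instantaneous_frequency(pulse: RFPulse) -> np.ndarray:
    """Finite-difference instantaneous frequency (Hz) of a pulse.

    Returns the derivative of the unwrapped sample phase divided by
    ``2*pi*dt``; the result has ``n - 1`` elements.
    """
    if pulse.n < 2:
        raise ValueError("instantaneous frequency requires at least 2 samples")
    phase = np.unwrap(np.angle(pulse.samples))
    return np.diff(phase) / (2.0 * np.pi * pulse.dt)


def from_config(cfg: dict) -> RFPulse:
    """Build a pulse from its structured-config description."""
    kind = cfg["kind"]
    if kind == "rect":
        return make_rect(cfg["duration_s"], cfg.get("amplitude", 1.0), cfg["dt_s"])
    if kind == "chirp":
        return make_chirp(
            cfg["duration_s"], cfg["bandwidth_hz"], cfg.get("amplitude", 1.0),
            cfg["dt_s"], cfg.get("smooth_fraction", 0.1),
        )
    if kind == "hs8":
        return make_hs8(
            cfg["duration_s"], cfg["bandwidth_hz"], cfg.get("amplitude", 1.0),
            cfg["dt_s"], cfg.get("truncation", 0.01),
        )
    raise ValueError(f"unknown pulse kind {kind!r}; expected rect, chirp or hs8")
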