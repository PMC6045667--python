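"""Analog self-interference cancellation chain for CEA MRI.

Models the front end between the RF power amplifier and the digitizer: a
directional coupler taps a small copy of the transmit waveform, a
voltage-controlled phase shifter and attenuator condition that copy, and a
power combiner subtracts it from the receive-coil output, where the transmit
signal leaks in through residual coil coupling despite the orthogonal
(geometric) placement of the Tx and Rx loops:

    s_Rx(t) = A_cpl * u_Tx(t) * exp(j*phi_cpl) + s_MR(t)
    s(t)    = s_Rx(t) - A * u_Tx(t) * exp(j*phi)

The actuators are described only through their measured transfer curves:
the phase shifter covers 280 deg between 0 and 12 V control voltage with a
saturating (varactor-type) characteristic, and the attenuator reaches its
1.3 dB minimum at 6.0 V with a ~1.2 dB/V slope between 3 and 6 V, steeper
below.  Device physics is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

logger = logging.getLogger(__name__)

ISOLATION_CAP_DB = 200.0  # reported isolation for an exactly-zero residual

__all__ = [
    "SignalTrace",
    "DirectionalCoupler",
    "PhaseShifter",
    "Attenuator",
    "CancellerSetting",
    "CouplingChannel",
    "PickupCoil",
    "AnalogFrontend",
    "split",
    "phase_response",
    "attenuation_response",
    "apply_canceller",
    "leak",
    "combine",
    "pickup",
    "isolation_db",
]


@dataclass(frozen=True)
class SignalTrace:
    """A sampled complex baseband voltage trace."""

    samples: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=complex)
        if not np.all(np.isfinite(arr)):
            raise ValueError("SignalTrace samples must be finite")
        object.__setattr__(self, "samples", arr)

    @property
    def n(self) -> int:
        return len(self.samples)

    def power(self) -> float:
        """Total power: sum of |samples|^2."""
        return float(np.sum(np.abs(self.samples) ** 2))

    def __mul__(self, k: complex) -> "SignalTrace":
        return SignalTrace(self.samples * k, self.dt)

    __rmul__ = __mul__


@dataclass(frozen=True)
class DirectionalCoupler:
    """Lossless directional coupler with amplitude coupling factor c."""

    coupling_factor: float = 0.28

    def __post_init__(self) -> None:
        if not 0.0 < self.coupling_factor < 1.0:
            raise ValueError("coupling factor must be in (0, 1)")


@dataclass(frozen=True)
class PhaseShifter:
    """Voltage-controlled reflection-type phase shifter.

    The voltage -> phase map is a saturating arctangent anchored so that the
    total coverage between 0 and 12 V is ``coverage_deg`` (280 deg measured):
    ``phi(V) = coverage * atan(V/v0) / atan(12/v0)``.  The curve is strictly
    monotone with decreasing slope, mimicking the varactor capacitance
    saturation.  Insertion loss is a fixed scalar (measured -0.8 dB).
    """

    v_min: float = 0.0
    v_max: float = 25.0
    coverage_deg: float = 280.0
    v_anchor: float = 12.0
    v0: float = 4.0
    insertion_loss_db: float = 0.8

    def phase_deg(self, v: float) -> float:
        return self.coverage_deg * np.arctan(v / self.v0) / np.arctan(self.v_anchor / self.v0)


@dataclass(frozen=True)
class Attenuator:
    """Voltage-controlled PIN-diode attenuator.

    Linear segment ``1.3 + 1.2*(6 - V)`` dB on [3, 6] V (measured anchors),
    continued below 3 V by a quadratic matched in value and slope at 3 V and
    reaching ``max_att_db`` at 0 V, so attenuation rises steeply toward low
    control voltages.
    """

    v_min: float = 0.0
    v_max: float = 6.0
    min_att_db: float = 1.3
    slope_db_per_v: float = 1.2
    knee_v: float = 3.0
    max_att_db: float = 30.0

    def attenuation_db(self, v: float) -> float:
        if v >= self.knee_v:
            return self.min_att_db + self.slope_db_per_v * (self.v_max - v)
        # quadratic a*v^2 + b*v + c with value/slope continuity at the knee
        # and attenuation(0) = max_att_db
        att_knee = self.min_att_db + self.slope_db_per_v * (self.v_max - self.knee_v)
        c = self.max_att_db
        # solve a*k^2 + b*k + c = att_knee ; 2*a*k + b = -slope
        k = self.knee_v
        a = (self.slope_db_per_v * k + att_knee - c) / (-(k**2))
        b = -self.slope_db_per_v - 2.0 * a * k
        return a * v**2 + b * v + c


@dataclass(frozen=True)
class CancellerSetting:
    """Control voltages for the cancellation path: phase (V1) and attenuation."""

    V1: float
    V_att: float


@dataclass(frozen=True)
class CouplingChannel:
    """The Tx -> Rx leakage path.

    ``A_cpl`` and ``phi_cpl_deg`` describe the coupling on top of the passive
    geometric isolation (orthogonal coil placement), so the total leakage
    amplitude ratio is ``10**(-geometric_isolation_db/20) * A_cpl``.  An
    optional linear frequency slope (dB/kHz, deg/kHz) models the measured
    off-resonance roll-off of the decoupling.
    """

    A_cpl: float = 1.0
    phi_cpl_deg: float = 0.0
    geometric_isolation_db: float = 30.0
    freq_slope: Optional[Tuple[float, float]] = None  # (dB/kHz, deg/kHz)

    def __post_init__(self) -> None:
        if self.A_cpl <= 0:
            raise ValueError("A_cpl must be positive")

    @property
    def leak_amplitude(self) -> float:
        return 10.0 ** (-self.geometric_isolation_db / 20.0) * self.A_cpl


@dataclass(frozen=True)
class PickupCoil:
    """Small monitor loop near the Tx coil sampling the transmit waveform."""

    amplitude: float = 0.05
    phase_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("pick-up coupling amplitude must be positive")


def split(u_tx: SignalTrace, coupler: DirectionalCoupler) -> Tuple[SignalTrace, SignalTrace]:
    """Tap the cancellation copy off the Tx line.

    Lossless convention: copy = c*u, main = sqrt(1-c^2)*u, so per-sample
    power is conserved.
    """
    c = coupler.coupling_factor
    return (
        SignalTrace(np.sqrt(1.0 - c**2) * u_tx.samples, u_tx.dt),
        SignalTrace(c * u_tx.samples, u_tx.dt),
    )


def _clamp(v: float, lo: float, hi: float, what: str) -> float:
    if v < lo or v > hi:
        logger.warning("%s voltage %.3f V outside [%g, %g] V; clamped", what, v, lo, hi)
        return min(max(v, lo), hi)
    return v


def phase_response(shifter: PhaseShifter, v1: float) -> float:
    """Phase shift in degrees at control voltage ``v1`` (clamped to range)."""
    v1 = _clamp(v1, shifter.v_min, shifter.v_max, "phase-shifter")
    return shifter.phase_deg(v1)


def attenuation_response(att: Attenuator, v_att: float) -> float:
    """Attenuation in dB at control voltage ``v_att`` (clamped to range)."""
    v_att = _clamp(v_att, att.v_min, att.v_max, "attenuator")
    return att.attenuation_db(v_att)


def apply_canceller(
    copy: SignalTrace,
    setting: CancellerSetting,
    shifter: PhaseShifter,
    att: Attenuator,
) -> SignalTrace:
    """Produce the cancellation reference A * u_Tx * exp(j*phi).

    The copy is scaled by the attenuator plus the phase shifter's fixed
    insertion loss and rotated by the phase-shifter response.
    """
    loss_db = attenuation_response(att, setting.V_att) + shifter.insertion_loss_db
    phi = np.deg2rad(phase_response(shifter, setting.V1))
    gain = 10.0 ** (-loss_db / 20.0) * np.exp(1j * phi)
    return SignalTrace(copy.samples * gain, copy.dt)


def _per_sample_freq_hz(trace: SignalTrace) -> np.ndarray:
    """Instantaneous frequency per sample (Hz), edge-padded to full length."""
    phase = np.unwrap(np.angle(trace.samples))
    f = np.diff(phase) / (2.0 * np.pi * trace.dt)
    return np.concatenate((f[:1], f)) if len(f) else np.zeros(trace.n)


def leak(u_tx_main: SignalTrace, channel: CouplingChannel) -> SignalTrace:
    """Transmit leakage appearing at the Rx coil output."""
    gain = channel.leak_amplitude * np.exp(1j * np.deg2rad(channel.phi_cpl_deg))
    samples = gain * u_tx_main.samples
    if channel.freq_slope is not None:
        db_per_khz, deg_per_khz = channel.freq_slope
        f_khz = _per_sample_freq_hz(u_tx_main) / 1e3
        samples = samples * 10.0 ** (db_per_khz * f_khz / 20.0) * np.exp(
            1j * np.deg2rad(deg_per_khz * f_khz)
        )
    return SignalTrace(samples, u_tx_main.dt)


def combine(s_rx: SignalTrace, cancel_ref: SignalTrace) -> SignalTrace:
    """Power-combiner subtraction: s = s_Rx - cancellation reference."""
    if s_rx.n != cancel_ref.n or s_rx.dt != cancel_ref.dt:
        raise ValueError("combine requires equal-length traces on the same clock")
    return SignalTrace(s_rx.samples - cancel_ref.samples, s_rx.dt)


def pickup(u_tx: SignalTrace, puc: PickupCoil) -> SignalTrace:
    """Monitor-coil copy of the transmit waveform."""
    gain = puc.amplitude * np.exp(1j * np.deg2rad(puc.phase_deg))
    return SignalTrace(gain * u_tx.samples, u_tx.dt)


def isolation_db(leak_trace: SignalTrace, residual: SignalTrace) -> float:
    """Suppression in dB: 10*log10(leak power / residual power).

    A residual of exactly zero power reports ``ISOLATION_CAP_DB``.
    """
    p_leak = leak_trace.power()
    if p_leak <= 0.0 or leak_trace.n == 0:
        raise ValueError("leak trace must have nonzero power")
    p_res = residual.power()
    if p_res == 0.0:
        return ISOLATION_CAP_DB
    return min(10.0 * np.log10(p_leak / p_res), ISOLATION_CAP_DB)


@dataclass
class AnalogFrontend:
    """The assembled analog chain: coupler + actuators (+ pick-up coil).

    Convenience wrapper used by the feedback controller and the full-chain
    simulator; all physics lives in the free functions above.
    """

    coupler: DirectionalCoupler = field(default_factory=DirectionalCoupler)
    shifter: PhaseShifter = field(default_factory=PhaseShifter)
    attenuator: Attenuator = field(default_factory=Attenuator)
    puc: PickupCoil = field(default_factory=PickupCoil)

    def receive(
        self,
        u_tx: SignalTrace,
        channel: CouplingChannel,
        setting: CancellerSetting,
        s_mr: Optional[SignalTrace] = None,
    ) -> Tuple[SignalTrace, SignalTrace]:
        """One concurrent acquisition: returns (combiner output, leakage).

        The leakage trace is what the Rx coil picks up from the transmitter;
        the output is that plus any MR signal, minus the conditioned copy.
        """
        main, copy = split(u_tx, self.coupler)
        lk = leak(main, channel)
        rx = lk.samples.copy()
        if s_mr is not None:
            rx = rx + s_mr.samples
        ref = apply_canceller(copy, setting, self.shifter, self.attenuator)
        out = SignalTrace(rx - ref.samples, u_tx.dt)
        return out, lk

    def optimal_setting(self, channel: CouplingChannel) -> CancellerSetting:
        """Analytically invert the actuator maps for a given channel.

        Used by fixtures to place feedback starting points near the optimum
        ("initial voltage levels were determined experimentally" in practice).
        Solves phase(V1) = phi_cpl (mod 360) and attenuation so the copy
        magnitude matches the leakage magnitude.
        """
        from scipy.optimize import brentq

        sh, at = self.shifter, self.attenuator
        target_phi = channel.phi_cpl_deg % 360.0
        lo, hi = sh.phase_deg(sh.v_min), sh.phase_deg(sh.v_max)
        if not (lo <= target_phi <= hi):
            raise ValueError(
                f"coupling phase {target_phi:.1f} deg outside shifter coverage "
                f"[{lo:.1f}, {hi:.1f}] deg"
            )
        v1 = brentq(lambda v: sh.phase_deg(v) - target_phi, sh.v_min, sh.v_max)

        # required total loss: copy*c -> match leak amplitude
        c = self.coupler.coupling_factor
        main_scale = np.sqrt(1.0 - c**2)
        need_db = -20.0 * np.log10(channel.leak_amplitude * main_scale / c)
        att_needed = need_db - sh.insertion_loss_db
        att_lo = at.attenuation_db(at.v_max)
        att_hi = at.attenuation_db(at.v_min)
        if not (att_lo <= att_needed <= att_hi):
            raise ValueError(
                f"required attenuation {att_needed:.2f} dB outside "
                f"[{att_lo:.2f}, {att_hi:.2f}] dB"
            )
        v_att = brentq(lambda v: at.attenuation_db(v) - att_needed, at.v_min, at.v_max)
        return CancellerSetting(V1=float(v1), V_att=float(v_att))
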