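"""MR signal generation for concurrent excitation and acquisition.

The received MR signal during a swept low-power excitation is modeled as a
causal convolution of the transmit envelope with the spin system's impulse
response (the FID under the readout gradient):

    s_MR[n] = h[0] u_Tx[n] + h[1] u_Tx[n-1] + ...

valid in the small-flip-angle regime (effective flips here are well below
one degree).  ``fid_response`` evaluates h analytically for an isochromat
ensemble; ``bloch_simulate`` integrates the Bloch equations with per-step
rotation matrices and serves as the independent validation oracle for the
convolution model.

Units: gradients in mT/m, positions in m, times in s; the RF amplitude is
in arbitrary voltage units mapped to nutation frequency through a single
scale (Hz per unit amplitude) standing in for coil efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .analog_frontend import AnalogFrontend, CancellerSetting, CouplingChannel, SignalTrace
from .rf_pulses import RFPulse

GAMMA_BAR = 42.577e6  # Hz/T, proton gyromagnetic ratio over 2*pi

__all__ = [
    "GAMMA_BAR",
    "Phantom",
    "GradientWaveform",
    "SpokeAcquisition",
    "ImpulseResponse",
    "Protocol",
    "fid_response",
    "cea_signal",
    "bloch_simulate",
    "spoke_directions",
    "acquire_dataset",
    "full_chain",
]


@dataclass(frozen=True)
class Phantom:
    """Isochromat ensemble: positions (m), densities, T2* (s), shifts (Hz)."""

    positions: np.ndarray  # (n, 3)
    m0: np.ndarray  # (n,)
    t2star: np.ndarray  # (n,) seconds
    chem_shift: np.ndarray  # (n,) Hz
    name: str = ""

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "positions", pos)
        for attr in ("m0", "t2star", "chem_shift"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), dtype=float))
        if np.any(self.t2star <= 0):
            raise ValueError("T2* must be positive")
        if not np.all(np.isfinite(pos)):
            raise ValueError("isochromat positions must be finite")

    @property
    def n_isochromats(self) -> int:
        return len(self.m0)


@dataclass(frozen=True)
class GradientWaveform:
    """Constant-direction readout gradient with a linear ramp then plateau."""

    direction: np.ndarray  # unit 3-vector
    amplitude: float  # mT/m
    ramp_time: float = 0.0  # s
    max_amplitude: float = 40.0  # mT/m, protocol hardware limit

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
            raise ValueError("gradient direction must be a unit vector")
        object.__setattr__(self, "direction", d)
        if abs(self.amplitude) > self.max_amplitude:
            raise ValueError(
                f"gradient amplitude {self.amplitude} mT/m exceeds limit "
                f"{self.max_amplitude} mT/m"
            )

    def magnitude(self, t: np.ndarray) -> np.ndarray:
        """|G|(t) in mT/m with linear ramp over ramp_time."""
        t = np.asarray(t, dtype=float)
        if self.ramp_time <= 0:
            return np.full_like(t, self.amplitude)
        return self.amplitude * np.clip(t / self.ramp_time, 0.0, 1.0)

    def moment(self, t: np.ndarray) -> np.ndarray:
        """Zeroth moment int |G| dt' in (mT/m)*s, exact for the trapezoid."""
        t = np.asarray(t, dtype=float)
        if self.ramp_time <= 0:
            return self.amplitude * t
        ramp = np.minimum(t, self.ramp_time)
        m_ramp = self.amplitude * ramp**2 / (2.0 * self.ramp_time)
        m_plat = self.amplitude * np.maximum(t - self.ramp_time, 0.0)
        return m_ramp + m_plat

    def k_radius(self, t: np.ndarray) -> np.ndarray:
        """k-space radius gamma_bar * int G dt in 1/m."""
        return GAMMA_BAR * self.moment(t) * 1e-3


@dataclass(frozen=True)
class ImpulseResponse:
    """Per-spoke FID h[n]; the quantity that is gridded into k-space."""

    h: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "h", np.asarray(self.h, dtype=complex))

    @property
    def length(self) -> int:
        return len(self.h)


@dataclass(frozen=True)
class SpokeAcquisition:
    """One radial spoke: direction, concurrently acquired signal, k radii."""

    direction: np.ndarray
    s_mr: SignalTrace
    k_traj: np.ndarray  # per-sample k radius, 1/m
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.k_traj) != self.s_mr.n:
            raise ValueError("k trajectory length must match the signal")
        if np.any(np.diff(self.k_traj) < -1e-12):
            raise ValueError("k radius must be monotone along a spoke")


@dataclass(frozen=True)
class Protocol:
    """Acquisition protocol for a radial CEA dataset."""

    n_spokes: int
    n_samples: int
    pulse: RFPulse
    grad_amplitude: float  # mT/m
    ramp_time: float = 0.0
    dims: int = 3
    fov: float = 0.32  # m
    tr: float = 0.0
    max_gradient: float = 40.0

    def __post_init__(self) -> None:
        if self.n_spokes < 1:
            raise ValueError("spoke count must be >= 1")
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")


def fid_response(
    phantom: Phantom,
    grad: GradientWaveform,
    dt: float,
    n: int,
    gamma_bar: float = GAMMA_BAR,
) -> ImpulseResponse:
    """Analytic FID of the ensemble under the (ramped) readout gradient.

    h[m] = sum_i M0_i exp(-t_m/T2*_i) exp(j 2 pi (gamma_bar (G.r_i) moment
    + df_i t_m)) with t_m = m dt and the gradient entering through its exact
    trapezoidal moment.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    t = np.arange(n) * dt
    proj = phantom.positions @ grad.direction  # (n_iso,) meters
    moment = grad.moment(t) * 1e-3  # (T/m)*s
    # phase (n_iso, n): gradient encoding + chemical shift
    phase = 2.0 * np.pi * (
        gamma_bar * np.outer(proj, moment) + np.outer(phantom.chem_shift, t)
    )
    decay = np.exp(-np.outer(1.0 / phantom.t2star, t))
    h = (phantom.m0[:, None] * decay * np.exp(1j * phase)).sum(axis=0)
    return ImpulseResponse(h, dt)


def cea_signal(
    phantom: Phantom,
    pulse: RFPulse,
    grad: GradientWaveform,
    n: int,
    gamma_bar: float = GAMMA_BAR,
) -> SignalTrace:
    """Small-tip MR signal: causal convolution of the FID with the pulse."""
    imp = fid_response(phantom, grad, pulse.dt, n, gamma_bar)
    s = np.convolve(pulse.samples, imp.h)[:n]
    return SignalTrace(s, pulse.dt)


def _rotate(m: np.ndarray, axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rodrigues rotation of magnetization vectors m (k,3) about per-row axes."""
    norm = np.linalg.norm(axis, axis=1, keepdims=True)
    small = norm[:, 0] < 1e-30
    nhat = np.where(small[:, None], np.array([0.0, 0.0, 1.0]), axis / np.where(norm == 0, 1, norm))
    ang = np.where(small, 0.0, angle)
    c = np.cos(ang)[:, None]
    s = np.sin(ang)[:, None]
    dot = np.sum(nhat * m, axis=1, keepdims=True)
    cross = np.cross(nhat, m)
    return m * c + cross * s + nhat * dot * (1.0 - c)


def bloch_simulate(
    phantom: Phantom,
    pulse: RFPulse,
    grad: GradientWaveform,
    n: int,
    b1_scale_hz: float = 1.0,
    gamma_bar: float = GAMMA_BAR,
    t1: Optional[float] = None,
) -> SignalTrace:
    """Rotation-matrix Bloch integration; the oracle for the convolution model.

    Each isochromat starts at equilibrium (0, 0, M0) and is rotated per
    sample step about the effective field (B1 real/imag and the gradient +
    chemical-shift off-resonance), with transverse decay exp(-dt/T2*)
    applied after each step.  The summed transverse magnetization is scaled
    by 1/(j 2 pi b1_scale dt) so that at small flip angles the output
    matches ``cea_signal`` sample for sample.

    Raises if the per-step rotation exceeds 0.5 rad (reduce dt).
    """
    dt = pulse.dt
    t = np.arange(n) * dt
    proj = phantom.positions @ grad.direction  # m
    gmag = grad.magnitude(t) * 1e-3  # T/m at each sample
    # off-resonance (Hz) per isochromat per step
    df = gamma_bar * np.outer(proj, gmag) + phantom.chem_shift[:, None]  # (n_iso, n)

    u = np.zeros(n, dtype=complex)
    u[: min(n, pulse.n)] = pulse.samples[: min(n, pulse.n)]
    w1 = 2.0 * np.pi * b1_scale_hz * u  # rad/s complex nutation

    wz = 2.0 * np.pi * df
    max_rot = np.max(np.sqrt(np.abs(w1[None, :]) ** 2 + wz**2)) * dt
    if max_rot > 0.5:
        raise ValueError(
            f"per-step rotation {max_rot:.2f} rad exceeds 0.5 rad; reduce dt "
            "or the off-resonance/B1 range"
        )

    n_iso = phantom.n_isochromats
    m = np.zeros((n_iso, 3))
    m[:, 2] = phantom.m0
    e2 = np.exp(-dt / phantom.t2star)
    out = np.zeros(n, dtype=complex)
    for i in range(n):
        # effective rotation vector in the rotating frame (left-handed
        # precession convention, matched to the +j encoding of the FID model)
        ax = np.empty((n_iso, 3))
        ax[:, 0] = -w1[i].real
        ax[:, 1] = -w1[i].imag
        ax[:, 2] = wz[:, i]
        ang = np.linalg.norm(ax, axis=1) * dt
        m = _rotate(m, ax, ang)
        m[:, 0] *= e2
        m[:, 1] *= e2
        if t1 is not None:
            m[:, 2] = phantom.m0 + (m[:, 2] - phantom.m0) * np.exp(-dt / t1)
        out[i] = np.sum(m[:, 0] + 1j * m[:, 1])
    scale = 1j * 2.0 * np.pi * b1_scale_hz * dt
    return SignalTrace(out / scale, dt)


def _spherical_spiral(n: int) -> np.ndarray:
    """Deterministic near-uniform directions on the half sphere, mirrored.

    Generates n/2 points on a spherical (Fibonacci) spiral and appends their
    antipodes, so spoke i and spoke i + n/2 always form an opposite pair.
    """
    half = n // 2
    i = np.arange(half) + 0.5
    z = i / half  # upper hemisphere
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return np.concatenate([pts, -pts], axis=0)


def spoke_directions(n_spokes: int, dims: int) -> np.ndarray:
    """Spoke directions in antipodal pairs: (i, i + n/2) are opposite.

    2D: equal-angle spread of n/2 directions over [0, pi); 3D: deterministic
    spherical-spiral coverage of the half sphere.  Requires an even count.
    """
    if n_spokes < 1:
        raise ValueError("spoke count must be >= 1")
    if n_spokes % 2 != 0:
        raise ValueError("spoke count must be even (antipodal pairing)")
    if dims == 2:
        ang = np.arange(n_spokes // 2) * np.pi / (n_spokes // 2)
        d = np.stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)], axis=1)
        return np.concatenate([d, -d], axis=0)
    return _spherical_spiral(n_spokes)


def acquire_dataset(phantom: Phantom, protocol: Protocol) -> List[SpokeAcquisition]:
    """Simulate a radial CEA acquisition: one convolution signal per spoke.

    The k radius is sampled at the half-open convention t_m = (m + 0.5) dt,
    which fixes the sign of the later center-shift correction.
    """
    dirs = spoke_directions(protocol.n_spokes, protocol.dims)
    dt = protocol.pulse.dt
    t_k = (np.arange(protocol.n_samples) + 0.5) * dt
    spokes = []
    for i, d in enumerate(dirs):
        grad = GradientWaveform(
            d, protocol.grad_amplitude, protocol.ramp_time, protocol.max_gradient
        )
        s = cea_signal(phantom, protocol.pulse, grad, protocol.n_samples)
        spokes.append(
            SpokeAcquisition(
                direction=d,
                s_mr=s,
                k_traj=grad.k_radius(t_k),
                meta={"spoke": i, "tr": protocol.tr, "pulse": protocol.pulse.kind},
            )
        )
    return spokes


def full_chain(
    phantom: Phantom,
    protocol: Protocol,
    frontend: AnalogFrontend,
    channel: CouplingChannel,
    setting: CancellerSetting,
    noise_sigma: float = 0.0,
    tx_noise_factor: float = 0.0,
    seed: int = 0,
) -> List[SpokeAcquisition]:
    """Compose leakage, cancellation, MR signal and receiver noise per spoke.

    Per spoke: s = (leak + s_MR) - canceller reference + white complex
    receiver noise (sigma) + optional Tx-noise proportional to the pulse
    envelope.  The acquired leakage and the pick-up coil trace are stored in
    the spoke metadata for the digital cancellation stage.
    """
    from .analog_frontend import pickup

    rng = np.random.default_rng(seed)
    clean = acquire_dataset(phantom, protocol)
    u_tx = SignalTrace(
        np.pad(protocol.pulse.samples, (0, max(0, protocol.n_samples - protocol.pulse.n)))[
            : protocol.n_samples
        ],
        protocol.pulse.dt,
    )
    out_spokes = []
    for sp in clean:
        rx, lk = frontend.receive(u_tx, channel, setting, s_mr=sp.s_mr)
        samples = rx.samples.copy()
        if noise_sigma > 0:
            samples = samples + noise_sigma * (
                rng.standard_normal(len(samples)) + 1j * rng.standard_normal(len(samples))
            )
        if tx_noise_factor > 0:
            samples = samples + tx_noise_factor * np.abs(u_tx.samples) * (
                rng.standard_normal(len(samples)) + 1j * rng.standard_normal(len(samples))
            )
        puc_trace = pickup(u_tx, frontend.puc)
        meta = dict(sp.meta)
        meta.update({"leak_power": lk.power(), "has_leakage": True})
        out_spokes.append(
            SpokeAcquisition(
                direction=sp.direction,
                s_mr=SignalTrace(samples, sp.s_mr.dt),
                k_traj=sp.k_traj,
                meta={**meta, "puc": puc_trace.samples},
            )
        )
    return out_spokes
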