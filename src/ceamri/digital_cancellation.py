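"""Digital removal of the residual, frequency-dependent transmit leakage.

Analog cancellation is calibrated at one frequency; away from it the
residual leakage has a frequency-dependent amplitude and phase.  For chirp
excitations the sweep maps time to frequency monotonically, so the residual
amplitude is fit piecewise-linearly on each side of the sweep center and
the phase by a quadratic polynomial of the difference to the pick-up coil
(PUC) trace.  For HS8 excitations there is no such map and the leakage is
modeled as the theoretical pulse times a quadratic-plus-linear complex time
modulation with a phase constant, fitted by simulated annealing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .analog_frontend import SignalTrace
from .rf_pulses import RFPulse

__all__ = [
    "ChirpLeakFit",
    "HS8LeakFit",
    "SACoolingConfig",
    "fit_chirp_leakage",
    "fit_hs8_leakage",
    "refine_against_model",
]


@dataclass(frozen=True)
class ChirpLeakFit:
    """Piecewise-linear amplitude + quadratic phase model of chirp leakage.

    Amplitude: ``a0 + slope_left*(t-tc)`` left of the sweep-center time tc,
    ``a0 + slope_right*(t-tc)`` right of it (shared intercept keeps the
    model continuous at the center frequency).  Phase: quadratic polynomial
    (coefficients highest-first) of time, applied on top of the PUC phase.
    """

    slope_left: float
    slope_right: float
    intercept: float
    phase_poly: np.ndarray  # (3,) quadratic coefficients, np.polyval order
    center_time: float

    def amplitude(self, t: np.ndarray) -> np.ndarray:
        dt = t - self.center_time
        slope = np.where(dt < 0, self.slope_left, self.slope_right)
        return self.intercept + slope * dt


@dataclass(frozen=True)
class HS8LeakFit:
    """Time-modulation model of HS8 leakage: u(t)(a2 t^2 + a1 t + a0) e^{j theta0}."""

    a2: complex
    a1: complex
    a0: complex
    theta0: float
    residual_power: float
    converged: bool = True

    def evaluate(self, pulse: RFPulse) -> np.ndarray:
        t = pulse.t
        mod = self.a2 * t**2 + self.a1 * t + self.a0
        return pulse.samples * mod * np.exp(1j * self.theta0)


@dataclass(frozen=True)
class SACoolingConfig:
    """Simulated-annealing schedule: geometric cooling with Gaussian proposals."""

    n_iter: int = 2000
    cooling: float = 0.95
    steps_per_temp: int = 20
    initial_scale: float = 0.5


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="same")


def _moving_average_complex(x: np.ndarray, window: int) -> np.ndarray:
    return _moving_average(x.real, window) + 1j * _moving_average(x.imag, window)


def fit_chirp_leakage(
    s: SignalTrace,
    puc: SignalTrace,
    pulse: RFPulse,
    smooth_window: int = 32,
    mr_reference: Optional[SignalTrace] = None,
) -> Tuple[ChirpLeakFit, SignalTrace]:
    """Fit and subtract residual chirp leakage using the PUC reference.

    Steps: map sample time to instantaneous frequency through the pulse's
    analytic sweep rate; fit the received amplitude profile with one linear
    segment on each side of the sweep center (shared intercept, signed);
    fit the phase difference between the received signal and the PUC trace
    with a quadratic polynomial; rebuild the leakage estimate as amplitude
    model x phase-corrected unit PUC trace and subtract it.

    The blind fit cannot tell residual leakage from the part of the MR
    signal whose modulation is as smooth as the leak model, and it absorbs
    that part.  ``mr_reference`` (a calculated MR signal, e.g. from the
    Bloch oracle or the convolution model of an assumed object) removes the
    ambiguity: the model is then fitted to ``s - mr_reference``, which is
    the automated counterpart of refining the fit against a computed spin
    response, and only the fitted leakage is subtracted from ``s``.
    """
    if mr_reference is not None:
        if mr_reference.n != s.n:
            raise ValueError("MR reference must match the trace length")
        delta = SignalTrace(s.samples - mr_reference.samples, s.dt)
        fit, leak_est = _fit_chirp_core(delta, puc, pulse, smooth_window)
        return fit, SignalTrace(s.samples - leak_est, s.dt)
    fit, leak_est = _fit_chirp_core(s, puc, pulse, smooth_window)
    return fit, SignalTrace(s.samples - leak_est, s.dt)


def _fit_chirp_core(
    s: SignalTrace,
    puc: SignalTrace,
    pulse: RFPulse,
    smooth_window: int,
) -> Tuple[ChirpLeakFit, np.ndarray]:
    if pulse.kind not in ("chirp",):
        raise ValueError(
            "chirp leakage fit requires a swept chirp pulse; use the HS8 path "
            "or direct PUC-scale subtraction for other pulses"
        )
    if s.n != puc.n:
        raise ValueError("signal and PUC traces must be aligned and equal length")
    n = s.n
    t = np.arange(n) * s.dt
    tc = pulse.duration / 2.0  # sweep center time (linear sweep)

    # the PUC trace, normalized to unit peak, carries the transmit envelope
    # (including the smoothed chirp edges) and the transmit phase; the
    # piecewise-linear model describes the frequency-dependent modulation of
    # the residual leakage on top of it
    puc_mag = np.abs(puc.samples)
    peak = float(puc_mag.max())
    if peak == 0:
        raise ValueError("PUC trace is identically zero")
    env = puc_mag / peak
    # the model is evaluated wherever the envelope is nonzero — leaving the
    # tapered pulse edges uncorrected would park raw leakage exactly in the
    # ill-conditioned directions of the later deconvolution — but only
    # samples with appreciable envelope inform the fits
    nonzero = puc_mag > 1e-12 * peak
    valid = env > 0.05
    phase_unit = np.zeros(n, dtype=complex)
    np.divide(puc.samples, puc_mag, out=phase_unit, where=nonzero)

    # fit only on the flat part of the envelope (the moving average distorts
    # the profile wherever the envelope ramps) and away from the center kink
    margin = max(smooth_window, 1)
    keep = env > 0.95
    idx_keep = np.flatnonzero(keep)
    if len(idx_keep) > 2 * margin:
        keep[idx_keep[:margin]] = False
        keep[idx_keep[-margin:]] = False
    ic = int(round(tc / s.dt))
    keep[max(0, ic - margin): min(n, ic + margin)] = False

    dtc = t - tc
    design = env[:, None] * np.stack(
        [np.ones(n), np.where(dtc < 0, dtc, 0.0), np.where(dtc >= 0, dtc, 0.0)], axis=1
    )

    # The phase of the smoothed product s * conj(PUC) seeds the quadratic
    # phase correction.  The product is squared before taking the angle so
    # that a residual whose amplitude crosses zero at the calibrated
    # frequency (the usual V-shaped off-resonance profile) does not inject a
    # pi step into the unwrap: the signed amplitude model carries the flip
    # instead.  Smoothing the complex product averages fast MR beats out of
    # the mean, which keeps the unwrap from being hijacked where the leakage
    # dips below the MR signal.
    prod = _moving_average_complex((s.samples * np.conj(phase_unit)) ** 2, smooth_window)
    dphi = 0.5 * np.unwrap(np.angle(prod[valid]))
    w_phase = env[valid].copy()
    poly = np.polyfit(t[valid], dphi, 2, w=w_phase)

    # Robust alternating refit (IRLS, Tukey bisquare).  The MR signal enters
    # the trace as bursts localized around each spin packet's sweep crossing,
    # while the leakage spans the whole window; downweighting large-residual
    # samples therefore rejects the MR instead of absorbing a fixed fraction
    # of it into the model, at any MR-to-leakage ratio.
    w = np.ones(n)
    intercept = sl = sr = 0.0
    for _ in range(4):
        phase_ref = phase_unit * np.exp(1j * np.polyval(poly, t))
        coh = _moving_average((s.samples * np.conj(phase_ref)).real, smooth_window)
        wk = (w * keep)[:, None]
        coef, *_ = np.linalg.lstsq(design * wk, coh * wk[:, 0], rcond=None)
        intercept, sl, sr = (float(c) for c in coef)
        amp = intercept + np.where(dtc < 0, sl, sr) * dtc
        leak_est = amp * env * phase_ref
        e = np.abs(s.samples - leak_est)
        sigma = 1.4826 * float(np.median(e[keep])) + 1e-30
        u = e / (4.685 * sigma)
        w = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
        # refit the phase with the same robust weights
        poly = np.polyfit(t[valid], dphi, 2, w=w_phase * w[valid])

    fit = ChirpLeakFit(sl, sr, intercept, np.asarray(poly), tc)
    phase_ref = phase_unit * np.exp(1j * np.polyval(poly, t))
    leak_est = fit.amplitude(t) * env * phase_ref
    return fit, leak_est


def _hs8_model(pulse: RFPulse, x: np.ndarray) -> np.ndarray:
    """Leak model from the 7-vector (Re/Im a2, a1, a0, theta0)."""
    a2 = x[0] + 1j * x[1]
    a1 = x[2] + 1j * x[3]
    a0 = x[4] + 1j * x[5]
    t = pulse.t
    return pulse.samples * (a2 * t**2 + a1 * t + a0) * np.exp(1j * x[6])


def _polish_linear(pulse: RFPulse, s: np.ndarray, theta0: float) -> np.ndarray:
    """Exact least-squares for the modulation coefficients at fixed theta0.

    The complex parametrization makes the model linear in (a2, a1, a0), so
    the annealer's best point can always be finished with one exact solve.
    """
    t = pulse.t
    basis = pulse.samples[:, None] * np.stack([t**2, t, np.ones_like(t)], axis=1)
    basis = basis * np.exp(1j * theta0)
    coef, *_ = np.linalg.lstsq(basis, s, rcond=None)
    x = np.empty(7)
    x[0], x[1] = coef[0].real, coef[0].imag
    x[2], x[3] = coef[1].real, coef[1].imag
    x[4], x[5] = coef[2].real, coef[2].imag
    x[6] = theta0
    return x


def fit_hs8_leakage(
    s: SignalTrace,
    pulse: RFPulse,
    sa_cfg: Optional[SACoolingConfig] = None,
    seed: int = 0,
    mr_reference: Optional[SignalTrace] = None,
) -> Tuple[HS8LeakFit, SignalTrace]:
    """Fit and subtract residual HS8 leakage by simulated annealing.

    Minimizes the total power of ``s - u(t)(a2 t^2 + a1 t + a0) e^{j theta0}``
    over complex modulation coefficients and the phase constant with a
    geometric-cooling annealer (seeded, reproducible), finishing the best
    iterate with an exact least-squares solve of the coefficients (the model
    is linear in them at fixed theta0).
    """
    if pulse.kind != "hs8":
        raise ValueError("HS8 leakage fit requires an hs8 pulse")
    if mr_reference is not None:
        if mr_reference.n != s.n:
            raise ValueError("MR reference must match the trace length")
        delta = SignalTrace(s.samples - mr_reference.samples, s.dt)
        fit, _ = fit_hs8_leakage(delta, pulse, sa_cfg, seed)
        return fit, SignalTrace(s.samples - fit.evaluate(pulse)[: s.n], s.dt)
    cfg = sa_cfg or SACoolingConfig()
    rng = np.random.default_rng(seed)
    y = s.samples

    def cost(x: np.ndarray) -> float:
        return float(np.sum(np.abs(y - _hs8_model(pulse, x)) ** 2))

    # parameter scales for the Gaussian proposals: modulation amplitudes
    # referred to the pulse scale, times in units of the duration
    u_rms = max(float(np.sqrt(np.mean(np.abs(pulse.samples) ** 2))), 1e-30)
    amp0 = float(np.sqrt(np.mean(np.abs(y) ** 2))) / u_rms
    T = pulse.duration
    scales = np.array(
        [amp0 / T**2, amp0 / T**2, amp0 / T, amp0 / T, amp0, amp0, np.pi]
    )

    x = np.zeros(7)
    f = cost(x)
    best_x, best_f = x.copy(), f
    f0 = f
    temp = max(f, 1e-30)
    evals = 0
    while evals < cfg.n_iter:
        for _ in range(cfg.steps_per_temp):
            if evals >= cfg.n_iter:
                break
            prop = x + rng.standard_normal(7) * scales * cfg.initial_scale
            prop[6] = (prop[6] + np.pi) % (2.0 * np.pi) - np.pi
            fp = cost(prop)
            evals += 1
            if fp < f or rng.random() < np.exp(-(fp - f) / max(temp, 1e-300)):
                x, f = prop, fp
                if f < best_f:
                    best_x, best_f = x.copy(), f
        temp *= cfg.cooling
    converged = best_f < f0 or f0 == 0.0

    x = _polish_linear(pulse, y, float(best_x[6]))
    f = cost(x)
    if f < best_f:
        best_x, best_f = x, f

    fit = HS8LeakFit(
        a2=best_x[0] + 1j * best_x[1],
        a1=best_x[2] + 1j * best_x[3],
        a0=best_x[4] + 1j * best_x[5],
        theta0=float(best_x[6]),
        residual_power=best_f,
        converged=converged,
    )
    s_mr_est = SignalTrace(y - fit.evaluate(pulse)[: s.n], s.dt)
    return fit, s_mr_est


def refine_against_model(s_mr_est: SignalTrace, reference: SignalTrace) -> float:
    """Relative RMS deviation of the corrected signal from a Bloch reference.

    ``||est - ref|| / ||ref||`` — the norm in the denominator is that of the
    reference.  Used as an agreement diagnostic in tests, never inside the
    correction itself.
    """
    if s_mr_est.n != reference.n:
        raise ValueError("traces must have equal length")
    p_ref = np.linalg.norm(reference.samples)
    if p_ref == 0:
        raise ValueError("reference trace has zero power")
    return float(np.linalg.norm(s_mr_est.samples - reference.samples) / p_ref)
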