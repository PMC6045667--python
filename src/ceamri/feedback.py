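"""Automated real-time calibration of the analog cancellation circuit.

The controller minimizes the mean magnitude of the received calibration
signal (a 4 ms rectangular transmit pulse acquired concurrently) over the
two control voltages of the canceller: the phase-shifter voltage V1 and the
attenuator voltage V_att.  True gradients are unavailable from a scalar
objective, so "gradient descent" is realized as coordinate descent with
sign probing: evaluate the objective one step up and one step down, move in
the decreasing direction until the objective rises, then shrink the step.

Schedule (matching the hardware loop): phase passes at 0.3 V then 0.1 V,
attenuation passes at 0.05 V then 5 mV, then optional alternating
refinement passes with step sizes halved down to a floor.  During
refinement the voltage steps are scaled inversely with the local slope of
the actuator transfer curve (variable voltage step sizes), so a nominal
step produces the same phase/attenuation increment everywhere on the
nonlinear curve as it does on the shallow, characterized end.  One
"iteration" is one objective evaluation, i.e. one simulated calibration
acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence

import numpy as np

from .analog_frontend import (
    AnalogFrontend,
    CancellerSetting,
    CouplingChannel,
    SignalTrace,
    isolation_db,
)
from .rf_pulses import RFPulse

__all__ = [
    "ControllerConfig",
    "CalibrationResult",
    "objective",
    "calibrate",
    "monitor_and_retrigger",
    "perturb_load",
]


@dataclass(frozen=True)
class ControllerConfig:
    """Tuning of the feedback loop.

    ``phase_steps`` / ``att_steps`` are the coarse-to-fine voltage step
    schedules; ``refine_floor`` is the smallest nominal step used by the
    optional alternating refinement passes (applied to both actuators).
    ``threshold_isolation_db`` is the stopping criterion expressed as total
    Tx-Rx isolation (geometric baseline plus analog cancellation) and is
    converted internally to an objective amplitude.
    """

    phase_steps: Sequence[float] = (0.3, 0.1)
    att_steps: Sequence[float] = (0.05, 0.005)
    refine_floor: float = 0.005
    threshold_isolation_db: float = 85.0
    max_iter: int = 400
    n_samples: int = 400
    enable_refinement: bool = True
    adaptive_refinement_steps: bool = True

    def __post_init__(self) -> None:
        for steps in (self.phase_steps, self.att_steps):
            if any(b >= a for a, b in zip(steps, steps[1:])):
                raise ValueError("step schedules must be strictly decreasing")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class CalibrationResult:
    setting: CancellerSetting
    iterations: int
    achieved_isolation_db: float
    converged: bool
    trace: List[dict] = field(default_factory=list)

    @property
    def analog_suppression_db(self) -> float:
        """Suppression from the cancellation stage alone (total minus baseline)."""
        return self.achieved_isolation_db - self.geometric_isolation_db

    geometric_isolation_db: float = 0.0


def objective(s_rx: SignalTrace, n: int) -> float:
    """Mean magnitude of the first ``n`` received samples (the loop's cost)."""
    if n <= 0:
        raise ValueError("N must be positive")
    if s_rx.n < n:
        raise ValueError(f"trace has {s_rx.n} samples, need {n}")
    return float(np.mean(np.abs(s_rx.samples[:n])))


class _Evaluator:
    """Counts objective evaluations and logs the calibration trace."""

    def __init__(
        self,
        frontend: AnalogFrontend,
        channel: CouplingChannel,
        u_tx: SignalTrace,
        n: int,
        max_iter: int,
    ) -> None:
        self.frontend = frontend
        self.channel = channel
        self.u_tx = u_tx
        self.n = n
        self.max_iter = max_iter
        self.count = 0
        self.trace: List[dict] = []
        self.leak_obj: Optional[float] = None
        self.best: Optional[tuple] = None  # (objective, setting)

    def __call__(self, setting: CancellerSetting) -> float:
        out, lk = self.frontend.receive(self.u_tx, self.channel, setting)
        if self.leak_obj is None:
            self.leak_obj = objective(lk, self.n)
        f = objective(out, self.n)
        self.count += 1
        iso = (
            20.0 * np.log10(self.leak_obj / f) if f > 0 else np.inf
        ) + self.channel.geometric_isolation_db
        self.trace.append(
            {
                "iteration": self.count,
                "V1": setting.V1,
                "V_att": setting.V_att,
                "objective": f,
                "isolation_db": min(iso, 200.0),
            }
        )
        if self.best is None or f < self.best[0]:
            self.best = (f, setting)
        return f

    @property
    def exhausted(self) -> bool:
        return self.count >= self.max_iter


def _descend_axis(
    ev: _Evaluator,
    setting: CancellerSetting,
    f0: float,
    axis: str,
    step: float,
    bounds: tuple,
    threshold: float,
    step_scale: Optional[Callable[[float], float]] = None,
) -> tuple:
    """One coordinate-descent pass along ``axis`` ('V1' or 'V_att').

    Probes +-step, walks in the decreasing direction until the objective
    rises, the threshold is met, bounds clamp the move, or the iteration
    budget runs out.  Returns the updated (setting, objective).
    """

    def shifted(s: CancellerSetting, delta: float) -> CancellerSetting:
        v = getattr(s, axis) + delta
        v = min(max(v, bounds[0]), bounds[1])
        return replace(s, **{axis: v})

    def eff(s: CancellerSetting) -> float:
        if step_scale is None:
            return step
        return step * step_scale(getattr(s, axis))

    if f0 <= threshold or ev.exhausted:
        return setting, f0

    # probe the two directions
    direction = 0
    for sign in (+1, -1):
        cand = shifted(setting, sign * eff(setting))
        if getattr(cand, axis) == getattr(setting, axis):
            continue  # clamped against a bound
        f = ev(cand)
        if f < f0:
            setting, f0, direction = cand, f, sign
            break
        if ev.exhausted:
            return setting, f0
    if direction == 0:
        return setting, f0

    while not ev.exhausted and f0 > threshold:
        cand = shifted(setting, direction * eff(setting))
        if getattr(cand, axis) == getattr(setting, axis):
            break
        f = ev(cand)
        if f >= f0:
            break
        setting, f0 = cand, f
    return setting, f0


def _threshold_objective(ev: _Evaluator, channel: CouplingChannel, cfg: ControllerConfig) -> float:
    """Objective amplitude equivalent to the configured isolation threshold."""
    analog_db = cfg.threshold_isolation_db - channel.geometric_isolation_db
    assert ev.leak_obj is not None
    return ev.leak_obj * 10.0 ** (-analog_db / 20.0)


def calibrate(
    frontend: AnalogFrontend,
    channel: CouplingChannel,
    pulse: RFPulse,
    cfg: ControllerConfig,
    initial: CancellerSetting,
) -> CalibrationResult:
    """Run the automated feedback loop on a simulated calibration acquisition.

    Returns the best setting found, the number of objective evaluations, and
    the achieved total isolation (geometric baseline plus analog stage).
    ``converged`` is False when the budget is exhausted above threshold.
    """
    u_tx = SignalTrace(pulse.samples, pulse.dt)
    n = min(cfg.n_samples, u_tx.n)
    ev = _Evaluator(frontend, channel, u_tx, n, cfg.max_iter)

    sh, at = frontend.shifter, frontend.attenuator
    phase_bounds = (sh.v_min, sh.v_max)
    att_bounds = (at.v_min, at.v_max)

    setting = initial
    f0 = ev(setting)
    thr = _threshold_objective(ev, channel, cfg)

    # slope-adaptive step scaling for the refinement passes: hold the
    # phase/attenuation increment per nominal step at the value it has on
    # the shallow end of each transfer curve
    dv = 1e-4

    def phase_scale(v: float) -> float:
        ref = (sh.phase_deg(sh.v_anchor) - sh.phase_deg(sh.v_anchor - dv)) / dv
        loc = (sh.phase_deg(min(v + dv, sh.v_max)) - sh.phase_deg(max(v - dv, sh.v_min))) / (
            min(v + dv, sh.v_max) - max(v - dv, sh.v_min)
        )
        return abs(ref) / max(abs(loc), 1e-9)

    def att_scale(v: float) -> float:
        ref = at.slope_db_per_v
        loc = (
            at.attenuation_db(max(v - dv, at.v_min)) - at.attenuation_db(min(v + dv, at.v_max))
        ) / (min(v + dv, at.v_max) - max(v - dv, at.v_min))
        return abs(ref) / max(abs(loc), 1e-9)

    # stage 1: phase passes, coarse then fine (raw voltage steps)
    for step in cfg.phase_steps:
        setting, f0 = _descend_axis(ev, setting, f0, "V1", step, phase_bounds, thr)
    # stage 2: attenuation passes
    for step in cfg.att_steps:
        setting, f0 = _descend_axis(ev, setting, f0, "V_att", step, att_bounds, thr)

    # stage 3: alternating refinement with halved, slope-adaptive steps
    if cfg.enable_refinement:
        p_step = cfg.phase_steps[-1] / 2.0
        a_step = cfg.att_steps[-1]
        p_scale = phase_scale if cfg.adaptive_refinement_steps else None
        a_scale = att_scale if cfg.adaptive_refinement_steps else None
        while f0 > thr and not ev.exhausted:
            p_step = max(p_step, cfg.refine_floor)
            a_step = max(a_step, cfg.refine_floor)
            f_before = f0
            setting, f0 = _descend_axis(
                ev, setting, f0, "V1", p_step, phase_bounds, thr, p_scale
            )
            setting, f0 = _descend_axis(
                ev, setting, f0, "V_att", a_step, att_bounds, thr, a_scale
            )
            at_floor = p_step <= cfg.refine_floor and a_step <= cfg.refine_floor
            if f0 >= f_before and at_floor:
                break  # stalled at the finest resolution
            p_step /= 2.0
            a_step /= 2.0

    assert ev.best is not None and ev.leak_obj is not None
    f_best, best_setting = ev.best
    analog_db = 200.0 if f_best == 0 else min(20.0 * np.log10(ev.leak_obj / f_best), 200.0)
    achieved = analog_db + channel.geometric_isolation_db
    return CalibrationResult(
        setting=best_setting,
        iterations=ev.count,
        achieved_isolation_db=achieved,
        converged=achieved >= cfg.threshold_isolation_db,
        trace=ev.trace,
        geometric_isolation_db=channel.geometric_isolation_db,
    )


def monitor_and_retrigger(
    frontend: AnalogFrontend,
    channel_timeline: Sequence[CouplingChannel],
    cfg: ControllerConfig,
    pulse: RFPulse,
    initial: CancellerSetting,
) -> List[CalibrationResult]:
    """Calibrate, then watch a sequence of coupling states and re-calibrate.

    Emulates the load-change experiment: after each change of the coupling
    channel (e.g. a hand moving over the coils), the loop re-runs from the
    current setting whenever the residual exceeds the threshold.
    """
    if len(channel_timeline) == 0:
        raise ValueError("channel timeline must be nonempty")
    results = [calibrate(frontend, channel_timeline[0], pulse, cfg, initial)]
    for channel in channel_timeline[1:]:
        setting = results[-1].setting
        u_tx = SignalTrace(pulse.samples, pulse.dt)
        n = min(cfg.n_samples, u_tx.n)
        out, lk = frontend.receive(u_tx, channel, setting)
        f = objective(out, n)
        leak_obj = objective(lk, n)
        thr = leak_obj * 10.0 ** (
            -(cfg.threshold_isolation_db - channel.geometric_isolation_db) / 20.0
        )
        if f > thr:
            results.append(calibrate(frontend, channel, pulse, cfg, setting))
    return results


def _leak_gain(frontend: AnalogFrontend, channel: CouplingChannel) -> complex:
    """Complex gain from u_Tx to the leakage at the combiner input."""
    c = frontend.coupler.coupling_factor
    return (
        np.sqrt(1.0 - c**2)
        * channel.leak_amplitude
        * np.exp(1j * np.deg2rad(channel.phi_cpl_deg))
    )


def _canceller_gain(frontend: AnalogFrontend, setting: CancellerSetting) -> complex:
    from .analog_frontend import attenuation_response, phase_response

    c = frontend.coupler.coupling_factor
    loss_db = (
        attenuation_response(frontend.attenuator, setting.V_att)
        + frontend.shifter.insertion_loss_db
    )
    return c * 10.0 ** (-loss_db / 20.0) * np.exp(
        1j * np.deg2rad(phase_response(frontend.shifter, setting.V1))
    )


def perturb_load(
    channel: CouplingChannel,
    target_leak_increase: float,
    frontend: AnalogFrontend,
    setting: CancellerSetting,
    pulse: RFPulse,
    rng_seed: int,
    n_samples: int = 400,
    max_tries: int = 64,
) -> CouplingChannel:
    """Random coupling jump raising the residual objective by a set amount.

    Models a load change (hand motion): (A_cpl, phi_cpl) jump in a random
    direction whose magnitude is solved so that, at the *current* canceller
    setting, the mean-magnitude objective increases by
    ``target_leak_increase`` (in the fixture's voltage units).  Directions
    that would push the coupling phase outside the shifter's coverage or
    the required attenuation out of range are rejected and redrawn, so the
    perturbed channel stays recoverable by re-calibration.
    """
    if target_leak_increase < 0:
        raise ValueError("target increase must be non-negative")
    if target_leak_increase == 0.0:
        return channel
    rng = np.random.default_rng(rng_seed)
    u = np.abs(pulse.samples[: min(n_samples, len(pulse.samples))])
    m = float(np.mean(u))
    if m <= 0:
        raise ValueError("calibration pulse has zero amplitude")

    g_leak = _leak_gain(frontend, channel)
    g_canc = _canceller_gain(frontend, setting)
    r0 = abs(g_leak - g_canc)
    r_new = r0 + target_leak_increase / m

    c = frontend.coupler.coupling_factor
    base = np.sqrt(1.0 - c**2) * 10.0 ** (-channel.geometric_isolation_db / 20.0)
    for _ in range(max_tries):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        g_new = g_canc + r_new * np.exp(1j * theta)
        a_new = abs(g_new) / base
        phi_new = float(np.rad2deg(np.angle(g_new))) % 360.0
        cand = CouplingChannel(
            A_cpl=float(a_new),
            phi_cpl_deg=phi_new,
            geometric_isolation_db=channel.geometric_isolation_db,
            freq_slope=channel.freq_slope,
        )
        try:
            frontend.optimal_setting(cand)
        except ValueError:
            continue
        return cand
    raise ValueError(
        "could not find a feasible coupling perturbation for the requested increase"
    )
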