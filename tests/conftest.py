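import numpy as np
import pytest

from ceamri import rf_pulses
from ceamri.analog_frontend import AnalogFrontend, PickupCoil, SignalTrace, pickup
from ceamri.spin_sim import GradientWaveform, Phantom


@pytest.fixture(scope="session")
def frontend() -> AnalogFrontend:
    return AnalogFrontend()


@pytest.fixture(scope="session")
def chirp_pulse() -> rf_pulses.RFPulse:
    """The imaging chirp: 4.1 ms, 16 kHz sweep, 10% smoothed edges."""
    return rf_pulses.make_chirp(4.1e-3, 16e3, 1.0, 8e-6, 0.1)


@pytest.fixture(scope="session")
def hs8_pulse() -> rf_pulses.RFPulse:
    """The head-protocol HS8 pulse: 2 ms, 64 kHz sweep."""
    return rf_pulses.make_hs8(2e-3, 64e3, 1.0, 2e-6)


@pytest.fixture()
def point_phantom() -> Phantom:
    return Phantom(
        positions=np.array([[0.02, 0.0, 0.0]]),
        m0=np.array([1.0]),
        t2star=np.array([200e-6]),
        chem_shift=np.array([0.0]),
    )


@pytest.fixture()
def x_gradient() -> GradientWaveform:
    return GradientWaveform(np.array([1.0, 0.0, 0.0]), 4.0, ramp_time=0.0)


def padded_trace(pulse: rf_pulses.RFPulse, n: int) -> SignalTrace:
    u = np.zeros(n, dtype=complex)
    m = min(n, pulse.n)
    u[:m] = pulse.samples[:m]
    return SignalTrace(u, pulse.dt)


@pytest.fixture()
def puc_of(chirp_pulse):
    def _make(n: int, coil: PickupCoil = PickupCoil(0.05, 23.0)) -> SignalTrace:
        return pickup(padded_trace(chirp_pulse, n), coil)

    return _make
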