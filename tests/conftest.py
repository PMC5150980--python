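import dataclasses

import pytest

from oxylume import simulate as sim


@pytest.fixture
def base_config() -> sim.SimulationConfig:
    """Noiseless, zero-delay default acquisition at 0.5 Hz."""
    return sim.SimulationConfig(
        decay_constant_k=0.05,
        sensitivity=0.3,
        baseline_counts=100.0,
        noise_sd=0.0,
        transit_delay_tau=0.0,
        sampling_rate=0.5,
        duration=300.0,
        seed=0,
    )


@pytest.fixture
def make_config(base_config):
    """Factory returning the base config with overridden fields."""

    def _make(**overrides) -> sim.SimulationConfig:
        return dataclasses.replace(base_config, **overrides)

    return _make


def rk4_concentration(schedule, k, c0, t_end, dt=1e-3):
    """Independent fourth-order Runge-Kutta oracle for dC/dt = P(t) - k*C.

    Integrates each constant-production segment separately so no step
    straddles a discontinuity in P(t).
    """
    boundaries = sorted(
        {0.0, t_end}
        | {b for start, end, _ in schedule for b in (start, end) if 0.0 < b < t_end}
    )
    c = c0
    for seg_start, seg_end in zip(boundaries, boundaries[1:]):

        def production(t):
            for start, end, rate in schedule:
                if start <= t < end:
                    return rate
            return 0.0

        p = production((seg_start + seg_end) / 2.0)

        def f(c_val):
            return p - k * c_val

        n = max(1, int(round((seg_end - seg_start) / dt)))
        h = (seg_end - seg_start) / n
        for _ in range(n):
            k1 = f(c)
            k2 = f(c + h * k1 / 2)
            k3 = f(c + h * k2 / 2)
            k4 = f(c + h * k3)
            c += h * (k1 + 2 * k2 + 2 * k3 + k4) / 6
    return c
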