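import numpy as np
import pytest

from vsplink import (
    AtomSelection,
    ContactScheduleSpec,
    SweepSpec,
    synth_contact_trajectory,
    synth_sensing_sweep,
)


@pytest.fixture(scope="session")
def schedule_spec():
    """A 50 ns two-group schedule with two bound windows and mild noise."""
    return ContactScheduleSpec(
        duration_ns=50.0,
        frame_interval_ns=0.1,
        bound_intervals=((10.0, 20.0), (30.0, 34.2)),
        noise_sd_A=0.05,
        seed=42,
    )


@pytest.fixture(scope="session")
def schedule_trajectory(schedule_spec):
    return synth_contact_trajectory(schedule_spec)


@pytest.fixture(scope="session")
def linker_selection():
    return AtomSelection.residue_range(252, 255, label="linker motif")


@pytest.fixture(scope="session")
def ti_loop_selection():
    return AtomSelection.residue_range(400, 402, label="TI-loop motif")


@pytest.fixture()
def mono_sweep():
    """Noiseless single-exponential off-sweep: 2 µA, τ = 20 ms."""
    return synth_sensing_sweep(
        SweepSpec(components=((2.0, 20.0),), duration_ms=500.0, sample_interval_ms=0.5)
    )


@pytest.fixture()
def bi_sweep():
    """Noiseless biexponential off-sweep: (1 µA, 5 ms) + (0.5 µA, 80 ms)."""
    return synth_sensing_sweep(
        SweepSpec(
            components=((1.0, 5.0), (0.5, 80.0)),
            duration_ms=500.0,
            sample_interval_ms=0.5,
        )
    )
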