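"""Shared fixtures: small simulation setups and trees."""

import numpy as np
import pytest

from dartpulse.scoring import DisplacementTrace
from dartpulse.simulate import SimulationParams, TrialSpec


@pytest.fixture
def params():
    """Default study conditions with a fixed seed."""
    return SimulationParams(seed=123)


@pytest.fixture
def quiet_params():
    """Noise-free, drift-free conditions for exact-recovery checks."""
    return SimulationParams(seed=123, noise_sd=0.0, drift_slope=0.0, drift_wobble=0.0)


@pytest.fixture
def control_spec():
    return TrialSpec("d01_t0", day=1, order_index=0, species="C_aspersum", is_control=True)


@pytest.fixture
def ten_tip_newick():
    return (
        "(((t1:0.3,t2:0.3):0.7,((t3:0.4,t4:0.4):0.3,t5:0.7):0.3):0.5,"
        "((t6:0.5,t7:0.5):0.5,(t8:0.2,(t9:0.1,t10:0.1):0.1):0.8):0.5);"
    )


def make_trace(d_control, d_response, dt=5.0, trial_id="t", organ="diverticulum"):
    """Build a DisplacementTrace directly from per-segment displacement values."""
    d_control = np.asarray(d_control, dtype=float)
    d_response = np.asarray(d_response, dtype=float)
    t_c = dt * np.arange(d_control.size)
    t_r = dt * np.arange(d_response.size) + (t_c[-1] + dt if d_control.size else 0) + 300.0
    return DisplacementTrace(
        trial_id=trial_id,
        organ=organ,
        t=np.concatenate([t_c, t_r]),
        d=np.concatenate([d_control, d_response]),
        segment=np.array(["control"] * d_control.size + ["response"] * d_response.size),
        dt=dt,
    )
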