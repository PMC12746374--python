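import numpy as np
import pytest

from hpurea import (
    AcquisitionParams,
    PhysioParams,
    VIFParams,
    run_noise_study,
    simulate_dynamic_signal,
)
from hpurea.kinetics import vif_concentration


@pytest.fixture(scope="session")
def defaults():
    return PhysioParams(), VIFParams(), AcquisitionParams()


@pytest.fixture(scope="session")
def default_curve(defaults):
    physio, vif, acq = defaults
    return simulate_dynamic_signal(physio, acq, vif, "I")


@pytest.fixture(scope="session")
def noise_study_snr25():
    """The Monte-Carlo noise study at reference SNR 25 (100 repetitions).

    Session-scoped: this is the expensive study shared by several
    accuracy/reproducibility tests.
    """
    return run_noise_study([25.0], n_reps=100, seed=20251)


def fine_step_signal(p, acq, vif, model="I", dt=1e-3):
    """Independent fine-step simulator of snapshot spoiled-GRE sampling.

    Propagates the extravascular concentration with explicit per-step
    decay and transfer operators (exact exponential decay over each 1-ms
    step, midpoint-evaluated vascular inflow) and applies the pulse
    operator (record sin(flip) * signal, scale the extravascular pool by
    cos(flip)) at every TR.  Shares no code with the package's
    piecewise-analytic forward operator.
    """
    if model == "I":
        v_vasc, v_ev = p.vb, p.vee
    elif model == "II":
        v_vasc, v_ev = 0.0, p.vee
    elif model == "III":
        v_vasc, v_ev = p.vb, 1.0 - p.vb
    else:
        raise ValueError(model)
    rate = p.kve / v_ev
    alpha = rate + 1.0 / p.t1
    sinf, cosf = np.sin(np.deg2rad(acq.flip_deg)), np.cos(np.deg2rad(acq.flip_deg))
    n = int(np.floor(acq.duration / acq.tr + 1e-9))
    steps_per_tr = int(round(acq.tr / dt))
    dt = acq.tr / steps_per_tr
    decay = np.exp(-alpha * dt)
    gain = (1.0 - decay) / alpha
    out = np.empty(n)
    ce = 0.0
    t = vif.onset
    for k in range(n):
        out[k] = sinf * (v_vasc * vif_concentration(t, vif) + v_ev * ce)
        ce *= cosf
        for _ in range(steps_per_tr):
            cb_mid = vif_concentration(t + 0.5 * dt, vif)
            ce = ce * decay + rate * cb_mid * gain
            t += dt
    return out
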