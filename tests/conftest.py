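import numpy as np
import pandas as pd
import pytest

from rkt.config import GeneratorConfig
from rkt.io import CHANNELS, TrialRecord
from rkt.simulate import simulate_cohort


def make_trial_from_curve(inverse_fn, torque_limit=6.0, m=100,
                          subject="S1", knee="L", day=1, cycles=(1, 2, 3)):
    """Build a noiseless TrialRecord by sampling torque uniformly per sweep
    and mapping it through ``inverse_fn(torque) -> rotation``."""
    frames = []
    plan = [(1, "ER"), (1, "IR"), (1, "ER"), (2, "IR"), (2, "ER"),
            (3, "IR"), (3, "ER")]
    plan = [(c, s) for c, s in plan if c in cycles]
    for cycle, sweep in plan:
        tau = np.linspace(-torque_limit, torque_limit, m)
        if sweep == "ER":
            tau = tau[::-1]
        theta = inverse_fn(tau)
        frame = pd.DataFrame({
            "cycle": cycle, "sweep": sweep, "sample_idx": np.arange(m),
            "torque_nm": tau, "rot_z_deg": theta,
        })
        for ch in CHANNELS[1:]:
            frame[ch] = 0.1 * theta
        frames.append(frame)
    samples = pd.concat(frames, ignore_index=True)
    return TrialRecord(subject_id=subject, knee=knee, day=day, samples=samples)


def cubic_inverse(tau):
    """Inverse of the symmetric curve tau = 0.01 * theta**3."""
    return np.sign(tau) * np.abs(100.0 * np.asarray(tau, float)) ** (1.0 / 3.0)


@pytest.fixture(scope="session")
def cubic_trial():
    return make_trial_from_curve(cubic_inverse)


@pytest.fixture(scope="session")
def small_cohort():
    """Small noisy curve-level cohort at the default study conditions."""
    cfg = GeneratorConfig(n_subjects=6, n_days=3, samples_per_sweep=60)
    return simulate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def quiet_cohort():
    """Curve-level cohort with modest feature scatter and no extraction
    failures, for plumbing tests that need every trial to extract."""
    vcs = {
        "slack":       {"subject": 2.0, "knee": 0.2, "day": 0.2, "residual": 0.05},
        "er_laxity":   {"subject": 0.15, "knee": 0.02, "day": 0.02, "residual": 0.01},
        "ir_laxity":   {"subject": 0.15, "knee": 0.02, "day": 0.02, "residual": 0.01},
        "rot_at_zero": {"subject": 1.0, "knee": 0.2, "day": 0.2, "residual": 0.05},
    }
    cfg = GeneratorConfig(n_subjects=5, n_days=2, samples_per_sweep=60,
                          variance_components=vcs, noise_rotation_sd=0.1,
                          noise_translation_sd=0.3)
    return simulate_cohort(cfg, seed=4)
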