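"""Shared fixtures: seeded subjects, records and a small cohort.

Everything is generated at test time from fixed seeds; the session scope
keeps the expensive waveform synthesis to one pass.
"""

import numpy as np
import pytest

from bpbeat import simulate as sim


@pytest.fixture(scope="session")
def subject() -> sim.SimSubject:
    return sim.sample_subject("S01", np.random.default_rng(5))


@pytest.fixture(scope="session")
def clean_record(subject) -> sim.WaveformRecord:
    """Two noiseless minutes of one subject."""
    traj = sim.simulate_bp_trajectory(subject, 120.0, seed=11)
    return sim.synthesize_record(subject, traj, sim.NoiseConfig.none(), seed=12)


@pytest.fixture(scope="session")
def noisy_record(subject) -> sim.WaveformRecord:
    """Two minutes at the default noise configuration."""
    traj = sim.simulate_bp_trajectory(subject, 120.0, seed=11)
    return sim.synthesize_record(subject, traj, sim.NoiseConfig(), seed=13)


@pytest.fixture(scope="session")
def small_cohort() -> list:
    """Six default-noise subjects, three minutes each, single visit."""
    cfg = sim.CohortConfig(duration_s=180.0)
    return sim.generate_cohort(6, 0, cfg, seed=42)
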