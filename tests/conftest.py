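import numpy as np
import pytest

import claudigait as cg


@pytest.fixture(scope="session")
def clean_config():
    """Deterministic, noise-free cohort settings (no subject jitter)."""
    return cg.CohortConfig(noise_sd=0.0, subject_sd=0.0)


@pytest.fixture(scope="session")
def clean_cycles(clean_config):
    """One noise-free mean gait cycle per class, via the full pipeline."""
    cycles = {}
    for label, sig in cg.DEFAULT_SIGNATURES.items():
        rng = np.random.default_rng(0)
        ang = cg.generate_angle_waveforms(sig, clean_config, rng)
        traj = cg.angles_to_markers(ang)
        starts = cg.detect_stance_starts(traj)
        cycles[label] = cg.mean_cycle(cg.compute_angles(traj), starts)
    return cycles


@pytest.fixture(scope="session")
def small_cohort_features():
    """Feature matrix of a small (3-per-class) default-signature cohort."""
    cfg = cg.CohortConfig(n_per_class={c: 3 for c in cg.CLASS_LABELS}, seed=7)
    cohort = cg.generate_cohort(cfg=cfg)
    df = cg.cohort_feature_matrix(cohort.subjects)
    X = df[list(cg.FEATURE_NAMES)].to_numpy(float)
    y = df["class"].to_numpy(object)
    return df, X, y


def random_angle_series(rng, n_frames=100):
    """Arbitrary smooth-ish angle series with all four angles well inside
    (0, 2*pi), for round-trip and oracle tests."""
    base = np.array([np.pi, np.pi, np.pi * 0.85, np.pi / 2])
    amp = rng.uniform(0.05, 0.4, size=4)
    phase = rng.uniform(0, 2 * np.pi, size=4)
    freq = rng.integers(1, 4, size=4)
    t = np.arange(n_frames)[:, None]
    vals = base + amp * np.sin(2 * np.pi * freq * t / n_frames + phase)
    return cg.AngleSeries(vals)
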