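import numpy as np
import pytest

from camptokin.kinematics import compute_camptocormia, compute_inclinations
from camptokin.preprocessing import smooth_recording
from camptokin.synth import (
    NOISE_FREE,
    default_study_script,
    generate_truth,
    project_accelerometers,
)


def forward_leg_oracle(phi_th, phi_sh, u, l):
    """Brute-force 2D forward kinematics for the two-pendulum leg.

    Places hip at the origin, the knee at the end of the thigh tilted
    phi_th anterior, the ankle at the end of the shank (whose sensor
    angle phi_sh counts the opposite rotation sense), and returns the
    signed angle of the hip->ankle vector against the vertical.
    Independent of the cosine-law route used by the package.
    """
    a = np.radians(phi_th)
    b = np.radians(phi_sh)
    knee = np.array([u * np.sin(a), -u * np.cos(a)])
    ankle = knee + np.array([-l * np.sin(b), -l * np.cos(b)])
    return np.degrees(np.arctan2(ankle[0], -ankle[1]))


@pytest.fixture(scope="session")
def study_truth():
    """Ground truth for the default four-minute study script."""
    script = default_study_script()
    return script, generate_truth(script)


@pytest.fixture(scope="session")
def noise_free_pipeline(study_truth):
    """Noise-free closed loop: truth -> accelerometers -> smoothed -> angles."""
    script, truth = study_truth
    rec = project_accelerometers(truth, NOISE_FREE)
    incl = compute_inclinations(smooth_recording(rec))
    series = compute_camptocormia(incl, script.anthro)
    return truth, series
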