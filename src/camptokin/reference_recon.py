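"""Reference angles from optical marker trajectories.

The motion-capture reference carries four markers: C7 and L5 on the
trunk, the iliac crest (IC) near the hip's rotation axis, and the
lateral malleolus (LM) at the ankle.  The trunk reference angle is the
inclination of the L5->C7 segment from vertical; the leg reference is
the absolute inclination of LM->L5 (camptocormia convention) or LM->IC
(true hip axis); their sum gives the reference malleolus angle.

All three formulas are implemented on marker displacement *differences*
(C7 - L5, top - LM): a segment direction must be translation-invariant,
and only coordinate differences are.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from camptokin.io_formats import MarkerTrajectory


@dataclass
class ReferenceAngles:
    """Time-indexed reference angles, degrees.

    CA_ref_L5 = Phi_per_ref + Phi_leg_ref_L5 exactly; the leg references
    are non-negative by construction (absolute value).
    """

    sample_rate: float
    phi_per_ref: np.ndarray
    phi_leg_ref_l5: np.ndarray
    phi_leg_ref_ic: np.ndarray
    ca_ref_l5: np.ndarray
    start_time: float = 0.0

    @property
    def n_frames(self) -> int:
        return self.phi_per_ref.shape[0]

    @property
    def time(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_frames) / self.sample_rate


def ref_trunk_angle(c7: np.ndarray, l5: np.ndarray) -> np.ndarray:
    """Inclination of the L5->C7 segment from vertical, degrees in [0, 180).

    atan2 of the horizontal displacement magnitude against the vertical
    displacement; coincident markers are an error.
    """
    c7 = np.atleast_2d(np.asarray(c7, float))
    l5 = np.atleast_2d(np.asarray(l5, float))
    d = c7 - l5
    horiz = np.hypot(d[:, 0], d[:, 1])
    if np.any((horiz == 0) & (d[:, 2] == 0)):
        raise ValueError("C7 and L5 markers coincide in at least one frame")
    ang = np.degrees(np.arctan2(horiz, d[:, 2]))
    return ang if ang.shape[0] > 1 else float(ang[0])


def ref_leg_angle(top: np.ndarray, lm: np.ndarray) -> np.ndarray:
    """Absolute inclination of the LM->top segment from vertical, [0, 90).

    ``top`` is L5 or IC; it must lie above LM in every frame (the leg
    reference is undefined otherwise).
    """
    top = np.atleast_2d(np.asarray(top, float))
    lm = np.atleast_2d(np.asarray(lm, float))
    d = top - lm
    if np.any(d[:, 2] <= 0):
        bad = int(np.argmax(d[:, 2] <= 0))
        raise ValueError(f"top marker not above LM at frame {bad}")
    ang = np.abs(np.degrees(np.arctan(np.hypot(d[:, 0], d[:, 1]) / d[:, 2])))
    return ang if ang.shape[0] > 1 else float(ang[0])


def ref_ca_l5(phi_per_ref, phi_leg_ref_l5):
    """Reference malleolus angle: exact sum of trunk and L5 leg references."""
    return np.asarray(phi_per_ref, float) + np.asarray(phi_leg_ref_l5, float)


def compute_reference_angles(traj: MarkerTrajectory) -> ReferenceAngles:
    """All reference angle series from a marker trajectory."""
    p = traj.positions
    phi_per = np.atleast_1d(ref_trunk_angle(p["C7"], p["L5"]))
    phi_leg_l5 = np.atleast_1d(ref_leg_angle(p["L5"], p["LM"]))
    phi_leg_ic = np.atleast_1d(ref_leg_angle(p["IC"], p["LM"]))
    return ReferenceAngles(
        sample_rate=traj.sample_rate,
        phi_per_ref=phi_per,
        phi_leg_ref_l5=phi_leg_l5,
        phi_leg_ref_ic=phi_leg_ic,
        ca_ref_l5=ref_ca_l5(phi_per, phi_leg_l5),
        start_time=traj.start_time,
    )


def write_reference_tsv(path: str | Path, ref: ReferenceAngles) -> None:
    pd.DataFrame(
        {
            "time_s": ref.time,
            "phi_per_ref": ref.phi_per_ref,
            "phi_leg_ref_l5": ref.phi_leg_ref_l5,
            "phi_leg_ref_ic": ref.phi_leg_ref_ic,
            "ca_ref_l5": ref.ca_ref_l5,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.9g")
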