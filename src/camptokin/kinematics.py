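"""Core angle computations.

Gravity is the absolute inclination reference: with the body at rest,
each tri-axial accelerometer measures the negative gravity vector in its
own frame, so segment inclination follows from the projection of that
unit vector onto the sensor axes.

Axis conventions (fixed by the simulator, switchable for real hardware):

* trunk sensors (C7, L5): +x along the cranial axis, so upright stance
  reads a_x = -1 g and the trunk inclination is
  ``-arctan(sqrt(a_y^2 + a_z^2) / a_x)`` — 0 deg upright, positive
  forward lean, implemented quadrant-safe so a horizontal sensor gives
  exactly 90 deg;
* leg sensors (TH, SH): anterior tilt drives a_y negative, so the signed
  leg-segment inclination is ``-arctan(a_y / sqrt(a_x^2 + a_z^2))`` —
  0 deg vertical, positive anterior.

The trunk model maps the two spine inclinations to the perpendicular
camptocormia angle through an affine chain-of-vertebrae model

    CA_per = 0.3856 + 0.4542 * phi_L5 + 0.5458 * phi_C7   [degrees]

and the leg is a planar two-pendulum chain (thigh length u, shank
length l) whose hip-to-ankle line makes the signed angle Phi_leg with
the vertical; the malleolus camptocormia angle is the sum
CA_mal = CA_per + Phi_leg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from camptokin.io_formats import Anthropometry, AccelRecording, SENSORS

# Affine spine-chain model coefficients, degrees in / degrees out.
CA_PER_INTERCEPT = 0.3856
CA_PER_COEF_L5 = 0.4542
CA_PER_COEF_C7 = 0.5458

#: Consensus cutoff: forward flexion beyond this malleolus-method angle
#: defines camptocormia.
CAMPTOCORMIA_CUTOFF_DEG = 30.0

_ARCCOS_CLAMP_TOL = 1e-9


@dataclass
class InclinationSet:
    """Time-indexed sensor inclinations phi_C7, phi_L5, phi_TH, phi_SH.

    ``angles[name]`` in degrees; ``mask[name]`` True where the sample is
    low-confidence or invalid.
    """

    sample_rate: float
    angles: dict[str, np.ndarray]
    mask: dict[str, np.ndarray] = field(default_factory=dict)
    start_time: float = 0.0
    calibrated: bool = False

    def __post_init__(self) -> None:
        lengths = {np.asarray(v).shape[0] for v in self.angles.values()}
        if len(lengths) != 1:
            raise ValueError(f"unequal series lengths: {sorted(lengths)}")
        n = lengths.pop()
        for s in self.angles:
            self.angles[s] = np.asarray(self.angles[s], dtype=float)
            if s not in self.mask:
                self.mask[s] = np.zeros(n, dtype=bool)
            if np.any(~np.isfinite(self.angles[s]) & ~self.mask[s]):
                raise ValueError(f"channel {s}: non-finite angle at unmasked sample")

    @property
    def n_samples(self) -> int:
        return next(iter(self.angles.values())).shape[0]

    @property
    def time(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate


@dataclass
class CamptocormiaSeries:
    """Camptocormia angles over time: CA_per, Phi_leg, CA_mal, knee theta.

    The identity CA_mal = CA_per + Phi_leg holds exactly at every sample.
    ``invalid`` marks samples whose knee angle left (0, 180] or whose
    inputs were masked.
    """

    sample_rate: float
    ca_per: np.ndarray
    phi_leg: np.ndarray
    ca_mal: np.ndarray
    knee: np.ndarray
    invalid: np.ndarray
    start_time: float = 0.0
    calibration: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.ca_per.shape[0]

    @property
    def time(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate


def trunk_inclination(a_x, a_y, a_z):
    """Trunk sensor inclination from vertical, degrees in [0, 180).

    Quadrant-safe form of -arctan(sqrt(a_y^2+a_z^2)/a_x): the two-argument
    arctangent of the lateral magnitude against -a_x, so a_x -> 0 gives
    exactly 90 deg instead of a division blow-up.  Zero-magnitude input
    yields NaN (callers mask such samples).
    """
    a_x, a_y, a_z = np.broadcast_arrays(
        np.asarray(a_x, float), np.asarray(a_y, float), np.asarray(a_z, float)
    )
    lat = np.hypot(a_y, a_z)
    ang = np.degrees(np.arctan2(lat, -a_x))
    zero = (lat == 0) & (a_x == 0)
    return np.where(zero, np.nan, ang)


def leg_inclination(a_x, a_y, a_z):
    """Leg segment inclination from vertical, signed degrees in (-90, 90).

    Quadrant-safe form of -arctan(a_y / sqrt(a_x^2+a_z^2)); positive when
    the segment's distal end is anterior.
    """
    a_x, a_y, a_z = np.broadcast_arrays(
        np.asarray(a_x, float), np.asarray(a_y, float), np.asarray(a_z, float)
    )
    denom = np.hypot(a_x, a_z)
    ang = np.degrees(np.arctan2(-a_y, denom))
    zero = (denom == 0) & (a_y == 0)
    return np.where(zero, np.nan, ang)


def ca_perpendicular(phi_l5, phi_c7):
    """Perpendicular-method camptocormia angle, degrees.

    Affine chain-of-vertebrae model: CA_per = 0.3856 + 0.4542 phi_L5 +
    0.5458 phi_C7.  Pure affine map, no guards.
    """
    return (
        CA_PER_INTERCEPT
        + CA_PER_COEF_L5 * np.asarray(phi_l5, float)
        + CA_PER_COEF_C7 * np.asarray(phi_c7, float)
    )


def knee_angle(phi_th, phi_sh):
    """Interior knee angle theta = 180 - phi_TH - phi_SH, degrees.

    Follows from the interior angles of the two triangles formed by the
    thigh and shank with the vertical.  A straight vertical leg gives
    180 deg; values outside (0, 180] are physically invalid and are
    flagged by :func:`leg_angle`.
    """
    return 180.0 - np.asarray(phi_th, float) - np.asarray(phi_sh, float)


def leg_angle(phi_th, phi_sh, anthro: Anthropometry):
    """Signed leg angle Phi_leg of the hip-to-ankle line vs. vertical.

    Two-pendulum construction: the vertical drops of thigh and shank are
    Z_u = u cos(phi_TH) and Z_l = l cos(phi_SH); the hip-ankle distance
    H follows from the cosine law with the knee angle theta; the
    magnitude is arccos((Z_u + Z_l)/H) with the argument clamped to
    [-1, 1] within a 1e-9 guard.  The sign is that of the ankle's
    horizontal anterior offset u sin(phi_TH) - l sin(phi_SH): positive
    when the foot is in front of the frontal plane.

    Returns
    -------
    (phi_leg, theta, H, Z_u, Z_l, invalid) — arrays broadcast over the
    inputs; ``invalid`` is True where theta leaves (0, 180] or the
    arccos argument is numerically inconsistent beyond the guard.
    """
    phi_th = np.asarray(phi_th, float)
    phi_sh = np.asarray(phi_sh, float)
    u, l = anthro.u, anthro.l
    theta = knee_angle(phi_th, phi_sh)
    invalid = (theta <= 0) | (theta > 180)

    z_u = u * np.cos(np.radians(phi_th))
    z_l = l * np.cos(np.radians(phi_sh))
    h = np.sqrt(u * u + l * l - 2.0 * u * l * np.cos(np.radians(theta)))
    if np.any(h == 0):
        raise ValueError("degenerate geometry: hip and ankle coincide (H = 0)")
    arg = (z_u + z_l) / h
    inconsistent = np.abs(arg) > 1.0 + _ARCCOS_CLAMP_TOL
    invalid = invalid | inconsistent
    anterior = u * np.sin(np.radians(phi_th)) - l * np.sin(np.radians(phi_sh))
    # atan2(anterior, Z_u + Z_l) is algebraically identical to the signed
    # arccos((Z_u+Z_l)/H) since H = hypot(anterior, Z_u+Z_l), but keeps full
    # precision near the straight vertical leg where the arccos argument
    # approaches 1.
    phi_leg = np.degrees(np.arctan2(anterior, z_u + z_l))
    return phi_leg, theta, h, z_u, z_l, invalid


def ca_malleolus(ca_per, phi_leg):
    """Malleolus-method camptocormia angle: CA_mal = CA_per + Phi_leg."""
    return np.asarray(ca_per, float) + np.asarray(phi_leg, float)


def classify_camptocormia(ca_mal, threshold: float = CAMPTOCORMIA_CUTOFF_DEG):
    """True where CA_mal strictly exceeds the cutoff (default 30 deg)."""
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    return np.asarray(ca_mal, float) > threshold


def compute_inclinations(
    rec: AccelRecording, mask: dict[str, np.ndarray] | None = None
) -> InclinationSet:
    """Per-sensor inclination series from an acceleration recording.

    Trunk sensors use :func:`trunk_inclination`, leg sensors
    :func:`leg_inclination`.  An optional per-sensor low-confidence mask
    (see :func:`camptokin.preprocessing.flag_low_confidence`) is carried
    through; zero-magnitude samples are masked rather than raising.
    """
    angles: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    for s in rec.sensors:
        a = rec.channels[s]
        fn = trunk_inclination if s in ("C7", "L5") else leg_inclination
        ang = fn(a[:, 0], a[:, 1], a[:, 2])
        m = ~np.isfinite(ang)
        if mask is not None and s in mask:
            m = m | mask[s]
        key = f"phi_{s}"
        angles[key] = ang
        masks[key] = m
    return InclinationSet(
        sample_rate=rec.sample_rate, angles=angles, mask=masks, start_time=rec.start_time
    )


def compute_camptocormia(
    incl: InclinationSet, anthro: Anthropometry | None = None
) -> CamptocormiaSeries:
    """Full camptocormia series from sensor inclinations.

    With ``anthro`` given, computes the malleolus chain (Phi_leg, knee
    angle, CA_mal); without it, a two-sensor perpendicular-only run with
    Phi_leg = 0 so the CA_mal = CA_per + Phi_leg identity still holds.
    """
    ca_per = ca_perpendicular(incl.angles["phi_L5"], incl.angles["phi_C7"])
    invalid = incl.mask["phi_C7"] | incl.mask["phi_L5"]
    if anthro is not None:
        if "phi_TH" not in incl.angles or "phi_SH" not in incl.angles:
            raise ValueError(
                "malleolus method needs the TH and SH sensors; this recording "
                "carries the trunk sensors only"
            )
        phi_leg, theta, _, _, _, leg_invalid = leg_angle(
            incl.angles["phi_TH"], incl.angles["phi_SH"], anthro
        )
        invalid = invalid | incl.mask["phi_TH"] | incl.mask["phi_SH"] | leg_invalid
    else:
        phi_leg = np.zeros_like(ca_per)
        theta = np.full_like(ca_per, 180.0)
    # the affine spine model is untested far outside the clinical range:
    # treat |CA_per| > 90 deg as suspicious rather than extrapolating
    invalid = invalid | (np.abs(ca_per) > 90.0)
    return CamptocormiaSeries(
        sample_rate=incl.sample_rate,
        ca_per=ca_per,
        phi_leg=phi_leg,
        ca_mal=ca_malleolus(ca_per, phi_leg),
        knee=theta,
        invalid=invalid,
        start_time=incl.start_time,
    )
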