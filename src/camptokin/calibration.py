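"""Zero and patient-specific calibration.

Zero calibration averages each sensor inclination over an upright
standing window (60 s by default) and subtracts the means from the
subsequent recording.  Patient-specific calibration compares the IMU
camptocormia angles, averaged over a standing-forward-lean window,
with the two angles measured manually from a still photograph of the
same posture; the differences (offset_per, offset_mal) shift the CA
series so the calibration posture reads the photo value exactly.

offset_leg is the approximately constant gap between the leg reference
angle taken from L5 (the camptocormia convention) and from the iliac
crest (the hip's true rotation axis); it is estimated once from marker
data and may be subtracted from the recorded leg angle.  offset_mal and
offset_leg address the same anatomical discrepancy through different
routes, so enabling both on one CA_mal stream is a configuration error
guarded at run time.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from camptokin.kinematics import CamptocormiaSeries, InclinationSet


@dataclass
class CalibrationState:
    """Calibration offsets, all in degrees, with provenance.

    ``zero_refs`` maps inclination channel name to its upright-window
    mean; the three scalar offsets apply to the leg angle and the two CA
    streams respectively.
    """

    method: str = "none"
    zero_refs: dict[str, float] = field(default_factory=dict)
    offset_leg: float = 0.0
    offset_per: float = 0.0
    offset_mal: float = 0.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in ("zero", "patient_specific", "none"):
            raise ValueError(f"unknown calibration method {self.method!r}")
        for name, value in [
            ("offset_leg", self.offset_leg),
            ("offset_per", self.offset_per),
            ("offset_mal", self.offset_mal),
        ]:
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value}")


def _window_indices(n: int, rate: float, start_time: float, window: tuple[float, float]):
    t0, t1 = window
    if t1 - t0 < 5.0:
        raise ValueError(f"calibration window of {t1 - t0:.3g} s is shorter than 5 s")
    i0 = int(np.ceil((t0 - start_time) * rate))
    i1 = int(np.floor((t1 - start_time) * rate)) + 1
    # samples span [start, start + n/rate): a window ending exactly at the
    # recording end is valid and clamps to the last sample
    if i0 < 0 or t1 > start_time + n / rate + 1e-9:
        raise ValueError(
            f"window [{t0}, {t1}] s not covered by recording of "
            f"[{start_time}, {start_time + n / rate}] s"
        )
    return i0, min(i1, n)


def zero_calibrate(
    incl: InclinationSet, window: tuple[float, float] | None = None
) -> CalibrationState:
    """Zero calibration from an upright standing window (default first 60 s).

    The per-channel mean over the window becomes the zero reference; more
    than 50% masked samples in the window abort the calibration.
    """
    if window is None:
        window = (incl.start_time, incl.start_time + 60.0)
    i0, i1 = _window_indices(incl.n_samples, incl.sample_rate, incl.start_time, window)
    zero_refs = {}
    for name, series in incl.angles.items():
        m = incl.mask[name][i0:i1]
        if m.mean() > 0.5:
            raise ValueError(
                f"channel {name}: {100 * m.mean():.0f}% of the calibration "
                "window is masked"
            )
        zero_refs[name] = float(np.mean(series[i0:i1][~m]))
    return CalibrationState(
        method="zero",
        zero_refs=zero_refs,
        provenance={"window_s": list(window), "n_samples": i1 - i0},
    )


def patient_specific_calibrate(
    measured_ca_per: float,
    measured_ca_mal: float,
    photo_ca_per: float,
    photo_ca_mal: float,
    window: tuple[float, float] | None = None,
) -> CalibrationState:
    """Patient-specific calibration from photo-derived CA angles.

    ``measured_*`` are the IMU camptocormia angles averaged over the
    annotated forward-lean calibration window; ``photo_*`` are the two
    numbers read off the still photograph.  The offsets are photo minus
    measured and are added to subsequent CA series.
    """
    values = [measured_ca_per, measured_ca_mal, photo_ca_per, photo_ca_mal]
    if not all(np.isfinite(v) for v in values):
        raise ValueError(f"all calibration angles must be finite, got {values}")
    return CalibrationState(
        method="patient_specific",
        offset_per=photo_ca_per - measured_ca_per,
        offset_mal=photo_ca_mal - measured_ca_mal,
        provenance={
            "photo_ca_per": photo_ca_per,
            "photo_ca_mal": photo_ca_mal,
            "measured_ca_per": measured_ca_per,
            "measured_ca_mal": measured_ca_mal,
            "window_s": list(window) if window is not None else None,
        },
    )


def estimate_offset_leg(
    ref_l5: np.ndarray,
    ref_ic: np.ndarray,
    window: slice | np.ndarray | None = None,
) -> float:
    """Mean gap between the L5-referenced and IC-referenced leg angles.

    Estimated once over a static window (standing with forward lean) and
    assumed practically constant thereafter, so it can be subtracted from
    the recorded leg angle.
    """
    ref_l5 = np.asarray(ref_l5, float)
    ref_ic = np.asarray(ref_ic, float)
    if window is not None:
        ref_l5 = ref_l5[window]
        ref_ic = ref_ic[window]
    if ref_l5.size == 0 or ref_ic.size == 0:
        raise ValueError("empty window for offset_leg estimation")
    if ref_l5.shape != ref_ic.shape:
        raise ValueError("reference series must be aligned")
    return float(np.mean(ref_l5 - ref_ic))


def apply_calibration(series, cal: CalibrationState):
    """Apply a calibration state to an InclinationSet or CamptocormiaSeries.

    Zero references subtract from inclination channels; offset_per /
    offset_mal add to their own CA streams.  offset_leg (the L5-minus-IC
    reference gap) adds to the hip-referenced IMU leg angle, expressing
    it in the L5 frame that the malleolus convention requires.
    Application is recorded in provenance and refused the second time;
    requesting both offset_mal and offset_leg corrections on one CA
    stream is rejected as a configuration error.
    """
    if isinstance(series, InclinationSet):
        if series.calibrated:
            raise ValueError("inclination set is already calibrated")
        angles = {
            name: arr - cal.zero_refs.get(name, 0.0)
            for name, arr in series.angles.items()
        }
        return InclinationSet(
            sample_rate=series.sample_rate,
            angles=angles,
            mask={k: v.copy() for k, v in series.mask.items()},
            start_time=series.start_time,
            calibrated=True,
        )
    if isinstance(series, CamptocormiaSeries):
        if series.calibration.get("applied"):
            raise ValueError("camptocormia series is already calibrated")
        if cal.offset_mal != 0.0 and cal.offset_leg != 0.0:
            raise ValueError(
                "offset_mal and offset_leg both correct the L5-vs-hip "
                "discrepancy; enabling both on one CA_mal stream is a "
                "configuration error"
            )
        # Each offset shifts its own stream: offset_per acts on CA_per only,
        # offset_mal on CA_mal only, offset_leg on the leg angle (and hence
        # on CA_mal through the sum).
        phi_leg = series.phi_leg + cal.offset_leg
        return CamptocormiaSeries(
            sample_rate=series.sample_rate,
            ca_per=series.ca_per + cal.offset_per,
            phi_leg=phi_leg,
            ca_mal=series.ca_per + phi_leg + cal.offset_mal,
            knee=series.knee.copy(),
            invalid=series.invalid.copy(),
            start_time=series.start_time,
            calibration={
                "applied": True,
                "method": cal.method,
                "offset_per": cal.offset_per,
                "offset_mal": cal.offset_mal,
                "offset_leg": cal.offset_leg,
                "provenance": copy.deepcopy(cal.provenance),
            },
        )
    raise TypeError(f"cannot calibrate object of type {type(series).__name__}")
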