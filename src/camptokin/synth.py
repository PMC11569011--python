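"""Forward-kinematics generator for matched sensor and marker data.

The generator turns a scripted sequence of activity blocks — each
prescribing the true trunk flexion CA_per(t), the true leg angle
Phi_leg(t) and the knee flexion kappa(t) — into

* exact ground-truth angle series for every sensor channel,
* tri-axial accelerometer recordings obtained by projecting the unit
  gravity vector into each (possibly noisy) sensor frame, and
* optical marker trajectories (C7, L5, IC, LM) placed on the same
  body model,

so the entire measurement pipeline can be exercised without laboratory
recordings.  The default script mirrors a four-minute laboratory
session: 60 s standing upright, 50 s standing with forward lean, 25 s
walking and 80 s of mimicked parkinsonian gait.

Sensor truths are obtained by inverting the measurement models: the
spine-chain model is solved for (phi_L5, phi_C7) under a configurable
distribution ratio (equal angles by default — any pair satisfying the
affine model is valid truth), and the two-pendulum chain is solved in
closed form: with kappa = phi_TH + phi_SH the hip-to-ankle direction
factors as u*e^(i*phi_TH) + l*e^(i*(phi_TH - kappa)), giving

    phi_TH = Phi_leg + atan2(l sin kappa, u + l cos kappa)
    phi_SH = kappa - phi_TH.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from camptokin.io_formats import (
    AccelRecording,
    ActivitySegments,
    Anthropometry,
    MarkerTrajectory,
)
from camptokin.kinematics import (
    CA_PER_COEF_C7,
    CA_PER_COEF_L5,
    CA_PER_INTERCEPT,
)

TRUNK_LIMIT_DEG = 80.0
LEG_LIMIT_DEG = 60.0


@dataclass(frozen=True)
class Waveform:
    """Scalar angle trajectory over a block: constant, ramp, or sinusoid.

    kind="constant": value = mean.
    kind="ramp":     linear from ``mean`` to ``end`` over the block.
    kind="sine":     mean + amplitude * sin(2*pi*frequency*t), t local.
    """

    kind: str = "constant"
    mean: float = 0.0
    amplitude: float = 0.0
    frequency: float = 0.0
    end: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "ramp", "sine"):
            raise ValueError(f"unknown waveform kind {self.kind!r}")

    def sample(self, t: np.ndarray, duration: float) -> np.ndarray:
        if self.kind == "constant":
            return np.full_like(t, self.mean)
        if self.kind == "ramp":
            return self.mean + (self.end - self.mean) * (t / duration)
        return self.mean + self.amplitude * np.sin(2 * np.pi * self.frequency * t)


@dataclass(frozen=True)
class ActivityBlock:
    """One labeled block of a posture script."""

    label: str
    duration_s: float
    ca_per: Waveform = field(default_factory=Waveform)
    phi_leg: Waveform = field(default_factory=Waveform)
    knee_flexion: Waveform = field(default_factory=Waveform)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"block {self.label!r}: duration must be positive")


@dataclass(frozen=True)
class PostureScript:
    """Ordered activity blocks plus the body parameters shared by all.

    ``spine_ratio`` r distributes the trunk flexion over the two spine
    sensors as phi_C7 = r * phi_L5; any ratio is a valid truth for the
    affine spine model.
    """

    blocks: tuple[ActivityBlock, ...]
    anthro: Anthropometry = field(default_factory=lambda: Anthropometry(u=0.45, l=0.45))
    spine_ratio: float = 1.0
    #: Posture transitions between blocks are blended over this many
    #: seconds with a cosine ease — a subject moves continuously from one
    #: activity to the next, never discontinuously.
    transition_s: float = 1.0

    @property
    def duration_s(self) -> float:
        return sum(b.duration_s for b in self.blocks)

    def segments(self) -> ActivitySegments:
        out, t = [], 0.0
        for b in self.blocks:
            out.append((b.label, t, t + b.duration_s))
            t += b.duration_s
        return ActivitySegments(out)


@dataclass(frozen=True)
class NoiseModel:
    """Additive measurement noise for the simulated sensors and markers.

    White accelerometer noise of 0.02 g reflects consumer-grade IMU
    noise plus mild soft-tissue vibration; short motion-artifact bursts
    (off by default) emulate impacts; marker jitter of 0.5 mm is typical
    residual error of an optical capture volume.
    """

    accel_sigma_g: float = 0.02
    burst_amplitude_g: float = 0.0
    burst_rate_hz: float = 0.0
    marker_sigma_m: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("accel_sigma_g", "burst_amplitude_g", "burst_rate_hz", "marker_sigma_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


NOISE_FREE = NoiseModel(accel_sigma_g=0.0, marker_sigma_m=0.0)


@dataclass
class TruthSeries:
    """Exact ground-truth angle series at the sampling rate, degrees."""

    sample_rate: float
    labels: np.ndarray
    phi_c7: np.ndarray
    phi_l5: np.ndarray
    phi_th: np.ndarray
    phi_sh: np.ndarray
    ca_per_true: np.ndarray
    phi_leg_true: np.ndarray
    ca_mal_true: np.ndarray
    knee_true: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.ca_per_true.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


def default_study_script() -> PostureScript:
    """A four-minute script mirroring the laboratory activity sequence.

    60 s upright standing with a small habitual trunk angle, 50 s of
    held forward lean (the camptocormia-mimicking posture), 25 s of
    walking with sinusoidal antiphase leg swing at cadence ~1 Hz, and
    80 s of stooped, small-stride parkinsonian gait.
    """
    return PostureScript(
        blocks=(
            ActivityBlock(
                "standing_upright",
                60.0,
                ca_per=Waveform("constant", mean=8.0),
                phi_leg=Waveform("constant", mean=0.0),
                knee_flexion=Waveform("constant", mean=3.0),
            ),
            ActivityBlock(
                "standing_forward_lean",
                50.0,
                ca_per=Waveform("constant", mean=40.0),
                phi_leg=Waveform("constant", mean=8.0),
                knee_flexion=Waveform("constant", mean=15.0),
            ),
            ActivityBlock(
                "walking",
                25.0,
                ca_per=Waveform("sine", mean=10.0, amplitude=2.0, frequency=1.0),
                phi_leg=Waveform("sine", mean=0.0, amplitude=15.0, frequency=1.0),
                knee_flexion=Waveform("sine", mean=20.0, amplitude=15.0, frequency=1.0),
            ),
            ActivityBlock(
                "parkinsonian_gait",
                80.0,
                ca_per=Waveform("sine", mean=35.0, amplitude=3.0, frequency=0.8),
                phi_leg=Waveform("sine", mean=2.0, amplitude=8.0, frequency=0.8),
                knee_flexion=Waveform("sine", mean=12.0, amplitude=8.0, frequency=0.8),
            ),
        ),
        transition_s=2.0,
    )


def quasistatic_study_script() -> PostureScript:
    """The study block structure with slow posture dynamics only.

    Same 60/50/25/80 s labeled blocks as :func:`default_study_script`,
    but every trajectory varies at <= 0.1 Hz (ramps and slow sinusoids).
    Within the one-second cubic smoothing window such signals are locally
    polynomial, so this script isolates the angle-computation chain from
    the filter's finite bandwidth — it is the script used to verify the
    full pipeline end to end at numerical precision.
    """
    return PostureScript(
        blocks=(
            ActivityBlock(
                "standing_upright",
                60.0,
                ca_per=Waveform("constant", mean=8.0),
                phi_leg=Waveform("constant", mean=0.0),
                knee_flexion=Waveform("constant", mean=3.0),
            ),
            ActivityBlock(
                "standing_forward_lean",
                50.0,
                ca_per=Waveform("ramp", mean=10.0, end=45.0),
                phi_leg=Waveform("ramp", mean=0.0, end=8.0),
                knee_flexion=Waveform("ramp", mean=3.0, end=15.0),
            ),
            ActivityBlock(
                "walking",
                25.0,
                ca_per=Waveform("sine", mean=10.0, amplitude=2.0, frequency=0.08),
                phi_leg=Waveform("sine", mean=0.0, amplitude=10.0, frequency=0.08),
                knee_flexion=Waveform("sine", mean=10.0, amplitude=8.0, frequency=0.08),
            ),
            ActivityBlock(
                "parkinsonian_gait",
                80.0,
                ca_per=Waveform("sine", mean=35.0, amplitude=3.0, frequency=0.05),
                phi_leg=Waveform("sine", mean=2.0, amplitude=6.0, frequency=0.05),
                knee_flexion=Waveform("sine", mean=12.0, amplitude=6.0, frequency=0.05),
            ),
        ),
        transition_s=4.0,
    )


def _leg_split(phi_leg: np.ndarray, kappa: np.ndarray, u: float, l: float):
    """Closed-form (phi_TH, phi_SH) realizing a leg angle and knee flexion."""
    kr = np.radians(kappa)
    psi = np.degrees(np.arctan2(l * np.sin(kr), u + l * np.cos(kr)))
    phi_th = phi_leg + psi
    phi_sh = kappa - phi_th
    return phi_th, phi_sh


def generate_truth(script: PostureScript, rate: float = 128.0) -> TruthSeries:
    """Exact ground-truth series for every channel of a posture script.

    By construction the spine model evaluated at (phi_L5, phi_C7)
    reproduces CA_per_true and the two-pendulum model evaluated at
    (phi_TH, phi_SH) reproduces Phi_leg_true, both to numerical
    precision.  Blocks whose angles leave the physical bounds (trunk
    80 deg, leg segments 60 deg, knee flexion outside [0, 180)) raise
    an error naming the block.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    u, l = script.anthro.u, script.anthro.l
    spine_gain = CA_PER_COEF_L5 + CA_PER_COEF_C7 * script.spine_ratio
    if spine_gain == 0:
        raise ValueError("spine_ratio makes the spine model non-invertible")
    chunks = []
    for block in script.blocks:
        n = int(round(block.duration_s * rate))
        t = np.arange(n) / rate
        ca = block.ca_per.sample(t, block.duration_s)
        leg = block.phi_leg.sample(t, block.duration_s)
        knee = block.knee_flexion.sample(t, block.duration_s)
        if np.any(np.abs(ca) > TRUNK_LIMIT_DEG):
            raise ValueError(f"block {block.label!r}: trunk angle exceeds {TRUNK_LIMIT_DEG} deg")
        if np.any((knee < 0) | (knee >= 180)):
            raise ValueError(f"block {block.label!r}: knee flexion outside [0, 180) deg")
        chunks.append((np.full(n, block.label, dtype=object), ca, leg, knee))
    labels = np.concatenate([c[0] for c in chunks])
    ca_per = np.concatenate([c[1] for c in chunks])
    phi_leg = np.concatenate([c[2] for c in chunks])
    kappa = np.concatenate([c[3] for c in chunks])
    if script.transition_s > 0 and len(script.blocks) > 1:
        bounds = np.cumsum([int(round(b.duration_s * rate)) for b in script.blocks])[:-1]
        sizes = [int(round(b.duration_s * rate)) for b in script.blocks]
        for k, ib in enumerate(bounds):
            h = int(round(script.transition_s * rate / 2))
            h = min(h, sizes[k] // 2, sizes[k + 1] // 2)
            if h < 1:
                continue
            i0, i1 = ib - h, ib + h
            w = 0.5 * (1 - np.cos(np.linspace(0, np.pi, i1 - i0)))
            for series in (ca_per, phi_leg, kappa):
                series[i0:i1] = series[i0] * (1 - w) + series[i1 - 1] * w
    phi_l5 = (ca_per - CA_PER_INTERCEPT) / spine_gain
    phi_c7 = script.spine_ratio * phi_l5
    phi_th, phi_sh = _leg_split(phi_leg, kappa, u, l)
    for name, series in [("phi_TH", phi_th), ("phi_SH", phi_sh)]:
        bad = np.abs(series) > LEG_LIMIT_DEG
        if np.any(bad):
            block = labels[int(np.argmax(bad))]
            raise ValueError(
                f"block {block!r}: {name} exceeds {LEG_LIMIT_DEG} deg "
                "(infeasible leg angle / knee flexion combination)"
            )
    return TruthSeries(
        sample_rate=rate,
        labels=labels,
        phi_c7=phi_c7,
        phi_l5=phi_l5,
        phi_th=phi_th,
        phi_sh=phi_sh,
        ca_per_true=ca_per,
        phi_leg_true=phi_leg,
        ca_mal_true=ca_per + phi_leg,
        knee_true=180.0 - kappa,
    )


def _bursts(rng: np.random.Generator, n: int, rate: float, noise: NoiseModel) -> np.ndarray:
    out = np.zeros((n, 3))
    if noise.burst_rate_hz <= 0 or noise.burst_amplitude_g <= 0:
        return out
    n_events = rng.poisson(noise.burst_rate_hz * n / rate)
    for _ in range(n_events):
        i = rng.integers(0, n)
        out[i] += rng.normal(0.0, noise.burst_amplitude_g, size=3)
    return out


def project_accelerometers(
    truth: TruthSeries, noise: NoiseModel = NOISE_FREE
) -> AccelRecording:
    """Gravity-projection accelerometer channels for all four sensors.

    Each sensor reads the unit gravity reaction vector rotated into its
    frame: trunk sensors carry the in-plane component on a_z
    (a = (-cos phi, 0, sin phi)), leg sensors on a_y
    (a = (-cos phi, -sin phi, 0)), matching the package axis
    conventions; white noise and optional bursts are then added.  A
    noise-free round trip through the inclination formulas reproduces
    the truth angles to numerical precision.
    """
    rng = np.random.default_rng(noise.seed)
    n = truth.n_samples
    channels: dict[str, np.ndarray] = {}
    for sensor, phi in [
        ("C7", truth.phi_c7),
        ("L5", truth.phi_l5),
        ("TH", truth.phi_th),
        ("SH", truth.phi_sh),
    ]:
        pr = np.radians(phi)
        a = np.zeros((n, 3))
        a[:, 0] = -np.cos(pr)
        if sensor in ("C7", "L5"):
            a[:, 2] = np.sin(pr)
        else:
            a[:, 1] = -np.sin(pr)
        if noise.accel_sigma_g > 0:
            a = a + rng.normal(0.0, noise.accel_sigma_g, size=a.shape)
        a = a + _bursts(rng, n, truth.sample_rate, noise)
        channels[sensor] = a
    return AccelRecording(sample_rate=truth.sample_rate, channels=channels)


@dataclass(frozen=True)
class BodyDimensions:
    """Marker-placement geometry for the simulated body, meters.

    The hip rotation axis (where the IC marker sits) is the fixed pivot;
    L5 sits ``l5_posterior_m`` behind and ``l5_superior_m`` above it,
    which is the anatomical source of the offset between the
    L5-referenced and IC-referenced leg angles (the defaults give about
    a 7-degree gap for a leg of 0.9 m).  C7 lies ``trunk_length_m``
    along the trunk line from L5.
    """

    trunk_length_m: float = 0.45
    l5_posterior_m: float = 0.117
    l5_superior_m: float = 0.05
    hip_height_m: float = 0.95


def project_markers(
    truth: TruthSeries,
    anthro: Anthropometry | None = None,
    body: BodyDimensions = BodyDimensions(),
    noise: NoiseModel = NOISE_FREE,
) -> MarkerTrajectory:
    """Marker trajectories (C7, L5, IC, LM) consistent with the truth.

    The hip pivot is fixed; the ankle hangs from it through the
    two-pendulum leg, the trunk line rises from L5 at the true
    perpendicular angle.  Noise-free reference reconstruction therefore
    returns Phi_per_ref = CA_per_true and Phi_leg_ref_IC =
    |Phi_leg_true| exactly, while the L5-referenced leg angle carries
    the anatomical offset.  Marker jitter uses an independent stream of
    the same seed.
    """
    if anthro is None:
        anthro = Anthropometry(u=0.45, l=0.45)
    rng = np.random.default_rng([noise.seed, 1])
    n = truth.n_samples
    u, l = anthro.u, anthro.l
    hip = np.array([0.0, 0.0, body.hip_height_m])
    thr = np.radians(truth.phi_th)
    shr = np.radians(truth.phi_sh)
    ankle = np.zeros((n, 3))
    ankle[:, 0] = hip[0] + u * np.sin(thr) - l * np.sin(shr)
    ankle[:, 2] = hip[2] - (u * np.cos(thr) + l * np.cos(shr))
    ic = np.tile(hip, (n, 1))
    l5 = ic + np.array([-body.l5_posterior_m, 0.0, body.l5_superior_m])
    car = np.radians(truth.ca_per_true)
    c7 = l5 + body.trunk_length_m * np.column_stack(
        [np.sin(car), np.zeros(n), np.cos(car)]
    )
    positions = {"C7": c7, "L5": l5, "IC": ic, "LM": ankle}
    if noise.marker_sigma_m > 0:
        positions = {
            m: p + rng.normal(0.0, noise.marker_sigma_m, size=p.shape)
            for m, p in positions.items()
        }
    return MarkerTrajectory(sample_rate=truth.sample_rate, positions=positions)


def write_truth_tsv(path: str | Path, truth: TruthSeries) -> None:
    pd.DataFrame(
        {
            "time_s": truth.time,
            "label": truth.labels,
            "phi_C7": truth.phi_c7,
            "phi_L5": truth.phi_l5,
            "phi_TH": truth.phi_th,
            "phi_SH": truth.phi_sh,
            "ca_per_true": truth.ca_per_true,
            "phi_leg_true": truth.phi_leg_true,
            "ca_mal_true": truth.ca_mal_true,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.9g")
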