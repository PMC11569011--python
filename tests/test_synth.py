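import numpy as np
import pytest

from camptokin.io_formats import Anthropometry, MARKERS
from camptokin.kinematics import ca_perpendicular, leg_angle
from camptokin.reference_recon import compute_reference_angles
from camptokin.synth import (
    ActivityBlock,
    BodyDimensions,
    NOISE_FREE,
    NoiseModel,
    PostureScript,
    Waveform,
    default_study_script,
    generate_truth,
    project_accelerometers,
    project_markers,
)


def single_block_script(ca=0.3856, leg=0.0, knee=0.0, duration=10.0, label="standing_upright"):
    return PostureScript(
        blocks=(
            ActivityBlock(
                label,
                duration,
                ca_per=Waveform("constant", mean=ca),
                phi_leg=Waveform("constant", mean=leg),
                knee_flexion=Waveform("constant", mean=knee),
            ),
        ),
    )


class TestGenerateTruth:
    def test_intercept_posture_gives_zero_inclinations(self):
        truth = generate_truth(single_block_script(ca=0.3856))
        np.testing.assert_allclose(truth.phi_l5, 0.0, atol=1e-12)
        np.testing.assert_allclose(truth.phi_c7, 0.0, atol=1e-12)

    def test_straight_leg_splits_antisymmetrically(self):
        truth = generate_truth(single_block_script(leg=10.0, knee=0.0))
        np.testing.assert_allclose(truth.phi_th, 10.0, atol=1e-9)
        np.testing.assert_allclose(truth.phi_sh, -10.0, atol=1e-9)

    def test_truth_satisfies_both_measurement_models(self):
        script = default_study_script()
        truth = generate_truth(script)
        np.testing.assert_allclose(
            ca_perpendicular(truth.phi_l5, truth.phi_c7), truth.ca_per_true, atol=1e-9
        )
        phi, *_ , invalid = leg_angle(truth.phi_th, truth.phi_sh, script.anthro)
        np.testing.assert_allclose(phi, truth.phi_leg_true, atol=1e-9)
        assert not invalid.any()

    def test_sinusoidal_block_reaches_stated_extremes(self):
        script = PostureScript(
            blocks=(
                ActivityBlock(
                    "standing_forward_lean",
                    20.0,
                    ca_per=Waveform("sine", mean=20.0, amplitude=10.0, frequency=0.1),
                ),
            ),
        )
        truth = generate_truth(script)
        assert truth.ca_per_true.max() == pytest.approx(30.0, abs=1e-6)
        assert truth.ca_per_true.min() == pytest.approx(10.0, abs=1e-6)

    def test_infeasible_block_named_in_error(self):
        with pytest.raises(ValueError, match="parkinsonian_gait"):
            generate_truth(
                single_block_script(leg=55.0, knee=100.0, label="parkinsonian_gait")
            )

    def test_spine_ratio_distributes_flexion(self):
        script = PostureScript(
            blocks=single_block_script(ca=30.0).blocks, spine_ratio=2.0
        )
        truth = generate_truth(script)
        np.testing.assert_allclose(truth.phi_c7, 2 * truth.phi_l5, atol=1e-12)
        np.testing.assert_allclose(
            ca_perpendicular(truth.phi_l5, truth.phi_c7), 30.0, atol=1e-9
        )


class TestProjectAccelerometers:
    def test_upright_trunk_channel_reads_minus_one_g(self):
        truth = generate_truth(single_block_script(ca=0.3856))
        rec = project_accelerometers(truth, NOISE_FREE)
        np.testing.assert_allclose(rec.channels["C7"], [[-1.0, 0.0, 0.0]] * truth.n_samples, atol=1e-12)

    def test_45_degree_lean_projection(self):
        script = single_block_script(ca=ca_perpendicular(45.0, 45.0))
        truth = generate_truth(script)
        rec = project_accelerometers(truth, NOISE_FREE)
        expected = [-np.cos(np.radians(45)), 0.0, np.sin(np.radians(45))]
        np.testing.assert_allclose(rec.channels["L5"][0], expected, atol=1e-9)

    def test_same_seed_bit_identical_different_seed_distinct(self):
        truth = generate_truth(single_block_script())
        noise = NoiseModel(accel_sigma_g=0.02, seed=42)
        a = project_accelerometers(truth, noise)
        b = project_accelerometers(truth, noise)
        c = project_accelerometers(truth, NoiseModel(accel_sigma_g=0.02, seed=43))
        for s in ("C7", "TH"):
            np.testing.assert_array_equal(a.channels[s], b.channels[s])
        assert not np.array_equal(a.channels["C7"], c.channels["C7"])


class TestProjectMarkers:
    def test_upright_references_are_zero_with_collocated_hip(self):
        # degenerate body with L5 on the hip axis: every reference angle is 0
        truth = generate_truth(single_block_script(ca=0.0, leg=0.0, knee=0.0))
        body = BodyDimensions(l5_posterior_m=0.0, l5_superior_m=0.0)
        ref = compute_reference_angles(project_markers(truth, body=body, noise=NOISE_FREE))
        np.testing.assert_allclose(ref.phi_per_ref, 0.0, atol=1e-9)
        np.testing.assert_allclose(ref.phi_leg_ref_l5, 0.0, atol=1e-9)
        np.testing.assert_allclose(ref.phi_leg_ref_ic, 0.0, atol=1e-9)

    def test_reference_reproduces_truth_angles(self):
        script = default_study_script()
        truth = generate_truth(script)
        ref = compute_reference_angles(
            project_markers(truth, script.anthro, noise=NOISE_FREE)
        )
        np.testing.assert_allclose(ref.phi_per_ref, truth.ca_per_true, atol=1e-6)
        np.testing.assert_allclose(
            ref.phi_leg_ref_ic, np.abs(truth.phi_leg_true), atol=1e-6
        )

    def test_rigid_azimuthal_rotation_leaves_references_unchanged(self):
        truth = generate_truth(single_block_script(ca=25.0, leg=5.0, knee=10.0))
        traj = project_markers(truth, noise=NOISE_FREE)
        ref = compute_reference_angles(traj)
        ang = np.radians(118.0)
        rot = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
        )
        traj.positions = {m: traj.positions[m] @ rot.T for m in MARKERS}
        ref_rot = compute_reference_angles(traj)
        np.testing.assert_allclose(ref_rot.ca_ref_l5, ref.ca_ref_l5, atol=1e-9)

    def test_marker_jitter_reproducible_by_seed(self):
        truth = generate_truth(single_block_script())
        noise = NoiseModel(marker_sigma_m=0.001, seed=3)
        a = project_markers(truth, noise=noise)
        b = project_markers(truth, noise=noise)
        np.testing.assert_array_equal(a.positions["LM"], b.positions["LM"])


class TestClosedLoop:
    def test_noise_free_pipeline_recovers_truth(self, noise_free_pipeline):
        truth, series = noise_free_pipeline
        # static blocks: exact recovery; dynamic gait blocks are limited by
        # the smoothing filter's bandwidth, so check the static majority
        core = np.isin(truth.labels, ["standing_upright", "standing_forward_lean"])
        edges = np.flatnonzero(truth.labels[1:] != truth.labels[:-1]) + 1
        margin = int(3 * truth.sample_rate)
        for e in edges:  # exclude the scripted posture transitions
            core[max(0, e - margin) : e + margin] = False
        err = series.ca_mal[core] - truth.ca_mal_true[core]
        assert np.sqrt(np.mean(err**2)) < 0.01

    def test_identity_holds_rowwise(self, noise_free_pipeline):
        _, series = noise_free_pipeline
        np.testing.assert_array_equal(
            series.ca_mal, series.ca_per + series.phi_leg
        )

    def test_camptocormia_classification_on_study_script(self, noise_free_pipeline):
        from camptokin.kinematics import classify_camptocormia

        truth, series = noise_free_pipeline
        flags = classify_camptocormia(series.ca_mal)
        lean = truth.labels == "standing_forward_lean"
        upright = truth.labels == "standing_upright"
        # forward lean (CA_mal = 48 deg) exceeds the 30-deg cutoff; upright never
        assert flags[lean][128 * 5 : -128 * 5].all()
        assert not flags[upright][128 * 5 : -128 * 5].any()
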