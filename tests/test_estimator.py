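import numpy as np
import pytest

from mapdyn.dynamics import link_kinematics
from mapdyn.estimator import (DLayout, KinematicStreams, MeasurementChannel,
                              PriorConfig, build_dynamics_system,
                              build_measurement_system, channel_slices,
                              channel_variances, extract_torques, map_solve,
                              proper_body_from_sensor, proper_sensor_from_body,
                              run_estimation)
from mapdyn.model import SystemState
from mapdyn.spatial import GRAVITY, SpatialTransform
from mapdyn.synthetic import (TrajectorySpec, default_channels,
                              generate_measurements, make_biped_model,
                              make_chain_model, simulate_trajectory)

from conftest import random_rotation

TIGHT = PriorConfig(sigma_D=1e-10, sigma_d=1e4)


class TestLayout:
    def test_size_and_bijection(self, biped):
        layout = DLayout(biped)
        NB, n = biped.n_links, biped.n_joints
        assert layout.size == 12 * NB + 7 * n
        rng = np.random.default_rng(0)
        alpha = rng.normal(size=(NB, 6))
        ext = rng.normal(size=(NB, 6))
        jw = rng.normal(size=(n, 6))
        sdd = rng.normal(size=n)
        d = layout.pack(alpha, ext, jw, sdd)
        out = layout.unpack(d)
        assert np.allclose(out["alpha_g"], alpha)
        assert np.allclose(out["ext_wrench"], ext)
        assert np.allclose(out["joint_wrench"], jw)
        assert np.allclose(out["s_ddot"], sdd)

    def test_slices_cover_d_exactly_once(self, biped):
        layout = DLayout(biped)
        hits = np.zeros(layout.size, dtype=int)
        for i in range(biped.n_links):
            hits[layout.alpha(i)] += 1
            hits[layout.ext_wrench(i)] += 1
        for j in range(1, biped.n_joints + 1):
            hits[layout.joint_wrench(j)] += 1
            hits[layout.s_ddot(j)] += 1
        assert (hits == 1).all()


class TestAccelerationConversions:
    def test_zero_velocity_is_identity(self, rng):
        alpha = rng.normal(size=6)
        assert np.allclose(proper_body_from_sensor(alpha, np.zeros(6)),
                           alpha)

    def test_round_trip(self, rng):
        alpha = rng.normal(size=6)
        v = rng.normal(size=6)
        back = proper_sensor_from_body(proper_body_from_sensor(alpha, v), v)
        assert np.allclose(back, alpha, atol=1e-12)

    def test_static_link_reads_gravity(self, rng):
        """A static link's proper sensor acceleration is the gravity
        offset rotated into the link frame: linear norm 9.81."""
        R = random_rotation(rng)
        a_g = -np.concatenate([R.T @ GRAVITY, np.zeros(3)])
        alpha = proper_sensor_from_body(a_g, np.zeros(6))
        assert np.isclose(np.linalg.norm(alpha[:3]), 9.81)
        assert np.allclose(alpha[3:], 0)


class TestDynamicsSystem:
    def test_shape_and_base_row_structure(self, biped):
        layout = DLayout(biped)
        state = SystemState(np.zeros(3), np.eye(3),
                            np.zeros(biped.n_joints),
                            base_acceleration=np.zeros(6),
                            s_ddot=np.zeros(biped.n_joints))
        D, b = build_dynamics_system(biped, state)
        assert D.shape == (12 * biped.n_links, layout.size)
        assert b.shape == (12 * biped.n_links,)
        Dd = D.toarray()
        # base acceleration rows touch only the base alpha slice
        base_rows = Dd[0:6]
        mask = np.ones(layout.size, dtype=bool)
        mask[layout.alpha(0)] = False
        assert np.allclose(base_rows[:, mask], 0)
        assert np.allclose(base_rows[:, layout.alpha(0)], -np.eye(6))

    def test_ground_truth_lies_in_nullspace(self, gait_gt, biped):
        """D d_true + b_D = 0 at every sample of a simulated trial."""
        worst = 0.0
        for t in range(len(gait_gt)):
            D, b = build_dynamics_system(biped, gait_gt.states[t])
            worst = max(worst, np.abs(D @ gait_gt.d[t] + b).max())
        assert worst < 1e-8

    def test_quasi_static_base_row_without_acceleration(self, biped):
        """Without base acceleration information the base rows pin alpha_B
        to the velocity-product term alone."""
        state = SystemState(np.zeros(3), np.eye(3),
                            np.zeros(biped.n_joints))
        D, b = build_dynamics_system(biped, state)
        assert np.allclose(b[0:6], 0)   # zero velocity: pure quasi-static


class TestMeasurementSystem:
    def test_origin_mounted_imu_selects_alpha(self, biped):
        layout = DLayout(biped)
        state = SystemState(np.zeros(3), np.eye(3),
                            np.zeros(biped.n_joints))
        ch = [MeasurementChannel("imu", "pelvis")]
        Y, b = build_measurement_system(biped, ch, state)
        Yd = Y.toarray()
        assert np.allclose(Yd[:, layout.alpha(0)],
                           np.hstack([np.eye(3), np.zeros((3, 3))]))
        assert np.allclose(b, 0)

    def test_coincident_ft_is_identity_block(self, biped):
        layout = DLayout(biped)
        state = SystemState(np.zeros(3), np.eye(3),
                            np.zeros(biped.n_joints))
        link = biped.link_index("shank_r")
        ch = [MeasurementChannel("ft", "shank_r")]
        Y, _ = build_measurement_system(biped, ch, state)
        assert np.allclose(Y.toarray()[:, layout.ext_wrench(link)],
                           np.eye(6))

    def test_noiseless_measurements_are_reproduced(self, gait_gt, biped,
                                                   gait_channels,
                                                   gait_measurements):
        worst = 0.0
        for t in range(0, len(gait_gt), 5):
            Y, b = build_measurement_system(biped, gait_channels,
                                            gait_gt.states[t])
            worst = max(worst,
                        np.abs(Y @ gait_gt.d[t] + b
                               - gait_measurements[t]).max())
        assert worst < 1e-10

    def test_offset_imu_consistency(self, biped, gait_gt):
        """An IMU mounted away from the link origin still reproduces the
        rigid-body-transported ground-truth reading."""
        mount = SpatialTransform(
            random_rotation(np.random.default_rng(5)), [0.03, -0.01, 0.08])
        ch = [MeasurementChannel("imu", "thigh_r", mount=mount)]
        t = len(gait_gt) // 2
        Y, b = build_measurement_system(biped, ch, gait_gt.states[t])
        y = Y @ gait_gt.d[t] + b
        # independent forward computation from link kinematics
        kin = gait_gt.kinematics[t]
        link = biped.link_index("thigh_r")
        pose_S = kin.poses[link].compose(mount)
        # classical acceleration of the sensor point, world frame
        from mapdyn.dynamics import body_accel_to_mixed
        a_g = kin.a_g[link]
        v = kin.v[link]
        R_L = kin.poses[link].rotation
        a_mixed = body_accel_to_mixed(
            R_L, v, a_g + np.concatenate([R_L.T @ GRAVITY, np.zeros(3)]))
        omega_w = R_L @ v[3:]
        r = R_L @ mount.origin
        o_ddot_S = (a_mixed[:3] + np.cross(a_mixed[3:], r)
                    + np.cross(omega_w, np.cross(omega_w, r)))
        expected = pose_S.rotation.T @ (o_ddot_S - GRAVITY)
        assert np.allclose(y, expected, atol=1e-9)

    def test_unknown_target_rejected(self, biped):
        state = SystemState(np.zeros(3), np.eye(3),
                            np.zeros(biped.n_joints))
        with pytest.raises(Exception):
            build_measurement_system(
                biped, [MeasurementChannel("imu", "nope")], state)


class TestMapSolve:
    def test_recovers_truth_from_noiseless_data(self, gait_gt, biped,
                                                gait_channels,
                                                gait_measurements):
        t = len(gait_gt) // 3
        D, bD = build_dynamics_system(biped, gait_gt.states[t])
        Y, bY = build_measurement_system(biped, gait_channels,
                                         gait_gt.states[t])
        est = map_solve(Y, bY, gait_measurements[t], 1e-10, D, bD, TIGHT)
        scale = np.maximum(np.abs(gait_gt.d[t]), 1.0)
        assert (np.abs(est.mean - gait_gt.d[t]) / scale).max() < 1e-6

    def test_no_sensor_trust_reverts_to_dynamics_prior_solution(
            self, gait_gt, biped, gait_channels, gait_measurements, rng):
        """With huge sensor variance the posterior equals the
        dynamics-plus-prior solution, cross-checked by a dense weighted
        least-squares solve built independently."""
        t = 10
        D, bD = build_dynamics_system(biped, gait_gt.states[t])
        Y, bY = build_measurement_system(biped, gait_channels,
                                         gait_gt.states[t])
        prior = PriorConfig(sigma_D=1e-6, sigma_d=1e2)
        est = map_solve(Y, bY, gait_measurements[t], 1e12, D, bD, prior)
        Dd = D.toarray()
        A = np.vstack([Dd / np.sqrt(1e-6), np.eye(Dd.shape[1])
                       / np.sqrt(1e2)])
        rhs = np.concatenate([-bD / np.sqrt(1e-6),
                              np.zeros(Dd.shape[1])])
        direct, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        assert np.abs(est.mean - direct).max() < 1e-6

    def test_posterior_is_exact_weighted_lsq_minimizer(self, gait_gt, biped,
                                                       gait_channels,
                                                       gait_measurements):
        """Brute-force dense solve of the full stacked weighted problem
        agrees with map_solve to 1e-10."""
        t = 25
        D, bD = build_dynamics_system(biped, gait_gt.states[t])
        Y, bY = build_measurement_system(biped, gait_channels,
                                         gait_gt.states[t])
        sy = channel_variances(gait_channels)
        prior = PriorConfig(sigma_D=1e-5, sigma_d=1e3)
        est = map_solve(Y, bY, gait_measurements[t], sy, D, bD, prior)
        Dd, Yd = D.toarray(), Y.toarray()
        nd = Dd.shape[1]
        A = np.vstack([Yd / np.sqrt(sy)[:, None],
                       Dd / np.sqrt(1e-5),
                       np.eye(nd) / np.sqrt(1e3)])
        rhs = np.concatenate([(gait_measurements[t] - bY) / np.sqrt(sy),
                              -bD / np.sqrt(1e-5), np.zeros(nd)])
        direct, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        assert np.abs(est.mean - direct).max() < 1e-10

    def test_posterior_covariance_spd_and_contracting(self, gait_gt, biped,
                                                      gait_channels,
                                                      gait_measurements):
        t = 5
        D, bD = build_dynamics_system(biped, gait_gt.states[t])
        Y, bY = build_measurement_system(biped, gait_channels,
                                         gait_gt.states[t])
        sy = channel_variances(gait_channels)
        prior = PriorConfig(sigma_D=1e-4, sigma_d=1e2)
        est = map_solve(Y, bY, gait_measurements[t], sy, D, bD, prior)
        Sigma = est.covariance
        assert np.allclose(Sigma, Sigma.T, atol=1e-10)
        eig = np.linalg.eigvalsh(Sigma)
        assert eig.min() > 0
        # conditioning contracts the variance of every entry below prior
        assert np.diag(Sigma).max() < 1e2

    def test_measurement_trust_monotonicity(self, gait_gt, biped,
                                            gait_channels):
        """Halving a channel's variance reduces that channel's posterior
        residual on noisy data."""
        y = generate_measurements(gait_gt, gait_channels, noise_std=0.05,
                                  seed=99)
        slices = channel_slices(gait_channels)
        target = "imu:thigh_r"
        t = 20
        D, bD = build_dynamics_system(biped, gait_gt.states[t])
        Y, bY = build_measurement_system(biped, gait_channels,
                                         gait_gt.states[t])
        prior = PriorConfig(sigma_D=1e-6, sigma_d=1e4)

        def residual(scale):
            sy = channel_variances(gait_channels).copy()
            sy[slices[target]] *= scale
            est = map_solve(Y, bY, y[t], sy, D, bD, prior)
            r = Y @ est.mean + bY - y[t]
            return np.linalg.norm(r[slices[target]])

        assert residual(0.5) < residual(1.0)

    def test_dimension_mismatch_rejected(self, biped, gait_gt):
        t = 0
        D, bD = build_dynamics_system(biped, gait_gt.states[t])
        with pytest.raises(ValueError):
            map_solve(D[:, :-1], bD, bD, 1e-4, D, bD, PriorConfig())


class TestTorqueExtraction:
    def test_axis_projection(self, biped):
        layout = DLayout(biped)
        mean = np.zeros(layout.size)
        # hip_r is joint 1 or 2 depending on BFS order; find it
        jidx = next(i for i in range(1, biped.n_links)
                    if biped.joint_of(i).name == "hip_r")
        sl = layout.joint_wrench(jidx)
        mean[sl.start + 4] = 5.0      # moment about y, the hip axis
        est_cov = np.eye(layout.size)
        est = type("E", (), {})()
        from mapdyn.estimator import GaussianEstimate
        est = GaussianEstimate(mean, lambda B: est_cov @ B)
        tau, var = extract_torques(est, biped)
        assert tau[jidx - 1] == pytest.approx(5.0)
        assert (var >= 0).all()
        assert var[jidx - 1] == pytest.approx(1.0)   # S' I S = |axis|^2

    def test_full_pipeline_matches_oracle(self, gait_gt, biped,
                                          gait_channels, gait_measurements):
        t = 30
        D, bD = build_dynamics_system(biped, gait_gt.states[t])
        Y, bY = build_measurement_system(biped, gait_channels,
                                         gait_gt.states[t])
        est = map_solve(Y, bY, gait_measurements[t], 1e-10, D, bD, TIGHT)
        tau, var = extract_torques(est, biped)
        assert np.abs(tau - gait_gt.tau[t]).max() < 1e-6
        assert (var > 0).all()


class TestPermutationInvariance:
    def test_link_numbering_does_not_change_torques(self):
        """Re-declaring the same tree with legs in the opposite order
        permutes d but leaves named joint torques unchanged."""
        from mapdyn.model import MultiBodyModel

        m1 = make_biped_model()
        # same physical model, link declaration order reversed
        m2 = MultiBodyModel(list(reversed(m1.links)), list(m1.joints),
                            frames={name: (m1.links[i].name, T)
                                    for name, (i, T) in m1.frames.items()})
        spec1 = TrajectorySpec(m1, schedule=[("right", 0.3)], seed=4)
        spec2 = TrajectorySpec(
            m2, schedule=[("right", 0.3)], seed=4,
            amplitude=_by_joint(m1, m2, spec1.amplitude),
            frequency=_by_joint(m1, m2, spec1.frequency),
            phase=_by_joint(m1, m2, spec1.phase),
            offset=_by_joint(m1, m2, spec1.offset))
        gt1 = simulate_trajectory(spec1)
        gt2 = simulate_trajectory(spec2)
        t = 7
        tau1 = {j.name: gt1.tau[t][k] for k, j in enumerate(m1.joints)}
        tau2 = {j.name: gt2.tau[t][k] for k, j in enumerate(m2.joints)}
        for name in tau1:
            assert tau1[name] == pytest.approx(tau2[name], abs=1e-9)
        # and through the estimator
        for model, gt in ((m1, gt1), (m2, gt2)):
            ch = default_channels(model, ["RF", "LF"])
            y = generate_measurements(gt, ch, 0.0)
            D, bD = build_dynamics_system(model, gt.states[t])
            Y, bY = build_measurement_system(model, ch, gt.states[t])
            est = map_solve(Y, bY, y[t], 1e-10, D, bD, TIGHT)
            tau, _ = extract_torques(est, model)
            ref = {j.name: gt.tau[t][k] for k, j in enumerate(model.joints)}
            for k, j in enumerate(model.joints):
                assert tau[k] == pytest.approx(ref[j.name], abs=1e-6)


def _by_joint(m_src, m_dst, values):
    by_name = {j.name: values[k] for k, j in enumerate(m_src.joints)}
    return np.array([by_name[j.name] for j in m_dst.joints])


class TestRunEstimation:
    def test_single_sample_equals_manual_stages(self, gait_gt, biped,
                                                gait_channels,
                                                gait_measurements):
        t = 12
        st = gait_gt.states[t]
        streams = KinematicStreams(
            gait_gt.times[t:t + 1], gait_gt.s[t:t + 1],
            gait_gt.s_dot[t:t + 1],
            np.array([st.base_position]), np.array([st.base_rotation]),
            base_velocity=np.array([st.base_velocity]),
            base_acceleration=np.array([st.base_acceleration]))
        from mapdyn.contact import ContactSet
        contacts = ContactSet(gait_gt.contacts.labels[t:t + 1])
        run = run_estimation(biped, streams, gait_measurements[t:t + 1],
                             gait_channels, contacts, TIGHT)
        D, bD = build_dynamics_system(biped, st)
        Y, bY = build_measurement_system(biped, gait_channels, st)
        est = map_solve(Y, bY, gait_measurements[t],
                        channel_variances(gait_channels), D, bD, TIGHT)
        assert np.allclose(run.d_mean[0], est.mean, atol=1e-10)

    def test_contact_log_follows_labels(self, gait_gt, biped, gait_channels,
                                        gait_measurements):
        streams = KinematicStreams(
            gait_gt.times, gait_gt.s, gait_gt.s_dot,
            np.array([st.base_position for st in gait_gt.states]),
            np.array([st.base_rotation for st in gait_gt.states]))
        run = run_estimation(biped, streams, gait_measurements,
                             gait_channels, gait_gt.contacts)
        for t, label in enumerate(gait_gt.contacts.labels):
            expected = {"double": ["RF", "LF"], "right": ["RF"],
                        "left": ["LF"]}[label]
            assert run.contact_log[t] == expected

    def test_pipeline_base_velocity_matches_truth(self, gait_gt, biped,
                                                  gait_channels,
                                                  gait_measurements):
        streams = KinematicStreams(
            gait_gt.times, gait_gt.s, gait_gt.s_dot,
            np.array([st.base_position for st in gait_gt.states]),
            np.array([st.base_rotation for st in gait_gt.states]))
        run = run_estimation(biped, streams, gait_measurements,
                             gait_channels, gait_gt.contacts)
        truth = np.array([st.base_velocity for st in gait_gt.states])
        assert np.abs(run.base_velocity - truth).max() < 1e-8
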