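import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from digikit.acquisition import (
    TrackerConfig,
    compensate_head,
    detect_tracker_mismatch,
    endpoint_timeseries,
    sample_measurement,
)
from digikit.errors import InsufficientDataError, MissingTrackerError, UnknownDeviceError
from digikit.geometry import EndpointOffset, RigidTransform
from digikit.posestream import DeviceTrack, PoseStream
from digikit.simulator import generate_layout, simulate_session

from conftest import make_random_transform, small_scenario
from oracles import stability_by_hand


def _static_stream(rotation=None, translation=(0.0, 0.0, 0.0), n=100, rate=90.0):
    rot = np.eye(3) if rotation is None else rotation
    times = np.arange(n) / rate
    return PoseStream(
        tracks={
            "controller": DeviceTrack(
                times,
                np.broadcast_to(rot, (n, 3, 3)).copy(),
                np.broadcast_to(np.asarray(translation, float), (n, 3)).copy(),
            )
        }
    )


class TestEndpointTimeseries:
    def test_zero_offset_gives_origin_trajectory(self):
        stream = _static_stream(translation=(4.0, 5.0, 6.0))
        _, pts = endpoint_timeseries(stream, "controller", EndpointOffset(np.zeros(3)))
        np.testing.assert_allclose(pts, np.tile([4.0, 5.0, 6.0], (100, 1)))

    def test_27mm_stub_offset(self):
        # a 27-mm stylus stub along the device x axis
        stream = _static_stream()
        _, pts = endpoint_timeseries(
            stream, "controller", EndpointOffset([27.0, 0.0, 0.0])
        )
        np.testing.assert_allclose(pts, np.tile([27.0, 0.0, 0.0], (100, 1)))
        assert np.linalg.norm(pts[0]) == pytest.approx(27.0)

    def test_rotation_about_tip_keeps_endpoint_fixed(self):
        offset = np.array([27.0, 0.0, -5.0])
        tip = np.array([50.0, 60.0, 70.0])
        n, times = 50, np.arange(50) / 90.0
        rots = Rotation.from_rotvec(
            np.outer(np.linspace(0, 1.2, n), [0.3, 0.5, 0.8])
        ).as_matrix()
        trans = tip - np.einsum("nij,j->ni", rots, offset)
        stream = PoseStream(tracks={"controller": DeviceTrack(times, rots, trans)})
        _, pts = endpoint_timeseries(stream, "controller", EndpointOffset(offset))
        assert np.linalg.norm(pts - tip, axis=1).max() < 1e-9
        # while the device origin itself sweeps a wide arc
        assert np.linalg.norm(trans - trans.mean(axis=0), axis=1).max() > 1.0

    def test_unknown_device(self):
        with pytest.raises(UnknownDeviceError):
            endpoint_timeseries(_static_stream(), "ghost", EndpointOffset(np.zeros(3)))


class TestSampleMeasurement:
    def test_constant_series_valid_zero_stability(self):
        times = np.arange(100) / 90.0
        pts = np.tile([1.0, 2.0, 3.0], (100, 1))
        m = sample_measurement(times, pts, times[-1])
        assert m.valid
        assert m.stability_mm == 0.0
        np.testing.assert_allclose(m.position, [1.0, 2.0, 3.0])

    def test_step_before_trigger_invalid(self):
        # 5-mm step 0.3 s before the trigger: the windowed-mean stability
        # must flag it (>= 2.5 mm) and match an independent recomputation
        rate, t_trig = 100.0, 2.0
        times = np.arange(int(rate * 2) + 1) / rate
        pts = np.where(times[:, None] < t_trig - 0.3, 0.0, 5.0) * np.array([1.0, 0, 0])
        m = sample_measurement(times, pts, t_trig)
        pos_oracle, stab_oracle = stability_by_hand(times, pts, t_trig, 1.0, 0.5)
        assert not m.valid
        assert m.stability_mm >= 2.5
        assert m.stability_mm == pytest.approx(stab_oracle, abs=1e-12)
        np.testing.assert_allclose(m.position, pos_oracle, atol=1e-12)

    def test_bounded_jitter_valid(self):
        rng = np.random.default_rng(0)
        times = np.arange(200) / 90.0
        jitter = rng.uniform(-1, 1, (200, 3))
        jitter *= 0.4 / np.linalg.norm(jitter, axis=1, keepdims=True)
        jitter -= jitter.mean(axis=0)
        m = sample_measurement(times, jitter, times[-1])
        assert m.valid
        assert m.stability_mm <= 1.0

    def test_insufficient_samples(self):
        times = np.array([0.0, 1.0, 2.0])  # only one sample in any 1-s window
        pts = np.zeros((3, 3))
        with pytest.raises(InsufficientDataError):
            sample_measurement(times, pts, 2.0)

    def test_avg_window_must_not_exceed_stab_window(self):
        times = np.arange(100) / 90.0
        with pytest.raises(ValueError):
            sample_measurement(times, np.zeros((100, 3)), 1.0, avg_window=2.0)


class TestCompensateHead:
    def test_identity_tracker_equals_global(self):
        ident = RigidTransform.identity()
        per, combined = compensate_head(
            [1.0, 2.0, 3.0], {"t1": ident}, {"t1": ident}
        )
        np.testing.assert_allclose(per["t1"], [1.0, 2.0, 3.0])
        np.testing.assert_allclose(combined, [1.0, 2.0, 3.0])

    def test_head_translation_cancelled(self, rng):
        # fixed point on the head measured before/after a 10-mm head shift
        mount = make_random_transform(rng)
        head_point = np.array([10.0, 20.0, 30.0])
        shift = RigidTransform.from_translation([10.0, 0.0, 0.0])
        pose0, pose1 = mount, shift @ mount
        p0 = head_point
        p1 = shift.apply(head_point)
        per0, comb0 = compensate_head(p0, {"t": pose0}, {"t": pose0})
        per1, comb1 = compensate_head(p1, {"t": pose1}, {"t": pose0})
        np.testing.assert_allclose(per0["t"], per1["t"], atol=1e-9)
        np.testing.assert_allclose(comb0, comb1, atol=1e-9)
        assert np.linalg.norm(p1 - p0) == pytest.approx(10.0)

    def test_two_rigid_trackers_agree(self, rng):
        m1, m2 = make_random_transform(rng), make_random_transform(rng)
        head_motion = make_random_transform(rng)
        point0 = np.array([5.0, -10.0, 80.0])
        poses0 = {"t1": m1, "t2": m2}
        poses1 = {"t1": head_motion @ m1, "t2": head_motion @ m2}
        _, comb0 = compensate_head(point0, poses0, poses0)
        _, comb1 = compensate_head(head_motion.apply(point0), poses1, poses0)
        np.testing.assert_allclose(comb0, comb1, atol=1e-9)

    def test_missing_tracker(self):
        with pytest.raises(MissingTrackerError):
            compensate_head([0.0, 0.0, 0.0], {}, {})


class TestTrackerMismatch:
    def _stream(self, slip_mm=None, slip_time=15.0, seed=7):
        cfg = small_scenario(
            seed=seed, n_electrodes=8, n_trackers=2,
            tracker_slip_mm=slip_mm, tracker_slip_time_s=slip_time if slip_mm else None,
            head_motion=[
                {"t": 0.0, "translation_mm": [0, 0, 0]},
                {"t": 30.0, "translation_mm": [8, 3, -2], "rotvec_deg": [1, 0, 3]},
            ],
        )
        return simulate_session(generate_layout(cfg), cfg)

    def test_comoving_trackers_no_mismatch(self):
        report = detect_tracker_mismatch(
            self._stream(), TrackerConfig(("tracker1", "tracker2"))
        )
        assert report.applicable
        assert not report.mismatch
        assert report.max_magnitude_mm < 1e-6

    def test_5mm_slip_flagged(self):
        report = detect_tracker_mismatch(
            self._stream(slip_mm=(0.0, 5.0, 0.0)), TrackerConfig(("tracker1", "tracker2"))
        )
        assert report.mismatch
        assert report.first_time == pytest.approx(15.0, abs=0.1)
        assert report.magnitude_mm == pytest.approx(5.0, rel=0.2)

    def test_1mm_slip_below_threshold(self):
        report = detect_tracker_mismatch(
            self._stream(slip_mm=(0.0, 1.0, 0.0)), TrackerConfig(("tracker1", "tracker2"))
        )
        assert not report.mismatch
        assert report.max_magnitude_mm < 3.0

    def test_single_tracker_not_applicable(self):
        report = detect_tracker_mismatch(self._stream(), TrackerConfig(("tracker1",)))
        assert not report.applicable
        assert not report.mismatch

    def test_tracker_ids_must_be_distinct(self):
        with pytest.raises(ValueError):
            TrackerConfig(("a", "a"))
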