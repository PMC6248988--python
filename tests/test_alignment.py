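import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from digikit.alignment import (
    CorrespondenceSet,
    alignment_residual,
    evaluate_dataset,
    reference_selection,
    reject_electrodes,
    rigid_align,
    welch_ttest,
)
from digikit.errors import DegeneracyError, UnknownLabelError
from digikit.geometry import RigidTransform
from digikit.montage import Montage
from digikit.session import DigitizationSession, DigitizedPoint
from digikit.simulator import ScenarioConfig, generate_layout, truth_session

from conftest import make_random_transform
from oracles import brute_force_rigid_residual, moments_list, welch_by_hand

WELCH_T_EXACT = -1.224744871391589  # -sqrt(6)/2 for {1,2,3} vs {2,3,4}
WELCH_P_EXACT = 0.2878641347266906  # 1 - 15*sqrt(33)/121, df = 4


def _cloud(n, seed=0, scale=90.0):
    return np.random.default_rng(seed).uniform(-scale, scale, (n, 3))


def _pairs(test, ref):
    return CorrespondenceSet([f"p{i}" for i in range(len(test))], test, ref)


def _session_from_points(points: dict[str, np.ndarray], fiducials=None):
    s = DigitizationSession(montage=Montage(list(points), name="m"))
    for l, p in points.items():
        s.add_electrode(DigitizedPoint(l, "electrode", p))
    for name, p in (fiducials or {}).items():
        s.add_fiducial(name, p)
    return s


class TestRigidAlign:
    def test_identical_sets_identity(self):
        pts = _cloud(10)
        t = rigid_align(_pairs(pts, pts))
        assert t.isclose(RigidTransform.identity(), atol=1e-9)

    def test_recover_30deg_plus_translation(self):
        pts = _cloud(12, seed=1)
        rot = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        truth = RigidTransform(rot, np.array([5.0, 5.0, 0.0]))
        ref = truth.apply(pts)
        t = rigid_align(_pairs(pts, ref))
        np.testing.assert_allclose(t.rotation, rot, atol=1e-9)
        np.testing.assert_allclose(t.translation, [5.0, 5.0, 0.0], atol=1e-9)
        assert np.linalg.norm(t.apply(pts) - ref, axis=1).max() < 1e-9

    def test_residual_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for trial in range(3):
            pts = rng.uniform(-60, 60, (10, 3))
            truth = make_random_transform(rng)
            ref = truth.apply(pts) + rng.normal(0, 2.0, (10, 3))
            pairs = _pairs(pts, ref)
            fit = alignment_residual(pairs, rigid_align(pairs))
            oracle = brute_force_rigid_residual(pts, ref)
            assert abs(np.sqrt(fit / 10) - np.sqrt(oracle / 10)) < 1e-4

    def test_residual_not_worse_than_identity(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-60, 60, (8, 3))
        ref = pts + rng.normal(0, 3.0, (8, 3))
        pairs = _pairs(pts, ref)
        assert alignment_residual(pairs, rigid_align(pairs)) <= alignment_residual(
            pairs, RigidTransform.identity()
        ) + 1e-9

    def test_collinear_rejected(self):
        pts = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegeneracyError):
            rigid_align(_pairs(pts, pts))

    def test_reflection_handled_det_plus_one(self):
        # mirrored cloud would prefer a reflection; det must stay +1
        pts = _cloud(6, seed=4)
        ref = pts * np.array([-1.0, 1.0, 1.0])
        t = rigid_align(_pairs(pts, ref))
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_needs_three_pairs(self):
        pts = _cloud(2, seed=5)
        with pytest.raises(DegeneracyError):
            rigid_align(_pairs(pts, pts))


class TestEvaluateDataset:
    def _layout_sessions(self, seed=6):
        truth = generate_layout(ScenarioConfig(seed=seed))
        ref = truth_session(truth)
        test = truth_session(truth)
        return truth, test, ref

    def test_identical_sessions_zero_error(self):
        _, test, ref = self._layout_sessions()
        res = evaluate_dataset(test, ref, mode="electrodes")
        assert res.rmse < 1e-9
        assert res.max_error < 1e-9
        assert res.n_used == 128

    def test_exact_perturbation_bounds(self):
        rng = np.random.default_rng(7)
        truth, test, ref = self._layout_sessions()
        for pt in test.electrodes.values():
            d = rng.standard_normal(3)
            pt.position = pt.position + 2.0 * d / np.linalg.norm(d)
        res = evaluate_dataset(test, ref, mode="electrodes")
        assert res.rmse <= 2.0 + 1e-9
        assert res.max_error <= 4.0

    def test_transform_invariance(self, rng):
        _, test, ref = self._layout_sessions()
        base = evaluate_dataset(test, ref, mode="electrodes")
        t = make_random_transform(rng)
        for pt in test.electrodes.values():
            pt.position = t.apply(pt.position)
        for name, reps in test.fiducials.repeats.items():
            test.fiducials.repeats[name] = [t.apply(p) for p in reps]
        moved = evaluate_dataset(test, ref, mode="electrodes")
        assert moved.rmse == pytest.approx(base.rmse, abs=1e-9)
        for l, e in base.per_label_error.items():
            assert moved.per_label_error[l] == pytest.approx(e, abs=1e-9)

    def test_electrode_mode_beats_fiducial_mode(self):
        rng = np.random.default_rng(8)
        for trial in range(10):
            truth, test, ref = self._layout_sessions(seed=20 + trial)
            for pt in test.electrodes.values():
                pt.position = pt.position + rng.normal(0, 1.5, 3)
            for name in list(test.fiducials.repeats):
                test.fiducials.repeats[name] = [
                    p + rng.normal(0, 1.5, 3) for p in test.fiducials.repeats[name]
                ]
            by_el = evaluate_dataset(test, ref, mode="electrodes")
            by_fid = evaluate_dataset(test, ref, mode="fiducials")
            assert by_el.rmse <= by_fid.rmse + 1e-9

    def test_fiducial_mode_needs_three(self):
        _, test, ref = self._layout_sessions()
        test.fiducials.repeats.pop("nasion")
        with pytest.raises(DegeneracyError):
            evaluate_dataset(test, ref, mode="fiducials")


class TestRejectElectrodes:
    def test_reject_two_of_128(self):
        truth = generate_layout(ScenarioConfig(seed=9))
        s = truth_session(truth)
        reject_electrodes(s, ["A5", "C17"])
        assert s.n_rejected() == 2
        assert len(s.usable_electrodes()) == 126

    def test_reject_none_unchanged(self):
        truth = generate_layout(ScenarioConfig(seed=9))
        s = truth_session(truth)
        reject_electrodes(s, [])
        assert s.n_rejected() == 0
        assert len(s.usable_electrodes()) == 128

    def test_reject_fiducial_name_errors(self):
        truth = generate_layout(ScenarioConfig(seed=9))
        s = truth_session(truth)
        with pytest.raises(UnknownLabelError):
            reject_electrodes(s, ["nasion"])

    def test_rejected_excluded_from_errors(self):
        truth = generate_layout(ScenarioConfig(seed=10))
        test, ref = truth_session(truth), truth_session(truth)
        test.electrodes["B7"].position = test.electrodes["B7"].position + 50.0
        reject_electrodes(test, ["B7"])
        res = evaluate_dataset(test, ref, mode="electrodes")
        assert "B7" not in res.per_label_error
        assert res.rmse < 1e-9


class TestWelch:
    def test_identical_groups(self):
        res = welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_textbook_example_to_1e10(self):
        res = welch_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        t_hand, df_hand = welch_by_hand([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.t == pytest.approx(WELCH_T_EXACT, abs=1e-10)
        assert res.t == pytest.approx(t_hand, abs=1e-12)
        assert res.df == pytest.approx(4.0, abs=1e-10)
        assert res.df == pytest.approx(df_hand, abs=1e-12)
        assert res.p == pytest.approx(WELCH_P_EXACT, abs=1e-10)

    def test_matches_scipy_reference(self):
        from scipy import stats

        rng = np.random.default_rng(11)
        a, b = rng.normal(1.5, 0.4, 6), rng.normal(2.0, 0.7, 9)
        res = welch_ttest(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_phantom_summary_scale(self):
        # group moments 1.12 +/- 0.15 vs 2.30 +/- 0.16 (n=5 each) must be
        # overwhelmingly separated
        a = moments_list(1.12, 0.15, 5)
        b = moments_list(2.30, 0.16, 5)
        assert np.mean(a) == pytest.approx(1.12) and np.std(a, ddof=1) == pytest.approx(0.15)
        res = welch_ttest(a, b)
        assert res.p < 0.001

    def test_zero_variance_convention(self):
        res = welch_ttest([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.degenerate
        assert res.t == 0.0 and res.p == 1.0

    def test_too_small_groups(self):
        with pytest.raises(ValueError):
            welch_ttest([1.0], [1.0, 2.0])


class TestReferenceSelection:
    def _with_rejections(self, n_rej, seed=12):
        truth = generate_layout(ScenarioConfig(seed=seed))
        s = truth_session(truth)
        reject_electrodes(s, list(truth.electrodes)[:n_rej])
        return s

    def test_default_first(self):
        sessions = [self._with_rejections(0), self._with_rejections(0)]
        assert reference_selection(sessions) == 0

    def test_fewer_rejections_wins(self):
        sessions = [self._with_rejections(2), self._with_rejections(0)]
        assert reference_selection(sessions) == 1

    def test_single_candidate(self):
        assert reference_selection([self._with_rejections(1)]) == 0

    def test_empty_list(self):
        with pytest.raises(ValueError):
            reference_selection([])
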