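"""Axial deviation angles, robust summaries, histograms and profiles."""
import numpy as np
import numpy.testing as npt
import pytest

from myolam import frame as frame_mod
from myolam import stats, stensor, synthetic
from myolam.core import EigenField, ValidityError
from myolam.stats import (
    angle_pair_difference,
    axial_angle,
    axial_circular_mean,
    eigen_confidence_distribution,
    quadrant_rose,
    summarize,
    transmural_profile,
)


class TestAxialAngle:
    def test_identical_and_orthogonal(self):
        a = np.array([1.0, 0, 0])
        assert axial_angle(a, a) == pytest.approx(0.0)
        assert axial_angle(a, [0.0, 1, 0]) == pytest.approx(90.0)

    def test_45_degrees_and_sign_invariance(self):
        a = np.array([1.0, 0, 0])
        b = np.array([1.0, 1, 0]) / np.sqrt(2)
        assert axial_angle(a, b) == pytest.approx(45.0)
        assert axial_angle(a, -b) == pytest.approx(45.0)
        assert axial_angle(-a, b) == pytest.approx(45.0)

    def test_symmetric_and_in_range(self, rng):
        a = rng.normal(size=(200, 3))
        b = rng.normal(size=(200, 3))
        a /= np.linalg.norm(a, axis=1, keepdims=True)
        b /= np.linalg.norm(b, axis=1, keepdims=True)
        d1 = axial_angle(a, b)
        d2 = axial_angle(b, a)
        npt.assert_allclose(d1, d2, atol=1e-10)
        assert np.all((d1 >= 0) & (d1 <= 90))

    def test_zero_vector_flagged(self):
        assert np.isnan(axial_angle(np.zeros(3), np.array([1.0, 0, 0])))

    def test_global_rotation_median_equals_rotation_angle(self, rng):
        """A field rotated by θ about a shared axis deviates by exactly θ."""
        from scipy.spatial.transform import Rotation

        v = rng.normal(size=(500, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        # rotate about each vector's own perpendicular so every deviation is θ
        for theta in (10.0, 30.0):
            devs = []
            for vec in v[:100]:
                perp = np.cross(vec, [0.0, 0.0, 1.0])
                if np.linalg.norm(perp) < 1e-6:
                    perp = np.cross(vec, [0.0, 1.0, 0.0])
                perp /= np.linalg.norm(perp)
                R = Rotation.from_rotvec(np.deg2rad(theta) * perp)
                devs.append(axial_angle(vec, R.apply(vec)))
            assert np.median(devs) == pytest.approx(theta, abs=1e-6)


class TestAnglePairDifference:
    def test_equal_angles(self):
        assert angle_pair_difference(12.0, 12.0) == 0.0

    def test_wraps_at_period_180(self):
        assert angle_pair_difference(80.0, -80.0) == pytest.approx(20.0)

    def test_matches_brute_force_offset_minimization(self, rng):
        x = rng.uniform(-90, 90, size=500)
        y = rng.uniform(-90, 90, size=500)
        d = angle_pair_difference(x, y)
        oracle = np.min(np.abs(x[:, None] - y[:, None] + 180.0 * np.array([-1, 0, 1])),
                        axis=1)
        npt.assert_allclose(d, oracle, atol=1e-12)
        assert np.all((d >= 0) & (d <= 90))


class TestSummarize:
    def test_constant_values(self):
        s = summarize([5.0, 5.0, 5.0])
        assert s["median"] == 5.0 and s["mad"] == 0.0 and s["iqr"] == 0.0

    def test_hand_computable_with_outlier(self):
        s = summarize([1, 2, 3, 4, 100])
        assert s["median"] == 3.0
        assert s["mad"] == 1.0

    def test_matches_sorting_oracle(self, rng):
        v = rng.integers(0, 90, size=201).astype(float)
        s = summarize(v)
        srt = np.sort(v)
        med = srt[100]  # odd length
        assert s["median"] == med
        assert s["mad"] == np.sort(np.abs(v - med))[100]
        q1 = np.quantile(srt, 0.25)
        q3 = np.quantile(srt, 0.75)
        assert s["iqr"] == pytest.approx(q3 - q1, abs=1e-12)
        assert s["mean"] == pytest.approx(v.mean())
        assert s["sd"] == pytest.approx(v.std(ddof=1))

    def test_empty_flagged(self):
        s = summarize([])
        assert s["empty"] and np.isnan(s["median"])


class TestQuadrantRose:
    def test_all_zero_mass_in_first_bin(self):
        h = quadrant_rose(np.zeros(10), n_bins=9)
        assert h["count"].iloc[0] == 10
        assert h["count"].sum() == 10

    def test_counts_conserved_and_match_binning_oracle(self, rng):
        v = rng.uniform(0, 90, size=300)
        n_bins = 9
        h = quadrant_rose(v, n_bins=n_bins)
        assert h["count"].sum() == 300
        oracle = np.minimum((v / 10.0).astype(int), n_bins - 1)
        expected = np.bincount(oracle, minlength=n_bins)
        npt.assert_array_equal(h["count"].to_numpy(), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidityError):
            quadrant_rose(np.array([91.0]))

    def test_boundary_90_counted(self):
        h = quadrant_rose(np.array([90.0]), n_bins=9)
        assert h["count"].iloc[-1] == 1


class TestTransmuralProfile:
    def test_constant_field_flat_profile(self):
        prof = transmural_profile(np.full(100, 33.0), np.linspace(0, 1, 100),
                                  n_bins=5)
        npt.assert_allclose(prof["mean"], 33.0, atol=1e-10)
        npt.assert_allclose(prof["sd"], 0.0, atol=1e-8)

    def test_annulus_profile_recovers_generative_rule(self, annulus_phantom):
        """The ±60° linear helix rule is recovered to <2° per depth bin."""
        spec, vol, truth = annulus_phantom
        nx, ny, _ = spec.shape
        centre = np.array([(nx - 1) / 2, (ny - 1) / 2, 0.0]) * spec.spacing
        fr = frame_mod.build_frame(spec.shape, spec.spacing, centre, (0, 0, 1.0))
        alpha = frame_mod.helix_angle(truth.m, fr)
        inside = truth.inside
        prof = transmural_profile(alpha[inside], truth.depth[inside], n_bins=10)
        expected = synthetic.helix_angle_rule(spec, prof["depth_mid"].to_numpy())
        assert not prof["empty"].any()
        npt.assert_allclose(prof["mean"].to_numpy(), expected, atol=2.0)
        # endo-to-epi span ~120 degrees
        span = abs(prof["mean"].iloc[0] - prof["mean"].iloc[-1])
        assert span == pytest.approx(120.0, abs=15.0)

    def test_circular_mean_handles_wraparound(self):
        # angles straddling the +-90 fold average to the fold, not to 0
        assert abs(axial_circular_mean(np.array([85.0, -85.0]))) == pytest.approx(90.0)

    def test_empty_bins_flagged(self):
        prof = transmural_profile(np.array([10.0]), np.array([0.05]), n_bins=4)
        assert prof["empty"].iloc[1]


class TestAxialProperties:
    """Hypothesis-driven invariants of the axial angle algebra."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    angles = st.floats(min_value=-90.0, max_value=90.0, allow_nan=False)

    @given(x=angles, y=angles)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_pair_difference_symmetric_bounded(self, x, y):
        d = angle_pair_difference(x, y)
        assert 0.0 <= d <= 90.0
        assert d == pytest.approx(angle_pair_difference(y, x), abs=1e-9)

    @given(a=st.floats(min_value=-720, max_value=720, allow_nan=False))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_folding_is_idempotent_and_periodic(self, a):
        from myolam.frame import fold_axial_degrees

        f = fold_axial_degrees(a)
        assert -90.0 < f <= 90.0
        assert fold_axial_degrees(f) == pytest.approx(f, abs=1e-9)
        assert fold_axial_degrees(a + 180.0) == pytest.approx(f, abs=1e-9)


class TestEigenConfidence:
    def _field(self, eigvals):
        w = np.broadcast_to(np.asarray(eigvals, dtype=float), (4, 4, 4, 3)).copy()
        v = np.broadcast_to(np.eye(3), (4, 4, 4, 3, 3)).copy()
        return EigenField(eigvals=w, eigvecs=v, spacing=200.0)

    def test_identical_eigenvalues_no_confidence(self):
        out = eigen_confidence_distribution(self._field([1.0, 1.0, 1.0]),
                                            "dti", "laminar")
        npt.assert_allclose(out["ratio"], 100.0)
        assert out["fraction_at_least"][85.0] == 1.0

    def test_constructed_ratio_50_percent(self):
        out = eigen_confidence_distribution(self._field([2.0, 1.0, 0.5]),
                                            "dti", "laminar")
        npt.assert_allclose(out["ratio"], 50.0)

    def test_st_laminar_pair_uses_top_two(self):
        out = eigen_confidence_distribution(self._field([2.0, 1.0, 0.5]),
                                            "st", "laminar")
        npt.assert_allclose(out["ratio"], 50.0)
        out_m = eigen_confidence_distribution(self._field([2.0, 1.0, 0.5]),
                                              "st", "myocyte")
        npt.assert_allclose(out_m["ratio"], 50.0)

    def test_summary_matches_division_oracle(self, rng):
        lam = np.sort(rng.uniform(0.5, 2.0, size=(4, 4, 4, 3)), axis=-1)[..., ::-1]
        field = EigenField(eigvals=lam, eigvecs=np.broadcast_to(
            np.eye(3), (4, 4, 4, 3, 3)).copy(), spacing=200.0)
        out = eigen_confidence_distribution(field, "dti", "laminar")
        oracle = 100.0 * lam[..., 2] / lam[..., 1]
        npt.assert_allclose(out["ratio"], oracle, rtol=1e-12)
        assert out["summary"]["median"] == pytest.approx(np.median(oracle))

    def test_unknown_pair_rejected(self):
        with pytest.raises(ValidityError):
            eigen_confidence_distribution(self._field([1, 1, 1]), "st", "nope")
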