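"""Re-referencing, flat-channel detection, and the two interpolators."""

import numpy as np
import pytest

import erpbench as eb
from erpbench.spatial import (
    InterpolationModel,
    detect_flat_channels,
    inverse_distance_interpolate,
    rereference_linked_mastoids,
    spherical_spline_interpolate,
)
from erpbench.montage import Montage


@pytest.fixture()
def recording(montage, rng):
    data = rng.standard_normal((montage.n_channels, 400)) * 10
    return eb.Recording(data=data, fs=500.0, events=[], montage=montage)


class TestRereference:
    def test_definition_arithmetic(self, montage):
        data = np.zeros((montage.n_channels, 1))
        data[montage.index("Fz"), 0] = 5.0
        data[montage.index("TP9"), 0] = 2.0
        data[montage.index("TP10"), 0] = 4.0
        rec = eb.Recording(data=data, fs=500.0, events=[], montage=montage)
        out = rereference_linked_mastoids(rec)
        assert out.data[montage.index("Fz"), 0] == pytest.approx(5.0 - 3.0)

    def test_common_signal_cancels(self, montage):
        data = np.tile(np.sin(np.arange(100) / 5.0), (montage.n_channels, 1))
        rec = eb.Recording(data=data, fs=500.0, events=[], montage=montage)
        out = rereference_linked_mastoids(rec)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_mastoid_mean_zero_and_idempotent(self, recording):
        once = rereference_linked_mastoids(recording)
        m = recording.montage
        mast = 0.5 * (once.data[m.index("TP9")] + once.data[m.index("TP10")])
        np.testing.assert_allclose(mast, 0.0, atol=1e-12)
        twice = rereference_linked_mastoids(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)

    def test_missing_mastoid_raises(self, montage, rng):
        sub = montage.subset([n for n in montage.channel_names if n != "TP9"])
        rec = eb.Recording(
            data=rng.standard_normal((sub.n_channels, 10)), fs=500.0,
            events=[], montage=sub,
        )
        with pytest.raises(KeyError, match="TP9"):
            rereference_linked_mastoids(rec)


class TestFlatDetection:
    fs = 500.0

    def _rec(self, montage, data):
        return eb.Recording(data=data, fs=self.fs, events=[], montage=montage)

    def test_all_zero_channel_flagged(self, montage, rng):
        data = rng.standard_normal((montage.n_channels, int(8 * self.fs)))
        data[montage.index("Oz")] = 0.0
        assert detect_flat_channels(self._rec(montage, data)) == ["Oz"]

    def test_four_second_flat_not_flagged(self, montage, rng):
        n = int(10 * self.fs)
        data = rng.standard_normal((montage.n_channels, n))
        ch = montage.index("Cz")
        data[ch, : int(4 * self.fs)] = 1.5
        data[ch, int(4 * self.fs):] = np.sin(np.arange(n - int(4 * self.fs)))
        assert detect_flat_channels(self._rec(montage, data)) == []

    def test_six_second_flat_mid_recording_flagged(self, montage, rng):
        n = int(12 * self.fs)
        data = rng.standard_normal((montage.n_channels, n))
        ch = montage.index("P3")
        data[ch, int(2 * self.fs): int(8 * self.fs)] = -3.0
        assert detect_flat_channels(self._rec(montage, data)) == ["P3"]

    def test_duration_longer_than_recording_raises(self, montage):
        rec = self._rec(montage, np.zeros((montage.n_channels, 100)))
        with pytest.raises(ValueError):
            detect_flat_channels(rec, min_duration_s=5.0)


class TestSphericalSpline:
    def test_constant_field_reproduced(self, montage):
        data = np.full((montage.n_channels, 3), 4.2)
        out = spherical_spline_interpolate(montage, data, ["FCz"])
        assert abs(out[montage.index("FCz"), 0] - 4.2) < 1e-6

    def test_first_order_harmonic_oracle(self, montage):
        """Field = cos(polar angle) (the l=1, m=0 spherical harmonic up to
        scale): interpolation of a held-out channel lands within 2% of the
        analytic value."""
        field = montage.positions[:, 2]  # cos(theta) on the unit sphere
        errors = []
        for bad in ("FCz", "Cz", "CP1", "Fz"):
            data = field[:, None].copy()
            truth = field[montage.index(bad)]
            data[montage.index(bad)] = 99.0  # garbage; must be ignored
            out = spherical_spline_interpolate(montage, data, [bad])
            errors.append(abs(out[montage.index(bad), 0] - truth) / 1.0)
        assert max(errors) < 0.02

    def test_good_channels_untouched(self, montage, rng):
        data = rng.standard_normal((montage.n_channels, 5))
        out = spherical_spline_interpolate(montage, data, ["Oz"])
        good = [i for i in range(montage.n_channels) if i != montage.index("Oz")]
        np.testing.assert_array_equal(out[good], data[good])

    def test_midpoint_of_antisymmetric_field_is_zero(self):
        """Bad channel on the mirror plane of a symmetric montage, field odd
        under the mirror: the spline estimate must vanish (v = −v)."""
        az = np.deg2rad(np.arange(0, 360, 45))
        ring = np.stack([np.cos(az), np.sin(az), np.zeros_like(az)], axis=1)
        pole = np.array([[0.0, 0.0, 1.0]])
        pos = np.vstack([ring, pole])
        names = tuple(f"R{i}" for i in range(8)) + ("TOP",)
        mont = Montage(names, pos)
        field = ring[:, 1]  # odd under the reflection y -> -y fixing TOP
        data = np.concatenate([field, [99.0]])[:, None]
        out = spherical_spline_interpolate(mont, data, ["TOP"])
        assert abs(out[-1, 0]) < 1e-6

    def test_midpoint_invariant_under_mirror(self):
        """Bad channel on a mirror plane: interpolating the field and
        interpolating its mirror image give the same value."""
        ang = 0.35
        pos = {
            "MID": (1.0, 0.0, 0.0),
            "L": (np.cos(ang), np.sin(ang), 0.0),
            "R": (np.cos(ang), -np.sin(ang), 0.0),
            "FL": (np.cos(1.2), np.sin(1.2), 0.0),
            "FR": (np.cos(1.2), -np.sin(1.2), 0.0),
            "TOP": (np.cos(ang), 0.0, np.sin(ang)),
        }
        names = tuple(pos)
        mont = Montage(names, np.array([pos[n] for n in names]))
        vals = {"MID": 0.0, "L": 3.0, "R": -1.0, "FL": 2.0, "FR": 0.5, "TOP": 1.0}
        mirrored = {"MID": 0.0, "L": -1.0, "R": 3.0, "FL": 0.5, "FR": 2.0, "TOP": 1.0}
        a = spherical_spline_interpolate(
            mont, np.array([[vals[n]] for n in names]), ["MID"])
        b = spherical_spline_interpolate(
            mont, np.array([[mirrored[n]] for n in names]), ["MID"])
        assert a[0, 0] == pytest.approx(b[0, 0], abs=1e-9)

    def test_large_ridge_tends_to_constant_fit(self, montage, rng):
        data = rng.standard_normal((montage.n_channels, 1))
        model = InterpolationModel(ridge=1e6)
        out = spherical_spline_interpolate(montage, data, ["FCz"], model)
        good = [i for i in range(montage.n_channels) if i != montage.index("FCz")]
        assert out[montage.index("FCz"), 0] == pytest.approx(
            data[good, 0].mean(), rel=0.05
        )


class TestInverseDistance:
    def test_single_neighbor_copies_value(self):
        pos = np.array([[1.0, 0, 0], [np.cos(0.3), np.sin(0.3), 0],
                        [-1.0, 0, 0], [0, -1.0, 0]])
        mont = Montage(("A", "B", "C", "D"), pos)
        data = np.array([[0.0], [7.0], [1.0], [2.0]])
        out = inverse_distance_interpolate(mont, data, ["A"])
        assert out[0, 0] == pytest.approx(7.0)

    def test_equidistant_neighbors_average(self):
        pos = np.array([[1.0, 0, 0],
                        [np.cos(0.4), np.sin(0.4), 0],
                        [np.cos(0.4), -np.sin(0.4), 0],
                        [0, 0, 1.0]])
        mont = Montage(("X", "L", "R", "TOP"), pos)
        data = np.array([[0.0], [3.0], [5.0], [100.0]])
        out = inverse_distance_interpolate(mont, data, ["X"])
        assert out[0, 0] == pytest.approx(4.0)

    def test_half_distance_double_weight(self):
        a1, a2 = 0.2, 0.4
        pos = np.array([[1.0, 0, 0],
                        [np.cos(a1), np.sin(a1), 0],
                        [np.cos(a2), -np.sin(a2), 0],
                        [0, 0, 1.0]])
        mont = Montage(("X", "NEAR", "FAR", "TOP"), pos)
        data = np.array([[0.0], [3.0], [9.0], [0.0]])
        out = inverse_distance_interpolate(mont, data, ["X"])
        expected = (3.0 / a1 + 9.0 / a2) / (1 / a1 + 1 / a2)
        assert out[0, 0] == pytest.approx(expected, rel=1e-9)

    def test_no_neighbor_in_range_raises(self):
        pos = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0]])
        mont = Montage(("A", "B", "C", "D"), pos)
        data = np.zeros((4, 1))
        with pytest.raises(ValueError, match="A"):
            inverse_distance_interpolate(mont, data, ["A"])


@pytest.mark.parametrize("method", ["spherical_spline", "inverse_distance"])
def test_interpolators_are_linear_operators(montage, rng, method):
    from erpbench.spatial import interpolate

    model = InterpolationModel(method=method)
    x = rng.standard_normal((montage.n_channels, 4))
    y = rng.standard_normal((montage.n_channels, 4))
    a, b = 2.5, -1.25
    combined = interpolate(montage, a * x + b * y, ["FCz", "Oz"], model)
    separate = a * interpolate(montage, x, ["FCz", "Oz"], model) + b * interpolate(
        montage, y, ["FCz", "Oz"], model
    )
    np.testing.assert_allclose(combined, separate, rtol=1e-9, atol=1e-9)
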