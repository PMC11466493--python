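import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wedgecal import (
    SyntheticProfileParams,
    WedgeProfile,
    detect_edges,
    make_wedge_profile,
    read_profile,
    segment_slope,
    smooth_moving_mean,
    write_profile,
)
from wedgecal.profiles import (
    EdgeDetectionError,
    ProfileError,
    ProfileParseError,
    SegmentTooShortError,
)


class TestWedgeProfile:
    def test_validation(self):
        with pytest.raises(ProfileError, match="strictly increasing"):
            WedgeProfile(np.array([0, 2, 1] + list(range(3, 10))), np.ones(10))
        with pytest.raises(ProfileError, match="too short"):
            WedgeProfile(np.arange(5), np.ones(5))
        with pytest.raises(ProfileError, match="non-negative"):
            WedgeProfile(np.arange(10), -np.ones(10))
        with pytest.raises(ProfileError, match="length"):
            WedgeProfile(np.arange(10), np.ones(11))


class TestReadProfile:
    def test_two_column_csv(self, tmp_path):
        path = tmp_path / "p.csv"
        rows = "\n".join(f"{i},{i + 1}" for i in range(12))
        path.write_text(rows + "\n")
        prof = read_profile(path)
        assert np.array_equal(prof.positions, np.arange(12))
        assert np.array_equal(prof.values, np.arange(12) + 1)

    def test_metadata_header(self, tmp_path):
        path = tmp_path / "p.csv"
        rows = "\n".join(f"{i}\t{i}" for i in range(12))
        path.write_text("# depth=10\n# energy=6\n" + rows + "\n")
        prof = read_profile(path)
        assert prof.metadata["depth"] == 10
        assert prof.metadata["energy"] == 6

    def test_unsorted_positions_are_reordered(self, tmp_path):
        path = tmp_path / "p.csv"
        pos = list(range(12))[::-1]
        path.write_text("\n".join(f"{p} {p * 2}" for p in pos) + "\n")
        prof = read_profile(path)
        assert np.all(np.diff(prof.positions) > 0)
        assert np.array_equal(prof.values, prof.positions * 2)

    def test_round_trip(self, tmp_path, reference_profile):
        path = tmp_path / "rt.csv"
        write_profile(reference_profile, path)
        back = read_profile(path)
        assert np.array_equal(back.positions, reference_profile.positions)
        assert np.array_equal(back.values, reference_profile.values)
        assert back.metadata["target_drc"] == 0.454

    def test_parse_error_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("0,1\n1,2\nbad,row\n3,4\n")
        with pytest.raises(ProfileParseError, match=r"bad\.csv:3"):
            read_profile(path)

    def test_too_short_file(self, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text("0,1\n1,2\n2,3\n")
        with pytest.raises(ProfileParseError, match="at least 10"):
            read_profile(path)


class TestDetectEdges:
    def test_trapezoid_edges_at_ramp_midpoints(self, trapezoid_profile):
        left, right = detect_edges(trapezoid_profile)
        assert left == 15.0
        assert right == 85.0

    def test_fixture_field_width_recovered(self):
        params = SyntheticProfileParams(target_drc=0.454, field_width=100.0)
        left, right = detect_edges(make_wedge_profile(params))
        assert right - left == pytest.approx(100.0, abs=1.0)

    def test_reversed_positions_give_same_edges(self, reference_profile):
        flipped = WedgeProfile(
            -reference_profile.positions[::-1],
            reference_profile.values[::-1],
        )
        assert detect_edges(flipped) == detect_edges(reference_profile)

    def test_scaling_and_translation_invariance(self, reference_profile):
        base = detect_edges(reference_profile)
        scaled = WedgeProfile(
            reference_profile.positions, reference_profile.values * 7.3
        )
        assert detect_edges(scaled) == base
        shifted = WedgeProfile(
            reference_profile.positions + 11.0, reference_profile.values
        )
        left, right = detect_edges(shifted)
        assert (left - 11.0, right - 11.0) == base

    def test_monotone_profile_rejected(self):
        x = np.arange(30.0)
        with pytest.raises(EdgeDetectionError, match="manual windowing"):
            detect_edges(WedgeProfile(x, x + 1.0))

    def test_inverted_profile_same_edges(self, reference_profile):
        inverted = WedgeProfile(
            reference_profile.positions,
            reference_profile.values.max() - reference_profile.values + 0.1,
        )
        assert detect_edges(inverted) == detect_edges(reference_profile)


class TestSegmentSlope:
    def test_linear_ramp_closed_form(self, linear_ramp_profile):
        seg = segment_slope(linear_ramp_profile, 0.2, 0.8)
        assert seg.rd_max == pytest.approx(1.24, abs=1e-9)
        assert seg.rd_min == pytest.approx(0.76, abs=1e-9)
        assert seg.drc == pytest.approx(0.48, abs=1e-9)

    def test_wider_window_scales_drc(self, linear_ramp_profile):
        seg = segment_slope(linear_ramp_profile, 0.1, 0.9)
        assert seg.drc == pytest.approx(0.64, abs=1e-9)
        assert seg.drc > segment_slope(linear_ramp_profile, 0.2, 0.8).drc

    def test_constant_field_has_zero_drc(self, trapezoid_profile):
        seg = segment_slope(trapezoid_profile)
        assert seg.drc == pytest.approx(0.0, abs=1e-12)

    def test_cax_normalization_interpolates_to_one(self, linear_ramp_profile):
        seg = segment_slope(linear_ramp_profile)
        at_cax = np.interp(seg.cax_position, seg.positions, seg.relative_doses)
        assert at_cax == pytest.approx(1.0, abs=1e-9)

    def test_drc_is_rd_difference(self, reference_profile):
        seg = segment_slope(reference_profile)
        assert seg.drc == seg.rd_max - seg.rd_min

    def test_nonmonotonic_warning_and_sorting(self):
        params = SyntheticProfileParams(target_drc=0.454, noise_sd=0.05, seed=3)
        noisy = make_wedge_profile(params)
        seg = segment_slope(noisy)
        assert not seg.monotonic
        assert seg.warnings
        seg_sorted = segment_slope(noisy, sort_nonmonotonic=True)
        diffs = np.diff(seg_sorted.relative_doses)
        assert np.all(diffs >= 0) or np.all(diffs <= 0)
        assert seg_sorted.drc == seg.drc  # sorting preserves max - min

    def test_invalid_window_rejected(self, reference_profile):
        with pytest.raises(ValueError, match="f_low"):
            segment_slope(reference_profile, 0.8, 0.2)

    def test_too_few_retained_samples(self):
        params = SyntheticProfileParams(
            target_drc=0.454, sample_spacing=8.0, penumbra_sigma=4.0,
            field_width=100.0,
        )
        with pytest.raises(SegmentTooShortError):
            segment_slope(make_wedge_profile(params))

    def test_json_serialization(self, reference_profile):
        import json

        seg = segment_slope(reference_profile)
        data = json.loads(seg.to_json())
        assert data["drc"] == pytest.approx(0.454)
        assert len(data["positions"]) == len(data["relative_doses"])

    @pytest.mark.parametrize("target", [0.2, 0.45, 0.7, 0.9])
    def test_recovers_generator_drc_noise_free(self, target):
        prof = make_wedge_profile(SyntheticProfileParams(target_drc=target))
        seg = segment_slope(prof)
        assert seg.drc == pytest.approx(target, rel=5e-3)

    @pytest.mark.parametrize("noise,tol", [(0.005, 0.02), (0.02, 0.05)])
    @pytest.mark.parametrize("target", [0.2, 0.45, 0.7, 0.9])
    def test_recovers_generator_drc_under_noise(self, target, noise, tol):
        errors = []
        for seed in range(8):
            prof = make_wedge_profile(
                SyntheticProfileParams(
                    target_drc=target, noise_sd=noise, seed=seed
                )
            )
            seg = segment_slope(
                prof, smooth_window=25, sort_nonmonotonic=True
            )
            errors.append(abs(seg.drc - target) / target)
        assert np.mean(errors) < tol

    @given(
        f_low=st.floats(0.05, 0.4),
        width=st.floats(0.2, 0.55),
        target=st.floats(0.1, 1.2),
    )
    @settings(max_examples=25, deadline=None)
    def test_widening_window_never_decreases_drc(self, f_low, width, target):
        prof = make_wedge_profile(SyntheticProfileParams(target_drc=target))
        f_high = f_low + width
        inner = segment_slope(prof, f_low, f_high)
        outer = segment_slope(prof, f_low - 0.04, f_high + 0.04)
        assert outer.drc >= inner.drc - 1e-12


class TestSmoothMovingMean:
    def test_constant_invariance(self):
        out = smooth_moving_mean([1.0] * 5, 3)
        assert np.array_equal(out, np.ones(5))

    def test_shrinking_boundary_windows(self):
        out = smooth_moving_mean([0.0, 3.0, 0.0], 3)
        assert np.allclose(out, [1.5, 1.0, 1.5])

    def test_linear_interior_preserved(self):
        x = np.arange(20.0)
        out = smooth_moving_mean(x, 5)
        assert np.allclose(out[2:-2], x[2:-2])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth_moving_mean(np.ones(10), 4)

    def test_window_longer_than_input_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            smooth_moving_mean(np.ones(3), 5)

    @given(
        st.lists(st.floats(0.0, 100.0), min_size=5, max_size=40),
        st.sampled_from([1, 3, 5]),
    )
    @settings(max_examples=50, deadline=None)
    def test_length_preserved_and_bounded(self, values, window):
        out = smooth_moving_mean(values, window)
        assert out.size == len(values)
        assert out.min() >= min(values) - 1e-9
        assert out.max() <= max(values) + 1e-9
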