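"""Dot detection, channel reduction, alignment-averaging, line profiles."""

import numpy as np
import pytest

from metkit.dots import (
    NoDotFoundError,
    align_and_average,
    extract_second_channel,
    find_dot,
    line_profile,
)
from metkit.puncta import compare_groups
from metkit.synthetic import DotStackSpec, NucleusImageSpec, gen_dot_stack


def _small_base(seed=0, **kw):
    base = dict(
        image_size=64, nucleus_center=(32.0, 32.0), nucleus_radius=20.0,
        total_intensity=100_000.0, puncta_count=1, puncta_fraction=0.4,
        background_rate=1.0, read_noise_sd=0.5, seed=seed,
    )
    base.update(kw)
    return NucleusImageSpec(**base)


def _stack_spec(seed=0, offset=(0.0, 0.0), dot=(32.0, 32.0, 3), n_z=7):
    return DotStackSpec(
        n_z=n_z, dot_position=dot, gfp_puncta_offset=offset,
        base=_small_base(seed), seed=seed,
    )


class TestFindDot:
    def test_detects_synthetic_dot_within_one_pixel(self):
        for seed in range(5):
            mch, _, truth = gen_dot_stack(_stack_spec(seed=seed, dot=(40.0, 25.0, 4)))
            det = find_dot(mch)
            dr, dc, dz = truth["dot"]
            assert det.z_index == dz
            assert abs(det.y - dr) <= 1 and abs(det.x - dc) <= 1

    def test_uniform_stack_has_no_dot(self):
        with pytest.raises(NoDotFoundError):
            find_dot(np.ones((5, 32, 32)))

    def test_tie_break_lowest_z_then_row_col(self):
        stack = np.zeros((4, 16, 16))
        stack[1, 5, 5] = 10.0
        stack[3, 10, 10] = 10.0
        det = find_dot(stack, smoothing_sigma=0.5)
        assert (det.z_index, det.y, det.x) == (1, 5, 5)


class TestExtractSecondChannel:
    def test_single_plane_same_z_equals_mip(self):
        _, gfp, _ = gen_dot_stack(_stack_spec(n_z=1, dot=(32.0, 32.0, 0)))
        det = find_dot(gen_dot_stack(_stack_spec(n_z=1, dot=(32.0, 32.0, 0)))[0])
        np.testing.assert_array_equal(
            extract_second_channel(gfp, det, "same_z"),
            extract_second_channel(gfp, det, "mip"),
        )

    def test_dominant_plane_is_the_mip(self):
        stack = np.ones((4, 8, 8))
        stack[2] = 5.0
        from metkit.dots import DotDetection

        det = DotDetection(x=4, y=4, z_index=0, dot_intensity=1.0)
        np.testing.assert_array_equal(extract_second_channel(stack, det, "mip"), stack[2])

    def test_off_plane_punctum_visible_only_in_mip(self):
        """A GFP spot away from the dot's z shows in the MIP, not in same-z."""
        stack = np.zeros((6, 32, 32))
        stack[5, 16, 16] = 100.0  # punctum at z=5
        from metkit.dots import DotDetection

        det = DotDetection(x=16, y=16, z_index=1, dot_intensity=1.0)
        same_z = extract_second_channel(stack, det, "same_z")
        mip = extract_second_channel(stack, det, "mip")
        assert same_z[16, 16] == 0.0
        assert mip[16, 16] == 100.0

    def test_mip_dominates_same_z_pixelwise(self):
        _, gfp, _ = gen_dot_stack(_stack_spec(seed=2))
        det = find_dot(gen_dot_stack(_stack_spec(seed=2))[0])
        assert np.all(
            extract_second_channel(gfp, det, "mip")
            >= extract_second_channel(gfp, det, "same_z")
        )


class TestAlignAndAverage:
    def test_single_image_identity(self, rng):
        img = rng.uniform(0, 10, (21, 21))
        out = align_and_average([img], [(10, 10)], window_halfwidth=5)
        np.testing.assert_allclose(out.averaged_image, img[5:16, 5:16])
        assert out.n_cells == 1

    def test_average_equals_direct_mean_of_windows(self, rng):
        """Oracle: accumulate the aligned windows with an explicit loop."""
        imgs = [rng.uniform(0, 5, (30, 30)) for _ in range(7)]
        centers = [(int(rng.integers(8, 22)), int(rng.integers(8, 22))) for _ in imgs]
        w = 6
        out = align_and_average(imgs, centers, w)
        expect = np.mean(
            [im[cy - w : cy + w + 1, cx - w : cx + w + 1] for im, (cx, cy) in zip(imgs, centers)],
            axis=0,
        )
        np.testing.assert_allclose(out.averaged_image, expect)

    def test_translation_equivariance(self, rng):
        img = rng.uniform(0, 5, (40, 40))
        base = align_and_average([img], [(20, 20)], 5).averaged_image
        shifted = np.roll(img, (3, 4), axis=(0, 1))
        moved = align_and_average([shifted], [(24, 23)], 5).averaged_image
        np.testing.assert_allclose(moved, base)

    def test_out_of_bounds_cells_dropped(self, rng):
        img = rng.uniform(0, 1, (20, 20))
        out = align_and_average([img, img], [(10, 10), (1, 1)], 5)
        assert out.n_cells == 1 and out.n_dropped == 1
        with pytest.raises(ValueError):
            align_and_average([img], [(0, 0)], 5)

    def test_puncta_at_dot_peak_at_center(self):
        """Population-averaged window peaks centrally iff puncta sit at the dot."""
        center_vals = {"at_dot": [], "offset": []}
        rng = np.random.default_rng(123)
        for kind in center_vals:
            images, centers = [], []
            for i in range(40):
                if kind == "at_dot":
                    off = (0.0, 0.0)
                else:
                    theta = rng.uniform(0, 2 * np.pi)
                    off = (12.0 * np.sin(theta), 12.0 * np.cos(theta))
                spec = _stack_spec(seed=500 + i, offset=off)
                mch, gfp, _ = gen_dot_stack(spec)
                det = find_dot(mch)
                images.append(extract_second_channel(gfp, det, "mip"))
                centers.append((det.x, det.y))
            out = align_and_average(images, centers, window_halfwidth=10)
            center_vals[kind] = out.averaged_image
        w = 10
        at_dot = center_vals["at_dot"]
        offset = center_vals["offset"]
        # peak at the center pixel when puncta coincide with the dot
        assert np.unravel_index(np.argmax(at_dot), at_dot.shape) == (w, w)
        # with 12-px random offsets the center is near the diffuse level
        assert offset[w, w] < 0.3 * at_dot[w, w]


class TestLineProfile:
    def test_symmetric_image_symmetric_profile(self):
        y, x = np.mgrid[-7:8, -7:8]
        img = np.exp(-(x**2 + y**2) / 8.0)
        from metkit.dots import DotAlignment

        prof = line_profile(DotAlignment(7, 1, img))
        np.testing.assert_allclose(prof.intensities, prof.intensities[::-1])
        assert prof.peak_center_value == img[7, 7]

    def test_horizontal_line_recovers_center_row(self, rng):
        img = rng.uniform(0, 1, (11, 11))
        from metkit.dots import DotAlignment

        prof = line_profile(DotAlignment(5, 1, img), angle=0.0)
        np.testing.assert_allclose(prof.intensities, img[5, :])
        assert len(prof.offsets) == 11

    def test_shared_vs_offset_populations_differ_at_center(self):
        """Center-profile values separate dot-colocalized puncta from offset ones."""
        rng = np.random.default_rng(7)
        center_values = {"at_dot": [], "offset": []}
        for kind, vals in center_values.items():
            for i in range(25):
                if kind == "at_dot":
                    off = (0.0, 0.0)
                else:
                    theta = rng.uniform(0, 2 * np.pi)
                    off = (12.0 * np.sin(theta), 12.0 * np.cos(theta))
                mch, gfp, _ = gen_dot_stack(_stack_spec(seed=900 + i, offset=off))
                det = find_dot(mch)
                out = align_and_average(
                    [extract_second_channel(gfp, det, "mip")], [(det.x, det.y)], 8
                )
                vals.append(line_profile(out).peak_center_value)
        _, p = compare_groups(center_values["at_dot"], center_values["offset"])
        assert p < 0.001
        assert np.mean(center_values["at_dot"]) > np.mean(center_values["offset"])
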