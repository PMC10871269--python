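"""Generators: determinism, photon conservation, distributional structure."""

import numpy as np
import pytest

from metkit.frap import normalize_trace
from metkit.synthetic import (
    DotStackSpec,
    FRAPSimSpec,
    MTACSimSpec,
    NucleusImageSpec,
    TwoChannelSpec,
    frap_expectation,
    gen_dot_stack,
    gen_frap_traces,
    gen_mtac_counts,
    gen_nucleus_image,
    gen_two_channel,
)

from conftest import diffuse_spec, punctate_spec


class TestNucleusImage:
    def test_determinism(self):
        spec = punctate_spec(seed=5)
        a = gen_nucleus_image(spec)
        b = gen_nucleus_image(spec)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_diffuse_limit_is_poisson(self):
        """No puncta, no read noise, no background: in-mask pixels are iid Poisson."""
        spec = diffuse_spec(seed=1, background_rate=0.0, read_noise_sd=0.0)
        img, mask, pos = gen_nucleus_image(spec)
        assert len(pos) == 0
        vals = img[mask]
        assert np.all(vals == np.floor(vals))
        lam = spec.total_intensity / mask.sum()
        assert vals.mean() == pytest.approx(lam, rel=0.02)
        # Poisson: variance approximates the mean
        assert vals.var() == pytest.approx(vals.mean(), rel=0.15)

    def test_zero_intensity_gives_blank_image(self):
        spec = diffuse_spec(seed=2, total_intensity=0.0, background_rate=0.0, read_noise_sd=0.0)
        img, _, _ = gen_nucleus_image(spec)
        assert np.all(img == 0)

    def test_puncta_raise_fano_over_diffuse(self):
        """Concentrating 90% of photons into 3 puncta overdisperses the pixels."""
        def fano(spec):
            img, mask, _ = gen_nucleus_image(spec)
            v = img[mask]
            return v.var(ddof=1) / v.mean()

        assert fano(punctate_spec(seed=3)) > fano(diffuse_spec(seed=3))

    def test_photon_conservation_in_expectation(self):
        spec = punctate_spec(puncta_fraction=0.5)
        totals = []
        for seed in range(20):
            img, mask, _ = gen_nucleus_image(punctate_spec(puncta_fraction=0.5, seed=seed))
            totals.append(img[mask].sum())
        expected = spec.total_intensity + spec.background_rate * mask.sum()
        # puncta margin keeps ~all punctum mass in-mask; 3 SE Monte-Carlo band
        se = np.std(totals, ddof=1) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - expected) < 3 * se + 0.01 * expected

    def test_fano_monotone_in_puncta_fraction(self):
        """Expected in-mask Fano strictly increases with the punctate fraction."""
        means = []
        for pf in (0.0, 0.25, 0.5, 0.75):
            fanos = []
            for seed in range(25):
                spec = NucleusImageSpec(puncta_count=4, puncta_fraction=pf, seed=1000 + seed)
                img, mask, _ = gen_nucleus_image(spec)
                v = img[mask]
                fanos.append(v.var(ddof=1) / v.mean())
            means.append(np.mean(fanos))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_impossible_geometry_rejected(self):
        with pytest.raises(ValueError, match="fit inside"):
            NucleusImageSpec(image_size=32, nucleus_center=(16, 16), nucleus_radius=20)
        with pytest.raises(ValueError, match="impossible geometry"):
            gen_nucleus_image(
                NucleusImageSpec(
                    image_size=64, nucleus_center=(32, 32), nucleus_radius=3,
                    psf_sigma=2.0, puncta_count=1, puncta_fraction=0.5,
                )
            )


class TestTwoChannel:
    def test_shared_puncta_same_positions_and_high_r(self):
        base = punctate_spec(read_noise_sd=0.0, background_rate=0.0)
        spec = TwoChannelSpec(base_a=base, base_b=base, coupling="shared_puncta", seed=4)
        a, b, mask = gen_two_channel(spec)
        r = np.corrcoef(a[mask], b[mask])[0, 1]
        assert r > 0.9

    def test_independent_diffuse_channels_uncorrelated(self):
        base = diffuse_spec(
            image_size=160, nucleus_center=(80, 80), nucleus_radius=60,
        )
        spec = TwoChannelSpec(base_a=base, base_b=base, coupling="independent", seed=6)
        a, b, mask = gen_two_channel(spec)
        assert mask.sum() >= 10_000
        assert abs(np.corrcoef(a[mask], b[mask])[0, 1]) < 0.05

    def test_same_seed_reproduces_pair(self):
        base = punctate_spec()
        spec = TwoChannelSpec(base_a=base, base_b=base, seed=9)
        a1, b1, _ = gen_two_channel(spec)
        a2, b2, _ = gen_two_channel(spec)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(b1, b2)

    def test_noise_independent_across_channels(self):
        """Shared geometry but independent shot noise: channels differ."""
        base = diffuse_spec()
        spec = TwoChannelSpec(base_a=base, base_b=base, seed=2)
        a, b, _ = gen_two_channel(spec)
        assert not np.array_equal(a, b)


class TestDotStack:
    def test_truth_positions_and_depth(self):
        spec = DotStackSpec(gfp_puncta_offset=(0.0, 20.0), seed=1)
        _, _, truth = gen_dot_stack(spec)
        assert truth["separation_px"] == 20.0
        assert truth["gfp_punctum"][:2] == (64.0, 84.0)
        # 14 planes at 0.4 um span 5.2 um
        assert truth["depth_um"] == pytest.approx(5.2)

    def test_zero_offset_punctum_at_dot(self):
        _, _, truth = gen_dot_stack(DotStackSpec(seed=2))
        assert truth["gfp_punctum"] == truth["dot"]

    def test_offset_outside_field_rejected(self):
        with pytest.raises(ValueError, match="outside the field"):
            DotStackSpec(gfp_puncta_offset=(0.0, 100.0))

    def test_dot_dominates_mcherry_channel(self):
        mch, _, truth = gen_dot_stack(DotStackSpec(seed=3))
        z, y, x = np.unravel_index(np.argmax(mch), mch.shape)
        dr, dc, dz = truth["dot"]
        assert z == dz and abs(y - dr) <= 1 and abs(x - dc) <= 1


class TestFrapTraces:
    def test_frame_counts(self):
        traces = gen_frap_traces(FRAPSimSpec(seed=1))
        assert len(traces) == 10
        # 3 pre-bleach frames + 270/3 = 90 post-bleach frames
        assert len(traces[0].times) == 93

    def test_halfway_at_half_time(self):
        """With full mobility the noiseless curve is halfway at t = t_half."""
        spec = FRAPSimSpec(mobile_fraction=1.0, noise_sd=0.0)
        val = frap_expectation(spec, np.array([spec.t_half_true]))[0]
        floor = 100.0 * spec.bleach_depth
        assert val == pytest.approx((floor + 100.0) / 2.0)

    def test_immobile_trace_stays_at_floor(self):
        spec = FRAPSimSpec(mobile_fraction=0.0, noise_sd=0.0, n_traces=1)
        tr = gen_frap_traces(spec)[0]
        post = tr.intensities[tr.n_prebleach:]
        np.testing.assert_allclose(post, 100.0 * spec.bleach_depth)

    def test_normalization_recovers_percent_trace_after_scaling(self):
        """A raw trace that is 7x a percent-unit trace normalises back exactly."""
        tr = gen_frap_traces(FRAPSimSpec(seed=5, n_traces=1))[0]
        raw = tr.__class__(tr.times, 7.0 * tr.intensities, tr.n_prebleach)
        norm = normalize_trace(raw)
        np.testing.assert_allclose(norm.normalized, normalize_trace(tr).normalized)

    def test_invalid_half_time_rejected(self):
        with pytest.raises(ValueError):
            FRAPSimSpec(t_half_true=0.0)


class TestMtacCounts:
    def _spec(self, **kw):
        base = dict(
            genome_layout=(("chr1", 200_000),),
            ndr_positions=tuple(("chr1", p, p + 400) for p in range(10_000, 190_000, 20_000)),
            vp=None,
        )
        base.update(kw)
        if base["vp"] is None:
            from metkit.mtac import ViewPoint

            base["vp"] = ViewPoint("chr1", 100_000)
        return MTACSimSpec(**base)

    def test_poisson_limit(self):
        """Zero dispersion: variance tracks the mean."""
        spec = self._spec(dispersion=0.0, library_sizes_targeted=tuple([1.0] * 500), seed=3)
        _, counts, _ = gen_mtac_counts(spec)
        row = counts.iloc[0].filter(like="targeted_").to_numpy(float)
        assert row.var(ddof=1) == pytest.approx(row.mean(), rel=0.2)

    def test_nb_mean_variance_relation(self):
        """Empirical variance matches mu + alpha mu^2 within 3 SE at n=10^4."""
        alpha, mu, n = 0.1, 100.0, 10_000
        spec = self._spec(
            dispersion=alpha,
            baseline_mean=mu,
            library_sizes_targeted=tuple([1.0] * n),
            library_sizes_control=(1.0,),
            ndr_positions=(("chr1", 10_000, 10_400),),
            seed=7,
        )
        _, counts, _ = gen_mtac_counts(spec)
        x = counts.iloc[0].filter(like="targeted_").to_numpy(float)
        expected_var = mu + alpha * mu**2
        m4 = np.mean((x - x.mean()) ** 4)
        se_var = np.sqrt((m4 - x.var(ddof=1) ** 2) / n)
        assert abs(x.var(ddof=1) - expected_var) < 3 * se_var

    def test_null_table_has_no_planted_structure(self):
        spec = self._spec(seed=5)
        _, counts, truth = gen_mtac_counts(spec)
        assert not truth["enriched"].any()
        assert (truth["log2fc_true"] == 0).all()

    def test_planted_fold_change_shows_in_means(self):
        """log2fc 2 at one NDR: targeted/control mean ratio near 4."""
        spec = self._spec(
            enriched_ndrs=((0, 2.0),),
            library_sizes_targeted=tuple([1.0] * 200),
            library_sizes_control=tuple([1.0] * 200),
            seed=9,
        )
        _, counts, truth = gen_mtac_counts(spec)
        t = counts.iloc[0].filter(like="targeted_").to_numpy(float).mean()
        c = counts.iloc[0].filter(like="control_").to_numpy(float).mean()
        assert t / c == pytest.approx(4.0, rel=0.1)
        assert bool(truth["enriched"][0])
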