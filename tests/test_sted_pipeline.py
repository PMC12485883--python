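"""Crosstalk correction, blur, sub-pixel refinement, linescan classification,
nearest-neighbor distances with the flipped-image control, tolerance sweep."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import best_gaussian_r2_grid, gaussian_kernel_1d

from memsheet import (
    CandidateExcluded,
    ChannelImage,
    EmitterSet,
    InvalidParameterError,
    MaximumCandidate,
    SquareROI,
    SubpixelPosition,
    analyze_sheet,
    apply_crosstalk,
    blur,
    classify,
    correct_crosstalk,
    find_maxima,
    flip_control,
    linescan_fit,
    make_two_color_scene,
    nn_distances,
    refine_subpixel,
    render_channel,
    tolerance_sweep,
)
from memsheet.sted import LinescanFit
from memsheet.synthetic import sted_render_params

PX = 25.0


def img(arr) -> ChannelImage:
    return ChannelImage(np.asarray(arr, dtype=float), PX, "sted")


def render_spot(center, shape=(41, 41), photons=1000.0, sigma_nm=40.0,
                background=0.0, noise=False, seed=0):
    em = EmitterSet(centers=np.array([center]), copies=np.array([1]),
                    affinity=0.0, channel_label="x", image_shape=shape)
    params = sted_render_params(
        psf_sigma_nm=sigma_nm, photons_per_emitter=photons,
        background_level=background, shot_noise=noise, seed=seed,
    )
    return render_channel(em, params)


class TestCrosstalkCorrection:
    def test_exact_multiple_cancels_to_zero(self):
        red = img(np.random.default_rng(0).poisson(40, (32, 32)).astype(float))
        longred = img(0.5 * red.pixels)
        out = correct_crosstalk(longred, red, 0.5)
        assert np.all(out.pixels == 0.0)

    def test_factor_zero_is_identity(self):
        a = img(np.arange(64.0).reshape(8, 8))
        assert np.array_equal(correct_crosstalk(a, a, 0.0).pixels, a.pixels)

    def test_roundtrip_with_apply_crosstalk_is_exact(self):
        # integer photon counts: add 0.5x bleed then subtract it, bit exact
        rng = np.random.default_rng(1)
        p = img(rng.poisson(30, (32, 32)).astype(float))
        b = img(rng.poisson(80, (32, 32)).astype(float))
        mixed = apply_crosstalk(p, b, 0.5)
        recovered = correct_crosstalk(mixed, b, 0.5)
        assert np.array_equal(recovered.pixels, p.pixels)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            correct_crosstalk(img(np.zeros((8, 8))), img(np.zeros((8, 9))), 0.5)


class TestBlur:
    def test_constant_image_unchanged(self):
        a = img(np.full((16, 16), 4.0))
        assert np.allclose(blur(a, 0.5).pixels, 4.0)

    def test_impulse_center_matches_kernel_oracle(self):
        a = np.zeros((21, 21))
        a[10, 10] = 1.0
        out = blur(img(a), 0.5)
        k = gaussian_kernel_1d(0.5)
        expected_center = float(k[len(k) // 2] ** 2)  # separable 2D kernel
        assert out.pixels[10, 10] == pytest.approx(expected_center, rel=0.01)

    def test_mass_conserved_for_interior_content(self):
        spot = render_spot((20.0, 20.0))
        out = blur(spot, 0.5)
        assert out.pixels.sum() == pytest.approx(spot.pixels.sum(), rel=1e-3)


class TestRefineSubpixel:
    def test_symmetric_spot_refines_to_integer_position(self):
        spot = render_spot((20.0, 20.0))
        cand = MaximumCandidate(20, 20, prominence=10.0)
        sub = refine_subpixel(spot, cand)
        assert sub.row_sub == pytest.approx(20.0, abs=1e-9)
        assert sub.col_sub == pytest.approx(20.0, abs=1e-9)

    def test_matches_hand_computed_centroid(self):
        # asymmetric weights along the row through the candidate only
        a = np.zeros((11, 11))
        weights = {(-2, 0): 1.0, (-1, 0): 2.0, (0, 0): 5.0, (1, 0): 3.0,
                   (2, 0): 1.0}
        for (dr, dc), w in weights.items():
            a[5 + dr, 5 + dc] = w
        sub = refine_subpixel(img(a), MaximumCandidate(5, 5, 1.0))
        total = sum(weights.values())
        expected_dr = sum(dr * w for (dr, _), w in weights.items()) / total
        assert sub.row_sub == pytest.approx(5 + expected_dr, abs=1e-12)
        assert sub.col_sub == pytest.approx(5.0, abs=1e-12)

    def test_recovers_known_subpixel_offset(self):
        spot = render_spot((20.3, 19.8))
        sub = refine_subpixel(spot, MaximumCandidate(20, 20, 1.0))
        assert abs(sub.row_sub - 20.3) < 0.1
        assert abs(sub.col_sub - 19.8) < 0.1

    def test_disc_outside_image_excludes_candidate(self):
        with pytest.raises(CandidateExcluded):
            refine_subpixel(img(np.ones((16, 16))), MaximumCandidate(1, 8, 1.0))

    def test_zero_intensity_falls_back_with_warning(self):
        a = img(np.zeros((16, 16)))
        with pytest.warns(UserWarning, match="baseline"):
            sub = refine_subpixel(a, MaximumCandidate(8, 8, 1.0))
        assert (sub.row_sub, sub.col_sub) == (8.0, 8.0)

    def test_stays_within_disc(self):
        rng = np.random.default_rng(3)
        a = img(rng.uniform(0, 10, (32, 32)))
        for _ in range(20):
            r, c = rng.integers(3, 29, size=2)
            sub = refine_subpixel(a, MaximumCandidate(int(r), int(c), 1.0))
            assert abs(sub.row_sub - r) <= 2.5
            assert abs(sub.col_sub - c) <= 2.5


def make_profile_image(profile: np.ndarray) -> ChannelImage:
    """41x41 image whose rows 19..21 all carry the given 31-px profile at
    columns 5..35, so the horizontal linescan at (20, 20) sees it exactly."""
    a = np.zeros((41, 41))
    for r in (19, 20, 21):
        a[r, 5:36] = profile
    return img(a)


class TestLinescanFit:
    def test_centered_gaussian_passes(self):
        x = np.arange(31.0)
        profile = 10.0 * np.exp(-((x - 15.0) ** 2) / (2 * 2.0**2)) + 1.0
        fit = linescan_fit(make_profile_image(profile),
                           MaximumCandidate(20, 20, 1.0), "horizontal")
        assert fit.r_squared > 0.999
        assert fit.peak_in_middle_third
        assert fit.center_px == pytest.approx(15.0, abs=0.01)
        assert fit.passes

    def test_off_center_gaussian_fails_middle_third(self):
        x = np.arange(31.0)
        profile = 10.0 * np.exp(-((x - 3.0) ** 2) / (2 * 2.0**2)) + 1.0
        fit = linescan_fit(make_profile_image(profile),
                           MaximumCandidate(20, 20, 1.0), "horizontal")
        assert not fit.peak_in_middle_third
        assert not fit.passes

    def test_linear_ramp_rejected(self):
        # a broad Gaussian flank can mimic a ramp (high R^2 with sigma at
        # the bound), but the fitted peak sits at the scan edge, so the
        # middle-third rule rejects it
        profile = np.linspace(1.0, 10.0, 31)
        fit = linescan_fit(make_profile_image(profile),
                           MaximumCandidate(20, 20, 1.0), "horizontal")
        assert not fit.peak_in_middle_third
        assert not fit.passes

    def test_noise_profile_rejected_by_fit_quality(self):
        rng = np.random.default_rng(8)
        profile = rng.uniform(1.0, 2.0, 31)
        fit = linescan_fit(make_profile_image(profile),
                           MaximumCandidate(20, 20, 1.0), "horizontal")
        assert fit.r_squared < 0.7
        # independent grid-search oracle agrees no Gaussian reaches 0.7
        assert best_gaussian_r2_grid(profile) < 0.7
        assert not fit.passes

    def test_window_outside_image_excludes_candidate(self):
        with pytest.raises(CandidateExcluded):
            linescan_fit(img(np.ones((41, 41))),
                         MaximumCandidate(20, 5, 1.0), "horizontal")

    def test_vertical_orientation_reads_columns(self):
        a = np.zeros((41, 41))
        x = np.arange(31.0)
        profile = 8.0 * np.exp(-((x - 15.0) ** 2) / (2 * 1.5**2))
        for c in (19, 20, 21):
            a[5:36, c] = profile
        fit = linescan_fit(img(a), MaximumCandidate(20, 20, 1.0), "vertical")
        assert fit.orientation == "vertical"
        assert fit.passes


def _fit(passes_r2: float, centered: bool) -> LinescanFit:
    return LinescanFit(
        orientation="horizontal", profile=tuple(np.zeros(31)),
        amplitude=1.0, center_px=15.0 if centered else 25.0, sigma_px=2.0,
        offset=0.0, r_squared=passes_r2,
        peak_in_middle_third=centered,
    )


class TestClassify:
    CAND = MaximumCandidate(10, 10, 5.0)
    SUB = SubpixelPosition(10.0, 10.0)

    def test_one_passing_linescan_suffices(self):
        cl = classify(self.CAND, self.SUB, (_fit(0.9, True), _fit(0.2, False)))
        assert cl.accepted

    def test_conjunction_is_per_linescan(self):
        # H: good fit, off-center peak; V: centered peak, poor fit -> reject
        cl = classify(self.CAND, self.SUB, (_fit(0.9, False), _fit(0.5, True)))
        assert not cl.accepted

    def test_both_failing_rejected(self):
        cl = classify(self.CAND, self.SUB, (_fit(0.3, False), _fit(0.1, False)))
        assert not cl.accepted


class TestNNDistances:
    def test_345_triangle_in_nm(self):
        d = nn_distances([SubpixelPosition(0, 0)], [SubpixelPosition(3, 4)],
                         pixel_size_nm=25.0)
        assert d[0] == pytest.approx(125.0)

    def test_coincident_target_gives_zero(self):
        d = nn_distances([SubpixelPosition(5, 5)], [SubpixelPosition(5, 5)])
        assert d[0] == 0.0

    def test_empty_targets_rejected(self):
        with pytest.raises(InvalidParameterError):
            nn_distances([SubpixelPosition(0, 0)], [])

    def test_csr_matches_poisson_closed_form(self):
        # homogeneous Poisson process: mean NN distance = 1 / (2 sqrt(lambda))
        rng = np.random.default_rng(99)
        side_nm = 25_000.0
        n = 10_000
        lam = n / side_nm**2
        pts = rng.uniform(0, side_nm / 25.0, size=(n, 2))
        targets = [SubpixelPosition(r, c) for r, c in pts]
        refs = [
            SubpixelPosition(r, c)
            for r, c in rng.uniform(100, side_nm / 25.0 - 100, size=(4000, 2))
        ]
        mean = float(np.mean(nn_distances(refs, targets, pixel_size_nm=25.0)))
        expected = 1.0 / (2.0 * np.sqrt(lam))
        assert abs(mean - expected) / expected < 0.02


class TestFlipControl:
    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        cols=st.integers(2, 500),
        col=st.floats(0, 499),
        row=st.floats(0, 499),
    )
    def test_flip_twice_is_identity(self, cols, col, row):
        if col > cols - 1:
            col = cols - 1.0
        p = [SubpixelPosition(row, col)]
        back = flip_control(flip_control(p, cols), cols)
        assert back[0].col_sub == pytest.approx(col, abs=1e-12)
        assert back[0].row_sub == row

    def test_center_column_fixed_point(self):
        p = [SubpixelPosition(3.0, 10.0)]
        assert flip_control(p, 21)[0].col_sub == 10.0

    def test_vertical_axis_mirrors_rows(self):
        p = [SubpixelPosition(2.0, 7.0)]
        out = flip_control(p, 32, axis="v", image_rows=10)
        assert (out[0].row_sub, out[0].col_sub) == (7.0, 7.0)

    def test_independent_channels_observed_matches_flipped(self):
        # flip changes nothing distributionally when channels are unrelated
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            refs = [SubpixelPosition(r, c)
                    for r, c in rng.uniform(0, 499, size=(500, 2))]
            targets = [SubpixelPosition(r, c)
                       for r, c in rng.uniform(0, 499, size=(500, 2))]
            obs = np.mean(nn_distances(refs, targets))
            flip = np.mean(nn_distances(refs, flip_control(targets, 500)))
            diffs.append(obs - flip)
        from scipy import stats

        _, p = stats.ttest_1samp(diffs, 0.0)
        assert p > 0.01


@pytest.fixture(scope="module")
def coplaced_scene():
    return make_two_color_scene(
        shape=(160, 160), n_clusters=(150, 150), affinity=(1.0, 1.0),
        shared_fraction=0.7, crosstalk_factor=0.5, seed=21,
    )


class TestFullPipeline:
    def test_coplaced_channels_closer_than_flipped_control(self, coplaced_scene):
        res = analyze_sheet(
            coplaced_scene.images["red"], coplaced_scene.images["longred"],
            reference_tolerance=2.0, target_tolerance=4.0,
        )
        assert res.nn.n >= 10
        assert res.nn.mean_nm < res.nn.flipped_mean_nm

    def test_pipeline_deterministic(self, coplaced_scene):
        kwargs = dict(reference_tolerance=2.0, target_tolerance=4.0)
        r1 = analyze_sheet(coplaced_scene.images["red"],
                           coplaced_scene.images["longred"], **kwargs)
        r2 = analyze_sheet(coplaced_scene.images["red"],
                           coplaced_scene.images["longred"], **kwargs)
        assert np.array_equal(r1.nn.distances_nm, r2.nn.distances_nm)
        assert np.array_equal(r1.nn.flipped_distances_nm,
                              r2.nn.flipped_distances_nm)

    def test_tolerance_sweep_monotone(self, coplaced_scene):
        ref = coplaced_scene.images["red"]
        tgt = coplaced_scene.images["longred"]
        sweeps = tolerance_sweep(ref, tgt, pairs=[(2, 4), (4, 8), (6, 12)])
        ref_counts = [
            len(find_maxima(blurred, noise_tolerance=t))
            for blurred, t in (
                (ref, 2), (ref, 4), (ref, 6),
            )
        ]
        assert ref_counts == sorted(ref_counts, reverse=True)
        # fewer target maxima at higher tolerance -> distances non-decreasing
        means = [nn.mean_nm for nn in sweeps]
        assert means[0] <= means[1] <= means[2]

    def test_empty_tolerance_pairs_rejected(self, coplaced_scene):
        with pytest.raises(InvalidParameterError):
            tolerance_sweep(coplaced_scene.images["red"],
                            coplaced_scene.images["longred"], pairs=[])
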