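"""Stimulus construction, local frequency/orientation, and MTF handling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfmap.stimulus import (
    GridSpec,
    PHASES,
    StimulusSpec,
    build_frequency_vectors,
    build_stimulus_set,
    fit_mtf,
    local_frequency,
    local_orientation,
    mtf_compensate,
    render,
)


class TestStimulusSet:
    def test_canonical_enumeration(self, vectors):
        assert len(vectors) == 48
        assert len({(v.radial_freq, v.angular_freq) for v in vectors}) == 48
        assert len(build_stimulus_set()) == 384
        pin = [v for v in vectors if v.category == "pinwheel"]
        assert all(v.radial_freq == 0 for v in pin)
        assert {v.angular_freq for v in pin} == {-6, -8, -11, -16, -23, -32, -45, -64, -91, -128}
        ann = [v for v in vectors if v.category == "annulus"]
        assert all(v.angular_freq == 0 for v in ann)
        fwd = [v for v in vectors if v.category == "forward-spiral"]
        rev = [v for v in vectors if v.category == "reverse-spiral"]
        assert all(v.radial_freq == -v.angular_freq for v in fwd)
        assert all(v.radial_freq == v.angular_freq for v in rev)

    def test_mixture_magnitudes_round_to_32(self, vectors):
        mags = [v.magnitude for v in vectors if v.category == "mixture"]
        assert len(mags) == 8
        assert all(round(m) == 32 for m in mags)

    def test_phases(self):
        specs = build_stimulus_set()
        per_vector = {p for s in specs for p in [s.phase]}
        assert per_vector == set(PHASES)
        assert len(PHASES) == 8

    def test_frequency_span_at_fixed_eccentricity(self, vectors):
        # the base magnitudes run from 4*sqrt(2) (smallest spirals) to
        # 91*sqrt(2) (largest spirals): an exact 91/4 = 22.75-fold span
        mags = [v.magnitude for v in vectors]
        assert max(mags) / min(mags) == pytest.approx(91 / 4, abs=1e-12)

    def test_zero_vector_rejected(self):
        from sfmap.stimulus import FrequencyVector

        with pytest.raises(ValueError):
            FrequencyVector(0, 0, "pinwheel")


class TestLocalProps:
    def test_printed_foveal_and_peripheral_extremes(self, vectors):
        freqs_foveal = [local_frequency(v, 1.5) for v in vectors]
        freqs_periph = [local_frequency(v, 11.5) for v in vectors]
        assert min(freqs_foveal) == pytest.approx(0.600, abs=5e-4)
        assert max(freqs_foveal) == pytest.approx(13.65, abs=5e-3)
        assert min(freqs_periph) == pytest.approx(0.078, abs=5e-4)
        # analytic band-center value is 1.7811; agreement to printed precision
        assert max(freqs_periph) == pytest.approx(1.780, abs=2e-3)

    def test_domain_error_at_fovea(self, vectors):
        with pytest.raises(ValueError):
            local_frequency(vectors[0], 0.0)

    @settings(deadline=None, derandomize=True)
    @given(r=st.floats(0.1, 12.0), idx=st.integers(0, 47))
    def test_inverse_eccentricity_scaling(self, r, idx):
        v = build_frequency_vectors()[idx]
        assert local_frequency(v, 2 * r) == pytest.approx(local_frequency(v, r) / 2)

    def test_orientation_conventions(self, vectors):
        annulus = next(v for v in vectors if v.category == "annulus")
        pinwheel = next(v for v in vectors if v.category == "pinwheel")
        fwd = next(v for v in vectors if v.radial_freq == 4 and v.angular_freq == -4)
        # annulus on the right horizontal meridian is locally vertical
        assert local_orientation(annulus, 0.0) == pytest.approx(0.0)
        assert local_orientation(pinwheel, 0.0) == pytest.approx(math.pi / 2)
        assert local_orientation(fwd, math.pi / 3) == pytest.approx(
            (math.pi / 3 - math.pi / 4) % math.pi
        )

    def test_local_period_linear_in_eccentricity(self, vectors):
        r = np.linspace(0.5, 12, 24)
        for v in (vectors[0], vectors[20], vectors[-1]):
            period = 1.0 / local_frequency(v, r)
            coef = np.polyfit(r, period, 1)
            # line through the origin, R^2 = 1
            assert abs(coef[1]) < 1e-12
            assert np.allclose(np.polyval(coef, r), period)


def _phase_gradient(vector, grid, sample_mask):
    """Numerical oracle: central differences of the phase map."""
    r, theta = grid.retinal_coords()
    with np.errstate(divide="ignore"):
        phase = vector.radial_freq * np.log(r) + vector.angular_freq * theta
    drow, dcol = np.gradient(phase)
    gx = dcol * grid.pixels_per_degree
    gy = -drow * grid.pixels_per_degree  # rows run top-down
    freq_cpd = np.hypot(gx, gy)[sample_mask] / (2 * math.pi)
    orient = np.mod(np.arctan2(gy, gx), math.pi)[sample_mask]
    return freq_cpd, orient


class TestGradientOracle:
    def _samples(self, grid, radius):
        r, theta = grid.retinal_coords()
        near = np.abs(r - radius) < 0.05
        away_from_cut = np.cos(theta) > -0.7  # branch cut of theta at +-pi
        return near & away_from_cut

    @pytest.mark.parametrize("radius", [2.0, 5.0, 10.0])
    def test_analytic_matches_numerical_everywhere(self, small_grid, radius, vectors):
        sample = self._samples(small_grid, radius)
        r, theta = small_grid.retinal_coords()
        for v in vectors:
            num_freq, num_orient = _phase_gradient(v, small_grid, sample)
            ana_freq = local_frequency(v, r[sample])
            assert np.median(np.abs(num_freq - ana_freq) / ana_freq) < 0.01
            ana_orient = local_orientation(v, theta[sample])
            diff = np.abs(num_orient - ana_orient)
            diff = np.minimum(diff, math.pi - diff)
            assert np.median(diff) < math.radians(1.0)

    def test_uniform_grating_control(self, small_grid):
        # a conventional 2D sine validates the oracle itself: constant
        # frequency and orientation everywhere
        grid = small_grid
        c = (grid.image_side - 1) / 2
        idx = np.arange(grid.image_side)
        x = (idx - c) / grid.pixels_per_degree
        y = (c - idx) / grid.pixels_per_degree
        xx, yy = np.meshgrid(x, y)
        f0, alpha = 1.3, math.radians(30)  # cpd, frequency-vector angle
        phase = 2 * math.pi * f0 * (np.cos(alpha) * xx + np.sin(alpha) * yy)
        drow, dcol = np.gradient(phase)
        gx = dcol * grid.pixels_per_degree
        gy = -drow * grid.pixels_per_degree
        interior = np.zeros_like(phase, dtype=bool)
        interior[2:-2, 2:-2] = True
        freq = np.hypot(gx, gy)[interior] / (2 * math.pi)
        orient = np.mod(np.arctan2(gy, gx), math.pi)[interior]
        assert np.allclose(freq, f0, rtol=1e-6)
        assert np.allclose(orient, alpha, atol=1e-6)


class TestRender:
    def test_carrier_values(self, small_grid, vectors):
        annulus = next(v for v in vectors if v.radial_freq == 6 and v.angular_freq == 0)
        img = render(StimulusSpec(annulus, 0.0), small_grid, masked=False)
        r, _ = small_grid.retinal_coords()
        at_1deg = np.abs(r - 1.0) < (0.5 / small_grid.pixels_per_degree)
        # ln(1) = 0 so the carrier is cos(0) = 1 on the unit circle
        assert np.allclose(img[at_1deg], 1.0, atol=0.02)

    def test_masked_image_range_and_mean(self, small_grid, vectors):
        # any stimulus with angular frequency != 0 completes an integer
        # number of cycles per revolution, so its mean over the annulus
        # cancels; annuli retain a residual DC that decays with w_r
        r, _ = small_grid.retinal_coords()
        annular = (r >= small_grid.inner_mask_radius) & (r <= small_grid.max_eccentricity)
        for v in vectors:
            img = render(StimulusSpec(v, 0.0), small_grid)
            assert img.min() >= -1.0 and img.max() <= 1.0
            if v.angular_freq != 0:
                assert abs(img[annular].mean()) < 1e-3
            else:
                assert abs(img[annular].mean()) < 0.25

    def test_masked_region_is_midgray(self, small_grid, vectors):
        img = render(StimulusSpec(vectors[3], 0.0), small_grid)
        r, _ = small_grid.retinal_coords()
        assert np.all(img[r < small_grid.inner_mask_radius] == 0)
        assert np.all(img[r > small_grid.max_eccentricity] == 0)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            GridSpec(image_side=100, pixels_per_degree=64)


class TestMTF:
    def test_flat_samples_give_unit_curve(self):
        mtf = fit_mtf([(p, 1.0) for p in (2, 4, 8, 16, 32, 64)])
        f = np.linspace(*mtf.domain, 50)
        assert np.allclose(mtf(f), 1.0, atol=1e-6)

    def test_nyquist_rolloff(self):
        periods = [2, 3, 4, 8, 16, 64, 256]
        contrasts = [0.5, 0.75, 0.9, 0.99, 1.0, 1.0, 1.0]
        mtf = fit_mtf(list(zip(periods, contrasts)))
        assert mtf(0.5) == pytest.approx(0.5, abs=0.05)

    def test_monotone_samples_fit_monotone(self):
        periods = np.array([2, 3, 4, 6, 8, 16, 32, 128])
        contrasts = np.linspace(0.4, 1.0, len(periods))
        mtf = fit_mtf(list(zip(periods, contrasts)))
        dense = mtf(np.linspace(*mtf.domain, 400))
        assert np.all(np.diff(dense) <= 1e-9)  # non-increasing in frequency

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            fit_mtf([(2, 0.5), (4, 0.8), (8, 1.0)])

    def test_compensation_envelope(self, small_grid, vectors):
        spec = StimulusSpec(next(v for v in vectors if v.magnitude > 100), 0.0)
        img = render(spec, small_grid, masked=False)
        flat = fit_mtf([(p, 1.0) for p in (2, 4, 8, 16, 32, 256)])
        assert np.allclose(mtf_compensate(img, spec, small_grid, flat), img)

        # MTF 1.0 at the image's highest frequency, lower at its lowest:
        # the lowest-frequency (peripheral) region is attenuated by the ratio
        r, _ = small_grid.retinal_coords()
        lo_f = spec.vector.magnitude / (2 * math.pi * small_grid.max_eccentricity) / small_grid.pixels_per_degree
        hi_f = spec.vector.magnitude / (2 * math.pi * small_grid.inner_mask_radius) / small_grid.pixels_per_degree
        sloped = fit_mtf(
            [(1 / f, 0.8 + 0.2 * (f - lo_f) / (hi_f - lo_f))
             for f in np.linspace(lo_f, hi_f, 8)]
        )
        out = mtf_compensate(img, spec, small_grid, sloped)
        periphery = np.abs(r - small_grid.max_eccentricity + 0.2) < 0.05
        ratio = out[periphery] / img[periphery]
        assert np.allclose(ratio, 0.8, atol=0.02)
        assert np.max(np.abs(out)) <= np.max(np.abs(img)) + 1e-12
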