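"""Generator contracts: symmetry, construction identities, noise statistics,
determinism, and conservation under blur."""

import math

import numpy as np
import pytest

from capscan.errors import GeometryError, ValidationError
from capscan.flip import normalize_trace, post_bleach
from capscan.simulate import (
    ChannelSpec,
    FlipModel,
    LifespanModel,
    NucleusSpec,
    cap_channel_pair,
    flat_density_field,
    gompertz_hazard,
    random_density_field,
    simulate_flip_trace,
    simulate_lifespan_cohort,
    simulate_nucleus_image,
    simulate_nucleus_stack,
    simulate_timer_pair,
    wrap_angle_difference,
)


def _angular_amplitude(spec, ring_image):
    """Recover the angular amplitude of a pre-blur ring raster by dividing out
    the known Gaussian radial factor at ring-adjacent pixels."""
    yy, xx = np.mgrid[0 : ring_image.shape[0], 0 : ring_image.shape[1]].astype(float)
    dx, dy = xx - spec.center[0], yy - spec.center[1]
    theta = np.arctan2(dy, dx)
    r = np.hypot(dx, dy)
    dr = r - spec.ellipse_radius(theta)
    on_ring = np.abs(dr) < 1.0
    radial = np.exp(-(dr**2) / (2.0 * spec.envelope_thickness**2))
    return theta[on_ring], ring_image[on_ring] / radial[on_ring]


class TestNucleusImage:
    def test_flat_density_ring_is_angularly_constant(self, circle_spec):
        """E=1, d=0, flat density: ring amplitude is uniform in angle."""
        _, truth = simulate_nucleus_image(
            circle_spec, [ChannelSpec(noise="none", psf_sigma=0.0)], seed=0
        )
        _, amp = _angular_amplitude(circle_spec, truth.noiseless[0])
        assert amp.max() / amp.min() == pytest.approx(1.0, abs=1e-9)

    def test_cap_enrichment_by_construction(self):
        """E=2: pre-blur mean ring amplitude over cap arc / complement = 2."""
        spec = NucleusSpec(
            semi_axes=(10.0, 10.0),
            npc_density_field=flat_density_field,
            cap_enrichment=2.0,
        )
        _, truth = simulate_nucleus_image(spec, [ChannelSpec(noise="none")], seed=0)
        theta, amp = _angular_amplitude(spec, truth.noiseless[0])
        in_cap = wrap_angle_difference(theta, spec.cap_center_angle) <= spec.cap_half_width
        assert amp[in_cap].mean() / amp[~in_cap].mean() == pytest.approx(2.0, abs=1e-6)

    def test_poisson_background_statistics(self):
        """Pure-background pixels follow the Poisson mean within 3 SEM."""
        spec = NucleusSpec(
            envelope_base_intensity=0.0,
            cluster_focus_intensity=0.0,
            center=(64.0, 64.0),
        )
        ch = ChannelSpec(background=50.0, gain=1.0, noise="poisson")
        img, _ = simulate_nucleus_image(spec, [ch], seed=42, shape=(128, 128))
        pixels = img.data[0].ravel()[:10_000]
        assert abs(pixels.mean() - 50.0) < 3.0 * math.sqrt(50.0 / 10_000)

    def test_photon_count_conserved_under_blur(self, circle_spec):
        """Normalized PSF blur preserves total intensity within 0.1%."""
        sums = []
        for sigma in (0.0, 2.0):
            _, truth = simulate_nucleus_image(
                circle_spec, [ChannelSpec(noise="none", psf_sigma=sigma, background=0.0)],
                seed=0,
            )
            sums.append(truth.expected[0].sum())
        assert abs(sums[1] - sums[0]) / sums[0] < 1e-3

    def test_cap_arc_matches_angular_definition_exactly(self):
        spec = NucleusSpec(cap_enrichment=2.0, cap_center_angle=1.0, cap_half_width=0.4)
        _, truth = simulate_nucleus_image(spec, cap_channel_pair(), seed=0)
        expected = np.flatnonzero(
            wrap_angle_difference(truth.contour_angles, 1.0) <= 0.4
        )
        assert np.array_equal(truth.cap_arc, expected)

    def test_identical_seed_identical_output(self, make_cap_image):
        a, _ = make_cap_image(enrichment=2.0, seed=7)
        b, _ = make_cap_image(enrichment=2.0, seed=7)
        assert np.array_equal(a.data, b.data)

    def test_ellipse_exceeding_canvas_raises(self):
        spec = NucleusSpec(center=(5.0, 32.0))
        with pytest.raises(GeometryError):
            simulate_nucleus_image(spec, [ChannelSpec()], seed=0)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(envelope_base_intensity=-1.0),
            dict(cap_enrichment=-0.5),
            dict(cap_half_width=4.0),
            dict(envelope_thickness=12.0),
        ],
    )
    def test_invalid_nucleus_parameters_raise(self, bad):
        with pytest.raises(ValidationError):
            simulate_nucleus_image(NucleusSpec(**bad), [ChannelSpec()], seed=0)

    def test_random_density_field_has_unit_mean_and_period(self):
        rng = np.random.default_rng(0)
        f = random_density_field(rng)
        theta = np.linspace(0, 2 * math.pi, 4096, endpoint=False)
        assert f(theta).mean() == pytest.approx(1.0, abs=1e-6)
        assert np.all(f(theta) >= 0)
        assert np.allclose(f(theta), f(theta + 2 * math.pi))

    def test_z_stack_has_middle_plane_in_focus(self, circle_spec):
        stack, truth = simulate_nucleus_stack(circle_spec, [ChannelSpec()], seed=0)
        assert stack.data.ndim == 4  # (Z, C, Y, X)
        focus = stack.data.shape[0] // 2
        ring_mass = [plane[0].sum() for plane in stack.data]
        assert np.argmax(ring_mass) == focus


class TestTimerPair:
    def test_equal_weights_give_unit_true_ratio(self, circle_spec):
        img = simulate_timer_pair(circle_spec, age_param=1.0, seed=0, noise="none")
        green, red = img.ground_truth.noiseless
        assert np.allclose(red, green)

    def test_zero_age_red_channel_is_background_only(self, circle_spec):
        img = simulate_timer_pair(circle_spec, age_param=0.0, seed=0, noise="none")
        red = img.data[1]
        assert np.allclose(red, ChannelSpec().background)

    def test_true_envelope_ratio_equals_age_param(self, circle_spec):
        img = simulate_timer_pair(circle_spec, age_param=0.37, seed=0, noise="none")
        green, red = img.ground_truth.noiseless
        mask = green > 1.0
        assert np.allclose(red[mask] / green[mask], 0.37)

    @pytest.mark.parametrize("age", [-0.1, 1.5])
    def test_age_param_out_of_range_raises(self, circle_spec, age):
        with pytest.raises(ValidationError):
            simulate_timer_pair(circle_spec, age_param=age, seed=0)


class TestFlipTraceGenerator:
    def test_no_exchange_means_constant_target(self):
        model = FlipModel(exchange_rate=0.0, acquisition_bleach_rate=0.0, noise_sigma=0.0)
        trace = simulate_flip_trace(model, seed=0)
        assert np.allclose(trace.target, trace.target[0])

    def test_infinite_bleach_gives_pure_exponential(self):
        """bleach_rate -> inf, k=0.2/s: target at 5 s post-onset is e^-1."""
        model = FlipModel(
            exchange_rate=0.2,
            bleach_rate=math.inf,
            acquisition_bleach_rate=0.0,
            noise_sigma=0.0,
        )
        trace = normalize_trace(simulate_flip_trace(model, seed=0))
        t, v = post_bleach(trace)
        i = int(np.argmin(np.abs(t - 5.0)))
        assert t[i] == pytest.approx(5.0)
        assert v[i] == pytest.approx(math.exp(-1.0), rel=1e-9)

    def test_cap_and_control_targets_identical_for_same_seed(self):
        model = FlipModel()
        a = simulate_flip_trace(model, "cap", seed=3)
        b = simulate_flip_trace(model, "control", seed=3)
        assert np.array_equal(a.target, b.target)
        assert np.array_equal(a.adjacent_cell, b.adjacent_cell)

    def test_adjacent_cell_decays_only_by_acquisition_bleaching(self):
        model = FlipModel(acquisition_bleach_rate=0.01, noise_sigma=0.0)
        trace = simulate_flip_trace(model, seed=0)
        frames = np.arange(model.n_frames)
        expected = trace.adjacent_cell[0] * np.exp(-0.01 * frames)
        assert np.allclose(trace.adjacent_cell, expected)

    def test_too_few_frames_raise(self):
        with pytest.raises(ValidationError):
            simulate_flip_trace(FlipModel(n_frames=5, pre_bleach_frames=5), seed=0)


class TestLifespanGenerator:
    def test_certain_death_at_first_division(self):
        model = LifespanModel(hazard=lambda t: np.ones_like(np.asarray(t, dtype=float)))
        cohort = simulate_lifespan_cohort(model, 100, seed=0)
        assert np.all(cohort.divisions == 1)
        assert np.all(cohort.observed)

    def test_constant_hazard_matches_geometric_mean(self):
        """h=0.1 per division: mean lifespan 1/h = 10."""
        model = LifespanModel(hazard=lambda t: np.full(np.shape(t), 0.1))
        cohort = simulate_lifespan_cohort(model, 5000, seed=1)
        assert abs(cohort.divisions.mean() - 10.0) < 0.5

    def test_same_seed_identical_cohorts(self):
        model = LifespanModel(censor_prob=0.02)
        a = simulate_lifespan_cohort(model, 200, seed=9)
        b = simulate_lifespan_cohort(model, 200, seed=9)
        assert np.array_equal(a.divisions, b.divisions)
        assert np.array_equal(a.observed, b.observed)

    def test_default_hazard_has_median_eighteen(self):
        assert LifespanModel().analytic_median() == 18

    def test_gompertz_hazard_is_clipped_and_increasing(self):
        h = gompertz_hazard(0.01, 0.3)
        t = np.arange(1, 60)
        vals = h(t)
        assert np.all(np.diff(vals) >= 0)
        assert vals.max() <= 1.0
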