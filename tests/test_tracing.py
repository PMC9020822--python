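"""Envelope tracing accuracy, equivariance, profile sampling and region
partitioning against generator ground truth."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import directed_hausdorff

from capscan.errors import BorderError, GeometryError, TracingError, ValidationError
from capscan.simulate import (
    ChannelSpec,
    NucleusSpec,
    cap_channel_pair,
    flat_density_field,
    simulate_nucleus_image,
)
from capscan.tracing import (
    find_cluster_focus,
    partition_regions,
    region_means,
    sample_profile,
    trace_envelope,
)

from conftest import circle_radial_errors


def hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])


class TestTraceEnvelope:
    def test_noiseless_circle_max_radial_error_below_half_pixel(self, circle_spec):
        img, _ = simulate_nucleus_image(circle_spec, [ChannelSpec(noise="none")], seed=0)
        contour = trace_envelope(img.data[0])
        errors = circle_radial_errors(contour, circle_spec.center, 10.0)
        assert errors.max() <= 0.5

    def test_rotation_equivariance(self, make_cap_image):
        """Rotating the image 90 deg rotates the contour (Hausdorff <= 0.5 px)."""
        img, _ = make_cap_image(enrichment=2.0, seed=1, noise="none")
        ch = img.data[0]
        p0 = trace_envelope(ch).points
        rotated = np.rot90(ch)  # (x, y) -> (y, W-1-x)
        p90 = trace_envelope(rotated).points
        expected = np.column_stack((p0[:, 1], ch.shape[1] - 1 - p0[:, 0]))
        assert hausdorff(p90, expected) <= 0.5

    def test_translation_equivariance(self, circle_spec):
        """Shifting the ring by a whole-pixel offset shifts the contour."""
        img, _ = simulate_nucleus_image(circle_spec, [ChannelSpec(noise="none")], seed=0)
        ch = img.data[0]
        shifted = np.roll(ch, shift=(3, -4), axis=(0, 1))  # dy=3, dx=-4
        p0 = trace_envelope(ch).points
        p1 = trace_envelope(shifted).points
        assert hausdorff(p1, p0 + np.array([-4.0, 3.0])) <= 0.5

    def test_rms_error_at_low_snr(self):
        """Peak SNR ~ 5: RMS radial error <= 1 px over seeds."""
        spec = NucleusSpec(
            semi_axes=(10.0, 10.0), envelope_base_intensity=32.0,
            npc_density_field=flat_density_field,
        )
        sq_errors = []
        for seed in range(10):
            img, _ = simulate_nucleus_image(
                spec, [ChannelSpec(background=10.0)], seed=seed
            )
            contour = trace_envelope(img.data[0])
            sq_errors.append(circle_radial_errors(contour, spec.center, 10.0) ** 2)
        assert math.sqrt(np.mean(sq_errors)) <= 1.0

    def test_blank_image_raises_no_envelope_found(self):
        rng = np.random.default_rng(0)
        blank = rng.poisson(40.0, (64, 64)).astype(float)
        with pytest.raises(TracingError):
            trace_envelope(blank, approx_center=(32.0, 32.0))

    def test_contour_is_angularly_ordered_and_closed(self, make_cap_image):
        img, _ = make_cap_image(seed=2)
        contour = trace_envelope(img.data[0])
        assert contour.n_samples == 180
        assert np.all(np.diff(contour.angles) > 0)
        # first point not duplicated at the end (closure implied)
        assert not np.allclose(contour.points[0], contour.points[-1])


class TestSampleProfile:
    def test_constant_image_gives_constant_profile(self, make_cap_image):
        img, _ = make_cap_image(seed=0)
        contour = trace_envelope(img.data[0])
        flat = np.full_like(img.data[:1], 7.5)
        profile = sample_profile(flat, contour)
        assert np.allclose(profile.values, 7.5)

    def test_cap_to_rest_profile_ratio_tracks_enrichment(self):
        """Noiseless E=2 ring: profile cap/rest mean in [1.8, 2.0]
        (PSF shoulder loss allowed)."""
        spec = NucleusSpec(cap_enrichment=2.0, npc_density_field=flat_density_field)
        img, truth = simulate_nucleus_image(spec, cap_channel_pair(noise="none"), seed=0)
        contour = trace_envelope(img.data[0])
        profile = sample_profile(img, contour)
        partition = partition_regions(
            profile, img, contour, cluster_focus=find_cluster_focus(img.data[1])
        )
        i_cap, i_rest = region_means(profile, partition, 0)
        bg = partition.background[0]
        assert 1.8 <= (i_cap - bg) / (i_rest - bg) <= 2.05

    def test_channels_sampled_at_identical_positions(self, make_coloc_image):
        img, _ = make_coloc_image(displaced=0.0, seed=3, noise="none")
        contour = trace_envelope(img.data[1])
        profile = sample_profile(img, contour)
        assert profile.values.shape == (2, 180)
        # d=0 noiseless: both channels share the density field exactly, so the
        # profiles are proportional
        r = np.corrcoef(profile.values[0], profile.values[1])[0, 1]
        assert r > 0.999

    def test_doubling_unit_linewidth_changes_mean_by_under_five_percent(
        self, circle_spec
    ):
        """Gaussian ring cross-section: widening the scan line from 1 to 2 px
        stays within the 5% envelope predicted by the cross-section integral."""
        img, _ = simulate_nucleus_image(circle_spec, [ChannelSpec(noise="none")], seed=0)
        contour = trace_envelope(img.data[0])
        m1 = sample_profile(img, contour, linewidth=1).values.mean()
        m2 = sample_profile(img, contour, linewidth=2).values.mean()
        assert abs(m2 - m1) / m1 < 0.05

    def test_linewidth_insensitivity_of_enrichment_ratio(self):
        """The cap/rest ratio is insensitive (<5%) to doubling the default
        linewidth, because the cross-section factor cancels in the ratio."""
        spec = NucleusSpec(cap_enrichment=2.0, npc_density_field=flat_density_field)
        img, _ = simulate_nucleus_image(spec, cap_channel_pair(noise="none"), seed=0)
        contour = trace_envelope(img.data[0])
        focus = find_cluster_focus(img.data[1])
        ratios = []
        for lw in (3, 6):
            profile = sample_profile(img, contour, linewidth=lw)
            partition = partition_regions(profile, img, contour, cluster_focus=focus)
            i_cap, i_rest = region_means(profile, partition, 0)
            ratios.append(i_cap / i_rest)
        assert abs(ratios[1] - ratios[0]) / ratios[0] < 0.05

    def test_contour_near_border_raises(self, circle_spec):
        img, _ = simulate_nucleus_image(circle_spec, [ChannelSpec(noise="none")], seed=0)
        contour = trace_envelope(img.data[0])
        contour.points[0] = (63.4, 32.0)
        with pytest.raises(BorderError):
            sample_profile(img, contour, linewidth=3)


class TestPartitionRegions:
    def test_cap_is_contiguous_and_centered_due_east(self, make_cap_image):
        img, _ = make_cap_image(enrichment=2.0, seed=0, noise="none")
        contour = trace_envelope(img.data[0])
        profile = sample_profile(img, contour)
        focus = (
            contour.center[0] + 9.0,
            contour.center[1],
        )  # due east of center
        partition = partition_regions(profile, img, contour, cluster_focus=focus)
        cap = partition.cap_indices
        # closed +/-30 deg window at 2 deg spacing: samples at -30..30 deg
        assert len(cap) == 31
        angles = contour.angles[cap]
        from capscan.simulate import wrap_angle_difference

        assert np.all(wrap_angle_difference(angles, 0.0) <= math.radians(30) + 1e-9)
        # contiguity modulo wrap-around
        gaps = np.diff(np.sort(cap))
        assert (gaps > 1).sum() <= 1

    def test_partition_covers_all_samples_disjointly(self, make_cap_image):
        img, _ = make_cap_image(enrichment=2.0, seed=1)
        contour = trace_envelope(img.data[0])
        profile = sample_profile(img, contour)
        partition = partition_regions(
            profile, img, contour, cluster_focus=find_cluster_focus(img.data[1])
        )
        merged = np.sort(np.concatenate([partition.cap_indices, partition.rest_indices]))
        assert np.array_equal(merged, np.arange(profile.n_samples))

    def test_detected_cap_overlaps_true_cap(self, make_cap_image):
        """Jaccard overlap of detected vs true cap indices >= 0.8."""
        img, truth = make_cap_image(enrichment=2.4, seed=5)
        contour = trace_envelope(img.data[0], n_samples=360)
        profile = sample_profile(img, contour)
        partition = partition_regions(
            profile, img, contour, cluster_focus=find_cluster_focus(img.data[1])
        )
        detected = set(partition.cap_indices.tolist())
        true = set(truth.cap_arc.tolist())
        jaccard = len(detected & true) / len(detected | true)
        assert jaccard >= 0.8

    def test_zero_background_outside_nucleus(self, circle_spec):
        img, _ = simulate_nucleus_image(
            circle_spec, [ChannelSpec(noise="none", background=0.0)], seed=0
        )
        contour = trace_envelope(img.data[0])
        profile = sample_profile(img, contour)
        partition = partition_regions(
            profile, img, contour, cap_bounds=(0.0, math.pi / 3)
        )
        assert partition.background[0] == pytest.approx(0.0, abs=1e-12)

    def test_focus_at_center_is_degenerate(self, make_cap_image):
        img, _ = make_cap_image(seed=0)
        contour = trace_envelope(img.data[0])
        profile = sample_profile(img, contour)
        with pytest.raises(GeometryError):
            partition_regions(profile, img, contour, cluster_focus=contour.center)

    def test_missing_focus_and_bounds_rejected(self, make_cap_image):
        img, _ = make_cap_image(seed=0)
        contour = trace_envelope(img.data[0])
        profile = sample_profile(img, contour)
        with pytest.raises(ValidationError):
            partition_regions(profile, img, contour)
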