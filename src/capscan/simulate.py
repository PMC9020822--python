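"""Synthetic fluorescence microscopy of yeast nuclei with known ground truth.

The generators in this module emulate the imaging regimes used to quantify
nucleoporin remodeling at DNA-circle-bound nuclear pore complexes:

* two-channel focal-plane images of a nucleus whose envelope is an elliptical
  ring with angularly varying NPC density, an enriched "cap" arc adjacent to
  a DNA-circle cluster focus, PSF blur and shot noise
  (:func:`simulate_nucleus_image`);
* tandem-fluorescent-timer channel pairs whose red/green envelope ratio
  encodes mean protein age (:func:`simulate_timer_pair`);
* two-compartment FLIP (fluorescence loss in photobleaching) ROI traces with
  equidistant-envelope and adjacent-cell controls (:func:`simulate_flip_trace`);
* replicative-lifespan cohorts with a configurable per-division death hazard
  (:func:`simulate_lifespan_cohort`).

Every generator is a pure function of its parameter object and an integer
seed, so downstream quantification can be tested against exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.ndimage import gaussian_filter

from .errors import GeometryError, ValidationError
from .flip import FlipTrace
from .lifespan import LifespanCohort

DensityField = Callable[[np.ndarray], np.ndarray]

_TWO_PI = 2.0 * math.pi


def wrap_angle_difference(a: np.ndarray | float, b: float) -> np.ndarray | float:
    """Absolute angular distance between ``a`` and ``b``, wrapped to [0, pi]."""
    d = np.mod(np.asarray(a) - b + math.pi, _TWO_PI) - math.pi
    return np.abs(d)


def flat_density_field(theta: np.ndarray) -> np.ndarray:
    """Angularly constant NPC density (mean 1 by construction)."""
    return np.ones_like(np.asarray(theta, dtype=float))


def fourier_log_density_field(
    amplitudes: Sequence[float],
    phases: Sequence[float],
    modes: Sequence[int],
) -> DensityField:
    """Positive, 2*pi-periodic density ``exp(sum_k a_k cos(k*theta + phi_k))``.

    The field is normalized to unit mean on a dense angular grid, so it is a
    valid NPC density modulation: nonnegative, periodic, mean 1 (to numerical
    precision).
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    phases = np.asarray(phases, dtype=float)
    modes = np.asarray(modes, dtype=int)
    if not (len(amplitudes) == len(phases) == len(modes)):
        raise ValidationError("amplitudes, phases and modes must have equal length")

    grid = np.linspace(0.0, _TWO_PI, 4096, endpoint=False)
    log_g = np.zeros_like(grid)
    for a, p, m in zip(amplitudes, phases, modes):
        log_g += a * np.cos(m * grid + p)
    norm = float(np.exp(log_g).mean())

    def density(theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        log_f = np.zeros_like(theta)
        for a, p, m in zip(amplitudes, phases, modes):
            log_f += a * np.cos(m * theta + p)
        return np.exp(log_f) / norm

    return density


def random_density_field(
    rng: np.random.Generator,
    n_modes: int = 6,
    sigma: float = 0.4,
    min_mode: int = 2,
) -> DensityField:
    """Draw a random angular NPC density field (log-amplitude std ~ ``sigma``).

    Models the punctate, cell-to-cell-variable distribution of NPCs along the
    nuclear envelope as a lognormal angular texture over low Fourier modes.
    """
    modes = np.arange(min_mode, min_mode + n_modes)
    amplitudes = sigma * math.sqrt(2.0 / n_modes) * rng.standard_normal(n_modes)
    phases = rng.uniform(0.0, _TWO_PI, n_modes)
    return fourier_log_density_field(amplitudes, phases, modes)


# ---------------------------------------------------------------------------
# parameter objects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NucleusSpec:
    """Geometry and true fluorophore distribution of one synthetic nucleus.

    Attributes
    ----------
    center : (x, y) in pixels (0-based, pixel centers at integers).
    semi_axes : ellipse semi-axes (a, b) in pixels.
    envelope_thickness : Gaussian radial width of the envelope ring, pixels.
    envelope_base_intensity : mean ring amplitude, photons/pixel.
    npc_density_field : nonnegative 2*pi-periodic mean-1 function of envelope
        angle shared by all channels (the "true NPC density"); ``None`` draws
        a random field from the seed stream.
    cap_center_angle, cap_half_width : angular position/extent (radians) of
        the NPC cap arc adjacent to the DNA-circle cluster.
    cap_enrichment : dimensionless factor E >= 0 multiplying ring intensity
        inside the cap arc.
    cluster_focus_intensity : amplitude of the DNA-circle-cluster blob placed
        just inside the envelope at ``cap_center_angle`` (rendered only in
        channels flagged as cluster markers).
    """

    center: tuple[float, float] = (32.0, 32.0)
    semi_axes: tuple[float, float] = (10.0, 8.5)
    envelope_thickness: float = 1.5
    envelope_base_intensity: float = 150.0
    npc_density_field: DensityField | None = None
    cap_center_angle: float = 0.0
    cap_half_width: float = math.radians(30.0)
    cap_enrichment: float = 1.0
    cluster_focus_intensity: float = 300.0

    def validate(self) -> None:
        a, b = self.semi_axes
        if not (min(a, b) > self.envelope_thickness > 0):
            raise ValidationError("require semi_axes > envelope_thickness > 0")
        if self.envelope_base_intensity < 0 or self.cluster_focus_intensity < 0:
            raise ValidationError("intensities must be nonnegative")
        if not (0.0 < self.cap_half_width < math.pi):
            raise ValidationError("cap_half_width must lie in (0, pi)")
        if self.cap_enrichment < 0:
            raise ValidationError("cap_enrichment must be >= 0")

    def ellipse_radius(self, theta: np.ndarray) -> np.ndarray:
        """Center-to-ring distance of the ellipse at geometric angle theta."""
        a, b = self.semi_axes
        return (a * b) / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)


@dataclass(frozen=True)
class ChannelSpec:
    """Per-channel labeling, optics and detection parameters.

    ``displaced_fraction`` d is the fraction of the channel's envelope signal
    that no longer follows the shared NPC density field (a nucleoporin leaving
    NPCs); it is redistributed along the arc with an independent random
    angular texture of mean 1, so total intensity is conserved in expectation
    while the angular structure decorrelates from the NPC density.
    """

    name: str = "GFP"
    displaced_fraction: float = 0.0
    maturation_weight: float = 1.0
    background: float = 40.0
    gain: float = 1.0
    # diffraction-limited sigma for GFP at NA 1.4 is ~0.077 um = 0.77 px at
    # 0.1 um/px; 0.75 px is the realistic default
    psf_sigma: float = 0.75
    noise: str = "poisson"  # "poisson", "gaussian", or "none"
    read_noise_sigma: float = 5.0  # used only for noise="gaussian"
    cluster_marker: bool = False

    def validate(self) -> None:
        if not (0.0 <= self.displaced_fraction <= 1.0):
            raise ValidationError("displaced_fraction must be in [0, 1]")
        if self.background < 0:
            raise ValidationError("background must be >= 0")
        if self.gain <= 0:
            raise ValidationError("gain must be > 0")
        if self.psf_sigma < 0:
            raise ValidationError("psf_sigma must be >= 0")
        if self.maturation_weight < 0:
            raise ValidationError("maturation_weight must be >= 0")
        if self.noise not in ("poisson", "gaussian", "none"):
            raise ValidationError(f"unknown noise model: {self.noise!r}")


@dataclass
class GroundTruth:
    """Exact generative state recorded alongside a simulated image."""

    contour: np.ndarray  # (n, 2) ordered closed polyline, (x, y)
    contour_angles: np.ndarray  # (n,) geometric angle of each contour point
    cap_arc: np.ndarray  # indices of contour samples inside the cap arc
    true_enrichment: float
    true_displaced: tuple[float, ...]
    noiseless: np.ndarray  # (C, Y, X) pre-blur, background-free images
    expected: np.ndarray  # (C, Y, X) blurred + background, pre-noise


@dataclass
class NucleusImage:
    """Multi-channel pixel raster with pixel-size metadata.

    ``data`` has axis order (channel, y, x); an optional z-stack variant uses
    (z, channel, y, x) with the middle plane in focus.
    """

    data: np.ndarray
    channel_names: list[str]
    pixel_size_um: float = 0.1
    ground_truth: GroundTruth | None = None

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def channel(self, index_or_name: int | str) -> np.ndarray:
        if isinstance(index_or_name, str):
            index_or_name = self.channel_names.index(index_or_name)
        return self.data[index_or_name]


# ---------------------------------------------------------------------------
# image generator
# ---------------------------------------------------------------------------


def _render_noiseless_channel(
    nucleus: NucleusSpec,
    channel: ChannelSpec,
    density: DensityField,
    displaced_field: DensityField,
    shape: tuple[int, int],
) -> np.ndarray:
    cx, cy = nucleus.center
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    dx, dy = xx - cx, yy - cy
    theta = np.arctan2(dy, dx)
    r = np.hypot(dx, dy)
    r_ring = nucleus.ellipse_radius(theta)

    d = channel.displaced_fraction
    angular = (1.0 - d) * density(theta) + d * displaced_field(theta)
    in_cap = wrap_angle_difference(theta, nucleus.cap_center_angle) <= nucleus.cap_half_width
    angular = angular * np.where(in_cap, nucleus.cap_enrichment, 1.0)

    sigma_t = nucleus.envelope_thickness
    ring = (
        nucleus.envelope_base_intensity
        * channel.maturation_weight
        * angular
        * np.exp(-((r - r_ring) ** 2) / (2.0 * sigma_t**2))
    )

    if channel.cluster_marker and nucleus.cluster_focus_intensity > 0:
        r_focus = nucleus.ellipse_radius(np.array(nucleus.cap_center_angle)) - 2.0 * sigma_t
        fx = cx + r_focus * math.cos(nucleus.cap_center_angle)
        fy = cy + r_focus * math.sin(nucleus.cap_center_angle)
        ring = ring + nucleus.cluster_focus_intensity * np.exp(
            -((xx - fx) ** 2 + (yy - fy) ** 2) / (2.0 * sigma_t**2)
        )
    return ring


def _apply_detection(
    expected: np.ndarray, channel: ChannelSpec, rng: np.random.Generator
) -> np.ndarray:
    if channel.noise == "poisson":
        return channel.gain * rng.poisson(expected).astype(float)
    if channel.noise == "gaussian":
        return channel.gain * expected + rng.normal(
            0.0, channel.read_noise_sigma, expected.shape
        )
    return channel.gain * expected


def simulate_nucleus_image(
    nucleus: NucleusSpec,
    channels: Sequence[ChannelSpec],
    seed: int,
    shape: tuple[int, int] = (64, 64),
    n_contour: int = 360,
) -> tuple[NucleusImage, GroundTruth]:
    """Render a multi-channel focal-plane image of one nucleus.

    The noiseless envelope intensity at angle theta is
    ``base * [(1-d)*density(theta) + d*displaced(theta)] * (E inside cap)``
    with a Gaussian radial cross-section; each channel is then PSF-blurred,
    background-added, gain-scaled and noised. Identical seeds give identical
    output.
    """
    nucleus.validate()
    for ch in channels:
        ch.validate()
    if not channels:
        raise ValidationError("at least one channel is required")

    a, b = nucleus.semi_axes
    cx, cy = nucleus.center
    margin = 3.0 * max(ch.psf_sigma for ch in channels)
    if (
        cx - (a + margin) < 0
        or cx + (a + margin) > shape[1] - 1
        or cy - (b + margin) < 0
        or cy + (b + margin) > shape[0] - 1
    ):
        raise GeometryError("ellipse plus 3*psf_sigma margin exceeds the canvas")

    rng = np.random.default_rng(seed)
    density = nucleus.npc_density_field or random_density_field(rng)
    # one independent displaced-pool texture per channel, drawn regardless of
    # d so the stream layout does not depend on parameter values
    displaced_fields = [random_density_field(rng) for _ in channels]

    noiseless = np.stack(
        [
            _render_noiseless_channel(nucleus, ch, density, disp, shape)
            for ch, disp in zip(channels, displaced_fields)
        ]
    )
    expected = np.stack(
        [
            gaussian_filter(noiseless[i], channels[i].psf_sigma, mode="constant")
            + channels[i].background
            if channels[i].psf_sigma > 0
            else noiseless[i] + channels[i].background
            for i in range(len(channels))
        ]
    )
    data = np.stack(
        [_apply_detection(expected[i], channels[i], rng) for i in range(len(channels))]
    )

    angles = np.linspace(0.0, _TWO_PI, n_contour, endpoint=False)
    radii = nucleus.ellipse_radius(angles)
    contour = np.column_stack((cx + radii * np.cos(angles), cy + radii * np.sin(angles)))
    cap_arc = np.flatnonzero(
        wrap_angle_difference(angles, nucleus.cap_center_angle) <= nucleus.cap_half_width
    )

    truth = GroundTruth(
        contour=contour,
        contour_angles=angles,
        cap_arc=cap_arc,
        true_enrichment=nucleus.cap_enrichment,
        true_displaced=tuple(ch.displaced_fraction for ch in channels),
        noiseless=noiseless,
        expected=expected,
    )
    image = NucleusImage(
        data=data,
        channel_names=[ch.name for ch in channels],
        ground_truth=truth,
    )
    return image, truth


def simulate_nucleus_stack(
    nucleus: NucleusSpec,
    channels: Sequence[ChannelSpec],
    seed: int,
    n_slices: int = 6,
    slice_spacing_um: float = 0.5,
    shape: tuple[int, int] = (64, 64),
) -> tuple[NucleusImage, GroundTruth]:
    """Optional z-stack emulation: middle plane in focus, off-focus planes
    rendered with extra blur and attenuated ring amplitude. Quantification
    always uses a single focal plane (the middle slice)."""
    image, truth = simulate_nucleus_image(nucleus, channels, seed, shape=shape)
    focus = n_slices // 2
    planes = []
    rng = np.random.default_rng(seed + 1)
    for z in range(n_slices):
        dz_um = abs(z - focus) * slice_spacing_um
        atten = math.exp(-((dz_um / 0.6) ** 2))
        extra_blur = 2.0 * dz_um / 0.1 * 0.1  # ~2 px extra sigma per micron defocus
        plane = np.stack(
            [
                _apply_detection(
                    gaussian_filter(truth.noiseless[i] * atten, channels[i].psf_sigma + extra_blur, mode="constant")
                    + channels[i].background,
                    channels[i],
                    rng,
                )
                for i in range(len(channels))
            ]
        )
        planes.append(plane)
    planes[focus] = image.data
    stack = NucleusImage(
        data=np.stack(planes),  # (Z, C, Y, X)
        channel_names=list(image.channel_names),
        ground_truth=truth,
    )
    return stack, truth


def cap_channel_pair(
    displaced_fraction: float = 0.0, noise: str = "poisson"
) -> list[ChannelSpec]:
    """Channels for cap-enrichment imaging: a GFP-nucleoporin ring plus a
    cluster-marker channel (TetR-mCherry-like) rendering only the DNA-circle
    cluster blob (no envelope ring)."""
    return [
        ChannelSpec(name="GFP", displaced_fraction=displaced_fraction, noise=noise),
        ChannelSpec(
            name="mCherry",
            maturation_weight=0.0,
            noise=noise,
            cluster_marker=True,
        ),
    ]


def coloc_channel_pair(
    displaced_fraction: float = 0.0,
    reference_displaced_fraction: float = 0.0,
    noise: str = "poisson",
) -> list[ChannelSpec]:
    """Channels for colocalization imaging: target-Nup GFP ring and
    reference-Nup mCherry ring sharing the NPC density field."""
    return [
        ChannelSpec(name="GFP", displaced_fraction=displaced_fraction, noise=noise),
        ChannelSpec(
            name="mCherry", displaced_fraction=reference_displaced_fraction, noise=noise
        ),
    ]


# ---------------------------------------------------------------------------
# tandem fluorescent timer
# ---------------------------------------------------------------------------


def simulate_timer_pair(
    nucleus: NucleusSpec,
    age_param: float,
    seed: int,
    shape: tuple[int, int] = (64, 64),
    noise: str = "poisson",
) -> NucleusImage:
    """Tandem-timer image pair: green channel fully matured, red channel
    weighted by ``age_param`` so the true red/green envelope ratio equals
    ``age_param`` exactly (before noise)."""
    if not (0.0 <= age_param <= 1.0):
        raise ValidationError("age_param must lie in [0, 1]")
    green = ChannelSpec(name="sfGFP", maturation_weight=1.0, noise=noise)
    red = ChannelSpec(name="mCherry", maturation_weight=age_param, noise=noise)
    image, _ = simulate_nucleus_image(nucleus, [green, red], seed, shape=shape)
    return image


# ---------------------------------------------------------------------------
# FLIP traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlipModel:
    """Two-compartment FLIP model: an envelope-bound pool exchanging with a
    nucleoplasmic pool that is depleted while the bleach laser is on.

    Bleaching is continuous from onset (every frame from
    ``pre_bleach_frames`` onward is a bleach frame), matching continuous
    nuclear-ROI bleaching during acquisition at 500 ms frame intervals.
    ``acquisition_bleach_rate`` is a per-frame global loss applied to all
    ROIs including the adjacent-cell control.
    """

    bound_fraction: float = 0.5
    exchange_rate: float = 0.2  # /s, envelope <-> nucleoplasm
    bleach_rate: float = 20.0  # /s on the nucleoplasmic pool; np.inf allowed
    acquisition_bleach_rate: float = 0.0  # per frame
    frame_interval: float = 0.5  # s
    n_frames: int = 60
    pre_bleach_frames: int = 5
    intensity_scale: float = 1000.0
    noise_sigma: float = 0.02  # relative gaussian noise per ROI sample

    def validate(self) -> None:
        if not (0.0 < self.bound_fraction < 1.0):
            raise ValidationError("bound_fraction must lie in (0, 1)")
        for name in ("exchange_rate", "bleach_rate", "acquisition_bleach_rate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.pre_bleach_frames < 1:
            raise ValidationError("pre_bleach_frames must be >= 1")
        if self.n_frames <= self.pre_bleach_frames:
            raise ValidationError("n_frames must exceed pre_bleach_frames")
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be > 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")


def simulate_flip_trace(model: FlipModel, bleach_target: str = "cap", seed: int = 0) -> FlipTrace:
    """Simulate one FLIP experiment (target ROI, equidistant-envelope control
    ROI, adjacent-cell control ROI).

    Both nuclear ROIs sit on the envelope and follow the same bound-pool
    kinetics; the adjacent-cell ROI decays only by acquisition bleaching.
    With ``bleach_rate = inf`` the bound pool decays as exp(-k*t) after
    bleach onset.
    """
    model.validate()
    if bleach_target not in ("cap", "control"):
        raise ValidationError("bleach_target must be 'cap' or 'control'")
    rng = np.random.default_rng(seed)

    k = model.exchange_rate
    b0 = model.bound_fraction
    n0 = 1.0 - b0
    k_on = k * b0 / n0  # detailed balance: pre-bleach pools are at equilibrium
    dt = model.frame_interval

    bound = np.empty(model.n_frames)
    nucleo = np.empty(model.n_frames)
    state = np.array([b0, n0])
    infinite_bleach = math.isinf(model.bleach_rate)
    prop_idle = expm(np.array([[-k, k_on], [k, -k_on]]) * dt)
    if not infinite_bleach:
        prop_bleach = expm(
            np.array([[-k, k_on], [k, -(k_on + model.bleach_rate)]]) * dt
        )
    for i in range(model.n_frames):
        bound[i], nucleo[i] = state
        bleaching = i >= model.pre_bleach_frames - 1  # active after last pre-bleach frame
        if bleaching and infinite_bleach:
            state = np.array([state[0] * math.exp(-k * dt), 0.0])
        else:
            state = (prop_bleach if bleaching else prop_idle) @ state

    frames = np.arange(model.n_frames)
    time = frames * dt
    acq = np.exp(-model.acquisition_bleach_rate * frames)
    scale = model.intensity_scale

    def noisy(series: np.ndarray) -> np.ndarray:
        if model.noise_sigma == 0:
            return series.copy()
        return series * (1.0 + model.noise_sigma * rng.standard_normal(series.shape))

    target = noisy(scale * bound * acq)
    control = noisy(scale * bound * acq)
    adjacent = noisy(scale * b0 * acq)

    return FlipTrace(
        time=time,
        target=target,
        control_ne=control,
        adjacent_cell=adjacent,
        bleach_onset_frame=model.pre_bleach_frames,
        label=bleach_target,
    )


# ---------------------------------------------------------------------------
# replicative lifespan cohorts
# ---------------------------------------------------------------------------


def gompertz_hazard(h0: float = 0.0035, g: float = 0.2) -> Callable[[np.ndarray], np.ndarray]:
    """Discrete Gompertz-like per-division death hazard min(1, h0*exp(g*t))."""
    if h0 < 0 or g < 0:
        raise ValidationError("h0 and g must be >= 0")

    def hazard(t: np.ndarray) -> np.ndarray:
        return np.minimum(1.0, h0 * np.exp(g * np.asarray(t, dtype=float)))

    return hazard


@dataclass(frozen=True)
class LifespanModel:
    """Per-division hazard model for replicative-lifespan cohorts.

    ``hazard`` maps division number (1-based) to a death probability in
    [0, 1]; the default is Gompertz-like with a median lifespan of about 18
    divisions, typical of wild-type cells on microfluidic platforms.
    ``censor_prob`` is the per-division probability of loss to follow-up.
    """

    hazard: Callable[[np.ndarray], np.ndarray] | None = None
    censor_prob: float = 0.0

    def validate(self) -> None:
        if not (0.0 <= self.censor_prob < 1.0):
            raise ValidationError("censor_prob must lie in [0, 1)")

    def hazard_function(self) -> Callable[[np.ndarray], np.ndarray]:
        return self.hazard if self.hazard is not None else gompertz_hazard()

    def analytic_survival(self, max_divisions: int = 100_000, s_floor: float = 1e-14) -> np.ndarray:
        """Exact survival probabilities S(t) for t = 1..T from the hazard,
        truncated once S drops below ``s_floor`` (or the hazard hits 1)."""
        h = self.hazard_function()
        surv: list[float] = []
        s = 1.0
        for t in range(1, max_divisions + 1):
            ht = float(h(t))
            if not (0.0 <= ht <= 1.0):
                raise ValidationError("hazard values must lie in [0, 1]")
            s *= 1.0 - ht
            surv.append(s)
            if s <= s_floor:
                break
        else:
            raise ValidationError("hazard never terminates simulated cells")
        return np.asarray(surv)

    def analytic_median(self) -> int:
        """Smallest division t with S(t) <= 0.5 under the model hazard."""
        surv = self.analytic_survival()
        idx = np.flatnonzero(surv <= 0.5)
        if len(idx) == 0:
            raise ValidationError("median undefined: survival never reaches 0.5")
        return int(idx[0] + 1)


def simulate_lifespan_cohort(
    model: LifespanModel, n_cells: int, seed: int, strain: str = "synthetic"
) -> LifespanCohort:
    """Simulate a cohort of mother cells dying per the model hazard.

    Death and censoring are drawn by inverse transform: the death division is
    the smallest t with cumulative mortality >= U, censoring (if enabled) is
    geometric per division, and ties resolve to death (a cell observed dying
    at division t is counted as dead, not lost).
    """
    model.validate()
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)

    surv = model.analytic_survival()
    u = rng.random(n_cells)
    # S(t) is decreasing; death at smallest t with 1 - S(t) >= u
    death = np.searchsorted(-surv, -(1.0 - u), side="left") + 1
    death = np.minimum(death, len(surv))

    if model.censor_prob > 0:
        censor = rng.geometric(model.censor_prob, n_cells)
        observed = death <= censor
        divisions = np.where(observed, death, censor)
    else:
        observed = np.ones(n_cells, dtype=bool)
        divisions = death

    return LifespanCohort(
        divisions=divisions.astype(int), observed=observed, strain=strain
    )


__all__ = [
    "ChannelSpec",
    "DensityField",
    "FlipModel",
    "GroundTruth",
    "LifespanModel",
    "NucleusImage",
    "NucleusSpec",
    "cap_channel_pair",
    "coloc_channel_pair",
    "flat_density_field",
    "fourier_log_density_field",
    "gompertz_hazard",
    "random_density_field",
    "simulate_flip_trace",
    "simulate_lifespan_cohort",
    "simulate_nucleus_image",
    "simulate_nucleus_stack",
    "simulate_timer_pair",
    "wrap_angle_difference",
]
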