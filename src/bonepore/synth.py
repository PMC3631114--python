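"""Synthetic fixtures with known ground truth for every pipeline stage.

No imaging or mechanical raw data are bundled with this package, so each
downstream stage is exercised against generated inputs that emulate the
acquisition conditions of a demineralized-bone study:

* microscopy: 8-bit grayscale fields (nominally 2048 x 2048 px at
  2.971 um^2/pixel) containing dark, pore-like elliptical objects with
  controllable axis ratio and boundary roughness on a bright tissue
  background, degraded by a smooth illumination gradient and
  salt-and-pepper noise;

* compression: nonlinear force-deformation curves for ~5 mm cubes, with
  a failure drop for transversely loaded (T) samples and monotone
  hardening for longitudinal (L) ones, recorded from a 0.1 N trigger;

* acoustic emission: 44,000 S/s waveforms of Gaussian baseline noise
  plus exponentially decaying sinusoidal bursts at Poisson times, a
  fraction of which carry 5-15x higher energy.

Objects are drawn by rasterizing an analytic boundary with pixel-center
inclusion, so true areas are computable (analytically for pure ellipses,
by quadrature for roughened ones) and digitization error is
quantifiable. All generators are bitwise reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .acoustic import AERecord
from .mechanics import FORCE_TRIGGER_N, MechanicalRecord
from .segmentation import CalibratedImage

__all__ = [
    "SyntheticImageSpec",
    "GroundTruthObject",
    "SyntheticCurveSpec",
    "SyntheticAESpec",
    "GroundTruthBurst",
    "PlacementError",
    "generate_pore_image",
    "generate_compression_curve",
    "generate_ae_waveform",
]

_ROUGHNESS_HARMONICS = np.arange(3, 9)  # k = 3..8: lobed, non-self-intersecting
_PLACEMENT_ATTEMPTS = 1000
_QUADRATURE_POINTS = 720  # theta samples for true-area quadrature / radii export


class PlacementError(ValueError):
    """Objects cannot be placed without overlap; the spec is overcrowded."""


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Parameters of one synthetic microscopy field.

    ``axis_length_range_px`` bounds the semi-major axis; the semi-minor
    axis follows from a ratio drawn in ``axis_ratio_range``.
    ``roughness_amplitude`` is the relative radial perturbation of the
    boundary (0 = smooth ellipse). ``n_border_objects`` of the objects
    are centered on a raster edge so they clip the border (for testing
    border exclusion); all others stay >= 2 px inside. Object boundaries
    are kept at least ``min_gap_px`` apart (default 5, wider than the 5x5
    median footprint) so neighbouring pores remain resolvable after
    denoising.
    """

    width_px: int = 2048
    height_px: int = 2048
    pixel_area_um2: float = 2.971
    n_objects: int = 30
    axis_length_range_px: tuple[float, float] = (8.0, 40.0)
    axis_ratio_range: tuple[float, float] = (1.0, 4.0)
    roughness_amplitude: float = 0.0
    background_level: int = 200
    object_level: int = 30
    illumination_gradient_amplitude: float = 0.0
    noise_fraction: float = 0.0
    n_border_objects: int = 0
    min_gap_px: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_area_um2 <= 0:
            raise ValueError("pixel_area_um2 must be positive")
        if self.n_objects < 0 or not 0 <= self.n_border_objects <= self.n_objects:
            raise ValueError("invalid object counts")
        lo, hi = self.axis_length_range_px
        if not 0 < lo <= hi:
            raise ValueError("axis_length_range_px must be positive and ordered")
        rlo, rhi = self.axis_ratio_range
        if not 1.0 <= rlo <= rhi:
            raise ValueError("axis ratios must be >= 1 and ordered")
        if not 0.0 <= self.roughness_amplitude < 0.5:
            raise ValueError("roughness_amplitude must be in [0, 0.5)")
        if not 0 <= self.object_level < self.background_level <= 255:
            raise ValueError("need 0 <= object_level < background_level <= 255")
        if not 0.0 <= self.illumination_gradient_amplitude < 1.0:
            raise ValueError("illumination_gradient_amplitude must be in [0, 1)")
        if not 0.0 <= self.noise_fraction <= 0.2:
            raise ValueError("noise_fraction must be in [0, 0.2]")
        if self.min_gap_px < 0:
            raise ValueError("min_gap_px must be non-negative")


@dataclass(frozen=True)
class GroundTruthObject:
    """The analytic description of one drawn pore."""

    centroid_px: tuple[float, float]  # (row, col)
    semi_major_px: float
    semi_minor_px: float
    orientation_rad: float
    true_area_um2: float
    true_elongation: float
    boundary_radii_px: np.ndarray = field(repr=False)
    touches_border: bool = False


def _radial_profile(
    theta: np.ndarray,
    a: float,
    b: float,
    phi: float,
    amp: float,
    harmonics_a: np.ndarray,
    harmonics_phase: np.ndarray,
) -> np.ndarray:
    """Boundary radius r(theta) of a roughened ellipse.

    r0 is the polar radius of the (a, b) ellipse rotated by phi; the
    perturbation is amp * sum_k a_k cos(k theta + phi_k) with the a_k
    normalized to unit absolute sum, so |r - r0| <= amp * r0 and the
    boundary never self-intersects for amp < 0.5.
    """
    psi = theta - phi
    r0 = a * b / np.sqrt((b * np.cos(psi)) ** 2 + (a * np.sin(psi)) ** 2)
    if amp == 0:
        return r0
    pert = np.zeros_like(theta)
    for k, ak, pk in zip(_ROUGHNESS_HARMONICS, harmonics_a, harmonics_phase):
        pert += ak * np.cos(k * theta + pk)
    return r0 * (1.0 + amp * pert)


def generate_pore_image(
    spec: SyntheticImageSpec,
) -> tuple[CalibratedImage, list[GroundTruthObject]]:
    """Draw non-overlapping pore-like objects on a bright background.

    Pixels whose center lies inside the analytic boundary take
    ``object_level``; the clean image is then multiplied by a smooth
    polynomial illumination field (mean 1, relative amplitude
    ``illumination_gradient_amplitude``) and ``noise_fraction`` of pixels
    are replaced by 0 or 255. Raises :class:`PlacementError` when an
    object cannot be placed in 1000 attempts.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    base = np.full((h, w), spec.background_level, dtype=float)
    truth: list[GroundTruthObject] = []
    placed: list[tuple[float, float, float]] = []  # (row, col, clearance radius)
    theta_q = np.linspace(0.0, 2.0 * math.pi, _QUADRATURE_POINTS, endpoint=False)

    for i in range(spec.n_objects):
        on_border = i < spec.n_border_objects
        a = rng.uniform(*spec.axis_length_range_px)
        ratio = rng.uniform(*spec.axis_ratio_range)
        b = a / ratio
        phi = rng.uniform(0.0, math.pi)
        amp = spec.roughness_amplitude
        if amp > 0:
            ha = rng.uniform(0.2, 1.0, size=_ROUGHNESS_HARMONICS.size)
            ha /= np.abs(ha).sum()
            hp = rng.uniform(0.0, 2.0 * math.pi, size=_ROUGHNESS_HARMONICS.size)
        else:
            ha = np.zeros(_ROUGHNESS_HARMONICS.size)
            hp = np.zeros(_ROUGHNESS_HARMONICS.size)
        r_max = a * (1.0 + amp)
        margin = r_max + 2.0

        for attempt in range(_PLACEMENT_ATTEMPTS):
            if on_border:
                # center on a randomly chosen edge so the object clips it
                edge = rng.integers(4)
                if edge == 0:
                    cr, cc = 0.0, rng.uniform(0, w - 1)
                elif edge == 1:
                    cr, cc = float(h - 1), rng.uniform(0, w - 1)
                elif edge == 2:
                    cr, cc = rng.uniform(0, h - 1), 0.0
                else:
                    cr, cc = rng.uniform(0, h - 1), float(w - 1)
            else:
                if h - 1 - margin <= margin or w - 1 - margin <= margin:
                    raise PlacementError("objects larger than the usable field")
                cr = rng.uniform(margin, h - 1 - margin)
                cc = rng.uniform(margin, w - 1 - margin)
            if all(
                math.hypot(cr - pr, cc - pc) > r_max + prad + spec.min_gap_px
                for pr, pc, prad in placed
            ):
                break
        else:
            raise PlacementError(
                f"could not place object {i + 1}/{spec.n_objects} in "
                f"{_PLACEMENT_ATTEMPTS} attempts; spec is overcrowded"
            )
        placed.append((cr, cc, r_max))

        # rasterize: pixel-center inclusion within the analytic boundary
        r0 = max(0, int(math.floor(cr - r_max - 1)))
        r1 = min(h - 1, int(math.ceil(cr + r_max + 1)))
        c0 = max(0, int(math.floor(cc - r_max - 1)))
        c1 = min(w - 1, int(math.ceil(cc + r_max + 1)))
        rows, cols = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
        dr = rows - cr
        dc = cols - cc
        dist = np.hypot(dr, dc)
        theta = np.arctan2(dc, dr)  # angle in pixel coordinates
        rb = _radial_profile(theta, a, b, phi, amp, ha, hp)
        inside = dist <= rb
        base[r0 : r1 + 1, c0 : c1 + 1][inside] = spec.object_level

        radii_q = _radial_profile(theta_q, a, b, phi, amp, ha, hp)
        if amp == 0:
            true_area = math.pi * a * b * spec.pixel_area_um2
        else:
            # area of a star-shaped region: 1/2 integral r(theta)^2 dtheta
            true_area = 0.5 * float((radii_q**2).sum()) * (
                2.0 * math.pi / _QUADRATURE_POINTS
            ) * spec.pixel_area_um2
        truth.append(
            GroundTruthObject(
                centroid_px=(cr, cc),
                semi_major_px=a,
                semi_minor_px=b,
                orientation_rad=phi,
                true_area_um2=true_area,
                true_elongation=a / b,
                boundary_radii_px=radii_q,
                touches_border=on_border,
            )
        )

    if spec.illumination_gradient_amplitude > 0:
        yy = np.linspace(-1.0, 1.0, h)[:, None]
        xx = np.linspace(-1.0, 1.0, w)[None, :]
        coef = rng.uniform(-1.0, 1.0, size=5)
        poly = (
            coef[0] * xx + coef[1] * yy + coef[2] * xx * yy
            + coef[3] * xx**2 + coef[4] * yy**2
        )
        poly -= poly.mean()
        peak = np.abs(poly).max()
        if peak > 0:
            field_ = 1.0 + spec.illumination_gradient_amplitude * poly / peak
            base = base * field_

    img = np.clip(np.rint(base), 0, 255).astype(np.uint8)

    if spec.noise_fraction > 0:
        n_noise = int(round(spec.noise_fraction * img.size))
        flat_idx = rng.choice(img.size, size=n_noise, replace=False)
        salt = rng.random(n_noise) < 0.5
        img.flat[flat_idx] = np.where(salt, 255, 0)

    return CalibratedImage(img, spec.pixel_area_um2), truth


def truth_to_dataframe(truth: list[GroundTruthObject]):
    """Tabulate a ground-truth list (one row per object) for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "centroid_row_px": [t.centroid_px[0] for t in truth],
            "centroid_col_px": [t.centroid_px[1] for t in truth],
            "semi_major_px": [t.semi_major_px for t in truth],
            "semi_minor_px": [t.semi_minor_px for t in truth],
            "orientation_rad": [t.orientation_rad for t in truth],
            "true_area_um2": [t.true_area_um2 for t in truth],
            "true_elongation": [t.true_elongation for t in truth],
            "touches_border": [t.touches_border for t in truth],
        }
    )


@dataclass(frozen=True)
class SyntheticCurveSpec:
    """Parameters of one synthetic compression curve.

    The loading law is stress = stress_scale * strain^nonlinearity_exponent
    (collagenous matrix hardens nonlinearly; exponent 1 gives a linear
    ramp for closed-form checks). T curves fail at ``failure_strain``
    with a >= 50% force drop within 2% strain; L curves are monotone
    non-decreasing through 60% strain.
    """

    sample_height_mm: float = 4.9
    cross_section_mm2: float = 24.0
    direction: str = "T"
    failure_strain: float = 0.5
    stress_scale_mpa: float = 12.0
    nonlinearity_exponent: float = 2.0
    noise_sd: float = 0.0
    n_samples: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_height_mm <= 0 or self.cross_section_mm2 <= 0:
            raise ValueError("sample geometry must be positive")
        if self.direction not in ("L", "T"):
            raise ValueError("direction must be 'L' or 'T'")
        if not 0.0 < self.failure_strain < 1.0:
            raise ValueError("failure_strain must be in (0, 1)")
        if self.stress_scale_mpa <= 0:
            raise ValueError("stress_scale_mpa must be positive")
        if self.nonlinearity_exponent < 1.0:
            raise ValueError("nonlinearity_exponent must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


_POST_FAILURE_LEVEL = 0.3  # residual force fraction after the failure drop
_DROP_STRAIN = 0.02  # strain interval over which the failure drop occurs
_L_MAX_STRAIN = 0.62  # L records run just past the 60% analysis window


def generate_compression_curve(spec: SyntheticCurveSpec) -> MechanicalRecord:
    """Synthesize a displacement-force record of one compression test.

    Recording starts at the first sample with force above the 0.1 N
    trigger. Gaussian force noise of ``noise_sd`` (N) is added when
    requested; L curves are kept monotone non-decreasing by a running
    maximum (emulating a stiff, non-failing response), and T curves keep
    a single global maximum at the failure point.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.direction == "T":
        # grid contains the failure strain exactly, so the force peak sits
        # on a sample and the ultimate point is recovered without grid bias
        max_strain = min(spec.failure_strain + 0.1, 0.99)
        n_pre = max(2, int(round(spec.n_samples * spec.failure_strain / max_strain)))
        n_post = max(2, spec.n_samples - n_pre)
        strain = np.concatenate(
            [
                np.linspace(0.0, spec.failure_strain, n_pre),
                np.linspace(spec.failure_strain, max_strain, n_post + 1)[1:],
            ]
        )
    else:
        max_strain = _L_MAX_STRAIN
        strain = np.linspace(0.0, max_strain, spec.n_samples)
    stress = spec.stress_scale_mpa * strain**spec.nonlinearity_exponent

    if spec.direction == "T":
        peak = spec.stress_scale_mpa * spec.failure_strain**spec.nonlinearity_exponent
        post = strain > spec.failure_strain
        drop = np.clip((strain - spec.failure_strain) / _DROP_STRAIN, 0.0, 1.0)
        stress = np.where(
            post, peak * (1.0 - (1.0 - _POST_FAILURE_LEVEL) * drop), stress
        )

    force = stress * spec.cross_section_mm2
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=force.size)
        if spec.direction == "T":
            # keep the failure peak the unique global maximum
            i_peak = int(np.argmax(force))
            noise[i_peak] = abs(noise[i_peak])
            force = force + noise
            head = np.delete(np.arange(force.size), i_peak)
            force[head] = np.minimum(force[head], force[i_peak] - 1e-9)
        else:
            force = np.maximum.accumulate(force + noise)
    force = np.maximum(force, 0.0)

    displacement = strain * spec.sample_height_mm
    start = int(np.argmax(force > FORCE_TRIGGER_N))
    if force[start] <= FORCE_TRIGGER_N:
        raise ValueError("curve never passes the 0.1 N recording trigger")
    return MechanicalRecord(
        displacement_mm=displacement[start:],
        force_n=force[start:],
        sample_height_mm=spec.sample_height_mm,
        cross_section_mm2=spec.cross_section_mm2,
        direction=spec.direction,
    )


@dataclass(frozen=True)
class SyntheticAESpec:
    """Parameters of one synthetic AE waveform.

    Bursts are exponentially decaying sinusoids at Poisson onset times;
    a ``high_energy_fraction`` of them carry energy multiplied by a
    factor drawn uniformly from ``high_energy_multiplier`` (the observed
    5-15x range of high-energy emissions over the basic signal). Energy
    is in the module's arbitrary units, V^2 * samples.
    """

    sampling_rate_hz: float = 44000.0
    duration_s: float = 10.0
    baseline_noise_sd: float = 0.002
    event_rate_hz: float = 5.0
    event_energy_scale: float = 1.0
    high_energy_fraction: float = 0.1
    high_energy_multiplier: tuple[float, float] | float = (5.0, 15.0)
    burst_decay_s: float = 0.003
    burst_freq_range_hz: tuple[float, float] = (2000.0, 8000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("sampling rate and duration must be positive")
        if self.baseline_noise_sd < 0:
            raise ValueError("baseline_noise_sd must be non-negative")
        if self.event_rate_hz < 0:
            raise ValueError("event_rate_hz must be non-negative")
        if self.event_energy_scale <= 0:
            raise ValueError("event_energy_scale must be positive")
        if not 0.0 <= self.high_energy_fraction <= 1.0:
            raise ValueError("high_energy_fraction must be in [0, 1]")
        m = self.high_energy_multiplier
        lo, hi = (m, m) if isinstance(m, (int, float)) else m
        if not 1.0 <= lo <= hi:
            raise ValueError("high_energy_multiplier must be >= 1 and ordered")


@dataclass(frozen=True)
class GroundTruthBurst:
    onset_s: float
    energy_au: float
    is_high_energy: bool


def generate_ae_waveform(
    spec: SyntheticAESpec,
) -> tuple[AERecord, list[GroundTruthBurst]]:
    """Gaussian baseline noise plus decaying sinusoidal bursts.

    Onset times follow a homogeneous Poisson process of rate
    ``event_rate_hz`` (strictly increasing, truncated to the record);
    each burst's noiseless energy (sum of squared samples) is returned as
    ground truth. ``event_rate_hz = 0`` yields pure noise and an empty
    truth list.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate_hz
    n = int(round(fs * spec.duration_s))
    if spec.baseline_noise_sd > 0:
        wave = rng.normal(0.0, spec.baseline_noise_sd, size=n)
    else:
        wave = np.zeros(n)

    truth: list[GroundTruthBurst] = []
    if spec.event_rate_hz > 0:
        t = 0.0
        onsets = []
        while True:
            t += rng.exponential(1.0 / spec.event_rate_hz)
            if t >= spec.duration_s:
                break
            onsets.append(t)
        m = spec.high_energy_multiplier
        mlo, mhi = (m, m) if isinstance(m, (int, float)) else m
        burst_len = int(round(5.0 * spec.burst_decay_s * fs))
        tt = np.arange(burst_len) / fs
        for onset in onsets:
            freq = rng.uniform(*spec.burst_freq_range_hz)
            phase = rng.uniform(0.0, 2.0 * math.pi)
            shape = np.exp(-tt / spec.burst_decay_s) * np.sin(
                2.0 * math.pi * freq * tt + phase
            )
            norm = float((shape**2).sum())
            if norm == 0:
                continue
            high = rng.random() < spec.high_energy_fraction
            energy = spec.event_energy_scale * (rng.uniform(mlo, mhi) if high else 1.0)
            burst = shape * math.sqrt(energy / norm)
            i0 = int(round(onset * fs))
            i1 = min(n, i0 + burst_len)
            if i1 <= i0:
                continue
            wave[i0:i1] += burst[: i1 - i0]
            actual_energy = float((burst[: i1 - i0] ** 2).sum())
            truth.append(GroundTruthBurst(onset_s=i0 / fs, energy_au=actual_energy, is_high_energy=high))

    rec = AERecord(waveform=wave, sampling_rate_hz=fs)
    return rec, truth
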