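"""Synthetic multi-channel carotid vessel-wall phantom.

The phantom emulates the measurement situation of a gated-vs-ungated
black-blood repeatability experiment:

* a 2D neck slice containing a circular lumen, a concentric vessel-wall
  annulus, and a rectangular block of sternocleidomastoid muscle on a zero
  background;
* double-inversion-recovery (DIR) prepared signal whose per-tissue amplitude
  follows the single-compartment longitudinal recovery
  ``m0 * |1 - 2 exp(-TI/T1) + exp(-TR/T1)|``;
* cardiac gating: the effective TR of a gated shot is ``rr_multiple`` times an
  R-R interval drawn per shot from a truncated-normal heart-rate model, so the
  image amplitude (the mean DIR signal over all shots) fluctuates between
  repeat scans, while ungated sequences keep TR fixed;
* a 4-channel receive array: independent complex Gaussian noise is added per
  channel and the channels are combined by root sum of squares, which makes
  pure-noise regions central-chi distributed (SD ~ 0.695 sigma for four
  channels — the origin of the SNR correction factor);
* a spatially matched noise-only image (zero RF amplitude, fixed receiver
  gain): same per-channel sigma, zero underlying signal.

Repeat scans share geometry exactly (no repositioning); gated repeats jitter
the lumen radius by a bounded zero-mean draw to emulate sampling a random
cardiac phase, ungated repeats use the phase-averaged radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from .exceptions import GeometryError, InvalidParameterError
from .protocols import ProtocolParams

__all__ = [
    "TissueProperties",
    "PhantomScene",
    "CardiacModel",
    "AcquisitionSet",
    "dir_signal",
    "dir_recovery_factor",
    "null_inversion_time",
    "sample_effective_tr",
    "render_scene",
    "sum_of_squares_noise",
    "central_chi_sd_factor",
    "raster_fraction_circle",
    "raster_fraction_rect",
    "calibrated_tissues",
    "default_scene",
    "DEFAULT_T1_MS",
    "AMPLITUDE_TARGETS",
]

# Longitudinal relaxation times at 3T. The lumen is an effective residual
# compartment (partial volume / slow flow remaining after black-blood
# preparation), not perfectly-nulled blood, so it carries its own T1.
DEFAULT_T1_MS: dict[str, float] = {"wall": 1115.0, "muscle": 1420.0, "lumen": 1200.0}

# Relative amplitude targets (wall = 1) used when calibrating tissue m0 for a
# protocol; ratios follow the observed muscle/wall/lumen SNR ratios of gated
# carotid acquisitions at each weighting.
AMPLITUDE_TARGETS: dict[str, dict[str, float]] = {
    "T1W": {"wall": 1.0, "muscle": 1.72, "lumen": 0.29},
    "T2W": {"wall": 1.0, "muscle": 1.28, "lumen": 0.37},
}


@dataclass(frozen=True)
class TissueProperties:
    """Relaxation and equilibrium-signal description of one tissue class."""

    label: str
    t1_ms: float
    m0: float

    def __post_init__(self) -> None:
        if self.label != "background" and self.t1_ms <= 0:
            raise InvalidParameterError("t1_ms must be > 0 for non-background tissue")
        if self.m0 < 0:
            raise InvalidParameterError("m0 must be >= 0")


@dataclass(frozen=True)
class CardiacModel:
    """Truncated-normal R-R interval model.

    ``sd_rr_ms`` is the shot-to-shot R-R standard deviation; draws below
    ``rr_floor_ms`` are clipped (no physiologic R-R is arbitrarily short).
    """

    mean_rr_ms: float = 1000.0
    sd_rr_ms: float = 50.0
    rr_floor_ms: float = 300.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mean_rr_ms <= 0:
            raise InvalidParameterError("mean_rr_ms must be > 0")
        if self.sd_rr_ms < 0:
            raise InvalidParameterError("sd_rr_ms must be >= 0")
        if self.rr_floor_ms <= 0:
            raise InvalidParameterError("rr_floor_ms must be > 0")


@dataclass(frozen=True)
class PhantomScene:
    """Geometry + tissue content of the synthetic neck slice.

    All coordinates are in mm with the pixel-center convention: pixel (row,
    col) sits at ``(y, x) = (row, col) * pixel_spacing_mm``.  ``muscle_region``
    is ``(center_x, center_y, width, height)``.
    """

    pixel_spacing_mm: float = 0.390625
    matrix: tuple[int, int] = (256, 256)
    lumen_center_mm: tuple[float, float] = (50.0, 35.0)
    lumen_radius_mm: float = 3.78
    outer_radius_mm: float = 4.82
    muscle_region: tuple[float, float, float, float] = (50.0, 65.0, 12.0, 12.0)
    tissues: dict[str, TissueProperties] = field(default_factory=dict)
    pulsation_amplitude_mm: float = 0.4

    def __post_init__(self) -> None:
        if self.pixel_spacing_mm <= 0:
            raise InvalidParameterError("pixel_spacing_mm must be > 0")
        if not (self.outer_radius_mm > self.lumen_radius_mm > 0):
            raise GeometryError("need outer_radius_mm > lumen_radius_mm > 0")
        if self.pulsation_amplitude_mm < 0:
            raise InvalidParameterError("pulsation_amplitude_mm must be >= 0")
        h_mm = (self.matrix[0] - 1) * self.pixel_spacing_mm
        w_mm = (self.matrix[1] - 1) * self.pixel_spacing_mm
        cx, cy = self.lumen_center_mm
        r = self.outer_radius_mm + self.pulsation_amplitude_mm
        if not (r <= cx <= w_mm - r and r <= cy <= h_mm - r):
            raise GeometryError("vessel extends outside the field of view")
        mx, my, mw, mh = self.muscle_region
        if not (0 <= mx - mw / 2 and mx + mw / 2 <= w_mm and 0 <= my - mh / 2 and my + mh / 2 <= h_mm):
            raise GeometryError("muscle region extends outside the field of view")

    @property
    def fov_mm(self) -> tuple[float, float]:
        return (self.matrix[0] * self.pixel_spacing_mm, self.matrix[1] * self.pixel_spacing_mm)


@dataclass
class AcquisitionSet:
    """Signal image + matched noise-only image for one sequence and repeat.

    ``per_channel_sigma`` and ``truth`` retain simulation ground truth (the
    Gaussian sigma per channel, rendered tissue amplitudes, and the geometry
    actually rasterized) for validation; an analysis pipeline must not use
    them as measurements.
    """

    signal_image: np.ndarray
    noise_image: np.ndarray
    protocol: ProtocolParams
    repeat_index: int
    channel_count: int
    per_channel_sigma: float
    pixel_spacing_mm: float
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.signal_image.shape != self.noise_image.shape:
            raise InvalidParameterError("signal and noise images must share a grid")
        if (self.signal_image < 0).any() or (self.noise_image < 0).any():
            raise InvalidParameterError("magnitude images must be non-negative")


def dir_recovery_factor(t1_ms: float, ti_ms: float, tr_ms):
    """Signed longitudinal recovery factor ``1 - 2 exp(-TI/T1) + exp(-TR/T1)``.

    Negative values mean the magnetization is still inverted at readout; the
    measured image magnitude takes the modulus only after shots are averaged.
    """
    tr = np.asarray(tr_ms, dtype=float)
    if np.any(tr <= 0) or ti_ms is None or ti_ms <= 0:
        raise InvalidParameterError("TI and TR must be > 0")
    if np.any(ti_ms >= tr):
        raise InvalidParameterError("require TI < TR")
    out = 1.0 - 2.0 * np.exp(-ti_ms / t1_ms) + np.exp(-tr / t1_ms)
    return out if out.ndim else float(out)


def dir_signal(tissue: TissueProperties, ti_ms, tr_ms):
    """Double-inversion-recovery magnitude signal for one tissue.

    ``m0 * |1 - 2 exp(-TI/T1) + exp(-TR/T1)|``; ``tr_ms`` may be an array of
    per-shot repetition times, in which case an array is returned.
    """
    out = tissue.m0 * np.abs(dir_recovery_factor(tissue.t1_ms, ti_ms, tr_ms))
    return out if np.ndim(out) else float(out)


def null_inversion_time(t1_ms: float, tr_ms: float) -> float:
    """Inversion time that nulls a tissue of ``t1_ms`` at repetition ``tr_ms``."""
    if t1_ms <= 0 or tr_ms <= 0:
        raise InvalidParameterError("t1_ms and tr_ms must be > 0")
    return -t1_ms * math.log((1.0 + math.exp(-tr_ms / t1_ms)) / 2.0)


def sample_effective_tr(
    protocol: ProtocolParams,
    cardiac: CardiacModel,
    n_shots: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-shot effective repetition times.

    Gated: ``rr_multiple`` times an independent truncated-normal R-R draw per
    shot.  Ungated: the protocol's fixed TR for every shot.
    """
    if n_shots < 1:
        raise InvalidParameterError("n_shots must be >= 1")
    if not protocol.gated:
        return np.full(n_shots, protocol.tr_ms, dtype=float)
    if rng is None:
        rng = np.random.default_rng(cardiac.seed)
    rr = cardiac.mean_rr_ms + cardiac.sd_rr_ms * rng.standard_normal(n_shots)
    rr = np.maximum(rr, cardiac.rr_floor_ms)
    return protocol.rr_multiple * rr


def central_chi_sd_factor(channels: int) -> float:
    """SD of a root-sum-of-squares pure-noise magnitude, per unit channel sigma.

    Closed form for the central chi distribution with ``2 * channels`` degrees
    of freedom: ``sqrt(2N - 2 * (Gamma(N + 1/2) / Gamma(N))^2)``.  For four
    channels this is ~0.6953 — the reciprocal basis of the 0.695 SNR
    correction used with four-channel coils.
    """
    if channels < 1:
        raise InvalidParameterError("channels must be >= 1")
    n = float(channels)
    ratio = math.exp(gammaln(n + 0.5) - gammaln(n))
    return math.sqrt(2.0 * n - 2.0 * ratio * ratio)


def sum_of_squares_noise(
    shape: tuple[int, int], sigma: float, channels: int, rng: np.random.Generator
) -> np.ndarray:
    """Root-sum-of-squares combination of pure complex Gaussian channel noise."""
    if sigma == 0:
        return np.zeros(shape, dtype=float)
    re = rng.standard_normal((channels, *shape))
    im = rng.standard_normal((channels, *shape))
    return sigma * np.sqrt((re * re + im * im).sum(axis=0))


def _supersampled_coords(shape, spacing, supersample):
    s = supersample
    rows = (np.arange(shape[0] * s) + 0.5) / s - 0.5
    cols = (np.arange(shape[1] * s) + 0.5) / s - 0.5
    return rows * spacing, cols * spacing


def _block_mean(a: np.ndarray, s: int) -> np.ndarray:
    h, w = a.shape[0] // s, a.shape[1] // s
    return a.reshape(h, s, w, s).mean(axis=(1, 3))


def raster_fraction_circle(
    shape: tuple[int, int],
    spacing_mm: float,
    center_mm: tuple[float, float],
    radius_mm: float,
    supersample: int = 4,
) -> np.ndarray:
    """Per-pixel area fraction covered by a disc, by supersampled rasterization."""
    y, x = _supersampled_coords(shape, spacing_mm, supersample)
    cx, cy = center_mm
    inside = (x[None, :] - cx) ** 2 + (y[:, None] - cy) ** 2 <= radius_mm**2
    return _block_mean(inside.astype(float), supersample)


def raster_fraction_rect(
    shape: tuple[int, int],
    spacing_mm: float,
    region_mm: tuple[float, float, float, float],
    supersample: int = 4,
) -> np.ndarray:
    """Per-pixel area fraction covered by an axis-aligned rectangle."""
    y, x = _supersampled_coords(shape, spacing_mm, supersample)
    cx, cy, w, h = region_mm
    inside = (
        (np.abs(x[None, :] - cx) <= w / 2) & (np.abs(y[:, None] - cy) <= h / 2)
    )
    return _block_mean(inside.astype(float), supersample)


def calibrated_tissues(
    protocol: ProtocolParams,
    weighting: str,
    targets: dict[str, float] | None = None,
    t1_ms: dict[str, float] | None = None,
    reference_rr_ms: float = 1000.0,
    recovery_floor: float = 0.01,
) -> dict[str, TissueProperties]:
    """Tissues whose m0 puts amplitudes at ``targets`` under the nominal TR.

    The nominal TR of a gated protocol is evaluated at the reference R-R
    (60 bpm by default); gating-induced fluctuation then acts around these
    calibrated amplitudes.  ``recovery_floor`` bounds the |recovery factor|
    used in the division: a tissue whose null TR falls at the nominal TR
    would otherwise get an unbounded m0 and unphysical TR sensitivity — with
    the floor it simply renders darker than its target, which is what a
    near-nulled tissue does.
    """
    targets = dict(targets if targets is not None else AMPLITUDE_TARGETS[weighting])
    t1_ms = dict(t1_ms if t1_ms is not None else DEFAULT_T1_MS)
    tr_nominal = protocol.rr_multiple * reference_rr_ms if protocol.gated else protocol.tr_ms
    tissues = {}
    for label, amp in targets.items():
        f = abs(dir_recovery_factor(t1_ms[label], protocol.ti_ms, tr_nominal))
        tissues[label] = TissueProperties(
            label=label, t1_ms=t1_ms[label], m0=amp / max(f, recovery_floor)
        )
    return tissues


def default_scene(
    protocol: ProtocolParams,
    weighting: str = "T1W",
    matrix: tuple[int, int] = (256, 256),
    pixel_spacing_mm: float = 0.390625,
    **kw,
) -> PhantomScene:
    """Default scene: 0.45 cm^2 lumen, 0.28 cm^2 wall annulus, 12 mm muscle block.

    Geometry defaults place the vessel and muscle inside the FOV for any
    matrix of at least ~64 pixels; tissue m0 is calibrated for ``protocol``.
    """
    h_mm = (matrix[0] - 1) * pixel_spacing_mm
    w_mm = (matrix[1] - 1) * pixel_spacing_mm
    geom = dict(
        lumen_center_mm=(0.5 * w_mm, 0.35 * h_mm),
        muscle_region=(0.5 * w_mm, 0.72 * h_mm, 12.0, 12.0),
    )
    geom.update(kw)
    return PhantomScene(
        pixel_spacing_mm=pixel_spacing_mm,
        matrix=matrix,
        tissues=calibrated_tissues(protocol, weighting),
        **geom,
    )


def render_scene(
    scene: PhantomScene,
    protocol: ProtocolParams,
    cardiac: CardiacModel,
    repeat_index: int,
    seed: int,
    per_channel_sigma: float = 0.1,
    channel_count: int = 4,
    supersample: int = 4,
) -> AcquisitionSet:
    """Render one repeat acquisition: signal image plus matched noise-only image.

    Per-tissue amplitude is ``signal_scale`` times the mean DIR signal over the
    per-shot effective TRs, so gated repeats acquire amplitude fluctuation
    through heart-rate variability.  Gated repeats also jitter the lumen
    radius by a uniform zero-mean draw bounded by the pulsation amplitude
    (ungated acquisitions average over the cardiac cycle and keep the base
    radius).  Complex Gaussian noise is added per channel before
    root-sum-of-squares combination; the noise-only image reuses the same
    sigma with zero signal, emulating a zero-RF acquisition at fixed receiver
    gain.  Identical seeds give bit-identical output.
    """
    if per_channel_sigma < 0:
        raise InvalidParameterError("per_channel_sigma must be >= 0")
    if channel_count < 1:
        raise InvalidParameterError("channel_count must be >= 1")
    if repeat_index < 1:
        raise InvalidParameterError("repeat_index starts at 1")
    for label in ("lumen", "wall", "muscle"):
        if label not in scene.tissues:
            raise InvalidParameterError(f"scene is missing tissue {label!r}")

    rng = np.random.default_rng(seed)
    n_shots = protocol.shots_per_image()
    trs = sample_effective_tr(protocol, cardiac, n_shots, rng=rng)
    # A sequence cannot cycle faster than its inversion preparation.
    if protocol.ti_ms is not None:
        trs = np.maximum(trs, protocol.ti_ms + 1.0)
    # Shots contribute signed recovery; the magnitude is taken on the
    # shot-averaged signal (image-level modulus), not per shot.
    amplitudes = {
        label: protocol.signal_scale
        * abs(float(np.mean(t.m0 * dir_recovery_factor(t.t1_ms, protocol.ti_ms, trs))))
        for label, t in scene.tissues.items()
    }

    # Pulsation distends lumen and outer boundary together, conserving the
    # wall cross-section; gated repeats sample a random cardiac phase while
    # ungated repeats average over the cycle (base radius).
    lumen_radius = scene.lumen_radius_mm
    outer_radius = scene.outer_radius_mm
    if protocol.gated and scene.pulsation_amplitude_mm > 0:
        lumen_radius += rng.uniform(-scene.pulsation_amplitude_mm, scene.pulsation_amplitude_mm)
        lumen_radius = max(lumen_radius, 0.25 * scene.lumen_radius_mm)
        outer_radius = math.sqrt(
            lumen_radius**2 + scene.outer_radius_mm**2 - scene.lumen_radius_mm**2
        )

    shape = scene.matrix
    sp = scene.pixel_spacing_mm
    f_lumen = raster_fraction_circle(shape, sp, scene.lumen_center_mm, lumen_radius, supersample)
    f_outer = raster_fraction_circle(shape, sp, scene.lumen_center_mm, outer_radius, supersample)
    f_muscle = raster_fraction_rect(shape, sp, scene.muscle_region, supersample)
    if np.any((f_outer > 0) & (f_muscle > 0)):
        raise GeometryError("vessel and muscle regions overlap")
    f_wall = np.clip(f_outer - f_lumen, 0.0, 1.0)
    ideal = (
        amplitudes["lumen"] * f_lumen
        + amplitudes["wall"] * f_wall
        + amplitudes["muscle"] * f_muscle
    )

    if per_channel_sigma == 0:
        signal_image = ideal.copy()
        noise_image = np.zeros_like(ideal)
    else:
        per_ch = ideal / math.sqrt(channel_count)
        re = per_ch + per_channel_sigma * rng.standard_normal((channel_count, *shape))
        im = per_channel_sigma * rng.standard_normal((channel_count, *shape))
        signal_image = np.sqrt((re * re + im * im).sum(axis=0))
        noise_image = sum_of_squares_noise(shape, per_channel_sigma, channel_count, rng)

    truth = {
        "amplitudes": amplitudes,
        "lumen_radius_mm": lumen_radius,
        "outer_radius_mm": outer_radius,
        "lumen_center_mm": scene.lumen_center_mm,
        "muscle_region": scene.muscle_region,
        "mean_effective_tr_ms": float(np.mean(trs)),
        "n_shots": n_shots,
        "seed": seed,
    }
    return AcquisitionSet(
        signal_image=signal_image,
        noise_image=noise_image,
        protocol=protocol,
        repeat_index=repeat_index,
        channel_count=channel_count,
        per_channel_sigma=per_channel_sigma,
        pixel_spacing_mm=sp,
        truth=truth,
    )
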