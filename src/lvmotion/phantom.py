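"""Synthetic tagged-MRI phantom with exactly model-consistent motion.

Frames are rendered by INVERSE-mapping every pixel center back to its
end-diastolic material coordinate and testing membership in the
undeformed annulus / tag grid, so the rendered tag pattern deforms
exactly according to the motion model (and exercises the closed-form
inverse in production code).  Tag contrast fades over the cycle and
additive Gaussian noise is optional; both are reproducible from the
seed.

Defaults emulate the acquisition geometry the fitter targets: 7.0 mm
tag spacing, 1.5 mm tag width, 11 frames per cycle with frame 0 =
end-diastole, ~1 mm pixels.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .preprocess import LVGeometry, TaggedSeries
from .transform import _inverse_xy

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "default_geometry",
    "default_profiles",
    "render_frame",
    "render_series",
    "PEAK_VALUES",
]

# printed normalized peak values (alpha/r_epi, beta/r_epi) at the three levels
PEAK_VALUES = {"apex": (0.34, 0.2), "mid": (0.4, 0.0), "base": (0.3, -0.08)}
PEAK_PHASE = 0.4


def default_geometry(frame_shape: tuple[int, int] = (256, 256)) -> LVGeometry:
    """256x256 frame, 1 mm pixels, r_epi 30 mm, r_endo 15 mm.

    The 0.5 radius ratio keeps realistic peak contractions inside the
    model's validity domain at the endocardium.
    """
    center = ((frame_shape[0] - 1) / 2.0, (frame_shape[1] - 1) / 2.0)
    return LVGeometry(center=center, r_epi=30.0, r_endo=15.0, pixel_spacing=(1.0, 1.0))


@dataclasses.dataclass
class PhantomSpec:
    """Full description of a synthetic tagged series."""

    geometry: LVGeometry = dataclasses.field(default_factory=default_geometry)
    frame_shape: tuple[int, int] = (256, 256)
    tag_spacing: float = 7.0
    tag_width: float = 1.5
    n_frames: int = 11
    T_cardiac: float = 1.0
    alpha_profile: np.ndarray | None = None  # normalized alpha/r_epi per frame
    beta_profile: np.ndarray | None = None  # normalized beta/r_epi per frame
    fading: np.ndarray | None = None  # tag/tissue contrast in (0, 1]; default 1.0 -> 0.4
    noise_sigma: float = 0.0
    seed: int = 0
    tissue_intensity: float = 0.9
    background_intensity: float = 0.15

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not (0 < self.tag_width < self.tag_spacing):
            raise ValueError("requires 0 < tag_width < tag_spacing")
        if self.alpha_profile is None:
            self.alpha_profile = np.zeros(self.n_frames)
        if self.beta_profile is None:
            self.beta_profile = np.zeros(self.n_frames)
        self.alpha_profile = np.asarray(self.alpha_profile, dtype=float)
        self.beta_profile = np.asarray(self.beta_profile, dtype=float)
        if len(self.alpha_profile) != self.n_frames or len(self.beta_profile) != self.n_frames:
            raise ValueError("profiles must have n_frames entries")
        if self.alpha_profile[0] != 0.0 or self.beta_profile[0] != 0.0:
            raise ValueError("frame 0 is end-diastole: profiles must start at (0, 0)")
        if self.fading is None:
            self.fading = np.linspace(1.0, 0.4, self.n_frames)
        self.fading = np.asarray(self.fading, dtype=float)
        if len(self.fading) != self.n_frames:
            raise ValueError("fading must have n_frames entries")


@dataclasses.dataclass
class GroundTruth:
    """Generator-side truth used by recovery tests."""

    alpha_norm: np.ndarray
    beta_norm: np.ndarray
    tag_masks: list[np.ndarray]
    geometry: LVGeometry


def default_profiles(level: str, n_frames: int = 11) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear normalized profiles for a slice level.

    The profile rises from 0 at end-diastole to the level's printed peak
    near phase 0.4, then falls back toward 0 by the end of the cycle.
    The peak vertex is snapped to the sampled phase closest to 0.4 so
    the series actually attains the peak value at a frame.  The
    mid-ventricle beta profile is identically zero (no rotation there).
    """
    if level not in PEAK_VALUES:
        raise ValueError(f"unknown slice level {level!r}; expected one of {sorted(PEAK_VALUES)}")
    a_peak, b_peak = PEAK_VALUES[level]
    phases = np.arange(n_frames) / n_frames
    peak_phase = phases[np.argmin(np.abs(phases - PEAK_PHASE))]

    def triangle(peak: float) -> np.ndarray:
        if peak == 0.0:
            return np.zeros(n_frames)
        up = phases <= peak_phase
        prof = np.empty(n_frames)
        prof[up] = peak * phases[up] / peak_phase
        prof[~up] = peak * (1.0 - phases[~up]) / (1.0 - peak_phase)
        return prof

    return triangle(a_peak), triangle(b_peak)


def _grid_distance(coord: np.ndarray, spacing: float) -> np.ndarray:
    """Distance from a coordinate to the nearest grid line (lines at k*spacing)."""
    return np.abs((coord + 0.5 * spacing) % spacing - 0.5 * spacing)


def render_frame(spec: PhantomSpec, frame_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Render one frame; returns ``(intensity image in [0,1], tag mask)``.

    The tag mask is the noise-free boolean set of tag-line pixels (the
    binarization ground truth).  Rendering is deterministic given
    ``(spec.seed, frame_index)``.
    """
    if frame_index >= spec.n_frames:
        raise ValueError(f"frame_index {frame_index} out of range (n_frames={spec.n_frames})")
    geom = spec.geometry
    r_epi_px = geom.r_epi / geom.mean_spacing
    if (
        geom.center[0] - r_epi_px < 0
        or geom.center[1] - r_epi_px < 0
        or geom.center[0] + r_epi_px > spec.frame_shape[0] - 1
        or geom.center[1] + r_epi_px > spec.frame_shape[1] - 1
    ):
        raise ValueError("annulus does not fit inside the frame")

    alpha = spec.alpha_profile[frame_index] * geom.r_epi
    beta = spec.beta_profile[frame_index] * geom.r_epi

    rows, cols = np.mgrid[0 : spec.frame_shape[0], 0 : spec.frame_shape[1]]
    x, y = geom.pixel_to_physical(rows, cols)

    if alpha == 0.0 and beta == 0.0:
        x0, y0 = x, y
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            x0, y0 = _inverse_xy(x, y, alpha, beta)
        center = np.hypot(x, y) == 0.0
        x0 = np.where(center, np.inf, x0)  # the center pixel is never tissue
        y0 = np.where(center, np.inf, y0)

    r0 = np.hypot(x0, y0)
    tissue = (r0 >= geom.r_endo) & (r0 <= geom.r_epi)
    half_w = 0.5 * spec.tag_width
    on_tag = (_grid_distance(x0, spec.tag_spacing) <= half_w) | (
        _grid_distance(y0, spec.tag_spacing) <= half_w
    )
    tag_mask = tissue & on_tag

    frame = np.full(spec.frame_shape, spec.background_intensity)
    frame[tissue] = spec.tissue_intensity
    # contrast factor 1 -> fully dark tags; 0.4 -> tags at 0.6 x tissue
    frame[tag_mask] = spec.tissue_intensity * (1.0 - spec.fading[frame_index])

    if spec.noise_sigma > 0:
        rng = np.random.default_rng([spec.seed, frame_index])
        frame = frame + rng.normal(0.0, spec.noise_sigma, size=frame.shape)
    return np.clip(frame, 0.0, 1.0), tag_mask


def render_series(spec: PhantomSpec) -> tuple[TaggedSeries, GroundTruth]:
    """Render all frames; timestamps are k * T_cardiac / n_frames."""
    frames, masks = [], []
    for k in range(spec.n_frames):
        frame, mask = render_frame(spec, k)
        frames.append(frame)
        masks.append(mask)
    times = np.arange(spec.n_frames) * spec.T_cardiac / spec.n_frames
    series = TaggedSeries(
        frames=frames,
        times=times,
        pixel_spacing=spec.geometry.pixel_spacing,
        T_cardiac=spec.T_cardiac,
        slice_level=spec.geometry.slice_level,
        geometry=spec.geometry,
    )
    truth = GroundTruth(
        alpha_norm=spec.alpha_profile.copy(),
        beta_norm=spec.beta_profile.copy(),
        tag_masks=masks,
        geometry=spec.geometry,
    )
    return series, truth
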