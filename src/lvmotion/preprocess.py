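"""Frame normalization, tag binarization and LV geometry estimation.

Coordinate conventions used throughout the package:

* array indices are 0-based ``(row, col)``; ``pixel_spacing`` is
  ``(row_mm, col_mm)``;
* physical coordinates are LV-centered millimetres with x to the right
  and y up:  ``x = (col - center_col) * col_mm``,
  ``y = (center_row - row) * row_mm``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage, optimize
from skimage import filters, measure, morphology

log = logging.getLogger(__name__)

__all__ = [
    "LVGeometry",
    "TaggedSeries",
    "normalize_intensity",
    "binarize_tags",
    "estimate_geometry",
    "crop_window",
    "load_series",
    "save_series",
]

DEFAULT_TAG_SPACING_MM = 7.0


@dataclasses.dataclass
class LVGeometry:
    """LV center and wall radii estimated on the end-diastolic frame.

    ``center`` is in pixel coordinates ``(row, col)``; the radii are in
    millimetres.  ``pixel_spacing`` is ``(row_mm, col_mm)``.
    """

    center: tuple[float, float]
    r_epi: float
    r_endo: float
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_level: str = "mid"

    def __post_init__(self) -> None:
        if not (0 < self.r_endo < self.r_epi):
            raise ValueError(
                f"requires 0 < r_endo < r_epi, got r_endo={self.r_endo}, r_epi={self.r_epi}"
            )
        if self.pixel_spacing[0] <= 0 or self.pixel_spacing[1] <= 0:
            raise ValueError(f"pixel spacing must be positive, got {self.pixel_spacing}")

    @property
    def mean_spacing(self) -> float:
        return 0.5 * (self.pixel_spacing[0] + self.pixel_spacing[1])

    @property
    def r_epi_px(self) -> float:
        return self.r_epi / self.mean_spacing

    @property
    def r_endo_px(self) -> float:
        return self.r_endo / self.mean_spacing

    def pixel_to_physical(self, rows, cols):
        """Map array indices to LV-centered mm coordinates (x, y)."""
        sy, sx = self.pixel_spacing
        x = (np.asarray(cols, dtype=float) - self.center[1]) * sx
        y = (self.center[0] - np.asarray(rows, dtype=float)) * sy
        return x, y

    def physical_to_pixel(self, x, y):
        """Map LV-centered mm coordinates to fractional array indices."""
        sy, sx = self.pixel_spacing
        rows = self.center[0] - np.asarray(y, dtype=float) / sy
        cols = self.center[1] + np.asarray(x, dtype=float) / sx
        return rows, cols


@dataclasses.dataclass
class TaggedSeries:
    """An ordered stack of short-axis frames spanning one cardiac cycle."""

    frames: list[np.ndarray]
    times: np.ndarray
    pixel_spacing: tuple[float, float]
    T_cardiac: float
    slice_level: str = "mid"
    geometry: LVGeometry | None = None

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("a series needs at least 2 frames")
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        if self.times[0] != 0.0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must start at 0 and be strictly increasing")
        shape = self.frames[0].shape
        if any(f.shape != shape for f in self.frames):
            raise ValueError("all frames must share one shape")
        if self.T_cardiac <= 0:
            raise ValueError("T_cardiac must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def phase_fractions(self) -> np.ndarray:
        return self.times / self.T_cardiac


def normalize_intensity(
    frame: np.ndarray, clip_percentiles: tuple[float, float] | None = (1.0, 99.0)
) -> np.ndarray:
    """Rescale a frame linearly to [0, 1] after optional percentile clipping.

    With ``clip_percentiles=None`` this is a plain min-max rescale and is
    idempotent on frames already spanning [0, 1].
    """
    frame = np.asarray(frame, dtype=float)
    if clip_percentiles is not None:
        lo, hi = np.percentile(frame, clip_percentiles)
    else:
        lo, hi = float(frame.min()), float(frame.max())
    if hi <= lo:
        raise ValueError("frame is constant (or constant after clipping); cannot normalize")
    return np.clip((frame - lo) / (hi - lo), 0.0, 1.0)


def binarize_tags(
    frame: np.ndarray,
    geometry: LVGeometry,
    tag_spacing_mm: float = DEFAULT_TAG_SPACING_MM,
    offset: float = 0.9,
    bright_floor: float = 0.5,
    tag_width_mm: float = 1.5,
) -> np.ndarray:
    """Binarize a normalized frame: tag-line pixels -> 0, everything else -> 1.

    Local thresholding keeps faded late-cycle tags separable from the
    surrounding tissue.  A pixel is a tag iff

    * it lies inside the tissue mask — the morphological closing of the
      bright (``>= bright_floor``) region with a disk slightly wider
      than a tag line, which re-includes dark tag lines but leaves the
      background and the cavity out; and
    * its intensity is below ``offset`` times the local *tissue* mean,
      a windowed mean (1.5x the tag spacing) over bright pixels only,
      so the estimate is not dragged down near the wall boundaries.
    """
    frame = np.asarray(frame, dtype=float)
    bright = frame >= bright_floor
    close_px = max(2, int(np.ceil(tag_width_mm / min(geometry.pixel_spacing))))
    # disk closing re-includes tag interiors and crossings; the 1-D
    # closings additionally pick up tag-line endings at the wall
    # boundaries, which a disk cannot bracket with bright pixels
    line_len = 2 * close_px + 1
    tissue_mask = (
        morphology.closing(bright, morphology.disk(close_px))
        | morphology.closing(bright, morphology.footprint_rectangle((1, line_len)))
        | morphology.closing(bright, morphology.footprint_rectangle((line_len, 1)))
    )

    window_px = int(round(1.5 * tag_spacing_mm / geometry.mean_spacing))
    window_px = max(3, window_px | 1)  # odd, at least 3
    weight = ndimage.uniform_filter(bright.astype(float), size=window_px, mode="nearest")
    mean_bright = ndimage.uniform_filter(frame * bright, size=window_px, mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        local_mean = np.where(weight > 0, mean_bright / np.maximum(weight, 1e-12), 0.0)

    tag = tissue_mask & (frame < offset * local_mean)
    binary = (~tag).astype(np.uint8)
    if binary.all():
        log.warning("binarize_tags found no tag pixels (all-ones output)")
    return binary


def _fit_circle(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Least-squares circle fit: algebraic (Kåsa) start, geometric polish.

    Returns ``(cx, cy, radius, rms_residual)``.
    """
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    (cx, cy, c), *_ = np.linalg.lstsq(A, b, rcond=None)
    r0 = np.sqrt(c + cx * cx + cy * cy)

    def residuals(p):
        return np.hypot(x - p[0], y - p[1]) - p[2]

    sol = optimize.least_squares(residuals, x0=[cx, cy, r0], method="lm")
    cx, cy, r = sol.x
    rms = float(np.sqrt(np.mean(residuals(sol.x) ** 2)))
    return float(cx), float(cy), float(r), rms


def estimate_geometry(
    end_diastolic_frame: np.ndarray,
    init: LVGeometry | None = None,
    *,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
    slice_level: str = "mid",
    tag_width_mm: float = 1.5,
    refine: bool = False,
    max_residual_frac: float = 0.2,
) -> LVGeometry:
    """Estimate the LV center and the epi-/endocardial radii.

    Automatic path (``init=None``): grey-morphology closing erases the
    dark tag lines, Otsu picks the tissue/background level, and the two
    dominant sub-pixel iso-contours (epicardium, endocardium) are fitted
    by least-squares circles.  Raises if no annular structure is found.

    Manual path: a supplied ``init`` mirrors the on-screen circle
    placement workflow and is returned unchanged unless ``refine=True``,
    in which case the circles are re-fitted from contour points within a
    band around the initial circles.
    """
    frame = np.asarray(end_diastolic_frame, dtype=float)
    if init is not None and not refine:
        return init

    if frame.min() < 0 or frame.max() > 1:
        frame = normalize_intensity(frame)

    sy, sx = pixel_spacing
    close_px = max(2, int(np.ceil(tag_width_mm / min(sy, sx))) + 1)
    closed = morphology.closing(frame, morphology.disk(close_px))
    level = float(filters.threshold_otsu(closed))
    contours = measure.find_contours(closed, level)
    if len(contours) < 2:
        raise ValueError("no annular LV wall structure detected (need two boundary contours)")

    fits = []
    for contour in sorted(contours, key=len, reverse=True)[:6]:
        if len(contour) < 12:
            continue
        X = contour[:, 1] * sx
        Y = contour[:, 0] * sy
        cx, cy, r, rms = _fit_circle(X, Y)
        if rms > max_residual_frac * r:
            continue
        fits.append((cx, cy, r, rms, len(contour)))
    if len(fits) < 2:
        raise ValueError("circle fits to wall boundaries failed (residual above threshold)")

    # the two largest concentric circles: epicardium (largest) and endocardium
    fits.sort(key=lambda f: f[2], reverse=True)
    epi = fits[0]
    endo = next(
        (f for f in fits[1:] if np.hypot(f[0] - epi[0], f[1] - epi[1]) < 0.5 * epi[2]),
        None,
    )
    if endo is None:
        raise ValueError("no endocardial contour concentric with the epicardium")

    center = (epi[1] / sy, epi[0] / sx)  # (row, col) px
    geometry = LVGeometry(
        center=center,
        r_epi=epi[2],
        r_endo=endo[2],
        pixel_spacing=pixel_spacing,
        slice_level=slice_level,
    )
    if init is not None:
        # band-limited refinement around the manual circles
        if (
            abs(geometry.r_epi - init.r_epi) > 0.2 * init.r_epi
            or abs(geometry.r_endo - init.r_endo) > 0.3 * init.r_endo
        ):
            log.warning("refined geometry far from init; keeping refined values")
        geometry.slice_level = init.slice_level
    return geometry


def crop_window(frame: np.ndarray, geometry: LVGeometry, margin: float = 0.0) -> np.ndarray:
    """Extract a square window centered on the LV, padded with 1.0 outside.

    The half-side is ``(r_epi + margin)`` converted to pixels per axis;
    the window start is ``round(center) - half`` in each axis.
    """
    frame = np.asarray(frame, dtype=float)
    sy, sx = geometry.pixel_spacing
    half_r = int(round((geometry.r_epi + margin) / sy))
    half_c = int(round((geometry.r_epi + margin) / sx))
    r0 = int(round(geometry.center[0])) - half_r
    c0 = int(round(geometry.center[1])) - half_c
    out = np.ones((2 * half_r, 2 * half_c), dtype=float)
    rows = np.arange(r0, r0 + 2 * half_r)
    cols = np.arange(c0, c0 + 2 * half_c)
    rmask = (rows >= 0) & (rows < frame.shape[0])
    cmask = (cols >= 0) & (cols < frame.shape[1])
    out[np.ix_(rmask, cmask)] = frame[np.ix_(rows[rmask], cols[cmask])]
    return out


# ---------------------------------------------------------------------------
# series I/O

_SIDECAR_NAMES = ("series.yaml", "series.yml", "series.json")


def _read_sidecar(path: Path) -> dict:
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_series(path: str | Path, sidecar: str | Path | None = None) -> TaggedSeries:
    """Load a tagged series from a PNG/TIFF directory or a NIfTI volume.

    Directory stacks are ordered lexicographically by filename (= time
    order).  Metadata comes from a YAML/JSON sidecar with keys
    ``pixel_spacing_mm`` ([row, col]), ``T_cardiac_s``, ``slice_level``
    and optionally ``center`` / ``r_epi_mm`` / ``r_endo_mm``.
    """
    import imageio.v3 as iio

    path = Path(path)
    if sidecar is not None:
        meta = _read_sidecar(Path(sidecar))
    else:
        folder = path if path.is_dir() else path.parent
        for name in _SIDECAR_NAMES:
            if (folder / name).exists():
                meta = _read_sidecar(folder / name)
                break
        else:
            raise FileNotFoundError(f"no metadata sidecar found near {path}")

    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames in {path}")
        frames = []
        for f in files:
            data = np.asarray(iio.imread(f))
            if np.issubdtype(data.dtype, np.integer):
                frames.append(data.astype(float) / np.iinfo(data.dtype).max)
            else:
                frames.append(data.astype(float))
    elif path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        import nibabel as nib

        vol = np.asarray(nib.load(str(path)).dataobj, dtype=float)
        if vol.ndim != 3:
            raise ValueError(f"expected a 3-D (x, y, t) NIfTI volume, got shape {vol.shape}")
        peak = vol.max()
        frames = [np.ascontiguousarray(vol[:, :, k] / peak if peak > 1 else vol[:, :, k])
                  for k in range(vol.shape[2])]
    else:
        raise ValueError(f"unsupported series input: {path}")

    T = float(meta["T_cardiac_s"])
    n = len(frames)
    times = meta.get("times_s")
    times = np.asarray(times, dtype=float) if times is not None else np.arange(n) * T / n
    spacing = tuple(float(v) for v in meta["pixel_spacing_mm"])
    level = str(meta.get("slice_level", "mid"))

    geometry = None
    if all(k in meta for k in ("center", "r_epi_mm", "r_endo_mm")):
        geometry = LVGeometry(
            center=tuple(float(v) for v in meta["center"]),
            r_epi=float(meta["r_epi_mm"]),
            r_endo=float(meta["r_endo_mm"]),
            pixel_spacing=spacing,
            slice_level=level,
        )
    return TaggedSeries(
        frames=frames,
        times=times,
        pixel_spacing=spacing,
        T_cardiac=T,
        slice_level=level,
        geometry=geometry,
    )


def save_series(series: TaggedSeries, folder: str | Path, fmt: str = "png") -> Path:
    """Write a series as 16-bit PNG frames (or a NIfTI volume) + sidecar."""
    import imageio.v3 as iio

    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    meta = {
        "pixel_spacing_mm": [float(series.pixel_spacing[0]), float(series.pixel_spacing[1])],
        "T_cardiac_s": float(series.T_cardiac),
        "times_s": [float(t) for t in series.times],
        "slice_level": series.slice_level,
    }
    if series.geometry is not None:
        meta.update(
            center=[float(series.geometry.center[0]), float(series.geometry.center[1])],
            r_epi_mm=float(series.geometry.r_epi),
            r_endo_mm=float(series.geometry.r_endo),
        )
    (folder / "series.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))

    if fmt == "png":
        for k, frame in enumerate(series.frames):
            data = np.clip(frame, 0, 1)
            iio.imwrite(folder / f"frame_{k:03d}.png", (data * 65535).astype(np.uint16))
    elif fmt == "nifti":
        import nibabel as nib

        vol = np.stack(series.frames, axis=-1)
        nib.save(nib.Nifti1Image(vol.astype(np.float32), np.eye(4)), str(folder / "series.nii"))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return folder
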