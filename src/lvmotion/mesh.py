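"""Simulated tag mesh: construction, deformation and rasterization.

The simulated mesh mimics the tag grid of the undeformed (end-diastolic)
frame: two orthogonal families of parallel lines at the tag spacing,
masked to the LV-wall annulus, sampled densely enough that rasterization
leaves no gaps.  Deforming the mesh with the motion model and comparing
its raster against the binarized tagged image is the core of the fit.

Chirality is handled here and only here: physical (x, y) mm map to array
indices via ``row = center_row - y / row_mm`` and
``col = center_col + x / col_mm``, which flips the y axis so that a
clockwise rotation in the head-to-toe physical view appears clockwise in
the displayed image.  Worked quadrant example: with center (128, 128)
and 1 mm pixels, the point (10, 10) mm (upper-right quadrant on screen)
lands at row 118, col 138; a clockwise quarter turn moves it to
(10, -10) mm = row 138, col 138, i.e. straight down in the image.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .preprocess import LVGeometry
from .transform import ModelParams, forward_points

log = logging.getLogger(__name__)

__all__ = ["TagMesh", "ModelImage", "build_uniform_mesh", "deform_mesh", "rasterize_mesh"]


@dataclasses.dataclass
class TagMesh:
    """Sub-pixel sample points of simulated tag lines inside an annulus.

    ``points`` is an ``(N, 2)`` float array of LV-centered mm
    coordinates; ``annulus = (r_inner, r_outer)`` in mm.
    """

    points: np.ndarray
    cell_spacing: float
    line_width: float
    annulus: tuple[float, float]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not (self.cell_spacing > self.line_width > 0):
            raise ValueError(
                f"requires cell_spacing > line_width > 0, got "
                f"{self.cell_spacing} and {self.line_width}"
            )

    @property
    def radii(self) -> np.ndarray:
        return np.hypot(self.points[:, 0], self.points[:, 1])


@dataclasses.dataclass
class ModelImage:
    """Binary raster of a tag mesh: 0 on mesh pixels, 1 elsewhere."""

    pixels: np.ndarray
    pixel_spacing: tuple[float, float]
    center_pixel: tuple[float, float]

    @property
    def n_mesh_pixels(self) -> int:
        return int((self.pixels == 0).sum())

    def to_png(self, path) -> None:
        """Export for visual overlay debugging (0 -> 0, 1 -> 255)."""
        import imageio.v3 as iio

        iio.imwrite(str(path), (self.pixels.astype(np.uint8) * 255))


def _line_positions(spacing: float, extent: float, phase: float) -> np.ndarray:
    """Grid-line offsets ``k*spacing + phase`` within ``[-extent, extent]``."""
    k_min = int(np.ceil((-extent - phase) / spacing))
    k_max = int(np.floor((extent - phase) / spacing))
    return phase + spacing * np.arange(k_min, k_max + 1)


def build_uniform_mesh(
    geometry: LVGeometry,
    cell_spacing: float,
    line_width: float,
    *,
    phase_offset: tuple[float, float] = (0.0, 0.0),
    sample_step: float | None = None,
) -> TagMesh:
    """Sample a uniform orthogonal line grid restricted to the wall annulus.

    Lines run through the LV center by default (``phase_offset`` shifts
    the x/y line families for real images whose tag grid is not centered
    — a manual setting, no phase estimation is attempted).  The sampling
    step along each line defaults to 0.4x the smaller pixel spacing so
    rasterized lines are 8-connected.
    """
    if cell_spacing <= 0:
        raise ValueError(f"cell_spacing must be positive, got {cell_spacing}")
    r_in, r_out = geometry.r_endo, geometry.r_epi
    if sample_step is None:
        sample_step = 0.4 * min(geometry.pixel_spacing)

    pts = []
    # vertical lines: x = const, sample along y
    for x0 in _line_positions(cell_spacing, r_out, phase_offset[0]):
        half = np.sqrt(max(r_out * r_out - x0 * x0, 0.0))
        ys = np.arange(-half, half + 0.5 * sample_step, sample_step)
        pts.append(np.column_stack([np.full_like(ys, x0), ys]))
    # horizontal lines: y = const, sample along x
    for y0 in _line_positions(cell_spacing, r_out, phase_offset[1]):
        half = np.sqrt(max(r_out * r_out - y0 * y0, 0.0))
        xs = np.arange(-half, half + 0.5 * sample_step, sample_step)
        pts.append(np.column_stack([xs, np.full_like(xs, y0)]))

    points = np.concatenate(pts, axis=0) if pts else np.empty((0, 2))
    r = np.hypot(points[:, 0], points[:, 1])
    points = points[(r >= r_in) & (r <= r_out)]
    return TagMesh(points=points, cell_spacing=cell_spacing, line_width=line_width,
                   annulus=(r_in, r_out))


def deform_mesh(mesh: TagMesh, params: ModelParams) -> TagMesh:
    """Map every mesh point through the forward model.

    Metadata is preserved; the annulus bounds are updated to the
    deformed radii ``r - alpha**2 / r`` of the original bounds.
    """
    try:
        moved = forward_points(mesh.points, params.alpha, params.beta)
    except ValueError as err:
        raise ValueError(f"mesh deformation failed: {err}") from err
    r_in, r_out = mesh.annulus
    a2 = params.alpha * params.alpha
    new_annulus = (r_in - a2 / r_in, r_out - a2 / r_out)
    return TagMesh(points=moved, cell_spacing=mesh.cell_spacing,
                   line_width=mesh.line_width, annulus=new_annulus)


def mesh_pixel_indices(
    mesh: TagMesh,
    frame_shape: tuple[int, int],
    pixel_spacing: tuple[float, float],
    center_pixel: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Unique (rows, cols) of pixels whose centers lie within
    ``line_width / 2`` of any mesh point; out-of-frame pixels clipped."""
    if mesh.points.shape[0] == 0:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    sy, sx = pixel_spacing
    cr, cc = center_pixel
    x, y = mesh.points[:, 0], mesh.points[:, 1]
    rows_f = cr - y / sy
    cols_f = cc + x / sx
    half = 0.5 * mesh.line_width
    nr, nc = half / sy, half / sx

    row_lo = np.floor(rows_f - nr)
    col_lo = np.floor(cols_f - nc)
    r_steps = int(np.ceil(2 * nr)) + 1
    c_steps = int(np.ceil(2 * nc)) + 1
    hits_r, hits_c = [], []
    for dr in range(r_steps + 1):
        cand_r = row_lo + dr
        dy = (cr - cand_r) * sy - y
        for dc in range(c_steps + 1):
            cand_c = col_lo + dc
            dx = (cand_c - cc) * sx - x
            inside = dx * dx + dy * dy <= half * half
            if inside.any():
                hits_r.append(cand_r[inside])
                hits_c.append(cand_c[inside])
    if not hits_r:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    rr = np.concatenate(hits_r).astype(np.intp)
    cc_idx = np.concatenate(hits_c).astype(np.intp)
    keep = (rr >= 0) & (rr < frame_shape[0]) & (cc_idx >= 0) & (cc_idx < frame_shape[1])
    n_clip = int((~keep).sum())
    if n_clip:
        log.debug("rasterize: clipped %d out-of-frame pixel hits", n_clip)
    rr, cc_idx = rr[keep], cc_idx[keep]
    flat = np.unique(rr * frame_shape[1] + cc_idx)
    return flat // frame_shape[1], flat % frame_shape[1]


def rasterize_mesh(
    mesh: TagMesh,
    frame_shape: tuple[int, int],
    pixel_spacing: tuple[float, float],
    center_pixel: tuple[float, float],
) -> ModelImage:
    """Rasterize a mesh into a binary image (0 on mesh, 1 elsewhere)."""
    if frame_shape[0] <= 0 or frame_shape[1] <= 0:
        raise ValueError(f"frame_shape must be positive, got {frame_shape}")
    if not (0 <= center_pixel[0] < frame_shape[0] and 0 <= center_pixel[1] < frame_shape[1]):
        raise ValueError(f"center {center_pixel} outside frame {frame_shape}")
    pixels = np.ones(frame_shape, dtype=np.uint8)
    rows, cols = mesh_pixel_indices(mesh, frame_shape, pixel_spacing, center_pixel)
    pixels[rows, cols] = 0
    return ModelImage(pixels=pixels, pixel_spacing=pixel_spacing, center_pixel=center_pixel)
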