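"""DEJ topographical-variation metric (an Ra-like surface roughness).

A band ROI centered on the basal plasma membrane (Itga6 channel) is
straightened along its centerline, the membrane is binarized and
skeletonized, its per-column offset from the centerline is traced, and the
mean absolute offset — converted to micrometers — is the "DEJ variation",
directly analogous to average roughness Ra in surface metrology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects, skeletonize

from .model import BandROI, MultichannelImage

__all__ = [
    "StraightenedBand",
    "MembraneTrace",
    "straighten_band",
    "trace_membrane",
    "dej_variation_metric",
]


@dataclass
class StraightenedBand:
    """Band resampled perpendicular to its centerline.

    ``grid`` has shape (width_px, L); row ``width_px // 2`` is the
    centerline; columns advance in unit arclength steps.
    """

    grid: np.ndarray
    width_px: int
    arclength_step_um: float

    @property
    def center_row(self) -> int:
        return self.width_px // 2


@dataclass
class MembraneTrace:
    """Per-column membrane offset (px, relative to the centerline row)."""

    offsets: np.ndarray
    valid: np.ndarray

    @property
    def coverage(self) -> float:
        return float(self.valid.mean()) if self.valid.size else 0.0


def straighten_band(
    image: MultichannelImage, band: BandROI, channel: str
) -> StraightenedBand:
    """Bilinearly resample the band into a (width_px, L) straightened frame."""
    if image.is_3d:
        raise ValueError("band straightening operates on 2D images")
    data = image.channel(channel)
    ls = LineString(band.centerline)
    n_cols = int(np.floor(ls.length)) + 1
    s = np.arange(n_cols, dtype=float)
    pts = np.array([ls.interpolate(si).coords[0] for si in s])  # (L, 2) x,y
    # tangent by central differences on the resampled points
    tang = np.gradient(pts, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)  # +90 deg, y-down
    w = band.width_px
    offsets = np.arange(w, dtype=float) - w // 2
    # sample positions: (w, L, 2)
    pos = pts[None, :, :] + offsets[:, None, None] * normal[None, :, :]
    x, y = pos[..., 0], pos[..., 1]
    h, wimg = data.shape
    if x.min() < -0.5 or y.min() < -0.5 or x.max() > wimg - 0.5 or y.max() > h - 0.5:
        raise ValueError("band exits image bounds")
    grid = ndimage.map_coordinates(data, [y, x], order=1, mode="nearest")
    return StraightenedBand(
        grid=grid, width_px=w, arclength_step_um=float(image.pixel_size_um[0])
    )


def trace_membrane(
    band_img: StraightenedBand,
    threshold: float | str = "otsu",
    *,
    max_offset_px: float | None = None,
    min_coverage: float = 0.5,
    min_object_px: int = 10,
) -> MembraneTrace:
    """Binarize, skeletonize, and read the membrane row per column.

    Connected binary objects smaller than ``min_object_px`` are discarded
    before skeletonizing (noise specks would otherwise contaminate the
    column means); the membrane ridge spans the band, so this never touches
    it.  Columns whose skeleton is empty are flagged invalid; when several
    skeleton pixels share a column their mean row is used.
    ``max_offset_px`` optionally discards skeleton pixels farther than that
    from the centerline (suppresses suprabasal staining branches); the
    default keeps everything within the band.
    """
    grid = band_img.grid
    if grid.max() <= grid.min():
        raise ValueError("band has no dynamic range")
    thr = threshold_otsu(grid) if threshold == "otsu" else float(threshold)
    binary = grid > thr
    if min_object_px > 1:
        binary = remove_small_objects(binary, max_size=min_object_px - 1)
    skel = skeletonize(binary)
    center = band_img.center_row
    if max_offset_px is not None:
        rows = np.arange(grid.shape[0], dtype=float)
        skel &= (np.abs(rows - center) <= max_offset_px)[:, None]
    counts = skel.sum(axis=0)
    valid = counts > 0
    rows = np.arange(grid.shape[0], dtype=float)
    mean_row = np.divide(
        (rows[:, None] * skel).sum(axis=0),
        counts,
        out=np.zeros(grid.shape[1]),
        where=valid,
    )
    offsets = np.where(valid, mean_row - center, 0.0)
    trace = MembraneTrace(offsets=offsets, valid=valid)
    if trace.coverage < min_coverage:
        raise ValueError(
            f"membrane trace too sparse: coverage {trace.coverage:.2f} < "
            f"{min_coverage}"
        )
    return trace


def dej_variation_metric(trace: MembraneTrace, pixel_size_um: float) -> float:
    """Mean absolute membrane offset over valid columns, in micrometers."""
    if not trace.valid.any():
        raise ValueError("no valid columns in membrane trace")
    return float(np.abs(trace.offsets[trace.valid]).mean() * pixel_size_um)
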