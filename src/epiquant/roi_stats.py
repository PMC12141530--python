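"""Simple per-ROI statistics: epithelial thickness, mean intensity, and
double-positive cell density per DEJ length."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point

from .model import MultichannelImage

__all__ = [
    "CellScore",
    "epithelial_thickness",
    "mean_roi_intensity",
    "double_positive_density",
    "dej_length",
]


@dataclass
class CellScore:
    """Per-cell mean intensities with deterministic positivity calls."""

    cell_id: str | int
    mean_intensity: dict[str, float]
    flags: dict[str, bool] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    def classify(self, thresholds: dict[str, float]) -> None:
        self.thresholds = dict(thresholds)
        self.flags = {
            ch: self.mean_intensity[ch] >= thr for ch, thr in thresholds.items()
        }


def epithelial_thickness(
    basal_boundary: np.ndarray,
    apical_surface: np.ndarray,
    pixel_size_um: float,
    n_samples: int = 200,
) -> float:
    """Mean basal-to-apical minimum distance along the basal boundary, in µm.

    Sampled at ``n_samples`` equally spaced arclength positions on the
    basal line; each sample contributes its shortest Euclidean distance to
    the apical surface polyline.
    """
    basal = LineString(np.asarray(basal_boundary, dtype=float))
    apical = LineString(np.asarray(apical_surface, dtype=float))
    if basal.crosses(apical):
        raise ValueError("basal and apical polylines intersect")
    s = np.linspace(0.0, basal.length, n_samples)
    dists = [apical.distance(basal.interpolate(si)) for si in s]
    return float(np.mean(dists) * pixel_size_um)


def mean_roi_intensity(
    image: MultichannelImage, mask: np.ndarray, channel: str
) -> float:
    """Arithmetic mean of a channel over a binary ROI mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    return float(image.channel(channel)[mask].mean())


def double_positive_density(
    cells: list[CellScore],
    ch_a: str,
    ch_b: str,
    thr_a: float,
    thr_b: float,
    dej_length_um: float,
) -> float:
    """Cells positive for both channels, per micrometer of DEJ."""
    if dej_length_um <= 0:
        raise ValueError("DEJ length must be positive")
    n = sum(
        1
        for c in cells
        if c.mean_intensity[ch_a] >= thr_a and c.mean_intensity[ch_b] >= thr_b
    )
    return n / dej_length_um


def dej_length(basal_boundary: np.ndarray, pixel_size_um: float) -> float:
    """Arclength of the basal boundary polyline, in µm."""
    pts = np.asarray(basal_boundary, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("polyline needs at least 2 vertices")
    return float(LineString(pts).length * pixel_size_um)
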