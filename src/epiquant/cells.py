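"""Per-cell protein-distribution and RNA-dispersion metrics.

Two single-cell statistics on a segmented cell mask:

* **cortical ratio** — mean intensity in the peripheral 15% of the cell
  divided by the mean in the most central 65%, where "peripheral" and
  "central" are zones of the normalized boundary-distance coordinate
  ``r = 1 - d_edge / max(d_edge)`` (0 at the cell's innermost point, 1 at
  the boundary).  An area-percentile zone definition is available behind a
  switch for sensitivity analysis.
* **peripheral distribution index (PDI)** — the intensity-weighted second
  moment about the geometric cell centroid, normalized by the same moment
  of a hypothetical uniform signal.  Exactly 1 for homogeneous signal,
  > 1 for peripherally concentrated, < 1 for perinuclear signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .model import CellRegion, MetricTable, MultichannelImage, params_hash

__all__ = [
    "RadialZones",
    "radial_zones",
    "cortical_ratio",
    "pdi",
    "batch_cell_metrics",
]

PERIPHERAL_FRACTION = 0.15
CENTRAL_FRACTION = 0.65


@dataclass
class RadialZones:
    r: np.ndarray  # normalized boundary coordinate on the mask, NaN outside
    peripheral: np.ndarray
    central: np.ndarray


def radial_zones(
    cell: CellRegion,
    peripheral_fraction: float = PERIPHERAL_FRACTION,
    central_fraction: float = CENTRAL_FRACTION,
    mode: str = "distance",
) -> RadialZones:
    """Peripheral / central zones of a cell mask.

    ``mode="distance"`` (default) thresholds the normalized boundary
    coordinate directly; ``mode="area"`` picks zone boundaries as quantiles
    of r so the zones hold the requested area fractions.
    """
    cell.validate()
    mask = cell.mask
    d = ndimage.distance_transform_edt(mask)
    dmax = d.max()
    if dmax <= 0:
        raise ValueError(f"cell {cell.label}: degenerate mask")
    r = np.full(mask.shape, np.nan)
    r[mask] = 1.0 - d[mask] / dmax
    if mode == "distance":
        lo, hi = 1.0 - peripheral_fraction, central_fraction
    elif mode == "area":
        vals = r[mask]
        lo = float(np.quantile(vals, 1.0 - peripheral_fraction))
        hi = float(np.quantile(vals, central_fraction))
    else:
        raise ValueError(f"unknown zone mode {mode!r}")
    peripheral = mask & (r >= lo)
    central = mask & (r <= hi)
    for name, zone in (("peripheral", peripheral), ("central", central)):
        if not zone.any():
            raise ValueError(f"cell {cell.label}: empty {name} zone")
    return RadialZones(r=r, peripheral=peripheral, central=central)


def cortical_ratio(
    cell: CellRegion,
    channel: np.ndarray,
    *,
    mode: str = "distance",
) -> float:
    """Mean peripheral-zone intensity over mean central-zone intensity."""
    zones = radial_zones(cell, mode=mode)
    channel = np.asarray(channel, dtype=np.float64)
    central_mean = float(channel[zones.central].mean())
    if central_mean <= 0:
        raise ValueError(f"cell {cell.label}: degenerate central signal")
    return float(channel[zones.peripheral].mean()) / central_mean


def pdi(cell: CellRegion, channel: np.ndarray) -> float:
    """Peripheral distribution index as a normalized second moment.

    PDI = (sum_p I(p)|p-c|^2 / sum_p I(p)) / (sum_p |p-c|^2 / N) with c the
    unweighted (geometric) centroid of the mask.  Uniform signal gives
    exactly 1 on any mask.
    """
    cell.validate()
    channel = np.asarray(channel, dtype=np.float64)
    ys, xs = np.nonzero(cell.mask)
    intensity = channel[ys, xs]
    total = float(intensity.sum())
    if total <= 0:
        raise ValueError(f"cell {cell.label}: zero total intensity")
    cy, cx = ys.mean(), xs.mean()
    r2 = (ys - cy) ** 2 + (xs - cx) ** 2
    weighted = float((intensity * r2).sum()) / total
    uniform = float(r2.mean())
    return weighted / uniform


def batch_cell_metrics(
    cells: list[CellRegion],
    image: MultichannelImage,
    channel: str,
    metric: str,
    sample: str = "sample",
) -> MetricTable:
    """One metric row per cell; per-cell failures are flagged, not fatal."""
    if metric not in ("cortical_ratio", "pdi"):
        raise ValueError(f"unknown metric {metric!r}")
    data = image.channel(channel)
    phash = params_hash({"metric": metric, "channel": channel})
    fn = cortical_ratio if metric == "cortical_ratio" else pdi
    table = MetricTable()
    for cell in cells:
        try:
            value = fn(cell, data)
        except ValueError as exc:
            table.add_failure(sample, cell.label, metric, str(exc), phash)
        else:
            table.add(sample, cell.label, metric, value, "ratio", phash)
    return table
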