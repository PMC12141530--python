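"""Core domain types and file IO shared by every analysis stage.

Coordinate convention (global, asserted by the test suite): 0-based pixel
indices, coordinates refer to pixel centers, y increases downward, and a
physical length is pixel count times ``pixel_size_um``.  Polylines are
``(N, 2)`` float arrays of ``(x, y)`` pixel coordinates.  Image arrays are
indexed ``(channel, [z,] y, x)``; channels are addressed by name, never by
position, so a channel swap between samples cannot pass silently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from shapely.geometry import LineString

logger = logging.getLogger("epiquant")

__all__ = [
    "MultichannelImage",
    "LayerSegmentation",
    "BandROI",
    "CellRegion",
    "MetricTable",
    "load_image",
    "save_image",
    "load_polyline",
    "save_polyline",
    "params_hash",
]


def params_hash(params: dict) -> str:
    """Short stable hash identifying the parameter set that produced a metric."""
    blob = json.dumps(params, sort_keys=True, default=str)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass
class MultichannelImage:
    """Named-channel intensity grid with physical pixel/voxel sizes.

    ``data`` has shape ``(C, Y, X)`` or ``(C, Z, Y, X)``;
    ``pixel_size_um`` is ``(x, y)`` or ``(x, y, z)`` in micrometers.
    """

    data: np.ndarray
    channels: list[str]
    pixel_size_um: tuple[float, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be (C, Y, X) or (C, Z, Y, X)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"channel count mismatch: {self.data.shape[0]} planes, "
                f"{len(self.channels)} names"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel names")
        expected_axes = self.data.ndim - 1  # spatial axes
        if len(self.pixel_size_um) != expected_axes:
            raise ValueError(
                f"pixel_size_um needs {expected_axes} entries, got "
                f"{len(self.pixel_size_um)}"
            )
        if any(not np.isfinite(s) or s <= 0 for s in self.pixel_size_um):
            raise ValueError("pixel sizes must be strictly positive and finite")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")
        n_neg = int(np.count_nonzero(self.data < 0))
        if n_neg:
            logger.info("clamping %d negative intensities to zero", n_neg)
            self.data = np.clip(self.data, 0.0, None)

    @property
    def is_3d(self) -> bool:
        return self.data.ndim == 4

    @property
    def shape(self) -> tuple[int, ...]:
        """Spatial shape ([Z,] Y, X)."""
        return self.data.shape[1:]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.pixel_size_um))

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; have {self.channels}"
            ) from None
        return self.data[idx]


@dataclass
class LayerSegmentation:
    """Binary mask of the BM-attached cell layer plus its two boundaries.

    The basal boundary traces the basement membrane, the apical boundary the
    opposite face of the layer; together they define the apico-basal axis
    along which depth is measured.
    """

    mask: np.ndarray
    basal_boundary: np.ndarray
    apical_boundary: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.basal_boundary = np.asarray(self.basal_boundary, dtype=np.float64)
        self.apical_boundary = np.asarray(self.apical_boundary, dtype=np.float64)

    def validate(self) -> None:
        if self.mask.ndim != 2 or not self.mask.any():
            raise ValueError("layer mask must be a nonempty 2D grid")
        _, n = ndimage.label(self.mask)
        if n != 1:
            raise ValueError(f"layer mask must be connected, found {n} components")
        b = LineString(self.basal_boundary)
        a = LineString(self.apical_boundary)
        if b.crosses(a) or (b.intersects(a) and not b.touches(a)):
            raise ValueError("basal and apical boundaries intersect")


@dataclass
class BandROI:
    """Centerline polyline plus an even pixel width: the straightened DEJ band."""

    centerline: np.ndarray
    width_px: int

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=np.float64)
        if self.width_px < 2 or self.width_px % 2 != 0:
            raise ValueError("width_px must be even and >= 2")
        if self.centerline.ndim != 2 or self.centerline.shape[0] < 2:
            raise ValueError("centerline needs at least 2 vertices")
        if LineString(self.centerline).length <= 0:
            raise ValueError("centerline has zero length")


@dataclass
class CellRegion:
    """Single-cell binary mask (one connected component) with an identifier."""

    mask: np.ndarray
    label: str | int
    min_area_px: int = 50

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    def validate(self) -> None:
        if not self.mask.any():
            raise ValueError(f"cell {self.label}: empty mask")
        _, n = ndimage.label(self.mask)
        if n != 1:
            raise ValueError(f"cell {self.label}: mask has {n} components")
        area = int(self.mask.sum())
        if area < self.min_area_px:
            raise ValueError(
                f"cell {self.label}: area {area} px below minimum {self.min_area_px}"
            )


_METRIC_COLUMNS = ["sample", "roi", "metric", "value", "units", "params_hash", "status"]


@dataclass
class MetricTable:
    """Long-format result table: one row per (sample, ROI/cell, metric).

    ``status`` is "ok" for computed values; a failed ROI keeps its row with
    the failure reason in ``status`` and a NaN value so exclusions are
    auditable rather than silent.
    """

    rows: list[dict] = field(default_factory=list)

    def add(
        self,
        sample: str,
        roi: str | int,
        metric: str,
        value: float,
        units: str,
        phash: str,
        status: str = "ok",
    ) -> None:
        self.rows.append(
            {
                "sample": sample,
                "roi": roi,
                "metric": metric,
                "value": value,
                "units": units,
                "params_hash": phash,
                "status": status,
            }
        )

    def add_failure(
        self, sample: str, roi: str | int, metric: str, reason: str, phash: str
    ) -> None:
        self.add(sample, roi, metric, float("nan"), "", phash, status=reason)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=_METRIC_COLUMNS)

    def validate(self) -> None:
        df = self.to_frame()
        ok = df[df["status"] == "ok"]
        if not np.all(np.isfinite(ok["value"].to_numpy(dtype=float))):
            raise ValueError("non-finite metric value in an ok row")
        dup = df.duplicated(subset=["sample", "roi", "metric"])
        if dup.any():
            raise ValueError("duplicate (sample, roi, metric) rows")

    @property
    def values(self) -> pd.DataFrame:
        df = self.to_frame()
        return df[df["status"] == "ok"]


def write_metrics(table: MetricTable, path: str | Path) -> None:
    """Write a validated metric table as CSV; byte-stable for identical input."""
    table.validate()
    df = table.to_frame()
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.12g")


def read_metrics(path: str | Path) -> MetricTable:
    df = pd.read_csv(path)
    t = MetricTable()
    for rec in df.to_dict("records"):
        rec.setdefault("status", "ok")
        if not isinstance(rec["status"], str) or rec["status"] == "":
            rec["status"] = "ok"
        t.rows.append({k: rec.get(k) for k in _METRIC_COLUMNS})
    return t


def load_image(
    path: str | Path,
    channel_names: Sequence[str],
    pixel_size_um: Sequence[float] | None,
    *,
    allow_missing_calibration: bool = False,
) -> MultichannelImage:
    """Read a single/multi-page TIFF into a validated :class:`MultichannelImage`.

    The leading array axis is the channel axis when more than one channel
    name is given; a single-channel file may be a bare 2D/3D grid.  Physical
    calibration is mandatory unless ``allow_missing_calibration`` is set, in
    which case unit pixel sizes are assumed.
    """
    arr = tifffile.imread(str(path))
    names = list(channel_names)
    if len(names) == 1:
        # a leading length-1 axis is taken as the channel axis; a bare 2D
        # grid or a (Z, Y, X) stack gains one
        if arr.ndim == 2 or (arr.ndim == 3 and arr.shape[0] != 1):
            arr = arr[None]
    if arr.ndim not in (3, 4):
        raise ValueError(f"unsupported TIFF dimensionality {arr.ndim}")
    if arr.shape[0] != len(names):
        raise ValueError(
            f"channel count mismatch: file has {arr.shape[0]} planes, "
            f"{len(names)} names given"
        )
    if pixel_size_um is None:
        if not allow_missing_calibration:
            raise ValueError(
                "pixel_size_um is required; pass allow_missing_calibration=True "
                "to analyze in pixel units"
            )
        pixel_size_um = (1.0,) * (arr.ndim - 1)
    return MultichannelImage(arr, names, tuple(float(s) for s in pixel_size_um))


def save_image(image: MultichannelImage, path: str | Path) -> None:
    tifffile.imwrite(
        str(path), image.data.astype(np.float32), photometric="minisblack"
    )


def load_polyline(path: str | Path) -> np.ndarray:
    """Read a polyline from CSV (``x,y`` columns) or a GeoJSON LineString.

    A closed ring (identical first and last vertex) is accepted with a
    warning and opened by dropping the duplicate terminal vertex.
    """
    path = Path(path)
    if path.suffix.lower() in (".json", ".geojson"):
        obj = json.loads(path.read_text())
        geom = obj.get("geometry", obj)
        if geom.get("type") != "LineString":
            raise ValueError(f"expected LineString, got {geom.get('type')}")
        pts = np.asarray(geom["coordinates"], dtype=np.float64)
    else:
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if "x" not in cols or "y" not in cols:
            raise ValueError("polyline CSV needs x and y columns")
        pts = df[[cols["x"], cols["y"]]].to_numpy(dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("polyline needs at least 2 vertices")
    if not np.all(np.isfinite(pts)):
        raise ValueError("polyline has non-finite coordinates")
    if pts.shape[0] > 2 and np.array_equal(pts[0], pts[-1]):
        warnings.warn("closed ring opened by dropping duplicate terminal vertex")
        pts = pts[:-1]
    return pts


def save_polyline(polyline: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(np.asarray(polyline), columns=["x", "y"]).to_csv(
        path, index=False, lineterminator="\n", float_format="%.12g"
    )
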