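"""Fibrillin-2 fiber quantification in 3D stacks.

A transparent voxel-based pipeline: fixed intensity threshold (shared
across samples of an experiment), 26-connected component labeling,
per-component volume and sphericity, removal of components that are both
small and spherical (debris, not fiber segments), and the cumulative kept
volume in cubic micrometers.

Sphericity is psi = pi^(1/3) (6V)^(2/3) / A with the surface area A
estimated from exposed voxel faces.  The face estimate overestimates A on
curved surfaces (by up to ~1.5x for spheres), so the psi scale here sits
below the continuum one: voxelized spheres measure psi ~ 0.64-0.69 and
elongated capsules ~ 0.43-0.46, which is why the default spherical-debris
cutoff is 0.55 rather than a continuum-intuition value near 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .model import MultichannelImage

__all__ = [
    "FiberSegmentation",
    "segment_fibers",
    "filter_fiberlike",
    "cumulative_fiber_volume",
    "DEFAULT_MIN_VOLUME_UM3",
    "DEFAULT_MAX_SPHERICITY",
]

# Calibrated on synthetic capsule/sphere scenes (see docs); config values,
# shared across conditions of an experiment.
DEFAULT_MIN_VOLUME_UM3 = 0.2
DEFAULT_MAX_SPHERICITY = 0.55


@dataclass
class FiberSegmentation:
    """Labeled 3D components with per-component geometry and keep/remove flags."""

    labels: np.ndarray
    components: pd.DataFrame  # label, voxels, volume_um3, surface_um2, sphericity, kept, reason
    voxel_size_um: tuple[float, float, float]  # (z, y, x)
    filtered: bool = field(default=False)

    @property
    def n_components(self) -> int:
        return len(self.components)


def _component_surface_areas(
    labels: np.ndarray, n: int, voxel_size_zyx: tuple[float, float, float]
) -> np.ndarray:
    """Exposed voxel-face area per label (index 0 unused)."""
    dz, dy, dx = voxel_size_zyx
    face_area = (dy * dx, dz * dx, dz * dy)  # faces perpendicular to z, y, x
    areas = np.zeros(n + 1)
    for axis, a in enumerate(face_area):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        left, right = labels[tuple(lo)], labels[tuple(hi)]
        exposed_left = left[(left > 0) & (right != left)]
        exposed_right = right[(right > 0) & (left != right)]
        areas += np.bincount(exposed_left, minlength=n + 1) * a
        areas += np.bincount(exposed_right, minlength=n + 1) * a
        for edge in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = edge
            face = labels[tuple(sl)]
            areas += np.bincount(face[face > 0], minlength=n + 1) * a
    return areas


def segment_fibers(
    stack: MultichannelImage, channel: str, threshold: float
) -> FiberSegmentation:
    """Threshold a 3D stack and label fiber candidates with 26-connectivity."""
    if not stack.is_3d:
        raise ValueError("fiber segmentation requires a 3D stack")
    if len(stack.pixel_size_um) != 3:
        raise ValueError("missing z voxel size")
    data = stack.channel(channel)
    binary = data >= threshold
    labels, n = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=int))
    sx, sy, sz = stack.pixel_size_um
    vs = (sz, sy, sx)
    vox_vol = sz * sy * sx
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    areas = _component_surface_areas(labels, n, vs)[1:]
    volumes = counts * vox_vol
    with np.errstate(divide="ignore", invalid="ignore"):
        sphericity = np.pi ** (1 / 3) * (6 * volumes) ** (2 / 3) / areas
    comp = pd.DataFrame(
        {
            "label": np.arange(1, n + 1),
            "voxels": counts,
            "volume_um3": volumes,
            "surface_um2": areas,
            "sphericity": sphericity,
            "kept": True,
            "reason": "",
        }
    )
    return FiberSegmentation(labels=labels, components=comp, voxel_size_um=vs)


def filter_fiberlike(
    seg: FiberSegmentation,
    min_volume_um3: float = DEFAULT_MIN_VOLUME_UM3,
    max_sphericity: float = DEFAULT_MAX_SPHERICITY,
) -> FiberSegmentation:
    """Remove components that are both small AND spherical.

    A component is removed iff volume < ``min_volume_um3`` and sphericity
    > ``max_sphericity``; large spheres and small elongated fragments are
    kept.  Thresholds must be applied identically across conditions.
    """
    if min_volume_um3 <= 0 or max_sphericity <= 0:
        raise ValueError("filter thresholds must be positive")
    comp = seg.components.copy()
    small = comp["volume_um3"] < min_volume_um3
    spherical = comp["sphericity"] > max_sphericity
    remove = small & spherical
    comp["kept"] = ~remove
    comp["reason"] = np.where(
        remove,
        f"V<{min_volume_um3:g}um3 and psi>{max_sphericity:g}",
        "",
    )
    return FiberSegmentation(
        labels=seg.labels,
        components=comp,
        voxel_size_um=seg.voxel_size_um,
        filtered=True,
    )


def cumulative_fiber_volume(seg: FiberSegmentation) -> float:
    """Total volume (µm³) of kept fiber components."""
    if not seg.filtered:
        raise ValueError("apply filter_fiberlike before summing fiber volume")
    kept = seg.components[seg.components["kept"]]
    return float(kept["volume_um3"].sum())
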