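"""Seeded synthetic-scene generators with closed-form ground truth.

Each generator emits an image (plus the segmentation object the downstream
stage expects) together with a :class:`GroundTruth` record holding the
parameters and the closed-form expectation of the metric the scene is
designed to test.  The scenes emulate the statistical structure the
metrics assume — not photorealism:

* a BM-attached cell layer whose RNA spot depth follows a known law
  (uniform, truncated-exponential, or point mass);
* a membrane band whose ridge undulates with a known waveform, so the
  Ra-like roughness has a closed form (0, 2A/pi, or A);
* a disk cell with controllable radial intensity profile (cortical
  contrast, peripheral concentration);
* a 3D stack of tubular capsules ("fibers") plus spherical debris with
  known per-object voxel counts.

All randomness flows through one ``numpy`` Generator seeded per call, so
identical (seed, parameters) reproduce the scene bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .model import BandROI, CellRegion, LayerSegmentation, MultichannelImage

__all__ = [
    "Expected",
    "GroundTruth",
    "expected_basal_fraction",
    "expected_bin_fractions",
    "expected_roughness_px",
    "generate_layer_section",
    "generate_membrane_band",
    "generate_cell",
    "generate_fiber_stack",
]

DEFAULT_PIXEL_SIZE_UM = 0.065  # 100x objective


@dataclass(frozen=True)
class Expected:
    value: float
    derivation: str


@dataclass
class GroundTruth:
    """Parameter record of a generated scene plus closed-form expectations."""

    generator: str
    seed: int
    params: dict
    expected: dict[str, Expected]
    extras: dict = field(default_factory=dict, repr=False)

    def to_json(self) -> dict:
        return {
            "generator": self.generator,
            "seed": self.seed,
            "params": self.params,
            "expected": {
                k: {"value": e.value, "derivation": e.derivation}
                for k, e in self.expected.items()
            },
        }


# ---------------------------------------------------------------- depth laws

def _depth_cdf(depth_law: str, tau: float | None, u0: float | None):
    """CDF of the normalized spot depth u on [0, 1]."""
    if depth_law == "uniform":
        return lambda u: np.clip(u, 0.0, 1.0)
    if depth_law == "exponential":
        if tau is None or tau <= 0:
            raise ValueError("exponential depth law needs tau > 0")
        z = 1.0 - math.exp(-1.0 / tau)
        return lambda u: (1.0 - np.exp(-np.clip(u, 0.0, 1.0) / tau)) / z
    if depth_law == "point_mass":
        if u0 is None or not 0.0 <= u0 <= 1.0:
            raise ValueError("point_mass depth law needs u0 in [0, 1]")
        return lambda u: (np.asarray(u) >= u0).astype(float)
    raise ValueError(f"unknown depth law {depth_law!r}")


def expected_basal_fraction(
    depth_law: str,
    cutoff: float = 0.3,
    tau: float | None = None,
    u0: float | None = None,
) -> Expected:
    """Closed-form basal fraction of a depth law: F(cutoff)."""
    cdf = _depth_cdf(depth_law, tau, u0)
    names = {
        "uniform": "cdf_uniform: cutoff",
        "exponential": "cdf_truncated_exponential: (1-exp(-c/tau))/(1-exp(-1/tau))",
        "point_mass": "cdf_point_mass: 1[u0 < cutoff]",
    }
    value = float(cdf(cutoff)) if depth_law != "point_mass" else (
        1.0 if u0 < cutoff else 0.0
    )
    return Expected(value=value, derivation=names[depth_law])


def expected_bin_fractions(
    depth_law: str,
    n_bins: int = 10,
    tau: float | None = None,
    u0: float | None = None,
) -> np.ndarray:
    """Closed-form per-bin mass of a depth law (basal-most bin first)."""
    cdf = _depth_cdf(depth_law, tau, u0)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    vals = cdf(edges)
    vals[-1] = 1.0  # last bin closed
    return np.diff(vals)


# ------------------------------------------------------------- layer scenes

def _deposit_bilinear(img: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> None:
    """Accumulate unit mass at subpixel positions by bilinear spreading."""
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    fy, fx = ys - y0, xs - x0
    h, w = img.shape
    for dy in (0, 1):
        for dx in (0, 1):
            wgt = (fy if dy else 1 - fy) * (fx if dx else 1 - fx)
            yy = np.clip(y0 + dy, 0, h - 1)
            xx = np.clip(x0 + dx, 0, w - 1)
            np.add.at(img, (yy, xx), wgt)


def generate_layer_section(
    shape: tuple[int, int] = (140, 220),
    layer_geometry: str = "flat",
    depth_law: str = "uniform",
    n_spots: int = 200,
    spot_sigma: float = 2.0,
    background: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    tau: float | None = None,
    u0: float | None = None,
    margin: int = 10,
    curve_amplitude: float = 15.0,
    curve_periods: float = 1.0,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> tuple[MultichannelImage, LayerSegmentation, GroundTruth]:
    """Synthetic tissue section: a BM-attached layer with RNA spots.

    The RNA channel is a sum of isotropic Gaussian spots whose normalized
    depth u (0 = basal boundary, 1 = apical) is drawn from ``depth_law``,
    plus a constant background and optional Gaussian noise clamped at zero.
    On flat layers the spot blur uses reflecting boundaries at the layer
    edges so the generated depth distribution stays the stated one.
    """
    if n_spots < 0:
        raise ValueError("n_spots must be >= 0")
    h, w = shape
    rng = np.random.default_rng(seed)
    cdf = _depth_cdf(depth_law, tau, u0)  # validates law parameters
    # inverse-CDF sampling of depth
    if depth_law == "uniform":
        u = rng.uniform(0.0, 1.0, n_spots)
    elif depth_law == "exponential":
        z = 1.0 - math.exp(-1.0 / tau)
        u = -tau * np.log(1.0 - rng.uniform(0.0, 1.0, n_spots) * z)
    else:  # point_mass
        u = np.full(n_spots, float(u0))

    rna = np.zeros(shape)
    if layer_geometry == "flat":
        r0, r1 = margin, h - margin - 1  # basal row, apical row
        c0, c1 = margin, w - margin - 1
        mask = np.zeros(shape, dtype=bool)
        mask[r0 : r1 + 1, c0 : c1 + 1] = True
        basal = np.array([[c0, r0], [c1, r0]], dtype=float)
        apical = np.array([[c0, r1], [c1, r1]], dtype=float)
        if n_spots and not mask.any():
            raise ValueError("spots requested but layer mask is empty")
        xs = rng.uniform(c0, c1, n_spots)
        ys = r0 + u * (r1 - r0)
        _deposit_bilinear(rna, ys, xs)
        if spot_sigma > 0:
            crop = rna[r0 : r1 + 1, c0 : c1 + 1]
            rna[r0 : r1 + 1, c0 : c1 + 1] = ndimage.gaussian_filter(
                crop, spot_sigma, mode="reflect"
            )
        rows = np.arange(h, dtype=float)
        analytic_u = np.full(shape, np.nan)
        analytic_u[mask] = (
            ((rows - r0) / (r1 - r0))[:, None] * np.ones((1, w))
        )[mask]
    elif layer_geometry == "curved":
        thickness = h - 4 * margin - 2 * int(abs(curve_amplitude))
        if thickness < 20:
            raise ValueError("shape too small for curved geometry")
        half = thickness / 2.0
        c0, c1 = margin, w - margin - 1
        xs_dense = np.linspace(c0, c1, 8 * (c1 - c0))
        kx = 2 * np.pi * curve_periods / (c1 - c0)
        yc = h / 2.0 + curve_amplitude * np.sin(kx * (xs_dense - c0))
        slope = curve_amplitude * kx * np.cos(kx * (xs_dense - c0))
        norm = np.sqrt(1.0 + slope**2)
        nx, ny = -slope / norm, 1.0 / norm  # unit normal, basal side is +n
        center = np.column_stack([xs_dense, yc])
        tree = cKDTree(center)
        yy, xx = np.mgrid[0:h, 0:w]
        pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        _, idx = tree.query(pts)
        off = (pts[:, 0] - center[idx, 0]) * nx[idx] + (
            pts[:, 1] - center[idx, 1]
        ) * ny[idx]
        inside = (np.abs(off) <= half) & (pts[:, 0] >= c0) & (pts[:, 0] <= c1)
        mask = inside.reshape(shape)
        analytic_u = np.full(shape, np.nan)
        analytic_u.ravel()[inside] = (half - off[inside]) / thickness
        step = 64
        basal = np.column_stack(
            [xs_dense[::step] + half * nx[::step], yc[::step] + half * ny[::step]]
        )
        apical = np.column_stack(
            [xs_dense[::step] - half * nx[::step], yc[::step] - half * ny[::step]]
        )
        if n_spots and not mask.any():
            raise ValueError("spots requested but layer mask is empty")
        t = rng.uniform(c0, c1, n_spots)
        ycs = h / 2.0 + curve_amplitude * np.sin(kx * (t - c0))
        sl = curve_amplitude * kx * np.cos(kx * (t - c0))
        nn = np.sqrt(1.0 + sl**2)
        nxs, nys = -sl / nn, 1.0 / nn
        sx = t + (half - u * thickness) * nxs
        sy = ycs + (half - u * thickness) * nys
        _deposit_bilinear(rna, sy, sx)
        if spot_sigma > 0:
            rna = ndimage.gaussian_filter(rna, spot_sigma, mode="constant")
    else:
        raise ValueError(f"unknown layer geometry {layer_geometry!r}")

    rna = rna + background
    if noise_sd > 0:
        rna = rna + rng.normal(0.0, noise_sd, shape)
    rna = np.clip(rna, 0.0, None)
    wga = mask.astype(float)  # structural channel, not quantified

    image = MultichannelImage(
        np.stack([rna, wga]), ["rna", "wga"], (pixel_size_um, pixel_size_um)
    )
    layer = LayerSegmentation(mask=mask, basal_boundary=basal, apical_boundary=apical)
    params = {
        "shape": list(shape),
        "layer_geometry": layer_geometry,
        "depth_law": depth_law,
        "tau": tau,
        "u0": u0,
        "n_spots": n_spots,
        "spot_sigma": spot_sigma,
        "background": background,
        "noise_sd": noise_sd,
    }
    gt = GroundTruth(
        generator="layer_section",
        seed=seed,
        params=params,
        expected={
            "basal_fraction": expected_basal_fraction(depth_law, 0.3, tau=tau, u0=u0)
        },
        extras={"analytic_depth": analytic_u, "spot_depths": u},
    )
    return image, layer, gt


# ------------------------------------------------------------ membrane band

def expected_roughness_px(waveform: str, amplitude: float = 0.0) -> Expected:
    """Closed-form mean |offset| of the membrane waveform, in pixels."""
    if waveform == "flat":
        return Expected(0.0, "flat: zero offset")
    if waveform == "sine":
        return Expected(2.0 * amplitude / math.pi, "mean |A sin| = 2A/pi")
    if waveform == "square":
        return Expected(float(amplitude), "square: |offset| constant at A")
    raise ValueError(f"unknown waveform {waveform!r}")


def _membrane_offsets(
    waveform: str, x: np.ndarray, amplitude: float, wavelength: float
) -> np.ndarray:
    if waveform == "flat":
        return np.zeros_like(x)
    if waveform == "sine":
        return amplitude * np.sin(2 * np.pi * x / wavelength)
    if waveform == "square":
        return np.where((x % wavelength) < wavelength / 2.0, amplitude, -amplitude)
    raise ValueError(f"unknown waveform {waveform!r}")


def generate_membrane_band(
    length_px: int = 360,
    width_px: int = 120,
    waveform: str = "flat",
    amplitude: float = 10.0,
    wavelength: float = 60.0,
    line_thickness_px: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> tuple[MultichannelImage, BandROI, GroundTruth]:
    """Membrane band scene: a bright ridge at a known offset from the centerline.

    The ridge is the set of pixels within ``line_thickness_px / 2`` of the
    continuous membrane polyline, so the drawn curve is not quantized to
    integer rows before thickening.
    """
    if waveform != "flat" and amplitude >= width_px / 2 - line_thickness_px:
        raise ValueError("amplitude exceeds band half-width")
    rng = np.random.default_rng(seed)
    w, length = width_px, length_px
    x = np.arange(length, dtype=float)
    off = _membrane_offsets(waveform, x, amplitude, wavelength)
    yc = w // 2 + off
    # dense polyline through the per-column membrane points
    verts = np.column_stack([x, yc])
    dense = []
    for a, b in zip(verts[:-1], verts[1:]):
        n = max(2, int(np.ceil(np.hypot(*(b - a)))) * 2)
        dense.append(np.linspace(a, b, n, endpoint=False))
    dense.append(verts[-1:])
    dense = np.vstack(dense)
    tree = cKDTree(dense)
    yy, xx = np.mgrid[0:w, 0:length]
    d, _ = tree.query(np.column_stack([xx.ravel(), yy.ravel()]).astype(float))
    ridge = (d <= line_thickness_px / 2.0).reshape(w, length).astype(float)
    img = ridge.copy()
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(img, 0.0, None)
    image = MultichannelImage(
        img[None], ["itga6"], (pixel_size_um, pixel_size_um)
    )
    band = BandROI(
        centerline=np.array([[0.0, w // 2], [length - 1.0, w // 2]]),
        width_px=w,
    )
    gt = GroundTruth(
        generator="membrane_band",
        seed=seed,
        params={
            "length_px": length,
            "width_px": w,
            "waveform": waveform,
            "amplitude": amplitude,
            "wavelength": wavelength,
            "line_thickness_px": line_thickness_px,
            "noise_sd": noise_sd,
        },
        expected={"roughness_px": expected_roughness_px(waveform, amplitude)},
        extras={"offsets_px": off},
    )
    return image, band, gt


# -------------------------------------------------------------- single cell

def generate_cell(
    radius_px: int = 40,
    profile: str = "uniform",
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    power: float = 1.0,
    contrast: float = 3.0,
    margin: int = 10,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> tuple[MultichannelImage, CellRegion, GroundTruth]:
    """Disk cell with a controllable radial intensity profile.

    ``uniform``: constant intensity.  ``radial_power``: intensity equal to
    (rho)^power with rho the normalized center distance.  ``two_zone``:
    intensity ``contrast`` in the peripheral 15% boundary-coordinate zone
    and 1 elsewhere, mirroring the cortical-ratio zone definition.
    """
    if radius_px < 20:
        raise ValueError("radius below 20 px discretization floor")
    rng = np.random.default_rng(seed)
    n = 2 * (radius_px + margin) + 1
    c = radius_px + margin
    yy, xx = np.mgrid[0:n, 0:n]
    rho_px = np.hypot(yy - c, xx - c)
    mask = rho_px <= radius_px

    expected: dict[str, Expected] = {}
    if profile == "uniform":
        intensity = mask.astype(float)
        expected["cortical_ratio"] = Expected(1.0, "uniform: equal zone means")
        expected["pdi"] = Expected(1.0, "uniform: weighted moment = uniform moment")
    elif profile == "radial_power":
        p = float(power)
        intensity = np.where(mask, (rho_px / radius_px) ** p, 0.0)
        a, b = 1.0 - PERIPHERAL_FRACTION_DEFAULT, CENTRAL_FRACTION_DEFAULT
        peri = (2 / (p + 2)) * (1 - a ** (p + 2)) / (1 - a**2)
        cent = (2 / (p + 2)) * b**p
        expected["cortical_ratio"] = Expected(
            peri / cent, "area-weighted annulus/central means of rho^p"
        )
        expected["pdi"] = Expected(
            2.0 * (p + 2) / (p + 4), "moment ratio: 2(p+2)/(p+4)"
        )
    elif profile == "two_zone":
        d = ndimage.distance_transform_edt(mask)
        r = np.full(mask.shape, np.nan)
        r[mask] = 1.0 - d[mask] / d.max()
        intensity = np.where(mask, 1.0, 0.0)
        intensity[mask & (r >= 1.0 - PERIPHERAL_FRACTION_DEFAULT)] = float(contrast)
        expected["cortical_ratio"] = Expected(
            float(contrast), "by construction: zone intensities c and 1"
        )
    else:
        raise ValueError(f"unknown cell profile {profile!r}")

    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, intensity.shape)
    intensity = np.clip(intensity, 0.0, None)
    image = MultichannelImage(
        intensity[None], ["signal"], (pixel_size_um, pixel_size_um)
    )
    cell = CellRegion(mask=mask, label="synthetic_cell")
    gt = GroundTruth(
        generator="cell",
        seed=seed,
        params={
            "radius_px": radius_px,
            "profile": profile,
            "power": power,
            "contrast": contrast,
            "noise_sd": noise_sd,
        },
        expected=expected,
    )
    return image, cell, gt


PERIPHERAL_FRACTION_DEFAULT = 0.15
CENTRAL_FRACTION_DEFAULT = 0.65


# -------------------------------------------------------------- fiber stack

def _segment_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between two 3D segments (q1 may equal q0: a point)."""
    # sample-based bound is enough for placement rejection
    t = np.linspace(0.0, 1.0, 32)
    a = p0[None] + t[:, None] * (p1 - p0)[None]
    b = q0[None] + t[:, None] * (q1 - q0)[None]
    return float(np.min(np.linalg.norm(a[:, None] - b[None], axis=-1)))


def generate_fiber_stack(
    shape: tuple[int, int, int] = (24, 96, 96),
    n_fibers: int = 3,
    fiber_radius_px: int = 2,
    n_spheres: int = 5,
    sphere_radius_px: int = 3,
    intensity: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    length_factor: float = 6.0,
    voxel_size_um: tuple[float, float, float] = (0.1, 0.1, 0.1),
    max_attempts: int = 1000,
) -> tuple[MultichannelImage, GroundTruth]:
    """3D stack of randomly oriented capsules (fibers) plus spherical debris.

    Object geometry lives in voxel-index space; ground truth records each
    object's voxel count and the total true fiber volume in µm³ (count ×
    voxel volume).  Placement is by rejection sampling; exceeding
    ``max_attempts`` raises rather than silently biasing object density.
    """
    if length_factor < 5.0:
        raise ValueError("fiber length must be at least 5x its diameter")
    rng = np.random.default_rng(seed)
    vol = np.zeros(shape)
    dims = np.array(shape, dtype=float)
    vox_vol = float(np.prod(voxel_size_um))
    objects: list[dict] = []  # kind, p0, p1, radius

    def too_close(p0, p1, radius) -> bool:
        for o in objects:
            if _segment_distance(p0, p1, o["p0"], o["p1"]) < radius + o["radius"] + 1:
                return True
        return False

    fiber_len = length_factor * 2 * fiber_radius_px
    for kind, count, radius in (
        ("fiber", n_fibers, fiber_radius_px),
        ("sphere", n_spheres, sphere_radius_px),
    ):
        for _ in range(count):
            for attempt in range(max_attempts):
                if kind == "fiber":
                    d = rng.normal(size=3)
                    d /= np.linalg.norm(d)
                    ctr = rng.uniform(radius + 1, dims - radius - 1)
                    p0 = ctr - d * fiber_len / 2
                    p1 = ctr + d * fiber_len / 2
                    if np.any(p0 < radius + 1) or np.any(p0 > dims - radius - 2):
                        continue
                    if np.any(p1 < radius + 1) or np.any(p1 > dims - radius - 2):
                        continue
                else:
                    p0 = p1 = rng.uniform(radius + 1, dims - radius - 2)
                if not too_close(p0, p1, radius):
                    objects.append(
                        {"kind": kind, "p0": p0, "p1": p1, "radius": radius}
                    )
                    break
            else:
                raise ValueError(
                    f"could not place {kind} without overlap in "
                    f"{max_attempts} attempts"
                )

    records = []
    for o in objects:
        p0, p1, radius = o["p0"], o["p1"], o["radius"]
        lo = np.maximum(np.floor(np.minimum(p0, p1) - radius - 1), 0).astype(int)
        hi = np.minimum(
            np.ceil(np.maximum(p0, p1) + radius + 2), dims
        ).astype(int)
        zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        pts = np.stack([zz, yy, xx], axis=-1).astype(float)
        v = p1 - p0
        vv = float(v @ v)
        if vv == 0:
            dist = np.linalg.norm(pts - p0, axis=-1)
        else:
            t = np.clip(((pts - p0) @ v) / vv, 0.0, 1.0)
            dist = np.linalg.norm(pts - (p0 + t[..., None] * v), axis=-1)
        sub = dist <= radius
        vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]][sub] = intensity
        nvox = int(sub.sum())
        records.append(
            {"kind": o["kind"], "voxels": nvox, "volume_um3": nvox * vox_vol}
        )

    if noise_sd > 0:
        vol = vol + rng.normal(0.0, noise_sd, shape)
    vol = np.clip(vol, 0.0, None)
    sz, sy, sx = voxel_size_um
    image = MultichannelImage(vol[None], ["fbn2"], (sx, sy, sz))
    total_fiber = sum(r["volume_um3"] for r in records if r["kind"] == "fiber")
    gt = GroundTruth(
        generator="fiber_stack",
        seed=seed,
        params={
            "shape": list(shape),
            "n_fibers": n_fibers,
            "fiber_radius_px": fiber_radius_px,
            "n_spheres": n_spheres,
            "sphere_radius_px": sphere_radius_px,
            "intensity": intensity,
            "noise_sd": noise_sd,
            "voxel_size_um": list(voxel_size_um),
        },
        expected={
            "total_fiber_volume_um3": Expected(
                float(total_fiber), "supra-threshold voxel count x voxel volume"
            )
        },
        extras={"objects": records},
    )
    return image, gt
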