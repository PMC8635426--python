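"""Seeded synthetic phantoms with machine-readable ground truth.

Every input class the quantification pipeline consumes can be generated
here with exactly known ground truth, so each stage's parameter recovery
can be validated end to end:

* trichrome phantoms — Beer-Lambert forward model from known per-pixel
  stain densities under the fixed stain matrix;
* immunofluorescence fields — disjoint disk nuclei plus marker blobs with
  exact pixel-area bookkeeping;
* clone fields — connected components of exactly requested areas,
  mutually non-touching, straddling the clone-area threshold;
* fiber textures — anti-aliased line segments with von Mises-distributed
  axial orientations of controlled concentration;
* fractal patterns — binary sets of analytically known box dimension.

A phantom is fully determined by its :class:`PhantomSpec` (including the
seed): identical specs give bit-identical images and ground truth.
Intensities are emulated only to the level the quantification needs
(two-level channels plus optional Gaussian noise), not photorealism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from skimage.draw import line_aa

from .deconvolution import TRICHROME_STAIN_MATRIX, StainMatrix, beer_lambert_transmit

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "PlacementError",
    "make_phantom",
    "make_trichrome_phantom",
    "make_if_phantom",
    "make_clone_phantom",
    "make_fiber_phantom",
    "make_fractal_phantom",
]

PHANTOM_KINDS = ("trichrome", "if_field", "clone_field", "fiber_texture", "fractal")

#: Rejection-sampling cap for non-overlapping object placement.  Hitting it
#: is an error reporting the achieved count, never a silent shortfall.
MAX_PLACEMENT_ATTEMPTS = 10_000

#: von Mises concentrations at or above this render all fibers exactly at
#: the mean angle (degenerate-concentration cap).
KAPPA_CAP = 1e6


class PlacementError(RuntimeError):
    """Requested objects could not be placed without overlap."""

    def __init__(self, requested: int, achieved: int, what: str):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"placed only {achieved}/{requested} {what} without overlap "
            f"within {MAX_PLACEMENT_ATTEMPTS} attempts"
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative phantom request; (kind, size, seed, params) fixes the output."""

    kind: str
    width: int = 256
    height: int = 256
    seed: int = 0
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"kind must be one of {PHANTOM_KINDS}, got {self.kind!r}")
        if self.width < 32 or self.height < 32:
            raise ValueError("width and height must be >= 32 pixels")


@dataclass
class GroundTruth:
    """Kind-matched truth record paired with one emitted phantom."""

    kind: str
    data: dict[str, Any]

    def summary(self) -> dict[str, Any]:
        """JSON-safe view: arrays are summarized or listified, units are pixels."""
        out: dict[str, Any] = {"kind": self.kind, "units": "pixels"}
        for k, v in self.data.items():
            if isinstance(v, np.ndarray):
                if v.ndim == 1 and v.size <= 10_000:
                    out[k] = [float(x) for x in v]
                else:
                    out[k] = {"shape": list(v.shape), "sum": float(v.sum())}
            elif isinstance(v, (np.integer,)):
                out[k] = int(v)
            elif isinstance(v, (np.floating,)):
                out[k] = float(v)
            else:
                out[k] = v
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Dispatch a spec to its generator."""
    maker = {
        "trichrome": make_trichrome_phantom,
        "if_field": make_if_phantom,
        "clone_field": make_clone_phantom,
        "fiber_texture": make_fiber_phantom,
        "fractal": make_fractal_phantom,
    }[spec.kind]
    return maker(spec)


# ---------------------------------------------------------------------------
# trichrome


def make_trichrome_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Bright-field trichrome image from known per-pixel stain densities.

    params
    ------
    uniform : 3-sequence, optional
        Constant density per stain over the whole field.
    coverage : mapping stain name -> {fraction, density, radius}, optional
        Blob layout per stain: non-overlapping disks are placed until the
        stain covers exactly ``round(fraction * n_pixels)`` pixels (the
        final disk is trimmed to hit the count exactly).
    stain_matrix : StainMatrix, default the fixed trichrome basis
    i0 : float, default 255
    noise_sigma : float, default 0 (intensity counts, additive Gaussian)

    Returns a float RGB image obeying the Beer-Lambert forward model (so
    deconvolution recovers the density planes to machine precision when
    noise is off) and truth holding the density planes plus the realized
    collagen (trichrome-blue) area fraction.
    """
    p = dict(spec.params)
    stains: StainMatrix = p.pop("stain_matrix", TRICHROME_STAIN_MATRIX)
    i0 = float(p.pop("i0", 255.0))
    noise_sigma = float(p.pop("noise_sigma", 0.0))
    uniform = p.pop("uniform", None)
    coverage = p.pop("coverage", None)
    if p:
        raise ValueError(f"unknown trichrome params: {sorted(p)}")
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)
    densities = np.zeros((h, w, 3))
    if uniform is not None:
        uniform = np.asarray(uniform, dtype=float)
        if uniform.shape != (3,):
            raise ValueError("uniform densities must be a 3-sequence")
        densities += uniform
    if coverage:
        for stain_name, cov in coverage.items():
            idx = stains.index_of(stain_name)
            frac = float(cov["fraction"])
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"coverage fraction must be in [0, 1], got {frac}")
            dens_val = float(cov.get("density", 1.0))
            radius = int(cov.get("radius", 8))
            target_px = round(frac * h * w)
            mask = _disk_coverage_mask(rng, (h, w), target_px, radius)
            densities[..., idx][mask] = dens_val
    if np.any(densities < 0):
        raise ValueError("stain densities must be non-negative")
    image = beer_lambert_transmit(densities, stains=stains, i0=i0)
    if noise_sigma > 0:
        image = np.clip(image + rng.normal(0.0, noise_sigma, image.shape), 0.0, i0)
    blue = densities[..., stains.index_of("trichrome_blue")]
    truth = GroundTruth(
        kind="trichrome",
        data={
            "density_planes": densities,
            "stain_names": list(stains.stain_names),
            "i0": i0,
            "collagen_area_fraction": float((blue > 0).mean()),
            "collagen_px": int((blue > 0).sum()),
        },
    )
    return image, truth


def _disk_coverage_mask(
    rng: np.random.Generator, shape: tuple[int, int], target_px: int, radius: int
) -> np.ndarray:
    """Random disks (overlap allowed, union counted) until exactly
    ``target_px`` pixels are covered; the final disk is trimmed to hit the
    count exactly."""
    mask = np.zeros(shape, dtype=bool)
    covered = 0
    attempts = 0
    while covered < target_px:
        if attempts >= MAX_PLACEMENT_ATTEMPTS:
            raise PlacementError(target_px, covered, "coverage pixels")
        attempts += 1
        r = int(rng.integers(0, shape[0]))
        c = int(rng.integers(0, shape[1]))
        rr, cc = _disk_pixels(r, c, radius, shape)
        new = ~mask[rr, cc]
        rr, cc = rr[new], cc[new]
        remaining = target_px - covered
        if rr.size > remaining:  # trim the last disk to the exact count
            rr, cc = rr[:remaining], cc[:remaining]
        mask[rr, cc] = True
        covered += rr.size
    return mask


# ---------------------------------------------------------------------------
# immunofluorescence fields


def make_if_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """IF composite: disk nuclei in blue, marker blobs in red/green.

    params
    ------
    n_nuclei : int, default 30
    nucleus_radius : (lo, hi) inclusive integer range, default (3, 6)
    nucleus_intensity : default 0.8; background : default 0.05
    markers : mapping channel ('red'/'green') -> {n_blobs, radius, intensity}
        Blobs are disjoint within their channel; realized pixel areas are
        recorded exactly in the truth.
    noise_sigma : default 0.01 (additive Gaussian on [0, 1], clipped)

    Nuclei are placed by rejection sampling with a hard attempt cap; an
    unplaceable request raises :class:`PlacementError` reporting the
    achieved count.
    """
    p = dict(spec.params)
    n_nuclei = int(p.pop("n_nuclei", 30))
    rad_lo, rad_hi = p.pop("nucleus_radius", (3, 6))
    nucleus_intensity = float(p.pop("nucleus_intensity", 0.8))
    background = float(p.pop("background", 0.05))
    markers = p.pop("markers", {})
    noise_sigma = float(p.pop("noise_sigma", 0.01))
    if p:
        raise ValueError(f"unknown if_field params: {sorted(p)}")
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)
    img = np.full((h, w, 3), background)
    occupied = np.zeros((h, w), dtype=bool)
    centers, radii = [], []
    for i in range(n_nuclei):
        placed = False
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            radius = int(rng.integers(rad_lo, rad_hi + 1))
            r = int(rng.integers(radius, h - radius))
            c = int(rng.integers(radius, w - radius))
            rr, cc = _disk_pixels(r, c, radius, (h, w), margin=2)
            if occupied[rr, cc].any():
                continue
            rr, cc = _disk_pixels(r, c, radius, (h, w))
            occupied[rr, cc] = True
            img[rr, cc, 2] = nucleus_intensity
            centers.append((r, c))
            radii.append(radius)
            placed = True
            break
        if not placed:
            raise PlacementError(n_nuclei, i, "nuclei")
    chan_idx = {"red": 0, "green": 1}
    marker_truth: dict[str, dict[str, int]] = {}
    for name, mp in markers.items():
        if name not in chan_idx:
            raise ValueError(f"marker channel must be 'red' or 'green', got {name!r}")
        n_blobs = int(mp.get("n_blobs", 5))
        radius = int(mp.get("radius", 5))
        intensity = float(mp.get("intensity", 0.6))
        ch_mask = np.zeros((h, w), dtype=bool)
        placed_blobs = 0
        attempts = 0
        while placed_blobs < n_blobs:
            if attempts >= MAX_PLACEMENT_ATTEMPTS:
                raise PlacementError(n_blobs, placed_blobs, f"{name} marker blobs")
            attempts += 1
            r = int(rng.integers(radius, h - radius))
            c = int(rng.integers(radius, w - radius))
            rr, cc = _disk_pixels(r, c, radius, (h, w), margin=2)
            if ch_mask[rr, cc].any():
                continue
            rr, cc = _disk_pixels(r, c, radius, (h, w))
            ch_mask[rr, cc] = True
            placed_blobs += 1
        img[..., chan_idx[name]][ch_mask] = intensity
        marker_truth[name] = {"area_px": int(ch_mask.sum()), "n_blobs": n_blobs}
    if noise_sigma > 0:
        img = np.clip(img + rng.normal(0.0, noise_sigma, img.shape), 0.0, 1.0)
    truth = GroundTruth(
        kind="if_field",
        data={
            "nucleus_count": n_nuclei,
            "nucleus_centers": centers,
            "nucleus_radii": radii,
            "nucleus_area_px": int(occupied.sum()),
            "markers": marker_truth,
            "background": background,
        },
    )
    return img, truth


# ---------------------------------------------------------------------------
# clone fields


def make_clone_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Multicolor reporter field of components with exactly requested areas.

    params
    ------
    areas : list of pixel areas (single green channel) or mapping
        channel ('red'/'green'/'blue') -> list of areas
    clone_min_area : int, default 2000 (used only to record the truth split)
    intensity : default 0.6; background : default 0.02
    noise_sigma : default 0.005

    Each component is a serpentine-filled near-square of *exactly* the
    requested pixel area, and components are mutually non-touching across
    all channels (>= 1 background pixel separation even diagonally), so
    8-connected labeling recovers the request exactly.
    """
    p = dict(spec.params)
    areas_param = p.pop("areas", [])
    clone_min_area = int(p.pop("clone_min_area", 2000))
    intensity = float(p.pop("intensity", 0.6))
    background = float(p.pop("background", 0.02))
    noise_sigma = float(p.pop("noise_sigma", 0.005))
    if p:
        raise ValueError(f"unknown clone_field params: {sorted(p)}")
    if isinstance(areas_param, dict):
        areas_by_channel = {k: list(v) for k, v in areas_param.items()}
    else:
        areas_by_channel = {"green": list(areas_param)}
    chan_idx = {"red": 0, "green": 1, "blue": 2}
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)
    img = np.full((h, w, 3), background)
    blocked = np.zeros((h, w), dtype=bool)  # occupied plus 1-px halo
    realized: dict[str, list[int]] = {}
    total_placed = 0
    n_requested = sum(len(v) for v in areas_by_channel.values())
    for name, area_list in areas_by_channel.items():
        if name not in chan_idx:
            raise ValueError(f"unknown clone channel {name!r}")
        realized[name] = []
        for area in area_list:
            area = int(area)
            if area < 1:
                raise ValueError(f"component area must be >= 1, got {area}")
            shape_rr, shape_cc = _serpentine_shape(area)
            sh, sw = shape_rr.max() + 1, shape_cc.max() + 1
            if sh > h or sw > w:
                raise PlacementError(n_requested, total_placed, "clone components")
            placed = False
            for _ in range(MAX_PLACEMENT_ATTEMPTS):
                r0 = int(rng.integers(0, h - sh + 1))
                c0 = int(rng.integers(0, w - sw + 1))
                rr, cc = shape_rr + r0, shape_cc + c0
                if blocked[rr, cc].any():
                    continue
                img[rr, cc, chan_idx[name]] = intensity
                for dr in (-1, 0, 1):  # halo keeps components non-touching
                    for dc in (-1, 0, 1):
                        blocked[
                            np.clip(rr + dr, 0, h - 1), np.clip(cc + dc, 0, w - 1)
                        ] = True
                realized[name].append(area)
                total_placed += 1
                placed = True
                break
            if not placed:
                raise PlacementError(n_requested, total_placed, "clone components")
    if noise_sigma > 0:
        img = np.clip(img + rng.normal(0.0, noise_sigma, img.shape), 0.0, 1.0)
    all_areas = [a for v in realized.values() for a in v]
    truth = GroundTruth(
        kind="clone_field",
        data={
            "areas_by_channel": realized,
            "areas": all_areas,
            "clone_min_area": clone_min_area,
            "n_clones": int(sum(a >= clone_min_area for a in all_areas)),
            "n_singletons": int(sum(a < clone_min_area for a in all_areas)),
        },
    )
    return img, truth


def _serpentine_shape(area: int) -> tuple[np.ndarray, np.ndarray]:
    """First ``area`` pixels of a near-square in serpentine row order.

    Always 4-connected (hence 8-connected) with exactly ``area`` pixels.
    """
    side = int(np.ceil(np.sqrt(area)))
    rr, cc = [], []
    count = 0
    for r in range(side):
        cols = range(side) if r % 2 == 0 else range(side - 1, -1, -1)
        for c in cols:
            rr.append(r)
            cc.append(c)
            count += 1
            if count == area:
                return np.array(rr), np.array(cc)
    return np.array(rr), np.array(cc)


# ---------------------------------------------------------------------------
# fiber textures


def make_fiber_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Grayscale texture of line segments with von Mises axial orientations.

    params
    ------
    n_fibers : int, default 300
    length : segment length in pixels, default 30
    mu : mean axial angle in radians on [0, pi), default 0
    kappa : von Mises concentration of the *doubled* angles, >= 0; kappa = 0
        is the uniform limit, kappa >= 1e6 pins every fiber at mu
    intensity : default 1.0 (peak line intensity; anti-aliased rendering)

    Axial angles are drawn by sampling phi ~ vonMises(2 mu, kappa) on the
    circle and halving: theta = (phi / 2) mod pi.  Truth stores the drawn
    angles (mathematical convention, ccw from +x with y up).
    """
    p = dict(spec.params)
    n_fibers = int(p.pop("n_fibers", 300))
    length = float(p.pop("length", 30.0))
    mu = float(p.pop("mu", 0.0)) % np.pi
    kappa = float(p.pop("kappa", 0.0))
    intensity = float(p.pop("intensity", 1.0))
    if p:
        raise ValueError(f"unknown fiber_texture params: {sorted(p)}")
    if kappa < 0:
        raise ValueError("von Mises concentration kappa must be >= 0")
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)
    if kappa >= KAPPA_CAP:
        theta = np.full(n_fibers, mu)
    else:
        phi = rng.vonmises(2.0 * mu, kappa, size=n_fibers)
        theta = np.mod(phi / 2.0, np.pi)
    img = np.zeros((h, w))
    half = length / 2.0
    for t in theta:
        r_mid = rng.uniform(0, h - 1)
        c_mid = rng.uniform(0, w - 1)
        # math convention: x = col, y = -row
        dr, dc = -np.sin(t) * half, np.cos(t) * half
        r0, c0 = int(round(r_mid - dr)), int(round(c_mid - dc))
        r1, c1 = int(round(r_mid + dr)), int(round(c_mid + dc))
        rr, cc, val = line_aa(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        rr, cc, val = rr[keep], cc[keep], val[keep]
        img[rr, cc] = np.maximum(img[rr, cc], intensity * val)
    truth = GroundTruth(
        kind="fiber_texture",
        data={"angles": theta, "mu": mu, "kappa": kappa, "n_fibers": n_fibers},
    )
    return img, truth


# ---------------------------------------------------------------------------
# fractal patterns


def make_fractal_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Binary mask of analytically known box-counting dimension.

    params
    ------
    pattern : 'filled_square' (D = 2), 'line' (D = 1), or
        'sierpinski_triangle' (D = log 3 / log 2)
    depth : recursion depth for the Sierpinski triangle; the pattern spans
        a 2**depth square and must fit the canvas.
    """
    p = dict(spec.params)
    pattern = p.pop("pattern", "sierpinski_triangle")
    depth = int(p.pop("depth", 7))
    if p:
        raise ValueError(f"unknown fractal params: {sorted(p)}")
    h, w = spec.height, spec.width
    mask = np.zeros((h, w), dtype=bool)
    if pattern == "filled_square":
        side = min(h, w)
        mask[:side, :side] = True
        dim = 2.0
    elif pattern == "line":
        mask[h // 2, :] = True
        dim = 1.0
    elif pattern == "sierpinski_triangle":
        size = 2**depth
        if size > min(h, w):
            raise ValueError(
                f"depth {depth} needs a {size}-px canvas; image is {h}x{w}"
            )
        i, j = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
        mask[:size, :size] = (i & j) == 0
        dim = np.log(3.0) / np.log(2.0)
    else:
        raise ValueError(f"unknown fractal pattern {pattern!r}")
    truth = GroundTruth(
        kind="fractal", data={"pattern": pattern, "dimension": float(dim)}
    )
    return mask, truth


# ---------------------------------------------------------------------------
# shared helpers


def _disk_pixels(
    r: int, c: int, radius: int, shape: tuple[int, int], margin: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of a disk (optionally grown by ``margin``), clipped."""
    rad = radius + margin
    rr, cc = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    inside = rr**2 + cc**2 <= rad**2
    rr, cc = rr[inside] + r, cc[inside] + c
    keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    return rr[keep], cc[keep]
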