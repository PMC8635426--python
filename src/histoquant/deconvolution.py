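"""Trichrome color deconvolution and collagen-content measurement.

Bright-field histology obeys the Beer-Lambert law: the optical density
``OD_c = -log10(I_c / I0_c)`` of each RGB channel is, to first order, a
*linear* mixture of the densities of the co-localized dyes,

    OD = C^T d,

where the rows of the stain matrix ``C`` are the unit absorbance vectors of
the individual dyes and ``d`` holds per-pixel dye densities.  With three
dyes and three channels the system is square, so unmixing is an exact 3x3
linear solve per pixel, followed by clipping of (physically meaningless)
negative densities.  The fraction of pixels that needed clipping is always
reported, never hidden.

On Masson's trichrome sections, collagen takes up the blue dye; the unmixed
blue-density plane therefore proxies collagen content, summarized per image
as an area fraction over a tissue mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TRICHROME_STAIN_MATRIX",
    "StainMatrix",
    "ODImage",
    "DensityMap",
    "CollagenResult",
    "rgb_to_od",
    "deconvolve",
    "tissue_mask_from_od",
    "collagen_content",
    "beer_lambert_transmit",
]

#: Offset (intensity counts) added to numerator and denominator of the OD
#: transform so that zero intensity stays finite.
OD_EPSILON = 1.0

#: Tolerance on the unit-norm invariant of stain-matrix rows.
ROW_NORM_TOL = 1e-3

#: Negative densities larger in magnitude than this count toward
#: ``clip_fraction``; smaller ones are treated as round-off.
CLIP_TOL = 1e-9


@dataclass(frozen=True)
class StainMatrix:
    """3x3 optical-density basis; rows are stains, columns are (R, G, B).

    Each row must be (approximately) a unit vector with non-negative
    entries, and the matrix must be invertible for unmixing to be defined.
    """

    values: np.ndarray
    stain_names: tuple[str, str, str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (3, 3):
            raise ValueError(f"stain matrix must be 3x3, got {v.shape}")
        if np.any(v < 0):
            raise ValueError("stain matrix entries must be non-negative")
        norms = np.linalg.norm(v, axis=1)
        if np.any(np.abs(norms - 1.0) > ROW_NORM_TOL):
            raise ValueError(
                f"stain matrix rows must be unit vectors (norms {norms})"
            )
        if len(self.stain_names) != 3:
            raise ValueError("exactly three stain names required")
        # Name the stain pair that collapses the system, not just "singular".
        if abs(np.linalg.det(v)) < 1e-8:
            pair = self._most_collinear_pair(v)
            raise ValueError(
                "stain matrix is singular; stains "
                f"{self.stain_names[pair[0]]!r} and {self.stain_names[pair[1]]!r} "
                "are collinear"
            )
        object.__setattr__(self, "values", v)

    @staticmethod
    def _most_collinear_pair(v: np.ndarray) -> tuple[int, int]:
        best, best_cos = (0, 1), -1.0
        for i in range(3):
            for j in range(i + 1, 3):
                c = abs(
                    float(v[i] @ v[j])
                    / (np.linalg.norm(v[i]) * np.linalg.norm(v[j]) + 1e-30)
                )
                if c > best_cos:
                    best, best_cos = (i, j), c
        return best

    def index_of(self, name: str) -> int:
        try:
            return self.stain_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown stain {name!r}; known: {self.stain_names}"
            ) from None


#: The fixed trichrome stain basis used throughout: rows are the absorbance
#: vectors of trichrome red, trichrome blue (collagen), and the counterstain.
TRICHROME_STAIN_MATRIX = StainMatrix(
    values=np.array(
        [
            [0.7995107, 0.5914, 0.1053],
            [0.1000, 0.7374, 0.6680],
            [0.5923, 0.3264, 0.7366],
        ]
    ),
    stain_names=("trichrome_red", "trichrome_blue", "counterstain"),
)


@dataclass
class ODImage:
    """Per-pixel optical densities (H, W, 3), dimensionless, >= 0."""

    od: np.ndarray
    i0: np.ndarray  # per-channel incident intensity actually used
    source: str = ""

    @property
    def od_max(self) -> np.ndarray:
        """Cap reached at zero transmitted intensity, per channel."""
        return np.log10((self.i0 + OD_EPSILON) / OD_EPSILON)


@dataclass
class DensityMap:
    """Unmixed per-stain density planes (H, W, n_stains), >= 0 after clipping."""

    densities: np.ndarray
    stains: StainMatrix
    clip_fraction: float
    source: str = ""

    def plane(self, stain: str) -> np.ndarray:
        return self.densities[..., self.stains.index_of(stain)]


@dataclass
class CollagenResult:
    """Per-image collagen summary from the unmixed blue plane."""

    image_id: str
    tissue_px: int
    collagen_px: int
    area_fraction: float
    mean_blue_density: float
    clip_fraction: float = 0.0


def rgb_to_od(image: np.ndarray, i0: float | np.ndarray = 255.0) -> ODImage:
    """Convert a transmitted-light RGB image to optical densities.

    ``OD_c = -log10((I_c + eps) / (i0_c + eps))`` with ``eps = 1`` count, so
    a blank pixel (I = i0) maps to 0 and zero intensity maps to the finite
    cap ``log10(i0 + 1)``.

    Parameters
    ----------
    image:
        (H, W, 3) array, any real dtype, intensities in ``[0, i0]``.
    i0:
        Incident (background) intensity, scalar or per-channel.  Defaults to
        255, the 8-bit channel maximum.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    i0_arr = np.broadcast_to(np.asarray(i0, dtype=float), (3,)).copy()
    if np.any(i0_arr <= 0):
        raise ValueError(f"i0 must be positive, got {i0_arr}")
    od = -np.log10((img + OD_EPSILON) / (i0_arr + OD_EPSILON))
    # Intensities above i0 (specular glints) would give tiny negative ODs.
    od = np.maximum(od, 0.0)
    return ODImage(od=od, i0=i0_arr)


def beer_lambert_transmit(
    densities: np.ndarray,
    stains: StainMatrix = TRICHROME_STAIN_MATRIX,
    i0: float | np.ndarray = 255.0,
) -> np.ndarray:
    """Forward model: per-pixel stain densities -> transmitted RGB image.

    Exact inverse of :func:`rgb_to_od` followed by :func:`deconvolve`: the
    OD of the output is the linear mixture ``C^T d`` and the epsilon offset
    of the OD transform is compensated, so the round trip is identity to
    floating-point precision for non-negative densities.  Output is float;
    quantize downstream if integer pixels are wanted.
    """
    d = np.asarray(densities, dtype=float)
    if d.shape[-1] != 3:
        raise ValueError("density array must have 3 stain planes on the last axis")
    if np.any(d < 0):
        raise ValueError("stain densities must be non-negative")
    i0_arr = np.broadcast_to(np.asarray(i0, dtype=float), (3,))
    od = d @ stains.values  # (..., 3) pixel OD = C^T d
    return (i0_arr + OD_EPSILON) * np.power(10.0, -od) - OD_EPSILON


def deconvolve(od: ODImage | np.ndarray, stains: StainMatrix = TRICHROME_STAIN_MATRIX) -> DensityMap:
    """Unmix an OD image into per-stain density planes.

    Solves the square system ``C^T d = od`` exactly per pixel, then clips
    negative components to zero; ``clip_fraction`` reports the fraction of
    pixels that had any component below ``-1e-9`` before clipping.
    """
    od_arr = od.od if isinstance(od, ODImage) else np.asarray(od, dtype=float)
    if od_arr.shape[-1] != 3:
        raise ValueError("OD array must have 3 channels on the last axis")
    flat = od_arr.reshape(-1, 3)
    # d = od @ inv(C^T)^T = od @ inv(C)
    dens = np.linalg.solve(stains.values.T, flat.T).T
    clipped = np.any(dens < -CLIP_TOL, axis=1)
    clip_fraction = float(clipped.mean()) if flat.size else 0.0
    dens = np.maximum(dens, 0.0).reshape(od_arr.shape)
    source = od.source if isinstance(od, ODImage) else ""
    return DensityMap(
        densities=dens, stains=stains, clip_fraction=clip_fraction, source=source
    )


def tissue_mask_from_od(od: ODImage, od_min: float = 0.05) -> np.ndarray:
    """Default tissue mask: pixels whose summed OD exceeds ``od_min``.

    Blank (white) background has OD ~ 0 in all channels and is excluded.
    """
    return od.od.sum(axis=-1) > od_min


def collagen_content(
    density_map: DensityMap,
    tissue_mask: np.ndarray,
    density_threshold: float = 0.15,
    image_id: str = "",
    collagen_stain: str = "trichrome_blue",
) -> CollagenResult:
    """Measure collagen coverage from an unmixed density map.

    A tissue pixel is collagen-positive when the blue-stain density exceeds
    ``density_threshold`` *and* blue is the arg-max stain at that pixel (the
    second condition rejects red/blue bleed-through double counting).
    """
    if density_threshold < 0:
        raise ValueError("density_threshold must be >= 0")
    mask = np.asarray(tissue_mask, dtype=bool)
    if mask.shape != density_map.densities.shape[:-1]:
        raise ValueError(
            f"tissue mask shape {mask.shape} does not match density map "
            f"{density_map.densities.shape[:-1]}"
        )
    tissue_px = int(mask.sum())
    if tissue_px == 0:
        raise ValueError("empty tissue mask: collagen fraction is undefined")
    blue_idx = density_map.stains.index_of(collagen_stain)
    blue = density_map.densities[..., blue_idx]
    argmax = np.argmax(density_map.densities, axis=-1)
    positive = mask & (blue > density_threshold) & (argmax == blue_idx)
    collagen_px = int(positive.sum())
    return CollagenResult(
        image_id=image_id,
        tissue_px=tissue_px,
        collagen_px=collagen_px,
        area_fraction=collagen_px / tissue_px,
        mean_blue_density=float(blue[mask].mean()),
        clip_fraction=density_map.clip_fraction,
    )
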