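"""Immunofluorescence quantification.

Confocal composites are split into channels: the blue (DAPI) channel is
binarized with an image-specific automated threshold (Otsu's between-class
variance criterion on a 256-bin histogram, the ``graythresh`` convention),
marker channels with a fixed threshold (0.3 by default) held constant
across all images of a stain.  Nuclei are counted as 8-connected
components at or above a minimum area (15 px by default); marker coverage
is normalized per cell; relative counts (e.g. GFP+ objects over DAPI
objects) use the same size filter on both masks.

Touching nuclei are deliberately *not* split by watershed: counting raw
thresholded components mirrors the original measurement procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .config import DEFAULT_MARKER_THRESHOLD, DEFAULT_MIN_NUCLEUS_AREA

__all__ = [
    "QuantResult",
    "RelativeCount",
    "normalize_channel",
    "auto_threshold",
    "binarize_fixed",
    "count_nuclei",
    "stain_area_per_cell",
    "relative_gfp_count",
    "quantify_if_image",
]

#: Histogram resolution of the automated threshold (8-bit convention).
OTSU_BINS = 256


@dataclass
class QuantResult:
    """Per-image IF summary: nucleus count, marker areas, areas per cell."""

    image_id: str
    nucleus_count: int
    marker_area: dict[str, int]
    area_per_cell: dict[str, float]
    thresholds: dict[str, float]
    small_nuclei_discarded: int = 0


@dataclass
class RelativeCount:
    """Size-filtered object-count ratio, numerator over denominator."""

    numerator: int
    denominator: int

    @property
    def ratio(self) -> float:
        if self.denominator == 0:
            raise ValueError("relative count undefined: zero denominator objects")
        return self.numerator / self.denominator


def normalize_channel(channel: np.ndarray) -> np.ndarray:
    """Scale an intensity plane to [0, 1] by its dtype maximum.

    Integer dtypes divide by their type maximum (255 for uint8, 65535 for
    uint16); float inputs are assumed already on [0, 1] and validated.
    """
    arr = np.asarray(channel)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    arr = arr.astype(float)
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("float channels must already be scaled to [0, 1]")
    return arr


def auto_threshold(channel: np.ndarray) -> float:
    """Image-specific automated threshold (Otsu, 256-bin histogram).

    Returns the threshold in [0, 1] that maximizes the between-class
    variance over all 255 possible histogram cuts; by construction it
    equals an exhaustive scan over every cut.  The returned value is the
    upper edge of the last bin assigned to the background class, so
    binarizing with a strict ``>`` keeps the two classes as Otsu split
    them.

    Raises
    ------
    ValueError
        If the channel is constant (degenerate single-spike histogram).
    """
    arr = normalize_channel(channel)
    if arr.size == 0:
        raise ValueError("empty channel")
    counts, edges = np.histogram(arr, bins=OTSU_BINS, range=(0.0, 1.0))
    n = counts.sum()
    if np.count_nonzero(counts) < 2:
        raise ValueError("constant channel: automated threshold is undefined")
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = counts / n
    omega0 = np.cumsum(w)  # P(class 0) for cut after bin k
    mu_cum = np.cumsum(w * centers)
    mu_total = mu_cum[-1]
    omega1 = 1.0 - omega0
    # Between-class variance for every cut; 0/0 at empty classes -> 0.
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega0 - mu_cum) ** 2 / (omega0 * omega1)
    sigma_b = np.nan_to_num(sigma_b[:-1], nan=0.0, posinf=0.0)
    k = int(np.argmax(sigma_b))
    return float(edges[k + 1])


def binarize_fixed(
    channel: np.ndarray, threshold: float = DEFAULT_MARKER_THRESHOLD
) -> np.ndarray:
    """Fixed-threshold binarization with a strict ``>`` comparison.

    A pixel exactly at the threshold is background; this tie rule is part
    of the contract (``0.30 -> False``).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return normalize_channel(channel) > threshold


def count_nuclei(
    dapi_mask: np.ndarray,
    min_area: int = DEFAULT_MIN_NUCLEUS_AREA,
    connectivity: int = 8,
) -> tuple[int, np.ndarray, int]:
    """Count size-filtered connected components in a binary DAPI mask.

    Components with area >= ``min_area`` (inclusive) are retained; smaller
    ones are discarded and tallied separately.

    Returns
    -------
    (count, labels, discarded):
        Retained component count, the relabeled image (retained components
        numbered 1..count, discarded ones zeroed), and the discarded count.
    """
    mask = _as_binary(dapi_mask)
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    labels = measure.label(mask, connectivity=_skimage_connectivity(connectivity))
    if labels.max() == 0:
        return 0, labels, 0
    areas = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(areas >= min_area) + 1
    discarded = int(labels.max() - keep.size)
    lut = np.zeros(labels.max() + 1, dtype=labels.dtype)
    lut[keep] = np.arange(1, keep.size + 1)
    return int(keep.size), lut[labels], discarded


def stain_area_per_cell(marker_mask: np.ndarray, nucleus_count: int) -> float:
    """Marker-positive pixel area divided by the nucleus count.

    A zero nucleus count is an error (the normalization is undefined),
    never a silent zero.
    """
    if nucleus_count <= 0:
        raise ValueError(
            "area per cell undefined: nucleus count must be positive, "
            f"got {nucleus_count}"
        )
    return int(_as_binary(marker_mask).sum()) / nucleus_count


def relative_gfp_count(
    gfp_mask: np.ndarray,
    dapi_mask: np.ndarray,
    min_area: int = DEFAULT_MIN_NUCLEUS_AREA,
) -> RelativeCount:
    """Ratio of size-filtered object counts, GFP+ over DAPI+.

    The same area filter is applied to both channels so that debris is
    rejected symmetrically.
    """
    gfp = _as_binary(gfp_mask)
    dapi = _as_binary(dapi_mask)
    if gfp.shape != dapi.shape:
        raise ValueError(
            f"mask shapes differ: {gfp.shape} vs {dapi.shape}"
        )
    n_gfp, _, _ = count_nuclei(gfp, min_area=min_area)
    n_dapi, _, _ = count_nuclei(dapi, min_area=min_area)
    rc = RelativeCount(numerator=n_gfp, denominator=n_dapi)
    if n_dapi == 0:
        raise ValueError("relative count undefined: no DAPI objects")
    return rc


def quantify_if_image(
    rgb: np.ndarray,
    image_id: str = "",
    marker_threshold: float = DEFAULT_MARKER_THRESHOLD,
    min_nucleus_area: int = DEFAULT_MIN_NUCLEUS_AREA,
) -> QuantResult:
    """Full per-image IF quantification of an RGB composite.

    Blue is treated as DAPI (automated threshold + size-filtered count);
    red and green are marker channels (fixed threshold, area per cell).
    """
    img = np.asarray(rgb)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) composite, got {img.shape}")
    dapi = normalize_channel(img[..., 2])
    dapi_thr = auto_threshold(dapi)
    dapi_mask = dapi > dapi_thr
    count, _, discarded = count_nuclei(dapi_mask, min_area=min_nucleus_area)
    marker_area: dict[str, int] = {}
    area_per_cell: dict[str, float] = {}
    for name, idx in (("marker_red", 0), ("marker_green", 1)):
        mask = binarize_fixed(img[..., idx], marker_threshold)
        marker_area[name] = int(mask.sum())
        area_per_cell[name] = (
            stain_area_per_cell(mask, count) if count > 0 else float("nan")
        )
    return QuantResult(
        image_id=image_id,
        nucleus_count=count,
        marker_area=marker_area,
        area_per_cell=area_per_cell,
        thresholds={
            "dapi": dapi_thr,
            "marker_red": marker_threshold,
            "marker_green": marker_threshold,
        },
        small_nuclei_discarded=discarded,
    )


def _as_binary(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype != bool:
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask must be binary")
        arr = arr.astype(bool)
    return arr


def _skimage_connectivity(connectivity: int) -> int:
    if connectivity == 4:
        return 1
    if connectivity == 8:
        return 2
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
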