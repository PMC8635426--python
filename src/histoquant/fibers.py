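"""Collagen fiber architecture: orientation, alignment, fractal dimension.

Fibers are *axial* data — an orientation is defined modulo 180 degrees —
so every circular statistic here first doubles the angles onto the full
circle.  The alignment coefficient R-bar is the mean resultant length of
the doubled angles: 1 for perfectly parallel fibers (fibrotic, scar-like),
near 0 for an isotropic basket weave (physiologic dermis).  Rayleigh's
test (z = n R-bar^2) assesses departure from circular uniformity.

The per-pixel orientation field comes from structure-tensor eigenanalysis:
the local fiber axis is the eigenvector of the smoothed gradient outer
product with the *smaller* eigenvalue, and the coherence
(l1 - l2) / (l1 + l2) gates which pixels contribute angles downstream.
This front end replaces per-fiber curvelet extraction; it feeds the same
alignment statistics but does not measure per-fiber length or curvature.

Tissue complexity is summarized by the box-counting fractal dimension of a
binary mask: the slope of log N(s) against log(1/s), where N(s) counts
occupied s-by-s grid boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.feature import structure_tensor

from .config import DEFAULT_BOX_SIZES, DEFAULT_COHERENCE_MIN, DEFAULT_FIBER_SIGMA

__all__ = [
    "OrientationField",
    "FiberMetrics",
    "PCAResult",
    "orientation_field",
    "alignment_statistic",
    "rayleigh_test",
    "fiber_feature_pca",
    "box_count_dimension",
    "fiber_metrics",
]

#: Minimum angle count for the Rayleigh p approximation to be meaningful.
RAYLEIGH_MIN_N = 4

#: Minimum number of box sizes for a fractal-dimension fit.
BOX_MIN_SIZES = 4


@dataclass
class OrientationField:
    """Per-pixel axial angles (radians, [0, pi)) with coherence weights."""

    theta: np.ndarray  # axial angle, mathematical convention (ccw from +x)
    coherence: np.ndarray  # in [0, 1]; 0 where the local tensor is isotropic
    sigma: float

    def retained_angles(self, coherence_min: float = DEFAULT_COHERENCE_MIN) -> np.ndarray:
        """Angles at pixels whose coherence exceeds the cutoff."""
        return self.theta[self.coherence > coherence_min]


@dataclass
class FiberMetrics:
    """Per-image fiber-architecture summary."""

    image_id: str
    n_angles: int
    alignment: float  # R-bar on doubled angles, in [0, 1]
    mean_axial_angle: float  # radians, [0, pi); NaN when alignment is 0
    rayleigh_z: float
    rayleigh_p: float
    fractal_dimension: float
    fractal_r2: float


@dataclass
class PCAResult:
    """Correlation-matrix PCA: loadings, scores, explained variance."""

    loadings: np.ndarray  # (n_features, n_components)
    scores: np.ndarray  # (n_samples, n_components), zero mean per column
    explained_variance_ratio: np.ndarray
    feature_names: list[str]


def orientation_field(
    image: np.ndarray, sigma: float = DEFAULT_FIBER_SIGMA
) -> OrientationField:
    """Structure-tensor orientation estimate of a grayscale image.

    ``theta`` is the local fiber axis in the mathematical convention
    (counter-clockwise from the +x / column axis, with y pointing up),
    wrapped to [0, pi).  A constant image yields coherence 0 everywhere,
    so no angles survive the downstream coherence gate.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    if sigma < 1:
        raise ValueError("sigma must be >= 1 pixel")
    arr_rr, arr_rc, arr_cc = structure_tensor(
        img, sigma=sigma, mode="nearest", order="rc"
    )
    # Fiber axis = minor eigenvector of the gradient tensor.  In math
    # coordinates (x = col, y = -row) this gives 2*theta = atan2(2*Jrc,
    # Jrr - Jcc); derived from rotating the gradient axis by 90 degrees.
    theta = 0.5 * np.arctan2(2.0 * arr_rc, arr_rr - arr_cc)
    theta = np.mod(theta, np.pi)
    trace = arr_rr + arr_cc
    spread = np.sqrt((arr_rr - arr_cc) ** 2 + 4.0 * arr_rc**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        coherence = np.where(trace > 0, spread / trace, 0.0)
    return OrientationField(theta=theta, coherence=coherence, sigma=float(sigma))


def alignment_statistic(angles: np.ndarray) -> tuple[float, float]:
    """Alignment coefficient and mean axial angle of undirected orientations.

    Angles are doubled onto the circle (phi = 2 theta); R-bar is the mean
    resultant length |sum exp(i phi)| / n and the mean axial angle is
    arg(sum exp(i phi)) / 2 mapped to [0, pi).  For R-bar = 0 the mean
    angle is undefined and returned as NaN.
    """
    theta = np.asarray(angles, dtype=float).ravel()
    if theta.size == 0:
        raise ValueError("alignment undefined for an empty angle list")
    z = np.exp(2j * theta).mean()
    rbar = float(np.abs(z))
    if rbar < 1e-12:
        return 0.0 if rbar == 0.0 else rbar, float("nan")
    mean_axial = float(np.mod(np.angle(z) / 2.0, np.pi))
    return rbar, mean_axial


def rayleigh_test(angles: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity on doubled axial angles.

    Returns ``z = n * R-bar^2`` and the finite-n series approximation

        p = exp( sqrt(1 + 4n + 4(n^2 - z n)) - (1 + 2n) ),

    clipped to (0, 1].  Requires n >= 4; the approximation degrades badly
    below that.
    """
    theta = np.asarray(angles, dtype=float).ravel()
    n = theta.size
    if n < RAYLEIGH_MIN_N:
        raise ValueError(f"Rayleigh test needs n >= {RAYLEIGH_MIN_N}, got {n}")
    rbar, _ = alignment_statistic(theta)
    z = n * rbar**2
    arg = 1.0 + 4.0 * n + 4.0 * (n**2 - z * n)
    p = float(np.exp(np.sqrt(max(arg, 0.0)) - (1.0 + 2.0 * n)))
    return float(z), min(max(p, np.finfo(float).tiny), 1.0)


def fiber_feature_pca(features: pd.DataFrame) -> PCAResult:
    """PCA of per-sample fiber features on the correlation matrix.

    Columns are centered to mean zero and scaled to unit (sample) variance
    before eigendecomposition, i.e. this is PCA of the correlation matrix.
    Components are ordered by decreasing eigenvalue; each loading vector's
    sign is fixed so its largest-magnitude entry is positive.

    Raises
    ------
    ValueError
        For < 3 samples, < 2 features, missing values, or a zero-variance
        feature (named in the message).
    """
    df = pd.DataFrame(features)
    n, p = df.shape
    if n < 3:
        raise ValueError(f"PCA needs >= 3 samples, got {n}")
    if p < 2:
        raise ValueError(f"PCA needs >= 2 features, got {p}")
    if df.isna().any().any():
        bad = [c for c in df.columns if df[c].isna().any()]
        raise ValueError(f"missing values in features: {bad}")
    x = df.to_numpy(dtype=float)
    std = x.std(axis=0, ddof=1)
    zero_var = [str(c) for c, s in zip(df.columns, std) if s == 0.0]
    if zero_var:
        raise ValueError(f"zero-variance feature(s): {zero_var}")
    z = (x - x.mean(axis=0)) / std
    corr = (z.T @ z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    loadings = eigvecs[:, order]
    # Deterministic sign: largest-magnitude loading per component positive.
    for j in range(loadings.shape[1]):
        k = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = z @ loadings
    return PCAResult(
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=eigvals / eigvals.sum(),
        feature_names=[str(c) for c in df.columns],
    )


def box_count_dimension(
    mask: np.ndarray, box_sizes: tuple[int, ...] = DEFAULT_BOX_SIZES
) -> tuple[float, float, dict[int, int]]:
    """Box-counting fractal dimension of a binary mask.

    For each box edge ``s`` the image is tiled from the (0, 0) origin
    (padded with background to a multiple of ``s``) and ``N(s)`` counts
    boxes containing at least one foreground pixel.  ``D`` is the slope of
    the least-squares fit of ``log N`` against ``log(1/s)``; the fit R^2
    is returned with the per-size counts.
    """
    arr = np.asarray(mask).astype(bool)
    if arr.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not arr.any():
        raise ValueError("empty mask: fractal dimension undefined")
    sizes = sorted({int(s) for s in box_sizes})
    if len(sizes) < BOX_MIN_SIZES:
        raise ValueError(f"need >= {BOX_MIN_SIZES} distinct box sizes, got {len(sizes)}")
    if sizes[0] < 1:
        raise ValueError("box sizes must be >= 1")
    counts: dict[int, int] = {}
    for s in sizes:
        h = -(-arr.shape[0] // s) * s
        w = -(-arr.shape[1] // s) * s
        padded = np.zeros((h, w), dtype=bool)
        padded[: arr.shape[0], : arr.shape[1]] = arr
        blocks = padded.reshape(h // s, s, w // s, s)
        counts[s] = int(blocks.any(axis=(1, 3)).sum())
    log_inv_s = np.log([1.0 / s for s in sizes])
    log_n = np.log([counts[s] for s in sizes])
    slope, intercept = np.polyfit(log_inv_s, log_n, 1)
    fitted = slope * log_inv_s + intercept
    ss_res = float(((log_n - fitted) ** 2).sum())
    ss_tot = float(((log_n - log_n.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return float(slope), r2, counts


def fiber_metrics(
    image: np.ndarray,
    image_id: str = "",
    sigma: float = DEFAULT_FIBER_SIGMA,
    coherence_min: float = DEFAULT_COHERENCE_MIN,
    box_sizes: tuple[int, ...] = DEFAULT_BOX_SIZES,
    mask_threshold: float = 0.5,
) -> FiberMetrics:
    """End-to-end fiber summary of one grayscale image.

    Orientation field -> coherence-gated angle sample -> alignment and
    Rayleigh statistics, plus the box-counting dimension of the image
    binarized at ``mask_threshold`` (on a [0, 1] scale; anti-aliased
    renderings use 0.5).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:  # RGB: collapse by luminance
        img = img @ np.array([0.2126, 0.7152, 0.0722])
    field_ = orientation_field(img, sigma=sigma)
    angles = field_.retained_angles(coherence_min)
    if angles.size == 0:
        rbar, mean_ax, z, p = 0.0, float("nan"), float("nan"), float("nan")
    else:
        rbar, mean_ax = alignment_statistic(angles)
        if angles.size >= RAYLEIGH_MIN_N:
            z, p = rayleigh_test(angles)
        else:
            z, p = float("nan"), float("nan")
    scale = img.max() if img.max() > 1.0 else 1.0
    binary = img / scale > mask_threshold
    if binary.any():
        d, r2, _ = box_count_dimension(binary, box_sizes)
    else:
        d, r2 = float("nan"), float("nan")
    return FiberMetrics(
        image_id=image_id,
        n_angles=int(angles.size),
        alignment=rbar,
        mean_axial_angle=mean_ax,
        rayleigh_z=z,
        rayleigh_p=p,
        fractal_dimension=d,
        fractal_r2=r2,
    )
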