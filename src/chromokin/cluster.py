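"""Clustering and colocalization statistics.

Punctate clustering of a nuclear protein is quantified by a local
variance filter: the per-pixel population variance over a circular
neighborhood (2-pixel radius by default), averaged over the nuclear
mask.  A clustered (punctate) distribution has a higher mean nuclear
variance than a diffuse one, and groups of nuclei are compared with a
two-tailed two-sample t test.  Channel overlap is quantified with
thresholded Manders coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu

from .errors import ValidationError


# ---------------------------------------------------------------------------
# Local variance filter
# ---------------------------------------------------------------------------


def circular_footprint(radius: int, ndim: int = 2) -> np.ndarray:
    """Boolean neighborhood of voxels whose center distance is <= radius."""
    if radius < 1:
        raise ValidationError("radius must be >= 1")
    grids = np.ogrid[tuple(slice(-radius, radius + 1) for _ in range(ndim))]
    dist2 = sum(g.astype(float) ** 2 for g in grids)
    return dist2 <= radius**2


@dataclass(frozen=True)
class VarianceMapResult:
    """Local-variance map and its nuclear mean."""

    variance_map: np.ndarray
    mean_nuclear_variance: float
    radius: int
    mask: np.ndarray


def local_variance_map(
    image: np.ndarray, radius: int = 2, mask: np.ndarray | None = None
) -> VarianceMapResult:
    """Population variance over a circular neighborhood at every voxel.

    The neighborhood is restricted to the mask (no padding): voxels
    outside the mask contribute neither to the local mean nor to the
    variance, and the map is only defined on the mask.  Implemented via
    mask-weighted box sums so it matches a brute-force double loop
    exactly.
    """
    arr = np.asarray(image, dtype=float)
    if mask is None:
        mask = np.ones(arr.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != arr.shape:
            raise ValidationError("mask shape must match image shape")
    foot = circular_footprint(radius, arr.ndim).astype(float)
    m = mask.astype(float)
    # Zero-outside-mask sums; dividing by the local mask count restricts
    # the statistic to in-mask neighbors.
    count = ndimage.correlate(m, foot, mode="constant", cval=0.0)
    s1 = ndimage.correlate(arr * m, foot, mode="constant", cval=0.0)
    s2 = ndimage.correlate(arr * arr * m, foot, mode="constant", cval=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = s1 / count
        var = s2 / count - mean**2
    var = np.where(mask & (count > 0), np.clip(var, 0.0, None), 0.0)
    mean_var = float(var[mask].mean()) if mask.any() else math.nan
    return VarianceMapResult(
        variance_map=var,
        mean_nuclear_variance=mean_var,
        radius=radius,
        mask=mask,
    )


# ---------------------------------------------------------------------------
# Two-sample test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoSampleSummary:
    """Two-tailed two-sample t test from samples or (mean, sd, n) summaries."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    df: float
    p: float
    variant: str


def _summarize(group) -> tuple[float, float, int]:
    if isinstance(group, tuple) and len(group) == 3:
        mean, sd, n = group
        return float(mean), float(sd), int(n)
    arr = np.asarray(group, dtype=float)
    if arr.size < 2:
        raise ValidationError("each group needs at least two samples")
    return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)


def two_sample_test(group_a, group_b, variant: str = "welch") -> TwoSampleSummary:
    """Two-tailed t test between two groups.

    Groups may be raw sample arrays or ``(mean, sd, n)`` summary tuples.
    ``variant`` selects Welch's unequal-variance test (default) or the
    pooled-variance Student test.
    """
    if variant not in ("welch", "pooled"):
        raise ValidationError("variant must be 'welch' or 'pooled'")
    mean_a, sd_a, n_a = _summarize(group_a)
    mean_b, sd_b, n_b = _summarize(group_b)
    if n_a < 2 or n_b < 2:
        raise ValidationError("each group needs n >= 2")
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = n_a + n_b - 2
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        if va + vb == 0:
            df = n_a + n_b - 2
        else:
            df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return TwoSampleSummary(
        mean_a=mean_a,
        sd_a=sd_a,
        n_a=n_a,
        mean_b=mean_b,
        sd_b=sd_b,
        n_b=n_b,
        t=float(res.statistic),
        df=float(df),
        p=float(res.pvalue) if res.pvalue > 0 else np.nextafter(0, 1),
        variant=variant,
    )


# ---------------------------------------------------------------------------
# Manders colocalization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColocResult:
    """Thresholded Manders coefficients.

    ``m1`` is the fraction of channel-A intensity found in voxels where
    channel B exceeds its threshold; ``m2`` is the symmetric quantity.
    """

    m1: float
    m2: float
    threshold_a: float
    threshold_b: float
    threshold_method: str


def manders_coefficients(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    threshold_a: float | None = None,
    threshold_b: float | None = None,
    mask: np.ndarray | None = None,
) -> ColocResult:
    """Thresholded Manders M1/M2 between two channels.

    Thresholds default to Otsu's method per channel; pass fixed values
    to override.  Coefficients are invariant under uniform scaling of
    the measured channel.
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("channels must share geometry")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValidationError("mask shape must match channel shape")
        a, b = a[mask], b[mask]
    method = "fixed"
    if threshold_a is None:
        threshold_a = float(threshold_otsu(a)) if np.ptp(a) > 0 else 0.0
        method = "otsu"
    if threshold_b is None:
        threshold_b = float(threshold_otsu(b)) if np.ptp(b) > 0 else 0.0
        method = "otsu" if method == "otsu" else "mixed"
    sum_a, sum_b = a.sum(), b.sum()
    m1 = float(a[b > threshold_b].sum() / sum_a) if sum_a > 0 else math.nan
    m2 = float(b[a > threshold_a].sum() / sum_b) if sum_b > 0 else math.nan
    return ColocResult(
        m1=m1,
        m2=m2,
        threshold_a=float(threshold_a),
        threshold_b=float(threshold_b),
        threshold_method=method,
    )


# ---------------------------------------------------------------------------
# False-color heat map
# ---------------------------------------------------------------------------


def _build_lut(name: str = "viridis") -> np.ndarray:
    """256-entry float RGB lookup table with all entries distinct."""
    from matplotlib import colormaps

    lut = np.asarray(colormaps[name](np.arange(256) / 255.0))[:, :3]
    # Bijectivity guard: a colormap with duplicate entries cannot be
    # inverted; nudge the blue channel by a sub-visible epsilon.
    _, idx = np.unique(lut, axis=0, return_index=True)
    if len(idx) != 256:
        lut = lut + np.arange(256)[:, None] * 1e-9
    return lut


def heatmap_render(image: np.ndarray, lut: np.ndarray | None = None) -> np.ndarray:
    """Map an 8-bit image through a fixed 256-entry false-color LUT.

    Returns a float RGB array; :func:`heatmap_invert` recovers the gray
    values exactly (the LUT is bijective).
    """
    arr = np.asarray(image)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValidationError("heatmap_render expects an 8-bit integer image")
    if arr.min() < 0 or arr.max() > 255:
        raise ValidationError("heatmap_render expects values in [0, 255]")
    table = _build_lut() if lut is None else lut
    return table[arr]


def heatmap_invert(rgb: np.ndarray, lut: np.ndarray | None = None) -> np.ndarray:
    """Recover the 8-bit gray image from a rendered heat map."""
    table = _build_lut() if lut is None else lut
    flat = np.asarray(rgb, dtype=float).reshape(-1, 3)
    lookup = {tuple(row): i for i, row in enumerate(table)}
    try:
        values = np.array([lookup[tuple(px)] for px in flat], dtype=np.uint8)
    except KeyError as exc:
        raise ValidationError("RGB value not produced by the LUT") from exc
    return values.reshape(np.asarray(rgb).shape[:-1])
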