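"""Image-quality covariates and the statistical tests of the analysis.

Two covariates explain much of the variation in detector performance on
time-lapse field imagery: the relative bounding-box area (how much of the
frame the arthropod occupies) and the sharpness of the image content inside
the box.  Sharpness is proxied by the Tenengrad focus measure — the squared
magnitude of the 3x3 Sobel gradient, averaged over the patch — and
normalised to [0, 1] by the dataset maximum (blur -> sharp).

Both covariates are strongly right-skewed (most visitors are small and
slightly out of focus), so group contrasts use a nonparametric permutation
test on the absolute difference of means and of medians rather than a
t-test.  Classification asymmetries (e.g. bees mislabelled as flies more
often than chance among all their mislabels) use a one-tailed exact binomial
test, and the area-sharpness association uses Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .annotations import Box

__all__ = [
    "FeatureRecord",
    "PermutationResult",
    "relative_area",
    "tenengrad_sharpness",
    "normalize_sharpness",
    "permutation_test",
    "binomial_test_one_tailed",
    "spearman_rho",
]

#: Rec. 601 luma weights for colour -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class FeatureRecord:
    """Per-box covariates joined with detection/classification outcomes."""

    box_id: str
    rel_area: float
    sharpness_raw: float
    sharpness_norm: float = float("nan")
    localised: bool = False
    correctly_classified: bool | None = None
    confidence: float | None = None


def relative_area(
    box: Box,
    image_w: float,
    image_h: float,
    clip: bool = True,
) -> float:
    """Box area as a proportion of the image area.

    A box extending past the image bounds triggers a warning and, with
    ``clip=True`` (default), is clipped to the image before the ratio.
    """
    if image_w <= 0 or image_h <= 0:
        raise ValueError("image dimensions must be positive")
    w, h = box.width, box.height
    if box.x_max > image_w or box.y_max > image_h:
        import warnings

        warnings.warn(
            f"box ({box.x_min}, {box.y_min}, {box.width}, {box.height}) exceeds "
            f"image bounds {image_w}x{image_h}",
            stacklevel=2,
        )
        if clip:
            w = min(box.x_max, image_w) - box.x_min
            h = min(box.y_max, image_h) - box.y_min
    return (w * h) / (image_w * image_h)


def tenengrad_sharpness(image_patch: np.ndarray) -> float:
    """Tenengrad focus measure of a patch: mean of Gx^2 + Gy^2 over the
    interior pixels, where Gx/Gy are 3x3 Sobel responses.

    Higher = more edge energy = sharper.  A constant patch scores 0.  The
    mean (rather than the sum) makes values comparable across patch sizes
    before the dataset-max normalisation.  Colour input (H, W, 3) is
    converted to grayscale with Rec. 601 luma weights first.  Border pixels,
    where the kernel would read outside the patch, are excluded.
    """
    patch = np.asarray(image_patch, dtype=float)
    if patch.ndim == 3:
        patch = patch @ _LUMA
    if patch.ndim != 2 or patch.shape[0] < 3 or patch.shape[1] < 3:
        raise ValueError(f"patch must be at least 3x3, got shape {patch.shape}")
    gx = ndimage.sobel(patch, axis=1, mode="nearest")
    gy = ndimage.sobel(patch, axis=0, mode="nearest")
    g2 = gx**2 + gy**2
    return float(g2[1:-1, 1:-1].mean())


def normalize_sharpness(values: Sequence[float]) -> np.ndarray:
    """Divide by the maximum observed value, mapping the sharpest patch of
    the analysed dataset to 1.0.  Scale-invariant: multiplying all inputs by
    a constant leaves the output unchanged."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no sharpness values")
    if np.any(arr < 0):
        raise ValueError("sharpness values must be non-negative")
    m = arr.max()
    if m == 0:
        raise ValueError("all sharpness values are zero; cannot normalise")
    return arr / m


@dataclass
class PermutationResult:
    """Observed |difference| of means/medians and their permutation p-values."""

    delta_mean: float
    delta_median: float
    p_mean: float
    p_median: float
    n_perm: int
    seed: int


def permutation_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Two-sided permutation test on |mean_a - mean_b| and
    |median_a - median_b|, sharing one set of resamples.

    Group labels are shuffled ``n_perm`` times preserving group sizes; the
    p-value is ``(1 + #{|delta*| >= |delta_obs|}) / (1 + n_perm)`` — the
    add-one correction counts the observed labelling among the resamples, so
    p is never exactly 0.  Deterministic for a fixed seed.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    obs_mean = abs(a.mean() - b.mean())
    obs_median = abs(np.median(a) - np.median(b))

    pool = np.concatenate([a, b])
    n_a, n_tot = a.size, pool.size
    rng = np.random.default_rng(seed)

    ge_mean = 0
    ge_median = 0
    # chunked so the permutation matrix stays small at dataset scale
    chunk = max(1, min(n_perm, int(5e6 // max(n_tot, 1)) or 1))
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((k, n_tot)), axis=1)
        perm = pool[idx]
        pa, pb = perm[:, :n_a], perm[:, n_a:]
        d_mean = np.abs(pa.mean(axis=1) - pb.mean(axis=1))
        d_median = np.abs(np.median(pa, axis=1) - np.median(pb, axis=1))
        ge_mean += int((d_mean >= obs_mean).sum())
        ge_median += int((d_median >= obs_median).sum())
        done += k

    return PermutationResult(
        delta_mean=float(obs_mean),
        delta_median=float(obs_median),
        p_mean=(1 + ge_mean) / (1 + n_perm),
        p_median=(1 + ge_median) / (1 + n_perm),
        n_perm=n_perm,
        seed=seed,
    )


def binomial_test_one_tailed(k: int, n: int, p0: float) -> float:
    """Exact upper-tail binomial p-value: P(X >= k) for X ~ Binomial(n, p0).

    Used to test whether a particular misclassification direction (e.g.
    Hymenoptera -> Diptera among all Hymenoptera mislabels) exceeds its
    chance share ``p0`` (1/7 over the fine labels, 1/2 over two groups).
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise TypeError("k and n must be integers")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    return float(stats.binom.sf(k - 1, n, p0))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Spearman rank correlation (Pearson correlation of mid-ranks; ties get
    average ranks).  Returns None for constant input, where the correlation
    is undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None
    return float(stats.spearmanr(x, y).statistic)
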