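"""Image-quality and segmentation-overlap metrics, and the evaluation
protocol (whole-image vs tumor-region restriction, paired t-tests, grayscale
histogram comparison).

PSNR and SSIM are computed from global statistics over the evaluated region,
exactly as the defining formulas are written: PSNR uses the squared maximum
pixel value of the two images over the mean squared error of the evaluated
pixels; SSIM uses the region means, variances and covariance with the
standard stabilizing constants c1=(0.01 L)^2, c2=(0.03 L)^2 at dynamic range
L=1 (a sliding-window Gaussian mode is available behind a flag for
cross-tool comparison).  The tumor-region restriction evaluates the
statistics over mask-foreground pixels only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats_mod
from scipy.spatial import cKDTree

K1, K2 = 0.01, 0.03
MS_SSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


def _as2d(x, name="array"):
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"{name} must be 2D")
    return x


def _check_same_shape(x, y):
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")


# ---------------------------------------------------------------------------
# reconstruction fidelity


def psnr(x, recon, region_mask=None) -> float:
    """Peak signal-to-noise ratio in dB:
    10 log10( MAX^2 / mean squared error ), MAX the maximum pixel value over
    both images, the MSE over the evaluated region.  Identical inputs give
    +inf (excluded from aggregates with a warning by :func:`evaluate`)."""
    x = _as2d(x, "x")
    r = _as2d(recon, "recon")
    _check_same_shape(x, r)
    if region_mask is not None:
        m = np.asarray(region_mask).astype(bool)
        _check_same_shape(x, m)
        if not m.any():
            raise ValueError("region_mask is empty")
        dx, dr = x[m], r[m]
    else:
        dx, dr = x.ravel(), r.ravel()
    mse = np.mean((dx - dr) ** 2)
    peak = max(x.max(), r.max())
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(peak ** 2 / mse))


def _weighted_stats(x, y, w):
    wsum = w.sum()
    mx = (w * x).sum() / wsum
    my = (w * y).sum() / wsum
    vx = (w * (x - mx) ** 2).sum() / wsum
    vy = (w * (y - my) ** 2).sum() / wsum
    cov = (w * (x - mx) * (y - my)).sum() / wsum
    return mx, my, vx, vy, cov


def _ssim_components(x, y, w, c1, c2):
    mx, my, vx, vy, cov = _weighted_stats(x, y, w)
    lum = (2 * mx * my + c1) / (mx ** 2 + my ** 2 + c1)
    cs = (2 * cov + c2) / (vx + vy + c2)
    return lum, cs


def ssim(x, recon, c1=None, c2=None, data_range=1.0, region_mask=None,
         windowed=False) -> float:
    """Structural similarity from global region statistics (default), or the
    standard sliding-window variant (``windowed=True``, whole image only)."""
    x = _as2d(x, "x")
    r = _as2d(recon, "recon")
    _check_same_shape(x, r)
    if c1 is None:
        c1 = (K1 * data_range) ** 2
    if c2 is None:
        c2 = (K2 * data_range) ** 2
    if windowed:
        if region_mask is not None:
            raise ValueError("windowed SSIM does not support a region mask")
        from skimage.metrics import structural_similarity

        return float(structural_similarity(x, r, data_range=data_range,
                                           gaussian_weights=True, K1=K1, K2=K2))
    if region_mask is not None:
        w = np.asarray(region_mask, dtype=np.float64)
        _check_same_shape(x, w)
        if w.sum() == 0:
            raise ValueError("region_mask is empty")
    else:
        w = np.ones_like(x)
    lum, cs = _ssim_components(x, r, w, c1, c2)
    return float(lum * cs)


def _downsample2(img):
    h, w = img.shape
    h2, w2 = h - h % 2, w - w % 2
    c = img[:h2, :w2]
    return 0.25 * (c[0::2, 0::2] + c[1::2, 0::2] + c[0::2, 1::2] + c[1::2, 1::2])


def ms_ssim(x, recon, scales=None, weights=None, data_range=1.0,
            region_mask=None) -> float:
    """Multi-scale SSIM: contrast-structure terms at every dyadic scale and
    the luminance term at the coarsest, combined as a weighted product with
    the standard five-scale weights (renormalized when fewer scales are
    used).  Negative component values are clamped at 0 before exponentiation.
    With scales=1 this reduces exactly to :func:`ssim`.

    A region mask, when given, is average-pooled alongside the images and
    used as pixel weights for the per-scale statistics.
    """
    x = _as2d(x, "x")
    r = _as2d(recon, "recon")
    _check_same_shape(x, r)
    min_dim = min(x.shape)
    max_scales = max(1, int(np.floor(np.log2(min_dim / 8))) + 1)
    if scales is None:
        scales = min(5, max_scales)
    elif scales > max_scales:
        raise ValueError(
            f"image too small for {scales} scales; at most {max_scales} "
            f"dyadic downsamplings keep >= 8 pixels per side")
    if weights is None:
        weights = np.asarray(MS_SSIM_WEIGHTS[:scales], dtype=np.float64)
        weights = weights / weights.sum()
    else:
        weights = np.asarray(weights, dtype=np.float64)
        if len(weights) != scales:
            raise ValueError("need one weight per scale")
    c1 = (K1 * data_range) ** 2
    c2 = (K2 * data_range) ** 2
    if region_mask is not None:
        w = np.asarray(region_mask, dtype=np.float64)
        _check_same_shape(x, w)
        if w.sum() == 0:
            raise ValueError("region_mask is empty")
    else:
        w = np.ones_like(x)
    value = 1.0
    for j in range(scales):
        lum, cs = _ssim_components(x, r, w, c1, c2)
        if j == scales - 1:
            value *= max(lum * cs, 0.0) ** weights[j]
        else:
            value *= max(cs, 0.0) ** weights[j]
            x, r, w = _downsample2(x), _downsample2(r), _downsample2(w)
    return float(value)


# ---------------------------------------------------------------------------
# segmentation overlap


def _as_binary(m, name):
    m = np.asarray(m)
    if not np.isin(np.unique(m), (0, 1)).all():
        raise ValueError(f"{name} must be a binary mask")
    return m.astype(bool)


def dice(y, pred) -> float:
    """Dice overlap 2|y n pred| / (|y| + |pred|); two empty masks count as
    perfect agreement (1) with a warning."""
    y = _as_binary(y, "y")
    p = _as_binary(pred, "pred")
    _check_same_shape(y, p)
    denom = y.sum() + p.sum()
    if denom == 0:
        warnings.warn("dice of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    return float(2.0 * np.logical_and(y, p).sum() / denom)


def hausdorff(y, pred) -> float:
    """Symmetric Hausdorff distance in pixels: the larger of the two directed
    max-min Euclidean distances between foreground coordinate sets.  Raises
    on an empty mask (distance to the empty set is undefined)."""
    y = _as_binary(y, "y")
    p = _as_binary(pred, "pred")
    _check_same_shape(y, p)
    a = np.argwhere(y).astype(np.float64)
    b = np.argwhere(p).astype(np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("hausdorff: empty mask")
    d_ab = cKDTree(b).query(a)[0].max()
    d_ba = cKDTree(a).query(b)[0].max()
    return float(max(d_ab, d_ba))


# ---------------------------------------------------------------------------
# statistics / protocol


@dataclass
class PairedTestResult:
    t: float
    p: float
    alpha: float
    significant: bool


def paired_t_test(values_a, values_b, alpha: float = 0.05) -> PairedTestResult:
    """Two-sided paired-samples t-test; significant iff p < alpha."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("values_a and values_b must be equal-length vectors")
    if len(a) < 2:
        raise ValueError("need at least 2 paired values")
    d = a - b
    if np.allclose(d.std(ddof=1), 0):
        if np.allclose(d, 0):
            raise ValueError("paired differences are identically zero: "
                             "t statistic undefined")
        raise ValueError("paired differences have zero variance: "
                         "t statistic undefined")
    t, p = _stats_mod.ttest_rel(a, b)
    return PairedTestResult(t=float(t), p=float(p), alpha=alpha,
                            significant=bool(p < alpha))


def histogram_compare(a, b, n_bins: int = 256):
    """Equal-width grayscale histograms over [0,1] (normalized to sum 1) and
    their total-variation distance (half the L1 distance, in [0,1])."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    for name, v in (("a", a), ("b", b)):
        if v.min() < 0 or v.max() > 1:
            raise ValueError(f"{name} has values outside [0,1]")
    ha = np.histogram(a.ravel(), bins=n_bins, range=(0.0, 1.0))[0]
    hb = np.histogram(b.ravel(), bins=n_bins, range=(0.0, 1.0))[0]
    pa = ha / ha.sum()
    pb = hb / hb.sum()
    return pa, pb, float(0.5 * np.abs(pa - pb).sum())


@dataclass
class MetricReport:
    """Per-sample metric values plus mean +/- SD aggregates, in the shape of
    the published evaluation tables."""

    per_sample: pd.DataFrame
    region: str
    method: str = ""
    aggregates: dict = field(default_factory=dict)
    psnr_inf_count: int = 0

    def summary(self) -> pd.DataFrame:
        rows = [{"metric": k, "mean": v[0], "sd": v[1]}
                for k, v in self.aggregates.items()]
        return pd.DataFrame(rows)


def evaluate(pairs, region: str = "whole", method: str = "",
             ms_scales=None) -> MetricReport:
    """Evaluate (original, synthetic) sample pairs.

    region="whole": PSNR/SSIM/MS-SSIM over the full images.
    region="tumor": PSNR/SSIM/MS-SSIM restricted to the original mask's
    foreground, plus Dice and Hausdorff between the two masks.
    """
    if region not in ("whole", "tumor"):
        raise ValueError("region must be 'whole' or 'tumor'")
    if not pairs:
        raise ValueError("no sample pairs to evaluate")
    rows = []
    for orig, synth in pairs:
        mask = orig.mask if region == "tumor" else None
        row = {
            "sample_id": orig.sample_id,
            "psnr": psnr(orig.image, synth.image, region_mask=mask),
            "ssim": ssim(orig.image, synth.image, region_mask=mask),
            "ms_ssim": ms_ssim(orig.image, synth.image, scales=ms_scales,
                               region_mask=mask),
        }
        if region == "tumor":
            row["dice"] = dice(orig.mask, synth.mask)
            row["hausdorff"] = (hausdorff(orig.mask, synth.mask)
                                if orig.mask.any() and synth.mask.any()
                                else np.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    aggregates = {}
    inf_count = int(np.isinf(df["psnr"]).sum())
    if inf_count:
        warnings.warn(f"{inf_count} PSNR value(s) are infinite (zero MSE); "
                      "excluded from aggregates", stacklevel=2)
    for col in df.columns:
        if col == "sample_id":
            continue
        vals = df[col].to_numpy(dtype=np.float64)
        vals = vals[np.isfinite(vals)]
        if len(vals):
            aggregates[col] = (float(vals.mean()),
                               float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
    return MetricReport(per_sample=df, region=region, method=method,
                        aggregates=aggregates, psnr_inf_count=inf_count)
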