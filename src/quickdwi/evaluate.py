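"""Full-reference image-quality metrics and paired statistical comparison.

MSE, SSIM (Gaussian-window formulation, 11x11 window, sigma 1.5,
K1 = 0.01, K2 = 0.03) and PSNR are computed per image pair; families of
paired quality scores are compared with a two-sided Wilcoxon signed-rank
test and Benjamini-Hochberg correction across the family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity

__all__ = [
    "QualityMetrics",
    "ComparisonReport",
    "image_metrics",
    "ssim",
    "wilcoxon_bh",
    "benjamini_hochberg",
]

SSIM_PARAMS = dict(
    gaussian_weights=True,
    sigma=1.5,
    win_size=11,
    use_sample_covariance=False,
    K1=0.01,
    K2=0.03,
)


@dataclass(frozen=True)
class QualityMetrics:
    """MSE, SSIM and PSNR of one test image against a reference."""

    mse: float
    ssim: float
    psnr: float  # dB; +inf when mse == 0


@dataclass
class ComparisonReport:
    """Outcome of one paired comparison inside a BH-corrected family."""

    metric_name: str
    values_a: np.ndarray
    values_b: np.ndarray
    raw_p: float
    adjusted_p: float = float("nan")
    significant: bool = False
    undefined: bool = False  # all pairs tied: the signed-rank test is undefined


def ssim(test: np.ndarray, ref: np.ndarray, data_range: float = 1.0) -> float:
    """Structural similarity index with the Gaussian-window defaults.

    For images smaller than the 11x11 window the window shrinks to the
    largest odd size that fits, so toy images remain comparable.
    """
    test = np.asarray(test, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if test.shape != ref.shape:
        raise ValueError(f"shape mismatch: {test.shape} vs {ref.shape}")
    params = dict(SSIM_PARAMS)
    smallest = min(test.shape)
    if smallest < params["win_size"]:
        params["win_size"] = smallest if smallest % 2 == 1 else smallest - 1
    return float(structural_similarity(test, ref, data_range=data_range, **params))


def image_metrics(test: np.ndarray, ref: np.ndarray, data_range: float = 1.0) -> QualityMetrics:
    """Compute MSE, SSIM and PSNR between a test and a reference image.

    ``data_range`` defaults to 1.0 for normalized images.  PSNR is
    ``10 log10(data_range^2 / mse)`` and reported as +inf for identical
    images.
    """
    test = np.asarray(test, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if test.shape != ref.shape:
        raise ValueError(f"shape mismatch: {test.shape} vs {ref.shape}")
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    mse = float(np.mean((test - ref) ** 2))
    psnr = math.inf if mse == 0 else 10.0 * math.log10(data_range**2 / mse)
    return QualityMetrics(mse=mse, ssim=ssim(test, ref, data_range), psnr=psnr)


def benjamini_hochberg(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adjusted_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


def _wilcoxon_two_sided(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided signed-rank p, zero differences dropped.

    Exact null distribution for n <= 25, otherwise the normal
    approximation with continuity correction.
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    d = d[d != 0]
    n = d.size
    exact = n <= 25
    res = stats.wilcoxon(
        d,
        zero_method="wilcox",
        correction=not exact,
        alternative="two-sided",
        method="exact" if exact else "approx",
    )
    return float(res.pvalue)


def wilcoxon_bh(
    paired_scores: dict[str, tuple[np.ndarray, np.ndarray]],
    alpha: float = 0.05,
) -> list[ComparisonReport]:
    """Paired Wilcoxon tests with BH correction across the whole family.

    Parameters
    ----------
    paired_scores : mapping of comparison name -> (scores_a, scores_b)
        Each pair of equal-length score vectors forms one comparison; the
        BH family is the full set passed in one call.
    alpha : float
        Significance level applied to the adjusted p-values.

    Comparisons whose pairs are all tied have an undefined test statistic;
    they are flagged ``undefined`` and excluded from the BH family rather
    than raising.
    """
    reports: list[ComparisonReport] = []
    for name, (a, b) in paired_scores.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError(f"comparison {name!r}: score vectors must be equal-length 1D")
        if np.all(a == b):
            reports.append(
                ComparisonReport(name, a, b, raw_p=float("nan"), undefined=True)
            )
            continue
        reports.append(ComparisonReport(name, a, b, raw_p=_wilcoxon_two_sided(a, b)))

    defined = [r for r in reports if not r.undefined]
    if defined:
        adjusted = benjamini_hochberg([r.raw_p for r in defined])
        for r, ap in zip(defined, adjusted):
            r.adjusted_p = float(ap)
            r.significant = bool(ap < alpha)
    return reports
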