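"""ADC fitting and region-of-interest statistics.

The apparent diffusion coefficient is obtained per voxel by ordinary
least squares on the log-signal across b-values (monoexponential model).
Negative fitted ADCs — which arise at low SNR when noise makes the signal
increase with b — are deliberately preserved: they carry information about
the noise distribution within a region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ADCMap", "ROIStats", "fit_adc", "roi_stats", "rdm", "mavd"]

#: Display convention: ADC is reported in units of 1e-3 mm^2/s.
ADC_DISPLAY_SCALE = 1e3


@dataclass
class ADCMap:
    """Voxel-wise ADC map in mm^2/s.

    ``valid`` flags voxels where the log-linear fit was defined (all
    signals strictly positive); voxels failing that rule are set to 0.
    """

    data: np.ndarray
    b_values_used: tuple[float, ...]
    source: str = "ground_truth"  # one of {noa1, noa_n, dnif, ground_truth}
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.source not in ("noa1", "noa_n", "dnif", "ground_truth"):
            raise ValueError(f"unknown ADC source tag {self.source!r}")
        if self.valid is None:
            self.valid = np.ones(self.data.shape, dtype=bool)


@dataclass(frozen=True)
class ROIStats:
    """Summary statistics of an ADC map over a region of interest."""

    mean_adc: float
    std_adc: float
    cov: float
    n_voxels: int


def fit_adc(
    images: np.ndarray,
    b_values: tuple[float, ...] | list[float],
    source: str = "noa_n",
    weighted: bool = False,
) -> ADCMap:
    """Monoexponential least-squares ADC fit across b-values.

    Parameters
    ----------
    images : ndarray, shape (n_b, rows, cols)
        One image per b-value, raw signal units.
    b_values : sequence of float
        Matching diffusion weightings in s/mm^2; at least 2 distinct.
    source : str
        Provenance tag recorded on the map.
    weighted : bool
        If True, weight the log-linear fit by the squared signal
        (first-order propagation of uniform image noise into log space).
        Off by default: the plain log-linear OLS fit.

    Notes
    -----
    Per voxel, (ln S0, -ADC) is the least-squares line of ln S against b.
    Voxels with any nonpositive signal get ADC 0 and ``valid=False``.
    """
    b = np.asarray(b_values, dtype=float)
    images = np.asarray(images, dtype=float)
    if b.ndim != 1 or b.size < 2 or np.unique(b).size < 2:
        raise ValueError("need at least 2 distinct b-values")
    if images.ndim != 3 or images.shape[0] != b.size:
        raise ValueError(
            f"images shape {images.shape} does not match {b.size} b-values"
        )

    valid = (images > 0).all(axis=0)
    logs = np.zeros_like(images)
    np.log(images, out=logs, where=images > 0)

    bb = b[:, None, None]
    if weighted:
        w = np.where(images > 0, images**2, 0.0)
        sw = w.sum(axis=0)
        bm = (w * bb).sum(axis=0) / sw
        lm = (w * logs).sum(axis=0) / sw
        cov_bl = (w * (bb - bm) * (logs - lm)).sum(axis=0)
        var_b = (w * (bb - bm) ** 2).sum(axis=0)
    else:
        bm = b.mean()
        lm = logs.mean(axis=0)
        cov_bl = ((bb - bm) * (logs - lm)).sum(axis=0)
        var_b = ((b - bm) ** 2).sum()
    slope = cov_bl / var_b
    adc = np.where(valid, -slope, 0.0)
    return ADCMap(data=adc, b_values_used=tuple(b.tolist()), source=source, valid=valid)


def roi_stats(adc: ADCMap, mask: np.ndarray) -> ROIStats:
    """Mean, population std and coefficient of variation over a mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != adc.data.shape:
        raise ValueError("mask shape does not match ADC map")
    if not mask.any():
        raise ValueError("empty ROI mask")
    vals = adc.data[mask]
    mean = float(vals.mean())
    std = float(vals.std(ddof=0))
    cov = std / mean if mean != 0 else float("nan")
    return ROIStats(mean_adc=mean, std_adc=std, cov=cov, n_voxels=int(vals.size))


def rdm(adc_test: ADCMap, adc_ref: ADCMap, mask: np.ndarray) -> float:
    """Relative difference of means, in percent.

    ``|mean_test - mean_ref| / mean_ref * 100`` with both means taken over
    the same ROI.
    """
    if adc_test.data.shape != adc_ref.data.shape:
        raise ValueError("ADC maps have different shapes")
    mean_test = roi_stats(adc_test, mask).mean_adc
    mean_ref = roi_stats(adc_ref, mask).mean_adc
    if mean_ref == 0:
        raise ZeroDivisionError("reference ROI mean is zero; RDM undefined")
    return abs(mean_test - mean_ref) / mean_ref * 100.0


def mavd(adc_a: ADCMap, adc_b: ADCMap, mask: np.ndarray) -> float:
    """Mean absolute voxel-wise difference over a mask, in mm^2/s.

    Multiply by 1e6 for the conventional 1e-6 mm^2/s reporting scale.
    """
    if adc_a.data.shape != adc_b.data.shape:
        raise ValueError("ADC maps have different shapes")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    return float(np.abs(adc_a.data - adc_b.data)[mask].mean())
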