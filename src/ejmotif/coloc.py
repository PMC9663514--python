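"""Two-channel colocalization coefficients and PLA signal per nucleus.

Implements the four-measure colocalization scheme used for all imaging
claims: Pearson correlation of pixel intensities, the Manders overlap
coefficient, the split coefficients m1/m2 (fraction of each channel's
intensity falling where the other channel is above threshold) and k1/k2
(which satisfy k1*k2 = overlap^2 by construction).  Proximity ligation
assay (PLA) quantification divides total above-threshold signal by the
number of detected nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage import filters, measure


@dataclass(frozen=True)
class ColocMetrics:
    pearson: float
    overlap: float
    m1: float
    m2: float
    k1: float
    k2: float


class ConstantChannelError(ValueError):
    """Pearson correlation is undefined for a constant channel."""


def coloc_metrics(ch1, ch2, mask=None, thresholds=(None, None)) -> ColocMetrics:
    """Colocalization coefficients for two aligned single-channel images.

    Parameters
    ----------
    ch1, ch2 : 2-D nonnegative intensity arrays of identical shape
        (integer images are promoted to float).
    mask : optional boolean array restricting the analyzed pixels.
    thresholds : per-channel thresholds (t1, t2) for the Manders split
        coefficients m1/m2; ``None`` uses Otsu's threshold on the masked
        pixels.  Pearson, overlap and k1/k2 are computed without
        thresholding.
    """
    a = np.asarray(ch1, dtype=float)
    b = np.asarray(ch2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("intensities must be nonnegative")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError("mask shape differs from the channels")
    x, y = a[mask], b[mask]
    if x.size < 2:
        raise ValueError("need at least 2 unmasked pixels")
    if x.std() == 0 or y.std() == 0:
        raise ConstantChannelError("constant channel within the mask")
    pearson = float(np.corrcoef(x, y)[0, 1])

    sxy = float(np.sum(x * y))
    sxx = float(np.sum(x * x))
    syy = float(np.sum(y * y))
    overlap = sxy / np.sqrt(sxx * syy) if sxx > 0 and syy > 0 else 0.0
    k1 = sxy / sxx if sxx > 0 else 0.0
    k2 = sxy / syy if syy > 0 else 0.0

    t1, t2 = thresholds
    if t1 is None:
        t1 = filters.threshold_otsu(x) if x.max() > x.min() else 0.0
    if t2 is None:
        t2 = filters.threshold_otsu(y) if y.max() > y.min() else 0.0
    sx, sy = x.sum(), y.sum()
    m1 = float(x[y > t2].sum() / sx) if sx > 0 else 0.0
    m2 = float(y[x > t1].sum() / sy) if sy > 0 else 0.0
    return ColocMetrics(pearson=pearson, overlap=overlap, m1=m1, m2=m2,
                        k1=k1, k2=k2)


def count_nuclei(nuclei_image, threshold: Optional[float] = None,
                 min_area: int = 20) -> int:
    """Nucleus count by global threshold + connected components.

    ``threshold=None`` uses Otsu; components below ``min_area`` pixels are
    discarded.
    """
    img = np.asarray(nuclei_image, dtype=float)
    if threshold is None:
        threshold = filters.threshold_otsu(img) if img.max() > img.min() else 0.0
    labeled = measure.label(img > threshold)
    regions = [r for r in measure.regionprops(labeled) if r.area >= min_area]
    return len(regions)


def pla_per_nucleus(signal_image, nuclei_image, signal_threshold: float = 0.0,
                    nuclei_threshold: Optional[float] = None,
                    min_nucleus_area: int = 20) -> float:
    """Total above-threshold PLA intensity normalized to the nucleus count."""
    sig = np.asarray(signal_image, dtype=float)
    n = count_nuclei(nuclei_image, threshold=nuclei_threshold,
                     min_area=min_nucleus_area)
    if n == 0:
        raise ZeroDivisionError("no nuclei detected")
    total = float(sig[sig > signal_threshold].sum())
    return total / n
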