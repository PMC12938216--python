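"""Method-comparison statistics and the no-reference blur metric.

Bland-Altman limits of agreement use the exact 1.96 multiplier on the
sample standard deviation of the paired differences.  The intraclass
correlation coefficient is the two-way random-effects, absolute-agreement,
single-measures form ICC(2,1) — the natural choice for two fixed methods
measured on the same subjects — with the standard F-based 95 % confidence
interval, banded as excellent (> 0.9), good (0.6-0.9), or moderate (< 0.6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["AgreementResult", "bland_altman", "paired_t_test",
           "icc_agreement", "mean_absolute_error", "blur_metric",
           "agreement_report"]


@dataclass(frozen=True)
class AgreementResult:
    bias: float
    loa_low: float
    loa_high: float
    p_value: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    icc_band: str
    mae: float
    n: int


def _pairs(a, b):
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    return a, b


def bland_altman(a, b) -> tuple[float, float, float]:
    """Bias and limits of agreement: mean(d) +/- 1.96 * sd(d), d = a - b."""
    a, b = _pairs(a, b)
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def paired_t_test(a, b) -> float:
    """Two-sided paired-samples t-test p-value.

    A degenerate sample (zero-variance differences with zero mean, i.e.
    identical pairs) returns p = 1 by convention.
    """
    a, b = _pairs(a, b)
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return 1.0 if np.allclose(d.mean(), 0.0) else 0.0
    res = sps.ttest_rel(a, b)
    return float(res.pvalue)


def icc_band(icc: float) -> str:
    """Agreement band: > 0.9 excellent, 0.6-0.9 good, < 0.6 moderate."""
    if icc > 0.9:
        return "excellent"
    if icc >= 0.6:
        return "good"
    return "moderate"


def icc_agreement(a, b, alpha: float = 0.05
                  ) -> tuple[float, tuple[float, float], str]:
    """ICC(2,1) with F-based confidence interval and agreement band.

    Mean-squares decomposition of the two-way layout (n subjects x k=2
    raters); the confidence interval follows McGraw & Wong's formulation
    with Satterthwaite degrees of freedom.
    """
    a, b = _pairs(a, b)
    n = a.size
    if n < 3:
        raise ValueError("ICC needs at least three pairs")
    x = np.column_stack([a, b])
    k = 2
    grand = x.mean()
    subj = x.mean(axis=1)
    rater = x.mean(axis=0)
    if np.allclose(subj.var(), 0.0) and np.allclose(x.var(), 0.0):
        raise ValueError("degenerate (constant) data; ICC undefined")
    msr = k * np.sum((subj - grand) ** 2) / (n - 1)
    msc = n * np.sum((rater - grand) ** 2) / (k - 1)
    sse = np.sum((x - subj[:, None] - rater[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("degenerate variance; ICC undefined")
    icc = (msr - mse) / denom

    if np.allclose(mse, 0.0):
        ci = (icc, icc)  # perfect agreement: interval collapses
    else:
        fj = msc / mse
        aa = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        bb = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 \
            else np.inf
        if np.isinf(aa):
            ci = (icc, icc)
        else:
            v = (aa * msc + bb * mse) ** 2 / (
                (aa * msc) ** 2 / (k - 1)
                + (bb * mse) ** 2 / ((n - 1) * (k - 1)))
            f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f_l * mse) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f_u * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr)
            ci = (float(lo), float(hi))
    return float(icc), ci, icc_band(float(icc))


def mean_absolute_error(a, b) -> float:
    a, b = _pairs(a, b)
    return float(np.mean(np.abs(a - b)))


def blur_metric(image: np.ndarray) -> float:
    """No-reference perceptual blur in [0, 1] (0 sharp, 1 blurred).

    Re-blurs the image with a strong low-pass kernel and compares the
    attenuation of neighboring-pixel gradients horizontally and vertically,
    returning the larger normalized attenuation ratio.  A constant image has
    no edges and is defined as fully blurred (1).
    """
    from skimage.measure import blur_effect
    image = np.asarray(image, float)
    if image.ndim != 2 or min(image.shape) < 8:
        raise ValueError("blur metric needs a 2D image of size >= 8x8")
    if np.ptp(image) == 0:
        return 1.0
    return float(blur_effect(image))


def agreement_report(a, b) -> AgreementResult:
    """Full method-comparison summary for one parameter."""
    a, b = _pairs(a, b)
    bias, lo, hi = bland_altman(a, b)
    p = paired_t_test(a, b)
    icc, (ci_lo, ci_hi), band = icc_agreement(a, b)
    return AgreementResult(bias=bias, loa_low=lo, loa_high=hi, p_value=p,
                           icc=icc, icc_ci_low=ci_lo, icc_ci_high=ci_hi,
                           icc_band=band, mae=mean_absolute_error(a, b),
                           n=a.size)
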