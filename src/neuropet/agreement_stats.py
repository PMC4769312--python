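"""Agreement and variability statistics for paired regional measurements.

Bland–Altman bias with 95 % limits of agreement (mean difference
± 1.96·SD, sample SD with n−1 denominator), per-region coefficients of
variation across subjects, and the gray/white flow ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BlandAltmanResult", "bland_altman", "cv_by_region", "gray_white_ratio",
           "bland_altman_plot"]


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    pair_means: np.ndarray = None
    differences: np.ndarray = None


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland–Altman agreement of paired measurements; differences are a − b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=a.size,
        pair_means=(a + b) / 2.0,
        differences=d,
    )


def cv_by_region(values_by_region: dict) -> pd.DataFrame:
    """Coefficient of variation (%) of subject-level regional means.

    ``values_by_region`` maps region name → per-subject values (≥ 2 each).
    CV% = 100·SD/mean with the n−1 SD.
    """
    rows = []
    for region, vals in values_by_region.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise ValueError(f"region {region!r} needs at least 2 subjects")
        mean = v.mean()
        if mean == 0:
            raise ValueError(f"region {region!r} has zero mean")
        rows.append({"region": region, "n": v.size,
                     "cv_percent": 100.0 * v.std(ddof=1) / mean})
    return pd.DataFrame(rows)


def gray_white_ratio(wbgm_mean: float, swm_mean: float) -> float:
    """Whole-brain gray matter / subcortical white matter flow ratio."""
    if not swm_mean > 0:
        raise ValueError("white-matter mean must be positive")
    return float(wbgm_mean) / float(swm_mean)


def bland_altman_plot(result: BlandAltmanResult, path, title: str = ""):
    """Difference-vs-mean scatter with bias and limits-of-agreement lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.pair_means, result.differences, s=12, alpha=0.7)
    ax.axhline(result.bias, linestyle=":", color="k", label=f"bias {result.bias:.3f}")
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, linestyle="--", color="gray")
    ax.set_xlabel("pair mean")
    ax.set_ylabel("difference")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
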