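"""Agreement statistics between ground-truth and predicted score vectors.

Pearson correlation, R^2, OLS regression of pred on gt, Bland-Altman
bias and 1.96-SD limits of agreement, and a two-sided paired t-test.
Differences are oriented pred - gt throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PairedScores:
    gt: np.ndarray
    pred: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.gt = np.asarray(self.gt, dtype=float)
        self.pred = np.asarray(self.pred, dtype=float)
        if self.gt.ndim != 1 or self.pred.ndim != 1:
            raise ValueError("score vectors must be one-dimensional")
        if self.gt.shape != self.pred.shape:
            raise ValueError("gt and pred must have equal length")
        if len(self.gt) < 2:
            raise ValueError("need at least two paired scores")
        if not (np.all(np.isfinite(self.gt)) and np.all(np.isfinite(self.pred))):
            raise ValueError("scores must be finite")

    @property
    def n(self) -> int:
        return len(self.gt)

    @property
    def diffs(self) -> np.ndarray:
        return self.pred - self.gt


@dataclass
class AgreementReport:
    label: str
    n: int
    pearson_r: Optional[float]
    r_squared: Optional[float]
    slope: Optional[float]
    intercept: Optional[float]
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    t_stat: Optional[float]
    p_value: Optional[float]
    diff_orientation: str = "pred-gt"

    def as_dict(self):
        return {
            "label": self.label, "n": self.n,
            "pearson_r": self.pearson_r, "r_squared": self.r_squared,
            "slope": self.slope, "intercept": self.intercept,
            "bias": self.bias, "sd_diff": self.sd_diff,
            "loa_low": self.loa_low, "loa_high": self.loa_high,
            "t_stat": self.t_stat, "p_value": self.p_value,
            "diff_orientation": self.diff_orientation,
        }


def agreement(pairs: PairedScores) -> AgreementReport:
    """Full agreement report for one gt/pred score vector pair.

    Zero-variance inputs yield missing (None) correlation/regression
    fields; n < 3 yields a missing p-value.  SD of differences uses the
    n-1 denominator.
    """
    gt, pred, n = pairs.gt, pairs.pred, pairs.n
    diffs = pairs.diffs
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd

    if np.var(gt) > 0 and np.var(pred) > 0:
        r = float(stats.pearsonr(gt, pred).statistic)
        r2 = r * r
    else:
        r = r2 = None
    if np.var(gt) > 0:
        fit = stats.linregress(gt, pred)
        slope, intercept = float(fit.slope), float(fit.intercept)
    else:
        slope = intercept = None

    if sd == 0.0:
        t = 0.0 if bias == 0.0 else math.copysign(math.inf, bias)
    else:
        t = bias / (sd / math.sqrt(n))
    p = None
    if n >= 3 and math.isfinite(t):
        p = float(2.0 * stats.t.sf(abs(t), df=n - 1))

    return AgreementReport(
        label=pairs.label, n=n, pearson_r=r, r_squared=r2, slope=slope,
        intercept=intercept, bias=bias, sd_diff=sd, loa_low=loa_low,
        loa_high=loa_high, t_stat=float(t), p_value=p)


def batch_agreement(all_pairs: List[PairedScores]) -> pd.DataFrame:
    """One agreement report row per input pair, in stable input order."""
    rows = [agreement(p).as_dict() for p in all_pairs]
    return pd.DataFrame(rows)


def bland_altman_plot(pairs: PairedScores, path, title: Optional[str] = None):
    """Bland-Altman plot: per-case mean vs difference with bias and LoA lines."""
    rep = agreement(pairs)
    means = (pairs.gt + pairs.pred) / 2.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, pairs.diffs, s=18, alpha=0.8)
    for y, style in ((rep.bias, "--"), (rep.loa_low, ":"), (rep.loa_high, ":")):
        ax.axhline(y, linestyle=style, color="gray")
    ax.set_xlabel("mean of GT and prediction")
    ax.set_ylabel("difference (pred - GT)")
    ax.set_title(title or pairs.label or "Bland-Altman")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return rep


def regression_plot(pairs: PairedScores, path, n_boot: int = 1000,
                    seed: int = 0, title: Optional[str] = None):
    """Scatter with OLS fit, bootstrap 95% percentile band, and unity line."""
    rep = agreement(pairs)
    if rep.slope is None:
        raise ValueError("regression undefined for zero-variance ground truth")
    rng = np.random.default_rng(seed)
    xs = np.linspace(pairs.gt.min(), pairs.gt.max(), 50)
    boot = np.empty((n_boot, xs.size))
    idx = np.arange(pairs.n)
    for b in range(n_boot):
        take = rng.choice(idx, size=pairs.n, replace=True)
        g, p = pairs.gt[take], pairs.pred[take]
        if np.var(g) == 0:
            boot[b] = np.mean(p)
            continue
        fit = stats.linregress(g, p)
        boot[b] = fit.intercept + fit.slope * xs
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(pairs.gt, pairs.pred, s=18, alpha=0.8)
    ax.plot(xs, rep.intercept + rep.slope * xs, color="C1", label="OLS fit")
    ax.fill_between(xs, lo, hi, color="C1", alpha=0.25, label="95% CI (bootstrap)")
    lims = [min(pairs.gt.min(), pairs.pred.min()),
            max(pairs.gt.max(), pairs.pred.max())]
    ax.plot(lims, lims, linestyle=":", color="gray", label="unity")
    ax.set_xlabel("ground truth")
    ax.set_ylabel("prediction")
    ax.set_title(title or pairs.label or "Regression")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return rep
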