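"""Tissue-distinguishability statistics.

Contrast enhancement is judged by whether attenuation samples drawn from
different tissues (connective, bone, cartilage) separate statistically:
Cohen's d for effect size, and two nonparametric two-sample tests
(Mann-Whitney and Kolmogorov-Smirnov) at the 5% level, reported per tissue
pair in a three-row table (L-B, B-C, C-L). A one-sample normality check
(Kolmogorov-Smirnov against a normal reference) screens whether parametric
summaries are defensible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "cohens_d",
    "TwoSampleTestResult",
    "two_sample_tests",
    "normality_check",
    "TissueStatsResult",
    "tissue_distinguishability",
    "TISSUE_PAIR_ORDER",
]

#: Row order of the distinguishability table: connective-bone, bone-cartilage,
#: cartilage-connective.
TISSUE_PAIR_ORDER = (("connective", "bone"), ("bone", "cartilage"),
                     ("cartilage", "connective"))
_PAIR_LABELS = {"connective": "L", "bone": "B", "cartilage": "C"}


def cohens_d(x, y, signed: bool = False) -> float:
    """Cohen's d with the pooled standard deviation.

    ``d = |mean(x) - mean(y)| / s_p`` where ``s_p^2 = ((n_x-1)s_x^2 +
    (n_y-1)s_y^2) / (n_x + n_y - 2)``. Reported as a magnitude by default
    (``signed=True`` keeps the sign of ``mean(x) - mean(y)``). A zero pooled
    sd with unequal means yields ``inf`` with a warning; with equal means,
    0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    delta = x.mean() - y.mean()
    if sp2 == 0:
        if delta == 0:
            return 0.0
        warnings.warn("zero pooled sd with unequal means: Cohen's d is infinite",
                      stacklevel=2)
        d = math.inf if delta > 0 else -math.inf
    else:
        d = float(delta / math.sqrt(sp2))
    return d if signed else abs(d)


@dataclass(frozen=True)
class TwoSampleTestResult:
    ks_stat: float
    ks_p: float
    mw_u: float
    mw_p: float
    alpha: float
    ks_reject: bool
    mw_reject: bool


def two_sample_tests(x, y, alpha: float = 0.05, method: str = "auto") -> TwoSampleTestResult:
    """Two-sided Mann-Whitney and two-sample Kolmogorov-Smirnov tests.

    ``method`` is forwarded to both scipy tests: ``"auto"`` (default) uses
    exact null distributions for small samples and asymptotics (with midrank
    tie correction for Mann-Whitney) otherwise; ``"asymptotic"`` forces the
    large-sample approximations. Rejection flags use ``alpha``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    ks = sps.ks_2samp(x, y, method=method)
    mw = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TwoSampleTestResult(
        ks_stat=float(ks.statistic), ks_p=float(ks.pvalue),
        mw_u=float(mw.statistic), mw_p=float(mw.pvalue),
        alpha=alpha,
        ks_reject=bool(ks.pvalue < alpha), mw_reject=bool(mw.pvalue < alpha),
    )


def normality_check(
    x, alpha: float = 0.05, method: str = "estimated"
) -> tuple[float, float, bool, str]:
    """One-sample Kolmogorov-Smirnov check of normality.

    ``method="estimated"`` (default) accounts for mean and sd being
    estimated from the data (Lilliefors correction); ``method="standardized"``
    standardizes and tests against a fixed standard normal, which is
    anti-conservative about estimated parameters but is the naive reading of
    a one-sample KS normality test. The method used is always reported back.

    Returns ``(statistic, p, passed, method)`` where ``passed`` means the
    normality hypothesis is *not* rejected at ``alpha``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("need n >= 5 for a meaningful normality check")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality check undefined (sd = 0)")
    if method == "estimated":
        stat, p = lilliefors(x, dist="norm")
    elif method == "standardized":
        stat, p = sps.kstest((x - x.mean()) / sd, "norm")
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(stat), float(p), bool(p >= alpha), method


@dataclass
class TissueStatsResult:
    """Distinguishability battery over the three tissue pairs."""

    table: pd.DataFrame  # rows L-B, B-C, C-L; cols cohens_d, ks_p, mw_p
    per_tissue: pd.DataFrame  # rows per tissue; cols n, mean, sd
    alpha: float = 0.05


def tissue_distinguishability(
    samples: dict[str, np.ndarray], alpha: float = 0.05, method: str = "auto"
) -> TissueStatsResult:
    """Pairwise effect sizes and tests for the three tissue samples.

    ``samples`` maps tissue names (``connective``, ``bone``, ``cartilage``)
    to attenuation samples. Cohen's d is reported as a magnitude.
    """
    missing = {a for pair in TISSUE_PAIR_ORDER for a in pair} - samples.keys()
    if missing:
        raise ValueError(f"missing tissue samples: {sorted(missing)}")
    rows = []
    for t1, t2 in TISSUE_PAIR_ORDER:
        res = two_sample_tests(samples[t1], samples[t2], alpha=alpha, method=method)
        rows.append(
            {
                "pair": f"{_PAIR_LABELS[t1]}-{_PAIR_LABELS[t2]}",
                "cohens_d": cohens_d(samples[t1], samples[t2]),
                "ks_p": res.ks_p,
                "mw_p": res.mw_p,
            }
        )
    table = pd.DataFrame(rows).set_index("pair")
    per_tissue = pd.DataFrame(
        {
            name: {
                "n": len(v := np.asarray(vals, dtype=float)),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            }
            for name, vals in samples.items()
        }
    ).T[["n", "mean", "sd"]]
    return TissueStatsResult(table=table, per_tissue=per_tissue, alpha=alpha)
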