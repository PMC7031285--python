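"""Distribution-shape predictors of the micronuclei-per-cell histogram.

Ten dimensionless statistics summarise the shape of a sample's MN/cell count
distribution. Writing M for the mean, V for the (n-1 denominator) variance,
n for the scored-cell count and f_0, f_3 for the fractions of cells with 0 or
>= 3 micronuclei:

==================  =========================================================
LnSum               ln n (heavily damaged cells fail to reach the binucleated
                    stage, so n itself carries dose information)
LnMean              ln M
LnVar               ln V
LnVarMean           ln(V / M), the index-of-dispersion on a log scale
LnZeroFrac          ln(1 + f_0)
Ln3Frac             ln(1 + f_3)
LnFD                ln of the squared scaled Fisher dispersion statistic,
                    ln[ ( (1/sqrt(2n)) [ (n-1) V/M - n ] )^2 ]
SEK                 signed-log of the sample excess kurtosis
                    (1/n) sum z_i^4 - 3, z standardized with the n-denominator SD
LnSkew              signed-log of m_3 / SD^3 (population moments)
LL_exp_Pois_dif     per-cell difference in maximized log likelihoods of a
                    geometric ("exponential") vs. a Poisson fit, both
                    maximized at the sample mean
==================  =========================================================

Overdispersed counts (Poisson mixtures from partial-body exposure, compound-
Poisson counts from neutron tracks) push LnVarMean, LnFD, SEK, LnSkew and
LL_exp_Pois_dif up relative to Poisson counts of the same mean, which is what
makes exposure *type* recoverable when mean yields are matched.

Excess kurtosis and skewness can be negative, where a bare logarithm is
undefined; SEK and LnSkew therefore use the sign-preserving transform
slog(x) = sign(x) * ln(1 + |x|), which is monotone, symmetric and equals
ln(1 + x) for x >= 0. Degenerate inputs (zero mean or variance) fall back to
ln(EPSILON) with the sample flagged, so every feature is always finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator, TransformerMixin

from .data import COUNT_COLUMNS, MNHistogram, N_BINS

EPSILON = 1e-6

FEATURE_NAMES = [
    "LnSum",
    "LnMean",
    "LnVar",
    "LnVarMean",
    "LnZeroFrac",
    "Ln3Frac",
    "LnFD",
    "SEK",
    "LnSkew",
    "LL_exp_Pois_dif",
]

_K = np.arange(N_BINS, dtype=float)  # top bin scored as exactly 5


def slog(x: float) -> float:
    """Sign-preserving log transform: sign(x) * ln(1 + |x|)."""
    return math.copysign(math.log1p(abs(x)), x) if x != 0 else 0.0


def moments(hist: MNHistogram) -> tuple[float, float, float, float]:
    """Mean, (n-1)-denominator variance, third central moment, excess kurtosis.

    The third central moment and excess kurtosis use population (n-denominator)
    moments; z-scores for the kurtosis are standardized with the n-denominator
    standard deviation. Returns NaN for m3 and g2 when the variance is zero.
    """
    c = np.asarray(hist.counts, dtype=float)
    n = c.sum()
    if n < 2:
        raise ValueError(f"need at least 2 cells, got {int(n)}")
    mean = float((_K * c).sum() / n)
    dev = _K - mean
    ss = float((c * dev**2).sum())
    var = ss / (n - 1)
    var_pop = ss / n
    if var_pop == 0.0:
        return mean, var, float("nan"), float("nan")
    m3 = float((c * dev**3).sum() / n)
    sd_pop = math.sqrt(var_pop)
    g2 = float((c * (dev / sd_pop) ** 4).sum() / n - 3.0)
    return mean, var, m3, g2


def _ln_or_eps(x: float) -> tuple[float, bool]:
    if x > 0:
        return math.log(x), False
    return math.log(EPSILON), True


@dataclass(frozen=True)
class FeatureVector:
    """The ten shape predictors for one sample, plus a degenerate-input flag."""

    values: dict[str, float]
    degenerate: bool = False

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=FEATURE_NAMES)


def compute_features(hist: MNHistogram) -> FeatureVector:
    """All ten shape predictors for one histogram (requires n >= 2 cells)."""
    c = np.asarray(hist.counts, dtype=float)
    n = float(c.sum())
    if n < 2:
        raise ValueError(f"need at least 2 cells, got {int(n)}")
    mean, var, m3, g2 = moments(hist)
    flagged = False

    ln_mean, f = _ln_or_eps(mean)
    flagged |= f
    ln_var, f = _ln_or_eps(var)
    flagged |= f

    if mean > 0:
        ratio = var / mean
        fisher_inner = ((n - 1.0) * ratio - n) / math.sqrt(2.0 * n)
        ln_fd, f = _ln_or_eps(fisher_inner**2)
        flagged |= f
        ln_vm, f = _ln_or_eps(ratio)
        flagged |= f
    else:
        ln_fd, ln_vm = math.log(EPSILON), math.log(EPSILON)
        flagged = True

    f0 = float(c[0] / n)
    f3 = float(c[3:].sum() / n)

    if math.isnan(g2):  # constant data: kurtosis/skewness undefined
        sek, ln_skew = 0.0, 0.0
        flagged = True
    else:
        sek = slog(g2)
        sd_pop = math.sqrt((c * (_K - mean) ** 2).sum() / n)
        ln_skew = slog(m3 / sd_pop**3)

    values = {
        "LnSum": math.log(n),
        "LnMean": ln_mean,
        "LnVar": ln_var,
        "LnVarMean": ln_vm,
        "LnZeroFrac": math.log1p(f0),
        "Ln3Frac": math.log1p(f3),
        "LnFD": ln_fd,
        "SEK": sek,
        "LnSkew": ln_skew,
        "LL_exp_Pois_dif": ll_exp_pois_dif(hist),
    }
    return FeatureVector(values=values, degenerate=flagged)


def ll_exp_pois_dif(hist: MNHistogram) -> float:
    """Per-cell gap in maximized log likelihood: geometric fit minus Poisson fit.

    Both families are maximized by setting their mean parameter to the sample
    mean M. For a cell with count k the geometric ("exponential-like") law
    contributes -(k+1) ln(1+M) + k ln M and the Poisson law contributes
    k ln M - M - ln k!. Positive values flag heavy-tailed, overdispersed
    samples. The convention 0*ln 0 = 0 makes the value 0 for an all-zero
    histogram.
    """
    c = np.asarray(hist.counts, dtype=float)
    n = float(c.sum())
    if n < 1:
        raise ValueError("empty histogram")
    mean = float((_K * c).sum() / n)
    if mean == 0.0:
        return 0.0
    ll_exp = float((c * (-(_K + 1.0) * math.log1p(mean) + _K * math.log(mean))).sum())
    ll_pois = float((c * (_K * math.log(mean) - mean - gammaln(_K + 1.0))).sum())
    return (ll_exp - ll_pois) / n


def features_frame(histograms, index=None) -> pd.DataFrame:
    """Feature table (one row per histogram) with a ``degenerate_flag`` column."""
    rows, flags = [], []
    for h in histograms:
        fv = compute_features(h)
        rows.append(fv.values)
        flags.append(fv.degenerate)
    df = pd.DataFrame(rows, columns=FEATURE_NAMES, index=index)
    df["degenerate_flag"] = flags
    return df


class ShapeFeatures(TransformerMixin, BaseEstimator):
    """Stateless transformer: MN histograms -> the ten shape predictors.

    Accepts either a sequence of :class:`~mnshape.data.MNHistogram` or a
    DataFrame carrying the canonical count columns ``mn0..mn5plus``; returns a
    DataFrame with one column per predictor (the degenerate flag is dropped so
    the output plugs straight into sklearn pipelines).
    """

    def fit(self, X, y=None):
        self.n_features_in_ = N_BINS
        return self

    def transform(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            hists = [MNHistogram(tuple(int(v) for v in row)) for row in X[COUNT_COLUMNS].to_numpy()]
            index = X.index
        else:
            hists, index = list(X), None
        return features_frame(hists, index=index)[FEATURE_NAMES]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
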