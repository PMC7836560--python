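"""Two-group differential expression with empirical-Bayes variance moderation.

The model follows the standard hierarchical treatment of gene-wise residual
variances: each gene's pooled variance s_g^2 is a scaled chi-square draw
around a true variance sigma_g^2, and the sigma_g^2 follow a scaled inverse
chi-square prior with d0 degrees of freedom and location s0^2.  The prior is
fitted by moment matching on log s_g^2 (digamma/trigamma equations); the
posterior variance

    s_post^2 = (d0 s0^2 + d s_g^2) / (d0 + d)

shrinks noisy gene-wise variances toward the common value, and the moderated
t-statistic t = logFC / sqrt(s_post^2 (1/n1 + 1/n2)) is referred to a
t-distribution with d0 + d degrees of freedom.  d0 = +inf means complete
shrinkage (no excess variance spread across genes); d0 = 0 recovers the
ordinary pooled two-sample t-test.

Gene classes use the fold-change + significance rule: "up" needs
logFC > log2(fc_threshold) and p* < p_threshold, "down" the mirror image,
with p* either the BH-adjusted (default) or the raw p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import EstimationError, UsageError
from .io_formats import NORMAL, TUMOUR
from .normalization import ExprMatrix

logger = logging.getLogger(__name__)

CLASS_UP = "up"
CLASS_DOWN = "down"
CLASS_NS = "ns"


@dataclass
class EBayesPrior:
    """Scaled inverse chi-square prior on gene-wise variances."""

    df_prior: float  # d0, may be +inf; 0 disables moderation
    var_prior: float  # s0^2

    def __post_init__(self) -> None:
        if self.df_prior < 0 or not self.var_prior > 0:
            raise UsageError("prior needs df_prior >= 0 and var_prior > 0")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex target)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-8:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> EBayesPrior:
    """Moment-matching fit of (d0, s0^2) from gene-wise variances.

    Matches mean and variance of log s2 to the moments implied by the scaled-F
    distribution of s2/s0^2; returns d0 = +inf when the spread of log s2 does
    not exceed pure chi-square sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    s2 = s2[ok]
    if len(s2) < 2:
        raise EstimationError("prior estimation needs >= 2 genes with positive variance")
    if df < 1:
        raise EstimationError("prior estimation needs residual df >= 1")
    if np.ptp(s2) == 0:
        # zero spread: complete shrinkage onto the common value
        return EBayesPrior(df_prior=np.inf, var_prior=float(s2[0]))
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s02 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(e_mean))
    return EBayesPrior(df_prior=d0, var_prior=s02)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise UsageError("bh_adjust expects a non-empty 1-d vector")
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise UsageError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def classify_de(
    logfc: np.ndarray,
    p: np.ndarray,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
) -> np.ndarray:
    """Label genes up/down/ns at |FC| > fc_threshold and p < p_threshold."""
    if fc_threshold <= 0 or p_threshold <= 0:
        raise UsageError("thresholds must be positive")
    logfc = np.asarray(logfc, dtype=float)
    p = np.asarray(p, dtype=float)
    lfc_cut = np.log2(fc_threshold)
    labels = np.full(logfc.shape, CLASS_NS, dtype=object)
    sig = p < p_threshold
    labels[sig & (logfc > lfc_cut)] = CLASS_UP
    labels[sig & (logfc < -lfc_cut)] = CLASS_DOWN
    return labels


def moderated_t(
    logcpm: ExprMatrix,
    groups: pd.Series,
    prior: EBayesPrior | None = None,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Per-gene tumour-vs-normal moderated t-test on logCPM.

    Returns a DataFrame indexed by gene with columns ``logFC`` (tumour minus
    normal, log2), ``AveExpr``, ``s2``, ``df_residual``, ``s2_post``, ``t``,
    ``p_value``, ``adj_p_value`` and ``de_class``.
    """
    if not logcpm.log:
        raise UsageError("moderated_t expects log-scale expression")
    groups = pd.Series(groups).reindex(logcpm.sample_ids)
    if groups.isna().any():
        raise UsageError("every sample needs a group label")
    tum = (groups == TUMOUR).to_numpy()
    nor = (groups == NORMAL).to_numpy()
    n1, n2 = int(tum.sum()), int(nor.sum())
    if n1 < 2 or n2 < 2:
        raise UsageError("each group needs at least 2 samples")

    x = logcpm.values.to_numpy(dtype=float)
    m1 = x[:, tum].mean(axis=1)
    m2 = x[:, nor].mean(axis=1)
    logfc = m1 - m2
    rss = ((x[:, tum] - m1[:, None]) ** 2).sum(axis=1)
    rss += ((x[:, nor] - m2[:, None]) ** 2).sum(axis=1)
    df_resid = n1 + n2 - 2
    s2 = rss / df_resid

    if prior is None:
        prior = estimate_prior(s2, df_resid)
    d0, s02 = prior.df_prior, prior.var_prior
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        t = np.where(se > 0, logfc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    adj = bh_adjust(p)
    p_star = adj if use_adjusted else p
    labels = classify_de(logfc, p_star, fc_threshold, p_threshold)

    return pd.DataFrame(
        {
            "logFC": logfc,
            "AveExpr": x.mean(axis=1),
            "s2": s2,
            "df_residual": float(df_resid),
            "s2_post": s2_post,
            "t": t,
            "p_value": p,
            "adj_p_value": adj,
            "de_class": labels,
        },
        index=pd.Index(logcpm.gene_ids, name="gene_id"),
    )


def volcano_table(result: pd.DataFrame, cap: float = 320.0) -> pd.DataFrame:
    """Volcano-plot coordinates: logFC vs -log10 adjusted p, capped for p = 0."""
    adj = result["adj_p_value"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        y = -np.log10(adj)
    capped = ~np.isfinite(y) | (y > cap)
    y = np.where(capped, cap, y)
    return pd.DataFrame(
        {
            "logFC": result["logFC"].to_numpy(),
            "neg_log10_adj_p": y,
            "capped": capped,
            "de_class": result["de_class"].to_numpy(),
        },
        index=result.index,
    )
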