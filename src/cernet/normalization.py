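"""Between-sample normalization of RNA-seq counts.

Implements the trimmed-mean-of-M-values (TMM) scaling-factor method: each
sample is compared with a reference sample on per-gene log-ratios (M) and
average log-abundances (A); after symmetric trimming (30% on M, 5% on A by
default) the weighted mean of the surviving M-values — weights are inverse
asymptotic binomial variances — gives the log2 scaling factor.  Factors are
rescaled to geometric mean 1.  The reference is the sample whose
upper-quartile count fraction is closest to the mean upper-quartile fraction.

Also provides (log)CPM computation with a library-size-scaled prior count,
and the low-expression filter that drops genes whose logCPM falls below a
threshold in more than a set fraction of samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import NormalizationError, UsageError
from .io_formats import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class NormFactors:
    """Per-sample library size and TMM scaling factor (geometric mean 1)."""

    lib_size: pd.Series
    factor: pd.Series

    def __post_init__(self) -> None:
        self.lib_size = pd.Series(self.lib_size, dtype=float)
        self.factor = pd.Series(self.factor, dtype=float)
        if not self.lib_size.index.equals(self.factor.index):
            raise UsageError("library sizes and factors index different samples")
        if (self.factor <= 0).any() or (self.lib_size <= 0).any():
            raise NormalizationError("library sizes and factors must be positive")

    @property
    def effective_lib_size(self) -> pd.Series:
        return self.lib_size * self.factor


@dataclass
class ExprMatrix:
    """Real-valued expression matrix (CPM or logCPM), genes x samples."""

    values: pd.DataFrame
    log: bool
    prior_count: float = 0.0

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if self.log and not np.isfinite(arr).all():
            raise UsageError("log-scale expression matrix contains non-finite values")
        if not self.log and (arr < 0).any():
            raise UsageError("CPM matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    sum_trim: float,
    a_cutoff: float,
    weighted: bool,
    sample_name: str,
) -> float:
    """Scaling factor of one sample against the reference (log2 scale -> 2^f)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / lib_obs) / (ref / lib_ref))
        abs_e = (np.log2(obs / lib_obs) + np.log2(ref / lib_ref)) / 2.0
        # asymptotic binomial variance of the M-value
        var = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    ok = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > a_cutoff)
    if not ok.any():
        raise NormalizationError(
            f"sample {sample_name!r} shares no expressed genes with the reference"
        )
    log_r, abs_e, var = log_r[ok], abs_e[ok], var[ok]
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = len(log_r)
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if weighted:
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.sum(log_r[keep] / var[keep]) / np.sum(1.0 / var[keep])
    else:
        f = np.mean(log_r[keep]) if keep.any() else np.nan
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(
    counts: CountMatrix,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    a_cutoff: float = -1e10,
    weighted: bool = True,
) -> NormFactors:
    """TMM scaling factors for every sample of a count matrix.

    Genes that are zero in all samples are ignored; genes with a zero in
    either member of a comparison drop out of that comparison.  Raises
    :class:`NormalizationError` when a sample shares no expressed gene with
    the reference.
    """
    x = counts.counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise UsageError("TMM needs at least 2 samples")
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.sample_ids[int(np.argmin(lib))]
        raise NormalizationError(f"sample {bad!r} has zero library size")
    x = x[(x > 0).any(axis=1)]

    q75 = np.quantile(x, 0.75, axis=0) / lib
    if np.median(q75) < 1e-20:
        ref_idx = int(np.argmax(np.sqrt(x).sum(axis=0)))
    else:
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    logger.debug("TMM reference sample: %s", counts.sample_ids[ref_idx])

    factors = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        factors[j] = _tmm_pair_factor(
            x[:, j],
            x[:, ref_idx],
            lib[j],
            lib[ref_idx],
            logratio_trim,
            sum_trim,
            a_cutoff,
            weighted,
            counts.sample_ids[j],
        )
    factors /= np.exp(np.mean(np.log(factors)))
    samples = pd.Index(counts.sample_ids)
    return NormFactors(
        pd.Series(lib, index=samples, name="lib_size"),
        pd.Series(factors, index=samples, name="factor"),
    )


def cpm(
    counts: CountMatrix,
    factors: NormFactors,
    log: bool = False,
    prior_count: float = 0.5,
) -> ExprMatrix:
    """Counts per million on effective (TMM-scaled) library sizes.

    On the log scale a prior count, scaled proportionally to each sample's
    effective library size, keeps zeros finite:
    ``log2((count + pc_s) / (L_s + 2 pc_s) * 1e6)``.
    """
    samples = pd.Index(counts.sample_ids)
    if not samples.equals(factors.factor.index):
        raise UsageError("normalization factors do not match the count matrix samples")
    eff = factors.effective_lib_size.to_numpy()
    if (eff <= 0).any():
        raise NormalizationError("zero effective library size")
    x = counts.counts.to_numpy(dtype=float)
    if log:
        if prior_count < 0:
            raise UsageError("prior_count must be >= 0")
        pc = prior_count * eff / eff.mean()
        values = np.log2((x + pc[None, :]) / (eff + 2 * pc)[None, :] * 1e6)
    else:
        values = x / eff[None, :] * 1e6
    df = pd.DataFrame(values, index=counts.counts.index, columns=samples)
    return ExprMatrix(df, log=log, prior_count=prior_count if log else 0.0)


def filter_low_expression(
    logcpm: ExprMatrix, threshold: float = 1.0, max_low_fraction: float = 0.5
) -> list[str]:
    """Gene ids whose logCPM is below ``threshold`` in no more than
    ``max_low_fraction`` of samples (strict "more than half" rule: a gene low
    in exactly half the samples is kept).  Order preserved."""
    if not logcpm.log:
        raise UsageError("filter_low_expression requires a log-scale matrix")
    low = (logcpm.values.to_numpy() < threshold).sum(axis=1)
    keep = low <= max_low_fraction * logcpm.values.shape[1]
    return [g for g, k in zip(logcpm.gene_ids, keep) if k]
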