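"""Per-gene univariate survival screening.

For each gene, patients are split at the median expression level (ties go to
the low group), overall survival is summarized by the Kaplan-Meier
product-limit estimator per group, groups are compared with the two-group
log-rank test, and the effect size is the Mantel-Haenszel hazard ratio
(O_high/E_high) / (O_low/E_low) formed from the log-rank observed and
expected event counts.  The variance term at tied event times uses the
hypergeometric form d (n - d) / (n - 1) * n_A n_B / n^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateSplitError, UsageError
from .io_formats import ClinicalTable
from .normalization import ExprMatrix

logger = logging.getLogger(__name__)

HIGH = "high"
LOW = "low"


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate at the distinct event times."""

    times: np.ndarray  # ascending distinct event times
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time

    def survival_at(self, t: float) -> float:
        """S(t); 1 before the first event time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class KMResult:
    """Median-split survival screen result for one gene."""

    gene: str
    groups: pd.Series  # sample -> high/low
    curve_high: KMCurve
    curve_low: KMCurve
    logrank_chi2: float
    logrank_p: float
    hazard_ratio: float


def median_split(values: pd.Series) -> pd.Series:
    """High/low labels at the median; values equal to the median go low."""
    values = pd.Series(values, dtype=float)
    if len(values) < 4:
        raise UsageError("median split needs at least 4 samples")
    if values.nunique() == 1:
        raise DegenerateSplitError("all expression values identical")
    med = float(values.median())
    return pd.Series(np.where(values > med, HIGH, LOW), index=values.index)


def _check_times_events(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.ndim != 1 or len(times) == 0:
        raise UsageError("need a non-empty vector of times")
    if (times <= 0).any():
        raise UsageError("times must be positive")
    if not np.isin(events, [0, 1]).all():
        raise UsageError("events must be 0 or 1")
    return times, events.astype(int)


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Censored subjects leave the risk set after their recorded time; only
    distinct event times appear in the curve.
    """
    times, events = _check_times_events(times, events)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])
    at_risk = np.empty(len(event_times))
    n_events = np.empty(len(event_times))
    surv = np.empty(len(event_times))
    s = 1.0
    for i, t in enumerate(event_times):
        n_i = int((times >= t).sum())
        d_i = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d_i / n_i
        at_risk[i] = n_i
        n_events[i] = d_i
        surv[i] = s
    return KMCurve(event_times, at_risk, n_events, surv)


def _logrank_tables(
    times_a, events_a, times_b, events_b
) -> tuple[float, float, float, float, float]:
    """(O_A, E_A, O_B, E_B, V) accumulated over the pooled event times."""
    times_a, events_a = _check_times_events(times_a, events_a)
    times_b, events_b = _check_times_events(times_b, events_b)
    event_times = np.unique(
        np.concatenate([times_a[events_a == 1], times_b[events_b == 1]])
    )
    o_a = float(events_a.sum())
    o_b = float(events_b.sum())
    e_a = e_b = v = 0.0
    for t in event_times:
        n_a = int((times_a >= t).sum())
        n_b = int((times_b >= t).sum())
        n = n_a + n_b
        d = int(((times_a == t) & (events_a == 1)).sum()) + int(
            ((times_b == t) & (events_b == 1)).sum()
        )
        e_a += d * n_a / n
        e_b += d * n_b / n
        if n > 1:
            v += d * (n - d) / (n - 1) * n_a * n_b / n**2
    return o_a, e_a, o_b, e_b, v


def logrank_test(
    times_a, events_a, times_b, events_b
) -> tuple[float, float]:
    """Two-group log-rank test: chi2 = (O_A - E_A)^2 / V, p from chi2(1).

    Returns (nan, nan) when neither group has an event (test undefined).
    """
    o_a, e_a, _, _, v = _logrank_tables(times_a, events_a, times_b, events_b)
    if v == 0:
        if o_a == 0 and e_a == 0:
            logger.warning("log-rank undefined: no events in either group")
            return float("nan"), float("nan")
        return 0.0, 1.0
    chi2 = (o_a - e_a) ** 2 / v
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), max(p, np.finfo(float).tiny)


def hazard_ratio(times_a, events_a, times_b, events_b) -> float:
    """Mantel-Haenszel hazard ratio (O_A/E_A) / (O_B/E_B), A = high group.

    Degenerate cases are flagged by value: +inf when only group A has events,
    0.0 when only group B does, nan when neither does.
    """
    o_a, e_a, o_b, e_b, _ = _logrank_tables(times_a, events_a, times_b, events_b)
    if o_a == 0 and o_b == 0:
        return float("nan")
    if o_a == 0:
        logger.warning("hazard ratio degenerate: all events in the low group")
        return 0.0
    if o_b == 0 or e_a == 0:
        logger.warning("hazard ratio degenerate: all events in the high group")
        return float("inf")
    return float((o_a / e_a) / (o_b / e_b))


def gene_survival_screen(
    expr: ExprMatrix,
    clinical: ClinicalTable,
    genes: Iterable[str] | None = None,
    return_results: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, list[KMResult]]:
    """Median-split KM / log-rank / HR screen over a gene panel.

    Samples without a clinical record (or clinical records without
    expression) are dropped with a logged count.  Genes with a degenerate
    split or fewer than 4 usable samples are skipped with a warning.
    Rows are ordered by gene id.
    """
    records = clinical.records.set_index("sample_id")
    usable = [s for s in records.index if s in expr.sample_ids]
    dropped = (len(records) - len(usable)) + (len(expr.sample_ids) - len(usable))
    if dropped:
        logger.info(
            "%d sample(s) lack either clinical or expression data and were dropped",
            dropped,
        )
    if genes is None:
        genes = expr.gene_ids
    genes = sorted(set(genes))

    rows = []
    results: list[KMResult] = []
    for gene in genes:
        if gene not in expr.values.index:
            logger.warning("gene %s absent from expression matrix; skipped", gene)
            continue
        values = expr.values.loc[gene, usable]
        if len(values) < 4:
            logger.warning("gene %s has < 4 usable samples; skipped", gene)
            continue
        try:
            labels = median_split(values)
        except DegenerateSplitError:
            logger.warning("gene %s has constant expression; skipped", gene)
            continue
        high = labels.index[labels == HIGH]
        low = labels.index[labels == LOW]
        t_h = records.loc[high, "time"].to_numpy()
        e_h = records.loc[high, "event"].to_numpy()
        t_l = records.loc[low, "time"].to_numpy()
        e_l = records.loc[low, "event"].to_numpy()
        chi2, p = logrank_test(t_h, e_h, t_l, e_l)
        hr = hazard_ratio(t_h, e_h, t_l, e_l)
        rows.append(
            {
                "gene": gene,
                "n_high": len(high),
                "n_low": len(low),
                "events_high": int(e_h.sum()),
                "events_low": int(e_l.sum()),
                "HR": hr,
                "logrank_chi2": chi2,
                "logrank_p": p,
            }
        )
        if return_results:
            results.append(
                KMResult(
                    gene=gene,
                    groups=labels,
                    curve_high=km_estimate(t_h, e_h) if e_h.sum() else KMCurve(
                        np.array([]), np.array([]), np.array([]), np.array([])
                    ),
                    curve_low=km_estimate(t_l, e_l) if e_l.sum() else KMCurve(
                        np.array([]), np.array([]), np.array([]), np.array([])
                    ),
                    logrank_chi2=chi2,
                    logrank_p=p,
                    hazard_ratio=hr,
                )
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene", "n_high", "n_low", "events_high", "events_low",
            "HR", "logrank_chi2", "logrank_p",
        ],
    )
    if return_results:
        return table, results
    return table
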