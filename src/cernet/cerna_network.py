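"""Triple-evidence ceRNA (lncRNA-miRNA-mRNA) network inference.

A lncRNA and an mRNA are called a competing-endogenous pair when three lines
of evidence agree:

1. **Shared-miRNA enrichment.**  With N miRNAs in the universe, K targeting
   the lncRNA, n targeting the mRNA and k shared, the upper-tail
   hypergeometric probability P(X >= k) must be small — the pair shares more
   miRNAs than chance allows.
2. **Positive co-expression.**  The lncRNA and mRNA must correlate positively
   (Pearson, two-sided t-transform p) across samples: a sponge and its
   protected transcript rise and fall together.
3. **Regulation similarity.**  The shared miRNAs must regulate both partners
   alike.  With per-miRNA correlations c_i^lnc and c_i^m (i = 1..M), the
   score is the mean of [1 - |c_i^lnc - c_i^m| / (|c_i^lnc| + |c_i^m|)]^M,
   which is 1 for identical regulation and 0 for opposite regulation.

Passed pairs assemble into a tripartite lncRNA-miRNA-mRNA network with
``lnc_mir`` and ``mir_mrna`` edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import UsageError
from .io_formats import LNCRNA, MIRNA, PROTEIN_CODING, GeneAnnotation, InteractionTable
from .normalization import ExprMatrix

logger = logging.getLogger(__name__)


@dataclass
class CeRNAThresholds:
    """Pass/fail cutoffs for the three evidence lines.

    Defaults (hypergeometric p < 0.05, positive correlation with p < 0.05,
    regulation similarity >= 0.5, at least one shared miRNA) are pipeline
    choices; all are configurable.
    """

    hyper_cut: float = 0.05
    cor_cut: float = 0.05
    regsim_cut: float = 0.5
    min_shared: int = 1
    regsim_exponent: float | None = None  # None -> number of shared miRNAs

    def __post_init__(self) -> None:
        if not (0 < self.hyper_cut <= 1 and 0 < self.cor_cut <= 1):
            raise UsageError("p-value cutoffs must lie in (0, 1]")
        if not (0 <= self.regsim_cut <= 1):
            raise UsageError("regsim_cut must lie in [0, 1]")
        if self.min_shared < 1:
            raise UsageError("min_shared must be >= 1")


@dataclass
class CeRNAPair:
    """One candidate lncRNA-mRNA pair with its three evidence statistics."""

    lncrna: str
    mrna: str
    shared_mirnas: tuple[str, ...]
    k: int
    K: int
    n: int
    N: int
    hyper_p: float
    cor_r: float
    cor_p: float
    reg_sim: float
    passed: bool

    @property
    def pair_id(self) -> str:
        return f"{self.lncrna}|{self.mrna}"


def shared_mirnas(
    lncrna_id: str,
    mrna_id: str,
    interactions: InteractionTable,
    universe: set[str],
    annotation: GeneAnnotation | None = None,
) -> tuple[set[str], int, int, int]:
    """Shared-miRNA set and hypergeometric counts (K, n, N) for one pair.

    Target sets are intersected with the miRNA universe before counting, so
    k <= min(K, n) <= N holds by construction.
    """
    if not universe:
        raise UsageError("miRNA universe is empty")
    if annotation is not None:
        if annotation.biotype_of(lncrna_id) != LNCRNA:
            raise UsageError(f"{lncrna_id!r} is not annotated as lncRNA")
        if annotation.biotype_of(mrna_id) != PROTEIN_CODING:
            raise UsageError(f"{mrna_id!r} is not annotated as protein_coding")
    lnc_set = interactions.mirnas_targeting(lncrna_id) & universe
    mrna_set = interactions.mirnas_targeting(mrna_id) & universe
    shared = lnc_set & mrna_set
    return shared, len(lnc_set), len(mrna_set), len(universe)


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise UsageError(f"inconsistent hypergeometric counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def pair_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with a two-sided p from the t-transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise UsageError("pair_correlation needs equal-length vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise UsageError("pair_correlation needs finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UsageError("correlation undefined for a zero-variance vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def regulation_similarity(
    cors_lnc: Sequence[float],
    cors_mrna: Sequence[float],
    exponent: float | None = None,
) -> float:
    """Similarity of shared-miRNA regulation between the two partners.

    score = (1/M) sum_i [1 - |c_i^lnc - c_i^m| / (|c_i^lnc| + |c_i^m|)]^expo
    with expo defaulting to M.  A position where both correlations are zero
    is uninformative and contributes the minimal term 0.
    """
    a = np.asarray(cors_lnc, dtype=float)
    b = np.asarray(cors_mrna, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise UsageError("regulation_similarity needs equal-length non-empty vectors")
    if (np.abs(a) > 1).any() or (np.abs(b) > 1).any():
        raise UsageError("correlations must lie in [-1, 1]")
    m = len(a)
    expo = float(m) if exponent is None else float(exponent)
    denom = np.abs(a) + np.abs(b)
    with np.errstate(invalid="ignore", divide="ignore"):
        term = 1.0 - np.abs(a - b) / denom
    term = np.where(denom == 0, 0.0, term)
    score = float(np.mean(np.clip(term, 0.0, 1.0) ** expo))
    return min(max(score, 0.0), 1.0)


def infer_cerna_pairs(
    de_lnc: Iterable[str],
    de_mrna: Iterable[str],
    de_mir: Iterable[str] | None,
    expr: ExprMatrix,
    mir_expr: ExprMatrix,
    interactions: InteractionTable,
    thresholds: CeRNAThresholds | None = None,
    samples: Sequence[str] | None = None,
) -> list[CeRNAPair]:
    """Evaluate every candidate lncRNA x mRNA pair on the three evidence lines.

    Parameters
    ----------
    de_lnc, de_mrna
        Candidate lncRNA and mRNA ids (normally the differentially expressed
        ones); ids without expression rows are skipped with a warning.
    de_mir
        Differentially expressed miRNA ids, or None to use every measured
        miRNA.  The miRNA universe for the hypergeometric test is the
        intersection of the interaction-table miRNAs, the measured miRNAs and
        (when given) this list, so all counts refer to one population.
    samples
        Sample columns used for the correlation evidence; default all shared
        columns.  The pipeline passes tumour samples only.
    expr, mir_expr
        Gene and miRNA logCPM matrices over the same samples.

    Pairs are returned sorted by hypergeometric p then ids (deterministic).
    """
    thresholds = thresholds or CeRNAThresholds()
    if list(expr.sample_ids) != list(mir_expr.sample_ids):
        raise UsageError("gene and miRNA expression matrices index different samples")
    if samples is None:
        samples = list(expr.sample_ids)
    else:
        samples = list(samples)
        missing = set(samples) - set(expr.sample_ids)
        if missing:
            raise UsageError(f"unknown sample(s) for correlation: {sorted(missing)}")

    measured_mir = set(mir_expr.gene_ids)
    universe = interactions.mirnas & measured_mir
    if de_mir is not None:
        universe &= set(de_mir)
    if not universe:
        logger.warning("empty miRNA universe; no pairs can be evaluated")
        return []

    expr_sub = expr.values[samples]
    mir_sub = mir_expr.values[samples]

    de_lnc = [g for g in de_lnc if g in expr.values.index]
    de_mrna = [g for g in de_mrna if g in expr.values.index]

    pairs: list[CeRNAPair] = []
    for lnc in de_lnc:
        lnc_set = interactions.mirnas_targeting(lnc) & universe
        if len(lnc_set) < thresholds.min_shared:
            continue
        for mrna in de_mrna:
            mrna_set = interactions.mirnas_targeting(mrna) & universe
            shared = lnc_set & mrna_set
            if len(shared) < thresholds.min_shared:
                continue
            k, K, n, N = len(shared), len(lnc_set), len(mrna_set), len(universe)
            hyper_p = hypergeom_pvalue(k, K, n, N)
            try:
                cor_r, cor_p = pair_correlation(
                    expr_sub.loc[lnc], expr_sub.loc[mrna]
                )
            except UsageError as exc:
                logger.warning("pair %s|%s excluded: %s", lnc, mrna, exc)
                continue
            shared_sorted = tuple(sorted(shared))
            cors_lnc, cors_mrna, kept = [], [], []
            for mir in shared_sorted:
                if mir not in mir_sub.index:
                    continue
                mv = mir_sub.loc[mir].to_numpy()
                if np.ptp(mv) == 0:
                    logger.warning(
                        "miRNA %s has constant expression; dropped from "
                        "regulation similarity of %s|%s", mir, lnc, mrna
                    )
                    continue
                cors_lnc.append(pair_correlation(mv, expr_sub.loc[lnc])[0])
                cors_mrna.append(pair_correlation(mv, expr_sub.loc[mrna])[0])
                kept.append(mir)
            if not kept:
                continue
            reg_sim = regulation_similarity(
                cors_lnc, cors_mrna, thresholds.regsim_exponent
            )
            passed = (
                hyper_p < thresholds.hyper_cut
                and cor_r > 0
                and cor_p < thresholds.cor_cut
                and reg_sim >= thresholds.regsim_cut
            )
            pairs.append(
                CeRNAPair(
                    lncrna=lnc,
                    mrna=mrna,
                    shared_mirnas=tuple(kept),
                    k=k,
                    K=K,
                    n=n,
                    N=N,
                    hyper_p=hyper_p,
                    cor_r=cor_r,
                    cor_p=cor_p,
                    reg_sim=reg_sim,
                    passed=passed,
                )
            )
    pairs.sort(key=lambda p: (p.hyper_p, p.lncrna, p.mrna))
    return pairs


def pairs_table(pairs: Iterable[CeRNAPair]) -> pd.DataFrame:
    """Flatten CeRNAPair records into the documented TSV layout."""
    rows = [
        {
            "lncRNA": p.lncrna,
            "mRNA": p.mrna,
            "n_shared": p.k,
            "shared_mirnas": ";".join(p.shared_mirnas),
            "K": p.K,
            "n": p.n,
            "N": p.N,
            "hyper_p": p.hyper_p,
            "cor_r": p.cor_r,
            "cor_p": p.cor_p,
            "reg_sim": p.reg_sim,
            "passed": p.passed,
        }
        for p in pairs
    ]
    columns = [
        "lncRNA", "mRNA", "n_shared", "shared_mirnas", "K", "n", "N",
        "hyper_p", "cor_r", "cor_p", "reg_sim", "passed",
    ]
    return pd.DataFrame(rows, columns=columns)


@dataclass
class CeRNANetwork:
    """Tripartite lncRNA-miRNA-mRNA graph built from passed pairs."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of(self, biotype: str) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("biotype") == biotype
        )


def build_network(pairs: Iterable[CeRNAPair]) -> CeRNANetwork:
    """Assemble the deduplicated tripartite network from passed pairs.

    Non-passed pairs are ignored.  Each shared miRNA of a passed pair
    contributes a ``lnc_mir`` and a ``mir_mrna`` edge; edges shared between
    pairs carry every contributing pair id in their ``evidence`` attribute.
    """
    graph = nx.Graph()
    evidence: dict[tuple[str, str], set[str]] = {}
    for pair in pairs:
        if not pair.passed:
            continue
        graph.add_node(pair.lncrna, biotype=LNCRNA)
        graph.add_node(pair.mrna, biotype=PROTEIN_CODING)
        for mir in pair.shared_mirnas:
            graph.add_node(mir, biotype=MIRNA)
            for u, v, kind in (
                (pair.lncrna, mir, "lnc_mir"),
                (mir, pair.mrna, "mir_mrna"),
            ):
                graph.add_edge(u, v, kind=kind)
                key = tuple(sorted((u, v)))
                evidence.setdefault(key, set()).add(pair.pair_id)
    for (u, v), pair_ids in evidence.items():
        graph.edges[u, v]["evidence"] = ";".join(sorted(pair_ids))
    return CeRNANetwork(graph)


def network_stats(net: CeRNANetwork) -> tuple[int, int, pd.DataFrame]:
    """Node count, edge count and per-node degree table (sorted by degree)."""
    rows = [
        {"node": n, "biotype": d.get("biotype", ""), "degree": net.graph.degree[n]}
        for n, d in net.graph.nodes(data=True)
    ]
    degrees = pd.DataFrame(rows, columns=["node", "biotype", "degree"])
    if len(degrees):
        degrees = degrees.sort_values(
            ["degree", "node"], ascending=[False, True]
        ).reset_index(drop=True)
    return net.n_nodes, net.n_edges, degrees
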