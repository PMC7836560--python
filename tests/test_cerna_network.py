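import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cernet import (
    CeRNAPair,
    CeRNAThresholds,
    ExprMatrix,
    GeneAnnotation,
    InteractionTable,
    UsageError,
    build_network,
    hypergeom_pvalue,
    infer_cerna_pairs,
    network_stats,
    pair_correlation,
    regulation_similarity,
    shared_mirnas,
)


def _interactions(rows):
    return InteractionTable(pd.DataFrame(rows, columns=["mirna", "target"]))


# ------------------------------------------------------------ shared miRNAs

def test_shared_mirna_set_arithmetic():
    table = _interactions(
        [(m, "L") for m in "abcd"] + [(m, "G") for m in "cde"]
    )
    universe = set("abcdefghij")
    shared, K, n, N = shared_mirnas("L", "G", table, universe)
    assert shared == {"c", "d"} and (K, n, N) == (4, 3, 10)


def test_disjoint_target_sets():
    table = _interactions([("a", "L"), ("b", "G")])
    shared, *_ = shared_mirnas("L", "G", table, {"a", "b"})
    assert shared == set()


def test_universe_restriction():
    table = _interactions(
        [(m, "L") for m in "abcd"] + [(m, "G") for m in "cde"]
    )
    universe = set("abcefghij")  # d excluded
    shared, K, n, N = shared_mirnas("L", "G", table, universe)
    assert shared == {"c"} and (K, n, N) == (3, 2, 9)


def test_wrong_biotype_rejected():
    ann = GeneAnnotation(pd.Series({"L": "lncRNA", "G": "miRNA"}))
    with pytest.raises(UsageError):
        shared_mirnas("L", "G", _interactions([("a", "L")]), {"a"}, ann)


# ----------------------------------------------------------- hypergeometric

def test_hypergeom_zero_overlap_is_one():
    assert hypergeom_pvalue(0, 4, 3, 10) == 1.0


def test_hypergeom_enumerated_example():
    # C(10,3)=120 draws of n=3 from N=10 with K=4 marked:
    # P(X=2)=C(4,2)C(6,1)/120=36/120, P(X=3)=C(4,3)/120=4/120 -> 1/3
    assert hypergeom_pvalue(2, 4, 3, 10) == pytest.approx(1 / 3, abs=1e-12)


def test_hypergeom_forced_overlap():
    assert hypergeom_pvalue(5, 5, 5, 5) == pytest.approx(1.0)


def test_hypergeom_inconsistent_counts_rejected():
    with pytest.raises(UsageError):
        hypergeom_pvalue(4, 3, 3, 10)
    with pytest.raises(UsageError):
        hypergeom_pvalue(1, 11, 3, 10)


def test_hypergeom_matches_enumeration_small_universe():
    for N in range(1, 9):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    expect = sum(
                        math.comb(K, j) * math.comb(N - K, n - j)
                        for j in range(k, min(K, n) + 1)
                    ) / math.comb(N, n)
                    assert hypergeom_pvalue(k, K, n, N) == pytest.approx(
                        expect, abs=1e-12
                    )


# -------------------------------------------------------------- correlation

def test_perfect_linear_correlations():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    r, p = pair_correlation(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    r, _ = pair_correlation(x, -x)
    assert r == pytest.approx(-1.0)


def test_correlation_against_sum_formula():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.0, 2.0, 3.0, 5.0])
    n = 4
    sxy = (x * y).sum() - x.sum() * y.sum() / n
    sxx = (x * x).sum() - x.sum() ** 2 / n
    syy = (y * y).sum() - y.sum() ** 2 / n
    r_expect = sxy / np.sqrt(sxx * syy)
    t = r_expect * np.sqrt((n - 2) / (1 - r_expect**2))
    from scipy import stats

    p_expect = 2 * stats.t.sf(abs(t), n - 2)
    r, p = pair_correlation(x, y)
    assert r == pytest.approx(r_expect, abs=1e-12)
    assert p == pytest.approx(p_expect, rel=1e-9)


def test_zero_variance_vector_flagged():
    with pytest.raises(UsageError, match="zero-variance"):
        pair_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ----------------------------------------------------- regulation similarity

def test_regsim_identical_regulation_is_one():
    assert regulation_similarity([-0.5], [-0.5]) == pytest.approx(1.0)


def test_regsim_opposite_regulation_is_zero():
    assert regulation_similarity([-0.5], [0.5]) == pytest.approx(0.0)


def test_regsim_hand_computed_two_mirnas():
    # terms (1-0)^2 = 1 and (1 - 0.3/0.9)^2 = 4/9 -> (1 + 4/9)/2 = 13/18
    score = regulation_similarity([-0.4, -0.6], [-0.4, -0.3])
    assert score == pytest.approx(13 / 18, abs=1e-12)


def test_regsim_both_zero_position_contributes_zero():
    assert regulation_similarity([0.0], [0.0]) == 0.0


def test_regsim_empty_rejected():
    with pytest.raises(UsageError):
        regulation_similarity([], [])


@settings(derandomize=True, max_examples=200)
@given(
    st.lists(
        st.tuples(st.floats(-1, 1, allow_nan=False), st.floats(-1, 1, allow_nan=False)),
        min_size=1,
        max_size=6,
    )
)
def test_regsim_symmetric_and_bounded(pairs):
    a = [p[0] for p in pairs]
    b = [p[1] for p in pairs]
    s_ab = regulation_similarity(a, b)
    s_ba = regulation_similarity(b, a)
    assert s_ab == pytest.approx(s_ba, abs=1e-12)
    assert 0.0 <= s_ab <= 1.0
    if a == b and any(v != 0 for v in a):
        assert s_ab == pytest.approx(1.0)


# ----------------------------------------------------------- pair inference

def _planted_expr(rng, n_samples=60, strength=0.9):
    """Tiny hand-built dataset: one real triple and one unrelated pair."""
    samples = [f"s{i}" for i in range(n_samples)]
    z = rng.normal(size=n_samples)
    noise = lambda: rng.normal(0, 0.4, n_samples)
    expr = pd.DataFrame(
        {
            "LNC1": 5 + strength * z + noise(),
            "LNC2": 5 + noise(),
            "GEN1": 6 + strength * z + noise(),
            "GEN2": 6 + noise(),
        }
    ).T
    expr.columns = samples
    mir = pd.DataFrame(
        {f"MIR{i}": 4 - (strength * z if i <= 3 else 0) + noise()
         for i in range(1, 8)}
    ).T
    mir.columns = samples
    return (
        ExprMatrix(expr, log=True),
        ExprMatrix(mir, log=True),
    )


def test_planted_pair_passes_and_unrelated_does_not(rng):
    expr, mir = _planted_expr(rng)
    interactions = _interactions(
        [(f"MIR{i}", t) for i in (1, 2, 3) for t in ("LNC1", "GEN1")]
        + [("MIR4", "LNC2"), ("MIR5", "LNC2"), ("MIR4", "GEN2"),
           ("MIR6", "GEN2"), ("MIR7", "LNC2")]
    )
    pairs = infer_cerna_pairs(
        ["LNC1", "LNC2"], ["GEN1", "GEN2"], None, expr, mir, interactions
    )
    by_id = {(p.lncrna, p.mrna): p for p in pairs}
    assert by_id[("LNC1", "GEN1")].passed
    assert by_id[("LNC1", "GEN1")].reg_sim > 0.5
    assert ("LNC2", "GEN2") not in by_id or not by_id[("LNC2", "GEN2")].passed


def test_pair_without_shared_mirnas_never_evaluated(rng):
    expr, mir = _planted_expr(rng)
    interactions = _interactions([("MIR1", "LNC1"), ("MIR2", "GEN1")])
    pairs = infer_cerna_pairs(
        ["LNC1"], ["GEN1"], None, expr, mir, interactions
    )
    assert pairs == []


def test_tightening_thresholds_never_adds_pairs(rng):
    expr, mir = _planted_expr(rng, strength=0.5)
    interactions = _interactions(
        [(m, t) for m in ("MIR1", "MIR2", "MIR3") for t in ("LNC1", "LNC2", "GEN1", "GEN2")]
    )
    loose = CeRNAThresholds(hyper_cut=0.9, cor_cut=0.9, regsim_cut=0.0)
    tight = CeRNAThresholds(hyper_cut=0.05, cor_cut=0.05, regsim_cut=0.6)
    args = (["LNC1", "LNC2"], ["GEN1", "GEN2"], None, expr, mir, interactions)
    passed_loose = {(p.lncrna, p.mrna) for p in infer_cerna_pairs(*args, loose) if p.passed}
    passed_tight = {(p.lncrna, p.mrna) for p in infer_cerna_pairs(*args, tight) if p.passed}
    assert passed_tight <= passed_loose


def test_sample_mismatch_rejected(rng):
    expr, mir = _planted_expr(rng)
    mir_short = ExprMatrix(mir.values.iloc[:, :-1], log=True)
    with pytest.raises(UsageError):
        infer_cerna_pairs(["LNC1"], ["GEN1"], None, expr, mir_short,
                          _interactions([("MIR1", "LNC1"), ("MIR1", "GEN1")]))


# ------------------------------------------------------------------ network

def _passed_pair(lnc, mrna, mirnas):
    k = len(mirnas)
    return CeRNAPair(
        lncrna=lnc, mrna=mrna, shared_mirnas=tuple(mirnas),
        k=k, K=k, n=k, N=10, hyper_p=0.001, cor_r=0.8, cor_p=0.001,
        reg_sim=0.9, passed=True,
    )


def test_empty_network():
    net = build_network([])
    assert (net.n_nodes, net.n_edges) == (0, 0)


def test_single_triple_network():
    net = build_network([_passed_pair("L", "G", ["M"])])
    assert net.n_nodes == 3 and net.n_edges == 2
    assert net.graph.edges["L", "M"]["kind"] == "lnc_mir"
    assert net.graph.edges["M", "G"]["kind"] == "mir_mrna"


def test_snhg1_fixture_network_has_eight_nodes():
    """SNHG1 with its four mediating miRNAs and three targets as separate
    passed pairs: 1 lncRNA + 4 miRNAs + 3 mRNAs = 8 nodes."""
    pairs = [
        _passed_pair("SNHG1", "E2F8", ["hsa-miR-421", "hsa-miR-377-3p"]),
        _passed_pair("SNHG1", "LMNB2", ["hsa-miR-330-5p"]),
        _passed_pair("SNHG1", "FANCE", ["hsa-miR-326"]),
    ]
    net = build_network(pairs)
    n_nodes, n_edges, degrees = network_stats(net)
    assert n_nodes == 8
    # 4 lnc-mir edges + 4 mir-mrna edges
    assert n_edges == 8
    assert degrees.iloc[0]["node"] == "SNHG1" and degrees.iloc[0]["degree"] == 4


def test_shared_mirna_deduplicated_across_pairs():
    pairs = [
        _passed_pair("L1", "G1", ["M"]),
        _passed_pair("L1", "G2", ["M"]),
    ]
    net = build_network(pairs)
    assert net.n_nodes == 4  # L1, M, G1, G2
    assert net.n_edges == 3  # L1-M deduplicated
    assert net.graph.edges["L1", "M"]["evidence"] == "L1|G1;L1|G2"


def test_network_is_tripartite():
    pairs = [
        _passed_pair("L1", "G1", ["M1", "M2"]),
        _passed_pair("L2", "G1", ["M2"]),
    ]
    net = build_network(pairs)
    for u, v, data in net.graph.edges(data=True):
        kinds = {net.graph.nodes[u]["biotype"], net.graph.nodes[v]["biotype"]}
        assert "miRNA" in kinds and len(kinds) == 2


def test_non_passed_pairs_excluded():
    pair = _passed_pair("L", "G", ["M"])
    pair.passed = False
    assert build_network([pair]).n_nodes == 0
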