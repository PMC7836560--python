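import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cernet import (
    EBayesPrior,
    EstimationError,
    ExprMatrix,
    UsageError,
    bh_adjust,
    classify_de,
    estimate_prior,
    moderated_t,
    volcano_table,
)


def _expr(x, n_tumour, n_normal):
    samples = [f"t{i}" for i in range(n_tumour)] + [f"n{i}" for i in range(n_normal)]
    genes = [f"g{i}" for i in range(x.shape[0])]
    em = ExprMatrix(pd.DataFrame(x, index=genes, columns=samples), log=True)
    groups = pd.Series(["tumour"] * n_tumour + ["normal"] * n_normal, index=samples)
    return em, groups


# ------------------------------------------------------------------ prior fit

def test_equal_variances_give_infinite_prior_df():
    prior = estimate_prior(np.full(50, 2.5), df=10)
    assert np.isinf(prior.df_prior)
    assert prior.var_prior == pytest.approx(2.5, rel=1e-6)


def test_single_gene_is_degenerate():
    with pytest.raises(EstimationError):
        estimate_prior(np.array([1.0]), df=10)


def test_prior_parameter_recovery():
    """Scaled inverse-chi-square truth (d0=4, s0^2=2) recovered from 5000
    gene variances with chi-square sampling noise at df=38."""
    rng = np.random.default_rng(123)
    d0, s02, df = 4.0, 2.0, 38
    sigma2 = s02 * d0 / rng.chisquare(d0, 5000)
    s2 = sigma2 * rng.chisquare(df, 5000) / df
    prior = estimate_prior(s2, df)
    assert 3.0 <= prior.df_prior <= 5.5
    assert 1.8 <= prior.var_prior <= 2.2


# ------------------------------------------------------------- moderated t

def test_identical_group_means_give_null_statistics(rng):
    x = rng.normal(5, 1, size=(20, 8))
    x[0, :] = 3.0  # identical values in both groups
    em, groups = _expr(x, 4, 4)
    res = moderated_t(em, groups)
    assert res.loc["g0", "logFC"] == 0
    assert res.loc["g0", "t"] == 0
    assert res.loc["g0", "p_value"] == pytest.approx(1.0)


def test_zero_prior_df_recovers_ordinary_pooled_t(rng):
    x = rng.normal(0, 1, size=(40, 12))
    em, groups = _expr(x, 6, 6)
    res = moderated_t(em, groups, prior=EBayesPrior(df_prior=0.0, var_prior=1.0))
    t_ref, p_ref = stats.ttest_ind(x[:, :6], x[:, 6:], axis=1, equal_var=True)
    assert res["t"].to_numpy() == pytest.approx(t_ref, rel=1e-10)
    assert res["p_value"].to_numpy() == pytest.approx(p_ref, rel=1e-10)


def test_group_label_swap_negates_logfc_and_t(rng):
    x = rng.normal(0, 1, size=(30, 10))
    em, groups = _expr(x, 5, 5)
    swapped = groups.map({"tumour": "normal", "normal": "tumour"})
    res = moderated_t(em, groups)
    res_sw = moderated_t(em, swapped)
    assert res_sw["logFC"].to_numpy() == pytest.approx(-res["logFC"].to_numpy())
    assert res_sw["t"].to_numpy() == pytest.approx(-res["t"].to_numpy())
    assert res_sw["p_value"].to_numpy() == pytest.approx(res["p_value"].to_numpy())


def test_sample_order_within_groups_is_irrelevant(rng):
    x = rng.normal(0, 1, size=(30, 10))
    em, groups = _expr(x, 5, 5)
    perm = ["t3", "t1", "t4", "t0", "t2", "n2", "n0", "n4", "n1", "n3"]
    em_perm = ExprMatrix(em.values[perm], log=True)
    res = moderated_t(em, groups)
    res_perm = moderated_t(em_perm, groups[perm])
    pd.testing.assert_frame_equal(res, res_perm)


def test_small_group_rejected(rng):
    em, groups = _expr(rng.normal(size=(5, 3)), 1, 2)
    with pytest.raises(UsageError):
        moderated_t(em, groups)


def test_null_type_one_error_calibrated(rng):
    """No group effect: raw p < 0.01 in about 1% of genes."""
    rates = []
    for _ in range(10):
        em, groups = _expr(rng.normal(5, 1, size=(2000, 40)), 20, 20)
        res = moderated_t(em, groups)
        rates.append((res["p_value"] < 0.01).mean())
    assert np.mean(rates) == pytest.approx(0.01, abs=0.005)


def test_moderated_t_matches_limma_reference(nb_counts, tmp_path):
    """Bioconductor limma (lmFit + eBayes, trend=FALSE) on edgeR logCPM."""
    from cernet import cpm, tmm_factors

    factors = tmm_factors(nb_counts)
    logcpm = cpm(nb_counts, factors, log=True, prior_count=0.5)
    res = moderated_t(logcpm, nb_counts.sample_groups)

    counts_path = tmp_path / "counts.tsv"
    nb_counts.counts.to_csv(counts_path, sep="\t")
    out_path = tmp_path / "limma.tsv"
    n1 = len(nb_counts.samples_in_group("tumour"))
    n2 = nb_counts.n_samples - n1
    script = tmp_path / "limma.R"
    script.write_text(f"""
suppressMessages({{library(edgeR); library(limma)}})
x <- as.matrix(read.delim("{counts_path}", row.names=1))
y <- calcNormFactors(DGEList(counts=x), method="TMM")
lcpm <- cpm(y, log=TRUE, prior.count=0.5)
design <- model.matrix(~0+factor(c(rep("t",{n1}),rep("n",{n2})), levels=c("t","n")))
colnames(design) <- c("t","n")
fit <- eBayes(contrasts.fit(lmFit(lcpm, design),
  makeContrasts(t-n, levels=design)), trend=FALSE)
write.table(data.frame(gene=rownames(x), logFC=fit$coefficients[,1],
  t=fit$t[,1], p=fit$p.value[,1], d0=fit$df.prior, s02=fit$s2.prior),
  "{out_path}", sep="\\t", row.names=FALSE, quote=FALSE)
""")
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    ref = pd.read_csv(out_path, sep="\t").set_index("gene")
    assert res["logFC"].to_numpy() == pytest.approx(ref["logFC"].to_numpy(), abs=1e-8)
    assert res["t"].to_numpy() == pytest.approx(ref["t"].to_numpy(), abs=1e-8)
    assert res["p_value"].to_numpy() == pytest.approx(ref["p"].to_numpy(), rel=1e-8)
    prior = estimate_prior(res["s2"].to_numpy(), res["df_residual"].iloc[0])
    assert prior.df_prior == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
    assert prior.var_prior == pytest.approx(ref["s02"].iloc[0], rel=1e-6)


# ----------------------------------------------------------------------- BH

def test_bh_step_up_hand_example():
    adj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
    assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_bh_trivial_cases():
    assert bh_adjust(np.array([0.37])) == pytest.approx([0.37])
    assert bh_adjust(np.ones(5)) == pytest.approx(np.ones(5))


def test_bh_matches_statsmodels(rng):
    p = rng.uniform(size=500)
    assert bh_adjust(p) == pytest.approx(
        multipletests(p, method="fdr_bh")[1], rel=1e-12
    )


def test_bh_rejects_out_of_range():
    with pytest.raises(UsageError):
        bh_adjust(np.array([0.5, 1.5]))


# -------------------------------------------------------------- classify_de

TABLE1 = [  # gene, log2 fold change, reported p
    ("SNHG1", 1.495397836, 6.43e-18),
    ("LMNB2", 1.115366226, 5.95e-13),
    ("FANCE", 1.459672439, 9.12e-14),
    ("E2F8", 3.729047657, 8.89e-27),
]


@pytest.mark.parametrize("gene,logfc,p", TABLE1)
def test_reported_network_genes_classify_up(gene, logfc, p):
    assert classify_de([logfc], [p])[0] == "up"


def test_fold_change_gate():
    # p tiny but FC about 1.87 < 2 -> not significant
    assert classify_de([0.9], [1e-10])[0] == "ns"
    assert classify_de([-1.2], [1e-3], p_threshold=0.01)[0] == "down"


@settings(derandomize=True, max_examples=200)
@given(
    logfc=st.floats(-10, 10, allow_nan=False),
    p=st.floats(0, 1, allow_nan=False),
    better_p=st.floats(0, 1, allow_nan=False),
    extra_fc=st.floats(0, 5, allow_nan=False),
)
def test_classify_monotone_in_evidence(logfc, p, better_p, extra_fc):
    """Decreasing p or pushing |logFC| outward never demotes up/down to ns."""
    label = classify_de([logfc], [p])[0]
    if label == "ns":
        return
    stronger_fc = logfc + extra_fc if label == "up" else logfc - extra_fc
    assert classify_de([stronger_fc], [min(p, better_p)])[0] == label


# ------------------------------------------------------------------- volcano

def test_volcano_coordinates():
    res = pd.DataFrame(
        {
            "logFC": [1.0, -2.0, 0.5],
            "adj_p_value": [0.01, 1.0, 0.0],
            "de_class": ["up", "ns", "ns"],
        },
        index=["a", "b", "c"],
    )
    v = volcano_table(res, cap=100.0)
    assert v.loc["a", "neg_log10_adj_p"] == pytest.approx(2.0)
    assert v.loc["b", "neg_log10_adj_p"] == pytest.approx(0.0)
    assert v.loc["c", "neg_log10_adj_p"] == 100.0
    assert bool(v.loc["c", "capped"]) and not bool(v.loc["a", "capped"])
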