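"""Seeded multi-omic count simulator with planted ground truth.

The generator emulates the statistical structure the ceRNA pipeline assumes
in a tumour/normal bulk cohort:

* negative-binomial counts per gene (variance mu + phi mu^2) on
  log-uniformly drawn library sizes, with per-sample column renormalization
  so that planted effects also exercise composition-bias correction;
* planted differential expression: a fraction of genes receives a log2
  fold-change between tumour and normal drawn from N(lfc_mean, lfc_sd) with
  random sign;
* planted ceRNA triples: each triple (one lncRNA, a few miRNAs, one mRNA)
  shares a per-sample Gaussian latent factor that loads positively
  (+triple_strength) on the lncRNA and mRNA log-means and negatively
  (-triple_strength) on its miRNAs, producing the signed correlation pattern
  ceRNA inference tests for.  Triple members are also planted as
  differentially expressed with coherent signs (lncRNA/mRNA up, miRNAs down)
  so the DE-restricted network stage can see them;
* a StarBase-like interaction table containing every planted triple edge plus
  independent background edges;
* exponential overall-survival times for tumour samples whose log-hazard
  increases by surv_beta for samples in the high-expression half of each
  chosen driver gene, with independent exponential censoring.

All randomness flows from ``SimConfig.seed`` through per-stage seed
sequences, so identical configurations reproduce byte-identical datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError
from .io_formats import (
    LNCRNA,
    MIRNA,
    NORMAL,
    PROTEIN_CODING,
    TUMOUR,
    ClinicalTable,
    CountMatrix,
    GeneAnnotation,
    InteractionTable,
)

logger = logging.getLogger(__name__)

# stage tags appended to the seed so the three operations draw from
# independent, reproducible streams
_EXPR_STREAM = 0
_INTERACTION_STREAM = 1
_CLINICAL_STREAM = 2


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic dataset.

    Defaults describe a mid-sized two-arm cohort: 50 tumour + 50 normal
    samples, 600 mRNAs / 120 lncRNAs / 120 miRNAs, 20% of genes
    differentially expressed at |log2FC| ~ N(2, 0.5), NB dispersion 0.05-0.2,
    library sizes log-uniform on [2e6, 1e7], five planted ceRNA triples of
    three miRNAs each at latent loading 0.8, background interaction
    probability 0.005, one survival driver gene at log HR = log 2 with 30%
    independent censoring around a 600-day baseline median survival.
    """

    n_tumour: int = 50
    n_normal: int = 50
    n_mrna: int = 600
    n_lncrna: int = 120
    n_mirna: int = 120
    frac_de: float = 0.2
    lfc_mean: float = 2.0
    lfc_sd: float = 0.5
    nb_dispersion: float | tuple[float, float] = (0.05, 0.2)
    lib_size_range: tuple[float, float] = (2e6, 1e7)
    n_triples: int = 5
    mirnas_per_triple: int = 3
    triple_strength: float = 0.8
    bg_edge_prob: float = 0.005
    surv_genes: tuple[str, ...] | None = None  # None -> first triple's mRNA
    surv_beta: float = float(np.log(2.0))
    censor_rate: float = 0.3
    base_hazard: float = float(np.log(2.0) / 600.0)  # per day
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tumour", "n_normal", "n_mrna", "n_lncrna", "n_mirna"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 <= self.frac_de <= 1:
            raise ConfigurationError("frac_de must lie in [0, 1]")
        if not 0 < self.triple_strength < 1:
            raise ConfigurationError("triple_strength must lie in (0, 1)")
        if not 0 <= self.censor_rate < 1:
            raise ConfigurationError("censor_rate must lie in [0, 1)")
        if not 0 <= self.bg_edge_prob <= 1:
            raise ConfigurationError("bg_edge_prob must lie in [0, 1]")
        if self.n_triples < 0 or self.mirnas_per_triple <= 0:
            raise ConfigurationError("invalid triple configuration")
        if self.n_triples > min(self.n_lncrna, self.n_mrna):
            raise ConfigurationError("more triples than available lncRNAs/mRNAs")
        if self.n_triples * self.mirnas_per_triple > self.n_mirna:
            raise ConfigurationError("more triple miRNAs than available miRNAs")
        lo, hi = self.lib_size_range
        if not 0 < lo <= hi:
            raise ConfigurationError("invalid lib_size_range")
        if self.base_hazard <= 0:
            raise ConfigurationError("base_hazard must be positive")


@dataclass(frozen=True)
class Triple:
    """One planted ceRNA triple."""

    lncrna: str
    mirnas: tuple[str, ...]
    mrna: str


@dataclass
class GroundTruth:
    """Planted effects underlying a simulated dataset."""

    de_genes: dict[str, float]  # gene id -> true log2 fold change
    triples: list[Triple]
    surv_effects: dict[str, float]  # gene id -> true log hazard ratio


def _dispersions(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    phi = config.nb_dispersion
    if np.isscalar(phi):
        if phi <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        return np.full(n, float(phi))
    lo, hi = phi
    if not 0 < lo <= hi:
        raise ConfigurationError("invalid nb_dispersion range")
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))


def _nb_counts(mu: np.ndarray, phi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """NB draws with mean mu and variance mu + phi mu^2 (size r = 1/phi)."""
    r = 1.0 / phi[:, None]
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(np.int64)


def _lib_sizes(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.lib_size_range
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))


def simulate_expression(
    config: SimConfig,
) -> tuple[CountMatrix, CountMatrix, GeneAnnotation, GroundTruth]:
    """Generate the RNA (mRNA+lncRNA) and miRNA count matrices.

    Returns the two count matrices, the biotype annotation covering every
    gene, and the planted ground truth (DE effects, triples, survival
    drivers).  Identical configurations give identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _EXPR_STREAM]))

    mrna_ids = [f"MRNA{i + 1:04d}" for i in range(config.n_mrna)]
    lnc_ids = [f"LNC{i + 1:04d}" for i in range(config.n_lncrna)]
    mir_ids = [f"MIR{i + 1:04d}" for i in range(config.n_mirna)]
    samples = [f"T{i + 1:03d}" for i in range(config.n_tumour)] + [
        f"N{i + 1:03d}" for i in range(config.n_normal)
    ]
    n_samples = len(samples)
    tumour_mask = np.array([s.startswith("T") for s in samples])
    groups = pd.Series(
        np.where(tumour_mask, TUMOUR, NORMAL), index=pd.Index(samples)
    )

    # planted triples: disjoint members drawn without replacement
    triples: list[Triple] = []
    tri_lnc = rng.choice(config.n_lncrna, size=config.n_triples, replace=False)
    tri_mrna = rng.choice(config.n_mrna, size=config.n_triples, replace=False)
    tri_mir = rng.choice(
        config.n_mirna,
        size=config.n_triples * config.mirnas_per_triple,
        replace=False,
    )
    for t in range(config.n_triples):
        mirs = tuple(
            mir_ids[j]
            for j in tri_mir[
                t * config.mirnas_per_triple : (t + 1) * config.mirnas_per_triple
            ]
        )
        triples.append(Triple(lnc_ids[tri_lnc[t]], mirs, mrna_ids[tri_mrna[t]]))

    # planted log2 fold changes
    de_genes: dict[str, float] = {}

    def _effect() -> float:
        return abs(rng.normal(config.lfc_mean, config.lfc_sd))

    for tri in triples:
        de_genes[tri.lncrna] = _effect()
        de_genes[tri.mrna] = _effect()
        for mir in tri.mirnas:
            de_genes[mir] = -_effect()
    if config.frac_de > 0:
        for gene in mrna_ids + lnc_ids + mir_ids:
            if gene in de_genes:
                continue
            if rng.random() < config.frac_de:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                de_genes[gene] = sign * _effect()

    rna_ids = mrna_ids + lnc_ids
    log2_base_rna = rng.uniform(3.0, 12.0, size=len(rna_ids))
    log2_base_mir = rng.uniform(3.0, 12.0, size=len(mir_ids))
    phi_rna = _dispersions(config, len(rna_ids), rng)
    phi_mir = _dispersions(config, len(mir_ids), rng)

    rna_index = {g: i for i, g in enumerate(rna_ids)}
    mir_index = {g: i for i, g in enumerate(mir_ids)}

    log2_mu_rna = np.tile(log2_base_rna[:, None], (1, n_samples))
    log2_mu_mir = np.tile(log2_base_mir[:, None], (1, n_samples))
    for gene, lfc in de_genes.items():
        if gene in rna_index:
            log2_mu_rna[rna_index[gene], tumour_mask] += lfc
        else:
            log2_mu_mir[mir_index[gene], tumour_mask] += lfc

    # shared latent factor per triple: + on lncRNA/mRNA, - on member miRNAs
    latent = rng.normal(size=(config.n_triples, n_samples))
    for t, tri in enumerate(triples):
        z = config.triple_strength * latent[t]
        log2_mu_rna[rna_index[tri.lncrna]] += z
        log2_mu_rna[rna_index[tri.mrna]] += z
        for mir in tri.mirnas:
            log2_mu_mir[mir_index[mir]] -= z

    lib_rna = _lib_sizes(config, n_samples, rng)
    lib_mir = _lib_sizes(config, n_samples, rng)

    def _counts(log2_mu, lib, phi):
        rel = np.exp2(log2_mu)
        rel /= rel.sum(axis=0, keepdims=True)
        return _nb_counts(rel * lib[None, :], phi, rng)

    rna_counts = _counts(log2_mu_rna, lib_rna, phi_rna)
    mir_counts = _counts(log2_mu_mir, lib_mir, phi_mir)

    rna = CountMatrix(
        pd.DataFrame(rna_counts, index=pd.Index(rna_ids, name="gene_id"),
                     columns=samples),
        groups,
    )
    mir = CountMatrix(
        pd.DataFrame(mir_counts, index=pd.Index(mir_ids, name="gene_id"),
                     columns=samples),
        groups,
    )
    annotation = GeneAnnotation(
        pd.Series(
            [PROTEIN_CODING] * len(mrna_ids)
            + [LNCRNA] * len(lnc_ids)
            + [MIRNA] * len(mir_ids),
            index=pd.Index(mrna_ids + lnc_ids + mir_ids, name="gene_id"),
        )
    )

    if config.surv_genes is not None:
        surv_genes = tuple(config.surv_genes)
    elif triples:
        surv_genes = (triples[0].mrna,)
    else:
        surv_genes = (mrna_ids[0],)
    truth = GroundTruth(
        de_genes=de_genes,
        triples=triples,
        surv_effects={g: config.surv_beta for g in surv_genes},
    )
    _check_truth_closure(truth, rna, mir)
    return rna, mir, annotation, truth


def _check_truth_closure(truth: GroundTruth, rna: CountMatrix, mir: CountMatrix):
    known = set(rna.gene_ids) | set(mir.gene_ids)
    for gene in truth.de_genes:
        if gene not in known:
            raise ConsistencyError(f"ground-truth DE gene {gene!r} not generated")
    for tri in truth.triples:
        for gene in (tri.lncrna, tri.mrna, *tri.mirnas):
            if gene not in known:
                raise ConsistencyError(f"triple member {gene!r} not generated")
    for gene in truth.surv_effects:
        if gene not in known:
            raise ConsistencyError(f"survival gene {gene!r} not generated")


def simulate_interactions(config: SimConfig, truth: GroundTruth) -> InteractionTable:
    """StarBase-like miRNA -> target edge table.

    Every planted triple contributes its miRNA->lncRNA and miRNA->mRNA edges;
    each remaining (miRNA, target) combination appears independently with
    probability ``bg_edge_prob``.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _INTERACTION_STREAM])
    )
    mrna_ids = [f"MRNA{i + 1:04d}" for i in range(config.n_mrna)]
    lnc_ids = [f"LNC{i + 1:04d}" for i in range(config.n_lncrna)]
    mir_ids = [f"MIR{i + 1:04d}" for i in range(config.n_mirna)]
    known = set(mrna_ids) | set(lnc_ids) | set(mir_ids)
    for tri in truth.triples:
        for gene in (tri.lncrna, tri.mrna, *tri.mirnas):
            if gene not in known:
                raise ConsistencyError(
                    f"ground truth references unknown gene {gene!r}"
                )

    edges: set[tuple[str, str]] = set()
    for tri in truth.triples:
        for mir in tri.mirnas:
            edges.add((mir, tri.lncrna))
            edges.add((mir, tri.mrna))
    targets = lnc_ids + mrna_ids
    if config.bg_edge_prob > 0:
        draw = rng.random((len(mir_ids), len(targets))) < config.bg_edge_prob
        for i, j in np.argwhere(draw):
            edges.add((mir_ids[i], targets[j]))
    rows = sorted(edges)
    return InteractionTable(
        pd.DataFrame(rows, columns=["mirna", "target"])
    )


def simulate_clinical(
    config: SimConfig, expr: CountMatrix, truth: GroundTruth
) -> ClinicalTable:
    """Exponential overall-survival records for the tumour samples.

    The per-patient log hazard is ``log(base_hazard) + sum_g surv_beta *
    1[patient in the high half of driver gene g]`` where the split is at the
    median CPM of the gene over tumour samples (ties low).  Censoring is an
    independent exponential clock with rate ``base_hazard * censor_rate /
    (1 - censor_rate)``, giving roughly ``censor_rate`` censored records at
    the baseline hazard.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _CLINICAL_STREAM])
    )
    tumour = expr.samples_in_group(TUMOUR)
    if not tumour:
        raise ConsistencyError("no tumour samples to attach survival records to")
    log_h = np.full(len(tumour), np.log(config.base_hazard))
    lib = expr.counts.sum(axis=0).astype(float)
    for gene, beta in truth.surv_effects.items():
        if gene not in expr.counts.index:
            raise ConsistencyError(f"survival gene {gene!r} absent from expression")
        values = (expr.counts.loc[gene, tumour] / lib[tumour] * 1e6).astype(float)
        med = float(values.median())
        log_h += beta * (values > med).to_numpy(dtype=float)
    hazard = np.exp(log_h)
    event_time = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        c_rate = config.base_hazard * config.censor_rate / (1.0 - config.censor_rate)
        censor_time = rng.exponential(1.0 / c_rate, size=len(tumour))
    else:
        censor_time = np.full(len(tumour), np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return ClinicalTable(
        pd.DataFrame(
            {"sample_id": tumour, "time": time, "event": event}
        )
    )


def simulate_dataset(config: SimConfig):
    """Convenience wrapper: expression, annotation, interactions, clinical, truth."""
    rna, mir, annotation, truth = simulate_expression(config)
    interactions = simulate_interactions(config, truth)
    clinical = simulate_clinical(config, rna, truth)
    return rna, mir, annotation, interactions, clinical, truth
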