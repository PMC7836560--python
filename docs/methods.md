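# Methods

`cernet` implements a complete competing-endogenous-RNA (ceRNA) analysis for
bulk tumour/normal transcriptome cohorts, together with a seeded simulator
that plants the structures the analysis is supposed to find.  This note
records the models, the defaults and the design decisions, and what the
validation on synthetic data does and does not establish.

## Normalization

Between-sample scaling uses the trimmed mean of M-values (TMM).  The
reference sample is the one whose upper-quartile count fraction is closest to
the mean upper-quartile fraction.  For sample *s* against the reference *r*,
per-gene log-ratios M_g = log2((x_gs/N_s)/(x_gr/N_r)) and average abundances
A_g are formed over genes expressed in both samples; after trimming the top
and bottom 30% by M and 5% by A, the scaling factor is

    f_s = 2^( Σ w_g M_g / Σ w_g ),   w_g = inverse asymptotic binomial
                                          variance of M_g,

rescaled so the factors have geometric mean 1.  These trim fractions and the
reference rule are the method's standard defaults.  Factors agree with
Bioconductor edgeR to machine precision on test fixtures (a cross-check the
suite runs through `Rscript`).

logCPM uses a prior count (default 0.5) scaled proportionally to each
sample's effective library size, `log2((x + pc_s)/(L_s + 2 pc_s) * 1e6)`, so
zeros stay finite and the low-expression filter threshold keeps its meaning.
The filter drops a gene when its logCPM falls below 1.0 in **more than** half
the samples (a gene low in exactly half is kept); it is applied separately to
the gene and miRNA matrices.  Note the prior-count floor
(~`log2(pc·1e6/L)`) sits below the threshold only at realistic sequencing
depths; toy matrices with library sizes in the tens of thousands will not
have absent genes filtered.

## Differential expression

Gene-wise pooled variances s²_g (residual df d = n₁+n₂−2) are shrunk with
the standard empirical-Bayes hierarchical model: a scaled inverse chi-square
prior (d₀, s₀²) fitted by moment matching on log s² (digamma/trigamma
equations, Newton inversion of the trigamma), posterior variance
(d₀s₀² + d s²)/(d₀+d), and a moderated t referred to d₀+d degrees of
freedom.  d₀ = ∞ (complete shrinkage) is returned when the spread of log s²
does not exceed chi-square sampling noise; when every variance is exactly
equal — a degenerate input no sampling model produces — the prior location
is taken as that common value directly.  d₀ = 0 reproduces the ordinary
pooled t-test exactly.  The implementation matches Bioconductor limma
(`lmFit` + `eBayes`, trend disabled) to machine precision on fixtures.  No
observation-level precision weights are used: moderation is applied directly
to logCPM, the minimal faithful reading for a two-group design.

Significance calls use |log2 FC| > 1 (fold change > 2, both directions) and
p* < 0.01, where p* is the Benjamini–Hochberg adjusted p by default; a flag
switches to raw-p thresholding, since published analyses are often ambiguous
about which scale the threshold was applied on.

## ceRNA pair inference

For every candidate lncRNA × mRNA pair (candidates default to the
differentially expressed genes) three lines of evidence are computed:

1. **Shared-miRNA enrichment** — upper-tail hypergeometric probability
   P(X ≥ k) of sharing k of the miRNAs targeting each partner.  The miRNA
   universe N is the intersection of the interaction-table miRNAs, the
   measured (post-filter) miRNAs and, when the DE restriction is active, the
   DE miRNAs; target sets and the shared set are intersected with the same
   universe so k ≤ min(K, n) ≤ N holds by construction.  The smallest
   defensible population is used because the original universe choice is not
   recoverable; it is configurable.
2. **Co-expression** — Pearson correlation of the two partners with a
   two-sided t-transform p; the pair must correlate positively.
3. **Regulation similarity** — with per-shared-miRNA correlations c_i^lnc
   and c_i^m, the score (1/M) Σ [1 − |c_i^lnc − c_i^m|/(|c_i^lnc| +
   |c_i^m|)]^M ∈ [0, 1] (exponent configurable, default M; a position where
   both correlations are zero contributes 0).

Correlations are computed over **tumour samples only** by default (the
sample list is a parameter).  Pooling tumour and normal samples lets the
group mean shift alone manufacture positive correlation between any two
co-directionally regulated genes, which would swamp the within-cohort signal
the sponge hypothesis is about.

Default cutoffs — hypergeometric p < 0.05, correlation p < 0.05 with r > 0,
regulation similarity ≥ 0.5, at least one shared miRNA — are pipeline
choices, clearly labelled as such and configurable; passed pairs assemble
into a tripartite lncRNA–miRNA–mRNA graph (one `lnc_mir` and one `mir_mrna`
edge per shared miRNA, deduplicated across pairs, pair ids kept as edge
evidence).

## Survival screening

Per gene: patients split at the median expression (ties to the low group — a
fixed rule keeps runs reproducible), Kaplan–Meier product-limit curves per
group, the two-group log-rank test with the tied-event variance correction
d(n−d)/(n−1)·n_A n_B/n², and the Mantel–Haenszel hazard ratio
(O_high/E_high)/(O_low/E_low) formed from the log-rank tables.  The O/E form
needs no iterative fitting; it is mildly conservative (biased toward 1)
under long follow-up with large effects — a Cox fit is the alternative when
an unattenuated estimate matters.  Degenerate cases are flagged by value
(HR 0/∞, log-rank NaN when there are no events).

## Synthetic data

The generator emulates the cohort structure the analysis assumes, with all
randomness drawn from per-stage streams of one seed:

* **Counts.**  Negative binomial per gene (variance μ + φμ², φ log-uniform
  on [0.05, 0.2] by default), library sizes log-uniform on [2·10⁶, 10⁷]
  (so TMM is exercised non-trivially), per-sample relative abundances
  renormalized to sum to one — planted effects therefore also create
  composition bias, and realized fold changes are defined relative to the
  non-DE background.
* **Differential expression.**  A fraction (default 0.2) of genes receives a
  log2 fold change of random sign with magnitude |N(2, 0.5)|.
* **ceRNA triples.**  Each of the default 5 triples (1 lncRNA, 3 miRNAs,
  1 mRNA, disjoint members) shares a per-sample N(0,1) latent factor added
  to log2 means with loading +0.8 on the lncRNA and mRNA and −0.8 on the
  miRNAs — the simplest mechanism producing the signed correlation pattern
  the inference tests for.  Triple members are additionally planted as DE
  with coherent signs (lncRNA/mRNA up, miRNAs down) so they survive the
  DE-restricted candidate selection; because magnitudes are drawn from the
  same |N(2, 0.5)| distribution, an occasional member lands below the
  fold-change threshold and its pair is legitimately missed — recovery of
  planted pairs is therefore expected to be high but not perfect.
* **Interactions.**  All planted triple edges plus independent background
  edges at probability 0.005 per (miRNA, target) combination.
* **Survival.**  Tumour samples only.  Exponential event times with
  log-hazard = log(h₀) + Σ_g β_g·1[sample in the high CPM half of driver
  gene g], h₀ = log 2/600 per day (600-day baseline median survival),
  β = log 2 for the default single driver (the first triple's mRNA), and an
  independent exponential censoring clock calibrated to censor ~30% of
  records at baseline.  The analysis splits on TMM logCPM while the
  generator splits on raw CPM, so a few near-median patients differ between
  the two dichotomizations; the recovered hazard ratio is accordingly
  slightly attenuated — deliberate, since a real analyst's normalization
  never matches the data-generating split exactly.

What the generator does **not** emulate: gene-length effects, GC bias,
batch structure, correlated miRNA families, non-proportional hazards,
covariates, or the sample sizes and biology of a real tumour cohort.
Passing the validation therefore shows the pipeline recovers the structures
it targets under its own assumptions — not that those assumptions hold in
any particular dataset.

## Validation sizes and numerical choices

The test suite and `scripts/acceptance.py` use problem sizes chosen to make
Monte-Carlo answers stable at interactive run times: hypergeometric
enumeration over all N ≤ 12; null DE calibration with 2000 genes × (20+20)
samples × 20 replicates; prior recovery from 5000 gene variances; planted
ceRNA recovery on the default configuration (5 triples, strength 0.8, 50+50
samples); survival ranking over 100 replicates of a 200-patient, 20-gene
panel and a 200-replicate log-rank null.  Ties in the M/A trimming use
average ranks; −log10 of an adjusted p of zero is capped (default 320) and
flagged; single-cell cluster summaries transform by log2(x+1) before
computing means, medians and quartiles and never compute clusterings —
labels are consumed as input.
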