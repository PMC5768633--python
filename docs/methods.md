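# Methods

## Overview

`lhnet` re-implements, as a tested pipeline over synthetic data with planted
ground truth, a learned-helplessness transcriptomics analysis: mice exposed to
inescapable stress are phenotyped as learned-helpless (LH) or resilient (NLH)
from shuttle-box readouts; bulk hippocampal FPKM profiles of four groups (LH,
NLH, shock-free controls Ctrl, and unhandled homecage mice HC) are compared to
isolate helplessness-specific mRNA and lncRNA transcripts; those feed a
lncRNA–mRNA co-expression network with cis/trans classification, Fisher-exact
functional enrichment, lncRNA–bioprocess networks, and 2^−ΔΔCt qPCR
validation.

The pipeline starts from an FPKM matrix; read alignment, transcript assembly
and quantification are out of scope, as are live queries to GO/annotation web
services (enrichment runs offline over user-supplied GMT gene sets) and
network rendering (Cytoscape-readable SIF/GraphML/TSV files are exported
instead).

## Behavioral phenotyping

Stressed mice are split in the (escape failures, mean escape latency) plane by
k-means with k = 2 on raw units — failures in [0, 30] over 30 trials, latency
in [0, 10] s (a failed trial contributes the 10 s cap). No feature scaling is
applied: the published discriminant coefficients act on raw counts and raw
seconds, and consistency with them drives the choice. Initialisation is 50
random restarts, best inertia kept; the cluster with the larger mean failure
count is named LH.

A Fisher linear discriminant with shared (pooled) within-class covariance and
empirical class priors is then fitted to the cluster labels, yielding one
linear score per class,

    score_c(F, L) = intercept_c + coef_F,c · F + coef_L,c · L ,

the same shape as the published equations. The frozen published instance is

    LH  = −24.75 + 0.23·F + 4.79·L
    NLH = −15.34 − 2.78·F + 10.31·L

so the plane is partitioned by 3.01·F − 5.52·L = 9.41. A mouse is called LH
when score_LH > score_NLH; exact ties go to NLH so helplessness is never
over-called. The per-class scores are computed in-package (pooled covariance
plus priors) because the binary scikit-learn LDA exposes only the single
decision function; scikit-learn predictions serve as an independent
cross-check in the tests. Group descriptives use one-way ANOVA with Bonferroni
pairwise post hoc tests (raw p times the number of comparisons, capped at 1).

## Differential expression and exclusion logic

Per comparison (LH vs Ctrl, LH vs NLH, Ctrl vs HC, Ctrl vs NLH) each
transcript gets a pooled-variance Student's t-test (df = n₁ + n₂ − 2),
two-sided, significant at p < 0.05 with no fold-change cutoff and no
multiple-testing correction — matching the stated analysis. Raw FPKM enters
the test by default; `log_transform` switches to log2(FPKM + 1) as common
practice. Zero-variance features with equal means are reported non-significant
(t = 0, p = 1) to keep the pipeline total; zero variance with unequal means is
flagged degenerate (p = 0).

Transcripts significant in Ctrl vs HC (handling/context effects) or
Ctrl vs NLH (resilience effects) are removed from the two LH comparisons:

    LHvsCtrl_specific = LHvsCtrl \ (CtrlvsHC ∪ CtrlvsNLH)
    LHvsNLH_specific  = LHvsNLH  \ (CtrlvsHC ∪ CtrlvsNLH)

Biotype tallies split each specific set by direction; the lncRNA subclasses
(lincRNA, antisense, sense intronic/overlapping, bidirectional-promoter
lncRNA, processed transcript) are additionally aggregated into one lncRNA row.

The QC step of the original analysis (190,451 → 80,137 transcripts) is never
specified at the source; the filter here (keep features with FPKM ≥ 0.1 in ≥ 1
sample, both thresholds configurable) is an explicit stand-in.

## Co-expression network

Transcript FPKM is collapsed to gene level by the unweighted arithmetic mean
over a gene's transcripts. For every (DE lncRNA gene, DE mRNA gene) pair a
Pearson correlation is computed over the comparison's samples (n = 8 by
default; which samples entered the original correlations is unstated, so
`correlation_scope: all` offers the 16-sample alternative). p values use the
t transform t = r·√((n−2)/(1−r²)) with df = n − 2. Edges require r² ≥ 0.9
(inclusive) and p < 0.01; positive and negative correlations are both kept.
At n = 8 the p threshold is implied by the r² threshold (|r| ≥ 0.9487 ⇒
p ≈ 3×10⁻⁴), which the acceptance suite asserts.

Genomic coordinates are 1-based inclusive as supplied by GTF. Edge locality is
*cis* when both genes share a chromosome and the gap between their closest
span boundaries (0 for overlapping spans) is ≤ 1,000,000 bp — the "within
1000 kb upstream or downstream" rule read as a strand-ignored symmetric,
inclusive window — otherwise *trans*; across chromosomes the distance is
undefined and the edge is trans. Gene biotype is the modal transcript biotype,
ties broken toward protein_coding. Zero-variance genes yield no candidates
(logged) rather than aborting a run.

On the real data the original analysis found all co-expressed mRNAs to be
potentially trans; that is an empirical outcome, not an invariant, and is not
asserted here (the generator deliberately plants both cis and trans pairs).

## Functional enrichment and lncRNA–function networks

Enrichment is the one-sided (greater) Fisher exact test on the 2×2 table
(k, n−k, K−k, N−K−n+k), i.e. the hypergeometric upper tail, per term of a flat
GMT collection; terms with fewer than 3 background members are skipped, and no
GO-hierarchy propagation is attempted. The background defaults to the
expressed universe (all genes surviving QC) rather than the whole organism —
statistically defensible and configurable. GO-level significance is p < 0.05;
pathway-level comparisons between the two LH comparisons use the stricter
p < 0.01 and partition terms into common / one-sided buckets.

For the lncRNA–bioprocess network, each network lncRNA's co-expressed mRNA
partner set is enrichment-tested; an edge to a term requires p < 0.05 with at
least 2 supporting partner genes (singleton links are suppressed). Whether the
original linking was per-lncRNA enrichment or intersection with the global
enriched list is unstated; per-lncRNA enrichment is implemented. The theme
summary reports the fraction of network lncRNAs linked to ≥ 1 term of a theme
set (e.g. synapse-related terms) and the number of distinct theme terms hit.

## qPCR quantification

Per sample, the target Ct (mean of up to three replicates) is normalised to a
reference housekeeping gene (ΔCt), then to the *mean* ΔCt of the control group
(ΔΔCt) — matching percent-of-the-average-control reporting — and expressed as
2^−ΔΔCt × 100%. Amplification efficiency is fixed at the ΔΔCt assumption of
2.0 per cycle; no efficiency or melt-curve analysis is attempted. Validation
is the two-tailed unpaired pooled-variance t-test on percent-of-control.

## Synthetic data generator

The generator defines the study conditions; every generator is a pure function
of configuration + seed.

* **Design**: 4 groups × 4 samples (`n_per_group=4`), 2000 transcripts by
  default, ~15% lncRNA genes.
* **Baselines**: log-normal FPKM (meanlog 1, sdlog 1.5) — heavy-tailed and
  positive; no distribution is stated at the source. Additive Gaussian FPKM
  noise (sd 0.5) clipped at zero, since FPKM is non-negative.
* **Differential expression**: multiplicative group shifts of 2^±3 (8-fold)
  planted in three classes — helplessness (LH group only; DE in both LH
  comparisons), handling (LH, NLH and Ctrl equally, so DE only vs HC) and
  resilience (NLH only; excluded from the LH sets by the Ctrl-vs-NLH
  comparison). 65% of planted effects are down-shifts, mirroring the
  predominant downregulation in this system. Planted features draw their
  baselines from the log-normal conditioned on FPKM ≥ 1 — effects are planted
  on expressed transcripts, where an 8-fold shift is detectable at n = 4; null
  features keep the unconditioned baseline.
* **Co-expression pairs**: each lncRNA–mRNA pair shares a per-sample latent
  factor in a multiplicative model, x = μx(1 + c·f + d·ε), with c, d chosen at
  fixed total CV 0.25 so the within-group population Pearson correlation
  equals `pair_r` (0.98 by default); with noise off, d = 0 and pairs are
  exactly proportional. Alternating pairs are placed within 1 Mb on one
  chromosome (cis truth) or on different chromosomes (trans truth). Pair
  members also carry an LH shift by default (`pairs_are_de`) so they survive
  the DE gate feeding the network; `pairs_are_de=False` isolates pure
  correlation recovery. At ρ = 0.98 and n = 8 the exact probability that a
  sample r² reaches 0.9 is ≈ 0.91, which bounds attainable edge sensitivity.
* **Behavior**: two bivariate Gaussian clusters with diagonal covariance —
  LH at (25 failures, 8 s), NLH at (5, 3), sds (3, 1) — matching roughly
  elliptical clouds separated by several pooled sds; Ctrl mice are drawn from
  the resilient cluster. Failures are rounded and clipped to [0, 30],
  latencies clipped to [0, 10] s, per the 30-trial / 10-s-cap protocol.
* **qPCR**: per-gene base Ct in 22–28 cycles, reference at 20; the target
  group's Ct drops by log2(fold). With noise, replicate noise plus a shared
  per-sample loading offset (which cancels under reference normalisation) are
  added; with zero noise the ΔΔCt computation inverts the planting to machine
  precision.
* **Gene sets**: ~40 terms of 10–40 protein-coding genes; 5 terms draw 80% of
  members from planted helplessness-DE genes, giving the enrichment stage
  guaranteed positives that double as the "theme" set.

What the generator does **not** emulate: read-count noise models
(negative-binomial mean–variance coupling), transcript-length effects,
between-sample normalisation artefacts, correlated co-regulation beyond the
planted pairs, or the real count distributions of the deposited dataset.
Passing recovery tests therefore demonstrates correctness of the statistical
machinery under its stated model, not performance on real RNA-seq data.

## Numerical and reporting choices

* Exact ties at thresholds: r² ≥ 0.9 is inclusive; p < α is strict everywhere.
* Degenerate inputs are reported, not dropped silently: zero-variance DE
  features (non-significant or flagged), zero-variance correlation genes
  (skipped with a log line), empty function networks (fraction 0 with a
  degenerate flag), 0/0 percentages (0 with a flag).
* Stage artifacts are always written to disk before the next stage runs, so
  every report number can be re-derived from files; runs are deterministic
  given config + seed.
* Problem sizes in the analysis scripts and acceptance measurements (2000
  transcripts, 100 behavioral seeds, 3000 pairs for the sensitivity estimate)
  are chosen so each script completes in seconds while keeping Monte-Carlo
  error well below the margins being asserted.

## Known source-data discrepancies

The published count tables contain two internal inconsistencies that the
consistency checker surfaces rather than reconciles: (i) the LH-vs-Ctrl
up-regulated total prints 1337 while its own per-biotype column sums to 1377
(and 2550 + 1377 = 3927 matches both the printed total and the abstract) — the
checker reports this identity as failed; (ii) the running text gives 2162
LH-vs-Ctrl protein-coding mRNAs where the table prints 2163, and the abstract's
340 lncRNAs sits next to per-comparison counts summing to 341 — de-duplication
across comparisons is unstated, so per-comparison and summed counts are both
reported explicitly.

## Limitations

* Student's (pooled-variance) t-tests on n = 4 FPKM samples have limited power
  and assume within-group normality; the choice mirrors the stated method, not
  best current practice (count-based models are a non-goal).
* Co-expression edges are marginal Pearson correlations: no partial
  correlation, soft thresholding or module detection, and no causal claims.
* Enrichment treats GO terms as flat, independent sets with no
  multiple-testing correction across terms, again mirroring the stated method.
* The discriminant refit will not reproduce the frozen published coefficients
  from synthetic data — the published per-animal table is not available — so
  the frozen model is kept as a constant and tested for its printed geometry.
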