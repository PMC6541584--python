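# Methods

`telodiff` implements a two-group transcriptome comparison of the kind used
to contrast blastocysts from women of advanced maternal age against young
donor controls: expression filtering, differential testing with FDR control,
a positional analysis asking whether differentially expressed (DE) genes
cluster near chromosome ends, and qPCR validation statistics. This note
records the model, the tunable parameters, the numerical choices, and what
the synthetic-data generator does and does not emulate.

## Differential expression

Input is a transcripts × samples matrix of non-negative, RPKM-like
continuous expression values with a case/control design (at least two
samples per group). Three filters run in a fixed order:

1. transcripts with all values exactly zero are removed;
2. among the remainder, the bottom quintile by mean expression across all
   samples is removed — exactly ⌊0.2 n⌋ transcripts, ties broken by stable
   input order (the rule has to be deterministic; input order is the only
   convention that is reproducible across runs);
3. transcripts with mean expression below `mean_threshold` (default 0.05,
   on the RPKM-like scale) are removed.

Fewer than five survivors is an error: a quintile on a handful of rows is
not meaningful.

Values are transformed to `log2(x + pseudocount)` with pseudocount 1.0 by
default. The base and offset are conventions, not data-driven choices: base
2 makes the per-transcript effect a log2 fold change, and the unit
pseudocount bounds the influence of zeros while leaving large values
essentially unchanged. Both are exposed as parameters.

Each transcript is tested with a pooled-variance, two-sided, independent
two-sample Student's t (df = n1 + n2 − 2); Welch's form is available behind
a flag for unequal-variance designs. Degenerate rows with zero pooled
variance get p = 1 when the group means agree and p = 0 with a `degenerate`
flag when they do not — visible rather than silently dropped. Raw p-values
are adjusted with the Benjamini–Hochberg step-up rule
(q(i) = min_{j≥i} p_(j)·m/j, clipped at 1); a transcript is significant when
q < α (strict), α = 0.05 by default. The reported `log2_ratio` is the
difference of group means of the log-transformed values (case − control),
consistent with the scale the test runs on, rather than the log of the
ratio of raw means.

Two optional, off-by-default QC rules approximate outlier screening:
samples farther than 5 MADs from the centroid on PC1/PC2 can be dropped
(never below two per group), and transcripts capturing more than 5% of any
sample's total signal can be removed as normalization artifacts. Both are
disclosed, explicit rules with configurable thresholds.

## Positional enrichment

For each chromosome with at least one significant transcript, the density
of DE gene start positions is estimated with a Gaussian kernel evaluated on
512 equally spaced points over [0, L]:

    f(g) = (1 / (n h)) Σ_i φ((g − x_i) / h)

No boundary correction is applied. The bandwidth h is anchored on a
reference chromosome (chr20 when present, else the shortest) at
`ref_bandwidth_bp` (default 2 Mb) and scaled linearly with chromosome
length. 2 Mb resolves structure at the scale of a 10 Mb sub-telomeric
window while smoothing over gene-level granularity; conclusions that are
sensitive to the exact bandwidth should be treated as qualitative, and the
parameter is exposed.

The null model redraws, `n_replicates` times (default 1000), the same
number of gene start sites uniformly at random without replacement from the
full analyzed universe — all filter-surviving, annotated transcripts,
genome-wide, with no per-chromosome stratification — and keeps those
landing on the chromosome under study. The pointwise 2.5th/97.5th
percentiles of the replicate densities form a 95% envelope. Because the
envelope is computed under the identical estimator, the kernel's boundary
mass leakage cancels between observed and null. Replicates that land zero
transcripts on a chromosome contribute an all-zero density.

The genome-wide draw restricted to one chromosome is realised through its
exact marginal law: the on-chromosome count is Hypergeometric(N, N_c,
n_select) and the retained members are a uniform without-replacement subset
of the chromosome's transcripts. This is distributionally identical to
materialising the genome-wide draw and restricting, and avoids doing so
once per chromosome.

A transcript is *telomeric* when its gene start lies within
`telomere_window_bp` (default 10 Mb) of either chromosome end, boundary
inclusive. A chromosome is flagged as sub-telomerically enriched when both
of the following hold: its telomeric fraction of DE transcripts exceeds
`telomere_flag_fraction` (default 0.30), and the observed density exceeds
the upper envelope at one or more grid points inside a telomeric window.
The conjunction prevents either a high fraction from sparse counts or an
isolated envelope excursion from flagging on its own. An optional
per-chromosome binomial test of the telomeric count against the expected
fraction min(2w/L, 1), BH-adjusted, is provided as a clearly labelled
surrogate; it is not part of the flagging rule.

## qPCR validation

Replicate wells are averaged per (sample, gene); the relative expression of
a target gene against a reference gene is

    ratio = E_target^ΔCq_target / E_ref^ΔCq_ref,
    ΔCq = meanCq_control − meanCq_case

with per-gene amplification efficiency E ∈ (1, 2], defaulting to 2.0
(perfect doubling) when no standard curve is supplied. Group-mean ΔCq is
used; per-sample ratios are not formed. The reference defaults to the
housekeeping candidate with the smallest standard deviation of
replicate-averaged Cq across samples (ties by input order).

Significance uses a pairwise fixed reallocation randomisation test on
|log2 ratio| (two-sided by construction): sample group labels are
reallocated, preserving group sizes, and the statistic recomputed. When the
number of distinct reallocations C(n, n_case) is at most `n_perm`, all are
enumerated and p = #{|log2 r*| ≥ |log2 r|} / N — the identity reallocation
is included, so p is never zero; for a noiseless 6 vs 6 design the smallest
attainable p is 2/924, because the statistic is invariant to swapping the
two groups. Otherwise `n_perm` (default 10,000) random reallocations are
drawn and p = (1 + #{≥}) / (1 + n_perm), the standard finite-sample
correction. Comparisons against the observed statistic use a 1e-12
tolerance so that exact ties (the identity and its complement) count as
ties under floating-point arithmetic.

## Sample-level summaries

PCA runs on the full filtered, log-transformed matrix with transcript means
removed; signs are fixed by making each component's largest-magnitude
loading positive so the embedding is deterministic. Hierarchical clustering
is intended for the significant-transcript submatrix and uses
1 − Pearson correlation between sample profiles with average linkage; a
zero-variance sample profile is a hard error naming the sample. The
two-cluster cut is reported against the design labels. The volcano table
classifies transcripts as down/up (significant, by sign) or ns.

## Synthetic data

The generator emulates the study design the pipeline targets: ~25,000
transcripts over the GRCh38 autosomes + X, 6 case and 6 control samples
(optionally dropping one control, as happens when a sample fails QC), a
fraction `frac_de` (default 0.08) of transcripts truly differential with
`frac_down_among_de` (default 0.95) down-regulated in the case group, and a
sub-telomeric excess of differential gene starts. The defaults reproduce
the headline structure: roughly 10% of filter-surviving transcripts
significant, ~95% of them down, and ~28% of differential gene starts within
10 Mb of a chromosome end.

The noise model is log-normal — Gaussian with sd `noise_sd_log2` (default
0.5) on the log2 scale around a per-transcript baseline drawn uniformly
from `baseline_logmean_range` (default (−2, 6), i.e. ~0.25–64 on the
expression scale), exponentiated back. A count model (negative binomial) is
deliberately not used: the analysis operates on continuous RPKM-like values
and tests on the log scale, so a log-normal generator matches the model the
test assumes. Case-group means of differential transcripts are shifted by
±`effect_size_log2` (default 1.5). Differential transcripts draw their
baselines from the upper 70% of the baseline range so that the
bottom-quintile filter cannot silently delete planted truth; without this
the ground-truth recall properties would be unattainable by construction.
Separate fractions of transcripts (5% + 5% by default) are set all-zero and
near-zero (mean < 0.05) so every filter stage has work to do.

Positions are assigned per transcript: chromosome with probability
proportional to length, start uniform on [0, L). Differential transcripts
draw from a two-component mixture — uniform genome-wide versus uniform
within the two telomeric windows — with the weight set so the probability
of landing in a window is min(`telomere_enrichment` × f, 1), where f is the
windows' length fraction of the chromosome. This parameterisation is
invertible, which is what makes planted-effect recovery checkable. The
default multiplier 1.9 applied genome-wide puts ~28% of differential starts
in sub-telomeric windows; `enriched_chroms` restricts the excess to a
designated subset for experiments that plant enrichment on specific
chromosomes.

The qPCR generator plants a per-gene log2 ratio by shifting the case
group's mean Cq by −ratio/log2(E) cycles around a uniform per-gene baseline
(18–28 cycles), with duplicate wells and Gaussian Cq noise, so the
downstream ratio estimator recovers the planted fold change exactly in the
noiseless case.

What the generator does not emulate: sequencing-depth or gene-length
effects, count noise at low expression, correlated transcripts
(co-regulation), batch effects, sample-quality gradients, chromosome-level
covariates such as gene-density variation, or qPCR efficiency drift.
Passing tests therefore demonstrate the statistical machinery is correct
and calibrated under the stated model, not that real blastocyst data meet
that model's assumptions.

All generator randomness flows through one seeded NumPy generator per call,
with fixed sub-stream keys for the truth designation, annotation,
expression and qPCR stages, so identical config + seed reproduces outputs
byte-for-byte while the stages stay independently reproducible.

## Problem sizes used in the checks

The test suite exercises the stochastic claims at reduced scale chosen for
statistical adequacy: envelope self-coverage uses 50 trials × 1000
replicates on a two-chromosome toy genome (64 grid points); planted
sub-telomeric recovery uses 50 runs of a six-chromosome genome with 2500
transcripts, enrichment planted on three chromosomes; null FDR calibration
uses 20 seeds of 2000 transcripts. The acceptance script runs the full
~25,000-transcript, 23-chromosome configuration with 1000 envelope
replicates and 512 grid points per chromosome.

## Known limitations

- The reference bandwidth has no data-driven default; per-chromosome
  results are sensitive to it near the window scale.
- The envelope is pointwise, not simultaneous: with ~512 grid points per
  chromosome some excursions are expected under the null, which is why the
  flagging rule requires the telomeric-fraction condition as well.
- The quintile filter uses mean expression only; a dispersion-aware filter
  would behave differently at low expression.
- Group-mean ΔCq ignores per-sample pairing information; designs with
  paired samples would warrant a paired statistic.
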