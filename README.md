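# telodiff

Differential expression with sub-telomeric positional enrichment analysis
for two-group transcriptome studies.

`telodiff` targets the analysis of bulk, RPKM-like expression matrices from
small two-group designs — the motivating setting is comparing human
blastocysts from women of advanced maternal age (case) against young donor
controls — where two questions matter: *is there a global shift in
transcription between the groups?* and *do the differentially expressed
genes cluster near chromosome ends, where telomere attrition is expected to
act?* It is written for bioinformaticians who have a quantified expression
matrix in hand and want a tested, seeded, fully reproducible pipeline for
the downstream statistics.

## What it computes

**Differential expression.** After a three-stage filter (all-zero
transcripts; the bottom quintile by mean expression; means below 0.05), the
values x are transformed to log2(x + 1) and each transcript is tested with
a pooled-variance two-sample Student's t:

    t = (x̄_case − x̄_ctrl) / (s_p √(1/n₁ + 1/n₂)),   df = n₁ + n₂ − 2

with Benjamini–Hochberg adjustment q(i) = min_{j≥i} p₍ⱼ₎·m/j and
significance at q < 0.05.

**Positional enrichment.** Per chromosome, the density of significant gene
start sites is estimated with a Gaussian kernel f(g) = (nh)⁻¹ Σᵢ φ((g−xᵢ)/h)
on a 512-point grid, with bandwidth anchored on a reference chromosome and
scaled linearly with length. A null envelope comes from redrawing the same
number of gene starts at random from all analyzed transcripts 1000 times
and taking pointwise 2.5th/97.5th percentiles. A chromosome is flagged when
>30% of its significant transcripts lie within 10 Mb of an end *and* the
observed density exceeds the upper envelope inside such a window.

**qPCR validation.** Efficiency-corrected relative expression
E_target^ΔCq_target / E_ref^ΔCq_ref against the most stable housekeeping
gene, with a fixed-reallocation randomisation test on |log2 ratio|
(exhaustive when the design is small enough).

**Synthetic data.** A seeded generator plants known differential
transcripts (with a configurable down-regulated fraction) and a
sub-telomeric excess of their gene starts, so every stage can be tested
against ground truth.

## Worked example

```python
from telodiff import (SimulationConfig, simulate_annotation, simulate_expression,
                      filter_transcripts, log_transform, run_de, KdeConfig,
                      positional_analysis)

cfg = SimulationConfig(n_transcripts=5000, seed=1)
ann = simulate_annotation(cfg)
matrix, truth = simulate_expression(cfg, ann)

filtered, report = filter_transcripts(matrix)
table, summary = run_de(log_transform(filtered))
print("retained:", report.n_retained, "of", report.n_input)
print("significant:", summary.n_significant,
      f"({100*summary.n_significant/summary.n_analyzed:.1f}% of analyzed)")
print(f"down among significant: {100*summary.frac_down_significant:.1f}%")

de_ids = list(table.index[table["significant"]])
envelopes, stats = positional_analysis(
    de_ids, list(table.index), ann, KdeConfig(n_replicates=1000, seed=1))
print(f"telomeric fraction: {100*stats.overall_fraction_telomeric:.1f}%")
print("flagged chromosomes:", sorted(stats.flagged_chroms))
```

prints

```
retained: 3800 of 5000
significant: 375 (9.9% of analyzed)
down among significant: 93.3%
telomeric fraction: 31.2%
flagged chromosomes: ['chr13', 'chr14', 'chr17', 'chr22', 'chr5', 'chr9', 'chrX']
```

The generator planted 8% of transcripts as differential, 95% of them
down-regulated, with a 1.9× sub-telomeric excess applied genome-wide: the
pipeline recovers ~10% significant, ~93% down (false discoveries dilute the
planted 95% slightly), and ~31% of significant gene starts within 10 Mb of
a chromosome end; the flagged set is the chromosomes where that excess
crossed both the fraction and envelope criteria at this seed. On a real
dataset, replace the simulated inputs with your matrix/design TSVs and
BED + chrom.sizes annotation.

The same pipeline is available from the shell:

```sh
telodiff simulate --out demo --seed 1
telodiff de --matrix demo/matrix.tsv --design demo/design.tsv --out demo/run
telodiff enrich --de-table demo/run.de.tsv --bed demo/annotation.bed \
    --sizes demo/chrom.sizes --out demo/enrich --seed 1
telodiff run --config pipeline.yaml --seed 1   # everything end to end
```

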