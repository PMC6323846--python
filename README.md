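# gselexmine

Genomic SELEX-Seq simulation and regulon mining for a DNA-binding
transcription factor, with a 1:1 binding-kinetics module for
biolayer-interferometry (BLI) sensorgrams.

## What problem this addresses

Genomic SELEX (gSELEX) enriches, round by round, the fragments of a
genomic library that bind a protein of interest; sequencing the selected
pools and mapping the reads back to the genome reveals the protein's in
vitro binding sites. Combined with differential-expression data from
strains that overproduce or lack the factor, the intersection separates
directly regulated genes from indirect targets. This package implements
that whole analysis as a reusable, tested pipeline, exercised end-to-end
on synthetic data that emulates the real inputs — a small multi-contig
genome with annotated start codons, 1000-bp upstream promoters carrying
planted binding sites, a ~100-bp linker-flanked fragment library,
affinity-weighted selection rounds, paired-end reads, and an expression
table whose log-ratios depend on promoter motif content.

The motif vocabulary is that of the fungal Zn(II)₂Cys₆ regulator of
xylanolytic/cellulolytic genes: the canonical hexamers 5′-GGCTAA-3′,
5′-GGCTGA-3′ and 5′-GGCTAG-3′, the degenerate monomer site
5′-CGGNTAAW-3′ and the dimer site 5′-TTAGSCTAA-3′.

## The models at the core

**Selection.** Each fragment gets a binding weight
*w* = *b* + Σₘ *wₘ·nₘ*, with *nₘ* the number of occurrences of motif
*m* on either strand. Round *k* draws *N* fragments multinomially with
probability ∝ (round *k−1* abundance) × *w*. The pool's mean weight,
normalized to round 0 = 1, is the enrichment curve.

**Peaks.** Trimmed, mapped fragment tags are tested in 50-bp sliding
windows against a Poisson local λ (scaled round-0 control, uniform
expectation, pseudocount — whichever is largest); significant windows
merge into peaks, the summit is the position of maximal coverage, and
fold enrichment FE compares per-million-scaled coverage at the summit.
50-bp summit windows are matched against the upstream-1000 promoter set
to name candidate regulated genes.

**Mining.** Differentially expressed genes (ratio > 5) intersect the
candidate set (Venn); Fisher's exact test compares canonical-motif
presence between intersection and non-intersection DEGs; Spearman and
Pearson correlations relate motif counts, motif-coexistence flags, FE
and summit position to the expression ratio.

**Kinetics.** Association
*R(t) = R_eq(1 − e^−(k_a·C+k_d)t)*, *R_eq = R_max·C/(C+K_D)*;
dissociation *R(t) = R(t_a)·e^−k_d·t*; a global least-squares fit
shares (*k_a*, *k_d*, *R_max*) across analyte concentrations and
reports *K_D = k_d/k_a* in nM.

## Worked example

```python
from gselexmine import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(), seed=1)
print("peaks:", report.n_peaks)
print("planted-promoter recall:", report.planted_recall)
print("enrichment curve:", [round(v, 2) for v in report.enrichment_curve])
print("top k-mer:", report.top_kmers[0])
```

prints

```
peaks: 31
planted-promoter recall: 1.0
enrichment curve: [1.0, 5.82, 7.79, 8.73]
top k-mer: ('GGCTAA', 3.7053872604435583)
```

i.e. on a 20-gene genome with 5 promoters carrying planted high-affinity
sites, three selection rounds raise the pool's mean binding weight
8.7-fold, the peak caller finds 31 enriched loci, every planted promoter
is recovered in the candidate list, and the top-ranked 6-mer in the
summit windows is the factor's major binding site GGCTAA.

The same pipeline is available from the shell:

```sh
gselexmine pipeline --seed 1 --out-dir out/       # all artifacts + report.json
gselexmine simulate --n-genes 20 --out-dir sim/   # genome/expression/library only
gselexmine kinetics simulate --noise-sd 0.01 --csv bli.csv
gselexmine kinetics fit --csv bli.csv
```

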