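# Methods

This note documents the models, parameter choices, numerical details and
known limitations of the package. All empirical statements below are
computed by the test suite or by `scripts/acceptance.py`.

## Synthetic study inputs

The generator produces every input the pipeline consumes, with explicit
ground truth, so that recovery can be measured.

- **Genome.** Background sequence is i.i.d. over ACGT (GC content
  configurable; no repeat structure or composition heterogeneity).
  Genes are laid out in disjoint blocks of `promoter_spacing` bp
  (default 2000) so each start codon owns a full 1000-bp upstream
  region; strand is random per gene. Default scale: 20 genes on two
  25-kb contigs.
- **Planted sites.** A plant plan maps genes to (motif, promoter
  position, strand) triples; IUPAC degeneracies are resolved uniformly
  at random and the realized sequence is recorded. Promoter coordinates
  are 1-based promoter-forward with position 1000 adjacent to the start
  codon. Overlapping plants are an error. Because the background is
  random, promoters also carry chance motif occurrences (≈0.49 expected
  both-strand occurrences of a given hexamer per kilobase); all
  downstream statistics see the scanned counts, planted plus chance,
  exactly as a scanner would on real data.
- **Expression.** `ln r = β₀ + β_AA·n_AA + β_GA·n_GA + β_AG·n_AG +
  β_coex·1[n_AA>0 ∧ n_GA>0] + ε`, `ε ~ N(0, σ²)`, reported as the
  linear ratio `r` (overproducer/disruptant). Defaults
  `β₀=0, β_AA=β_GA=0.3, β_AG=0.1, β_coex=1.0, σ=0.5` are synthetic
  choices, not measured values: they were selected so that the
  coexistence of the two major sites is the dominant correlate of
  expression, the qualitative structure the mining stage is designed to
  detect. With equal per-site and coexistence effects of comparable
  size the *total* site count tends to out-correlate the coexistence
  flag, which defeats the purpose of the recovery study; a coexistence
  effect about 3× the per-site effect makes the intended ordering the
  outcome in ~98% of seeds at n=72.
- **Fragment library.** Start positions uniform over the genome,
  lengths Normal(100, 15) truncated to [30, 300] and rounded, strand
  uniform, linkers ligated on both sides (the two adapter sequences
  used for trimming are their read-orientation counterparts).

All randomness flows from one top-level seed through named per-stage
substreams, so consuming more randomness in one stage never perturbs
another; identical seeds give byte-identical artifacts.

## Selection model

Binding weight is linear in motif content:
`w = b + Σ_m w_m · n_m(fragment)`, counts on both strands. Defaults
`b=1, w_GGCTAA=50, w_GGCTGA=25, w_GGCTAG=10, w_CGGNTAAW=25,
w_TTAGSCTAA=0` are invented magnitudes; only the ordering
GGCTAA > GGCTGA is anchored in the factor's measured preference. There
is no saturation (no occupancy model) and no PCR or GC bias. Bench
selection and re-amplification are collapsed into a single multinomial
draw of `pool_size` fragments per round with probability ∝ abundance ×
weight — the simplest model preserving proportionality to binding
weight. Three rounds and a pool of 5·10⁴ are the default study
conditions.

A statistical caveat uncovered while testing: because each round is an
independent multinomial resample, counts after three *neutral* rounds
have ≈3× the variance of a single multinomial, so a χ² goodness-of-fit
test of round 3 against round 0 rejects even though selection is
neutral. Neutrality is therefore asserted exactly where it is exact —
a single round is goodness-of-fit-indistinguishable from its input, and
the enrichment curve equals 1 in expectation at every round.

Reads: pairs are sampled ∝ abundance; read 1 is the 5′ prefix of
linker5+insert+linker3, read 2 the prefix of its reverse complement;
substitutions are uniform per base (default 0.001), qualities flat.
Reads are emitted untrimmed so the trimming stage is genuinely
exercised.

## Tag processing

- **Trimming.** Exact-overlap adapter removal: a 5′ adapter whose
  suffix of ≥15 bases equals the read prefix is cut (longest overlap
  wins), 3′ adapters symmetrically; reads under 20 nt after trimming
  are discarded.
- **Mapping.** Seed-and-verify on a 20-mer index; a read is kept only
  at a unique best hit with ≤ `max_mismatches` (default 0)
  substitutions; concordant mates (same contig, opposite strands,
  ≤1 kb apart) merge into one fragment interval.
- **Peak calling.** Sliding 50-bp windows at 10-bp steps; the selected
  count is tested against λ = max(library-size-scaled control count,
  genome-wide uniform expectation, pseudocount 0.5) with the Poisson
  upper tail at p < 10⁻⁵; windows within 50 bp merge; the summit is the
  leftmost maximum of per-base selected coverage; FE =
  (per-million selected coverage + 0.5)/(per-million control coverage
  + 0.5) at the summit; peaks rank by descending FE. The round-0 pool
  serves as control — it is the natural input background. Window
  counts use **distinct** fragment intervals: selection and resampling
  duplicate identical molecules, and duplicate-kept counts are
  overdispersed relative to the Poisson model, producing spurious
  single-stack peaks under a neutral model. Coverage, summit choice
  and FE still use every tag, so abundance-driven enrichment is fully
  retained. This mirrors the default duplicate handling of standard
  callers.
- **Summit windows.** `[summit − flank_left, summit + flank_right + 1)`
  with defaults (24, 25) giving 50 bp; a (24, 24) 49-bp variant is
  supported (conventions differ on whether the summit base counts
  toward a flank). Windows clipped at contig ends are flagged.

## Promoter annotation

The upstream-1000 set takes, for a + strand gene with start codon at
`s`, `genome[s−1000, s)` as-is; for a − strand gene, the reverse
complement of `genome[s+1, s+1001)`; truncated at contig ends with the
length recorded. Promoters may overlap neighboring coding sequence; no
masking. Windows are assigned to promoters by best full-overlap
ungapped matching in both orientations with thresholds match length
≥30 bp and identity ≥0.9 — deliberately permissive stand-ins for a
local-alignment annotation step (a 12-mer exact-seed prefilter skips
hopeless pairs). A window may hit several promoters (divergent gene
pairs); all hits are reported, and for mining the hit with the largest
FE is kept per gene. Summit positions convert to promoter-forward
coordinates (1000 = adjacent to the codon) and round-trip exactly on
both strands.

## Motif statistics and k-mer ranking

Scanning supports IUPAC codes A/C/G/T/N/W/S, reports overlapping
occurrences, and counts both strands by default (neither the strand nor
the overlap policy is uniquely conventional; both are configurable).
Coexistence flags are conjunctions of count positivity.

De novo motif discovery is replaced by a defined, deterministic k-mer
over-representation ranking: each k-mer merges with its reverse
complement into a canonical class and scores
`log2((fg+pc)/(fg_tot+pc·4^k)) − log2((bg+pc)/(bg_tot+pc·4^k))` with
pc = 0.5, ranked descending (ties break lexicographically). The
foreground is the top-100 summit windows, the background round-0
fragment sequences. Position-weight-matrix EM is out of scope. Note
the pseudocount mass `pc·4^k` dominates small samples; null-score
bounds (no k-mer above |score| = 1) hold once per-class counts are of
order 50+, which sets the sample sizes used in the null test.

## Integration statistics

- DEGs: ratio strictly greater than 5 ("more than five-fold").
- Venn: candidates-only / DEGs-only / intersection counts plus
  membership.
- Fisher: rows intersection vs non-intersection DEGs, columns canonical
  hexamer present vs absent; two-sided exact p (sum of hypergeometric
  tables no more probable than the observed one); odds ratio ad/bc with
  ∞/0 permitted; degenerate margins give p = 1. Verified against an
  exhaustive integer-arithmetic enumeration for every table with
  N ≤ 30.
- Correlations: Spearman (average ranks on ties, t-approximation p) and
  Pearson for each parameter — the three hexamer counts, their total,
  monomer and dimer counts, the three coexistence flags, FE and summit
  position — against expression. Pearson uses log(ratio) by default
  (ratios are multiplicative; Spearman is transform-invariant). Genes
  without a detected peak contribute count correlations but are dropped
  pairwise for FE/summit, matching the two-panel structure of the
  analysis (all DEGs vs peak-bearing DEGs). Constant vectors are
  flagged undefined. Raw p-values are reported; a Benjamini–Hochberg
  column is available but not used for headline decisions.

## Kinetics

Mass-transport-free 1:1 Langmuir model only; no baseline drift.
Association `R = R_eq(1 − e^−(k_aC+k_d)t)`, `R_eq = R_max C/(C+K_D)`;
dissociation decays from the association endpoint. The global fit
shares k_a, k_d and R_max across concentrations (one immobilized
surface; per-curve R_max behind a flag), runs in log-parameter space to
keep rates positive, initializes k_d from a log-linear regression of
the dissociation tail of the highest concentration, k_a at 10⁵ M⁻¹s⁻¹,
R_max at 1.5× the maximum observed response, and converges on a
relative step below 10⁻⁹. A 0-concentration trace, when present, is
subtracted as baseline. K_D = k_d/k_a is reported in nM at three
significant figures. Noiseless self-fits recover parameters to better
than 0.1%; at 2% relative noise the median K_D error over 20 seeds is
≈1%.

## Problem sizes and runtimes

The default study conditions — 20 genes / 50 kb genome, 5 regulated
promoters each planted with two GGCTAA and one GGCTGA site, 5·10⁴
fragments and pool size, 3 rounds, 1.5·10⁴ read pairs at 75 nt — run
end-to-end in a few seconds, so multi-seed recovery studies (20 seeds
for end-to-end recovery, 50 for the correlation-structure study) remain
desk-scale. The expression-only mining study uses 72 genes, the size of
the DEG set it emulates.

## What passing tests do and do not show

The synthetic genome has uniform base composition, no repeats, no
chromatin, and selection follows the exact model the simulator
implements; read errors are uniform substitutions. Recovery results
therefore validate the *pipeline logic* — trimming, mapping, peak
calling, annotation, counting and statistics are internally consistent
and recover planted truth — not the biological fidelity of any model
component on real sequencing data. Real libraries add PCR/GC bias,
duplicated sequence that defeats unique mapping, and binding
determinants (flanking shape, cooperativity) outside the additive
motif-weight model.
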