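# Methods

This note documents what `tealseq` computes, the defaults it ships with and
why, the numerical and algorithmic choices made where the design was open,
and what the synthetic-data tests do and do not demonstrate.

## Coordinates and sequence handling

All in-memory intervals are 0-based half-open. GFF3 (1-based inclusive) and
SAM (1-based positions) are converted at the I/O boundary only; BED is
native. Sequences are upper-cased on input and every non-ACGT character
collapses to N. Probes are synthesized oligos and must be fully specified,
so any candidate window containing N is rejected, and N in a genome never
matches anything during screening (it counts as a mismatch even against N).
SAM parsing requires aligner-reported NM tags rather than recomputing edit
distance, because the downstream filters are defined on NM as reported.

## Target selection

A gene cluster is targeted when its presence row-sum over the species'
genomes reaches `min_genomes`. Presence is per genome: paralogs (cluster
counts >1 in the Roary Rtab dialect) collapse to 1. Selection is monotone
in the threshold and returns clusters in sorted order. Mapping clusters to
reference coordinates is an explicit input (a cluster,genome,gene_id
table); clusters without a reference gene are listed as unmapped, never
silently dropped, and ambiguous clusters keep all their intervals.

## Melting temperature

Nearest-neighbor thermodynamics with the unified Allawi–SantaLucia
parameter set and the SantaLucia (1998) entropic salt correction:

    Tm = 1000·ΔH / (ΔS + 0.368·(N−1)·ln[Na⁺] + R·ln C) − 273.15

Defaults: 50 mM monovalent salt, 250 pM oligo, both configurable in
`PanelConfig`. The calculation is vectorized over candidate batches (a
4×4 ΔH/ΔS dinucleotide lookup), handles the terminal A·T/G·C initiation
terms and the self-complementary symmetry correction, and is verified in
the test suite against an independent published-parameter implementation
(Biopython's `Tm_NN` at identical settings) to within 0.5 °C. Duplex
symmetry — Tm(s) = Tm(revcomp(s)) — holds by construction and is property
tested.

## Candidate generation and composition filters

Candidates are tiled at step 1 over each target CDS on both strands
(capture templates are double-stranded after second-strand cDNA
synthesis). Composition rules: homopolymer runs of more than 6 bases fail
(a run of exactly 6 passes); Tm must fall inside the acceptance window.
The window defaults to percentile mode — trimming the lowest and highest
5% of the species' candidate Tm distribution — because the filter is
defined by its extremes rather than fixed bounds; an absolute window
(`tm_low`/`tm_high`) can be set instead.

## Specificity screens

Three screens gate every accepted probe:

* **Inclusion**: a perfect (0-mismatch) placement in at least
  `inclusion_min_genomes` target-species genomes, counted per genome
  (multiple hits in one genome count once). This keeps probes that
  tolerate within-species strain variation.
* **Exclusion**: no ungapped full-length placement with ≤4 mismatches
  ("fewer than five") on any off-target genome. A 40-mer alignment with
  ≤4 mismatches is effectively ungapped, so Hamming distance is the right
  metric; gapped off-target alignments are out of scope.
* **Host**: fewer than 25 of 40 bases matching any host transcript.
  "Matching" is read as matched bases within the best ungapped alignment
  diagonal on either strand — mismatches inside the alignment are allowed
  and simply not counted. This is the permissive reading (a contiguous-run
  reading would pass more probes); it is recorded here because the
  boundary between gapped-HSP identities and diagonal identities is a
  genuine interpretation choice.

The hit search is seed-and-verify with a pigeonhole guarantee: a probe of
length L split into m+1 disjoint seeds of length k = ⌊L/(m+1)⌋ must contain
one exact seed in any placement with ≤m mismatches (k = 8 covers L = 40,
m ≤ 4), so the search is complete, not heuristic. Hit reporting caps at
1,000 hits per probe per genome to bound pathological low-complexity
probes. The host screen is an exact vectorized scan over every alignment
diagonal rather than a seeded one: a seeded variant (e.g. 12-mer seeds)
is provably incomplete — a diagonal can carry ≥25 matched bases without
any 12-base exact run — and the exact scan is fast enough at panel scale
(~1 ms per probe against a 50 kb transcript set). Both primitives are
tested for exact agreement with brute-force sliding-window oracles.

## Panel assembly

Within a gene, accepted probes must start at least `min_spacing` (default
100) bases apart. Maximizing the number of points with pairwise distance
≥ d is the activity-selection problem, for which the left-to-right greedy
sweep is cardinality-optimal; the test suite confirms optimality against
exhaustive subset search. The per-gene budget (default 4 probes/CDS,
matching the observed ≈3.5 probes per covered CDS) is applied after
spacing optimization, keeping the probes whose Tm is closest to the
species median (ties: smaller start, then + strand). Spacing is enforced
within genes only; probes of adjacent genes may be closer than 100 bases.

MIP arms are paired per gene, contig and strand so the gap
(right.start − left.end) is `mip_gap_len` ± `mip_gap_tolerance` (default
120 ± 10; the published chemistry constrains only the final library size,
so the gap is a free parameter), each arm used at most once, and left-arm
starts of distinct MIPs ≥ `min_spacing` apart. `design_mip` solves this
exactly with a DP over arms ordered by start: under the default geometry
(arm+gap span < 2·spacing, spacing > 2·tolerance) the only forward
conflict a selection creates is its own right arm, which the DP carries as
state; degenerate geometries fall back to exhaustive search (bounded
instance size). Greedy pairing alone is suboptimal on constructible
instances (a left arm that grabs the nearest right arm can consume the
only viable left arm of the next MIP), which is why the exact DP exists.

The end-to-end pipeline (`tealseq.pipeline.design_panel`) evaluates the
specificity screens lazily, in greedy scan order, because screening every
step-1 candidate dominates design cost: a candidate is screened only when
the spacing sweep is about to accept it, cheapest screen first. For SPE
this provably selects the same set as greedy over the fully screened
candidate pool (hence remains cardinality-optimal), which is verified by a
dual-route test; the pipeline's MIP path uses lazily screened greedy
pairing (the exact DP is available on pre-screened candidates). Panel
design is a pure function of inputs and config; repeated runs are
byte-identical.

## Quantification

Trim rules per chemistry: SPE/bulk reads truncate at the first occurrence
of the adapter bait `AGATCGGAAGAG`; MIP reads drop their first 5 bases.
Reads shorter than 30 bases after trimming are discarded and counted (the
threshold is a configurable choice; the published pipelines do not state
one). Alignment filters are exclusive bounds: keep iff MAPQ > 30 and
NM < 1 (SPE probe alignments), NM < 3 (MIP), NM < 4 (genome alignments).
Secondary/supplementary records are dropped; with MAPQ > 30 residual
multi-mapping is negligible.

Probe counting uses bedtools-coverage default semantics — a read counts
toward every probe interval it overlaps by ≥1 base, half-open arithmetic —
and is cross-checked against `bedtools coverage` on identical toy inputs.
MIP probes are counted via their two 40-base arms (`/L`, `/R` reference
records) and the arm counts summed per probe. CPM is
1e6 · r_ijs / R_js with the total R_js taken per sample and species as the
sum of that species' probe counts (in probe-reference alignment mode each
mapped read contributes to exactly one probe, so this equals the mapped
total; it also makes the per-species CPM columns sum to exactly 10⁶).
RPKM = count / (mapped millions) / (CDS kb) for genome-mode CDS counts.

## Differential expression

Per probe, a negative-binomial GLM (log link) with library-size offsets is
fit over the design intercept + condition (+ optional covariate and
interaction), and the condition coefficient is Wald-tested. Dispersion is
estimated by method of moments from within-group means and variances with
a floor of 1e-8; the default is the pooled (common) estimate — the median
of per-probe estimates over well-measured probes — because with 3
replicates per condition per-probe moment estimates are dominated by
noise; per-probe mode is available. In the Poisson limit the Wald
statistic agrees with the closed-form Poisson Wald (tested within 10%).
This engine intentionally does not reproduce DESeq2 (no size-factor
shrinkage, no dispersion trend); the validated property is recovery of
planted effects, not coefficient parity. Reported log₂ fold changes use
normalized group means with pseudocount 0.5; BH adjustment runs across all
tested probes (all-zero probes are excluded and reported) before any
gene-level subsetting.

Gene calls use the median (interpolated for even counts) of probe log₂FC
and of probe adjusted P: up iff median log₂FC > 2 (strictly) and median
adjusted P < 0.05, down symmetric. The fold-change threshold 2 on the log₂
scale is the same rule as "fold change magnitude > 4"; the P threshold
defaults to 0.05 and is configurable (0.01 matches the stricter variant).
The median makes calls robust to single poorly performing probes.

Set over-representation is the upper-tail hypergeometric P(X ≥ k) with a
Bonferroni multiplier equal to the number of comparisons in the batch
(recorded in the result). SSE diagnostics square the per-CDS difference of
log₂(CPM+1) between paired samples and compare two such error
distributions with a two-sided Wilcoxon rank-sum test, exact for ≤25 per
group without ties, normal approximation with tie correction otherwise.
Sample pairings are explicit inputs. Pearson correlation matrices are
computed on log₂(CPM+1); zero-variance samples are reported missing, and
the distance matrix is the Euclidean distance between correlation-matrix
rows.

## Simulator

The simulator emulates the study conditions end to end; its defaults are
fixed once:

* **Pangenome**: per species 8 genomes, 60 core + 20 accessory genes
  (100 + 0 in the end-to-end study), gene lengths uniform 300–900 bp,
  AT-rich (GC 0.33) like staphylococcal genomes, per-strain SNP rate 0.005
  (within-species core-gene diversity of a few per mille), accessory
  presence probability 0.5. An off-target relative shares 10% of core
  genes at 8% divergence — close enough that some probe windows fall
  within 4 mismatches and the exclusion screen has real work to do.
  A host pool of 30 × 1.5 kb random transcripts feeds the host screen and
  the background read fraction.
* **Expression**: i.i.d. log-normal(µ=2, σ=1) baselines; a planted 10% of
  genes change by exactly 2^±3 in condition B.
* **Capture**: reads drawn multinomially with weight abundance ×
  efficiency. SPE efficiency is logistic in (Tm − panel median) — encoding
  the observed positive CPM–Tm relationship — times 0.5 per
  probe/template mismatch; MIP efficiency is flat and tolerates up to 3
  mismatches, zero above. These are stylized, declared parameters; no
  published data constrain their magnitudes, so only rank/qualitative
  behaviour should be read from them. Reads are 100 bases with
  substitution errors at 0.002; MIP reads carry 5 extra 5′ bases (the
  fixed-trim rule's target) and reads running off the template end read
  into the adapter bait. The truth SAM records each read's reference
  placement with exact NM; host background reads are unmapped records.

Everything derives from one seeded numpy Generator; identical (config,
seed) runs are byte-identical (tested).

What the simulator does **not** model: amplification bias, rRNA carryover,
quality-score structure, indels, coverage gradients along the replichore,
gene dropout within captured strains' coordinates, or realistic host
transcript composition. Passing tests therefore demonstrate the
correctness of the algorithms under the stated statistical model, not
instrument-level realism: on real data, probe-to-probe efficiency
variation is larger and partially unexplained, and absolute concordance
with bulk RNA-seq is limited by ribodepletion and probe effects.

## Study sizes and acceptance checks

The packaged study runs at desk scale: 2 species × 100 genes, 8 strains
each, 10⁵ reads per run, DE at 3 vs 3 replicates and depth 10⁵ — sizes
chosen so the full pipeline (panel design included) completes in well
under a minute per run while leaving every mechanism exercised (SNP-driven
inclusion failures, cross-species exclusion, host background, planted
DEGs). `scripts/acceptance.py` recomputes, from scratch at a given seed:
panel size/coverage, on-target fractions with and without host background,
CPM column conservation, abundance–CPM correlation, planted-DEG recall and
FDR, oracle agreement for the Hamming search, host screen and spacing
optimizer, closed-form agreement for the hypergeometric and Wilcoxon
statistics, and simulation determinism.

## Known limitations

* No secondary-structure, hairpin or cross-probe dimer screening; no
  vendor backbone/adapter sequences.
* Exclusion screening is ungapped; an off-target region matching a probe
  only via a gapped alignment would not be flagged.
* The DE engine is a deliberate simplification of DESeq2; with very few
  replicates and strong outliers its dispersion handling is cruder.
* BAM/CRAM are not parsed (SAM text is the contract at desk scale);
  pangenome construction itself (Roary) is upstream.
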