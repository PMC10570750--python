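# Methods

This note documents the models, defaults and numerical choices behind
`isletomics`, and what the synthetic benchmark does and does not show.

## Differential expression

Expression is modelled on `log2(TPM + 1)`; the +1 pseudocount stabilizes
low-expression variance and keeps zeros finite. The treatment effect is a
fixed effect in a donor random-intercept model. Two estimation paths:

- **Balanced complete paired designs** (every donor contributes exactly one
  control and one treated sample): the GLS/REML solution for the treatment
  effect is the mean of within-donor differences and its Wald test is the
  exact paired t-test (df = donors − 1). The implementation uses this
  closed form, vectorized across genes; it is reproducible to the last bit
  and needs no iterative fitter.
- **Unbalanced designs**: per-gene REML fit via `statsmodels MixedLM`
  (Wald test on the treatment coefficient).

Zero residual variance (exactly identical within-donor differences, which
happens in noise-free synthetic data) is reported as the degenerate limit:
p = 0 when the effect is non-zero, p = 1 otherwise, with a flag.

Filtering and selection follow the source analysis style: genes kept at
mean TPM > 0.5 (strict) in either condition; "regulated" means raw
p < 0.05. No multiplicity correction enters selection — BH q-values are
reported in the output so users can apply one. This is a deliberate
mirror of the published procedure, and it is prominently visible in the
output columns.

## Promoters, enhancers, signal matrices

- Promoter window: TSS −2000/+500 bp, strand-aware, clipped at chromosome
  ends. Multi-transcript genes use the longest transcript's TSS (ties:
  lower coordinate, then id). The window size is a conventional default;
  nothing downstream depends on it being exactly this.
- Overlap means ≥ 1 bp on half-open coordinates everywhere.
- Promoter state: H3K4me3 is the gate (no H3K4me3 → `unmarked`,
  regardless of H3K27ac); H3K27ac upgrades `marked_only` to `active`.
- Enhancers: ATAC peaks with (a) summit outside every promoter window and
  (b) any H3K4me1 overlap of the peak interval.
- Signal matrices: 6 kb windows centered at ATAC summits, 60 bins of
  100 bp. "Normalized" coverage is `value × (1e6 / total track mass)`
  (counts-per-million of bedGraph mass), then `log2(1 + x)`. Bin values
  are exact step-function integrals, so results do not depend on read
  order or bin alignment. Regions are never strand-flipped: the profiled
  marks are summit-symmetric. Windows that run off a chromosome read as
  zero.
- K-means: k = 3 on the column-standardized (z-scored, all marks jointly)
  matrix, Lloyd's algorithm, best of 10 restarts, seeded. Clusters are
  renamed by descending mean raw (unstandardized) H3K27ac window signal:
  `active_high ≥ active_low ≥ poised` holds by construction, ties broken
  by original cluster index so the renaming is total and deterministic
  even for degenerate inputs.
- Enhancer–gene assignment: nearest TSS by |summit − TSS|, ties to the
  lower coordinate then lexicographic gene id; an optional maximum
  distance drops the assignment. Distance is always measured to the TSS
  point (not clamped to zero inside the promoter window), which keeps the
  distance cap self-consistent.
- Motif enrichment: known PWMs (JASPAR text; counts → probabilities with
  a 0.01 pseudocount), log-odds against a uniform background, threshold
  defaulting to 80% of each PWM's maximum score — the behavior of common
  known-motif scanners. A region "contains" a motif when any position on
  either strand reaches the threshold; positions covering non-ACGT bases
  never match. Per-PWM 2×2 Fisher tests (foreground vs background
  containment) are BH-corrected; an infinite sample odds ratio is reported
  capped (1e6), and a fully degenerate margin reports odds ratio 1.

## Novel-transcript triage

Decision order (first match wins):

1. **Coding** (longest forward-frame ATG→stop ORF ≥ 100 codons on the
   spliced sense sequence; N breaks an ORF). Coding transcripts are
   checked for duplication against the reference transcriptome:
   identity ≥ 0.9 with query coverage ≥ 0.5 → `pseudogene_duplication`;
   coverage in [0.2, 0.5) → `partial_duplication`; else `coding_novel`.
   The ORF-length proxy stands in for external coding-potential tools; the
   threshold is a parameter. Duplication search is sense-strand only (the
   exon model resolves strand): a reversed or reverse-complemented
   sequence is not a match.
2. **lncRNA**: spliced length > 200 nt, promoter state `active`, mean TPM
   above the detection threshold (0.5, the same value as the expression
   filter — the natural choice absent a separate number). Antisense when
   any exon overlaps a reference gene's exon on the opposite strand
   (largest-overlap partner), else intergenic.
3. **Transcribed enhancer**: promoter lacks H3K4me3 but overlaps both
   H3K4me1 and H3K27ac.
4. `unresolved`.

Duplication detection is k-mer seeded (k = 15): the reference sharing the
most k-mers is the candidate, the matched query span is the densest
cluster of shared-k-mer positions (isolated stray hits, e.g. from
low-complexity motifs, are ignored; cluster gap 100 nt), identity comes
from an edlib infix alignment of that span, and coverage is the span's
fraction of the query.

Naming: antisense → `<PartnerGene>-as<k>`, k by genomic start within a
partner; intergenic → `Ri-lnc<n>` by descending mean expression (so the
most prominent lncRNA is number 1; coordinate order is available as an
option). Names are unique per run and reruns are byte-stable.

## Set statistics

`P(X ≥ k)` for X ~ Hypergeom(N, K, n) via `logsf`, exponentiated only for
reporting; `log10 p` is also returned so values below float underflow stay
usable. The universe N is a required argument everywhere — defaulting it
would silently fabricate p-values. Percent overlaps are rounded half away
from zero, which reproduces the printed prose values exactly. Rescue
classification: suppressed iff `il1b ≤ 0.70 × ctrl`; rescued iff
additionally `|cal − ctrl| ≤ 0.15 × ctrl`. The 0.30 suppression fraction
is the published criterion; the 0.15 "near control" tolerance is this
package's documented default for an unquantified phrase, and both are
parameters. A zero control level cannot be classified and is flagged.

## Single cells

QC bounds are inclusive on features/counts and strict on the mitochondrial
fraction (`mt-` prefixed genes). Marker merging averages
`ln(1 + 1e4 · count / cell_total)` per original cluster and applies the
0.3 / 0.18 thresholds to cluster means (strict on both sides; a mean
exactly at a threshold is Mid). The normalization scale is pinned so the
default thresholds are meaningful; users on another scale should pass
their own. Per-sample merged-cluster fractions sum to 1; condition
comparisons are two-sided two-sample t-tests per merged cluster against
the baseline condition, skipped (flagged) when a condition has fewer than
two samples; identical zero-variance groups report t = 0, p = 1.

## Synthetic data

The generator plants every structure the pipeline is supposed to find:

- **Layout**: 2 chromosomes × 2 Mb, features on 25 kb blocks (one gene,
  novel transcript, or gene-plus-enhancer per block). This guarantees
  unambiguous nearest-TSS assignment and non-overlapping promoters, and
  keeps brute-force interval oracles fast. Antisense lncRNAs are overlaid
  on the downstream exon of a plus-strand partner, opposite strand, with a
  promoter window disjoint from the partner's.
- **Sequences**: coding features get stop-free random codons behind an
  ATG; non-coding features get random sequence with a stop-in-all-frames
  stamp every ~90 nt, bounding any ORF far below the coding threshold.
  Pseudogene duplications copy a reference transcript with 5% point
  substitutions placed so the ORF frame gains no stop; the partial
  duplication copies only the ORF (~1/3 of its length) ahead of
  non-coding filler.
- **Bulk expression**: log-normal around planted baselines with a shared
  donor intercept (defaults: 3 donors, the triplicate design of the
  emulated study; σ_donor = 0.5, σ_noise = 0.3, effect 1.0 log2 units on
  10% of known genes and on all planted novels, which are "induced").
  Columns are normalized to 1e6 TPM at baseline and the planted
  fold-changes are applied afterwards, so planted effects are *exactly*
  recoverable on noise-free data; treated columns therefore exceed the
  nominal 1e6 mass by the planted perturbation (the same compositional
  bias a real TPM renormalization would fold into every gene).
  `renormalize_after_effects=True` restores strict TPM column sums at the
  cost of exact recovery.
- **Chromatin**: promoter/enhancer marks as narrowPeak records plus
  triangular coverage kernels at 10 bp resolution (H3K27ac amplitude
  10 / 3 / 0 for the three enhancer states, mirroring the clearly
  separated signal tiers of the emulated heatmap). Default per-category
  promoter profiles shape the novel-transcript funnel like the study's:
  75 novels → 19 with H3K4me3 → 10 active and expressed → 9 lncRNAs.
- **Cells**: Poisson counts over ~3000 background genes (cell totals
  ~10 k, features ~2.5 k, mito ~5% — inside the QC box), with the marker
  rate per maturity level solved numerically so the *expected cluster
  mean on the normalized scale* equals the configured gradient levels
  (0.5 / 0.24 / 0.05) under the actual cell-total and scale-factor
  distribution. Condition-dependent level proportions (High 0.4 vs 0.2,
  per-sample jitter 0.02) plant the shift the proportion test detects.

Everything derives from one seed; identical configs produce byte-identical
files.

**What the benchmark does not show.** The toy genome has uniform base
composition, no repeats, no splicing complexity beyond two-exon genes, no
overlapping genes except the planted antisense pairs, symmetric noise-free
coverage kernels, and no single-cell doublets or ambient RNA. Passing the
planted-truth suite demonstrates that the *logic* of each stage is correct
and calibrated, not that thresholds tuned here transfer to real data.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to make the checks
sharp but cheap: 30 known genes / 75 novels / 30 enhancers for recovery,
2000 genes × 6 donors for null calibration, 5000 cells for the merge, 200
random instances per oracle-equivalence check.

## Known limitations

- The mixed model assumes one variance across genes within a gene (no
  shrinkage across genes, no count-level model); very small donor numbers
  give few degrees of freedom, exactly as in a paired t-test.
- Coding potential is an ORF-length proxy; borderline ORFs (~100 codons)
  are sensitive to the threshold.
- Duplication detection requires a seed k-mer to survive (identity below
  ~0.85 over the whole match can be missed at k = 15).
- The motif stage tests containment, not occurrence counts or positional
  bias.
- Cluster merging inherits whatever errors the upstream graph clustering
  made; cells inherit their cluster's label regardless of their own
  marker level, by design.
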