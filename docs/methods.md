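# Methods

This note records the models, conventions and design decisions behind
`trapscan`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic validation does and does not
establish.

## Coordinates and gene extent

All internal coordinates are 0-based half-open; GTF input/output (1-based
closed, Ensembl dialect) converts at the boundary and nowhere else. This
makes the positional arithmetic unambiguous: a gene of span `[start, end)`
has length `L = end − start`, a position `x` inside it has relative
position `r = (x − start)/L` on the plus strand and `r = (end − 1 − x)/L`
on the minus strand, so `r ∈ [0, 1)` always, and the decile is
`⌊10r⌋ + 1`. Reflecting the genome (flipping strands and coordinates)
leaves every relative position unchanged, which the tests verify.

A gene's extent is its annotated gene-record span (TSS to transcription
end), not the union of its exons: positional profiles measure distance
from the TSS over the whole transcription unit, and intron insertions are
the main trapping mode, so exon-union spans would be the wrong ruler.
"Intergenic" means outside every gene span. Exon membership, by contrast,
is tested against the union of exons over all of a gene's transcripts,
because any isoform's exon can carry a fusion.

## Biotype taxonomy

Raw GTF biotype strings map to four major classes — protein coding,
lncRNA, small ncRNA, pseudogene — and, within lncRNA, to the positional
subclasses lincRNA, antisense, sense overlapping, sense intronic,
bidirectional promoter, processed transcript, 3′-overlapping, macro and
TEC. TEC is carried as an lncRNA subclass so that enrichment scans cover
it alongside the other lncRNA categories. Two fallback rules mirror
GENCODE naming (`*pseudogene*` → pseudogene; `IG_*_gene`/`TR_*_gene` →
protein coding); anything else is retained but flagged unclassified,
excluded from biotype tables and surfaced in a diagnostics report. The
table ships with the GENCODE vM8-era strings and is overridable from a
two-column TSV, so other annotation releases degrade gracefully rather
than failing.

The built-in annotated-gene census carries only the exactly published
lncRNA counts (9072 total; lincRNA 3579, antisense 2189, sense overlapping
23, sense intronic 253, bidirectional promoter 12). Classes without a
census entry simply get no percent-of-annotated figure (with a warning);
inventing a protein-coding census would suggest precision that does not
exist.

## Tag filtering

The filter consumes the mapping metadata as given input columns (alignment
quality, alignment count, representative flag) — it does not re-align
anything. Rules apply in a fixed order and each discarded tag is
attributed to the first rule that removed it: unmapped; mapped but without
a unique high-quality alignment; multiple high-quality alignments; not
representative. One integration per cell line is assumed; if two
representative tags survive for one cell line, the lexicographically
smallest tag id wins and a warning is logged — a deterministic resolution
of a situation the data model says should not occur. The report invariant
`n_input = n_retained + Σ discards` is asserted on every run.

## Statistical tests

**G-test.** `G = 2 Σ O_i ln(O_i/E_i)` with `E_i = n/10`, compared to
χ²(9). Zero cells contribute zero (the `0·ln 0` limit). No Williams or
continuity correction is applied: at library scale the correction is
negligible, and fixing the plain statistic keeps the oracle comparison
exact. Profiles count primary hits only, so each integration contributes
once. The implementation is cross-checked in the tests against a direct
evaluation of the formula and against scipy's log-likelihood-ratio mode on
strictly positive counts; its type-I error at α = 0.05 over 2000 uniform
replicates of n = 1000 falls inside [0.04, 0.06].

**Fisher/BH enrichment.** One-sided ("greater") exact tests, because the
question is over-representation. The universe is primary, non-intergenic
hits; at the subclass level it is restricted to lncRNA hits so that the
categories form a partition. All (vector, biotype) cells are adjusted
jointly (the conservative reading of a single heatmap of adjusted values;
per-vector adjustment is available as a config option). Significance is
`p_adj ≤ FDR` with FDR = 0.01 by default. `−log10(p_adj)` is capped at 300
so that underflowed zeros stay plottable. The Fisher p is verified against
brute-force hypergeometric enumeration for every 2×2 table with grand
total ≤ 60 (|Δ| ≤ 1e−12), and the BH step-up against a naive O(m²) double
loop.

**Primary-hit tie-breaking.** When a position lies in overlapping genes,
the primary hit prefers a sense-orientation gene, then the smallest span,
then lexicographic gene id: trap selection acts on sense insertions, and
the smallest containing gene is the most specific locus. Census-style
tables count *all* hit genes (an insertion in overlapping genes is
evidence for both loci), de-duplicated per (gene, cell line); positional
and enrichment statistics use primary hits only, to count events once.
Tags without a strand are treated as sense by convention.

**Mechanism classification.** The rule table is total, with precedence
intergenic > antisense orientation > structural subclass (bidirectional
promoter, sense overlapping) > vector-class behaviour: splice fusion for
splice-acceptor-bearing vectors in spliced hosts, then polyA exon capture
for polyA traps, then unspliced insertion. Specific structural context
dominates generic vector behaviour.

## Synthetic libraries

The generator emulates the features of the real resource that the
pipeline's statistics are sensitive to, at roughly 1/50 genome scale:

- **Genome.** Gene counts per biotype follow the mouse census proportions
  (~440 PCGs, ~180 lncRNAs split across subclasses, ~160 sncRNAs, ~160
  pseudogenes by default); genes are placed without overlap on synthetic
  chromosomes except for four deliberately planted arrangements — an
  antisense lncRNA over a PCG's 5′ end, a sense-intronic gene inside a
  host intron, a bidirectional-promoter pair, and a sense-overlapping host
  with a PCG in its intron — which exercise the overlap and mechanism
  rules. Per-biotype single-exon probabilities (e.g. 0.02 for PCGs, 0.25
  for lincRNAs, 1.0 for TEC and sncRNAs) create realistic spliced/
  non-spliced contrasts.
- **Vectors.** Positional bias is a truncated geometric distribution over
  deciles with parameter ρ (mass ∝ (1−ρ)^(d−1), mirrored for 3′ models):
  a one-parameter family matching the observed monotone 5′/3′ shapes while
  remaining analytically checkable. Defaults: an expression-dependent
  splice-acceptor promoter trap with ρ = 0.5 (5′) and an
  expression-independent polyA trap with ρ = 0.5 (3′). Biotype preference
  is a per-vector multiplier on gene sampling weights. Expression is a
  per-gene Bernoulli flag (fraction 0.85 for PCGs, 0.5 otherwise):
  promoter traps sample only expressed genes, polyA traps ignore the flag
  — the minimal model of expression-independent activation.
- **Events and noise.** 40% of events are intergenic (uniform over gap
  space), matching the published genic/intergenic split. Each clean
  integration is wrapped in a representative tag plus Poisson(0.2) extra
  non-representative duplicates; events are corrupted into unmapped (10%),
  low-quality (5%) or multi-mapping (10%) tags. Ground truth records every
  clean integration with the decile recomputed from the emitted
  coordinate, so truth and pipeline agree exactly by construction of the
  same convention (the tests then verify the pipeline reproduces it).
- **Determinism.** All randomness flows from the config seed; identical
  configs produce byte-identical GTF, tag TSV, ground truth and report
  files.

What the generator does *not* model: nucleotide sequence, vector cassette
structure, cryptic splicing, NMD kinetics beyond the 3′-bias parameter,
expression levels, chromatin accessibility, or hot/cold spots of
integration. Passing the validation studies therefore shows that the
pipeline's logic and statistics behave as specified under a faithful
abstraction of the data's structure — not that any biological conclusion
about a real library is automatic.

## Validation studies and their scale

The studies in `trapscan.validation` (run by the test suite and the
reproduction script) use problem sizes chosen to make their statistical
guarantees sharp while keeping a full run in the minutes range on one CPU:
2000 uniform replicates of n = 1000 for G-test calibration; 100 seeded
scans of two identically distributed vectors (n = 1000 each) for the null
enrichment check; 100 seeded scans of one planted vector (10× lincRNA
multiplier) against nine identical null vectors at n = 5000 per vector for
recovery; n = 10,000 for the 5′-bias positional signal.

One property of the enrichment design deserves a note. The 2×2 test
compares each vector against the pooled complement with fixed margins, so
a strong planted preference in one vector *genuinely* depletes the
complement's other categories: every null vector then shows a mild
one-sided over-representation in the subclasses the planted vector
avoids. This complement effect is a real feature of the statistic, not a
calibration failure — with two identically distributed vectors (no planted
signal) the scan is clean in ≥ 95% of seeds. The recovery study therefore
uses a many-vector comparison group, as in real libraries produced by many
vectors, which dilutes the effect to a small cell-level false-flag rate
(measured ~2.5%, reported alongside the recovery rate); isolated
complement flags in small comparison groups should be interpreted
accordingly.

## Known limitations

- GTF reading requires explicit gene and transcript records (Ensembl
  dialect); GFF3 and inference-requiring dialects are out of scope.
- Genes whose biotype string is absent from the taxonomy are excluded from
  biotype tables (they remain visible in diagnostics); a heavily
  non-GENCODE annotation needs a taxonomy override table.
- The one-integration-per-cell-line assumption is resolved, not verified:
  lines with genuinely multiple integrations are collapsed to one
  deterministic representative.
- Odds ratios for cells with empty margins are reported as inf/NaN rather
  than corrected; inference rests on the exact p-values.
- The spliced/non-spliced table uses primary hits, so a non-spliced guest
  gene inside a spliced host is attributed per the primary-hit rule.
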