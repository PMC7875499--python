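# trapscan

Analysis of gene-trap insertional-mutagenesis libraries in mouse ES cells:
tag filtering, insertion-site annotation against GENCODE-style gene models,
positional-bias testing along genes, and detection of vector-specific
biotype preferences.

Gene trapping mutates a gene and reports its expression in one step: a
generic vector integrates into the genome, and a short genomic sequence tag
identifies the disrupted locus in each ES cell line. Large international
programmes assembled hundreds of thousands of such lines, and because
trapping is (largely) untargeted, the libraries contain mutations not only
in protein-coding genes (PCGs) but also in long non-coding RNA (lncRNA)
genes, small ncRNA genes and pseudogenes. `trapscan` implements the desk
analysis of such a resource for anyone re-mining an insertion-site
database: which genes and biotypes are hit, where along each gene the
vectors land, and which vectors prefer which biotypes.

## The analysis

**Tag filtering.** Each cell line may be represented by several sequence
tags of varying mapping quality. Three rules, applied in order, reduce them
to one representative, uniquely and confidently mapped tag per vector
integration: (1) drop unmapped and low-quality tags, (2) drop tags with
multiple high-quality alignments, (3) keep only tags flagged
representative. A filter report accounts for every input tag exactly once.

**Annotation.** Every insertion point is intersected with gene spans
(0-based half-open internally; GTF converts at the boundary). A hit records
the relative position from the transcription start site,
`r = (x − start)/L` on the plus strand and `r = (end − 1 − x)/L` on the
minus strand, its decile `d = ⌊10r⌋ + 1`, exon/intron context (union of
exons over transcripts), orientation relative to the host, whether the host
is spliced, and an activation-mechanism class (splice fusion, polyA exon
capture, antisense insertion, bidirectional-promoter capture, host
read-through truncation, unspliced insertion, intergenic activation).

**Positional bias.** For each (vector class, gene class) stratum the decile
counts `O_1..O_10` are tested against uniformity with the likelihood-ratio
G-test,

```
G = 2 Σ_i O_i ln(O_i / E_i),   E_i = n/10,   G ~ χ²(9)
```

with empty cells contributing zero (the `0·ln 0` limit) and no continuity
correction.

**Biotype enrichment.** For every (vector, biotype) pair a 2×2 table
`[[a, b], [c, d]]` — this vector in this biotype vs everything else — is
tested one-sided for over-representation (hypergeometric upper tail,
Fisher's exact test). All cells are adjusted jointly with the
Benjamini–Hochberg step-up procedure; a cell is significant when its
adjusted p-value is at most the FDR constraint (0.01 by default). The
`−log10` adjusted-p matrix is the heatmap-ready summary.

**Synthetic libraries.** A seeded generator produces genome annotations
(all major biotypes, deliberately planted overlap arrangements, single-exon
genes) and tag libraries with configurable positional models (truncated
geometric over deciles, 5′ or 3′), per-biotype preference multipliers,
expression dependence and mapping noise — with full ground truth, so every
stage is testable without any external download.

## Worked example

```python
from trapscan import (SyntheticConfig, generate_annotation, generate_tags,
                      filter_tags, annotate_frame, positional_profiles,
                      profiles_to_frame)

config = SyntheticConfig(seed=42, n_integrations_per_vector=2000)
annotation = generate_annotation(config)
tags, truth = generate_tags(annotation, config)
integrations, report = filter_tags(tags)
hits = annotate_frame(integrations, annotation)
print(profiles_to_frame(positional_profiles(hits)).to_string(index=False))
```

prints (abridged to the first strata columns):

```
    vector_class     gene_class  decile_1  decile_2  decile_3 ...  decile_10   n           G       p_value
promoter_trap_SA protein_coding       291       126        73 ...          1 548 1058.817074 3.558714e-222
promoter_trap_SA         lncRNA        65        28        20 ...          0 132  231.769896  6.973607e-45
      polyA_trap protein_coding         0         2         3 ...        237 461  877.093464 5.326693e-183
      polyA_trap         lncRNA         1         1         1 ...         85 179  334.026231  1.549709e-66
```

The splice-acceptor promoter trap piles up in the 5′ deciles (a long fusion
transcript would inactivate its reporter), the polyA trap in the 3′ deciles
(upstream insertions are degraded by nonsense-mediated decay), and every
profile rejects positional uniformity decisively. The filter report for the
same run retains 2982 of 4595 tags — exactly the planted clean
integrations, with every discard attributed to one rule.

The `examples/` directory walks through each capability (simulation,
filtering, annotation, positional bias, enrichment, summary reports) as a
short narrative script; each prints the numbers it computes and what they
mean. A thin CLI mirrors the stages:

```
trapscan simulate --seed 42 --outdir lib/
trapscan run --config pipeline.yaml        # filter → annotate → test → report
```

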