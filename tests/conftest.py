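import numpy as np
import pandas as pd
import pytest

from trapscan import (
    AnnotationSet,
    BiotypeTaxonomy,
    GeneModel,
    SyntheticConfig,
    TranscriptModel,
    VectorSpec,
)


def make_gene(gene_id, chrom, start, end, strand, biotype, exons=None):
    """Build a one-transcript gene; default exon layout is two exons at the
    span's ends (spliced)."""
    if exons is None:
        third = (end - start) // 3
        exons = [(start, start + third), (end - third, end)]
    return GeneModel(
        gene_id=gene_id,
        symbol=gene_id.lower(),
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        raw_biotype=biotype,
        transcripts=(TranscriptModel(f"{gene_id}.T1", tuple(exons)),),
    )


@pytest.fixture(scope="session")
def taxonomy():
    return BiotypeTaxonomy()


@pytest.fixture(scope="session")
def tiny_annotation(taxonomy):
    """A hand-built genome exercising every biotype and overlap case."""
    genes = [
        make_gene("PC1", "chr1", 1000, 11000, "+", "protein_coding",
                  exons=[(1000, 2000), (5000, 6000), (10000, 11000)]),
        make_gene("LN1", "chr1", 20000, 30000, "+", "lincRNA",
                  exons=[(20000, 21000), (29000, 30000)]),
        make_gene("LN2", "chr1", 40000, 42000, "-", "lincRNA",
                  exons=[(40000, 42000)]),
        make_gene("SN1", "chr1", 50000, 50200, "+", "snoRNA",
                  exons=[(50000, 50200)]),
        # antisense pair: AS1 (-) overlaps the 5' end of PC2 (+)
        make_gene("PC2", "chr2", 1000, 9000, "+", "protein_coding"),
        make_gene("AS1", "chr2", 0, 3000, "-", "antisense",
                  exons=[(0, 500), (2500, 3000)]),
        # bidirectional promoter pair: BP1 (-) upstream of PC3 (+)
        make_gene("BP1", "chr2", 12000, 14000, "-", "bidirectional_promoter",
                  exons=[(12000, 14000)]),
        make_gene("PC3", "chr2", 14200, 20000, "+", "protein_coding"),
        # sense-overlapping host SO1 (+) contains PC4 (+) in its intron
        make_gene("SO1", "chr2", 30000, 54000, "+", "sense_overlapping",
                  exons=[(30000, 31000), (52000, 54000)]),
        make_gene("PC4", "chr2", 34000, 44000, "+", "protein_coding"),
        # sense-intronic SI1 inside PC5's intron, same strand
        make_gene("PC5", "chr3", 1000, 21000, "+", "protein_coding",
                  exons=[(1000, 2000), (20000, 21000)]),
        make_gene("SI1", "chr3", 6000, 9000, "+", "sense_intronic",
                  exons=[(6000, 9000)]),
        make_gene("PT1", "chr3", 30000, 36000, "-", "processed_transcript"),
        make_gene("PS1", "chr3", 40000, 43000, "+", "processed_pseudogene",
                  exons=[(40000, 43000)]),
        make_gene("TC1", "chr3", 50000, 52000, "+", "TEC",
                  exons=[(50000, 52000)]),
    ]
    return AnnotationSet(genes, taxonomy=taxonomy)


def integration_frame(rows):
    """rows: (cell_line_id, vector_id, vector_class, chrom, position, strand)"""
    return pd.DataFrame(
        rows,
        columns=["cell_line_id", "vector_id", "vector_class", "chrom", "position", "tag_strand"],
    ).assign(source_tag_id=lambda d: d["cell_line_id"] + ":T0")


@pytest.fixture()
def small_config():
    """A fast two-vector synthetic config used across tests."""
    return SyntheticConfig(seed=11, n_integrations_per_vector=400)


def primary_hits_frame(records):
    """Minimal hits frame for positional/enrichment/report unit tests.

    records: dicts with any of the hit columns; sensible defaults fill the
    rest (a primary, annotated, sense, spliced protein-coding hit).
    """
    defaults = {
        "cell_line_id": None,
        "vector_id": "V1",
        "vector_class": "promoter_trap_SA",
        "chrom": "chr1",
        "position": 0,
        "tag_strand": "+",
        "intergenic": False,
        "gene_id": "G",
        "raw_biotype": "protein_coding",
        "major_class": "protein_coding",
        "lnc_subclass": "none",
        "relative_position": 0.0,
        "decile": 1,
        "region": "intron",
        "strand_relation": "sense",
        "host_spliced": True,
        "is_primary": True,
        "mechanism": "sense_splice_fusion",
    }
    rows = []
    for i, rec in enumerate(records):
        row = dict(defaults)
        row.update(rec)
        if row["cell_line_id"] is None:
            row["cell_line_id"] = f"CL{i:04d}"
        rows.append(row)
    return pd.DataFrame(rows, columns=list(defaults))
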