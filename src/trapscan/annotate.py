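"""Map filtered integrations onto genomic loci.

For each integration the annotator reports every gene whose span contains
the insertion point, the insertion's position relative to the transcription
start site (and hence its decile along the gene), whether it fell in exonic
or intronic sequence, its orientation relative to the host gene, whether
the host is spliced, and a mechanistic class describing how a reporter
cassette would be activated from that context (splice fusion, polyA exon
capture, antisense insertion, and the structural special cases of
bidirectional-promoter and sense-overlapping hosts).
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import AnnotationSet, GeneModel, is_spliced

logger = logging.getLogger(__name__)

MECHANISMS = (
    "sense_splice_fusion",
    "polyA_exon_capture",
    "antisense_insertion",
    "bidirectional_promoter_capture",
    "host_readthrough_truncation",
    "unspliced_insertion",
    "intergenic_activation",
)

#: vector classes whose activation depends on a splice acceptor upstream of
#: the reporter (everything except polyA traps)
SA_BEARING_CLASSES = frozenset(
    {"promoter_trap_SA", "exon_trap", "combined", "secretory_trap"}
)

HIT_COLUMNS = [
    "cell_line_id",
    "vector_id",
    "vector_class",
    "chrom",
    "position",
    "tag_strand",
    "intergenic",
    "gene_id",
    "raw_biotype",
    "major_class",
    "lnc_subclass",
    "relative_position",
    "decile",
    "region",
    "strand_relation",
    "host_spliced",
    "is_primary",
    "mechanism",
]


@dataclass(frozen=True)
class GeneHit:
    gene_id: str
    major_class: str
    lnc_subclass: str
    relative_position: float
    decile: int
    region: str  # "exon" | "intron"
    strand_relation: str  # "sense" | "antisense"
    host_spliced: bool


@dataclass
class AnnotationResult:
    cell_line_id: str
    vector_id: str
    vector_class: str
    chrom: str
    position: int
    tag_strand: str
    hits: list[GeneHit]
    primary_hit: GeneHit | None
    intergenic: bool
    mechanism: str


def relative_position(gene: GeneModel, position: int) -> float:
    """Fractional distance of ``position`` from the gene's TSS, in [0, 1).

    On the plus strand the TSS is ``start``; on the minus strand it is
    ``end - 1`` and distance runs leftwards.
    """
    if not (gene.start <= position < gene.end):
        raise ValueError(
            f"position {position} outside gene {gene.gene_id} "
            f"[{gene.start},{gene.end})"
        )
    if gene.strand == "+":
        return (position - gene.start) / gene.length
    return (gene.end - 1 - position) / gene.length


def decile_of(rel_pos: float) -> int:
    """Decile 1..10 of a relative position in [0, 1)."""
    return int(rel_pos * 10) + 1


class _GeneContext:
    """Precomputed per-gene lookups reused across many integrations."""

    __slots__ = (
        "gene",
        "major",
        "sub",
        "spliced",
        "exon_starts",
        "exon_ends",
    )

    def __init__(self, gene: GeneModel, annset: AnnotationSet):
        self.gene = gene
        self.major, self.sub = annset.classify(gene)
        self.spliced = is_spliced(gene)
        union = gene.exon_union()
        self.exon_starts = [s for s, _ in union]
        self.exon_ends = [e for _, e in union]

    def in_exon(self, position: int) -> bool:
        i = bisect.bisect_right(self.exon_starts, position) - 1
        return i >= 0 and position < self.exon_ends[i]


class Annotator:
    """Annotates integrations against one :class:`AnnotationSet`."""

    def __init__(self, annset: AnnotationSet):
        self.annset = annset
        self._ctx: dict[str, _GeneContext] = {}

    def _context(self, gene: GeneModel) -> _GeneContext:
        ctx = self._ctx.get(gene.gene_id)
        if ctx is None:
            ctx = _GeneContext(gene, self.annset)
            self._ctx[gene.gene_id] = ctx
        return ctx

    def _make_hit(self, gene: GeneModel, position: int, tag_strand: str) -> GeneHit:
        ctx = self._context(gene)
        rel = relative_position(gene, position)
        relation = (
            "sense" if (not tag_strand or tag_strand == gene.strand) else "antisense"
        )
        return GeneHit(
            gene_id=gene.gene_id,
            major_class=ctx.major,
            lnc_subclass=ctx.sub,
            relative_position=rel,
            decile=decile_of(rel),
            region="exon" if ctx.in_exon(position) else "intron",
            strand_relation=relation,
            host_spliced=ctx.spliced,
        )

    def annotate(
        self,
        cell_line_id: str,
        vector_id: str,
        vector_class: str,
        chrom: str,
        position: int,
        tag_strand: str,
    ) -> AnnotationResult:
        if chrom not in self.annset.chromosomes:
            logger.warning(
                "chromosome %s absent from the annotation; %s treated as intergenic",
                chrom,
                cell_line_id,
            )
            genes: list[GeneModel] = []
        else:
            genes = self.annset.query(chrom, position)
        hits = [self._make_hit(g, position, tag_strand) for g in genes]
        primary = choose_primary(hits, {g.gene_id: g for g in genes})
        intergenic = not hits
        mech = classify_mechanism(primary, vector_class, intergenic)
        return AnnotationResult(
            cell_line_id=cell_line_id,
            vector_id=vector_id,
            vector_class=vector_class,
            chrom=chrom,
            position=position,
            tag_strand=tag_strand,
            hits=hits,
            primary_hit=primary,
            intergenic=intergenic,
            mechanism=mech,
        )


def choose_primary(hits: list[GeneHit], genes: dict[str, GeneModel]) -> GeneHit | None:
    """Tie-break overlapping-gene hits: sense first, then smallest span,
    then lexicographic gene id."""
    if not hits:
        return None
    return min(
        hits,
        key=lambda h: (
            h.strand_relation != "sense",
            genes[h.gene_id].length,
            h.gene_id,
        ),
    )


def classify_mechanism(
    hit: GeneHit | None, vector_class: str, intergenic: bool
) -> str:
    """Total rule table for the activation mechanism of one integration.

    Precedence: intergenic > antisense orientation > structural subclass
    (bidirectional promoter, sense overlapping) > vector-class behaviour
    (splice fusion for SA-bearing vectors, exon capture for polyA traps,
    unspliced insertion otherwise).
    """
    if intergenic:
        if hit is not None:
            raise ValueError("intergenic integration cannot carry a gene hit")
        return "intergenic_activation"
    if hit is None:
        raise ValueError("annotated integration requires a gene hit")
    if hit.strand_relation == "antisense":
        return "antisense_insertion"
    if hit.lnc_subclass == "bidirectional_promoter":
        return "bidirectional_promoter_capture"
    if hit.lnc_subclass == "sense_overlapping":
        return "host_readthrough_truncation"
    if hit.host_spliced and vector_class in SA_BEARING_CLASSES:
        return "sense_splice_fusion"
    if vector_class == "polyA_trap":
        return "polyA_exon_capture"
    return "unspliced_insertion"


def annotate_integration(integration, annset: AnnotationSet) -> AnnotationResult:
    """Annotate one integration (a mapping or dataclass with the
    integration fields) against ``annset``."""
    get = (
        integration.get
        if hasattr(integration, "get")
        else lambda k, d=None: getattr(integration, k, d)
    )
    return Annotator(annset).annotate(
        str(get("cell_line_id")),
        str(get("vector_id")),
        str(get("vector_class")),
        str(get("chrom")),
        int(get("position")),
        str(get("tag_strand") or ""),
    )


def annotate_frame(integrations: pd.DataFrame, annset: AnnotationSet) -> pd.DataFrame:
    """Annotate a whole integration frame.

    Returns one row per (integration, hit gene) plus one row per intergenic
    integration, with :data:`HIT_COLUMNS` in fixed order.  ``is_primary``
    marks the hit used for positional and enrichment statistics.
    """
    annotator = Annotator(annset)
    rows: list[tuple] = []
    for rec in integrations.itertuples(index=False):
        res = annotator.annotate(
            rec.cell_line_id,
            rec.vector_id,
            rec.vector_class,
            rec.chrom,
            int(rec.position),
            rec.tag_strand or "",
        )
        base = (
            res.cell_line_id,
            res.vector_id,
            res.vector_class,
            res.chrom,
            res.position,
            res.tag_strand,
        )
        if res.intergenic:
            rows.append(
                base
                + (True, "", "", "", "", np.nan, 0, "", "", False, False, res.mechanism)
            )
        else:
            for h in res.hits:
                primary = h is res.primary_hit
                rows.append(
                    base
                    + (
                        False,
                        h.gene_id,
                        annset.genes[h.gene_id].raw_biotype,
                        h.major_class,
                        h.lnc_subclass,
                        h.relative_position,
                        h.decile,
                        h.region,
                        h.strand_relation,
                        h.host_spliced,
                        primary,
                        res.mechanism if primary else "",
                    )
                )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def write_annotation(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "tag_strand": str, "gene_id": str, "region": str},
        keep_default_na=False,
        na_values=[""],
    )
    bool_map = {"True": True, "False": False, True: True, False: False}
    for col in ("intergenic", "is_primary", "host_spliced"):
        df[col] = df[col].map(lambda v: bool_map.get(v, bool(v)))
    return df


def write_bed(integrations: pd.DataFrame, path: str | Path) -> None:
    """BED6 of integration points (0-based half-open single-base intervals)."""
    bed = pd.DataFrame(
        {
            "chrom": integrations["chrom"],
            "start": integrations["position"],
            "end": integrations["position"] + 1,
            "name": integrations["cell_line_id"],
            "score": 0,
            "strand": integrations["tag_strand"].replace("", "."),
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)
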