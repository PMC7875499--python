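"""Gene models, biotype taxonomy and the annotation interval index.

Gene structures are read from GTF (Ensembl dialect, 1-based closed
coordinates) and held internally in 0-based half-open coordinates, the
convention used by every downstream positional computation.  Each gene is
classified into one of four major biotype classes (protein-coding, lncRNA,
small ncRNA, pseudogene) and, for lncRNAs, into a positional subclass
(lincRNA, antisense, sense overlapping, sense intronic, bidirectional
promoter, processed transcript, 3'-overlapping, macro, TEC) following the
GENCODE taxonomy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

MAJOR_CLASSES = ("protein_coding", "lncRNA", "sncRNA", "pseudogene")
UNCLASSIFIED = "unclassified"
NO_SUBCLASS = "none"

LNC_SUBCLASSES = (
    "lincRNA",
    "antisense",
    "sense_overlapping",
    "sense_intronic",
    "bidirectional_promoter",
    "processed_transcript",
    "three_prime_overlapping",
    "macro",
    "TEC",
)

#: raw GTF biotype string -> (major class, lncRNA subclass)
_DEFAULT_MAPPING: dict[str, tuple[str, str]] = {
    "protein_coding": ("protein_coding", NO_SUBCLASS),
    "lincRNA": ("lncRNA", "lincRNA"),
    "antisense": ("lncRNA", "antisense"),
    "antisense_RNA": ("lncRNA", "antisense"),
    "sense_overlapping": ("lncRNA", "sense_overlapping"),
    "sense_intronic": ("lncRNA", "sense_intronic"),
    "bidirectional_promoter": ("lncRNA", "bidirectional_promoter"),
    "bidirectional_promoter_lncRNA": ("lncRNA", "bidirectional_promoter"),
    "bidirectional_promoter_lncrna": ("lncRNA", "bidirectional_promoter"),
    "processed_transcript": ("lncRNA", "processed_transcript"),
    "3prime_overlapping_ncRNA": ("lncRNA", "three_prime_overlapping"),
    "3prime_overlapping_ncrna": ("lncRNA", "three_prime_overlapping"),
    "macro_lncRNA": ("lncRNA", "macro"),
    "TEC": ("lncRNA", "TEC"),
    "miRNA": ("sncRNA", NO_SUBCLASS),
    "snoRNA": ("sncRNA", NO_SUBCLASS),
    "snRNA": ("sncRNA", NO_SUBCLASS),
    "rRNA": ("sncRNA", NO_SUBCLASS),
    "misc_RNA": ("sncRNA", NO_SUBCLASS),
    "scaRNA": ("sncRNA", NO_SUBCLASS),
    "sRNA": ("sncRNA", NO_SUBCLASS),
    "ribozyme": ("sncRNA", NO_SUBCLASS),
    "Mt_tRNA": ("sncRNA", NO_SUBCLASS),
    "Mt_rRNA": ("sncRNA", NO_SUBCLASS),
}

#: annotated-gene census of the reference annotation (GENCODE vM8 /
#: Ensembl 83, GRCm38).  Only the lncRNA counts are published exactly;
#: classes without an entry simply get no percent-of-annotated figure.
DEFAULT_CENSUS: dict[str, int] = {
    "lncRNA": 9072,
    "lncRNA/lincRNA": 3579,
    "lncRNA/antisense": 2189,
    "lncRNA/sense_overlapping": 23,
    "lncRNA/sense_intronic": 253,
    "lncRNA/bidirectional_promoter": 12,
}


class GtfParseError(ValueError):
    """Raised for a malformed GTF record; carries the offending line number."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: an id plus sorted, non-overlapping half-open exons."""

    transcript_id: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"empty exon ({s},{e}) in {self.transcript_id}")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"exons unsorted/overlapping in {self.transcript_id}")
            prev_end = e


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene; coordinates 0-based half-open, span = gene record."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    raw_biotype: str
    transcripts: tuple[TranscriptModel, ...] = ()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        for t in self.transcripts:
            if t.exons[0][0] < self.start or t.exons[-1][1] > self.end:
                raise ValueError(
                    f"{self.gene_id}: transcript {t.transcript_id} outside gene span"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    def exon_union(self) -> tuple[tuple[int, int], ...]:
        """Merged exon intervals over all transcripts."""
        ivs = sorted(e for t in self.transcripts for e in t.exons)
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return tuple((s, e) for s, e in merged)


def is_spliced(gene: GeneModel) -> bool:
    """True iff any transcript of the gene has at least two exons."""
    return any(len(t.exons) >= 2 for t in gene.transcripts)


class BiotypeTaxonomy:
    """Maps raw GTF biotype strings onto (major class, lncRNA subclass).

    Strings absent from the explicit table fall back to two rules mirroring
    GENCODE naming: anything containing ``pseudogene`` is a pseudogene, and
    immunoglobulin/T-cell-receptor segment genes (``IG_*_gene``/``TR_*_gene``)
    count as protein coding.  Everything else is left unclassified and is
    excluded from biotype tables but surfaced in diagnostics.
    """

    def __init__(
        self,
        mapping: dict[str, tuple[str, str]] | None = None,
        census: dict[str, int] | None = None,
    ) -> None:
        self.mapping = dict(_DEFAULT_MAPPING if mapping is None else mapping)
        self.census = dict(DEFAULT_CENSUS if census is None else census)
        for raw, (major, sub) in self.mapping.items():
            if major not in MAJOR_CLASSES:
                raise ValueError(f"unknown major class {major!r} for {raw!r}")
            if (sub != NO_SUBCLASS) != (major == "lncRNA"):
                raise ValueError(
                    f"{raw!r}: subclass must be set iff major class is lncRNA"
                )
        if any(v < 0 for v in self.census.values()):
            raise ValueError("census counts must be nonnegative")

    def classify(self, raw_biotype: str) -> tuple[str, str]:
        if raw_biotype in self.mapping:
            return self.mapping[raw_biotype]
        if "pseudogene" in raw_biotype:
            return ("pseudogene", NO_SUBCLASS)
        if (
            raw_biotype.startswith(("IG_", "TR_"))
            and raw_biotype.endswith("_gene")
        ):
            return ("protein_coding", NO_SUBCLASS)
        return (UNCLASSIFIED, NO_SUBCLASS)

    @classmethod
    def from_tsv(cls, path: str | Path, census: dict[str, int] | None = None) -> "BiotypeTaxonomy":
        """Load an override table: two tab-separated columns, raw biotype and
        a class path (``protein_coding`` or ``lncRNA/lincRNA``)."""
        mapping: dict[str, tuple[str, str]] = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{i}: expected 2 tab-separated columns")
            raw, classpath = parts
            major, _, sub = classpath.partition("/")
            mapping[raw] = (major, sub or NO_SUBCLASS)
        return cls(mapping=mapping, census=census)


def classify_biotype(gene: GeneModel, taxonomy: BiotypeTaxonomy) -> tuple[str, str]:
    """Deterministic taxonomy lookup for one gene."""
    return taxonomy.classify(gene.raw_biotype)


class AnnotationSet:
    """A collection of genes with a per-chromosome point-overlap index."""

    def __init__(self, genes: Iterable[GeneModel], taxonomy: BiotypeTaxonomy | None = None):
        self.taxonomy = taxonomy if taxonomy is not None else BiotypeTaxonomy()
        self.genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(sorted(self._trees))

    def query(self, chrom: str, position: int) -> list[GeneModel]:
        """All genes whose span [start, end) contains ``position``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [self.genes[iv.data] for iv in tree.at(position)]
        hits.sort(key=lambda g: g.gene_id)
        return hits

    def classify(self, gene: GeneModel) -> tuple[str, str]:
        return self.taxonomy.classify(gene.raw_biotype)

    def major_class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g in self:
            major, _ = self.classify(g)
            counts[major] = counts.get(major, 0) + 1
        return counts

    def unclassified_genes(self) -> list[GeneModel]:
        return [g for g in self if self.classify(g)[0] == UNCLASSIFIED]

    def diagnostics(self) -> "pd.DataFrame":
        """Per-raw-biotype gene counts with their taxonomy call (TSV-ready)."""
        import pandas as pd

        rows: dict[tuple[str, str, str], int] = {}
        for g in self:
            major, sub = self.classify(g)
            key = (g.raw_biotype, major, sub)
            rows[key] = rows.get(key, 0) + 1
        return pd.DataFrame(
            [
                {"raw_biotype": r, "major_class": m, "lnc_subclass": s, "n_genes": n}
                for (r, m, s), n in sorted(rows.items())
            ]
        )


def _validate_gtf(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise GtfParseError(
                    f"{path}: line {lineno}: invalid coordinate range {start}-{end}"
                )
            if fields[6] not in ("+", "-", "."):
                raise GtfParseError(f"{path}: line {lineno}: bad strand {fields[6]!r}")


def _biotype_of(feature) -> str | None:
    for key in ("gene_biotype", "gene_type"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    return None


def read_gtf(path: str | Path, taxonomy: BiotypeTaxonomy | None = None) -> AnnotationSet:
    """Read an Ensembl-dialect GTF into an :class:`AnnotationSet`.

    Requires gene/transcript/exon records with ``gene_id``/``transcript_id``
    attributes and a ``gene_biotype`` (or ``gene_type``) attribute on gene
    records.  GTF 1-based closed coordinates are converted to 0-based
    half-open at this boundary.  Genes with no exon in any transcript are
    rejected with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_gtf(path)
    genes: list[GeneModel] = []
    if path.stat().st_size == 0 or not any(
        line.strip() and not line.startswith("#") for line in open(path)
    ):
        return AnnotationSet([], taxonomy=taxonomy)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, featuretype="transcript", order_by="start"):
            exons = tuple(
                sorted(
                    (e.start - 1, e.end)
                    for e in db.children(t, featuretype="exon")
                )
            )
            if exons:
                transcripts.append(TranscriptModel(t.id, exons))
        if not transcripts:
            logger.warning("gene %s has no exons in any transcript; rejected", g.id)
            continue
        biotype = _biotype_of(g)
        if biotype is None:
            logger.warning("gene %s lacks a biotype attribute; marked unclassified", g.id)
            biotype = "__missing__"
        symbol = g.attributes.get("gene_name", [g.id])[0]
        genes.append(
            GeneModel(
                gene_id=g.id,
                symbol=symbol,
                chrom=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand,
                raw_biotype=biotype,
                transcripts=tuple(transcripts),
            )
        )
    annset = AnnotationSet(genes, taxonomy=taxonomy)
    unclassified = annset.unclassified_genes()
    if unclassified:
        logger.info("%d genes carry biotypes absent from the taxonomy", len(unclassified))
    return annset


def write_gtf(annset: AnnotationSet, path: str | Path, source: str = "trapscan") -> None:
    """Write an AnnotationSet back to Ensembl-dialect GTF (1-based closed)."""
    lines: list[str] = []
    for g in sorted(annset, key=lambda g: (g.chrom, g.start, g.gene_id)):
        attrs = (
            f'gene_id "{g.gene_id}"; gene_name "{g.symbol}"; '
            f'gene_biotype "{g.raw_biotype}";'
        )
        lines.append(
            "\t".join(
                [g.chrom, source, "gene", str(g.start + 1), str(g.end), ".", g.strand, ".", attrs]
            )
        )
        for t in g.transcripts:
            tattrs = (
                f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_biotype "{g.raw_biotype}";'
            )
            lines.append(
                "\t".join(
                    [
                        g.chrom,
                        source,
                        "transcript",
                        str(t.exons[0][0] + 1),
                        str(t.exons[-1][1]),
                        ".",
                        g.strand,
                        ".",
                        tattrs,
                    ]
                )
            )
            for s, e in t.exons:
                lines.append(
                    "\t".join(
                        [g.chrom, source, "exon", str(s + 1), str(e), ".", g.strand, ".", tattrs]
                    )
                )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
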