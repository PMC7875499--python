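"""Synthetic gene-trap libraries with known ground truth.

The generator builds (a) a small genome annotation whose genes span the
major biotypes — including deliberately planted overlap arrangements
(an antisense pair, a sense-intronic host/guest, a bidirectional-promoter
pair and a sense-overlapping host) and single-exon genes — and (b) a raw
tag library produced by configurable vectors with 5'- or 3'-biased
positional models, per-biotype preference multipliers, optional expression
dependence, and mapping noise (unmapped / low-quality / multi-mapping tags
and extra non-representative duplicates).  Every integration is recorded in
a ground-truth table, so each pipeline stage can be checked against what
was planted.  All randomness flows from the config seed: identical config
implies byte-identical GTF, tag TSV and ground-truth outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genome import AnnotationSet, BiotypeTaxonomy, GeneModel, TranscriptModel, write_gtf

POSITIONAL_MODELS = ("five_prime_geometric", "three_prime_geometric", "uniform")


class ConfigError(ValueError):
    pass


@dataclass
class VectorSpec:
    vector_id: str
    vector_class: str
    positional_model: str = "uniform"
    rho: float = 0.5
    biotype_multipliers: dict[str, float] = field(default_factory=dict)
    expression_dependent: bool = False

    def __post_init__(self) -> None:
        if self.positional_model not in POSITIONAL_MODELS:
            raise ConfigError(f"unknown positional model {self.positional_model!r}")
        if not 0 < self.rho < 1:
            raise ConfigError("rho must lie in (0, 1)")
        if any(m < 0 for m in self.biotype_multipliers.values()):
            raise ConfigError("biotype multipliers must be nonnegative")


def decile_pmf(model: str, rho: float = 0.5) -> np.ndarray:
    """Probability mass over deciles 1..10 for a positional model.

    The geometric family puts mass (1-rho)^(d-1) on decile d (5' model) or
    its mirror image (3' model), normalised over the ten deciles.
    """
    if model == "uniform":
        return np.full(10, 0.1)
    w = (1.0 - rho) ** np.arange(10)
    w /= w.sum()
    if model == "three_prime_geometric":
        w = w[::-1].copy()
    return w


@dataclass
class NoiseSpec:
    p_unmapped: float = 0.10
    p_low_quality: float = 0.05
    p_multi_hit: float = 0.10
    extra_nonrepresentative_tags_per_integration: float = 0.2

    def __post_init__(self) -> None:
        for name in ("p_unmapped", "p_low_quality", "p_multi_hit"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.p_unmapped + self.p_low_quality + self.p_multi_hit > 1:
            raise ConfigError("noise probabilities must sum to at most 1")
        if self.extra_nonrepresentative_tags_per_integration < 0:
            raise ConfigError("extra tag rate must be nonnegative")


def _default_genes_per_biotype() -> dict[str, int]:
    # mouse census proportions at roughly 1/50 scale
    return {
        "protein_coding": 440,
        "lincRNA": 72,
        "antisense": 44,
        "sense_overlapping": 3,
        "sense_intronic": 6,
        "bidirectional_promoter": 3,
        "processed_transcript": 25,
        "TEC": 25,
        "3prime_overlapping_ncRNA": 2,
        "macro_lncRNA": 2,
        "miRNA": 60,
        "snoRNA": 30,
        "snRNA": 30,
        "processed_pseudogene": 160,
    }


def _default_single_exon_p() -> dict[str, float]:
    return {
        "protein_coding": 0.02,
        "lincRNA": 0.25,
        "antisense": 0.30,
        "sense_overlapping": 0.10,
        "sense_intronic": 0.50,
        "bidirectional_promoter": 0.30,
        "processed_transcript": 0.10,
        "TEC": 1.0,
        "3prime_overlapping_ncRNA": 0.50,
        "macro_lncRNA": 1.0,
        "miRNA": 1.0,
        "snoRNA": 1.0,
        "snRNA": 1.0,
        "processed_pseudogene": 0.90,
    }


def _default_expression_fraction() -> dict[str, float]:
    return {"protein_coding": 0.85, "default": 0.50}


def _default_vectors() -> list[VectorSpec]:
    return [
        VectorSpec(
            "pSAbgeo",
            "promoter_trap_SA",
            positional_model="five_prime_geometric",
            rho=0.5,
            expression_dependent=True,
        ),
        VectorSpec(
            "pPolyA",
            "polyA_trap",
            positional_model="three_prime_geometric",
            rho=0.5,
            expression_dependent=False,
        ),
    ]


@dataclass
class SyntheticConfig:
    seed: int = 0
    genes_per_biotype: dict[str, int] = field(default_factory=_default_genes_per_biotype)
    gene_length_range: tuple[int, int] = (2_000, 20_000)
    single_exon_probability: dict[str, float] = field(default_factory=_default_single_exon_p)
    mean_exons: float = 5.0
    expression_fraction: dict[str, float] = field(default_factory=_default_expression_fraction)
    vectors: list[VectorSpec] = field(default_factory=_default_vectors)
    n_integrations_per_vector: int = 5_000
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    intergenic_fraction: float = 0.40
    chromosome_length: int = 30_000_000
    max_chromosomes: int = 64

    def __post_init__(self) -> None:
        if isinstance(self.noise, dict):
            self.noise = NoiseSpec(**self.noise)
        self.vectors = [
            v if isinstance(v, VectorSpec) else VectorSpec(**v) for v in self.vectors
        ]
        self.gene_length_range = tuple(self.gene_length_range)
        if any(n < 0 for n in self.genes_per_biotype.values()):
            raise ConfigError("gene counts must be nonnegative")
        if not 0 <= self.intergenic_fraction <= 1:
            raise ConfigError("intergenic_fraction must lie in [0, 1]")
        for p in self.single_exon_probability.values():
            if not 0 <= p <= 1:
                raise ConfigError("single-exon probabilities must lie in [0, 1]")
        for p in self.expression_fraction.values():
            if not 0 <= p <= 1:
                raise ConfigError("expression fractions must lie in [0, 1]")
        if self.n_integrations_per_vector < 0:
            raise ConfigError("n_integrations_per_vector must be nonnegative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["gene_length_range"] = list(self.gene_length_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class GroundTruth:
    """Planted truth: one row per clean integration, plus the per-vector
    preference multipliers that generated them."""

    events: pd.DataFrame
    multipliers: dict[str, dict[str, float]]

    def to_tsv(self, path: str | Path) -> None:
        self.events.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotation generation

_SPECIAL_MARGIN = 2_000


def _draw_exons(
    rng: np.random.Generator, start: int, end: int, n_exons: int
) -> tuple[tuple[int, int], ...]:
    """Partition [start, end) into n exons separated by n-1 introns."""
    length = end - start
    if n_exons == 1 or length < 4 * n_exons:
        return ((start, end),)
    # 2n-2 interior cut points define alternating exon/intron segments
    cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 2, replace=False))
    bounds = np.concatenate([[0], cuts, [length]])
    exons = []
    for i in range(0, len(bounds) - 1, 2):
        s, e = int(bounds[i]), int(bounds[i + 1])
        if s == e:
            e += 1
        exons.append((start + s, start + e))
    # clamp any rounding overlap introduced by the degenerate-segment fix
    fixed = []
    prev_end = start - 1
    for s, e in exons:
        s = max(s, prev_end + 1)
        e = max(e, s + 1)
        fixed.append((min(s, end - 1), min(e, end)))
        prev_end = fixed[-1][1]
    fixed[0] = (start, fixed[0][1])
    fixed[-1] = (fixed[-1][0], end)
    if fixed[-1][0] >= fixed[-1][1]:
        return ((start, end),)
    return tuple(fixed)


class _Genome:
    """Sequential gene placement across synthetic chromosomes."""

    def __init__(self, config: SyntheticConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.chrom_idx = 1
        self.cursor = 0
        self.genes: list[GeneModel] = []
        self._gene_no = 0

    @property
    def chrom(self) -> str:
        return f"chrS{self.chrom_idx}"

    def _advance(self, span: int) -> tuple[str, int]:
        gap = int(self.rng.integers(2_000, 20_000))
        if self.cursor + gap + span > self.config.chromosome_length:
            self.chrom_idx += 1
            if self.chrom_idx > self.config.max_chromosomes:
                raise ConfigError(
                    "requested genes exceed synthetic chromosome capacity"
                )
            self.cursor = 0
            gap = int(self.rng.integers(2_000, 20_000))
        start = self.cursor + gap
        self.cursor = start + span
        return self.chrom, start

    def next_id(self) -> str:
        self._gene_no += 1
        return f"SG{self._gene_no:05d}"

    def add(self, biotype: str, length: int | None = None, strand: str | None = None,
            n_exons: int | None = None) -> GeneModel:
        cfg, rng = self.config, self.rng
        lo, hi = cfg.gene_length_range
        if length is None:
            length = int(rng.integers(lo, hi + 1))
        chrom, start = self._advance(length)
        gene = self._build(biotype, chrom, start, start + length, strand, n_exons)
        self.genes.append(gene)
        return gene

    def _build(self, biotype, chrom, start, end, strand=None, n_exons=None) -> GeneModel:
        cfg, rng = self.config, self.rng
        if strand is None:
            strand = "+" if rng.random() < 0.5 else "-"
        if n_exons is None:
            p1 = cfg.single_exon_probability.get(biotype, 0.2)
            if rng.random() < p1:
                n_exons = 1
            else:
                n_exons = 2 + int(rng.poisson(max(cfg.mean_exons - 2, 0)))
        gid = self.next_id()
        exons = _draw_exons(rng, start, end, n_exons)
        return GeneModel(
            gene_id=gid,
            symbol=f"Sim{gid[2:]}",
            chrom=chrom,
            start=start,
            end=end,
            strand=strand,
            raw_biotype=biotype,
            transcripts=(TranscriptModel(f"{gid}.T1", exons),),
        )

    def add_at(self, biotype, chrom, start, end, strand, n_exons=None) -> GeneModel:
        gene = self._build(biotype, chrom, start, end, strand, n_exons)
        self.genes.append(gene)
        return gene


def _plant_special_cases(genome: _Genome, remaining: dict[str, int]) -> None:
    """Overlap arrangements exercising the subclass-specific annotation and
    mechanism rules; each consumes genes from the requested counts."""
    rng = genome.rng

    def take(biotype: str, k: int = 1) -> bool:
        if remaining.get(biotype, 0) >= k and remaining.get("protein_coding", 0) >= 1:
            return True
        return False

    # antisense lncRNA overlapping the 5' end of a PCG, opposite strand
    if take("antisense"):
        pcg = genome.add("protein_coding", length=12_000, strand="+")
        a_start = max(pcg.start - 3_000, 0)
        genome.add_at("antisense", pcg.chrom, a_start, pcg.start + 4_000, "-")
        remaining["antisense"] -= 1
        remaining["protein_coding"] -= 1

    # sense-intronic lncRNA inside a host intron, same strand
    if take("sense_intronic"):
        host_len = 20_000
        chrom, start = genome._advance(host_len)
        end = start + host_len
        exons = ((start, start + 1_000), (end - 1_000, end))
        gid = genome.next_id()
        host = GeneModel(
            gene_id=gid, symbol=f"Sim{gid[2:]}", chrom=chrom, start=start, end=end,
            strand="+", raw_biotype="protein_coding",
            transcripts=(TranscriptModel(f"{gid}.T1", exons),),
        )
        genome.genes.append(host)
        genome.add_at("sense_intronic", chrom, start + 5_000, start + 9_000, "+")
        remaining["sense_intronic"] -= 1
        remaining["protein_coding"] -= 1

    # bidirectional-promoter lncRNA just upstream of a PCG, opposite strand
    if take("bidirectional_promoter"):
        pcg = genome.add("protein_coding", length=10_000, strand="+")
        b_start = max(pcg.start - 3_500, 0)
        genome.add_at(
            "bidirectional_promoter", pcg.chrom, b_start, pcg.start - 200, "-"
        )
        remaining["bidirectional_promoter"] -= 1
        remaining["protein_coding"] -= 1

    # sense-overlapping lncRNA hosting a PCG in its first intron, same strand
    if take("sense_overlapping"):
        host_len = 24_000
        chrom, start = genome._advance(host_len)
        end = start + host_len
        gid = genome.next_id()
        exons = ((start, start + 800), (end - 2_000, end))
        host = GeneModel(
            gene_id=gid, symbol=f"Sim{gid[2:]}", chrom=chrom, start=start, end=end,
            strand="+", raw_biotype="sense_overlapping",
            transcripts=(TranscriptModel(f"{gid}.T1", exons),),
        )
        genome.genes.append(host)
        genome.add_at("protein_coding", chrom, start + 4_000, start + 14_000, "+")
        remaining["sense_overlapping"] -= 1
        remaining["protein_coding"] -= 1


def generate_annotation(
    config: SyntheticConfig, taxonomy: BiotypeTaxonomy | None = None
) -> AnnotationSet:
    """Generate the synthetic genome annotation for ``config`` (deterministic
    in ``config.seed``)."""
    rng = np.random.default_rng([config.seed % (2**31), 101])
    genome = _Genome(config, rng)
    remaining = dict(config.genes_per_biotype)
    _plant_special_cases(genome, remaining)
    for biotype in sorted(remaining):
        for _ in range(remaining[biotype]):
            lo, hi = config.gene_length_range
            if biotype in ("miRNA", "snoRNA", "snRNA"):
                length = int(rng.integers(80, 300))
            else:
                length = int(rng.integers(lo, hi + 1))
            genome.add(biotype, length=length)
    return AnnotationSet(genome.genes, taxonomy=taxonomy)


# ---------------------------------------------------------------------------
# tag generation

TRUTH_COLUMNS = [
    "cell_line_id",
    "vector_id",
    "gene_id",
    "raw_biotype",
    "chrom",
    "position",
    "decile",
]


def _gene_arrays(ann: AnnotationSet):
    genes = sorted(ann, key=lambda g: g.gene_id)
    return {
        "gene": genes,
        "gene_id": np.array([g.gene_id for g in genes]),
        "raw": np.array([g.raw_biotype for g in genes]),
        "start": np.array([g.start for g in genes], dtype=np.int64),
        "end": np.array([g.end for g in genes], dtype=np.int64),
        "length": np.array([g.length for g in genes], dtype=np.int64),
        "plus": np.array([g.strand == "+" for g in genes]),
        "chrom": np.array([g.chrom for g in genes]),
        "major": np.array([ann.classify(g)[0] for g in genes]),
        "sub": np.array([ann.classify(g)[1] for g in genes]),
    }


def _intergenic_space(ann: AnnotationSet):
    """Per-chromosome complement of gene spans, as flat arrays for sampling."""
    spans: dict[str, list[tuple[int, int]]] = {}
    for g in ann:
        spans.setdefault(g.chrom, []).append((g.start, g.end))
    gaps = []
    for chrom in sorted(spans):
        merged: list[list[int]] = []
        for s, e in sorted(spans[chrom]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        cursor = 0
        for s, e in merged:
            if s - cursor > 2:
                gaps.append((chrom, cursor + 1, s - 1))
            cursor = e
        gaps.append((chrom, cursor + 1, cursor + 10_000))
    chroms = np.array([g[0] for g in gaps])
    starts = np.array([g[1] for g in gaps], dtype=np.int64)
    ends = np.array([g[2] for g in gaps], dtype=np.int64)
    lengths = (ends - starts).astype(float)
    return chroms, starts, ends, lengths / lengths.sum()


def _vector_weights(
    spec: VectorSpec, arrays, expressed: np.ndarray
) -> np.ndarray:
    mult = spec.biotype_multipliers
    known = set(arrays["raw"]) | set(arrays["sub"]) | set(arrays["major"])
    for key in mult:
        if key not in known:
            raise ConfigError(
                f"vector {spec.vector_id}: multiplier references unknown "
                f"biotype label {key!r}"
            )
    w = np.ones(len(arrays["raw"]))
    for i, (raw, sub, major) in enumerate(
        zip(arrays["raw"], arrays["sub"], arrays["major"])
    ):
        if raw in mult:
            w[i] = mult[raw]
        elif sub in mult:
            w[i] = mult[sub]
        elif major in mult:
            w[i] = mult[major]
    if spec.expression_dependent:
        w = w * expressed
    total = w.sum()
    if total <= 0:
        raise ConfigError(
            f"vector {spec.vector_id}: no eligible target genes (all weights zero)"
        )
    return w / total


def generate_tags(
    ann: AnnotationSet, config: SyntheticConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the raw tag library for ``ann`` under ``config``.

    Returns the tag frame (schema of :data:`trapscan.tags.TAG_COLUMNS`) and
    the :class:`GroundTruth` of planted clean integrations.  Expression
    flags are drawn per gene from ``config.expression_fraction`` using the
    config seed, so repeated calls are reproducible.
    """
    rng = np.random.default_rng([config.seed % (2**31), 202])
    arrays = _gene_arrays(ann)
    n_genes = len(arrays["gene_id"])
    if n_genes == 0 and config.intergenic_fraction < 1 and config.n_integrations_per_vector:
        raise ConfigError("annotation contains no genes to trap")

    frac = config.expression_fraction
    default_frac = frac.get("default", 0.5)
    p_expr = np.array(
        [
            frac.get(raw, frac.get(major, default_frac))
            for raw, major in zip(arrays["raw"], arrays["major"])
        ]
    )
    expressed = rng.random(n_genes) < p_expr

    gap_chroms, gap_starts, gap_ends, gap_p = _intergenic_space(ann)
    noise = config.noise

    tag_frames: list[pd.DataFrame] = []
    truth_rows: list[pd.DataFrame] = []
    for spec in config.vectors:
        m = config.n_integrations_per_vector
        weights = _vector_weights(spec, arrays, expressed)
        pmf = decile_pmf(spec.positional_model, spec.rho)

        is_inter = rng.random(m) < config.intergenic_fraction
        gene_idx = rng.choice(n_genes, size=m, p=weights) if n_genes else np.zeros(m, int)
        deciles = rng.choice(10, size=m, p=pmf) + 1
        u = rng.random(m)

        rel = (deciles - 1 + u) / 10.0
        L = arrays["length"][gene_idx]
        offset = np.floor(rel * L).astype(np.int64)
        pos = np.where(
            arrays["plus"][gene_idx],
            arrays["start"][gene_idx] + offset,
            arrays["end"][gene_idx] - 1 - offset,
        )
        chrom = arrays["chrom"][gene_idx].copy()
        strand = np.where(arrays["plus"][gene_idx], "+", "-")

        # overwrite intergenic events with gap-uniform positions
        n_inter = int(is_inter.sum())
        if n_inter:
            gi = rng.choice(len(gap_p), size=n_inter, p=gap_p)
            gpos = gap_starts[gi] + np.floor(
                rng.random(n_inter) * (gap_ends[gi] - gap_starts[gi])
            ).astype(np.int64)
            chrom[is_inter] = gap_chroms[gi]
            pos[is_inter] = gpos
            strand[is_inter] = np.where(rng.random(n_inter) < 0.5, "+", "-")

        r = rng.random(m)
        unmapped = r < noise.p_unmapped
        lowq = (~unmapped) & (r < noise.p_unmapped + noise.p_low_quality)
        multi = (
            (~unmapped)
            & (~lowq)
            & (r < noise.p_unmapped + noise.p_low_quality + noise.p_multi_hit)
        )
        clean = ~(unmapped | lowq | multi)

        cell_ids = np.array([f"{spec.vector_id}:CL{i:06d}" for i in range(m)])
        base = pd.DataFrame(
            {
                "tag_id": [f"{c}:T0" for c in cell_ids],
                "cell_line_id": cell_ids,
                "vector_id": spec.vector_id,
                "vector_class": spec.vector_class,
                "chrom": np.where(unmapped, "", chrom),
                "position": np.where(unmapped, -1, pos),
                "tag_strand": np.where(unmapped, "", strand),
                "mapped": ~unmapped,
                "alignment_quality": np.where(unmapped | lowq, "low", "high"),
                "n_high_quality_alignments": np.where(
                    unmapped | lowq, 0, np.where(multi, 2, 1)
                ),
                "representative": True,
            }
        )
        tag_frames.append(base)

        n_extra = rng.poisson(
            noise.extra_nonrepresentative_tags_per_integration, size=m
        )
        n_extra[~clean] = 0
        if n_extra.sum():
            src = np.repeat(np.nonzero(n_extra)[0], n_extra[n_extra > 0])
            ordinal = np.concatenate(
                [np.arange(1, k + 1) for k in n_extra[n_extra > 0]]
            )
            extra = base.iloc[src].copy()
            extra["tag_id"] = [
                f"{c}:T{j}" for c, j in zip(extra["cell_line_id"], ordinal)
            ]
            extra["representative"] = False
            tag_frames.append(extra)

        # ground truth of clean integrations; decile recomputed from the
        # emitted coordinate so the planted record matches the pipeline's
        # coordinate conventions exactly
        gsel = clean & ~is_inter
        truth_decile = np.zeros(m, dtype=np.int64)
        gi_sel = gene_idx[gsel]
        rel_back = np.where(
            arrays["plus"][gi_sel],
            (pos[gsel] - arrays["start"][gi_sel]) / arrays["length"][gi_sel],
            (arrays["end"][gi_sel] - 1 - pos[gsel]) / arrays["length"][gi_sel],
        )
        truth_decile[gsel] = (rel_back * 10).astype(np.int64) + 1
        truth = pd.DataFrame(
            {
                "cell_line_id": cell_ids[clean],
                "vector_id": spec.vector_id,
                "gene_id": np.where(
                    is_inter[clean], "", arrays["gene_id"][gene_idx[clean]]
                ),
                "raw_biotype": np.where(
                    is_inter[clean], "", arrays["raw"][gene_idx[clean]]
                ),
                "chrom": chrom[clean],
                "position": pos[clean],
                "decile": np.where(is_inter[clean], 0, truth_decile[clean]),
            }
        )
        truth_rows.append(truth)

    tags = pd.concat(tag_frames, ignore_index=True) if tag_frames else pd.DataFrame(columns=TRUTH_COLUMNS)
    tags = tags.sort_values(["cell_line_id", "tag_id"], kind="mergesort").reset_index(drop=True)
    truth_df = pd.concat(truth_rows, ignore_index=True)
    multipliers = {v.vector_id: dict(v.biotype_multipliers) for v in config.vectors}
    return tags, GroundTruth(events=truth_df, multipliers=multipliers)


def generate_library(
    config: SyntheticConfig, outdir: str | Path, taxonomy: BiotypeTaxonomy | None = None
) -> dict[str, Path]:
    """Generate annotation + tags and write GTF, tag TSV, truth TSV, config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann = generate_annotation(config, taxonomy=taxonomy)
    tags, truth = generate_tags(ann, config)
    paths = {
        "gtf": outdir / "annotation.gtf",
        "tags": outdir / "tags.tsv",
        "truth": outdir / "ground_truth.tsv",
        "config": outdir / "config.yaml",
    }
    write_gtf(ann, paths["gtf"])
    tags.to_csv(paths["tags"], sep="\t", index=False)
    truth.to_tsv(paths["truth"])
    config.to_yaml(paths["config"])
    return paths
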