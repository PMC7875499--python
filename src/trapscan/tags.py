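"""Gene-trap sequence-tag input and the representative-tag filter.

A trapped ES cell line is typically represented in the source database by
several sequence tags of varying mapping quality.  The filter reduces the
raw tag set to exactly one representative, uniquely and confidently mapped
tag per vector integration, applying in order: (1) drop unmapped or
low-quality tags, (2) drop tags with multiple high-quality alignments,
(3) keep only tags flagged representative.  One integration per cell line
is assumed; residual ties are resolved deterministically and logged.

Tags live in a pandas DataFrame with the :data:`TAG_COLUMNS` schema; the
:class:`SequenceTag` dataclass is the single-record view.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VECTOR_CLASSES = (
    "promoter_trap_SA",
    "exon_trap",
    "polyA_trap",
    "combined",
    "secretory_trap",
)

TAG_COLUMNS = [
    "tag_id",
    "cell_line_id",
    "vector_id",
    "vector_class",
    "chrom",
    "position",
    "tag_strand",
    "mapped",
    "alignment_quality",
    "n_high_quality_alignments",
    "representative",
]

INTEGRATION_COLUMNS = [
    "cell_line_id",
    "vector_id",
    "vector_class",
    "chrom",
    "position",
    "tag_strand",
    "source_tag_id",
]

_TRUE = {"1", "true", "True", "TRUE", True, 1}
_FALSE = {"0", "false", "False", "FALSE", False, 0, "", None}


class TagSchemaError(ValueError):
    """Raised when a tag table is missing required columns."""


@dataclass(frozen=True)
class SequenceTag:
    tag_id: str
    cell_line_id: str
    vector_id: str
    vector_class: str
    mapped: bool
    alignment_quality: str  # "high" | "low"
    n_high_quality_alignments: int
    representative: bool
    chrom: str | None = None
    position: int | None = None
    tag_strand: str | None = None

    def __post_init__(self) -> None:
        if not self.mapped and self.chrom is not None:
            raise ValueError(f"{self.tag_id}: unmapped tag must not carry coordinates")
        if self.n_high_quality_alignments == 0 and self.alignment_quality == "high":
            raise ValueError(
                f"{self.tag_id}: zero high-quality alignments but quality 'high'"
            )


@dataclass
class FilterReport:
    n_input: int = 0
    n_discarded_unmapped: int = 0
    n_discarded_no_unique_hq: int = 0
    n_discarded_multi_hq: int = 0
    n_discarded_nonrepresentative: int = 0
    n_retained: int = 0

    def check(self) -> None:
        total = (
            self.n_retained
            + self.n_discarded_unmapped
            + self.n_discarded_no_unique_hq
            + self.n_discarded_multi_hq
            + self.n_discarded_nonrepresentative
        )
        if total != self.n_input:
            raise AssertionError(
                f"filter report does not conserve tags: {total} != {self.n_input}"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _parse_bool(series: pd.Series, name: str) -> pd.Series:
    def one(v):
        if v in _TRUE:
            return True
        if v in _FALSE or (isinstance(v, float) and np.isnan(v)):
            return False
        raise ValueError(f"column {name}: cannot parse boolean {v!r}")

    return series.map(one)


def tags_to_frame(tags: Iterable[SequenceTag]) -> pd.DataFrame:
    rows = []
    for t in tags:
        d = asdict(t)
        d["chrom"] = t.chrom if t.chrom is not None else ""
        d["position"] = t.position if t.position is not None else -1
        d["tag_strand"] = t.tag_strand if t.tag_strand is not None else ""
        rows.append(d)
    df = pd.DataFrame(rows, columns=TAG_COLUMNS)
    return _normalise(df)


def _normalise(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["chrom"] = df["chrom"].fillna("").astype(str).replace({"nan": ""})
    df["tag_strand"] = df["tag_strand"].fillna("").astype(str).replace({"nan": ""})
    df["position"] = (
        pd.to_numeric(df["position"], errors="coerce").fillna(-1).astype(np.int64)
    )
    df["n_high_quality_alignments"] = df["n_high_quality_alignments"].astype(np.int64)
    for col in ("mapped", "representative"):
        if df[col].dtype != bool:
            df[col] = _parse_bool(df[col], col)
    return df[TAG_COLUMNS]


def read_tags(path: str | Path) -> pd.DataFrame:
    """Read a tag TSV into the canonical tag frame.

    The header must name every :data:`TAG_COLUMNS` field; booleans accept
    0/1/true/false; unmapped rows may leave chrom/position/strand empty.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "tag_strand": str})
    missing = [c for c in TAG_COLUMNS if c not in df.columns]
    if missing:
        raise TagSchemaError(f"{path}: missing required columns: {', '.join(missing)}")
    try:
        df = _normalise(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    bad = df.index[(df["mapped"]) & (df["position"] < 0)]
    if len(bad):
        # +2: one for the header line, one for 0-based indexing
        raise ValueError(
            f"{path}: line {bad[0] + 2}: mapped tag without a valid integer position"
        )
    return df


def read_tags_bed(bed_path: str | Path, meta_path: str | Path) -> pd.DataFrame:
    """Read tags from BED6 (positions) plus a sidecar metadata TSV.

    The BED name field carries ``tag_id``; the metadata TSV, joined on
    ``tag_id``, supplies everything except chrom/position/strand.
    """
    bed = pd.read_csv(
        bed_path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "tag_id", "score", "tag_strand"],
        dtype={"chrom": str},
    )
    meta = pd.read_csv(meta_path, sep="\t")
    needed = [c for c in TAG_COLUMNS if c not in ("chrom", "position", "tag_strand")]
    missing = [c for c in needed if c not in meta.columns]
    if missing:
        raise TagSchemaError(
            f"{meta_path}: missing required columns: {', '.join(missing)}"
        )
    df = meta.merge(bed[["tag_id", "chrom", "start", "tag_strand"]], on="tag_id", how="left")
    df["position"] = df.pop("start")
    return _normalise(df)


def write_tags(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def filter_tags(
    tags: pd.DataFrame | Iterable[SequenceTag],
) -> tuple[pd.DataFrame, FilterReport]:
    """Reduce raw tags to one representative integration per cell line.

    Returns the integration frame (:data:`INTEGRATION_COLUMNS`) and a
    :class:`FilterReport` in which every input tag is attributed to exactly
    one outcome, each discard to the first rule that removed it.
    """
    if not isinstance(tags, pd.DataFrame):
        tags = tags_to_frame(list(tags))
    report = FilterReport(n_input=len(tags))
    if len(tags) == 0:
        empty = pd.DataFrame(columns=INTEGRATION_COLUMNS)
        return empty, report

    unmapped = ~tags["mapped"]
    low = tags["mapped"] & (
        (tags["alignment_quality"] != "high") | (tags["n_high_quality_alignments"] == 0)
    )
    multi = tags["mapped"] & ~low & (tags["n_high_quality_alignments"] > 1)
    surviving = ~(unmapped | low | multi)
    nonrep = surviving & ~tags["representative"]
    keep = surviving & tags["representative"]

    report.n_discarded_unmapped = int(unmapped.sum())
    report.n_discarded_no_unique_hq = int(low.sum())
    report.n_discarded_multi_hq = int(multi.sum())
    report.n_discarded_nonrepresentative = int(nonrep.sum())

    kept = tags[keep].sort_values(["cell_line_id", "tag_id"], kind="mergesort")
    dup = kept.duplicated("cell_line_id", keep="first")
    ties = kept[dup]
    if len(ties):
        for cl in ties["cell_line_id"].unique():
            logger.warning(
                "cell line %s has multiple surviving representative tags; "
                "keeping lexicographically smallest tag_id",
                cl,
            )
        report.n_discarded_nonrepresentative += int(dup.sum())
        kept = kept[~dup]

    report.n_retained = len(kept)
    report.check()

    integrations = pd.DataFrame(
        {
            "cell_line_id": kept["cell_line_id"].to_numpy(),
            "vector_id": kept["vector_id"].to_numpy(),
            "vector_class": kept["vector_class"].to_numpy(),
            "chrom": kept["chrom"].to_numpy(),
            "position": kept["position"].to_numpy(),
            "tag_strand": kept["tag_strand"].to_numpy(),
            "source_tag_id": kept["tag_id"].to_numpy(),
        }
    ).reset_index(drop=True)
    return integrations, report


def integrations_to_tags(integrations: pd.DataFrame) -> pd.DataFrame:
    """Re-express integrations as clean representative tags (for round trips)."""
    df = pd.DataFrame(
        {
            "tag_id": integrations["source_tag_id"],
            "cell_line_id": integrations["cell_line_id"],
            "vector_id": integrations["vector_id"],
            "vector_class": integrations["vector_class"],
            "chrom": integrations["chrom"],
            "position": integrations["position"],
            "tag_strand": integrations["tag_strand"],
            "mapped": True,
            "alignment_quality": "high",
            "n_high_quality_alignments": 1,
            "representative": True,
        }
    )
    return _normalise(df)


def write_integrations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_integrations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "tag_strand": str})
    missing = [c for c in INTEGRATION_COLUMNS if c not in df.columns]
    if missing:
        raise TagSchemaError(f"{path}: missing required columns: {', '.join(missing)}")
    return df[INTEGRATION_COLUMNS]
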