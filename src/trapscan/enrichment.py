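"""Vector-by-biotype enrichment: Fisher's exact test with BH FDR control.

For every (vector, biotype) pair a 2x2 contingency table is formed over
annotated (non-intergenic) primary hits:

            this biotype   other biotypes
  vector         a               b
  others         c               d

and over-representation is tested one-sided (hypergeometric upper tail).
All cells are adjusted jointly with the Benjamini-Hochberg step-up
procedure; a cell is significant when its adjusted p-value passes the FDR
constraint (0.01 by default).  The matrix of -log10 adjusted p-values is
the heatmap-ready summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: canonical column order of the heatmap matrix
MAJOR_ORDER = ("protein_coding", "lncRNA", "sncRNA", "pseudogene")
SUBCLASS_ORDER = (
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

NEG_LOG10_CAP = 300.0


class EnrichmentError(ValueError):
    pass


@dataclass
class EnrichmentMatrix:
    cells: pd.DataFrame  # long format, one row per (vector, biotype)
    neg_log10_adj: pd.DataFrame  # vectors x biotypes

    def significant_cells(self) -> pd.DataFrame:
        return self.cells[self.cells["significant"]]


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided (over-representation) Fisher exact p for a 2x2 table."""
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be nonnegative")
    if a + b + c + d == 0:
        raise ValueError("empty contingency table")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def bh_adjust(
    p_values: Sequence[float], fdr: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance flags.

    ``significant[i]`` is true when the adjusted p-value is at most the FDR
    constraint.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("need a non-empty 1-d p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj, p_adj <= fdr


def _universe(hits: pd.DataFrame, level: str) -> pd.DataFrame:
    """Primary, annotated hits labelled at the requested level."""
    sel = hits[hits["is_primary"] & ~hits["intergenic"]].copy()
    if level == "major_class":
        sel["biotype_label"] = sel["major_class"]
        sel = sel[sel["major_class"].isin(MAJOR_ORDER)]
    elif level == "lnc_subclass":
        sel = sel[sel["major_class"] == "lncRNA"]
        sel["biotype_label"] = sel["lnc_subclass"]
    else:
        raise ValueError(f"unknown enrichment level {level!r}")
    return sel


def build_tables(hits: pd.DataFrame, level: str = "major_class") -> pd.DataFrame:
    """Fill the 2x2 table counts for every (vector, biotype) cell.

    Vectors are all vector ids present among annotated primary hits; a
    vector whose hits all fall outside the universe still yields all-zero
    ``a``/``b`` cells so that its absence is visible downstream.
    """
    uni = _universe(hits, level)
    vectors = sorted(
        hits.loc[hits["is_primary"] | hits["intergenic"], "vector_id"].unique()
    )
    if len(vectors) < 2:
        raise EnrichmentError("comparison group empty: need at least two vectors")
    labels = _label_order(uni["biotype_label"].unique(), level)
    if len(labels) < 2:
        raise EnrichmentError("need at least two biotype labels among annotated hits")

    counts = (
        uni.groupby(["vector_id", "biotype_label"], sort=False)
        .size()
        .unstack(fill_value=0)
        .reindex(index=vectors, columns=labels, fill_value=0)
    )
    grand = int(counts.to_numpy().sum())
    vec_tot = counts.sum(axis=1)
    bio_tot = counts.sum(axis=0)

    rows = []
    for v in vectors:
        for lab in labels:
            a = int(counts.loc[v, lab])
            b = int(vec_tot[v] - a)
            c = int(bio_tot[lab] - a)
            d = grand - a - b - c
            rows.append({"vector_id": v, "biotype_label": lab, "a": a, "b": b, "c": c, "d": d})
    return pd.DataFrame(rows)


def _label_order(present, level: str) -> list[str]:
    order = MAJOR_ORDER if level == "major_class" else SUBCLASS_ORDER
    present = set(present)
    ordered = [x for x in order if x in present]
    ordered += sorted(present - set(order))
    return ordered


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def enrichment_matrix(
    hits: pd.DataFrame,
    level: str = "major_class",
    fdr: float = 0.01,
    family: str = "global",
) -> EnrichmentMatrix:
    """Full enrichment scan: tables -> one-sided Fisher -> BH -> -log10 matrix.

    ``family`` selects the multiplicity family: ``"global"`` adjusts all
    (vector, biotype) cells jointly, ``"per_vector"`` adjusts within each
    vector's row of cells.
    """
    cells = build_tables(hits, level)
    cells["odds_ratio"] = [
        _odds_ratio(r.a, r.b, r.c, r.d) for r in cells.itertuples(index=False)
    ]
    cells["p_value"] = [
        1.0 if (r.a + r.b) == 0 else fisher_one_sided(r.a, r.b, r.c, r.d)
        for r in cells.itertuples(index=False)
    ]
    if family == "global":
        p_adj, sig = bh_adjust(cells["p_value"].to_numpy(), fdr=fdr)
        cells["p_adjusted"], cells["significant"] = p_adj, sig
    elif family == "per_vector":
        cells["p_adjusted"] = np.nan
        cells["significant"] = False
        for v, idx in cells.groupby("vector_id").groups.items():
            p_adj, sig = bh_adjust(cells.loc[idx, "p_value"].to_numpy(), fdr=fdr)
            cells.loc[idx, "p_adjusted"] = p_adj
            cells.loc[idx, "significant"] = sig
    else:
        raise ValueError(f"unknown multiplicity family {family!r}")

    with np.errstate(divide="ignore"):
        cells["neg_log10_adj"] = np.minimum(
            -np.log10(cells["p_adjusted"].to_numpy()), NEG_LOG10_CAP
        )

    # rows: vectors by descending annotated total, ties by id; columns canonical
    totals = cells.groupby("vector_id")[["a"]].sum()["a"]
    vec_order = sorted(totals.index, key=lambda v: (-totals[v], v))
    label_order = [
        lab for lab in cells["biotype_label"].unique()
    ]  # build_tables already emits canonical order
    matrix = (
        cells.pivot(index="vector_id", columns="biotype_label", values="neg_log10_adj")
        .reindex(index=vec_order, columns=label_order)
    )
    matrix.index.name = "vector_id"
    matrix.columns.name = None
    return EnrichmentMatrix(cells=cells, neg_log10_adj=matrix)


def write_enrichment(result: EnrichmentMatrix, cells_path: str | Path, matrix_path: str | Path) -> None:
    result.cells.to_csv(cells_path, sep="\t", index=False)
    result.neg_log10_adj.to_csv(matrix_path, sep="\t")
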