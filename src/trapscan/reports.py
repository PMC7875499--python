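"""Summary tables over the annotated library.

Three views are produced: a biotype census (trapped genes and integrations
per major class, with shares of the trapped set and of the annotated
census), a ncRNA subclass table (unique trapped genes per lncRNA subclass
and vector class, with the combined lincRNA+antisense share), and a
spliced/non-spliced table (fraction of integrations whose host gene has a
single exon, per vector class and gene class).

Counting convention: census-style tables count every hit gene (not only
the primary hit), de-duplicated per (gene, cell line); positional and
enrichment statistics elsewhere use primary hits only.  All report numbers
are pure functions of the annotation table; percentages are rounded
half-up at the report layer only.
"""

from __future__ import annotations

import logging
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

import numpy as np
import pandas as pd

from .enrichment import MAJOR_ORDER, SUBCLASS_ORDER
from .genome import BiotypeTaxonomy

logger = logging.getLogger(__name__)


def round_half_up(value: float, places: int = 1) -> float:
    """Decimal round-half-up (the convention of printed report tables)."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _gene_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """All annotated hits de-duplicated per (gene, cell line)."""
    sel = hits[~hits["intergenic"]]
    return sel.drop_duplicates(["gene_id", "cell_line_id"])


def census_from_counts(
    trapped_genes: Mapping[str, int],
    integrations: Mapping[str, int] | None = None,
    annotated: Mapping[str, int] | None = None,
    places: int = 1,
) -> pd.DataFrame:
    """The biotype-census arithmetic on explicit per-class counts.

    ``percent_of_trapped`` is each class's share of all trapped genes;
    ``percent_of_annotated`` is trapped/annotated for classes with a census
    entry (others get NaN and a logged warning).
    """
    classes = [c for c in MAJOR_ORDER if c in trapped_genes]
    classes += [c for c in trapped_genes if c not in classes]
    total = sum(trapped_genes.values())
    rows = []
    for cls in classes:
        n_trapped = trapped_genes[cls]
        pct_trapped = round_half_up(100.0 * n_trapped / total, places) if total else np.nan
        n_annot = (annotated or {}).get(cls)
        if n_annot:
            pct_annot = round_half_up(100.0 * n_trapped / n_annot, places)
        else:
            pct_annot = np.nan
            logger.warning("no annotated census for class %s", cls)
        rows.append(
            {
                "major_class": cls,
                "n_annotated": n_annot if n_annot else np.nan,
                "n_trapped_genes": n_trapped,
                "n_integrations": (integrations or {}).get(cls, np.nan),
                "percent_of_trapped": pct_trapped,
                "percent_of_annotated": pct_annot,
            }
        )
    return pd.DataFrame(rows)


def census_report(
    hits: pd.DataFrame, taxonomy: BiotypeTaxonomy | None = None, places: int = 1
) -> pd.DataFrame:
    """Biotype census of the annotated library (one row per major class)."""
    taxonomy = taxonomy or BiotypeTaxonomy()
    gh = _gene_hits(hits)
    gh = gh[gh["major_class"].isin(MAJOR_ORDER)]
    trapped = gh.groupby("major_class")["gene_id"].nunique().to_dict()
    integrations = gh.groupby("major_class").size().to_dict()
    return census_from_counts(
        trapped, integrations=integrations, annotated=taxonomy.census, places=places
    )


def ncrna_subclass_report(
    hits: pd.DataFrame, places: int = 1
) -> tuple[pd.DataFrame, dict]:
    """Unique trapped genes per ncRNA subclass, split by vector class.

    Returns the table plus a summary with the combined lincRNA+antisense
    count and its share of trapped lncRNA genes, and the total number of
    unique trapped ncRNA genes (lncRNA + sncRNA).
    """
    gh = _gene_hits(hits)
    lnc = gh[gh["major_class"] == "lncRNA"]
    snc = gh[gh["major_class"] == "sncRNA"]

    if len(lnc) == 0:
        table = pd.DataFrame()
    else:
        table = (
            lnc.groupby(["lnc_subclass", "vector_class"])["gene_id"]
            .nunique()
            .unstack(fill_value=0)
        )
        table["total"] = [
            lnc[lnc["lnc_subclass"] == sub]["gene_id"].nunique()
            for sub in table.index
        ]
        order = [s for s in SUBCLASS_ORDER if s in table.index]
        order += [s for s in table.index if s not in order]
        table = table.loc[order]
        table.index.name = "lnc_subclass"

    n_lnc = lnc["gene_id"].nunique()
    n_snc = snc["gene_id"].nunique()
    n_linc = lnc.loc[lnc["lnc_subclass"] == "lincRNA", "gene_id"].nunique()
    n_anti = lnc.loc[lnc["lnc_subclass"] == "antisense", "gene_id"].nunique()
    summary = {
        "n_trapped_lncRNA_genes": n_lnc,
        "n_trapped_sncRNA_genes": n_snc,
        "n_trapped_ncRNA_genes": n_lnc + n_snc,
        "n_lincRNA": n_linc,
        "n_antisense": n_anti,
        "n_lincRNA_plus_antisense": n_linc + n_anti,
        "percent_lincRNA_plus_antisense": (
            round_half_up(100.0 * (n_linc + n_anti) / n_lnc, places) if n_lnc else np.nan
        ),
    }
    return table, summary


def spliced_report(hits: pd.DataFrame, places: int = 1) -> pd.DataFrame:
    """Per (vector class, gene class): share of integrations whose host
    gene is non-spliced (single exon in every transcript)."""
    sel = hits[hits["is_primary"] & ~hits["intergenic"]].copy()
    sel = sel[sel["major_class"].isin(MAJOR_ORDER)]
    if len(sel) == 0:
        return pd.DataFrame(
            columns=[
                "vector_class",
                "gene_class",
                "n_integrations",
                "n_in_nonspliced",
                "percent_nonspliced",
            ]
        )
    rows = []
    for (vc, gc), grp in sel.groupby(["vector_class", "major_class"], sort=True):
        n = len(grp)
        k = int((~grp["host_spliced"].astype(bool)).sum())
        rows.append(
            {
                "vector_class": vc,
                "gene_class": gc,
                "n_integrations": n,
                "n_in_nonspliced": k,
                "percent_nonspliced": round_half_up(100.0 * k / n, places),
            }
        )
    return pd.DataFrame(rows)


def genic_share(n_genic: int, n_intergenic: int, places: int = 1) -> float:
    """Percentage of integrations falling inside annotated gene spans."""
    total = n_genic + n_intergenic
    if total == 0:
        return float("nan")
    return round_half_up(100.0 * n_genic / total, places)
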