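"""Decile positional profiles and the G-test of goodness-of-fit.

Each gene is divided into ten equal-length segments ordered by distance
from the transcription start site; a profile is the vector of integration
counts per segment for one (vector class, gene class) stratum.  Departure
from positional uniformity is tested with the likelihood-ratio G statistic

    G = 2 * sum_i O_i * ln(O_i / E_i),    E_i = n / 10,

referred to a chi-square distribution with 9 degrees of freedom.  Cells
with zero observations contribute zero (the 0*ln0 limit); no continuity or
Williams correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

N_DECILES = 10

#: the strata profiled by default: SA promoter traps and polyA traps,
#: each over protein-coding genes and lncRNA genes
DEFAULT_STRATA = (
    ("promoter_trap_SA", "protein_coding"),
    ("promoter_trap_SA", "lncRNA"),
    ("polyA_trap", "protein_coding"),
    ("polyA_trap", "lncRNA"),
)


@dataclass
class PositionalProfile:
    vector_class: str
    gene_class: str
    counts: np.ndarray
    n: int
    G: float
    df: int
    p_value: float

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n if self.n else np.zeros_like(self.counts, float)


def g_test_uniform(counts: Sequence[int]) -> tuple[float, float]:
    """G statistic and upper-tail chi-square p for uniformity over cells.

    Raises on an all-zero count vector (the statistic is undefined).
    """
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 1 or len(obs) < 2:
        raise ValueError("counts must be a 1-d vector of at least two cells")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    n = obs.sum()
    if n == 0:
        raise ValueError("G-test undefined for an all-zero count vector")
    expected = n / len(obs)
    pos = obs > 0
    g = 2.0 * float(np.sum(obs[pos] * np.log(obs[pos] / expected)))
    g = max(g, 0.0)  # clamp -0.0 / rounding noise at the uniform point
    p = float(stats.chi2.sf(g, df=len(obs) - 1))
    return g, p


def decile_counts(
    hits: pd.DataFrame, vector_class: str, gene_class: str
) -> np.ndarray:
    """Counts over deciles 1..10 of primary hits in one stratum.

    ``gene_class`` is a major biotype class (e.g. ``protein_coding`` or
    ``lncRNA``).  An empty stratum yields the zero vector.
    """
    sel = hits[
        hits["is_primary"]
        & (hits["vector_class"] == vector_class)
        & (hits["major_class"] == gene_class)
    ]
    counts = np.zeros(N_DECILES, dtype=np.int64)
    if len(sel):
        binned = np.bincount(sel["decile"].to_numpy(np.int64), minlength=N_DECILES + 1)
        counts = binned[1 : N_DECILES + 1]
    return counts


def positional_profiles(
    hits: pd.DataFrame,
    strata: Sequence[tuple[str, str]] = DEFAULT_STRATA,
) -> list[PositionalProfile]:
    profiles = []
    for vector_class, gene_class in strata:
        counts = decile_counts(hits, vector_class, gene_class)
        n = int(counts.sum())
        if n > 0:
            g, p = g_test_uniform(counts)
        else:
            g, p = float("nan"), float("nan")
        profiles.append(
            PositionalProfile(vector_class, gene_class, counts, n, g, N_DECILES - 1, p)
        )
    return profiles


def profiles_to_frame(profiles: Sequence[PositionalProfile]) -> pd.DataFrame:
    """One row per stratum: decile counts, n, G, df, p, and counts/n."""
    rows = []
    for p in profiles:
        row = {"vector_class": p.vector_class, "gene_class": p.gene_class}
        for i in range(N_DECILES):
            row[f"decile_{i + 1}"] = int(p.counts[i])
        row.update({"n": p.n, "G": p.G, "df": p.df, "p_value": p.p_value})
        for i in range(N_DECILES):
            row[f"freq_{i + 1}"] = p.frequencies[i]
        rows.append(row)
    return pd.DataFrame(rows)


def write_profiles(profiles: Sequence[PositionalProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False)
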