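"""Shape-frequency statistics: tables, coverage, correlation, space size.

The central objects are shape frequency tables: for one ensemble of folded
structures, the count, probability and rank of every distinct abstract
shape.  Comparing the table from random genotype sampling (f_pG) with the
table from a natural database (f_p) quantifies how strongly phenotype bias
predicts which shapes nature uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyInputError, InsufficientOverlapError, UnsupportedLevelError

#: Columns of a shape frequency table.
SHAPE_TABLE_COLUMNS = ("shape", "count", "probability", "rank")


def shape_frequency_table(shapes: Iterable[str]) -> pd.DataFrame:
    """Tabulate counts, probabilities and ranks of a multiset of shapes.

    Rank 1 is the most probable shape; ties are broken lexicographically on
    the shape string so the table is deterministic.
    """
    shapes = list(shapes)
    if not shapes:
        raise EmptyInputError("no shapes to tabulate")
    counts = pd.Series(shapes).value_counts()
    df = counts.rename_axis("shape").reset_index(name="count")
    df = df.sort_values(["count", "shape"], ascending=[False, True],
                        kind="mergesort", ignore_index=True)
    df["probability"] = df["count"] / len(shapes)
    df["rank"] = np.arange(1, len(df) + 1)
    return df[list(SHAPE_TABLE_COLUMNS)]


def coverage_fraction(natural: pd.DataFrame, sampled: pd.DataFrame) -> float:
    """Fraction of unique natural shapes also found in the sampled ensemble."""
    if natural.empty or sampled.empty:
        raise EmptyInputError("empty shape table")
    nat = set(natural["shape"])
    return len(nat & set(sampled["shape"])) / len(nat)


def log_log_correlation(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    pseudocount: bool = False,
) -> Tuple[float, float, int]:
    """Pearson correlation of log10 shape probabilities between two tables.

    By default the correlation is computed over the intersection of shapes
    (zero frequencies have no logarithm).  With ``pseudocount=True`` the
    union of shapes is used with add-one smoothed probabilities
    (count + 1) / (total + #union shapes).

    Returns (r, two-sided p-value, number of shapes used).
    """
    if pseudocount:
        merged = table_a.merge(table_b, on="shape", how="outer",
                               suffixes=("_a", "_b")).fillna(0)
        n_union = len(merged)
        total_a = table_a["count"].sum()
        total_b = table_b["count"].sum()
        pa = (merged["count_a"] + 1) / (total_a + n_union)
        pb = (merged["count_b"] + 1) / (total_b + n_union)
    else:
        merged = table_a.merge(table_b, on="shape", suffixes=("_a", "_b"))
        pa = merged["probability_a"]
        pb = merged["probability_b"]
    n_common = len(merged)
    if n_common < 3:
        raise InsufficientOverlapError(
            f"need >= 3 shared shapes, got {n_common}"
        )
    r, p = stats.pearsonr(np.log10(pa), np.log10(pb))
    return float(r), float(p), n_common


@dataclass(frozen=True)
class ShapeSpaceEstimate:
    L: int
    level: int
    estimate: float

    @property
    def log10(self) -> float:
        return math.log10(self.estimate)


def shape_space_size(L: int, level: int = 5) -> ShapeSpaceEstimate:
    """Asymptotic count of possible level-5 shapes of length L.

    Evaluates 2.44 · 1.32^L · L^(−3/2) (minimum hairpin length 3, 'min'
    ladder length, the convention matching thermodynamic MFE folding).
    Exponential in L: about 10^9 shapes at L = 100 and 10^45 at L = 400.
    """
    if level != 5:
        raise UnsupportedLevelError(
            f"shape-space estimate implemented for level 5 only, got {level}"
        )
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    return ShapeSpaceEstimate(L=L, level=5,
                              estimate=2.44 * 1.32 ** L * L ** -1.5)
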