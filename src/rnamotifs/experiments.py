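"""Headline study computations at reproducible, fixed problem sizes.

These functions bundle the two main simulation experiments of the analysis
so that scripts and tests run them identically:

* G-sampling shape diversity — fold uniform random sequences, abstract to
  level-5 shapes, count unique shapes;
* random-ensemble motif trends — fold uniform random sequences over the
  50-3000 nt length grid and fit the per-motif linear trends m = a·L + b.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .folding import ViennaEngine
from .motif_trends import DEFAULT_LENGTH_GRID, build_length_grid_dataset, ols_line
from .sampling import CompositionSpec, SeedLike, random_sequences
from .shape_stats import shape_frequency_table
from .shapes import abstract_shape
from .structure_core import FEATURE_ORDER


def unique_shape_count(
    n: int = 30_000,
    L: int = 100,
    seed: SeedLike = 0,
    engine=None,
) -> int:
    """Number of unique level-5 shapes among n folded uniform random
    sequences of length L (G-sampling diversity)."""
    engine = engine or ViennaEngine()
    seqs = random_sequences(n, L, CompositionSpec.uniform(), seed)
    shapes = [abstract_shape(engine.fold(s).structure) for s in seqs]
    return len(shape_frequency_table(shapes))


def random_trend_slopes(
    seed: SeedLike = 0,
    n_per_length: int = 25,
    lengths: Sequence[int] = DEFAULT_LENGTH_GRID,
    engine=None,
    return_points: bool = False,
):
    """OLS slopes of motif count vs length for uniform random sequences.

    Folds ``n_per_length`` sequences at each grid length with the Vienna
    engine (by default) and fits count = a·L + b per motif over all
    structure-level points.  Returns {motif: slope} (and the point table
    when ``return_points``).
    """
    engine = engine or ViennaEngine()
    points = build_length_grid_dataset(
        engine, lengths, n_per_length, CompositionSpec.uniform(), seed,
        ensemble="random",
    )
    slopes = {}
    for motif in FEATURE_ORDER:
        sub = points[points["motif"] == motif]
        a, _b = ols_line(sub["L"], sub["count"])
        slopes[motif] = a
    if return_points:
        return slopes, points
    return slopes
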