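"""Motif-count trends over a length grid: OLS fits with bootstrap CIs.

For each ensemble (random, scrambled, natural, pseudo-natural) and each of
the five motifs, the per-structure count m is regressed on sequence length
L as m = a·L + b over structure-level points, and 95% percentile bootstrap
intervals are attached to slope and intercept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDesignError
from .sampling import CompositionSpec, SeedLike, as_rng
from .structure_core import FEATURE_ORDER, build_tree, count_motifs, parse_dot_bracket

#: Default length grid spanning the 50-3000 nt analysis range.
DEFAULT_LENGTH_GRID = (50, 100, 200, 300, 400, 600, 800, 1000, 1500, 2000,
                       2500, 3000)

#: Long-format columns of a motif-point table.
MOTIF_POINT_COLUMNS = ("L", "motif", "count", "ensemble")


@dataclass(frozen=True)
class FitResult:
    """Linear trend m = a·L + b for one motif in one ensemble."""

    motif: str
    ensemble: str
    slope: float
    intercept: float
    ci_slope: Tuple[float, float]
    ci_intercept: Tuple[float, float]
    n_points: int

    def as_dict(self) -> dict:
        return {
            "motif": self.motif,
            "ensemble": self.ensemble,
            "slope": self.slope,
            "intercept": self.intercept,
            "ci_slope": list(self.ci_slope),
            "ci_intercept": list(self.ci_intercept),
            "n_points": self.n_points,
        }


def _check_design(L: np.ndarray) -> None:
    if len(L) < 3:
        raise DegenerateDesignError(f"need >= 3 points, got {len(L)}")
    if len(np.unique(L)) < 2:
        raise DegenerateDesignError("all points share one length")


def ols_line(L: Sequence[float], counts: Sequence[float]) -> Tuple[float, float]:
    """Ordinary least squares slope and intercept of count on length."""
    L = np.asarray(L, dtype=float)
    y = np.asarray(counts, dtype=float)
    _check_design(L)
    res = stats.linregress(L, y)
    return float(res.slope), float(res.intercept)


def bootstrap_fit_ci(
    L: Sequence[float],
    counts: Sequence[float],
    B: int = 1000,
    seed: SeedLike = 0,
) -> Tuple[Tuple[float, float], Tuple[float, float]]:
    """Nonparametric bootstrap 95% percentile CIs for slope and intercept.

    Points are resampled with replacement B times; degenerate resamples
    (single length) are redrawn implicitly by the closed-form slope being
    skipped — in practice resamples of structure-level data never collapse,
    but a guard keeps the estimate finite.
    """
    if B < 100:
        raise ValueError(f"need B >= 100 bootstrap replicates, got {B}")
    L = np.asarray(L, dtype=float)
    y = np.asarray(counts, dtype=float)
    _check_design(L)
    rng = as_rng(seed)
    n = len(L)
    idx = rng.integers(0, n, size=(B, n))
    Lb, yb = L[idx], y[idx]
    Lm = Lb.mean(axis=1, keepdims=True)
    ym = yb.mean(axis=1, keepdims=True)
    var = ((Lb - Lm) ** 2).sum(axis=1)
    cov = ((Lb - Lm) * (yb - ym)).sum(axis=1)
    ok = var > 0
    slopes = cov[ok] / var[ok]
    intercepts = ym[ok, 0] - slopes * Lm[ok, 0]
    ci_a = tuple(np.percentile(slopes, [2.5, 97.5]))
    ci_b = tuple(np.percentile(intercepts, [2.5, 97.5]))
    return (float(ci_a[0]), float(ci_a[1])), (float(ci_b[0]), float(ci_b[1]))


def motif_trend_fit(
    points: pd.DataFrame,
    motif: Optional[str] = None,
    ensemble: Optional[str] = None,
    B: int = 1000,
    seed: SeedLike = 0,
) -> FitResult:
    """Fit m = a·L + b for one motif/ensemble subset of a motif-point table.

    ``points`` is long-format (columns L, motif, count, ensemble); motif and
    ensemble restrict the subset when the table mixes several.
    """
    sub = points
    if motif is not None:
        sub = sub[sub["motif"] == motif]
    if ensemble is not None:
        sub = sub[sub["ensemble"] == ensemble]
    if sub.empty:
        raise DegenerateDesignError("no points for requested motif/ensemble")
    motifs = sub["motif"].unique()
    ensembles = sub["ensemble"].unique()
    if len(motifs) > 1 or len(ensembles) > 1:
        raise ValueError("points mix motifs/ensembles; pass motif=/ensemble=")
    L = sub["L"].to_numpy(dtype=float)
    y = sub["count"].to_numpy(dtype=float)
    slope, intercept = ols_line(L, y)
    ci_a, ci_b = bootstrap_fit_ci(L, y, B=B, seed=seed)
    return FitResult(motif=str(motifs[0]), ensemble=str(ensembles[0]),
                     slope=slope, intercept=intercept,
                     ci_slope=ci_a, ci_intercept=ci_b, n_points=len(sub))


def fit_all_motifs(
    points: pd.DataFrame, B: int = 1000, seed: SeedLike = 0
) -> list[FitResult]:
    """One FitResult per (ensemble, motif) pair present in the table.

    Subsets with a degenerate design (all one length) are skipped with a
    warning rather than aborting the whole study.
    """
    import logging

    rng = as_rng(seed)
    out = []
    for ens in sorted(points["ensemble"].unique()):
        for motif in FEATURE_ORDER:
            sub = points[(points["ensemble"] == ens)
                         & (points["motif"] == motif)]
            if sub.empty:
                continue
            try:
                out.append(motif_trend_fit(sub, B=B, seed=rng))
            except DegenerateDesignError as exc:
                logging.getLogger(__name__).warning(
                    "skipping %s/%s fit: %s", ens, motif, exc)
    return out


def structures_to_motif_points(structures, ensemble: str) -> pd.DataFrame:
    """Five long-format rows (one per motif) per folded structure."""
    rows = []
    for ss in structures:
        counts = count_motifs(build_tree(parse_dot_bracket(ss.structure)))
        L = len(ss.sequence)
        for motif, value in zip(FEATURE_ORDER, counts.feature_vector()):
            rows.append({"L": L, "motif": motif, "count": value,
                         "ensemble": ensemble})
    return pd.DataFrame(rows, columns=list(MOTIF_POINT_COLUMNS))


def build_length_grid_dataset(
    engine,
    lengths: Sequence[int] = DEFAULT_LENGTH_GRID,
    n_per_length: int = 25,
    comp: Optional[CompositionSpec] = None,
    seed: SeedLike = 0,
    ensemble: str = "random",
) -> pd.DataFrame:
    """Fold n sequences at each grid length; emit five MotifPoints each."""
    from .sampling import random_sequences  # local to avoid cycle at import

    comp = comp or CompositionSpec.uniform()
    rng = as_rng(seed)
    frames = []
    for L in lengths:
        seqs = random_sequences(n_per_length, int(L), comp, rng,
                                id_prefix=f"{ensemble}_L{L}")
        folded = [engine.fold(s) for s in seqs]
        frames.append(structures_to_motif_points(folded, ensemble))
    return pd.concat(frames, ignore_index=True)
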