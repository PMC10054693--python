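"""Labelled pseudo-natural vs random synthetic datasets.

The analysis pipeline contrasts natural non-coding RNA with uniform random
sequences of the same length.  Natural databases cannot ship with the
package, so this module generates a stand-in "pseudo-natural" ensemble with
the two statistical properties the downstream analysis relies on:

* per-sequence composition bias — each pseudo-natural sequence draws its GC
  fraction from a Beta law instead of the fixed uniform composition;
* motif-count shifts — a tunable effect-size vector δ over the five motifs
  (bulges, loops, junctions, helices, bonds) injected by
  selection-by-resampling: for each slot several candidate sequences are
  folded and one is kept with Boltzmann weight proportional to
  exp(motif vector · δ).  Selection acts on fold outcomes, the way natural
  selection does, so kept sequences remain ordinary foldable sequences; the
  selection strength grows smoothly with ‖δ‖ (uniform choice at δ = 0,
  hard argmax in the large-‖δ‖ limit).

With δ = 0 and ``gc_alpha = gc_beta = None`` the two classes are generated
by the identical process and are exactly exchangeable — the null
configuration used to calibrate classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .sampling import CompositionSpec, SeedLike, as_rng, random_sequences
from .structure_core import (
    FEATURE_ORDER,
    SecondaryStructure,
    build_tree,
    count_motifs,
    parse_dot_bracket,
)

#: Reference linear trend coefficients (slope, intercept) of motif count vs
#: length for natural and random ncRNA ensembles; used only to set default
#: effect sizes that mimic the natural-minus-random contrast.
REFERENCE_TRENDS = {
    "natural": {
        "bulges": (0.010, -0.65),
        "loops": (0.020, 0.94),
        "junctions": (0.0083, -0.60),
        "helices": (0.070, 1.78),
        "bonds": (0.31, 2.1),
    },
    "random": {
        "bulges": (0.013, -0.12),
        "loops": (0.018, 0.65),
        "junctions": (0.0085, -0.51),
        "helices": (0.073, -0.049),
        "bonds": (0.32, 5.8),
    },
}


def trend_contrast_shift(L: int) -> dict[str, float]:
    """Natural-minus-random expected motif-count difference at length L.

    Evaluates the reference trends at L and returns the per-motif contrast
    (negative for bulges and bonds, positive for loops at typical lengths).
    """
    out = {}
    for motif in FEATURE_ORDER:
        a_n, b_n = REFERENCE_TRENDS["natural"][motif]
        a_r, b_r = REFERENCE_TRENDS["random"][motif]
        out[motif] = (a_n - a_r) * L + (b_n - b_r)
    return out


@dataclass
class PseudoNaturalSpec:
    """Parameters of the pseudo-natural vs random generator.

    gc_alpha/gc_beta are the Beta shape parameters of the per-sequence GC
    fraction of the pseudo-natural class; both ``None`` means the fixed
    uniform composition (exchangeable with the random class when δ = 0).
    ``shift`` is δ in motif-count units, keyed by motif; ``None`` uses the
    reference natural-minus-random contrast at length L.
    """

    L: int = 200
    n: int = 200
    gc_alpha: Optional[float] = 2.0
    gc_beta: Optional[float] = 2.0
    shift: Optional[dict[str, float]] = None
    candidates_per_accept: int = 5

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.candidates_per_accept < 1:
            raise ValueError("candidates_per_accept must be >= 1")
        if (self.gc_alpha is None) != (self.gc_beta is None):
            raise ValueError("gc_alpha and gc_beta must be both set or both None")
        if self.shift is None:
            self.shift = trend_contrast_shift(self.L)
        unknown = set(self.shift) - set(FEATURE_ORDER)
        if unknown:
            raise ValueError(f"unknown motif(s) in shift: {sorted(unknown)}")
        if not all(np.isfinite(list(self.shift.values()))):
            raise ValueError("shift values must be finite")

    def delta_vector(self) -> np.ndarray:
        return np.array([self.shift.get(m, 0.0) for m in FEATURE_ORDER])


def _fold_features(engine, seq) -> tuple[SecondaryStructure, np.ndarray]:
    ss = engine.fold(seq)
    counts = count_motifs(build_tree(parse_dot_bracket(ss.structure)))
    return ss, np.array(counts.feature_vector(), dtype=float)


def generate_pseudo_natural(
    spec: PseudoNaturalSpec,
    engine,
    seed: SeedLike = 0,
) -> tuple[list[SecondaryStructure], list[str]]:
    """Generate a labelled dataset of 2n folded structures.

    Class "random": n uniform-composition sequences, folded.  Class
    "pseudo-natural": for each of n slots, draw a per-sequence GC fraction
    (Beta law, or uniform composition when unset), fold
    ``candidates_per_accept`` candidates, and keep one with probability
    proportional to exp(motif vector · δ), so δ = 0 is a uniform draw and
    large ‖δ‖ approaches a hard argmax.
    """
    rng = as_rng(seed)
    delta = spec.delta_vector()
    structures: list[SecondaryStructure] = []
    labels: list[str] = []

    for i, seq in enumerate(
        random_sequences(spec.n, spec.L, CompositionSpec.uniform(), rng,
                         id_prefix="rand")
    ):
        ss, _ = _fold_features(engine, seq)
        structures.append(ss)
        labels.append("random")

    for i in range(spec.n):
        if spec.gc_alpha is None:
            comp = CompositionSpec.uniform()
        else:
            gc = float(rng.beta(spec.gc_alpha, spec.gc_beta))
            comp = CompositionSpec.from_gc(gc)
        candidates = random_sequences(
            spec.candidates_per_accept, spec.L, comp, rng,
            id_prefix=f"pseudo_{i}",
        )
        folded, scores = [], []
        for cand in candidates:
            ss, feats = _fold_features(engine, cand)
            folded.append(ss)
            scores.append(float(feats @ delta))
        scores = np.asarray(scores)
        weights = np.exp(scores - scores.max())  # Boltzmann selection
        weights /= weights.sum()
        choice = int(rng.choice(len(folded), p=weights))
        structures.append(folded[choice])
        labels.append("pseudo-natural")
    return structures, labels


def make_feature_dataset(
    structures: Sequence[SecondaryStructure],
    labels: Sequence[str],
    positive_label: str = "pseudo-natural",
) -> pd.DataFrame:
    """One row per structure: the five motif counts plus a binary label.

    Column order is fixed: bulges, loops, junctions, helices, bonds, label
    (1 for ``positive_label``, 0 otherwise), so written TSVs are byte-stable
    across runs with the same inputs.
    """
    if len(structures) != len(labels):
        raise ValueError("structures and labels differ in length")
    rows = []
    for ss, lab in zip(structures, labels):
        counts = count_motifs(build_tree(parse_dot_bracket(ss.structure)))
        row = dict(zip(FEATURE_ORDER, counts.feature_vector()))
        row["label"] = int(lab == positive_label)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(FEATURE_ORDER) + ["label"])
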