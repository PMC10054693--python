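"""Random sequence generation, scrambling, and FASTA ingestion.

Randomness policy: every public operation takes either an integer seed or a
``numpy.random.Generator``.  Pipelines derive independent per-stage
substreams from one run seed via ``spawn_rngs``, so a single seed fully
determines a run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
from Bio import SeqIO

from .errors import EmptyInputError, InvalidCompositionError
from .folding import RNA_ALPHABET
from .structure_core import RnaSequence

logger = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "U")

SeedLike = Union[int, np.random.Generator]


def as_rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_rngs(seed: SeedLike, n: int) -> list[np.random.Generator]:
    """Derive n independent substreams from one seed (or generator)."""
    return as_rng(seed).spawn(n)


@dataclass(frozen=True)
class CompositionSpec:
    """Per-residue sampling probabilities for A, C, G, U (sum to 1)."""

    pA: float
    pC: float
    pG: float
    pU: float

    def __post_init__(self) -> None:
        probs = self.as_tuple()
        if min(probs) < 0 or abs(sum(probs) - 1.0) > 1e-9:
            raise InvalidCompositionError(
                f"probabilities must be >= 0 and sum to 1, got {probs}"
            )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.pA, self.pC, self.pG, self.pU)

    @classmethod
    def uniform(cls) -> "CompositionSpec":
        return cls(0.25, 0.25, 0.25, 0.25)

    @classmethod
    def from_gc(cls, gc: float) -> "CompositionSpec":
        """GC fraction with A/U and G/C each split evenly."""
        if not 0.0 <= gc <= 1.0:
            raise InvalidCompositionError(f"GC fraction must be in [0,1]: {gc}")
        au = (1.0 - gc) / 2.0
        return cls(au, gc / 2.0, gc / 2.0, au)


def random_sequences(
    n: int,
    L: int,
    comp: CompositionSpec = None,
    seed: SeedLike = 0,
    id_prefix: str = "rand",
) -> list[RnaSequence]:
    """Draw n i.i.d. sequences of length L, residues i.i.d. from ``comp``."""
    if n < 1 or L < 1:
        raise ValueError(f"need n >= 1 and L >= 1, got n={n}, L={L}")
    comp = comp or CompositionSpec.uniform()
    rng = as_rng(seed)
    mat = rng.choice(4, size=(n, L), p=list(comp.as_tuple()))
    lookup = np.array(_BASES)
    return [
        RnaSequence(id=f"{id_prefix}_{i}", residues="".join(lookup[row]))
        for i, row in enumerate(mat)
    ]


def scramble(seq: RnaSequence, seed: SeedLike = 0) -> RnaSequence:
    """Uniformly random permutation of the residues (composition preserved)."""
    rng = as_rng(seed)
    shuffled = "".join(np.array(list(seq.residues))[rng.permutation(len(seq))])
    return RnaSequence(id=f"{seq.id}|scrambled", residues=shuffled)


def read_fasta(path: Union[str, Path], dedupe: bool = False) -> list[RnaSequence]:
    """Read RNA sequences from FASTA, normalising T→U.

    Records containing ambiguity codes (N, R, Y, ...) are skipped with a
    logged warning.  ``dedupe`` drops exact duplicate sequences, keeping the
    first occurrence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    out: list[RnaSequence] = []
    seen: set[str] = set()
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        residues = str(rec.seq).upper().replace("T", "U")
        if set(residues) - RNA_ALPHABET:
            logger.warning("skipping %s: ambiguity code(s) present", rec.id)
            continue
        if dedupe:
            if residues in seen:
                continue
            seen.add(residues)
        out.append(RnaSequence(id=rec.id, residues=residues))
    if n_records == 0:
        raise EmptyInputError(f"no FASTA records in {path}")
    return out


def filter_by_length(
    seqs: Iterable[RnaSequence], L: int, tolerance: int = 0
) -> list[RnaSequence]:
    """Keep sequences with length within ``L ± tolerance`` (default exact)."""
    return [s for s in seqs if abs(len(s) - L) <= tolerance]


def write_fasta(seqs: Sequence[RnaSequence], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")
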