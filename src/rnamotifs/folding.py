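"""Folding engines: one MFE-style dot-bracket structure per sequence.

Two engines share one interface:

* ``ViennaEngine`` — adapter over the ViennaRNA Python bindings, the engine
  used for all headline analyses (thermodynamic MFE structure, package
  defaults: 37 °C, default dangles, no constraints).
* ``NussinovEngine`` — a dependency-free base-pair-maximisation baseline
  with deterministic traceback, for unit tests and toy pipelines.

Both are pure: identical input and parameters give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Tuple

from .errors import AlphabetError, EngineUnavailableError
from .structure_core import RnaSequence, SecondaryStructure

RNA_ALPHABET = frozenset("ACGU")

#: Watson-Crick pairs plus the GU wobble pair.
WOBBLE_PAIRS: FrozenSet[Tuple[str, str]] = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)


def normalize_rna(residues: str) -> str:
    """Uppercase and apply the DNA→RNA T→U substitution.

    Raises AlphabetError for residues outside {A, C, G, U} after
    normalization (ambiguity codes are the caller's concern to filter).
    """
    s = residues.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise AlphabetError(f"non-ACGU residue(s): {sorted(bad)!r}")
    return s


@dataclass
class ViennaEngine:
    """MFE folding through the ViennaRNA package with default parameters."""

    temperature: float = 37.0
    name: str = "vienna"

    def __post_init__(self) -> None:
        try:
            import RNA  # noqa: F401
        except ImportError as exc:  # pragma: no cover - environment guard
            raise EngineUnavailableError(
                "ViennaRNA Python bindings (module 'RNA') not importable"
            ) from exc
        self._rna = RNA

    @property
    def version(self) -> str:
        return f"ViennaRNA {self._rna.__version__}"

    def fold(self, seq: RnaSequence) -> SecondaryStructure:
        residues = normalize_rna(seq.residues)
        if self.temperature == 37.0:
            structure, _mfe = self._rna.fold(residues)
        else:
            md = self._rna.md()
            md.temperature = self.temperature
            fc = self._rna.fold_compound(residues, md)
            structure, _mfe = fc.mfe()
        return SecondaryStructure(id=seq.id, sequence=residues,
                                  structure=structure)


@dataclass
class NussinovEngine:
    """Base-pair maximisation with a minimum hairpin length constraint."""

    min_hairpin: int = 3
    pairs: FrozenSet[Tuple[str, str]] = WOBBLE_PAIRS
    name: str = "nussinov"
    version: str = field(default="nussinov-dp/1", repr=False)

    def fold(self, seq: RnaSequence) -> SecondaryStructure:
        residues = normalize_rna(seq.residues)
        structure = nussinov_fold(residues, self.min_hairpin, self.pairs)
        return SecondaryStructure(id=seq.id, sequence=residues,
                                  structure=structure)


def nussinov_fold(
    residues: str,
    min_hairpin: int = 3,
    pairs: FrozenSet[Tuple[str, str]] = WOBBLE_PAIRS,
) -> str:
    """Nussinov-style dynamic program maximising the number of allowed
    base pairs subject to nesting and ``j - i > min_hairpin``.

    Traceback is deterministic: position i is left unpaired whenever that
    attains the optimum; otherwise i pairs with the smallest optimal j.
    """
    seq = normalize_rna(residues)
    L = len(seq)
    # M[i][j] = max pairs in seq[i..j]; table stored as dict of rows only
    # where span > min_hairpin (otherwise 0)
    M = [[0] * L for _ in range(L)]
    for span in range(min_hairpin + 1, L):
        for i in range(L - span):
            j = i + span
            best = M[i + 1][j]
            for k in range(i + min_hairpin + 1, j + 1):
                if (seq[i], seq[k]) in pairs:
                    v = 1 + M[i + 1][k - 1]
                    if k + 1 <= j:
                        v += M[k + 1][j]
                    if v > best:
                        best = v
            M[i][j] = best
    struct = ["."] * L
    stack = [(0, L - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_hairpin:
            continue
        if M[i][j] == M[i + 1][j]:  # prefer i unpaired
            stack.append((i + 1, j))
            continue
        for k in range(i + min_hairpin + 1, j + 1):  # smallest partner first
            if (seq[i], seq[k]) not in pairs:
                continue
            v = 1 + M[i + 1][k - 1]
            if k + 1 <= j:
                v += M[k + 1][j]
            if v == M[i][j]:
                struct[i], struct[k] = "(", ")"
                stack.append((i + 1, k - 1))
                if k + 1 <= j:
                    stack.append((k + 1, j))
                break
    return "".join(struct)


def get_engine(name: str, **params):
    """Factory: 'vienna' or 'nussinov' with engine-specific keyword params."""
    if name == "vienna":
        return ViennaEngine(**params)
    if name == "nussinov":
        return NussinovEngine(**params)
    raise ValueError(f"unknown folding engine {name!r}")
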