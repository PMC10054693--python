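"""Dot-bracket parsing, loop decomposition and structural-motif counting.

The unit record of the pipeline is a nested (pseudoknot-free) RNA secondary
structure in dot-bracket notation.  This module turns the string into a pair
table, decomposes it into the classical loop faces (helix, hairpin, bulge,
internal loop, multiloop, exterior), and counts the five structural motifs
used throughout the analysis: bulges, hairpin loops, junctions (multiloops),
helices and bonds (base pairs).  Internal loops are tracked as an auxiliary
sixth count.

Motif definitions
-----------------
bond      one base pair, i.e. one matched '(' ')' couple
helix     maximal run of stacked pairs (i,j),(i+1,j-1),...
loop      hairpin loop: unpaired run closed by exactly one helix
bulge     face with one enclosed helix and unpaired bases on one side only
junction  face enclosing two or more helices (multiloop)
internal  face with one enclosed helix and unpaired bases on both sides
          (auxiliary count; not one of the five classification features)

The exterior (unenclosed) region contributes to no motif count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, Union

from .errors import (
    EmptyInputError,
    InvalidCharacterError,
    LimitExceededError,
    PseudoknotError,
    UnbalancedBracketsError,
)

UNPAIRED = -1

#: Canonical ordering of the five classification features.
FEATURE_ORDER = ("bulges", "loops", "junctions", "helices", "bonds")

_DB_ALPHABET = frozenset(".()")


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence over {A, C, G, U} with a free-text identifier."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise EmptyInputError("empty RNA sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SecondaryStructure:
    """A sequence together with its predicted dot-bracket structure."""

    id: str
    sequence: str
    structure: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.structure):
            raise ValueError(
                f"sequence/structure length mismatch for {self.id!r}: "
                f"{len(self.sequence)} vs {len(self.structure)}"
            )


def parse_dot_bracket(text: str) -> list[int]:
    """Parse a dot-bracket string into a 0-based pair table.

    Returns a list ``pt`` with ``pt[i] == j`` when positions i and j pair and
    ``pt[i] == UNPAIRED`` (-1) otherwise.  Matching is stack-based; only the
    plain '()' bracket alphabet is accepted, so pseudoknot syntax is rejected
    as an invalid character.

    Raises
    ------
    InvalidCharacterError
        for any character outside {., (, )}.
    UnbalancedBracketsError
        for an unmatched '(' or ')'.
    EmptyInputError
        for an empty string.
    """
    if not text:
        raise EmptyInputError("empty dot-bracket string")
    bad = set(text) - _DB_ALPHABET
    if bad:
        raise InvalidCharacterError(
            f"invalid dot-bracket character(s): {sorted(bad)!r}"
        )
    pt = [UNPAIRED] * len(text)
    stack: list[int] = []
    for i, c in enumerate(text):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise UnbalancedBracketsError(f"unmatched ')' at position {i}")
            j = stack.pop()
            pt[j] = i
            pt[i] = j
    if stack:
        raise UnbalancedBracketsError(
            f"unmatched '(' at position(s) {stack!r}"
        )
    return pt


def serialize_pair_table(pt: list[int]) -> str:
    """Inverse of :func:`parse_dot_bracket` for a valid nested pair table."""
    out = []
    for i, j in enumerate(pt):
        out.append("." if j == UNPAIRED else ("(" if j > i else ")"))
    return "".join(out)


def validate_pair_table(pt: list[int]) -> None:
    """Check involution and nestedness; raise PseudoknotError on violation."""
    L = len(pt)
    for i, j in enumerate(pt):
        if j == UNPAIRED:
            continue
        if not (0 <= j < L) or pt[j] != i or j == i:
            raise PseudoknotError(f"pair table not an involution at {i}")
    # nestedness: a stack scan must consume pairs in LIFO order
    stack: list[int] = []
    for i, j in enumerate(pt):
        if j > i:
            stack.append(i)
        elif j != UNPAIRED:
            if not stack or stack.pop() != j:
                raise PseudoknotError(f"crossing pairs at ({j}, {i})")


# ---------------------------------------------------------------------------
# Loop-decomposition tree
# ---------------------------------------------------------------------------


@dataclass
class Hairpin:
    unpaired: int


@dataclass
class Bulge:
    side: str  # "5'" or "3'": the strand carrying the unpaired run
    unpaired: int
    child: "Helix" = None  # type: ignore[assignment]


@dataclass
class Internal:
    unpaired5: int
    unpaired3: int
    child: "Helix" = None  # type: ignore[assignment]


@dataclass
class Multiloop:
    branches: list["Helix"] = field(default_factory=list)
    unpaired: int = 0


@dataclass
class Helix:
    bp: int
    child: Union[Hairpin, Bulge, Internal, Multiloop] = None  # type: ignore[assignment]


@dataclass
class Exterior:
    branches: list[Helix] = field(default_factory=list)
    unpaired: int = 0


StructureTree = Exterior
LoopNode = Union[Hairpin, Bulge, Internal, Multiloop]


def _branches_in(pt: list[int], lo: int, hi: int) -> tuple[list[tuple[int, int]], int]:
    """Directly enclosed pairs and unpaired count in the half-open run [lo, hi)."""
    branches = []
    unpaired = 0
    p = lo
    while p < hi:
        j = pt[p]
        if j == UNPAIRED:
            unpaired += 1
            p += 1
        else:
            branches.append((p, j))
            p = j + 1
    return branches, unpaired


def _build_helix(pt: list[int], i: int, j: int) -> Helix:
    """Build the helix closed by pair (i, j) and its enclosed subtree."""
    bp = 1
    while i + bp < j - bp and pt[i + bp] == j - bp:
        bp += 1
    inner_lo, inner_hi = i + bp, j - bp + 1  # half-open interior face
    branches, unpaired = _branches_in(pt, inner_lo, inner_hi)
    helix = Helix(bp=bp)
    if not branches:
        helix.child = Hairpin(unpaired=unpaired)
    elif len(branches) == 1:
        (k, l) = branches[0]
        u5 = k - inner_lo
        u3 = inner_hi - 1 - l
        # zero unpaired on both sides would mean a stacked pair, i.e. the
        # same helix — impossible once the helix was extended maximally
        assert u5 > 0 or u3 > 0, "degenerate zero-length interior face"
        sub = _build_helix(pt, k, l)
        if u3 == 0:
            helix.child = Bulge(side="5'", unpaired=u5, child=sub)
        elif u5 == 0:
            helix.child = Bulge(side="3'", unpaired=u3, child=sub)
        else:
            helix.child = Internal(unpaired5=u5, unpaired3=u3, child=sub)
    else:
        helix.child = Multiloop(
            branches=[_build_helix(pt, k, l) for k, l in branches],
            unpaired=unpaired,
        )
    return helix


def build_tree(pt: list[int]) -> StructureTree:
    """Decompose a valid pair table into its unique loop tree.

    Consecutive stacked pairs merge into one HELIX node; each helix's
    interior face is classified as hairpin, bulge, internal loop or
    multiloop by the number of enclosed helices and the sidedness of the
    unpaired runs.  The root EXTERIOR node collects the top-level helices.
    """
    validate_pair_table(pt)
    branches, unpaired = _branches_in(pt, 0, len(pt))
    return Exterior(
        branches=[_build_helix(pt, i, j) for i, j in branches],
        unpaired=unpaired,
    )


# ---------------------------------------------------------------------------
# Motif counting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifCounts:
    """Per-structure counts of the five motifs plus auxiliary internal loops."""

    bulges: int = 0
    loops: int = 0
    junctions: int = 0
    helices: int = 0
    bonds: int = 0
    internals: int = 0

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in FEATURE_ORDER}

    def feature_vector(self) -> tuple[int, ...]:
        """The five classification features in canonical order."""
        return tuple(getattr(self, name) for name in FEATURE_ORDER)

    def __add__(self, other: "MotifCounts") -> "MotifCounts":
        return MotifCounts(
            *(getattr(self, f) + getattr(other, f)
              for f in ("bulges", "loops", "junctions", "helices", "bonds",
                        "internals"))
        )


def count_motifs(tree: StructureTree, internal_as_bulge: bool = False) -> MotifCounts:
    """Count motifs by walking the loop tree.

    ``internal_as_bulge`` folds the auxiliary internal-loop count into the
    bulge count (sensitivity switch; default off keeps internal loops out of
    all five features).
    """
    counts = {"bulges": 0, "loops": 0, "junctions": 0, "helices": 0,
              "bonds": 0, "internals": 0}

    def visit_helix(h: Helix) -> None:
        counts["helices"] += 1
        counts["bonds"] += h.bp
        node = h.child
        if isinstance(node, Hairpin):
            counts["loops"] += 1
        elif isinstance(node, Bulge):
            counts["bulges"] += 1
            visit_helix(node.child)
        elif isinstance(node, Internal):
            counts["internals"] += 1
            visit_helix(node.child)
        elif isinstance(node, Multiloop):
            counts["junctions"] += 1
            for b in node.branches:
                visit_helix(b)
        else:  # pragma: no cover - tree invariant
            raise TypeError(f"unexpected node {node!r}")

    for h in tree.branches:
        visit_helix(h)
    if internal_as_bulge:
        counts["bulges"] += counts.pop("internals")
        counts["internals"] = 0
    return MotifCounts(**counts)


_HAIRPIN_RE = re.compile(r"\(\.*\)")


def motif_counts_scan(db: str, internal_as_bulge: bool = False) -> MotifCounts:
    """Motif counts by direct string / pair-table scanning (no tree).

    Independent of :func:`build_tree`; used as a test oracle.  Helix starts
    are pairs not stacked on an outer pair; hairpins are innermost
    ``(...)`` runs; bulge/internal/junction faces are found by scanning the
    interior of each helix-terminating pair.
    """
    db = db.strip()
    pt = parse_dot_bracket(db)
    bonds = db.count("(")
    helices = sum(
        1 for i, j in enumerate(pt)
        if j > i and not (i > 0 and pt[i - 1] == j + 1)
    )
    loops = len(_HAIRPIN_RE.findall(db))
    bulges = internals = junctions = 0
    for i, j in enumerate(pt):
        # (i, j) innermost pair of its helix => its interior is a loop face
        if j <= i or pt[i + 1] == j - 1:
            continue
        branches, _ = _branches_in(pt, i + 1, j)
        if len(branches) == 1:
            (k, l) = branches[0]
            u5 = k - (i + 1)
            u3 = j - 1 - l
            if u5 > 0 and u3 > 0:
                internals += 1
            else:
                bulges += 1
        elif len(branches) >= 2:
            junctions += 1
    if internal_as_bulge:
        bulges += internals
        internals = 0
    return MotifCounts(bulges=bulges, loops=loops, junctions=junctions,
                       helices=helices, bonds=bonds, internals=internals)


# ---------------------------------------------------------------------------
# Exhaustive enumeration (test oracle)
# ---------------------------------------------------------------------------

_ENUM_GUARD = 16


def enumerate_structures(L: int, min_hairpin: int = 3) -> Iterator[str]:
    """Yield every balanced dot-bracket string of length L whose hairpin
    loops all have at least ``min_hairpin`` unpaired bases.

    Exhaustive; guarded to L <= 16.
    """
    if L > _ENUM_GUARD:
        raise LimitExceededError(
            f"enumeration limited to L <= {_ENUM_GUARD}, got {L}"
        )

    @lru_cache(maxsize=None)
    def gen(n: int) -> tuple[str, ...]:
        if n == 0:
            return ("",)
        out = ["." + rest for rest in gen(n - 1)]
        # pair position 0 with position m+1 (inner span of length m)
        for m in range(min_hairpin, n - 1):
            for inner in gen(m):
                if "(" not in inner and len(inner) < min_hairpin:
                    continue
                for rest in gen(n - m - 2):
                    out.append("(" + inner + ")" + rest)
        return tuple(out)

    yield from gen(L)
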