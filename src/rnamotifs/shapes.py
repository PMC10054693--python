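"""Abstract-shape coarse-graining of dot-bracket structures.

An abstract shape discards fine structural detail and keeps only the
arrangement of helices, written in square-bracket notation.  Five levels of
increasing abstraction are supported, following the RNAshapes scheme:

level 1   every loop and every unpaired run shown ('_')
level 2   unpaired runs shown only inside bulges and internal loops
level 3   all helices shown, no unpaired runs
level 4   helices separated by bulges merged; internal loops still split
level 5   helices linked through bulges *or* internal loops merged — only
          helix nesting and adjacency survive

Level 5 is the normative level used throughout the analysis: it is coarse
enough that shape frequencies can be estimated from feasible sample sizes.
A structure with no pairs maps to the sentinel shape "_".
"""

from __future__ import annotations

from .errors import UnsupportedLevelError
from .structure_core import (
    Bulge,
    Exterior,
    Hairpin,
    Helix,
    Internal,
    Multiloop,
    build_tree,
    parse_dot_bracket,
)


def abstract_shape(db: str, level: int = 5) -> str:
    """Map a dot-bracket string to its abstract shape at the given level.

    Level 5 collapses every maximal chain of helices connected only through
    bulges/internal loops into a single '[' ']' pair; a chain ending in a
    hairpin renders "[]", a chain ending in a multiloop wraps the
    concatenated branch shapes; the exterior concatenates its branches.
    Zero-pair structures render "_".
    """
    if level not in (1, 2, 3, 4, 5):
        raise UnsupportedLevelError(f"shape level must be 1..5, got {level}")
    tree = build_tree(parse_dot_bracket(db))
    if not tree.branches:
        return "_"
    text = _render_exterior(tree, level)
    return text


def shape_bracket_count(shape: str) -> int:
    """Number of '[' characters (helix chains) in a shape string."""
    return shape.count("[")


def _render_exterior(tree: Exterior, level: int) -> str:
    parts = [_render_helix(h, level) for h in tree.branches]
    if level == 1:
        # interleave '_' for any unpaired run between/around branches; the
        # run lengths are not retained by the tree, so level 1 marks runs
        # only when the exterior has unpaired bases at all (best effort)
        sep = "_" if tree.unpaired else ""
        return sep + sep.join(parts) + sep if sep else "".join(parts)
    return "".join(parts)


def _merges(node, level: int) -> bool:
    """Does this loop face merge its flanking helices at this level?"""
    if isinstance(node, Bulge):
        return level >= 4
    if isinstance(node, Internal):
        return level == 5
    return False


def _render_helix(h: Helix, level: int) -> str:
    # walk down the chain of helices linked by merging faces
    node = h.child
    while _merges(node, level):
        node = node.child.child
    if isinstance(node, Hairpin):
        inner = "_" if level == 1 and node.unpaired else ""
        return "[" + inner + "]"
    if isinstance(node, (Bulge, Internal)):
        # face kept distinct at this level: nested helix, optionally with
        # unpaired markers at levels 1-2
        sub = _render_helix(node.child, level)
        if level <= 2:
            if isinstance(node, Bulge):
                mark5 = "_" if node.side == "5'" else ""
                mark3 = "_" if node.side == "3'" else ""
            else:
                mark5 = "_" if node.unpaired5 else ""
                mark3 = "_" if node.unpaired3 else ""
            return "[" + mark5 + sub + mark3 + "]"
        return "[" + sub + "]"
    if isinstance(node, Multiloop):
        parts = [_render_helix(b, level) for b in node.branches]
        if level == 1 and node.unpaired:
            return "[_" + "_".join(parts) + "_]"
        return "[" + "".join(parts) + "]"
    raise TypeError(f"unexpected node {node!r}")  # pragma: no cover
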