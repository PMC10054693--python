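"""Readers/writers for the package's plain-text artifact formats."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .structure_core import SecondaryStructure

PathLike = Union[str, Path]


def write_fold_records(structures: Sequence[SecondaryStructure],
                       path: PathLike) -> None:
    """Vienna-style records: '>id' header, sequence line, structure line."""
    with open(path, "w") as fh:
        for ss in structures:
            fh.write(f">{ss.id}\n{ss.sequence}\n{ss.structure}\n")


def read_fold_records(path: PathLike) -> list[SecondaryStructure]:
    """Read Vienna-style 3-line records, or headerless 2-line
    sequence/structure pairs, or bare one-structure-per-line files."""
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    out: list[SecondaryStructure] = []
    i = 0
    n_anon = 0
    while i < len(lines):
        if lines[i].startswith(">"):
            out.append(SecondaryStructure(id=lines[i][1:].strip(),
                                          sequence=lines[i + 1],
                                          structure=lines[i + 2]))
            i += 3
        elif (i + 1 < len(lines)
              and set(lines[i + 1]) <= set(".()")
              and not set(lines[i]) <= set(".()")):
            out.append(SecondaryStructure(id=f"record_{n_anon}",
                                          sequence=lines[i],
                                          structure=lines[i + 1]))
            n_anon += 1
            i += 2
        else:
            db = lines[i]
            # bare dot-bracket line: no sequence available, use a
            # placeholder of matching length
            out.append(SecondaryStructure(id=f"record_{n_anon}",
                                          sequence="A" * len(db),
                                          structure=db))
            n_anon += 1
            i += 1
    return out


def read_dot_brackets(path: PathLike) -> list[str]:
    """Plain text, one dot-bracket structure per line."""
    return [ln.strip() for ln in open(path) if ln.strip()]


def write_tsv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
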