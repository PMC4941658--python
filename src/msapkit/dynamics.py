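"""Counting methylation-state changes along ordered developmental paths.

Queries are written in a four-letter pattern alphabet applied position-wise
along an ordered sample path: ``N`` matches NON only, ``H`` matches HEMI,
``F`` matches FULL, and ``M`` matches either methylated state (HEMI or
FULL).  UNINF matches no symbol — transition rows describe determinate
states only — so a locus uninformative at any path stage never matches.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .io import StateMatrix

SYMBOL_MATCHES: dict[str, frozenset] = {
    "N": frozenset({"NON"}),
    "H": frozenset({"HEMI"}),
    "F": frozenset({"FULL"}),
    "M": frozenset({"HEMI", "FULL"}),
}


@dataclasses.dataclass(frozen=True)
class TransitionQuery:
    """An ordered sample path and an equal-length state pattern."""

    path: tuple[str, ...]
    pattern: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "path", tuple(self.path))
        object.__setattr__(self, "pattern", tuple(self.pattern))
        if len(self.path) < 1:
            raise ValueError("path must name at least one sample")
        if len(self.pattern) != len(self.path):
            raise ValueError(
                f"pattern length {len(self.pattern)} != path length {len(self.path)}"
            )
        bad = [s for s in self.pattern if s not in SYMBOL_MATCHES]
        if bad:
            raise ValueError(
                f"unknown pattern symbol {bad[0]!r}; alphabet is "
                f"{sorted(SYMBOL_MATCHES)}"
            )


@dataclasses.dataclass(frozen=True)
class TransitionCount:
    """A query together with its matching-locus count (and the loci)."""

    query: TransitionQuery
    count: int
    locus_ids: tuple[str, ...]


def count_transitions(states: StateMatrix, query: TransitionQuery) -> TransitionCount:
    """Count loci whose states along the path match the pattern position-wise."""
    unknown = [s for s in query.path if s not in states.samples]
    if unknown:
        raise KeyError(f"path references unknown sample(s): {unknown}")
    frame = states.states[list(query.path)]
    mask = np.ones(len(frame), dtype=bool)
    for pos, symbol in enumerate(query.pattern):
        col = frame.iloc[:, pos].to_numpy()
        mask &= np.isin(col, tuple(SYMBOL_MATCHES[symbol]))
    ids = tuple(lid for lid, hit in zip(states.locus_ids, mask) if hit)
    return TransitionCount(query=query, count=int(mask.sum()), locus_ids=ids)


def transition_table(states: StateMatrix,
                     queries: Sequence[TransitionQuery]) -> pd.DataFrame:
    """One row per query: path, pattern, label and matching-locus count."""
    rows = []
    for q in queries:
        tc = count_transitions(states, q)
        rows.append({
            "path": ",".join(q.path),
            "pattern": " ".join(q.pattern),
            "label": q.label,
            "count": tc.count,
        })
    return pd.DataFrame(rows, columns=["path", "pattern", "label", "count"])


def default_queries(
    leaf_path: Sequence[str] = ("youngLeaf", "matureLeaf"),
    vascular_path: Sequence[str] = ("phloem", "cambium", "matureXylem"),
) -> list[TransitionQuery]:
    """The canonical ten developmental-transition queries.

    Three patterns follow leaf maturation (young -> mature leaf) and seven
    follow the vascular stages in phloem-cambium-mature xylem column order,
    conditioning on cambium as the reference stage.
    """
    leaf = [
        (("M", "N"), "methylated young leaf -> non-methylated mature leaf"),
        (("F", "H"), "full young leaf -> hemi mature leaf"),
        (("H", "F"), "hemi young leaf -> full mature leaf"),
    ]
    vascular = [
        (("N", "M", "N"), "methylated only in cambium"),
        (("N", "M", "M"), "methylated in cambium, lost in phloem only"),
        (("M", "M", "N"), "methylated in cambium and phloem, lost in xylem"),
        (("H", "F", "F"), "full cambium -> hemi phloem, full xylem"),
        (("F", "F", "H"), "full cambium and phloem -> hemi xylem"),
        (("F", "H", "H"), "hemi cambium -> full phloem, hemi xylem"),
        (("H", "H", "F"), "hemi cambium and phloem -> full xylem"),
    ]
    out = [TransitionQuery(tuple(leaf_path), pat, lab) for pat, lab in leaf]
    out += [TransitionQuery(tuple(vascular_path), pat, lab) for pat, lab in vascular]
    return out
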