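"""Methylation-state calling from dual-enzyme band patterns.

HpaII and MspI are isoschizomers of the CCGG site with different methylation
sensitivities: both cut the unmethylated site; HpaII is blocked when either
cytosine is methylated on both strands; MspI is blocked when the external
cytosine is hemi-methylated.  Scoring each locus as present/absent in the
EcoRI/HpaII lane (h) and the EcoRI/MspI lane (m) therefore resolves four
states:

====  ====  =========================================
h     m     called state
====  ====  =========================================
1     1     NON    non-methylated CCGG
1     0     HEMI   hemi-methylated external cytosine
0     1     FULL   fully methylated internal cytosine
0     0     UNINF  uninformative (band absent in both)
====  ====  =========================================

The three informative states map bijectively onto their band patterns, so
calling is deterministic and lossless; (0,0) cannot distinguish site absence
from methylation that blocks both enzymes and is kept as a distinct UNINF
state, never imputed.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np
import pandas as pd

from .errors import CellValueError
from .io import BandMatrix, StateMatrix


class MethylationState(str, enum.Enum):
    """Per-locus, per-sample methylation call."""

    NON = "NON"
    HEMI = "HEMI"
    FULL = "FULL"
    UNINF = "UNINF"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: band pattern (h_present, m_present) -> state
PATTERN_TO_STATE: dict[tuple[int, int], MethylationState] = {
    (1, 1): MethylationState.NON,
    (1, 0): MethylationState.HEMI,
    (0, 1): MethylationState.FULL,
    (0, 0): MethylationState.UNINF,
}

#: inverse of :data:`PATTERN_TO_STATE`
STATE_TO_PATTERN: dict[MethylationState, tuple[int, int]] = {
    v: k for k, v in PATTERN_TO_STATE.items()
}

METHYLATED_STATES = frozenset({"HEMI", "FULL"})


def classify_band_pair(h_present: int, m_present: int) -> MethylationState:
    """Call one locus/sample from its two lane presence bits.

    Raises
    ------
    CellValueError
        If either input is not 0 or 1.
    """
    if h_present not in (0, 1) or m_present not in (0, 1):
        raise CellValueError(
            f"band presence must be 0 or 1, got (h={h_present!r}, m={m_present!r})"
        )
    return PATTERN_TO_STATE[(int(h_present), int(m_present))]


# code = 2*h + m  ->  0:UNINF, 1:FULL, 2:HEMI, 3:NON
_CODE_TO_TOKEN = np.array(["UNINF", "FULL", "HEMI", "NON"])


def call_states(bands: BandMatrix) -> StateMatrix:
    """Apply :func:`classify_band_pair` element-wise to a whole matrix."""
    h = bands.h_lane.to_numpy(dtype=np.int8)
    m = bands.m_lane.to_numpy(dtype=np.int8)
    tokens = _CODE_TO_TOKEN[2 * h + m]
    states = pd.DataFrame(tokens, index=bands.h_lane.index,
                          columns=bands.h_lane.columns)
    return StateMatrix(loci=list(bands.loci), states=states)


@dataclasses.dataclass(frozen=True)
class PolymorphismSummary:
    """Locus-level polymorphism accounting.

    A locus is polymorphic when its called state differs between at least
    two samples; ``polymorphic_fraction`` is on the 0-100 scale.
    """

    total_loci: int
    polymorphic_loci: int

    @property
    def monomorphic_loci(self) -> int:
        return self.total_loci - self.polymorphic_loci

    @property
    def polymorphic_fraction(self) -> float:
        if self.total_loci == 0:
            return float("nan")
        return 100.0 * self.polymorphic_loci / self.total_loci


def find_polymorphic(states: StateMatrix) -> tuple[PolymorphismSummary, list[str]]:
    """Identify loci whose state varies across samples.

    Returns the summary plus the polymorphic locus ids, in input row order.

    Raises
    ------
    ValueError
        If the matrix has fewer than two samples (polymorphism undefined).
    """
    if len(states.samples) < 2:
        raise ValueError("polymorphism requires at least two samples")
    arr = states.states.to_numpy()
    poly_mask = (arr != arr[:, [0]]).any(axis=1)
    poly_ids = [lid for lid, p in zip(states.locus_ids, poly_mask) if p]
    summary = PolymorphismSummary(total_loci=states.n_loci,
                                  polymorphic_loci=int(poly_mask.sum()))
    return summary, poly_ids


def per_sample_band_counts(states: StateMatrix) -> pd.DataFrame:
    """Per-sample counts of each state class and of bands present.

    Returns a DataFrame indexed by sample with columns ``non``, ``hemi``,
    ``full``, ``uninf``, ``methylated`` (= hemi + full) and ``bands``
    (= non + hemi + full, i.e. loci with a band in at least one lane).
    The four class counts partition each sample's loci.
    """
    arr = states.states.to_numpy()
    out = pd.DataFrame(index=pd.Index(states.samples, name="sample"))
    for name, token in (("non", "NON"), ("hemi", "HEMI"),
                        ("full", "FULL"), ("uninf", "UNINF")):
        out[name] = (arr == token).sum(axis=0)
    out["methylated"] = out["hemi"] + out["full"]
    out["bands"] = out["non"] + out["methylated"]
    return out
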