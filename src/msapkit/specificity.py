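"""Methylation breadth (tau), sample-specific sites and shared-site algebra.

The tau score summarises how broadly a gene or locus is methylated across
the n assayed samples.  With M_j = 1 when sample j is methylated (HEMI or
FULL; NON and UNINF both count 0),

    tau = (sum_j M_j - 1) / (n - 1)

so tau = 1 means methylated in every sample (no specificity) and tau = 0
means methylated in exactly one (maximal specificity).  Loci methylated
nowhere have no defined specificity and are reported as NA rather than the
formula's -1/(n-1).
"""

from __future__ import annotations

import dataclasses
import itertools
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import StateMatrix

#: state classes accepted by the set-algebra operations
CLASSES = ("HEMI", "FULL", "METHYLATED")


def _class_indicator(states: StateMatrix, cls: str) -> pd.DataFrame:
    if cls == "METHYLATED":
        return states.states.isin(("HEMI", "FULL"))
    if cls in ("HEMI", "FULL", "NON", "UNINF"):
        return states.states == cls
    raise ValueError(f"unknown state class {cls!r}; expected one of {CLASSES}")


def methylation_indicator(states: StateMatrix,
                          gene_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Binary gene/locus x sample methylation indicator (HEMI or FULL -> 1).

    With *gene_map* (locus id -> gene id) loci collapse to genes; a gene is
    methylated in a sample when any of its loci is.  Unmapped loci are
    dropped.
    """
    ind = _class_indicator(states, "METHYLATED").astype(np.int8)
    if gene_map is not None:
        mapped = ind.loc[[l for l in ind.index if l in gene_map]]
        if mapped.empty:
            raise ValueError("gene_map matches no locus id in the matrix")
        genes = [gene_map[l] for l in mapped.index]
        ind = mapped.groupby(pd.Index(genes, name="gene")).max().astype(np.int8)
    return ind


def tau(indicator: Sequence[int]) -> float:
    """Tau specificity of one binary methylation vector.

    Returns NaN when the gene is methylated in no sample.

    Raises
    ------
    ValueError
        If fewer than two samples, or any entry is not 0/1.
    """
    m = np.asarray(indicator)
    if m.ndim != 1 or len(m) < 2:
        raise ValueError("tau needs a 1-D indicator over at least two samples")
    if not np.isin(m, (0, 1)).all():
        raise ValueError("indicator entries must be 0 or 1")
    breadth = int(m.sum())
    if breadth == 0:
        return float("nan")
    return (breadth - 1) / (len(m) - 1)


def tau_table(states: StateMatrix,
              gene_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Tau and breadth for every gene/locus.

    Returns a DataFrame indexed by gene (or locus id when *gene_map* is
    None) with columns ``breadth`` and ``tau`` (NaN for breadth 0).
    """
    ind = methylation_indicator(states, gene_map)
    n = ind.shape[1]
    if n < 2:
        raise ValueError("tau needs at least two samples")
    breadth = ind.sum(axis=1)
    scores = (breadth - 1) / (n - 1)
    scores[breadth == 0] = np.nan
    return pd.DataFrame({"breadth": breadth.astype(int), "tau": scores})


@dataclasses.dataclass(frozen=True)
class SpecificCounts:
    """Per-sample counts of loci carrying a class in exactly that sample."""

    cls: str
    per_sample: pd.Series
    total: int
    total_loci: int

    @property
    def pct_of_loci(self) -> float:
        if self.total_loci == 0:
            return float("nan")
        return 100.0 * self.total / self.total_loci


def specific_sites(states: StateMatrix, cls: str = "METHYLATED") -> SpecificCounts:
    """Count loci whose class occurs in exactly one sample.

    For ``cls="METHYLATED"`` a locus is specific to sample j when it is
    methylated (HEMI or FULL) in j and in no other sample; for ``"HEMI"`` /
    ``"FULL"`` the carried class itself must be unique to j (other samples
    may hold any other state).
    """
    if len(states.samples) < 2:
        raise ValueError("specificity requires at least two samples")
    ind = _class_indicator(states, cls).to_numpy()
    singleton = ind.sum(axis=1) == 1
    counts = ind[singleton].sum(axis=0)
    per_sample = pd.Series(counts, index=pd.Index(states.samples, name="sample"),
                           name=f"specific_{cls.lower()}")
    return SpecificCounts(cls=cls, per_sample=per_sample,
                          total=int(singleton.sum()), total_loci=states.n_loci)


def shared_sites(states: StateMatrix, subset: Sequence[str],
                 cls: str = "METHYLATED") -> int:
    """Count loci carrying *cls* in every member of *subset*.

    For ``"METHYLATED"`` each member may carry HEMI or FULL independently;
    for ``"HEMI"``/``"FULL"`` every member must carry that exact class.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    unknown = [s for s in subset if s not in states.samples]
    if unknown:
        raise KeyError(f"unknown sample(s) in subset: {unknown}")
    ind = _class_indicator(states, cls)[subset].to_numpy()
    return int(ind.all(axis=1).sum())


def common_pattern_fraction(states: StateMatrix) -> float:
    """Percent of methylated loci with one identical methylated state everywhere.

    A locus counts when every sample carries the *same* methylated class
    (all HEMI or all FULL).  Denominator: loci methylated in at least one
    sample.  Returns NaN when no locus is methylated.
    """
    if len(states.samples) < 2:
        raise ValueError("common-pattern accounting requires at least two samples")
    arr = states.states.to_numpy()
    any_meth = np.isin(arr, ("HEMI", "FULL")).any(axis=1)
    if not any_meth.any():
        return float("nan")
    all_hemi = (arr == "HEMI").all(axis=1)
    all_full = (arr == "FULL").all(axis=1)
    common = (all_hemi | all_full).sum()
    return 100.0 * common / any_meth.sum()


def venn_regions(states: StateMatrix, subset: Sequence[str],
                 cls: str = "METHYLATED") -> dict[frozenset, int]:
    """Exhaustive Venn-region counts for a subset of up to five samples.

    Each key is the exact set of subset members carrying *cls* at a locus;
    the empty region (class in no member) is included.  Region counts sum to
    the total locus count.
    """
    subset = list(subset)
    if not 1 <= len(subset) <= 5:
        raise ValueError("venn regions are reported for subsets of 1-5 samples; "
                         "use shared_sites/specific_sites for larger subsets")
    unknown = [s for s in subset if s not in states.samples]
    if unknown:
        raise KeyError(f"unknown sample(s) in subset: {unknown}")
    ind = _class_indicator(states, cls)[subset].to_numpy()
    regions: dict[frozenset, int] = {
        frozenset(combo): 0
        for r in range(len(subset) + 1)
        for combo in itertools.combinations(subset, r)
    }
    for row in ind:
        key = frozenset(s for s, present in zip(subset, row) if present)
        regions[key] += 1
    return regions


@dataclasses.dataclass(frozen=True)
class SharingReport:
    """Shared and specific counts for one sample subset, all three classes."""

    subset: tuple[str, ...]
    shared_methylated: int
    shared_full: int
    shared_hemi: int
    specific_methylated: pd.Series
    specific_full: pd.Series
    specific_hemi: pd.Series


def sharing_report(states: StateMatrix, subset: Sequence[str]) -> SharingReport:
    """Shared counts over *subset* plus per-sample specific counts.

    Shared-methylated lets members differ between HEMI and FULL, which is
    why it can exceed shared-full + shared-hemi.
    """
    return SharingReport(
        subset=tuple(subset),
        shared_methylated=shared_sites(states, subset, "METHYLATED"),
        shared_full=shared_sites(states, subset, "FULL"),
        shared_hemi=shared_sites(states, subset, "HEMI"),
        specific_methylated=specific_sites(states, "METHYLATED").per_sample,
        specific_full=specific_sites(states, "FULL").per_sample,
        specific_hemi=specific_sites(states, "HEMI").per_sample,
    )
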