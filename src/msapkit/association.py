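"""Association between methylation state classes and transcript levels.

Two views are provided.  ``group_expression`` partitions genes by their
called state in one tissue and compares mean expression between the HEMI,
FULL and NON groups with pairwise t-tests — methylation tends to suppress
transcription, with hemi-methylation suppressing more strongly than full
methylation, so the expected ordering of means is HEMI < FULL < NON.
``pattern_correlation`` pools gene x tissue pairs and correlates an ordinal
encoding of the state with expression (Pearson's r with its t-test p-value).

The ordinal encoding NON=0, FULL=1, HEMI=2 mirrors the observed suppression
ordering; it is a modelling choice, is configurable, and is recorded in every
result object.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from collections.abc import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import ExpressionMatrix, StateMatrix
from .profiles import _two_sample_t

#: ordinal state encoding, increasing in expected transcriptional suppression
DEFAULT_STATE_ENCODING: dict[str, float] = {"NON": 0.0, "FULL": 1.0, "HEMI": 2.0}

#: tissues with RNA-based expression in the motivating study design
VASCULAR_TISSUES = ("phloem", "cambium", "developingXylem", "matureXylem")

_GROUPS = ("HEMI", "FULL", "NON")


def _resolve_gene_map(states: StateMatrix, expr: ExpressionMatrix,
                      gene_map: Mapping[str, str] | None) -> dict[str, str]:
    """Locus -> gene pairs present in both matrices (identity when unmapped)."""
    if gene_map is None:
        gene_map = {lid: lid for lid in states.locus_ids}
    genes = set(expr.genes)
    resolved = {l: g for l, g in gene_map.items()
                if l in states.states.index and g in genes}
    if not resolved:
        raise ValueError("no locus maps to a gene present in the expression matrix")
    return resolved


@dataclasses.dataclass(frozen=True)
class AssociationResult:
    """Group means and pairwise tests for one tissue."""

    tissue: str
    group_means: dict[str, float]
    group_sizes: dict[str, int]
    pairwise_t: dict[tuple[str, str], float]
    pairwise_p: dict[tuple[str, str], float]
    n_genes: int
    log_transform: bool
    encoding: dict[str, float]


def group_expression(states: StateMatrix, expr: ExpressionMatrix, tissue: str,
                     gene_map: Mapping[str, str] | None = None, *,
                     log_transform: bool = True,
                     equal_var: bool = True,
                     encoding: Mapping[str, float] | None = None) -> AssociationResult:
    """Compare expression between the HEMI, FULL and NON gene sets of a tissue.

    Genes uninformative (UNINF) in the tissue are excluded.  Group means are
    reported on the raw expression scale; t-tests run on log2(x+1) values by
    default because qRT-PCR/FPKM noise is multiplicative (``log_transform=
    False`` for raw scale).  A pair with a group of fewer than two genes
    gets a NaN p-value and a warning.
    """
    if tissue not in states.samples:
        raise KeyError(f"tissue {tissue!r} not in state matrix")
    if tissue not in expr.samples:
        raise KeyError(f"tissue {tissue!r} not in expression matrix")
    gmap = _resolve_gene_map(states, expr, gene_map)
    raw: dict[str, list[float]] = {g: [] for g in _GROUPS}
    for locus, gene in gmap.items():
        state = states.states.at[locus, tissue]
        if state in _GROUPS:
            raw[state].append(float(expr.values.at[gene, tissue]))
    arrays = {g: np.asarray(v, dtype=float) for g, v in raw.items()}
    tested = {g: (np.log2(a + 1.0) if log_transform else a)
              for g, a in arrays.items()}
    pairwise_t: dict[tuple[str, str], float] = {}
    pairwise_p: dict[tuple[str, str], float] = {}
    for ga, gb in itertools.combinations(_GROUPS, 2):
        if len(tested[ga]) < 2 or len(tested[gb]) < 2:
            warnings.warn(
                f"{tissue}: group {ga if len(tested[ga]) < 2 else gb} has fewer "
                f"than two genes; ({ga}, {gb}) test reported as NA",
                stacklevel=2,
            )
            pairwise_t[(ga, gb)] = float("nan")
            pairwise_p[(ga, gb)] = float("nan")
            continue
        t, p = _two_sample_t(tested[ga], tested[gb], equal_var)
        pairwise_t[(ga, gb)] = t
        pairwise_p[(ga, gb)] = p
    return AssociationResult(
        tissue=tissue,
        group_means={g: (float(a.mean()) if len(a) else float("nan"))
                     for g, a in arrays.items()},
        group_sizes={g: len(a) for g, a in arrays.items()},
        pairwise_t=pairwise_t,
        pairwise_p=pairwise_p,
        n_genes=sum(len(a) for a in arrays.values()),
        log_transform=log_transform,
        encoding=dict(encoding or DEFAULT_STATE_ENCODING),
    )


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of encoded state vs. expression over gene x tissue pairs."""

    pearson_r: float
    pearson_p: float
    n_pairs: int
    tissues: tuple[str, ...]
    encoding: dict[str, float]


def pattern_correlation(states: StateMatrix, expr: ExpressionMatrix,
                        tissues: Sequence[str] | None = None,
                        gene_map: Mapping[str, str] | None = None, *,
                        encoding: Mapping[str, float] | None = None,
                        ) -> CorrelationResult:
    """Pearson r between ordinally encoded state and expression.

    Pools every (gene, tissue) pair with an informative state over the
    given tissues (default: the four vascular tissues).  Returns NaN r and
    p with a warning when either pooled vector has zero variance.
    """
    enc = dict(encoding or DEFAULT_STATE_ENCODING)
    if tissues is None:
        tissues = [t for t in VASCULAR_TISSUES if t in states.samples]
    tissues = list(tissues)
    unknown = [t for t in tissues if t not in states.samples or t not in expr.samples]
    if unknown:
        raise KeyError(f"tissue(s) not present in both matrices: {unknown}")
    gmap = _resolve_gene_map(states, expr, gene_map)
    xs: list[float] = []
    ys: list[float] = []
    for locus, gene in gmap.items():
        for tissue in tissues:
            state = states.states.at[locus, tissue]
            if state in enc:
                xs.append(enc[state])
                ys.append(float(expr.values.at[gene, tissue]))
    n = len(xs)
    if n < 3:
        raise ValueError(
            f"need at least 3 informative (gene, tissue) pairs, got {n}"
        )
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance in state encoding or expression; "
                      "correlation undefined", stacklevel=2)
        return CorrelationResult(float("nan"), float("nan"), n,
                                 tuple(tissues), enc)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), n, tuple(tissues), enc)
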