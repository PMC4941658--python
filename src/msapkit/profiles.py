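"""Relative methylation levels per sample and between-group comparisons.

Because MSAP only interrogates CCGG sites that amplify, methylation levels
are *relative*: each class percentage uses the full analysed marker count as
denominator, so uninformative loci depress the informative classes rather
than being dropped.  Profiles can be computed on the whole matrix or on a
locus subset (e.g. a candidate-gene panel), in which case the subset size is
the denominator.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import StateMatrix

#: metrics accepted by :func:`compare_groups`
LEVEL_METRICS = ("hemi_pct", "full_pct", "non_pct", "uninf_pct", "methylated_pct")

#: conventional split of the ten study samples for wood-formation contrasts
XYLEM_SAMPLES = ("developingXylem", "matureXylem")


def relative_levels(states: StateMatrix,
                    subset: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-sample relative level of each methylation class.

    Parameters
    ----------
    states
        Called state matrix.
    subset
        Optional locus ids restricting the analysis; percentages then use
        the subset size as denominator.

    Returns
    -------
    DataFrame indexed by sample with columns ``hemi_pct``, ``full_pct``,
    ``non_pct``, ``uninf_pct`` (summing to 100 per row), ``methylated_pct``
    (= hemi + full) and ``denominator``.
    """
    frame = states.states
    if subset is not None:
        subset = list(subset)
        if len(subset) == 0:
            raise ValueError("locus subset must be non-empty")
        missing = [s for s in subset if s not in frame.index]
        if missing:
            raise KeyError(f"unknown locus id(s) in subset: {missing[:5]}")
        frame = frame.loc[subset]
    n = len(frame)
    if n == 0:
        raise ValueError("state matrix has no loci")
    arr = frame.to_numpy()
    out = pd.DataFrame(index=pd.Index(frame.columns, name="sample"))
    for name, token in (("hemi_pct", "HEMI"), ("full_pct", "FULL"),
                        ("non_pct", "NON"), ("uninf_pct", "UNINF")):
        out[name] = 100.0 * (arr == token).sum(axis=0) / n
    out["methylated_pct"] = out["hemi_pct"] + out["full_pct"]
    out["denominator"] = n
    return out


def summarize_levels(profiles: pd.DataFrame) -> pd.DataFrame:
    """Mean/min/max of each level metric across samples, with extremal samples.

    Returns a DataFrame indexed by metric with columns ``mean``, ``min``,
    ``max``, ``argmin`` and ``argmax`` (sample labels attaining the extremes;
    ties resolve to the first sample in row order).
    """
    if len(profiles) == 0:
        raise ValueError("no profiles to summarize")
    rows = {}
    for metric in LEVEL_METRICS:
        col = profiles[metric]
        rows[metric] = {
            "mean": float(col.mean()),
            "min": float(col.min()),
            "max": float(col.max()),
            "argmin": col.idxmin(),
            "argmax": col.idxmax(),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclasses.dataclass(frozen=True)
class GroupComparison:
    """Two-sample t-test of one level metric between sample groups."""

    metric: str
    group_a: str
    group_b: str
    samples_a: tuple[str, ...]
    samples_b: tuple[str, ...]
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    equal_var: bool

    def significant(self, alpha: float = 0.05) -> bool:
        return bool(self.p_value < alpha)


def _two_sample_t(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float]:
    # Degenerate zero-variance cases: scipy returns nan; define them by the
    # limit of the statistic instead.
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        return (np.inf if a[0] > b[0] else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def compare_groups(profiles: pd.DataFrame,
                   assignment: Mapping[str, str],
                   metric: str,
                   *,
                   equal_var: bool = True) -> GroupComparison:
    """Compare one relative-level metric between two sample groups.

    Student's equal-variance two-sided t-test by default (the classical
    procedure for this design); pass ``equal_var=False`` for Welch.

    Parameters
    ----------
    profiles
        Output of :func:`relative_levels`.
    assignment
        Mapping sample -> group label; exactly two labels must occur among
        the profiled samples, and each group needs at least two samples.
    metric
        One of :data:`LEVEL_METRICS`.
    """
    if metric not in LEVEL_METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {LEVEL_METRICS}")
    unknown = [s for s in assignment if s not in profiles.index]
    if unknown:
        raise KeyError(f"assignment references unknown sample(s): {unknown[:5]}")
    groups: dict[str, list[str]] = {}
    for sample in profiles.index:
        if sample in assignment:
            groups.setdefault(assignment[sample], []).append(sample)
    if len(groups) != 2:
        raise ValueError(
            f"need exactly two groups, got {sorted(groups)} from assignment"
        )
    (label_a, samples_a), (label_b, samples_b) = groups.items()
    for label, members in ((label_a, samples_a), (label_b, samples_b)):
        if len(members) < 2:
            raise ValueError(
                f"group {label!r} has {len(members)} sample(s); the t-test "
                f"needs at least two per group"
            )
    a = profiles.loc[samples_a, metric].to_numpy(dtype=float)
    b = profiles.loc[samples_b, metric].to_numpy(dtype=float)
    t, p = _two_sample_t(a, b, equal_var)
    return GroupComparison(
        metric=metric, group_a=label_a, group_b=label_b,
        samples_a=tuple(samples_a), samples_b=tuple(samples_b),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        t_statistic=t, p_value=p, equal_var=equal_var,
    )


def xylem_assignment(samples: Sequence[str],
                     xylem: Sequence[str] = XYLEM_SAMPLES) -> dict[str, str]:
    """Split samples into ``"xylem"`` and ``"nonXylem"`` groups."""
    xylem_set = set(xylem)
    missing = xylem_set - set(samples)
    if missing:
        raise KeyError(f"xylem sample(s) not in matrix: {sorted(missing)}")
    return {s: ("xylem" if s in xylem_set else "nonXylem") for s in samples}
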