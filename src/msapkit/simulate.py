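"""Synthetic MSAP data with known ground truth.

The generator works at the level the assay cannot see: each locus/sample is
assigned a *biochemical* CCGG state — unmethylated, internal-cytosine full
methylation, external-cytosine hemi-methylation, or methylation blocking
both enzymes — and band presence in the two lanes follows deterministically
from the enzymes' sensitivities.  Calling the simulated bands recovers the
truth exactly except for BLOCKED_BOTH loci, which (like real site absence)
surface as UNINF: a documented information loss of the assay itself.

Default per-tissue class frequencies emulate a ten-tissue poplar survey:
hemi-methylation 7.9-11.9% (mean 9.52), full methylation 9.4-14.2%
(mean 11.90), non-methylated 32.7-39.3% (mean 36.17), remainder blocked or
absent; 18% of loci are monomorphic across tissues.  Expression is
log-normal with additive log-scale suppression per methylated state, the
hemi offset exceeding the full offset so suppression follows
HEMI > FULL > none.
"""

from __future__ import annotations

import dataclasses
import enum
from collections import Counter
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import BandMatrix, ExpressionMatrix, LocusMeta, StateMatrix

__all__ = [
    "BiochemicalState", "ClassProbs", "SimulationConfig", "SimulationResult",
    "simulate_band_pattern", "generate_band_matrix", "generate_stage_series",
    "states_from_pattern_counts", "generate_expression",
    "generate_replicates", "consensus_states",
    "DEFAULT_SAMPLE_PROFILES",
]


class BiochemicalState(str, enum.Enum):
    """True methylation status of a CCGG site (not all are assay-visible)."""

    UNMETH = "UNMETH"
    INTERNAL_FULL = "INTERNAL_FULL"
    EXTERNAL_HEMI = "EXTERNAL_HEMI"
    BLOCKED_BOTH = "BLOCKED_BOTH"


#: biochemical state -> (HpaII lane, MspI lane) presence
BAND_PATTERN: dict[BiochemicalState, tuple[int, int]] = {
    BiochemicalState.UNMETH: (1, 1),
    BiochemicalState.INTERNAL_FULL: (0, 1),
    BiochemicalState.EXTERNAL_HEMI: (1, 0),
    BiochemicalState.BLOCKED_BOTH: (0, 0),
}

#: biochemical state -> the state a caller will assign from the bands
TRUE_CALL: dict[str, str] = {
    "UNMETH": "NON",
    "INTERNAL_FULL": "FULL",
    "EXTERNAL_HEMI": "HEMI",
    "BLOCKED_BOTH": "UNINF",
}

_BIOCHEM_ORDER = ("UNMETH", "INTERNAL_FULL", "EXTERNAL_HEMI", "BLOCKED_BOTH")
_CALL_ORDER = ("NON", "FULL", "HEMI", "UNINF")
_STATES = ("NON", "HEMI", "FULL", "UNINF")


def simulate_band_pattern(state: BiochemicalState) -> tuple[int, int]:
    """Band presence (h, m) produced by one biochemical state."""
    return BAND_PATTERN[BiochemicalState(state)]


@dataclasses.dataclass(frozen=True)
class ClassProbs:
    """Per-sample biochemical class probabilities (must sum to 1)."""

    p_unmeth: float
    p_internal_full: float
    p_external_hemi: float
    p_blocked: float

    def __post_init__(self) -> None:
        vec = self.as_array()
        if (vec < 0).any():
            raise ConfigError(f"class probabilities must be >= 0, got {vec}")
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ConfigError(
                f"class probabilities must sum to 1 (got {vec.sum():.12f})"
            )

    def as_array(self) -> np.ndarray:
        """Probabilities in UNMETH, INTERNAL_FULL, EXTERNAL_HEMI, BLOCKED_BOTH order."""
        return np.array([self.p_unmeth, self.p_internal_full,
                         self.p_external_hemi, self.p_blocked])

    @classmethod
    def from_levels(cls, hemi_pct: float, full_pct: float,
                    non_pct: float) -> "ClassProbs":
        """Build from relative levels on the 0-100 scale; remainder is blocked."""
        blocked = 100.0 - hemi_pct - full_pct - non_pct
        return cls(non_pct / 100.0, full_pct / 100.0, hemi_pct / 100.0,
                   blocked / 100.0)


# Ten-tissue default calibrated to the study conditions: hemi / full /
# non-methylated relative levels in percent, with column means 9.52 / 11.90
# / 36.17 and the reported per-tissue extremes preserved.
_DEFAULT_LEVELS: dict[str, tuple[float, float, float]] = {
    "shootApex":       (11.93, 13.00, 37.40),
    "youngLeaf":       (9.00, 10.60, 32.70),
    "matureLeaf":      (8.80, 10.88, 35.50),
    "phloem":          (9.40, 14.16, 36.50),
    "cambium":         (10.50, 12.60, 36.00),
    "developingXylem": (10.20, 12.60, 35.20),
    "matureXylem":     (9.30, 12.50, 36.20),
    "root":            (9.20, 12.60, 37.00),
    "maleCatkin":      (9.00, 10.70, 39.33),
    "femaleCatkin":    (7.87, 9.36, 35.90),
}

DEFAULT_SAMPLE_PROFILES: dict[str, ClassProbs] = {
    name: ClassProbs.from_levels(*levels)
    for name, levels in _DEFAULT_LEVELS.items()
}


def _default_samples() -> dict[str, ClassProbs]:
    return dict(DEFAULT_SAMPLE_PROFILES)


@dataclasses.dataclass
class SimulationConfig:
    """Everything the generators need; the defaults are the study conditions.

    Parameters
    ----------
    n_loci, n_primer_pairs
        Matrix size: 12,575 loci from 135 selective primer combinations.
    samples
        Ordered mapping sample -> :class:`ClassProbs`.
    monomorphic_fraction
        Fraction of loci drawn once and copied to every sample (default
        0.18, the complement of an 82% polymorphic fraction).
    primer_group_range, fragment_length_range
        Bounds for loci per primer pair (11-204) and band length (55-550 bp).
    stage_change_prob
        Per-step probability that a locus redraws its state along a stage
        path (stage-series generator).
    expr_log_mean, expr_log_sd
        Baseline natural-log mean/sd of expression (mu=4.6 puts the median
        near FPKM ~100).
    delta_hemi, delta_full
        Log-scale suppression offsets for hemi- and fully methylated genes;
        delta_hemi > delta_full encodes the stronger hemi suppression.
    seed
        Seed for all randomness; output is bit-reproducible.
    """

    n_loci: int = 12575
    n_primer_pairs: int = 135
    samples: dict[str, ClassProbs] = dataclasses.field(default_factory=_default_samples)
    monomorphic_fraction: float = 0.18
    primer_group_range: tuple[int, int] = (11, 204)
    fragment_length_range: tuple[int, int] = (55, 550)
    stage_change_prob: float = 0.25
    expr_log_mean: float = 4.6
    expr_log_sd: float = 0.5
    delta_hemi: float = 1.0
    delta_full: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ConfigError("n_loci must be >= 1")
        if not self.samples:
            raise ConfigError("at least one sample is required")
        if not 0.0 <= self.monomorphic_fraction <= 1.0:
            raise ConfigError("monomorphic_fraction must be in [0, 1]")
        if not 0.0 <= self.stage_change_prob <= 1.0:
            raise ConfigError("stage_change_prob must be in [0, 1]")
        if self.expr_log_sd <= 0:
            raise ConfigError("expr_log_sd must be > 0")
        if self.delta_hemi < 0 or self.delta_full < 0:
            raise ConfigError("suppression deltas must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclasses.dataclass
class SimulationResult:
    """Simulated bands plus both layers of ground truth."""

    bands: BandMatrix
    true_states: StateMatrix       # what a perfect caller sees
    biochemical: pd.DataFrame      # the underlying truth incl. BLOCKED_BOTH


def _primer_assignment(cfg: SimulationConfig,
                       rng: np.random.Generator) -> list[str]:
    """Per-locus primer-pair labels with group sizes in the configured range."""
    lo, hi = cfg.primer_group_range
    npp = min(cfg.n_primer_pairs, cfg.n_loci)
    sizes = rng.integers(lo, hi + 1, size=npp)
    # repair the total while keeping every group inside [lo, hi] if possible
    diff = cfg.n_loci - int(sizes.sum())
    step = 1 if diff > 0 else -1
    guard = 0
    while diff != 0:
        i = int(rng.integers(npp))
        new = sizes[i] + step
        if lo <= new <= hi or guard > 50 * abs(cfg.n_loci):
            sizes[i] = max(new, 1)
            diff -= step
        guard += 1
    labels = [f"E{i % 99 + 1:02d}+H/M{i // 99 + 30:02d}" for i in range(npp)]
    out: list[str] = []
    for lab, size in zip(labels, sizes):
        out.extend([lab] * int(size))
    return out[: cfg.n_loci]


def _draw_biochem(probs: np.ndarray, size: int,
                  rng: np.random.Generator) -> np.ndarray:
    idx = rng.choice(4, size=size, p=probs)
    return np.array(_BIOCHEM_ORDER, dtype=object)[idx]


def generate_band_matrix(cfg: SimulationConfig,
                         rng: np.random.Generator | None = None) -> SimulationResult:
    """Draw a full multi-sample band matrix with ground truth.

    A ``monomorphic_fraction`` of loci is drawn once (from the mean class
    probabilities across samples) and copied to every sample; the rest are
    drawn independently per sample.  Band lanes follow
    :func:`simulate_band_pattern`.
    """
    rng = cfg.rng() if rng is None else rng
    sample_names = list(cfg.samples)
    n = cfg.n_loci
    n_mono = int(round(cfg.monomorphic_fraction * n))
    prob_matrix = np.vstack([cfg.samples[s].as_array() for s in sample_names])
    mean_probs = prob_matrix.mean(axis=0)
    mean_probs = mean_probs / mean_probs.sum()

    biochem = np.empty((n, len(sample_names)), dtype=object)
    mono = _draw_biochem(mean_probs, n_mono, rng)
    biochem[:n_mono, :] = mono[:, None]
    for j, s in enumerate(sample_names):
        biochem[n_mono:, j] = _draw_biochem(prob_matrix[j], n - n_mono, rng)

    # permute rows so monomorphic loci are not a prefix block
    order = rng.permutation(n)
    biochem = biochem[order]

    primer = _primer_assignment(cfg, rng)
    lo, hi = cfg.fragment_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    width = len(str(n))
    loci = [LocusMeta(f"L{i + 1:0{width}d}", primer[i], int(lengths[i]))
            for i in range(n)]
    ids = [l.locus_id for l in loci]

    h = np.empty((n, len(sample_names)), dtype=np.int8)
    m = np.empty_like(h)
    called = np.empty_like(biochem)
    for token in _BIOCHEM_ORDER:
        mask = biochem == token
        hp, mp = BAND_PATTERN[BiochemicalState(token)]
        h[mask] = hp
        m[mask] = mp
        called[mask] = TRUE_CALL[token]

    bands = BandMatrix(
        loci=loci,
        h_lane=pd.DataFrame(h, index=ids, columns=sample_names),
        m_lane=pd.DataFrame(m, index=ids, columns=sample_names),
    )
    truth = StateMatrix(
        loci=list(loci),
        states=pd.DataFrame(called, index=ids, columns=sample_names),
    )
    biochem_df = pd.DataFrame(biochem, index=ids, columns=sample_names)
    return SimulationResult(bands=bands, true_states=truth, biochemical=biochem_df)


def generate_stage_series(cfg: SimulationConfig,
                          path: Sequence[str] | None = None,
                          rng: np.random.Generator | None = None,
                          ) -> tuple[StateMatrix, Counter]:
    """Called-state matrix along an ordered stage path, with exact pattern counts.

    Stage one draws each locus from that sample's class probabilities
    (mapped to called states); each later stage keeps the previous state
    with probability ``1 - stage_change_prob`` and redraws otherwise.
    Returns the matrix and a Counter over fully specified state tuples —
    the ground truth for transition-count oracles; counts sum to ``n_loci``.
    """
    rng = cfg.rng() if rng is None else rng
    if path is None:
        path = list(cfg.samples)
    path = list(path)
    unknown = [s for s in path if s not in cfg.samples]
    if unknown:
        raise ConfigError(f"stage path references unknown sample(s): {unknown}")
    if len(path) < 2:
        raise ConfigError("a stage path needs at least two stages")
    n = cfg.n_loci
    call_order = np.array(_CALL_ORDER, dtype=object)

    def draw(sample: str, size: int) -> np.ndarray:
        return call_order[rng.choice(4, size=size, p=cfg.samples[sample].as_array())]

    cols = [draw(path[0], n)]
    for stage in path[1:]:
        prev = cols[-1].copy()
        change = rng.random(n) < cfg.stage_change_prob
        prev[change] = draw(stage, int(change.sum()))
        cols.append(prev)
    arr = np.column_stack(cols)
    width = len(str(n))
    loci = [LocusMeta(f"L{i + 1:0{width}d}") for i in range(n)]
    states = StateMatrix(
        loci=loci,
        states=pd.DataFrame(arr, index=[l.locus_id for l in loci], columns=path),
    )
    counts = Counter(tuple(row) for row in arr)
    return states, counts


def states_from_pattern_counts(path: Sequence[str],
                               counts: Mapping[Sequence[str], int]) -> StateMatrix:
    """Deterministically build a matrix realising exact transition counts.

    *counts* maps fully specified state tuples (over NON/HEMI/FULL/UNINF,
    same length as *path*) to the number of loci that should carry them.
    """
    path = list(path)
    rows: list[tuple[str, ...]] = []
    for pattern, k in counts.items():
        pattern = tuple(pattern)
        if len(pattern) != len(path):
            raise ValueError(f"pattern {pattern} does not match path length "
                             f"{len(path)}")
        bad = [s for s in pattern if s not in _STATES]
        if bad:
            raise ValueError(f"unknown state token {bad[0]!r} in pattern")
        rows.extend([pattern] * int(k))
    if not rows:
        raise ValueError("no loci requested")
    width = len(str(len(rows)))
    loci = [LocusMeta(f"L{i + 1:0{width}d}") for i in range(len(rows))]
    frame = pd.DataFrame(rows, index=[l.locus_id for l in loci], columns=path)
    return StateMatrix(loci=loci, states=frame)


def generate_expression(truth: StateMatrix, cfg: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        ) -> ExpressionMatrix:
    """Log-normal expression suppressed by the methylation state.

    Per gene x tissue: ``exp(Normal(mu - delta(state), sigma))`` with
    delta(NON) = delta(UNINF) = 0, delta(FULL) = ``delta_full`` and
    delta(HEMI) = ``delta_hemi``; genes are the loci of *truth*.
    """
    rng = cfg.rng() if rng is None else rng
    arr = truth.states.to_numpy()
    delta = np.zeros(arr.shape)
    delta[arr == "FULL"] = cfg.delta_full
    delta[arr == "HEMI"] = cfg.delta_hemi
    log_vals = rng.normal(cfg.expr_log_mean - delta, cfg.expr_log_sd)
    values = pd.DataFrame(np.exp(log_vals), index=truth.states.index,
                          columns=truth.samples)
    return ExpressionMatrix(values)


def generate_replicates(truth: StateMatrix, cfg: SimulationConfig,
                        n_replicates: int = 3, error_rate: float = 0.02,
                        rng: np.random.Generator | None = None,
                        ) -> list[StateMatrix]:
    """Noisy biological replicates of a called-state matrix.

    Each cell is independently replaced, with probability *error_rate*, by
    one of the three other states (uniformly) — a simple model of gel
    scoring error.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ConfigError("error_rate must be in [0, 1)")
    rng = cfg.rng() if rng is None else rng
    base = truth.states.to_numpy()
    states = np.array(_STATES, dtype=object)
    reps = []
    for _ in range(n_replicates):
        arr = base.copy()
        flip = rng.random(arr.shape) < error_rate
        if flip.any():
            idx = np.argwhere(flip)
            for i, j in idx:
                others = [s for s in states if s != arr[i, j]]
                arr[i, j] = others[int(rng.integers(3))]
        reps.append(StateMatrix(
            loci=list(truth.loci),
            states=pd.DataFrame(arr, index=truth.states.index,
                                columns=truth.samples),
        ))
    return reps


def consensus_states(replicates: Sequence[StateMatrix]) -> StateMatrix:
    """Majority-vote consensus across replicate state matrices (ties -> UNINF)."""
    if not replicates:
        raise ValueError("need at least one replicate")
    first = replicates[0]
    for rep in replicates[1:]:
        if rep.states.shape != first.states.shape or \
                list(rep.samples) != list(first.samples):
            raise ValueError("replicates must share shape and sample labels")
    stack = np.stack([rep.states.to_numpy() for rep in replicates])
    n_rep, n_loci, n_samp = stack.shape
    out = np.empty((n_loci, n_samp), dtype=object)
    for i in range(n_loci):
        for j in range(n_samp):
            votes = Counter(stack[:, i, j])
            (top, k), *rest = votes.most_common()
            if rest and rest[0][1] == k:
                out[i, j] = "UNINF"   # tie: no determinate call
            else:
                out[i, j] = top
    return StateMatrix(
        loci=list(first.loci),
        states=pd.DataFrame(out, index=first.states.index, columns=first.samples),
    )
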