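"""Ground-truth generators: determinism, calibration and caller roundtrip."""

import numpy as np
import pytest

from msapkit import (
    BiochemicalState,
    ClassProbs,
    ConfigError,
    SimulationConfig,
    call_states,
    classify_band_pair,
    consensus_states,
    find_polymorphic,
    generate_band_matrix,
    generate_expression,
    generate_replicates,
    generate_stage_series,
    simulate_band_pattern,
)
from msapkit.simulate import DEFAULT_SAMPLE_PROFILES, TRUE_CALL


@pytest.mark.parametrize(
    "state, pattern",
    [
        (BiochemicalState.UNMETH, (1, 1)),
        (BiochemicalState.INTERNAL_FULL, (0, 1)),
        (BiochemicalState.EXTERNAL_HEMI, (1, 0)),
        (BiochemicalState.BLOCKED_BOTH, (0, 0)),
    ],
)
def test_band_pattern_follows_enzyme_sensitivities(state, pattern):
    assert simulate_band_pattern(state) == pattern


def test_simulate_then_classify_roundtrip_identity():
    """The caller inverts the generator on the three informative states;
    doubly blocked methylation is indistinguishable from site absence."""
    for state in BiochemicalState:
        h, m = simulate_band_pattern(state)
        called = classify_band_pair(h, m)
        assert called.value == TRUE_CALL[state.value]


def test_class_probs_validation():
    with pytest.raises(ConfigError, match="sum to 1"):
        ClassProbs(0.5, 0.2, 0.2, 0.2)
    with pytest.raises(ConfigError):
        ClassProbs(1.2, -0.2, 0.0, 0.0)


def test_default_profiles_reproduce_study_level_means():
    levels = np.array([[p.p_external_hemi, p.p_internal_full, p.p_unmeth]
                       for p in DEFAULT_SAMPLE_PROFILES.values()]) * 100
    means = levels.mean(axis=0)
    assert means[0] == pytest.approx(9.52, abs=0.005)
    assert means[1] == pytest.approx(11.90, abs=0.005)
    assert means[2] == pytest.approx(36.17, abs=0.005)
    assert len(DEFAULT_SAMPLE_PROFILES) == 10


def test_generator_is_seed_deterministic():
    cfg = SimulationConfig(n_loci=300, seed=42)
    a = generate_band_matrix(cfg)
    b = generate_band_matrix(cfg)
    assert a.bands.h_lane.equals(b.bands.h_lane)
    assert a.bands.m_lane.equals(b.bands.m_lane)
    assert a.true_states.states.equals(b.true_states.states)
    ea = generate_expression(a.true_states, cfg)
    eb = generate_expression(b.true_states, cfg)
    assert ea.values.equals(eb.values)


def test_calling_recovers_truth():
    cfg = SimulationConfig(n_loci=500, seed=7)
    res = generate_band_matrix(cfg)
    called = call_states(res.bands)
    # truth is expressed on the caller's scale, so agreement is exact ...
    assert called.states.equals(res.true_states.states)
    # ... and BLOCKED_BOTH loci are the UNINF calls (information loss)
    blocked = res.biochemical.to_numpy() == "BLOCKED_BOTH"
    assert (called.states.to_numpy()[blocked] == "UNINF").all()
    informative = ~blocked
    assert (called.states.to_numpy()[informative] != "UNINF").all()


def test_pure_unmethylated_config_gives_zero_polymorphism():
    pure = ClassProbs(1.0, 0.0, 0.0, 0.0)
    cfg = SimulationConfig(n_loci=100, samples={"a": pure, "b": pure},
                           monomorphic_fraction=0.0, seed=1)
    res = generate_band_matrix(cfg)
    assert (res.bands.h_lane.to_numpy() == 1).all()
    assert (res.bands.m_lane.to_numpy() == 1).all()
    summary, _ = find_polymorphic(call_states(res.bands))
    assert summary.polymorphic_loci == 0


def test_fully_monomorphic_config_gives_zero_polymorphism():
    cfg = SimulationConfig(n_loci=400, monomorphic_fraction=1.0, seed=3)
    res = generate_band_matrix(cfg)
    summary, _ = find_polymorphic(res.true_states)
    assert summary.polymorphic_loci == 0


def test_class_frequencies_within_binomial_bounds():
    """Called class frequencies converge to the configured probabilities
    (3-sigma binomial envelope at large n)."""
    n = 100_000
    cfg = SimulationConfig(
        n_loci=n, monomorphic_fraction=0.0, seed=11,
        samples={"t1": DEFAULT_SAMPLE_PROFILES["phloem"],
                 "t2": DEFAULT_SAMPLE_PROFILES["shootApex"]})
    res = generate_band_matrix(cfg)
    for sample in ("t1", "t2"):
        probs = cfg.samples[sample]
        col = res.true_states.states[sample]
        for token, p in (("NON", probs.p_unmeth), ("FULL", probs.p_internal_full),
                         ("HEMI", probs.p_external_hemi),
                         ("UNINF", probs.p_blocked)):
            count = (col == token).sum()
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(count - n * p) <= 3 * sigma


def test_primer_pairs_and_fragment_lengths_in_range():
    cfg = SimulationConfig(n_loci=3000, n_primer_pairs=30, seed=5)
    res = generate_band_matrix(cfg)
    lengths = [l.fragment_length for l in res.bands.loci]
    assert min(lengths) >= 55 and max(lengths) <= 550
    assert len({l.primer_pair for l in res.bands.loci}) <= 30


def test_stage_series_pattern_counts_are_exact(rng):
    cfg = SimulationConfig(n_loci=800, seed=9)
    path = ("phloem", "cambium", "matureXylem")
    series, counts = generate_stage_series(cfg, path)
    assert sum(counts.values()) == cfg.n_loci  # partition
    tallied = series.states.apply(tuple, axis=1).value_counts()
    for pattern, k in counts.items():
        assert tallied[pattern] == k


def test_stage_series_zero_change_prob_is_constant():
    cfg = SimulationConfig(n_loci=300, stage_change_prob=0.0, seed=2)
    series, counts = generate_stage_series(cfg, ("phloem", "cambium"))
    arr = series.states.to_numpy()
    assert (arr[:, 0] == arr[:, 1]).all()
    assert all(a == b for (a, b) in counts)


def test_stage_series_unknown_sample():
    cfg = SimulationConfig(n_loci=10, seed=0)
    with pytest.raises(ConfigError, match="unknown sample"):
        generate_stage_series(cfg, ("phloem", "nope"))


def test_expression_suppression_ordering_recovered():
    """With delta_hemi > delta_full > 0, sample group means order
    NON > FULL > HEMI in nearly every seeded run at n >= 100 genes."""
    path = ("cambium",)
    hits = 0
    for seed in range(40):
        cfg = SimulationConfig(n_loci=150, seed=seed)
        res = generate_band_matrix(cfg)
        expr = generate_expression(res.true_states, cfg)
        means = {}
        for token in ("NON", "FULL", "HEMI"):
            mask = res.true_states.states["cambium"] == token
            means[token] = expr.values.loc[mask.to_numpy(), "cambium"].mean()
        hits += means["HEMI"] < means["FULL"] < means["NON"]
    assert hits >= 38


def test_expression_zero_deltas_equal_population_means():
    cfg = SimulationConfig(n_loci=40_000, delta_hemi=0.0, delta_full=0.0, seed=4,
                           samples={"t": DEFAULT_SAMPLE_PROFILES["cambium"]})
    res = generate_band_matrix(cfg)
    expr = generate_expression(res.true_states, cfg)
    logs = np.log(expr.values["t"])
    by_state = {}
    for token in ("NON", "FULL", "HEMI"):
        mask = (res.true_states.states["t"] == token).to_numpy()
        by_state[token] = logs[mask].mean()
    # all log-means near mu within 4 standard errors
    for token, m in by_state.items():
        n_tok = (res.true_states.states["t"] == token).sum()
        assert abs(m - cfg.expr_log_mean) < 4 * cfg.expr_log_sd / np.sqrt(n_tok)


def test_replicates_and_consensus_majority_vote():
    cfg = SimulationConfig(n_loci=200, seed=6)
    res = generate_band_matrix(cfg)
    reps = generate_replicates(res.true_states, cfg, n_replicates=3,
                               error_rate=0.05)
    assert len(reps) == 3
    consensus = consensus_states(reps)
    # with 5% independent errors, majority vote recovers almost all truth
    agree = (consensus.states.to_numpy() == res.true_states.states.to_numpy())
    assert agree.mean() > 0.97


def test_consensus_tie_goes_uninf():
    from conftest import make_state_matrix
    a = make_state_matrix([("HEMI",)], ["t"])
    b = make_state_matrix([("FULL",)], ["t"])
    consensus = consensus_states([a, b])
    assert consensus.states.iat[0, 0] == "UNINF"


def test_config_validation():
    with pytest.raises(ConfigError):
        SimulationConfig(expr_log_sd=0.0)
    with pytest.raises(ConfigError):
        SimulationConfig(delta_hemi=-1.0)
    with pytest.raises(ConfigError):
        SimulationConfig(monomorphic_fraction=1.2)
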