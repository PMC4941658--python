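"""Tau breadth score, specific/shared sites and common-pattern accounting."""

import itertools
import math

import numpy as np
import pytest

from msapkit import (
    common_pattern_fraction,
    methylation_indicator,
    shared_sites,
    sharing_report,
    specific_sites,
    tau,
    tau_table,
    venn_regions,
)

from conftest import make_state_matrix, random_state_matrix


class TestTau:
    def test_methylated_everywhere_scores_one(self):
        assert tau([1] * 10) == 1.0

    def test_methylated_in_one_sample_scores_zero(self):
        assert tau([1] + [0] * 9) == 0.0

    def test_breadth_five_of_ten(self):
        assert tau([1] * 5 + [0] * 5) == pytest.approx(4 / 9)

    def test_breadth_zero_is_na(self):
        assert math.isnan(tau([0] * 10))

    def test_monotone_in_breadth_and_bounded(self):
        scores = [tau([1] * b + [0] * (10 - b)) for b in range(1, 11)]
        assert all(0.0 <= s <= 1.0 for s in scores)
        assert scores == sorted(scores)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            tau([1])
        with pytest.raises(ValueError):
            tau([1, 2, 0])


def test_tau_table_and_indicator_uninf_counts_unmethylated():
    sm = make_state_matrix(
        [("HEMI", "FULL", "HEMI"),     # breadth 3 -> tau 1
         ("FULL", "NON", "UNINF"),     # breadth 1 -> tau 0
         ("NON", "UNINF", "NON"),      # breadth 0 -> NA
         ("HEMI", "HEMI", "NON")],     # breadth 2 -> 1/2
        ["a", "b", "c"])
    ind = methylation_indicator(sm)
    assert ind.to_numpy().tolist() == [[1, 1, 1], [1, 0, 0], [0, 0, 0], [1, 1, 0]]
    table = tau_table(sm)
    assert table["breadth"].tolist() == [3, 1, 0, 2]
    assert table["tau"].tolist()[:2] == [1.0, 0.0]
    assert math.isnan(table["tau"].iloc[2])
    assert table["tau"].iloc[3] == pytest.approx(0.5)


def test_tau_table_gene_map_collapses_loci():
    sm = make_state_matrix(
        [("HEMI", "NON"), ("NON", "FULL"), ("NON", "NON")], ["a", "b"])
    table = tau_table(sm, gene_map={"L1": "g1", "L2": "g1", "L3": "g2"})
    # g1 methylated in both samples via either locus
    assert table.at["g1", "breadth"] == 2 and table.at["g1", "tau"] == 1.0
    assert table.at["g2", "breadth"] == 0


def _brute_specific(sm, cls):
    tokens = {"HEMI": {"HEMI"}, "FULL": {"FULL"},
              "METHYLATED": {"HEMI", "FULL"}}[cls]
    counts = {s: 0 for s in sm.samples}
    for _, row in sm.states.iterrows():
        carriers = [s for s in sm.samples if row[s] in tokens]
        if len(carriers) == 1:
            counts[carriers[0]] += 1
    return counts


@pytest.mark.parametrize("cls", ["HEMI", "FULL", "METHYLATED"])
def test_specific_sites_brute_force_oracle(rng, cls):
    for _ in range(10):
        sm = random_state_matrix(rng, 60, ["a", "b", "c", "d"])
        res = specific_sites(sm, cls)
        expected = _brute_specific(sm, cls)
        assert res.per_sample.to_dict() == expected
        assert res.total == sum(expected.values())


def test_specific_sites_identical_columns_yield_zero():
    sm = make_state_matrix([("HEMI", "HEMI"), ("FULL", "FULL")], ["a", "b"])
    assert specific_sites(sm).total == 0


def test_specific_total_equals_breadth_one_loci(rng):
    sm = random_state_matrix(rng, 150, ["a", "b", "c", "d", "e"])
    res = specific_sites(sm, "METHYLATED")
    breadth = methylation_indicator(sm).sum(axis=1)
    assert res.total == int((breadth == 1).sum())
    assert res.per_sample.sum() == res.total


def test_shared_sites_degenerate_and_disjoint():
    sm = make_state_matrix(
        [("HEMI", "NON"), ("NON", "FULL"), ("FULL", "NON")], ["a", "b"])
    # single-member subset equals that sample's class count
    assert shared_sites(sm, ["a"], "METHYLATED") == 2
    # disjoint methylation across samples -> nothing shared
    assert shared_sites(sm, ["a", "b"], "METHYLATED") == 0


def test_shared_methylated_allows_mixed_classes():
    sm = make_state_matrix([("HEMI", "FULL")], ["a", "b"])
    assert shared_sites(sm, ["a", "b"], "METHYLATED") == 1
    assert shared_sites(sm, ["a", "b"], "HEMI") == 0
    assert shared_sites(sm, ["a", "b"], "FULL") == 0


def test_shared_sites_intersection_oracle_and_antimonotone(rng):
    samples = ["a", "b", "c", "d", "e"]
    for _ in range(10):
        sm = random_state_matrix(rng, 50, samples)
        meth_sets = {
            s: {lid for lid, v in sm.states[s].items() if v in ("HEMI", "FULL")}
            for s in samples}
        subset = ["a", "c", "e"]
        expected = set.intersection(*(meth_sets[s] for s in subset))
        assert shared_sites(sm, subset) == len(expected)
        # anti-monotonicity while growing the subset
        prev = sm.n_loci
        grown = []
        for s in samples:
            grown.append(s)
            count = shared_sites(sm, grown)
            assert count <= prev
            prev = count


def test_shared_sites_unknown_sample():
    sm = make_state_matrix([("NON", "NON")], ["a", "b"])
    with pytest.raises(KeyError):
        shared_sites(sm, ["a", "zz"])


def test_common_pattern_fraction_cases(rng):
    everywhere = make_state_matrix([("HEMI",) * 3, ("FULL",) * 3],
                                   ["a", "b", "c"])
    assert common_pattern_fraction(everywhere) == 100.0

    nowhere = make_state_matrix([("HEMI", "NON"), ("FULL", "HEMI")], ["a", "b"])
    assert common_pattern_fraction(nowhere) == 0.0

    # brute-force oracle on a random matrix
    sm = random_state_matrix(rng, 200, ["a", "b", "c"],
                             p=(0.2, 0.35, 0.35, 0.1))
    num = sum(1 for _, row in sm.states.iterrows()
              if len(set(row)) == 1 and row.iloc[0] in ("HEMI", "FULL"))
    den = sum(1 for _, row in sm.states.iterrows()
              if any(v in ("HEMI", "FULL") for v in row))
    assert common_pattern_fraction(sm) == pytest.approx(100.0 * num / den)


def test_venn_regions_partition_loci(rng):
    sm = random_state_matrix(rng, 80, ["a", "b", "c", "d", "e"])
    subset = ["a", "b", "c", "d", "e"]
    regions = venn_regions(sm, subset)
    assert len(regions) == 2 ** 5
    assert sum(regions.values()) == sm.n_loci
    # shared count equals the all-member region
    assert regions[frozenset(subset)] == shared_sites(sm, subset)
    with pytest.raises(ValueError, match="1-5"):
        venn_regions(sm, subset + ["a2"])


def test_sharing_report_consistency(rng):
    sm = random_state_matrix(rng, 100, ["a", "b", "c"])
    rep = sharing_report(sm, ["a", "b"])
    assert rep.shared_methylated >= rep.shared_full
    assert rep.shared_methylated >= rep.shared_hemi
    assert rep.shared_methylated <= rep.shared_full + rep.shared_hemi + \
        shared_sites(sm, ["a", "b"], "METHYLATED")
    assert rep.specific_methylated.sum() == specific_sites(sm).total
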