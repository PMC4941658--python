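import numpy as np
import pandas as pd
import pytest

from msapkit import BandMatrix, LocusMeta, StateMatrix


def make_state_matrix(rows, samples):
    """Build a StateMatrix from a list of per-locus state tuples."""
    loci = [LocusMeta(f"L{i + 1}") for i in range(len(rows))]
    frame = pd.DataFrame(list(rows), index=[l.locus_id for l in loci],
                         columns=list(samples))
    return StateMatrix(loci=loci, states=frame)


def make_band_matrix(h_rows, m_rows, samples):
    loci = [LocusMeta(f"L{i + 1}", "P1", 100 + i) for i in range(len(h_rows))]
    ids = [l.locus_id for l in loci]
    h = pd.DataFrame(np.array(h_rows, dtype=np.int8), index=ids, columns=samples)
    m = pd.DataFrame(np.array(m_rows, dtype=np.int8), index=ids, columns=samples)
    return BandMatrix(loci=loci, h_lane=h, m_lane=m)


def random_state_matrix(rng, n_loci, samples, p=(0.36, 0.10, 0.12, 0.42)):
    """Random matrix over (NON, HEMI, FULL, UNINF) with given frequencies."""
    tokens = np.array(["NON", "HEMI", "FULL", "UNINF"], dtype=object)
    rows = tokens[rng.choice(4, size=(n_loci, len(samples)), p=list(p))]
    return make_state_matrix([tuple(r) for r in rows], samples)


@pytest.fixture
def four_state_matrix():
    """One locus per state pattern across two samples."""
    return make_state_matrix(
        [("NON", "NON"), ("HEMI", "HEMI"), ("FULL", "FULL"), ("UNINF", "UNINF")],
        ["s1", "s2"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20160712)
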