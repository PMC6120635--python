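"""Clone enumeration, dropout explainability, deconvolution, ordering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dropclone as dc
from dropclone.clones import clone_label, largest_dominating_parent

SITES = ["s1", "s2", "s3"]


def _gm(vectors: list[tuple], prefix="c") -> dc.GenotypeMatrix:
    df = pd.DataFrame(
        [list(v) for v in vectors],
        index=[f"{prefix}{i}" for i in range(len(vectors))],
        columns=SITES,
        dtype=float,
    )
    return dc.GenotypeMatrix(df)


def test_single_clone_frequency_one():
    table = dc.enumerate_clones(_gm([(0, 0, 0)] * 10), SITES)
    assert len(table.table) == 1
    assert table.frequency_of((0, 0, 0)) == 1.0
    assert table.table["label"].iloc[0] == "WT"


def test_three_clone_partition():
    vectors = [(0, 0, 0)] * 6 + [(1, 0, 0)] * 3 + [(1, 1, 1)]
    table = dc.enumerate_clones(_gm(vectors), SITES)
    assert table.frequency_of((0, 0, 0)) == pytest.approx(0.6)
    assert table.frequency_of((1, 0, 0)) == pytest.approx(0.3)
    assert table.frequency_of((1, 1, 1)) == pytest.approx(0.1)
    assert table.table["frequency"].sum() == pytest.approx(1.0)


def test_spikein_and_missing_cells_excluded():
    vectors = [(0, 0, 0)] * 4 + [(1, 1, float("nan"))] + [(1, 1, 1)]
    gm = _gm(vectors)
    table = dc.enumerate_clones(gm, SITES, spikein_cells=["c5"])
    assert table.n_cells == 4
    assert table.n_excluded_missing == 1
    assert table.n_excluded_spikein == 1


def test_empty_cell_set_warns():
    table = dc.enumerate_clones(_gm([]), SITES)
    assert table.warning is not None and table.n_cells == 0


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    vectors=st.lists(
        st.tuples(*[st.integers(0, 2)] * 3), min_size=1, max_size=40
    )
)
def test_clone_table_partitions_cells(vectors):
    """Counts sum to retained cells; every vector lands in exactly one clone."""
    table = dc.enumerate_clones(_gm(vectors), SITES)
    assert table.n_cells == len(vectors)
    assert table.table["frequency"].sum() == pytest.approx(1.0)
    from collections import Counter

    for geno, n in Counter(vectors).items():
        assert table.count_of(geno) == n


def test_clone_labels():
    assert clone_label((1, 0, 2), SITES) == "s1+s3(hom)"
    assert clone_label((0, 0, 0), SITES) == "WT"


def _binom_sf_oracle(k_or_more: int, n: int, q: float) -> float:
    """P(X >= k) by direct pmf summation with exact binomial coefficients."""
    total = 0.0
    for k in range(k_or_more, n + 1):
        total += math.comb(n, k) * q**k * (1 - q) ** (n - k)
    return min(total, 1.0)


def test_explainability_binomial_tail_matches_oracle():
    """Parent 1,000 cells, q=0.035: observed 30 explainable, 120 not."""
    vectors = [(1, 1, 0)] * 1000 + [(0, 1, 0)] * 30
    table = dc.enumerate_clones(_gm(vectors), SITES)
    res = dc.ado_explainability(table, (0, 1, 0), (1, 1, 0), locus_rates=0.07)
    assert res.per_cell_prob == pytest.approx(0.035)
    assert res.expected_count == pytest.approx(35.0)
    assert res.p_value == pytest.approx(_binom_sf_oracle(30, 1000, 0.035), rel=1e-9)
    assert res.explainable

    vectors = [(1, 1, 0)] * 1000 + [(0, 1, 0)] * 120
    table = dc.enumerate_clones(_gm(vectors), SITES)
    res = dc.ado_explainability(table, (0, 1, 0), (1, 1, 0), locus_rates=0.07)
    assert res.p_value == pytest.approx(_binom_sf_oracle(120, 1000, 0.035), rel=1e-9)
    assert res.p_value < 0.05 and not res.explainable


def test_zero_observed_count_always_explainable():
    table = dc.enumerate_clones(_gm([(1, 1, 1)] * 50), SITES)
    res = dc.ado_explainability(table, (2, 1, 1), (1, 1, 1), locus_rates=0.07)
    assert res.observed_count == 0 and res.p_value == 1.0 and res.explainable


def test_pvalue_monotone_decreasing_in_observed_count():
    pvals = []
    for observed in (5, 20, 40, 80):
        vectors = [(1, 0, 0)] * 500 + [(0, 0, 0)] * observed
        table = dc.enumerate_clones(_gm(vectors), SITES)
        res = dc.ado_explainability(table, (0, 0, 0), (1, 0, 0), locus_rates=0.08)
        pvals.append(res.p_value)
    assert pvals == sorted(pvals, reverse=True)


def test_underivable_candidate_names_site():
    table = dc.enumerate_clones(_gm([(1, 0, 0)] * 10), SITES)
    with pytest.raises(ValueError, match="s2"):
        dc.ado_explainability(table, (1, 1, 0), (1, 0, 0), locus_rates=0.07)


def test_largest_dominating_parent_default():
    vectors = [(1, 1, 0)] * 500 + [(1, 0, 0)] * 100 + [(0, 0, 0)] * 50
    table = dc.enumerate_clones(_gm(vectors), SITES)
    assert largest_dominating_parent(table, (0, 1, 0)) == (1, 1, 0)


def test_deconvolution_recovers_pre_dropout_fractions():
    """Applying the dropout channel then deconvolving returns the input."""
    rng = np.random.default_rng(77)
    r = 0.09
    true = {(0, 0, 0): 0.26, (1, 0, 0): 0.02, (1, 1, 0): 0.08, (1, 1, 1): 0.64}
    vectors = []
    for geno, frac in true.items():
        for _ in range(int(round(frac * 20000))):
            observed = []
            for dose in geno:
                if dose == 1 and rng.random() < r:
                    observed.append(0 if rng.random() < 0.5 else 2)
                else:
                    observed.append(dose)
            vectors.append(tuple(observed))
    table = dc.enumerate_clones(_gm(vectors), SITES)
    assert table.frequency_of((1, 1, 1)) < 0.60  # attenuated before correction
    corrected = dc.deconvolve_ado(table, r)
    for geno, frac in true.items():
        assert corrected.frequency_of(geno) == pytest.approx(frac, abs=0.015)
    assert corrected.table["frequency"].sum() == pytest.approx(1.0)


def test_compare_timepoints_deltas():
    t1 = dc.enumerate_clones(_gm([(1, 1, 1)] * 7 + [(0, 0, 0)] * 93), SITES)
    t2 = dc.enumerate_clones(_gm([(1, 1, 1)] * 64 + [(0, 0, 0)] * 36), SITES)
    delta = dc.compare_timepoints(t1, t2)
    assert delta.loc[[(1, 1, 1)], "delta"].iloc[0] == pytest.approx(0.57)
    same = dc.compare_timepoints(t1, t1)
    assert (same["delta"].abs() < 1e-12).all()
    # clone present only at timepoint 1
    t3 = dc.enumerate_clones(_gm([(0, 0, 0)] * 10), SITES)
    gone = dc.compare_timepoints(t1, t3)
    assert gone.loc[[(1, 1, 1)], "delta"].iloc[0] == pytest.approx(-0.07)


def test_heatmap_order_deterministic_blocks_and_sort_oracle():
    rng = np.random.default_rng(3)
    vectors = [tuple(rng.integers(0, 3, 3)) for _ in range(40)]
    gm = _gm(vectors)
    order1, sites1 = dc.order_for_heatmap(gm, SITES)
    shuffled = dc.GenotypeMatrix(gm.calls.sample(frac=1, random_state=9))
    order2, _ = dc.order_for_heatmap(shuffled, SITES)
    assert order1 == order2 and sites1 == SITES
    # brute-force sort oracle: descending dosage tuples, cell id as tie-break
    oracle = sorted(
        gm.calls.index,
        key=lambda c: tuple(-v for v in gm.calls.loc[c]) + (c,),
    )
    assert order1 == oracle
    # two-clone matrix: contiguous blocks
    two = _gm([(1, 1, 0)] * 5 + [(0, 0, 0)] * 5, prefix="z")
    order, _ = dc.order_for_heatmap(two, SITES)
    labels = ["mut" if two.calls.loc[c, "s1"] == 1 else "wt" for c in order]
    assert labels == ["mut"] * 5 + ["wt"] * 5
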