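"""Mann–Whitney U: exact enumeration, approximation, and published p-values."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from rilate import (ValidationError, exact_u_distribution, mann_whitney_u,
                    run_paper_comparisons)


def brute_force_u_distribution(n1, n2):
    """Independent oracle: enumerate every interleaving of the two samples."""
    counts = np.zeros(n1 * n2 + 1)
    for positions in itertools.combinations(range(n1 + n2), n1):
        ranks = np.asarray(positions) + 1
        u1 = ranks.sum() - n1 * (n1 + 1) / 2
        counts[int(u1)] += 1
    return counts / counts.sum()


@pytest.mark.parametrize("n1,n2", [(1, 1), (2, 2), (3, 5), (4, 4), (6, 3), (8, 8)])
def test_recurrence_equals_brute_force_enumeration(n1, n2):
    np.testing.assert_allclose(exact_u_distribution(n1, n2),
                               brute_force_u_distribution(n1, n2), atol=1e-12)


def test_exact_distribution_symmetric_and_bounded():
    pmf = exact_u_distribution(7, 5)
    assert pmf.size == 36
    np.testing.assert_allclose(pmf, pmf[::-1], atol=1e-15)  # U symmetric about n1*n2/2
    assert math.isclose(pmf.sum(), 1.0)


def test_small_sample_exact_example():
    # x = {1,2}, y = {3,4}: U = 0; 1 of 6 interleavings is as extreme each side
    r = mann_whitney_u([1, 2], [3, 4])
    assert r.u == 0 and r.method == "exact"
    assert r.p_value == pytest.approx(1 / 3, abs=1e-12)


def test_u_identities_and_label_symmetry():
    rng = np.random.default_rng(5)
    x, y = rng.normal(0, 1, 9), rng.normal(1, 1, 6)
    r = mann_whitney_u(x, y)
    assert r.u1 + r.u2 == r.n1 * r.n2
    assert 0 <= r.u <= r.n1 * r.n2
    r_swapped = mann_whitney_u(y, x)
    assert r_swapped.p_value == pytest.approx(r.p_value, abs=1e-12)
    assert r_swapped.u == r.u


def test_sample_against_itself_is_null():
    x = [3.0, 1.0, 4.0, 1.5, 9.0]
    r = mann_whitney_u(x, x)
    assert r.tied
    assert r.p_value == pytest.approx(1.0, abs=0.05)


def test_all_identical_values_give_p_one():
    r = mann_whitney_u([5.0] * 4, [5.0] * 6)
    assert r.p_value == 1.0 and r.tied


def test_empty_sample_rejected():
    with pytest.raises(ValidationError):
        mann_whitney_u([], [1.0])


def test_cross_sample_ties_route_to_approximation():
    r = mann_whitney_u([1.0, 2.0, 3.0], [3.0, 4.0, 5.0])
    assert r.tied and r.method == "normal_approx"
    # within-sample ties keep the exact path (they do not alter U)
    r2 = mann_whitney_u([1.0, 1.0, 2.0], [3.0, 4.0, 5.0])
    assert not r2.tied and r2.method == "exact"


@settings(max_examples=40, derandomize=True, deadline=None)
@given(n1=st.integers(2, 12), n2=st.integers(2, 12), seed=st.integers(0, 2**31 - 1))
def test_exact_p_matches_scipy_oracle(n1, n2, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n1)
    y = rng.normal(0.8, 1, n2)
    ours = mann_whitney_u(x, y)
    ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
    assert ours.method == "exact"
    assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)


def test_approximate_p_close_to_scipy_at_moderate_n():
    rng = np.random.default_rng(17)
    x = np.round(rng.normal(0, 1, 30), 1)
    y = np.round(rng.normal(0.5, 1, 28), 1)
    ours = mann_whitney_u(x, y)
    ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert ours.method == "normal_approx"
    assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)


def test_location_shift_decreases_p_in_expectation():
    rng = np.random.default_rng(23)
    mean_p = []
    for shift in (0.0, 0.8, 1.6):
        ps = []
        for _ in range(40):
            x = rng.normal(0, 1, 12)
            y = rng.normal(shift, 1, 12)
            ps.append(mann_whitney_u(x, y).p_value)
        mean_p.append(np.mean(ps))
    assert mean_p[0] > mean_p[1] > mean_p[2]


# ---------------------------------------------------------------------------
# the published eight comparisons
# ---------------------------------------------------------------------------

def test_paper_comparisons_fixed_order_and_tags(table1):
    results = run_paper_comparisons(table1)
    assert [r.label for r in results] == [
        "marSeal critical above-vs-below",
        "marSeal necrosis above-vs-below",
        "marSeal frontier above-vs-below",
        "marSeal rilate above-vs-below",
        "BiCision critical above-vs-below",
        "BiCision necrosis above-vs-below",
        "BiCision frontier above-vs-below",
        "BiCision rilate above-vs-below",
    ]
    assert all(r.n1 == r.n2 == 15 for r in results)
    assert all(r.reported_p for r in results)
    assert [r.borderline for r in results] == [False, False, False, True,
                                               False, False, False, False]


def test_published_p_values_reproduced_where_attainable(table1):
    by_label = {r.label: r for r in run_paper_comparisons(table1)}
    assert f"{by_label['marSeal critical above-vs-below'].p_value:.4f}" == "0.0006"
    assert by_label["BiCision critical above-vs-below"].p_value < 0.0001
    assert f"{by_label['BiCision frontier above-vs-below'].p_value:.3f}" == "0.002"
    assert by_label["BiCision rilate above-vs-below"].p_value < 0.0001
    # non-significant calls
    assert not by_label["marSeal necrosis above-vs-below"].significant
    assert not by_label["marSeal frontier above-vs-below"].significant
    assert not by_label["BiCision necrosis above-vs-below"].significant


def test_missing_group_rejected(table1):
    with pytest.raises(ValidationError, match="no rows"):
        run_paper_comparisons(table1[table1.side == "above"])
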