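"""Permutation engine: statistics against independent oracles, exhaustive
enumeration on tiny instances, and engine-level invariants."""

import numpy as np
import pytest
import scipy.stats

from lakestream import resampling as rs
from lakestream.errors import InsufficientDataError

from oracles import exhaustive_extreme_fraction

# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def test_mean_diff_hand_cases():
    assert rs.stat_mean_diff([2, 2, 2, 1, 1, 1], list("LLLSSS")) == 1.0
    assert rs.stat_mean_diff([5, 7, 7, 5], list("ABAB")) == 0.0


def test_mean_diff_respects_group_order_and_missing():
    v = [1.0, np.nan, 3.0, 5.0]
    g = ["stream", "stream", "lake", "lake"]
    assert rs.stat_mean_diff(v, g, group_order=("lake", "stream")) == 3.0


def test_mean_diff_empty_group_raises():
    with pytest.raises(InsufficientDataError):
        rs.stat_mean_diff([np.nan, 1.0], ["A", "B"], group_order=("A", "B"))


def test_mean_diff_matches_brute_force(rng):
    v = rng.normal(size=30)
    g = np.array(["L"] * 14 + ["S"] * 16)
    expect = v[g == "L"].mean() - v[g == "S"].mean()
    assert rs.stat_mean_diff(v, g, group_order=("L", "S")) == pytest.approx(expect)


def test_var_of_group_means_hand_case():
    # lake site means (1, 3): var 2; stream site means (2, 2): var 0
    got = rs.stat_var_of_group_means(
        [1, 3, 2, 2], ["lake", "lake", "stream", "stream"],
        group_order=("lake", "stream"),
    )
    assert got == 2.0
    assert rs.stat_var_of_group_means([1, 3, 5, 7], list("ABAB")) == 0.0


def test_var_of_group_means_needs_two_populations_per_level():
    with pytest.raises(InsufficientDataError):
        rs.stat_var_of_group_means([1, 2, 3], ["lake", "lake", "stream"])


def test_chi_square_hand_and_scipy_oracle(rng):
    t0 = rs.ContingencyTable(["a", "b"], ["x", "y"], np.array([[5, 5], [10, 10]]))
    assert rs.stat_chi_square(t0) == 0.0
    t1 = rs.ContingencyTable(["a", "b"], ["x", "y"], np.array([[10, 0], [0, 10]]))
    assert rs.stat_chi_square(t1) == 20.0  # E = 5 in every cell
    for _ in range(10):
        counts = rng.integers(1, 30, size=(3, 4))
        t = rs.ContingencyTable(list("abc"), list("wxyz"), counts)
        ref = scipy.stats.chi2_contingency(counts, correction=False).statistic
        assert rs.stat_chi_square(t) == pytest.approx(ref, rel=1e-12)


def test_chi_square_degenerate_table_is_zero_with_warning():
    t = rs.ContingencyTable(["a"], ["x", "y"], np.array([[3, 4]]))
    with pytest.warns(UserWarning, match="degenerate"):
        assert rs.stat_chi_square(t) == 0.0


def test_anova_F_identical_means_is_zero():
    assert rs.stat_anova_F([1, 2, 3, 1, 2, 3], list("AAABBB")) == 0.0


def test_anova_F_two_groups_equals_t_squared(rng):
    a, b = rng.normal(size=12), rng.normal(1.0, 1.0, size=9)
    f = rs.stat_anova_F(np.r_[a, b], ["A"] * 12 + ["B"] * 9)
    t = scipy.stats.ttest_ind(a, b, equal_var=True).statistic
    assert f == pytest.approx(t**2, rel=1e-10)


def test_anova_F_matches_scipy_oracle(rng):
    v = rng.normal(size=40)
    g = rng.choice(list("ABCD"), size=40)
    ref = scipy.stats.f_oneway(*(v[g == lev] for lev in "ABCD")).statistic
    assert rs.stat_anova_F(v, g) == pytest.approx(ref, rel=1e-10)


def test_contingency_from_labels_counts():
    t = rs.contingency_from_labels(
        ["full", "low", "full", None], ["lake", "lake", "stream", "stream"]
    )
    assert t.rows == ["lake", "stream"] and t.cols == ["full", "low"]
    assert t.counts.tolist() == [[1, 1], [1, 0]]


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------


def test_floor_p_with_maximally_separated_groups():
    """Cleanly separated 20v20 groups reach the attainable floor 1/(B+1)."""
    values = [1.0] * 20 + [0.0] * 20
    labels = ["lake"] * 20 + ["stream"] * 20
    res = rs.perm_test(values, labels, "mean_diff", B=9999, seed=11,
                       group_order=("lake", "stream"))
    assert res.p_value == pytest.approx(1 / 10000)
    assert res.n_extreme == 0


def test_monte_carlo_agrees_with_exhaustive_3v3(rng):
    values = rng.normal(size=6)
    labels = ["L"] * 3 + ["S"] * 3
    frac = exhaustive_extreme_fraction(
        values, labels,
        lambda v, g: rs.stat_mean_diff(v, g, group_order=("L", "S")),
        two_sided=True,
    )
    B = 4999
    res = rs.perm_test(values, labels, "mean_diff", B=B, seed=5,
                       group_order=("L", "S"))
    expect = (B * frac + 1) / (B + 1)
    tol = 4 * np.sqrt(frac * (1 - frac) / B) + 2 / B
    assert abs(res.p_value - expect) <= tol


def test_monte_carlo_agrees_with_exhaustive_4v4_variance(rng):
    pop_means = rng.normal(size=8)
    habitats = ["L"] * 4 + ["S"] * 4  # 70 distinct assignments
    frac = exhaustive_extreme_fraction(
        pop_means, habitats,
        lambda v, g: rs.stat_var_of_group_means(v, g, group_order=("L", "S")),
        two_sided=True,
    )
    B = 4999
    res = rs.perm_test(pop_means, habitats, "var_of_group_means", B=B, seed=6,
                       group_order=("L", "S"))
    expect = (B * frac + 1) / (B + 1)
    tol = 4 * np.sqrt(frac * (1 - frac) / B) + 2 / B
    assert abs(res.p_value - expect) <= tol


def test_p_value_invariant_to_group_label_swap(rng):
    values = rng.normal(size=20)
    labels = ["lake"] * 10 + ["stream"] * 10
    p1 = rs.perm_test(values, labels, "mean_diff", B=999, seed=3,
                      group_order=("lake", "stream")).p_value
    p2 = rs.perm_test(values, labels, "mean_diff", B=999, seed=3,
                      group_order=("stream", "lake")).p_value
    assert p1 == p2


def test_same_seed_reproduces_result(rng):
    values = rng.normal(size=16)
    labels = ["L"] * 8 + ["S"] * 8
    r1 = rs.perm_test(values, labels, "mean_diff", B=500, seed=42)
    r2 = rs.perm_test(values, labels, "mean_diff", B=500, seed=42)
    assert r1 == r2


def test_constant_response_gives_p_one_with_warning():
    with pytest.warns(UserWarning, match="constant"):
        res = rs.perm_test([2.0] * 10, ["L"] * 5 + ["S"] * 5, "mean_diff", B=99)
    assert res.p_value == 1.0


def test_invalid_B_rejected():
    with pytest.raises(ValueError):
        rs.perm_test([1, 2], ["a", "b"], "mean_diff", B=0)


def test_chi_square_permutation_on_plate_morphs(rng):
    morphs = ["full"] * 18 + ["low"] * 2 + ["full"] * 5 + ["low"] * 15
    habitat = ["lake"] * 20 + ["stream"] * 20
    res = rs.perm_test(morphs, habitat, "chi_square", B=999, seed=9)
    assert res.sidedness == "one_sided_ge"
    assert res.observed > 0
    assert res.p_value <= 0.01  # strong association
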