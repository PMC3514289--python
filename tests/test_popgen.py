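"""Weir-Cockerham theta against a hand-coded formula oracle, permutation
P-values against exhaustive enumeration, and maximum-differentiation
recoding properties."""

import itertools

import numpy as np
import pytest

from lakestream import popgen
from lakestream import synthetic_data as synth
from lakestream.errors import UndefinedThetaError
from lakestream.io_formats import GenotypeMatrix

from oracles import wc_theta_one_locus


def matrix_from_genotypes(genosA, genosB, locus="L1"):
    """Build a 2-pop, 1-locus GenotypeMatrix from (a1, a2) tuple lists."""
    calls = np.array([[g] for g in genosA + genosB], dtype=np.int64)
    n = len(genosA) + len(genosB)
    return GenotypeMatrix(
        [f"i{k}" for k in range(n)],
        ["A"] * len(genosA) + ["B"] * len(genosB),
        [locus],
        calls.reshape(n, 1, 2),
    )


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def test_allele_frequencies_hand_count():
    g = matrix_from_genotypes([(1, 1), (1, 2)], [(2, 2)])
    freqs, n, h = popgen.allele_frequencies(g, "A", "L1")
    assert n == 2
    assert freqs == {1: 0.75, 2: 0.25}
    assert h == {1: 0.5, 2: 0.5}


def test_allele_frequencies_monomorphic_population():
    g = matrix_from_genotypes([(3, 3), (3, 3)], [(1, 2)])
    freqs, n, h = popgen.allele_frequencies(g, "A", "L1")
    assert freqs == {3: 1.0} and h == {3: 0.0}


def test_allele_frequencies_recover_simulated_frequencies(rng):
    truth = np.array([0.5, 0.3, 0.2])
    n = 10_000
    draws = rng.choice(3, size=(n, 2), p=truth) + 1
    g = matrix_from_genotypes([tuple(d) for d in draws], [(1, 1)])
    freqs, _, _ = popgen.allele_frequencies(g, "A", "L1")
    for k, p in enumerate(truth, start=1):
        se = np.sqrt(p * (1 - p) / (2 * n))
        assert abs(freqs[k] - p) < 3 * se


# ---------------------------------------------------------------------------
# theta vs the independent hand-formula oracle
# ---------------------------------------------------------------------------


def test_theta_fixed_difference_is_one():
    g = matrix_from_genotypes([(1, 1)] * 4, [(2, 2)] * 3)
    assert popgen.wc_theta_pair(g, "A", "B").theta == pytest.approx(1.0, abs=1e-12)


def test_theta_duplicated_population_is_at_most_zero():
    genos = [(1, 1), (1, 2), (2, 2), (1, 2), (2, 3)]
    g = matrix_from_genotypes(genos, genos)
    assert popgen.wc_theta_pair(g, "A", "B").theta <= 1e-12


def test_theta_toy_matches_oracle_to_1e12():
    genosA = [(1, 1), (1, 1), (1, 2)]
    genosB = [(2, 2), (2, 2), (1, 2)]
    g = matrix_from_genotypes(genosA, genosB)
    expect = wc_theta_one_locus(genosA, genosB)
    assert popgen.wc_theta_pair(g, "A", "B").theta == pytest.approx(expect, abs=1e-12)


def test_theta_random_instances_match_oracle(rng):
    for _ in range(25):
        nA, nB = rng.integers(2, 12, size=2)
        k = rng.integers(2, 5)
        genosA = [tuple(rng.integers(1, k + 1, size=2)) for _ in range(nA)]
        genosB = [tuple(rng.integers(1, k + 1, size=2)) for _ in range(nB)]
        expect = wc_theta_one_locus(genosA, genosB)
        g = matrix_from_genotypes(genosA, genosB)
        if expect is None:
            with pytest.raises(UndefinedThetaError):
                popgen.wc_theta_pair(g, "A", "B")
        else:
            got = popgen.wc_theta_pair(g, "A", "B").theta
            assert got == pytest.approx(expect, abs=1e-12)


def test_theta_multilocus_is_ratio_of_sums(rng):
    """Two loci combine by summing components, not averaging ratios."""
    genosA1 = [(1, 1), (1, 2), (2, 2), (1, 1)]
    genosB1 = [(2, 2), (2, 2), (1, 2), (2, 2)]
    genosA2 = [(1, 2), (1, 1), (1, 2), (2, 2)]
    genosB2 = [(1, 2), (2, 2), (1, 1), (1, 2)]
    calls = np.array(
        [[a, b] for a, b in zip(genosA1 + genosB1, genosA2 + genosB2)],
        dtype=np.int64,
    )
    g = GenotypeMatrix(
        [f"i{k}" for k in range(8)], ["A"] * 4 + ["B"] * 4, ["L1", "L2"], calls
    )
    res = popgen.wc_theta_pair(g, "A", "B")
    comps = res.components_by_locus
    num = sum(c.a for c in comps)
    den = sum(c.a + c.b + c.c for c in comps)
    assert res.theta == pytest.approx(num / den, abs=1e-14)
    # and differs from the average of per-locus ratios for this instance
    t1 = wc_theta_one_locus(genosA1, genosB1)
    t2 = wc_theta_one_locus(genosA2, genosB2)
    assert res.theta != pytest.approx((t1 + t2) / 2, abs=1e-6)


def test_theta_all_monomorphic_is_undefined():
    g = matrix_from_genotypes([(1, 1)] * 3, [(1, 1)] * 3)
    with pytest.raises(UndefinedThetaError):
        popgen.wc_theta_pair(g, "A", "B")


def test_theta_tolerates_random_missing_calls(small_cfg):
    g = synth.gen_microsats(small_cfg.with_(n_pops=2, n_ind=30, seed=4))
    base = popgen.wc_theta_pair(g, "POP_1", "POP_2").theta
    rng = np.random.default_rng(0)
    calls = g.calls.copy()
    miss = rng.random(calls.shape[:2]) < 0.05
    calls[miss] = 0
    g2 = GenotypeMatrix(g.individuals, g.populations, g.loci, calls)
    degraded = popgen.wc_theta_pair(g2, "POP_1", "POP_2").theta
    assert np.isfinite(degraded)
    assert abs(degraded - base) < 0.1


# ---------------------------------------------------------------------------
# permutation P
# ---------------------------------------------------------------------------


def test_fst_perm_floor_for_fixed_difference():
    g = matrix_from_genotypes([(1, 1)] * 10, [(2, 2)] * 10)
    p = popgen.fst_perm_p(g, "A", "B", B=999, seed=1)
    assert p == pytest.approx(0.001)


def test_fst_perm_matches_exhaustive_2v2():
    genosA = [(1, 1), (1, 2)]
    genosB = [(2, 2), (2, 2)]
    g = matrix_from_genotypes(genosA, genosB)
    observed = popgen.wc_theta_pair(g, "A", "B").theta
    combined = genosA + genosB
    n_ext = 0
    splits = list(itertools.combinations(range(4), 2))
    for keep in splits:  # all 6 assignments of 2 individuals to pop A
        gA = [combined[i] for i in keep]
        gB = [combined[i] for i in range(4) if i not in keep]
        theta = wc_theta_one_locus(gA, gB)
        if theta is not None and theta >= observed:
            n_ext += 1
    exact_frac = n_ext / len(splits)
    B = 3000
    p = popgen.fst_perm_p(g, "A", "B", B=B, seed=2)
    expect = (B * exact_frac + 1) / (B + 1)
    tol = 4 * np.sqrt(exact_frac * (1 - exact_frac) / B) + 2 / B
    assert abs(p - expect) <= tol


def test_fst_perm_null_is_roughly_uniform(small_cfg):
    """One population split in two at random: p should not pile up low."""
    rng = np.random.default_rng(3)
    pvals = []
    for rep in range(60):
        draws = rng.choice(4, size=(30, 2), p=[0.4, 0.3, 0.2, 0.1]) + 1
        genos = [tuple(d) for d in draws]
        g = matrix_from_genotypes(genos[:15], genos[15:])
        pvals.append(popgen.fst_perm_p(g, "A", "B", B=99, seed=int(rng.integers(2**31))))
    assert 0.25 < np.mean(pvals)  # mean of uniform is 0.5
    assert np.mean(np.array(pvals) <= 0.05) < 0.2


# ---------------------------------------------------------------------------
# maximum-differentiation recoding / standardized F_ST
# ---------------------------------------------------------------------------


def _pop_allele_sets(g, pop):
    idx = g.pop_indices(pop)
    return [
        set(np.unique(g.calls[idx, li, :])) - {0} for li in range(len(g.loci))
    ]


def test_recode_shares_no_alleles_and_preserves_heterozygosity(small_cfg):
    g = synth.gen_microsats(small_cfg.with_(n_pops=2, n_ind=20, seed=9))
    rec = popgen.recode_max(g, "POP_1", "POP_2")
    for sa, sb in zip(_pop_allele_sets(rec, "POP_1"), _pop_allele_sets(rec, "POP_2")):
        assert not (sa & sb)
    # observed heterozygosity per population/locus is untouched
    for pop in ("POP_1", "POP_2"):
        i0, i1 = g.pop_indices(pop), rec.pop_indices(pop)
        h0 = (g.calls[i0, :, 0] != g.calls[i0, :, 1]).mean(axis=0)
        h1 = (rec.calls[i1, :, 0] != rec.calls[i1, :, 1]).mean(axis=0)
        assert np.allclose(h0, h1)


def test_recode_keeps_missing_calls_missing(small_cfg):
    g = synth.gen_microsats(small_cfg.with_(n_pops=2, n_ind=20, missing_rate=0.1,
                                            seed=5))
    rec = popgen.recode_max(g, "POP_1", "POP_2")
    assert np.array_equal(rec.calls == 0, g.calls == 0)


def test_standardized_fst_fixed_difference_is_all_one():
    g = matrix_from_genotypes([(1, 1)] * 5, [(2, 2)] * 5)
    res = popgen.standardized_fst(g, "A", "B")
    assert res.theta == pytest.approx(1.0, abs=1e-12)
    assert res.theta_max == pytest.approx(1.0, abs=1e-12)
    assert res.theta_std == pytest.approx(1.0, abs=1e-12)


def test_standardized_fst_heterozygous_private_alleles():
    """Fully heterozygous populations sharing no alleles: theta < 1 but
    the standardized value is exactly 1 (recoding changes nothing)."""
    g = matrix_from_genotypes([(1, 2)] * 6, [(3, 4)] * 6)
    res = popgen.standardized_fst(g, "A", "B")
    assert res.theta < 1.0
    assert res.theta_std == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------


def test_fst_matrix_structure_and_identical_pops(small_cfg):
    g = synth.gen_microsats(small_cfg.with_(n_pops=3, n_ind=15, seed=2))
    # make POP_3 an exact copy of POP_1
    i1, i3 = g.pop_indices("POP_1"), g.pop_indices("POP_3")
    calls = g.calls.copy()
    calls[i3] = calls[i1]
    g = GenotypeMatrix(g.individuals, g.populations, g.loci, calls)
    results = popgen.fst_matrix(g, B=None, standardized=False)
    assert set(results) == {("POP_1", "POP_2"), ("POP_1", "POP_3"),
                            ("POP_2", "POP_3")}
    assert results[("POP_1", "POP_3")].theta <= 1e-12
    table = popgen.format_fst_table(results)
    assert list(table.index) == ["POP_1", "POP_2", "POP_3"]
    assert (table.values.diagonal() == "").all()


def test_fst_matrix_propagates_undefined_pairs():
    calls = np.array([[[1, 1]]] * 4 + [[[2, 2]]] * 2, dtype=np.int64)
    g = GenotypeMatrix(
        [f"i{k}" for k in range(6)],
        ["A", "A", "B", "B", "C", "C"],
        ["L1"],
        calls,
    )
    results = popgen.fst_matrix(g, B=None, standardized=False)
    assert np.isnan(results[("A", "B")].theta)  # both monomorphic for allele 1
    assert results[("A", "C")].theta == pytest.approx(1.0, abs=1e-12)
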