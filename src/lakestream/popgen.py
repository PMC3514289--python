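"""Multi-allelic Weir-Cockerham F_ST, permutation P-values, and Hedrick's
standardized F'_ST via maximum-differentiation allele recoding.

The estimator is Weir & Cockerham's theta for r = 2 populations: for
every locus and every allele, variance components are computed from the
per-population sample sizes n_i, allele frequencies p_i and observed
heterozygote proportions h_i,

    a  among populations,
    b  among individuals within populations,
    c  within individuals (heterozygosity),

and theta-hat is the ratio of sums sum(a) / sum(a + b + c) over all loci
and alleles (not an average of per-locus ratios). Loci monomorphic
across both populations contribute nothing; small negative theta values
are legitimate unbiased-estimator behaviour and are reported as
computed. Pairwise matrices are computed pair by pair on the two
populations only, never sliced from a global estimate.

P-values permute whole multilocus individuals between the two
populations (preserving sample sizes and within-individual linkage),
one-sided on theta, with p = (1 + #{theta* >= theta}) / (B + 1); the
floor with B = 999 is exactly 0.001.

F'_ST divides theta by the maximum theta attainable given the observed
within-population heterozygosities, obtained by recoding alleles so the
two populations share none while each keeps its own allele-frequency
spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lakestream.errors import (
    UndefinedStandardizationError,
    UndefinedThetaError,
    ValidationError,
)
from lakestream.io_formats import GenotypeMatrix


@dataclass
class VarianceComponents:
    locus: str
    allele: int
    a: float
    b: float
    c: float


@dataclass
class FstResult:
    pop_pair: tuple[str, str]
    theta: float
    theta_max: float | None = None
    theta_std: float | None = None
    p_value: float | None = None
    B: int = 0
    components_by_locus: list[VarianceComponents] = field(default_factory=list)


# ---------------------------------------------------------------------------
# allele bookkeeping
# ---------------------------------------------------------------------------


def allele_frequencies(
    g: GenotypeMatrix, pop: str, locus: str
) -> tuple[dict[int, float], int, dict[int, float]]:
    """Allele frequencies, typed-individual count, and per-allele observed
    heterozygote proportions for one population at one locus.

    Returns ``(freqs, n, h)`` where ``h[A]`` is the proportion of typed
    individuals carrying exactly one copy of allele A.
    """
    li = g.locus_index(locus)
    calls = g.calls[g.pop_indices(pop), li, :]
    typed = calls[calls[:, 0] > 0]
    n = typed.shape[0]
    if n == 0:
        raise UndefinedThetaError(f"no typed individuals in {pop!r} at {locus!r}")
    alleles = np.unique(typed)
    freqs, h = {}, {}
    for al in alleles:
        copies = (typed == al).sum()
        freqs[int(al)] = copies / (2 * n)
        h[int(al)] = float(((typed == al).sum(axis=1) == 1).mean())
    return freqs, n, h


def _locus_components(cA: np.ndarray, cB: np.ndarray) -> tuple | None:
    """WC84 per-allele components (a, b, c) for one locus, r = 2.

    ``cA``/``cB`` are (n, 2) call arrays; returns (alleles, a, b, c) as
    vectors, or None when the locus is skipped (untyped in a population,
    monomorphic across both, or too few typed individuals).
    """
    tA = cA[cA[:, 0] > 0]
    tB = cB[cB[:, 0] > 0]
    nA, nB = tA.shape[0], tB.shape[0]
    if nA == 0 or nB == 0:
        return None
    alleles = np.unique(np.concatenate([tA.ravel(), tB.ravel()]))
    if alleles.size < 2:
        return None  # monomorphic across both populations
    nbar = (nA + nB) / 2.0
    if nbar <= 1.0:
        return None
    nc = (nA + nB) - (nA * nA + nB * nB) / (nA + nB)  # r - 1 = 1

    eqA = tA[:, :, None] == alleles[None, None, :]  # (nA, 2, K)
    eqB = tB[:, :, None] == alleles[None, None, :]
    pA = eqA.sum(axis=(0, 1)) / (2 * nA)
    pB = eqB.sum(axis=(0, 1)) / (2 * nB)
    hA = (eqA.sum(axis=1) == 1).mean(axis=0)
    hB = (eqB.sum(axis=1) == 1).mean(axis=0)

    pbar = (nA * pA + nB * pB) / (nA + nB)
    # s^2 = sum_i n_i (p_i - pbar)^2 / ((r-1) nbar), r = 2
    s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / nbar
    hbar = (nA * hA + nB * hB) / (nA + nB)

    pq = pbar * (1.0 - pbar)
    a = (nbar / nc) * (s2 - (pq - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (pq - s2 / 2.0 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2.0
    return alleles, a, b, c


def _theta_from_calls(
    callsA: np.ndarray,
    callsB: np.ndarray,
    loci: list[str] | None = None,
    collect: bool = False,
) -> tuple[float, list[VarianceComponents]]:
    """Ratio-of-sums theta over all loci/alleles of two call arrays."""
    num = den = 0.0
    comps: list[VarianceComponents] = []
    for li in range(callsA.shape[1]):
        out = _locus_components(callsA[:, li, :], callsB[:, li, :])
        if out is None:
            continue
        alleles, a, b, c = out
        num += a.sum()
        den += (a + b + c).sum()
        if collect:
            name = loci[li] if loci else str(li)
            comps.extend(
                VarianceComponents(name, int(al), float(x), float(y), float(z))
                for al, x, y, z in zip(alleles, a, b, c)
            )
    if den == 0.0:
        raise UndefinedThetaError("all loci monomorphic across the pair")
    return num / den, comps


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def wc_theta_pair(g: GenotypeMatrix, popA: str, popB: str) -> FstResult:
    """Pairwise Weir-Cockerham theta-hat with per-locus/allele components."""
    iA, iB = g.pop_indices(popA), g.pop_indices(popB)
    theta, comps = _theta_from_calls(
        g.calls[iA], g.calls[iB], loci=g.loci, collect=True
    )
    return FstResult((popA, popB), theta, components_by_locus=comps)


def fst_perm_p(
    g: GenotypeMatrix, popA: str, popB: str, B: int = 999, seed: int = 0
) -> float:
    """One-sided permutation P for theta: individuals re-assigned between
    the two populations uniformly at random, sample sizes preserved."""
    if B < 1:
        raise ValueError("B must be >= 1")
    iA, iB = g.pop_indices(popA), g.pop_indices(popB)
    observed, _ = _theta_from_calls(g.calls[iA], g.calls[iB])
    combined = g.calls[np.concatenate([iA, iB])]
    nA = iA.size
    rng = np.random.default_rng(seed)
    n_extreme = 0
    for _ in range(B):
        perm = rng.permutation(combined.shape[0])
        theta_star, _ = _theta_from_calls(
            combined[perm[:nA]], combined[perm[nA:]]
        )
        if theta_star >= observed:
            n_extreme += 1
    return (n_extreme + 1) / (B + 1)


def recode_max(g: GenotypeMatrix, popA: str, popB: str) -> GenotypeMatrix:
    """Recode alleles so the two populations share none (maximum
    differentiation given observed heterozygosities).

    Within each population the relabelling is a bijection per locus, so
    each population's allele-frequency spectrum and heterozygosity are
    preserved exactly; missing calls stay missing. The returned matrix
    contains only the two populations.
    """
    sub = g.subset_populations([popA, popB])
    pops = np.asarray(sub.populations)
    maskA = pops == popA
    calls = sub.calls.copy()
    for li in range(calls.shape[1]):
        next_label = 1
        for mask in (maskA, ~maskA):
            col = calls[mask, li, :]
            observed = np.unique(col[col > 0])
            mapping = {int(al): next_label + k for k, al in enumerate(observed)}
            next_label += observed.size
            if mapping:
                recoded = col.copy()
                for old, new in mapping.items():
                    recoded[col == old] = new
                calls[mask, li, :] = recoded
    return GenotypeMatrix(sub.individuals, sub.populations, list(sub.loci), calls)


def standardized_fst(
    g: GenotypeMatrix,
    popA: str,
    popB: str,
    B: int | None = None,
    seed: int = 0,
) -> FstResult:
    """theta, theta_max (on maximum-differentiation recoded data), and
    F'_ST = theta / theta_max; optional permutation P when ``B`` is set."""
    res = wc_theta_pair(g, popA, popB)
    recoded = recode_max(g, popA, popB)
    res.theta_max = wc_theta_pair(recoded, popA, popB).theta
    if res.theta_max <= 0:
        raise UndefinedStandardizationError(
            f"theta_max = {res.theta_max:.3g} <= 0 for pair ({popA}, {popB})"
        )
    res.theta_std = res.theta / res.theta_max
    if B is not None:
        res.p_value = fst_perm_p(g, popA, popB, B=B, seed=seed)
        res.B = B
    return res


def fst_matrix(
    g: GenotypeMatrix,
    B: int | None = 999,
    seed: int = 0,
    standardized: bool = True,
) -> dict[tuple[str, str], FstResult]:
    """All C(k,2) pairwise results, each pair computed independently.

    Undefined theta or standardization for a pair yields NaN fields for
    that pair without aborting the rest of the matrix.
    """
    pops = g.population_labels
    if len(pops) < 2:
        raise ValidationError("fst_matrix needs >= 2 populations")
    results: dict[tuple[str, str], FstResult] = {}
    for i, pA in enumerate(pops):
        for pB in pops[i + 1 :]:
            try:
                if standardized:
                    res = standardized_fst(g, pA, pB)
                else:
                    res = wc_theta_pair(g, pA, pB)
                if B is not None:
                    res.p_value = fst_perm_p(g, pA, pB, B=B, seed=seed)
                    res.B = B
            except UndefinedThetaError:
                res = FstResult((pA, pB), float("nan"))
            except UndefinedStandardizationError:
                res = wc_theta_pair(g, pA, pB)
                res.theta_max = res.theta_std = float("nan")
                if B is not None:
                    res.p_value = fst_perm_p(g, pA, pB, B=B, seed=seed)
                    res.B = B
            results[(pA, pB)] = res
    return results


def format_fst_table(
    results: dict[tuple[str, str], FstResult], pops: list[str] | None = None
):
    """Display-style square table: upper semimatrix "theta (P)" to two
    decimals, lower semimatrix standardized F'_ST, empty diagonal.

    Returns a pandas DataFrame of strings; pair full-precision export is
    :func:`fst_long_table`.
    """
    import pandas as pd

    if pops is None:
        seen: dict[str, None] = {}
        for a, b in results:
            seen.setdefault(a, None)
            seen.setdefault(b, None)
        pops = list(seen)
    table = pd.DataFrame("", index=pops, columns=pops, dtype=object)
    for (a, b), r in results.items():
        cell = f"{r.theta:.2f}"
        if r.p_value is not None:
            cell += f" ({r.p_value:.3f})"
        table.loc[a, b] = cell
        table.loc[b, a] = "" if r.theta_std is None else f"{r.theta_std:.2f}"
    return table


def fst_long_table(results: dict[tuple[str, str], FstResult]):
    """Full-precision long-format companion table (one row per pair)."""
    import pandas as pd

    rows = []
    for (a, b), r in results.items():
        rows.append(
            {
                "pop_a": a,
                "pop_b": b,
                "theta": r.theta,
                "theta_max": r.theta_max,
                "theta_std": r.theta_std,
                "p_value": r.p_value,
                "B": r.B,
            }
        )
    return pd.DataFrame(rows)
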