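"""Collapse aligned mtDNA D-loop sequences into haplotypes and build a
distance-based haplotype network.

Identical sequences merge into haplotypes with per-population counts;
segregating sites (SNPs) are alignment columns showing at least two
bases among {A,C,G,T}. The genealogy is visualized as a minimum-
spanning tree over pairwise Hamming distances — for a handful of SNPs
this recovers the same topology class as a likelihood genealogy while
remaining exactly testable. ``N`` and gap characters are treated as
missing and excluded from both haplotype identity and distance (policy
configurable). All alignment coordinates in outputs are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from lakestream.errors import ValidationError
from lakestream.io_formats import Alignment

_BASES = frozenset("ACGT")


@dataclass
class HaplotypeTable:
    """Distinct sequence variants with per-population counts.

    ``counts`` is a DataFrame indexed H1..Hk (same order as
    ``haplotypes``) with one column per population; ``snp_positions``
    are 1-based alignment columns.
    """

    haplotypes: list[str]
    counts: pd.DataFrame
    snp_positions: list[int]

    @property
    def total_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass
class HaploNetwork:
    """Spanning tree over haplotypes; edges weighted by Hamming distance."""

    nodes: list[str]  # haplotype ids, H1..Hk
    node_counts: dict[str, int]
    edges: list[tuple[str, str, int]]


def hamming(h1: str, h2: str, ignore: str = "missing") -> int:
    """Number of differing columns; missing (N/-) columns are skipped
    under the default policy, compared literally under ``ignore="none"``."""
    if len(h1) != len(h2):
        raise ValidationError(
            f"sequence lengths differ ({len(h1)} vs {len(h2)})"
        )
    if ignore == "none":
        return sum(a != b for a, b in zip(h1, h2))
    return sum(
        a != b for a, b in zip(h1.upper(), h2.upper())
        if a in _BASES and b in _BASES
    )


def snp_columns(sequences: list[str]) -> list[int]:
    """1-based columns with >= 2 observed bases among {A,C,G,T}."""
    if not sequences:
        return []
    arr = np.array([list(s.upper()) for s in sequences])
    positions = []
    for j in range(arr.shape[1]):
        observed = {b for b in arr[:, j] if b in _BASES}
        if len(observed) >= 2:
            positions.append(j + 1)
    return positions


def collapse_haplotypes(a: Alignment, ignore: str = "missing") -> HaplotypeTable:
    """Merge identical sequences into haplotypes, tabulated per population.

    Under ``ignore="missing"`` a sequence joins the first existing
    haplotype it matches at every mutually non-missing column (first-
    match policy, input order); under ``ignore="none"`` identity is
    exact string equality.
    """
    if not a.sequences:
        raise ValidationError("empty alignment")
    reps: list[str] = []
    assignment: dict[str, int] = {}
    for sid, seq in a.sequences.items():
        seq = seq.upper()
        hit = None
        for k, rep in enumerate(reps):
            if ignore == "none":
                match = seq == rep
            else:
                match = hamming(seq, rep, ignore="missing") == 0
            if match:
                hit = k
                break
        if hit is None:
            reps.append(seq)
            hit = len(reps) - 1
        assignment[sid] = hit

    pops = list(dict.fromkeys(a.population_of[sid] for sid in a.sequences))
    hap_ids = [f"H{k + 1}" for k in range(len(reps))]
    counts = pd.DataFrame(0, index=hap_ids, columns=pops, dtype=np.int64)
    for sid, k in assignment.items():
        counts.loc[hap_ids[k], a.population_of[sid]] += 1
    return HaplotypeTable(reps, counts, snp_columns(list(a.sequences.values())))


def mst_network(t: HaplotypeTable, ignore: str = "missing") -> HaploNetwork:
    """Minimum-spanning tree over pairwise Hamming distances.

    Ties are broken deterministically by lexicographic haplotype
    sequence order (Kruskal over edges pre-sorted that way).
    """
    k = len(t.haplotypes)
    hap_ids = list(t.counts.index)
    node_counts = {h: int(c) for h, c in t.total_counts.items()}
    if k == 1:
        return HaploNetwork(hap_ids, node_counts, [])
    lex = sorted(range(k), key=lambda i: t.haplotypes[i])
    graph = nx.Graph()
    graph.add_nodes_from(hap_ids)
    for ii, i in enumerate(lex):
        for j in lex[ii + 1 :]:
            d = hamming(t.haplotypes[i], t.haplotypes[j], ignore=ignore)
            graph.add_edge(hap_ids[i], hap_ids[j], weight=d)
    mst = nx.minimum_spanning_tree(graph, algorithm="kruskal")
    edges = sorted(
        (u, v, int(d["weight"])) if u < v else (v, u, int(d["weight"]))
        for u, v, d in mst.edges(data=True)
    )
    return HaploNetwork(hap_ids, node_counts, edges)


def write_haplotype_tables(
    t: HaplotypeTable, net: HaploNetwork, counts_path: str | Path, edges_path: str | Path
) -> None:
    """Emit the per-population count TSV and the network edge-list TSV."""
    out = t.counts.copy()
    out.insert(0, "haplotype_id", out.index)
    out.insert(1, "sequence", t.haplotypes)
    out.to_csv(Path(counts_path), sep="\t", index=False)
    pd.DataFrame(net.edges, columns=["hap_i", "hap_j", "distance"]).to_csv(
        Path(edges_path), sep="\t", index=False
    )
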