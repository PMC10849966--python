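"""Pairwise differences between consensus genomes and matriline grouping.

Individuals sharing an mtDNA genome with zero pairwise differences over
the jointly covered positions are the same individual or maternal
relatives.  Because consensus genomes contain N at uncalled sites,
zero-difference is not transitive; groups are therefore maximal cliques of
the zero-difference graph, with a minimum-overlap guard so that pairs
sharing too few called positions are not grouped on vacuous evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._seq import N, encode


def _as_codes(genome) -> np.ndarray:
    if isinstance(genome, str):
        return encode(genome)
    if hasattr(genome, "sequence"):
        return encode(genome.sequence)
    return np.asarray(genome, dtype=np.uint8)


def pairwise_differences(g1, g2) -> tuple[int, int]:
    """(n_diff, n_compared) over positions non-N in both genomes."""
    a, b = _as_codes(g1), _as_codes(g2)
    if len(a) != len(b):
        raise ValueError(f"genome lengths differ: {len(a)} vs {len(b)}")
    valid = (a != N) & (b != N)
    n_compared = int(valid.sum())
    n_diff = int(np.sum(a[valid] != b[valid]))
    return n_diff, n_compared


@dataclass
class DifferenceMatrix:
    ids: list[str]
    n_diff: np.ndarray
    n_compared: np.ndarray

    def to_dataframes(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        return (
            pd.DataFrame(self.n_diff, index=self.ids, columns=self.ids),
            pd.DataFrame(self.n_compared, index=self.ids, columns=self.ids),
        )

    def write(self, diff_path, compared_path) -> None:
        d, c = self.to_dataframes()
        d.to_csv(diff_path, sep="\t")
        c.to_csv(compared_path, sep="\t")


def difference_matrix(genomes: Mapping[str, object]) -> DifferenceMatrix:
    """All-pairs difference counts for >= 2 equal-length genomes."""
    ids = list(genomes)
    if len(ids) < 2:
        raise ValueError("need at least 2 genomes")
    codes = {i: _as_codes(genomes[i]) for i in ids}
    k = len(ids)
    n_diff = np.zeros((k, k), dtype=np.int64)
    n_comp = np.zeros((k, k), dtype=np.int64)
    for x in range(k):
        n_comp[x, x] = int(np.sum(codes[ids[x]] != N))
    for x, y in combinations(range(k), 2):
        d, c = pairwise_differences(codes[ids[x]], codes[ids[y]])
        n_diff[x, y] = n_diff[y, x] = d
        n_comp[x, y] = n_comp[y, x] = c
    return DifferenceMatrix(ids=ids, n_diff=n_diff, n_compared=n_comp)


def zero_difference_groups(
    matrix: DifferenceMatrix, min_overlap: int = 1000
) -> list[list[str]]:
    """Maximal cliques of the zero-difference graph.

    An edge joins two genomes with n_diff == 0 and n_compared >=
    ``min_overlap``.  Every genome appears in at least one group (isolated
    genomes form singletons).  Groups are sorted by decreasing size, then
    lexicographically; ids within a group are sorted.
    """
    g = nx.Graph()
    g.add_nodes_from(matrix.ids)
    k = len(matrix.ids)
    for x, y in combinations(range(k), 2):
        if matrix.n_diff[x, y] == 0 and matrix.n_compared[x, y] >= min_overlap:
            g.add_edge(matrix.ids[x], matrix.ids[y])
    groups = [sorted(c) for c in nx.find_cliques(g)]
    groups.sort(key=lambda grp: (-len(grp), grp))
    return groups


def low_overlap_zero_pairs(
    matrix: DifferenceMatrix, min_overlap: int = 1000
) -> list[tuple[str, str, int]]:
    """Zero-difference pairs rejected for insufficient joint coverage."""
    out = []
    for x, y in combinations(range(len(matrix.ids)), 2):
        if matrix.n_diff[x, y] == 0 and matrix.n_compared[x, y] < min_overlap:
            out.append((matrix.ids[x], matrix.ids[y], int(matrix.n_compared[x, y])))
    return out
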