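"""Vectorised neighbour joining.

Saitou-Nei neighbour joining with the standard Q-criterion, operating on a
numpy distance matrix and emitting a dendropy tree (unrooted, trifurcating
at the seed node).  Ties in the Q matrix break deterministically in
row-major (taxon-order) fashion.  Used instead of a pure-Python NJ because
the column bootstrap in tip dating re-runs tree building hundreds of times
per estimate; equivalence with dendropy's own NJ is asserted in the test
suite.
"""

from __future__ import annotations

from typing import Sequence

import dendropy
import numpy as np


def neighbor_joining(
    ids: Sequence[str],
    distances: np.ndarray,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 taxa for neighbour joining")
    D = np.asarray(distances, dtype=float)
    if D.shape != (n, n):
        raise ValueError(f"distance matrix shape {D.shape} does not match {n} taxa")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")

    taxa = taxon_namespace or dendropy.TaxonNamespace(list(ids))
    nodes: list[dendropy.Node] = [
        dendropy.Node(taxon=taxa.get_taxon(label)) for label in ids
    ]
    D = D.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[active[i]])
        parent.add_child(nodes[active[j]])
        nodes[active[i]].edge.length = max(li, 0.0)
        nodes[active[j]].edge.length = max(lj, 0.0)

        # distances from the new node to every other active node
        k_idx = [a for t, a in enumerate(active) if t not in (i, j)]
        dk = 0.5 * (D[active[i], k_idx] + D[active[j], k_idx] - dij)
        new_index = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        D[new_index, k_idx] = dk
        D[k_idx, new_index] = dk
        nodes.append(parent)
        active = k_idx + [new_index]

    # resolve the final three lineages around a central node
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    center = dendropy.Node()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(length, 0.0)

    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = center
    tree.is_rooted = False
    return tree
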