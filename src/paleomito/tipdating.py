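"""Least-squares strict-clock tip dating of mtDNA genomes.

Estimates the age of an undated query genome from radiocarbon-dated
calibration genomes: Jukes-Cantor distances -> neighbour-joining tree ->
rooting on an outgroup -> ordinary least squares of root-to-tip distance
against tip date (years before present) over the calibration tips ->
inversion of the regression at the query's root-to-tip distance.  Under a
strict clock, root-to-tip distance y and tip age t obey
y = intercept - rate * t (older tips sit closer to the root), so
t_query = (intercept - y_query) / rate.

Uncertainty comes from a nonparametric bootstrap over alignment columns,
re-running the entire chain per replicate, with percentile intervals.
This is a transparent approximation to full Bayesian tip calibration: no
coalescent tree prior, no posterior — a point estimate with bootstrap
intervals, suitable where the calibration set brackets the query's age.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from ._nj import neighbor_joining
from ._seq import N, encode

logger = logging.getLogger(__name__)


class ClockError(RuntimeError):
    """Raised when the clock fit cannot support date inversion."""


def jc_distance(a: str, b: str) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - (4/3) p); sites with N in
    either sequence are excluded from the mismatch fraction p."""
    ca, cb = encode(a), encode(b)
    if len(ca) != len(cb):
        raise ValueError("sequences must have equal length")
    valid = (ca != N) & (cb != N)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no jointly resolved sites; distance undefined")
    p = float(np.sum(ca[valid] != cb[valid])) / n
    return _jc_correct(p)


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        raise ValueError(f"mismatch fraction {p:.3f} >= 0.75; JC distance undefined")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def jc_distance_matrix(sequences: Mapping[str, str]) -> pd.DataFrame:
    """All-pairs JC distance matrix as a labelled DataFrame."""
    ids = list(sequences)
    M = np.stack([encode(sequences[i]) for i in ids])
    return _jc_matrix_from_codes(ids, M, None)


def _jc_matrix_from_codes(
    ids: Sequence[str], M: np.ndarray, cols: np.ndarray | None
) -> pd.DataFrame:
    sub = M if cols is None else M[:, cols]
    k = len(ids)
    D = np.zeros((k, k))
    for x, y in combinations(range(k), 2):
        a, b = sub[x], sub[y]
        valid = (a != N) & (b != N)
        n = int(valid.sum())
        if n == 0:
            raise ValueError(f"no jointly resolved sites between {ids[x]} and {ids[y]}")
        D[x, y] = D[y, x] = _jc_correct(float(np.sum(a[valid] != b[valid])) / n)
    return pd.DataFrame(D, index=list(ids), columns=list(ids))


def build_nj_tree(distance_matrix: pd.DataFrame) -> dendropy.Tree:
    """Neighbour-joining tree from a labelled distance matrix.

    Negative branch lengths (an NJ artefact) are clamped to zero; ties
    break deterministically by taxon order.
    """
    if len(distance_matrix) < 3:
        raise ValueError("need at least 3 taxa for neighbour joining")
    return neighbor_joining(
        list(distance_matrix.index), distance_matrix.to_numpy()
    )


def _leaf_label_sets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    sets: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset([node.taxon.label])
        else:
            acc: set[str] = set()
            for ch in node.child_nodes():
                acc |= sets[ch]
            sets[node] = frozenset(acc)
    return sets


def root_on_outgroup(
    tree: dendropy.Tree, outgroup_ids: Sequence[str], in_place: bool = False
) -> dendropy.Tree:
    """Root at the midpoint of the branch separating the outgroup tips from
    the rest; raises if the outgroup is not separable (non-monophyletic)."""
    if not in_place:
        tree = tree.clone(depth=1)
    all_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    og = frozenset(outgroup_ids)
    missing = og - all_labels
    if missing:
        raise ValueError(f"outgroup tip(s) not in tree: {sorted(missing)}")
    if og == all_labels:
        raise ValueError("outgroup cannot contain every tip")
    ingroup = frozenset(all_labels - og)
    sets = _leaf_label_sets(tree)
    target = None
    for node, labels in sets.items():
        if node.parent_node is None:
            continue
        if labels == og or labels == ingroup:
            target = node
            break
    if target is None:
        raise ValueError(
            f"outgroup {sorted(og)} is not monophyletic; cannot place root"
        )
    edge = target.edge
    half = (edge.length or 0.0) / 2.0
    tree.reroot_at_edge(edge, length1=half, length2=half, update_bipartitions=False)
    tree.is_rooted = True
    return tree


def root_to_tip_distances(tree: dendropy.Tree) -> dict[str, float]:
    out: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        out[leaf.taxon.label] = d
    return out


@dataclass
class ClockFit:
    rate: float  # substitutions / site / year
    intercept: float
    r_squared: float
    residuals: dict[str, float]
    n_calibration: int


@dataclass
class DateEstimate:
    point: float  # years before present
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    fit: ClockFit
    n_boot_failed: int = 0

    def to_dict(self) -> dict:
        return {
            "point_years_bp": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
            "n_boot_failed": self.n_boot_failed,
            "seed": self.seed,
            "clock_rate": self.fit.rate,
            "clock_r_squared": self.fit.r_squared,
            "n_calibration": self.fit.n_calibration,
            "method": "least-squares root-to-tip strict clock (approximation; "
            "not a Bayesian posterior)",
        }


def fit_strict_clock(
    rooted_tree: dendropy.Tree, tip_dates: Mapping[str, float]
) -> ClockFit:
    """OLS of root-to-tip distance against tip date over calibration tips.

    Requires >= 3 dated tips spanning a nonzero date range.  The fitted
    slope is -rate; the fit itself never raises on a non-positive rate —
    inversion does.
    """
    rtt = root_to_tip_distances(rooted_tree)
    tips = [t for t in tip_dates if t in rtt]
    if len(tips) < 3:
        raise ValueError(f"need >= 3 dated calibration tips in tree, have {len(tips)}")
    t = np.array([tip_dates[x] for x in tips], dtype=float)
    y = np.array([rtt[x] for x in tips], dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("calibration tip dates are all identical; clock fit degenerate")
    res = stats.linregress(t, y)
    fitted = res.intercept + res.slope * t
    return ClockFit(
        rate=-res.slope,
        intercept=res.intercept,
        r_squared=res.rvalue**2,
        residuals={x: float(yy - ff) for x, yy, ff in zip(tips, y, fitted)},
        n_calibration=len(tips),
    )


def invert_clock(fit: ClockFit, root_to_tip: float) -> float:
    if fit.rate <= 0:
        raise ClockError(
            f"fitted clock rate {fit.rate:.3g} <= 0; cannot invert for a date"
        )
    return (fit.intercept - root_to_tip) / fit.rate


def estimate_tip_date(
    alignment: Mapping[str, str],
    tip_dates: Mapping[str, float],
    query_id: str,
    outgroup_ids: Sequence[str],
    n_boot: int = 200,
    seed: int = 0,
) -> DateEstimate:
    """Full dating chain with a column bootstrap for the 95% interval.

    ``tip_dates`` covers the calibration tips (outgroup tips and the query
    are excluded from the regression even if dated: the outgroup stem is
    not clock-comparable to the ingroup).  Bootstrap replicates that fail
    (undefined distance, non-positive rate, unresolvable rooting) are
    dropped and counted.
    """
    if query_id not in alignment:
        raise ValueError(f"query {query_id!r} not in alignment")
    missing_og = [o for o in outgroup_ids if o not in alignment]
    if missing_og:
        raise ValueError(f"outgroup tip(s) not in alignment: {missing_og}")
    calibration = {
        t: float(d)
        for t, d in tip_dates.items()
        if t in alignment and t != query_id and t not in set(outgroup_ids)
    }
    if len(calibration) < 3:
        raise ValueError("need >= 3 dated calibration tips")

    ids = list(alignment)
    lengths = {len(alignment[i]) for i in ids}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must have equal length")
    L = lengths.pop()
    M = np.stack([encode(alignment[i]) for i in ids])
    k = len(ids)

    # Per-pair column indicators; a bootstrap replicate is then two
    # matrix-vector products against the column-resampling weights.
    pairs = list(combinations(range(k), 2))
    valid_ind = np.empty((len(pairs), L), dtype=np.uint8)
    neq_ind = np.empty((len(pairs), L), dtype=np.uint8)
    for pi, (x, y) in enumerate(pairs):
        v = (M[x] != N) & (M[y] != N)
        valid_ind[pi] = v
        neq_ind[pi] = v & (M[x] != M[y])

    def chain(weights: np.ndarray | None) -> tuple[float, ClockFit]:
        if weights is None:
            n_valid = valid_ind.sum(axis=1).astype(float)
            n_neq = neq_ind.sum(axis=1).astype(float)
        else:
            n_valid = valid_ind @ weights
            n_neq = neq_ind @ weights
        if np.any(n_valid == 0):
            raise ValueError("a genome pair shares no resolved sites")
        p = n_neq / n_valid
        if np.any(p >= 0.75):
            raise ValueError("mismatch fraction >= 0.75; JC distance undefined")
        d = -0.75 * np.log1p(-4.0 * p / 3.0)
        D = np.zeros((k, k))
        for pi, (x, y) in enumerate(pairs):
            D[x, y] = D[y, x] = d[pi]
        tree = neighbor_joining(ids, D)
        rooted = root_on_outgroup(tree, outgroup_ids, in_place=True)
        fit = fit_strict_clock(rooted, calibration)
        rtt = root_to_tip_distances(rooted)
        return invert_clock(fit, rtt[query_id]), fit

    point, fit = chain(None)

    rng = np.random.default_rng(seed)
    boots: list[float] = []
    n_failed = 0
    for _ in range(n_boot):
        cols = rng.integers(0, L, size=L)
        weights = np.bincount(cols, minlength=L).astype(float)
        try:
            est, _ = chain(weights)
            boots.append(est)
        except (ValueError, ClockError):
            n_failed += 1
    if boots:
        ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
        ci_low = float(min(ci_low, point))
        ci_high = float(max(ci_high, point))
    else:
        ci_low = ci_high = point
    if n_failed:
        logger.warning(
            "estimate_tip_date: %d/%d bootstrap replicates failed", n_failed, n_boot
        )
    return DateEstimate(
        point=float(point),
        ci_low=ci_low,
        ci_high=ci_high,
        n_boot=n_boot,
        seed=seed,
        fit=fit,
        n_boot_failed=n_failed,
    )
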