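"""Jukes-Cantor distances, neighbour joining, outgroup rooting and the
strict-clock root-to-tip dating chain."""

import io

import dendropy
import numpy as np
import pandas as pd
import pytest
from dendropy.calculate import treecompare

from paleomito import simulate, tipdating
from paleomito._nj import neighbor_joining
from paleomito.tipdating import ClockError


class TestJCDistance:
    def test_identical_zero(self):
        assert tipdating.jc_distance("ACGT" * 100, "ACGT" * 100) == 0.0

    def test_closed_form_p003(self):
        """p = 0.03 -> d = -(3/4) ln(1 - 0.04) = 0.0306183..."""
        a = "A" * 1000
        b = "C" * 30 + "A" * 970
        d = tipdating.jc_distance(a, b)
        assert d == pytest.approx(-0.75 * np.log(1 - 0.04), rel=1e-9)
        assert d == pytest.approx(0.0306165, abs=1e-6)

    def test_all_n_overlap_undefined(self):
        with pytest.raises(ValueError, match="resolved"):
            tipdating.jc_distance("NNNN", "ACGT")

    def test_saturation_undefined(self):
        with pytest.raises(ValueError, match="0.75"):
            tipdating.jc_distance("A" * 100, "C" * 100)

    def test_n_sites_excluded(self):
        a = "AANA"
        b = "AGNA"
        # one mismatch over three resolved sites
        assert tipdating.jc_distance(a, b) == pytest.approx(
            -0.75 * np.log(1 - 4 / 3 * (1 / 3))
        )


def _additive_matrix():
    """Distances from the 4-taxon tree ((A:2,B:3):1,(C:4,D:5)) with internal
    branch 1 (unrooted quartet AB|CD)."""
    ids = ["A", "B", "C", "D"]
    D = pd.DataFrame(
        [
            [0, 5, 7, 8],
            [5, 0, 8, 9],
            [7, 8, 0, 9],
            [8, 9, 9, 0],
        ],
        index=ids,
        columns=ids,
        dtype=float,
    )
    return D


class TestNeighborJoining:
    def test_additive_matrix_recovered_exactly(self):
        D = _additive_matrix()
        tree = tipdating.build_nj_tree(D)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for a in D.index:
            for b in D.index:
                if a != b:
                    assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(
                        D.loc[a, b], abs=1e-9
                    )
        # quartet AB|CD: path A-B avoids the internal branch
        assert pdm.patristic_distance(taxa["A"], taxa["B"]) == 5

    def test_three_taxa_star(self):
        ids = ["a", "b", "c"]
        D = pd.DataFrame(
            [[0, 2, 3], [2, 0, 5], [3, 5, 0]], index=ids, columns=ids, dtype=float
        )
        tree = tipdating.build_nj_tree(D)
        assert len(tree.seed_node.child_nodes()) == 3
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.patristic_distance(taxa["a"], taxa["b"]) == pytest.approx(2)

    def test_permuted_input_same_tree(self):
        D = _additive_matrix()
        perm = ["C", "A", "D", "B"]
        t1 = tipdating.build_nj_tree(D)
        t2 = tipdating.build_nj_tree(D.loc[perm, perm])
        tns = dendropy.TaxonNamespace(["A", "B", "C", "D"])
        n1 = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick",
                               taxon_namespace=tns)
        n2 = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick",
                               taxon_namespace=tns)
        n1.encode_bipartitions()
        n2.encode_bipartitions()
        assert treecompare.symmetric_difference(n1, n2) == 0

    def test_agrees_with_dendropy_nj(self):
        """Dual-route check: our vectorised NJ against dendropy's own
        implementation on random distance matrices."""
        rng = np.random.default_rng(5)
        for _ in range(3):
            n = int(rng.integers(5, 12))
            pts = rng.random((n, 5))
            D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            ids = [f"t{i}" for i in range(n)]
            tns = dendropy.TaxonNamespace(ids)
            mine = neighbor_joining(ids, D, taxon_namespace=tns)
            csv = "," + ",".join(ids) + "\n" + "\n".join(
                ids[i] + "," + ",".join(f"{D[i, j]:.12f}" for j in range(n))
                for i in range(n)
            )
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                io.StringIO(csv), delimiter=",", taxon_namespace=tns
            )
            ref = pdm.nj_tree()
            mine.encode_bipartitions()
            ref.encode_bipartitions()
            assert treecompare.symmetric_difference(mine, ref) == 0
            pdm1 = mine.phylogenetic_distance_matrix()
            pdm2 = ref.phylogenetic_distance_matrix()
            for a in tns:
                for b in tns:
                    if a is not b:
                        assert pdm1.patristic_distance(a, b) == pytest.approx(
                            pdm2.patristic_distance(a, b), abs=1e-8
                        )


class TestRooting:
    def _quartet_tree(self):
        return tipdating.build_nj_tree(_additive_matrix())

    def test_single_outgroup_gives_ingroup_clade(self):
        tree = self._quartet_tree()
        rooted = tipdating.root_on_outgroup(tree, ["D"])
        kids = rooted.seed_node.child_nodes()
        assert len(kids) == 2
        sizes = sorted(len(k.leaf_nodes()) for k in kids)
        assert sizes == [1, 3]

    def test_outgroup_pair(self):
        tree = self._quartet_tree()
        rooted = tipdating.root_on_outgroup(tree, ["C", "D"])
        og = {
            leaf.taxon.label
            for k in rooted.seed_node.child_nodes()
            for leaf in k.leaf_nodes()
            if {l.taxon.label for l in k.leaf_nodes()} == {"C", "D"}
        }
        assert og == {"C", "D"}

    def test_non_monophyletic_outgroup_rejected(self):
        tree = self._quartet_tree()
        with pytest.raises(ValueError, match="monophyletic"):
            tipdating.root_on_outgroup(tree, ["A", "C"])

    def test_rooting_preserves_path_lengths(self):
        tree = self._quartet_tree()
        rooted = tipdating.root_on_outgroup(tree, ["D"])
        D = _additive_matrix()
        pdm = rooted.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in rooted.taxon_namespace}
        for a in D.index:
            for b in D.index:
                if a != b:
                    assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(
                        D.loc[a, b], abs=1e-9
                    )


def _clocklike_tree(rate=2e-8):
    """Hand-built rooted tree exactly clock-like in time.

    Root age 100k; tips: a@0, b@20k, c@50k, d@10k; branch lengths =
    rate * duration (distance units).
    """
    tns = dendropy.TaxonNamespace(["a", "b", "c", "d"])
    newick = (
        f"((a:{rate * 60_000},b:{rate * 40_000}):{rate * 40_000},"
        f"(c:{rate * 30_000},d:{rate * 70_000}):{rate * 20_000}):0;"
    )
    tree = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=tns)
    tree.is_rooted = True
    dates = {"a": 0.0, "b": 20_000.0, "c": 50_000.0, "d": 10_000.0}
    return tree, dates


class TestClockFit:
    def test_perfect_clock_recovers_rate(self):
        rate = 2e-8
        tree, dates = _clocklike_tree(rate)
        fit = tipdating.fit_strict_clock(tree, dates)
        assert fit.rate == pytest.approx(rate, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.intercept == pytest.approx(rate * 100_000, rel=1e-6)

    def test_identical_dates_degenerate(self):
        tree, _ = _clocklike_tree()
        with pytest.raises(ValueError, match="identical"):
            tipdating.fit_strict_clock(tree, {"a": 0.0, "b": 0.0, "c": 0.0})

    def test_inversion_requires_positive_rate(self):
        fit = tipdating.ClockFit(
            rate=-1e-9, intercept=0.001, r_squared=0.5, residuals={}, n_calibration=3
        )
        with pytest.raises(ClockError):
            tipdating.invert_clock(fit, 0.0005)

    def test_rate_recovery_unbiased_across_seeds(self):
        """Simulated strict-clock alignments give a rate estimate centred on
        the truth (20 seeds)."""
        tip_dates = {"out": 150_000.0, "q": 45_000.0}
        for i in range(10):
            tip_dates[f"c{i}"] = i * 5_500.0
        cal = {k: v for k, v in tip_dates.items() if k.startswith("c") and k != "q"}
        rate = 2.5e-8
        rates = []
        for seed in range(20):
            tree = simulate.random_serial_tree(
                tip_dates, seed=seed, coalescent_scale=15_000, outgroup=["out"]
            )
            cfg = simulate.ClockSimConfig(
                tree=tree, rate=rate, seq_length=16_569, tip_dates=tip_dates,
                seed=seed + 500,
            )
            aln, _ = simulate.simulate_clock_alignment(cfg)
            D = tipdating.jc_distance_matrix(aln)
            nj = tipdating.build_nj_tree(D)
            rooted = tipdating.root_on_outgroup(nj, ["out"])
            fit = tipdating.fit_strict_clock(rooted, cal)
            rates.append(fit.rate)
        assert abs(np.mean(rates) - rate) / rate < 0.15


class TestEstimateTipDate:
    def _setup(self, seed=1, rate=2.5e-8):
        tip_dates = {"out1": 120_000.0, "out2": 118_000.0, "query": 45_000.0}
        for i in range(12):
            tip_dates[f"cal{i:02d}"] = i * 5_000.0
        tree = simulate.random_serial_tree(
            tip_dates, seed=seed, coalescent_scale=15_000, outgroup=["out1", "out2"]
        )
        cfg = simulate.ClockSimConfig(
            tree=tree, rate=rate, seq_length=16_569, tip_dates=tip_dates, seed=seed + 50
        )
        aln, _ = simulate.simulate_clock_alignment(cfg)
        cal = {k: v for k, v in tip_dates.items() if k.startswith("cal")}
        return aln, cal

    def test_ci_brackets_point_and_is_deterministic(self):
        aln, cal = self._setup()
        est1 = tipdating.estimate_tip_date(aln, cal, "query", ["out1", "out2"],
                                           n_boot=50, seed=3)
        est2 = tipdating.estimate_tip_date(aln, cal, "query", ["out1", "out2"],
                                           n_boot=50, seed=3)
        assert est1.ci_low <= est1.point <= est1.ci_high
        assert est1.point == est2.point and est1.ci_low == est2.ci_low

    def test_relabelling_invariance(self):
        aln, cal = self._setup(seed=2)
        est1 = tipdating.estimate_tip_date(aln, cal, "query", ["out1", "out2"],
                                           n_boot=20, seed=1)
        shuffled = dict(reversed(list(aln.items())))
        est2 = tipdating.estimate_tip_date(shuffled, cal, "query", ["out1", "out2"],
                                           n_boot=20, seed=1)
        assert est1.point == pytest.approx(est2.point, rel=1e-9)

    def test_query_identical_to_calibration_tip(self):
        aln, cal = self._setup(seed=4)
        aln["query"] = aln["cal09"]  # dated 45,000
        est = tipdating.estimate_tip_date(aln, cal, "query", ["out1", "out2"],
                                          n_boot=100, seed=2)
        assert est.ci_low <= 45_000 <= est.ci_high

    def test_rate_zero_fails_explicitly(self):
        tip_dates = {"out": 100_000.0, "query": 45_000.0}
        for i in range(5):
            tip_dates[f"c{i}"] = i * 10_000.0
        tree = simulate.random_serial_tree(tip_dates, seed=1, outgroup=["out"])
        cfg = simulate.ClockSimConfig(
            tree=tree, rate=0.0, seq_length=2_000, tip_dates=tip_dates, seed=1
        )
        aln, _ = simulate.simulate_clock_alignment(cfg)
        cal = {k: v for k, v in tip_dates.items() if k.startswith("c")}
        with pytest.raises((ClockError, ValueError)):
            tipdating.estimate_tip_date(aln, cal, "query", ["out"], n_boot=5, seed=1)

    def test_missing_query_rejected(self):
        aln, cal = self._setup(seed=5)
        with pytest.raises(ValueError, match="nope"):
            tipdating.estimate_tip_date(aln, cal, "nope", ["out1"], n_boot=5, seed=1)
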