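"""Simulator behaviour: determinism, channel isolation, calibrated rates,
circular SAM round-trips and strict-clock sequence evolution."""

import numpy as np
import pytest
from scipy import stats

from paleomito import alignment, simulate
from paleomito._seq import C, N, T, encode


class TestReference:
    def test_exact_length_and_determinism(self):
        a = simulate.simulate_reference(16569, gc=0.44, seed=1)
        b = simulate.simulate_reference(16569, gc=0.44, seed=1)
        assert len(a) == 16569
        assert a.sequence == b.sequence
        assert a.circular

    def test_gc_content_converges(self):
        ref = simulate.simulate_reference(100_000, gc=0.44, seed=7)
        gc = np.isin(ref.encoded, [1, 2]).mean()
        assert 0.43 <= gc <= 0.45

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate.simulate_reference(500)
        with pytest.raises(ValueError):
            simulate.simulate_reference(2000, gc=1.5)


class TestFragments:
    def test_no_mutation_channels_matches_reference(self, ref_small):
        frags, truth = simulate.simulate_fragments(
            ref_small,
            simulate.DamageModel.none(),
            simulate.LibraryConfig(n_fragments=200, seed=1),
        )
        for f in frags:
            assert np.array_equal(f.obs_base, ref_small.encoded[f.obs_ref_pos])
        assert truth.n_contaminant() == 0
        assert all(not truth[f.id].damage_positions for f in frags)

    def test_truth_table_complete(self, ref_small):
        frags, truth = simulate.simulate_fragments(
            ref_small,
            simulate.DamageModel(),
            simulate.LibraryConfig(n_fragments=300, contamination_fraction=0.3, seed=2),
        )
        assert len(truth) == len(frags)
        assert {f.id for f in frags} == set(truth.records)

    def test_contaminant_count_binomial(self, ref_small):
        n, c = 10_000, 0.2
        frags, truth = simulate.simulate_fragments(
            ref_small,
            simulate.DamageModel(),
            simulate.LibraryConfig(n_fragments=n, contamination_fraction=c, seed=3),
        )
        lo, hi = stats.binom.interval(0.999, n, c)
        assert lo <= truth.n_contaminant() <= hi

    def test_terminal_damage_rate_exact_binomial(self, ref_mt):
        """With error off, T at read position 1 among template-C reads is a
        Binomial(opportunities, delta5[0]) draw; check the exact 99% interval."""
        delta0 = 0.4
        dm = simulate.DamageModel(
            delta5=simulate.geometric_decay(delta0),
            delta3=simulate.geometric_decay(0.35),
            error_rate=0.0,
        )
        frags, truth = simulate.simulate_fragments(
            ref_mt, dm, simulate.LibraryConfig(n_fragments=20_000, seed=5)
        )
        n_opp = n_t = 0
        for f in frags:
            at0 = f.obs_read_pos == 0
            tmpl = ref_mt.encoded[f.obs_ref_pos[at0]]
            base = f.obs_base[at0]
            if f.strand == "-":
                from paleomito._seq import complement

                tmpl, base = complement(tmpl), complement(base)
            if tmpl[0] == C:
                n_opp += 1
                n_t += base[0] == T
        lo, hi = stats.binom.interval(0.99, n_opp, delta0)
        assert lo <= n_t <= hi
        # with error off, the truth table reproduces the observed channel exactly
        n_truth = sum(0 in truth[f.id].damage_positions for f in frags)
        assert n_truth == n_t

    def test_determinism_byte_identical_sam(self, ref_small, tmp_path):
        lib = simulate.LibraryConfig(n_fragments=150, contamination_fraction=0.1, seed=9)
        for tag in ("a", "b"):
            frags, _ = simulate.simulate_fragments(ref_small, simulate.DamageModel(), lib)
            simulate.write_sam(frags, ref_small, tmp_path / f"{tag}.sam")
        assert (tmp_path / "a.sam").read_bytes() == (tmp_path / "b.sam").read_bytes()

    def test_empty_reference_rejected(self):
        ref = simulate.ReferenceGenome("empty", "")
        with pytest.raises(ValueError):
            simulate.simulate_fragments(
                ref, simulate.DamageModel(), simulate.LibraryConfig(n_fragments=5)
            )


class TestDuplicates:
    def test_rate_zero_identity(self, ref_small):
        frags, truth = simulate.simulate_fragments(
            ref_small, simulate.DamageModel(), simulate.LibraryConfig(n_fragments=50, seed=1)
        )
        out, truth2 = simulate.inject_duplicates(frags, truth, 0.0, seed=2)
        assert out is frags and truth2 is truth

    def test_explicit_three_copies(self, ref_small):
        frags, truth = simulate.simulate_fragments(
            ref_small, simulate.DamageModel(), simulate.LibraryConfig(n_fragments=5, seed=1)
        )
        rng = np.random.default_rng(0)
        new_truth = simulate.TruthTable(dict(truth.records))
        for k in range(3):
            copy, rec = simulate.replicate_fragment(
                frags[0], truth[frags[0].id], 0.001, rng, f"{frags[0].id}_d{k}"
            )
            assert copy.ref_start == frags[0].ref_start
            assert copy.strand == frags[0].strand
            new_truth.add(rec)
        sets = new_truth.duplicate_sets()
        assert len(sets[frags[0].id]) == 4

    def test_duplicate_count_binomial(self, ref_small):
        n, rate = 10_000, 0.2
        frags, truth = simulate.simulate_fragments(
            ref_small, simulate.DamageModel(), simulate.LibraryConfig(n_fragments=n, seed=4)
        )
        out, truth2 = simulate.inject_duplicates(frags, truth, rate, seed=5)
        n_copies = len(out) - n
        lo, hi = stats.binom.interval(0.99, n, rate)
        assert lo <= n_copies <= hi
        # every copy shares coordinates with its original
        by_id = {f.id: f for f in out}
        for set_id, members in truth2.duplicate_sets().items():
            if len(members) > 1:
                orig = by_id[set_id]
                for m in members:
                    assert by_id[m].ref_start == orig.ref_start
                    assert by_id[m].strand == orig.strand
                    assert by_id[m].read_length == orig.read_length


class TestSamRoundTrip:
    def test_observations_survive_roundtrip(self, ref_small, tmp_path):
        frags, _ = simulate.simulate_fragments(
            ref_small,
            simulate.DamageModel(),
            simulate.LibraryConfig(n_fragments=100, contamination_fraction=0.1, seed=11),
        )
        path = tmp_path / "frags.sam"
        simulate.write_sam(frags, ref_small, path)
        back = alignment.read_sam(path, ref_small)
        assert len(back) == len(frags)
        for a, b in zip(frags, back):
            assert a.id == b.id and a.strand == b.strand and a.mapq == b.mapq
            assert np.array_equal(a.obs_ref_pos, b.obs_ref_pos)
            assert np.array_equal(a.obs_read_pos, b.obs_read_pos)
            assert np.array_equal(a.obs_base, b.obs_base)

    def test_origin_wrapping_fragment_recovered(self, ref_small, tmp_path):
        from .conftest import make_fragment

        frag = make_fragment(ref_small, start=1990, length=40, frag_id="wrap")
        path = tmp_path / "wrap.sam"
        simulate.write_sam([frag], ref_small, path)
        (back,) = alignment.read_sam(path, ref_small)
        assert np.array_equal(back.obs_ref_pos, frag.obs_ref_pos)
        assert set(back.obs_ref_pos) >= {1990, 1999, 0, 29}

    def test_empty_fragment_list_header_only(self, ref_small, tmp_path):
        path = tmp_path / "empty.sam"
        simulate.write_sam([], ref_small, path)
        assert alignment.read_sam(path, ref_small) == []
        text = path.read_text()
        assert f"LN:{len(ref_small)}" in text


class TestClockSimulation:
    TREE = "((a:10000,b:10000):5000,c:15000):0;"
    DATES = {"a": 0.0, "b": 0.0, "c": 0.0}

    def test_rate_zero_all_identical(self):
        cfg = simulate.ClockSimConfig(
            tree=self.TREE, rate=0.0, seq_length=500, tip_dates=self.DATES, seed=1
        )
        aln, _ = simulate.simulate_clock_alignment(cfg)
        assert len(set(aln.values())) == 1

    def test_determinism(self):
        cfg = simulate.ClockSimConfig(
            tree=self.TREE, rate=1e-6, seq_length=500, tip_dates=self.DATES, seed=3
        )
        assert simulate.simulate_clock_alignment(cfg)[0] == simulate.simulate_clock_alignment(cfg)[0]

    def test_sister_difference_matches_jukes_cantor(self):
        """Raw difference fraction between sisters with total path 2t follows
        p = (3/4)(1 - exp(-(8/3) rate t))."""
        rate, t, L = 1e-6, 10_000, 20_000
        cfg = simulate.ClockSimConfig(
            tree=self.TREE, rate=rate, seq_length=L, tip_dates=self.DATES, seed=5
        )
        aln, _ = simulate.simulate_clock_alignment(cfg)
        p_obs = np.mean(encode(aln["a"]) != encode(aln["b"]))
        p_exp = 0.75 * (1 - np.exp(-8.0 / 3.0 * rate * t))
        lo, hi = stats.binom.interval(0.999, L, p_exp)
        assert lo / L <= p_obs <= hi / L

    def test_non_ultrametric_rejected(self):
        cfg = simulate.ClockSimConfig(
            tree=self.TREE, rate=1e-6, seq_length=100,
            tip_dates={"a": 0.0, "b": 3000.0, "c": 0.0}, seed=1,
        )
        with pytest.raises(ValueError, match="ultrametric"):
            simulate.simulate_clock_alignment(cfg)

    def test_random_serial_tree_respects_dates_and_outgroup(self):
        dates = {"x": 0.0, "y": 20_000.0, "z": 5_000.0, "og": 80_000.0}
        tree = simulate.random_serial_tree(dates, seed=2, outgroup=["og"])
        # ultrametric check built into the simulator should accept it
        cfg = simulate.ClockSimConfig(
            tree=tree, rate=1e-7, seq_length=1000, tip_dates=dates, seed=1
        )
        aln, _ = simulate.simulate_clock_alignment(cfg)
        assert set(aln) == set(dates)
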