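"""Simulator: reference generation, packaging models, shearing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pacscope import (
    CircularGenome,
    PackagingSpec,
    Strategy,
    build_concatemer,
    make_reference,
    package_fixed_termini,
    package_random,
    package_series,
    shear_and_read,
    simulate,
)
from pacscope.simulate import circular_substring, shear_fragments


class TestMakeReference:
    def test_gc_zero_forces_at_only(self):
        g = make_reference(length=10, gc=0.0, seed=7)
        assert set(g.sequence) <= {"A", "T"}

    def test_realized_gc_near_default_target(self):
        g = make_reference(length=86_193, gc=0.4907, seed=1)
        gc = (g.sequence.count("G") + g.sequence.count("C")) / g.length
        assert abs(gc - 0.4907) < 0.01

    def test_gc_count_matches_independent_letter_tally(self):
        g = make_reference(length=2_000, gc=0.5, seed=3)
        tally = sum(1 for c in g.sequence if c in "GC")
        assert tally == g.sequence.count("G") + g.sequence.count("C")
        assert abs(tally / 2_000 - 0.5) < 0.05

    def test_deterministic_for_fixed_seed(self):
        assert make_reference(500, 0.4, 42).sequence == make_reference(500, 0.4, 42).sequence
        assert make_reference(500, 0.4, 42).sequence != make_reference(500, 0.4, 43).sequence

    @pytest.mark.parametrize("length,gc", [(0, 0.5), (-5, 0.5), (10, -0.1), (10, 1.2)])
    def test_rejects_bad_parameters(self, length, gc):
        with pytest.raises(ValueError):
            make_reference(length, gc, 1)


class TestConcatemer:
    def test_single_copy_origin_one_is_identity(self, small_genome):
        assert build_concatemer(small_genome, 1, 1) == small_genome.sequence

    def test_rotation_and_repeat(self):
        g = CircularGenome(id="x", sequence="ACGT")
        assert build_concatemer(g, 2, 3) == "GTACGTAC"

    def test_periodicity(self, small_genome):
        G = small_genome.length
        cat = build_concatemer(small_genome, 3, origin=17)
        assert cat[:G] == cat[G : 2 * G] == cat[2 * G :]

    def test_rejects_bad_arguments(self, small_genome):
        with pytest.raises(ValueError):
            build_concatemer(small_genome, 0, 1)
        with pytest.raises(ValueError):
            build_concatemer(small_genome, 1, small_genome.length + 1)


def _headful_spec(G, pac, H, S, sd=0.0):
    return PackagingSpec(
        strategy=Strategy.HEADFUL_PAC,
        pac_position=pac,
        headful_length=H,
        headful_sd=sd,
        series_length=S,
    )


class TestPackageSeries:
    def test_single_headful_starts_at_pac(self):
        g = make_reference(100, 0.5, 5)
        spec = _headful_spec(100, pac=11, H=110, S=1)
        cat = build_concatemer(g, 3, origin=11)
        (mol,) = package_series(cat, spec, 100)
        assert (mol.start, mol.length, mol.series_index) == (11, 110, 0)

    def test_deterministic_continuation_starts(self):
        g = make_reference(100, 0.5, 5)
        spec = _headful_spec(100, pac=11, H=110, S=3)
        cat = build_concatemer(g, 5, origin=11)
        mols = package_series(cat, spec, 100)
        assert [m.start for m in mols] == [11, 21, 31]
        assert all(m.length == 110 for m in mols)

    def test_headful_must_exceed_genome(self):
        with pytest.raises(ValueError):
            _headful_spec(100, pac=1, H=100, S=2).validate(100)

    def test_concatemer_too_short(self):
        g = make_reference(100, 0.5, 5)
        spec = _headful_spec(100, pac=1, H=110, S=4)
        with pytest.raises(ValueError):
            package_series(build_concatemer(g, 2, 1), spec, 100)

    def test_jittered_series_only_first_molecule_at_pac(self, rng):
        g = make_reference(1_000, 0.5, 2)
        spec = _headful_spec(1_000, pac=333, H=1_040, S=4, sd=20.0)
        cat = build_concatemer(g, 6, origin=333)
        mols = package_series(cat, spec, 1_000, rng=rng)
        assert mols[0].start == 333
        assert all(m.start != 333 for m in mols[1:])
        # each molecule abuts the previous cut on the concatemer
        assert sum(m.length for m in mols) <= len(cat)


class TestFixedTermini:
    def test_dtr_repeats_first_bases_at_end(self):
        g = make_reference(50, 0.5, 9)
        spec = PackagingSpec(strategy=Strategy.DTR_SHORT, dtr_length=5, start=1)
        mols = package_fixed_termini(g, spec, n=3)
        assert all(m.length == 55 for m in mols)
        assert all(m.sequence[-5:] == m.sequence[:5] for m in mols)

    def test_cos_molecules_identical_with_overhang_annotation(self):
        g = make_reference(50, 0.5, 9)
        spec = PackagingSpec(strategy=Strategy.COS_5P, overhang_length=4, start=7)
        mols = package_fixed_termini(g, spec, n=4)
        assert len({m.sequence for m in mols}) == 1
        assert all(m.length == 50 and m.overhang == 4 and m.overhang_end == "5p" for m in mols)

    def test_dtr_long_molecules_are_circular_substrings(self):
        g = make_reference(200, 0.5, 3)
        spec = PackagingSpec(strategy=Strategy.DTR_LONG, dtr_length=40, start=77)
        doubled = g.sequence + g.sequence
        for m in package_fixed_termini(g, spec, n=2):
            assert m.sequence in doubled
            assert m.sequence == circular_substring(g.sequence, m.start, m.length)

    def test_dtr_length_must_be_below_genome(self):
        g = make_reference(50, 0.5, 9)
        with pytest.raises(ValueError):
            package_fixed_termini(g, PackagingSpec(strategy=Strategy.DTR_SHORT, dtr_length=50))

    def test_rejects_headful_strategy(self):
        g = make_reference(50, 0.5, 9)
        with pytest.raises(ValueError):
            package_fixed_termini(g, _headful_spec(50, 1, 55, 1))


class TestPackageRandom:
    def test_empty_request(self):
        g = make_reference(100, 0.5, 1)
        spec = PackagingSpec(strategy=Strategy.HEADFUL_RANDOM, headful_length=110)
        assert package_random(g, spec, 0, seed=1) == []

    def test_starts_roughly_uniform(self):
        g = make_reference(1_000, 0.5, 1)
        spec = PackagingSpec(strategy=Strategy.HEADFUL_RANDOM, headful_length=1_050)
        mols = package_random(g, spec, 5_000, seed=2)
        counts = np.bincount([m.start - 1 for m in mols], minlength=1_000)
        assert counts.max() <= 10 * counts.mean()

    def test_reproducible_for_fixed_seed(self):
        g = make_reference(100, 0.5, 1)
        spec = PackagingSpec(strategy=Strategy.HEADFUL_RANDOM, headful_length=110)
        a = package_random(g, spec, 1, seed=5)[0]
        b = package_random(g, spec, 1, seed=5)[0]
        assert (a.start, a.length, a.sequence) == (b.start, b.length, b.sequence)


class TestShearAndRead:
    def test_unsheared_molecule_yields_single_fragment(self):
        g = make_reference(1_000, 0.5, 4)
        mol = package_fixed_termini(
            g, PackagingSpec(strategy=Strategy.COS_5P, overhang_length=4, start=101), n=1
        )[0]
        mol.length = 300
        mol.sequence = mol.sequence[:300]
        reads = shear_and_read([mol], g.length, frag_mean=300, frag_sd=0, read_length=100, seed=1)
        assert len(reads) == 2  # one fragment, two mates
        fwd = reads.ref_start[reads.forward]
        assert list(fwd) == [101]

    def test_fragment_lengths_conserve_molecule_length(self, rng):
        for L in (300, 999, 5_000):
            frags = shear_fragments(L, 550, 55, rng)
            assert frags.sum() == L
            assert (frags > 0).all()

    def test_pac_read_count_at_least_series_initiations(self, headful_sim):
        pac = headful_sim.spec.pac_position
        n_initiating = sum(1 for m in headful_sim.molecules if m.series_index == 0)
        reads = headful_sim.reads
        at_pac = int(((reads.ref_start == pac) & reads.forward).sum())
        assert at_pac >= n_initiating

    def test_rejects_nonpositive_depth_and_read_length(self, small_genome):
        with pytest.raises(ValueError):
            shear_and_read([], small_genome.length, read_length=0)
        with pytest.raises(ValueError):
            shear_and_read([], small_genome.length, depth=0.0)
        with pytest.raises(ValueError):
            simulate("headful_pac", genome_length=1_000, depth=0.0)

    def test_warns_when_fragments_shorter_than_reads(self, small_genome):
        with pytest.warns(UserWarning, match="truncated"):
            shear_and_read([], small_genome.length, frag_mean=100, read_length=251)


class TestSimulateProperties:
    @pytest.mark.parametrize(
        "strategy", ["cos_5p", "cos_3p", "dtr_short", "dtr_long", "headful_pac", "headful_random"]
    )
    def test_molecules_are_circular_substrings(self, strategy):
        sim = simulate(
            strategy, genome_length=5_000, seed=3, depth=20, pac_position=321, dtr_length=400
        )
        doubled = sim.genome.sequence * 3
        for m in sim.molecules[:10]:
            assert m.sequence == circular_substring(sim.genome.sequence, m.start, m.length)
            if m.length <= 2 * sim.genome.length:
                assert m.sequence in doubled

    def test_pac_start_fraction_matches_series_length(self):
        sim = simulate(
            "headful_pac", genome_length=2_000, seed=8, depth=4_000,
            pac_position=500, series_length=4,
        )
        mols = sim.molecules
        assert len(mols) >= 1_000
        frac = sum(1 for m in mols if m.start == 500) / len(mols)
        S = sim.spec.series_length
        se = np.sqrt((1 / S) * (1 - 1 / S) / len(mols))
        assert abs(frac - 1 / S) <= 3 * se

    def test_total_read_bases_tracks_requested_depth(self):
        sim = simulate("headful_pac", genome_length=10_000, seed=5, depth=50)
        realized = sim.reads.total_bases() / sim.genome.length
        assert 0.7 * 50 <= realized <= 1.5 * 50

    def test_bit_reproducible_for_fixed_seed(self):
        a = simulate("dtr_short", genome_length=3_000, seed=9, depth=30)
        b = simulate("dtr_short", genome_length=3_000, seed=9, depth=30)
        assert a.genome.sequence == b.genome.sequence
        assert np.array_equal(a.reads.ref_start, b.reads.ref_start)
        assert np.array_equal(a.reads.forward, b.reads.forward)
        assert np.array_equal(a.reads.read_length, b.reads.read_length)


@given(st.integers(1, 60), st.integers(1, 200), st.integers(0, 2**31 - 1))
def test_circular_substring_equals_doubled_slice(start_frac, length, seed):
    seq = make_reference(60, 0.5, seed % 1000).sequence
    start = start_frac
    reps = length // 60 + 2
    assert circular_substring(seq, start, length) == (seq * reps)[start - 1 : start - 1 + length]
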