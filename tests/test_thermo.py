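import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbmotif.thermo import (EnergyMatrix, SequenceError, WindowDesign,
                            encode_sequence, enumerate_windows,
                            normalize_matrix, occupancy_vector,
                            probe_occupancy, reverse_complement,
                            window_energy, window_occupancy)

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


def brute_force_occupancy(seq, m, strandedness):
    """Independent oracle: nested loops over windows and positions."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def occ(sub):
        E = m.dG0 + sum(m.ddG[p, "ACGT".index(b)] for p, b in enumerate(sub))
        return m.protein_conc / (m.protein_conc + math.exp(E))

    total = 0.0
    for off in range(len(seq) - m.length + 1):
        sub = seq[off:off + m.length]
        if strandedness == "double":
            rc = "".join(comp[b] for b in reversed(sub))
            total += min(occ(sub) + occ(rc), 1.0)
        else:
            total += occ(sub)
    return total


class TestNormalize:
    def test_constant_row_collapses_to_zero(self):
        m = normalize_matrix(np.ones((1, 4)), dG0=0.0)
        np.testing.assert_allclose(m.ddG, 0.0)
        assert m.dG0 == pytest.approx(1.0)

    def test_mean_subtraction(self):
        m = normalize_matrix(np.array([[0.0, 0, 0, 4]]), dG0=0.0)
        np.testing.assert_allclose(m.ddG, [[-1, -1, -1, 3]])
        assert m.dG0 == pytest.approx(1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = normalize_matrix(rng.normal(size=(5, 4)), dG0=-2.0)
        m2 = m.normalized()
        np.testing.assert_allclose(m2.ddG, m.ddG, atol=1e-15)
        assert m2.dG0 == pytest.approx(m.dG0)

    def test_preserves_window_energies(self):
        rng = np.random.default_rng(1)
        raw = rng.normal(size=(3, 4))
        m = normalize_matrix(raw, dG0=0.5)
        raw_m = EnergyMatrix(raw - raw.mean(axis=1, keepdims=True),
                             0.5 + raw.mean(axis=1).sum())
        for w in enumerate_windows("ACGTAC", 3):
            raw_E = 0.5 + sum(raw[p, np.argmax(w.encoded[p])] for p in range(3))
            assert window_energy(w, m) == pytest.approx(raw_E)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            normalize_matrix(np.array([[np.inf, 0, 0, 0]]))


class TestWindows:
    def test_forward_enumeration(self):
        ws = enumerate_windows("ACGT", 2, "single")
        assert [w.sequence for w in ws] == ["AC", "CG", "GT"]
        assert [w.offset for w in ws] == [0, 1, 2]

    def test_window_count(self):
        seq = "A" * 36
        assert len(enumerate_windows(seq, 5, "single")) == 32

    def test_double_strand_adds_rc(self):
        ws = enumerate_windows("ACGT", 2, "double")
        fw = [w for w in ws if w.strand == "fw"]
        rc = [w for w in ws if w.strand == "rc"]
        assert len(fw) == 3 and len(rc) == 3
        assert rc[0].sequence == "GT"  # rc of "AC"

    def test_too_long_motif_raises(self):
        with pytest.raises(ValueError):
            enumerate_windows("ACG", 4)

    @settings(deadline=None, derandomize=True)
    @given(dna, st.integers(1, 6))
    def test_count_property(self, seq, L):
        if L > len(seq):
            return
        assert len(enumerate_windows(seq, L)) == len(seq) - L + 1


class TestEnergiesAndOccupancy:
    def test_zero_matrix_energy_is_dG0(self):
        m = EnergyMatrix(np.zeros((2, 4)), dG0=-1.0)
        for w in enumerate_windows("ACGTA", 2):
            assert window_energy(w, m) == pytest.approx(-1.0)

    def test_single_term(self):
        ddG = np.zeros((2, 4))
        ddG[0, 0] = -2.0  # A at position 0
        m = EnergyMatrix(ddG, dG0=0.0)
        w = enumerate_windows("AC", 2)[0]
        assert window_energy(w, m) == pytest.approx(-2.0)

    def test_hand_sum(self):
        ddG = np.full((3, 4), -0.5)
        m = EnergyMatrix(ddG, dG0=1.0)  # not normalized on purpose
        w = enumerate_windows("ACG", 3)[0]
        assert window_energy(w, m) == pytest.approx(-0.5)

    def test_occupancy_closed_forms(self):
        assert window_occupancy(0.0) == pytest.approx(0.5, abs=1e-12)
        assert window_occupancy(math.log(9)) == pytest.approx(0.1, abs=1e-12)
        assert window_occupancy(-math.log(9)) == pytest.approx(0.9, abs=1e-12)

    def test_occupancy_decreasing_in_energy(self):
        es = np.linspace(-5, 5, 50)
        occ = [window_occupancy(e) for e in es]
        assert np.all(np.diff(occ) < 0)

    def test_probe_occupancy_sums_windows(self):
        m = EnergyMatrix(np.zeros((2, 4)), dG0=0.0)
        assert probe_occupancy("ACG", m, "single") == pytest.approx(1.0)

    def test_double_strand_offset_capped_at_one(self):
        # fw and rc window occupancy both 0.9 at the single offset
        m = EnergyMatrix(np.zeros((2, 4)), dG0=-math.log(9))
        assert probe_occupancy("AT", m, "double") == pytest.approx(1.0)

    def test_competitive_rule(self):
        m = EnergyMatrix(np.zeros((2, 4)), dG0=-math.log(9))
        expect = 0.9 + 0.9 - 0.81
        assert probe_occupancy("AT", m, "double", ds_rule="competitive") == \
            pytest.approx(expect)

    def test_high_dG0_limit(self):
        m = EnergyMatrix(np.zeros((2, 4)), dG0=1e4)
        assert probe_occupancy("ACGT", m) == pytest.approx(0.0, abs=1e-30)

    def test_short_probe_raises(self):
        m = EnergyMatrix(np.zeros((5, 4)))
        with pytest.raises(ValueError):
            probe_occupancy("ACG", m)


class TestOccupancyVector:
    @pytest.mark.parametrize("strandedness", ["single", "double"])
    def test_matches_brute_force(self, strandedness):
        rng = np.random.default_rng(5)
        for _ in range(50):
            L = int(rng.integers(1, 7))
            n = int(rng.integers(L, 41))
            seq = "".join(rng.choice(list("ACGT"), n))
            m = EnergyMatrix(rng.normal(0, 1.5, (L, 4)), float(rng.normal()))
            got = probe_occupancy(seq, m, strandedness)
            want = brute_force_occupancy(seq, m, strandedness)
            assert got == pytest.approx(want, abs=1e-10)

    def test_identical_probes_identical_occupancy(self, toy_probes):
        from pbmotif.probeio import Probe, ProbeSet
        ps = ProbeSet((Probe("x", "ACGTAC", 0.1), Probe("y", "ACGTAC", 0.2)))
        m = EnergyMatrix(np.random.default_rng(0).normal(size=(3, 4)), 0.0)
        occ = occupancy_vector(ps, m)
        assert occ[0] == pytest.approx(occ[1], abs=1e-15)

    def test_lowering_present_base_energy_raises_occupancy(self):
        from pbmotif.probeio import Probe, ProbeSet
        ps = ProbeSet((Probe("x", "GTCGTC", 0.1),))
        ddG = np.zeros((3, 4))
        base = occupancy_vector(ps, EnergyMatrix(ddG, 0.0))[0]
        ddG2 = ddG.copy()
        ddG2[0, 2] = -1.0  # G present at offsets 0 and 3
        assert occupancy_vector(ps, EnergyMatrix(ddG2, 0.0))[0] > base

    def test_gauge_invariance(self, random_probes):
        rng = np.random.default_rng(9)
        m = EnergyMatrix(rng.normal(size=(4, 4)), dG0=-1.0)
        shifts = rng.normal(size=4)
        shifted = EnergyMatrix(m.ddG + shifts[:, None], m.dG0 - shifts.sum())
        np.testing.assert_allclose(occupancy_vector(random_probes, m),
                                   occupancy_vector(random_probes, shifted),
                                   atol=1e-10)

    def test_occupancy_bounds(self, random_probes):
        rng = np.random.default_rng(11)
        m = EnergyMatrix(rng.normal(size=(3, 4)), dG0=-2.0)
        occ = occupancy_vector(random_probes, m)
        n_windows = np.array([len(s) - 2 for s in random_probes.sequences])
        assert np.all(occ > 0) and np.all(occ <= n_windows)

    def test_reverse_complement_symmetry(self):
        from dataclasses import replace

        from pbmotif.probeio import Probe, ProbeSet
        rng = np.random.default_rng(13)
        probes = tuple(
            Probe(f"p{i}", "".join(rng.choice(list("ACGT"), 25)), 0.0)
            for i in range(30))
        ps = ProbeSet(probes, strandedness="double")
        ps_rc = ProbeSet(tuple(
            replace(p, sequence=reverse_complement(p.sequence))
            for p in probes), strandedness="double")
        m = EnergyMatrix(rng.normal(size=(4, 4)), dG0=-0.5)
        np.testing.assert_allclose(occupancy_vector(ps, m),
                                   occupancy_vector(ps_rc, m.reverse_complement()),
                                   atol=1e-10)


class TestSequenceUtils:
    def test_encode_rejects_iupac(self):
        with pytest.raises(SequenceError):
            encode_sequence("ACGN")

    @settings(deadline=None, derandomize=True)
    @given(dna)
    def test_reverse_complement_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_matrix_revcomp_involution(self):
        m = EnergyMatrix(np.random.default_rng(1).normal(size=(5, 4)), -1.0)
        back = m.reverse_complement().reverse_complement()
        np.testing.assert_array_equal(back.ddG, m.ddG)


class TestSerialization:
    @pytest.mark.parametrize("fmt", ["json", "text"])
    def test_round_trip_bit_exact(self, tmp_path, fmt):
        rng = np.random.default_rng(3)
        m = EnergyMatrix(rng.normal(size=(6, 4)), dG0=rng.normal(),
                         protein_conc=2.5)
        path = tmp_path / f"m.{fmt}"
        m.save(path, fmt=fmt)
        back = EnergyMatrix.load(path)
        np.testing.assert_allclose(back.ddG, m.ddG, atol=1e-15, rtol=0)
        assert back.dG0 == pytest.approx(m.dG0, abs=1e-15)
        assert back.protein_conc == m.protein_conc
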