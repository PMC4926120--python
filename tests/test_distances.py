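"""K2P distances, divergence summaries, base composition, classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barcodiag.distances import (
    base_composition,
    classify_query,
    divergence_summary,
    k2p_distance,
    pairwise_matrix,
)
from barcodiag.errors import DistanceError
from barcodiag.seqio import Alignment, SeqRecord


def brute_force_k2p(a: str, b: str):
    """Independent oracle: direct site classification + closed form."""
    ts = tv = n = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if {x, y} in ({"A", "G"}, {"C", "T"}):
            ts += 1
        else:
            tv += 1
    P, Q = ts / n, tv / n
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


class TestK2P:
    def test_identity(self):
        seq = "ACGT" * 164 + "AC"  # 658 nt
        res = k2p_distance(seq, seq)
        assert (res.P, res.Q, res.d) == (0.0, 0.0, 0.0)
        assert res.n_sites == 658

    def test_single_transition_closed_form(self):
        res = k2p_distance("ACGTACGTAC", "GCGTACGTAC")
        assert res.P == pytest.approx(0.1)
        assert res.Q == 0.0
        expected = -0.5 * math.log(0.8)  # second log term vanishes
        assert res.d == pytest.approx(expected, abs=1e-9)
        assert res.d == pytest.approx(0.11157, abs=5e-6)

    def test_pairwise_deletion_excludes_gaps_and_ambiguity(self):
        res = k2p_distance("ACGT-N", "ACGAAN")
        assert res.n_sites == 4
        assert res.P == pytest.approx(0.0)
        assert res.Q == pytest.approx(0.25)  # T<->A at site 4

    def test_unequal_lengths_error(self):
        with pytest.raises(DistanceError):
            k2p_distance("ACGT", "ACG")

    def test_no_comparable_sites_error(self):
        with pytest.raises(DistanceError):
            k2p_distance("----", "ACGT")

    def test_saturation_flagged_not_raised(self):
        # all-transversion pair: Q = 1 -> log argument <= 0
        res = k2p_distance("AAAA", "CCCC")
        assert res.saturated
        assert math.isnan(res.d)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_and_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        a = "".join(rng.choice(list("ACGT"), n))
        b = "".join(
            c if rng.random() > 0.15 else rng.choice(list("ACGT"))
            for c in a
        )
        ab, ba = k2p_distance(a, b), k2p_distance(b, a)
        assert ab.d == pytest.approx(ba.d)
        if not ab.saturated:
            assert ab.d == pytest.approx(brute_force_k2p(a, b), abs=1e-12)
        assert (ab.d == 0) == (ab.P == 0 and ab.Q == 0)

    def test_monotone_in_p_when_q_zero(self):
        # with Q = 0 the formula reduces to -1/2 ln(1 - 2P): increasing in P
        grid = np.linspace(0.0, 0.45, 40)
        vals = [-0.5 * math.log(1 - 2 * p) for p in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestMatrix:
    def test_identical_records_zero_matrix(self):
        aln = Alignment([SeqRecord(f"r{i}", "sp", "ACGTACGT") for i in range(3)])
        m = pairwise_matrix(aln)
        assert np.allclose(m.values, 0.0)

    def test_two_records_matches_pairwise(self):
        aln = Alignment([
            SeqRecord("a", "x", "ACGTACGTAC"),
            SeqRecord("b", "y", "GCGTACGTAC"),
        ])
        m = pairwise_matrix(aln)
        assert m.get("a", "b") == pytest.approx(k2p_distance("ACGTACGTAC", "GCGTACGTAC").d)

    def test_matrix_equals_brute_force(self):
        rng = np.random.default_rng(7)
        records = []
        base = "".join(rng.choice(list("ACGT"), 120))
        for i in range(10):
            seq = "".join(
                c if rng.random() > 0.1 else rng.choice(list("ACGT"))
                for c in base
            )
            records.append(SeqRecord(f"r{i}", "sp", seq))
        m = pairwise_matrix(Alignment(records))
        for i in range(10):
            for j in range(10):
                if i == j:
                    assert m.values[i, j] == 0.0
                else:
                    expected = brute_force_k2p(records[i].sequence, records[j].sequence)
                    assert m.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_phylip_export_header(self, sim_matrix):
        text = sim_matrix.to_phylip()
        assert text.splitlines()[0].strip() == str(len(sim_matrix.labels))


class TestDivergenceSummary:
    def test_one_sequence_per_species(self):
        aln = Alignment([
            SeqRecord("a", "spA", "ACGTACGTAC"),
            SeqRecord("b", "spB", "GCGTACGTAC"),
        ])
        m = pairwise_matrix(aln)
        s = divergence_summary(m, {"a": "spA", "b": "spB"})
        assert s.intra["spA"].average is None  # single-sequence species: empty
        assert s.inter["spA"].min == s.inter["spA"].max == s.inter["spA"].average

    def test_hand_built_two_species(self):
        # 4 sequences, 2 species: 2 intra pairs + 4 inter pairs, enumerated
        seqs = {
            "a1": "ACGTACGTACGTACGTACGT",
            "a2": "ACGTACGTACGTACGTACGA",
            "b1": "GCGTACGTACGTACGTGCGT",
            "b2": "GCGTACGTACGTACGTGCGA",
        }
        species = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        aln = Alignment([SeqRecord(k, species[k], v) for k, v in seqs.items()])
        m = pairwise_matrix(aln)
        s = divergence_summary(m, species)

        def pct(x, y):
            return 100 * brute_force_k2p(seqs[x], seqs[y])

        intra_a = [pct("a1", "a2")]
        inter = [pct(x, y) for x in ("a1", "a2") for y in ("b1", "b2")]
        assert s.intra["A"].average == pytest.approx(np.mean(intra_a))
        assert s.overall_inter.min == pytest.approx(min(inter))
        assert s.overall_inter.max == pytest.approx(max(inter))
        assert s.overall_inter.average == pytest.approx(np.mean(inter))

    def test_min_le_average_le_max(self, sim_matrix, sim_library):
        s = divergence_summary(sim_matrix, sim_library.species_of)
        for stats in list(s.intra.values()) + list(s.inter.values()):
            if stats.average is not None:
                assert stats.min <= stats.average <= stats.max

    def test_simulated_regime_non_overlapping(self, sim_matrix, sim_library):
        """Intra stays below 2%, inter above 16%: the barcode-gap premise."""
        s = divergence_summary(sim_matrix, sim_library.species_of)
        assert s.overall_intra.max < 2.0
        assert s.overall_inter.min > 16.0

    def test_unknown_label_error(self, sim_matrix):
        with pytest.raises(DistanceError):
            divergence_summary(sim_matrix, {})


class TestBaseComposition:
    def test_single_record(self):
        aln = Alignment([SeqRecord("a", "", "ATGC")])
        comp = base_composition(aln)
        assert comp == {"A": 25.0, "T": 25.0, "G": 25.0, "C": 25.0, "AT": 50.0}

    def test_at_only(self):
        comp = base_composition(Alignment([SeqRecord("a", "", "AATT")]))
        assert comp["A"] == comp["T"] == 50.0
        assert comp["AT"] == 100.0

    def test_hand_tallied_multi_record(self):
        seqs = ["ACGTAN", "AAAAAA", "GG-CCT", "TTTTTT", "ACACAC", "GTGTGT"]
        aln = Alignment([SeqRecord(f"r{i}", "", s) for i, s in enumerate(seqs)])
        pooled = "".join(seqs).replace("-", "").replace("N", "")
        comp = base_composition(aln)
        for b in "ACGT":
            assert comp[b] == pytest.approx(100 * pooled.count(b) / len(pooled))

    def test_simulated_library_at_rich(self, sim_library):
        comp = base_composition(sim_library.alignment)
        assert comp["AT"] > 55.0  # insect mitochondrial AT bias preserved


class TestClassification:
    def test_exact_match(self, sim_library):
        rec = sim_library.alignment[0]
        res = classify_query(rec.sequence, sim_library.alignment, sim_library.species_of)
        assert res.species == sim_library.species_of[rec.id]
        assert res.best_distance == 0.0

    def test_one_percent_mutant_assigned(self, sim_library):
        from barcodiag.fixtures import mutate_at_rate

        rec = sim_library.alignment[0]
        q = mutate_at_rate(rec.sequence, 0.01, rng=5)
        res = classify_query(q, sim_library.alignment, sim_library.species_of)
        assert res.species == sim_library.species_of[rec.id]
        assert 100 * res.best_distance <= 2.0

    def test_distant_outgroup_no_match(self, sim_library):
        rng = np.random.default_rng(11)
        q = "".join(rng.choice(list("ACGT"), sim_library.alignment.length))
        res = classify_query(q, sim_library.alignment, sim_library.species_of)
        assert res.species == "no-match"

    def test_length_mismatch_error(self, sim_library):
        with pytest.raises(DistanceError):
            classify_query("ACGT", sim_library.alignment, sim_library.species_of)
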