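"""Diagnostic sites, the three criterion rule lists, pairing, assay design."""

import pytest

from barcodiag.design import (
    DEFAULT_CONFIG,
    design_assay,
    diagnostic_positions,
    evaluate_primer,
    evaluate_probe,
    evaluate_qpcr_pair,
    pair_primers,
    product_length,
)
from barcodiag.errors import DesignError
from barcodiag.seqio import Alignment, PrimerRecord, ProbeRecord, SeqRecord


class TestDiagnosticPositions:
    def test_constructed_single_column(self):
        aln = Alignment([
            SeqRecord("t1", "X", "ACGTACATAC"),
            SeqRecord("t2", "X", "ACGTACATAC"),
            SeqRecord("o1", "Y", "ACGTACGTAC"),
            SeqRecord("o2", "Z", "ACGTACCTAC"),
        ])
        diag = diagnostic_positions(aln, target="X")
        assert diag == [(7, "A")]

    def test_identical_alignment_empty(self):
        aln = Alignment([SeqRecord(f"r{i}", "XY"[i % 2], "ACGTACGT") for i in range(4)])
        assert diagnostic_positions(aln, target="X") == []

    def test_absent_target_error(self):
        aln = Alignment([SeqRecord("a", "X", "ACGT")])
        with pytest.raises(DesignError):
            diagnostic_positions(aln, target="Z")

    def test_planted_sites_detected(self, sim_library):
        for sp, planted in sim_library.diagnostic_positions.items():
            diag = dict(diagnostic_positions(
                sim_library.alignment, sim_library.species_of, sp
            ))
            assert set(planted) <= set(diag)


class TestProductLength:
    # the six published pairs: product = rev_start + rev_len - fwd_start
    EXPECTED = {
        ("Tde25F20", "Tde451R24"): 450,
        ("Tbr63F23", "Tbr394R23"): 354,
        ("Tma41F22", "Tma508R23"): 490,
        ("Tfr379F22", "Tfr526R23"): 170,
        ("Tca33F26", "Tca346R24"): 337,
        ("Tco261F23", "Tco474R25"): 238,
    }

    def test_all_six_published_products(self, ref_pairs):
        got = {(f.name, r.name): product_length(f, r) for f, r in ref_pairs}
        assert got == self.EXPECTED

    def test_declared_product_column_agrees(self, ref_pairs):
        for f, r in ref_pairs:
            assert f.declared_product == product_length(f, r)


class TestEndpointCriteria:
    def test_published_primers_pass_length_and_gc(self, ref_primers):
        for p in ref_primers:
            report = evaluate_primer(p)
            assert report["SP1"].passed, p.name
            assert report["SP5"].passed, p.name
            assert 30.0 <= report["SP5"].measured <= 70.0

    def test_short_candidate_fails_length(self):
        p = PrimerRecord(name="x", sequence="ACGTACGTACGTACGTA")  # 17 nt
        assert evaluate_primer(p)["SP1"].passed is False

    def test_context_criteria_skipped_without_library(self, ref_primers):
        report = evaluate_primer(ref_primers[0])
        for cid in ("SP3", "SP6", "SP7"):
            assert report[cid].passed is None

    def test_conserved_window_fails_specificity(self):
        # a primer copied from a window identical across all species:
        # conserved 30-nt head, then species-variable tail
        import numpy as np

        rng = np.random.default_rng(17)
        head = "".join(rng.choice(list("ACGT"), 30))
        records = []
        for i, sp in enumerate(["X", "X", "Y", "Z"]):
            tail = "".join(rng.choice(list("ACGT"), 60))
            records.append(SeqRecord(f"r{i}", sp, head + tail))
        aln = Alignment(records)
        p = PrimerRecord(name="cons", sequence=head[:20])
        report = evaluate_primer(p, library=aln, target="X")
        assert report["SP3"].passed is False
        assert report["SP6"].passed is False
        # a window shared by every species necessarily primes elsewhere
        assert report["SP7"].passed is False


class TestPairPrimers:
    def test_published_pairs_recovered(self, ref_primers):
        forwards = [p for p in ref_primers if p.orientation == "forward"]
        reverses = [p for p in ref_primers if p.orientation == "reverse"]
        pairs = pair_primers(forwards, reverses)
        by_name = {(c.forward.name, c.reverse.name): c.product_length for c in pairs}
        assert by_name[("Tde25F20", "Tde451R24")] == 450
        assert by_name[("Tfr379F22", "Tfr526R23")] == 170

    def test_reverse_upstream_excluded(self):
        f = PrimerRecord(name="X500F20", sequence="A" * 20)
        r = PrimerRecord(name="X100R20", sequence="T" * 20)
        assert pair_primers([f], [r]) == []


class TestProbeCriteria:
    def test_published_probes_pass_key_rules(self, ref_taqman):
        _, probes = ref_taqman
        for probe in probes:
            report = evaluate_probe(probe)
            assert report["PR1"].passed, probe.name
            assert report["PR4"].passed, probe.name   # no 5' G
            assert report["PR5"].passed, probe.name   # no GGGG

    def test_tdep_c_exceeds_g(self, ref_taqman):
        _, probes = ref_taqman
        tdep = next(p for p in probes if p.name == "TdeP")
        assert tdep.sequence.count("C") == 5
        assert tdep.sequence.count("G") == 4
        assert evaluate_probe(tdep)["PR2"].passed

    def test_five_prime_g_fails(self):
        probe = ProbeRecord(name="bad", sequence="GACCTTAATCGGTAATGACC")
        assert evaluate_probe(probe)["PR4"].passed is False

    def test_gap_rule(self):
        probe = ProbeRecord(name="p", sequence="TCCTTAATCGGTAATGACCA")
        near = evaluate_probe(probe, probe_gap=3)
        far = evaluate_probe(probe, probe_gap=30)
        assert near["PR6"].passed is True
        assert far["PR6"].passed is False


class TestQpcrCriteria:
    def _pair(self, primers, fname, rname):
        by_name = {p.name: p for p in primers}
        return by_name[fname], by_name[rname]

    def test_tfr_lengths_pass(self, ref_taqman):
        primers, _ = ref_taqman
        f, r = self._pair(primers, "TfrF", "TfrR")
        assert (len(f), len(r)) == (22, 22)
        assert evaluate_qpcr_pair(f, r)["QP1"].passed

    def test_tmar_three_prime_a_fails(self, ref_taqman):
        primers, _ = ref_taqman
        f, r = self._pair(primers, "TmaF", "TmaR")
        assert r.sequence.endswith("A")
        assert evaluate_qpcr_pair(f, r)["QP3"].passed is False

    def test_tde_length_difference_fails(self, ref_taqman):
        primers, _ = ref_taqman
        f, r = self._pair(primers, "TdeF", "TdeR")
        assert (len(f), len(r)) == (18, 24)
        assert evaluate_qpcr_pair(f, r)["QP1"].passed is False

    def test_gc_clamp_rule(self):
        f = PrimerRecord(name="f", sequence="ATATATATATATATATAGGG")
        r = PrimerRecord(name="r", sequence="ATATATATATATATATATGC")
        report = evaluate_qpcr_pair(f, r)
        assert report["QP5"].passed is False


class TestDesignAssay:
    def test_endpoint_designs_cover_planted_sites(self, sim_library):
        aln = sim_library.alignment
        for target in sim_library.species_names()[:2]:
            designs = design_assay(
                aln, sim_library.species_of, target=target,
                max_candidates_per_side=10,
            )
            assert designs
            best = designs[0]
            assert best.overall
            diag = {p for p, _ in diagnostic_positions(
                aln, sim_library.species_of, target
            )}
            for primer in (best.forward, best.reverse):
                start, end = primer.footprint
                assert any(start <= pos <= end for pos in diag), primer.name

    def test_reevaluation_idempotent(self, sim_library):
        aln = sim_library.alignment
        designs = design_assay(
            aln, sim_library.species_of, target="sp01", max_candidates_per_side=5
        )
        best = designs[0]
        again = evaluate_primer(
            best.forward, library=aln, species_of=sim_library.species_of,
            target="sp01",
        )
        assert again.overall

    def test_no_interspecies_difference_empty(self):
        aln = Alignment([
            SeqRecord(f"r{i}", "XY"[i % 2], "ACGTACGTACGT" * 20) for i in range(4)
        ])
        assert design_assay(aln, target="X") == []

    def test_taqman_probes_pass_all_rules(self, sim_library):
        sets = design_assay(
            sim_library.alignment, sim_library.species_of, target="sp02",
            mode="taqman", max_candidates_per_side=8,
        )
        assert sets
        for s in sets[:5]:
            assert s.probe_report.overall
            assert s.pair_report.overall
            hard = [c for c in s.probe_report.criteria if c.hard]
            assert {c.id for c in hard} >= {"PR1", "PR2", "PR3", "PR4", "PR5", "PR6", "PR7"}

    def test_absent_target_error(self, sim_library):
        with pytest.raises(DesignError):
            design_assay(sim_library.alignment, sim_library.species_of, target="nope")
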