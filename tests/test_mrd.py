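"""Tracking, consensus counts, MRD frequency, OPA and Phred arithmetic."""

import numpy as np
import pytest

import mrdtrack as m
from mrdtrack.mrd import AlignmentRecord
from mrdtrack.synthetic import ContrivedSample, NoiseModel, Read


def _sample(reads=None, templates=None, mass=2e6, ref=None):
    return ContrivedSample(
        sample_id="s", dna_mass_pg=mass, expected_malignant_cells=0,
        per_sequence_templates=templates or {},
        reference_templates=ref if ref is not None else 2 * round(mass / 6.53),
        reads=reads,
    )


class TestMatchTracked:
    def _profile(self, seq, n):
        return m.TrackingProfile(
            patient_id="p", tracked=[m.TrackedSequence(seq, "IGH", n, 6.0)]
        )

    def test_identical_sequence_matches_with_zero_budget(self):
        prof = self._profile("ACGTACGT", 0)
        recs = m.match_tracked(_sample(reads=[Read("IGH", "ACGTACGT", 5)]), prof)
        (rec,) = recs["ACGTACGT"]
        assert (rec.mismatches, rec.abundance) == (0, 5)

    def test_hamming_budget_is_a_hard_cutoff(self):
        prof = self._profile("AAAA", 1)
        one = _sample(reads=[Read("IGH", "AAAT", 3)])
        two = _sample(reads=[Read("IGH", "AATT", 3)])
        assert len(m.match_tracked(one, prof)["AAAA"]) == 1
        assert m.match_tracked(two, prof)["AAAA"] == []

    def test_length_mismatch_is_not_a_match(self):
        prof = self._profile("AAAA", 3)
        recs = m.match_tracked(_sample(reads=[Read("IGH", "AAAAA", 3)]), prof)
        assert recs["AAAA"] == []

    def test_tie_goes_to_lowest_index_tracked_sequence(self):
        prof = m.TrackingProfile(
            patient_id="p",
            tracked=[
                m.TrackedSequence("AACC", "IGH", 2, 6.0),
                m.TrackedSequence("AAGG", "IGH", 2, 6.0),
            ],
        )
        recs = m.match_tracked(_sample(reads=[Read("IGH", "AACG", 1)]), prof)
        assert len(recs["AACC"]) == 1 and recs["AAGG"] == []

    def test_empty_profile_is_an_error(self):
        with pytest.raises(m.MissingDataError):
            m.match_tracked(_sample(), m.TrackingProfile("p", []))

    def test_match_rate_under_low_error_injection(self, clone3, profile3):
        # per-base error 1e-3 on 45 nt, N=3: P(>3 errors) ~ C(45,4)e-12, so
        # essentially every template is recovered
        noise = NoiseModel(per_base_error_rate=1e-3)
        matched = generated = 0
        for i in range(200):
            s = m.contrive_sample(clone3, None, 2e6, 100, noise=noise,
                                  seed=i, sample_id=f"s{i}", with_reads=True)
            generated += sum(s.per_sequence_templates.values())
            recs = m.match_tracked(s, profile3)
            matched += sum(r.abundance for v in recs.values() for r in v)
        assert matched / generated >= 0.999


class TestTotalNucleatedCells:
    def test_20ug_gives_3_million_cells(self):
        assert m.total_nucleated_cells(_sample(mass=2e7)) == 3_062_787

    def test_500ng_gives_76570_cells(self):
        assert m.total_nucleated_cells(_sample(mass=5e5)) == 76_570

    def test_reference_templates_halved(self):
        assert m.total_nucleated_cells(_sample(ref=10)) == 5.0

    def test_mass_fallback_when_reference_absent(self):
        s = _sample(mass=6.53, ref=0)
        assert m.total_nucleated_cells(s) == pytest.approx(1.0)


class TestConsensus:
    def test_single_sequence_identity(self):
        assert m.consensus_malignant_cells({"a": 3.0}) == 3.0

    def test_mean_of_two_sequences(self):
        assert m.consensus_malignant_cells({"a": 2.0, "b": 4.0}) == 3.0

    def test_all_zero_counts(self):
        assert m.consensus_malignant_cells({"a": 0.0, "b": 0.0}) == 0.0

    def test_empty_profile_is_missing_data(self):
        with pytest.raises(m.MissingDataError):
            m.consensus_malignant_cells({})

    @pytest.mark.parametrize("mode,expected", [("max", 4.0), ("sum", 6.0)])
    def test_alternative_modes(self, mode, expected):
        assert m.consensus_malignant_cells({"a": 2.0, "b": 4.0}, mode=mode) == expected


class TestMRDFrequency:
    def test_two_cells_in_20ug(self):
        # Freq 1 of the linearity design: 2 cells / 3,062,787 = 0.000065%
        freq = m.mrd_frequency(2.0, 3_062_787)
        assert freq == pytest.approx(6.53e-7, rel=1e-4)
        assert round(100 * freq, 6) == 0.000065

    def test_zero_cells_is_exactly_zero(self):
        assert m.mrd_frequency(0.0, 3_062_787) == 0.0

    def test_full_disease_load_is_one(self):
        assert m.mrd_frequency(30_628, 30_628) == 1.0

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(m.InvalidParameterError):
            m.mrd_frequency(1.0, 0.0)

    def test_frequency_invariant_under_uniform_scaling(self):
        assert m.mrd_frequency(3.0, 1000.0) == m.mrd_frequency(300.0, 100_000.0)


class TestOPA:
    def test_hand_computed_pa_na(self):
        records = [AlignmentRecord(20, 1, 3, 5), AlignmentRecord(20, 0, 3, 95)]
        rep = m.compute_opa(records)
        assert (rep.positive_agreement, rep.negative_agreement) == (1995, 5)
        assert rep.opa == pytest.approx(99.75)

    def test_mismatch_free_records_give_100(self):
        rep = m.compute_opa([AlignmentRecord(45, 0, 3, 10)])
        assert rep.opa == 100.0

    def test_zero_nucleotides_undefined(self):
        with pytest.raises(m.UndefinedStatisticError):
            m.compute_opa([])

    def test_record_beyond_budget_rejected(self):
        with pytest.raises(m.InvalidParameterError):
            m.compute_opa([AlignmentRecord(20, 4, 3, 1)])

    def test_abundance_rebucketing_invariance(self):
        bulk = [AlignmentRecord(30, 1, 2, 10)]
        split = [AlignmentRecord(30, 1, 2, 4), AlignmentRecord(30, 1, 2, 6)]
        assert m.compute_opa(bulk).opa == m.compute_opa(split).opa

    def test_injected_error_rate_recovered(self, clone3, profile3):
        rate = 1e-3
        noise = NoiseModel(per_base_error_rate=rate)
        recs = []
        for i in range(300):
            s = m.contrive_sample(clone3, None, 2e6, 500, noise=noise,
                                  seed=i, sample_id=f"s{i}", with_reads=True)
            for v in m.match_tracked(s, profile3).values():
                recs.extend(v)
        rep = m.compute_opa(recs)
        observed = rep.negative_agreement / rep.nucleotides_assessed
        se = np.sqrt(rate / rep.nucleotides_assessed)
        assert observed == pytest.approx(rate, abs=4 * se)


class TestPhred:
    def test_paper_scale_pairings(self):
        # disagreement 3.5e-5 ~ Phred 44.5-44.6; 4.0e-5 ~ 44.0
        assert m.phred_score(3.5e-5) == pytest.approx(44.56, abs=0.01)
        assert m.phred_score(4.0e-5) == pytest.approx(43.98, abs=0.01)

    def test_definition_at_rate_point_one(self):
        assert m.phred_score(0.1) == pytest.approx(10.0)

    def test_zero_rate_hits_cap(self):
        assert m.phred_score(0.0) == 60.0
        assert m.phred_score(0.0, cap=50.0) == 50.0

    @pytest.mark.parametrize("rate", [-0.1, 1.5])
    def test_rate_out_of_range(self, rate):
        with pytest.raises(m.InvalidParameterError):
            m.phred_score(rate)

    def test_monotone_decreasing_in_error_rate(self):
        rates = np.geomspace(1e-6, 0.5, 20)
        scores = [m.phred_score(r) for r in rates]
        assert all(a > b for a, b in zip(scores, scores[1:]))


class TestEndToEnd:
    def test_noise_free_identity(self, clone3, profile3_exact):
        # no error injection, N=0: per-sequence counts equal the generated
        # template counts exactly and OPA is exactly 100
        recs_all = []
        for i in range(20):
            s = m.contrive_sample(clone3, None, 2e6, 30, seed=i,
                                  sample_id=f"s{i}", with_reads=True)
            result = m.quantify(s, profile3_exact)
            assert result.per_sequence_cells == {
                k: float(v) for k, v in s.per_sequence_templates.items()
            }
            for v in m.match_tracked(s, profile3_exact).values():
                recs_all.extend(v)
        assert m.compute_opa(recs_all).opa == 100.0

    def test_detection_flag_requires_a_template(self, clone3, profile3_exact):
        s = m.contrive_sample(clone3, None, 2e6, 0.0, seed=1)
        r = m.quantify(s, profile3_exact)
        assert not r.detected and r.mrd_frequency == 0.0
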