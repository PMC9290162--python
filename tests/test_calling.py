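import numpy as np
import pytest
from hypothesis import given, strategies as st

from clamp.align import align_read, build_pileup, stack_observations
from clamp.calling import (
    CallStatus,
    call_known,
    classify,
    positive_results,
    scan_de_novo,
)
from clamp.errors import PipelineError
from clamp.panel import codon_to_positions
from clamp.read_prep import filter_reads
from clamp.simulate import CloneSpec, SimulationSpec, simulate_reads


def _mini(panel):
    return panel.isoforms[0]


def _alignments(ref, reads):
    return [align_read(r, ref.sequence) for r in reads]


def _mutant_seq(ref, codon_number, alt_codon):
    p1, _, p3 = codon_to_positions(ref, codon_number)
    return ref.sequence[: p1 - 1] + alt_codon + ref.sequence[p3:]


class TestClassify:
    @pytest.mark.parametrize(
        "vaf,expected",
        [
            (0.0, CallStatus.NEGATIVE),
            (0.004, CallStatus.NEGATIVE),
            (0.0049999, CallStatus.NEGATIVE),
            (0.005, CallStatus.POSITIVE),       # inclusive at the positive cutoff
            (0.008, CallStatus.POSITIVE),
            (0.01, CallStatus.POSITIVE),        # the clinical boundary itself is not "above"
            (0.0100001, CallStatus.CLINICALLY_REPORTABLE),
            (0.021, CallStatus.CLINICALLY_REPORTABLE),
            (1.0, CallStatus.CLINICALLY_REPORTABLE),
        ],
    )
    def test_boundary_semantics(self, panel, vaf, expected):
        assert classify(vaf, panel) is expected

    def test_rejects_out_of_range(self, panel):
        with pytest.raises(ValueError):
            classify(1.5, panel)

    @given(
        v1=st.floats(0, 1, allow_nan=False),
        v2=st.floats(0, 1, allow_nan=False),
    )
    def test_monotone_in_vaf(self, panel, v1, v2):
        order = [CallStatus.NEGATIVE, CallStatus.POSITIVE, CallStatus.CLINICALLY_REPORTABLE]
        lo, hi = sorted([v1, v2])
        assert order.index(classify(lo, panel)) <= order.index(classify(hi, panel))


class TestScanDeNovo:
    def test_clean_sample_has_no_calls(self, tiny_panel):
        ref = _mini(tiny_panel)
        pileup = build_pileup(_alignments(ref, [ref.sequence] * 200), len(ref))
        assert scan_de_novo(pileup, ref, tiny_panel) == []

    def test_spiked_substitution_called_with_label(self, tiny_panel):
        ref = _mini(tiny_panel)
        mutant = _mutant_seq(ref, 3, "ATT")  # T3I, one nucleotide change
        reads = [ref.sequence] * 190 + [mutant] * 10
        pileup = build_pileup(_alignments(ref, reads), len(ref))
        calls = scan_de_novo(pileup, ref, tiny_panel)
        assert len(calls) == 1
        call = calls[0]
        p1, p2, p3 = codon_to_positions(ref, 3)
        assert call.position == p2 and call.alt_base == "T"
        assert call.alt_count == 10 and call.coverage == 200
        assert call.aa_label == "T3I" and call.known
        assert call.status is CallStatus.CLINICALLY_REPORTABLE

    def test_below_min_alt_reads_not_called(self, tiny_panel):
        ref = _mini(tiny_panel)
        mutant = _mutant_seq(ref, 3, "ATT")
        reads = [ref.sequence] * 99 + [mutant]  # vaf 1% but only 1 read < floor 2
        pileup = build_pileup(_alignments(ref, reads), len(ref))
        assert scan_de_novo(pileup, ref, tiny_panel) == []

    def test_synonymous_change_has_no_aa_label(self, tiny_panel):
        ref = _mini(tiny_panel)
        mutant = _mutant_seq(ref, 3, "ACC")  # ACT -> ACC, still threonine
        reads = [ref.sequence] * 90 + [mutant] * 10
        pileup = build_pileup(_alignments(ref, reads), len(ref))
        calls = scan_de_novo(pileup, ref, tiny_panel)
        assert len(calls) == 1
        assert calls[0].aa_label is None and not calls[0].known

    def test_leader_position_is_noncoding(self, tiny_panel):
        ref = _mini(tiny_panel)
        mutant = "T" + ref.sequence[1:] if ref.sequence[0] != "T" else "A" + ref.sequence[1:]
        reads = [ref.sequence] * 90 + [mutant] * 10
        pileup = build_pileup(_alignments(ref, reads), len(ref))
        calls = scan_de_novo(pileup, ref, tiny_panel)
        assert len(calls) == 1 and calls[0].aa_label is None


class TestCallKnown:
    def test_every_panel_mutation_reported_once_including_negatives(self, tiny_panel):
        ref = _mini(tiny_panel)
        obs = stack_observations(_alignments(ref, [ref.sequence] * 50), len(ref))
        results = call_known(obs, tiny_panel, ref)
        assert [r.label for r in results] == ["T3I", "E5K", "L7M"]
        assert all(r.status is CallStatus.NEGATIVE and r.vaf == 0.0 for r in results)
        assert all(r.codon_coverage == 50 for r in results)

    def test_fifty_percent_mutation_quantified_exactly(self, tiny_panel):
        ref = _mini(tiny_panel)
        mutant = _mutant_seq(ref, 3, "ATT")
        obs = stack_observations(
            _alignments(ref, [ref.sequence] * 25 + [mutant] * 25), len(ref)
        )
        by_label = {r.label: r for r in call_known(obs, tiny_panel, ref)}
        assert by_label["T3I"].vaf == 0.5
        assert by_label["T3I"].supporting_reads == 25
        assert by_label["T3I"].status is CallStatus.CLINICALLY_REPORTABLE
        assert by_label["E5K"].status is CallStatus.NEGATIVE

    def test_codon_interrupted_by_deletion_excluded_from_denominator(self, tiny_panel):
        ref = _mini(tiny_panel)
        # delete the codon's middle base (unique context, so the gap cannot
        # shift into a neighbouring homopolymer)
        _, p2, _ = codon_to_positions(ref, 3)
        del_read = ref.sequence[: p2 - 1] + ref.sequence[p2:]
        obs = stack_observations(
            _alignments(ref, [ref.sequence] * 40 + [del_read] * 10), len(ref)
        )
        by_label = {r.label: r for r in call_known(obs, tiny_panel, ref)}
        assert by_label["T3I"].codon_coverage == 40
        assert by_label["E5K"].codon_coverage == 50

    def test_third_amino_acid_counted_as_other_and_excluded(self, tiny_panel):
        ref = _mini(tiny_panel)
        # codon 3 ACT(T) -> GCT = alanine: neither ref nor the catalogued alt
        other = _mutant_seq(ref, 3, "GCT")
        alt = _mutant_seq(ref, 3, "ATT")
        obs = stack_observations(
            _alignments(ref, [ref.sequence] * 80 + [alt] * 10 + [other] * 10), len(ref)
        )
        res = {r.label: r for r in call_known(obs, tiny_panel, ref)}["T3I"]
        assert res.codon_coverage == 100
        assert res.other_reads == 10
        assert res.informative_reads == 90
        assert res.vaf == pytest.approx(10 / 90)

    def test_same_codon_alternates_distinguished(self, panel):
        """F359I and F359V share a codon; per-read translation separates them."""
        ref = panel.isoforms[0]
        ile = _mutant_seq(ref, 359, "ATC")
        val = _mutant_seq(ref, 359, "GTC")
        obs = stack_observations(
            _alignments(ref, [ref.sequence] * 60 + [ile] * 30 + [val] * 10), len(ref)
        )
        res = {r.label: r for r in call_known(obs, panel, ref)}
        assert res["F359I"].vaf == pytest.approx(0.30)
        assert res["F359V"].vaf == pytest.approx(0.10)
        assert res["F359C"].vaf == 0.0
        # a V-codon read is informative (catalogued) for the F359I denominator
        assert res["F359I"].informative_reads == 100

    def test_zero_codon_coverage_is_internal_error(self, tiny_panel):
        ref = _mini(tiny_panel)
        empty = np.full((5, len(ref.sequence)), 255, dtype=np.uint8)
        with pytest.raises(PipelineError):
            call_known(empty, tiny_panel, ref)


class TestSimulatedCalling:
    def test_two_mutation_sample_recovers_both_statuses(self, panel, simulate_and_run):
        """Dominant mutation plus a ~1.7% secondary on a separate clone."""
        art, _ = simulate_and_run(
            panel,
            [(("Y253H",), 0.96), (("E255V",), 0.017)],
            n_reads=4000,
            seed=21,
        )
        res = {r.label: r for r in art.record.known_results}
        assert res["Y253H"].status is CallStatus.CLINICALLY_REPORTABLE
        assert res["E255V"].status is CallStatus.CLINICALLY_REPORTABLE
        assert res["Y253H"].vaf == pytest.approx(0.96, abs=3 * np.sqrt(0.96 * 0.04 / 4000))
        assert res["E255V"].vaf == pytest.approx(
            0.017, abs=3 * np.sqrt(0.017 * 0.983 / 4000)
        )
        assert sum(1 for r in art.record.known_results
                   if r.status is not CallStatus.NEGATIVE) == 2

    def test_de_novo_and_known_calls_agree_on_direction(self, panel, simulate_and_run):
        """A clinically reportable catalogued call implies a de novo hit at its site."""
        art, _ = simulate_and_run(panel, [(("T315I",), 0.05)], n_reads=4000, seed=22)
        rec = art.record
        reportable = [
            r for r in rec.known_results
            if r.status is CallStatus.CLINICALLY_REPORTABLE
        ]
        assert [r.label for r in reportable] == ["T315I"]
        assert any(c.aa_label == "T315I" for c in rec.de_novo)

    def test_vaf_estimator_exact_at_zero_error(self, panel, simulate_and_run):
        """With no sequencing noise the stratified draw makes VAF exact."""
        for f in (0.005, 0.01, 0.05, 0.5):
            art, _ = simulate_and_run(
                panel, [(("T315I",), f)], n_reads=2000, seed=23,
                sub_error_rate=0.0, indel_error_rate=0.0,
            )
            res = {r.label: r for r in art.record.known_results}["T315I"]
            assert res.vaf == pytest.approx(f, abs=1e-12)

    def test_mean_vaf_unbiased_over_seeds_at_zero_error(self, panel):
        """Estimator property over 50 seeded replicates at each truth fraction."""
        for f in (0.005, 0.05):
            vafs = []
            for seed in range(50):
                spec = SimulationSpec(
                    "e14a2", [CloneSpec(("T315I",), f)], n_reads=400,
                    sub_error_rate=0.0, indel_error_rate=0.0, seed=seed,
                )
                reads, _ = simulate_reads(spec, panel)
                kept, _ = filter_reads(reads, panel)
                ref = panel.isoforms[0]
                obs = stack_observations(
                    [align_read(r.sequence, ref.sequence, backend="edlib") for r in kept],
                    len(ref),
                )
                res = {r.label: r for r in call_known(obs, panel, ref)}["T315I"]
                vafs.append(res.vaf)
            se_of_mean = np.sqrt(f * (1 - f) / 400 / 50)
            assert abs(np.mean(vafs) - f) <= max(2 * se_of_mean, 1e-12)
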