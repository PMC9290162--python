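import json

import pytest

from clamp.calling import KnownMutationResult, classify
from clamp.errors import ValidationError
from clamp.panel import KnownMutation
from clamp.qc import QCResult
from clamp.results import (
    B_SUPERSET,
    BOTH_NEGATIVE,
    FULL_AGREEMENT,
    CallSet,
    ResultStore,
    SampleRecord,
    compare_call_sets,
    load_call_sets_tsv,
    query_samples,
    render_report,
    store_result,
    validation_cohort_call_sets,
    utc_now_iso,
)


def _record(panel, sample_id="S1", vafs=None, status="ok", timestamp=None):
    """Minimal record with every panel mutation reported (negatives included)."""
    vafs = vafs or {}
    known = [
        KnownMutationResult(
            mutation=m,
            supporting_reads=int(1000 * vafs.get(m.label, 0.0)),
            codon_coverage=1000,
            informative_reads=1000,
            other_reads=0,
            vaf=vafs.get(m.label, 0.0),
            status=classify(vafs.get(m.label, 0.0), panel),
        )
        for m in panel.known_mutations
    ]
    passed = status == "ok"
    return SampleRecord(
        sample_id=sample_id,
        run_timestamp=timestamp or "2024-05-01T10:00:00+00:00",
        status=status,
        isoform_id="e14a2" if passed else None,
        qc=QCResult(passed, 400 if passed else 12, 100,
                    [] if passed else [1, 2, 3]),
        known_results=known if passed else [],
        pipeline_version="1.0.0",
        panel_hash=panel.panel_hash,
    )


class TestStore:
    def test_roundtrip_preserves_every_field(self, panel, tmp_path):
        store_path = tmp_path / "store.jsonl"
        rec = _record(panel, vafs={"T315I": 0.968, "F359C": 0.021})
        rid = store_result(rec, store_path)
        fetched = ResultStore(store_path).get(rid)
        assert fetched.to_dict() == rec.to_dict()
        # canonical serialization is bit-stable
        assert json.dumps(fetched.to_dict(), sort_keys=True) == json.dumps(
            rec.to_dict(), sort_keys=True
        )

    def test_reanalysis_appends_never_overwrites(self, panel, tmp_path):
        store = ResultStore(tmp_path / "store.jsonl")
        r1 = store.append(_record(panel, timestamp="2024-05-01T10:00:00+00:00"))
        r2 = store.append(_record(panel, timestamp="2024-06-01T10:00:00+00:00"))
        assert r1 != r2 and len(store) == 2
        assert {rec.record_id for rec in store.records()} == {r1, r2}

    def test_store_survives_process_style_reopen(self, panel, tmp_path):
        path = tmp_path / "store.jsonl"
        store_result(_record(panel), path)
        assert len(ResultStore(path)) == 1

    def test_thirty_nine_record_fixture_load(self, panel, tmp_path):
        store = ResultStore(tmp_path / "store.jsonl")
        for i in range(1, 40):
            store.append(_record(panel, sample_id=str(i)))
        assert len(store.records()) == 39


class TestQuery:
    @pytest.fixture()
    def cohort_store(self, panel, tmp_path):
        """Store seeded from the packaged validation fixture's long-read calls."""
        _, lrsms = validation_cohort_call_sets()
        store = ResultStore(tmp_path / "store.jsonl")
        panel_labels = set(panel.labels)
        for cs in lrsms:
            vafs = {
                lbl: v / 100.0 for lbl, v in cs.calls
                if lbl in panel_labels and v is not None
            }
            store.append(_record(panel, sample_id=cs.sample_id, vafs=vafs))
        return store

    def test_mutation_filter_at_clinical_level(self, cohort_store):
        hits = query_samples(
            cohort_store, mutation="T315I", status="clinically_reportable"
        )
        assert [r.sample_id for r in hits] == ["1", "2", "10", "12", "14", "15", "16", "24"]

    def test_unknown_label_matches_nothing(self, cohort_store):
        assert query_samples(cohort_store, mutation="Q252H") == []

    def test_no_filter_returns_everything(self, cohort_store):
        assert len(query_samples(cohort_store)) == 39

    def test_date_range_filter(self, panel, tmp_path):
        store = ResultStore(tmp_path / "store.jsonl")
        store.append(_record(panel, timestamp="2024-01-01T00:00:00+00:00"))
        store.append(_record(panel, timestamp="2024-09-01T00:00:00+00:00"))
        hits = query_samples(store, date_from="2024-06-01")
        assert len(hits) == 1 and hits[0].run_timestamp.startswith("2024-09")


class TestRenderReport:
    def test_every_panel_mutation_listed_with_negatives(self, panel):
        rec = _record(panel, vafs={"T315I": 0.31, "F359C": 0.021,
                                   "D276G": 0.015, "H396R": 0.012})
        text = render_report(rec, "text")
        for label in panel.labels:
            assert label in text
        assert text.count("negative") == len(panel.labels) - 4
        assert "clinically_reportable" in text

    def test_vafs_shown_as_percent_one_decimal(self, panel):
        text = render_report(_record(panel, vafs={"T315I": 0.968}), "text")
        assert "96.8" in text

    def test_qc_failed_report_makes_no_negative_claims(self, panel):
        text = render_report(_record(panel, status="qc_failed"), "text")
        assert "QC FAILED" in text
        assert "negative" not in text.lower().replace(
            "no mutation is reported negative", ""
        )

    def test_rerender_is_byte_identical(self, panel):
        rec = _record(panel, vafs={"T315I": 0.5})
        assert render_report(rec, "text") == render_report(rec, "text")
        assert render_report(rec, "html") == render_report(rec, "html")

    def test_html_is_standalone_document(self, panel):
        html = render_report(_record(panel), "html")
        assert html.startswith("<!DOCTYPE html>") and "</html>" in html


class TestConcordance:
    def test_validation_cohort_counts(self):
        """The packaged 39-sample fixture reproduces the published tallies."""
        sanger, lrsms = validation_cohort_call_sets()
        s = compare_call_sets(sanger, lrsms, clinical_cutoff=0.01)
        assert s.n_samples == 39
        assert s.mutations_in_a == 17
        assert s.mutations_in_a_missed_by_b == 0
        assert s.mutations_only_in_b == 16
        assert s.only_in_b_above_clinical == 8
        assert s.samples_both_negative == 21
        assert s.samples_with_mutations == 18
        assert s.samples_full_agreement == 5
        assert s.samples_b_found_more == 13

    def test_self_comparison_has_zero_discordance(self):
        _, lrsms = validation_cohort_call_sets()
        s = compare_call_sets(lrsms, lrsms)
        assert s.mutations_only_in_b == 0 and s.mutations_in_a_missed_by_b == 0
        assert s.samples_b_found_more == 0
        assert s.samples_with_mutations == s.samples_full_agreement

    def test_empty_b_misses_everything_in_a(self):
        a = [CallSet("s1", "m1", (("T315I", None),)), CallSet("s2", "m1", ())]
        b = [CallSet("s1", "m2", ()), CallSet("s2", "m2", ())]
        s = compare_call_sets(a, b)
        assert s.mutations_in_a_missed_by_b == s.mutations_in_a == 1
        assert s.per_sample == {"s1": "other", "s2": BOTH_NEGATIVE}

    def test_bare_codon_label_matches_by_prefix(self):
        a = [CallSet("s1", "m1", (("E255K", None),))]
        b = [CallSet("s1", "m2", (("E255", 1.7),))]
        s = compare_call_sets(a, b)
        assert s.mutations_only_in_b == 0 and s.mutations_in_a_missed_by_b == 0
        assert s.per_sample["s1"] == FULL_AGREEMENT

    def test_bare_label_distinct_when_no_codon_mate(self):
        a = [CallSet("s1", "m1", (("Y253H", None),))]
        b = [CallSet("s1", "m2", (("Y253H", 98.1), ("E255", 1.7)))]
        s = compare_call_sets(a, b)
        assert s.mutations_only_in_b == 1
        assert s.only_in_b_above_clinical == 1
        assert s.per_sample["s1"] == B_SUPERSET

    def test_sample_id_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compare_call_sets(
                [CallSet("s1", "a", ())], [CallSet("s2", "b", ())]
            )

    def test_strictly_above_clinical_cutoff(self):
        a = [CallSet("s1", "m1", ())]
        b = [CallSet("s1", "m2", (("T315I", 1.0), ("M244V", 1.1)))]
        s = compare_call_sets(a, b, clinical_cutoff=0.01)
        assert s.mutations_only_in_b == 2
        assert s.only_in_b_above_clinical == 1  # 1.0% is not above 1%

    def test_tsv_loader_groups_by_method(self, tmp_path):
        p = tmp_path / "calls.tsv"
        p.write_text(
            "sample\tmethod\tlabel\tvaf_percent\n"
            "s1\tx\tT315I\t12.5\n"
            "s1\ty\tT315I\n"
            "s2\tx\t.\n"
            "s2\ty\t.\n"
        )
        sets = load_call_sets_tsv(p)
        assert set(sets) == {"x", "y"}
        x_s1 = next(cs for cs in sets["x"] if cs.sample_id == "s1")
        assert x_s1.calls == (("T315I", 12.5),)
        y_s1 = next(cs for cs in sets["y"] if cs.sample_id == "s1")
        assert y_s1.calls == (("T315I", None),)


def test_utc_timestamp_is_iso8601():
    ts = utc_now_iso()
    assert "T" in ts and ts.endswith("+00:00")
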