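"""Results persistence, clinician-facing reports and assay concordance (step 7).

Per-sample results live in an append-only JSON-Lines store: one canonical
JSON record per line, re-analysis appends a new record and never overwrites.
Reports list EVERY catalogued mutation — negatives included, because "tested
and negative" is a clinical statement — except after a QC failure, where no
negative claim is made at all.

The concordance surface compares a reference call set without frequencies
(Sanger-style) against a frequency-bearing call set (the long-read pipeline)
per sample and in aggregate. A bare codon label like ``E255`` (alternate
amino acid unresolved) matches any label on the other side that shares its
wild-type amino acid and codon number.
"""
from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Sequence

from .calling import CallStatus, KnownMutationResult, VariantCall
from .errors import ValidationError
from .panel import KnownMutation
from .phasing import Clone, CloneTable
from .qc import QCResult
from .read_prep import FilterStats

logger = logging.getLogger(__name__)

_FULL_LABEL = re.compile(r"^([A-Z])(\d+)([A-Z*])$")
_BARE_LABEL = re.compile(r"^([A-Z])(\d+)$")


# ---------------------------------------------------------------------------
# Sample records and the JSON-Lines store
# ---------------------------------------------------------------------------

@dataclass
class SampleRecord:
    sample_id: str
    run_timestamp: str                       # ISO-8601, UTC
    status: str                              # "ok" | "qc_failed"
    isoform_id: str | None
    qc: QCResult
    known_results: list[KnownMutationResult] = field(default_factory=list)
    de_novo: list[VariantCall] = field(default_factory=list)
    clones: CloneTable | None = None
    filter_stats: FilterStats | None = None
    isoform_votes: list[dict] = field(default_factory=list)
    n_partial_reads: int = 0
    pipeline_version: str = ""
    panel_hash: str = ""
    record_id: str | None = None             # assigned by the store

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "sample_id": self.sample_id,
            "run_timestamp": self.run_timestamp,
            "status": self.status,
            "isoform_id": self.isoform_id,
            "qc": self.qc.to_dict(),
            "known_results": [r.to_dict() for r in self.known_results],
            "de_novo": [c.to_dict() for c in self.de_novo],
            "clones": self.clones.to_dict() if self.clones is not None else None,
            "filter_stats": self.filter_stats.to_dict() if self.filter_stats else None,
            "isoform_votes": self.isoform_votes,
            "n_partial_reads": self.n_partial_reads,
            "pipeline_version": self.pipeline_version,
            "panel_hash": self.panel_hash,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SampleRecord":
        qc_d = d["qc"]
        qc = QCResult(
            passed=qc_d["passed"],
            min_observed_coverage=qc_d["min_observed_coverage"],
            threshold_used=qc_d["threshold_used"],
            failing_positions=list(qc_d.get("failing_positions", [])),
        )
        known = [
            KnownMutationResult(
                mutation=KnownMutation.from_label(r["label"]),
                supporting_reads=r["supporting_reads"],
                codon_coverage=r["codon_coverage"],
                informative_reads=r["informative_reads"],
                other_reads=r["other_reads"],
                vaf=r["vaf"],
                status=CallStatus(r["status"]),
            )
            for r in d.get("known_results", [])
        ]
        de_novo = [
            VariantCall(
                position=c["position"],
                ref_base=c["ref_base"],
                alt_base=c["alt_base"],
                alt_count=c["alt_count"],
                coverage=c["coverage"],
                vaf=c["vaf"],
                aa_label=c["aa_label"],
                known=c["known"],
                status=CallStatus(c["status"]),
            )
            for c in d.get("de_novo", [])
        ]
        clones = None
        if d.get("clones") is not None:
            cd = d["clones"]
            clones = CloneTable(
                sites=list(cd["sites"]),
                clones=[
                    Clone(tuple(c["mutations"]), c["read_count"], c["fraction"])
                    for c in cd["clones"]
                ],
                n_informative_reads=cd["n_informative_reads"],
                n_dropped_reads=cd.get("n_dropped_reads", 0),
                available=cd.get("available", True),
            )
        fs = None
        if d.get("filter_stats") is not None:
            fd = d["filter_stats"]
            fs = FilterStats(fd["total"], fd["kept"], dict(fd["rejections"]))
        return cls(
            sample_id=d["sample_id"],
            run_timestamp=d["run_timestamp"],
            status=d["status"],
            isoform_id=d.get("isoform_id"),
            qc=qc,
            known_results=known,
            de_novo=de_novo,
            clones=clones,
            filter_stats=fs,
            isoform_votes=list(d.get("isoform_votes", [])),
            n_partial_reads=d.get("n_partial_reads", 0),
            pipeline_version=d.get("pipeline_version", ""),
            panel_hash=d.get("panel_hash", ""),
            record_id=d.get("record_id"),
        )


def utc_now_iso() -> str:
    return datetime.now(timezone.utc).replace(microsecond=0).isoformat()


class ResultStore:
    """Append-only JSON-Lines store of :class:`SampleRecord` objects."""

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def append(self, record: SampleRecord) -> str:
        existing = self._read_all()
        record_id = f"r{len(existing) + 1:06d}"
        payload = record.to_dict()
        payload["record_id"] = record_id
        canonical = json.dumps(payload, sort_keys=True, separators=(",", ":"))
        for old in existing:
            old_cmp = dict(old)
            new_cmp = dict(payload)
            old_cmp.pop("record_id"), new_cmp.pop("record_id")
            if old_cmp == new_cmp:
                logger.warning(
                    "record for sample %s duplicates %s; stored anyway as %s",
                    record.sample_id, old.get("record_id"), record_id,
                )
                break
        try:
            with open(self.path, "a") as fh:
                fh.write(canonical + "\n")
        except OSError as exc:
            raise OSError(f"cannot write results store {self.path}: {exc}") from exc
        record.record_id = record_id
        return record_id

    def _read_all(self) -> list[dict]:
        if not self.path.exists():
            return []
        out = []
        with open(self.path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    out.append(json.loads(line))
        return out

    def records(self) -> list[SampleRecord]:
        return [SampleRecord.from_dict(d) for d in self._read_all()]

    def get(self, record_id: str) -> SampleRecord:
        for rec in self.records():
            if rec.record_id == record_id:
                return rec
        raise KeyError(f"no record {record_id!r} in {self.path}")

    def __len__(self) -> int:
        return len(self._read_all())


def store_result(record: SampleRecord, store_path: str | Path) -> str:
    """Append one record; returns the assigned record id."""
    return ResultStore(store_path).append(record)


def query_samples(
    store: ResultStore,
    sample_id: str | None = None,
    mutation: str | None = None,
    status: str | None = None,
    date_from: str | None = None,
    date_to: str | None = None,
) -> list[SampleRecord]:
    """Filter stored records; deterministic order (sample id, then timestamp).

    The ``mutation`` filter matches records with a positive or clinically
    reportable call of that label; combined with ``status`` it narrows to
    that class only.
    """
    matching = []
    for rec in store.records():
        if sample_id is not None and rec.sample_id != sample_id:
            continue
        if date_from is not None and rec.run_timestamp < date_from:
            continue
        if date_to is not None and rec.run_timestamp > date_to:
            continue
        if mutation is not None or status is not None:
            wanted = {CallStatus.POSITIVE, CallStatus.CLINICALLY_REPORTABLE}
            if status is not None:
                wanted &= {CallStatus(status)}
            hits = [
                r for r in rec.known_results
                if r.status in wanted and (mutation is None or r.label == mutation)
            ] + [
                c for c in rec.de_novo
                if c.status in wanted and (mutation is None or c.aa_label == mutation)
            ]
            if not hits:
                continue
        matching.append(rec)
    matching.sort(key=lambda r: (_natural_sample_key(r.sample_id), r.run_timestamp))
    return matching


def _natural_sample_key(sample_id: str):
    return (0, int(sample_id)) if sample_id.isdigit() else (1, sample_id)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def render_report(record: SampleRecord, format: str = "text") -> str:
    """Render one sample's clinician-facing report (deterministic)."""
    if format == "text":
        return _render_text(record)
    if format == "html":
        return _render_html(record)
    raise ValidationError(f"unknown report format {format!r}")


def _vaf_pct(vaf: float) -> str:
    return f"{100.0 * vaf:.1f}"


def _render_text(record: SampleRecord) -> str:
    lines = []
    w = lines.append
    w("=" * 64)
    w(f"Sample report: {record.sample_id}")
    w(f"Analyzed:      {record.run_timestamp}")
    w(f"Isoform:       {record.isoform_id or 'n/a'}")
    w(f"Pipeline:      v{record.pipeline_version}   panel {record.panel_hash}")
    w("=" * 64)
    qc = record.qc
    if record.status == "qc_failed":
        w("")
        w("*** QC FAILED — ANALYSIS ABORTED ***")
        w(f"Minimum observed coverage {qc.min_observed_coverage} is below the")
        w(f"required {qc.threshold_used} reads at {len(qc.failing_positions)} position(s).")
        w("No mutation is reported negative: insufficient coverage cannot")
        w("support an absence claim.")
        w("=" * 64)
        return "\n".join(lines) + "\n"

    w(f"QC: PASSED (minimum coverage {qc.min_observed_coverage} >= {qc.threshold_used})")
    if record.filter_stats is not None:
        fs = record.filter_stats
        w(f"Reads: {fs.total} total, {fs.kept} on-target, {fs.rejected} rejected, "
          f"{record.n_partial_reads} partial")
    w("")
    w("Known resistance mutations")
    w(f"  {'mutation':<10}{'VAF %':>8}  {'reads':>7}  status")
    for r in record.known_results:
        marker = " *" if r.status is not CallStatus.NEGATIVE else ""
        w(f"  {r.label:<10}{_vaf_pct(r.vaf):>8}  {r.supporting_reads:>7}  "
          f"{r.status.value}{marker}")
    novel = [c for c in record.de_novo if not c.known]
    w("")
    if novel:
        w("De novo substitutions")
        w(f"  {'site':<14}{'VAF %':>8}  {'reads':>7}  status")
        for c in novel:
            site = f"{c.position}{c.ref_base}>{c.alt_base}"
            aa = f" ({c.aa_label})" if c.aa_label else ""
            w(f"  {site + aa:<14}{_vaf_pct(c.vaf):>8}  {c.alt_count:>7}  {c.status.value}")
    else:
        w("De novo substitutions: none")
    w("")
    if record.clones is not None and record.clones.available:
        w("Clonal distribution (informative reads: "
          f"{record.clones.n_informative_reads})")
        for clone in record.clones.clones:
            name = " + ".join(clone.mutations) if clone.mutations else "wild type"
            bar = "#" * max(1, round(40 * clone.fraction)) if clone.read_count else ""
            w(f"  {name:<24}{clone.fraction * 100:>6.1f}%  {bar}")
    elif record.clones is not None:
        w("Clonal distribution: no informative reads")
    else:
        w("Clonal distribution: not applicable (< 2 positive mutations)")
    w("=" * 64)
    return "\n".join(lines) + "\n"


def _render_html(record: SampleRecord) -> str:
    body = _render_text(record)
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        f"<title>Sample {record.sample_id}</title></head>\n"
        "<body><pre>\n" + body + "</pre></body></html>\n"
    )


# ---------------------------------------------------------------------------
# Concordance between two call sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CallSet:
    """One sample's mutation calls from one method; Sanger-style sets carry
    no frequencies (``vaf_percent`` None)."""

    sample_id: str
    method: str
    calls: tuple[tuple[str, float | None], ...]  # (label, vaf in percent or None)

    def __post_init__(self) -> None:
        labels = [lbl for lbl, _ in self.calls]
        if len(set(labels)) != len(labels):
            raise ValidationError(
                f"duplicate labels in call set {self.sample_id}/{self.method}"
            )

    @property
    def labels(self) -> list[str]:
        return [lbl for lbl, _ in self.calls]


BOTH_NEGATIVE = "both_negative"
FULL_AGREEMENT = "full_agreement"
B_SUPERSET = "b_superset"
OTHER = "other"


@dataclass
class ConcordanceSummary:
    n_samples: int
    per_sample: dict[str, str]
    mutations_in_a: int
    mutations_only_in_b: int
    only_in_b_above_clinical: int
    samples_both_negative: int
    samples_with_mutations: int
    samples_full_agreement: int
    samples_b_found_more: int
    mutations_in_a_missed_by_b: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _label_parts(label: str) -> tuple[str, int, str | None]:
    m = _FULL_LABEL.match(label)
    if m:
        return m.group(1), int(m.group(2)), m.group(3)
    m = _BARE_LABEL.match(label)
    if m:
        return m.group(1), int(m.group(2)), None
    raise ValidationError(f"malformed call label {label!r}")


def _labels_match(x: str, y: str) -> bool:
    """Exact match, or codon-prefix match when either side lacks an alternate."""
    if x == y:
        return True
    rx, cx, ax = _label_parts(x)
    ry, cy, ay = _label_parts(y)
    return rx == ry and cx == cy and (ax is None or ay is None)


def compare_call_sets(
    a: Sequence[CallSet],
    b: Sequence[CallSet],
    clinical_cutoff: float = 0.01,
) -> ConcordanceSummary:
    """Aggregate agreement between a reference method ``a`` (frequency-free)
    and a frequency-bearing method ``b`` over the same samples.

    ``mutations_only_in_b`` counts b's calls at full sensitivity (every
    listed call); ``only_in_b_above_clinical`` additionally requires
    VAF strictly above the clinical cutoff.
    """
    a_by_sample = {cs.sample_id: cs for cs in a}
    b_by_sample = {cs.sample_id: cs for cs in b}
    if set(a_by_sample) != set(b_by_sample):
        raise ValidationError("call sets must cover the same sample ids")
    if len(a_by_sample) != len(a) or len(b_by_sample) != len(b):
        raise ValidationError("duplicate sample ids in a call-set list")

    per_sample: dict[str, str] = {}
    mutations_in_a = 0
    only_in_b = 0
    only_in_b_clinical = 0
    a_missed = 0
    cutoff_pct = 100.0 * clinical_cutoff

    for sid, cs_a in a_by_sample.items():
        cs_b = b_by_sample[sid]
        a_labels = cs_a.labels
        b_calls = list(cs_b.calls)
        mutations_in_a += len(a_labels)

        b_extra = [
            (lbl, vaf) for lbl, vaf in b_calls
            if not any(_labels_match(lbl, al) for al in a_labels)
        ]
        a_unmatched = [
            al for al in a_labels
            if not any(_labels_match(al, bl) for bl, _ in b_calls)
        ]
        only_in_b += len(b_extra)
        only_in_b_clinical += sum(
            1 for _, vaf in b_extra if vaf is not None and vaf > cutoff_pct
        )
        a_missed += len(a_unmatched)

        if not a_labels and not b_calls:
            per_sample[sid] = BOTH_NEGATIVE
        elif not a_unmatched and not b_extra:
            per_sample[sid] = FULL_AGREEMENT
        elif not a_unmatched:
            per_sample[sid] = B_SUPERSET
        else:
            per_sample[sid] = OTHER

    classes = list(per_sample.values())
    return ConcordanceSummary(
        n_samples=len(per_sample),
        per_sample=per_sample,
        mutations_in_a=mutations_in_a,
        mutations_only_in_b=only_in_b,
        only_in_b_above_clinical=only_in_b_clinical,
        samples_both_negative=classes.count(BOTH_NEGATIVE),
        samples_with_mutations=len(classes) - classes.count(BOTH_NEGATIVE),
        samples_full_agreement=classes.count(FULL_AGREEMENT),
        samples_b_found_more=classes.count(B_SUPERSET),
        mutations_in_a_missed_by_b=a_missed,
    )


def load_call_sets_tsv(
    path: str | Path, method: str | None = None
) -> dict[str, list[CallSet]]:
    """Read a call-set table (columns: sample, method, label, vaf_percent).

    A label of ``.`` marks a sample reported mutation-free by that method.
    Returns call sets grouped by method name (optionally restricted to one).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample", "method", "label"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: call-set table needs columns {sorted(required)}"
        )
    grouped: dict[str, dict[str, list[tuple[str, float | None]]]] = {}
    for row in df.itertuples(index=False):
        meth = row.method
        if method is not None and meth != method:
            continue
        calls = grouped.setdefault(meth, {}).setdefault(row.sample, [])
        if row.label != ".":
            vaf_raw = getattr(row, "vaf_percent", "")
            vaf = float(vaf_raw) if vaf_raw not in ("", None) else None
            calls.append((row.label, vaf))
    return {
        meth: [
            CallSet(sid, meth, tuple(calls)) for sid, calls in samples.items()
        ]
        for meth, samples in grouped.items()
    }


def validation_cohort_call_sets() -> tuple[list[CallSet], list[CallSet]]:
    """The packaged validation-cohort fixture: (reference method, long-read)."""
    with resources.as_file(resources.files("clamp.data") / "validation_cohort_calls.tsv") as p:
        sets = load_call_sets_tsv(p)
    return sets["sanger"], sets["lrsms"]
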