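"""End-to-end per-sample orchestration of the analysis workflow.

Runs the seven-stage amplicon analysis on one sample's reads: primer filter,
reference-isoform assignment, alignment + pileup, coverage QC (with
controlled abort), de novo substitution scan, catalogued-mutation calling,
and — when at least two mutations are positive — clonal phasing. The result
is a :class:`clamp.results.SampleRecord` ready for the append-only store.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from . import __version__
from .align import (
    DEFAULT_SCORING,
    Pileup,
    Scoring,
    align_reads,
    build_pileup,
    is_partial,
    stack_observations,
)
from .calling import call_known, positive_results, scan_de_novo
from .isoform import DEFAULT_SAMPLE_CAP, assign_reference
from .panel import AmpliconPanel
from .phasing import clonal_distribution, extract_haplotypes
from .qc import QCResult, check_coverage
from .read_prep import RawRead, filter_reads, read_fastq
from .results import SampleRecord, utc_now_iso

#: Alignments spanning less than this fraction of the reference are treated as
#: partial (truncated/chimeric molecules) and excluded from pileup and phasing.
MIN_REF_SPAN_FRACTION = 0.5


@dataclass
class RunArtifacts:
    """Intermediate objects kept alongside the record for export/inspection."""

    record: SampleRecord
    pileup: Pileup | None = None
    obs_matrix: np.ndarray | None = None


def run_sample(
    reads: Iterable[RawRead] | str | Path,
    panel: AmpliconPanel,
    sample_id: str,
    seed: int = 0,
    scoring: Scoring = DEFAULT_SCORING,
    backend: str = "edlib",
    sample_cap: int = DEFAULT_SAMPLE_CAP,
    min_ref_span: float = MIN_REF_SPAN_FRACTION,
    timestamp: str | None = None,
) -> RunArtifacts:
    """Analyze one sample; never raises on QC failure (returns a qc_failed record)."""
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    kept, stats = filter_reads(reads, panel)
    timestamp = timestamp or utc_now_iso()

    def failed(qc: QCResult, isoform_id: str | None) -> RunArtifacts:
        return RunArtifacts(
            SampleRecord(
                sample_id=sample_id,
                run_timestamp=timestamp,
                status="qc_failed",
                isoform_id=isoform_id,
                qc=qc,
                filter_stats=stats,
                pipeline_version=__version__,
                panel_hash=panel.panel_hash,
            )
        )

    if not kept:
        qc = QCResult(
            passed=False,
            min_observed_coverage=0,
            threshold_used=panel.min_coverage,
            failing_positions=list(range(1, len(panel.isoforms[0].sequence) + 1)),
        )
        return failed(qc, None)

    ref, votes, tie = assign_reference(
        kept, panel, sample_cap=sample_cap, seed=seed, scoring=scoring, backend=backend
    )
    vote_dicts = [v.to_dict() for v in votes]
    if tie:
        vote_dicts.append({"note": "vote tie resolved by panel order"})

    alignments = align_reads(kept, ref, scoring, backend)
    full = [a for a in alignments if not is_partial(a, len(ref), min_ref_span)]
    n_partial = len(alignments) - len(full)
    pileup = build_pileup(full, len(ref))
    obs = stack_observations(full, len(ref))

    qc = check_coverage(pileup, panel.min_coverage)
    if not qc.passed:
        art = failed(qc, ref.isoform_id)
        art.record.isoform_votes = vote_dicts
        art.record.n_partial_reads = n_partial
        art.pileup = pileup
        return art

    de_novo = scan_de_novo(pileup, ref, panel)
    known = call_known(obs, panel, ref)

    clones = None
    positives = positive_results(known)
    if len(positives) >= 2:
        read_ids = [a.read_id for a in full]
        haplotypes = extract_haplotypes(obs, positives, ref, read_ids)
        clones = clonal_distribution(haplotypes, [r.label for r in positives])

    record = SampleRecord(
        sample_id=sample_id,
        run_timestamp=timestamp,
        status="ok",
        isoform_id=ref.isoform_id,
        qc=qc,
        known_results=known,
        de_novo=de_novo,
        clones=clones,
        filter_stats=stats,
        isoform_votes=vote_dicts,
        n_partial_reads=n_partial,
        pipeline_version=__version__,
        panel_hash=panel.panel_hash,
    )
    return RunArtifacts(record, pileup, obs)
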