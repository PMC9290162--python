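"""Dominant-isoform determination (workflow step 2).

Samples differ slightly in exon usage of the fusion transcript, so the panel
carries one reference per candidate isoform. A seeded random subsample of the
kept reads (default 500) is scored against every candidate; each read votes
for its best-scoring isoform and the majority wins, with ties broken by panel
order. The chosen isoform becomes the sample's reference for alignment,
calling and phasing. Minority-isoform reads are NOT discarded: they simply
align to the chosen reference with gaps.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .align import DEFAULT_SCORING, Scoring, align_read
from .errors import AssignmentError
from .panel import AmpliconPanel, IsoformReference
from .read_prep import OrientedRead

DEFAULT_SAMPLE_CAP = 500


@dataclass
class IsoformVote:
    isoform_id: str
    votes: int
    mean_score: float | None  # average alignment score over the sampled reads

    def to_dict(self) -> dict:
        return {
            "isoform_id": self.isoform_id,
            "votes": self.votes,
            "mean_score": self.mean_score,
        }


def score_read(
    read: OrientedRead,
    ref: IsoformReference,
    scoring: Scoring = DEFAULT_SCORING,
    backend: str = "edlib",
) -> int:
    """Semi-global alignment score of ``read`` against ``ref`` (higher is better)."""
    return align_read(read, ref, scoring, backend=backend).score


def assign_reference(
    reads: Sequence[OrientedRead],
    panel: AmpliconPanel,
    sample_cap: int = DEFAULT_SAMPLE_CAP,
    seed: int = 0,
    scoring: Scoring = DEFAULT_SCORING,
    backend: str = "edlib",
) -> tuple[IsoformReference, list[IsoformVote], bool]:
    """Pick the sample's reference isoform by per-read best-score majority vote.

    Returns ``(chosen, votes, tie)`` where ``tie`` flags an exact vote tie
    resolved by panel order. Single-isoform panels skip scoring entirely.
    Raises :class:`AssignmentError` on an empty read set (the pipeline aborts).
    """
    if not reads:
        raise AssignmentError("cannot assign a reference isoform from zero reads")
    if len(panel.isoforms) == 1:
        iso = panel.isoforms[0]
        return iso, [IsoformVote(iso.isoform_id, len(reads), None)], False

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))[: min(len(reads), sample_cap)]
    sampled = [reads[i] for i in order]

    scores = np.empty((len(sampled), len(panel.isoforms)), dtype=np.int64)
    for j, iso in enumerate(panel.isoforms):
        scores[:, j] = [score_read(r, iso, scoring, backend) for r in sampled]
    winners = np.argmax(scores, axis=1)  # argmax ties -> lowest index = panel order

    votes = [
        IsoformVote(
            iso.isoform_id,
            int(np.count_nonzero(winners == j)),
            float(scores[:, j].mean()),
        )
        for j, iso in enumerate(panel.isoforms)
    ]
    counts = np.array([v.votes for v in votes])
    best = int(np.argmax(counts))
    tie = bool(np.count_nonzero(counts == counts[best]) > 1)
    return panel.isoforms[best], votes, tie
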