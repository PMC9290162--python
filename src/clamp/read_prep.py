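"""Primer filtering and read orientation (workflow step 1).

Only reads carrying both expected primers — the forward primer at the 5' end
and the reverse complement of the reverse primer at the 3' end, in either
strand orientation — belong to the targeted amplicon; everything else is
rejected with a reason. Kept reads are put on the reference strand and both
primer spans are trimmed so that primer-synthesis errors can never surface as
variant sites.

Primer matching is anchored: only the terminal ``len(primer)`` bases are
compared, by Hamming distance, with a configurable mismatch tolerance
(panel default 2). ``N`` counts as a mismatch.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import ValidationError
from .panel import AmpliconPanel

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Rejection reasons emitted by :func:`orient_and_trim`.
NO_5PRIME = "no_5prime_primer"
NO_3PRIME = "no_3prime_primer"
BOTH_FAIL = "both_orientations_fail"
EMPTY_AFTER_TRIM = "empty_after_trim"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RawRead:
    read_id: str
    sequence: str
    qualities: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"read {self.read_id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValidationError(f"read {self.read_id!r}: quality/sequence length mismatch")


@dataclass(frozen=True)
class OrientedRead:
    """A primer-trimmed read on the reference strand."""

    read_id: str
    sequence: str
    original_orientation: str  # "forward" | "reverse"


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str


@dataclass(frozen=True)
class PrimerMatch:
    matched: bool
    mismatches: int


def match_primer(window: str, primer: str, max_mismatches: int) -> PrimerMatch:
    """Anchored Hamming comparison of ``primer`` against an equal-length window.

    A window shorter than the primer never matches. Total function: no errors.
    """
    if len(window) < len(primer):
        return PrimerMatch(False, len(primer))
    window = window[: len(primer)].upper()
    mism = sum(1 for a, b in zip(window, primer) if a != b)
    return PrimerMatch(mism <= max_mismatches, mism)


def orient_and_trim(read: RawRead, panel: AmpliconPanel) -> OrientedRead | Rejection:
    """Test forward then reverse layout; return the trimmed on-strand read.

    Forward layout: forward primer at the 5' end and the reverse complement of
    the reverse primer at the 3' end. Reverse layout: the reverse complement
    of the read satisfies the forward layout.
    """
    fwd = panel.forward_primer
    rev_rc = revcomp(panel.reverse_primer)
    tol = panel.max_primer_mismatches
    seq = read.sequence.upper()

    five_seen = False
    for orientation, s in (("forward", seq), ("reverse", revcomp(seq))):
        m5 = match_primer(s[: len(fwd)], fwd, tol)
        if not m5.matched:
            continue
        five_seen = True
        m3 = match_primer(s[len(s) - len(rev_rc):], rev_rc, tol)
        if not m3.matched:
            continue
        insert = s[len(fwd): len(s) - len(rev_rc)]
        if not insert:
            return Rejection(read.read_id, EMPTY_AFTER_TRIM)
        return OrientedRead(read.read_id, insert, orientation)

    if not five_seen:
        return Rejection(read.read_id, NO_5PRIME)
    # Some orientation anchored its 5' primer but lacked the 3' one.
    return Rejection(read.read_id, NO_3PRIME)


@dataclass
class FilterStats:
    total: int = 0
    kept: int = 0
    rejections: dict[str, int] = field(default_factory=dict)

    @property
    def rejected(self) -> int:
        return sum(self.rejections.values())

    def to_dict(self) -> dict:
        return {"total": self.total, "kept": self.kept, "rejections": dict(self.rejections)}


def filter_reads(
    reads: Iterable[RawRead], panel: AmpliconPanel
) -> tuple[list[OrientedRead], FilterStats]:
    """Keep on-target reads (input order preserved) and tally rejection reasons.

    Conservation: ``stats.total == stats.kept + stats.rejected``. An empty
    input yields an empty result — downstream coverage QC then aborts the run.
    """
    kept: list[OrientedRead] = []
    stats = FilterStats()
    for read in reads:
        stats.total += 1
        result = orient_and_trim(read, panel)
        if isinstance(result, OrientedRead):
            kept.append(result)
            stats.kept += 1
        else:
            stats.rejections[result.reason] = stats.rejections.get(result.reason, 0) + 1
    return kept, stats


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Stream a FASTQ file (plain or gzipped) as :class:`RawRead` records."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            quals = rec.letter_annotations.get("phred_quality")
            qual_str = (
                "".join(chr(min(q, 93) + 33) for q in quals) if quals is not None else None
            )
            yield RawRead(rec.id, str(rec.seq).upper(), qual_str)


def write_fastq(reads: Iterable[RawRead], path: str | Path) -> int:
    """Write reads as plain FASTQ; returns the number written."""
    path = Path(path)
    n = 0
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as out:
        for read in reads:
            qual = read.qualities or "I" * len(read.sequence)
            out.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n
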