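"""Semi-global read-to-reference alignment and base-count pileup.

Alignment shape: the whole read must align, while reference positions outside
the read's span are free (free end-gaps on the reference side). This is the
correct geometry for primer-trimmed amplicon reads, which are near-full-length
copies of the reference. Gap costs are affine with the opening penalty charged
on the first gapped base: a gap of length g costs ``gap_open + (g-1) *
gap_extend``.

Two backends produce identical aligned-pair semantics:

``dp``
    Exact affine-gap dynamic programming (Gotoh), numpy-vectorized per row.
    Deterministic traceback with ties broken match/mismatch > deletion >
    insertion. This is the definitional aligner.
``edlib``
    Edit-distance alignment (infix mode) via the edlib library, converted to
    the same observation encoding and re-scored under the affine scheme. For
    high-accuracy reads the paths coincide with the DP paths up to gap
    placement inside homopolymers; orders of magnitude faster, used by the
    pipeline by default.

Observations are encoded as small integers: A=0 C=1 G=2 T=3 N=4 deletion=5.
Deletions count toward coverage (the molecule was observed across the locus);
insertions are tabulated in a side table and never become substitution calls.
"""
from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import PipelineError, ValidationError
from .panel import IsoformReference
from .read_prep import OrientedRead

# Observation codes.
A, C, G, T, N, DEL = range(6)
OBS_CHARS = "ACGTN-"
NOT_COVERED = 255

_ENCODE_LUT = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i
_DECODE = np.frombuffer(OBS_CHARS.encode(), dtype=np.uint8)

NEG_INF = np.int32(-(10 ** 8))


def encode_bases(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (anything outside ACGT becomes N)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_bases(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class Scoring:
    """Affine alignment scores; ``gap_open`` includes the first gapped base."""

    match: int = 2
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0):
            # The single-pass gap recurrence assumes opening is never cheaper
            # than extending.
            raise ValidationError("scoring requires gap_open <= gap_extend <= 0")
        if self.match <= 0 or self.mismatch >= 0:
            raise ValidationError("scoring requires match > 0 > mismatch")


DEFAULT_SCORING = Scoring()


@dataclass
class ReadAlignment:
    """One read aligned to the reference.

    ``obs`` holds the observation code for every reference position in the
    contiguous run ``ref_start..ref_end`` (1-based inclusive). Insertions are
    kept as ``(after_position, inserted_sequence)`` with ``after_position`` 0
    meaning before the first reference base.
    """

    read_id: str
    ref_start: int
    obs: np.ndarray
    insertions: list[tuple[int, str]] = field(default_factory=list)
    score: int = 0

    @property
    def ref_end(self) -> int:
        return self.ref_start + len(self.obs) - 1

    @property
    def aligned_pairs(self) -> dict[int, str]:
        """Mapping reference position -> observed character (tests/debugging)."""
        return {
            self.ref_start + i: OBS_CHARS[code] for i, code in enumerate(self.obs)
        }

    def span_fraction(self, ref_length: int) -> float:
        return len(self.obs) / ref_length


def is_partial(alignment: ReadAlignment, ref_length: int, min_fraction: float = 0.5) -> bool:
    """Flag truncated/chimeric molecules whose alignment spans too little reference."""
    return alignment.span_fraction(ref_length) < min_fraction


# ---------------------------------------------------------------------------
# Exact affine-gap DP backend
# ---------------------------------------------------------------------------

def _dp_matrices(read_codes: np.ndarray, ref_codes: np.ndarray, sc: Scoring):
    """Fill Gotoh matrices H/E/F for semi-global alignment (free ref end-gaps).

    E ends in a gap consuming reference (deletion in the read), F in a gap
    consuming read bases (insertion). Row-wise vectorization; the horizontal
    E recurrence is resolved with a prefix-maximum scan, valid because
    gap_open <= gap_extend makes split gaps never optimal.
    """
    n, m = len(read_codes), len(ref_codes)
    H = np.empty((n + 1, m + 1), dtype=np.int32)
    E = np.empty((n + 1, m + 1), dtype=np.int32)
    F = np.empty((n + 1, m + 1), dtype=np.int32)
    H[0, :] = 0                      # leading reference positions are free
    E[0, :] = NEG_INF
    F[0, :] = NEG_INF
    open_, ext = np.int32(sc.gap_open), np.int32(sc.gap_extend)
    # substitution score matrix lookup: match only when both are ACGT and equal
    j_idx = np.arange(1, m + 1)
    for i in range(1, n + 1):
        rc = read_codes[i - 1]
        if rc <= T:
            subst = np.where(ref_codes == rc, sc.match, sc.mismatch).astype(np.int32)
        else:  # N in the read scores as mismatch everywhere
            subst = np.full(m, sc.mismatch, dtype=np.int32)
        F[i, :] = np.maximum(H[i - 1, :] + open_, F[i - 1, :] + ext)
        diag = H[i - 1, :m] + subst
        # E[i, j] = max_{k<j} S[k] + open + (j-1-k)*ext,  S = best non-E state
        S = np.empty(m + 1, dtype=np.int64)
        S[0] = F[i, 0]
        S[1:] = np.maximum(diag, F[i, 1:])
        running = np.maximum.accumulate(S[:-1] - np.arange(m) * ext)
        E[i, 0] = NEG_INF
        E[i, 1:] = running + open_ + (j_idx - 1) * ext
        H[i, 0] = F[i, 0]
        H[i, 1:] = np.maximum(np.maximum(diag, E[i, 1:]), F[i, 1:])
    return H, E, F


def _dp_traceback(
    read_codes: np.ndarray, ref_codes: np.ndarray, H, E, F, sc: Scoring
) -> tuple[int, np.ndarray, list[tuple[int, str]], int]:
    """Deterministic traceback: match/mismatch preferred, then deletion, then insertion."""
    n, m = len(read_codes), len(ref_codes)
    end_j = int(np.argmax(H[n, :]))  # leftmost maximum -> smallest trailing free gap span
    score = int(H[n, end_j])
    i, j = n, end_j
    state = "H"
    obs_rev: list[tuple[int, int]] = []           # (ref position 1-based, code)
    ins_rev: list[tuple[int, int]] = []           # (after ref position, read index)
    open_, ext = sc.gap_open, sc.gap_extend
    while i > 0:
        if state == "H":
            if j == 0:
                state = "F"
                continue
            rc = read_codes[i - 1]
            s = sc.match if (rc <= T and rc == ref_codes[j - 1]) else sc.mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                obs_rev.append((j, int(rc)))
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            elif H[i, j] == F[i, j]:
                state = "F"
            else:  # pragma: no cover - DP invariant
                raise PipelineError("alignment traceback lost")
        elif state == "E":  # gap consuming reference: deletion observation
            obs_rev.append((j, DEL))
            if j >= 1 and E[i, j] == H[i, j - 1] + open_:
                state = "H"
            j -= 1
        else:  # state == "F": gap consuming read: insertion
            ins_rev.append((j, i - 1))
            if F[i, j] == H[i - 1, j] + open_:
                state = "H"
            i -= 1

    if obs_rev:
        first = obs_rev[-1][0]
        last = obs_rev[0][0]
        obs = np.full(last - first + 1, DEL, dtype=np.uint8)
        for pos, code in obs_rev:
            obs[pos - first] = code
        ref_start = first
    else:  # read aligned entirely as an insertion (degenerate)
        obs = np.empty(0, dtype=np.uint8)
        ref_start = max(j, 0) + 1

    # group consecutive inserted read bases into runs
    insertions: list[tuple[int, str]] = []
    for after_pos, ridx in reversed(ins_rev):
        base = OBS_CHARS[read_codes[ridx]]
        if insertions and insertions[-1][0] == after_pos:
            insertions[-1] = (after_pos, insertions[-1][1] + base)
        else:
            insertions.append((after_pos, base))
    return ref_start, obs, insertions, score


def _align_dp(read_id: str, read_seq: str, ref_seq: str, sc: Scoring) -> ReadAlignment:
    read_codes = encode_bases(read_seq)
    ref_codes = encode_bases(ref_seq)
    H, E, F = _dp_matrices(read_codes, ref_codes, sc)
    ref_start, obs, insertions, score = _dp_traceback(read_codes, ref_codes, H, E, F, sc)
    return ReadAlignment(read_id, ref_start, obs, insertions, score)


# ---------------------------------------------------------------------------
# edlib fast backend
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _align_edlib(read_id: str, read_seq: str, ref_seq: str, sc: Scoring) -> ReadAlignment:
    import edlib

    res = edlib.align(read_seq, ref_seq, mode="HW", task="path")
    start0, _ = res["locations"][0]
    cigar = res["cigar"]
    read_codes = encode_bases(read_seq)

    ref_start = start0 + 1
    obs_parts: list[np.ndarray] = []
    insertions: list[tuple[int, str]] = []
    score = 0
    ri = 0                      # read cursor
    rpos = start0               # 0-based reference cursor
    for num, op in _CIGAR_RE.findall(cigar):
        k = int(num)
        if op in "=XM":
            obs_parts.append(read_codes[ri: ri + k])
            if op == "=":
                score += k * sc.match
            elif op == "X":
                score += k * sc.mismatch
            else:  # 'M': compare explicitly
                seg = read_codes[ri: ri + k]
                refseg = encode_bases(ref_seq[rpos: rpos + k])
                matches = int(np.count_nonzero((seg == refseg) & (seg <= T)))
                score += matches * sc.match + (k - matches) * sc.mismatch
            ri += k
            rpos += k
        elif op == "D":         # reference bases absent from the read: deletion
            obs_parts.append(np.full(k, DEL, dtype=np.uint8))
            score += sc.gap_open + (k - 1) * sc.gap_extend
            rpos += k
        else:                   # 'I': extra read bases: insertion after rpos
            insertions.append((rpos, read_seq[ri: ri + k]))
            score += sc.gap_open + (k - 1) * sc.gap_extend
            ri += k
    obs = (
        np.concatenate(obs_parts) if obs_parts else np.empty(0, dtype=np.uint8)
    )
    # edlib scores N-vs-N as a match; our scheme treats N as mismatch everywhere.
    n_mask = obs == N
    if n_mask.any():
        refc = encode_bases(ref_seq)[start0: start0 + len(obs)]
        n_as_match = int(np.count_nonzero(n_mask & (refc == N)))
        score += n_as_match * (sc.mismatch - sc.match)
    return ReadAlignment(read_id, ref_start, obs, insertions, score)


def align_read(
    read: OrientedRead | str,
    ref: IsoformReference | str,
    scoring: Scoring = DEFAULT_SCORING,
    backend: str = "dp",
) -> ReadAlignment:
    """Align one read to the reference; see module docstring for the geometry."""
    read_id = read.read_id if isinstance(read, OrientedRead) else "read"
    read_seq = read.sequence if isinstance(read, OrientedRead) else read
    ref_seq = ref.sequence if isinstance(ref, IsoformReference) else ref
    if backend == "dp":
        return _align_dp(read_id, read_seq, ref_seq, scoring)
    if backend == "edlib":
        return _align_edlib(read_id, read_seq, ref_seq, scoring)
    raise ValidationError(f"unknown alignment backend {backend!r}")


def align_reads(
    reads: Sequence[OrientedRead],
    ref: IsoformReference,
    scoring: Scoring = DEFAULT_SCORING,
    backend: str = "edlib",
) -> list[ReadAlignment]:
    return [align_read(r, ref, scoring, backend) for r in reads]


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------

@dataclass
class Pileup:
    """Per-position counts of A/C/G/T/N/deletion over the reference.

    Coverage at a position is the number of reads with a definite observation
    there: ``A + C + G + T + deletion`` (N excluded).
    """

    ref_length: int
    counts: np.ndarray                    # shape (ref_length, 6), int64
    insertion_table: Counter = field(default_factory=Counter)
    n_reads: int = 0

    @classmethod
    def empty(cls, ref_length: int) -> "Pileup":
        return cls(ref_length, np.zeros((ref_length, 6), dtype=np.int64))

    @property
    def coverage(self) -> np.ndarray:
        cols = [A, C, G, T, DEL]
        return self.counts[:, cols].sum(axis=1)

    def base_count(self, position: int, code_or_char: int | str) -> int:
        code = OBS_CHARS.index(code_or_char) if isinstance(code_or_char, str) else code_or_char
        return int(self.counts[position - 1, code])

    def __add__(self, other: "Pileup") -> "Pileup":
        if self.ref_length != other.ref_length:
            raise ValidationError("cannot add pileups over different references")
        return Pileup(
            self.ref_length,
            self.counts + other.counts,
            self.insertion_table + other.insertion_table,
            self.n_reads + other.n_reads,
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Pileup)
            and self.ref_length == other.ref_length
            and np.array_equal(self.counts, other.counts)
            and self.insertion_table == other.insertion_table
        )

    def to_dataframe(self, ref: IsoformReference | None = None):
        """Pileup as a tidy table: position, ref base, A/C/G/T/N/del, coverage."""
        import pandas as pd

        df = pd.DataFrame(self.counts, columns=["A", "C", "G", "T", "N", "del"])
        df.insert(0, "position", np.arange(1, self.ref_length + 1))
        if ref is not None:
            df.insert(1, "ref_base", list(ref.sequence))
        df["coverage"] = self.coverage
        return df


def build_pileup(alignments: Iterable[ReadAlignment], ref_length: int) -> Pileup:
    """Accumulate alignments into a pileup; insertions go to the side table."""
    pileup = Pileup.empty(ref_length)
    counts = pileup.counts
    for aln in alignments:
        if len(aln.obs) == 0:
            continue
        if aln.ref_start < 1 or aln.ref_end > ref_length:
            raise PipelineError(
                f"alignment of {aln.read_id!r} spans {aln.ref_start}..{aln.ref_end}, "
                f"outside reference of length {ref_length}"
            )
        sl = counts[aln.ref_start - 1: aln.ref_end]
        np.add.at(sl, (np.arange(len(aln.obs)), aln.obs), 1)
        for after_pos, ins in aln.insertions:
            pileup.insertion_table[(after_pos, ins)] += 1
        pileup.n_reads += 1
    return pileup


def stack_observations(
    alignments: Sequence[ReadAlignment], ref_length: int
) -> np.ndarray:
    """Dense (n_reads, ref_length) observation matrix; 255 marks 'not covered'.

    The substrate for per-read codon extraction (known-mutation calling and
    phasing); memory is ~ref_length bytes per read.
    """
    mat = np.full((len(alignments), ref_length), NOT_COVERED, dtype=np.uint8)
    for k, aln in enumerate(alignments):
        if len(aln.obs):
            mat[k, aln.ref_start - 1: aln.ref_end] = aln.obs
    return mat
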