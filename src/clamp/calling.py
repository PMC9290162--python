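"""Substitution scan, VAF computation and clinical classification (steps 4-5).

Two complementary callers run on every QC-passing sample:

* :func:`scan_de_novo` scans the nucleotide pileup for previously unreported
  substitutions — any (position, alt base) whose count clears the absolute
  read floor and the positive VAF cutoff.
* :func:`call_known` interrogates every catalogued mutation at codon level,
  per read: a read supports T315I only if its three aligned codon bases
  translate to isoleucine. Codon-level counting is what separates F359I from
  F359V and F359C, which share a position but not a substitution.

VAF semantics for known mutations: the denominator is the number of reads
whose codon translates to the wild-type amino acid or to any catalogued
alternate at that codon. Codons interrupted by deletions or N, and codons
translating to an uncatalogued amino acid, are tallied separately and
excluded — they are almost always sequencing-error artifacts in high-accuracy
amplicon data, and excluding them keeps the estimator unbiased to first order
in the per-base error rate (and consistent with the informative-read
denominator used for clonal phasing).

Classification boundaries: a VAF at or above the positive cutoff (default
0.5 %, inclusive, since mutations down to 0.5 % are reliably detectable) is
``positive``; strictly above the clinical cutoff (default 1 %) it becomes
``clinically_reportable``.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .align import OBS_CHARS, Pileup, T, stack_observations
from .errors import PipelineError
from .panel import (
    AmpliconPanel,
    IsoformReference,
    KnownMutation,
    codon_to_positions,
    translate,
)


class CallStatus(str, Enum):
    NEGATIVE = "negative"
    POSITIVE = "positive"
    CLINICALLY_REPORTABLE = "clinically_reportable"


def classify(vaf: float, panel: AmpliconPanel) -> CallStatus:
    """Monotone three-way classification of a VAF against panel cutoffs."""
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"VAF must be a fraction in [0, 1], got {vaf}")
    if vaf < panel.positive_cutoff:
        return CallStatus.NEGATIVE
    if vaf > panel.clinical_cutoff:
        return CallStatus.CLINICALLY_REPORTABLE
    return CallStatus.POSITIVE


@dataclass
class VariantCall:
    """One nucleotide substitution from the de novo scan."""

    position: int        # 1-based reference position
    ref_base: str
    alt_base: str
    alt_count: int
    coverage: int
    vaf: float
    aa_label: str | None  # None for non-coding positions or synonymous changes
    known: bool
    status: CallStatus

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["status"] = self.status.value
        return d


@dataclass
class KnownMutationResult:
    """Per-sample result for one catalogued mutation (negatives included)."""

    mutation: KnownMutation
    supporting_reads: int
    codon_coverage: int      # reads with all three codon bases observed, no gap/N
    informative_reads: int   # of those, translating to ref or a catalogued alt
    other_reads: int         # codon translates to an uncatalogued amino acid
    vaf: float               # supporting / informative
    status: CallStatus

    @property
    def label(self) -> str:
        return self.mutation.label

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "supporting_reads": self.supporting_reads,
            "codon_coverage": self.codon_coverage,
            "informative_reads": self.informative_reads,
            "other_reads": self.other_reads,
            "vaf": self.vaf,
            "status": self.status.value,
        }


def _aa_change_label(
    ref: IsoformReference, position: int, alt_base: str
) -> str | None:
    """Amino-acid label of a substitution, or None if non-coding/synonymous."""
    if position < ref.cds_start:
        return None
    offset = position - ref.cds_start
    codon_number = ref.codon_offset + offset // 3
    if codon_number > ref.max_codon:
        return None
    p1, _, _ = codon_to_positions(ref, codon_number)
    codon = list(ref.sequence[p1 - 1: p1 + 2])
    ref_aa = translate("".join(codon))
    codon[position - p1] = alt_base
    alt_aa = translate("".join(codon))
    if alt_aa == ref_aa:
        return None
    return f"{ref_aa}{codon_number}{alt_aa}"


def scan_de_novo(
    pileup: Pileup, ref: IsoformReference, panel: AmpliconPanel
) -> list[VariantCall]:
    """Emit every substitution with ``alt_count >= min_alt_reads`` and
    ``vaf >= positive_cutoff``; N is never an alternate allele."""
    ref_codes = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
    from .align import encode_bases

    ref_enc = encode_bases(ref.sequence)
    coverage = pileup.coverage
    calls: list[VariantCall] = []
    counts = pileup.counts
    known_labels = set(panel.labels)
    for alt_code in range(T + 1):  # A, C, G, T only
        col = counts[:, alt_code]
        with np.errstate(divide="ignore", invalid="ignore"):
            vaf = np.where(coverage > 0, col / np.maximum(coverage, 1), 0.0)
        hits = np.flatnonzero(
            (col >= panel.min_alt_reads)
            & (vaf >= panel.positive_cutoff)
            & (ref_enc != alt_code)
        )
        for idx in hits:
            position = int(idx) + 1
            alt_base = OBS_CHARS[alt_code]
            label = _aa_change_label(ref, position, alt_base)
            calls.append(
                VariantCall(
                    position=position,
                    ref_base=chr(ref_codes[idx]),
                    alt_base=alt_base,
                    alt_count=int(col[idx]),
                    coverage=int(coverage[idx]),
                    vaf=float(vaf[idx]),
                    aa_label=label,
                    known=label in known_labels,
                    status=classify(float(vaf[idx]), panel),
                )
            )
    calls.sort(key=lambda c: (c.position, c.alt_base))
    return calls


def codon_observations(
    obs_matrix: np.ndarray, ref: IsoformReference, codon_number: int
) -> np.ndarray:
    """Slice the (n_reads, 3) codon observation block for one protein position."""
    p1, _, p3 = codon_to_positions(ref, codon_number)
    return obs_matrix[:, p1 - 1: p3]


def translate_codon_column(codons: np.ndarray) -> np.ndarray:
    """Translate an (n_reads, 3) observation block to amino-acid characters.

    Reads with a deletion, N, or uncovered base anywhere in the codon get
    ``'.'`` (unusable observation).
    """
    usable = (codons <= T).all(axis=1)
    aas = np.full(len(codons), ".", dtype="<U1")
    if usable.any():
        u = codons[usable].astype(np.int64)
        packed = u[:, 0] * 16 + u[:, 1] * 4 + u[:, 2]
        aas[usable] = _CODON_TABLE[packed]
    return aas


def _build_codon_table() -> np.ndarray:
    bases = "ACGT"
    table = np.empty(64, dtype="<U1")
    for i, b1 in enumerate(bases):
        for j, b2 in enumerate(bases):
            for k, b3 in enumerate(bases):
                table[i * 16 + j * 4 + k] = translate(b1 + b2 + b3)
    return table


_CODON_TABLE = _build_codon_table()


def call_known(
    obs_or_alignments,
    panel: AmpliconPanel,
    ref: IsoformReference,
) -> list[KnownMutationResult]:
    """Codon-level call for every panel mutation; every label appears exactly
    once, negatives included.

    Accepts either a dense observation matrix from
    :func:`clamp.align.stack_observations` or a sequence of alignments.
    """
    obs_matrix = _as_obs_matrix(obs_or_alignments, ref)
    results: list[KnownMutationResult] = []
    aa_cache: dict[int, np.ndarray] = {}
    for mut in panel.known_mutations:
        if mut.codon_number not in aa_cache:
            aa_cache[mut.codon_number] = translate_codon_column(
                codon_observations(obs_matrix, ref, mut.codon_number)
            )
        aas = aa_cache[mut.codon_number]
        catalogued = {mut.ref_aa} | {
            m.alt_aa for m in panel.mutations_at_codon(mut.codon_number)
        }
        codon_coverage = int(np.count_nonzero(aas != "."))
        if codon_coverage == 0:
            raise PipelineError(
                f"no codon coverage for {mut.label}; QC should have aborted this sample"
            )
        informative = int(np.count_nonzero(np.isin(aas, sorted(catalogued))))
        supporting = int(np.count_nonzero(aas == mut.alt_aa))
        vaf = supporting / informative if informative else 0.0
        results.append(
            KnownMutationResult(
                mutation=mut,
                supporting_reads=supporting,
                codon_coverage=codon_coverage,
                informative_reads=informative,
                other_reads=codon_coverage - informative,
                vaf=vaf,
                status=classify(vaf, panel),
            )
        )
    return results


def _as_obs_matrix(obs_or_alignments, ref: IsoformReference) -> np.ndarray:
    if isinstance(obs_or_alignments, np.ndarray):
        return obs_or_alignments
    return stack_observations(list(obs_or_alignments), len(ref))


def positive_results(results: Sequence[KnownMutationResult]) -> list[KnownMutationResult]:
    return [r for r in results if r.status is not CallStatus.NEGATIVE]
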