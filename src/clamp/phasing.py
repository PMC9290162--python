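"""Per-read haplotype extraction and clonal composition (workflow step 6).

Full-length amplicon reads make phasing exact: each read either carries a
mutation or it does not, so clones are recovered by grouping reads on their
exact genotype over the sample's positive mutation sites — no statistical
haplotype inference. Reads with an unusable observation at any phased site
(deletion, N, or an amino acid matching neither the wild type nor that site's
alternate) are dropped from the clone fractions but counted, which keeps an
exact identity: the clone fractions containing mutation m sum to m's VAF over
the informative reads.

Categorical co-occurrence statements ("X occurs only with Y") need an
operational noise floor; counts below ``max(2 reads, 0.2 % of informative
reads)`` are treated as zero to guard against chimeric molecules and residual
sequencing errors.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calling import KnownMutationResult, codon_observations, translate_codon_column
from .errors import ValidationError
from .panel import IsoformReference

REF, ALT, MISSING = "ref", "alt", "missing"

SAME_CLONE_ONLY = "same_clone_only"
EXCLUSIVE = "exclusive"
MIXED = "mixed"


@dataclass(frozen=True)
class ReadHaplotype:
    read_id: str
    genotype: tuple[str, ...]  # over the phased sites, each in {ref, alt, missing}

    @property
    def informative(self) -> bool:
        return MISSING not in self.genotype


@dataclass
class Clone:
    mutations: tuple[str, ...]  # sorted mutation labels; () is the wild-type clone
    read_count: int
    fraction: float

    def to_dict(self) -> dict:
        return {
            "mutations": list(self.mutations),
            "read_count": self.read_count,
            "fraction": self.fraction,
        }


@dataclass
class CloneTable:
    sites: list[str]                  # phased mutation labels, panel order
    clones: list[Clone]               # descending read count; wild type always listed
    n_informative_reads: int
    n_dropped_reads: int = 0
    available: bool = True            # False when zero reads were informative

    def mutation_vaf(self, label: str) -> float:
        """Informative-read VAF of ``label``: sum of its clones' fractions."""
        if label not in self.sites:
            raise ValidationError(f"mutation {label!r} was not phased")
        return sum(c.fraction for c in self.clones if label in c.mutations)

    def clone_count(self, mutations: Sequence[str]) -> int:
        key = tuple(sorted(mutations))
        for clone in self.clones:
            if clone.mutations == key:
                return clone.read_count
        return 0

    def to_dict(self) -> dict:
        return {
            "sites": self.sites,
            "clones": [c.to_dict() for c in self.clones],
            "n_informative_reads": self.n_informative_reads,
            "n_dropped_reads": self.n_dropped_reads,
            "available": self.available,
        }


def extract_haplotypes(
    obs_matrix: np.ndarray,
    positive_mutations: Sequence[KnownMutationResult],
    ref: IsoformReference,
    read_ids: Sequence[str] | None = None,
) -> list[ReadHaplotype]:
    """Genotype every read over the positive mutation sites.

    A site is ``alt`` when the read's translated codon equals that mutation's
    alternate amino acid, ``ref`` when it equals the wild type, and
    ``missing`` otherwise. Requires at least two positive mutations — with
    fewer there is nothing to phase and the caller skips this step.
    """
    if len(positive_mutations) < 2:
        raise ValidationError("phasing needs at least two positive mutations")
    n_reads = len(obs_matrix)
    columns = []
    for res in positive_mutations:
        aas = translate_codon_column(
            codon_observations(obs_matrix, ref, res.mutation.codon_number)
        )
        col = np.full(n_reads, MISSING, dtype="<U7")
        col[aas == res.mutation.ref_aa] = REF
        col[aas == res.mutation.alt_aa] = ALT
        columns.append(col)
    ids = read_ids if read_ids is not None else [f"read_{k}" for k in range(n_reads)]
    return [
        ReadHaplotype(ids[k], tuple(col[k] for col in columns))
        for k in range(n_reads)
    ]


def clonal_distribution(
    haplotypes: Sequence[ReadHaplotype],
    sites: Sequence[str] | None = None,
) -> CloneTable:
    """Group informative reads by their exact mutation set.

    ``sites`` names the phased mutations in genotype order; defaults to
    ``site_0..`` placeholders when phasing is driven directly from haplotypes
    in tests.
    """
    if not haplotypes:
        raise ValidationError("clonal_distribution needs at least one haplotype")
    n_sites = len(haplotypes[0].genotype)
    site_names = list(sites) if sites is not None else [f"site_{i}" for i in range(n_sites)]
    if len(site_names) != n_sites:
        raise ValidationError("site-name count does not match genotype length")

    counts: Counter[tuple[str, ...]] = Counter()
    dropped = 0
    for hap in haplotypes:
        if len(hap.genotype) != n_sites:
            raise ValidationError("inconsistent genotype lengths across haplotypes")
        if not hap.informative:
            dropped += 1
            continue
        muts = tuple(
            sorted(name for name, g in zip(site_names, hap.genotype) if g == ALT)
        )
        counts[muts] += 1

    n_informative = sum(counts.values())
    if n_informative == 0:
        return CloneTable(site_names, [], 0, dropped, available=False)
    counts.setdefault((), 0)  # the wild-type clone is always listed
    clones = [
        Clone(muts, n, n / n_informative)
        for muts, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return CloneTable(site_names, clones, n_informative, dropped)


def merge_haplotypes(*groups: Sequence[ReadHaplotype]) -> list[ReadHaplotype]:
    merged: list[ReadHaplotype] = []
    for g in groups:
        merged.extend(g)
    return merged


@dataclass
class CooccurrenceResult:
    descriptor: str               # same_clone_only | exclusive | mixed
    both: int
    a_only: int
    b_only: int
    neither: int
    noise_floor: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def cooccurrence_test(
    clone_table: CloneTable, mutation_a: str, mutation_b: str
) -> CooccurrenceResult:
    """Directional co-occurrence of two phased mutations.

    ``same_clone_only``: b never appears without a (b-without-a count is zero
    after the noise floor) while true double mutants exist. ``exclusive``:
    the double-mutant count itself falls under the floor — including the
    degenerate case where both effective counts vanish, which carries no
    co-occurrence evidence. Anything else is ``mixed``.
    """
    for label in (mutation_a, mutation_b):
        if label not in clone_table.sites:
            raise ValidationError(f"mutation {label!r} is not among the phased sites")
    both = a_only = b_only = neither = 0
    for clone in clone_table.clones:
        has_a = mutation_a in clone.mutations
        has_b = mutation_b in clone.mutations
        if has_a and has_b:
            both += clone.read_count
        elif has_a:
            a_only += clone.read_count
        elif has_b:
            b_only += clone.read_count
        else:
            neither += clone.read_count
    floor = max(2.0, 0.002 * clone_table.n_informative_reads)
    eff_both = both if both >= floor else 0
    eff_b_only = b_only if b_only >= floor else 0
    if eff_both == 0:
        descriptor = EXCLUSIVE
    elif eff_b_only == 0:
        descriptor = SAME_CLONE_ONLY
    else:
        descriptor = MIXED
    return CooccurrenceResult(descriptor, both, a_only, b_only, neither, floor)
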