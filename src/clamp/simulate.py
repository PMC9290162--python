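"""Synthetic amplicon read generator with known clonal ground truth.

Emulates one sequencing run of a multi-clone sample: each clone is a set of
substitutions (catalogued mutation labels or raw ``(position, alt_base)``
pairs) present at a stated population fraction; reads are decorated with the
panel primers, reverse-complemented with probability ``reverse_fraction``,
and corrupted by iid per-base substitution and indel errors at rates typical
of circular-consensus reads. Optional off-target reads are primer-free random
sequences.

Clone membership is drawn as an exact largest-remainder allocation of
``n_reads`` to the stated fractions followed by a seeded shuffle — a
stratified draw honoring the fractions exactly, so the expected VAF of each
mutation is reproduced deterministically rather than to within multinomial
noise. Orientation and errors remain independent per read/base.

The truth record produced alongside the reads stores per-read clone identity
and the exact expected VAF of every mutation, so tests never re-derive ground
truth from generator internals.

Deliberate simplifications relative to real instrument data: errors are iid
and uniform over alternate bases (no homopolymer bias, no quality-score
realism), primer bases are error-free, and no chimeras or PCR bias are
modelled.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .align import decode_bases, encode_bases
from .errors import ConfigError, ValidationError
from .panel import (
    GENETIC_CODE,
    AmpliconPanel,
    IsoformReference,
    codon_to_positions,
    parse_mutation_label,
)
from .read_prep import RawRead, revcomp

MAX_ERROR_RATE = 0.1


@dataclass(frozen=True)
class CloneSpec:
    """One clone: its substitutions and population fraction."""

    mutations: tuple = ()       # mutation labels or (position, alt_base) pairs
    fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValidationError(f"clone fraction {self.fraction} outside [0, 1]")

    @property
    def key(self) -> tuple[str, ...]:
        return tuple(sorted(_mutation_key(m) for m in self.mutations))


def _mutation_key(mut) -> str:
    if isinstance(mut, str):
        return mut
    position, alt = mut
    return f"pos{position}{alt}"


@dataclass
class SimulationSpec:
    isoform_id: str
    clones: list[CloneSpec]
    n_reads: int
    sub_error_rate: float = 0.003
    indel_error_rate: float = 0.001
    reverse_fraction: float = 0.5
    off_target_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValidationError("n_reads must be >= 1")
        for name in ("sub_error_rate", "indel_error_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= MAX_ERROR_RATE:
                raise ValidationError(f"{name} {rate} outside [0, {MAX_ERROR_RATE}]")
        if not 0.0 <= self.reverse_fraction <= 1.0:
            raise ValidationError("reverse_fraction outside [0, 1]")
        if not 0.0 <= self.off_target_fraction <= 1.0:
            raise ValidationError("off_target_fraction outside [0, 1]")
        total = sum(c.fraction for c in self.clones)
        if total > 1.0 + 1e-9:
            raise ValidationError(
                f"clone fractions sum to {total:.6f} > 1 (wild-type remainder is implicit)"
            )


def load_sim_spec(path: str | Path, seed: int | None = None) -> SimulationSpec:
    """Read a simulation scenario from YAML/JSON; ``seed`` overrides the file."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read simulation spec {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: simulation spec must be a mapping")
    try:
        clones = [
            CloneSpec(
                tuple(
                    m if isinstance(m, str) else (int(m[0]), str(m[1]))
                    for m in c.get("mutations", [])
                ),
                float(c["fraction"]),
            )
            for c in doc.get("clones", [])
        ]
        spec = SimulationSpec(
            isoform_id=str(doc["isoform_id"]),
            clones=clones,
            n_reads=int(doc["n_reads"]),
            sub_error_rate=float(doc.get("sub_error_rate", 0.003)),
            indel_error_rate=float(doc.get("indel_error_rate", 0.001)),
            reverse_fraction=float(doc.get("reverse_fraction", 0.5)),
            off_target_fraction=float(doc.get("off_target_fraction", 0.0)),
            seed=int(doc.get("seed", 0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc!r}") from exc
    if seed is not None:
        spec.seed = seed
    return spec


def packaged_scenario(name: str, seed: int | None = None) -> SimulationSpec:
    """Load one of the shipped simulation scenarios by file stem.

    Available: ``validation_sample1``, ``validation_sample2``, ``validation_sample14``,
    ``validation_sample15``, ``clonal_composition``.
    """
    from importlib import resources

    res = resources.files("clamp.data") / "scenarios" / f"{name}.yaml"
    with resources.as_file(res) as p:
        if not p.exists():
            raise ConfigError(f"no packaged scenario named {name!r}")
        return load_sim_spec(p, seed=seed)


def expected_vafs(spec: SimulationSpec) -> dict[str, float]:
    """Mutation -> expected VAF: the sum of fractions of clones carrying it."""
    vafs: dict[str, float] = {}
    for clone in spec.clones:
        for mut in clone.mutations:
            key = _mutation_key(mut)
            vafs[key] = vafs.get(key, 0.0) + clone.fraction
    return vafs


def resolve_mutation(
    mut, ref: IsoformReference
) -> list[tuple[int, str]]:
    """Expand a mutation spec into reference-position substitutions.

    A label like ``T315I`` becomes the minimal set of nucleotide changes that
    turns the reference codon into a codon for the alternate amino acid,
    choosing the codon with the fewest changes (ties broken alphabetically).
    """
    if not isinstance(mut, str):
        position, alt = mut
        alt = str(alt).upper()
        if not 1 <= position <= len(ref.sequence):
            raise ValidationError(f"substitution position {position} outside reference")
        if alt not in "ACGT" or ref.sequence[position - 1] == alt:
            raise ValidationError(f"invalid substitution ({position}, {alt!r})")
        return [(position, alt)]

    ref_aa, codon_number, alt_aa = parse_mutation_label(mut)
    p1, _, _ = codon_to_positions(ref, codon_number)
    ref_codon = ref.sequence[p1 - 1: p1 + 2]
    if GENETIC_CODE[ref_codon] != ref_aa:
        raise ValidationError(
            f"label {mut}: reference codon {ref_codon} translates to "
            f"{GENETIC_CODE[ref_codon]}, not {ref_aa}"
        )
    candidates = sorted(c for c, aa in GENETIC_CODE.items() if aa == alt_aa)
    if not candidates:
        raise ValidationError(f"label {mut}: no codon encodes {alt_aa!r}")
    best = min(
        candidates,
        key=lambda c: (sum(a != b for a, b in zip(c, ref_codon)), c),
    )
    return [
        (p1 + i, best[i]) for i in range(3) if best[i] != ref_codon[i]
    ]


def _largest_remainder_counts(fractions: list[float], n: int) -> list[int]:
    quotas = [f * n for f in fractions]
    counts = [int(q) for q in quotas]
    short = n - sum(counts)
    order = sorted(
        range(len(fractions)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in order[:short]:
        counts[i] += 1
    return counts


@dataclass
class SimulationTruth:
    spec: SimulationSpec
    clone_keys: list[tuple[str, ...]]   # per clone (wild type last), sorted labels
    clone_counts: list[int]
    read_clone: dict[str, int]          # read id -> clone index; -1 = off-target
    expected_vafs: dict[str, float] = field(default_factory=dict)
    n_off_target: int = 0

    def to_dict(self) -> dict:
        return {
            "isoform_id": self.spec.isoform_id,
            "seed": self.spec.seed,
            "n_reads": self.spec.n_reads,
            "sub_error_rate": self.spec.sub_error_rate,
            "indel_error_rate": self.spec.indel_error_rate,
            "clones": [
                {"mutations": list(k), "n_reads": c}
                for k, c in zip(self.clone_keys, self.clone_counts)
            ],
            "expected_vafs": self.expected_vafs,
            "n_off_target": self.n_off_target,
            "read_clone": self.read_clone,
        }


def simulate_reads(
    spec: SimulationSpec, panel: AmpliconPanel
) -> tuple[list[RawRead], SimulationTruth]:
    """Generate one sample's reads plus the ground-truth record."""
    ref = panel.get_isoform(spec.isoform_id)
    rng = np.random.default_rng(spec.seed)

    # clone insert sequences (encoded), wild type appended as the remainder clone
    clone_arrays: list[np.ndarray] = []
    clone_keys: list[tuple[str, ...]] = []
    fractions: list[float] = []
    for clone in spec.clones:
        arr = encode_bases(ref.sequence).copy()
        for mut in clone.mutations:
            for position, alt in resolve_mutation(mut, ref):
                arr[position - 1] = "ACGT".index(alt)
        clone_arrays.append(arr)
        clone_keys.append(clone.key)
        fractions.append(clone.fraction)
    wt_fraction = 1.0 - sum(fractions)
    clone_arrays.append(encode_bases(ref.sequence).copy())
    clone_keys.append(())
    fractions.append(max(wt_fraction, 0.0))

    n_off = int(round(spec.off_target_fraction * spec.n_reads))
    n_on = spec.n_reads - n_off
    clone_counts = _largest_remainder_counts(fractions, n_on)

    assignment = np.repeat(np.arange(len(clone_counts)), clone_counts)
    assignment = np.concatenate([assignment, np.full(n_off, -1)])
    rng.shuffle(assignment)

    fwd = encode_bases(panel.forward_primer)
    rev_rc = encode_bases(revcomp(panel.reverse_primer))
    insert_len = len(ref.sequence)
    read_len = insert_len + len(fwd) + len(rev_rc)

    reads: list[RawRead] = []
    read_clone: dict[str, int] = {}
    for i, clone_idx in enumerate(assignment):
        read_id = f"sim_{i:05d}"
        if clone_idx < 0:
            seq_codes = rng.integers(0, 4, read_len).astype(np.uint8)
        else:
            insert = clone_arrays[clone_idx].copy()
            insert = _apply_errors(insert, spec, rng)
            seq_codes = np.concatenate([fwd, insert, rev_rc])
            if rng.random() < spec.reverse_fraction:
                seq_codes = (3 - seq_codes)[::-1]
        seq = decode_bases(seq_codes)
        reads.append(RawRead(read_id, seq, "I" * len(seq)))
        read_clone[read_id] = int(clone_idx)

    truth = SimulationTruth(
        spec=spec,
        clone_keys=clone_keys,
        clone_counts=clone_counts,
        read_clone=read_clone,
        expected_vafs=expected_vafs(spec),
        n_off_target=n_off,
    )
    return reads, truth


def _apply_errors(
    insert: np.ndarray, spec: SimulationSpec, rng: np.random.Generator
) -> np.ndarray:
    L = len(insert)
    if spec.sub_error_rate > 0:
        mask = rng.random(L) < spec.sub_error_rate
        k = int(mask.sum())
        if k:
            insert[mask] = (insert[mask] + rng.integers(1, 4, k)) % 4
    if spec.indel_error_rate > 0:
        mask = rng.random(L) < spec.indel_error_rate
        positions = np.flatnonzero(mask)
        if len(positions):
            is_del = rng.random(len(positions)) < 0.5
            ins_bases = rng.integers(0, 4, len(positions))
            parts: list[np.ndarray] = []
            prev = 0
            for pos, d, b in zip(positions, is_del, ins_bases):
                if d:
                    parts.append(insert[prev:pos])
                else:
                    parts.append(insert[prev: pos + 1])
                    parts.append(np.array([b], dtype=np.uint8))
                prev = pos + 1
            parts.append(insert[prev:])
            insert = np.concatenate(parts)
    return insert
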