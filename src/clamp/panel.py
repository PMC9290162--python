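"""Amplicon panel model: isoform references, known mutations, thresholds.

The panel is the single source of assay configuration. Mutation positions are
expressed in protein coordinates (ABL1 numbering for the BCR-ABL1 assay) and
mapped onto each isoform's nucleotide sequence through two per-isoform metadata
fields: ``cds_start`` (1-based position of the first base of the first complete
codon) and ``codon_offset`` (the amino-acid number assigned to that codon).
Gene structure is therefore configuration, never code.

Coordinates are 1-based inclusive in every user-facing structure; internal
array code uses 0-based half-open offsets.
"""
from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigError, ValidationError

# Standard genetic code, translation table 1.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

#: Marker returned by :func:`translate` for codons containing a non-ACGT base.
UNDEFINED_AA = "X"

_DNA_RE = re.compile(r"^[ACGT]+$")
_LABEL_RE = re.compile(r"^([A-Z])(\d+)([A-Z*])$")


def translate(codon: str) -> str:
    """Translate a 3-base codon; non-ACGT bases yield :data:`UNDEFINED_AA`.

    Never raises on ambiguous bases — an ``N`` in a read is a fact of the data,
    not a caller error.
    """
    if len(codon) != 3:
        raise ValueError(f"codon must have exactly 3 bases, got {codon!r}")
    return GENETIC_CODE.get(codon.upper(), UNDEFINED_AA)


@dataclass(frozen=True)
class IsoformReference:
    """One candidate isoform of the fusion transcript amplicon."""

    isoform_id: str
    sequence: str
    cds_start: int      # 1-based first base of the first complete codon
    codon_offset: int   # protein number assigned to that codon
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 3 or not _DNA_RE.match(self.sequence):
            raise ValidationError(
                f"isoform {self.isoform_id!r}: sequence must be >=3 bases of A/C/G/T only"
            )
        if not 1 <= self.cds_start <= len(self.sequence) - 2:
            raise ValidationError(
                f"isoform {self.isoform_id!r}: cds_start {self.cds_start} outside sequence"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def max_codon(self) -> int:
        """Largest protein number whose codon lies fully inside the sequence."""
        n_codons = (len(self.sequence) - self.cds_start + 1) // 3
        return self.codon_offset + n_codons - 1

    def codon_sequence(self, codon_number: int) -> str:
        p1, _, p3 = codon_to_positions(self, codon_number)
        return self.sequence[p1 - 1 : p3]


def codon_to_positions(ref: IsoformReference, codon_number: int) -> tuple[int, int, int]:
    """Map a protein number to its three 1-based nucleotide positions on ``ref``."""
    if codon_number < ref.codon_offset:
        raise ValidationError(
            f"codon {codon_number} precedes numbering frame of {ref.isoform_id!r} "
            f"(first codon is {ref.codon_offset})"
        )
    start = ref.cds_start + 3 * (codon_number - ref.codon_offset)
    if start + 2 > len(ref.sequence):
        raise ValidationError(
            f"codon {codon_number} lies beyond the end of {ref.isoform_id!r} "
            f"(last complete codon is {ref.max_codon})"
        )
    return (start, start + 1, start + 2)


def parse_mutation_label(label: str) -> tuple[str, int, str]:
    """Split ``"T315I"`` into ``("T", 315, "I")``."""
    m = _LABEL_RE.match(label)
    if not m:
        raise ValidationError(f"malformed mutation label {label!r} (expected e.g. 'T315I')")
    return m.group(1), int(m.group(2)), m.group(3)


@dataclass(frozen=True)
class KnownMutation:
    """A catalogued resistance mutation, e.g. T315I."""

    ref_aa: str
    codon_number: int
    alt_aa: str

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValidationError(f"mutation {self.label}: ref and alt amino acid identical")

    @property
    def label(self) -> str:
        return f"{self.ref_aa}{self.codon_number}{self.alt_aa}"

    @classmethod
    def from_label(cls, label: str) -> "KnownMutation":
        ref_aa, codon, alt_aa = parse_mutation_label(label)
        return cls(ref_aa, codon, alt_aa)


@dataclass
class AmpliconPanel:
    """Primers, isoform references, mutation catalogue and call thresholds."""

    forward_primer: str
    reverse_primer: str
    isoforms: list[IsoformReference]
    known_mutations: list[KnownMutation] = field(default_factory=list)
    max_primer_mismatches: int = 2
    positive_cutoff: float = 0.005
    clinical_cutoff: float = 0.01
    min_coverage: int = 100
    min_alt_reads: int = 3

    def __post_init__(self) -> None:
        for name in ("forward_primer", "reverse_primer"):
            p = getattr(self, name)
            if len(p) < 10 or not _DNA_RE.match(p):
                raise ValidationError(f"{name} must be >=10 bases of A/C/G/T")
        if not self.isoforms:
            raise ValidationError("panel needs at least one isoform")
        ids = [iso.isoform_id for iso in self.isoforms]
        if len(set(ids)) != len(ids):
            raise ValidationError("isoform ids must be unique")
        labels = [m.label for m in self.known_mutations]
        if len(set(labels)) != len(labels):
            raise ValidationError("known-mutation labels must be unique")
        if not 0.0 < self.positive_cutoff < 1.0 or not 0.0 < self.clinical_cutoff < 1.0:
            raise ValidationError("cutoffs must be fractions in (0, 1)")
        if self.positive_cutoff > self.clinical_cutoff:
            raise ValidationError(
                f"positive_cutoff ({self.positive_cutoff}) must not exceed "
                f"clinical_cutoff ({self.clinical_cutoff})"
            )
        if self.max_primer_mismatches < 0:
            raise ValidationError("max_primer_mismatches must be >= 0")
        self._check_reference_consistency()

    def _check_reference_consistency(self) -> None:
        # Every catalogued mutation must sit on a reference codon that actually
        # translates to its stated wild-type amino acid, on every isoform that
        # spans it. Catches off-by-one numbering metadata at load time.
        for mut in self.known_mutations:
            spanned = False
            for iso in self.isoforms:
                if not iso.codon_offset <= mut.codon_number <= iso.max_codon:
                    continue
                spanned = True
                aa = translate(iso.codon_sequence(mut.codon_number))
                if aa != mut.ref_aa:
                    raise ValidationError(
                        f"panel inconsistency: codon {mut.codon_number} of "
                        f"{iso.isoform_id!r} translates to {aa}, but mutation "
                        f"{mut.label} expects reference {mut.ref_aa}"
                    )
            if not spanned:
                raise ValidationError(
                    f"mutation {mut.label}: codon {mut.codon_number} not covered "
                    f"by any panel isoform"
                )

    @property
    def labels(self) -> list[str]:
        return [m.label for m in self.known_mutations]

    def get_isoform(self, isoform_id: str) -> IsoformReference:
        for iso in self.isoforms:
            if iso.isoform_id == isoform_id:
                return iso
        raise ValidationError(f"unknown isoform {isoform_id!r}")

    def mutations_at_codon(self, codon_number: int) -> list[KnownMutation]:
        return [m for m in self.known_mutations if m.codon_number == codon_number]

    def to_dict(self) -> dict:
        return {
            "forward_primer": self.forward_primer,
            "reverse_primer": self.reverse_primer,
            "max_primer_mismatches": self.max_primer_mismatches,
            "positive_cutoff": self.positive_cutoff,
            "clinical_cutoff": self.clinical_cutoff,
            "min_coverage": self.min_coverage,
            "min_alt_reads": self.min_alt_reads,
            "isoforms": [
                {
                    "isoform_id": iso.isoform_id,
                    "sequence": iso.sequence,
                    "cds_start": iso.cds_start,
                    "codon_offset": iso.codon_offset,
                    "description": iso.description,
                }
                for iso in self.isoforms
            ],
            "known_mutations": self.labels,
        }

    @property
    def panel_hash(self) -> str:
        """Stable content hash recorded in every sample report."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _require(doc: dict, key: str, path) -> object:
    if key not in doc:
        raise ConfigError(f"{path}: missing required field {key!r}")
    return doc[key]


def load_panel(path: str | Path) -> AmpliconPanel:
    """Load and validate a panel from a YAML/JSON config file.

    Isoform sequences may be inline (``sequence``) or referenced by a FASTA
    path (``fasta``, resolved relative to the config file) whose record id
    must equal the isoform id.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read panel config {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: panel config must be a mapping")

    iso_docs = _require(doc, "isoforms", path)
    if not isinstance(iso_docs, list) or not iso_docs:
        raise ConfigError(f"{path}: 'isoforms' must be a non-empty list")
    isoforms = []
    for i, iso in enumerate(iso_docs):
        where = f"{path}: isoforms[{i}]"
        if not isinstance(iso, dict):
            raise ConfigError(f"{where}: must be a mapping")
        if "sequence" in iso:
            seq = str(iso["sequence"]).upper()
        elif "fasta" in iso:
            seq = _read_fasta_record(path.parent / iso["fasta"], iso.get("isoform_id"))
        else:
            raise ConfigError(f"{where}: needs 'sequence' or 'fasta'")
        try:
            isoforms.append(
                IsoformReference(
                    isoform_id=str(_require(iso, "isoform_id", where)),
                    sequence=seq,
                    cds_start=int(_require(iso, "cds_start", where)),
                    codon_offset=int(_require(iso, "codon_offset", where)),
                    description=str(iso.get("description", "")),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{where}: {exc}") from exc

    raw_muts = doc.get("known_mutations", [])
    if not isinstance(raw_muts, list):
        raise ConfigError(f"{path}: 'known_mutations' must be a list of labels")
    mutations = [KnownMutation.from_label(str(lbl)) for lbl in raw_muts]

    kwargs = {}
    for key, cast in (
        ("max_primer_mismatches", int),
        ("positive_cutoff", float),
        ("clinical_cutoff", float),
        ("min_coverage", int),
        ("min_alt_reads", int),
    ):
        if key in doc:
            try:
                kwargs[key] = cast(doc[key])
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"{path}: field {key!r}: {exc}") from exc

    return AmpliconPanel(
        forward_primer=str(_require(doc, "forward_primer", path)).upper(),
        reverse_primer=str(_require(doc, "reverse_primer", path)).upper(),
        isoforms=isoforms,
        known_mutations=mutations,
        **kwargs,
    )


def _read_fasta_record(fasta_path: Path, record_id: str | None) -> str:
    from Bio import SeqIO

    try:
        records = list(SeqIO.parse(str(fasta_path), "fasta"))
    except OSError as exc:
        raise ConfigError(f"cannot read FASTA {fasta_path}: {exc}") from exc
    if record_id is not None:
        for rec in records:
            if rec.id == record_id:
                return str(rec.seq).upper()
    if len(records) == 1:
        return str(records[0].seq).upper()
    raise ConfigError(f"{fasta_path}: no record matching isoform id {record_id!r}")


def demo_panel() -> AmpliconPanel:
    """The packaged demo panel (synthetic stand-in reference, 15 mutations)."""
    with resources.as_file(resources.files("clamp.data") / "demo_panel.yaml") as p:
        return load_panel(p)
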