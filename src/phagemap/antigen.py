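"""Reference antigen model and coordinate bookkeeping.

The display library is built from fragments of a single fusion-protein CDS
(e.g. a two-domain carrier--antigen fusion).  Everything downstream maps
against this reference, but epitope literature numbers residues in the
antigen's own (local) coordinate system.  This module holds the reference
sequence, validates it, and converts residue spans between the fusion-wide
and antigen-local numbering via a single integer offset:

    fusion_residue = antigen_local_residue + numbering_offset

All residue and nucleotide coordinates are 1-based and inclusive on both
ends, matching the ``S140-K254`` style of fragment labels used in the field.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

FUSION = "fusion"
ANTIGEN_LOCAL = "antigen_local"

_COORDINATE_SYSTEMS = (FUSION, ANTIGEN_LOCAL)


class ReferenceValidationError(ValueError):
    """Raised when a reference antigen fails an internal consistency check."""


class AnnotationRequiredError(ValueError):
    """Raised when an operation needs an annotation that was not supplied."""


@dataclass(frozen=True, order=True)
class ResidueSpan:
    """A 1-based, both-ends-inclusive residue interval.

    ``coordinate_system`` is either ``"fusion"`` (positions on the displayed
    fusion protein) or ``"antigen_local"`` (the antigen's own numbering).
    """

    start_res: int
    end_res: int
    coordinate_system: str = FUSION

    def __post_init__(self) -> None:
        if not (1 <= self.start_res <= self.end_res):
            raise ValueError(
                f"invalid span: need 1 <= start <= end, got "
                f"({self.start_res}, {self.end_res})"
            )
        if self.coordinate_system not in _COORDINATE_SYSTEMS:
            raise ValueError(f"unknown coordinate system {self.coordinate_system!r}")

    def __len__(self) -> int:
        return self.end_res - self.start_res + 1

    def contains(self, other: "ResidueSpan") -> bool:
        """True if this span fully covers ``other`` (same coordinate system)."""
        if self.coordinate_system != other.coordinate_system:
            raise ValueError("cannot compare spans in different coordinate systems")
        return self.start_res <= other.start_res and self.end_res >= other.end_res

    def label(self, protein: str | None = None) -> str:
        """Human-readable label, e.g. ``S140-K254`` when ``protein`` is given."""
        if protein is None:
            return f"{self.start_res}-{self.end_res}"
        return (
            f"{protein[self.start_res - 1]}{self.start_res}-"
            f"{protein[self.end_res - 1]}{self.end_res}"
        )


def translate_cds(cds: str) -> str:
    """Translate ``cds`` (standard code); any stop codon is an error.

    Library inserts are displayed as internal fusions to a capsid protein, so
    a valid reference CDS must read through without stops.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ReferenceValidationError(
            f"CDS length {len(cds)} is not divisible by 3"
        )
    protein = str(Seq(cds).translate())
    if "*" in protein:
        i = protein.index("*")
        raise ReferenceValidationError(
            f"stop codon {cds[3 * i:3 * i + 3]} at codon {i + 1} inside the ORF"
        )
    return protein


@dataclass
class ReferenceAntigen:
    """The reference fusion antigen every read and span is mapped against.

    ``contact_points`` and annotation spans are stored in antigen-local
    numbering (as they appear in the structural literature) and validated
    against the region of the fusion the offset covers.
    """

    name: str
    cds: str
    protein: str = ""
    numbering_offset: int = 0
    domain_annotations: list[tuple[str, int, int]] = field(default_factory=list)
    contact_points: list[int] | None = None

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()
        derived = translate_cds(self.cds)
        if not self.protein:
            self.protein = derived
        elif self.protein != derived:
            for i, (a, b) in enumerate(zip(derived, self.protein)):
                if a != b:
                    raise ReferenceValidationError(
                        f"codon {i + 1} ({self.cds[3 * i:3 * i + 3]}) translates "
                        f"to {a!r} but the supplied protein has {b!r}"
                    )
            raise ReferenceValidationError(
                f"protein length {len(self.protein)} != translated length "
                f"{len(derived)}"
            )
        n_local = self.n_residues - self.numbering_offset
        for label, start, end in self.domain_annotations:
            if not (1 <= start <= end <= n_local):
                raise ReferenceValidationError(
                    f"annotation {label!r} span ({start}, {end}) outside "
                    f"antigen-local range 1..{n_local}"
                )
        if self.contact_points is not None:
            if len(set(self.contact_points)) != len(self.contact_points):
                raise ReferenceValidationError("contact points are not unique")
            for c in self.contact_points:
                if not (1 <= c <= n_local):
                    raise ReferenceValidationError(
                        f"contact point {c} outside antigen-local range 1..{n_local}"
                    )

    @property
    def n_residues(self) -> int:
        return len(self.protein)

    @property
    def n_nt(self) -> int:
        return len(self.cds)


def load_reference(
    cds_file: str,
    protein_file: str | None = None,
    annotations: str | None = None,
    numbering_offset: int = 0,
    name: str | None = None,
) -> ReferenceAntigen:
    """Build a validated :class:`ReferenceAntigen` from FASTA (+ optional TSV).

    The annotation TSV has columns ``type`` (``domain`` or ``contact``),
    ``label``, ``start``, ``end``; coordinates are antigen-local.  For
    ``contact`` rows every residue in ``start..end`` is a contact point
    (single residues use start == end).
    """
    cds_rec = next(SeqIO.parse(cds_file, "fasta"))
    cds = str(cds_rec.seq).upper()
    protein = ""
    if protein_file is not None:
        protein = str(next(SeqIO.parse(protein_file, "fasta")).seq).upper()
    domains: list[tuple[str, int, int]] = []
    contacts: list[int] = []
    if annotations is not None:
        with open(annotations, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                kind = row["type"].strip().lower()
                start, end = int(row["start"]), int(row["end"])
                if kind == "domain":
                    domains.append((row["label"], start, end))
                elif kind == "contact":
                    contacts.extend(range(start, end + 1))
                else:
                    raise ReferenceValidationError(
                        f"unknown annotation type {row['type']!r}"
                    )
    return ReferenceAntigen(
        name=name or cds_rec.id,
        cds=cds,
        protein=protein,
        numbering_offset=numbering_offset,
        domain_annotations=domains,
        contact_points=contacts or None,
    )


def convert_span(
    span: ResidueSpan, target: str, ref: ReferenceAntigen
) -> ResidueSpan:
    """Express ``span`` in the ``target`` coordinate system.

    Round-trip conversion is the identity; spans falling outside the region
    the offset covers raise ``ValueError``.
    """
    if target not in _COORDINATE_SYSTEMS:
        raise ValueError(f"unknown coordinate system {target!r}")
    if span.coordinate_system == target:
        return span
    k = ref.numbering_offset
    if target == FUSION:
        start, end = span.start_res + k, span.end_res + k
        if not (1 <= start and end <= ref.n_residues):
            raise ValueError(
                f"antigen-local span ({span.start_res}, {span.end_res}) maps "
                f"outside the fusion protein (offset {k})"
            )
    else:
        start, end = span.start_res - k, span.end_res - k
        if start < 1:
            raise ValueError(
                f"fusion span ({span.start_res}, {span.end_res}) lies (partly) "
                f"outside the region covered by the antigen-local numbering "
                f"(offset {k})"
            )
    return ResidueSpan(start, end, target)


def contact_coverage(
    span: ResidueSpan, ref: ReferenceAntigen
) -> tuple[int, int]:
    """Count annotated antigen-antibody contact points inside ``span``.

    Returns ``(covered, total)``.  Contact points are user-supplied
    annotation (e.g. from a crystal structure); without them this raises
    :class:`AnnotationRequiredError`.
    """
    if ref.contact_points is None:
        raise AnnotationRequiredError(
            "contact-point annotation required: supply 'contact' rows in the "
            "reference annotation TSV"
        )
    local = convert_span(span, ANTIGEN_LOCAL, ref)
    covered = sum(1 for c in ref.contact_points if local.start_res <= c <= local.end_res)
    return covered, len(ref.contact_points)
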