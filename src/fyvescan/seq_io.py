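"""File formats shared by the whole pipeline.

Protein sequences move around as FASTA, domain annotations and reports as
plain TSV. Every coordinate in these formats is 1-based and inclusive at
both ends (the convention of SMART/Pfam span reports); the converters at the
bottom of this module are the only sanctioned bridge to Python's 0-based
half-open slicing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard residues. ``X`` is tolerated on input but flagged and is
#: excluded from charge/hydropathy sums; B/Z/U/J/O are rejected outright so
#: that titration math stays well-defined.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS) | {"X"}

#: Controlled vocabulary for domain annotations. Anything else is accepted
#: under an ``OTHER:<name>`` prefix with a logged warning.
DOMAIN_VOCABULARY = frozenset(
    {"FYVE", "Fab1_TCP", "PIPKc", "DUF500", "PH_PLC", "RCC1", "ATS1", "DZC"}
)

REPORT_COLUMNS = [
    "id",
    "n_fyve_domains",
    "motif_class",
    "architecture_class",
    "net_charge_pH6.5",
    "rcc1_blades",
    "flags",
]


class FastaParseError(ValueError):
    """Raised when a FASTA file violates the format or record invariants."""


class DomainTableError(ValueError):
    """Raised for malformed rows in a domain-annotation TSV."""


class ReportError(ValueError):
    """Raised when report inputs disagree about which proteins exist."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: accession-like id plus an upper-case sequence."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record requires a non-empty id")
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.id}: invalid residue(s) {sorted(bad)}; only the 20 "
                "standard amino acids plus X are accepted"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_ambiguous(self) -> bool:
        """True when the sequence carries at least one X placeholder."""
        return "X" in self.sequence


@dataclass(frozen=True)
class DomainAnnotation:
    """One annotated domain span on a protein (1-based inclusive)."""

    protein_id: str
    domain_name: str
    start: int
    end: int
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"{self.protein_id}/{self.domain_name}: invalid span "
                f"[{self.start},{self.end}] (1-based inclusive required)"
            )


def normalize_domain_name(name: str) -> str:
    """Map a raw domain name onto the controlled vocabulary.

    Unknown names come back prefixed ``OTHER:`` so they survive round-trips
    without being mistaken for rule-bearing domains.
    """
    if name in DOMAIN_VOCABULARY or name.startswith("OTHER:"):
        return name
    logger.warning("unknown domain name %r mapped to OTHER:%s", name, name)
    return f"OTHER:{name}"


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, order preserved.

    Sequences are upper-cased and whitespace-stripped. Malformed headers and
    empty sequences raise :class:`FastaParseError` naming the offending line;
    duplicate ids are rejected.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    header_lines = [i + 1 for i, line in enumerate(lines) if line.startswith(">")]
    first_content = next(
        (i + 1 for i, line in enumerate(lines) if line.strip()), None
    )
    if first_content is None:
        return []
    if not lines[first_content - 1].startswith(">"):
        raise FastaParseError(
            f"{path}: line {first_content}: expected a '>' header before "
            "sequence data"
        )

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        line_no = header_lines[idx] if idx < len(header_lines) else 0
        seq = str(rec.seq).upper().replace(" ", "")
        if not rec.id:
            raise FastaParseError(f"{path}: line {line_no}: header has no id")
        if not seq:
            raise FastaParseError(
                f"{path}: line {line_no}: record {rec.id!r} has an empty sequence"
            )
        if rec.id in seen:
            raise FastaParseError(
                f"{path}: line {line_no}: duplicate id {rec.id!r}"
            )
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        try:
            records.append(ProteinRecord(rec.id, seq, desc))
        except ValueError as exc:
            raise FastaParseError(f"{path}: line {line_no}: {exc}") from exc
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")


_TABLE_COLUMNS = ["protein_id", "domain_name", "start", "end", "source"]


def read_domain_table(path: str | Path) -> list[DomainAnnotation]:
    """Read a domain-annotation TSV (header: protein_id, domain_name, start,
    end, source). Coordinate errors report the offending row number; unknown
    domain names are mapped to ``OTHER:<name>`` with a warning."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise DomainTableError(f"{path}: missing column(s) {missing}")

    annotations: list[DomainAnnotation] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        row_no = i + 2  # header is row 1
        try:
            start = int(getattr(row, "start"))
            end = int(getattr(row, "end"))
        except ValueError as exc:
            raise DomainTableError(
                f"{path}: row {row_no}: non-integer coordinates"
            ) from exc
        name = normalize_domain_name(getattr(row, "domain_name"))
        try:
            annotations.append(
                DomainAnnotation(
                    getattr(row, "protein_id"), name, start, end,
                    getattr(row, "source"),
                )
            )
        except ValueError as exc:
            raise DomainTableError(f"{path}: row {row_no}: {exc}") from exc
    return annotations


def write_domain_table(
    annotations: Iterable[DomainAnnotation], path: str | Path
) -> None:
    frame = pd.DataFrame(
        [
            (a.protein_id, a.domain_name, a.start, a.end, a.source)
            for a in annotations
        ],
        columns=_TABLE_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def validate_annotations(
    annotations: Iterable[DomainAnnotation],
    records: Sequence[ProteinRecord],
) -> None:
    """Cross-check annotation spans against the sequences they point at."""
    lengths = {r.id: len(r.sequence) for r in records}
    for ann in annotations:
        if ann.protein_id not in lengths:
            raise DomainTableError(
                f"annotation for unknown protein {ann.protein_id!r}"
            )
        if ann.end > lengths[ann.protein_id]:
            raise DomainTableError(
                f"{ann.protein_id}/{ann.domain_name}: end {ann.end} beyond "
                f"sequence length {lengths[ann.protein_id]}"
            )


def write_report(
    calls: Mapping[str, Sequence],
    classes: Mapping[str, object],
    charges: Mapping[str, float],
    path: str | Path,
    blades: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Write the per-protein summary TSV.

    ``calls`` maps protein id to its FYVE domain calls, ``classes`` to
    architecture labels (strings or objects with a ``label``), ``charges`` to
    the net charge at pH 6.5. Ids must agree across tables; orphans are
    listed in the error.
    """
    key_sets = {"calls": set(calls), "classes": set(classes), "charges": set(charges)}
    if blades is not None:
        key_sets["blades"] = set(blades)
    universe = set.union(*key_sets.values()) if key_sets else set()
    orphans = sorted(
        pid
        for pid in universe
        if any(pid not in ks for ks in key_sets.values())
    )
    if orphans:
        raise ReportError(f"inconsistent protein ids across inputs: {orphans}")

    rows = []
    for pid in sorted(universe):
        protein_calls = list(calls[pid])
        label = getattr(classes[pid], "label", classes[pid])
        motif_class = protein_calls[0].motif_class if protein_calls else "NA"
        flags: set[str] = set()
        for call in protein_calls:
            flags.update(call.flags)
        rows.append(
            (
                pid,
                len(protein_calls),
                motif_class,
                label,
                round(float(charges[pid]), 3),
                (blades or {}).get(pid, 0),
                ";".join(sorted(flags)) or "-",
            )
        )
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)
    return frame


def to_zero_based(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive [start, end] -> 0-based half-open [start0, end0)."""
    if start < 1 or start > end:
        raise ValueError(f"invalid 1-based span [{start},{end}]")
    return start - 1, end


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open [start0, end0) -> 1-based inclusive [start, end]."""
    if start0 < 0 or end0 <= start0:
        raise ValueError(f"invalid 0-based span [{start0},{end0})")
    return start0 + 1, end0
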