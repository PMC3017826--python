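"""FYVE domain calling, misannotation filtering and architecture classes.

Plant FYVE proteins fall into five domain-architecture classes:

* I   -- FYVE followed by Fab1_TCP and PIPKc (PIKfyve/Fab1 kinase homologs);
* II  -- FYVE plus a DUF500 domain;
* III -- a lone FYVE in the N-terminal half of the protein;
* IV  -- a lone FYVE in the C-terminal half;
* V   -- PH_PLC, then a run of RCC1/ATS1 propeller blades, then FYVE, often
         with a C-terminal DZC motif.

Which of the two single-domain classes is the N-terminal one is a package
convention (FYVE midpoint in the N-terminal half -> III), overridable via
``fyve_n_terminal_label``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .motif_engine import (
    DEFAULT_SCAFFOLD_CONFIG,
    BindingMotifCall,
    MotifHit,
    Region,
    ScaffoldConfig,
    ScaffoldHit,
    classify_binding_motif,
    extract_dimer_interface,
    extract_turret_loop,
    find_fyve_scaffold,
)
from .seq_io import DomainAnnotation, ProteinRecord, read_domain_table

logger = logging.getLogger(__name__)

ARCHITECTURE_LABELS = ("I", "II", "III", "IV", "V", "UNCLASSIFIED")
_BLADE_NAMES = frozenset({"RCC1", "ATS1"})
#: annotator disagreement tolerance for the class-V blade run
CLASS_V_BLADE_RANGE = (3, 7)
NO_SCAFFOLD_REASON = "no 8-cysteine FYVE scaffold"


@dataclass(frozen=True)
class FyveDomainCall:
    """One FYVE domain on one protein, with its annotated regions."""

    protein_id: str
    scaffold: ScaffoldHit
    motif_class: str
    submotifs: tuple[MotifHit, ...]
    turret_loop: Region | None
    dimer_interface: Region | None
    flags: frozenset[str]

    @property
    def start(self) -> int:
        return self.scaffold.start

    @property
    def end(self) -> int:
        return self.scaffold.end


def call_fyve_domains(
    protein: ProteinRecord, config: ScaffoldConfig | None = None
) -> list[FyveDomainCall]:
    """Detect and annotate every FYVE domain on one protein.

    Composition of scaffold detection, binding-signature classification and
    region extraction; proteins without an eight-cysteine scaffold yield an
    empty list.
    """
    cfg = config or DEFAULT_SCAFFOLD_CONFIG
    calls = []
    for scaffold in find_fyve_scaffold(protein.sequence, cfg):
        classification = classify_binding_motif(protein.sequence, scaffold, cfg)
        central_start = classification.central_start or scaffold.central_anchor
        turret = extract_turret_loop(
            protein.sequence, scaffold, cfg.turret_window, central_start
        )
        anchor = next(
            (h for h in classification.submotifs if h.pattern_name in ("wxxd", "wxxg")),
            None,
        )
        flags = set(classification.flags)
        if anchor is not None:
            interface = extract_dimer_interface(
                protein.sequence, anchor.end,
                cfg.interface_offset, cfg.interface_length,
            )
        else:
            interface = None
            flags.add("no-nterm-anchor")
        calls.append(
            FyveDomainCall(
                protein_id=protein.id,
                scaffold=scaffold,
                motif_class=classification.label,
                submotifs=classification.submotifs,
                turret_loop=turret,
                dimer_interface=interface,
                flags=frozenset(flags),
            )
        )
    return calls


def filter_misannotated(
    candidates: Iterable[ProteinRecord],
    config: ScaffoldConfig | None = None,
) -> tuple[list[ProteinRecord], list[tuple[ProteinRecord, str]]]:
    """Split FYVE-annotated candidates into real FYVE proteins and impostors.

    A candidate is retained when at least one eight-cysteine scaffold call
    succeeds; everything else is rejected with the reason recorded. This is
    the sequence-level check that catches database entries annotated as FYVE
    proteins that do not actually possess the domain.
    """
    retained: list[ProteinRecord] = []
    rejected: list[tuple[ProteinRecord, str]] = []
    for record in candidates:
        if call_fyve_domains(record, config):
            retained.append(record)
        else:
            rejected.append((record, NO_SCAFFOLD_REASON))
    return retained, rejected


# ---------------------------------------------------------------------------
# architecture classes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureClass:
    label: str
    evidence: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if self.label not in ARCHITECTURE_LABELS:
            raise ValueError(f"unknown architecture label {self.label!r}")


def _rule_class_i(names: Sequence[str]) -> tuple[tuple[str, int], ...] | None:
    order = {}
    for idx, name in enumerate(names):
        if name in ("FYVE", "Fab1_TCP", "PIPKc") and name not in order:
            order[name] = idx
    if {"FYVE", "Fab1_TCP", "PIPKc"} <= set(order) and (
        order["FYVE"] < order["Fab1_TCP"] < order["PIPKc"]
    ):
        return tuple((n, order[n]) for n in ("FYVE", "Fab1_TCP", "PIPKc"))
    return None


def _rule_class_ii(names: Sequence[str]) -> tuple[tuple[str, int], ...] | None:
    if "FYVE" in names and "DUF500" in names:
        return (("FYVE", names.index("FYVE")), ("DUF500", names.index("DUF500")))
    return None


def _rule_class_v(names: Sequence[str]) -> tuple[tuple[str, int], ...] | None:
    try:
        ph = names.index("PH_PLC")
    except ValueError:
        return None
    blades = [i for i, n in enumerate(names) if n in _BLADE_NAMES and i > ph]
    if not blades:
        return None
    fyves = [i for i, n in enumerate(names) if n == "FYVE" and i > blades[-1]]
    lo, hi = CLASS_V_BLADE_RANGE
    if not fyves or not (lo <= len(blades) <= hi):
        return None
    evidence = [("PH_PLC", ph)]
    evidence += [(names[i], i) for i in blades]
    evidence.append(("FYVE", fyves[0]))
    dzc = [i for i, n in enumerate(names) if n == "DZC"]
    evidence += [("DZC", i) for i in dzc]
    return tuple(evidence)


def assign_architecture_class(
    annotations: Sequence[DomainAnnotation],
    protein_length: int,
    fyve_n_terminal_label: str = "III",
) -> ArchitectureClass:
    """Assign one protein's architecture class from its domain annotations.

    A pure function of the annotation multiset and N-to-C order: rows are
    sorted by start before rule matching, so input row order is irrelevant.
    Unknown (``OTHER:*``) domains are ignored for rule matching but never
    cause a failure. When several class rules match, the rule with the
    larger evidence set wins; exact ties are reported UNCLASSIFIED with a
    warning rather than guessed.
    """
    ordered = sorted(annotations, key=lambda a: (a.start, a.end))
    names = [a.domain_name for a in ordered if not a.domain_name.startswith("OTHER:")]
    if "FYVE" not in names:
        raise ValueError("protein carries no FYVE annotation")

    matches: list[ArchitectureClass] = []
    ev = _rule_class_i(names)
    if ev:
        matches.append(ArchitectureClass("I", ev))
    ev = _rule_class_ii(names)
    if ev:
        matches.append(ArchitectureClass("II", ev))
    ev = _rule_class_v(names)
    if ev:
        matches.append(ArchitectureClass("V", ev))
    if set(names) == {"FYVE"}:
        fyve = next(a for a in ordered if a.domain_name == "FYVE")
        midpoint = (fyve.start + fyve.end) / 2.0
        n_terminal = midpoint <= protein_length / 2.0
        label = (
            fyve_n_terminal_label
            if n_terminal
            else ("IV" if fyve_n_terminal_label == "III" else "III")
        )
        matches.append(ArchitectureClass(label, (("FYVE", names.index("FYVE")),)))

    if not matches:
        return ArchitectureClass("UNCLASSIFIED", ())
    matches.sort(key=lambda m: -len(m.evidence))
    if len(matches) > 1 and len(matches[0].evidence) == len(matches[1].evidence):
        logger.warning(
            "architecture rules tie (%s vs %s); reporting UNCLASSIFIED",
            matches[0].label, matches[1].label,
        )
        return ArchitectureClass("UNCLASSIFIED", ())
    return matches[0]


@dataclass(frozen=True)
class ProteomeSummary:
    per_protein: Mapping[str, ArchitectureClass]
    census: Mapping[str, tuple[str, ...]]

    def census_counts(self) -> dict[str, int]:
        return {label: len(ids) for label, ids in self.census.items()}


def _build_summary(
    class_by_id: Mapping[str, ArchitectureClass]
) -> ProteomeSummary:
    census: dict[str, list[str]] = {}
    for pid, arch in class_by_id.items():
        census.setdefault(arch.label, []).append(pid)
    return ProteomeSummary(
        per_protein=dict(class_by_id),
        census={label: tuple(sorted(ids)) for label, ids in sorted(census.items())},
    )


def summarize_proteome(
    records: Sequence[ProteinRecord],
    annotations: Sequence[DomainAnnotation],
    fyve_n_terminal_label: str = "III",
) -> ProteomeSummary:
    """Classify every FYVE-annotated protein and tally the class census.

    Proteins without a FYVE annotation are not FYVE proteins and are left
    out of the census.
    """
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for ann in annotations:
        by_protein.setdefault(ann.protein_id, []).append(ann)
    lengths = {r.id: len(r.sequence) for r in records}
    class_by_id = {}
    for record in records:
        anns = by_protein.get(record.id, [])
        if not any(a.domain_name == "FYVE" for a in anns):
            continue
        class_by_id[record.id] = assign_architecture_class(
            anns, lengths[record.id], fyve_n_terminal_label
        )
    return _build_summary(class_by_id)


def census_from_table(
    annotations: Sequence[DomainAnnotation],
    protein_lengths: Mapping[str, int],
    fyve_n_terminal_label: str = "III",
) -> ProteomeSummary:
    """Architecture census straight from an annotation table (no sequences)."""
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for ann in annotations:
        by_protein.setdefault(ann.protein_id, []).append(ann)
    class_by_id = {}
    for pid, anns in sorted(by_protein.items()):
        if not any(a.domain_name == "FYVE" for a in anns):
            continue
        if pid not in protein_lengths:
            raise ValueError(f"no protein length for {pid!r}")
        class_by_id[pid] = assign_architecture_class(
            anns, protein_lengths[pid], fyve_n_terminal_label
        )
    return _build_summary(class_by_id)


# ---------------------------------------------------------------------------
# curated Arabidopsis architecture fixture
# ---------------------------------------------------------------------------

def load_arabidopsis_architectures() -> tuple[list[DomainAnnotation], dict[str, int]]:
    """The 15 Arabidopsis FYVE proteins' domain architectures.

    Ids and domain layouts are curated from the published class
    descriptions; the residue coordinates are plausible placeholders (no
    sequences ship with the package), adequate for architecture-rule and
    census work but not for sequence lookups.
    """
    data = resources.files("fyvescan.data")
    with resources.as_file(data / "atfyve_architectures.tsv") as path:
        annotations = read_domain_table(path)
    lengths: dict[str, int] = {}
    with resources.as_file(data / "atfyve_protein_lengths.tsv") as path:
        for line in path.read_text().splitlines()[1:]:
            pid, length = line.split("\t")
            lengths[pid] = int(length)
    return annotations, lengths
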