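"""Ground-truthed synthetic proteomes for exercising the pipeline.

Every emitter here is a pure function of a seed, and each emitted object
comes with its truth: FYVE domain boundaries, the eight cysteine positions,
the binding-motif class, architecture class, blade spans and contact sets.
Study conditions are encoded in the defaults of :class:`SyntheticSpec`: the
proteome census mirrors the five-class family (2/2/1/1/9), class V proteins
carry six-blade propeller arrays at a 57-residue period, and docking
experiments comprise six runs per headgroup.

Two identifiability choices are deliberate and documented:

* generated proteins are *verified* at zero mutation — the skeleton is
  resampled (deterministically) until scaffold detection, motif
  classification, architecture assignment and blade detection all recover
  the recorded truth, so the zero-noise recovery theorem holds by
  construction rather than with high probability;
* point mutations never substitute *to* cysteine and never touch the eight
  scaffold cysteines or the central binding motif (unless ``corrupt_core``
  is requested), so the mutation rate dials motif degradation without
  changing zinc-scaffold arity. Mutation positions and target residues are
  drawn once per seed, independently of the rate, making damage nested
  across rates: recovery curves on a fixed seed ladder degrade
  monotonically by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .docking_consensus import ContactRun, Residue
from .fyve_classifier import (
    assign_architecture_class,
    load_arabidopsis_architectures,
)
from .motif_engine import classify_binding_motif, find_fyve_scaffold
from .rcc1_repeats import DEFAULT_BLADE_PROFILE, BladeProfile, detect_repeats
from .seq_io import AMINO_ACIDS, DomainAnnotation, ProteinRecord

#: substitution targets for point mutations; cysteine excluded by design
_SUB_ALPHABET = "ADEFGHIKLMNPQRSTVWY"
_HYDROPHOBIC = "AVLIMF"

#: the four database entries annotated as FYVE proteins that carry no
#: eight-cysteine scaffold; used for the misannotation fixture
DECOY_ACCESSIONS = ("AT1G61620", "AT1G66040", "AT1G66050", "AT5G39550")

CLASS_LABELS = ("I", "II", "III", "IV", "V")
_CLASS_CODES = {label: i + 1 for i, label in enumerate(CLASS_LABELS)}


@dataclass(frozen=True)
class SyntheticSpec:
    """All knobs of the generator; the seed fixes every random draw."""

    seed: int = 0
    background_composition: Mapping[str, float] | None = None
    mutation_rate: float = 0.0
    class_counts: Mapping[str, int] = field(
        default_factory=lambda: {"I": 2, "II": 2, "III": 1, "IV": 1, "V": 9}
    )
    rcc1_blades: int = 6
    blade_period: int = 57
    contact_noise: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mutation_rate < 1.0):
            raise ValueError("mutation_rate must lie in [0, 1)")
        if not (0.0 <= self.contact_noise < 1.0):
            raise ValueError("contact_noise must lie in [0, 1)")
        if not (3 <= self.rcc1_blades <= 7):
            raise ValueError("rcc1_blades must lie in [3, 7]")
        if not (51 <= self.blade_period <= 68):
            raise ValueError("blade_period must lie in [51, 68]")
        for label in self.class_counts:
            if label not in CLASS_LABELS:
                raise ValueError(f"unknown class label {label!r}")


def _composition_arrays(
    composition: Mapping[str, float] | None, exclude: str = ""
) -> tuple[list[str], np.ndarray]:
    if composition is None:
        composition = {aa: 1.0 for aa in AMINO_ACIDS}
    letters = [aa for aa in composition if aa not in exclude]
    weights = np.array([composition[aa] for aa in letters], dtype=float)
    return letters, weights / weights.sum()


def _random_sequence(
    rng: np.random.Generator,
    n: int,
    composition: Mapping[str, float] | None = None,
    exclude: str = "",
) -> str:
    if n == 0:
        return ""
    letters, probs = _composition_arrays(composition, exclude)
    return "".join(rng.choice(letters, size=n, p=probs))


def _mutate(
    sequence: str,
    rng: np.random.Generator,
    rate: float,
    protected: set[int],
) -> str:
    """Point substitutions outside ``protected`` (1-based positions).

    Positions and target residues are drawn unconditionally so that runs at
    different rates from the same generator state produce nested mutation
    sets.
    """
    n = len(sequence)
    u = rng.random(n)
    targets = rng.integers(0, len(_SUB_ALPHABET), n)
    if rate == 0.0:
        return sequence
    out = list(sequence)
    for i in range(n):
        if u[i] < rate and (i + 1) not in protected:
            out[i] = _SUB_ALPHABET[targets[i]]
    return "".join(out)


# ---------------------------------------------------------------------------
# FYVE domain templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FyveDomainTruth:
    """Ground truth of one generated FYVE domain (domain-local, 1-based)."""

    motif_class: str
    cys_positions: tuple[int, ...]
    central_span: tuple[int, int]
    wanchor_span: tuple[int, int]
    turret_span: tuple[int, int]
    interface_span: tuple[int, int]
    cterm_span: tuple[int, int]
    corrupted: bool = False

    def shifted(self, offset: int) -> "FyveDomainTruth":
        shift = lambda span: (span[0] + offset, span[1] + offset)
        return FyveDomainTruth(
            self.motif_class,
            tuple(p + offset for p in self.cys_positions),
            shift(self.central_span),
            shift(self.wanchor_span),
            shift(self.turret_span),
            shift(self.interface_span),
            shift(self.cterm_span),
            self.corrupted,
        )


def _fyve_template(
    motif_class: str,
    rng: np.random.Generator,
    composition: Mapping[str, float] | None = None,
) -> tuple[str, FyveDomainTruth]:
    """Build one FYVE domain with the full motif layout of its class.

    Filler positions avoid C (scaffold arity must stay exactly eight) and W
    (so the N-terminal WxxD/WxxG anchor is unique).
    """
    if motif_class not in ("classic", "variant"):
        raise ValueError(f"motif_class must be classic or variant, got {motif_class!r}")

    def fill(n: int) -> str:
        return _random_sequence(rng, n, composition, exclude="CW")

    def hydro(n: int) -> str:
        return "".join(rng.choice(list(_HYDROPHOBIC), size=n))

    parts: list[str] = [fill(2)]
    if motif_class == "classic":
        parts.append("W" + fill(2) + "D")          # 3-6   WxxD
        parts.append(fill(1))                      # 7
        parts.append(hydro(10))                    # 8-17  dimer interface
        parts.append("C" + fill(2) + "C")          # 18-21 cys pair 1
        parts.append(fill(6))                      # 22-27
        parts.append("C" + fill(2) + "C")          # 28-31 cys pair 2
        turret = list(fill(6))                     # 32-37 turret loop
        turret[int(rng.integers(6))] = str(rng.choice(list(_HYDROPHOBIC)))
        parts.append("".join(turret))
        parts.append("RRHHCR")                     # 38-43 central motif (C=42)
        parts.append(fill(2) + "C")                # 44-46 cys 6
        parts.append(fill(8))                      # 47-54
        parts.append("RVC")                        # 55-57 R(V/I)C (C=57)
        parts.append(fill(2) + "C")                # 58-60 cys 8
        parts.append(fill(4))                      # 61-64
        truth = FyveDomainTruth(
            motif_class="classic",
            cys_positions=(18, 21, 28, 31, 42, 46, 57, 60),
            central_span=(38, 43),
            wanchor_span=(3, 6),
            turret_span=(32, 37),
            interface_span=(8, 17),
            cterm_span=(55, 57),
        )
    else:
        parts.append("W" + fill(2) + "G")          # 3-6   WxxG
        parts.append(fill(1))                      # 7
        parts.append("A" + hydro(2) + "AP" + hydro(5))  # 8-17, AxxAP at 8-12
        parts.append("C" + fill(2) + "C")          # 18-21
        parts.append(fill(6))                      # 22-27
        parts.append("C" + fill(2) + "C")          # 28-31
        parts.append(fill(1) + "F" + fill(3) + "R")  # 32-37 turret (F second, R last)
        parts.append("KRHNCY")                     # 38-43 variant central (C=42)
        parts.append(fill(2) + "C")                # 44-46 cys 6
        parts.append("H" + fill(2) + "SSKK")       # 47-53 class-V accessory motif
        parts.append(fill(1))                      # 54
        parts.append("LYR")                        # 55-57 (L/F/P)YR
        parts.append(fill(1) + "C")                # 58-59 cys 7
        parts.append(fill(2) + "C")                # 60-62 cys 8
        parts.append(fill(4))                      # 63-66
        truth = FyveDomainTruth(
            motif_class="variant",
            cys_positions=(18, 21, 28, 31, 42, 46, 59, 62),
            central_span=(38, 43),
            wanchor_span=(3, 6),
            turret_span=(32, 37),
            interface_span=(8, 17),
            cterm_span=(55, 57),
        )
    return "".join(parts), truth


def make_fyve_domain(
    motif_class: str,
    seed: int,
    mutation_rate: float = 0.0,
    corrupt_core: bool = False,
    composition: Mapping[str, float] | None = None,
) -> tuple[str, FyveDomainTruth]:
    """One FYVE domain sequence plus its ground truth.

    ``corrupt_core`` knocks out the fourth cysteine pair (the decoy used for
    misannotation fixtures): the result keeps a FYVE-like layout but only
    six cysteines, so scaffold detection must fail.
    """
    rng = np.random.default_rng([int(seed), 11])
    seq, truth = _fyve_template(motif_class, rng, composition)
    if corrupt_core:
        chars = list(seq)
        for pos in truth.cys_positions[6:]:
            chars[pos - 1] = "S"
        seq = "".join(chars)
        truth = FyveDomainTruth(
            truth.motif_class, truth.cys_positions, truth.central_span,
            truth.wanchor_span, truth.turret_span, truth.interface_span,
            truth.cterm_span, corrupted=True,
        )
    if mutation_rate > 0.0:
        rng_mut = np.random.default_rng([int(seed), 13])
        protected = set(truth.cys_positions) | set(
            range(truth.central_span[0], truth.central_span[1] + 1)
        )
        seq = _mutate(seq, rng_mut, mutation_rate, protected)
    return seq, truth


# ---------------------------------------------------------------------------
# blades
# ---------------------------------------------------------------------------

def _blade_sequence(
    rng: np.random.Generator,
    period: int,
    profile: BladeProfile = DEFAULT_BLADE_PROFILE,
) -> str:
    """One consensus blade: anchors planted exactly, filler avoids the
    anchor residues (and C) so the anchor score is exactly 1.0."""
    exclude = "C" + "".join(sorted({aa for cls, _ in profile.anchors for aa in cls}))
    chars = list(_random_sequence(rng, period, exclude=exclude))
    for residues, fraction in profile.anchors:
        chars[profile.anchor_center(fraction, period)] = sorted(residues)[0]
    return "".join(chars)


def make_blade_array(
    n_blades: int,
    period: int = 57,
    seed: int = 0,
    profile: BladeProfile = DEFAULT_BLADE_PROFILE,
) -> tuple[str, list[tuple[int, int]]]:
    """A tandem blade array plus the true (start, end) span of each blade."""
    rng = np.random.default_rng([int(seed), 17])
    parts, spans = [], []
    pos = 1
    for _ in range(n_blades):
        parts.append(_blade_sequence(rng, period, profile))
        spans.append((pos, pos + period - 1))
        pos += period
    return "".join(parts), spans


# ---------------------------------------------------------------------------
# whole proteins and proteomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinTruth:
    protein_id: str
    architecture_class: str
    motif_class: str
    fyve_span: tuple[int, int]
    domain_truth: FyveDomainTruth      # absolute coordinates
    blade_spans: tuple[tuple[int, int], ...] = ()


@dataclass(frozen=True)
class Proteome:
    records: tuple[ProteinRecord, ...]
    annotations: tuple[DomainAnnotation, ...]
    truth: tuple[ProteinTruth, ...]

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            (
                t.protein_id,
                t.architecture_class,
                t.motif_class,
                t.fyve_span[0],
                t.fyve_span[1],
                ";".join(str(p) for p in t.domain_truth.cys_positions),
                len(t.blade_spans),
                ";".join(f"{s}-{e}" for s, e in t.blade_spans),
            )
            for t in self.truth
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "protein_id", "architecture_class", "motif_class",
                "fyve_start", "fyve_end", "cys_positions",
                "n_blades", "blade_spans",
            ],
        )


def _assemble_protein(
    label: str,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    protein_id: str,
    with_dzc: bool,
) -> tuple[str, list[DomainAnnotation], ProteinTruth]:
    comp = spec.background_composition
    motif_class = "variant" if label == "V" else "classic"

    segments: list[tuple[str, str | None]] = []  # (sequence, domain name)

    def linker(n: int) -> None:
        segments.append((_random_sequence(rng, n, comp), None))

    def block(name: str, n: int) -> None:
        segments.append((_random_sequence(rng, n, comp), name))

    fyve_seq, fyve_truth = _fyve_template(motif_class, rng, comp)
    blade_spans_local: list[tuple[int, int]] = []

    if label == "I":
        linker(25); segments.append((fyve_seq, "FYVE")); linker(20)
        block("Fab1_TCP", 120); linker(15); block("PIPKc", 150); linker(10)
    elif label == "II":
        linker(25); segments.append((fyve_seq, "FYVE")); linker(20)
        block("DUF500", 130); linker(15)
    elif label == "III":
        linker(15); segments.append((fyve_seq, "FYVE")); linker(200)
    elif label == "IV":
        linker(200); segments.append((fyve_seq, "FYVE")); linker(15)
    elif label == "V":
        linker(20); block("PH_PLC", 110); linker(25)
        array, blade_spans_local = make_blade_array(
            spec.rcc1_blades, spec.blade_period,
            seed=int(rng.integers(2**31)),
        )
        segments.append((array, "RCC1-array"))
        linker(40); segments.append((fyve_seq, "FYVE")); linker(10)
        if with_dzc:
            block("DZC", 40); linker(8)
    else:
        raise ValueError(f"unknown architecture class {label!r}")

    sequence_parts: list[str] = []
    annotations: list[DomainAnnotation] = []
    pos = 1
    fyve_offset = 0
    blade_spans_abs: tuple[tuple[int, int], ...] = ()
    for seg_seq, name in segments:
        start, end = pos, pos + len(seg_seq) - 1
        if name == "FYVE":
            fyve_offset = start - 1
            annotations.append(DomainAnnotation(protein_id, "FYVE", start, end))
        elif name == "RCC1-array":
            blade_spans_abs = tuple(
                (s + start - 1, e + start - 1) for s, e in blade_spans_local
            )
            for s, e in blade_spans_abs:
                annotations.append(DomainAnnotation(protein_id, "RCC1", s, e))
        elif name is not None:
            annotations.append(DomainAnnotation(protein_id, name, start, end))
        sequence_parts.append(seg_seq)
        pos = end + 1

    sequence = "".join(sequence_parts)
    truth = ProteinTruth(
        protein_id=protein_id,
        architecture_class=label,
        motif_class=motif_class,
        fyve_span=(fyve_offset + 1, fyve_offset + len(fyve_seq)),
        domain_truth=fyve_truth.shifted(fyve_offset),
        blade_spans=blade_spans_abs,
    )
    return sequence, annotations, truth


def _truth_recovered(
    sequence: str,
    annotations: Sequence[DomainAnnotation],
    truth: ProteinTruth,
) -> bool:
    """Zero-mutation identifiability check used by the resampling loop."""
    scaffolds = find_fyve_scaffold(sequence)
    if len(scaffolds) != 1:
        return False
    if scaffolds[0].cys_positions != truth.domain_truth.cys_positions:
        return False
    call = classify_binding_motif(sequence, scaffolds[0])
    if call.label != truth.motif_class:
        return False
    arch = assign_architecture_class(annotations, len(sequence))
    if arch.label != truth.architecture_class:
        return False
    repeats = detect_repeats(sequence)
    if len(repeats) != len(truth.blade_spans):
        return False
    if truth.blade_spans:
        if abs(repeats[0].start - truth.blade_spans[0][0]) > 3:
            return False
    return True


def make_protein(
    architecture_class: str,
    spec: SyntheticSpec,
    index: int = 0,
    with_dzc: bool | None = None,
) -> tuple[ProteinRecord, list[DomainAnnotation], ProteinTruth]:
    """One synthetic protein of the given architecture class, plus truth.

    The unmutated skeleton is resampled (deterministically, bounded) until
    every pipeline stage recovers the recorded truth; mutations at
    ``spec.mutation_rate`` are applied afterwards, outside the protected
    core.
    """
    if architecture_class not in CLASS_LABELS:
        raise ValueError(f"unknown architecture class {architecture_class!r}")
    code = _CLASS_CODES[architecture_class]
    if with_dzc is None:
        # seven of nine class V proteins carry the C-terminal DZC motif
        with_dzc = architecture_class == "V" and (index % 9) < 7
    protein_id = f"SYN-{architecture_class}-{index + 1:03d}"

    for attempt in range(30):
        rng = np.random.default_rng([spec.seed, code, index, attempt])
        sequence, annotations, truth = _assemble_protein(
            architecture_class, spec, rng, protein_id, with_dzc
        )
        if _truth_recovered(sequence, annotations, truth):
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError(f"could not assemble identifiable {protein_id}")

    if spec.mutation_rate > 0.0:
        rng_mut = np.random.default_rng([spec.seed, code, index, 101])
        protected = set(truth.domain_truth.cys_positions) | set(
            range(truth.domain_truth.central_span[0],
                  truth.domain_truth.central_span[1] + 1)
        )
        sequence = _mutate(sequence, rng_mut, spec.mutation_rate, protected)

    record = ProteinRecord(
        protein_id, sequence, f"synthetic class {architecture_class}"
    )
    return record, annotations, truth


def make_proteome(spec: SyntheticSpec) -> Proteome:
    """A full proteome per ``spec.class_counts``, with annotations and truth."""
    records, annotations, truths = [], [], []
    for label in CLASS_LABELS:
        for index in range(spec.class_counts.get(label, 0)):
            record, anns, truth = make_protein(label, spec, index)
            records.append(record)
            annotations.extend(anns)
            truths.append(truth)
    return Proteome(tuple(records), tuple(annotations), tuple(truths))


def write_proteome(proteome: Proteome, outdir: str | Path) -> dict[str, Path]:
    """Write proteins.fasta, domains.tsv and truth.tsv under ``outdir``."""
    from .seq_io import write_domain_table, write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteins.fasta",
        "domains": outdir / "domains.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(proteome.records, paths["fasta"])
    write_domain_table(proteome.annotations, paths["domains"])
    proteome.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# misannotation fixture
# ---------------------------------------------------------------------------

def make_misannotation_fixture(
    seed: int = 0,
) -> tuple[list[ProteinRecord], set[str]]:
    """The 19-entry FYVE-annotated fixture: 15 genuine + 4 scaffold-less.

    Genuine entries get a complete eight-cysteine domain of their class's
    binding signature (classic for I-IV, variant for V); the four decoy
    accessions get a corrupt-core template with only six cysteines. Returns
    the records and the set of genuinely-FYVE ids.
    """
    annotations, lengths = load_arabidopsis_architectures()
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for ann in annotations:
        by_protein.setdefault(ann.protein_id, []).append(ann)

    records: list[ProteinRecord] = []
    true_ids: set[str] = set()
    for i, pid in enumerate(sorted(by_protein)):
        arch = assign_architecture_class(by_protein[pid], lengths[pid])
        motif_class = "variant" if arch.label == "V" else "classic"
        domain, _ = make_fyve_domain(motif_class, seed=_sub_seed(seed, 29, i))
        rng = np.random.default_rng([int(seed), 37, i])
        seq = (
            _random_sequence(rng, 25, exclude="C")
            + domain
            + _random_sequence(rng, 25, exclude="C")
        )
        records.append(ProteinRecord(pid, seq, "annotated-as-FYVE"))
        true_ids.add(pid)
    for i, pid in enumerate(DECOY_ACCESSIONS):
        domain, _ = make_fyve_domain(
            "classic", seed=_sub_seed(seed, 41, i), corrupt_core=True
        )
        rng = np.random.default_rng([int(seed), 43, i])
        seq = (
            _random_sequence(rng, 25, exclude="C")
            + domain
            + _random_sequence(rng, 25, exclude="C")
        )
        records.append(ProteinRecord(pid, seq, "annotated-as-FYVE decoy"))
    return records, true_ids


def _sub_seed(seed: int, stream: int, index: int) -> int:
    return int(np.random.default_rng([int(seed), stream, index]).integers(2**31))


# ---------------------------------------------------------------------------
# contact runs and coordinate complexes
# ---------------------------------------------------------------------------

def make_contact_runs(
    true_contacts: Iterable[Residue],
    n_runs_per_headgroup: int = 6,
    contact_noise: float = 0.0,
    seed: int = 0,
    headgroups: Sequence[str] = ("Ins13P2", "Ins15P2"),
    decoy_pool: Sequence[Residue] | None = None,
) -> list[ContactRun]:
    """Noisy replicate contact runs around one true contact set.

    Noise model: each true contact is dropped independently with probability
    ``contact_noise``; with the same probability one spurious residue (drawn
    from ``decoy_pool``) is added to the run. Half the runs per headgroup
    are labelled rigid, half flexible, mirroring the usual paired docking
    scenarios.
    """
    if n_runs_per_headgroup < 1:
        raise ValueError("need at least one run per headgroup")
    truth = sorted(set(true_contacts))
    if decoy_pool is None:
        decoy_pool = tuple((900 + i, "ALA") for i in range(max(10, 3 * len(truth))))
    rng = np.random.default_rng([int(seed), 31])
    runs: list[ContactRun] = []
    for headgroup in headgroups:
        for i in range(n_runs_per_headgroup):
            contacts = {r for r in truth if rng.random() >= contact_noise}
            if decoy_pool and rng.random() < contact_noise:
                contacts.add(decoy_pool[int(rng.integers(len(decoy_pool)))])
            runs.append(
                ContactRun(
                    run_id=f"{headgroup}_run{i + 1}",
                    headgroup=headgroup,
                    scenario="rigid" if i < n_runs_per_headgroup / 2 else "flexible",
                    contacts=frozenset(contacts),
                )
            )
    return runs


def _pdb_atom_line(
    serial: int, name: str, resname: str, chain: str, resseq: int,
    xyz: tuple[float, float, float], element: str, record: str = "ATOM",
) -> str:
    x, y, z = xyz
    return (
        f"{record:<6}{serial:>5} {name:<4} {resname:>3} {chain}{resseq:>4}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2}"
    )


def make_contact_complex(
    true_positions: Sequence[int],
    n_residues: int = 20,
    contact_distance: float = 3.0,
) -> tuple[str, str, frozenset[Residue]]:
    """A synthetic receptor/ligand PDB pair with planted contacts.

    The receptor is a row of alanine C-alpha atoms 10 Å apart; the ligand
    places one phosphorus atom ``contact_distance`` away from each planted
    residue and one far decoy atom. Deterministic geometry; the expected
    contact set at any cutoff above ``contact_distance`` (and below the
    inter-residue spacing) is exactly the planted residues.
    """
    receptor_lines = [
        _pdb_atom_line(i, "CA", "ALA", "A", i, (10.0 * i, 0.0, 0.0), "C")
        for i in range(1, n_residues + 1)
    ]
    ligand_lines = [
        _pdb_atom_line(
            j + 1, f"P{j + 1}", "INS", "L", 1,
            (10.0 * pos, contact_distance, 0.0), "P", record="HETATM",
        )
        for j, pos in enumerate(true_positions)
    ]
    ligand_lines.append(
        _pdb_atom_line(
            len(ligand_lines) + 1, "O1", "INS", "L", 1,
            (0.0, 500.0, 0.0), "O", record="HETATM",
        )
    )
    receptor_pdb = "\n".join(receptor_lines + ["END"]) + "\n"
    ligand_pdb = "\n".join(ligand_lines + ["END"]) + "\n"
    expected = frozenset((pos, "ALA") for pos in true_positions)
    return receptor_pdb, ligand_pdb, expected
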