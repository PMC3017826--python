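"""Consensus aggregation of ligand-protein contact lists from docking runs.

Docking a phosphoinositide headgroup repeatedly against the same receptor
yields one residue contact set per run. A residue is called a consensus
interactor for a headgroup when it contacts the ligand in at least a
threshold fraction of that headgroup's runs — with the conventional 50%
threshold over six runs this means 3 or more times, the ceiling being taken
so that "50% or more" stays literal for odd run counts.

Contacts can be read from a run TSV or derived from receptor/ligand
coordinates with a heavy-atom distance criterion (default 4.0 Å between any
receptor heavy atom and any ligand heavy atom). The distance cutoff is a
contact definition, not a docking-grid energy cutoff, and is a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

Residue = tuple[int, str]  # (sequence position, 3-letter residue name)


@dataclass(frozen=True)
class ContactRun:
    """The residue contact set of one docking run."""

    run_id: str
    headgroup: str
    scenario: str
    contacts: frozenset[Residue]
    protein_id: str = ""

    def __post_init__(self) -> None:
        if self.scenario not in ("rigid", "flexible"):
            raise ValueError("scenario must be 'rigid' or 'flexible'")


@dataclass(frozen=True)
class ConsensusContacts:
    """Aggregate of one headgroup's runs under a support threshold."""

    headgroup: str
    threshold_fraction: float
    n_runs: int
    min_count: int
    residues: Mapping[Residue, int]  # support count for every residue seen
    protein_id: str = ""

    @property
    def reported(self) -> tuple[Residue, ...]:
        """Residues at or above the support threshold, ordered by position."""
        return tuple(
            sorted(r for r, n in self.residues.items() if n >= self.min_count)
        )


def consensus(
    runs: Iterable[ContactRun],
    threshold_fraction: float = 0.5,
    pool_scenarios: bool = True,
) -> dict[str, ConsensusContacts]:
    """Per-headgroup consensus contacts.

    ``min_count = ceil(threshold_fraction * n_runs)`` for each headgroup's
    own run count. With ``pool_scenarios`` False, rigid and flexible runs
    are aggregated separately under keys ``"<headgroup>/<scenario>"``.
    """
    runs = list(runs)
    if not runs:
        raise ValueError("no contact runs supplied")
    if not (0.0 < threshold_fraction <= 1.0):
        raise ValueError("threshold_fraction must lie in (0, 1]")
    seen_ids = [r.run_id for r in runs]
    if len(set(seen_ids)) != len(seen_ids):
        raise ValueError("run_id values must be unique within a collection")

    groups: dict[str, list[ContactRun]] = {}
    for run in runs:
        key = run.headgroup if pool_scenarios else f"{run.headgroup}/{run.scenario}"
        groups.setdefault(key, []).append(run)

    out: dict[str, ConsensusContacts] = {}
    for key, members in groups.items():
        support: dict[Residue, int] = {}
        for run in members:
            for residue in run.contacts:
                support[residue] = support.get(residue, 0) + 1
        n = len(members)
        protein_ids = {r.protein_id for r in members if r.protein_id}
        if len(protein_ids) > 1:
            raise ValueError(f"{key}: runs span multiple proteins {protein_ids}")
        out[key] = ConsensusContacts(
            headgroup=key,
            threshold_fraction=threshold_fraction,
            n_runs=n,
            min_count=math.ceil(threshold_fraction * n),
            residues=dict(sorted(support.items())),
            protein_id=next(iter(protein_ids), ""),
        )
    return out


@dataclass(frozen=True)
class HeadgroupComparison:
    shared: tuple[Residue, ...]
    only_first: tuple[Residue, ...]
    only_second: tuple[Residue, ...]


def compare_headgroups(
    consensus_a: ConsensusContacts, consensus_b: ConsensusContacts
) -> HeadgroupComparison:
    """Shared and exclusive consensus residues of two headgroups.

    Answers whether the two phosphoinositide headgroups are coordinated by
    the same residue set. Both consensuses must describe the same protein.
    """
    if (
        consensus_a.protein_id
        and consensus_b.protein_id
        and consensus_a.protein_id != consensus_b.protein_id
    ):
        raise ValueError(
            f"protein mismatch: {consensus_a.protein_id!r} vs "
            f"{consensus_b.protein_id!r}"
        )
    a, b = set(consensus_a.reported), set(consensus_b.reported)
    return HeadgroupComparison(
        shared=tuple(sorted(a & b)),
        only_first=tuple(sorted(a - b)),
        only_second=tuple(sorted(b - a)),
    )


# ---------------------------------------------------------------------------
# coordinate mode
# ---------------------------------------------------------------------------

def _heavy_atoms(structure) -> list[tuple[int, str, np.ndarray]]:
    """(residue position, residue name, coord) for every non-hydrogen atom."""
    out = []
    for model in structure:
        for chain in model:
            for residue in chain:
                resseq = residue.id[1]
                resname = residue.get_resname().strip()
                for atom in residue:
                    if atom.element in ("H", "D"):
                        continue
                    out.append((resseq, resname, atom.coord))
        break  # first model only
    return out


def _as_structure(source, label: str):
    from Bio.PDB import PDBParser

    if isinstance(source, (str, Path)):
        parser = PDBParser(QUIET=True)
        try:
            return parser.get_structure(label, str(source))
        except Exception as exc:  # Bio.PDB raises assorted types
            raise ValueError(f"cannot parse {label} coordinates: {exc}") from exc
    return source


def contacts_from_coordinates(
    receptor_structure,
    ligand_structure,
    cutoff: float = 4.0,
    run_id: str = "run",
    headgroup: str = "other:unknown",
    scenario: str = "rigid",
    protein_id: str = "",
) -> ContactRun:
    """Residues with any heavy atom within ``cutoff`` of a ligand heavy atom.

    Structures may be paths to PDB files or parsed Bio.PDB entities. The
    criterion is symmetric and monotone: shrinking the cutoff never adds
    residues.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    receptor = _as_structure(receptor_structure, "receptor")
    ligand = _as_structure(ligand_structure, "ligand")
    receptor_atoms = _heavy_atoms(receptor)
    ligand_atoms = _heavy_atoms(ligand)
    if not receptor_atoms or not ligand_atoms:
        raise ValueError("structures contain no heavy atoms")

    tree = cKDTree(np.array([c for _, _, c in ligand_atoms], dtype=float))
    receptor_coords = np.array([c for _, _, c in receptor_atoms], dtype=float)
    neighbor_lists = tree.query_ball_point(receptor_coords, r=cutoff)
    contacts = frozenset(
        (receptor_atoms[i][0], receptor_atoms[i][1])
        for i, hits in enumerate(neighbor_lists)
        if hits
    )
    return ContactRun(run_id, headgroup, scenario, contacts, protein_id)


# ---------------------------------------------------------------------------
# TSV interchange
# ---------------------------------------------------------------------------

_RUN_COLUMNS = ["run_id", "headgroup", "scenario", "residue_position", "residue_name"]


def read_contact_table(path: str | Path) -> list[ContactRun]:
    """Read a contact-run TSV (one row per contact)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _RUN_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    grouped: dict[tuple[str, str, str], set[Residue]] = {}
    for row in frame.itertuples(index=False):
        key = (row.run_id, row.headgroup, row.scenario)
        grouped.setdefault(key, set()).add(
            (int(row.residue_position), row.residue_name)
        )
    return [
        ContactRun(run_id, headgroup, scenario, frozenset(contacts))
        for (run_id, headgroup, scenario), contacts in sorted(grouped.items())
    ]


def write_contact_table(runs: Iterable[ContactRun], path: str | Path) -> None:
    rows = [
        (r.run_id, r.headgroup, r.scenario, pos, name)
        for r in runs
        for pos, name in sorted(r.contacts)
    ]
    pd.DataFrame(rows, columns=_RUN_COLUMNS).to_csv(path, sep="\t", index=False)


def write_consensus_table(
    consensuses: Mapping[str, ConsensusContacts], path: str | Path
) -> None:
    rows = []
    for key in sorted(consensuses):
        cons = consensuses[key]
        for (pos, name), count in sorted(cons.residues.items()):
            rows.append(
                (key, pos, name, count, cons.n_runs,
                 int(count >= cons.min_count))
            )
    pd.DataFrame(
        rows,
        columns=["headgroup", "residue_position", "residue_name",
                 "support", "n_runs", "reported"],
    ).to_csv(path, sep="\t", index=False)
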