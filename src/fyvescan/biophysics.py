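"""Sequence-based charge and hydropathy characterization of FYVE domains.

Net charge is computed as a sum of independent Henderson-Hasselbalch
titrations over the ionizable side chains (plus, optionally, the chain
termini), with the two structural Zn2+ ions added explicitly. This is a
sequence-level proxy: it deliberately ignores the electrostatic coupling a
Poisson-Boltzmann treatment would capture, so absolute values are expected
to differ from structure-based totals and only orderings and trends should
be compared across domains.

The default pH is 6.5, the regime where the EEA1 FYVE domain is estimated
to be predominantly binding-competent. The eight scaffold cysteines are, by
default, treated as zinc-coordinated and charge-neutral (``cys_mode
"coordinated_neutral"``); the two alternatives — fully titratable
(``"free"``) or deprotonated thiolates at -1 each (``"thiolate"``) — are one
flag away, since the protonation state of zinc-bound thiols in such models
is genuinely ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .motif_engine import KYTE_DOOLITTLE, ScaffoldHit, hydrophobicity

#: EMBOSS-like side-chain pKa set; overridable per model.
DEFAULT_PKA: Mapping[str, float] = {
    "D": 3.65,
    "E": 4.25,
    "H": 6.0,
    "C": 8.3,
    "Y": 10.07,
    "K": 10.53,
    "R": 12.48,
}
PKA_N_TERMINUS = 8.6
PKA_C_TERMINUS = 3.6

_BASIC = frozenset("KRH")
_ACIDIC = frozenset("DECY")

#: residues counted as hydrophobic in turret-loop censuses
HYDROPHOBIC_RESIDUES = frozenset("AVLIMFWY")

CYS_MODES = ("free", "coordinated_neutral", "thiolate")


@dataclass(frozen=True)
class TitrationModel:
    """Parameters of the per-group titration proxy.

    zinc_count defaults to the two structural ions of the FYVE fold; each
    ion contributes +2 regardless of pH.
    """

    pka: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PKA))
    include_termini: bool = False
    zinc_count: int = 2
    zinc_charge: float = 2.0
    cys_mode: str = "coordinated_neutral"

    def __post_init__(self) -> None:
        if self.zinc_count < 0:
            raise ValueError("zinc_count must be >= 0")
        if self.cys_mode not in CYS_MODES:
            raise ValueError(f"cys_mode must be one of {CYS_MODES}")
        for residue, value in self.pka.items():
            if not (0.0 < value < 14.0):
                raise ValueError(f"pKa({residue})={value} outside (0, 14)")


DEFAULT_MODEL = TitrationModel()


@dataclass(frozen=True)
class ChargeProfile:
    """Per-residue charge contributions and their total at one pH."""

    contributions: tuple[tuple[int, str, float], ...]
    zinc_contribution: float
    net_charge: float
    ph: float

    def __post_init__(self) -> None:
        total = sum(q for _, _, q in self.contributions) + self.zinc_contribution
        if abs(total - self.net_charge) > 1e-9:
            raise ValueError("net_charge does not equal the contribution sum")


def _basic_charge(ph: float, pka: float) -> float:
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


def _acidic_charge(ph: float, pka: float) -> float:
    return -1.0 / (1.0 + 10.0 ** (pka - ph))


def charge_profile(
    domain_sequence: str,
    ph: float = 6.5,
    model: TitrationModel | None = None,
    scaffold: ScaffoldHit | None = None,
) -> ChargeProfile:
    """Per-group Henderson-Hasselbalch charges at one pH.

    ``scaffold`` identifies which cysteines are the zinc-coordinating ones;
    it is required whenever ``cys_mode != "free"`` and the sequence contains
    cysteine. Non-scaffold cysteines always titrate freely. X placeholders
    contribute nothing.
    """
    mdl = model or DEFAULT_MODEL
    if not (0.0 < ph < 14.0):
        raise ValueError("pH must lie in (0, 14)")
    seq = domain_sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    if mdl.cys_mode != "free" and scaffold is None and "C" in seq:
        raise ValueError(
            f"cys_mode {mdl.cys_mode!r} requires a scaffold to identify the "
            "coordinating cysteines"
        )
    scaffold_cys = set(scaffold.cys_positions) if scaffold else set()

    contribs: list[tuple[int, str, float]] = []
    for pos, aa in enumerate(seq, start=1):
        if aa == "C" and pos in scaffold_cys:
            if mdl.cys_mode == "coordinated_neutral":
                q = 0.0
            elif mdl.cys_mode == "thiolate":
                q = -1.0
            else:
                q = _acidic_charge(ph, mdl.pka["C"])
        elif aa in _BASIC:
            q = _basic_charge(ph, mdl.pka[aa])
        elif aa in _ACIDIC:
            q = _acidic_charge(ph, mdl.pka[aa])
        else:
            q = 0.0
        contribs.append((pos, aa, q))
    if mdl.include_termini:
        contribs.append((1, "N-terminus", _basic_charge(ph, PKA_N_TERMINUS)))
        contribs.append((len(seq), "C-terminus", _acidic_charge(ph, PKA_C_TERMINUS)))

    zinc = mdl.zinc_count * mdl.zinc_charge
    net = sum(q for _, _, q in contribs) + zinc
    return ChargeProfile(tuple(contribs), zinc, net, ph)


def net_charge(
    domain_sequence: str,
    ph: float = 6.5,
    model: TitrationModel | None = None,
    scaffold: ScaffoldHit | None = None,
) -> float:
    """Signed net charge of the sequence at ``ph`` under ``model``."""
    return charge_profile(domain_sequence, ph, model, scaffold).net_charge


def titration_curve(
    domain_sequence: str,
    ph_grid: Sequence[float],
    model: TitrationModel | None = None,
    scaffold: ScaffoldHit | None = None,
) -> list[tuple[float, float]]:
    """Net charge evaluated over a strictly increasing pH grid."""
    grid = list(ph_grid)
    if not grid:
        raise ValueError("empty pH grid")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("pH grid must be strictly increasing")
    return [
        (ph, net_charge(domain_sequence, ph, model, scaffold)) for ph in grid
    ]


def region_hydrophobic_load(call) -> tuple[int, float]:
    """Hydrophobic census of one FYVE domain call.

    Returns the number of hydrophobic residues (AVLIMFWY) in the turret
    loop and the mean Kyte-Doolittle hydropathy of the dimerization
    interface. Both regions must be present and non-empty.
    """
    turret = call.turret_loop
    interface = call.dimer_interface
    if turret is None or len(turret) == 0:
        raise ValueError(f"{call.protein_id}: empty turret loop")
    if interface is None or len(interface) == 0:
        raise ValueError(f"{call.protein_id}: empty dimerization interface")
    count = sum(1 for aa in turret.sequence if aa in HYDROPHOBIC_RESIDUES)
    return count, hydrophobicity(interface.sequence, KYTE_DOOLITTLE)
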