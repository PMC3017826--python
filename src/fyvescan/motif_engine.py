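"""PROSITE-style motif scanning and FYVE zinc-finger detection.

The FYVE fold is a small zinc finger held together by eight cysteines that
coordinate two Zn2+ ions in pairs. On sequence alone the fold shows up as
four cysteine pairs with short intra-pair and longer inter-pair spacings,
plus a small set of short motifs around the phosphoinositide-binding pocket:

* classic signature (PtdIns(3)P binders): N-terminal ``WxxD``, central
  ``R(R/K)HHCR`` and C-terminal ``R(V/I)C``;
* plant variant signature: ``WxxG`` (when present at all), central
  ``(K/R)(R/K)HNCY``, C-terminal ``(L/F/P)YR`` and an accessory
  ``(H/K/N)xx(S/T)(S/N)(K/R)K`` motif.

This module parses PROSITE-syntax patterns, enumerates *all* their matches
(including overlaps and every expansion of variable-length wildcards), finds
eight-cysteine scaffolds, and classifies the binding signature of a detected
scaffold as classic, variant or atypical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .seq_io import AMINO_ACIDS, VALID_RESIDUES

logger = logging.getLogger(__name__)

_ALPHABET = frozenset(AMINO_ACIDS)
_WILDCARD = frozenset(VALID_RESIDUES)  # x matches any residue, X included


class PrositeSyntaxError(ValueError):
    """Raised on malformed PROSITE pattern text; carries the char offset."""

    def __init__(self, message: str, position: int):
        super().__init__(f"position {position}: {message}")
        self.position = position


@dataclass(frozen=True)
class PatternElement:
    """One pattern element: an allowed-residue set with a repeat range."""

    token: str                 # canonical token text, without repeat suffix
    allowed: frozenset[str]
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.min_repeat <= self.max_repeat):
            raise ValueError(
                f"repeat range ({self.min_repeat},{self.max_repeat}) inverted"
            )


@dataclass(frozen=True)
class MotifPattern:
    name: str
    elements: tuple[PatternElement, ...]

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("pattern requires at least one element")

    def to_text(self) -> str:
        """Canonical PROSITE text; ``parse_prosite`` round-trips it."""
        parts = []
        for el in self.elements:
            if el.min_repeat == el.max_repeat:
                suffix = "" if el.min_repeat == 1 else f"({el.min_repeat})"
            else:
                suffix = f"({el.min_repeat},{el.max_repeat})"
            parts.append(el.token + suffix)
        return "-".join(parts)


@dataclass(frozen=True)
class MotifHit:
    """A pattern match; coordinates are 1-based inclusive."""

    pattern_name: str
    start: int
    end: int
    matched_text: str


def _parse_repeat(token: str, base_end: int, offset: int) -> tuple[int, int]:
    """Parse the optional ``(n)`` / ``(n,m)`` suffix of an element token."""
    rest = token[base_end:]
    if not rest:
        return 1, 1
    if not (rest.startswith("(") and rest.endswith(")")):
        raise PrositeSyntaxError(f"unexpected text {rest!r}", offset + base_end)
    body = rest[1:-1]
    try:
        if "," in body:
            lo_s, hi_s = body.split(",", 1)
            lo, hi = int(lo_s), int(hi_s)
        else:
            lo = hi = int(body)
    except ValueError as exc:
        raise PrositeSyntaxError(
            f"malformed repeat {rest!r}", offset + base_end
        ) from exc
    if lo < 0 or lo > hi:
        raise PrositeSyntaxError(
            f"invalid repeat range ({lo},{hi})", offset + base_end
        )
    return lo, hi


def _parse_element(token: str, offset: int) -> PatternElement:
    if not token:
        raise PrositeSyntaxError("empty element", offset)
    head = token[0]
    if head == "[" or head == "{":
        close = "]" if head == "[" else "}"
        end = token.find(close)
        if end == -1:
            raise PrositeSyntaxError(f"unbalanced {head!r}", offset)
        residues = token[1:end]
        if not residues:
            raise PrositeSyntaxError("empty residue class", offset)
        bad = set(residues) - _ALPHABET
        if bad:
            raise PrositeSyntaxError(
                f"non-residue character(s) {sorted(bad)} in class", offset
            )
        if head == "[":
            allowed = frozenset(residues)
        else:
            allowed = frozenset(_WILDCARD - set(residues))
        lo, hi = _parse_repeat(token, end + 1, offset)
        return PatternElement(token[: end + 1], allowed, lo, hi)
    if head == "x":
        lo, hi = _parse_repeat(token, 1, offset)
        return PatternElement("x", _WILDCARD, lo, hi)
    if head in _ALPHABET:
        lo, hi = _parse_repeat(token, 1, offset)
        return PatternElement(head, frozenset(head), lo, hi)
    raise PrositeSyntaxError(f"unexpected character {head!r}", offset)


def parse_prosite(text: str, name: str = "pattern") -> MotifPattern:
    """Parse a PROSITE-style pattern string.

    Supported syntax: fixed residues (``W``), classes (``[RK]``), negated
    classes (``{P}``), wildcards (``x``), each with an optional ``(n)`` or
    ``(n,m)`` repeat; elements joined by ``-``. A trailing ``.`` is ignored.
    """
    body = text.strip().rstrip(".")
    if not body:
        raise PrositeSyntaxError("empty pattern", 0)
    elements = []
    offset = 0
    for token in body.split("-"):
        elements.append(_parse_element(token.strip(), offset))
        offset += len(token) + 1
    return MotifPattern(name, tuple(elements))


def _match_ends(seq: str, pos: int, elements: Sequence[PatternElement], k: int
                ) -> Iterator[int]:
    """Yield every 0-based exclusive end at which elements[k:] match seq[pos:]."""
    if k == len(elements):
        yield pos
        return
    el = elements[k]
    for repeat in range(el.min_repeat, el.max_repeat + 1):
        stop = pos + repeat
        if stop > len(seq):
            break
        if all(seq[i] in el.allowed for i in range(pos, stop)):
            yield from _match_ends(seq, stop, elements, k + 1)
        elif repeat > el.min_repeat:
            # a longer run of the same element can never match if the
            # shorter prefix already failed
            break


def scan(sequence: str, pattern: MotifPattern) -> list[MotifHit]:
    """All matches of ``pattern`` on ``sequence``, overlaps included.

    Variable-length wildcards are expanded over every admissible length, so
    one start position may produce several hits of different extents. Hits
    are reported 1-based inclusive, sorted by (start, end). Zero-length
    matches are suppressed.
    """
    seq = sequence.upper()
    hits: set[tuple[int, int]] = set()
    for start0 in range(len(seq)):
        for end0 in _match_ends(seq, start0, pattern.elements, 0):
            if end0 > start0:
                hits.add((start0, end0))
    return [
        MotifHit(pattern.name, s0 + 1, e0, seq[s0:e0])
        for s0, e0 in sorted(hits)
    ]


def load_pattern_file(path: str | Path | None = None) -> dict[str, MotifPattern]:
    """Load a ``name<TAB>pattern`` file; defaults to the shipped FYVE set."""
    if path is None:
        path = Path(__file__).parent / "data" / "fyve_motifs.tsv"
    patterns: dict[str, MotifPattern] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, _, body = line.partition("\t")
        patterns[name] = parse_prosite(body, name=name)
    return patterns


# ---------------------------------------------------------------------------
# eight-cysteine scaffold detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaffoldConfig:
    """Spacing envelope for the four zinc-binding cysteine pairs.

    Gaps count residues strictly between two cysteines. The defaults bracket
    the EEA1/Vps27p-like folds without pinning one family member; everything
    is overridable.
    """

    intra_pair_gap: tuple[int, int] = (1, 4)
    inter_pair_gap: tuple[int, int] = (4, 30)
    max_span: int = 90
    #: which of the 8 cysteines (1-based, linear order) must carry the
    #: central binding motif's C
    anchor_cys_index: int = 5
    #: tolerance in *pairs* around that index (1 pair = 2 cysteines)
    anchor_pair_tolerance: int = 0
    #: how far upstream of the scaffold the WxxD/WxxG anchor may sit
    wxxd_upstream: int = 30
    #: how far past the last scaffold cysteine the C-terminal motif may end
    motif_downstream: int = 10
    turret_window: int = 6
    interface_offset: int = 2
    interface_length: int = 10


DEFAULT_SCAFFOLD_CONFIG = ScaffoldConfig()


@dataclass(frozen=True)
class ScaffoldHit:
    """One detected eight-cysteine scaffold (all coordinates 1-based)."""

    cys_positions: tuple[int, ...]
    start: int
    end: int
    central_anchor: int

    def __post_init__(self) -> None:
        if len(self.cys_positions) != 8:
            raise ValueError("a FYVE scaffold has exactly 8 cysteines")
        if list(self.cys_positions) != sorted(set(self.cys_positions)):
            raise ValueError("cysteine positions must be strictly increasing")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def _anchor_positions(hit_cys: Sequence[int], config: ScaffoldConfig) -> set[int]:
    """Scaffold cysteine positions allowed to carry the central motif's C."""
    base = config.anchor_cys_index - 1
    allowed = set()
    for d in range(-config.anchor_pair_tolerance, config.anchor_pair_tolerance + 1):
        idx = base + 2 * d
        if 0 <= idx < 8:
            allowed.add(hit_cys[idx])
    return allowed


def find_fyve_scaffold(
    sequence: str, config: ScaffoldConfig | None = None
) -> list[ScaffoldHit]:
    """Find eight-cysteine zinc-finger scaffolds.

    Cysteines are matched as four pairs under the configured spacing
    envelope; every admissible 8-tuple is enumerated and overlapping
    alternatives are resolved leftmost-longest (alternatives are logged at
    debug level for audit).
    """
    cfg = config or DEFAULT_SCAFFOLD_CONFIG
    seq = sequence.upper()
    cys = [i for i, aa in enumerate(seq) if aa == "C"]
    n = len(cys)
    candidates: list[tuple[int, ...]] = []

    def extend(chain: list[int]) -> None:
        k = len(chain)
        if k == 8:
            candidates.append(tuple(cys[j] for j in chain))
            return
        lo, hi = cfg.intra_pair_gap if k % 2 == 1 else cfg.inter_pair_gap
        prev = cys[chain[-1]]
        first = cys[chain[0]]
        for j in range(chain[-1] + 1, n):
            gap = cys[j] - prev - 1
            if gap > hi or cys[j] - first + 1 > cfg.max_span:
                break
            if gap < lo:
                continue
            chain.append(j)
            extend(chain)
            chain.pop()

    for i in range(n):
        extend([i])

    # leftmost-longest resolution of overlapping candidates
    ordered = sorted(set(candidates), key=lambda t: (t[0], -(t[7] - t[0]), t))
    hits: list[ScaffoldHit] = []
    last_end = -1
    for tup in ordered:
        if tup[0] <= last_end:
            logger.debug("scaffold alternative suppressed at %d", tup[0] + 1)
            continue
        positions = tuple(p + 1 for p in tup)
        anchor_cys = positions[cfg.anchor_cys_index - 1]
        hits.append(
            ScaffoldHit(
                cys_positions=positions,
                start=positions[0],
                end=positions[-1],
                central_anchor=max(positions[0], anchor_cys - 2),
            )
        )
        last_end = tup[7]
    return hits


# ---------------------------------------------------------------------------
# binding-signature classification
# ---------------------------------------------------------------------------

CLASSIC_CORE = parse_prosite("[RK]-H-H-C-R", name="central_classic_core")
CLASSIC_RVC = parse_prosite("R-[VI]-C", name="rvc")
CLASSIC_WXXD = parse_prosite("W-x(2)-D", name="wxxd")
VARIANT_CORE = parse_prosite("[KR]-[RK]-H-N-C-Y", name="central_variant")
VARIANT_LYR = parse_prosite("[LFP]-Y-R", name="lyr")
VARIANT_WXXG = parse_prosite("W-x(2)-G", name="wxxg")
VARIANT_ACCESSORY = parse_prosite(
    "[HKN]-x(2)-[ST]-[SN]-[KR]-K", name="class_v_accessory"
)


@dataclass(frozen=True)
class BindingMotifCall:
    """Outcome of classifying the binding signature on one scaffold."""

    label: str                      # classic | variant | atypical
    submotifs: tuple[MotifHit, ...]
    flags: frozenset[str]
    central: MotifHit | None

    @property
    def central_start(self) -> int | None:
        return self.central.start if self.central else None


def _anchored_core(
    sequence: str,
    pattern: MotifPattern,
    c_offset: int,
    anchors: set[int],
) -> MotifHit | None:
    """First core hit whose cysteine (at ``c_offset`` within the match)
    coincides with an allowed scaffold cysteine."""
    for hit in scan(sequence, pattern):
        if hit.start + c_offset in anchors:
            return hit
    return None


def classify_binding_motif(
    domain_sequence: str,
    scaffold: ScaffoldHit | None,
    config: ScaffoldConfig | None = None,
) -> BindingMotifCall:
    """Classify the phosphoinositide-binding signature of a scaffold.

    classic  -- central ``(R/K)HHCR`` core anchored on the scaffold (leading
                R optional, its absence flagged ``missing-first-arg``) plus a
                downstream ``R(V/I)C``;
    variant  -- anchored ``(K/R)(R/K)HNCY`` core plus a downstream
                ``(L/F/P)YR``;
    atypical -- anything else.

    WxxD / WxxG and the class-V accessory motif are reported when present
    but never required, matching how degenerate N-terminal anchors occur in
    the family.
    """
    if scaffold is None:
        raise ValueError("not a FYVE domain: no eight-cysteine scaffold")
    cfg = config or DEFAULT_SCAFFOLD_CONFIG
    seq = domain_sequence.upper()
    for pos in scaffold.cys_positions:
        if pos < 1 or pos > len(seq) or seq[pos - 1] != "C":
            raise ValueError(
                f"scaffold cysteine at {pos} does not match the sequence"
            )
    anchors = _anchor_positions(scaffold.cys_positions, cfg)
    tail_limit = min(len(seq), scaffold.end + cfg.motif_downstream)
    head_limit = max(1, scaffold.start - cfg.wxxd_upstream)

    submotifs: list[MotifHit] = []
    flags: set[str] = set()

    classic_core = _anchored_core(seq, CLASSIC_CORE, 3, anchors)
    variant_core = _anchored_core(seq, VARIANT_CORE, 4, anchors)

    def _after_core(pattern: MotifPattern, core: MotifHit) -> MotifHit | None:
        for hit in scan(seq, pattern):
            if hit.start > core.end and hit.end <= tail_limit:
                return hit
        return None

    def _nterm_anchor(pattern: MotifPattern, before: int) -> MotifHit | None:
        for hit in scan(seq, pattern):
            if hit.end < before and hit.start >= head_limit:
                return hit
        return None

    label = "atypical"
    central: MotifHit | None = None

    if classic_core is not None:
        if classic_core.start > 1 and seq[classic_core.start - 2] == "R":
            central = MotifHit(
                "central_classic",
                classic_core.start - 1,
                classic_core.end,
                seq[classic_core.start - 2 : classic_core.end],
            )
        else:
            central = replace(classic_core, pattern_name="central_classic")
            flags.add("missing-first-arg")
        rvc = _after_core(CLASSIC_RVC, classic_core)
        wxxd = _nterm_anchor(CLASSIC_WXXD, central.start)
        submotifs.append(central)
        if wxxd:
            submotifs.append(wxxd)
        else:
            flags.add("wxxd-absent")
        if rvc is not None:
            submotifs.append(rvc)
            label = "classic"

    if label != "classic" and variant_core is not None:
        central = replace(variant_core, pattern_name="central_variant")
        lyr = _after_core(VARIANT_LYR, variant_core)
        wxxg = _nterm_anchor(VARIANT_WXXG, central.start)
        accessory = _after_core(VARIANT_ACCESSORY, variant_core)
        submotifs = [central]
        flags = set()  # classic-signature flags no longer apply
        if wxxg:
            submotifs.append(wxxg)
        else:
            flags.add("wxxg-absent")
        if accessory:
            submotifs.append(accessory)
        else:
            flags.add("class-v-accessory-absent")
        if lyr is not None:
            submotifs.append(lyr)
            label = "variant"

    if label == "atypical":
        flags.add("no-binding-signature" if central is None else
                  "incomplete-binding-signature")

    if classic_core is not None and variant_core is not None:
        flags.add("ambiguous-motif-class")

    return BindingMotifCall(
        label=label,
        submotifs=tuple(submotifs),
        flags=frozenset(flags),
        central=central,
    )


# ---------------------------------------------------------------------------
# region extraction and hydropathy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    """A contiguous stretch of a sequence, 1-based inclusive."""

    start: int
    end: int
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def extract_turret_loop(
    domain_sequence: str,
    scaffold: ScaffoldHit,
    window: int = 6,
    central_start: int | None = None,
) -> Region:
    """The ``window`` residues immediately N-terminal to the central motif.

    This is the membrane-penetration ("turret") loop. ``central_start``
    defaults to the scaffold's central anchor; when a classification has
    located the actual central motif, pass its start instead. Clipped at the
    domain start; may be empty when the motif opens the domain.
    """
    cs = central_start if central_start is not None else scaffold.central_anchor
    start = max(1, cs - window)
    end = cs - 1
    seq = domain_sequence[start - 1 : end] if end >= start else ""
    return Region(start, end, seq)


def extract_dimer_interface(
    domain_sequence: str,
    anchor_end: int,
    offset: int = 2,
    length: int = 10,
) -> Region:
    """The putative dimerization-interface stretch.

    Defined as ``length`` residues beginning ``offset`` positions C-terminal
    of the N-terminal WxxD/WxxG anchor's end, clipped at the domain end. The
    offsets mirror the EEA1-defined dimer region and are exposed so they can
    be recalibrated against an EEA1 alignment.
    """
    start = anchor_end + offset
    end = min(len(domain_sequence), start + length - 1)
    seq = domain_sequence[start - 1 : end] if end >= start else ""
    return Region(start, end, seq)


#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE: Mapping[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


def hydrophobicity(
    region_sequence: str, scale: Mapping[str, float] | None = None
) -> float:
    """Arithmetic mean hydropathy of a region; X placeholders are excluded."""
    table = scale or KYTE_DOOLITTLE
    values = [table[aa] for aa in region_sequence.upper() if aa != "X"]
    if not values:
        raise ValueError("empty region (or all-X): hydropathy undefined")
    return sum(values) / len(values)
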