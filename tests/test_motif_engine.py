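"""Pattern parsing/scanning against a brute-force oracle, scaffold detection
and binding-signature classification."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fyvescan import motif_engine as me
from fyvescan import synthetic_data as sd
from fyvescan.seq_io import AMINO_ACIDS

# ---------------------------------------------------------------------------
# independent oracle: translate the pattern to a regex and full-match every
# substring — enumerates overlaps and every wildcard expansion by definition
# ---------------------------------------------------------------------------

def _pattern_to_regex(pattern: me.MotifPattern) -> str:
    parts = []
    for el in pattern.elements:
        if el.token == "x":
            base = "."
        elif el.token.startswith("["):
            base = el.token
        elif el.token.startswith("{"):
            base = "[^" + el.token[1:-1] + "]"
        else:
            base = el.token
        if el.min_repeat == el.max_repeat:
            rep = "" if el.min_repeat == 1 else f"{{{el.min_repeat}}}"
        else:
            rep = f"{{{el.min_repeat},{el.max_repeat}}}"
        parts.append(base + rep)
    return "".join(parts)


def brute_force_scan(sequence: str, pattern: me.MotifPattern) -> set[tuple[int, int]]:
    regex = re.compile(_pattern_to_regex(pattern))
    hits = set()
    for i in range(len(sequence)):
        for j in range(i + 1, len(sequence) + 1):
            if regex.fullmatch(sequence, i, j):
                hits.add((i + 1, j))
    return hits


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def test_parse_wxxd():
    pattern = me.parse_prosite("W-x(2)-D")
    assert len(pattern.elements) == 3
    assert pattern.elements[0].allowed == frozenset("W")
    assert pattern.elements[1].min_repeat == pattern.elements[1].max_repeat == 2
    assert pattern.elements[2].allowed == frozenset("D")


def test_parse_central_classic():
    pattern = me.parse_prosite("[RK]-[RK]-H-H-C-R")
    assert len(pattern.elements) == 6
    assert pattern.elements[0].allowed == frozenset("RK")
    assert pattern.elements[1].allowed == frozenset("RK")


@pytest.mark.parametrize(
    "text",
    ["x(2,1)", "[RK", "[]", "W--D", "W-x(a)-D", "", "w-x-D"],
)
def test_parse_errors(text):
    with pytest.raises(me.PrositeSyntaxError):
        me.parse_prosite(text)


@pytest.mark.parametrize(
    "text",
    ["W-x(2)-D", "[RK]-[RK]-H-H-C-R", "{P}(2)-x(1,3)-[AVL]", "A-x-C(3)"],
)
def test_canonical_round_trip(text):
    pattern = me.parse_prosite(text)
    again = me.parse_prosite(pattern.to_text())
    assert again.elements == pattern.elements


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def test_scan_overlapping_wxxd():
    hits = me.scan("WAADWRRD", me.parse_prosite("W-x(2)-D", name="wxxd"))
    assert [(h.start, h.end) for h in hits] == [(1, 4), (5, 8)]
    assert hits[0].matched_text == "WAAD"


def test_scan_no_match():
    assert me.scan("AAAA", me.parse_prosite("W-x(2)-D")) == []


def test_scan_variant_core():
    hits = me.scan("KRHNCY", me.parse_prosite("[KR]-[RK]-H-N-C-Y"))
    assert [(h.start, h.end) for h in hits] == [(1, 6)]


def test_scan_variable_wildcard_reports_all_lengths():
    hits = me.scan("WAAAD", me.parse_prosite("W-x(0,4)-D"))
    assert [(h.start, h.end) for h in hits] == [(1, 5)]
    hits = me.scan("WDAD", me.parse_prosite("W-x(0,2)-D"))
    assert {(h.start, h.end) for h in hits} == {(1, 2), (1, 4)}


_element = st.one_of(
    st.sampled_from(list("ACDRWKHG")),
    st.sampled_from(["[RK]", "[AVL]", "{P}", "{RK}"]),
)
_variable = st.sampled_from(["x", "x(2)", "x(0,2)", "x(1,3)", "x(2,4)"])


@st.composite
def _patterns(draw):
    n_fixed = draw(st.integers(1, 4))
    n_var = draw(st.integers(0, 3))
    tokens = draw(
        st.lists(_element, min_size=n_fixed, max_size=n_fixed)
    ) + draw(st.lists(_variable, min_size=n_var, max_size=n_var))
    tokens = draw(st.permutations(tokens))
    return me.parse_prosite("-".join(tokens))


@settings(max_examples=150, derandomize=True, deadline=None)
@given(
    pattern=_patterns(),
    sequence=st.text(alphabet=AMINO_ACIDS, min_size=0, max_size=200),
)
def test_scan_equals_brute_force(pattern, sequence):
    got = {(h.start, h.end) for h in me.scan(sequence, pattern)}
    assert got == brute_force_scan(sequence, pattern)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    pattern=_patterns(),
    sequence=st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=120),
)
def test_every_hit_revalidates(pattern, sequence):
    regex = re.compile(_pattern_to_regex(pattern))
    for hit in me.scan(sequence, pattern):
        assert hit.matched_text == sequence[hit.start - 1 : hit.end]
        assert regex.fullmatch(hit.matched_text)


# ---------------------------------------------------------------------------
# scaffold detection
# ---------------------------------------------------------------------------

def test_scaffold_on_classic_template(classic_domain):
    seq, truth = classic_domain
    (hit,) = me.find_fyve_scaffold(seq)
    assert hit.cys_positions == truth.cys_positions
    # central anchor sits in the HHCR core that carries the 5th cysteine
    c5 = hit.cys_positions[4]
    assert hit.central_anchor <= c5 <= hit.central_anchor + 3


def test_scaffold_requires_eight_cysteines():
    seq, _ = sd.make_fyve_domain("classic", seed=4, corrupt_core=True)
    assert seq.count("C") == 6
    assert me.find_fyve_scaffold(seq) == []


def test_two_templates_two_scaffolds(classic_domain, variant_domain):
    seq = classic_domain[0] + "A" * 50 + variant_domain[0]
    hits = me.find_fyve_scaffold(seq)
    assert len(hits) == 2
    assert hits[0].cys_positions == classic_domain[1].cys_positions
    offset = len(classic_domain[0]) + 50
    assert hits[1].cys_positions == tuple(
        p + offset for p in variant_domain[1].cys_positions
    )


@settings(max_examples=50, derandomize=True, deadline=None)
@given(sequence=st.text(alphabet=AMINO_ACIDS, min_size=0, max_size=300))
def test_scaffold_hits_are_all_cysteines(sequence):
    for hit in me.find_fyve_scaffold(sequence):
        assert all(sequence[p - 1] == "C" for p in hit.cys_positions)
        assert hit.span <= me.DEFAULT_SCAFFOLD_CONFIG.max_span


# ---------------------------------------------------------------------------
# binding-signature classification
# ---------------------------------------------------------------------------

def test_classic_classification(classic_domain, classic_scaffold):
    seq, _ = classic_domain
    call = me.classify_binding_motif(seq, classic_scaffold)
    assert call.label == "classic"
    names = {h.pattern_name for h in call.submotifs}
    assert {"central_classic", "wxxd", "rvc"} <= names


def test_variant_classification(variant_domain):
    seq, truth = variant_domain
    (scaffold,) = me.find_fyve_scaffold(seq)
    call = me.classify_binding_motif(seq, scaffold)
    assert call.label == "variant"
    names = {h.pattern_name for h in call.submotifs}
    assert {"central_variant", "wxxg", "lyr", "class_v_accessory"} <= names
    central = next(h for h in call.submotifs if h.pattern_name == "central_variant")
    assert "HNCY" in central.matched_text


def test_mutated_core_is_atypical(classic_domain, classic_scaffold):
    seq, truth = classic_domain
    start, _ = truth.central_span
    # HHCR -> QQCR: the central motif is gone, the scaffold survives
    chars = list(seq)
    chars[start + 1] = "Q"
    chars[start + 2] = "Q"
    mutated = "".join(chars)
    (scaffold,) = me.find_fyve_scaffold(mutated)
    call = me.classify_binding_motif(mutated, scaffold)
    assert call.label == "atypical"


def test_missing_first_arginine_still_classic(classic_domain, classic_scaffold):
    seq, truth = classic_domain
    chars = list(seq)
    chars[truth.central_span[0] - 1] = "S"  # R(R/K)HHCR -> S(R/K)HHCR
    call = me.classify_binding_motif("".join(chars), me.find_fyve_scaffold("".join(chars))[0])
    assert call.label == "classic"
    assert "missing-first-arg" in call.flags


def test_classify_without_scaffold_errors():
    with pytest.raises(ValueError, match="not a FYVE domain"):
        me.classify_binding_motif("ACDEF", None)


# ---------------------------------------------------------------------------
# regions and hydropathy
# ---------------------------------------------------------------------------

def test_turret_loop_arithmetic(classic_scaffold, classic_domain):
    seq, _ = classic_domain
    region = me.extract_turret_loop(seq, classic_scaffold, window=6, central_start=30)
    assert (region.start, region.end) == (24, 29)
    clipped = me.extract_turret_loop(seq, classic_scaffold, window=6, central_start=3)
    assert (clipped.start, clipped.end) == (1, 2)


def test_classic_turret_contains_hydrophobic(classic_domain, classic_scaffold):
    seq, truth = classic_domain
    call = me.classify_binding_motif(seq, classic_scaffold)
    region = me.extract_turret_loop(seq, classic_scaffold, 6, call.central_start)
    assert (region.start, region.end) == truth.turret_span
    assert any(aa in "AVLIMFWY" for aa in region.sequence)


def test_dimer_interface_placement(classic_domain):
    seq, truth = classic_domain
    region = me.extract_dimer_interface(seq, anchor_end=truth.wanchor_span[1])
    assert (region.start, region.end) == truth.interface_span
    assert len(region) == 10


@pytest.mark.parametrize(
    "region, expected",
    [("IIII", 4.5), ("RRRR", -4.5), ("ILKR", (4.5 + 3.8 - 3.9 - 4.5) / 4)],
)
def test_hydrophobicity_values(region, expected):
    assert me.hydrophobicity(region) == pytest.approx(expected)


def test_hydrophobicity_excludes_x_and_rejects_empty():
    assert me.hydrophobicity("IXI") == pytest.approx(4.5)
    with pytest.raises(ValueError):
        me.hydrophobicity("")
    with pytest.raises(ValueError):
        me.hydrophobicity("XX")
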