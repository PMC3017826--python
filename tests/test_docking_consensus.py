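"""The >=50% contact-consensus rule, its set-theoretic sandwich, headgroup
comparison, and coordinate-based contact extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fyvescan import docking_consensus as dc
from fyvescan import synthetic_data as sd

R1, R2, R3 = (10, "ARG"), (14, "HIS"), (21, "LYS")


def _runs(contact_sets, headgroup="Ins13P2"):
    return [
        dc.ContactRun(f"{headgroup}_run{i}", headgroup,
                      "rigid" if i % 2 else "flexible", frozenset(cs))
        for i, cs in enumerate(contact_sets)
    ]


def test_support_three_of_six_reported_two_not():
    sets = [{R1, R2}, {R1, R2}, {R1, R2}, {R2}, {R2}, set()]
    cons = dc.consensus(_runs(sets), 0.5)["Ins13P2"]
    assert cons.n_runs == 6
    assert cons.min_count == 3  # ceil(0.5 * 6): "3 or more times"
    assert R1 in cons.reported            # support 3
    assert cons.residues[R2] == 5
    sets2 = [{R1}, {R1}, set(), set(), set(), set()]
    cons2 = dc.consensus(_runs(sets2), 0.5)["Ins13P2"]
    assert R1 not in cons2.reported       # support 2
    assert cons2.residues[R1] == 2        # still counted


def test_threshold_one_equals_intersection():
    sets = [{R1, R2, R3}, {R1, R2}, {R1, R3}]
    cons = dc.consensus(_runs(sets), 1.0)["Ins13P2"]
    assert set(cons.reported) == {R1}


def test_odd_run_count_keeps_50_percent_literal():
    sets = [{R1}, {R1}, {R2}, {R2}, {R3}]
    cons = dc.consensus(_runs(sets), 0.5)["Ins13P2"]
    assert cons.min_count == 3  # ceil(2.5)
    assert cons.reported == ()


def test_headgroups_aggregate_separately():
    runs = _runs([{R1}] * 6, "Ins13P2") + _runs([{R2}] * 6, "Ins15P2")
    result = dc.consensus(runs, 0.5)
    assert set(result["Ins13P2"].reported) == {R1}
    assert set(result["Ins15P2"].reported) == {R2}
    per_scenario = dc.consensus(runs, 0.5, pool_scenarios=False)
    assert set(per_scenario) == {
        "Ins13P2/rigid", "Ins13P2/flexible", "Ins15P2/rigid", "Ins15P2/flexible",
    }


def test_consensus_input_validation():
    with pytest.raises(ValueError):
        dc.consensus([], 0.5)
    with pytest.raises(ValueError):
        dc.consensus(_runs([{R1}]), 0.0)
    dup = _runs([{R1}, {R1}])
    dup[1] = dc.ContactRun(dup[0].run_id, "Ins13P2", "rigid", frozenset({R1}))
    with pytest.raises(ValueError, match="unique"):
        dc.consensus(dup, 0.5)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    data=st.lists(
        st.sets(st.sampled_from([R1, R2, R3, (5, "SER"), (33, "TRP")])),
        min_size=1, max_size=8,
    ),
    threshold=st.floats(0.01, 1.0),
)
def test_consensus_sandwich_and_monotonicity(data, threshold):
    runs = _runs(data)
    reported = set(dc.consensus(runs, threshold)["Ins13P2"].reported)
    intersection = set.intersection(*(set(r.contacts) for r in runs))
    union = set.union(*(set(r.contacts) for r in runs))
    assert intersection <= reported <= union
    # monotone non-increasing in the threshold
    tighter = set(dc.consensus(runs, min(1.0, threshold + 0.25))["Ins13P2"].reported)
    assert tighter <= reported


def test_consensus_invariant_to_run_order_and_ids():
    sets = [{R1, R2}, {R1}, {R2}, {R1, R2}, {R1}, set()]
    a = dc.consensus(_runs(sets), 0.5)["Ins13P2"]
    shuffled = _runs(list(reversed(sets)))
    relabeled = [
        dc.ContactRun(f"zz{i}", r.headgroup, r.scenario, r.contacts)
        for i, r in enumerate(shuffled)
    ]
    b = dc.consensus(relabeled, 0.5)["Ins13P2"]
    assert a.reported == b.reported
    assert a.residues == b.residues


def test_compare_headgroups_identical_disjoint_planted():
    sets = [{R1, R2}] * 6
    c13 = dc.consensus(_runs(sets, "Ins13P2"), 0.5)["Ins13P2"]
    c15 = dc.consensus(_runs(sets, "Ins15P2"), 0.5)["Ins15P2"]
    same = dc.compare_headgroups(c13, c15)
    assert set(same.shared) == {R1, R2}
    assert same.only_first == same.only_second == ()

    c15_disjoint = dc.consensus(_runs([{R3}] * 6, "Ins15P2"), 0.5)["Ins15P2"]
    disjoint = dc.compare_headgroups(c13, c15_disjoint)
    assert disjoint.shared == ()

    overlap = {R1, R2, (30, "ARG"), (55, "TYR")}
    runs13 = sd.make_contact_runs(overlap | {(70, "GLY")}, 6, 0.0, seed=1,
                                  headgroups=("Ins13P2",))
    runs15 = sd.make_contact_runs(overlap | {(80, "ASN")}, 6, 0.0, seed=1,
                                  headgroups=("Ins15P2",))
    c_a = dc.consensus(runs13, 0.5)["Ins13P2"]
    c_b = dc.consensus(runs15, 0.5)["Ins15P2"]
    assert len(dc.compare_headgroups(c_a, c_b).shared) == 4


def test_compare_headgroups_protein_mismatch():
    a = dc.ConsensusContacts("Ins13P2", 0.5, 6, 3, {R1: 6}, protein_id="P1")
    b = dc.ConsensusContacts("Ins15P2", 0.5, 6, 3, {R1: 6}, protein_id="P2")
    with pytest.raises(ValueError, match="mismatch"):
        dc.compare_headgroups(a, b)


# ---------------------------------------------------------------------------
# coordinate mode
# ---------------------------------------------------------------------------

@pytest.fixture()
def complex_paths(tmp_path):
    receptor, ligand, expected = sd.make_contact_complex([3, 5, 9, 12, 17])
    rp, lp = tmp_path / "receptor.pdb", tmp_path / "ligand.pdb"
    rp.write_text(receptor)
    lp.write_text(ligand)
    return rp, lp, expected


def test_planted_contacts_recovered(complex_paths):
    rp, lp, expected = complex_paths
    run = dc.contacts_from_coordinates(rp, lp, cutoff=4.0)
    assert run.contacts == expected


def test_tight_cutoff_yields_empty_run(complex_paths):
    rp, lp, _ = complex_paths
    run = dc.contacts_from_coordinates(rp, lp, cutoff=0.5)
    assert run.contacts == frozenset()


def test_shrinking_cutoff_never_adds_residues(complex_paths):
    rp, lp, _ = complex_paths
    previous = None
    for cutoff in (6.0, 4.0, 3.5, 1.0):
        contacts = dc.contacts_from_coordinates(rp, lp, cutoff=cutoff).contacts
        if previous is not None:
            assert contacts <= previous
        previous = contacts


def test_contacts_input_validation(tmp_path, complex_paths):
    rp, lp, _ = complex_paths
    with pytest.raises(ValueError):
        dc.contacts_from_coordinates(rp, lp, cutoff=0.0)
    empty = tmp_path / "empty.pdb"
    empty.write_text("END\n")
    with pytest.raises(ValueError, match="heavy atoms"):
        dc.contacts_from_coordinates(rp, empty, cutoff=4.0)


def test_contact_table_round_trip(tmp_path):
    runs = sd.make_contact_runs({R1, R2, R3}, 6, 0.1, seed=9)
    path = tmp_path / "runs.tsv"
    dc.write_contact_table(runs, path)
    back = dc.read_contact_table(path)
    assert {(r.run_id, r.headgroup, r.scenario, r.contacts) for r in back} == {
        (r.run_id, r.headgroup, r.scenario, r.contacts)
        for r in runs if r.contacts
    }
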