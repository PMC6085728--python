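"""Reaction-engine semantics: folding, sequestration, invasion, erasure,
and the global invariants (conservation, termination, confluence,
late-complement monotonicity)."""

import random

import pytest
from gate_instances import all_gate_mixes, run_mix

from prismlogic.assembly import build_prism
from prismlogic.errors import EngineError
from prismlogic.logic import _system_prism_state
from prismlogic.sdr_engine import (
    ReactionSystem,
    enumerate_invasions,
    erase,
    fold_hairpins,
    react_to_fixed_point,
    resolve_solution_hybridization,
)
from prismlogic.strand_model import complement_strand


def _system(strands, *free, prism=True, excess=5):
    sys_ = ReactionSystem()
    if prism:
        sys_.add_complex(build_prism(strands), 1)
    for name in free:
        sys_.add_free(strands[name], excess)
    return sys_


# ---------------------------------------------------------------------------
# fold
# ---------------------------------------------------------------------------


def test_hairpin_strand_folds_and_its_payload_is_caged(strands):
    sys_ = _system(strands, "C2-hairpin", prism=True)
    fold_hairpins(sys_)
    assert not sys_.free  # all copies folded into complexes
    folded = [e for _, e in sys_.live_entries() if "C2-hairpin" in e.complex.strand_names]
    assert folded
    # the folded hairpin cannot invade edge 2 of the prism
    assert enumerate_invasions(sys_) == []


def test_fold_is_a_no_op_without_hairpins(strands):
    sys_ = _system(strands, "C1", prism=False)
    fold_hairpins(sys_)
    assert sys_.free["C1"][1] == 5
    empty = ReactionSystem()
    fold_hairpins(empty)
    assert empty.trace == []


# ---------------------------------------------------------------------------
# sequester
# ---------------------------------------------------------------------------


def test_complementary_free_inputs_annihilate_into_waste(strands):
    sys_ = _system(strands, "C1", "C1p", prism=False)
    resolve_solution_hybridization(sys_)
    assert not sys_.free
    (_, entry), = sys_.live_entries()
    assert entry.inert
    assert entry.count == 5
    assert entry.complex.total_paired_nt == 16


def test_non_complementary_strands_stay_free(strands):
    sys_ = _system(strands, "C1", "C2p", prism=False)
    resolve_solution_hybridization(sys_)
    assert sys_.free["C1"][1] == 5
    assert sys_.free["C2p"][1] == 5


def test_xor_inputs_pair_via_both_extensions(strands):
    sys_ = _system(strands, "C1-ext", "C2-ext", prism=False)
    resolve_solution_hybridization(sys_)
    assert not sys_.free
    (_, entry), = sys_.live_entries()
    assert entry.inert
    assert entry.complex.total_paired_nt == 20  # both 10-nt extensions pair


# ---------------------------------------------------------------------------
# invasion enumeration
# ---------------------------------------------------------------------------


def test_free_opener_invasion_of_its_edge_is_listed(strands):
    sys_ = _system(strands, "C2")
    cands = enumerate_invasions(sys_)
    assert cands
    assert cands[0].invader_label == "C2"
    assert cands[0].gain == 6  # the 6-nt toehold is the net pairing gain


def test_blocker_cannot_invade_the_closed_prism(strands):
    sys_ = _system(strands, "C1p")
    assert enumerate_invasions(sys_) == []


def test_and_input2_opens_the_folded_hairpin_via_2nt_toehold(strands):
    sys_ = _system(strands, "C2-hairpin", "C3-ext2", prism=False)
    fold_hairpins(sys_)
    cands = enumerate_invasions(sys_)
    hairpin_openings = [c for c in cands if "C2-hairpin" in c.target_label]
    assert hairpin_openings
    assert hairpin_openings[0].gain == 2


def test_invasions_below_min_toehold_are_suppressed(strands):
    sys_ = ReactionSystem(min_toehold=4)
    sys_.add_complex(build_prism(strands), 1)
    sys_.add_free(strands["C2-hairpin"], 5)
    sys_.add_free(strands["C3-ext2"], 5)
    react_to_fixed_point(sys_)
    # the 2-nt hairpin toehold is now too short; only edge 3 opens
    assert _system_prism_state(sys_).label == "mono-SD(C3)"


# ---------------------------------------------------------------------------
# fixed point
# ---------------------------------------------------------------------------


def test_all_three_openers_deconstruct_the_prism(strands):
    sys_, state = run_mix(strands, ("C1", "C2", "C3"))
    assert state.label == "tri-SD(C1/C2/C3)"
    assert not state.connected
    face_complexes = [
        e for _, e in sys_.live_entries()
        if {"A1", "A2", "A3"} <= set(e.complex.strand_names)
    ]
    assert len(face_complexes) == 1
    assert set(face_complexes[0].complex.strand_names) == {"A1", "A2", "A3", "L"}


def test_hairpin_activation_cascade_opens_edges_two_and_three(strands):
    _, state = run_mix(strands, ("C2-hairpin", "C3-ext2"))
    assert state.opened_edges == frozenset({2, 3})


def test_empty_system_reaches_fixed_point_unchanged(strands):
    sys_, state = run_mix(strands, ())
    assert state.label == "closed"
    assert [r for r in sys_.trace if r.rule == "invade"] == []


def test_iteration_guard_raises_engine_error(strands):
    sys_ = _system(strands, "C1")
    with pytest.raises(EngineError):
        react_to_fixed_point(sys_, max_iter=0)


# ---------------------------------------------------------------------------
# erase
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("edge", [1, 2])
def test_erase_strips_the_opener_and_recloses_the_edge(strands, edge):
    sys_ = _system(strands, f"Is{edge}")
    react_to_fixed_point(sys_)
    assert _system_prism_state(sys_).opened_edges == frozenset({edge})
    erase(sys_, strands[f"Es{edge}"])
    assert _system_prism_state(sys_).label == "closed"
    wastes = [e for _, e in sys_.live_entries()
              if set(e.complex.strand_names) == {f"Is{edge}", f"Es{edge}"}]
    assert sum(e.count for e in wastes) == 5  # fuel ends as waste duplex


def test_erase_without_bound_opener_is_a_warned_no_op(strands):
    sys_ = _system(strands)
    census = sys_.strand_census()
    erase(sys_, strands["Es2"])
    assert sys_.strand_census() == census
    assert sys_.trace[-1].rule == "erase"
    assert "no-op" in sys_.trace[-1].note


def test_three_open_erase_rounds_end_closed(strands):
    sys_ = _system(strands, prism=True)
    for _ in range(3):
        sys_.add_free(strands["Is1"], 5)
        react_to_fixed_point(sys_)
        assert _system_prism_state(sys_).opened_edges == frozenset({1})
        erase(sys_, strands["Es1"])
        assert _system_prism_state(sys_).label == "closed"


# ---------------------------------------------------------------------------
# global invariants over every published gate instance
# ---------------------------------------------------------------------------


def test_strand_conservation_on_every_gate_instance(strands):
    for label, mix in all_gate_mixes():
        sys_ = _system(strands, *mix)
        before = sys_.strand_census()
        react_to_fixed_point(sys_)
        assert sys_.strand_census() == before, label


def test_trace_records_name_rule_reactants_and_products(strands):
    sys_, _ = run_mix(strands, ("C2-hairpin", "C3-ext2"))
    rules = {r.rule for r in sys_.trace}
    assert "fold" in rules and "invade" in rules
    for r in sys_.trace_records():
        assert {"rule", "reactants", "products", "pairing_gain"} <= set(r)


def test_confluence_under_same_priority_permutations(strands):
    """The final prism state must not depend on which of several
    equally-ranked (same pairing gain) displacements fires first."""
    rng = random.Random(0)

    def random_top(cands):
        top = [c for c in cands if c.gain == cands[0].gain]
        return rng.choice(top)

    for label, mix in all_gate_mixes():
        _, reference = run_mix(strands, mix)
        for _ in range(5):
            _, state = run_mix(strands, mix, choose=random_top)
            assert state == reference, label


def test_late_complement_addition_never_opens_more_edges(strands, registry):
    """Sequestration monotonicity: after a gate instance has reacted,
    adding the full complement of any input that still has free copies
    must not increase the set of opened edges."""
    for label, mix in all_gate_mixes():
        sys_, state = run_mix(strands, mix)
        free_names = [n for n, (_, c) in sys_.free.items() if c > 0]
        for name in free_names:
            sys2, state2 = run_mix(strands, mix)
            anti = complement_strand(registry, strands[name])
            sys2.add_free(anti, 5)
            react_to_fixed_point(sys2)
            state3 = _system_prism_state(sys2)
            assert state3.opened_edges <= state.opened_edges, (label, name)
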