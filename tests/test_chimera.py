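import numpy as np
import pytest

from brcarray.chimera import (
    call_chimera,
    classify_sites,
    compare_alleles,
    segment_min_switches,
)
from brcarray.diagnostic import (
    DiagnosticSet,
    DiagnosticSite,
    IndelBlock,
    find_diagnostic_sites,
)
from brcarray.simulate import simulate_contraction_replicate

from oracles import min_switches_exhaustive

REF_A = "KATLWQNDRS"
REF_B = "KGTIWENDKS"
# diagnostic columns: 1 (A/G), 3 (L/I), 5 (Q/E), 8 (R/K)
DSET = find_diagnostic_sites(REF_A, REF_B)


def _vector_from_states(states: str):
    """Synthetic state vector: one substitution site per character."""
    sites = tuple(DiagnosticSite(j, "A", "B") for j in range(len(states)))
    dset = DiagnosticSet("a", "b", sites, ())
    query = "".join({"A": "A", "B": "B", "o": "X"}[c] for c in states)
    return classify_sites(query, dset)


# ---------------------------------------------------------------------------
# site classification


def test_query_identical_to_reference_is_all_A():
    vec = classify_sites(REF_A, DSET)
    assert vec.states == "AAAA"


def test_half_and_half_query_shows_switch_pattern():
    query = REF_A[:4] + REF_B[4:]
    assert classify_sites(query, DSET).states == "AABB"


def test_indel_block_contributes_single_majority_entry():
    sites = (DiagnosticSite(0, "K", "R"),)
    blocks = (IndelBlock(2, 8, "a"),)
    dset = DiagnosticSet("a", "b", sites, blocks)
    assert classify_sites("KAQQQQQQA", dset).states == "AA"
    assert classify_sites("KA------A", dset).states == "AB"
    # exactly half present counts as present
    assert classify_sites("KAQQQ---A", dset).states == "AA"


def test_empty_diagnostic_set_is_an_error():
    with pytest.raises(ValueError, match="empty"):
        classify_sites("KAT", DiagnosticSet("a", "b", (), ()))


# ---------------------------------------------------------------------------
# minimal-switch segmentation


@pytest.mark.parametrize(
    "states, verdict, n_breakpoints",
    [
        ("AAAA", "pure_A", 0),
        ("BBB", "pure_B", 0),
        ("AAABBB", "chimeric", 1),
        ("AABBAA", "chimeric", 2),
        ("ABBA", "ambiguous", 2),  # minimal switches 2, outer segments support 1
        ("AoABB", "chimeric", 1),  # uninformative entries never open segments
        ("AABoB", "chimeric", 1),
    ],
)
def test_segmentation_examples(states, verdict, n_breakpoints):
    call = segment_min_switches(_vector_from_states(states))
    assert call.verdict == verdict
    assert len(call.breakpoints) == n_breakpoints
    assert call.n_switches == min_switches_exhaustive(states)


def test_breakpoint_interval_sits_between_flanking_sites():
    call = segment_min_switches(_vector_from_states("AAABBB"))
    # sites at columns 0..5; switch between entries 2 and 3
    assert call.breakpoints == ((3, 4),)


def test_all_other_vector_is_an_error():
    with pytest.raises(ValueError, match="informative"):
        segment_min_switches(_vector_from_states("ooo"))


def test_dp_matches_exhaustive_enumeration_on_random_vectors():
    rng = np.random.default_rng(12345)
    for _ in range(300):
        k = int(rng.integers(1, 13))
        states = "".join(rng.choice(list("ABo"), size=k))
        if not any(c in "AB" for c in states):
            continue
        call = segment_min_switches(_vector_from_states(states))
        assert call.n_switches == min_switches_exhaustive(states)


def test_reversal_mirrors_the_segmentation():
    rng = np.random.default_rng(54321)
    for _ in range(100):
        k = int(rng.integers(2, 12))
        states = "".join(rng.choice(list("ABo"), size=k))
        if not any(c in "AB" for c in states):
            continue
        fwd = segment_min_switches(_vector_from_states(states))
        rev = segment_min_switches(_vector_from_states(states[::-1]))
        assert [s.state for s in rev.segments] == [
            s.state for s in reversed(fwd.segments)
        ]
        assert [s.support for s in rev.segments] == [
            s.support for s in reversed(fwd.segments)
        ]


# ---------------------------------------------------------------------------
# full chimera calls and homoplasy


def test_pure_unit_and_planted_breakpoint_containment():
    rng = np.random.default_rng(77)
    rep = simulate_contraction_replicate(rng, p_sub=0.0)
    dset = find_diagnostic_sites(rep.ref_a, rep.ref_b, rep.panel_a, rep.panel_b)
    assert call_chimera(rep.ref_a, dset).verdict == "pure_A"
    assert call_chimera(rep.ref_b, dset).verdict == "pure_B"
    call = call_chimera(rep.query, dset, source_id="junction")
    assert call.verdict == "chimeric"
    (lo, hi) = call.breakpoints[0]
    assert lo <= rep.true_breakpoint < hi


def test_identical_calls_are_consistent_with_ibd():
    rng = np.random.default_rng(78)
    rep = simulate_contraction_replicate(rng, p_sub=0.0)
    dset = find_diagnostic_sites(rep.ref_a, rep.ref_b, rep.panel_a, rep.panel_b)
    c1 = call_chimera(rep.query, dset, source_id="x")
    c2 = call_chimera(rep.query, dset, source_id="y")
    verdict = compare_alleles(c1, c2)
    assert verdict.verdict == "consistent_with_IBD"
    assert verdict.same_breakpoint


def test_distinct_planted_breakpoints_are_homoplasious(scenario, scenario_refs):
    records, truth = scenario
    ref_a = scenario_refs.row("ref2").residues
    ref_b = scenario_refs.row("ref4").residues
    dset = find_diagnostic_sites(ref_a, ref_b)
    calls = []
    for leaf in ("shortA", "shortB"):
        lt = truth.leaves[leaf]
        junction_idx = lt.classes.index("2|4")
        calls.append(
            call_chimera(lt.unit_seqs[junction_idx], dset, source_id=leaf)
        )
    verdict = compare_alleles(*calls)
    assert verdict.verdict == "homoplasious"
    assert truth.homoplasious_leaf_pairs() == [("shortA", "shortB")]


def test_block_state_mismatch_forces_homoplasy():
    sites = tuple(DiagnosticSite(j, "A", "B") for j in (0, 1, 8, 9))
    dset = DiagnosticSet("a", "b", sites, (IndelBlock(3, 7, "a"),))
    with_block = call_chimera("AAXQQQQXBB", dset, source_id="w")
    without_block = call_chimera("AAX----XBB", dset, source_id="wo")
    assert with_block.verdict == without_block.verdict == "chimeric"
    assert compare_alleles(with_block, without_block).verdict == "homoplasious"


def test_calls_on_different_sets_cannot_be_compared():
    c1 = segment_min_switches(_vector_from_states("AABB"))
    rng = np.random.default_rng(79)
    rep = simulate_contraction_replicate(rng, p_sub=0.0)
    dset = find_diagnostic_sites(rep.ref_a, rep.ref_b, rep.panel_a, rep.panel_b)
    c2 = call_chimera(rep.query, dset)
    with pytest.raises(ValueError, match="different"):
        compare_alleles(c1, c2)
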