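"""Congener structure, naming, enumeration and chlorine-site classes."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pcbdechlor as pcb
from pcbdechlor.congeners import (
    MIRROR,
    VALID_POSITIONS,
    all_ring_patterns,
    flanking_of,
    homolog_molecular_weight,
    position_class,
)

from conftest import PRINTED_CONGENER_NAMES


def independent_ring_normal(positions):
    """Mirror-minimal form computed without RingPattern (test oracle)."""
    direct = tuple(sorted(positions))
    mirrored = tuple(sorted({2: 6, 3: 5, 4: 4, 5: 3, 6: 2}[p] for p in positions))
    return min(direct, mirrored)


def independent_congener_key(ra, rb):
    """Order-free canonical key for a ring pair (test oracle)."""
    a, b = independent_ring_normal(ra), independent_ring_normal(rb)
    return frozenset([(a, b), (b, a)])


@pytest.mark.parametrize("name", PRINTED_CONGENER_NAMES)
def test_parse_render_round_trip_on_printed_names(name):
    assert pcb.parse_congener(name).name == name


@pytest.mark.parametrize(
    "positions, expected",
    [
        ({3, 6}, "25"),  # mirror {2,5} sorts smaller
        ({4}, "4"),  # mirror-symmetric
        ({2, 5, 6}, "236"),  # mirror {2,3,6} sorts smaller
        (set(), ""),
        ({2, 3, 4, 5, 6}, "23456"),
    ],
)
def test_canonicalize_ring_examples(positions, expected):
    assert str(pcb.canonicalize_ring(positions)) == expected


@given(st.sets(st.sampled_from([2, 3, 4, 5, 6])))
@settings(deadline=None)
def test_canonicalize_is_idempotent_and_mirror_invariant(positions):
    canon = pcb.canonicalize_ring(positions)
    assert pcb.canonicalize_ring(canon.positions) == canon
    mirrored = {MIRROR[p] for p in positions}
    assert pcb.canonicalize_ring(mirrored) == canon
    assert canon.positions == independent_ring_normal(positions)


def test_exactly_twenty_canonical_ring_patterns():
    rings = all_ring_patterns()
    assert len(rings) == 20
    # brute force over all 32 subsets collapses to the same 20
    oracle = {
        independent_ring_normal(c)
        for r in range(6)
        for c in itertools.combinations(sorted(VALID_POSITIONS), r)
    }
    assert {rp.positions for rp in rings} == oracle


def test_enumeration_yields_209_with_standard_homolog_counts():
    congeners = pcb.enumerate_all_congeners()
    assert len(congeners) == 209
    assert len(set(congeners)) == 209
    counts = {}
    for c in congeners:
        counts[c.homolog] = counts.get(c.homolog, 0) + 1
    assert counts == {
        "mono": 3, "di": 12, "tri": 24, "tetra": 42, "penta": 46,
        "hexa": 42, "hepta": 24, "octa": 12, "nona": 3, "deca": 1,
    }


def test_enumeration_matches_all_pairs_oracle():
    """Brute force over all 32x32 ordered subset pairs, deduplicated with
    an independent normalization, gives the same congener set."""
    subsets = [
        c
        for r in range(6)
        for c in itertools.combinations(sorted(VALID_POSITIONS), r)
    ]
    oracle = set()
    for ra in subsets:
        for rb in subsets:
            if len(ra) + len(rb) >= 1:
                oracle.add(independent_congener_key(ra, rb))
    assert len(oracle) == 209
    ours = {
        independent_congener_key(c.ring_a.positions, c.ring_b.positions)
        for c in pcb.enumerate_all_congeners()
    }
    assert ours == oracle


def test_deca_is_unique_fully_substituted_congener():
    (deca,) = pcb.congeners_of_homolog("deca")
    assert deca.name == "23456-23456-CB"
    assert len(pcb.congeners_of_homolog("hexa")) == 42


@pytest.mark.parametrize(
    "ring, expected",
    [
        ("2345", {2: ("ortho", "singly_flanked"),
                  3: ("meta", "doubly_flanked"),
                  4: ("para", "doubly_flanked"),
                  5: ("meta", "singly_flanked")}),
        ("25", {2: ("ortho", "unflanked"), 5: ("meta", "unflanked")}),
        ("34", {3: ("meta", "singly_flanked"), 4: ("para", "singly_flanked")}),
    ],
)
def test_chlorine_site_classification(ring, expected):
    c = pcb.parse_congener(f"{ring}-CB")
    sites = {
        s.position: (s.position_class, s.flanking)
        for s in pcb.classify_chlorines(c)
        if s.ring_index == 0
    }
    assert sites == expected


def test_flanking_agrees_with_brute_force_neighbor_scan():
    for ring in all_ring_patterns():
        for p in ring.positions:
            neighbors = sum(
                1
                for q in (p - 1, p + 1)
                if q in VALID_POSITIONS and q in ring
            )
            expected = ["unflanked", "singly_flanked", "doubly_flanked"][neighbors]
            assert flanking_of(ring, p) == expected
            # carbon 1 never flanks: ortho positions cannot be doubly flanked
            if p in (2, 6):
                assert expected != "doubly_flanked"


def test_classify_chlorines_emits_one_site_per_chlorine():
    for c in pcb.enumerate_all_congeners()[::7]:
        assert len(pcb.classify_chlorines(c)) == c.n_chlorines


@pytest.mark.parametrize(
    "name, expected",
    [("2-CB", 188.65), ("245-245-CB", 360.85), ("23456-23456-CB", 498.61)],
)
def test_molecular_weight(name, expected):
    assert pcb.molecular_weight(pcb.parse_congener(name)) == pytest.approx(
        expected, abs=0.1
    )
    assert homolog_molecular_weight(6) == pytest.approx(360.85, abs=0.1)


@pytest.mark.parametrize(
    "bad",
    ["", "CB", "129-CB", "224-25-CB", "2345-245", "17-CB", "2345--CB",
     "-CB", "abc-CB"],
)
def test_parse_errors_on_malformed_names(bad):
    with pytest.raises(pcb.CongenerError):
        pcb.parse_congener(bad)


def test_congener_needs_at_least_one_chlorine():
    with pytest.raises(pcb.CongenerError):
        pcb.Congener(pcb.canonicalize_ring(()), pcb.canonicalize_ring(()))


def test_ring_ordering_matches_printed_convention():
    # more-chlorinated ring first; ties broken by smaller position string
    assert pcb.Congener(
        pcb.canonicalize_ring((2, 5)), pcb.canonicalize_ring((2, 4))
    ).name == "24-25-CB"
    assert pcb.Congener(
        pcb.canonicalize_ring((2, 4, 5)), pcb.canonicalize_ring((2, 3, 5))
    ).name == "235-245-CB"
    assert pcb.Congener(
        pcb.canonicalize_ring((2, 4)), pcb.canonicalize_ring((2, 3, 6))
    ).name == "236-24-CB"
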