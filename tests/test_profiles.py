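"""Profile arithmetic: unit conversion, homolog statistics, deltas,
chlorine release and growth yield."""

import numpy as np
import pytest

import pcbdechlor as pcb
from pcbdechlor.congeners import homolog_molecular_weight


def test_weight_to_mol_single_congener_is_identity():
    out = pcb.weight_to_mol({"245-245-CB": 100.0})
    assert out.entries == {"245-245-CB": pytest.approx(100.0)}
    assert out.unit == "mol_percent"


def test_weight_to_mol_favors_lighter_congener():
    out = pcb.weight_to_mol({"23456-23456-CB": 50.0, "2-CB": 50.0})
    assert out.entries["2-CB"] > out.entries["23456-23456-CB"]


def test_weight_to_mol_two_component_closed_form():
    """Equal weights of a hexa- and a hepta-CB give a mole ratio equal to
    the inverse molecular-weight ratio."""
    out = pcb.weight_to_mol({"245-245-CB": 50.0, "2345-245-CB": 50.0})
    ratio = out.entries["245-245-CB"] / out.entries["2345-245-CB"]
    expected = homolog_molecular_weight(7) / homolog_molecular_weight(6)
    assert ratio == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(1.095, abs=0.005)


def test_weight_mol_round_trip():
    weights = {"2345-245-CB": 40.0, "245-245-CB": 35.0, "24-25-CB": 25.0}
    back = pcb.mol_to_weight(pcb.weight_to_mol(weights))
    for k, v in weights.items():
        assert back.entries[k] == pytest.approx(v, rel=1e-6)


def test_homolog_distribution_of_control(control_homologs):
    dist = pcb.homolog_distribution(control_homologs)
    assert dist.mean_chlorines == pytest.approx(6.39, abs=0.005)
    assert dist["hexa"] == pytest.approx(47.75)


def test_homolog_distribution_of_dechlorinated(dechlorinated_homologs):
    dist = pcb.homolog_distribution(dechlorinated_homologs)
    assert dist.mean_chlorines == pytest.approx(5.59, abs=0.005)


def test_homolog_distribution_single_congener():
    p = pcb.CongenerProfile({"245-245-CB": 100.0})
    dist = pcb.homolog_distribution(p)
    assert dist.mol_percent == {"hexa": pytest.approx(100.0)}
    assert dist.mean_chlorines == pytest.approx(6.0)


def test_homolog_distribution_sums_to_profile_total():
    mix = pcb.generate_mixture(pcb.MixtureSpec(seed=3))
    dist = pcb.homolog_distribution(mix)
    assert sum(dist.mol_percent.values()) == pytest.approx(
        sum(mix.entries.values()), abs=1e-9
    )


def test_delta_profile_reproduces_homolog_changes(
    control_homologs, dechlorinated_homologs
):
    d = pcb.delta_profile(control_homologs, dechlorinated_homologs)
    assert d.per_homolog["tetra"] == pytest.approx(26.72, abs=0.005)
    assert d.per_homolog["hexa"] == pytest.approx(-28.23, abs=0.005)
    assert "hexa" in d.decreased and "tetra" in d.increased
    assert "nona" in d.unchanged  # -0.01 is below the 2 mol% threshold


def test_delta_profile_identity_is_all_zero(control_homologs):
    d = pcb.delta_profile(control_homologs, control_homologs)
    assert all(v == 0.0 for v in d.per_congener.values())
    assert not d.decreased and not d.increased


def test_delta_profile_rejects_unit_mismatch():
    a = pcb.CongenerProfile({"245-245-CB": 100.0}, unit="mol_percent")
    b = pcb.CongenerProfile({"245-245-CB": 100.0}, unit="weight_percent")
    with pytest.raises(pcb.ProfileError):
        pcb.delta_profile(a, b)


def test_percent_decrease_by_homolog(control_homologs, dechlorinated_homologs):
    before = pcb.homolog_distribution(control_homologs)
    after = pcb.homolog_distribution(dechlorinated_homologs)
    dec = pcb.percent_decrease_by_homolog(before, after)
    assert dec["hexa"] == pytest.approx(59.12, abs=0.01)
    assert dec["hepta"] == pytest.approx(30.44, abs=0.01)
    assert dec["octa"] == pytest.approx(2.18, abs=0.01)
    # homologs that increased carry no % decrease entry
    assert "tetra" not in dec and "penta" not in dec
    # no change -> 0
    same = pcb.percent_decrease_by_homolog(before, before)
    assert all(v == 0.0 for v in same.values())


def test_percent_decrease_warns_on_new_homolog():
    before = pcb.homolog_distribution(
        pcb.homolog_profile({"hexa": 100.0})
    )
    after = pcb.homolog_distribution(
        pcb.homolog_profile({"hexa": 95.0, "penta": 5.0})
    )
    with pytest.warns(UserWarning):
        dec = pcb.percent_decrease_by_homolog(before, after)
    assert "penta" not in dec  # undefined (absent before), omitted
    assert dec["hexa"] == pytest.approx(5.0)


def test_chlorine_removal_matches_reported_endpoint(
    control_homologs, dechlorinated_homologs
):
    removed = pcb.chlorine_removal(control_homologs, dechlorinated_homologs)
    # (6.3873 - 5.5908) x 81 µM; printed endpoint is 64.23 nmol/mL
    assert removed == pytest.approx(64.52, abs=0.05)
    assert abs(removed - 64.23) / 64.23 < 0.01


def test_chlorine_removal_trivial_cases(control_homologs):
    assert pcb.chlorine_removal(control_homologs, control_homologs) == pytest.approx(0.0)
    mono = pcb.CongenerProfile({"2-CB": 100.0}, total_um=81.0)
    # hypothetical complete dechlorination is not representable (zero
    # chlorines is not a congener), but one full chlorine per biphenyl
    # equals the concentration by unit definition
    di = pcb.CongenerProfile({"25-CB": 100.0}, total_um=81.0)
    assert pcb.chlorine_removal(di, mono) == pytest.approx(81.0)


def test_chlorine_removal_requires_matching_concentration(control_homologs):
    other = pcb.homolog_profile(
        pcb.AROCLOR1260_CONTROL_HOMOLOGS, total_um=50.0
    )
    with pytest.raises(pcb.ProfileError):
        pcb.chlorine_removal(control_homologs, other)
    no_conc = pcb.homolog_profile(pcb.AROCLOR1260_CONTROL_HOMOLOGS)
    with pytest.raises(pcb.ProfileError):
        pcb.chlorine_removal(no_conc, no_conc)


def test_chlorine_removal_invariant_to_within_homolog_redistribution():
    rng = np.random.default_rng(7)
    base = pcb.generate_mixture(pcb.MixtureSpec(seed=11))
    after = pcb.generate_mixture(pcb.MixtureSpec(seed=12))
    ref = pcb.chlorine_removal(base, after)
    # redistribute mass among hexa congeners of 'after' without changing
    # the homolog marginal
    entries = dict(after.entries)
    hexas = [k for k in entries if pcb.parse_congener(k).homolog == "hexa"]
    total_hexa = sum(entries[k] for k in hexas)
    shares = rng.dirichlet(np.ones(len(hexas)))
    for k, s in zip(hexas, shares):
        entries[k] = total_hexa * s
    shuffled = pcb.CongenerProfile(entries, total_um=after.total_um)
    assert pcb.chlorine_removal(base, shuffled) == pytest.approx(ref, abs=1e-9)


def test_growth_yield_formula():
    gy = pcb.growth_yield(1.1e7, 36.49)
    assert gy.yield_cells_per_mol == pytest.approx(3.0145e14, rel=1e-3)
    assert pcb.growth_yield(3.3e5, 1.0).yield_cells_per_mol == pytest.approx(3.3e14)
    assert pcb.growth_yield(0.0, 10.0).yield_cells_per_mol == 0.0
    with pytest.raises(pcb.ProfileError):
        pcb.growth_yield(1e7, 0.0)


def test_profile_validation():
    with pytest.raises(pcb.ProfileError):
        pcb.CongenerProfile({"245-245-CB": 90.0})  # sum far from 100
    with pytest.raises(pcb.ProfileError):
        pcb.CongenerProfile({"245-245-CB": 110.0, "24-25-CB": -10.0})
    with pytest.raises(pcb.ProfileError):
        pcb.CongenerProfile({"245-245-CB": 50.0, "hexa": 50.0})  # mixed levels
    renorm = pcb.CongenerProfile({"245-245-CB": 99.8}).renormalized()
    assert sum(renorm.entries.values()) == pytest.approx(100.0)


def test_homolog_level_profiles_rejected_by_structure_operations(
    control_homologs,
):
    with pytest.raises(pcb.ProfileError):
        control_homologs.require_congener_level("classification")
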