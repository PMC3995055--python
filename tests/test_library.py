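"""The interaction library: completeness, structural constraints, emergent
binding semantics."""

import numpy as np
import pytest

from fcerilib.library import (
    MOLECULE_TYPES,
    ModelSelection,
    SelectionError,
    build_model,
    default_parameters,
    ffl_model,
    implicit_phosphatase_entries,
    library_index,
    list_rules,
    phosphosites,
)
from fcerilib.network import generate_network
from fcerilib.sitegraph import parse_complex


def test_all_51_numbered_rules_present_exactly_once():
    df = list_rules("lat_downstream+lipid_background")
    numbers = sorted(df.number.dropna().astype(int))
    assert numbers == list(range(1, 52))


def test_every_library_rule_parses_and_validates():
    for sub, entries in library_index().items():
        for e in entries:
            rule = e.parse()
            for p in rule.reactants + rule.products:
                p.validate_pattern(MOLECULE_TYPES)
            rule.transformation  # must be computable


def test_membrane_enhancement_ratios_are_100():
    """Membrane-associated Inpp5d binds its targets 100x faster than the
    cytosolic form, for both receptor binding and product-lipid binding."""
    params = default_parameters()
    by_number = {e.number: e.parse() for e in
                 library_index()["lat_downstream"]}
    r38, r39 = by_number[38], by_number[39]
    assert r39.rate_forward.value(params) / r38.rate_forward.value(params) \
        == pytest.approx(100.0)
    r41, r42 = by_number[41], by_number[42]
    assert r42.rate_forward.value(params) / r41.rate_forward.value(params) \
        == pytest.approx(100.0)


def test_syk_activation_loop_speeds_up_catalysis():
    p = default_parameters()
    assert p["kpSykLat136_1"] >= p["kpSykLat136_2"]
    assert p["kpSykLat175_2"] >= p["kpSykLat175_1"]


def test_all_parameters_strictly_positive_except_resting_signal():
    p = default_parameters()
    for name, value in p.items():
        if name == "signal":
            continue
        assert value > 0, name


def test_ligand_has_exactly_two_binding_competent_sites():
    lig = MOLECULE_TYPES["Lig"]
    assert len(lig.sites) == 2
    for site in lig.sites:
        assert set(site.states) == {"i", "a"}  # inaccessible / accessible
    # and the binding rules engage both sites at equal rates
    binds = [e for e in library_index()["ligand_receptor"]
             if e.name.startswith("lig_bind")]
    assert {e.name.split("_")[2] for e in binds} == {"d1", "d2"}
    rates = {e.parse().rate_forward.constant_name for e in binds}
    assert rates == {"kfLigRec"}


def test_receptor_is_bivalent_for_ligand():
    rec = MOLECULE_TYPES["Rec"]
    fab = [s.name for s in rec.sites if s.name.startswith("f")]
    assert fab == ["f1", "f2"]


def test_grb2_and_grap2_exclusion_on_lat_y175_emerges_from_single_bonds():
    """No generated species carries two partners on Lat Y175."""
    sel = ModelSelection(
        sublibraries=("lat_downstream",),
        rule_numbers=(9, 10),
        seeds={
            "Lat(Y136~0,Y175~P)": 100,
            "Grb2(SH2,cSH3)": 100,
            "Grap2(SH2,SH3)": 100,
        },
    )
    net = generate_network(build_model(sel))
    for sp in net.species:
        for mol in sp.molecules:
            if mol.name == "Lat":
                # at most one bond on Y175 by construction; the two adaptors
                # can never co-occupy the site
                partners = [m.name for m in sp.molecules
                            if m.name in ("Grb2", "Grap2")]
                assert len(partners) <= 1


def test_inpp5d_and_lyn_bind_receptor_noncompetitively():
    """Species exist with both beta-chain tyrosines occupied (Lyn on
    b_Y210, Inpp5d on b_Y224)."""
    sel = ModelSelection(
        sublibraries=("lat_downstream",),
        rule_numbers=(38, 39, 40),
        seeds={
            "Rec(f1,f2,u,b_Y210~P,b_Y224~P,g~0)": 100,
            "Lyn(U,SH2,SH3,PTK,Yc~0)": 100,
            "Inpp5d(SH2,C2,IPP)": 100,
        },
    )
    model = build_model(sel)
    # Lyn SH2 recruitment to the phosphorylated beta N-terminal tyrosine
    lyn_sh2 = [e for e in library_index()["proximal"]
               if e.name == "lyn_rec_sh2"][0]
    model.rules.append(lyn_sh2.parse())
    net = generate_network(model)
    both_bound = [
        sp for sp in net.species
        if any(m.name == "Rec"
               and isinstance(m.sites["b_Y210"].bond, tuple)
               and isinstance(m.sites["b_Y224"].bond, tuple)
               for m in sp.molecules)
    ]
    assert both_bound, "no species with both beta tyrosines engaged"


INOSITOL = {"PI45P2": 1, "PI345P3": 1, "PI34P2": 1, "PI4P": 1, "IP3": 1,
            "DAG": 0}


def test_inositol_conservation_of_lipid_rules():
    """Lipid interconversion and cleavage rules conserve total inositol
    (DAG carries none)."""
    conserved_rules = set(range(21, 24)) | set(range(28, 31)) | \
        set(range(35, 38)) | set(range(44, 52))
    checked = 0
    for sub in ("lat_downstream", "lipid_background"):
        for e in library_index()[sub]:
            if e.number not in conserved_rules:
                continue
            rule = e.parse()
            before = sum(INOSITOL.get(m.name, 0)
                         for p in rule.reactants for m in p.molecules)
            after = sum(INOSITOL.get(m.name, 0)
                        for p in rule.products for m in p.molecules)
            assert before == after, f"rule {e.number} changes inositol count"
            checked += 1
    assert checked == len(conserved_rules)


def test_implicit_phosphatase_covers_every_phosphosite():
    sites = set(phosphosites())
    entries = implicit_phosphatase_entries()
    covered = set()
    for e in entries:
        rule = e.parse()
        mol = rule.reactants[0].molecules[0]
        (site_name,) = mol.sites
        covered.add((mol.name, site_name))
        # acts only on unbound phosphosites by default
        assert mol.sites[site_name].bond == "free"
        assert mol.sites[site_name].state == "P"
    assert covered == sites


def test_empty_selection_gives_types_only():
    model = build_model(ModelSelection())
    assert model.rules == [] and model.seeds == []
    assert set(model.molecule_types) == set(MOLECULE_TYPES)


def test_selection_with_unknown_sublibrary_rejected():
    with pytest.raises(SelectionError):
        build_model(ModelSelection(sublibraries=("nonexistent",)))


def test_feedback_flag_controls_gab2_pip3_interactions():
    without = ffl_model(feedback=False)
    with_fb = ffl_model(feedback=True)
    names_without = {r.name for r in without.rules}
    names_with = {r.name for r in with_fb.rules}
    assert "rule_15" not in names_without
    assert "rule_15" in names_with
    assert "gab2_feedback_phos" in names_with
    assert "gab2_feedback_pi3k" in names_with
    assert names_with - names_without == {
        "rule_15", "gab2_feedback_phos", "gab2_feedback_pi3k"}


def test_list_rules_filters():
    ship = list_rules("Inpp5d")
    assert sorted(ship.number.dropna().astype(int)) == list(range(38, 49))
    assert len(list_rules("no_such_thing")) == 0


def test_clamped_input_holds_kinase_activity_constant():
    model = ffl_model(feedback=False, input_mode="clamped", syk_level=0.5)
    assert not any(r.name.endswith("activation") for r in model.rules)
    active = [a for g, a in model.seeds
              if any(m.name == "Anchor" for m in g.molecules)]
    assert len(active) == 2  # anchored Syk and anchored Fyn
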