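"""Core site-graph algorithms: canonical labels, embeddings, components."""

import itertools

import networkx as nx
import numpy as np
import pytest

from fcerilib.sitegraph import (
    ANY,
    FREE,
    SiteGraph,
    SiteGraphError,
    automorphism_count,
    canonical_label,
    connected_components,
    find_embeddings,
    format_complex,
    parse_complex,
)

from conftest import permuted_copy, random_complex


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def isomorphic_bruteforce(g1: SiteGraph, g2: SiteGraph) -> bool:
    """Try all type-respecting molecule bijections; check sites and bonds."""
    n = len(g1.molecules)
    if n != len(g2.molecules):
        return False
    for perm in itertools.permutations(range(n)):
        ok = True
        for i, j in enumerate(perm):
            m1, m2 = g1.molecules[i], g2.molecules[j]
            if m1.name != m2.name or set(m1.sites) != set(m2.sites):
                ok = False
                break
            for sn, s1 in m1.sites.items():
                s2 = m2.sites[sn]
                if s1.state != s2.state:
                    ok = False
                    break
                b1, b2 = s1.bond, s2.bond
                if isinstance(b1, tuple) != isinstance(b2, tuple):
                    ok = False
                    break
                if isinstance(b1, tuple):
                    if (perm[b1[0]], b1[1]) != b2:
                        ok = False
                        break
            if not ok:
                break
        if ok:
            return True
    return False


def embedding_count_bruteforce(pattern: SiteGraph, species: SiteGraph) -> int:
    """Count constraint-satisfying injections over all candidate maps."""
    np_, ns = len(pattern.molecules), len(species.molecules)
    count = 0
    for choice in itertools.permutations(range(ns), np_):
        ok = True
        for p, t in enumerate(choice):
            pm, tm = pattern.molecules[p], species.molecules[t]
            if pm.name != tm.name:
                ok = False
                break
            for sn, ps in pm.sites.items():
                if sn not in tm.sites:
                    ok = False
                    break
                ts = tm.sites[sn]
                if ps.state is not None and ps.state != ts.state:
                    ok = False
                    break
                if ps.bond == FREE and ts.bond != FREE:
                    ok = False
                    break
                if ps.bond == ANY and not isinstance(ts.bond, tuple):
                    ok = False
                    break
                if isinstance(ps.bond, tuple):
                    if not isinstance(ts.bond, tuple):
                        ok = False
                        break
                    q, qs = ps.bond
                    if ts.bond != (choice[q], qs):
                        ok = False
                        break
            if not ok:
                break
        if ok:
            count += 1
    return count


# ---------------------------------------------------------------------------
# Canonical labeling
# ---------------------------------------------------------------------------

def test_label_independent_of_site_listing_order():
    assert (parse_complex("Lat(Y136~0,Y175~0)").label
            == parse_complex("Lat(Y175~0,Y136~0)").label)


def test_label_independent_of_bond_index_choice():
    assert (parse_complex("A(x!1).B(y!1)").label
            == parse_complex("B(y!7).A(x!7)").label)


def test_label_invariant_under_100_random_permutations(rng):
    graph = random_complex(rng, n_molecules=5)
    reference = canonical_label(graph)
    for _ in range(100):
        assert canonical_label(permuted_copy(graph, rng)) == reference


def test_equal_labels_iff_bruteforce_isomorphic(rng):
    graphs = [random_complex(rng, n_molecules=4) for _ in range(12)]
    for g1, g2 in itertools.combinations(graphs, 2):
        assert (canonical_label(g1) == canonical_label(g2)) == \
            isomorphic_bruteforce(g1, g2)


def test_label_distinguishes_states_and_topology():
    a = parse_complex("A(x~0,l,r)")
    b = parse_complex("A(x~P,l,r)")
    assert a.label != b.label
    chain = parse_complex("A(l,r!1,x~0).A(l!1,r!2,x~0).A(l!2,r,x~0)")
    ring_free = parse_complex("A(l,r!1,x~0).A(l!1,r,x~0)")
    assert chain.label != ring_free.label


def test_symmetric_dimer_label_stable():
    d1 = parse_complex("A(a!1).A(a!1)")
    d2 = parse_complex("A(a!42).A(a!42)")
    assert d1.label == d2.label
    assert automorphism_count(d1) == 2


def test_disconnected_species_rejected():
    g = parse_complex("A(x)")
    g.add_molecule(g.molecules[0].copy())
    with pytest.raises(SiteGraphError):
        canonical_label(g)


# ---------------------------------------------------------------------------
# Embeddings
# ---------------------------------------------------------------------------

def test_bound_wildcard_requires_bound_site():
    # a kinase pattern demanding receptor engagement must not match the
    # cytosolic (free-tSH2) form
    pattern = parse_complex("Syk(tSH2!+,PTK)")
    cytosolic = parse_complex("Syk(tSH2,PTK,Y519_Y520~0)")
    assert find_embeddings(pattern, cytosolic) == []
    engaged = parse_complex("Syk(tSH2!1,PTK,Y519_Y520~0).Rec(g~P!1)")
    assert len(find_embeddings(pattern, engaged)) == 1


def test_absent_molecule_type_gives_no_embeddings():
    assert find_embeddings(parse_complex("Lyn(U)"),
                           parse_complex("Syk(tSH2,PTK,Y519_Y520~0)")) == []


def test_two_symmetric_matches_counted():
    pattern = parse_complex("A(x)")
    species = parse_complex("A(x,y!1).A(x,y!1)")
    assert len(find_embeddings(pattern, species)) == 2


def test_embedding_counts_match_exhaustive_enumeration(rng):
    for _ in range(20):
        species = random_complex(rng, n_molecules=int(rng.integers(2, 7)))
        # patterns: single molecules with partial constraints
        pattern = SiteGraph()
        src = species.molecules[int(rng.integers(len(species.molecules)))]
        mol = src.copy()
        for site in mol.sites.values():
            if isinstance(site.bond, tuple):
                site.bond = ANY
            if rng.random() < 0.5:
                site.state = None
        if rng.random() < 0.5:
            mol.sites.pop(list(mol.sites)[0])
        pattern.add_molecule(mol)
        assert (len(find_embeddings(pattern, species))
                == embedding_count_bruteforce(pattern, species))


def test_connected_pattern_embeddings_match_oracle(rng):
    species = parse_complex(
        "A(l,r!1,x~0).B(l!1,r!2,x~P).A(l!2,r,x~0)")
    pattern = parse_complex("A(r!1).B(l!1)")
    assert (len(find_embeddings(pattern, species))
            == embedding_count_bruteforce(pattern, species) == 1)


def test_embeddings_compose_with_automorphisms(rng):
    species = parse_complex("A(a!1,x~0).A(a!1,x~0)")
    pattern = parse_complex("A(x~0)")
    embs = set(find_embeddings(pattern, species))
    autos = find_embeddings(species, species, exact=True)
    assert len(autos) == 2
    for emb in embs:
        for auto in autos:
            composed = tuple(auto[t] for t in emb)
            assert composed in embs


def test_omitted_sites_are_unconstrained():
    # binding state of unmentioned sites is irrelevant
    pattern = parse_complex("Syk(PTK!1).Lat(Y136~0!1)")
    species = parse_complex(
        "Syk(tSH2!2,PTK!1,Y519_Y520~P).Rec(g~P!2).Lat(Y136~0!1,Y175~0)")
    assert len(find_embeddings(pattern, species)) == 1


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------

def test_component_split_after_bond_removal():
    dimer = parse_complex("A(x!1).B(y!1)")
    assert len(connected_components(dimer)) == 1
    dimer.remove_bond(0, "x")
    assert len(connected_components(dimer)) == 2


def test_components_agree_with_networkx_oracle(rng):
    for _ in range(10):
        g = SiteGraph()
        n = 8
        from fcerilib.sitegraph import Molecule, Site

        for i in range(n):
            g.add_molecule(Molecule("A", {"l": Site(), "r": Site()}))
        nxg = nx.Graph()
        nxg.add_nodes_from(range(n))
        for _ in range(int(rng.integers(0, 7))):
            i, j = int(rng.integers(n)), int(rng.integers(n))
            if i == j:
                continue
            si = "l" if g.molecules[i].sites["l"].bond == FREE else "r"
            sj = "r" if g.molecules[j].sites["r"].bond == FREE else "l"
            if g.molecules[i].sites[si].bond == FREE and \
                    g.molecules[j].sites[sj].bond == FREE:
                g.add_bond(i, si, j, sj)
                nxg.add_edge(i, j)
        parts = connected_components(g)
        expected = sorted(len(c) for c in nx.connected_components(nxg))
        assert sorted(len(p.molecules) for p in parts) == expected


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st


@st.composite
def chain_species(draw):
    """Linear heteropolymers with random types and phospho-states."""
    n = draw(st.integers(min_value=1, max_value=6))
    types = draw(st.lists(st.sampled_from("ABC"), min_size=n, max_size=n))
    states = draw(st.lists(st.sampled_from("0P"), min_size=n, max_size=n))
    from fcerilib.sitegraph import Molecule, Site, SiteGraph

    g = SiteGraph()
    for t, s in zip(types, states):
        g.add_molecule(Molecule(t, {"l": Site(), "r": Site(),
                                    "x": Site(state=s)}))
    for i in range(1, n):
        g.add_bond(i, "l", i - 1, "r")
    return g


@settings(derandomize=True, max_examples=60, deadline=None)
@given(chain_species(), st.randoms(use_true_random=False))
def test_property_label_is_permutation_invariant(graph, pyrandom):
    order = list(range(len(graph.molecules)))
    pyrandom.shuffle(order)
    permuted = parse_complex(format_complex(graph, order))
    assert permuted.label == graph.label


@settings(derandomize=True, max_examples=40, deadline=None)
@given(chain_species())
def test_property_single_molecule_pattern_count_equals_occurrences(graph):
    from fcerilib.sitegraph import Molecule, Site, SiteGraph

    pattern = SiteGraph([Molecule("A", {"x": Site(state="P")})])
    expected = sum(1 for m in graph.molecules
                   if m.name == "A" and m.sites["x"].state == "P")
    assert len(find_embeddings(pattern, graph)) == expected
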