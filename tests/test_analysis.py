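"""Bifurcation sweeps, rise times, and motif identification."""

import itertools

import networkx as nx
import numpy as np
import pytest

from fcerilib.analysis import (
    InfluenceGraph,
    RiseTimeError,
    bifurcation_sweep,
    build_influence_graph,
    enumerate_motifs,
    library_influence_graph,
    rise_time,
    rise_time_ratio,
)
from fcerilib.fixtures import generate_toy_fixture
from fcerilib.model import parse_model_text
from fcerilib.network import generate_network
from fcerilib.simulate import SimulationSpec, simulate_odes


# ---------------------------------------------------------------------------
# Bifurcation sweeps
# ---------------------------------------------------------------------------

def cubic_root_count(coeffs, s):
    roots = np.roots(list(coeffs) + [s])
    real = roots[np.abs(roots.imag) < 1e-9].real
    return int(np.sum(real > 1e-9)), np.sort(real[real > 1e-9])


def test_bistable_toy_window_matches_root_finding_oracle():
    fx = generate_toy_fixture("bistable_toy", seed=0)
    values = np.linspace(0.02, 0.6, 24)
    diagram = bifurcation_sweep(
        fx.model, values, parameter="s", direction="both",
        ss_tol=1e-9, t_start=1.0, max_time=1e7, floor=1e-6, rel_tol=0.01)
    oracle = np.array([
        cubic_root_count(fx.expectations["cubic"], s)[0] == 3 for s in values
    ])
    # hysteresis: branch disagreement exactly where the cubic has three
    # positive roots (boundary points may fall either way within one step)
    mismatches = np.nonzero(diagram.bistable_mask != oracle)[0]
    interior = [
        i for i in mismatches
        if 0 < i < len(values) - 1 and oracle[i - 1] == oracle[i + 1] == oracle[i]
    ]
    assert not interior
    assert diagram.bistable_mask.any() and not diagram.bistable_mask.all()


def test_bistable_branch_values_match_cubic_roots():
    fx = generate_toy_fixture("bistable_toy", seed=0)
    # the up branch ignites above the fold (~0.475); sweeping past it lets
    # the down sweep ride the high branch back through the window
    values = np.array([0.1, 0.3, 0.55])
    diagram = bifurcation_sweep(fx.model, values, parameter="s",
                                ss_tol=1e-9, t_start=1.0, floor=1e-6)
    for i, s in enumerate(values[:2]):
        _, roots = cubic_root_count(fx.expectations["cubic"], s)
        low, high = roots[0], roots[-1]
        assert diagram.up[i, 0] == pytest.approx(low, rel=1e-3)
        assert diagram.down[i, 0] == pytest.approx(high, rel=1e-3)


def test_monostable_system_has_identical_branches():
    fx = generate_toy_fixture("dimerization", seed=0)
    values = np.geomspace(1e-4, 1e-2, 6)
    diagram = bifurcation_sweep(fx.model, values, parameter="kf",
                                ss_tol=1e-9, t_start=1.0)
    assert diagram.bistable_window is None
    assert np.allclose(diagram.up, diagram.down, rtol=1e-6)


def test_sweep_requires_increasing_values():
    fx = generate_toy_fixture("dimerization", seed=0)
    with pytest.raises(ValueError):
        bifurcation_sweep(fx.model, [0.1, 0.1], parameter="kf")


# ---------------------------------------------------------------------------
# Rise times
# ---------------------------------------------------------------------------

def _exponential_trajectory(k, T=None, n=300):
    model = parse_model_text(f"""
begin parameters
  k {k}
end parameters
begin molecule types
  A(s~a~b)
end molecule types
begin seed species
  A(s~a) 100
end seed species
begin observables
  Molecules B A(s~b)
end observables
begin reaction rules
  A(s~a) -> A(s~b) k
end reaction rules
""")
    net = generate_network(model)
    T = T if T is not None else 30.0 / k
    times = np.insert(np.geomspace(T * 1e-5, T, n), 0, 0.0)
    return simulate_odes(SimulationSpec(net, times,
                                        observables=model.observables,
                                        rtol=1e-9, atol=1e-12))


def test_rise_time_of_exponential_is_ln20_over_k():
    k = 0.2
    traj = _exponential_trajectory(k)
    assert rise_time(traj, "B", 0.95) == pytest.approx(np.log(20) / k,
                                                       rel=2e-3)


def test_rise_time_zero_when_already_at_steady_state():
    traj = _exponential_trajectory(2.0, T=2000.0)
    # restrict to the flat tail
    from fcerilib.simulate import Trajectory

    tail = Trajectory(traj.times[-50:] - traj.times[-50],
                      traj.species[-50:], traj.observable_names,
                      traj.observables[-50:])
    assert rise_time(tail, "B", 0.95) == 0.0


def test_rise_time_errors_when_not_settled():
    k = 0.2
    traj = _exponential_trajectory(k, T=5.0)  # cut well before steady state
    with pytest.raises(RiseTimeError):
        rise_time(traj, "B", 0.95)


def test_rise_time_nondecreasing_in_fraction():
    traj = _exponential_trajectory(0.5)
    fractions = [0.5, 0.8, 0.9, 0.95, 0.99]
    rts = [rise_time(traj, "B", f) for f in fractions]
    assert all(a <= b for a, b in zip(rts, rts[1:]))


def test_rise_time_ratio_of_identical_models_is_one():
    fx = generate_toy_fixture("bistable_toy", seed=0)
    df = rise_time_ratio(fx.model, fx.model, [0.5], observable="Xtot",
                         parameter="s")
    assert df.ratio.iloc[0] == pytest.approx(1.0, rel=1e-6)


def test_rise_time_ratio_of_exponentials_with_rates_k_and_2k():
    slow = parse_model_text(_two_state_text(0.1))
    fast = parse_model_text(_two_state_text(0.2))
    df = rise_time_ratio(slow, fast, [1.0], observable="B", parameter="dummy")
    assert df.ratio.iloc[0] == pytest.approx(2.0, rel=5e-3)


def _two_state_text(k):
    return f"""
begin parameters
  k {k}
  dummy 0
end parameters
begin molecule types
  A(s~a~b)
end molecule types
begin seed species
  A(s~a) 100
end seed species
begin observables
  Molecules B A(s~b)
end observables
begin reaction rules
  A(s~a) -> A(s~b) k
end reaction rules
"""


# ---------------------------------------------------------------------------
# Influence graph & motifs
# ---------------------------------------------------------------------------

def test_empty_rule_set_gives_empty_graph():
    g = build_influence_graph([])
    assert len(g.graph.nodes) == 0


def test_lipid_phosphatase_edges_signed_from_annotations():
    g = library_influence_graph(condensed=False)
    assert g.sign("Inpp5d", "PIP3") == -1      # PIP3 dephosphorylation
    assert g.sign("PI34P2", "Inpp5d") == 1     # product binding
    assert g.sign("Inpp5d", "PI34P2") == 1     # product generation
    assert g.sign("Csk", "Lyn") == -1          # inhibitory C-terminal phos


def test_gab2_pi3k_pip3_cycle_edges_all_positive():
    g = library_influence_graph(condensed=False)
    assert g.sign("Gab2", "PI3K") == 1
    assert g.sign("PI3K", "PIP3") == 1
    assert g.sign("PIP3", "Gab2") == 1


def test_three_node_coherent_ffl_by_definition():
    g = InfluenceGraph()
    g.add_edge("X", "Y", 1, "r1")
    g.add_edge("Y", "Z", 1, "r2")
    g.add_edge("X", "Z", 1, "r3")
    rep = enumerate_motifs(g)
    assert rep.coherent_ffls == [("X", "Y", "Z")]
    assert rep.incoherent_ffls == []


def _bruteforce_motifs(g: nx.DiGraph, max_len: int):
    """Independent enumeration over node sequences and triples."""
    cycles = set()
    nodes = list(g.nodes)
    for length in range(1, max_len + 1):
        for seq in itertools.permutations(nodes, length):
            if all(g.has_edge(seq[i], seq[(i + 1) % length])
                   for i in range(length)):
                rot = min(tuple(seq[i:] + seq[:i]) for i in range(length))
                sign = 1
                for i in range(length):
                    sign *= g[seq[i]][seq[(i + 1) % length]]["sign"]
                cycles.add((rot, sign))
    pos = sorted(c for c, s in cycles if s > 0)
    neg = sorted(c for c, s in cycles if s < 0)
    coh, inc = [], []
    for x, y, z in itertools.permutations(nodes, 3):
        if g.has_edge(x, z) and g.has_edge(x, y) and g.has_edge(y, z):
            direct = g[x][z]["sign"]
            indirect = g[x][y]["sign"] * g[y][z]["sign"]
            (coh if direct == indirect else inc).append((x, y, z))
    return pos, neg, sorted(coh), sorted(inc)


def test_motifs_match_bruteforce_on_random_graphs(rng):
    for _ in range(15):
        g = InfluenceGraph()
        nodes = [f"n{i}" for i in range(6)]
        for i, src in enumerate(nodes):
            for dst in nodes:
                r = rng.random()
                if r < 0.18:
                    g.add_edge(src, dst, 1, "r")
                elif r < 0.3:
                    g.add_edge(src, dst, -1, "r")
        rep = enumerate_motifs(g, max_cycle_len=6)
        pos, neg, coh, inc = _bruteforce_motifs(g.graph, 6)
        assert sorted(rep.positive_cycles) == pos
        assert sorted(rep.negative_cycles) == neg
        assert rep.coherent_ffls == coh
        assert rep.incoherent_ffls == inc


def test_all_signed_three_node_digraphs_classified_by_sign_product():
    """Exhaustive check of FFL classification on every signed 3-node
    digraph over the FFL edge skeleton."""
    for sxz, sxy, syz in itertools.product((1, -1), repeat=3):
        g = InfluenceGraph()
        g.add_edge("X", "Z", sxz, "r")
        g.add_edge("X", "Y", sxy, "r")
        g.add_edge("Y", "Z", syz, "r")
        rep = enumerate_motifs(g)
        coherent = sxz == sxy * syz
        assert (("X", "Y", "Z") in rep.coherent_ffls) == coherent
        assert (("X", "Y", "Z") in rep.incoherent_ffls) == (not coherent)


def test_conflicting_edge_signs_excluded_and_reported():
    g = InfluenceGraph()
    g.add_edge("A", "B", 1, "r1")
    g.add_edge("A", "B", -1, "r2")
    assert not g.graph.has_edge("A", "B")
    assert g.excluded
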