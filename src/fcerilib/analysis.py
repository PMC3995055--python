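"""Analyses: input sweeps, bistability/hysteresis, rise times, network motifs.

Bifurcation analysis follows the simulation-based protocol: the bifurcation
parameter (an input-signal strength controlling Syk/Fyn activation) is varied
systematically from low to high and back, each steady state found by
integration continued from the previous point's steady state; only stable
steady states are recorded.  A bistable window is reported where the up- and
down-sweep branches disagree by more than a relative threshold.

Rise time is the time for an observable to first reach a fraction (default
95%) of its final steady-state value; ratios of rise times compare two models
at matched input levels.

The influence graph is a signed digraph over molecules/lipids/activities
whose edges come from explicit annotations carried by the library rules
(binding/recruitment positive, phosphatase action on lipids negative,
inhibitory-site phosphorylation negative), plus optional condensed edges at
the granularity of the published motif map.  Motif enumeration reports
positive/negative feedback cycles and coherent/incoherent feed-forward loops.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .model import Model
from .network import ReactionNetwork, generate_network
from .simulate import (
    SimulationSpec,
    SteadyStateError,
    Trajectory,
    find_steady_state,
    observable_weights,
    simulate_odes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BifurcationDiagram",
    "bifurcation_sweep",
    "rise_time",
    "rise_time_ratio",
    "RiseTimeError",
    "InfluenceGraph",
    "build_influence_graph",
    "library_influence_graph",
    "MotifReport",
    "enumerate_motifs",
]


# ---------------------------------------------------------------------------
# Bifurcation sweeps
# ---------------------------------------------------------------------------

@dataclass
class BifurcationDiagram:
    parameter: str
    values: np.ndarray                  # ordered parameter grid
    observable_names: list
    up: np.ndarray                      # (n_values, n_observables); NaN = failed
    down: np.ndarray
    bistable_mask: np.ndarray           # bool per grid point
    rel_tol: float

    @property
    def bistable_window(self) -> Optional[tuple]:
        """(lowest, highest) parameter value with branch disagreement."""
        idx = np.nonzero(self.bistable_mask)[0]
        if len(idx) == 0:
            return None
        return (float(self.values[idx[0]]), float(self.values[idx[-1]]))

    def to_frame(self) -> pd.DataFrame:
        data = {self.parameter: self.values}
        for j, name in enumerate(self.observable_names):
            data[f"{name}_up"] = self.up[:, j]
            data[f"{name}_down"] = self.down[:, j]
        data["bistable"] = self.bistable_mask
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


def _sweep_branch(net, values, x0, parameter, ss_kwargs):
    params = dict(net.parameters)
    states = []
    x = np.asarray(x0, dtype=float)
    for v in values:
        params[parameter] = float(v)
        try:
            ss = find_steady_state(net, x, parameters=params, **ss_kwargs)
            x = ss.state
            states.append(x.copy())
        except SteadyStateError as exc:
            logger.warning("sweep point %s=%g did not converge: %s",
                           parameter, v, exc)
            states.append(None)
    return states


def bifurcation_sweep(
    model_or_network,
    values: Sequence[float],
    parameter: str = "signal",
    observables: Optional[list] = None,
    direction: str = "both",
    rel_tol: float = 0.01,
    floor: float = 1.0,
    max_agg: int = 14,
    **ss_kwargs,
) -> BifurcationDiagram:
    """Up/down steady-state sweep of an input parameter.

    ``values`` must be increasing.  The up sweep starts from the network's
    seed amounts; the down sweep is continued from the up sweep's final
    steady state (or from the seeds when ``direction="down"``).  Points where
    the steady-state search fails are flagged (NaN) and the sweep continues.
    A point is marked bistable when any observable differs between branches
    by more than ``rel_tol`` relative (with absolute floor ``floor``).
    """
    if isinstance(model_or_network, Model):
        net = generate_network(model_or_network, max_agg=max_agg)
        if observables is None:
            observables = model_or_network.observables
    else:
        net = model_or_network
        if observables is None:
            raise ValueError("observables required when passing a network")
    values = np.asarray(list(values), dtype=float)
    if np.any(np.diff(values) <= 0):
        raise ValueError("sweep values must be strictly increasing")
    if direction not in ("up", "down", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    ss_defaults = dict(ss_tol=1e-7, rtol=1e-7, atol=1e-9, t_start=100.0,
                       max_time=3e7, floor=1e-3)
    ss_defaults.update(ss_kwargs)

    W = observable_weights(net, observables)
    names = [o.name for o in observables]
    n, m = len(values), len(names)
    up = np.full((n, m), np.nan)
    down = np.full((n, m), np.nan)

    x0 = net.initial_state()
    up_states = None
    if direction in ("up", "both"):
        up_states = _sweep_branch(net, values, x0, parameter, ss_defaults)
        for i, st in enumerate(up_states):
            if st is not None:
                up[i] = W @ st
    if direction in ("down", "both"):
        if direction == "both" and up_states is not None and \
                up_states[-1] is not None:
            start = up_states[-1]
        else:
            start = x0
        down_states = _sweep_branch(net, values[::-1], start, parameter,
                                    ss_defaults)
        for i, st in enumerate(down_states):
            if st is not None:
                down[n - 1 - i] = W @ st

    if direction == "up":
        down = up.copy()
    elif direction == "down":
        up = down.copy()

    with np.errstate(invalid="ignore"):
        diff = np.abs(up - down) / (np.abs(up) + np.abs(down) + floor)
    bistable = np.any(np.nan_to_num(diff) > rel_tol, axis=1)
    return BifurcationDiagram(parameter, values, names, up, down, bistable,
                              rel_tol)


# ---------------------------------------------------------------------------
# Rise times
# ---------------------------------------------------------------------------

class RiseTimeError(RuntimeError):
    """Trajectory not at steady state, or fraction outside (0, 1)."""


def rise_time(
    trajectory: Trajectory,
    observable: str,
    fraction: float = 0.95,
    steady_rel: float = 0.01,
) -> float:
    """Time for an observable to reach ``fraction`` of its final value.

    The trajectory must have settled: the observable may change by at most
    ``steady_rel`` (relative) over the trailing 10% of the time span,
    otherwise :class:`RiseTimeError` is raised.  The crossing time is
    linearly interpolated between grid points.  For non-monotone approaches
    the last upward crossing is returned with a logged warning.
    """
    if not 0.0 < fraction < 1.0:
        raise RiseTimeError("fraction must be in (0, 1)")
    t = trajectory.times
    y = trajectory.observable(observable)
    final = y[-1]
    tail = y[t >= t[0] + 0.9 * (t[-1] - t[0])]
    scale = max(abs(final), 1e-12)
    if np.max(np.abs(tail - final)) > steady_rel * scale:
        raise RiseTimeError(
            f"observable {observable!r} is not at steady state at the end of "
            f"the trajectory"
        )
    threshold = fraction * final
    above = y >= threshold
    if above[0]:
        return 0.0
    if not above.any():
        raise RiseTimeError(f"observable {observable!r} never reaches "
                            f"{fraction:.0%} of its final value")
    crossings = np.nonzero(above[1:] & ~above[:-1])[0]
    if len(crossings) > 1 or not above[crossings[0] + 1:].all():
        logger.warning("non-monotone approach of %r; using last crossing",
                       observable)
    i = crossings[-1]
    # linear interpolation on [t_i, t_{i+1}]
    y0, y1 = y[i], y[i + 1]
    if y1 == y0:
        return float(t[i + 1])
    return float(t[i] + (threshold - y0) * (t[i + 1] - t[i]) / (y1 - y0))


def _settled_trajectory(net, observables, parameters=None, rel=1e-6,
                        max_time=3e7, n_points=400) -> Trajectory:
    """Integrate to steady state, then re-simulate on a dense grid."""
    ss = find_steady_state(net, parameters=parameters, ss_tol=rel,
                           rtol=1e-7, atol=1e-9, t_start=100.0,
                           max_time=max_time, floor=1e-3)
    T = max(ss.time, 1.0) * 1.5
    times = np.insert(np.geomspace(T * 1e-6, T, n_points), 0, 0.0)
    return simulate_odes(SimulationSpec(net, times, observables=observables,
                                        rtol=1e-7, atol=1e-9,
                                        parameters=parameters))


def rise_time_ratio(
    model_a: Model,
    model_b: Model,
    input_levels: Sequence[float],
    observable: str = "IP3",
    parameter: str = "signal",
    fraction: float = 0.95,
    max_agg: int = 14,
) -> pd.DataFrame:
    """Elementwise rise-time ratio (model_a / model_b) at matched inputs.

    Both models must expose the observable.  Failures at individual levels
    propagate as NaN rows with the error message recorded.
    """
    nets = [generate_network(model_a, max_agg=max_agg),
            generate_network(model_b, max_agg=max_agg)]
    obs = [model_a.observables, model_b.observables]
    rows = []
    for level in input_levels:
        rts = []
        note = ""
        for net, ob in zip(nets, obs):
            params = dict(net.parameters)
            params[parameter] = float(level)
            try:
                traj = _settled_trajectory(net, ob, parameters=params)
                rts.append(rise_time(traj, observable, fraction))
            except (RiseTimeError, SteadyStateError) as exc:
                rts.append(np.nan)
                note = str(exc)
        rows.append({parameter: level, "rise_time_a": rts[0],
                     "rise_time_b": rts[1],
                     "ratio": rts[0] / rts[1] if rts[1] else np.nan,
                     "note": note})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Influence graph and motifs
# ---------------------------------------------------------------------------

@dataclass
class InfluenceGraph:
    """Signed digraph over molecules/activities with rule provenance."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    excluded: list = field(default_factory=list)   # unsigned/conflicting edges

    def add_edge(self, src: str, dst: str, sign: int, rule: str) -> None:
        if sign not in (-1, 1):
            self.excluded.append((src, dst, sign, rule))
            logger.warning("unsigned influence %s->%s from %s excluded",
                           src, dst, rule)
            return
        if self.graph.has_edge(src, dst):
            data = self.graph[src][dst]
            if data["sign"] != sign:
                logger.warning("conflicting signs for %s->%s; edge excluded",
                               src, dst)
                self.excluded.append((src, dst, sign, rule))
                self.graph.remove_edge(src, dst)
                return
            data["rules"].append(rule)
        else:
            self.graph.add_edge(src, dst, sign=sign, rules=[rule])

    def sign(self, src: str, dst: str) -> int:
        return self.graph[src][dst]["sign"]

    def to_dot(self) -> str:
        lines = ["digraph influence {"]
        for node in sorted(self.graph.nodes):
            lines.append(f'  "{node}";')
        for src, dst in sorted(self.graph.edges):
            data = self.graph[src][dst]
            style = "normal" if data["sign"] > 0 else "tee"
            label = "+" if data["sign"] > 0 else "-"
            lines.append(
                f'  "{src}" -> "{dst}" [label="{label}", arrowhead={style}];'
            )
        lines.append("}")
        return "\n".join(lines) + "\n"


def build_influence_graph(rules: Iterable, extra_edges: Iterable = ()) -> InfluenceGraph:
    """Collect signed edges from rule annotations into an influence graph.

    Each rule may carry ``annotation["edges"] = [(src, dst, sign), ...]``;
    rules without annotations contribute nothing (the sign dictionary is
    explicit curated data, not a heuristic inference).  ``extra_edges`` takes
    ``(src, dst, sign, provenance)`` tuples, e.g. condensed path-summary
    edges.
    """
    g = InfluenceGraph()
    for rule in rules:
        ann = getattr(rule, "annotation", None) or {}
        for src, dst, sign in ann.get("edges", ()):
            g.add_edge(src, dst, sign, getattr(rule, "name", "?"))
    for src, dst, sign, prov in extra_edges:
        g.add_edge(src, dst, sign, prov)
    return g


def library_influence_graph(condensed: bool = True) -> InfluenceGraph:
    """The influence graph of the full interaction library."""
    from .library import CONDENSED_EDGES, library_index

    g = InfluenceGraph()
    seen = set()
    for sub, entries in library_index().items():
        for e in entries:
            if e.name in seen:
                continue
            seen.add(e.name)
            for src, dst, sign in e.edges:
                g.add_edge(src, dst, sign, e.name)
    if condensed:
        for src, dst, sign, prov in CONDENSED_EDGES:
            g.add_edge(src, dst, sign, prov)
    return g


@dataclass
class MotifReport:
    positive_cycles: list    # node tuples, e.g. ("Gab2", "PI3K", "PIP3")
    negative_cycles: list
    coherent_ffls: list      # (x, y, z) with x->z direct and x->y->z
    incoherent_ffls: list

    def summary(self) -> dict:
        return {
            "positive_cycles": len(self.positive_cycles),
            "negative_cycles": len(self.negative_cycles),
            "coherent_ffls": len(self.coherent_ffls),
            "incoherent_ffls": len(self.incoherent_ffls),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kind, items in (
            ("positive_feedback", self.positive_cycles),
            ("negative_feedback", self.negative_cycles),
            ("coherent_ffl", self.coherent_ffls),
            ("incoherent_ffl", self.incoherent_ffls),
        ):
            for nodes in items:
                rows.append({"motif": kind, "nodes": "->".join(nodes)})
        return pd.DataFrame(rows, columns=["motif", "nodes"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    def has_cycle(self, nodes: Sequence[str], positive: bool) -> bool:
        pool = self.positive_cycles if positive else self.negative_cycles
        target = _canonical_rotation(tuple(nodes))
        return target in {_canonical_rotation(c) for c in pool}


def _canonical_rotation(cycle: tuple) -> tuple:
    n = len(cycle)
    rotations = [tuple(cycle[i:] + cycle[:i]) for i in range(n)]
    return min(rotations)


def enumerate_motifs(graph: InfluenceGraph, max_cycle_len: int = 5) -> MotifReport:
    """All simple cycles (up to a length cap) and feed-forward triples.

    A cycle is positive iff the product of its edge signs is positive.  A
    feed-forward loop is a triple ``x -> z`` with an indirect path
    ``x -> y -> z`` (x, y, z distinct); it is coherent iff the direct sign
    equals the product of the indirect signs.  Cycles are deduplicated up to
    rotation (self-loops count as length-1 cycles).
    """
    g = graph.graph
    pos_cycles, neg_cycles = [], []
    for cyc in nx.simple_cycles(g, length_bound=max_cycle_len):
        cyc = tuple(cyc)
        sign = 1
        for i in range(len(cyc)):
            sign *= g[cyc[i]][cyc[(i + 1) % len(cyc)]]["sign"]
        (pos_cycles if sign > 0 else neg_cycles).append(
            _canonical_rotation(cyc))
    pos_cycles = sorted(set(pos_cycles))
    neg_cycles = sorted(set(neg_cycles))

    coherent, incoherent = [], []
    for x, z in g.edges:
        if x == z:
            continue
        direct = g[x][z]["sign"]
        for y in g.successors(x):
            if y in (x, z) or not g.has_edge(y, z):
                continue
            indirect = g[x][y]["sign"] * g[y][z]["sign"]
            (coherent if direct == indirect else incoherent).append((x, y, z))
    return MotifReport(pos_cycles, neg_cycles, sorted(coherent),
                       sorted(incoherent))
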