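"""Reaction-network generation: from rules and seeds to mass-action reactions.

Network generation is a fixed-point iteration.  Starting from the seed
species, every (expanded, irreversible) rule is applied to all tuples of
current species; product species not seen before are added, and the loop
repeats until no new species appear or a cap is hit.  Species are indexed in
discovery order, which makes generation deterministic and -- because every
ordered tuple is visited exactly once -- independent of rule order.

Reactions store their generating rule, the rate law, and the accumulated
symmetry-corrected multiplicity, so the numeric rate-constant vector can be
recomputed cheaply for any parameter set (used by parameter sweeps).
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import Model, ModelParseError, ParameterSet, parse_molecule_type
from .rules import RateLaw, Rule, apply_rule
from .sitegraph import SiteGraph, parse_complex

logger = logging.getLogger(__name__)

__all__ = ["Reaction", "ReactionNetwork", "generate_network",
           "write_network_text", "read_network_text"]


@dataclass
class Reaction:
    """A concrete mass-action reaction between indexed species."""

    reactants: tuple  # species indices, repeated per stoichiometry
    products: tuple
    rate_law: RateLaw
    factor: float          # symmetry-corrected embedding multiplicity
    rule_name: str

    def rate_constant(self, parameters) -> float:
        return self.rate_law.value(parameters) * self.factor


@dataclass
class ReactionNetwork:
    species: list = field(default_factory=list)         # SiteGraph, discovery order
    reactions: list = field(default_factory=list)       # Reaction
    parameters: ParameterSet = field(default_factory=ParameterSet)
    seed_amounts: dict = field(default_factory=dict)    # species index -> amount
    truncated: bool = False
    molecule_types: dict = field(default_factory=dict)

    @property
    def labels(self) -> list:
        return [s.label for s in self.species]

    def index_of(self, species_text: str) -> int:
        label = parse_complex(species_text).label
        for i, s in enumerate(self.species):
            if s.label == label:
                return i
        raise KeyError(species_text)

    def initial_state(self) -> np.ndarray:
        x0 = np.zeros(len(self.species))
        for i, amount in self.seed_amounts.items():
            x0[i] = amount
        return x0

    def rate_vector(self, parameters=None) -> np.ndarray:
        p = self.parameters if parameters is None else parameters
        return np.array([r.rate_constant(p) for r in self.reactions])

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense stoichiometric matrix S (species x reactions)."""
        S = np.zeros((len(self.species), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for i in rxn.reactants:
                S[i, j] -= 1
            for i in rxn.products:
                S[i, j] += 1
        return S

    def conserved_moieties(self, tol: float = 1e-9) -> np.ndarray:
        """Left null vectors of S: rows are conserved weightings of species."""
        S = self.stoichiometric_matrix()
        if S.size == 0:
            return np.eye(len(self.species))
        u, s, _ = np.linalg.svd(S)
        rank = int(np.sum(s > tol * max(S.shape) * (s[0] if len(s) else 1.0)))
        return u[:, rank:].T


def generate_network(
    model: Model,
    max_agg: int = 6,
    max_iter: int = 100,
    max_species: int = 20000,
) -> ReactionNetwork:
    """Enumerate the reaction network implied by a model's rules and seeds.

    ``max_agg`` caps the number of molecules per species (needed because
    bivalent ligand/receptor chemistry admits unbounded chains); reactions
    whose products exceed the cap are dropped and the network is flagged
    ``truncated`` (with a logged warning) rather than failing silently.
    """
    model.validate()
    net = ReactionNetwork(
        parameters=ParameterSet(model.parameters),
        molecule_types=dict(model.molecule_types),
    )

    ir_rules = []
    for rule in model.rules:
        if rule.reversible:
            ir_rules.append(rule.forward_part())
            ir_rules.append(rule.reverse_part())
        else:
            ir_rules.append(rule)

    label_to_idx: dict = {}

    def add_species(graph: SiteGraph) -> int:
        lab = graph.label
        if lab in label_to_idx:
            return label_to_idx[lab]
        idx = len(net.species)
        net.species.append(graph)
        label_to_idx[lab] = idx
        return idx

    for i in range(len(model.seeds)):
        graph, _ = model.seeds[i]
        graph = graph.copy()
        graph.validate_species(model.molecule_types)
        idx = add_species(graph)
        net.seed_amounts[idx] = net.seed_amounts.get(idx, 0.0) + model.seed_amount(i)

    # precompute required molecule type names per pattern
    rule_required = [
        [p.type_names() for p in r.reactants] for r in ir_rules
    ]

    rxn_index: dict = {}  # (rule pos, reactant labels, product labels) -> Reaction

    new_range = (0, len(net.species))
    for iteration in range(max_iter):
        lo, hi = new_range
        if lo == hi:
            break
        n_before = len(net.species)
        for rpos, rule in enumerate(ir_rules):
            arity = len(rule.reactants)
            if arity == 0:
                if iteration > 0:
                    continue
                tuples = [()]
            else:
                cand = []
                for req in rule_required[rpos]:
                    cand.append(
                        [
                            i
                            for i in range(n_before)
                            if req <= net.species[i].type_names()
                        ]
                    )
                tuples = [
                    t
                    for t in itertools.product(*cand)
                    if any(lo <= i < hi for i in t)
                ]
            for t in tuples:
                sp_tuple = [net.species[i] for i in t]
                outcomes = apply_rule(rule, sp_tuple, model.molecule_types)
                for prods, factor in outcomes:
                    if any(len(p.molecules) > max_agg for p in prods):
                        if not net.truncated:
                            logger.warning(
                                "aggregate cap %d exceeded by rule %s; "
                                "network truncated",
                                max_agg,
                                rule.name,
                            )
                        net.truncated = True
                        continue
                    pidx = tuple(sorted(add_species(p) for p in prods))
                    ridx = tuple(sorted(t))
                    key = (rpos, ridx, pidx)
                    if key in rxn_index:
                        rxn_index[key].factor += factor
                    else:
                        rxn = Reaction(ridx, pidx, rule.rate_forward, factor,
                                       rule.name)
                        rxn_index[key] = rxn
                        net.reactions.append(rxn)
                if len(net.species) > max_species:
                    raise RuntimeError(
                        f"species cap {max_species} exceeded during generation"
                    )
        new_range = (n_before, len(net.species))
        logger.info(
            "iteration %d: %d species, %d reactions",
            iteration + 1,
            len(net.species),
            len(net.reactions),
        )
    else:
        if new_range[0] != new_range[1]:
            logger.warning("network generation stopped at max_iter=%d without "
                           "closure; truncated", max_iter)
            net.truncated = True

    # drop null reactions (products identical to reactants)
    net.reactions = [r for r in net.reactions
                     if tuple(sorted(r.reactants)) != tuple(sorted(r.products))]
    return net


# ---------------------------------------------------------------------------
# Plain-text serialization (lossless round trip)
# ---------------------------------------------------------------------------

def write_network_text(net: ReactionNetwork) -> str:
    out = []
    out.append("begin parameters")
    for k in sorted(net.parameters):
        out.append(f"  {k} {net.parameters[k]!r}")
    out.append("end parameters")
    out.append("begin molecule types")
    for name in sorted(net.molecule_types):
        out.append(f"  {net.molecule_types[name].to_text()}")
    out.append("end molecule types")
    out.append("begin species")
    for i, sp in enumerate(net.species):
        amount = net.seed_amounts.get(i, 0.0)
        out.append(f"  {i} {sp.label} {amount!r}")
    out.append("end species")
    out.append("begin reactions")
    for r in net.reactions:
        rt = ",".join(str(i) for i in r.reactants) or "-"
        pt = ",".join(str(i) for i in r.products) or "-"
        out.append(
            f"  {rt} {pt} {r.rate_law.to_text()} {r.factor!r} {r.rule_name}"
        )
    out.append("end reactions")
    if net.truncated:
        out.append("# truncated: aggregate or iteration cap reached")
    return "\n".join(out) + "\n"


def read_network_text(text: str) -> ReactionNetwork:
    from .model import _parse_rate_expr  # shared rate grammar

    net = ReactionNetwork()
    block = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            if raw.strip().startswith("# truncated"):
                net.truncated = True
            continue
        m = re.match(r"^begin\s+(.+)$", line)
        if m:
            block = m.group(1)
            continue
        if re.match(r"^end\s+", line):
            block = None
            continue
        try:
            if block == "parameters":
                name, value = line.split()
                net.parameters[name] = float(value)
            elif block == "molecule types":
                tdef = parse_molecule_type(line)
                net.molecule_types[tdef.name] = tdef
            elif block == "species":
                idx_s, label, amount = line.split()
                idx = int(idx_s)
                if idx != len(net.species):
                    raise ValueError(f"species index {idx} out of order")
                net.species.append(parse_complex(label))
                if float(amount) != 0.0:
                    net.seed_amounts[idx] = float(amount)
            elif block == "reactions":
                rt, pt, rate_text, factor, rule_name = line.split()
                reactants = tuple(int(i) for i in rt.split(",")) if rt != "-" else ()
                products = tuple(int(i) for i in pt.split(",")) if pt != "-" else ()
                for i in reactants + products:
                    if i >= len(net.species):
                        raise ValueError(f"reaction references unknown species {i}")
                net.reactions.append(
                    Reaction(reactants, products, _parse_rate_expr(rate_text),
                             float(factor), rule_name)
                )
            else:
                raise ValueError(f"statement outside known block: {line!r}")
        except ValueError as exc:
            raise ModelParseError(str(exc), lineno) from exc
    return net
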