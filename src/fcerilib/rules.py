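"""Rules and their transformations.

A rule is a pair of ordered pattern lists (reactants, products) plus a rate
law.  The *transformation* of a rule is the edit script -- bond additions and
deletions, internal-state changes, molecule deletions and creations -- that
turns the reactant patterns into the product patterns.  It is computed once
per rule by matching reactant and product molecules positionally by type
(left to right within each side), which is how rules are conventionally
written.

Applying a rule to a tuple of concrete species enumerates all embeddings of
the reactant patterns, replays the edit script on a disjoint copy of the
species, splits the result into connected components, and reports one outcome
per distinct product multiset together with a symmetry-corrected rate factor:

    factor = (number of embedding combinations yielding that outcome)
             / (automorphisms of the reactant pattern set)

so that each unordered set of reactant molecules is counted exactly once, the
standard mass-action convention for rule-derived reaction networks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .sitegraph import (
    ANY,
    FREE,
    UNSPEC,
    Molecule,
    MoleculeTypeDefinition,
    SiteGraph,
    SiteGraphError,
    automorphism_count,
    connected_components,
    find_embeddings,
    format_complex,
    pattern_key,
)

__all__ = [
    "RateLaw",
    "Rule",
    "RuleError",
    "Transformation",
    "compute_transformation",
    "apply_rule",
]


class RuleError(ValueError):
    """A rule whose product side cannot be derived from its reactant side."""


@dataclass(frozen=True)
class RateLaw:
    """A rate constant reference: ``multiplier * parameter`` (or a bare number).

    ``constant_name is None`` denotes a literal numeric rate equal to
    ``multiplier``.
    """

    constant_name: Optional[str] = None
    multiplier: float = 1.0

    def value(self, parameters: Mapping[str, float]) -> float:
        if self.constant_name is None:
            return self.multiplier
        try:
            return self.multiplier * parameters[self.constant_name]
        except KeyError:
            raise RuleError(f"unresolved rate parameter {self.constant_name!r}")

    def to_text(self) -> str:
        if self.constant_name is None:
            return repr(self.multiplier)
        if self.multiplier == 1.0:
            return self.constant_name
        return f"{self.multiplier:g}*{self.constant_name}"


@dataclass
class Transformation:
    """Edit script mapping reactant patterns to product patterns.

    Molecule references are global positions over the concatenated reactant
    patterns; created molecules are referenced as ``("new", k)``.
    """

    state_changes: list = field(default_factory=list)   # (ridx, site, new_state)
    bond_deletions: list = field(default_factory=list)  # ((ridx, site), (ridx, site))
    bond_additions: list = field(default_factory=list)  # ((ref, site), (ref, site))
    deletions: list = field(default_factory=list)       # [ridx]
    creations: list = field(default_factory=list)       # [Molecule template]

    def is_identity(self) -> bool:
        return not (
            self.state_changes
            or self.bond_deletions
            or self.bond_additions
            or self.deletions
            or self.creations
        )


@dataclass
class Rule:
    name: str
    reactants: list
    products: list
    rate_forward: RateLaw
    rate_reverse: Optional[RateLaw] = None
    delete_molecules: bool = False
    annotation: dict = field(default_factory=dict)

    @property
    def reversible(self) -> bool:
        return self.rate_reverse is not None

    def __post_init__(self):
        self._transformation: Optional[Transformation] = None
        self._symmetry: Optional[float] = None

    # -- derived, cached -------------------------------------------------

    @property
    def transformation(self) -> Transformation:
        if self._transformation is None:
            self._transformation = compute_transformation(self)
        return self._transformation

    @property
    def symmetry_factor(self) -> float:
        """|Aut| of the reactant pattern multiset (pattern swaps x internal)."""
        if self._symmetry is None:
            g = 1.0
            counts: dict = {}
            for p in self.reactants:
                counts[pattern_key(p)] = counts.get(pattern_key(p), 0) + 1
                g *= automorphism_count(p)
            for c in counts.values():
                for k in range(2, c + 1):
                    g *= k
            self._symmetry = g
        return self._symmetry

    def forward_part(self) -> "Rule":
        r = Rule(
            self.name,
            self.reactants,
            self.products,
            self.rate_forward,
            None,
            self.delete_molecules,
            self.annotation,
        )
        return r

    def reverse_part(self) -> "Rule":
        if not self.reversible:
            raise RuleError(f"rule {self.name} is not reversible")
        return Rule(
            self.name + "_rev",
            self.products,
            self.reactants,
            self.rate_reverse,
            None,
            self.delete_molecules,
            self.annotation,
        )

    def to_text(self) -> str:
        lhs = " + ".join(format_complex(p) for p in self.reactants) or "0"
        rhs = " + ".join(format_complex(p) for p in self.products) or "0"
        arrow = "<->" if self.reversible else "->"
        rates = self.rate_forward.to_text()
        if self.reversible:
            rates += ", " + self.rate_reverse.to_text()
        text = f"{lhs} {arrow} {rhs} {rates}"
        if self.delete_molecules:
            text += " DeleteMolecules"
        return text

    def __repr__(self):
        return f"Rule({self.name!r}: {self.to_text()})"


# ---------------------------------------------------------------------------
# Transformation computation
# ---------------------------------------------------------------------------

def _globalize(patterns: Sequence[SiteGraph]) -> list:
    """Flatten patterns into (global index -> (pattern idx, local idx, Molecule))."""
    out = []
    for pi, pat in enumerate(patterns):
        for li, mol in enumerate(pat.molecules):
            out.append((pi, li, mol))
    return out


def compute_transformation(rule: Rule) -> Transformation:
    rmols = _globalize(rule.reactants)
    pmols = _globalize(rule.products)

    # positional correspondence by type, left to right within each side
    rby: dict = {}
    for g, (_, _, mol) in enumerate(rmols):
        rby.setdefault(mol.name, []).append(g)
    pby: dict = {}
    for g, (_, _, mol) in enumerate(pmols):
        pby.setdefault(mol.name, []).append(g)

    corr: dict = {}       # product global -> reactant global
    created: list = []    # product globals with no reactant counterpart
    deleted: list = []    # reactant globals with no product counterpart
    for tname in sorted(set(rby) | set(pby)):
        rs = rby.get(tname, [])
        ps = pby.get(tname, [])
        for rg, pg in zip(rs, ps):
            corr[pg] = rg
        deleted.extend(rs[len(ps):])
        created.extend(ps[len(rs):])

    tr = Transformation()
    tr.deletions = sorted(deleted)

    rcorr = {rg: pg for pg, rg in corr.items()}

    # per-molecule site comparison
    for pg, rg in sorted(corr.items()):
        rmol = rmols[rg][2]
        pmol = pmols[pg][2]
        if set(rmol.sites) != set(pmol.sites):
            raise RuleError(
                f"rule {rule.name}: molecule {rmol.name} mentions different "
                f"sites on the two sides"
            )
        for sn in rmol.sites:
            rs_, ps_ = rmol.sites[sn], pmol.sites[sn]
            if rs_.state != ps_.state:
                if rs_.state is None or ps_.state is None:
                    raise RuleError(
                        f"rule {rule.name}: state of {rmol.name}.{sn} is "
                        f"unspecified on one side but set on the other"
                    )
                tr.state_changes.append((rg, sn, ps_.state))
            if (rs_.bond in (ANY, UNSPEC) or ps_.bond in (ANY, UNSPEC)) and (
                rs_.bond != ps_.bond
            ):
                raise RuleError(
                    f"rule {rule.name}: wildcard bond on {rmol.name}.{sn} "
                    f"differs between sides"
                )

    # bond sets with endpoints in global coordinates
    def bond_set(patterns, globalize):
        offsets = []
        g = 0
        for pat in patterns:
            offsets.append(g)
            g += len(pat.molecules)
        bonds = set()
        for pi, pat in enumerate(patterns):
            for (i, sa), (j, sb) in pat.bonds():
                bonds.add(frozenset([(offsets[pi] + i, sa), (offsets[pi] + j, sb)]))
        return bonds

    rbonds = bond_set(rule.reactants, rmols)
    pbonds_raw = bond_set(rule.products, pmols)

    # map product bonds into reactant coordinates / creation refs
    created_index = {pg: k for k, pg in enumerate(sorted(created))}

    def pref(pg, sn):
        if pg in corr:
            return (("r", corr[pg]), sn)
        return (("n", created_index[pg]), sn)

    pbonds = set()
    for b in pbonds_raw:
        (i, sa), (j, sb) = tuple(b)
        pbonds.add(frozenset([pref(i, sa), pref(j, sb)]))

    rbonds_as_refs = {
        frozenset([(("r", i), sa), (("r", j), sb)])
        for b in rbonds
        for (i, sa), (j, sb) in [tuple(b)]
    }

    deleted_set = set(deleted)
    for b in rbonds_as_refs - pbonds:
        (ri, sa), (rj, sb) = sorted(b, key=repr)
        if ri[1] in deleted_set or rj[1] in deleted_set:
            continue  # implied by molecule deletion
        tr.bond_deletions.append(tuple(sorted(((ri[1], sa), (rj[1], sb)))))
    for b in pbonds - rbonds_as_refs:
        (xi, sa), (xj, sb) = sorted(b, key=repr)
        tr.bond_additions.append(((xi, sa), (xj, sb)))
    tr.bond_deletions.sort()
    tr.bond_additions.sort(key=repr)

    for pg in sorted(created):
        tmpl = pmols[pg][2].copy()
        for site in tmpl.sites.values():
            if site.bond in (ANY, UNSPEC):
                raise RuleError(
                    f"rule {rule.name}: created molecule {tmpl.name} has a "
                    f"wildcard bond"
                )
            site.bond = FREE  # bonds of new molecules are in bond_additions
        tr.creations.append(tmpl)

    return tr


# ---------------------------------------------------------------------------
# Rule application
# ---------------------------------------------------------------------------

def _complete_molecule(
    mol: Molecule, types: Optional[Mapping[str, MoleculeTypeDefinition]]
) -> Molecule:
    """Fill in unmentioned sites of a created molecule (stateless sites only)."""
    if types is None or mol.name not in types:
        return mol
    tdef = types[mol.name]
    for sdef in tdef.sites:
        if sdef.name not in mol.sites:
            if sdef.states:
                raise RuleError(
                    f"created molecule {mol.name} must specify a state for "
                    f"site {sdef.name}"
                )
            from .sitegraph import Site

            mol.sites[sdef.name] = Site()
    return mol


def apply_rule(
    rule: Rule,
    species_tuple: Sequence[SiteGraph],
    types: Optional[Mapping[str, MoleculeTypeDefinition]] = None,
):
    """Apply an irreversible rule to one species per reactant pattern.

    Returns a list of ``(products, factor)`` where ``products`` is a tuple of
    canonical product species (connected components, sorted by label) and
    ``factor`` is the symmetry-corrected multiplicity: embeddings in the
    outcome class divided by the automorphism count of the reactant pattern
    set.  Empty list when no embedding exists.
    """
    if rule.reversible:
        raise RuleError("apply_rule expects an irreversible rule part")
    if len(species_tuple) != len(rule.reactants):
        raise RuleError(
            f"rule {rule.name} takes {len(rule.reactants)} species, "
            f"got {len(species_tuple)}"
        )
    per_pattern = []
    for pat, sp in zip(rule.reactants, species_tuple):
        embs = find_embeddings(pat, sp)
        if not embs:
            return []
        per_pattern.append(embs)

    tr = rule.transformation
    offsets = []
    total = 0
    for sp in species_tuple:
        offsets.append(total)
        total += len(sp.molecules)

    # reactant global index -> (pattern idx, local idx)
    rglobal = []
    for pi, pat in enumerate(rule.reactants):
        for li in range(len(pat.molecules)):
            rglobal.append((pi, li))

    outcomes: dict = {}
    for combo in itertools.product(*per_pattern) if per_pattern else [()]:
        work = SiteGraph()
        for sp in species_tuple:
            for mol in sp.molecules:
                work.add_molecule(mol.copy())
        # fix bond indices to working coordinates
        for k, sp in enumerate(species_tuple):
            off = offsets[k]
            for i in range(len(sp.molecules)):
                for site in work.molecules[off + i].sites.values():
                    if isinstance(site.bond, tuple):
                        site.bond = (site.bond[0] + off, site.bond[1])

        def widx(rg: int) -> int:
            pi, li = rglobal[rg]
            return offsets[pi] + combo[pi][li]

        for rg, sn, new_state in tr.state_changes:
            work.molecules[widx(rg)].sites[sn].state = new_state
        for (rg1, s1), (_rg2, _s2) in tr.bond_deletions:
            work.remove_bond(widx(rg1), s1)
        new_idx = []
        for tmpl in tr.creations:
            mol = _complete_molecule(tmpl.copy(), types)
            new_idx.append(work.add_molecule(mol))
        for (ref1, s1), (ref2, s2) in tr.bond_additions:
            i = widx(ref1[1]) if ref1[0] == "r" else new_idx[ref1[1]]
            j = widx(ref2[1]) if ref2[0] == "r" else new_idx[ref2[1]]
            work.add_bond(i, s1, j, s2)

        doomed = {widx(rg) for rg in tr.deletions}
        if doomed and not rule.delete_molecules:
            # without DeleteMolecules, deleting a molecule removes the whole
            # complex it sits in after the other edits are applied
            comps_idx = _component_ids(work)
            doomed = {
                i
                for i in range(len(work.molecules))
                if comps_idx[i] in {comps_idx[d] for d in doomed}
            }
        if doomed:
            keep = [i for i in range(len(work.molecules)) if i not in doomed]
            remap = {old: new for new, old in enumerate(keep)}
            final = SiteGraph()
            for old in keep:
                mol = work.molecules[old]
                for site in mol.sites.values():
                    if isinstance(site.bond, tuple):
                        if site.bond[0] in doomed:
                            site.bond = FREE
                        else:
                            site.bond = (remap[site.bond[0]], site.bond[1])
                final.add_molecule(mol)
            work = final

        comps = connected_components(work)
        for c in comps:
            if types is not None:
                c.validate_species(types)
        key = tuple(sorted(c.label for c in comps))
        if key in outcomes:
            outcomes[key][1] += 1
        else:
            outcomes[key] = [tuple(sorted(comps, key=lambda c: c.label)), 1]

    g = rule.symmetry_factor
    return [(prods, count / g) for prods, count in outcomes.values()]


def _component_ids(graph: SiteGraph) -> list:
    n = len(graph.molecules)
    comp = [-1] * n
    c = 0
    for s in range(n):
        if comp[s] != -1:
            continue
        comp[s] = c
        stack = [s]
        while stack:
            i = stack.pop()
            for site in graph.molecules[i].sites.values():
                if isinstance(site.bond, tuple) and comp[site.bond[0]] == -1:
                    comp[site.bond[0]] = c
                    stack.append(site.bond[0])
        c += 1
    return comp
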