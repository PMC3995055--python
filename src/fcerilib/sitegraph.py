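"""Site graphs: the structured representation of molecules, complexes, and patterns.

A molecule is a typed node carrying named sites; a site may hold an internal
state (e.g. a phosphorylation flag ``~0``/``~P``) and may participate in at most
one bond.  A *species* is a fully specified, connected graph of molecules --
the unit of chemical identity in a rule-based model.  A *pattern* is a partial
graph used on the left/right side of rules and in observables: sites may be
omitted (no constraint), states may be left unspecified, and a bond may be
required without naming the partner (the ``!+`` wildcard).

This module provides the three core graph algorithms everything else builds on:

* :func:`canonical_label` -- a deterministic text label equal for two species
  iff they are isomorphic as labeled site graphs (color refinement with
  individualization on ties),
* :func:`find_embeddings` -- all maps of a pattern into a species that respect
  types, states, and bonds (symmetric matches are all reported; deduplication
  and symmetry factors are the rule engine's job),
* :func:`connected_components` -- partition of a molecule/bond collection into
  maximal connected subgraphs.

Text notation follows the BNGL dialect used throughout the rule library:
``Syk(tSH2!+,PTK)``, ``Lat(Y136~P!1).Plcg1(SH2!1)``, ``IP3()``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

__all__ = [
    "FREE",
    "ANY",
    "UNSPEC",
    "SiteDefinition",
    "MoleculeTypeDefinition",
    "Site",
    "Molecule",
    "SiteGraph",
    "SiteGraphError",
    "parse_complex",
    "format_complex",
    "canonical_label",
    "find_embeddings",
    "connected_components",
    "automorphism_count",
]


class SiteGraphError(ValueError):
    """Malformed species/pattern text or violated graph invariant."""


#: Bond status sentinels.  A concrete bond is stored as the partner endpoint
#: ``(molecule_index, site_name)`` instead of a sentinel.
FREE = "free"
ANY = "any"       # the "!+" wildcard: bound, partner unconstrained
UNSPEC = "unspec"  # the "!?" wildcard: no constraint on bond status

BondStatus = Union[str, tuple]


@dataclass(frozen=True)
class SiteDefinition:
    """A named site of a molecule type with its finite set of internal states."""

    name: str
    states: tuple = ()

    def __post_init__(self):
        if len(set(self.states)) != len(self.states):
            raise SiteGraphError(f"duplicate states for site {self.name!r}")


@dataclass(frozen=True)
class MoleculeTypeDefinition:
    """A molecule type: a name plus an ordered collection of site definitions."""

    name: str
    sites: tuple = ()

    def __post_init__(self):
        names = [s.name for s in self.sites]
        if len(set(names)) != len(names):
            raise SiteGraphError(f"duplicate site names in molecule type {self.name!r}")

    @property
    def site_names(self) -> tuple:
        return tuple(s.name for s in self.sites)

    def site(self, name: str) -> SiteDefinition:
        for s in self.sites:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_text(self) -> str:
        parts = []
        for s in self.sites:
            parts.append(s.name + "".join(f"~{st}" for st in s.states))
        return f"{self.name}({','.join(parts)})"


@dataclass
class Site:
    """State and bond status of one site on one molecule instance."""

    state: Optional[str] = None
    bond: BondStatus = FREE

    def copy(self) -> "Site":
        return Site(self.state, self.bond)


@dataclass
class Molecule:
    """A molecule instance inside a graph: type name plus its mentioned sites."""

    name: str
    sites: dict = field(default_factory=dict)  # site name -> Site

    def copy(self) -> "Molecule":
        return Molecule(self.name, {k: v.copy() for k, v in self.sites.items()})


class SiteGraph:
    """A collection of molecules joined by bonds; used for species and patterns.

    Bonds are stored symmetrically: if site ``a`` of molecule ``i`` is bonded to
    site ``b`` of molecule ``j``, then ``molecules[i].sites[a].bond == (j, b)``
    and vice versa.
    """

    def __init__(self, molecules: Optional[Sequence[Molecule]] = None):
        self.molecules: list = list(molecules) if molecules else []
        self._label: Optional[str] = None

    # -- construction ----------------------------------------------------

    def copy(self) -> "SiteGraph":
        g = SiteGraph([m.copy() for m in self.molecules])
        return g

    def add_molecule(self, mol: Molecule) -> int:
        self._label = None
        self.molecules.append(mol)
        return len(self.molecules) - 1

    def add_bond(self, i: int, site_a: str, j: int, site_b: str) -> None:
        sa = self.molecules[i].sites[site_a]
        sb = self.molecules[j].sites[site_b]
        if isinstance(sa.bond, tuple) or isinstance(sb.bond, tuple):
            raise SiteGraphError("site already participates in a bond")
        sa.bond = (j, site_b)
        sb.bond = (i, site_a)
        self._label = None

    def remove_bond(self, i: int, site_a: str) -> None:
        sa = self.molecules[i].sites[site_a]
        if not isinstance(sa.bond, tuple):
            raise SiteGraphError(f"site {site_a} of molecule {i} is not bonded")
        j, site_b = sa.bond
        self.molecules[j].sites[site_b].bond = FREE
        sa.bond = FREE
        self._label = None

    # -- queries ---------------------------------------------------------

    def bonds(self) -> list:
        """Unordered bond list as pairs of (molecule index, site name)."""
        seen = set()
        out = []
        for i, mol in enumerate(self.molecules):
            for sn, site in mol.sites.items():
                if isinstance(site.bond, tuple):
                    j, sb = site.bond
                    key = frozenset([(i, sn), (j, sb)])
                    if key not in seen:
                        seen.add(key)
                        out.append(((i, sn), (j, sb)))
        return out

    def type_names(self) -> frozenset:
        return frozenset(m.name for m in self.molecules)

    def is_connected(self) -> bool:
        n = len(self.molecules)
        if n <= 1:
            return True
        seen = {0}
        stack = [0]
        while stack:
            i = stack.pop()
            for site in self.molecules[i].sites.values():
                if isinstance(site.bond, tuple):
                    j = site.bond[0]
                    if j not in seen:
                        seen.add(j)
                        stack.append(j)
        return len(seen) == n

    def check_bond_consistency(self) -> None:
        for i, mol in enumerate(self.molecules):
            for sn, site in mol.sites.items():
                if isinstance(site.bond, tuple):
                    j, sb = site.bond
                    back = self.molecules[j].sites[sb].bond
                    if back != (i, sn):
                        raise SiteGraphError(
                            f"asymmetric bond at molecule {i} site {sn}"
                        )

    def validate_species(
        self, types: Optional[Mapping[str, MoleculeTypeDefinition]] = None
    ) -> None:
        """Check full SpeciesGraph invariants (raises :class:`SiteGraphError`).

        A species must be connected, every bond symmetric, and -- when type
        definitions are supplied -- fully specified: every site of each type
        present, states drawn from the allowed set, no wildcard bonds.
        """
        if not self.molecules:
            raise SiteGraphError("empty species")
        self.check_bond_consistency()
        if not self.is_connected():
            raise SiteGraphError("species graph is not connected")
        for i, mol in enumerate(self.molecules):
            for sn, site in mol.sites.items():
                if site.bond in (ANY, UNSPEC):
                    raise SiteGraphError(
                        f"wildcard bond on species molecule {mol.name}.{sn}"
                    )
            if types is not None:
                if mol.name not in types:
                    raise SiteGraphError(f"unknown molecule type {mol.name!r}")
                tdef = types[mol.name]
                if set(mol.sites) != set(tdef.site_names):
                    raise SiteGraphError(
                        f"species molecule {mol.name} must list all sites "
                        f"{tdef.site_names}"
                    )
                for sdef in tdef.sites:
                    st = mol.sites[sdef.name].state
                    if sdef.states:
                        if st not in sdef.states:
                            raise SiteGraphError(
                                f"state {st!r} not allowed for {mol.name}.{sdef.name}"
                            )
                    elif st is not None:
                        raise SiteGraphError(
                            f"site {mol.name}.{sdef.name} carries no states"
                        )

    def validate_pattern(
        self, types: Optional[Mapping[str, MoleculeTypeDefinition]] = None
    ) -> None:
        self.check_bond_consistency()
        if types is None:
            return
        for mol in self.molecules:
            if mol.name not in types:
                raise SiteGraphError(f"unknown molecule type {mol.name!r}")
            tdef = types[mol.name]
            for sn, site in mol.sites.items():
                if sn not in tdef.site_names:
                    raise SiteGraphError(f"unknown site {mol.name}.{sn}")
                if site.state is not None and site.state not in tdef.site(sn).states:
                    raise SiteGraphError(
                        f"state {site.state!r} not allowed for {mol.name}.{sn}"
                    )

    # -- identity --------------------------------------------------------

    @property
    def label(self) -> str:
        if self._label is None:
            self._label = canonical_label(self, _check=False)
        return self._label

    def __eq__(self, other):
        return isinstance(other, SiteGraph) and self.label == other.label

    def __hash__(self):
        return hash(self.label)

    def __repr__(self):
        return f"SiteGraph({format_complex(self)!r})"


# ---------------------------------------------------------------------------
# Text notation
# ---------------------------------------------------------------------------

_SITE_RE = re.compile(
    r"^(?P<name>[A-Za-z0-9_]+)(?P<mods>(?:~[A-Za-z0-9_]+|![0-9]+|!\+|!\?)*)$"
)
_MOL_RE = re.compile(r"^(?P<name>[A-Za-z0-9_]+)\((?P<sites>[^()]*)\)$")


def parse_complex(text: str) -> SiteGraph:
    """Parse one dotted complex (species or pattern) from BNGL-style text.

    Tolerates whitespace anywhere (the typeset rules in the source literature
    render ``!+`` as ``! +``).  Bond indices are arbitrary labels local to the
    complex; each index must occur exactly twice.
    """
    compact = re.sub(r"\s+", "", text)
    if not compact:
        raise SiteGraphError("empty complex text")
    graph = SiteGraph()
    half_bonds: dict = {}
    for mol_text in compact.split("."):
        m = _MOL_RE.match(mol_text)
        if not m:
            raise SiteGraphError(f"cannot parse molecule {mol_text!r}")
        mol = Molecule(m.group("name"))
        idx = graph.add_molecule(mol)
        sites_text = m.group("sites")
        if sites_text:
            for site_text in sites_text.split(","):
                sm = _SITE_RE.match(site_text)
                if not sm:
                    raise SiteGraphError(f"cannot parse site {site_text!r}")
                sname = sm.group("name")
                if sname in mol.sites:
                    raise SiteGraphError(
                        f"site {sname!r} listed twice on {mol.name!r}"
                    )
                site = Site()
                bond_token: Optional[str] = None
                for mod in re.findall(r"~[A-Za-z0-9_]+|![0-9]+|!\+|!\?", sm.group("mods")):
                    if mod.startswith("~"):
                        if site.state is not None:
                            raise SiteGraphError(f"two states on site {sname!r}")
                        site.state = mod[1:]
                    else:
                        if bond_token is not None:
                            raise SiteGraphError(f"two bonds on site {sname!r}")
                        bond_token = mod[1:]
                mol.sites[sname] = site
                if bond_token == "+":
                    site.bond = ANY
                elif bond_token == "?":
                    site.bond = UNSPEC
                elif bond_token is not None:
                    if bond_token in half_bonds:
                        j, sb = half_bonds.pop(bond_token)
                        graph.add_bond(idx, sname, j, sb)
                    else:
                        half_bonds[bond_token] = (idx, sname)
    if half_bonds:
        raise SiteGraphError(f"dangling bond indices: {sorted(half_bonds)}")
    return graph


def format_complex(graph: SiteGraph, order: Optional[Sequence[int]] = None) -> str:
    """Serialize a graph back to dotted text with bond indices from 1."""
    if order is None:
        order = range(len(graph.molecules))
    bond_ids: dict = {}
    counter = [0]

    def bond_id(i: int, sn: str) -> int:
        key = (i, sn)
        if key not in bond_ids:
            counter[0] += 1
            j, sb = graph.molecules[i].sites[sn].bond
            bond_ids[key] = counter[0]
            bond_ids[(j, sb)] = counter[0]
        return bond_ids[key]

    mol_texts = []
    for i in order:
        mol = graph.molecules[i]
        parts = []
        for sn in sorted(mol.sites):
            site = mol.sites[sn]
            t = sn
            if site.state is not None:
                t += f"~{site.state}"
            if site.bond == ANY:
                t += "!+"
            elif site.bond == UNSPEC:
                t += "!?"
            elif isinstance(site.bond, tuple):
                t += f"!{bond_id(i, sn)}"
            parts.append(t)
        mol_texts.append(f"{mol.name}({','.join(parts)})")
    return ".".join(mol_texts)


# ---------------------------------------------------------------------------
# Canonical labeling
# ---------------------------------------------------------------------------

def _initial_colors(graph: SiteGraph) -> list:
    colors = []
    for mol in graph.molecules:
        sig = []
        for sn in sorted(mol.sites):
            site = mol.sites[sn]
            if isinstance(site.bond, tuple):
                bk = "b"
            else:
                bk = {FREE: "f", ANY: "+", UNSPEC: "?"}[site.bond]
            sig.append((sn, site.state if site.state is not None else "\0", bk))
        colors.append((mol.name, tuple(sig)))
    return colors


def _refine(graph: SiteGraph, colors: list) -> list:
    """Iterative color refinement on (color, bonded-neighborhood colors)."""
    n = len(colors)
    while True:
        keys = []
        for i, mol in enumerate(graph.molecules):
            nbr = []
            for sn in sorted(mol.sites):
                b = mol.sites[sn].bond
                if isinstance(b, tuple):
                    j, sb = b
                    nbr.append((sn, sb, colors[j]))
            keys.append((colors[i], tuple(nbr)))
        ranking = {k: r for r, k in enumerate(sorted(set(keys), key=repr))}
        new = [ranking[k] for k in keys]
        if len(set(new)) == len(set(colors)):
            # stable partition; keep ordered ranks for deterministic sorting
            return new
        colors = new
        if len(set(colors)) == n:
            return colors


def _serialize(graph: SiteGraph, colors: list) -> str:
    order = sorted(range(len(colors)), key=lambda i: (colors[i], i))
    return format_complex(graph, order)


def _canon_search(graph: SiteGraph, colors: list) -> str:
    colors = _refine(graph, colors)
    classes: dict = {}
    for i, c in enumerate(colors):
        classes.setdefault(c, []).append(i)
    ambiguous = [members for c, members in sorted(classes.items()) if len(members) > 1]
    if not ambiguous:
        return _serialize(graph, colors)
    target = ambiguous[0]
    best = None
    base = max(colors) + 1
    for m in target:
        trial = list(colors)
        trial[m] = base  # individualize, then re-refine
        label = _canon_search(graph, trial)
        if best is None or label < best:
            best = label
    return best


def canonical_label(species: SiteGraph, _check: bool = True) -> str:
    """Deterministic label equal for two species iff they are isomorphic.

    Uses iterative color refinement on (molecule type, site states, bond
    partners) with trial individualization on ties; the label is the
    lexicographically smallest serialization over the surviving orderings.
    Molecule order and bond index numbering in the input are immaterial.
    """
    if _check:
        species.check_bond_consistency()
        if not species.is_connected():
            raise SiteGraphError("canonical_label requires a connected species")
    if not species.molecules:
        raise SiteGraphError("empty graph has no label")
    return _canon_search(species, _initial_colors(species))


def pattern_key(pattern: SiteGraph) -> str:
    """Canonical identity key for a (possibly disconnected) pattern graph."""
    comps = connected_components(pattern)
    return " | ".join(sorted(_canon_search(c, _initial_colors(c)) for c in comps))


# ---------------------------------------------------------------------------
# Embedding search
# ---------------------------------------------------------------------------

def _match_site(psite: Site, tsite: Site, exact: bool) -> bool:
    if exact:
        if psite.state != tsite.state:
            return False
        pb, tb = psite.bond, tsite.bond
        if isinstance(pb, tuple) != isinstance(tb, tuple):
            return False
        if not isinstance(pb, tuple) and pb != tb:
            return False
        return True
    if psite.state is not None and psite.state != tsite.state:
        return False
    b = psite.bond
    if b == FREE:
        return tsite.bond == FREE
    if b == ANY:
        return isinstance(tsite.bond, tuple)
    if b == UNSPEC:
        return True
    return isinstance(tsite.bond, tuple)  # concrete bond: partner checked later


def _search_order(pattern: SiteGraph) -> list:
    """Order pattern molecules so each extends a bonded prefix when possible."""
    n = len(pattern.molecules)
    remaining = set(range(n))
    order = []
    while remaining:
        start = min(remaining)
        stack = [start]
        remaining.discard(start)
        while stack:
            i = stack.pop()
            order.append(i)
            for site in pattern.molecules[i].sites.values():
                if isinstance(site.bond, tuple):
                    j = site.bond[0]
                    if j in remaining:
                        remaining.discard(j)
                        stack.append(j)
    return order


def find_embeddings(
    pattern: SiteGraph, target: SiteGraph, exact: bool = False
) -> list:
    """All embeddings of ``pattern`` into ``target``.

    An embedding is a tuple ``m`` with ``m[p] = t`` mapping pattern molecule
    positions to distinct target molecule positions such that molecule types
    agree and every state/bond constraint of the pattern is satisfied.  Omitted
    sites impose no constraint; ``!+`` is matched only by bound sites.  All
    symmetric embeddings are reported.

    With ``exact=True`` the match requires constraint *identity* (used to count
    automorphisms of patterns): states must agree exactly (including
    "unspecified") and bond statuses must be of identical kind.
    """
    np_, nt = len(pattern.molecules), len(target.molecules)
    if np_ == 0:
        return [()]
    if np_ > nt:
        return []
    order = _search_order(pattern)
    candidates: dict = {}
    for p in order:
        pmol = pattern.molecules[p]
        cands = []
        for t, tmol in enumerate(target.molecules):
            if tmol.name != pmol.name:
                continue
            if exact and set(pmol.sites) != set(tmol.sites):
                continue
            ok = True
            for sn, psite in pmol.sites.items():
                tsite = tmol.sites.get(sn)
                if tsite is None or not _match_site(psite, tsite, exact):
                    ok = False
                    break
            if ok:
                cands.append(t)
        if not cands:
            return []
        candidates[p] = cands

    assignment: dict = {}
    used = set()
    results = []

    def consistent(p: int, t: int) -> bool:
        pmol = pattern.molecules[p]
        tmol = target.molecules[t]
        for sn, psite in pmol.sites.items():
            if isinstance(psite.bond, tuple):
                q, qs = psite.bond
                tb = tmol.sites[sn].bond
                if not isinstance(tb, tuple):
                    return False
                if q in assignment:
                    if tb != (assignment[q], qs):
                        return False
        return True

    def rec(k: int):
        if k == len(order):
            results.append(tuple(assignment[p] for p in range(np_)))
            return
        p = order[k]
        for t in candidates[p]:
            if t in used:
                continue
            if not consistent(p, t):
                continue
            assignment[p] = t
            used.add(t)
            rec(k + 1)
            used.discard(t)
            del assignment[p]

    rec(0)
    return results


def automorphism_count(pattern: SiteGraph) -> int:
    """Number of constraint-preserving self-bijections of a pattern graph."""
    return len(find_embeddings(pattern, pattern, exact=True))


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------

def connected_components(graph: SiteGraph) -> list:
    """Split a molecule/bond collection into maximal connected subgraphs.

    Components are returned in order of their smallest original molecule
    index; molecule order within a component follows the original order.
    """
    n = len(graph.molecules)
    comp = [-1] * n
    ncomp = 0
    for start in range(n):
        if comp[start] != -1:
            continue
        comp[start] = ncomp
        stack = [start]
        while stack:
            i = stack.pop()
            for site in graph.molecules[i].sites.values():
                if isinstance(site.bond, tuple):
                    j = site.bond[0]
                    if comp[j] == -1:
                        comp[j] = ncomp
                        stack.append(j)
        ncomp += 1
    out = []
    for c in range(ncomp):
        members = [i for i in range(n) if comp[i] == c]
        remap = {old: new for new, old in enumerate(members)}
        sub = SiteGraph()
        for old in members:
            mol = graph.molecules[old].copy()
            for site in mol.sites.values():
                if isinstance(site.bond, tuple):
                    j, sb = site.bond
                    site.bond = (remap[j], sb)
            sub.add_molecule(mol)
        out.append(sub)
    return out
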