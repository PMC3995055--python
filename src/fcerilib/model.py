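"""Model container and the BNGL-subset text format.

A model bundles molecule type declarations, a parameter set, seed species
with initial copy numbers, observables, and reaction rules.  The supported
text format is the conventional block layout::

    begin parameters
      kf 1e-6
    end parameters
    begin molecule types
      A(b,y~0~P)
    end molecule types
    begin seed species
      A(b,y~0) 1000
    end seed species
    begin observables
      Molecules A_phos A(y~P)
    end observables
    begin reaction rules
      bind: A(b) + B(a) <-> A(b!1).B(a!1) kf, kr
    end reaction rules

Supported rule syntax: ``->`` and ``<->`` arrows (the typeset variants
``- >``/``< - >`` are tolerated), ``!+`` bound wildcards, ``!?`` unspecified
bonds, ``~`` internal states, ``.`` complexes, ``0`` for an empty side,
numeric or ``name`` or ``number*name`` rate expressions, and the
``DeleteMolecules`` keyword.  Comments start with ``#``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Optional

from .sitegraph import (
    MoleculeTypeDefinition,
    SiteDefinition,
    SiteGraph,
    SiteGraphError,
    format_complex,
    parse_complex,
)
from .rules import RateLaw, Rule, RuleError

__all__ = [
    "ParameterSet",
    "Observable",
    "Model",
    "ModelParseError",
    "parse_model_text",
    "write_model_text",
    "parse_molecule_type",
]


class ModelParseError(ValueError):
    def __init__(self, message, line: Optional[int] = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ParameterSet(dict):
    """Mapping of rate-constant / amount names to nonnegative finite values."""

    def __setitem__(self, key, value):
        value = float(value)
        if not math.isfinite(value) or value < 0:
            raise ValueError(f"parameter {key!r} must be finite and >= 0")
        super().__setitem__(key, value)

    def updated(self, overrides) -> "ParameterSet":
        p = ParameterSet(self)
        for k, v in dict(overrides).items():
            p[k] = v
        return p


@dataclass
class Observable:
    """A pattern-defined model output.

    ``kind`` is ``"Molecules"`` (embedding-weighted sum over species amounts)
    or ``"Species"`` (sum of amounts of species containing at least one
    match).
    """

    name: str
    kind: str
    patterns: list

    def __post_init__(self):
        if self.kind not in ("Molecules", "Species"):
            raise ValueError(f"unknown observable kind {self.kind!r}")


@dataclass
class Model:
    molecule_types: dict = field(default_factory=dict)  # name -> MoleculeTypeDefinition
    parameters: ParameterSet = field(default_factory=ParameterSet)
    seeds: list = field(default_factory=list)  # (SiteGraph, amount: float | str)
    observables: list = field(default_factory=list)
    rules: list = field(default_factory=list)

    def seed_amount(self, i: int) -> float:
        amount = self.seeds[i][1]
        if isinstance(amount, str):
            try:
                return self.parameters[amount]
            except KeyError:
                raise RuleError(f"unresolved seed amount parameter {amount!r}")
        return float(amount)

    def validate(self) -> None:
        for g, _ in self.seeds:
            g.validate_species(self.molecule_types)
        for i in range(len(self.seeds)):
            self.seed_amount(i)
        for rule in self.rules:
            for p in rule.reactants + rule.products:
                p.validate_pattern(self.molecule_types)
            rule.rate_forward.value(self.parameters)
            if rule.rate_reverse is not None:
                rule.rate_reverse.value(self.parameters)
            rule.transformation  # raises RuleError if inconsistent
        for obs in self.observables:
            for p in obs.patterns:
                p.validate_pattern(self.molecule_types)

    def to_text(self) -> str:
        return write_model_text(self)

    def structurally_equal(self, other: "Model") -> bool:
        """Equality up to formatting: same types, parameters, seeds, rules."""
        from .sitegraph import pattern_key

        def rule_sig(r):
            return (
                tuple(pattern_key(p) for p in r.reactants),
                tuple(pattern_key(p) for p in r.products),
                r.rate_forward,
                r.rate_reverse,
                r.delete_molecules,
            )

        def obs_sig(o):
            return (o.name, o.kind, tuple(pattern_key(p) for p in o.patterns))

        return (
            self.molecule_types == other.molecule_types
            and dict(self.parameters) == dict(other.parameters)
            and [(g.label, a) for g, a in self.seeds]
            == [(g.label, a) for g, a in other.seeds]
            and [rule_sig(r) for r in self.rules]
            == [rule_sig(r) for r in other.rules]
            and [obs_sig(o) for o in self.observables]
            == [obs_sig(o) for o in other.observables]
        )


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_MOLTYPE_RE = re.compile(r"^(?P<name>[A-Za-z0-9_]+)\((?P<sites>[^()]*)\)$")
_RATE_RE = re.compile(
    r"^(?:(?P<num>[0-9.eE+-]+)\*)?(?P<name>[A-Za-z_][A-Za-z0-9_]*)$"
    r"|^(?P<lit>[0-9.eE+-]+)$"
)


def parse_molecule_type(text: str) -> MoleculeTypeDefinition:
    compact = re.sub(r"\s+", "", text)
    m = _MOLTYPE_RE.match(compact)
    if not m:
        raise SiteGraphError(f"cannot parse molecule type {text!r}")
    sites = []
    if m.group("sites"):
        for part in m.group("sites").split(","):
            bits = part.split("~")
            sites.append(SiteDefinition(bits[0], tuple(bits[1:])))
    return MoleculeTypeDefinition(m.group("name"), tuple(sites))


def _parse_rate_expr(text: str) -> RateLaw:
    m = _RATE_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse rate expression {text!r}")
    if m.group("lit") is not None:
        return RateLaw(None, float(m.group("lit")))
    mult = float(m.group("num")) if m.group("num") else 1.0
    return RateLaw(m.group("name"), mult)


def _split_patterns(side_text: str) -> list:
    compact = re.sub(r"\s+", "", side_text)
    if compact in ("0", ""):
        return []
    parts = re.split(r"(?<!!)\+", compact)
    return [parse_complex(p) for p in parts]


def parse_rule_line(line: str, name: Optional[str] = None) -> Rule:
    """Parse one reaction-rule line (arrow normalization included)."""
    text = line.strip()
    text = re.sub(r"<\s*-\s*>", "<->", text)
    text = re.sub(r"(?<!<)-\s*>", "->", text)
    text = re.sub(r"!\s*\+", "!+", text)

    m = re.match(r"^([A-Za-z0-9_]+):\s*(.*)$", text)
    if m and "(" not in m.group(1):
        name = m.group(1)
        text = m.group(2)

    if "<->" in text:
        lhs_text, rhs_text = text.split("<->", 1)
        reversible = True
    elif "->" in text:
        lhs_text, rhs_text = text.split("->", 1)
        reversible = False
    else:
        raise ValueError(f"no reaction arrow in {line!r}")

    reactants = _split_patterns(lhs_text)

    tokens = rhs_text.split()
    delete_molecules = False
    if tokens and tokens[-1] == "DeleteMolecules":
        delete_molecules = True
        tokens = tokens[:-1]
    # trailing paren-free tokens form the rate section; "+" and a bare "0"
    # belong to the product side
    rate_tokens = []
    while tokens and "(" not in tokens[-1] and tokens[-1] not in ("0", "+"):
        rate_tokens.insert(0, tokens.pop())
    if not rate_tokens:
        raise ValueError(f"missing rate in {line!r}")
    rate_text = " ".join(rate_tokens)
    product_text = " ".join(tokens)
    exprs = [e for e in (s.strip() for s in rate_text.split(",")) if e]
    if reversible and len(exprs) != 2:
        raise ValueError(f"reversible rule needs two rates: {line!r}")
    if not reversible and len(exprs) != 1:
        raise ValueError(f"irreversible rule needs one rate: {line!r}")
    products = _split_patterns(product_text)

    return Rule(
        name or "rule",
        reactants,
        products,
        _parse_rate_expr(exprs[0]),
        _parse_rate_expr(exprs[1]) if reversible else None,
        delete_molecules,
    )


def parse_model_text(text: str) -> Model:
    """Parse a model file in the supported BNGL subset.

    Raises :class:`ModelParseError` carrying the offending line number for
    unknown molecules/sites/states and unresolved parameters.
    """
    model = Model()
    block = None
    rule_counter = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = re.match(r"^begin\s+(.+)$", line)
        if m:
            if block is not None:
                raise ModelParseError(f"nested block {m.group(1)!r}", lineno)
            block = m.group(1).strip()
            continue
        m = re.match(r"^end\s+(.+)$", line)
        if m:
            if block != m.group(1).strip():
                raise ModelParseError(f"mismatched end {m.group(1)!r}", lineno)
            block = None
            continue
        try:
            if block == "parameters":
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"expected 'name value', got {line!r}")
                model.parameters[parts[0]] = float(parts[1])
            elif block == "molecule types":
                tdef = parse_molecule_type(line)
                if tdef.name in model.molecule_types:
                    raise ValueError(f"duplicate molecule type {tdef.name!r}")
                model.molecule_types[tdef.name] = tdef
            elif block in ("seed species", "species"):
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"expected 'species amount', got {line!r}")
                graph = parse_complex(parts[0])
                amount: object
                try:
                    amount = float(parts[1])
                except ValueError:
                    amount = parts[1]
                model.seeds.append((graph, amount))
            elif block == "observables":
                parts = line.split()
                if len(parts) < 3:
                    raise ValueError(f"expected 'kind name patterns', got {line!r}")
                patterns = [parse_complex(p) for p in parts[2:]]
                model.observables.append(Observable(parts[1], parts[0], patterns))
            elif block == "reaction rules":
                rule_counter += 1
                rule = parse_rule_line(line, name=f"r{rule_counter}")
                model.rules.append(rule)
            elif block is None:
                raise ValueError(f"statement outside any block: {line!r}")
            else:
                raise ValueError(f"unknown block {block!r}")
        except (ValueError, SiteGraphError, RuleError) as exc:
            raise ModelParseError(str(exc), lineno) from exc
    if block is not None:
        raise ModelParseError(f"unterminated block {block!r}")
    try:
        model.validate()
    except (SiteGraphError, RuleError, ValueError) as exc:
        raise ModelParseError(str(exc)) from exc
    return model


def write_model_text(model: Model) -> str:
    """Serialize a model; deterministic byte stream for identical inputs."""
    out = []
    out.append("begin parameters")
    for k in model.parameters:
        out.append(f"  {k} {model.parameters[k]!r}")
    out.append("end parameters")
    out.append("begin molecule types")
    for tdef in model.molecule_types.values():
        out.append(f"  {tdef.to_text()}")
    out.append("end molecule types")
    out.append("begin seed species")
    for graph, amount in model.seeds:
        atext = amount if isinstance(amount, str) else repr(float(amount))
        out.append(f"  {format_complex(graph)} {atext}")
    out.append("end seed species")
    out.append("begin observables")
    for obs in model.observables:
        pats = " ".join(format_complex(p) for p in obs.patterns)
        out.append(f"  {obs.kind} {obs.name} {pats}")
    out.append("end observables")
    out.append("begin reaction rules")
    for rule in model.rules:
        out.append(f"  {rule.name}: {rule.to_text()}")
    out.append("end reaction rules")
    return "\n".join(out) + "\n"
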