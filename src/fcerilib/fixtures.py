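"""Deterministic toy model fixtures with brute-force oracle expectations.

Each fixture is a small, fully specified model exercising one aspect of the
engine, shipped together with the independently derivable facts about it
(species counts after network generation, analytic steady states, bistable
windows from a cubic root oracle).  The ``seed`` argument deterministically
randomizes non-structural quantities (seed copy numbers) so property tests
can draw variants; structure and rate constants are fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Model, parse_model_text

__all__ = ["ToyFixture", "generate_toy_fixture", "FIXTURE_KINDS"]


@dataclass
class ToyFixture:
    kind: str
    model: Model
    expectations: dict = field(default_factory=dict)


def _dimerization(rng) -> ToyFixture:
    a0 = float(rng.integers(50, 500))
    b0 = float(rng.integers(50, 500))
    text = f"""
begin parameters
  kf 0.001
  kr 0.1
end parameters
begin molecule types
  A(b)
  B(a)
end molecule types
begin seed species
  A(b) {a0}
  B(a) {b0}
end seed species
begin observables
  Molecules AB A(b!1).B(a!1)
end observables
begin reaction rules
  bind: A(b) + B(a) <-> A(b!1).B(a!1) kf, kr
end reaction rules
"""
    # analytic equilibrium: kf (a0-c)(b0-c) = kr c
    kf, kr = 0.001, 0.1
    disc = (kf * (a0 + b0) + kr) ** 2 - 4 * kf * kf * a0 * b0
    c = ((kf * (a0 + b0) + kr) - disc ** 0.5) / (2 * kf)
    return ToyFixture("dimerization", parse_model_text(text), {
        "n_species": 3,
        "n_reactions": 2,
        "equilibrium_complex": c,
        "a0": a0,
        "b0": b0,
    })


def _catalytic(rng) -> ToyFixture:
    e0 = float(rng.integers(10, 100))
    s0 = float(rng.integers(100, 1000))
    text = f"""
begin parameters
  kf 0.001
  kr 0.1
  kcat 1.0
end parameters
begin molecule types
  E(s)
  S(e,y~0~P)
end molecule types
begin seed species
  E(s) {e0}
  S(e,y~0) {s0}
end seed species
begin observables
  Molecules product S(y~P)
  Molecules complex E(s!1).S(e!1)
end observables
begin reaction rules
  bind: E(s) + S(e,y~0) <-> E(s!1).S(e!1,y~0) kf, kr
  cat:  E(s!1).S(e!1,y~0) -> E(s) + S(e,y~P) kcat
end reaction rules
"""
    return ToyFixture("catalytic", parse_model_text(text), {
        # E, S0, E.S0, SP  (E.SP unreachable: binding requires y~0)
        "n_species": 4,
        "n_reactions": 3,
        "final_product": s0,  # all substrate converted eventually
        "e0": e0,
        "s0": s0,
    })


def _bivalent_aggregation(rng) -> ToyFixture:
    l0 = float(rng.integers(100, 500))
    r0 = float(rng.integers(100, 500))
    text = f"""
begin parameters
  kf1 0.001
  kf2 0.0005
  kr 0.05
end parameters
begin molecule types
  L(d1,d2)
  R(f1,f2)
end molecule types
begin seed species
  L(d1,d2) {l0}
  R(f1,f2) {r0}
end seed species
begin observables
  Molecules crosslinked L(d1!+,d2!+)
end observables
begin reaction rules
  b11: L(d1,d2) + R(f1) -> L(d1!1,d2).R(f1!1) kf1
  b12: L(d1,d2) + R(f2) -> L(d1!1,d2).R(f2!1) kf1
  b21: L(d2,d1) + R(f1) -> L(d2!1,d1).R(f1!1) kf1
  b22: L(d2,d1) + R(f2) -> L(d2!1,d1).R(f2!1) kf1
  x11: L(d1,d2!+) + R(f1) -> L(d1!1,d2!+).R(f1!1) kf2
  x12: L(d1,d2!+) + R(f2) -> L(d1!1,d2!+).R(f2!1) kf2
  x21: L(d2,d1!+) + R(f1) -> L(d2!1,d1!+).R(f1!1) kf2
  x22: L(d2,d1!+) + R(f2) -> L(d2!1,d1!+).R(f2!1) kf2
  u11: L(d1!1).R(f1!1) -> L(d1) + R(f1) kr
  u12: L(d1!1).R(f2!1) -> L(d1) + R(f2) kr
  u21: L(d2!1).R(f1!1) -> L(d2) + R(f1) kr
  u22: L(d2!1).R(f2!1) -> L(d2) + R(f2) kr
end reaction rules
"""
    return ToyFixture("bivalent_aggregation", parse_model_text(text), {
        # with a 3-molecule cap: L, R, 4 distinct L.R bond placements,
        # 4 distinct L.R.L chains, 4 distinct R.L.R chains (sites are named,
        # so placements are distinguishable)
        "n_species_cap3": 14,
        "l0": l0,
        "r0": r0,
    })


def _bistable_toy(rng) -> ToyFixture:
    # cubic autocatalysis (Schloegl-type): dx/dt = s + (kauto/2) x^2
    #   - (krev/6) x^3 - kdeg x ; bistable over a window of s
    text = """
begin parameters
  kauto 6.0
  krev 6.0
  kdeg 2.2
  s 0.1
end parameters
begin molecule types
  X()
end molecule types
begin seed species
  X() 0.0
end seed species
begin observables
  Molecules Xtot X()
end observables
begin reaction rules
  auto: X() + X() -> X() + X() + X() kauto
  rev:  X() + X() + X() -> X() + X() krev
  syn:  0 -> X() s
  deg:  X() -> 0 kdeg
end reaction rules
"""
    return ToyFixture("bistable_toy", parse_model_text(text), {
        "n_species": 1,
        "n_reactions": 4,
        # steady states solve -x^3 + 3 x^2 - 2.2 x + s = 0 (after symmetry
        # factors kauto/2 = 3, krev/6 = 1)
        "cubic": (-1.0, 3.0, -2.2),
        "parameter": "s",
    })


_GENERATORS = {
    "dimerization": _dimerization,
    "catalytic": _catalytic,
    "bivalent_aggregation": _bivalent_aggregation,
    "bistable_toy": _bistable_toy,
}

FIXTURE_KINDS = tuple(_GENERATORS)


def generate_toy_fixture(kind: str, seed: int = 0) -> ToyFixture:
    """Build a toy fixture; deterministic given (kind, seed)."""
    if kind not in _GENERATORS:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"choose from {FIXTURE_KINDS}")
    rng = np.random.default_rng(seed)
    return _GENERATORS[kind](rng)
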