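import numpy as np
import pytest

from fcerilib.sitegraph import Molecule, Site, SiteGraph


@pytest.fixture
def rng():
    return np.random.default_rng(20140415)


def random_complex(rng, n_molecules=5, types=("A", "B", "C")):
    """A random connected species: a spanning tree plus random extra bonds.

    Every molecule gets sites l/r/x with a random 0/P state on x; tree bonds
    use l-r pairs, extra bonds use the x sites when still free.
    """
    g = SiteGraph()
    for i in range(n_molecules):
        name = types[int(rng.integers(len(types)))]
        g.add_molecule(Molecule(name, {
            "l": Site(), "r": Site(),
            "x": Site(state="P" if rng.random() < 0.5 else "0"),
        }))
    order = rng.permutation(n_molecules)
    for k in range(1, n_molecules):
        child = int(order[k])
        parent = int(order[int(rng.integers(k))])
        if g.molecules[child].sites["l"].bond == "free" and \
                g.molecules[parent].sites["r"].bond == "free":
            g.add_bond(child, "l", parent, "r")
        elif g.molecules[child].sites["r"].bond == "free" and \
                g.molecules[parent].sites["l"].bond == "free":
            g.add_bond(child, "r", parent, "l")
        else:
            g.add_bond(child, "x", parent, "x") if (
                g.molecules[child].sites["x"].bond == "free"
                and g.molecules[parent].sites["x"].bond == "free"
            ) else None
    if not g.is_connected():  # fall back to a simple chain
        g = SiteGraph()
        for i in range(n_molecules):
            name = types[int(rng.integers(len(types)))]
            g.add_molecule(Molecule(name, {
                "l": Site(), "r": Site(),
                "x": Site(state="P" if rng.random() < 0.5 else "0"),
            }))
        for i in range(1, n_molecules):
            g.add_bond(i, "l", i - 1, "r")
    return g


def permuted_copy(graph, rng):
    """Re-serialize with a random molecule order and fresh bond indices."""
    from fcerilib.sitegraph import format_complex, parse_complex

    order = list(rng.permutation(len(graph.molecules)))
    return parse_complex(format_complex(graph, order))
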