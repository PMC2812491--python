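import numpy as np
import pytest

from kinens.network import ParameterSet, Reaction, ReactionNetwork, Species
from kinens.toy import build_toy_network


@pytest.fixture(scope="session")
def toy():
    return build_toy_network()


def make_network(species_rows, reaction_rows):
    """Compact builder: species_rows = [(id, init)], reaction_rows =
    [("A + B", "C", value)]; rate ids auto-named k1..kn."""
    from kinens.network import _infer_kind
    from kinens.toy import _parse_terms

    species = [Species(sid, "cytosol", init) for sid, init in species_rows]
    reactions = []
    values = []
    for i, (lhs, rhs_, val) in enumerate(reaction_rows):
        r, p = _parse_terms(lhs), _parse_terms(rhs_)
        reactions.append(Reaction(i, r, p, f"k{i + 1}", _infer_kind(r, p)))
        values.append(val)
    net = ReactionNetwork(species, reactions)
    params = ParameterSet(np.array(values), {sid: v for sid, v in species_rows if v > 0})
    return net, params


@pytest.fixture
def linear_chain():
    """A -> B -> M -> 0 linear chain with zero-order supply of A."""
    return make_network(
        [("A", 1.0), ("B", 0.0), ("M", 0.0)],
        [("", "A", 2e-4), ("A", "B", 1e-3), ("B", "M", 1e-3), ("M", "", 5e-4),
         ("A", "", 5e-4)],
    )


def random_network(rng, n_species=10, n_reactions=14):
    """Random mass-action network for property tests (arity <= 3)."""
    ids = [f"S{i}" for i in range(n_species)]
    species_rows = [(s, float(rng.uniform(0.1, 2.0))) for s in ids]
    rows = []
    for _ in range(n_reactions):
        nr = int(rng.integers(0, 4))
        npd = int(rng.integers(1, 3)) if nr else 1
        lhs = " + ".join(rng.choice(ids, size=nr, replace=True)) if nr else ""
        rhs_ = " + ".join(rng.choice(ids, size=npd, replace=True))
        rows.append((lhs, rhs_, float(rng.uniform(1e-4, 1e-2))))
    return make_network(species_rows, rows)
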