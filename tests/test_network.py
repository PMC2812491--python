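"""Network parsing, stoichiometry and analytic derivative matrices."""

import numpy as np
import pytest
import sympy

from kinens.network import (
    NetworkParseError,
    ParameterSet,
    conserved_moieties,
    jacobian,
    load_network,
    load_parameters,
    massaction_rates,
    parameter_jacobian,
    rhs,
    write_network,
    write_parameters,
)

from conftest import make_network, random_network


def write(tmp_path, text):
    p = tmp_path / "net.txt"
    p.write_text(text)
    return p


class TestParser:
    def test_minimal_association(self, tmp_path):
        net, params = load_network(write(tmp_path, """
[SPECIES]
A | cytosol | 1.0 | 0
B | cytosol | 2.0 | 0
C | cytosol | 0 | 0
[REACTIONS]
1 | A + B | -> | C | k1=0.5
"""))
        assert net.n_species == 3 and net.n_reactions == 1
        assert list(net.stoich[:, 0]) == [-1, -1, 1]
        assert params.rate_constants[0] == 0.5

    def test_reversible_sugar_expands_to_two_irreversible(self, tmp_path):
        net, _ = load_network(write(tmp_path, """
[SPECIES]
A | cytosol | 1 | 0
B | cytosol | 1 | 0
C | cytosol | 0 | 0
[REACTIONS]
1 | A + B | <-> | C | kf, kr
"""))
        assert net.n_reactions == 2
        assert list(net.stoich[:, 0]) == [-1, -1, 1]
        assert list(net.stoich[:, 1]) == [1, 1, -1]
        assert net.parameter_names == ["kf", "kr"]

    def test_undeclared_species_is_an_error(self, tmp_path):
        with pytest.raises(NetworkParseError, match="undeclared species"):
            load_network(write(tmp_path, """
[SPECIES]
A | cytosol | 1 | 0
[REACTIONS]
1 | A | -> | D | k1
"""))

    def test_nonpositive_rate_value_is_an_error(self, tmp_path):
        with pytest.raises(NetworkParseError, match="non-positive"):
            load_network(write(tmp_path, """
[SPECIES]
A | cytosol | 1 | 0
[REACTIONS]
1 | A | -> |  | k1=0
"""))

    def test_coefficient_syntax_and_zero_order(self, tmp_path):
        net, _ = load_network(write(tmp_path, """
[SPECIES]
A | cytosol | 1 | 0
P | cytosol | 0 | 1
[REACTIONS]
1 | 2*A | -> | A | k1     # catalytic self-consumption, net -1
2 |  | -> | P | k2        # zero-order expression
"""))
        assert net.stoich[0, 0] == -1
        assert list(net.stoich[:, 1]) == [0, 1]
        assert net.reactions[1].kind == "zero-order"

    def test_roundtrip_through_flat_format(self, tmp_path, toy):
        path = tmp_path / "toy.txt"
        write_network(toy.network, path, params=toy.theta_star)
        net2, params2 = load_network(path)
        assert net2.species_ids == toy.network.species_ids
        assert net2.parameter_names == toy.network.parameter_names
        np.testing.assert_array_equal(net2.stoich, toy.network.stoich)
        np.testing.assert_allclose(
            params2.rate_constants, toy.theta_star.rate_constants, rtol=0)

    def test_parameter_file_roundtrip(self, tmp_path, toy):
        path = tmp_path / "params.txt"
        write_parameters(toy.theta_star, toy.network, path)
        p2 = load_parameters(path, toy.network)
        np.testing.assert_array_equal(p2.rate_constants, toy.theta_star.rate_constants)
        assert p2.nonzero_initial_conditions == toy.theta_star.nonzero_initial_conditions


class TestRates:
    def test_bimolecular_rate_value(self):
        net, params = make_network([("A", 3.0), ("B", 4.0), ("C", 0.0)],
                                   [("A + B", "C", 2.0)])
        r = massaction_rates(np.array([3.0, 4.0, 0.0]), params, net)
        assert r[0] == pytest.approx(24.0)

    def test_zero_concentration_reactant_gives_zero_rate(self):
        net, params = make_network([("A", 0.0), ("B", 4.0), ("C", 0.0)],
                                   [("A + B", "C", 2.0)])
        assert massaction_rates(np.array([0.0, 4.0, 0.0]), params, net)[0] == 0.0

    def test_negative_state_raises(self):
        net, params = make_network([("A", 1.0)], [("A", "", 1.0)])
        with pytest.raises(ValueError, match="negative"):
            massaction_rates(np.array([-0.5]), params, net)

    def test_rates_match_symbolic_oracle_on_random_network(self):
        rng = np.random.default_rng(3)
        net, params = random_network(rng)
        x = rng.uniform(0.0, 2.0, net.n_species)
        syms = sympy.symbols([f"x{i}" for i in range(net.n_species)])
        expected = []
        for q, rxn in enumerate(net.reactions):
            expr = sympy.Float(params.rate_constants[q])
            for sid, coef in rxn.reactants:
                expr *= syms[net.species_index[sid]] ** coef
            expected.append(float(expr.subs(dict(zip(syms, x)))))
        np.testing.assert_allclose(massaction_rates(x, params, net), expected, rtol=1e-12)

    def test_reversible_split_matches_net_reversible_flux_symbolically(self):
        # net flux of the two irreversible halves == kf*prod(react) - kr*prod(prod)
        rng = np.random.default_rng(11)
        for _ in range(5):
            na, nb = int(rng.integers(1, 3)), int(rng.integers(1, 3))
            ids = [f"S{i}" for i in range(na + nb)]
            lhs = " + ".join(ids[:na])
            rhs_side = " + ".join(ids[na:])
            kf, kr = rng.uniform(0.1, 2, 2)
            net, params = make_network(
                [(s, 1.0) for s in ids],
                [(lhs, rhs_side, kf), (rhs_side, lhs, kr)],
            )
            syms = sympy.symbols([f"y{i}" for i in range(len(ids))])
            r = [sympy.Float(params.rate_constants[q]) for q in range(2)]
            for q, rxn in enumerate(net.reactions):
                for sid, coef in rxn.reactants:
                    r[q] *= syms[net.species_index[sid]] ** coef
            # compare the net rate of change of the first species
            i0 = 0
            net_flux = net.stoich[i0, 0] * r[0] + net.stoich[i0, 1] * r[1]
            reversible = -(sympy.Float(kf) * sympy.prod(syms[:na])
                           - sympy.Float(kr) * sympy.prod(syms[na:]))
            assert sympy.simplify(net_flux - reversible) == 0

    def test_rhs_simple_decay(self):
        net, params = make_network([("A", 1.0), ("B", 0.0)], [("A", "B", 1.0)])
        np.testing.assert_allclose(rhs(np.array([1.0, 0.0]), params, net), [-1.0, 1.0])


class TestDerivativeMatrices:
    def test_linear_system_jacobian(self):
        net, params = make_network([("A", 1.0), ("B", 0.0)], [("A", "B", 0.7)])
        A = jacobian(np.array([1.0, 0.0]), params, net)
        np.testing.assert_allclose(A, [[-0.7, 0.0], [0.7, 0.0]])

    def test_bimolecular_jacobian_entries(self):
        net, params = make_network([("A", 3.0), ("B", 4.0), ("C", 0.0)],
                                   [("A + B", "C", 2.0)])
        A = jacobian(np.array([3.0, 4.0, 0.0]), params, net)
        # d(dA/dt)/dA = -k[B]; d(dA/dt)/dB = -k[A]
        assert A[0, 0] == pytest.approx(-8.0)
        assert A[0, 1] == pytest.approx(-6.0)
        assert A[2, 0] == pytest.approx(8.0)

    def test_parameter_jacobian_column(self):
        net, params = make_network([("A", 2.0), ("B", 0.0)], [("A", "B", 0.3)])
        B = parameter_jacobian(np.array([2.0, 0.0]), params, net)
        np.testing.assert_allclose(B[:, 0], [-2.0, 2.0])

    def test_zero_reactant_gives_zero_parameter_column(self):
        net, params = make_network([("A", 0.0), ("B", 0.0)], [("A", "B", 0.3)])
        B = parameter_jacobian(np.array([0.0, 0.0]), params, net)
        np.testing.assert_allclose(B[:, 0], 0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_analytic_matrices_match_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        net, params = random_network(rng)
        for _ in range(5):
            x = rng.uniform(0.05, 2.0, net.n_species)
            _assert_fd_match(net, params, x)


def _assert_fd_match(net, params, x, rtol=1e-5):
    f0 = rhs(x, params, net)
    A = jacobian(x, params, net)
    A_fd = np.empty_like(A)
    for m in range(net.n_species):
        h = 1e-6 * max(1.0, abs(x[m]))
        xp, xm = x.copy(), x.copy()
        xp[m] += h
        xm[m] -= h
        A_fd[:, m] = (rhs(xp, params, net) - rhs(xm, params, net)) / (2 * h)
    scale = np.maximum(np.abs(A_fd), 1e-8)
    assert np.max(np.abs(A - A_fd) / scale) < rtol

    B = parameter_jacobian(x, params, net)
    k = params.rate_constants
    B_fd = np.empty_like(B)
    for j in range(net.n_reactions):
        h = 1e-6 * max(1.0, k[j])
        kp, km = k.copy(), k.copy()
        kp[j] += h
        km[j] -= h
        B_fd[:, j] = (rhs(x, kp, net) - rhs(x, km, net)) / (2 * h)
    scale = np.maximum(np.abs(B_fd), 1e-8)
    assert np.max(np.abs(B - B_fd) / scale) < rtol


def test_conserved_moieties_left_null_space(toy):
    V = conserved_moieties(toy.network)
    assert V.shape[0] >= 10  # kinase pools, AR pool, eIF4E/4EBP, RIB, L, ...
    np.testing.assert_allclose(V @ toy.network.stoich, 0.0, atol=1e-10)


# -- property-based round trip ----------------------------------------------

from hypothesis import given, settings, strategies as st

_ids = st.lists(st.from_regex(r"[A-Za-z][A-Za-z0-9_]{0,6}", fullmatch=True),
                min_size=2, max_size=6, unique=True)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(ids=_ids, data=st.data())
def test_flat_format_roundtrip_random_networks(tmp_path_factory, ids, data):
    """write_network(load_network(...)) is the identity on random networks."""
    from kinens.network import ParameterSet, Reaction, ReactionNetwork, Species
    from kinens.network import _infer_kind

    rng_species = [Species(s, "cytosol", float(i)) for i, s in enumerate(ids)]
    n_rxn = data.draw(st.integers(1, 5))
    reactions, values = [], []
    for q in range(n_rxn):
        nr = data.draw(st.integers(0, 2))
        npd = data.draw(st.integers(1, 2))
        reactants = tuple(
            (data.draw(st.sampled_from(ids)), data.draw(st.integers(1, 3)))
            for _ in range(nr)
        )
        products = tuple(
            (data.draw(st.sampled_from(ids)), data.draw(st.integers(1, 3)))
            for _ in range(npd)
        )
        reactions.append(Reaction(q, reactants, products, f"k{q}",
                                  _infer_kind(reactants, products)))
        values.append(data.draw(st.floats(1e-6, 1e3, allow_nan=False)))
    net = ReactionNetwork(rng_species, reactions)
    params = ParameterSet(np.array(values))

    path = tmp_path_factory.mktemp("roundtrip") / "net.txt"
    write_network(net, path, params=params)
    net2, params2 = load_network(path)
    assert net2.species_ids == net.species_ids
    np.testing.assert_array_equal(net2.stoich, net.stoich)
    np.testing.assert_array_equal(params2.rate_constants, params.rate_constants)
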