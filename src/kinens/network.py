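"""Reaction-network data model and mass-action ODE right-hand side.

A network is a list of species and irreversible mass-action reactions.
Writing the system as ``dx/dt = S r(x; k)`` with stoichiometric matrix ``S``
and rate vector ``r_q = k_q * prod_j x_j**sigma_jq`` keeps the structure
regular enough that the right-hand side, the analytic state Jacobian
``A = d(dx/dt)/dx`` and the parameter-derivative matrix
``B = d(dx/dt)/dk`` can all be generated mechanically from the reaction
list.  Every rate depends linearly on exactly one rate constant, so
``B[:, q] = S[:, q] * r_q / k_q`` in closed form.

Concentrations are arbitrary units (A.U.); rate constants are per second
(zero-order A.U. s^-1, first-order s^-1, second-order A.U.^-1 s^-1).
Reversible reactions exist only as input-file sugar: the loader always
expands ``<->`` into two irreversible steps, and parameter vectors index
irreversible reactions only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

COMPARTMENTS = ("cytosol", "membrane", "extracellular")
REACTION_KINDS = ("association", "dissociation", "catalytic", "zero-order")


class NetworkParseError(ValueError):
    """Raised when a network flat file cannot be parsed or validated."""


@dataclass(frozen=True)
class Species:
    id: str
    compartment: str = "cytosol"
    initial_value: float = 0.0
    synthesized: bool = False

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r} for {self.id}")
        if self.initial_value < 0:
            raise ValueError(f"negative initial value for species {self.id}")


@dataclass(frozen=True)
class Reaction:
    """One irreversible mass-action step.

    ``reactants``/``products`` are tuples of ``(species_id, coefficient)``
    with positive integer coefficients; a zero-order reaction has an empty
    reactant tuple.  Catalytic steps list the enzyme on both sides (net 0
    in the stoichiometric matrix) rather than using a modifier field.
    """

    index: int
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_constant_id: str
    kind: str = "catalytic"

    def __post_init__(self):
        if self.kind not in REACTION_KINDS:
            raise ValueError(f"unknown reaction kind {self.kind!r}")
        for sid, coef in self.reactants + self.products:
            if int(coef) != coef or coef < 1:
                raise ValueError(
                    f"reaction {self.index}: coefficient for {sid} must be a positive integer"
                )


@dataclass
class ParameterSet:
    """Rate-constant vector plus the non-zero initial conditions.

    All entries are strictly positive; log-space Monte-Carlo proposals
    preserve positivity by construction.
    """

    rate_constants: np.ndarray
    nonzero_initial_conditions: dict[str, float] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self):
        self.rate_constants = np.asarray(self.rate_constants, dtype=float)
        if np.any(self.rate_constants <= 0) or not np.all(np.isfinite(self.rate_constants)):
            raise ValueError("rate constants must be strictly positive and finite")

    def copy(self, label: str | None = None) -> "ParameterSet":
        return ParameterSet(
            self.rate_constants.copy(),
            dict(self.nonzero_initial_conditions),
            self.label if label is None else label,
        )


class ReactionNetwork:
    """Ordered species + irreversible reactions + stoichiometric matrix.

    Species and reaction order follow the input file and are part of the
    reproducibility contract (matrix layouts, output columns).
    """

    def __init__(self, species: list[Species], reactions: list[Reaction]):
        ids = [s.id for s in species]
        if len(set(ids)) != len(ids):
            raise NetworkParseError("duplicate species id")
        self.species = list(species)
        self.reactions = list(reactions)
        self.species_index = {s.id: i for i, s in enumerate(self.species)}
        for rxn in self.reactions:
            for sid, _ in rxn.reactants + rxn.products:
                if sid not in self.species_index:
                    raise NetworkParseError(
                        f"reaction {rxn.index} references undeclared species {sid!r}"
                    )
        names = [r.rate_constant_id for r in self.reactions]
        if len(set(names)) != len(names):
            raise NetworkParseError("duplicate rate-constant id")
        self.parameter_names = names
        self.parameter_index = {n: j for j, n in enumerate(names)}
        self.stoich = build_stoichiometric_matrix(self)
        # per-reaction reactant slots (species index, exponent) for fast
        # evaluation; repeated reactant species are merged into one slot
        self._slots: list[list[tuple[int, int]]] = []
        for rxn in self.reactions:
            merged: dict[int, int] = {}
            for sid, coef in rxn.reactants:
                idx = self.species_index[sid]
                merged[idx] = merged.get(idx, 0) + coef
            self._slots.append(list(merged.items()))
        # padded slot arrays: unused slots point at a dummy species with exponent 0
        n_slots = max((len(s) for s in self._slots), default=1) or 1
        nr, ns = len(self.reactions), len(self.species)
        self._slot_idx = np.full((nr, n_slots), ns, dtype=np.intp)
        self._slot_exp = np.zeros((nr, n_slots), dtype=float)
        for q, slots in enumerate(self._slots):
            for s, (idx, e) in enumerate(slots):
                self._slot_idx[q, s] = idx
                self._slot_exp[q, s] = e
        # unused slots hit the dummy entry (value 1), and 1**0 == 1, so
        # explicit powers are only needed where the exponent exceeds 1
        self._pow_slots = np.nonzero(self._slot_exp > 1)
        self._pow_exp = self._slot_exp[self._pow_slots]
        self._xp_buf = np.ones(ns + 1)
        self._stoich_f = self.stoich.astype(float)

    # -- basic introspection -------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    n_parameters = n_reactions

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def initial_state(self, params: ParameterSet | None = None) -> np.ndarray:
        """Initial concentration vector; ParameterSet overrides win."""
        x0 = np.array([s.initial_value for s in self.species], dtype=float)
        if params is not None:
            for sid, value in params.nonzero_initial_conditions.items():
                x0[self.species_index[sid]] = value
        return x0


def build_stoichiometric_matrix(net: ReactionNetwork) -> np.ndarray:
    """Integer S with S[i, q] = net production of species i in reaction q."""
    S = np.zeros((len(net.species), len(net.reactions)), dtype=int)
    for q, rxn in enumerate(net.reactions):
        for sid, coef in rxn.reactants:
            S[net.species_index[sid], q] -= coef
        for sid, coef in rxn.products:
            S[net.species_index[sid], q] += coef
    return S


def _rate_vector(x: np.ndarray, k: np.ndarray, net: ReactionNetwork) -> np.ndarray:
    xp = net._xp_buf
    xp[:-1] = x
    P = xp[net._slot_idx]
    if net._pow_exp.size:
        P[net._pow_slots] **= net._pow_exp
    return k * np.multiply.reduce(P, axis=1)


def _rate_jacobian(x: np.ndarray, k: np.ndarray, net: ReactionNetwork) -> np.ndarray:
    """dr/dx (n_reactions x n_species) by the per-slot product rule."""
    xp = np.append(x, 1.0)  # fresh buffer: P below must not alias _xp_buf
    idx, e = net._slot_idx, net._slot_exp
    P = xp[idx] ** e  # per-slot factors
    n_slots = idx.shape[1]
    drdx = np.zeros((len(net.reactions), len(net.species) + 1))
    for s in range(n_slots):
        others = [o for o in range(n_slots) if o != s]
        prod_other = np.prod(P[:, others], axis=1) if others else np.ones(len(net.reactions))
        term = k * e[:, s] * xp[idx[:, s]] ** (e[:, s] - 1.0) * prod_other
        # slot species are unique within a reaction, so plain fancy
        # assignment cannot collide
        drdx[np.arange(len(net.reactions)), idx[:, s]] += term
    return drdx[:, :-1]


def _kvec(params) -> np.ndarray:
    return params.rate_constants if isinstance(params, ParameterSet) else np.asarray(params, float)


def massaction_rates(
    state: np.ndarray, params, net: ReactionNetwork, *, clip: bool = False
) -> np.ndarray:
    """Rate vector r_q = k_q * prod over reactants x_j**sigma_jq.

    Zero-order reactions return k_q.  States more negative than the
    integrator tolerance signal an upstream failure and raise; tiny
    negative round-off is clipped to zero.
    """
    x = np.asarray(state, dtype=float)
    if clip:
        x = np.maximum(x, 0.0)
    elif np.any(x < -1e-9):
        raise ValueError(f"negative concentration (min {x.min():.3g})")
    else:
        x = np.maximum(x, 0.0)
    return _rate_vector(x, _kvec(params), net)


def rhs(state, params, net: ReactionNetwork) -> np.ndarray:
    """dx/dt = S r(x)."""
    return net.stoich @ massaction_rates(state, params, net)


def jacobian(state, params, net: ReactionNetwork) -> np.ndarray:
    """Analytic A[i, m] = d(dx_i/dt)/dx_m; mass-action terms are polynomial."""
    x = np.maximum(np.asarray(state, dtype=float), 0.0)
    return net._stoich_f @ _rate_jacobian(x, _kvec(params), net)


def parameter_jacobian(state, params, net: ReactionNetwork) -> np.ndarray:
    """Analytic B[i, j] = d(dx_i/dt)/dk_j = S[i, j] * r_j / k_j.

    Each rate depends on exactly one rate constant, linearly, so the
    closed form is exact for any state.
    """
    k = _kvec(params)
    if np.any(k == 0):
        raise ValueError("zero rate constant violates positivity invariant")
    x = np.maximum(np.asarray(state, dtype=float), 0.0)
    monomials = _rate_vector(x, np.ones_like(k), net)  # r_j / k_j
    return net.stoich * monomials[np.newaxis, :]


def conserved_moieties(net: ReactionNetwork, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis (rows) of the left null space of S.

    Each row v satisfies v @ dx/dt = 0 for every rate vector, so v @ x is a
    conserved total along any trajectory (e.g. free + complexed receptor).
    """
    ns = null_space(net.stoich.T.astype(float), rcond=tol)
    return ns.T


# ---------------------------------------------------------------------------
# flat-file format
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(?:(\d+)\s*\*\s*)?([A-Za-z_]\w*)$")


def _parse_side(text: str, index: int) -> tuple[tuple[str, int], ...]:
    text = text.strip()
    if not text:
        return ()
    terms = []
    for part in text.split("+"):
        m = _TERM_RE.match(part.strip())
        if not m:
            raise NetworkParseError(f"reaction {index}: cannot parse term {part.strip()!r}")
        coef = int(m.group(1)) if m.group(1) else 1
        terms.append((m.group(2), coef))
    return tuple(terms)


def _infer_kind(reactants, products) -> str:
    if not reactants:
        return "zero-order"
    r_ids = {s for s, _ in reactants}
    p_ids = {s for s, _ in products}
    if r_ids & p_ids:
        return "catalytic"
    if len(r_ids) >= 2 and len(p_ids) == 1:
        return "association"
    if len(r_ids) == 1 and len(p_ids) >= 2:
        return "dissociation"
    return "catalytic"


def load_network(path) -> tuple[ReactionNetwork, ParameterSet | None]:
    """Parse the network flat format.

    Sections ``[SPECIES]`` (``id | compartment | initial_value | synthesized``)
    and ``[REACTIONS]`` (``id | reactants | -> or <-> | products | rate ids``),
    pipe- or tab-delimited, ``#`` comments, ``2*A`` coefficient syntax.
    A ``<->`` line expands to two irreversible reactions and must carry two
    rate-constant ids (``kf, kr``).  Rate ids may embed values (``k1=0.5``);
    when every reaction carries a value a ParameterSet is returned alongside
    the network, otherwise None.
    """
    species: list[Species] = []
    reactions: list[Reaction] = []
    values: dict[str, float] = {}
    section = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.upper() in ("[SPECIES]", "[REACTIONS]"):
                section = line.upper()
                continue
            fields = [f.strip() for f in re.split(r"\||\t", line)]
            try:
                if section == "[SPECIES]":
                    sid, compartment, init, synth = (fields + ["cytosol", "0", "0"])[:4]
                    species.append(
                        Species(sid, compartment, float(init), synth.lower() in ("1", "true", "yes"))
                    )
                elif section == "[REACTIONS]":
                    _parse_reaction_line(fields, lineno, reactions, values)
                else:
                    raise NetworkParseError("content before a section header")
            except (ValueError, IndexError) as exc:
                raise NetworkParseError(f"{path}:{lineno}: {exc}") from exc
    net = ReactionNetwork(species, reactions)
    params = None
    if values and len(values) == net.n_reactions:
        k = np.array([values[n] for n in net.parameter_names])
        if np.any(k <= 0):
            raise NetworkParseError(f"{path}: non-positive rate constant value")
        params = ParameterSet(k)
    return net, params


def _parse_reaction_line(fields, lineno, reactions, values):
    if len(fields) == 1:
        # compact syntax: "A+B->C | k1" split only on |
        raise NetworkParseError("reaction line needs id|reactants|arrow|products|rates")
    if len(fields) == 2:  # "A+B->C" , "k1"  (compact)
        lhs, rates = fields
        m = re.match(r"^(.*?)(<->|->)(.*)$", lhs)
        if not m:
            raise NetworkParseError("no reaction arrow found")
        rid = str(len(reactions) + 1)
        react_s, arrow, prod_s = m.group(1), m.group(2), m.group(3)
    else:
        rid, react_s, arrow, prod_s, rates = (fields + [""])[:5]
        if arrow not in ("->", "<->"):
            raise NetworkParseError(f"bad arrow {arrow!r}")
    reactants = _parse_side(react_s, lineno)
    products = _parse_side(prod_s, lineno)
    rate_ids = [t.strip() for t in rates.split(",") if t.strip()]

    def one(name, rts, pds):
        kname = name
        if "=" in name:
            kname, val = name.split("=", 1)
            kname = kname.strip()
            values[kname] = float(val)
        reactions.append(
            Reaction(len(reactions), rts, pds, kname, _infer_kind(rts, pds))
        )

    if arrow == "->":
        if len(rate_ids) != 1:
            raise NetworkParseError("irreversible reaction takes exactly one rate id")
        one(rate_ids[0], reactants, products)
    else:  # reversible sugar: always expand to two irreversible steps
        if len(rate_ids) != 2:
            raise NetworkParseError("reversible reaction takes two rate ids (kf, kr)")
        one(rate_ids[0], reactants, products)
        one(rate_ids[1], products, reactants)


def write_network(net: ReactionNetwork, path, params: ParameterSet | None = None) -> None:
    """Write the expanded irreversible network in the flat format."""
    with open(path, "w") as fh:
        fh.write("[SPECIES]\n")
        for s in net.species:
            fh.write(f"{s.id} | {s.compartment} | {s.initial_value:.17g} | {int(s.synthesized)}\n")
        fh.write("[REACTIONS]\n")
        for q, rxn in enumerate(net.reactions):
            side = lambda terms: " + ".join(
                (f"{c}*{sid}" if c > 1 else sid) for sid, c in terms
            )
            kid = rxn.rate_constant_id
            if params is not None:
                kid = f"{kid}={params.rate_constants[q]:.17g}"
            fh.write(f"{q + 1} | {side(rxn.reactants)} | -> | {side(rxn.products)} | {kid}\n")


def load_parameters(path, net: ReactionNetwork, label: str = "") -> ParameterSet:
    """Read the two-column ``parameter_id  value`` text format.

    Lines whose id starts with ``x0:`` set a non-zero initial condition.
    """
    k = np.full(net.n_reactions, np.nan)
    x0: dict[str, float] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            name, value = line.split()
            if name.startswith("x0:"):
                x0[name[3:]] = float(value)
            else:
                k[net.parameter_index[name]] = float(value)
    if np.any(np.isnan(k)):
        missing = [n for n, v in zip(net.parameter_names, k) if np.isnan(v)]
        raise NetworkParseError(f"missing parameter values: {missing[:5]}...")
    return ParameterSet(k, x0, label)


def write_parameters(params: ParameterSet, net: ReactionNetwork, path) -> None:
    with open(path, "w") as fh:
        for name, value in zip(net.parameter_names, params.rate_constants):
            fh.write(f"{name} {value:.17g}\n")
        for sid, value in params.nonzero_initial_conditions.items():
            fh.write(f"x0:{sid} {value:.17g}\n")
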