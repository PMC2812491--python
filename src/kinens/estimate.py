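"""Ensemble parameter estimation against arbitrary-unit training data.

Immunoblot-style observations are accurate only to a multiplicative
constant, so each (dataset, species) series gets its own scale factor
beta chosen to minimize the normalized squared error; the simulation
error is the normalized mean squared error over all observations,

    E = (1/N_obs) * sum_ij ((M_ij - beta_j * xhat_ij) / sigma_ij)**2 .

The ensemble is generated by a maximum-likelihood random walk: additive
Gaussian proposals in log parameter space (preserving positivity),
Boltzmann acceptance with temperature E0 (probability 1 for improvements,
exp(-dE/E0) otherwise), and autocorrelation-based thinning — the spacing
between retained sets is the lag at which an exponential fit to the
chain's error autocorrelation drops to 5% of its initial value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from statsmodels.tsa.stattools import acf

from .network import ParameterSet, ReactionNetwork
from .simulate import SimulationProtocol, apply_clone, find_steady_state, integrate


@dataclass(frozen=True)
class Observation:
    dataset_id: str
    species_id: str
    condition: float | str  # time in hours, or labeled perturbation condition
    value: float
    std: float

    def __post_init__(self):
        if self.std <= 0:
            raise ValueError("observation std must be > 0")


@dataclass
class DatasetProtocol:
    """How to simulate one training dataset.

    ``mode='timecourse'``: run ``protocol`` from the approximate steady
    state and read species at observation times.  ``mode='steady'``: for
    each labeled condition, apply its perturbation events (initial-
    condition/parameter scalings), re-equilibrate, and read the steady
    state.  ``score='scale'`` fits beta per (dataset, species);
    ``score='fold'`` divides both observed and simulated series by the
    control condition instead.
    """

    clone: str = "AD"
    mode: str = "timecourse"
    protocol: SimulationProtocol | None = None
    conditions: dict[str, list] = field(default_factory=dict)  # label -> [Event,...]
    score: str = "scale"
    control: str | None = None  # control condition label for score='fold'


@dataclass
class TrainingSet:
    observations: list[Observation]
    protocols: dict[str, DatasetProtocol]
    clones: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        ids = {o.dataset_id for o in self.observations}
        missing = ids - set(self.protocols)
        if missing:
            raise ValueError(f"datasets without protocol: {sorted(missing)}")
        for did in self.protocols:
            if did not in ids:
                raise ValueError(f"protocol {did!r} has no observations")


@dataclass
class ChainConfig:
    sigma: float = 0.05  # proposal std in log space
    E0: float = 1.0  # acceptance temperature
    n_steps: int = 1000
    seed: int = 0
    block_size: int | None = None  # parameters perturbed per step; None = all

    def __post_init__(self):
        if self.sigma <= 0 or self.E0 <= 0:
            raise ValueError("sigma and E0 must be > 0")


@dataclass
class ChainRecord:
    params: np.ndarray  # (n_steps+1, n_params) chain states (with repeats)
    errors: np.ndarray  # E at each chain state
    accepted: np.ndarray  # bool per proposal
    seed: int = 0

    @property
    def acceptance_rate(self) -> float:
        return float(np.mean(self.accepted))


@dataclass
class Ensemble:
    members: list[ParameterSet]
    errors: np.ndarray
    provenance: list[int] = field(default_factory=list)  # chain step indices
    thinning_interval: int = 1
    seed: int = 0

    def matrix(self) -> np.ndarray:
        return np.array([m.rate_constants for m in self.members])


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def scale_factor(observed, simulated, stds) -> float | None:
    """Closed-form beta minimizing sum ((M - beta*xhat)/sigma)**2.

    beta = sum(M xhat / sigma^2) / sum(xhat^2 / sigma^2), clamped to >= 0.
    Returns None when the simulated series is identically zero (beta is
    then undefined and the dataset is scored unscaled).
    """
    M = np.asarray(observed, float)
    x = np.asarray(simulated, float)
    s2 = np.asarray(stds, float) ** 2
    denom = np.sum(x * x / s2)
    if denom == 0.0:
        return None
    return max(float(np.sum(M * x / s2) / denom), 0.0)


def default_stds(values, flagged=None, fraction=0.10, augment=0.5, floor=1e-6):
    """Assumed measurement errors when none were reported.

    sigma = 10% of |M| by default, with a strictly positive floor; flagged
    observations (unclear quantification) get an augmented fraction in
    [0.20, 1.00] instead.
    """
    if not 0.20 <= augment <= 1.00:
        raise ValueError("augmented error fraction must lie in [0.20, 1.00]")
    values = np.asarray(values, float)
    frac = np.full(values.shape, fraction)
    if flagged is not None:
        frac = np.where(np.asarray(flagged, bool), augment, frac)
    return np.maximum(frac * np.abs(values), floor)


def _simulate_dataset(net, params, dsp: DatasetProtocol, obs: list[Observation], clones,
                      ss_cache: dict | None = None):
    """Simulated value for each observation of one dataset.

    ``ss_cache`` (valid for one parameter set only) lets datasets sharing
    a clone and perturbation reuse the steady-state search.
    """
    if ss_cache is None:
        ss_cache = {}

    def cached_ss(key, p, x):
        if key not in ss_cache:
            ss_cache[key] = find_steady_state(net, p, x)[0]
        return ss_cache[key]

    p = apply_clone(params, dsp.clone, clones, net) if clones else params
    x0 = net.initial_state(p)
    if dsp.mode == "timecourse":
        xss = cached_ss((dsp.clone, ()), p, x0)
        times = sorted({float(o.condition) for o in obs})
        proto = SimulationProtocol(
            events=list(dsp.protocol.events) if dsp.protocol else [],
            t_end=max(dsp.protocol.t_end if dsp.protocol else 0.0, max(times)),
            output_grid=np.array(times),
        )
        traj = integrate(net, p, xss, proto)
        tindex = {t: i for i, t in enumerate(times)}
        return np.array(
            [traj.states[tindex[float(o.condition)], net.species_index[o.species_id]] for o in obs]
        )
    elif dsp.mode == "steady":
        cache: dict[str, np.ndarray] = {}
        for label in {o.condition for o in obs} | ({dsp.control} - {None}):
            if label not in dsp.conditions:
                raise ValueError(f"dataset condition {label!r} not defined in protocol")
            pc = p.copy()
            xc = x0.copy()
            for ev in dsp.conditions.get(label, []):
                if ev.kind == "scale_initial_condition":
                    xc[net.species_index[ev.target]] *= ev.value
                elif ev.kind == "scale_parameter":
                    pc.rate_constants[net.parameter_index[ev.target]] *= ev.value
                else:
                    raise ValueError(f"steady-mode condition cannot use event kind {ev.kind!r}")
            key = (dsp.clone, tuple((ev.kind, ev.target, ev.value) for ev in dsp.conditions.get(label, [])))
            cache[label] = cached_ss(key, pc, xc)
        out = np.array([cache[o.condition][net.species_index[o.species_id]] for o in obs])
        if dsp.score == "fold":
            ctrl = cache[dsp.control]
            out = np.array(
                [
                    v / max(ctrl[net.species_index[o.species_id]], 1e-300)
                    for v, o in zip(out, obs)
                ]
            )
        return out
    raise ValueError(f"unknown dataset mode {dsp.mode!r}")


def simulation_error(params: ParameterSet, training: TrainingSet, net: ReactionNetwork) -> float:
    """Normalized mean squared error E over all observations.

    Each dataset is simulated from its own approximate steady state; beta
    is fitted per (dataset, species) unless the dataset is scored in fold
    mode.  Any simulation failure yields E = +inf so the proposal is
    auto-rejected.
    """
    by_dataset: dict[str, list[Observation]] = {}
    for o in training.observations:
        by_dataset.setdefault(o.dataset_id, []).append(o)
    total, n_obs = 0.0, 0
    ss_cache: dict = {}
    for did, obs in by_dataset.items():
        dsp = training.protocols[did]
        try:
            sim = _simulate_dataset(net, params, dsp, obs, training.clones, ss_cache)
        except (RuntimeError, ValueError):
            return np.inf
        M = np.array([o.value for o in obs])
        std = np.array([o.std for o in obs])
        # beta per (dataset, species) pair
        resid = np.empty(len(obs))
        species = np.array([o.species_id for o in obs])
        for sp in np.unique(species):
            m = species == sp
            if dsp.score == "fold":
                beta = 1.0
            else:
                beta = scale_factor(M[m], sim[m], std[m])
                if beta is None:
                    beta = 1.0  # undefined beta: dataset scored unscaled
            resid[m] = (M[m] - beta * sim[m]) / std[m]
        total += float(np.sum(resid**2))
        n_obs += len(obs)
    return total / n_obs


# ---------------------------------------------------------------------------
# Metropolis random walk in log space
# ---------------------------------------------------------------------------

def propose(current: ParameterSet, config: ChainConfig, rng: np.random.Generator) -> ParameterSet:
    """log k_new = log k + N(0, sigma^2), elementwise or on a random block."""
    logk = np.log(current.rate_constants)
    n = logk.size
    if config.block_size is None or config.block_size >= n:
        logk = logk + rng.normal(0.0, config.sigma, size=n)
    else:
        idx = rng.choice(n, size=config.block_size, replace=False)
        logk = logk.copy()
        logk[idx] += rng.normal(0.0, config.sigma, size=config.block_size)
    return ParameterSet(np.exp(logk), dict(current.nonzero_initial_conditions), current.label)


def accept(E_current: float, E_proposed: float, config: ChainConfig, rng) -> bool:
    """Boltzmann acceptance: 1 for improvements, exp(-dE/E0) otherwise."""
    if not np.isfinite(E_proposed):
        return False
    if E_proposed <= E_current:
        return True
    return bool(rng.random() < np.exp(-(E_proposed - E_current) / config.E0))


def run_chain(
    start: ParameterSet,
    training_or_errorfn,
    config: ChainConfig,
    net: ReactionNetwork | None = None,
) -> ChainRecord:
    """Metropolis random walk; deterministic under a fixed seed.

    ``training_or_errorfn`` is either a TrainingSet (scored with
    :func:`simulation_error`, requires ``net``) or any callable
    ``E(ParameterSet) -> float``.
    """
    if callable(training_or_errorfn):
        errorfn = training_or_errorfn
    else:
        errorfn = lambda p: simulation_error(p, training_or_errorfn, net)
    rng = np.random.default_rng(config.seed)
    current = start.copy()
    E_cur = float(errorfn(current))
    states = np.empty((config.n_steps + 1, current.rate_constants.size))
    errors = np.empty(config.n_steps + 1)
    accepted = np.zeros(config.n_steps, dtype=bool)
    states[0], errors[0] = current.rate_constants, E_cur
    for step in range(config.n_steps):
        cand = propose(current, config, rng)
        E_new = float(errorfn(cand))
        if accept(E_cur, E_new, config, rng):
            current, E_cur = cand, E_new
            accepted[step] = True
        states[step + 1], errors[step + 1] = current.rate_constants, E_cur
    return ChainRecord(states, errors, accepted, seed=config.seed)


def run_chains(
    start: ParameterSet,
    training_or_errorfn,
    config: ChainConfig,
    n_chains: int = 4,
    net: ReactionNetwork | None = None,
) -> list[ChainRecord]:
    """Multiple independent Metropolis trajectories from one start.

    Chain i is seeded with ``config.seed + i``; the pooled, individually
    thinned chains form the ensemble (see :func:`pool_ensembles`).
    """
    from dataclasses import replace

    return [
        run_chain(start, training_or_errorfn, replace(config, seed=config.seed + i), net=net)
        for i in range(n_chains)
    ]


def pool_ensembles(ensembles: list["Ensemble"]) -> "Ensemble":
    """Concatenate independently thinned chains into one ensemble."""
    members = [m for e in ensembles for m in e.members]
    errors = np.concatenate([e.errors for e in ensembles])
    prov = [i for e in ensembles for i in e.provenance]
    interval = max(e.thinning_interval for e in ensembles)
    return Ensemble(members, errors, prov, interval, seed=ensembles[0].seed)


def autocorrelation_interval(series: np.ndarray, cutoff: float = 0.05) -> int:
    """Thinning interval from an exponential fit to the autocorrelation.

    Fits C(tau) = exp(-tau/tau_c) to the empirical autocorrelation of the
    series (the fit smooths noise in the raw autocorrelation) and returns
    ceil of the lag at which the fit reaches ``cutoff``:
    tau = tau_c * ln(1/cutoff).
    """
    series = np.asarray(series, float)
    if series.size < 10 or np.ptp(series) == 0:
        return 1
    nlags = min(series.size // 4, 500)
    C = acf(series, nlags=nlags, fft=True)
    lags = np.arange(nlags + 1)
    # fit only the informative head: down to where C first drops below ~cutoff/2
    below = np.where(C < cutoff / 2)[0]
    stop = int(below[0]) + 1 if below.size else nlags + 1
    stop = max(stop, 3)
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # flat autocorrelation: covariance undefined
            (tau_c,), _ = curve_fit(
                lambda t, tau: np.exp(-t / tau), lags[:stop], C[:stop], p0=[max(stop / 3, 1.0)]
            )
    except RuntimeError:
        tau_c = 1.0
    if not np.isfinite(tau_c) or tau_c <= 0:
        return 1
    return max(int(np.ceil(tau_c * np.log(1.0 / cutoff))), 1)


def thin_by_autocorrelation(
    chain: ChainRecord, burn_in: float = 0.1, cutoff: float = 0.05
) -> Ensemble:
    """Decorrelate a chain by keeping every interval-th state.

    The interval is the lag at which the exponential fit to the error
    autocorrelation drops to ``cutoff`` (5%) of its initial value.
    """
    n = chain.errors.size
    start = int(np.floor(burn_in * n))
    interval = autocorrelation_interval(chain.errors[start:], cutoff=cutoff)
    idx = np.arange(start, n, interval)
    members = [ParameterSet(chain.params[i].copy(), label=f"step{i}") for i in idx]
    return Ensemble(
        members, chain.errors[idx].copy(), provenance=list(idx),
        thinning_interval=interval, seed=chain.seed,
    )


def ensemble_stats(ensemble: Ensemble) -> dict:
    """Per-parameter mean, std, CV and the fraction of parameters with CV > 100%."""
    K = ensemble.matrix()
    mean = K.mean(axis=0)
    std = K.std(axis=0, ddof=1) if K.shape[0] > 1 else np.zeros(K.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, std / mean, 0.0)
    return {
        "mean": mean,
        "std": std,
        "cv": cv,
        "frac_cv_gt_1": float(np.mean(cv > 1.0)),
    }
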