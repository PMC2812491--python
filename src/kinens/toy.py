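"""Bundled toy signaling network, ground truth and pseudo-immunoblot data.

The toy is a structural surrogate for a hormone/growth-factor signaling
network: small enough to simulate in milliseconds, but exercising every
feature class the analysis pipeline must handle — conserved moieties,
zero-order expression, a three-tier kinase cascade, a translation branch,
bimolecular coupling between two signaling axes (so synergy is non-zero),
and a single clone-differentiating expression parameter.

Wiring (all mass-action, reversible steps pre-expanded):

* growth factor L activates receptor R -> Ra; Ra auto-activates R and
  recruits adaptor AD into the signaling complex cRAD;
* a phosphatase PHOS deactivates Ra; PHOS expression is constitutive
  (zero-order transcription of mPHOS) and repressed by active hormone
  receptor — this is the clone-differentiating negative feedback;
* cRAD drives a MAPK-like cascade K3 -> K2a -> K1a and a parallel
  PI3K/Akt/TOR-like branch P3K -> AKTa -> TORa; TORa liberates the
  translation factor E4F from its sequestering complex cE4 (E4F.E4BP);
* hormone H activates the nuclear receptor AR (sequestered by HSP as
  cHA); K1a provides hormone-independent ("outlaw") AR activation;
* active AR drives transcription of the marker gene PSAlike (mPSA) and
  represses mPHOS; the K1a-activated transcription factor TFa drives the
  proliferation gene CYCDlike (mCYCD);
* translation of every mRNA requires free E4F and ribosome RIB, so
  protein output couples the MAPK axis (mRNA supply) and the Akt axis
  (E4F supply) multiplicatively.

Clone variants scale only the PHOS transcription rate: AD 1.0 (hormone-
dependent baseline), MID 0.5, AI 0.01 (hormone-independent).  With PHOS
expression nearly off, basal receptor activity and outlaw AR activation
rise, so the AI clone shows high hormone-free marker expression while
the AD clone shows the larger relative response to hormone addition.

Concentrations are arbitrary units; rate constants are per second.  The
bundle is fully deterministic; only training-data generation consumes a
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimate import (
    ChainConfig,
    DatasetProtocol,
    Observation,
    TrainingSet,
    default_stds,
    ensemble_stats,
    simulation_error,
    thin_by_autocorrelation,
)
from .network import ParameterSet, Reaction, ReactionNetwork, Species
from .simulate import Event, SimulationProtocol, apply_clone, find_steady_state, integrate

CLONES: dict[str, dict[str, float]] = {
    "AD": {},
    "MID": {"k_tx_PHOS": 0.5},
    "AI": {"k_tx_PHOS": 0.01},
}

#: parameters directly constrained by the observed species (PSA, CYCD,
#: ARa, K1a, AKTa) through the shape of their responses; used to judge
#: parameter recovery.  Absolute production rates are absorbed by the
#: per-blot scale factors and are not in this set.
IDENTIFIABLE_PARAMS = [
    "k_act_AR_H",
    "k_act_AR_K1",
    "k_deact_AR",
    "k_act_K1",
    "k_deact_K1",
    "k_act_AKT",
    "k_deact_AKT",
    "k_deg_PSA",
    "k_deg_CYCD",
]


@dataclass
class ToyModelBundle:
    network: ReactionNetwork
    theta_star: ParameterSet
    clones: dict[str, dict[str, float]] = field(default_factory=lambda: dict(CLONES))
    stimulus_species: str = "H"
    stimulus_amount: float = 10.0
    stimulus_hour: float = 1.0


_SPECIES = [
    # id, compartment, initial value (A.U.), synthesized
    ("L", "extracellular", 0.5, False),
    ("H", "extracellular", 0.0, False),
    ("R", "membrane", 1.0, False),
    ("Ra", "membrane", 0.0, False),
    ("AD", "cytosol", 1.0, False),
    ("cRAD", "membrane", 0.0, False),
    ("PHOS", "cytosol", 0.0, True),
    ("mPHOS", "cytosol", 0.0, True),
    ("K3", "cytosol", 1.0, False),
    ("K3a", "cytosol", 0.0, False),
    ("K2", "cytosol", 1.0, False),
    ("K2a", "cytosol", 0.0, False),
    ("K1", "cytosol", 1.0, False),
    ("K1a", "cytosol", 0.0, False),
    ("P3K", "cytosol", 1.0, False),
    ("P3Ka", "cytosol", 0.0, False),
    ("AKT", "cytosol", 1.0, False),
    ("AKTa", "cytosol", 0.0, False),
    ("TOR", "cytosol", 1.0, False),
    ("TORa", "cytosol", 0.0, False),
    ("E4F", "cytosol", 0.2, False),
    ("E4BP", "cytosol", 0.3, False),
    ("cE4", "cytosol", 0.8, False),
    ("AR", "cytosol", 1.0, False),
    ("ARa", "cytosol", 0.0, False),
    ("HSP", "cytosol", 2.0, False),
    ("cHA", "cytosol", 0.0, False),
    ("TF", "cytosol", 1.0, False),
    ("TFa", "cytosol", 0.0, False),
    ("mPSA", "cytosol", 0.0, True),
    ("PSA", "cytosol", 0.0, True),
    ("mCYCD", "cytosol", 0.0, True),
    ("CYCD", "cytosol", 0.0, True),
    ("RIB", "cytosol", 1.0, False),
]

# (reactants, products, rate id, value at theta*) -- kinds are inferred
_REACTIONS = [
    # receptor module
    ("L + R", "L + Ra", "k_act_R_L", 2e-3),
    ("Ra + R", "2*Ra", "k_act_R_auto", 1e-3),
    ("R", "Ra", "k_act_R_basal", 2e-5),
    ("Ra", "R", "k_deact_R", 1e-3),
    ("Ra + PHOS", "R + PHOS", "k_deph_R", 2e-2),
    # adaptor complex
    ("Ra + AD", "cRAD", "kon_RAD", 1e-2),
    ("cRAD", "Ra + AD", "koff_RAD", 2e-3),
    # MAPK-like cascade
    ("K3 + cRAD", "K3a + cRAD", "k_act_K3", 1e-2),
    ("K3a", "K3", "k_deact_K3", 2e-2),
    ("K2 + K3a", "K2a + K3a", "k_act_K2", 1e-2),
    ("K2a", "K2", "k_deact_K2", 2e-2),
    ("K1 + K2a", "K1a + K2a", "k_act_K1", 1e-2),
    ("K1a", "K1", "k_deact_K1", 2e-2),
    # PI3K/Akt/TOR-like branch and translation-factor release
    ("P3K + cRAD", "P3Ka + cRAD", "k_act_P3K", 1e-2),
    ("P3Ka", "P3K", "k_deact_P3K", 2e-2),
    ("AKT + P3Ka", "AKTa + P3Ka", "k_act_AKT", 1e-2),
    ("AKTa", "AKT", "k_deact_AKT", 2e-2),
    ("TOR + AKTa", "TORa + AKTa", "k_act_TOR", 1e-2),
    ("TORa", "TOR", "k_deact_TOR", 2e-2),
    ("cE4 + TORa", "E4F + E4BP + TORa", "k_rel_E4F", 5e-3),
    ("E4F + E4BP", "cE4", "kon_E4", 1e-2),
    # hormone receptor with HSP sequestration and outlaw activation
    ("AR + H", "ARa + H", "k_act_AR_H", 1e-3),
    ("AR + K1a", "ARa + K1a", "k_act_AR_K1", 2e-3),
    ("ARa", "AR", "k_deact_AR", 5e-3),
    ("AR + HSP", "cHA", "kon_HSP", 5e-3),
    ("cHA", "AR + HSP", "koff_HSP", 1e-3),
    # MAPK-driven transcription factor
    ("TF + K1a", "TFa + K1a", "k_act_TF", 1e-2),
    ("TFa", "TF", "k_deact_TF", 2e-3),
    # gene expression: transcription
    ("ARa", "ARa + mPSA", "k_tx_PSA", 2e-4),
    ("TFa", "TFa + mCYCD", "k_tx_CYCD", 2e-4),
    ("", "mPHOS", "k_tx_PHOS", 2e-4),
    ("mPHOS + ARa", "ARa", "k_rep_PHOS", 5e-3),
    # translation requires free E4F and ribosome
    ("mPSA + E4F + RIB", "mPSA + E4F + RIB + PSA", "k_tl_PSA", 2e-3),
    ("mCYCD + E4F + RIB", "mCYCD + E4F + RIB + CYCD", "k_tl_CYCD", 2e-3),
    ("mPHOS + E4F + RIB", "mPHOS + E4F + RIB + PHOS", "k_tl_PHOS", 2e-3),
    # turnover of synthesized species
    ("mPSA", "", "k_deg_mPSA", 3e-4),
    ("mCYCD", "", "k_deg_mCYCD", 3e-4),
    ("mPHOS", "", "k_deg_mPHOS", 3e-4),
    ("PSA", "", "k_deg_PSA", 2e-4),
    ("CYCD", "", "k_deg_CYCD", 2e-4),
    ("PHOS", "", "k_deg_PHOS", 2e-4),
]


def _parse_terms(text):
    out = []
    for part in text.split("+"):
        part = part.strip()
        if not part:
            continue
        if "*" in part:
            c, sid = part.split("*")
            out.append((sid.strip(), int(c)))
        else:
            out.append((part, 1))
    return tuple(out)


def build_toy_network() -> ToyModelBundle:
    """Deterministic toy bundle: network, ground truth, clone table."""
    from .network import _infer_kind

    species = [Species(*row) for row in _SPECIES]
    reactions = []
    for i, (lhs, rhs_, kid, _val) in enumerate(_REACTIONS):
        reactants, products = _parse_terms(lhs), _parse_terms(rhs_)
        reactions.append(Reaction(i, reactants, products, kid, _infer_kind(reactants, products)))
    net = ReactionNetwork(species, reactions)
    k = np.array([val for *_ignored, val in _REACTIONS])
    x0_nonzero = {s.id: s.initial_value for s in species if s.initial_value > 0}
    theta = ParameterSet(k, x0_nonzero, label="theta_star")
    return ToyModelBundle(net, theta)


def hand_tuned_start(bundle: ToyModelBundle, spread: float = 0.15, seed: int = 8675309) -> ParameterSet:
    """A deterministic imperfect initial guess k0 (log-perturbed truth).

    Stands in for the hand-tuned starting point a modeler would supply:
    right order of magnitude everywhere, exact nowhere.
    """
    rng = np.random.default_rng(seed)
    logk = np.log(bundle.theta_star.rate_constants) + rng.normal(
        0.0, spread, bundle.network.n_reactions
    )
    return ParameterSet(
        np.exp(logk), dict(bundle.theta_star.nonzero_initial_conditions), label="k0"
    )


# ---------------------------------------------------------------------------
# pseudo-immunoblot training data
# ---------------------------------------------------------------------------

def _dht_protocol(bundle) -> SimulationProtocol:
    return SimulationProtocol(
        events=[Event(bundle.stimulus_hour, "add_species", bundle.stimulus_species,
                      bundle.stimulus_amount)],
        t_end=24.0,
    )


def training_protocols(bundle: ToyModelBundle) -> dict[str, DatasetProtocol]:
    """The seven bundled dataset designs (clone, stimulus, observables)."""
    half = lambda sid, f: [Event(0.0, "scale_initial_condition", sid, f)]
    pert_conditions = {
        "control": [],
        "R_up": half("R", 1.5),
        "R_dn": half("R", 0.5),
        "K1_up": half("K1", 1.5),
        "K1_dn": half("K1", 0.5),
    }
    gf = SimulationProtocol(events=[Event(1.0, "add_species", "L", 1.0)], t_end=8.0)
    return {
        "dht_AD": DatasetProtocol(clone="AD", protocol=_dht_protocol(bundle)),
        "dht_MID": DatasetProtocol(clone="MID", protocol=_dht_protocol(bundle)),
        "dht_AI": DatasetProtocol(clone="AI", protocol=_dht_protocol(bundle)),
        "gf_AD": DatasetProtocol(clone="AD", protocol=gf),
        "pert_AD": DatasetProtocol(clone="AD", mode="steady", conditions=pert_conditions),
        "pert_AI": DatasetProtocol(clone="AI", mode="steady", conditions=pert_conditions),
    }


_DATASET_DESIGN = {
    # dataset -> (species list, time points in hours or condition labels)
    "dht_AD": (["PSA", "ARa"], [0.5, 2.0, 4.0, 8.0, 16.0, 24.0]),
    "dht_MID": (["PSA"], [0.5, 2.0, 4.0, 8.0, 16.0, 24.0]),
    "dht_AI": (["PSA", "ARa"], [0.5, 2.0, 4.0, 8.0, 16.0, 24.0]),
    "gf_AD": (["K1a", "AKTa"], [0.5, 1.25, 1.5, 2.0, 3.0, 6.0]),
    "pert_AD": (["PSA", "CYCD"], ["control", "R_up", "R_dn", "K1_up", "K1_dn"]),
    "pert_AI": (["PSA", "CYCD"], ["control", "R_up", "R_dn", "K1_up", "K1_dn"]),
}


def generate_training_data(
    bundle: ToyModelBundle,
    seed: int,
    noise_fraction: float = 0.10,
    noiseless: bool = False,
    return_scales: bool = False,
):
    """Simulate the bundled datasets at theta* and blur them like blots.

    Each (dataset, species) series is multiplied by a hidden scale drawn
    log-uniformly in [0.1, 10] (the arbitrary-units convention the beta
    machinery must absorb) and perturbed by Gaussian noise with sigma
    equal to 10% of the value; the recorded std is the 10% rule applied
    to the noisy value.
    """
    from .estimate import _simulate_dataset

    rng = np.random.default_rng(seed)
    protocols = training_protocols(bundle)
    observations: list[Observation] = []
    hidden_scales: dict[tuple[str, str], float] = {}
    for did, (species_list, conds) in _DATASET_DESIGN.items():
        dsp = protocols[did]
        clean_obs = [
            Observation(did, sp, c, value=1.0, std=1.0) for sp in species_list for c in conds
        ]
        sim = _simulate_dataset(bundle.network, bundle.theta_star, dsp, clean_obs, bundle.clones)
        for sp in species_list:
            scale = 10.0 ** rng.uniform(-1.0, 1.0)  # hidden per-blot scale
            hidden_scales[(did, sp)] = scale
            idx = [i for i, o in enumerate(clean_obs) if o.species_id == sp]
            vals = sim[idx] * scale
            if not noiseless:
                vals = vals + rng.normal(0.0, noise_fraction * np.abs(vals))
            stds = default_stds(vals, fraction=noise_fraction)
            for j, i in enumerate(idx):
                observations.append(
                    Observation(did, sp, clean_obs[i].condition, float(vals[j]), float(stds[j]))
                )
    training = TrainingSet(observations, protocols, clones=dict(bundle.clones))
    if return_scales:
        return training, hidden_scales
    return training


# ---------------------------------------------------------------------------
# recovery experiment
# ---------------------------------------------------------------------------

def recovery_experiment(
    bundle: ToyModelBundle,
    config: ChainConfig,
    seed: int,
    training: TrainingSet | None = None,
    n_chains: int = 4,
    burn_in: float = 0.3,
) -> dict:
    """Fit the toy data and report how well the ensemble covers theta*.

    Runs ``n_chains`` independent Metropolis trajectories from the
    hand-tuned start, thins each by its error autocorrelation, and pools
    them into the ensemble.  Returns the ensemble plus per-parameter
    z-scores of theta* against the ensemble (z = (log k* - mean log k) /
    std log k, computed in log space where the walk lives), and the
    fraction of the designed-identifiable parameters with |z| <= 2.
    """
    from .estimate import pool_ensembles, run_chains

    net = bundle.network
    if training is None:
        training = generate_training_data(bundle, seed)
    start = hand_tuned_start(bundle)
    chains = run_chains(start, training, config, n_chains=n_chains, net=net)
    ensemble = pool_ensembles(
        [thin_by_autocorrelation(c, burn_in=burn_in) for c in chains]
    )
    stats = ensemble_stats(ensemble)
    logK = np.log(ensemble.matrix())
    mu, sd = logK.mean(axis=0), logK.std(axis=0, ddof=1)
    sd = np.maximum(sd, 1e-12)
    z = (np.log(bundle.theta_star.rate_constants) - mu) / sd
    ident_idx = [net.parameter_index[n] for n in IDENTIFIABLE_PARAMS]
    frac_ok = float(np.mean(np.abs(z[ident_idx]) <= 2.0))
    return {
        "chains": chains,
        "ensemble": ensemble,
        "stats": stats,
        "z_scores": z,
        "identifiable_params": list(IDENTIFIABLE_PARAMS),
        "frac_identifiable_within_2sd": frac_ok,
        "E_theta_star": simulation_error(bundle.theta_star, training, net),
    }


def basal_and_stimulated_marker(
    bundle: ToyModelBundle, params: ParameterSet, clone: str, marker: str = "PSA",
    response_hours: float = 24.0,
) -> tuple[float, float]:
    """(basal steady-state marker, marker at `response_hours` after stimulus)."""
    p = apply_clone(params, clone, bundle.clones, bundle.network)
    xss, _ = find_steady_state(bundle.network, p, bundle.network.initial_state(p))
    basal = float(xss[bundle.network.species_index[marker]])
    proto = SimulationProtocol(
        events=[Event(bundle.stimulus_hour, "add_species", bundle.stimulus_species,
                      bundle.stimulus_amount)],
        t_end=bundle.stimulus_hour + response_hours,
        output_grid=np.array([0.0, bundle.stimulus_hour + response_hours]),
    )
    traj = integrate(bundle.network, p, xss, proto)
    return basal, float(traj[marker][-1])
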