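"""End-to-end fixture workflow: generate, fit, analyze, report.

Each stage reads only files written by earlier stages (plus a seed), so
any artifact is reproducible from its manifest.  All randomness flows
from the stage seeds through ``numpy.random.default_rng``; re-running a
stage with the same inputs and seed is bit-identical.

Stage problem sizes default to a scaled-down study — a few hundred
Monte-Carlo steps and an ensemble of O(10) members — chosen so the whole
pipeline completes in minutes on one CPU while still exercising every
analysis; pass a larger ``n_steps``/member cap for production runs.
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as kio
from .estimate import ChainConfig, TrainingSet, thin_by_autocorrelation
from .network import load_network, load_parameters, write_network, write_parameters
from .robustness import robustness_panel
from .sensitivity import ossc_protocol, rank_shift_test
from .simulate import Event, SimulationProtocol, apply_clone, find_steady_state, integrate
from .synergy import synergy_screen
from .toy import build_toy_network, generate_training_data, hand_tuned_start

MARKERS = ["CYCD", "PSA", "K1a", "ARa"]
TARGETS = ["K3", "K2", "K1", "AKT", "TOR", "E4F", "E4BP"]
AXIS_MAPK = ["K1", "K1a"]
AXIS_AKT = ["AKT", "AKTa"]


def _select_members(ensemble, cap: int):
    """Deterministic evenly spaced member subset (analysis cost control)."""
    members = ensemble.members
    if cap is None or len(members) <= cap:
        return list(members)
    idx = np.linspace(0, len(members) - 1, cap).round().astype(int)
    return [members[i] for i in sorted(set(idx))]


def generate_fixtures(outdir, seed: int) -> dict:
    """Write the toy network, ground truth, start guess and observations."""
    t0 = time.time()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = build_toy_network()
    training = generate_training_data(bundle, seed)
    write_network(bundle.network, out / "network.txt")
    write_parameters(bundle.theta_star, bundle.network, out / "theta_star.txt")
    write_parameters(hand_tuned_start(bundle), bundle.network, out / "k0.txt")
    kio.write_observations_csv(training, out / "observations.csv")
    kio.write_protocols_yaml(training.protocols, bundle.clones, out / "protocols.yaml")
    kio.write_manifest(out / "manifest_generate.json", "generate", seed,
                       {"datasets": sorted(training.protocols)}, t0)
    return {"bundle": bundle, "training": training}


def _load_fixtures(outdir):
    out = Path(outdir)
    net, _ = load_network(out / "network.txt")
    protocols, clones = kio.read_protocols_yaml(out / "protocols.yaml")
    observations = kio.read_observations_csv(out / "observations.csv")
    training = TrainingSet(observations, protocols, clones=clones)
    k0 = load_parameters(out / "k0.txt", net, label="k0")
    return net, training, k0


def fit(outdir, seed: int, n_steps: int = 250, sigma: float = 0.1, E0: float = 0.5,
        burn_in: float = 0.3, n_chains: int = 2) -> None:
    """Run Metropolis trajectories on the fixture data; archive the pooled ensemble."""
    from .estimate import pool_ensembles, run_chains

    t0 = time.time()
    out = Path(outdir)
    net, training, k0 = _load_fixtures(out)
    config = ChainConfig(sigma=sigma, E0=E0, n_steps=n_steps, seed=seed)
    chains = run_chains(k0, training, config, n_chains=n_chains, net=net)
    ensemble = pool_ensembles([thin_by_autocorrelation(c, burn_in=burn_in) for c in chains])
    kio.write_ensemble_h5(ensemble, net, out / "ensemble.h5", config=config)
    kio.write_ensemble_text(ensemble, net, out / "ensemble_stats.csv")
    pd.concat(
        [pd.DataFrame({"chain": i, "step": np.arange(c.errors.size), "E": c.errors})
         for i, c in enumerate(chains)]
    ).to_csv(out / "chain_errors.csv", index=False, float_format="%.10g")
    kio.write_manifest(out / "manifest_fit.json", "fit", seed,
                       {"n_steps": n_steps, "sigma": sigma, "E0": E0, "n_chains": n_chains,
                        "acceptance_rate": float(np.mean([c.acceptance_rate for c in chains])),
                        "thinning_interval": ensemble.thinning_interval,
                        "n_members": len(ensemble.members)}, t0)


def _load_ensemble(outdir):
    out = Path(outdir)
    net, training, k0 = _load_fixtures(out)
    ensemble = kio.read_ensemble_h5(out / "ensemble.h5", ics=k0.nonzero_initial_conditions)
    return net, training, ensemble


def sensitivity(outdir, seed: int, clones_to_rank=("AD", "AI"), max_members: int = 12) -> None:
    """OSSC rankings per clone over the ensemble plus AD-vs-AI rank shifts."""
    t0 = time.time()
    out = Path(outdir)
    net, training, ensemble = _load_ensemble(out)
    members = _select_members(ensemble, max_members)
    ranks = {}
    osscs = {}
    for clone in clones_to_rank:
        R, O = [], []
        for m in members:
            rk = ossc_protocol(net, m, clone, training.clones)
            R.append(rk.rank)
            O.append(rk.ossc)
        ranks[clone] = np.array(R)
        osscs[clone] = np.array(O)
    kio.write_rankings_csv(ranks, osscs, net.parameter_names, out / "ossc_rankings.csv")
    a, b = clones_to_rank[0], clones_to_rank[-1]
    shifts = rank_shift_test(ranks[a], ranks[b], net.parameter_names)
    shifts.to_csv(out / "rank_shifts.csv", index=False, float_format="%.10g")
    kio.write_manifest(out / "manifest_sensitivity.json", "sensitivity", seed,
                       {"clones": list(clones_to_rank), "n_members": len(members)}, t0)


def robustness(outdir, seed: int, clone: str = "AI", max_members: int = 8) -> None:
    """Knock-in/down/out robustness panel, ensemble averaged."""
    t0 = time.time()
    out = Path(outdir)
    net, training, ensemble = _load_ensemble(out)
    members = _select_members(ensemble, max_members)
    panel = robustness_panel(net, members, MARKERS, TARGETS, clone=clone,
                             clones=training.clones)
    panel.to_csv(out / "robustness_panel.csv", index=False, float_format="%.10g")
    kio.plot_robustness_heatmap(panel, out / "robustness_panel.png")
    kio.write_manifest(out / "manifest_robustness.json", "robustness", seed,
                       {"clone": clone, "markers": MARKERS, "targets": TARGETS,
                        "n_members": len(members)}, t0)


def synergy(outdir, seed: int, clone: str = "AI", max_members: int = 12) -> None:
    """MAPK-axis x Akt-axis synergy screen over all species and fluxes."""
    t0 = time.time()
    out = Path(outdir)
    net, training, ensemble = _load_ensemble(out)
    members = _select_members(ensemble, max_members)
    result = synergy_screen(net, members, AXIS_MAPK, AXIS_AKT, clone=clone,
                            clones=training.clones)
    result.table.to_csv(out / "synergy_screen.csv", index=False, float_format="%.10g")
    kio.write_manifest(out / "manifest_synergy.json", "synergy", seed,
                       {"clone": clone, "axisA": AXIS_MAPK, "axisB": AXIS_AKT,
                        "n_members": len(members)}, t0)


def report(outdir, seed: int, clones_to_plot=("AD", "AI"), marker: str = "PSA",
           max_members: int = 12) -> None:
    """Ensemble mean +/- std stimulus-response trajectories for the marker."""
    t0 = time.time()
    out = Path(outdir)
    net, training, ensemble = _load_ensemble(out)
    members = _select_members(ensemble, max_members)
    grid = np.linspace(0.0, 25.0, 101)
    rows = []
    for clone in clones_to_plot:
        proto = SimulationProtocol(
            events=[Event(1.0, "add_species", "H", 10.0)], t_end=25.0, output_grid=grid
        )
        curves = []
        for m in members:
            p = apply_clone(m, clone, training.clones, net)
            xss, _ = find_steady_state(net, p, net.initial_state(p))
            traj = integrate(net, p, xss, proto)
            curves.append(traj[marker])
        curves = np.array(curves)
        for t, mu, sd in zip(grid, curves.mean(axis=0), curves.std(axis=0)):
            rows.append({"clone": clone, "time_h": t, "mean": mu, "std": sd})
    report_df = pd.DataFrame(rows)
    report_df.to_csv(out / f"report_{marker}_response.csv", index=False,
                     float_format="%.10g")
    kio.plot_response_band(report_df, out / f"report_{marker}_response.png", marker=marker)
    kio.write_manifest(out / "manifest_report.json", "report", seed,
                       {"clones": list(clones_to_plot), "marker": marker,
                        "n_members": len(members)}, t0)


def run_all(outdir, seed: int, n_steps: int = 400, max_members: int = 12) -> None:
    """The full fixture workflow, one call; deterministic under the seed."""
    generate_fixtures(outdir, seed)
    fit(outdir, seed, n_steps=n_steps)
    sensitivity(outdir, seed, max_members=max_members)
    robustness(outdir, seed, max_members=max(max_members // 2, 4))
    synergy(outdir, seed, max_members=max_members)
    report(outdir, seed, max_members=max_members)

CSV_OUTPUTS = [
    "observations.csv", "ensemble_stats.csv", "chain_errors.csv",
    "ossc_rankings.csv", "rank_shifts.csv", "robustness_panel.csv",
    "synergy_screen.csv", "report_PSA_response.csv",
]
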