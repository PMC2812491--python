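"""Serialization: protocol configs, observations, ensembles, result tables.

Formats are deliberately plain: YAML for protocol/run configuration, CSV
for observations and result tables (columns fixed so downstream scripts
can rely on them), HDF5 for the ensemble archive (member matrix, errors,
seeds, chain settings) with a plain-text export alongside.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .estimate import ChainConfig, DatasetProtocol, Ensemble, Observation, TrainingSet
from .network import ParameterSet, ReactionNetwork
from .simulate import Event, SimulationProtocol, Trajectory


# -- trajectories -----------------------------------------------------------

def write_trajectory_csv(traj: Trajectory, path) -> None:
    df = pd.DataFrame(traj.states, columns=traj.species_ids)
    df.insert(0, "time_h", traj.times)
    df.to_csv(path, index=False, float_format="%.10g")


# -- observations -----------------------------------------------------------

OBS_COLUMNS = ["dataset_id", "species_id", "condition", "value", "std", "flag"]


def write_observations_csv(training: TrainingSet, path) -> None:
    rows = [
        {
            "dataset_id": o.dataset_id,
            "species_id": o.species_id,
            "condition": o.condition,
            "value": o.value,
            "std": o.std,
            "flag": 0,
        }
        for o in training.observations
    ]
    # full precision: the fit stage re-reads these values
    pd.DataFrame(rows, columns=OBS_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_observations_csv(path) -> list[Observation]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for row in df.itertuples(index=False):
        cond = row.condition
        try:
            cond = float(cond)
        except (TypeError, ValueError):
            pass
        out.append(Observation(row.dataset_id, row.species_id, cond, float(row.value), float(row.std)))
    return out


# -- protocols --------------------------------------------------------------

def _event_to_dict(ev: Event) -> dict:
    return {"time": ev.time, "kind": ev.kind, "target": ev.target, "value": ev.value}


def _event_from_dict(d: dict) -> Event:
    return Event(float(d["time"]), d["kind"], d["target"], float(d["value"]))


def write_protocols_yaml(
    protocols: dict[str, DatasetProtocol], clones: dict[str, dict[str, float]], path
) -> None:
    doc = {"clones": clones, "datasets": {}}
    for did, dsp in protocols.items():
        entry = {"clone": dsp.clone, "mode": dsp.mode, "score": dsp.score}
        if dsp.protocol is not None:
            entry["events"] = [_event_to_dict(e) for e in dsp.protocol.events]
            entry["t_end"] = dsp.protocol.t_end
        if dsp.conditions:
            entry["conditions"] = {
                lab: [_event_to_dict(e) for e in evs] for lab, evs in dsp.conditions.items()
            }
        if dsp.control:
            entry["control"] = dsp.control
        doc["datasets"][did] = entry
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_protocols_yaml(path) -> tuple[dict[str, DatasetProtocol], dict]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    protocols = {}
    for did, entry in doc.get("datasets", {}).items():
        proto = None
        if "events" in entry or "t_end" in entry:
            proto = SimulationProtocol(
                events=[_event_from_dict(d) for d in entry.get("events", [])],
                t_end=float(entry.get("t_end", 24.0)),
            )
        conditions = {
            lab: [_event_from_dict(d) for d in evs]
            for lab, evs in entry.get("conditions", {}).items()
        }
        protocols[did] = DatasetProtocol(
            clone=entry.get("clone", "AD"),
            mode=entry.get("mode", "timecourse"),
            protocol=proto,
            conditions=conditions,
            score=entry.get("score", "scale"),
            control=entry.get("control"),
        )
    return protocols, doc.get("clones", {})


# -- ensemble archive -------------------------------------------------------

def write_ensemble_h5(ensemble: Ensemble, net: ReactionNetwork, path,
                      config: ChainConfig | None = None) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("members", data=ensemble.matrix())
        h5.create_dataset("errors", data=ensemble.errors)
        h5.create_dataset("provenance", data=np.asarray(ensemble.provenance, dtype=np.int64))
        h5.create_dataset(
            "parameter_names", data=np.array(net.parameter_names, dtype=h5py.string_dtype())
        )
        h5.attrs["thinning_interval"] = ensemble.thinning_interval
        h5.attrs["seed"] = ensemble.seed
        if config is not None:
            for key in ("sigma", "E0", "n_steps", "seed"):
                h5.attrs[f"chain_{key}"] = getattr(config, key)


def read_ensemble_h5(path, ics: dict[str, float] | None = None) -> Ensemble:
    with h5py.File(path, "r") as h5:
        members = h5["members"][...]
        errors = h5["errors"][...]
        prov = list(h5["provenance"][...])
        interval = int(h5.attrs["thinning_interval"])
        seed = int(h5.attrs["seed"])
    sets = [ParameterSet(row, dict(ics or {}), label=f"member{i}") for i, row in enumerate(members)]
    return Ensemble(sets, errors, prov, interval, seed)


def write_ensemble_text(ensemble: Ensemble, net: ReactionNetwork, path) -> None:
    """Plain-text per-parameter ensemble mean/std table."""
    K = ensemble.matrix()
    df = pd.DataFrame(
        {
            "parameter_id": net.parameter_names,
            "mean": K.mean(axis=0),
            "std": K.std(axis=0, ddof=1) if K.shape[0] > 1 else 0.0,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


# -- result tables ----------------------------------------------------------

def write_rankings_csv(rankings_by_member: dict[str, np.ndarray], ossc_by_member: dict[str, np.ndarray],
                       param_names: list[str], path) -> None:
    """Rankings CSV: parameter_id, clone, ossc_mean/std, rank_mean/std."""
    rows = []
    for clone in rankings_by_member:
        R = np.asarray(rankings_by_member[clone], float)
        O = np.asarray(ossc_by_member[clone], float)
        for j, name in enumerate(param_names):
            rows.append(
                {
                    "parameter_id": name,
                    "clone": clone,
                    "ossc_mean": O[:, j].mean(),
                    "ossc_std": O[:, j].std(ddof=1) if O.shape[0] > 1 else 0.0,
                    "rank_mean": R[:, j].mean(),
                    "rank_std": R[:, j].std(ddof=1) if R.shape[0] > 1 else 0.0,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


# -- run manifest -----------------------------------------------------------

def write_manifest(path, stage: str, seed: int, config: dict, started: float) -> None:
    from . import __version__

    manifest = {
        "stage": stage,
        "seed": seed,
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "package_version": __version__,
        "wall_time_s": round(time.time() - started, 3),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


# -- figures ----------------------------------------------------------------

def plot_robustness_heatmap(panel: pd.DataFrame, path) -> None:
    """Heatmap of log10 f over (target x factor) rows and marker columns."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wide = panel.pivot_table(index=["target", "label"], columns="marker", values="f_mean")
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(wide) + 1.5))
    with np.errstate(divide="ignore"):
        img = ax.imshow(np.log10(wide.to_numpy()), aspect="auto", cmap="RdBu_r",
                        vmin=-1.5, vmax=1.5)
    ax.set_xticks(range(wide.shape[1]), wide.columns)
    ax.set_yticks(range(wide.shape[0]), [f"{t} {l}" for t, l in wide.index])
    fig.colorbar(img, ax=ax, label="log10 robustness coefficient f")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_response_band(report: pd.DataFrame, path, marker: str = "PSA") -> None:
    """Ensemble mean +/- one standard deviation response per clone."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for clone, grp in report.groupby("clone"):
        ax.plot(grp.time_h, grp["mean"], label=clone)
        ax.fill_between(grp.time_h, grp["mean"] - grp["std"], grp["mean"] + grp["std"],
                        alpha=0.25)
    ax.set_xlabel("time (h)")
    ax.set_ylabel(f"{marker} (A.U.)")
    ax.legend(title="clone")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
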