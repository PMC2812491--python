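"""Knock-in / knock-down / knock-out robustness coefficients.

A perturbation scales a target protein's abundance by a factor (10 for
knock-in, 0.1 for knock-down, 0 for knock-out).  The robustness
coefficient of marker i under perturbation j is the ratio of the
marker's time-integrated concentration in the perturbed versus the
unperturbed system,

    f(i, j) = int marker dt (perturbed) / int marker dt (wild type),

both runs starting from their own approximate steady state, with the
stimulus (10 nM hormone at 1 h) applied and integration carried to 72 h
after stimulus addition.  f > 1 means the perturbation increases the
output, f < 1 decreases it, f = 1 no influence.

Scaling convention: both the target's initial condition and any
zero-order expression source feeding it are scaled, so a knock-out stays
out instead of being regenerated by constitutive expression.  A species
held inside a conserved complex can still be regenerated from its
partners; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import ParameterSet, ReactionNetwork
from .simulate import Event, SimulationProtocol, apply_clone, find_steady_state, integrate

DEFAULT_FACTORS = (10.0, 0.1, 0.0)
FACTOR_LABELS = {10.0: "knock-in", 0.1: "knock-down", 0.0: "knock-out", 1.0: "null"}


@dataclass(frozen=True)
class PerturbationSpec:
    target: str
    factor: float

    def __post_init__(self):
        if self.factor < 0:
            raise ValueError("perturbation factor must be >= 0")

    @property
    def label(self) -> str:
        return FACTOR_LABELS.get(self.factor, f"x{self.factor:g}")


def apply_expression_perturbation(
    net: ReactionNetwork, params: ParameterSet, x0: np.ndarray, spec: PerturbationSpec
) -> tuple[ParameterSet, np.ndarray]:
    """Scale the target's initial condition and its zero-order sources."""
    idx = net.species_index[spec.target]
    x = np.array(x0, float)
    x[idx] *= spec.factor
    p = params.copy()
    for q, rxn in enumerate(net.reactions):
        if rxn.kind == "zero-order" and any(sid == spec.target for sid, _ in rxn.products):
            if spec.factor > 0:
                p.rate_constants[q] *= spec.factor
            else:
                p.rate_constants[q] *= 1e-300  # positivity invariant; effectively off
    return p, x


def _log_grid(t0_hours: float, tf_hours: float, n: int = 500) -> np.ndarray:
    """Shared output grid, log-spaced to resolve the fast post-stimulus phase."""
    span = tf_hours - t0_hours
    pts = t0_hours + np.logspace(np.log10(1e-3), np.log10(span), n - 1)
    return np.concatenate([[t0_hours], pts])


def _integrated_marker(
    net, params, x0, marker, stimulus_species, stimulus_amount, stimulus_hour, tf_hours, grid
):
    proto = SimulationProtocol(
        events=[Event(stimulus_hour, "add_species", stimulus_species, stimulus_amount)],
        t_end=tf_hours,
        output_grid=grid,
    )
    traj = integrate(net, params, x0, proto)
    return float(np.trapezoid(traj[marker], traj.times)), traj


def robustness_coefficient(
    net: ReactionNetwork,
    params: ParameterSet,
    marker: str,
    perturbation: PerturbationSpec,
    clone: str = "AI",
    clones: dict | None = None,
    stimulus_species: str = "H",
    stimulus_amount: float = 10.0,
    stimulus_hour: float = 1.0,
    horizon_hours: float = 72.0,
    n_grid: int = 500,
) -> float:
    """Robustness coefficient f for one marker and one perturbation.

    Both the perturbed and wild-type systems are re-equilibrated to their
    own steady states before the stimulus; integrals use the trapezoid
    rule on a shared log-spaced grid over [t0, t0 + stimulus + 72 h].
    Returns NaN when the wild-type integral is zero (f undefined).
    """
    p = apply_clone(params, clone, clones, net) if clones else params
    tf = stimulus_hour + horizon_hours
    grid = _log_grid(0.0, tf, n_grid)

    xss_wt, _ = find_steady_state(net, p, net.initial_state(p))
    int_wt, _ = _integrated_marker(
        net, p, xss_wt, marker, stimulus_species, stimulus_amount, stimulus_hour, tf, grid
    )
    if perturbation.factor == 1.0:
        return 1.0 if int_wt != 0 else np.nan

    p_pert, x_pert = apply_expression_perturbation(net, p, net.initial_state(p), perturbation)
    xss_pert, _ = find_steady_state(net, p_pert, x_pert)
    int_pert, _ = _integrated_marker(
        net, p_pert, xss_pert, marker, stimulus_species, stimulus_amount, stimulus_hour, tf, grid
    )
    if int_wt == 0.0:
        return np.nan
    return int_pert / int_wt


def robustness_panel(
    net: ReactionNetwork,
    members: list[ParameterSet],
    markers: list[str],
    targets: list[str],
    clone: str = "AI",
    clones: dict | None = None,
    factors=DEFAULT_FACTORS,
    **kwargs,
) -> pd.DataFrame:
    """Ensemble-averaged f over a markers x targets x factors grid.

    Returns a tidy frame ``marker, target, factor, label, f_mean, f_std``
    with the mean and standard deviation over ensemble members.
    """
    stimulus_species = kwargs.pop("stimulus_species", "H")
    stimulus_amount = kwargs.pop("stimulus_amount", 10.0)
    stimulus_hour = kwargs.pop("stimulus_hour", 1.0)
    horizon_hours = kwargs.pop("horizon_hours", 72.0)
    n_grid = kwargs.pop("n_grid", 500)
    tf = stimulus_hour + horizon_hours
    grid = _log_grid(0.0, tf, n_grid)

    f_vals: dict[tuple[str, str, float], list[float]] = {}
    for params in members:
        p = apply_clone(params, clone, clones, net) if clones else params
        xss_wt, _ = find_steady_state(net, p, net.initial_state(p))
        _, traj_wt = _integrated_marker(
            net, p, xss_wt, markers[0], stimulus_species, stimulus_amount, stimulus_hour, tf, grid
        )
        int_wt = {m: float(np.trapezoid(traj_wt[m], traj_wt.times)) for m in markers}
        for target in targets:
            for factor in factors:
                spec = PerturbationSpec(target, factor)
                p_pert, x_pert = apply_expression_perturbation(net, p, net.initial_state(p), spec)
                xss_pert, _ = find_steady_state(net, p_pert, x_pert)
                _, traj_pert = _integrated_marker(
                    net, p_pert, xss_pert, markers[0], stimulus_species, stimulus_amount,
                    stimulus_hour, tf, grid,
                )
                for marker in markers:
                    num = float(np.trapezoid(traj_pert[marker], traj_pert.times))
                    f = num / int_wt[marker] if int_wt[marker] != 0 else np.nan
                    f_vals.setdefault((marker, target, factor), []).append(f)
    rows = []
    for target in targets:
        for factor in factors:
            for marker in markers:
                vals = np.array(f_vals[(marker, target, factor)])
                rows.append(
                    {
                        "marker": marker,
                        "target": target,
                        "factor": factor,
                        "label": PerturbationSpec(target, factor).label,
                        "f_mean": float(np.nanmean(vals)),
                        "f_std": float(np.nanstd(vals)),
                    }
                )
    return pd.DataFrame(rows)
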