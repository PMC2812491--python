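"""Steady-state synergy coefficients between two signaling axes.

Super- or sub-additive coupling between two axes (e.g. the MAPK and Akt
arms of a growth-factor network) is detected by comparing steady states
of four systems: wild type, each single knock-out, and the double
knock-out, which serves as the control.  With q the steady-state value of
a species concentration or reaction flux and

    dA  = q(B knocked out) - q(control)     # contribution of axis A alone
    dB  = q(A knocked out) - q(control)
    dAB = q(wild type)     - q(control)

the synergy coefficient is the interaction contrast normalized by the
wild-type level:

    alpha = (dAB - dA - dB) / q_wt .

alpha > 0: the wild type exceeds the sum of the single-axis
contributions (positive synergy); alpha < 0: negative synergy;
alpha = 0: the quantity is additively (or not at all) coupled to the two
axes.  Knock-out of an axis zeroes the total protein of the axis — the
initial conditions of every species carrying it and any zero-order
expression source — the same convention as the robustness module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import ParameterSet, ReactionNetwork, massaction_rates
from .robustness import PerturbationSpec, apply_expression_perturbation
from .simulate import apply_clone, find_steady_state


@dataclass
class SynergyResult:
    table: pd.DataFrame  # quantity_id, type, alpha_mean, ci_lo, ci_hi, class, sign_consistent


def _axis_species(axis) -> list[str]:
    return [axis] if isinstance(axis, str) else list(axis)


def _knockout(net, params, x0, axis):
    p, x = params, x0
    for sid in _axis_species(axis):
        p, x = apply_expression_perturbation(net, p, x, PerturbationSpec(sid, 0.0))
    return p, x


def _steady_quantities(net, params, x0):
    """Steady-state species concentrations and reaction fluxes, concatenated."""
    xss, _ = find_steady_state(net, params, x0)
    r = massaction_rates(xss, params, net)
    return np.concatenate([xss, r])


def synergy_coefficients(
    net: ReactionNetwork,
    params: ParameterSet,
    axisA,
    axisB,
    clone: str | None = None,
    clones: dict | None = None,
) -> np.ndarray:
    """alpha for every species and flux in one parameter set.

    Returns a vector of length n_species + n_reactions; entries with
    q_wt = 0 are NaN (undefined).
    """
    p = apply_clone(params, clone, clones, net) if clone and clones else params
    x0 = net.initial_state(p)
    q_wt = _steady_quantities(net, p, x0)
    q_A = _steady_quantities(net, *_knockout(net, p, x0, axisB))  # A present
    q_B = _steady_quantities(net, *_knockout(net, p, x0, axisA))  # B present
    pc, xc = _knockout(net, *_knockout(net, p, x0, axisA), axisB)
    q_ctrl = _steady_quantities(net, pc, xc)
    dA = q_A - q_ctrl
    dB = q_B - q_ctrl
    dAB = q_wt - q_ctrl
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(q_wt != 0, (dAB - dA - dB) / q_wt, np.nan)
    return alpha


def synergy_coefficient(net, params, axisA, axisB, quantity, clone=None, clones=None) -> float:
    """alpha for a single species id or reaction index (prefix 'flux:')."""
    alpha = synergy_coefficients(net, params, axisA, axisB, clone, clones)
    if isinstance(quantity, str) and quantity.startswith("flux:"):
        idx = net.n_species + int(quantity[5:])
    elif isinstance(quantity, str):
        idx = net.species_index[quantity]
    else:
        idx = int(quantity)
    return float(alpha[idx])


def synergy_screen(
    net: ReactionNetwork,
    members: list[ParameterSet],
    axisA,
    axisB,
    clone: str | None = None,
    clones: dict | None = None,
    ci: float = 0.95,
    tol: float = 1e-8,
) -> SynergyResult:
    """Ensemble screen over all species and fluxes.

    Classification requires the percentile confidence interval over the
    ensemble (2.5-97.5% by default) to exclude zero; a degenerate
    all-identical ensemble is classified by sign with a small tolerance.
    ``sign_consistent`` reports whether every member agrees in sign.
    """
    A = np.array([synergy_coefficients(net, m, axisA, axisB, clone, clones) for m in members])
    lo_q, hi_q = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    import warnings

    with warnings.catch_warnings():
        # quantities undefined in every member (q_wt = 0) stay NaN
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(A, axis=0)
        lo = np.nanpercentile(A, lo_q, axis=0)
        hi = np.nanpercentile(A, hi_q, axis=0)
    classes = []
    for m, a, b in zip(mean, lo, hi):
        if np.isnan(m):
            classes.append("none")
        elif b - a < tol:  # degenerate interval: classify by sign
            classes.append("positive" if m > tol else "negative" if m < -tol else "none")
        elif a > 0:
            classes.append("positive")
        elif b < 0:
            classes.append("negative")
        else:
            classes.append("none")
    signs = np.sign(np.where(np.abs(A) < tol, 0.0, A))
    consistent = [bool(len(set(col[~np.isnan(col)])) <= 1) for col in signs.T]
    names = net.species_ids + [f"flux:{q}" for q in range(net.n_reactions)]
    types = ["species"] * net.n_species + ["flux"] * net.n_reactions
    table = pd.DataFrame(
        {
            "quantity_id": names,
            "type": types,
            "alpha_mean": mean,
            "ci_lo": lo,
            "ci_hi": hi,
            "class": classes,
            "sign_consistent": consistent,
        }
    )
    return SynergyResult(table)
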