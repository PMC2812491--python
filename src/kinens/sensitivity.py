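"""First-order parameter sensitivities, OSSC aggregation and rank shifts.

The sensitivities s_ij(t) = dx_i/dk_j obey the forward (kinetic-
sensitivity) equations

    ds_j/dt = A(t) s_j + b_j(t),   s_j(0) = 0,

where A is the analytic state Jacobian and b_j the j-th column of the
parameter-derivative matrix B, both evaluated along the unperturbed
solution.  States and all sensitivity columns are integrated jointly as
one extended system so A and b_j are always evaluated on the current
solution point.

The Overall State Sensitivity Coefficient aggregates over states and time,

    OSSC_j = sqrt( (1/(N_T N_x)) sum_t sum_i shat_ij(t)^2 ),

with scaled sensitivities shat_ij = (k_j / max(x_i, eps)) * s_ij.  This
scaled RMS form is a reconstruction in the lineage of Stelling-style
overall sensitivity measures and is deliberately isolated in one function
so it can be swapped; it is the one formula in this package not pinned
down by an external closed form.  Large OSSC marks fragile (important)
interactions, so parameters are ranked ascending: the largest OSSC gets
rank P.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.stats import ttest_ind

from .network import ParameterSet, ReactionNetwork, jacobian, parameter_jacobian, rhs
from .simulate import HOUR, apply_clone, find_steady_state


@dataclass
class SensitivityResult:
    times: np.ndarray  # seconds
    states: np.ndarray  # (n_times, n_species)
    s: np.ndarray  # (n_times, n_species, n_params)
    param_names: list[str]
    species_ids: list[str]


@dataclass
class OSSCRanking:
    ossc: np.ndarray
    rank: np.ndarray  # permutation of 1..P; 1 = least sensitive
    clone: str
    param_names: list[str]


def solve_sensitivities(
    net: ReactionNetwork,
    params: ParameterSet,
    x0: np.ndarray,
    t_end_seconds: float,
    param_subset: list[int] | None = None,
    n_times: int = 101,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SensitivityResult:
    """Integrate the extended kinetic-sensitivity system.

    All requested parameter columns are solved in a single call together
    with the states; the initial condition for every rate-constant
    sensitivity is zero.
    """
    if param_subset is None:
        param_subset = list(range(net.n_reactions))
    cols = np.asarray(param_subset, dtype=int)
    n, p = net.n_species, len(cols)
    k = params.rate_constants

    def extended_rhs(t, y):
        x = y[:n]
        S = y[n:].reshape(n, p)
        A = jacobian(x, k, net)
        B = parameter_jacobian(x, k, net)[:, cols]
        dS = A @ S + B
        return np.concatenate([rhs(x, k, net), dS.ravel()])

    y0 = np.concatenate([np.asarray(x0, float), np.zeros(n * p)])
    t_eval = np.linspace(0.0, t_end_seconds, n_times)
    sol = solve_ivp(
        extended_rhs, (0.0, t_end_seconds), y0, method="LSODA",
        t_eval=t_eval, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"sensitivity integration failed: {sol.message}")
    Y = sol.y.T
    states = Y[:, :n]
    s = Y[:, n:].reshape(len(t_eval), n, p)
    return SensitivityResult(
        sol.t, states, s, [net.parameter_names[j] for j in cols], net.species_ids
    )


def ossc(
    sens: SensitivityResult,
    params: ParameterSet,
    param_subset: list[int] | None = None,
    eps_fraction: float = 1e-6,
) -> np.ndarray:
    """Scaled RMS aggregation of s_ij(t) over all states and time points."""
    n_t, n_x, n_p = sens.s.shape
    if param_subset is None:
        k = params.rate_constants[: n_p]
    else:
        k = params.rate_constants[np.asarray(param_subset, int)]
    eps = eps_fraction * max(float(np.max(sens.states)), 1e-300)
    xsafe = np.maximum(sens.states, eps)  # (n_t, n_x)
    shat = (k[np.newaxis, np.newaxis, :] / xsafe[:, :, np.newaxis]) * sens.s
    return np.sqrt(np.sum(shat**2, axis=(0, 1)) / (n_t * n_x))


def rank_parameters(ossc_values: np.ndarray) -> np.ndarray:
    """Ascending ranks 1..P (largest OSSC -> rank P); ties broken by index."""
    order = np.lexsort((np.arange(ossc_values.size), ossc_values))
    ranks = np.empty(ossc_values.size, dtype=int)
    ranks[order] = np.arange(1, ossc_values.size + 1)
    return ranks


def ossc_protocol(
    net: ReactionNetwork,
    params: ParameterSet,
    clone: str,
    clones: dict[str, dict[str, float]],
    stimulus_species: str = "H",
    stimulus_amount: float = 10.0,
    window_seconds: float = 100.0,
    n_times: int = 101,
) -> OSSCRanking:
    """Post-stimulus sensitivity protocol.

    Run the clone to approximate steady state, add the stimulus (10 nM
    hormone by default) at the window start, solve the sensitivities over
    a 100 s window on 101 uniform points, aggregate to OSSC and rank.
    """
    p = apply_clone(params, clone, clones, net)
    xss, _ = find_steady_state(net, p, net.initial_state(p))
    x0 = xss.copy()
    x0[net.species_index[stimulus_species]] += stimulus_amount
    sens = solve_sensitivities(net, p, x0, window_seconds, n_times=n_times)
    values = ossc(sens, p)
    return OSSCRanking(values, rank_parameters(values), clone, list(net.parameter_names))


def rank_shift_test(
    ranks_a: np.ndarray, ranks_b: np.ndarray, param_names: list[str], alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Welch t-test on per-parameter rank samples between two clones.

    ``ranks_a``/``ranks_b`` are (n_members, n_params) rank matrices over
    the ensemble.  Shift = mean rank (B) - mean rank (A); a shift is
    flagged "large" when its magnitude exceeds one standard deviation of
    all shifts.  No multiple-testing correction is applied by default; a
    Benjamini-Hochberg switch is available.
    """
    ranks_a = np.asarray(ranks_a, float)
    ranks_b = np.asarray(ranks_b, float)
    if ranks_a.shape[0] < 3 or ranks_b.shape[0] < 3:
        raise ValueError("need at least 3 ensemble members per clone")
    shift = ranks_b.mean(axis=0) - ranks_a.mean(axis=0)
    t, pvals = ttest_ind(ranks_b, ranks_a, axis=0, equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)  # zero-variance identical ranks
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        signif = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    else:
        signif = pvals < alpha
    large = np.abs(shift) > np.std(shift)
    return pd.DataFrame(
        {
            "parameter_id": param_names,
            "mean_shift": shift,
            "t_statistic": t,
            "p_value": pvals,
            "significant": signif,
            "large_shift": large,
        }
    )
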