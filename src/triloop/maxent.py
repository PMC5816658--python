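"""Maximum-entropy reweighting of ensemble snapshots against
lower-bounded NOE averages, and greedy representative-structure selection.

Snapshots t with initial (uniform) weights are reweighted to
W(t) = exp(-sum_i lambda_i NOE_i(t)) / Z so that every ensemble average
<NOE_i> = sum_t W(t) NOE_i(t) meets its experimental lower bound
NOE_i,exp = 1/r_hi^6.  The multipliers are found by iterating

    lambda_i += K * [<NOE_i> - (NOE_i,exp + lambda_i sigma^2)]

with lambda_i clamped to (-inf, 0] after every update (one-sided
restraints: only too-long average distances are corrected).  The
sigma^2 term relaxes the bound to absorb experimental error; with
sigma > 0 the fixed point of an active restraint sits slightly below
the strict bound, so two stopping rules are exposed (see ``stop_rule``).

Among all weight vectors satisfying the constraints, the exponential
form minimizes the Kullback-Leibler divergence from the uniform
distribution -- the maximum-entropy solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .restraints import NOEMatrix
from .structure import check_simplex

#: working-unit conversion: NOE values are supplied in A^-6; the update
#: constants K and sigma are calibrated for nm^-6 values (order 1-10^4)
_A6_PER_NM6 = 1.0e6


@dataclass
class ReweightConfig:
    K: float = 1e-5                 #: multiplier step constant (working units)
    sigma: float = 0.5              #: experimental-error scale (working units)
    max_iterations: int = 10_000_000
    tolerance: float = 1e-10        #: absolute satisfaction tolerance, working units
    units: str = "nm"               #: 'nm' (default) or 'angstrom' working units
    stop_rule: str = "strict"       #: 'strict' (<NOE> >= exp) or 'relaxed' (fixed point)
    scheme: str = "synchronous"     #: 'synchronous' or 'sequential' multiplier sweeps
    stall_window: int = 2000        #: sweeps with no progress before declaring a stall

    def __post_init__(self):
        if self.K <= 0 or self.sigma < 0:
            raise ValueError("require K > 0 and sigma >= 0")
        if self.units not in ("nm", "angstrom"):
            raise ValueError("units must be 'nm' or 'angstrom'")
        if self.stop_rule not in ("strict", "relaxed"):
            raise ValueError("stop_rule must be 'strict' or 'relaxed'")
        if self.scheme not in ("synchronous", "sequential"):
            raise ValueError("scheme must be 'synchronous' or 'sequential'")


@dataclass
class ReweightResult:
    weights: np.ndarray
    multipliers: np.ndarray        #: lambda_i <= 0, working units
    iterations: int
    satisfied: np.ndarray          #: per-restraint strict satisfaction flags
    averages: np.ndarray           #: final <NOE_i>, input (A^-6) units
    status: str                    #: 'satisfied' | 'converged_with_slack' |
                                   #: 'max_iterations' | 'infeasible'
    infeasible: list[str] = field(default_factory=list)
    slack: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return self.status in ("satisfied", "converged_with_slack")

    @property
    def effective_sample_size(self) -> float:
        return float(1.0 / np.sum(self.weights ** 2))


def kl_from_uniform(weights) -> float:
    """KL divergence (nats) of a simplex weight vector from uniform:
    sum_t W(t) ln(N W(t))."""
    w = check_simplex(weights)
    n = len(w)
    nz = w > 0
    return float(np.sum(w[nz] * np.log(n * w[nz])))


def _softmax_weights(noe_values: np.ndarray, lam: np.ndarray) -> np.ndarray:
    logw = -noe_values @ lam
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def reweight(noe: NOEMatrix, noe_exp, config: ReweightConfig | None = None) -> ReweightResult:
    """Maximum-entropy reweighting of an NOE matrix against lower bounds.

    ``noe_exp``: per-restraint lower bounds on the NOE value, in the same
    (A^-6) units as the matrix.  Deterministic; returns a non-convergence
    result (never raises) when the iteration budget is exhausted.
    """
    cfg = config or ReweightConfig()
    exp_in = np.asarray(noe_exp, float)
    if exp_in.shape != (noe.n_restraints,):
        raise ValueError("noe_exp length must match the restraint count")
    scale = _A6_PER_NM6 if cfg.units == "nm" else 1.0
    values = noe.values * scale
    exp = exp_in * scale
    tol = cfg.tolerance
    sigma2 = cfg.sigma ** 2

    infeasible_mask = values.max(axis=0) < exp - tol
    infeasible = [noe.restraint_ids[i] for i in np.flatnonzero(infeasible_mask)]

    lam = np.zeros(noe.n_restraints)
    w = _softmax_weights(values, lam)
    avg = w @ values
    feasible = ~infeasible_mask
    it = 0
    status = "satisfied"
    best_short = np.inf
    stall_count = 0
    while True:
        if cfg.stop_rule == "strict":
            ok = avg >= exp - tol
        else:
            ok = avg >= exp + lam * sigma2 - tol
        if np.all(ok[feasible]):
            status = "infeasible" if infeasible else (
                "satisfied" if np.all(avg >= exp - tol) else "converged_with_slack")
            break
        if it >= cfg.max_iterations:
            status = "max_iterations"
            break
        if cfg.scheme == "synchronous":
            lam = np.minimum(lam + cfg.K * (avg - (exp + lam * sigma2)), 0.0)
            w = _softmax_weights(values, lam)
            avg = w @ values
        else:
            for i in range(noe.n_restraints):
                lam[i] = min(lam[i] + cfg.K * (avg[i] - (exp[i] + lam[i] * sigma2)), 0.0)
                w = _softmax_weights(values, lam)
                avg = w @ values
        it += 1
        # stall detection: shortfall no longer improving (sigma^2 fixed point
        # below the strict bound, or numerically flat progress)
        shortfall = float(np.max((exp - avg)[feasible], initial=0.0))
        if shortfall < best_short - tol * 0.01:
            best_short = shortfall
            stall_count = 0
        else:
            stall_count += 1
            if stall_count >= cfg.stall_window and cfg.stop_rule == "strict":
                at_fixed_point = np.all(
                    (avg >= exp + lam * sigma2 - max(tol, 1e-9 * np.abs(exp).max()))[feasible])
                if at_fixed_point:
                    status = "infeasible" if infeasible else "converged_with_slack"
                    break
                stall_count = 0

    satisfied = avg >= exp - tol
    slack = [noe.restraint_ids[i] for i in np.flatnonzero(~satisfied & feasible)]
    return ReweightResult(
        weights=w,
        multipliers=lam,
        iterations=it,
        satisfied=satisfied,
        averages=(w @ values) / scale,
        status=status,
        infeasible=infeasible,
        slack=slack,
    )


def select_representatives(result: ReweightResult, noe: NOEMatrix, noe_exp,
                           pool_size: int = 20) -> list[int]:
    """Greedy representative-structure selection.

    From the pool of the ``pool_size`` highest-weight snapshots: start
    with the top-weight snapshot, then scan the rest in descending
    weight, adding any snapshot that strictly reduces the number of
    restraints unsatisfied by every selected snapshot (a snapshot
    satisfies restraint i when its own NOE value meets the bound, i.e.
    its distance is within r_hi).  Stops as soon as every restraint is
    satisfied in at least one selected snapshot, or the pool is
    exhausted.  Returns snapshot ids in selection order.
    """
    if pool_size < 1:
        raise ValueError("pool must be non-empty")
    pool_size = min(pool_size, noe.n_snapshots)
    exp = np.asarray(noe_exp, float)
    order = np.argsort(result.weights)[::-1][:pool_size]
    sat = noe.values >= exp[None, :]  # per-snapshot satisfaction
    selected = [order[0]]
    covered = sat[order[0]].copy()
    for t in order[1:]:
        if covered.all():
            break
        if np.any(sat[t] & ~covered):
            selected.append(t)
            covered |= sat[t]
    return [noe.snapshot_ids[t] for t in selected]


def write_weights(result: ReweightResult, snapshot_ids, path) -> None:
    """Two-column text: snapshot id, weight."""
    with open(path, "w") as fh:
        fh.write(f"# status={result.status} iterations={result.iterations} "
                 f"ess={result.effective_sample_size:.2f}\n")
        for sid, w in zip(snapshot_ids, result.weights):
            fh.write(f"{sid}\t{w:.12e}\n")
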