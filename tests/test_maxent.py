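"""Maximum-entropy reweighting: invariants, KKT structure, optimality
against brute-force oracles, and planted-ensemble recovery."""

import itertools

import numpy as np
import pytest

from triloop.maxent import (ReweightConfig, kl_from_uniform, reweight,
                            select_representatives)
from triloop.restraints import NOEMatrix

#: tight-tolerance settings for the small oracle instances (the default
#: step constant is stable here; larger K values overshoot the dual
#: ascent and stop at feasible but non-optimal weights)
FAST = dict(K=1e-7, max_iterations=5_000_000, tolerance=1e-9)


def _matrix(values):
    values = np.asarray(values, float)
    return NOEMatrix(values, [f"r{i}" for i in range(values.shape[1])],
                     list(range(1, values.shape[0] + 1)))


def test_kl_from_uniform_limits():
    assert kl_from_uniform([0.25] * 4) == pytest.approx(0.0, abs=1e-12)
    assert kl_from_uniform([1.0, 0.0, 0.0]) == pytest.approx(np.log(3))
    rng = np.random.default_rng(0)
    for _ in range(20):
        assert kl_from_uniform(rng.dirichlet(np.ones(6))) >= -1e-12


def test_satisfied_at_uniform_returns_uniform_and_zero_multipliers():
    """Complementary slackness: nothing to correct, no iterations."""
    noe = _matrix([[2.0], [1.5], [1.8]])
    res = reweight(noe, [1.0], ReweightConfig(sigma=0.0))
    assert res.iterations == 0
    assert np.allclose(res.weights, 1 / 3)
    assert np.all(res.multipliers == 0.0)
    assert res.status == "satisfied"


def test_active_constraint_reaches_bound_two_snapshots():
    """3.3 A / 8 A snapshots against a strong (3.6 A) bound: the weighted
    average must be pulled up to the bound exactly (sigma = 0)."""
    vals = np.array([[3.3 ** -6], [8.0 ** -6]])
    exp = np.array([3.6 ** -6])
    res = reweight(_matrix(vals), exp, ReweightConfig(sigma=0.0, **FAST))
    assert res.status == "satisfied"
    w_analytic = (exp[0] - vals[1, 0]) / (vals[0, 0] - vals[1, 0])
    assert res.weights[0] == pytest.approx(w_analytic, abs=1e-3)
    assert res.multipliers[0] < 0


def _grid_kl_oracle(values, exp, n_grid=400):
    """Brute-force minimum-KL-from-uniform over the simplex subject to
    the NOE lower bounds (2 or 3 snapshots)."""
    t = values.shape[0]
    best, best_kl = None, np.inf
    axes = [np.linspace(0, 1, n_grid + 1)] * (t - 1)
    for ws in itertools.product(*axes):
        w = np.array(list(ws) + [1 - sum(ws)])
        if w[-1] < -1e-12:
            continue
        w = np.clip(w, 0, 1)
        w /= w.sum()
        if np.all(values.T @ w >= exp - 1e-12):
            kl = kl_from_uniform(w)
            if kl < best_kl:
                best, best_kl = w, kl
    return best


@pytest.mark.parametrize("values,exp", [
    (np.array([[3.3 ** -6], [8.0 ** -6]]), np.array([3.6 ** -6])),
    (np.array([[4.0 ** -6, 5.5 ** -6],
               [7.0 ** -6, 4.0 ** -6],
               [9.0 ** -6, 9.0 ** -6]]),
     np.array([4.5 ** -6, 4.5 ** -6])),
    (np.array([[3.8 ** -6], [5.0 ** -6], [7.5 ** -6]]), np.array([4.2 ** -6])),
])
def test_maxent_optimality_against_grid_search(values, exp):
    """At sigma = 0 the returned weights minimize KL from uniform among
    all simplex points satisfying the constraints."""
    res = reweight(_matrix(values), exp, ReweightConfig(sigma=0.0, **FAST))
    assert res.status == "satisfied"
    oracle = _grid_kl_oracle(values, exp)
    assert oracle is not None
    # agreement limited by the oracle's grid spacing (1/400 per axis)
    assert np.allclose(res.weights, oracle, atol=2 / 400)


def test_kkt_structure_at_sigma_zero():
    """Restraints with negative multipliers are active (average at the
    bound); zero-multiplier restraints are strictly satisfied."""
    values = np.array([[4.0 ** -6, 2.0 ** -6],
                       [8.0 ** -6, 2.5 ** -6],
                       [6.0 ** -6, 2.2 ** -6]])
    exp = np.array([4.5 ** -6, 3.6 ** -6])   # first active, second slack
    res = reweight(_matrix(values), exp, ReweightConfig(sigma=0.0, **FAST))
    assert res.status == "satisfied"
    avg = res.weights @ values
    assert res.multipliers[0] < -1e-12
    assert avg[0] == pytest.approx(exp[0], rel=1e-6)
    assert res.multipliers[1] == 0.0
    assert avg[1] > exp[1] * 1.05


def test_multipliers_never_positive_and_weights_on_simplex(two_state,
                                                          reweighted_two_state):
    res = reweighted_two_state
    assert np.all(res.multipliers <= 0.0)
    assert np.all(res.weights >= 0.0)
    assert res.weights.sum() == pytest.approx(1.0, abs=1e-12)


def test_permutation_equivariance():
    values = np.array([[4.0 ** -6], [8.0 ** -6], [5.0 ** -6], [6.5 ** -6]])
    exp = np.array([4.5 ** -6])
    cfg = ReweightConfig(sigma=0.0, **FAST)
    res = reweight(_matrix(values), exp, cfg)
    perm = np.array([2, 0, 3, 1])
    res_p = reweight(_matrix(values[perm]), exp, cfg)
    assert np.allclose(res_p.weights, res.weights[perm], atol=1e-9)


def test_infeasible_restraint_detected_up_front():
    """A bound no snapshot can meet is reported, not looped on."""
    values = np.array([[6.0 ** -6], [8.0 ** -6]])
    res = reweight(_matrix(values), np.array([3.6 ** -6]),
                   ReweightConfig(sigma=0.0, max_iterations=50_000))
    assert res.status == "infeasible"
    assert res.infeasible == ["r0"]


def test_sigma_relaxation_reports_slack():
    """With sigma > 0 the printed update's fixed point sits below the
    strict bound; the solver stops there and says so instead of looping
    forever."""
    values = np.array([[3.3 ** -6], [8.0 ** -6]])
    res = reweight(_matrix(values), np.array([3.6 ** -6]),
                   ReweightConfig(sigma=0.5, K=1e-7, max_iterations=5_000_000,
                                  stall_window=500))
    assert res.status == "converged_with_slack"
    assert res.slack == ["r0"]
    # the stall point is the sigma^2-relaxed fixed point (working units)
    avg_nm = (res.weights @ values)[0] * 1e6
    fixed_point = 3.6 ** -6 * 1e6 + res.multipliers[0] * 0.5 ** 2
    assert avg_nm == pytest.approx(fixed_point, rel=1e-3)


def test_sequential_scheme_agrees_with_synchronous():
    values = np.array([[4.0 ** -6, 5.0 ** -6],
                       [8.0 ** -6, 4.2 ** -6],
                       [6.0 ** -6, 7.0 ** -6]])
    exp = np.array([4.5 ** -6, 5.2 ** -6])
    a = reweight(_matrix(values), exp, ReweightConfig(sigma=0.0, **FAST))
    b = reweight(_matrix(values), exp,
                 ReweightConfig(sigma=0.0, scheme="sequential", K=1e-7,
                                max_iterations=5_000_000, tolerance=1e-9))
    assert np.allclose(a.weights, b.weights, atol=1e-3)


# ---------------------------------------------------------------------------
# planted-ensemble pipeline
# ---------------------------------------------------------------------------

def test_reweighting_satisfies_all_planted_noes(two_state, reweighted_two_state):
    """The 7-violated synthetic ensemble is reweighted until every NOE
    bound is met."""
    _, _, experiment = two_state
    res = reweighted_two_state
    assert res.status == "satisfied"
    assert bool(res.satisfied.all())
    assert np.all(res.averages >= experiment.noe_exp * (1 - 1e-9))


def test_two_state_weight_recovery(two_state_noiseless):
    """Noise-free two-state ensemble: the maximum-entropy solution puts
    exactly the minimum feasible weight w* on the discriminating state."""
    _, truth, experiment = two_state_noiseless
    res = reweight(experiment.noe, experiment.noe_exp,
                   ReweightConfig(sigma=0.0))
    assert res.status == "satisfied"
    w_a = res.weights[truth.state_mask(0)].sum()
    assert experiment.w_star - 1e-6 <= w_a <= experiment.w_star + 0.05


# ---------------------------------------------------------------------------
# representative selection
# ---------------------------------------------------------------------------

def _greedy_oracle(weights, sat, pool_size):
    """Independent re-implementation of the greedy selection rule."""
    order = np.argsort(weights)[::-1][:pool_size]
    chosen = [order[0]]
    covered = sat[order[0]].copy()
    for t in order[1:]:
        if covered.all():
            break
        if (sat[t] & ~covered).any():
            chosen.append(t)
            covered |= sat[t]
    return chosen


def test_top_snapshot_covering_everything_gives_singleton():
    values = np.array([[5.5 ** -6, 5.5 ** -6],
                       [9.0 ** -6, 9.0 ** -6],
                       [9.0 ** -6, 9.0 ** -6]])
    noe = _matrix(values)
    exp = np.array([5.8 ** -6, 5.8 ** -6])   # violated at uniform weights
    res = reweight(noe, exp, ReweightConfig(sigma=0.0, **FAST))
    assert res.weights[0] == res.weights.max()
    ids = select_representatives(res, noe, exp, pool_size=3)
    assert ids == [1]   # snapshot 1 satisfies both restraints on its own


def test_engineered_pool_needs_five_structures():
    """A 20-snapshot pool built so each top-weight snapshot covers one
    disjoint restraint block: greedy must pick 5 jointly covering all."""
    n_snap, n_rst = 20, 10
    good, bad = 5.0 ** -6, 9.0 ** -6
    values = np.full((n_snap, n_rst), bad)
    for k in range(5):                       # snapshots 0..4: 2 restraints each
        values[k, 2 * k: 2 * k + 2] = good
    noe = _matrix(values)
    exp = np.full(n_rst, 6.5 ** -6)
    weights = np.linspace(0.2, 0.01, n_snap)
    weights /= weights.sum()
    from triloop.maxent import ReweightResult
    res = ReweightResult(weights=weights, multipliers=np.zeros(n_rst),
                         iterations=0, satisfied=np.ones(n_rst, bool),
                         averages=weights @ values, status="satisfied")
    ids = select_representatives(res, noe, exp, pool_size=20)
    assert len(ids) == 5
    sat = values >= exp[None, :]
    chosen = [noe.snapshot_ids.index(i) for i in ids]
    assert np.all(sat[chosen].any(axis=0))


def test_greedy_matches_independent_reimplementation(rng):
    for _ in range(25):
        n_snap, n_rst = 15, 8
        values = rng.uniform(3.0, 9.0, (n_snap, n_rst)) ** -6.0
        noe = _matrix(values)
        exp = np.full(n_rst, 6.0 ** -6)
        weights = rng.dirichlet(np.ones(n_snap))
        from triloop.maxent import ReweightResult
        res = ReweightResult(weights=weights, multipliers=np.zeros(n_rst),
                             iterations=0, satisfied=np.ones(n_rst, bool),
                             averages=weights @ values, status="satisfied")
        ids = select_representatives(res, noe, exp, pool_size=10)
        oracle = _greedy_oracle(weights, values >= exp[None, :], 10)
        assert ids == [noe.snapshot_ids[t] for t in oracle]


def test_representatives_cover_all_planted_noes(two_state, reweighted_two_state):
    """At most 5 high-weight structures jointly satisfy every NOE."""
    _, _, experiment = two_state
    ids = select_representatives(reweighted_two_state, experiment.noe,
                                 experiment.noe_exp, pool_size=20)
    assert 1 <= len(ids) <= 5
    idx = [experiment.noe.snapshot_ids.index(i) for i in ids]
    sat = experiment.noe.values[idx] >= experiment.noe_exp[None, :]
    assert np.all(sat.any(axis=0))
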