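"""Independent oracles used by the test suite.

These deliberately avoid the code paths they verify: the rank-sum oracle
enumerates every rank assignment with itertools, and the rigid-fit oracle
minimizes the raw objective numerically over rotation-vector parameters.
"""

from itertools import combinations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation
from scipy.stats import rankdata


def ranksum_enumeration_p(x, y):
    """Exact one-tailed (x greater) rank-sum p by full enumeration.

    Assumes no ties. Counts the fraction of all C(n, n_x) rank assignments
    whose x rank sum is >= the observed one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_x = x.size
    n = n_x + y.size
    ranks = rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n_x].sum()
    hits = total = 0
    for combo in combinations(range(1, n + 1), n_x):
        total += 1
        if sum(combo) >= w_obs:
            hits += 1
    return hits / total


def brute_force_rigid_residual(template, observed, n_starts=12, seed=0):
    """Minimum RMS point residual over rigid motions, found numerically.

    Parametrizes the rotation as a rotation vector and minimizes the mean
    squared residual with BFGS from several random starts.
    """
    template = np.asarray(template, dtype=float)
    observed = np.asarray(observed, dtype=float)

    def objective(params):
        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        resid = observed - (template @ rot.T + params[3:])
        return np.mean(np.sum(resid**2, axis=1))

    rng = np.random.default_rng(seed)
    best = np.inf
    starts = [np.zeros(6)] + [
        np.concatenate([rng.uniform(-np.pi, np.pi, 3), rng.normal(0, 1, 3)])
        for _ in range(n_starts)
    ]
    for x0 in starts:
        res = minimize(objective, x0, method="BFGS", options={"gtol": 1e-14})
        best = min(best, res.fun)
    return float(np.sqrt(best))


def simulate_group_reductions(rng, beta, alpha=5.0, noise_sd=1.0):
    """12-subject cohort: overall deviations and one region's cross-shoe
    average reduction, first 6 subjects drawn as high deviators.

    Uses the printed group statistics (12.5 +/- 2.7 vs 6.2 +/- 2.3 deg).
    Returns (deviations, reductions) arrays of length 12.
    """
    dev = np.concatenate(
        [rng.normal(12.5, 2.7, 6), rng.normal(6.2, 2.3, 6)]
    )
    dev = np.clip(dev, 0.0, None)
    red = alpha + beta * dev + rng.normal(0.0, noise_sd, 12)
    return dev, np.clip(red, 0.0, None)
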