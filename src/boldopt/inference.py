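"""One-tailed permutation tests on closed-loop run logs.

Two questions are tested.  First, could the observed SPSA convergence
speed have arisen by chance?  The null distribution replays the SPSA
update dynamics with the pooled, empirically observed objective values
randomly reassigned to iteration slots, records each simulated run's
convergence iteration (capped at 50), and averages over runs.  Second,
could the group-level GP optimum lie as close to the hypothesized
optimum by chance?  The null refits the GP with objective values
shuffled against their stimulus coordinates and records the distance of
the resulting predicted optimum from the hypothesized one.

Both tests are one-tailed with smaller-is-better statistics and use the
add-one estimator p = (1 + #{null <= observed}) / (1 + n_permutations),
which never returns exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve

from .bayesopt import GpModel, KernelParams, kernel_matrix
from .grid import GridSpec
from .simloop import euclidean_distance
from .spsa import SpsaConfig, SpsaState

__all__ = [
    "PermutationTestResult",
    "permtest_convergence",
    "permtest_group_optimum",
]


@dataclass(frozen=True)
class PermutationTestResult:
    observed_statistic: float
    null_samples: np.ndarray
    p_value: float
    n_permutations: int
    statistic_kind: str


def _replay_spsa_batch(
    scores: np.ndarray,
    start_thetas: np.ndarray,
    spec: GridSpec,
    config: SpsaConfig,
    cap: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized SPSA-dynamics replay with externally supplied scores.

    ``scores`` has shape (n_runs, cap): the objective value consumed by
    each run at each iteration.  Returns the convergence iteration per
    run (``cap`` for runs that never converge within ``cap`` steps).
    """
    n_runs = scores.shape[0]
    theta = start_thetas.astype(float).copy()
    bounds_lo = np.array([1.0, 1.0])
    bounds_hi = np.array([float(spec.n_visual), float(spec.n_auditory)])
    streak = np.zeros(n_runs, dtype=int)  # consecutive iterations with unchanged theta
    conv_iter = np.full(n_runs, cap, dtype=int)
    active = np.ones(n_runs, dtype=bool)
    for k in range(cap):
        delta = rng.choice([-1.0, 1.0], size=(n_runs, 2))
        g_hat = scores[:, k : k + 1] / (2.0 * config.perturbation_c) * delta
        new_theta = np.clip(np.rint(theta + config.gain(k) * g_hat), bounds_lo, bounds_hi)
        same = np.all(new_theta == theta, axis=1)
        streak = np.where(same, streak + 1, 0)
        theta = new_theta
        just_converged = active & (streak >= config.convergence_k - 1)
        conv_iter[just_converged] = k + 1
        active &= ~just_converged
        if not active.any():
            break
    return conv_iter


def _observed_convergence(run, cap: int, null_mean: float, policy: str) -> float:
    converged = getattr(run, "converged", None)
    faulty = getattr(run, "faulty", False)
    n_iter = getattr(run, "iteration", None)
    if n_iter is None:
        n_iter = len(run.entries)
        converged = bool(run.config.get("converged", False)) if run.config else False
        faulty = bool(run.config.get("faulty", False)) if run.config else False
    if converged and not faulty:
        return float(n_iter)
    return float(cap) if policy == "cap" else float(null_mean)


def permtest_convergence(
    run_logs,
    spec: GridSpec,
    config: SpsaConfig | None = None,
    cap: int = 50,
    nonconverged_policy: str = "cap",
    statistic: str = "mean",
    n_perm: int = 10000,
    seed: int = 0,
) -> PermutationTestResult:
    """Permutation test of the SPSA convergence rate.

    ``run_logs`` may be :class:`~boldopt.spsa.SpsaState` objects or
    :class:`~boldopt.simloop.RunLog` records (with ``converged`` /
    ``faulty`` flags in their config).  The pooled objective values of
    all runs are randomly reassigned to iteration slots and the SPSA
    dynamics replayed for each permutation; a simulated run not
    converging within ``cap`` iterations scores ``cap``.  Runs that did
    not converge (or converged faultily) enter the observed statistic
    as ``cap`` under the conservative policy, or as the null mean under
    the liberal one.
    """
    if config is None:
        config = SpsaConfig()
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    if nonconverged_policy not in ("cap", "null_mean"):
        raise ValueError("nonconverged_policy must be 'cap' or 'null_mean'")
    runs = list(run_logs)
    if len(runs) < 2:
        raise ValueError("need at least two runs")
    pool = []
    for run in runs:
        if isinstance(run, SpsaState):
            pool.extend(h[3] for h in run.history)
        else:
            pool.extend(run.values())
    pool = np.asarray(pool, dtype=float)
    if pool.size == 0:
        raise ValueError("empty objective-value pool")
    n_runs = len(runs)
    rng = np.random.default_rng(seed)
    agg = np.mean if statistic == "mean" else np.median
    n_slots = n_runs * cap
    reps = int(np.ceil(n_slots / pool.size))
    positions = spec.positions()
    # every pooled value is used once per cycle through the pool; all
    # permutations are replayed in one vectorized batch
    keys = rng.random((n_perm, reps, pool.size))
    perms = pool[np.argsort(keys, axis=-1)].reshape(n_perm, -1)[:, :n_slots]
    scores = perms.reshape(n_perm * n_runs, cap)
    starts = positions[rng.integers(len(positions), size=n_perm * n_runs)]
    conv = _replay_spsa_batch(scores, starts, spec, config, cap, rng)
    null = agg(conv.reshape(n_perm, n_runs), axis=1)
    null_mean = float(null.mean())
    observed = agg(
        [_observed_convergence(r, cap, null_mean, nonconverged_policy) for r in runs]
    )
    p_value = (1.0 + np.sum(null <= observed)) / (1.0 + n_perm)
    return PermutationTestResult(
        observed_statistic=float(observed),
        null_samples=null,
        p_value=float(p_value),
        n_permutations=n_perm,
        statistic_kind=f"{statistic}_rate",
    )


def permtest_group_optimum(
    observations,
    hypothesized: tuple[int, int],
    params: KernelParams,
    spec: GridSpec,
    n_perm: int = 10000,
    seed: int = 0,
) -> PermutationTestResult:
    """Permutation test of the group-level predicted optimum.

    ``observations`` is a sequence of (coordinate, value) pairs pooled
    over runs/subjects.  The observed statistic is the Euclidean
    distance between the GP posterior-mean argmax over the grid and the
    hypothesized optimum.  The null shuffles values against coordinates
    and refits; since the coordinates (and hence the kernel matrix) are
    fixed, all permutations share one Cholesky factorization.
    """
    coords = np.array([np.asarray(c, dtype=float) for c, _ in observations])
    values = np.array([float(v) for _, v in observations])
    if len(values) < 6:
        raise ValueError("need at least six observations")
    if np.ptp(values) == 0:
        raise ValueError("degenerate observations: all values equal")
    model = GpModel(params=params, X=coords, y=values)
    cand = spec.positions().astype(float)
    Ks = kernel_matrix(cand, coords, params)

    def opt_distance(y_matrix: np.ndarray) -> np.ndarray:
        # y_matrix: (n_obs, m) column per permutation; flat mean via centering
        yc = y_matrix - y_matrix.mean(axis=0, keepdims=True)
        alpha = cho_solve(model._factor, yc)
        means = Ks @ alpha  # (n_cells, m); the added-back center is constant per column
        best = cand[np.argmax(means, axis=0)]
        return np.sqrt(((best - np.asarray(hypothesized, dtype=float)) ** 2).sum(axis=1))

    observed = float(opt_distance(values[:, None])[0])
    rng = np.random.default_rng(seed)
    perms = np.column_stack([rng.permutation(values) for _ in range(n_perm)])
    null = opt_distance(perms)
    p_value = (1.0 + np.sum(null <= observed)) / (1.0 + n_perm)
    return PermutationTestResult(
        observed_statistic=observed,
        null_samples=null,
        p_value=float(p_value),
        n_permutations=n_perm,
        statistic_kind="optimum_distance",
    )
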