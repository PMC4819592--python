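"""Discrete simultaneous-perturbation stochastic approximation (SPSA).

At each iteration the optimizer perturbs its current grid estimate
theta along a random +-1 direction in both dimensions, presents the two
perturbed stimulus combinations, and moves theta along the sign of the
comparative feedback.  The scalar feedback is the oriented t-contrast
from :func:`boldopt.objective.spsa_objective`: positive means the
plus-probe better matched the target brain state.

The run converges when the same theta is proposed on three consecutive
iterations and is capped at 14 iterations (the scan-time limit of a
10-minute run at 20 s per comparison, plus setup).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec

__all__ = ["SpsaConfig", "SpsaState", "propose_pair", "update", "run_spsa"]


@dataclass(frozen=True)
class SpsaConfig:
    """Gain sequence and stopping parameters.

    The step at iteration k (0-based) is a_k = a / (k + 1 + A)**decay_alpha
    with Spall's recommended decay exponent 0.602; the perturbation
    half-width c is a fixed integer number of grid cells.  Following
    Spall's guidance, the default gain a is scaled to the feedback: a
    typical decisive t-contrast (|t| ~ 5-15 for strong block-design
    sensory activation) then moves the estimate by one to three grid
    cells early in the run, while near-optimum comparisons (whose t is
    dominated by noise) round to a zero step and let the estimate hold.
    """

    step_gain_a: float = 1.5
    stability_A: float = 1.0
    decay_alpha: float = 0.602
    perturbation_c: int = 1
    max_iterations: int = 14
    convergence_k: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_gain_a <= 0 or self.perturbation_c < 1:
            raise ValueError("step gain and perturbation size must be positive")
        if not 0 < self.decay_alpha <= 1:
            raise ValueError("decay_alpha must lie in (0, 1]")
        if self.stability_A < 0 or self.max_iterations < 0 or self.convergence_k < 1:
            raise ValueError("invalid stopping parameters")

    def gain(self, iteration: int) -> float:
        return self.step_gain_a / (iteration + 1 + self.stability_A) ** self.decay_alpha


@dataclass
class SpsaState:
    """Trajectory of one SPSA run.

    ``chosen`` records, per iteration, the probe judged optimal by the
    feedback (the plus-probe for a positive score).  Convergence means
    the run proposed the same stimulus combination (theta) on
    ``convergence_k`` consecutive iterations.
    """

    theta: tuple[int, int]
    iteration: int = 0
    history: list = field(default_factory=list)  # (theta, (plus, minus), delta, score)
    chosen: list = field(default_factory=list)  # winning probe per iteration
    converged: bool = False
    faulty: bool = False
    pending: tuple | None = None  # (plus, minus, delta) awaiting a score


def _clip_probe(spec: GridSpec, theta: np.ndarray, delta: np.ndarray, c: int) -> tuple:
    plus = spec.clip(theta + c * delta)
    minus = spec.clip(theta - c * delta)
    return plus, minus


def propose_pair(
    state: SpsaState, config: SpsaConfig, spec: GridSpec, rng: np.random.Generator
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Draw a +-1 perturbation direction and return the two probe coordinates.

    Probes are clipped componentwise to the grid.  If clipping collapses
    the pair onto a single cell (possible in a corner), the direction is
    redrawn a bounded number of times, after which theta is nudged one
    cell toward the grid interior.
    """
    theta = np.asarray(state.theta)
    for _ in range(16):
        delta = rng.choice([-1, 1], size=2)
        plus, minus = _clip_probe(spec, theta, delta, config.perturbation_c)
        if plus != minus:
            state.pending = (plus, minus, tuple(int(d) for d in delta))
            return plus, minus
    # degenerate corner: move theta one cell inward and retry once
    center = np.array([(spec.n_visual + 1) / 2, (spec.n_auditory + 1) / 2])
    theta = theta + np.sign(center - theta).astype(int)
    state.theta = spec.clip(theta)
    delta = rng.choice([-1, 1], size=2)
    plus, minus = _clip_probe(spec, np.asarray(state.theta), delta, config.perturbation_c)
    state.pending = (plus, minus, tuple(int(d) for d in delta))
    return plus, minus


def update(
    state: SpsaState, config: SpsaConfig, spec: GridSpec, combined_score: float
) -> SpsaState:
    """Consume the comparative score for the pending probe pair.

    The simultaneous-perturbation gradient estimate is
    g_hat = score / (2c) * delta (delta has +-1 entries, so elementwise
    inversion equals delta itself); theta moves by a_k * g_hat, rounded
    and clipped to the grid.  The run is converged once the same theta
    has been proposed on ``convergence_k`` consecutive iterations.
    """
    if state.pending is None:
        raise RuntimeError("update() called before propose_pair()")
    plus, minus, delta = state.pending
    delta = np.asarray(delta, dtype=float)
    g_hat = combined_score / (2.0 * config.perturbation_c) * delta
    a_k = config.gain(state.iteration)
    new_theta = spec.clip(np.asarray(state.theta) + a_k * g_hat)
    state.history.append((state.theta, (plus, minus), tuple(int(d) for d in delta), combined_score))
    state.chosen.append(plus if combined_score > 0 else minus)
    state.theta = new_theta
    state.iteration += 1
    state.pending = None
    k = config.convergence_k
    thetas = [h[0] for h in state.history[-(k - 1):]] + [state.theta]
    if len(state.history) >= k - 1 and len(set(thetas)) == 1:
        state.converged = True
    return state


def run_spsa(
    objective_callback,
    spec: GridSpec,
    config: SpsaConfig | None = None,
    start: tuple[int, int] | None = None,
) -> SpsaState:
    """Run the closed loop until convergence or the iteration cap.

    ``objective_callback(plus, minus)`` must return either a float
    combined score or an object with a ``combined_score`` attribute
    (e.g. :class:`boldopt.objective.ComparisonResult`) for the pair of
    probe coordinates; positive means the plus-probe was closer to the
    target brain state.
    """
    config = config or SpsaConfig()
    rng = np.random.default_rng(config.seed)
    if start is None:
        pos = spec.positions()
        start_pos = pos[rng.integers(len(pos))]
        start = (int(start_pos[0]), int(start_pos[1]))
    state = SpsaState(theta=start)
    for _ in range(config.max_iterations):
        plus, minus = propose_pair(state, config, spec, rng)
        try:
            result = objective_callback(plus, minus)
        except Exception as exc:
            raise RuntimeError(
                f"objective callback failed at iteration {state.iteration + 1}"
            ) from exc
        score = getattr(result, "combined_score", result)
        update(state, config, spec, float(score))
        if state.converged:
            break
    return state
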