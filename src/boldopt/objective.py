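"""GLM-derived optimizer feedback from cleaned ROI windows.

Two scalar objectives feed the optimizers:

* Study 1 (SPSA) compares two successively presented stimuli within a
  20-TR window: each ROI gets an intercept + two-regressor GLM and a
  post-hoc t-contrast between the two stimulus betas.  The oriented t
  of larger magnitude decides which stimulus better matched the target
  brain state.
* Study 2 (Bayesian optimization) scores one stimulus per 10-TR window
  as the difference between occipital and temporal stimulus betas.

No autocorrelation correction is applied anywhere; betas are in raw
BOLD units (unit-height boxcars, unnormalized regressors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal import HrfKernel, RoiTimeSeries, double_gamma_hrf, make_regressor

__all__ = [
    "GlmFit",
    "ComparisonResult",
    "ObjectiveValue",
    "fit_glm",
    "t_contrast",
    "spsa_design",
    "bayes_design",
    "spsa_objective",
    "bayes_objective",
    "empirical_cnr",
]


@dataclass(frozen=True)
class GlmFit:
    """Ordinary-least-squares fit of one ROI window."""

    betas: np.ndarray
    residual_variance: float
    dof: int
    design: np.ndarray


@dataclass(frozen=True)
class ComparisonResult:
    """Study-1 feedback: which of two stimuli better evoked the target state.

    Both t-values are oriented so that positive favors the first
    stimulus; ``combined_score`` is the oriented t of larger absolute
    value and its sign picks the winner.
    """

    t_occipital: float
    t_temporal: float
    combined_score: float

    @property
    def winner(self) -> str:
        return "first" if self.combined_score > 0 else "second"


@dataclass(frozen=True)
class ObjectiveValue:
    """Study-2 feedback: occipital minus temporal stimulus beta."""

    value: float
    coordinate: tuple[int, int] | None = None


def fit_glm(values: np.ndarray, design: np.ndarray) -> GlmFit:
    """OLS regression of a window on a design matrix.

    Residual variance is RSS / dof with dof = n_points - n_regressors.
    """
    y = np.asarray(values, dtype=float)
    X = np.asarray(design, dtype=float)
    if y.ndim != 1 or X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("window length must match design rows")
    n, p = X.shape
    if n <= p:
        raise ValueError("need more time points than regressors")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    betas, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ betas
    dof = n - p
    return GlmFit(betas=betas, residual_variance=float(resid @ resid / dof), dof=dof, design=X)


def t_contrast(fit: GlmFit, contrast: np.ndarray) -> float:
    """t = c'b / sqrt(sigma^2 c'(X'X)^-1 c) for a contrast vector c."""
    c = np.asarray(contrast, dtype=float)
    if c.shape != fit.betas.shape:
        raise ValueError("contrast length must match number of betas")
    xtx_inv = np.linalg.inv(fit.design.T @ fit.design)
    denom = fit.residual_variance * (c @ xtx_inv @ c)
    if denom <= 0:
        raise ValueError("zero-variance t denominator")
    return float((c @ fit.betas) / np.sqrt(denom))


def spsa_design(
    n_points: int = 20,
    stim1_onset: int = 0,
    stim2_onset: int = 10,
    block_len_tr: int = 5,
    hrf: HrfKernel | None = None,
) -> np.ndarray:
    """Intercept + two stimulus regressors for the 20-TR comparison window.

    Default layout: stimulus 1 at TR 0, its baseline, stimulus 2 at TR
    10, its baseline — two 10 s blocks each followed by 10 s rest at
    TR = 2 s.
    """
    hrf = hrf or double_gamma_hrf()
    r1 = make_regressor([stim1_onset], block_len_tr, n_points, hrf)
    r2 = make_regressor([stim2_onset], block_len_tr, n_points, hrf)
    return np.column_stack([np.ones(n_points), r1, r2])


def bayes_design(
    n_points: int = 10,
    stim_onset: int = 0,
    block_len_tr: int = 5,
    hrf: HrfKernel | None = None,
) -> np.ndarray:
    """Intercept + one stimulus regressor for the 10-TR window."""
    hrf = hrf or double_gamma_hrf()
    r = make_regressor([stim_onset], block_len_tr, n_points, hrf)
    return np.column_stack([np.ones(n_points), r])


def spsa_objective(
    occ_window: RoiTimeSeries,
    temp_window: RoiTimeSeries,
    target_state: int = 1,
    design: np.ndarray | None = None,
) -> ComparisonResult:
    """Two-stimulus comparison from a pair of cleaned 20-TR ROI windows.

    Fits the intercept + two-regressor GLM per ROI, computes the
    t-contrast (stimulus 1 minus stimulus 2), orients each t so that
    positive favors stimulus 1 under the target state (the temporal t
    is negated for state 1, the occipital t for state 2), and takes
    whichever oriented t has larger magnitude as the combined score.
    """
    if target_state not in (1, 2):
        raise ValueError("target_state must be 1 or 2")
    design = spsa_design(n_points=len(occ_window)) if design is None else design
    contrast = np.array([0.0, 1.0, -1.0])
    t_occ = t_contrast(fit_glm(occ_window.values, design), contrast)
    t_temp = t_contrast(fit_glm(temp_window.values, design), contrast)
    if target_state == 1:
        t_occ_o, t_temp_o = t_occ, -t_temp
    else:
        t_occ_o, t_temp_o = -t_occ, t_temp
    combined = t_occ_o if abs(t_occ_o) >= abs(t_temp_o) else t_temp_o
    return ComparisonResult(
        t_occipital=t_occ_o, t_temporal=t_temp_o, combined_score=combined
    )


def bayes_objective(
    occ_window: RoiTimeSeries,
    temp_window: RoiTimeSeries,
    design: np.ndarray | None = None,
    coordinate: tuple[int, int] | None = None,
) -> ObjectiveValue:
    """Single-stimulus objective: occipital beta minus temporal beta."""
    design = bayes_design(n_points=len(occ_window)) if design is None else design
    b_occ = fit_glm(occ_window.values, design).betas[1]
    b_temp = fit_glm(temp_window.values, design).betas[1]
    return ObjectiveValue(value=float(b_occ - b_temp), coordinate=coordinate)


def empirical_cnr(
    objective_values,
    occ_series: RoiTimeSeries,
    temp_series: RoiTimeSeries,
) -> float:
    """Contrast-to-noise ratio of a recorded run.

    The mean absolute signal amplitude (|beta difference| per
    observation) divided by the mean standard deviation of the two ROI
    time series.  No autocorrelation correction is applied, so the
    estimate carries the corresponding bias.
    """
    values = np.asarray(
        [v.value if isinstance(v, ObjectiveValue) else float(v) for v in objective_values]
    )
    if values.size == 0:
        raise ValueError("need at least one objective value")
    sds = np.array([np.std(occ_series.values), np.std(temp_series.values)])
    if np.any(sds == 0):
        raise ValueError("zero-variance time series")
    return float(np.mean(np.abs(values)) / np.mean(sds))
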