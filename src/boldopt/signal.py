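"""HRF regressors, synthetic two-ROI BOLD series, and real-time cleaning.

The real-time pipeline extracts one mean BOLD value per TR from each
target region (occipital, temporal) and cleans the scalar series in two
causal stages: an exponential-moving-average (EMA) detrend that removes
slow scanner drift, followed by a scalar Kalman filter that suppresses
high-frequency noise and replaces large signal spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import gamma as gamma_dist

from .grid import GridSpec

__all__ = [
    "RoiTimeSeries",
    "HrfKernel",
    "CleanerState",
    "double_gamma_hrf",
    "make_regressor",
    "ema_step",
    "ema_detrend",
    "ema_time_constant",
    "ema_cutoff_hz",
    "init_cleaner",
    "kalman_step",
    "kalman_clean",
    "clean_series",
    "synth_bold",
]


def ema_time_constant(ema_alpha: float = 0.96, tr_seconds: float = 2.0) -> float:
    """Drift time constant of the EMA detrend, tau = -TR / ln(alpha) seconds.

    The recursive EMA is a first-order IIR low-pass whose impulse
    response decays as alpha**k; alpha = 0.96 at TR = 2 s gives
    tau = 49 s.
    """
    if not 0 < ema_alpha < 1 or tr_seconds <= 0:
        raise ValueError("need 0 < alpha < 1 and TR > 0")
    return -tr_seconds / np.log(ema_alpha)


def ema_cutoff_hz(ema_alpha: float = 0.96, tr_seconds: float = 2.0) -> float:
    """High-pass cut-off frequency implied by the EMA, 1/(2 pi tau) Hz."""
    return 1.0 / (2.0 * np.pi * ema_time_constant(ema_alpha, tr_seconds))


@dataclass(frozen=True)
class RoiTimeSeries:
    """Per-TR scalar BOLD signal for one region of interest."""

    values: np.ndarray
    tr_seconds: float = 2.0
    roi_label: str = "occipital"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("ROI time series must be one-dimensional")
        if not np.all(np.isfinite(values)):
            raise ValueError("ROI time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class HrfKernel:
    """Canonical double-gamma hemodynamic response, sampled at the TR."""

    samples: np.ndarray
    tr_seconds: float
    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    ratio: float = 6.0


def double_gamma_hrf(
    tr_seconds: float = 2.0,
    duration_s: float = 32.0,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    peak_disp_s: float = 1.0,
    undershoot_disp_s: float = 1.0,
    ratio: float = 6.0,
) -> HrfKernel:
    """Canonical double-gamma HRF (SPM convention: 6/16/1/1/6).

    The kernel is the difference of two gamma densities in time: a main
    lobe peaking ~5 s after onset and an undershoot scaled down by
    ``ratio``, sampled at the TR and normalized to unit peak.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    if duration_s < 24:
        raise ValueError("duration_s must cover the undershoot (>= 24 s)")
    t = np.arange(0.0, duration_s + 1e-9, tr_seconds)
    peak = gamma_dist.pdf(t, a=peak_delay_s / peak_disp_s, scale=peak_disp_s)
    under = gamma_dist.pdf(
        t, a=undershoot_delay_s / undershoot_disp_s, scale=undershoot_disp_s
    )
    samples = peak - under / ratio
    samples = samples / np.max(samples)
    return HrfKernel(
        samples=samples,
        tr_seconds=tr_seconds,
        peak_delay_s=peak_delay_s,
        undershoot_delay_s=undershoot_delay_s,
        ratio=ratio,
    )


def make_regressor(
    onsets_tr: list[int],
    block_len_tr: int,
    n_points: int,
    hrf: HrfKernel,
) -> np.ndarray:
    """Convolve a 0/1 stimulus boxcar with the HRF, truncated to the window.

    ``onsets_tr`` are 0-based TR indices of block starts within an
    ``n_points``-TR window; each block is ``block_len_tr`` TRs of
    height-1 boxcar.
    """
    if block_len_tr < 1:
        raise ValueError("block_len_tr must be >= 1")
    boxcar = np.zeros(n_points)
    for onset in onsets_tr:
        if not 0 <= onset < n_points:
            raise ValueError(f"onset {onset} outside [0, {n_points}) window")
        boxcar[onset : onset + block_len_tr] = 1.0
    return np.convolve(boxcar, hrf.samples)[:n_points]


@dataclass(frozen=True)
class CleanerState:
    """State of the causal EMA-detrend + Kalman-despike pipeline.

    ``ema_alpha`` is the EMA smoothing factor (0.96 at TR = 2 s gives a
    drift time constant of 49 s, i.e. a ~0.003 Hz high-pass).  The
    Kalman stage models the cleaned signal as a random walk observed in
    white noise; an innovation larger than ``spike_threshold`` times
    its predicted standard deviation is treated as a spike and replaced
    by the filter's one-step prediction.
    """

    ema_value: float = 0.0
    ema_alpha: float = 0.96
    ema_initialized: bool = False
    kalman_estimate: float = 0.0
    kalman_variance: float = 1.0
    kalman_initialized: bool = False
    process_var: float = 0.01
    measurement_var: float = 1.0
    spike_threshold: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 < self.ema_alpha < 1.0:
            raise ValueError("ema_alpha must lie in (0, 1)")
        if self.kalman_variance < 0:
            raise ValueError("kalman_variance must be nonnegative")
        if self.process_var <= 0 or self.measurement_var <= 0:
            raise ValueError("noise variances must be positive")
        if self.spike_threshold <= 0:
            raise ValueError("spike_threshold must be positive")


def init_cleaner(
    ema_alpha: float = 0.96,
    process_var: float = 0.01,
    measurement_var: float = 1.0,
    spike_threshold: float = 3.0,
) -> CleanerState:
    """Fresh cleaner state; EMA and Kalman stages self-initialize on the
    first sample they see (the EMA starts at the first sample, avoiding a
    start-up transient toward zero)."""
    return CleanerState(
        ema_alpha=ema_alpha,
        process_var=process_var,
        measurement_var=measurement_var,
        spike_threshold=spike_threshold,
    )


def ema_step(state: CleanerState, sample: float) -> tuple[float, CleanerState]:
    """One causal EMA detrending step: returns (sample - EMA, new state)."""
    if not state.ema_initialized:
        ema = float(sample)
    else:
        ema = state.ema_alpha * state.ema_value + (1.0 - state.ema_alpha) * sample
    new = replace(state, ema_value=ema, ema_initialized=True)
    return float(sample - ema), new


def kalman_step(
    state: CleanerState, sample: float
) -> tuple[float, CleanerState, bool]:
    """One scalar random-walk Kalman update with innovation-gated despiking.

    Returns (cleaned sample, new state, spike_flag).  When the
    innovation exceeds ``spike_threshold`` predicted SDs, the
    measurement is discarded: the update proceeds as if the prediction
    itself had been observed, so the spike never enters the estimate.
    """
    if not state.kalman_initialized:
        new = replace(
            state,
            kalman_estimate=float(sample),
            kalman_variance=state.measurement_var,
            kalman_initialized=True,
        )
        return float(sample), new, False
    pred = state.kalman_estimate
    pred_var = state.kalman_variance + state.process_var
    innovation = sample - pred
    innov_var = pred_var + state.measurement_var
    spike = abs(innovation) > state.spike_threshold * np.sqrt(innov_var)
    gain = pred_var / innov_var
    estimate = pred if spike else pred + gain * innovation
    variance = (1.0 - gain) * pred_var
    new = replace(state, kalman_estimate=float(estimate), kalman_variance=float(variance))
    return float(estimate), new, bool(spike)


def ema_detrend(values: np.ndarray, ema_alpha: float = 0.96) -> np.ndarray:
    """Apply the causal EMA detrend to a whole series."""
    state = init_cleaner(ema_alpha=ema_alpha)
    out = np.empty(len(values))
    for i, x in enumerate(np.asarray(values, dtype=float)):
        out[i], state = ema_step(state, x)
    return out


def kalman_clean(
    values: np.ndarray,
    process_var: float = None,
    measurement_var: float = None,
    spike_threshold: float = 3.0,
    calibration_len: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the despiking Kalman filter over a series.

    Unless given, the measurement variance defaults to the sample
    variance of the first ``calibration_len`` points and the process
    variance to 1% of it.  Returns (cleaned values, spike flags).
    """
    values = np.asarray(values, dtype=float)
    if measurement_var is None:
        window = values[: max(calibration_len, 2)]
        measurement_var = float(np.var(window)) or 1.0
    if process_var is None:
        process_var = 0.01 * measurement_var
    state = init_cleaner(
        process_var=process_var,
        measurement_var=measurement_var,
        spike_threshold=spike_threshold,
    )
    out = np.empty(len(values))
    flags = np.zeros(len(values), dtype=bool)
    for i, x in enumerate(values):
        out[i], state, flags[i] = kalman_step(state, x)
    return out, flags


def clean_series(series: RoiTimeSeries, ema_alpha: float = 0.96, **kalman_kwargs) -> RoiTimeSeries:
    """Stage-2 real-time cleaning: EMA detrend first, then Kalman despike."""
    detrended = ema_detrend(series.values, ema_alpha=ema_alpha)
    cleaned, _ = kalman_clean(detrended, **kalman_kwargs)
    return RoiTimeSeries(cleaned, tr_seconds=series.tr_seconds, roi_label=series.roi_label)


def synth_bold(
    spec: GridSpec,
    amplitudes: tuple[float, float],
    onsets_tr: list[int],
    block_len_tr: int,
    n_points: int,
    white_sd: float = 0.0,
    drift_amplitude: float = 0.0,
    drift_period_s: float = 300.0,
    spike_rate: float = 0.0,
    spike_amplitude: float = 5.0,
    tr_seconds: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> tuple[RoiTimeSeries, RoiTimeSeries]:
    """Generate synthetic occipital and temporal ROI series.

    Each series is amplitude x (boxcar * HRF) plus a slow sinusoidal
    drift, Gaussian white noise of SD ``white_sd``, and sparse spikes
    occurring independently per TR with probability ``spike_rate``.
    Identical seeds give identical output.
    """
    for name, value in (
        ("white_sd", white_sd),
        ("drift_amplitude", drift_amplitude),
        ("spike_rate", spike_rate),
    ):
        if value < 0:
            raise ValueError(f"{name} must be nonnegative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    hrf = double_gamma_hrf(tr_seconds=tr_seconds)
    regressor = make_regressor(onsets_tr, block_len_tr, n_points, hrf)
    t = np.arange(n_points) * tr_seconds
    out = []
    for amp, label in zip(amplitudes, ("occipital", "temporal")):
        drift = drift_amplitude * np.sin(2 * np.pi * t / drift_period_s + rng.uniform(0, 2 * np.pi))
        noise = rng.normal(0.0, white_sd, n_points) if white_sd > 0 else np.zeros(n_points)
        spikes = np.zeros(n_points)
        if spike_rate > 0:
            hit = rng.random(n_points) < spike_rate
            spikes[hit] = rng.choice([-1.0, 1.0], hit.sum()) * spike_amplitude
        out.append(
            RoiTimeSeries(
                amp * regressor + drift + noise + spikes,
                tr_seconds=tr_seconds,
                roi_label=label,
            )
        )
    return out[0], out[1]
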