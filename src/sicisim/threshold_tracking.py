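"""Proportional threshold tracking and the semi-logarithmic threshold estimator.

Thresholds (RMT_0.2mV, TS_1mV, conditioned thresholds) are never read off a
single staircase reversal.  Instead the stimulator output is adjusted
proportionally to the logarithmic error of each MEP relative to the target
amplitude, and the threshold is computed afterwards by a weighted
regression of log10(MEP) on stimulus intensity, restricted to the
log-linear 0.02--2 mV amplitude window: the threshold is the intensity at
which the fitted line crosses the target amplitude.

Tracking is deemed stable once six "valid" estimates have accumulated; an
estimate is valid when the MEP hits the target line within a 20% tracking
error on the log scale, or when two successive MEPs bracket it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .virtual_subject import ExcitabilityModel, generate_mep, sample_prestim_event

__all__ = [
    "TrialRecord",
    "ThresholdEstimate",
    "TrackerConfig",
    "proportional_step",
    "is_valid_estimate",
    "regression_threshold",
    "track_threshold",
]


@dataclass
class TrialRecord:
    """One delivered stimulus and its outcome."""

    trial_index: int
    condition: str  # ISI in ms as str, or "control" / "rmt" / "ts1mv"
    ts_intensity: float  # %MSO
    mep_mv: float
    cs_intensity: float | None = None  # %MSO, paired trials only
    gated: bool = False  # prestimulus contamination; excluded everywhere
    channel_id: str = ""
    cycle: int = 0
    time_s: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ts_intensity <= 100.0:
            raise ValueError("ts_intensity outside [0, 100] %MSO")
        if self.mep_mv < 0:
            raise ValueError("mep_mv must be non-negative")


@dataclass(frozen=True)
class ThresholdEstimate:
    """A regression-derived threshold in %MSO with its provenance."""

    value: float  # nan when invalid
    target_mep: float
    n_trials_used: int
    n_excluded: int
    valid: bool


@dataclass(frozen=True)
class TrackerConfig:
    """Tuning of the proportional tracker.

    ``gain`` is in %MSO per log10 unit of MEP error; by default it equals
    ``max_step`` so the maximum step is taken only for a >=10-fold miss.
    """

    target_mep: float = 0.2
    max_step: float = 2.0  # initial RMT/TS tracking; in-protocol channels use 1
    gain: float | None = None
    valid_estimates_required: int = 6
    tracking_error_tol: float = 0.2  # fractional, on log scale
    regression_window_mv: tuple[float, float] = (0.02, 2.0)
    prestim_gate_mv: float = 0.015
    max_trials: int = 100  # safety cap per tracked threshold

    def __post_init__(self) -> None:
        if self.max_step <= 0:
            raise ValueError("max_step must be positive")
        if not 0.0 < self.tracking_error_tol < 1.0:
            raise ValueError("tracking_error_tol must lie in (0, 1)")

    @property
    def effective_gain(self) -> float:
        return self.max_step if self.gain is None else self.gain


def proportional_step(
    current: float, observed_mep: float, cfg: TrackerConfig
) -> float:
    """Next stimulus intensity under proportional log-error control.

    The step is ``-gain * log10(observed/target)`` clipped to
    ``[-max_step, +max_step]``; the intensity is decreased, increased or
    unchanged when the MEP is above, below or on target, and always stays
    in [0, 100] %MSO.
    """
    obs = max(observed_mep, 1e-6)
    step = -cfg.effective_gain * math.log10(obs / cfg.target_mep)
    step = max(-cfg.max_step, min(cfg.max_step, step))
    return max(0.0, min(100.0, current + step))


def is_valid_estimate(
    prev_mep: float | None, cur_mep: float, cfg: TrackerConfig
) -> bool:
    """Whether the latest MEP hit or bracketed the target line.

    A hit is ``|log10(cur/target)| <= log10(1 + tol)``; a bracket is a sign
    change of the log error between the previous and current MEP.
    """
    cur_err = math.log10(cur_mep / cfg.target_mep)
    if abs(cur_err) <= math.log10(1.0 + cfg.tracking_error_tol):
        return True
    if prev_mep is None:
        return False
    prev_err = math.log10(prev_mep / cfg.target_mep)
    return (prev_err < 0 < cur_err) or (cur_err < 0 < prev_err)


def _tukey_irls_fit(x: np.ndarray, y: np.ndarray, n_iter: int = 3) -> tuple[float, float]:
    """Weighted straight-line fit, Tukey-biweight IRLS seeded by OLS.

    Returns (intercept, slope).  Points closer to the running fit get
    larger weights; with exact collinearity (zero residual scale) the OLS
    fit is returned unchanged.
    """
    slope, intercept = np.polyfit(x, y, 1)
    c = 4.685
    for _ in range(n_iter):
        resid = y - (intercept + slope * x)
        scale = 1.4826 * np.median(np.abs(resid))
        if scale <= 1e-12:
            break
        u = resid / (c * scale)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w.sum() <= 0 or np.count_nonzero(w) < 2:
            break
        sw = np.sqrt(w)
        A = np.column_stack([np.ones_like(x), x]) * sw[:, None]
        coef, *_ = np.linalg.lstsq(A, y * sw, rcond=None)
        if not np.isfinite(coef).all():
            break
        intercept, slope = float(coef[0]), float(coef[1])
    return float(intercept), float(slope)


def regression_threshold(
    trials: list[TrialRecord],
    target_mep: float,
    window: tuple[float, float] = (0.02, 2.0),
) -> ThresholdEstimate:
    """Threshold from the weighted semi-log regression of MEP on intensity.

    Gated trials and trials whose MEP lies outside the log-linear
    ``window`` are excluded.  The fit is log10(MEP) = a + b*intensity and
    the threshold is ``(log10(target) - a) / b``; fewer than two usable
    trials, a non-positive fitted slope, or a crossing outside
    [0, 100] %MSO yield an invalid estimate.
    """
    lo, hi = window
    usable = [t for t in trials if not t.gated and lo <= t.mep_mv <= hi]
    n_excluded = len(trials) - len(usable)
    if len(usable) < 2:
        return ThresholdEstimate(math.nan, target_mep, len(usable), n_excluded, False)
    x = np.array([t.ts_intensity for t in usable], dtype=float)
    y = np.log10([t.mep_mv for t in usable])
    if np.ptp(x) <= 0:
        return ThresholdEstimate(math.nan, target_mep, len(usable), n_excluded, False)
    intercept, slope = _tukey_irls_fit(x, y)
    if not math.isfinite(slope) or slope <= 0:
        return ThresholdEstimate(math.nan, target_mep, len(usable), n_excluded, False)
    value = (math.log10(target_mep) - intercept) / slope
    valid = 0.0 <= value <= 100.0
    return ThresholdEstimate(
        float(value) if valid else math.nan, target_mep, len(usable), n_excluded, valid
    )


def track_threshold(
    model: ExcitabilityModel,
    cfg: TrackerConfig,
    start_intensity: float,
    rng: np.random.Generator,
    condition: str = "rmt",
) -> tuple[ThresholdEstimate, list[TrialRecord]]:
    """Track one threshold until six valid estimates, then regress.

    Runs the proportional tracker from ``start_intensity``, counting valid
    estimates (hits or brackets); contaminated sweeps are recorded as
    gated and neither step the tracker nor count toward validity.  Stops
    once ``valid_estimates_required`` is reached or the safety cap on
    total trials; the estimate is the semi-log regression over all
    non-gated trials (invalid if the cap was hit without enough validity).
    """
    if not 0.0 <= start_intensity <= 100.0:
        raise ValueError("start_intensity outside [0, 100] %MSO")
    intensity = start_intensity
    prev_mep: float | None = None
    n_valid = 0
    trials: list[TrialRecord] = []
    converged = False
    for i in range(cfg.max_trials):
        contaminated, peak = sample_prestim_event(model, rng)
        gated = contaminated and peak > cfg.prestim_gate_mv
        mep = generate_mep(model, intensity, 0.0, rng)
        trials.append(
            TrialRecord(
                trial_index=i,
                condition=condition,
                ts_intensity=intensity,
                mep_mv=mep,
                gated=gated,
                channel_id=condition,
                time_s=5.0 * i,
            )
        )
        if gated:
            continue
        mep_eff = max(mep, model.mep_floor)
        if is_valid_estimate(prev_mep, mep_eff, cfg):
            n_valid += 1
        prev_mep = mep_eff
        intensity = proportional_step(intensity, mep_eff, cfg)
        if n_valid >= cfg.valid_estimates_required:
            converged = True
            break
    estimate = regression_threshold(trials, cfg.target_mep, cfg.regression_window_mv)
    if not converged:
        estimate = ThresholdEstimate(
            math.nan, cfg.target_mep, estimate.n_trials_used, estimate.n_excluded, False
        )
    return estimate, trials
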