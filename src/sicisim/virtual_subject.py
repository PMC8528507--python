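"""Virtual subjects for paired-pulse TMS simulation.

A virtual subject is a stochastic motor-evoked-potential (MEP) generator
built on the classic semi-logarithmic recruitment model: over roughly a
100-fold amplitude range (0.02--2 mV) the logarithm of the MEP amplitude
grows linearly with stimulus intensity (in % of maximum stimulator output,
%MSO).  The resting motor threshold RMT_0.2mV is defined as the intensity
at which the noise-free curve passes through 0.2 mV, the midpoint of that
log-linear interval.

A subthreshold conditioning stimulus delivered 1--7 ms before the test
stimulus shifts the recruitment curve along the intensity axis: inhibition
(ISIs 1--3 ms) shifts it rightward (a higher conditioned threshold),
facilitation (ISI 7 ms) leftward.  The shift ``delta`` is parameterised as
a percentage of the subject's true threshold, so that the threshold-tracked
SICI readout ``(conditioned threshold - RMT)/RMT * 100`` recovers it
directly, while the amplitude-ratio readout of the conventional protocol
follows ``100 * 10**(-slope_b * delta_abs)`` at a fixed test intensity.

Trial-to-trial variability is log-normal (additive Gaussian noise on
log10 amplitude), sessions carry a slowly varying excitability drift, and
sweeps are occasionally contaminated by prestimulus EMG activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "DEFAULT_ISIS",
    "DEFAULT_INHIBITION_PROFILE",
    "ExcitabilityModel",
    "CohortParams",
    "sample_cohort",
    "generate_mep",
    "sample_prestim_event",
    "delta_abs",
    "realize_examination",
]

#: Interstimulus intervals (ms) of both SICI protocols.
DEFAULT_ISIS: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 7.0)

#: Default group-mean threshold shift per ISI, as % of the true resting
#: threshold (positive = inhibition, negative = facilitation).  Values at
#: ISIs 1, 2.5 and 3 ms reflect typical threshold-tracked group means in
#: healthy subjects; the remaining ISIs interpolate the canonical SICI
#: curve with facilitation at 7 ms.
DEFAULT_INHIBITION_PROFILE: dict[float, float] = {
    1.0: 10.3,
    1.5: 8.0,
    2.0: 7.0,
    2.5: 7.5,
    3.0: 5.5,
    3.5: 4.0,
    4.0: 2.0,
    5.0: 0.0,
    7.0: -4.0,
}

# Log-linear portion of the recruitment curve (mV).
_LIN_LO_MV = 0.02
_LIN_HI_MV = 2.0
_LOG_LIN_LO = math.log10(_LIN_LO_MV)
_LOG_LIN_HI = math.log10(_LIN_HI_MV)
_TARGET_MV = 0.2


class ConfigurationError(ValueError):
    """Invalid cohort or model configuration."""


@dataclass(frozen=True)
class ExcitabilityModel:
    """True (latent) corticomotor excitability of one virtual subject.

    Parameters
    ----------
    theta_true
        True resting threshold in %MSO: the intensity at which the
        noise-free recruitment curve equals 0.2 mV exactly.
    slope_b
        Recruitment slope in log10(mV) per %MSO; must be positive.
    sigma_log
        SD of trial-to-trial MEP variability in log10(mV) units.
    mep_floor, mep_ceiling
        Baseline noise amplitude and saturation amplitude (mV).  The curve
        is exactly linear (in log10) between 0.02 and 2 mV and saturates
        smoothly toward these bounds outside that window.
    inhibition_profile
        Map ISI (ms) -> true conditioned threshold shift, % of
        ``theta_true`` (positive = inhibition).
    inhibition_sd_within
        SD of an independent per-ISI, per-examination fluctuation of the
        shift (% of ``theta_true``), emulating physiological SICI
        variability between examinations.
    session_drift_sd
        SD (%MSO) of a per-examination additive shift of ``theta_true``.
    contamination_rate
        Per-sweep probability of a prestimulus EMG event.
    contamination_amp_mv
        Mean of the exponential distribution of contamination peak
        amplitudes (mV).
    """

    theta_true: float
    slope_b: float = 0.065
    sigma_log: float = 0.2
    mep_floor: float = 0.005
    mep_ceiling: float = 5.0
    inhibition_profile: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_INHIBITION_PROFILE)
    )
    inhibition_sd_within: float = 2.5
    session_drift_sd: float = 1.5
    contamination_rate: float = 0.02
    contamination_amp_mv: float = 0.03

    def __post_init__(self) -> None:
        if self.slope_b <= 0:
            raise ConfigurationError("slope_b must be positive")
        if self.sigma_log < 0:
            raise ConfigurationError("sigma_log must be non-negative")
        if not (self.mep_floor < _LIN_LO_MV and _LIN_HI_MV <= self.mep_ceiling):
            raise ConfigurationError(
                "mep_floor must lie below 0.02 mV and mep_ceiling at or above 2 mV"
            )


@dataclass(frozen=True)
class CohortParams:
    """Population distribution from which virtual subjects are drawn.

    Between-subject inhibition variability has two components: a shared
    multiplicative inhibition-strength factor per subject
    (``Normal(1, inhibition_scale_sd)``) scaling the whole profile, plus
    independent per-ISI additive wiggle
    (``Normal(0, inhibition_profile_sd_between)`` %RMT).  The shared factor
    makes a weakly inhibited subject weak at every ISI, matching the
    subject-level concordance seen in real SICI curves.
    """

    n_subjects: int = 18
    rmt_mean: float = 55.2
    rmt_sd: float = 8.4
    slope_mean: float = 0.065
    slope_sd: float = 0.012
    sigma_log_mean: float = 0.2
    inhibition_profile_mean: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_INHIBITION_PROFILE)
    )
    inhibition_profile_sd_between: float = 2.0
    inhibition_scale_sd: float = 0.55
    inhibition_sd_within: float = 2.5
    session_drift_sd: float = 1.5
    contamination_rate: float = 0.02
    contamination_amp_mv: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be at least 1")
        for name in (
            "rmt_sd",
            "slope_sd",
            "sigma_log_mean",
            "inhibition_profile_sd_between",
            "inhibition_scale_sd",
            "inhibition_sd_within",
            "session_drift_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not 0 <= self.contamination_rate <= 1:
            raise ConfigurationError("contamination_rate must lie in [0, 1]")


# Thresholds are truncated so that a 120% RMT test stimulus stays
# deliverable within stimulator power.
_THETA_LO, _THETA_HI = 20.0, 95.0


def sample_cohort(params: CohortParams) -> list[ExcitabilityModel]:
    """Draw a cohort of virtual subjects, deterministically from the seed.

    Thresholds come from Normal(rmt_mean, rmt_sd) truncated to
    [20, 95] %MSO; recruitment slopes from a positive-truncated normal.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_subjects

    if params.rmt_sd > 0:
        a = (_THETA_LO - params.rmt_mean) / params.rmt_sd
        b = (_THETA_HI - params.rmt_mean) / params.rmt_sd
        thetas = stats.truncnorm.rvs(
            a, b, loc=params.rmt_mean, scale=params.rmt_sd, size=n, random_state=rng
        )
    else:
        thetas = np.full(n, float(np.clip(params.rmt_mean, _THETA_LO, _THETA_HI)))

    if params.slope_sd > 0:
        a = (1e-3 - params.slope_mean) / params.slope_sd
        slopes = stats.truncnorm.rvs(
            a, np.inf, loc=params.slope_mean, scale=params.slope_sd, size=n,
            random_state=rng,
        )
    else:
        slopes = np.full(n, params.slope_mean)

    scales = rng.normal(1.0, params.inhibition_scale_sd, size=n)
    isis = sorted(params.inhibition_profile_mean)
    wiggle = rng.normal(0.0, params.inhibition_profile_sd_between, size=(n, len(isis)))

    cohort = []
    for i in range(n):
        profile = {
            isi: scales[i] * params.inhibition_profile_mean[isi] + wiggle[i, j]
            for j, isi in enumerate(isis)
        }
        cohort.append(
            ExcitabilityModel(
                theta_true=float(thetas[i]),
                slope_b=float(slopes[i]),
                sigma_log=params.sigma_log_mean,
                inhibition_profile=profile,
                inhibition_sd_within=params.inhibition_sd_within,
                session_drift_sd=params.session_drift_sd,
                contamination_rate=params.contamination_rate,
                contamination_amp_mv=params.contamination_amp_mv,
            )
        )
    return cohort


def _soft_clamp_log(x: float, log_floor: float, log_ceiling: float) -> float:
    """Clamp a log10 amplitude smoothly to [log_floor, log_ceiling].

    Identity on the log-linear window [log10(0.02), log10(2)]; outside it
    the curve saturates exponentially toward the floor/ceiling with a C1
    join, so regression over in-window points is never distorted.
    """
    if x > _LOG_LIN_HI:
        span = log_ceiling - _LOG_LIN_HI
        if span <= 0:
            return log_ceiling
        return _LOG_LIN_HI + span * (1.0 - math.exp(-(x - _LOG_LIN_HI) / span))
    if x < _LOG_LIN_LO:
        span = _LOG_LIN_LO - log_floor
        return _LOG_LIN_LO - span * (1.0 - math.exp(-(_LOG_LIN_LO - x) / span))
    return x


def generate_mep(
    model: ExcitabilityModel,
    intensity: float,
    delta_shift: float = 0.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Simulate one MEP amplitude (mV) for a (conditioned) stimulus.

    The noise-free core is ``log10(MEP) = log10(0.2) +
    slope_b * (intensity - delta_shift - theta_true)`` clamped smoothly to
    [mep_floor, mep_ceiling]; conditioning enters only through
    ``delta_shift`` (%MSO), a shift of the curve along the intensity axis.
    Log-normal trial noise (SD ``sigma_log`` in log10 space) is applied
    when an ``rng`` is given.
    """
    if not 0.0 <= intensity <= 100.0:
        raise ValueError(f"intensity {intensity} outside [0, 100] %MSO")
    x = math.log10(_TARGET_MV) + model.slope_b * (
        intensity - delta_shift - model.theta_true
    )
    y = _soft_clamp_log(x, math.log10(model.mep_floor), math.log10(model.mep_ceiling))
    if rng is not None and model.sigma_log > 0:
        y += rng.normal(0.0, model.sigma_log)
    return 10.0 ** y


def sample_prestim_event(
    model: ExcitabilityModel, rng: np.random.Generator
) -> tuple[bool, float]:
    """Draw the prestimulus EMG state of one sweep.

    Returns ``(contaminated, peak_mv)``; the peak is exponential with mean
    ``contamination_amp_mv`` when contaminated, else 0.
    """
    if model.contamination_rate > 0 and rng.random() < model.contamination_rate:
        return True, float(rng.exponential(model.contamination_amp_mv))
    return False, 0.0


def delta_abs(model: ExcitabilityModel, isi: float) -> float:
    """Absolute conditioned threshold shift (%MSO) at one ISI."""
    try:
        pct = model.inhibition_profile[isi]
    except KeyError:
        raise KeyError(f"no inhibition profile entry for ISI {isi} ms") from None
    return pct / 100.0 * model.theta_true


def realize_examination(
    model: ExcitabilityModel, rng: np.random.Generator
) -> ExcitabilityModel:
    """Snapshot the subject's state for one examination.

    Draws the session excitability drift (added to ``theta_true``) and the
    per-ISI within-subject SICI fluctuation, returning an effective model
    whose ``session_drift_sd`` and ``inhibition_sd_within`` are zeroed so
    the snapshot is not re-drawn downstream.
    """
    drift = rng.normal(0.0, model.session_drift_sd) if model.session_drift_sd > 0 else 0.0
    if model.inhibition_sd_within > 0:
        profile = {
            isi: d + rng.normal(0.0, model.inhibition_sd_within)
            for isi, d in model.inhibition_profile.items()
        }
    else:
        profile = dict(model.inhibition_profile)
    return replace(
        model,
        theta_true=model.theta_true + drift,
        inhibition_profile=profile,
        session_drift_sd=0.0,
        inhibition_sd_within=0.0,
    )
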