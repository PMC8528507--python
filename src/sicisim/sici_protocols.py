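"""One complete T-SICI or A-SICI examination on a virtual subject.

Both protocols deliver nine conditioned-stimulus conditions (ISIs 1--7 ms)
ten times each plus thirty control stimuli, in ten pseudorandomised cycles
of the twelve conditions.

T-SICI (threshold tracking): the test stimulus of each ISI condition is
tracked independently in 1 %MSO steps (doubled after two consecutive
same-side misses) toward the 0.2 mV target, while RMT_0.2mV is tracked
concurrently on three control channels; the conditioning stimulus is 70%
of the running control-channel RMT average, updated after every cycle.
The readout per ISI is the relative rise of the regression-derived
conditioned threshold over RMT: positive = inhibition.

A-SICI (automated conventional): all intensities are frozen at the start
(CS = 70% RMT_0.2mV, TS = TS_1mV) and the readout is the geometric-mean
conditioned/control MEP amplitude ratio: below 100% = inhibition.

Sweeps with prestimulus EMG contamination above 15 uV are discarded and
redelivered at the end of the current cycle so per-condition counts stay
fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gmean

from .threshold_tracking import (
    TrackerConfig,
    TrialRecord,
    ThresholdEstimate,
    proportional_step,
    regression_threshold,
)
from .virtual_subject import (
    DEFAULT_ISIS,
    ExcitabilityModel,
    delta_abs,
    generate_mep,
    sample_prestim_event,
)

__all__ = [
    "ProtocolConfig",
    "ExaminationResult",
    "BAND_1_3_5",
    "BAND_1_7",
    "build_schedule",
    "gate_prestimulus",
    "compute_t_sici",
    "compute_a_sici",
    "run_t_sici",
    "run_a_sici",
]

CONTROL = "control"

#: ISI bands conventionally reported as averages.
BAND_1_3_5: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5)
BAND_1_7: tuple[float, ...] = DEFAULT_ISIS


@dataclass(frozen=True)
class ProtocolConfig:
    """Shared layout of both SICI protocols."""

    isis: tuple[float, ...] = DEFAULT_ISIS
    reps_per_isi: int = 10
    control_reps: int = 30
    cs_fraction: float = 0.70  # of RMT_0.2mV
    ts_init_fraction: float = 1.20  # of RMT_0.2mV, T-SICI starting TS
    channel_step: float = 1.0  # %MSO, in-protocol tracking
    target_mep: float = 0.2  # mV, T-SICI tracked target
    tracking_error_tol: float = 0.2
    regression_window_mv: tuple[float, float] = (0.02, 2.0)
    prestim_gate_mv: float = 0.015
    prestim_window_ms: float = 270.0  # metadata: gating window before stimulus
    online_gate_uv: float = 15.0  # metadata: equivalent online gate
    max_redelivery_factor: int = 2  # cap on redeliveries, x scheduled length

    def __post_init__(self) -> None:
        if self.control_reps != 3 * self.reps_per_isi:
            raise ValueError("control_reps must equal 3 cycles' worth (3 * reps_per_isi)")

    @property
    def controls_per_cycle(self) -> int:
        return self.control_reps // self.reps_per_isi


@dataclass
class ExaminationResult:
    """All per-ISI SICI values plus the thresholds of one examination."""

    protocol: str  # "T" or "A"
    rmt_0_2: float
    per_isi: dict[float, float]
    band_1_3_5: float
    band_1_7: float
    ts_1mv: float | None = None
    trials: list[TrialRecord] = field(default_factory=list)
    gated_count: int = 0


def build_schedule(
    cfg: ProtocolConfig, rng: np.random.Generator
) -> list[tuple[int, object]]:
    """Pseudorandomised condition order: ``(cycle, condition)`` pairs.

    Each of ``reps_per_isi`` cycles is an independent permutation of the
    twelve conditions (nine ISIs + three control slots), so every ISI
    appears ``reps_per_isi`` times and control ``control_reps`` times.
    """
    conditions: list[object] = list(cfg.isis) + [CONTROL] * cfg.controls_per_cycle
    schedule = []
    for cycle in range(cfg.reps_per_isi):
        order = rng.permutation(len(conditions))
        schedule.extend((cycle, conditions[i]) for i in order)
    return schedule


def gate_prestimulus(peak_mv: float, cfg: ProtocolConfig) -> bool:
    """Keep the sweep unless the prestimulus EMG peak exceeds the gate."""
    if peak_mv < 0:
        raise ValueError("peak_mv must be non-negative")
    return peak_mv <= cfg.prestim_gate_mv


def compute_t_sici(conditioned_threshold: float, rmt: float) -> float:
    """T-SICI = (conditioned threshold - RMT)/RMT * 100 (% of RMT).

    Positive values reflect inhibition, negative facilitation.
    """
    if rmt <= 0:
        raise ValueError("rmt must be positive")
    return (conditioned_threshold - rmt) / rmt * 100.0


def compute_a_sici(
    conditioned_meps: list[float], control_meps: list[float]
) -> float:
    """A-SICI = 100 * geomean(conditioned) / geomean(control) (% of control).

    Values below 100% reflect inhibition, above 100% facilitation; empty
    lists after gating yield a missing value (nan).
    """
    if not conditioned_meps or not control_meps:
        return math.nan
    if min(conditioned_meps) <= 0 or min(control_meps) <= 0:
        raise ValueError("MEP amplitudes must be positive after gating")
    return 100.0 * float(gmean(conditioned_meps)) / float(gmean(control_meps))


class _SteppedChannel:
    """Fixed-step tracker of one conditioned-ISI test stimulus.

    Steps 1 %MSO toward the target, doubling the step after two
    consecutive misses (outside the 20% log tolerance) on the same side;
    the doubling state resets whenever the MEP lands within tolerance.
    """

    def __init__(self, intensity: float, cfg: ProtocolConfig):
        self.intensity = intensity
        self._cfg = cfg
        self._last_miss_side = 0  # -1 below target, +1 above, 0 no live miss

    def update(self, mep_mv: float) -> None:
        cfg = self._cfg
        err = math.log10(max(mep_mv, 1e-6) / cfg.target_mep)
        missed = abs(err) > math.log10(1.0 + cfg.tracking_error_tol)
        side = 1 if err > 0 else (-1 if err < 0 else 0)
        if missed and side == self._last_miss_side:
            step = 2.0 * cfg.channel_step
        else:
            step = cfg.channel_step
        self._last_miss_side = side if missed else 0
        self.intensity = max(0.0, min(100.0, self.intensity - side * step))


def _deliver(
    model: ExcitabilityModel,
    cfg: ProtocolConfig,
    rng: np.random.Generator,
    ts_intensity: float,
    delta: float,
) -> tuple[float, bool]:
    """One sweep: returns (mep_mv, gated)."""
    contaminated, peak = sample_prestim_event(model, rng)
    gated = not gate_prestimulus(peak if contaminated else 0.0, cfg)
    mep = generate_mep(model, ts_intensity, delta, rng)
    return mep, gated


def _t_band(per_isi: dict[float, float], members: tuple[float, ...]) -> float:
    vals = [per_isi[i] for i in members if i in per_isi and math.isfinite(per_isi[i])]
    return float(np.mean(vals)) if vals else math.nan


def run_t_sici(
    model: ExcitabilityModel,
    rmt_estimate: float,
    cfg: ProtocolConfig,
    rng: np.random.Generator,
) -> ExaminationResult:
    """Execute one threshold-tracking SICI examination.

    Nine conditioned channels start at 120% of the incoming RMT estimate
    and are stepped toward the 0.2 mV target; three control channels track
    RMT_0.2mV with 1 %MSO proportional steps.  After each cycle the CS is
    recomputed as ``cs_fraction`` times the mean of the three
    control-channel regression estimates.  Per-ISI thresholds and the
    examination RMT come from the semi-log regression; an invalid
    conditioned regression yields a missing value for that ISI.
    """
    if not math.isfinite(rmt_estimate) or rmt_estimate <= 0:
        raise ValueError("run_t_sici requires a valid RMT estimate")
    ctrl_cfg = TrackerConfig(
        target_mep=cfg.target_mep,
        max_step=cfg.channel_step,
        tracking_error_tol=cfg.tracking_error_tol,
        regression_window_mv=cfg.regression_window_mv,
        prestim_gate_mv=cfg.prestim_gate_mv,
    )
    channels = {
        isi: _SteppedChannel(min(100.0, cfg.ts_init_fraction * rmt_estimate), cfg)
        for isi in cfg.isis
    }
    ctrl_intensity = [min(100.0, rmt_estimate)] * cfg.controls_per_cycle
    ctrl_trials: dict[int, list[TrialRecord]] = {
        i: [] for i in range(cfg.controls_per_cycle)
    }
    cond_trials: dict[float, list[TrialRecord]] = {isi: [] for isi in cfg.isis}
    all_trials: list[TrialRecord] = []
    cs_intensity = min(100.0, cfg.cs_fraction * rmt_estimate)
    gated_count = 0
    trial_index = 0
    max_total = cfg.max_redelivery_factor * cfg.reps_per_isi * (
        len(cfg.isis) + cfg.controls_per_cycle
    )

    base_schedule = build_schedule(cfg, rng)
    by_cycle: dict[int, list[object]] = {}
    for cycle, cond in base_schedule:
        by_cycle.setdefault(cycle, []).append(cond)

    for cycle in sorted(by_cycle):
        queue = list(by_cycle[cycle])
        ctrl_slot = 0
        slot_of: dict[int, int] = {}  # queue position bookkeeping not needed; track per trial
        qi = 0
        while qi < len(queue):
            cond = queue[qi]
            qi += 1
            if trial_index >= max_total:
                break
            if cond == CONTROL:
                ch = ctrl_slot % cfg.controls_per_cycle
                ctrl_slot += 1
                inten = ctrl_intensity[ch]
                mep, gated = _deliver(model, cfg, rng, inten, 0.0)
                rec = TrialRecord(
                    trial_index, CONTROL, inten, mep, cs_intensity=None,
                    gated=gated, channel_id=f"control{ch}", cycle=cycle,
                    time_s=5.0 * trial_index,
                )
                all_trials.append(rec)
                trial_index += 1
                if gated:
                    gated_count += 1
                    ctrl_slot -= 1  # redelivery reuses the same channel slot
                    queue.append(CONTROL)
                    continue
                ctrl_trials[ch].append(rec)
                ctrl_intensity[ch] = proportional_step(
                    inten, max(mep, model.mep_floor), ctrl_cfg
                )
            else:
                isi = float(cond)
                chan = channels[isi]
                delta = delta_abs(model, isi)
                mep, gated = _deliver(model, cfg, rng, chan.intensity, delta)
                rec = TrialRecord(
                    trial_index, f"{isi:g}", chan.intensity, mep,
                    cs_intensity=cs_intensity, gated=gated,
                    channel_id=f"isi{isi:g}", cycle=cycle,
                    time_s=5.0 * trial_index,
                )
                all_trials.append(rec)
                trial_index += 1
                if gated:
                    gated_count += 1
                    queue.append(cond)
                    continue
                cond_trials[isi].append(rec)
                chan.update(mep)
        # CS follows the running control-channel RMT average.
        estimates = []
        for ch in range(cfg.controls_per_cycle):
            est = regression_threshold(
                ctrl_trials[ch], cfg.target_mep, cfg.regression_window_mv
            )
            estimates.append(est.value if est.valid else ctrl_intensity[ch])
        cs_intensity = min(100.0, cfg.cs_fraction * float(np.mean(estimates)))

    rmt_est = regression_threshold(
        [t for ts in ctrl_trials.values() for t in ts],
        cfg.target_mep,
        cfg.regression_window_mv,
    )
    rmt = rmt_est.value if rmt_est.valid else rmt_estimate
    per_isi: dict[float, float] = {}
    for isi in cfg.isis:
        est = regression_threshold(
            cond_trials[isi], cfg.target_mep, cfg.regression_window_mv
        )
        per_isi[isi] = compute_t_sici(est.value, rmt) if est.valid else math.nan
    return ExaminationResult(
        protocol="T",
        rmt_0_2=rmt,
        per_isi=per_isi,
        band_1_3_5=_t_band(per_isi, BAND_1_3_5),
        band_1_7=_t_band(per_isi, BAND_1_7),
        trials=all_trials,
        gated_count=gated_count,
    )


def run_a_sici(
    model: ExcitabilityModel,
    rmt_estimate: float,
    ts1mv_estimate: float,
    cfg: ProtocolConfig,
    rng: np.random.Generator,
) -> ExaminationResult:
    """Execute one automated conventional SICI examination.

    Intensities are fixed for the whole examination (CS = 70% of the RMT
    estimate, TS = TS_1mV); per-ISI A-SICI is the geometric-mean amplitude
    ratio over the ten conditioned and thirty control sweeps, and band
    values pool the per-sweep data of the member ISIs.
    """
    for v, name in ((rmt_estimate, "RMT"), (ts1mv_estimate, "TS_1mV")):
        if not math.isfinite(v) or v <= 0:
            raise ValueError(f"run_a_sici requires a valid {name} estimate")
    cs_intensity = min(100.0, cfg.cs_fraction * rmt_estimate)
    ts_intensity = min(100.0, ts1mv_estimate)
    cond_meps: dict[float, list[float]] = {isi: [] for isi in cfg.isis}
    control_meps: list[float] = []
    all_trials: list[TrialRecord] = []
    gated_count = 0
    trial_index = 0
    max_total = cfg.max_redelivery_factor * cfg.reps_per_isi * (
        len(cfg.isis) + cfg.controls_per_cycle
    )

    base_schedule = build_schedule(cfg, rng)
    by_cycle: dict[int, list[object]] = {}
    for cycle, cond in base_schedule:
        by_cycle.setdefault(cycle, []).append(cond)

    for cycle in sorted(by_cycle):
        queue = list(by_cycle[cycle])
        qi = 0
        while qi < len(queue):
            cond = queue[qi]
            qi += 1
            if trial_index >= max_total:
                break
            is_control = cond == CONTROL
            delta = 0.0 if is_control else delta_abs(model, float(cond))
            mep, gated = _deliver(model, cfg, rng, ts_intensity, delta)
            rec = TrialRecord(
                trial_index,
                CONTROL if is_control else f"{float(cond):g}",
                ts_intensity,
                mep,
                cs_intensity=None if is_control else cs_intensity,
                gated=gated,
                channel_id=CONTROL if is_control else f"isi{float(cond):g}",
                cycle=cycle,
                time_s=5.0 * trial_index,
            )
            all_trials.append(rec)
            trial_index += 1
            if gated:
                gated_count += 1
                queue.append(cond)
                continue
            if is_control:
                control_meps.append(mep)
            else:
                cond_meps[float(cond)].append(mep)

    per_isi = {
        isi: compute_a_sici(cond_meps[isi], control_meps) for isi in cfg.isis
    }

    def band(members: tuple[float, ...]) -> float:
        pooled = [m for isi in members for m in cond_meps.get(isi, [])]
        return compute_a_sici(pooled, control_meps)

    return ExaminationResult(
        protocol="A",
        rmt_0_2=rmt_estimate,
        ts_1mv=ts1mv_estimate,
        per_isi=per_isi,
        band_1_3_5=band(BAND_1_3_5),
        band_1_7=band(BAND_1_7),
        trials=all_trials,
        gated_count=gated_count,
    )
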