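"""Full test-retest study on a simulated cohort.

The design mirrors a four-session reliability study: two days (5--7 days
apart), morning and afternoon sessions on each day, and two examinations
per protocol per session by observer 1 — eight intraobserver examinations
per subject per protocol — plus one additional examination per protocol by
a second observer in one session, for nine in total.  Every examination
re-estimates RMT_0.2mV (and TS_1mV before the conventional protocol) by
threshold tracking before the SICI protocol runs.

``summarize_reliability`` computes per-parameter coefficients of
repeatability for each session, intraday / interday / interobserver
ICC(2,1), repeated-measures ANOVA over the eight examinations and paired
observer tests; ``summarize_group_curves`` produces the group SICI-vs-ISI
curves, per-ISI one-sample tests against the control condition and the
inter-method regression of T-SICI on log10 A-SICI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .reliability_stats import (
    MeasurementMatrix,
    classify_icc,
    coefficient_of_repeatability,
    icc_2_1,
    method_regression,
    one_sample_condition_test,
    paired_t,
    rm_anova,
)
from .sici_protocols import (
    BAND_1_3_5,
    BAND_1_7,
    ExaminationResult,
    ProtocolConfig,
    run_a_sici,
    run_t_sici,
)
from .threshold_tracking import TrackerConfig, regression_threshold, track_threshold
from .virtual_subject import (
    CohortParams,
    ExcitabilityModel,
    realize_examination,
    sample_cohort,
)

__all__ = [
    "StudyDesign",
    "StudyDataset",
    "ExamKey",
    "run_study",
    "summarize_reliability",
    "summarize_group_curves",
    "write_study",
    "load_study",
]

SESSIONS = ("morning", "afternoon")
PROTOCOLS = ("T", "A")

#: Parameters summarised per protocol: selected single ISIs, bands and
#: thresholds.  A-SICI parameters are analysed on the log10 scale.
REPORT_ISIS = (1.0, 2.5, 3.0)


@dataclass(frozen=True)
class StudyDesign:
    days: int = 2
    sessions_per_day: int = 2
    exams_per_session: int = 2  # per protocol, observer 1
    interobserver_day: int = 1
    interobserver_session: str = "afternoon"
    interday_gap_days: tuple[int, int] = (5, 7)  # metadata only
    observer_offset_sd: float = 0.0  # %MSO, additive on tracked intensities
    rmt_start_intensity: float = 60.0  # %MSO, tracking start

    @property
    def intraobserver_exams(self) -> int:
        return self.days * self.sessions_per_day * self.exams_per_session

    @property
    def total_exams_per_protocol(self) -> int:
        return self.intraobserver_exams + 1


@dataclass(frozen=True)
class ExamKey:
    subject: int
    observer: int
    day: int
    session: str
    exam_index: int  # within (session, protocol), 1-based
    protocol: str


@dataclass
class StudyDataset:
    examinations: dict[ExamKey, ExaminationResult | None]
    cohort: list[ExcitabilityModel]
    design: StudyDesign
    protocol_cfg: ProtocolConfig
    seed: int

    def get(self, **query) -> list[tuple[ExamKey, ExaminationResult]]:
        out = []
        for key, res in self.examinations.items():
            if res is None:
                continue
            if all(getattr(key, k) == v for k, v in query.items()):
                out.append((key, res))
        return out

    def parameter_value(self, res: ExaminationResult, parameter: str) -> float:
        """Extract one named parameter from an examination result."""
        if parameter == "RMT":
            return res.rmt_0_2
        if parameter == "TS_1mV":
            return res.ts_1mv if res.ts_1mv is not None else math.nan
        if parameter == "band_1_3.5":
            return res.band_1_3_5
        if parameter == "band_1_7":
            return res.band_1_7
        return res.per_isi.get(float(parameter), math.nan)


def _run_one_examination(
    model: ExcitabilityModel,
    protocol: str,
    cfg: ProtocolConfig,
    design: StudyDesign,
    rng: np.random.Generator,
    observer_offset: float,
) -> ExaminationResult | None:
    """Threshold estimation plus one protocol run; None when tracking fails."""
    eff = realize_examination(model, rng)
    if observer_offset:
        eff = replace(eff, theta_true=eff.theta_true + observer_offset)
    rmt_cfg = TrackerConfig(target_mep=cfg.target_mep, prestim_gate_mv=cfg.prestim_gate_mv)
    rmt_est, _ = track_threshold(eff, rmt_cfg, design.rmt_start_intensity, rng)
    if not rmt_est.valid:
        return None
    if protocol == "T":
        return run_t_sici(eff, rmt_est.value, cfg, rng)
    ts_cfg = TrackerConfig(target_mep=1.0, prestim_gate_mv=cfg.prestim_gate_mv)
    start = min(100.0, rmt_est.value + math.log10(1.0 / cfg.target_mep) / eff.slope_b * 0.9)
    ts_est, _ = track_threshold(eff, ts_cfg, start, rng, condition="ts1mv")
    if not ts_est.valid:
        return None
    return run_a_sici(eff, rmt_est.value, ts_est.value, cfg, rng)


def run_study(
    cohort_params: CohortParams,
    design: StudyDesign = StudyDesign(),
    protocol_cfg: ProtocolConfig = ProtocolConfig(),
    seed: int = 0,
) -> StudyDataset:
    """Simulate the complete study, fully reproducible from the seeds.

    The cohort comes from ``cohort_params.seed``; examination randomness
    derives from ``seed`` through per-examination child streams, so any
    single examination is reproducible independently of the others.
    """
    cohort = sample_cohort(cohort_params)
    ss = np.random.SeedSequence(seed)
    results: dict[ExamKey, ExaminationResult | None] = {}

    for subj, model in enumerate(cohort):
        for day in range(1, design.days + 1):
            for session in SESSIONS[: design.sessions_per_day]:
                for protocol in PROTOCOLS:
                    for exam_index in range(1, design.exams_per_session + 1):
                        key = ExamKey(subj, 1, day, session, exam_index, protocol)
                        rng = np.random.default_rng(_child_seed(ss, key))
                        results[key] = _run_one_examination(
                            model, protocol, protocol_cfg, design, rng, 0.0
                        )
        # Second observer: one examination per protocol in one session.
        obs_rng = np.random.default_rng(_child_seed(ss, (subj, "observer2")))
        offset = (
            obs_rng.normal(0.0, design.observer_offset_sd)
            if design.observer_offset_sd > 0
            else 0.0
        )
        for protocol in PROTOCOLS:
            key = ExamKey(
                subj, 2, design.interobserver_day, design.interobserver_session,
                1, protocol,
            )
            rng = np.random.default_rng(_child_seed(ss, key))
            results[key] = _run_one_examination(
                model, protocol, protocol_cfg, design, rng, offset
            )
    return StudyDataset(results, cohort, design, protocol_cfg, seed)


def _child_seed(ss: np.random.SeedSequence, key) -> np.random.SeedSequence:
    """Stable per-examination stream keyed on the exam identity."""
    if isinstance(key, ExamKey):
        ident = (
            key.subject,
            key.observer,
            key.day,
            SESSIONS.index(key.session),
            key.exam_index,
            PROTOCOLS.index(key.protocol),
        )
    else:
        ident = (key[0], 999)
    return np.random.SeedSequence(entropy=ss.entropy, spawn_key=ident)


def _parameters(protocol: str) -> list[tuple[str, str]]:
    """(parameter, scale) pairs summarised for one protocol."""
    prefix = "T-SICI" if protocol == "T" else "A-SICI"
    scale = "linear" if protocol == "T" else "log10"
    params = [(f"{isi:g}", scale) for isi in REPORT_ISIS]
    params += [("band_1_3.5", scale), ("band_1_7", scale)]
    params += [("RMT", "linear")]
    if protocol == "A":
        params += [("TS_1mV", "linear")]
    return [(p, s) for p, s in params]


def _exam_order(design: StudyDesign) -> list[tuple[int, str, int]]:
    """Chronological (day, session, exam_index) order of the 8 exams."""
    return [
        (day, session, idx)
        for day in range(1, design.days + 1)
        for session in SESSIONS[: design.sessions_per_day]
        for idx in range(1, design.exams_per_session + 1)
    ]


def _matrix(
    ds: StudyDataset, protocol: str, parameter: str, scale: str,
    slots: list[tuple[int, str, int]],
) -> MeasurementMatrix:
    """Subjects x slots matrix of one parameter (observer 1)."""
    rows = []
    for subj in range(len(ds.cohort)):
        row = []
        for day, session, idx in slots:
            res = ds.examinations.get(
                ExamKey(subj, 1, day, session, idx, protocol)
            )
            val = ds.parameter_value(res, parameter) if res is not None else math.nan
            row.append(val)
        rows.append(row)
    arr = np.array(rows, dtype=float)
    if scale == "log10":
        arr = np.where(arr > 0, arr, np.nan)
        arr = np.log10(arr)
    name = parameter if parameter in ("RMT", "TS_1mV") else (
        ("T-SICI_" if protocol == "T" else "A-SICI_") + parameter
    )
    return MeasurementMatrix(arr, parameter_name=name, scale=scale)


def summarize_reliability(ds: StudyDataset) -> pd.DataFrame:
    """Tidy table of CR, ICC, rmANOVA and interobserver tests.

    Per parameter and protocol: CR for each (day, session) examination
    pair; intraday ICC for the morning pair, the afternoon pair and the
    first-morning/first-afternoon pair of each day; interday ICC from the
    first examination of matching sessions across days; rmANOVA over all
    eight examinations; interobserver ICC and paired t test against the
    first observer-1 examination of the matching session.
    """
    design = ds.design
    rows: list[dict] = []

    def add(protocol, parameter, statistic, context, value, ci=(math.nan, math.nan),
            band="", extra=None):
        row = {
            "protocol": protocol, "parameter": parameter, "statistic": statistic,
            "context": context, "value": value, "ci_low": ci[0], "ci_high": ci[1],
            "band": band,
        }
        if extra:
            row.update(extra)
        rows.append(row)

    for protocol in PROTOCOLS:
        for parameter, scale in _parameters(protocol):
            # Repeatability: CR per session (two exams in direct succession).
            for day in range(1, design.days + 1):
                for session in SESSIONS[: design.sessions_per_day]:
                    slots = [
                        (day, session, i)
                        for i in range(1, design.exams_per_session + 1)
                    ]
                    m = _matrix(ds, protocol, parameter, scale, slots)
                    try:
                        cr, ci = coefficient_of_repeatability(m)
                    except ValueError:
                        continue
                    if scale == "log10":
                        cr, ci = 10.0**cr, (10.0 ** ci[0], 10.0 ** ci[1])
                    add(protocol, m.parameter_name, "CR", f"day{day}_{session}",
                        cr, ci)
            # Intraday ICC.
            for day in range(1, design.days + 1):
                pairs = {
                    "morning": [(day, "morning", 1), (day, "morning", 2)],
                    "afternoon": [(day, "afternoon", 1), (day, "afternoon", 2)],
                    "morning_afternoon": [(day, "morning", 1), (day, "afternoon", 1)],
                }
                for context, slots in pairs.items():
                    _add_icc(ds, protocol, parameter, scale, slots,
                             f"intraday_day{day}_{context}", add)
            # Interday ICC: first exam of matching sessions across days.
            interday = {
                "morning": [(1, "morning", 1), (2, "morning", 1)],
                "afternoon": [(1, "afternoon", 1), (2, "afternoon", 1)],
                "morning_afternoon": [(1, "morning", 1), (2, "afternoon", 1)],
            }
            for context, slots in interday.items():
                _add_icc(ds, protocol, parameter, scale, slots,
                         f"interday_{context}", add)
            # Reproducibility: rmANOVA over all eight examinations.
            m_all = _matrix(ds, protocol, parameter, scale, _exam_order(design))
            try:
                an = rm_anova(m_all)
                add(protocol, m_all.parameter_name, "rmANOVA_F", "all_exams", an.F,
                    extra={"p": an.p, "df1": an.df1, "df2": an.df2,
                           "epsilon": an.epsilon, "mauchly_p": an.mauchly_p})
            except ValueError:
                pass
            # Interobserver: observer 2 vs matching observer-1 examination.
            _interobserver(ds, protocol, parameter, scale, add)
    return pd.DataFrame(rows)


def _add_icc(ds, protocol, parameter, scale, slots, context, add):
    m = _matrix(ds, protocol, parameter, scale, slots)
    try:
        icc, ci = icc_2_1(m)
    except ValueError:
        return
    add(protocol, m.parameter_name, "ICC", context, icc, ci, classify_icc(icc))


def _interobserver(ds, protocol, parameter, scale, add):
    design = ds.design
    slot1 = (design.interobserver_day, design.interobserver_session, 1)
    a, b = [], []
    for subj in range(len(ds.cohort)):
        r1 = ds.examinations.get(ExamKey(subj, 1, *slot1, protocol))
        r2 = ds.examinations.get(
            ExamKey(subj, 2, design.interobserver_day,
                    design.interobserver_session, 1, protocol)
        )
        if r1 is None or r2 is None:
            continue
        v1 = ds.parameter_value(r1, parameter)
        v2 = ds.parameter_value(r2, parameter)
        if scale == "log10":
            if v1 <= 0 or v2 <= 0:
                continue
            v1, v2 = math.log10(v1), math.log10(v2)
        if math.isfinite(v1) and math.isfinite(v2):
            a.append(v1)
            b.append(v2)
    if len(a) < 2:
        return
    name = parameter if parameter in ("RMT", "TS_1mV") else (
        ("T-SICI_" if protocol == "T" else "A-SICI_") + parameter
    )
    m = MeasurementMatrix(np.column_stack([a, b]), parameter_name=name, scale=scale)
    try:
        icc, ci = icc_2_1(m)
        add(protocol, name, "ICC", "interobserver", icc, ci, classify_icc(icc))
    except ValueError:
        pass
    t, df, p = paired_t(np.array(a), np.array(b))
    add(protocol, name, "paired_t", "interobserver", t, extra={"p": p, "df": df})


def summarize_group_curves(ds: StudyDataset) -> dict:
    """Group SICI-vs-ISI curves, per-ISI tests, inter-method regression.

    Per-subject means over the eight intraobserver examinations are
    arithmetic for T-SICI and geometric for A-SICI; one-sample t tests
    compare each ISI against the control condition (0 %RMT for T-SICI;
    100% test MEP for A-SICI, tested on the log10 scale).  The pooled
    regression relates the nine group-mean T-SICI values to log10
    group-mean A-SICI (the inter-method linearity analysis); per-ISI
    regressions relate per-subject means across subjects.
    """
    isis = ds.protocol_cfg.isis
    n = len(ds.cohort)
    t_subject = np.full((n, len(isis)), np.nan)
    a_subject = np.full((n, len(isis)), np.nan)
    for subj in range(n):
        t_vals = {isi: [] for isi in isis}
        a_vals = {isi: [] for isi in isis}
        for key, res in ds.examinations.items():
            if res is None or key.subject != subj or key.observer != 1:
                continue
            store = t_vals if res.protocol == "T" else a_vals
            for isi in isis:
                v = res.per_isi.get(isi, math.nan)
                if math.isfinite(v) and (res.protocol == "T" or v > 0):
                    store[isi].append(v)
        for j, isi in enumerate(isis):
            if t_vals[isi]:
                t_subject[subj, j] = float(np.mean(t_vals[isi]))
            if a_vals[isi]:
                a_subject[subj, j] = float(gmean(a_vals[isi]))

    per_isi_rows = []
    for j, isi in enumerate(isis):
        t_col = t_subject[:, j][np.isfinite(t_subject[:, j])]
        a_col = a_subject[:, j][np.isfinite(a_subject[:, j])]
        t_mean = float(np.mean(t_col)) if t_col.size else math.nan
        a_gmean = float(gmean(a_col)) if a_col.size else math.nan
        t_t, _, t_p = one_sample_condition_test(t_col, 0.0)
        a_t, _, a_p = one_sample_condition_test(np.log10(a_col), math.log10(100.0))
        row = {
            "isi": isi,
            "t_sici_mean": t_mean,
            "t_sici_sem": float(np.std(t_col, ddof=1) / math.sqrt(t_col.size)),
            "t_p": t_p,
            "a_sici_gmean": a_gmean,
            "a_p": a_p,
        }
        both = np.isfinite(t_subject[:, j]) & np.isfinite(a_subject[:, j])
        if both.sum() >= 3:
            reg = method_regression(t_subject[both, j], a_subject[both, j])
            row["method_r"] = reg.r
        per_isi_rows.append(row)
    curves = pd.DataFrame(per_isi_rows)

    pooled = method_regression(
        curves["t_sici_mean"].to_numpy(), curves["a_sici_gmean"].to_numpy()
    )
    return {"curves": curves, "pooled_regression": pooled}


def write_study(ds: StudyDataset, out_dir: str | Path) -> None:
    """Write per-examination trial logs plus study-level result tables."""
    out = Path(out_dir)
    logs = out / "trial_logs"
    logs.mkdir(parents=True, exist_ok=True)
    result_rows = []
    for key, res in sorted(
        ds.examinations.items(),
        key=lambda kv: (kv[0].subject, kv[0].observer, kv[0].day,
                        kv[0].session, kv[0].protocol, kv[0].exam_index),
    ):
        tag = (f"s{key.subject:02d}_obs{key.observer}_d{key.day}_"
               f"{key.session}_{key.protocol}_{key.exam_index}")
        if res is None:
            result_rows.append({"subject": key.subject, "observer": key.observer,
                                "day": key.day, "session": key.session,
                                "exam_index": key.exam_index,
                                "protocol": key.protocol, "status": "failed"})
            continue
        log = pd.DataFrame(
            {
                "subject_id": key.subject, "observer": key.observer,
                "day": key.day, "session": key.session,
                "exam_index": key.exam_index, "protocol": key.protocol,
                "trial_index": [t.trial_index for t in res.trials],
                "cycle": [t.cycle for t in res.trials],
                "condition": [t.condition for t in res.trials],
                "cs_intensity": [t.cs_intensity for t in res.trials],
                "ts_intensity": [t.ts_intensity for t in res.trials],
                "mep_mv": [t.mep_mv for t in res.trials],
                "gated": [int(t.gated) for t in res.trials],
                "time_s": [t.time_s for t in res.trials],
            }
        )
        log.to_csv(logs / f"{tag}.csv", index=False)
        row = {"subject": key.subject, "observer": key.observer, "day": key.day,
               "session": key.session, "exam_index": key.exam_index,
               "protocol": key.protocol, "status": "ok",
               "rmt_0_2": res.rmt_0_2, "ts_1mv": res.ts_1mv,
               "band_1_3.5": res.band_1_3_5, "band_1_7": res.band_1_7,
               "gated_count": res.gated_count}
        row.update({f"isi_{isi:g}": v for isi, v in res.per_isi.items()})
        result_rows.append(row)
    pd.DataFrame(result_rows).to_csv(out / "examinations.csv", index=False)
    summarize_reliability(ds).to_csv(out / "reliability_report.csv", index=False)
    summarize_group_curves(ds)["curves"].to_csv(out / "group_curves.csv", index=False)


def _examination_from_log(
    df: pd.DataFrame, cfg: ProtocolConfig, fallback_rmt: float = math.nan
) -> ExaminationResult:
    """Recompute one examination's readouts from its trial-log rows.

    T-SICI: semi-log regression thresholds per conditioned condition and
    over the pooled control trials; A-SICI: geometric-mean amplitude
    ratios.  Gated rows are excluded exactly as during acquisition.
    """
    from .sici_protocols import CONTROL, compute_a_sici, compute_t_sici, _t_band
    from .threshold_tracking import TrialRecord as _TR

    protocol = str(df["protocol"].iloc[0])
    kept = df[df["gated"] == 0]
    gated_count = int((df["gated"] != 0).sum())
    if protocol == "T":
        def records(sub: pd.DataFrame) -> list[_TR]:
            return [
                _TR(int(r.trial_index), str(r.condition), float(r.ts_intensity),
                    float(r.mep_mv))
                for r in sub.itertuples()
            ]

        ctrl = kept[kept["condition"] == CONTROL]
        rmt_est = regression_threshold(
            records(ctrl), cfg.target_mep, cfg.regression_window_mv
        )
        # mirror acquisition: fall back to the pre-examination tracked RMT
        # when the pooled control regression is degenerate
        rmt = rmt_est.value if rmt_est.valid else fallback_rmt
        per_isi: dict[float, float] = {}
        for isi in cfg.isis:
            sub = kept[kept["condition"] == f"{isi:g}"]
            est = regression_threshold(
                records(sub), cfg.target_mep, cfg.regression_window_mv
            )
            per_isi[isi] = (
                compute_t_sici(est.value, rmt)
                if est.valid and math.isfinite(rmt)
                else math.nan
            )
        return ExaminationResult(
            protocol="T", rmt_0_2=rmt, per_isi=per_isi,
            band_1_3_5=_t_band(per_isi, BAND_1_3_5),
            band_1_7=_t_band(per_isi, BAND_1_7),
            gated_count=gated_count,
        )
    control_meps = kept.loc[kept["condition"] == CONTROL, "mep_mv"].tolist()
    cond = {
        isi: kept.loc[kept["condition"] == f"{isi:g}", "mep_mv"].tolist()
        for isi in cfg.isis
    }
    per_isi = {isi: compute_a_sici(cond[isi], control_meps) for isi in cfg.isis}

    def band(members):
        pooled = [m for isi in members for m in cond.get(isi, [])]
        return compute_a_sici(pooled, control_meps)

    ts = kept["ts_intensity"].iloc[0] if len(kept) else math.nan
    return ExaminationResult(
        protocol="A", rmt_0_2=math.nan, ts_1mv=float(ts), per_isi=per_isi,
        band_1_3_5=band(BAND_1_3_5), band_1_7=band(BAND_1_7),
        gated_count=gated_count,
    )


def load_study(
    in_dir: str | Path,
    design: StudyDesign = StudyDesign(),
    protocol_cfg: ProtocolConfig = ProtocolConfig(),
) -> StudyDataset:
    """Rebuild a StudyDataset by re-analysing written trial-log CSVs.

    Threshold and SICI values are recomputed from the logged sweeps, not
    read from the result tables, so the analysis pipeline can be audited
    end-to-end from raw logs.  RMT/TS for A-SICI examinations are taken
    from the examinations table when present (they come from tracking runs
    that are not part of the protocol log).
    """
    in_path = Path(in_dir)
    exam_table = None
    exams_csv = in_path / "examinations.csv"
    if exams_csv.exists():
        exam_table = pd.read_csv(exams_csv)
    examinations: dict[ExamKey, ExaminationResult | None] = {}
    subjects: set[int] = set()
    for log_path in sorted((in_path / "trial_logs").glob("*.csv")):
        df = pd.read_csv(log_path)
        first = df.iloc[0]
        key = ExamKey(
            int(first["subject_id"]), int(first["observer"]), int(first["day"]),
            str(first["session"]), int(first["exam_index"]), str(first["protocol"]),
        )
        subjects.add(key.subject)
        recorded_rmt = math.nan
        if exam_table is not None:
            match = exam_table[
                (exam_table["subject"] == key.subject)
                & (exam_table["observer"] == key.observer)
                & (exam_table["day"] == key.day)
                & (exam_table["session"] == key.session)
                & (exam_table["exam_index"] == key.exam_index)
                & (exam_table["protocol"] == key.protocol)
            ]
            if len(match) and "rmt_0_2" in match:
                recorded_rmt = float(match["rmt_0_2"].iloc[0])
        res = _examination_from_log(df, protocol_cfg, fallback_rmt=recorded_rmt)
        if res.protocol == "A" and math.isfinite(recorded_rmt):
            res.rmt_0_2 = recorded_rmt
        examinations[key] = res
    n = (max(subjects) + 1) if subjects else 0
    return StudyDataset(examinations, [None] * n, design, protocol_cfg, seed=-1)
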