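"""End-to-end pipeline: simulate (or load) a cohort, preprocess photometry,
build drinks and microstructure, extract peri-event metrics and write the
tidy report bundle.

The default simulated cohort mirrors the study design: 14 animals (9 male,
5 female), six drinking weeks of five sessions each (Monday-Thursday 2 h,
Friday 4 h), water in weeks 1-3 and 20 % alcohol in weeks 4-6, with
home-cage water measured between sessions.  All randomness flows from one
master seed, split deterministically per animal, session and stage, so a
rerun with the same seed is byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import build_cohort_table, correlate_intersession, quartile_bin, weekly_aggregate
from .lickometer import (
    LickSession,
    bin_to_drinks,
    clean_events,
    microstructure,
    read_lick_log,
    summary_frame,
)
from .perievent import align_to_drinks, bin_grid, metrics_table
from .photometry import (
    QCThresholds,
    process_recording,
    read_photometry_csv,
    write_dff_csv,
)
from .synthetic import (
    ArtifactInjection,
    BleachParams,
    BoutModel,
    KernelParams,
    MotionParams,
    SimConfig,
    default_amplitude_map,
    simulate_session,
)

__all__ = ["IntakeModel", "CohortConfig", "ReportBundle", "run_pipeline", "session_schedule"]


@dataclass
class IntakeModel:
    """Per-session intended intakes, g/kg, and their coupling to the
    preceding inter-session water intake (negative coupling = a quenched
    thirst state predicts lower intake in the next session)."""

    water_gkg_2h: float = 32.0
    water_cv: float = 0.20
    alcohol_gkg_2h: float = 4.0
    alcohol_cv: float = 0.20
    friday_scale: float = 1.5
    intersession_g: dict = field(default_factory=lambda: {"male": 3.5, "female": 4.5})
    intersession_cv: float = 0.30
    coupling: dict = field(
        default_factory=lambda: {
            ("male", "water"): -0.25,
            ("female", "water"): -0.25,
            ("male", "alcohol"): 0.0,
            ("female", "alcohol"): -0.4,
        }
    )
    body_weight_g: dict = field(default_factory=lambda: {"male": 27.0, "female": 22.0})


@dataclass
class CohortConfig:
    """Study-design and generator settings for a simulated cohort."""

    n_male: int = 9
    n_female: int = 5
    weeks: int = 6
    sessions_per_week: int = 5
    weekday_duration: float = 7200.0
    friday_duration: float = 14400.0
    frame_rate: float = 15.0
    bleach_415: BleachParams = field(default_factory=BleachParams)
    channel_scale: float = 2.0
    kernel: KernelParams = field(default_factory=KernelParams)
    amplitude_map: dict = field(default_factory=default_amplitude_map)
    amplitude_cv: float = 0.10
    motion: MotionParams = field(default_factory=MotionParams)
    noise_sigma: float = 0.30
    #: drinks per standard 2-h session; scaled by session duration
    bout_counts: dict = field(
        default_factory=lambda: {
            ("male", "water"): 40,
            ("female", "water"): 40,
            ("male", "alcohol"): 45,
            ("female", "alcohol"): 32,
        }
    )
    bout_reference_duration: float = 7200.0
    bout_model: BoutModel = field(default_factory=BoutModel)
    intake: IntakeModel = field(default_factory=IntakeModel)
    # processing knobs
    dff_mode: str = "ratio"
    censor_motion: bool = True
    clean_threshold: float = 3.0
    n_bins: int = 150
    window: tuple[float, float] = (-5.0, 5.0)
    qc: QCThresholds = field(default_factory=QCThresholds)
    seed: int = 0

    @property
    def water_weeks(self) -> int:
        return self.weeks // 2

    def animals(self) -> list[tuple[str, str]]:
        males = [(f"M{i + 1:02d}", "male") for i in range(self.n_male)]
        females = [(f"F{i + 1:02d}", "female") for i in range(self.n_female)]
        return males + females


def session_schedule(config: CohortConfig) -> list[tuple[int, int, float, str]]:
    """(session_index, week, duration, fluid) for every session of the
    cohort schedule; the fifth session of each week is the 4-h Friday."""
    out = []
    for week in range(1, config.weeks + 1):
        fluid = "water" if week <= config.water_weeks else "alcohol"
        for day in range(1, config.sessions_per_week + 1):
            s = (week - 1) * config.sessions_per_week + day
            duration = (
                config.friday_duration
                if day == config.sessions_per_week
                else config.weekday_duration
            )
            out.append((s, week, duration, fluid))
    return out


def _stage_seed(master: int, *key: int) -> int:
    """Deterministic child seed below 2**31 for a (master, key...) path."""
    ss = np.random.SeedSequence([int(master), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31))


def _build_session_config(
    config: CohortConfig,
    animal_idx: int,
    animal_id: str,
    sex: str,
    session: int,
    week: int,
    duration: float,
    fluid: str,
    intake_g: float,
    intersession_g: float,
    body_weight: float,
) -> SimConfig:
    scale = duration / config.bout_reference_duration
    bouts = max(int(round(config.bout_counts[(sex, fluid)] * scale)), 1)
    bout_model = BoutModel(
        n_bouts=bouts,
        events_per_bout_mean=config.bout_model.events_per_bout_mean,
        lick_rate_hz=config.bout_model.lick_rate_hz,
        event_duration_mean=config.bout_model.event_duration_mean,
        event_duration_cv=config.bout_model.event_duration_cv,
        min_gap_s=config.bout_model.min_gap_s,
    )
    return SimConfig(
        session_duration=duration,
        frame_rate=config.frame_rate,
        bleach_415=config.bleach_415,
        channel_scale=config.channel_scale,
        kernel=config.kernel,
        amplitude_map=config.amplitude_map,
        amplitude_cv=config.amplitude_cv,
        motion=config.motion,
        noise_sigma=config.noise_sigma,
        bout_model=bout_model,
        artifacts=ArtifactInjection(),
        sex=sex,
        fluid=fluid,
        animal_id=animal_id,
        session_index=session,
        intake_g=intake_g,
        intersession_g=intersession_g,
        body_weight_g=body_weight,
        seed=_stage_seed(config.seed, 1, animal_idx, session),
    )


def _intended_intakes(config: CohortConfig, animal_idx: int, sex: str,
                      schedule) -> list[tuple[float, float, float]]:
    """Per-session (solution grams, intersession grams, body weight).

    The intended g/kg is lognormal-free: base x (1 + cv*eps), floored at
    5 % of base, shifted by the coupling slope times the z-scored
    inter-session water intake drawn for the preceding interval.
    """
    im = config.intake
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 2, int(animal_idx)])
    )
    bw = im.body_weight_g[sex] * (1.0 + 0.05 * rng.standard_normal())
    out = []
    for _, _, duration, fluid in schedule:
        scale = im.friday_scale if duration > config.weekday_duration else 1.0
        inter_mean = im.intersession_g[sex]
        inter_g = max(inter_mean * (1.0 + im.intersession_cv * rng.standard_normal()), 0.1)
        inter_z = (inter_g - inter_mean) / (im.intersession_cv * inter_mean)
        if fluid == "water":
            base, cv = im.water_gkg_2h * scale, im.water_cv
        else:
            base, cv = im.alcohol_gkg_2h * scale, im.alcohol_cv
        slope = im.coupling[(sex, fluid)]
        gkg = base * (1.0 + cv * rng.standard_normal()) + slope * inter_z * cv * base
        gkg = max(gkg, 0.05 * base)
        bw_kg = bw / 1000.0
        if fluid == "water":
            sol_g = gkg * bw_kg
        else:
            from .lickometer import DENSITY_ETOH, DENSITY_ETOH_SOLUTION, ETOH_FRACTION

            sol_g = gkg * bw_kg / (ETOH_FRACTION * DENSITY_ETOH) * DENSITY_ETOH_SOLUTION
        out.append((float(sol_g), float(inter_g), float(bw)))
    return out


@dataclass
class ReportBundle:
    """Paths and in-memory tables of one pipeline run."""

    out_dir: Path
    microstructure: pd.DataFrame
    metrics: pd.DataFrame
    cohort: pd.DataFrame
    group_traces: pd.DataFrame
    qc: list[dict]
    analysis: dict
    paths: dict[str, Path] = field(default_factory=dict)


class _GroupTraceAccumulator:
    """Streaming per-(sex, fluid, side) mean ± SEM of aligned rows."""

    def __init__(self, n_bins: int):
        self.n_bins = n_bins
        self.stats: dict[tuple, list] = {}

    def add(self, key: tuple, block: np.ndarray) -> None:
        if key not in self.stats:
            self.stats[key] = [0, np.zeros(self.n_bins), np.zeros(self.n_bins)]
        entry = self.stats[key]
        entry[0] += block.shape[0]
        entry[1] += block.sum(axis=0)
        entry[2] += (block**2).sum(axis=0)

    def frame(self, offsets: np.ndarray) -> pd.DataFrame:
        rows = []
        for key in sorted(self.stats):
            n, s, s2 = self.stats[key]
            mean = s / n
            if n >= 2:
                var = np.maximum((s2 - n * mean**2) / (n - 1), 0.0)
                sem = np.sqrt(var / n)
            else:
                sem = np.full(self.n_bins, np.nan)
            frame = pd.DataFrame(
                {"sex": key[0], "fluid": key[1], "side": key[2],
                 "offset_s": offsets, "mean": mean, "sem": sem, "n": n}
            )
            rows.append(frame)
        if not rows:
            return pd.DataFrame(
                columns=["sex", "fluid", "side", "offset_s", "mean", "sem", "n"]
            )
        return pd.concat(rows, ignore_index=True)


def _process_session(
    config: CohortConfig,
    rec_left,
    rec_right,
    lick: LickSession,
    micro_rows: list,
    metric_rows: list[pd.DataFrame],
    drink_rows: list,
    qc_entries: list,
    traces: _GroupTraceAccumulator,
    write_traces: bool,
    trace_dir: Path | None,
) -> None:
    drinks = bin_to_drinks(lick)
    kept, removed, _model = clean_events(drinks, config.clean_threshold)
    summ = microstructure(lick, kept)
    summ.n_drinks_removed = len(removed)
    micro_rows.append((lick, summ))
    for d in kept:
        drink_rows.append(
            {
                "animal": lick.animal_id,
                "sex": lick.sex,
                "fluid": lick.fluid,
                "week": lick.week,
                "session": lick.session_index,
                "start_s": d.start,
                "length_s": d.length,
                "n_events": d.n_events,
                "event_duration_s": d.event_duration,
            }
        )
    for rec in (rec_left, rec_right):
        seed = _stage_seed(config.seed, 3, zlib.crc32(lick.animal_id.encode()),
                           lick.session_index, 0 if rec.fiber_side == "left" else 1)
        trace, diag = process_recording(
            rec,
            seed,
            dff_mode=config.dff_mode,
            censor=config.censor_motion,
            qc_thresholds=config.qc,
        )
        fit = diag["fit"]
        qc_entries.append(
            {
                "animal": lick.animal_id,
                "session": lick.session_index,
                "side": rec.fiber_side,
                "passed": trace.qc.passed,
                "reason": trace.qc.reason,
                "r_squared": round(fit.r_squared, 6),
                "bleach_tau1": round(fit.tau1, 3),
                "bleach_tau2": round(fit.tau2, 3),
                "inlier_fraction": round(diag["scaled"].inlier_fraction, 6),
            }
        )
        if not trace.qc.passed:
            continue
        if write_traces and trace_dir is not None:
            stem = f"{lick.animal_id}_s{lick.session_index:02d}_{rec.fiber_side}"
            write_dff_csv(trace, rec.fiber_side, trace_dir / f"{stem}_dff.csv")
        matrix = align_to_drinks(
            trace,
            kept,
            window=config.window,
            n_bins=config.n_bins,
            meta={
                "animal": lick.animal_id,
                "sex": lick.sex,
                "fluid": lick.fluid,
                "week": lick.week,
                "session": lick.session_index,
                "side": rec.fiber_side,
            },
        )
        if matrix.n_rows == 0:
            continue
        traces.add((lick.sex, lick.fluid, rec.fiber_side), matrix.values)
        metric_rows.append(metrics_table(matrix))


def run_pipeline(
    out_dir: str | Path,
    config: CohortConfig | None = None,
    in_dir: str | Path | None = None,
    seed: int | None = None,
    write_traces: bool = False,
) -> ReportBundle:
    """Run the full pipeline and write the report bundle.

    With ``in_dir`` None the cohort is simulated from ``config`` (a
    default :class:`CohortConfig` when omitted); otherwise lick logs
    (``*_lick.csv``) and photometry CSVs (``*_left.csv``/``*_right.csv``)
    are read from ``in_dir``.  ``seed`` overrides ``config.seed``.
    """
    config = config or CohortConfig()
    if seed is not None:
        config.seed = int(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trace_dir = out_dir / "dff"
    if write_traces:
        trace_dir.mkdir(exist_ok=True)

    micro_rows: list = []
    metric_rows: list[pd.DataFrame] = []
    drink_rows: list = []
    qc_entries: list = []
    traces = _GroupTraceAccumulator(config.n_bins)

    if in_dir is None:
        schedule = session_schedule(config)
        for a_idx, (animal_id, sex) in enumerate(config.animals()):
            intakes = _intended_intakes(config, a_idx, sex, schedule)
            for (session, week, duration, fluid), (sol_g, inter_g, bw) in zip(
                schedule, intakes
            ):
                sim = _build_session_config(
                    config, a_idx, animal_id, sex, session, week, duration, fluid,
                    sol_g, inter_g, bw,
                )
                rec_left, rec_right, lick, _truth = simulate_session(sim)
                _process_session(
                    config, rec_left, rec_right, lick, micro_rows, metric_rows,
                    drink_rows, qc_entries, traces, write_traces, trace_dir,
                )
    else:
        in_dir = Path(in_dir)
        lick_files = sorted(in_dir.glob("*_lick.csv"))
        if not lick_files:
            raise FileNotFoundError(f"no *_lick.csv files in {in_dir}")
        for lick_path in lick_files:
            lick = read_lick_log(lick_path)
            stem = lick_path.name[: -len("_lick.csv")]
            recs = []
            for side in ("left", "right"):
                p = in_dir / f"{stem}_{side}.csv"
                if p.exists():
                    recs.extend(read_photometry_csv(p))
            if len(recs) != 2:
                raise FileNotFoundError(f"missing photometry CSVs for {stem}")
            _process_session(
                config, recs[0], recs[1], lick, micro_rows, metric_rows,
                drink_rows, qc_entries, traces, write_traces, trace_dir,
            )

    micro = summary_frame(micro_rows)
    metrics = (
        pd.concat(metric_rows, ignore_index=True)
        if metric_rows
        else pd.DataFrame(
            columns=["animal", "sex", "fluid", "week", "session", "side",
                     "drink_index", "drink_start", "drink_length",
                     "peak_amplitude", "time_to_peak", "auc", "drink_end"]
        )
    )
    drinks_df = pd.DataFrame(drink_rows)
    cohort = build_cohort_table(micro, metrics)
    group_traces = traces.frame(bin_grid(config.window, config.n_bins))

    analysis: dict = {}
    if len(drinks_df) >= 4:
        qa_len = quartile_bin(drinks_df["length_s"].to_numpy())
        drinks_df["length_quartile"] = qa_len.labels
        analysis["drink_length_quartiles"] = {
            "breakpoints_s": [float(b) for b in qa_len.breakpoints],
            "counts": qa_len.counts(),
        }
        per_session = drinks_df.groupby(["animal", "session"]).size()
        if len(per_session) >= 4:
            qa_n = quartile_bin(per_session.to_numpy())
            analysis["drinks_per_session_quartiles"] = {
                "breakpoints": [float(b) for b in qa_n.breakpoints],
                "counts": qa_n.counts(),
            }
    analysis["correlations"] = {}
    for fluid in ("water", "alcohol"):
        try:
            analysis["correlations"][fluid] = correlate_intersession(
                micro, fluid=fluid, seed=_stage_seed(config.seed, 4, zlib.crc32(fluid.encode()))
            )
        except ValueError as exc:
            analysis["correlations"][fluid] = {"error": str(exc)}
    weekly = {}
    for measure in ("intake", "intersession_intake", "total_events", "n_drinks"):
        if measure in micro.columns:
            _, per_group = weekly_aggregate(micro, measure)
            weekly[measure] = per_group
    weekly_df = (
        pd.concat(weekly, names=["measure", None]).reset_index(level=0).reset_index(drop=True)
        if weekly
        else pd.DataFrame()
    )

    paths = {
        "microstructure": out_dir / "microstructure.csv",
        "metrics": out_dir / "drink_metrics.csv",
        "drinks": out_dir / "drinks.csv",
        "cohort": out_dir / "cohort.csv",
        "group_traces": out_dir / "group_traces.csv",
        "weekly": out_dir / "weekly.csv",
        "qc": out_dir / "qc.json",
        "analysis": out_dir / "analysis.json",
        "log": out_dir / "run_log.txt",
    }
    fmt = "%.10g"
    micro.to_csv(paths["microstructure"], index=False, float_format=fmt)
    metrics.to_csv(paths["metrics"], index=False, float_format=fmt)
    drinks_df.to_csv(paths["drinks"], index=False, float_format=fmt)
    cohort.to_csv(paths["cohort"], index=False, float_format=fmt)
    group_traces.to_csv(paths["group_traces"], index=False, float_format=fmt)
    weekly_df.to_csv(paths["weekly"], index=False, float_format=fmt)
    with open(paths["qc"], "w") as fh:
        json.dump(qc_entries, fh, indent=1, sort_keys=True)
    with open(paths["analysis"], "w") as fh:
        json.dump(analysis, fh, indent=1, sort_keys=True, default=float)
    def _stringify_keys(obj):
        if isinstance(obj, dict):
            return {str(k): _stringify_keys(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_stringify_keys(v) for v in obj]
        return obj

    config_json = json.dumps(_stringify_keys(asdict(config)), sort_keys=True, default=str)
    config_hash = hashlib.sha256(config_json.encode()).hexdigest()
    n_failed = sum(1 for e in qc_entries if not e["passed"])
    with open(paths["log"], "w") as fh:
        fh.write(f"photolick {__version__}\n")
        fh.write(f"numpy {np.__version__}, pandas {pd.__version__}\n")
        fh.write(f"config sha256 {config_hash}\n")
        fh.write(f"seed {config.seed}\n")
        fh.write(f"sessions {len(micro_rows)}, recordings {len(qc_entries)}, "
                 f"qc_failed {n_failed}\n")
        fh.write(f"aligned events {len(metrics)}\n")

    return ReportBundle(
        out_dir=out_dir,
        microstructure=micro,
        metrics=metrics,
        cohort=cohort,
        group_traces=group_traces,
        qc=qc_entries,
        analysis=analysis,
        paths=paths,
    )


def load_cohort_config(path: str | Path) -> CohortConfig:
    """Build a CohortConfig from a YAML mapping of overrides (flat keys
    matching the dataclass fields; nested dataclasses take mappings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    config = CohortConfig()
    nested = {
        "bleach_415": BleachParams,
        "kernel": KernelParams,
        "motion": MotionParams,
        "bout_model": BoutModel,
        "qc": QCThresholds,
        "intake": IntakeModel,
    }
    for key, value in raw.items():
        if not hasattr(config, key):
            raise ValueError(f"unknown config key {key!r}")
        if key in nested and isinstance(value, dict):
            setattr(config, key, nested[key](**value))
        else:
            setattr(config, key, value)
    if isinstance(config.window, list):
        config.window = tuple(config.window)
    return config
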