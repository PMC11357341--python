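"""Lickometer log parsing, drink construction, artifact cleaning and
drinking-microstructure features.

The home-cage lickometer samples the state of an infrared beam in front of
the bottle valve and writes to device memory every 3 s.  Each stored record
is one occupied 3-s window: the number of beam breaks in the window
("events") and the total time the beam was broken ("event duration").  Any
tube interaction spanning consecutive occupied windows is a "drink".

Cleaning removes drinks whose event-count/event-duration relationship is
anomalous (slow bottle leaks: long duration, few events; chews: many
near-instantaneous events) by fitting an ordinary least-squares line of
events on event duration per session and dropping drinks with an absolute
raw residual above a threshold (3 event-count units by default).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BIN_S",
    "DENSITY_ETOH_SOLUTION",
    "DENSITY_ETOH",
    "ETOH_FRACTION",
    "LickRecord",
    "LickSession",
    "Drink",
    "MicrostructureSummary",
    "read_lick_log",
    "write_lick_log",
    "bin_to_drinks",
    "clean_events",
    "microstructure",
    "compute_intake",
    "intersession_intake",
]

#: Device write interval, seconds.
BIN_S = 3.0
#: Density of 20 % v/v ethanol in water, g/mL.
DENSITY_ETOH_SOLUTION = 0.9687
#: Density of absolute ethanol, g/mL.
DENSITY_ETOH = 0.78945
#: Volume fraction of ethanol in the drinking solution.
ETOH_FRACTION = 0.20

SEXES = ("male", "female")
FLUIDS = ("water", "alcohol")


@dataclass(frozen=True)
class LickRecord:
    """One occupied 3-s device window."""

    bin_start: float
    n_events: int
    event_duration: float


@dataclass
class LickSession:
    """One animal-session of 3-s-binned beam-break records plus weights.

    ``duration`` is 7200 s for Monday-Thursday sessions and 14400 s for the
    Friday session.  ``homecage_pre/post`` are the home-cage water bottle
    weights bracketing the inter-session interval (NaN when not measured).
    """

    animal_id: str
    sex: str
    fluid: str
    session_index: int
    week: int
    duration: float
    records: list[LickRecord] = field(default_factory=list)
    bottle_pre: float = math.nan
    bottle_post: float = math.nan
    body_weight: float = math.nan
    homecage_pre: float = math.nan
    homecage_post: float = math.nan

    def validate(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.fluid not in FLUIDS:
            raise ValueError(f"unknown fluid {self.fluid!r}")
        if self.duration <= 0:
            raise ValueError("session duration must be positive")
        prev = -math.inf
        for i, r in enumerate(self.records):
            row = i + 1
            if r.bin_start < 0 or r.bin_start >= self.duration:
                raise ValueError(f"record {row}: bin_start {r.bin_start} outside session")
            if abs(r.bin_start / BIN_S - round(r.bin_start / BIN_S)) > 1e-9:
                raise ValueError(f"record {row}: bin_start {r.bin_start} not a multiple of {BIN_S} s")
            if r.bin_start <= prev:
                raise ValueError(f"record {row}: bin_start values must be strictly increasing")
            if not 0.0 <= r.event_duration <= BIN_S + 1e-9:
                raise ValueError(
                    f"record {row}: event_duration {r.event_duration} outside [0, {BIN_S}] s"
                )
            if r.n_events < 1:
                raise ValueError(f"record {row}: stored records must have n_events >= 1")
            prev = r.bin_start
        if (
            math.isfinite(self.bottle_pre)
            and math.isfinite(self.bottle_post)
            and self.bottle_post > self.bottle_pre + 1e-9
        ):
            raise ValueError("bottle_post exceeds bottle_pre")

    @property
    def total_events(self) -> int:
        return int(sum(r.n_events for r in self.records))

    @property
    def total_event_duration(self) -> float:
        return float(sum(r.event_duration for r in self.records))


@dataclass
class Drink:
    """A contiguous drinking episode: merged run of consecutive occupied
    3-s windows.  ``records`` keeps the component windows so that
    window-resolved features (front-loading) survive the merge."""

    start: float
    end: float
    n_events: int
    event_duration: float
    records: list[LickRecord] = field(default_factory=list)

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class MicrostructureSummary:
    """Per-session drinking microstructure.  Undefined features are NaN:
    latency when there are no beam breaks at all, mean inter-drink interval
    with fewer than two drinks."""

    total_events: int
    total_event_duration: float
    n_drinks: int
    latency_to_drink: float
    mean_inter_drink_interval: float
    frontload_events: int
    intake: float = math.nan
    intersession_intake: float = math.nan
    # raw (pre-cleaning) session totals, exported alongside the cleaned ones
    total_events_raw: int = 0
    total_event_duration_raw: float = 0.0
    n_drinks_removed: int = 0


# ---------------------------------------------------------------------------
# I/O

_META_FIELDS = {
    "animal_id": str,
    "sex": str,
    "fluid": str,
    "session_index": int,
    "week": int,
    "duration": float,
    "bottle_pre": float,
    "bottle_post": float,
    "body_weight": float,
    "homecage_pre": float,
    "homecage_post": float,
}


def write_lick_log(session: LickSession, path: str | Path) -> None:
    """Write a lick session as CSV with ``# key=value`` metadata header
    lines followed by ``bin_start_s,n_events,event_duration_s`` rows."""
    path = Path(path)
    with open(path, "w") as fh:
        for key in _META_FIELDS:
            fh.write(f"# {key}={getattr(session, key)}\n")
        fh.write("bin_start_s,n_events,event_duration_s\n")
        for r in session.records:
            fh.write(f"{r.bin_start:.1f},{r.n_events},{r.event_duration:.6f}\n")


def read_lick_log(path: str | Path) -> LickSession:
    """Parse a lickometer log written by :func:`write_lick_log`.

    Malformed rows are reported with their line number in the file.
    """
    path = Path(path)
    meta: dict[str, object] = {}
    records: list[LickRecord] = []
    with open(path) as fh:
        lines = fh.readlines()
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ")
            if "=" not in body:
                raise ValueError(f"{path.name}:{lineno}: malformed metadata line")
            key, _, value = body.partition("=")
            key = key.strip()
            if key in _META_FIELDS:
                caster = _META_FIELDS[key]
                meta[key] = caster(value.strip())
            continue
        if not header_seen:
            cols = [c.strip() for c in line.split(",")]
            if cols != ["bin_start_s", "n_events", "event_duration_s"]:
                raise ValueError(
                    f"{path.name}:{lineno}: expected columns "
                    f"bin_start_s,n_events,event_duration_s, got {cols}"
                )
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise ValueError(f"{path.name}:{lineno}: expected 3 fields, got {len(parts)}")
        try:
            rec = LickRecord(float(parts[0]), int(parts[1]), float(parts[2]))
        except ValueError as exc:
            raise ValueError(f"{path.name}:{lineno}: {exc}") from exc
        records.append(rec)
    missing = {"animal_id", "sex", "fluid", "session_index", "week", "duration"} - set(meta)
    if missing:
        raise ValueError(f"{path.name}: missing metadata keys {sorted(missing)}")
    session = LickSession(records=records, **meta)  # type: ignore[arg-type]
    try:
        session.validate()
    except ValueError as exc:
        raise ValueError(f"{path.name}: {exc}") from exc
    return session


# ---------------------------------------------------------------------------
# Drinks


def bin_to_drinks(session: LickSession) -> list[Drink]:
    """Merge consecutive occupied 3-s windows into drinks.

    Windows whose ``bin_start`` values differ by exactly one device
    interval belong to the same drink; events and event durations sum over
    the merged windows.  Returns drinks sorted by start time.
    """
    session.validate()
    drinks: list[Drink] = []
    current: list[LickRecord] = []
    for rec in session.records:
        if current and abs(rec.bin_start - (current[-1].bin_start + BIN_S)) < 1e-9:
            current.append(rec)
        else:
            if current:
                drinks.append(_make_drink(current))
            current = [rec]
    if current:
        drinks.append(_make_drink(current))
    return drinks


def _make_drink(recs: list[LickRecord]) -> Drink:
    return Drink(
        start=recs[0].bin_start,
        end=recs[-1].bin_start + BIN_S,
        n_events=int(sum(r.n_events for r in recs)),
        event_duration=float(sum(r.event_duration for r in recs)),
        records=list(recs),
    )


@dataclass
class CleaningModel:
    slope: float
    intercept: float
    residuals: np.ndarray
    threshold: float


def clean_events(
    drinks: list[Drink], threshold: float = 3.0
) -> tuple[list[Drink], list[Drink], CleaningModel | None]:
    """Remove leak/chew artifacts from a session's drinks.

    Fits ``n_events = a + b * event_duration`` over the session's drinks
    and removes drinks whose absolute raw residual exceeds ``threshold``
    (event-count units).  The line is fit by the Theil-Sen estimator (the
    median of pairwise slopes; deterministic, no tuning) rather than
    ordinary least squares: leak artifacts are extreme *duration* values,
    i.e. high-leverage points that drag a least-squares line toward
    themselves until the artifacts look like inliers and ordinary drinks
    like outliers.  The robust line stays anchored to the session's clean
    events-per-second relationship, so the stated residual rule removes
    exactly the anomalous drinks.

    With fewer than 3 drinks, or a degenerate fit (all durations equal),
    the input is passed through untouched with a warning.
    """
    if len(drinks) < 3:
        if drinks:
            warnings.warn("fewer than 3 drinks; cleaning skipped", stacklevel=2)
        return list(drinks), [], None
    dur = np.array([d.event_duration for d in drinks], dtype=float)
    ev = np.array([d.n_events for d in drinks], dtype=float)
    if np.ptp(dur) == 0.0:
        warnings.warn("degenerate cleaning fit (all durations equal); cleaning skipped",
                      stacklevel=2)
        return list(drinks), [], None
    slope = float(stats.theilslopes(ev, dur)[0])
    # robust intercept: median residual about the Theil-Sen slope (scipy's
    # median(y) - slope*median(x) lets leaks/chews shift the two marginal
    # medians in opposite directions)
    intercept = float(np.median(ev - slope * dur))
    resid = ev - (intercept + slope * dur)
    model = CleaningModel(float(slope), float(intercept), resid, float(threshold))
    kept = [d for d, r in zip(drinks, resid) if abs(r) <= threshold]
    removed = [d for d, r in zip(drinks, resid) if abs(r) > threshold]
    return kept, removed, model


# ---------------------------------------------------------------------------
# Features


def microstructure(session: LickSession, drinks: list[Drink],
                   frontload_window_s: float = 1800.0) -> MicrostructureSummary:
    """Summarise a session given its cleaned drinks.

    Latency to drink is the first *raw* beam-break window (cleaning targets
    leaks and chews, not the animal's first approach); every other feature
    is computed over the cleaned drinks.  The mean inter-drink interval is
    the mean of successive drink start-to-start gaps; front-loading counts
    events in windows beginning within the first 30 min.
    """
    latency = session.records[0].bin_start if session.records else math.nan
    starts = [d.start for d in drinks]
    idi = float(np.mean(np.diff(starts))) if len(starts) >= 2 else math.nan
    frontload = int(
        sum(r.n_events for d in drinks for r in d.records if r.bin_start < frontload_window_s)
    )
    summary = MicrostructureSummary(
        total_events=int(sum(d.n_events for d in drinks)),
        total_event_duration=float(sum(d.event_duration for d in drinks)),
        n_drinks=len(drinks),
        latency_to_drink=latency,
        mean_inter_drink_interval=idi,
        frontload_events=frontload,
        total_events_raw=session.total_events,
        total_event_duration_raw=session.total_event_duration,
    )
    if (
        math.isfinite(session.bottle_pre)
        and math.isfinite(session.bottle_post)
        and math.isfinite(session.body_weight)
    ):
        summary.intake = compute_intake(
            session.bottle_pre, session.bottle_post, session.body_weight, session.fluid
        )
    if (
        math.isfinite(session.homecage_pre)
        and math.isfinite(session.homecage_post)
        and math.isfinite(session.body_weight)
    ):
        summary.intersession_intake = intersession_intake(
            session.homecage_pre, session.homecage_post, session.body_weight
        )
    return summary


def compute_intake(
    bottle_pre: float,
    bottle_post: float,
    body_weight: float,
    fluid: str,
    *,
    rho_solution: float = DENSITY_ETOH_SOLUTION,
    rho_ethanol: float = DENSITY_ETOH,
    ethanol_fraction: float = ETOH_FRACTION,
) -> float:
    """Session intake in g/kg from the bottle-weight difference.

    Water: grams of water per kg body weight.  Alcohol: grams of *ethanol*
    per kg -- the consumed solution mass is converted to volume with the
    20 % v/v solution density, and the ethanol volume fraction to grams
    with the density of ethanol.
    """
    if body_weight <= 0:
        raise ValueError("body weight must be positive")
    if bottle_pre < bottle_post - 1e-9:
        raise ValueError("negative consumption: bottle_post exceeds bottle_pre")
    consumed_g = max(bottle_pre - bottle_post, 0.0)
    bw_kg = body_weight / 1000.0
    if fluid == "water":
        return consumed_g / bw_kg
    if fluid == "alcohol":
        solution_ml = consumed_g / rho_solution
        ethanol_g = solution_ml * ethanol_fraction * rho_ethanol
        return ethanol_g / bw_kg
    raise ValueError(f"unknown fluid {fluid!r}")


def intersession_intake(homecage_pre: float, homecage_post: float, body_weight: float) -> float:
    """Home-cage water consumed between sessions, g/kg body weight."""
    return compute_intake(homecage_pre, homecage_post, body_weight, "water")


def summary_frame(sessions_and_summaries: list[tuple[LickSession, MicrostructureSummary]]
                  ) -> pd.DataFrame:
    """Tidy one-row-per-session table of microstructure features."""
    rows = []
    for session, summ in sessions_and_summaries:
        row = {
            "animal": session.animal_id,
            "sex": session.sex,
            "fluid": session.fluid,
            "week": session.week,
            "session": session.session_index,
            "duration_s": session.duration,
        }
        row.update(asdict(summ))
        rows.append(row)
    return pd.DataFrame(rows)
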