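"""Synthetic dual-fiber photometry and lickometer sessions with known
ground truth, so every downstream stage is testable by parameter recovery.

Signal model per fiber (415 = isosbestic, 470 = GCaMP):

    F415(t) = bleach(t) + motion(t) + noise
    F470(t) = s * bleach(t) + motion(t) + sum_i A_i * kernel(t - t_i) + noise

with ``bleach`` the same biexponential-plus-offset family the pipeline
fits, ``s`` the true inter-channel scale, ``motion`` additive boxcar
artifacts identical on both channels of a fiber, and one calcium transient
per drink whose amplitude depends on (sex, fluid, hemisphere).  The lick
stream is bout-structured: each bout is a regular run of beam breaks that
the 3-s device binning maps to one drink; slow-leak and chew artifacts can
be injected for testing the cleaning rule.

Everything is driven by a single integer seed; two runs with an equal
config are bit-identical.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .lickometer import LickRecord, LickSession, BIN_S
from .photometry import PhotometryRecording

__all__ = [
    "BleachParams",
    "KernelParams",
    "MotionParams",
    "BoutModel",
    "ArtifactInjection",
    "SimConfig",
    "GroundTruth",
    "LickEvent",
    "transient_kernel",
    "make_lick_schedule",
    "inject_artifacts",
    "bin_stream",
    "simulate_session",
    "default_amplitude_map",
    "write_session",
]

SIDES = ("left", "right")


def default_amplitude_map() -> dict[tuple[str, str, str], float]:
    """Mean transient amplitude (a.u.) per (sex, fluid, hemisphere).

    Mirrors the qualitative pattern of the recorded circuit: in males the
    left-hemisphere response is larger for alcohol than water while the
    right-hemisphere response is smaller; female effects are attenuated.
    """
    return {
        ("male", "water", "left"): 2.5,
        ("male", "alcohol", "left"): 4.0,
        ("male", "water", "right"): 2.5,
        ("male", "alcohol", "right"): 1.5,
        ("female", "water", "left"): 2.0,
        ("female", "alcohol", "left"): 2.4,
        ("female", "water", "right"): 2.2,
        ("female", "alcohol", "right"): 2.0,
    }


@dataclass
class BleachParams:
    """Biexponential photobleaching with offset, a.u. and seconds."""

    A1: float = 3.0
    tau1: float = 60.0
    A2: float = 5.0
    tau2: float = 900.0
    C: float = 10.0


@dataclass
class KernelParams:
    """Double-exponential indicator kinetics (slow GCaMP variant)."""

    rise_tau: float = 0.3
    decay_tau: float = 1.5


@dataclass
class MotionParams:
    """Additive boxcar artifacts shared by both channels of a fiber."""

    rate_per_min: float = 0.5
    amplitude: float = 2.0
    duration: float = 1.0


@dataclass
class BoutModel:
    """Bout-structured lick stream: ``n_bouts`` bouts, each a regular run
    of beam breaks at ``lick_rate_hz`` with per-break durations drawn
    around ``event_duration_mean`` (CV ``event_duration_cv``), separated
    by at least ``min_gap_s`` so bouts map to distinct drinks."""

    n_bouts: int = 40
    events_per_bout_mean: float = 20.0
    events_per_bout_dispersion: float = 2.0
    lick_rate_hz: float = 8.0
    event_duration_mean: float = 0.070
    event_duration_cv: float = 0.10
    min_gap_s: float = 10.0
    #: mean licks per burst; bursts within a bout are separated by pauses
    #: shorter than the 3-s device window, so the bout stays one drink
    burst_len_mean: float = 8.0
    pause_range_s: tuple = (0.5, 2.5)


@dataclass
class ArtifactInjection:
    n_leak_drinks: int = 0
    leak_duration_multiplier: float = 10.0
    n_chew_drinks: int = 0
    chew_event_multiplier: float = 10.0


@dataclass
class SimConfig:
    """Configuration of one simulated animal-session (both fibers)."""

    session_duration: float = 7200.0
    frame_rate: float = 15.0
    bleach_415: BleachParams = field(default_factory=BleachParams)
    channel_scale: float = 2.0
    kernel: KernelParams = field(default_factory=KernelParams)
    amplitude_map: dict = field(default_factory=default_amplitude_map)
    amplitude_cv: float = 0.10
    motion: MotionParams = field(default_factory=MotionParams)
    noise_sigma: float = 0.30
    bout_model: BoutModel = field(default_factory=BoutModel)
    artifacts: ArtifactInjection = field(default_factory=ArtifactInjection)
    sex: str = "male"
    fluid: str = "water"
    animal_id: str = "sim"
    session_index: int = 1
    intake_g: float = 0.8           # grams of solution removed from the bottle
    intersession_g: float = 4.0     # home-cage water consumed since last session
    body_weight_g: float = 26.0
    bottle_pre_g: float = 150.0
    homecage_pre_g: float = 300.0
    seed: int = 0

    @property
    def week(self) -> int:
        return (self.session_index - 1) // 5 + 1

    def validate(self) -> None:
        b = self.bleach_415
        if min(b.tau1, b.tau2) <= 0:
            raise ValueError("bleach time constants must be positive")
        k = self.kernel
        if k.rise_tau <= 0 or k.decay_tau <= 0:
            raise ValueError("kernel time constants must be positive")
        if k.rise_tau >= k.decay_tau:
            raise ValueError("kernel requires rise_tau < decay_tau")
        if _kernel_support(k.decay_tau) > self.session_duration:
            raise ValueError("transient kernel support exceeds session length")
        if self.session_duration <= 0 or self.frame_rate <= 0:
            raise ValueError("session duration and frame rate must be positive")
        if self.sex not in ("male", "female") or self.fluid not in ("water", "alcohol"):
            raise ValueError(f"unknown sex/fluid ({self.sex}, {self.fluid})")


@dataclass
class GroundTruth:
    """Latent values behind one simulated session."""

    bleach_415: BleachParams
    channel_scale: float
    drink_onsets: list[float]
    amplitudes: dict[str, list[float]]          # side -> per-drink amplitude
    motion_windows: dict[str, list[tuple[float, float]]]  # side -> (start, duration)
    leak_indices: list[int]
    chew_indices: list[int]
    intake_g: float
    n_frames: int


class LickEvent(NamedTuple):
    """One beam break: onset (s), broken duration (s), parent bout index."""

    onset: float
    duration: float
    bout: int


def _kernel_support(decay_tau: float) -> float:
    return 8.0 * decay_tau


def transient_kernel(rise_tau: float, decay_tau: float, dt: float) -> np.ndarray:
    """Unit-peak double-exponential kernel sampled at ``dt``.

    kernel(t) ∝ exp(-t/decay_tau) - exp(-t/rise_tau), normalized by its
    analytic peak value so max ≈ 1 (exactly 1 when the argmax
    t* = ln(decay/rise)·rise·decay/(decay-rise) lands on the grid);
    kernel(0) = 0 and the kernel is nonnegative everywhere.
    """
    if rise_tau <= 0 or decay_tau <= 0:
        raise ValueError("time constants must be positive")
    if rise_tau >= decay_tau:
        raise ValueError("requires rise_tau < decay_tau")
    t_star = np.log(decay_tau / rise_tau) * rise_tau * decay_tau / (decay_tau - rise_tau)
    peak = np.exp(-t_star / decay_tau) - np.exp(-t_star / rise_tau)
    t = np.arange(0.0, _kernel_support(decay_tau), dt)
    return (np.exp(-t / decay_tau) - np.exp(-t / rise_tau)) / peak


def make_lick_schedule(bout_model: BoutModel, session_duration: float, seed
                       ) -> list[LickEvent]:
    """Draw a bout-structured beam-break stream.

    Bout spans are laid out left to right with at least ``min_gap_s``
    between the end of one bout and the start of the next, remaining free
    time split randomly; raises when the requested bouts cannot fit.
    """
    rng = np.random.default_rng(seed)
    m = bout_model
    if m.n_bouts == 0:
        return []
    # bout sizes are overdispersed (real lick bouts range from single licks
    # to hundreds): shifted negative binomial, 1 + NB(r, p) with the
    # requested mean, capped so a single bout cannot swallow the session
    r = m.events_per_bout_dispersion
    mu = max(m.events_per_bout_mean - 1.0, 0.1)
    p = r / (r + mu)
    counts = 1 + rng.negative_binomial(r, p, m.n_bouts)
    counts = np.minimum(counts, int(60.0 * m.lick_rate_hz))
    spacing = 1.0 / m.lick_rate_hz
    lo_pause, hi_pause = m.pause_range_s
    if hi_pause >= BIN_S:
        raise ValueError("intra-bout pauses must stay below the 3-s device window")
    offsets_per_bout = []
    durations = []
    for c in counts:
        d = rng.normal(m.event_duration_mean, m.event_duration_cv * m.event_duration_mean, c)
        durations.append(np.clip(d, 0.005, 0.9 * spacing))
        # licks come in bursts; a pause (< 3 s) follows each burst
        steps = np.full(c, spacing)
        if m.burst_len_mean > 0 and c > 1:
            breaks = rng.random(c - 1) < 1.0 / m.burst_len_mean
            steps[1:][breaks] += rng.uniform(lo_pause, hi_pause, int(breaks.sum()))
        offsets_per_bout.append(np.concatenate([[0.0], np.cumsum(steps[1:])]))
    spans = np.array(
        [off[-1] + d[-1] for off, d in zip(offsets_per_bout, durations)]
    )
    free = session_duration - spans.sum() - m.n_bouts * m.min_gap_s - 1.0
    if free < 0:
        raise ValueError("infeasible schedule: bouts do not fit in the session")
    weights = rng.random(m.n_bouts + 1)
    gaps = weights / weights.sum() * free
    events: list[LickEvent] = []
    cursor = gaps[0]
    for b in range(m.n_bouts):
        start = cursor
        for j in range(counts[b]):
            events.append(LickEvent(start + offsets_per_bout[b][j], float(durations[b][j]), b))
        cursor = start + spans[b] + m.min_gap_s + gaps[b + 1]
    return events


def inject_artifacts(events: list[LickEvent], injection: ArtifactInjection, seed,
                     session_duration: float | None = None
                     ) -> tuple[list[LickEvent], dict[str, list[int]]]:
    """Inject slow-leak and chew artifacts into a lick stream.

    Leak bouts keep their event count but have every break duration
    multiplied (slow dribble: long duration, few events); chew bouts gain
    near-zero-duration breaks (many events, negligible duration).  Returns
    the modified stream and the injected bout/drink indices.
    """
    rng = np.random.default_rng(seed)
    n_leak, n_chew = injection.n_leak_drinks, injection.n_chew_drinks
    if n_leak == 0 and n_chew == 0:
        return list(events), {"leak": [], "chew": []}
    bouts = sorted({e.bout for e in events})
    if n_leak + n_chew > len(bouts):
        raise ValueError("more artifact injections requested than drinks")
    by_bout: dict[int, list[LickEvent]] = {b: [] for b in bouts}
    for e in events:
        by_bout[e.bout].append(e)
    starts = {b: min(e.onset for e in evs) for b, evs in by_bout.items()}
    ends = {b: max(e.onset + e.duration for e in evs) for b, evs in by_bout.items()}
    session_edge = session_duration - 1.0 if session_duration is not None else np.inf
    next_start = {
        b: min([starts[b2] for b2 in bouts if starts[b2] > starts[b]], default=np.inf)
        for b in bouts
    }
    # leak bouts stretch in time; only bouts with room before the next bout
    # (or session edge) are eligible, so injected indices stay valid drinks
    leak_candidates = []
    for b in bouts:
        total = sum(e.duration for e in by_bout[b])
        needed = total * injection.leak_duration_multiplier + 0.06 * len(by_bout[b]) + 7.0
        limit = next_start[b] - 7.0 if np.isfinite(next_start[b]) else session_edge
        if starts[b] + needed < limit:
            leak_candidates.append(b)
    if len(leak_candidates) < n_leak:
        raise ValueError("not enough room to inject the requested leak drinks")
    leak = sorted(rng.choice(leak_candidates, size=n_leak, replace=False).tolist()) if n_leak else []
    chew_pool = [b for b in bouts if b not in leak]
    chew = sorted(rng.choice(chew_pool, size=n_chew, replace=False).tolist()) if n_chew else []
    out: list[LickEvent] = []
    for b in bouts:
        evs = sorted(by_bout[b], key=lambda e: e.onset)
        if b in leak:
            cursor = starts[b]
            for e in evs:
                d = e.duration * injection.leak_duration_multiplier
                out.append(LickEvent(cursor, d, b))
                cursor += d + 0.05
        elif b in chew:
            out.extend(evs)
            n_extra = int(round((injection.chew_event_multiplier - 1) * len(evs)))
            span = max(ends[b] - starts[b], 0.01)
            extras = starts[b] + rng.random(n_extra) * span
            out.extend(LickEvent(float(t), 0.001, b) for t in extras)
        else:
            out.extend(evs)
    out.sort(key=lambda e: e.onset)
    return out, {"leak": leak, "chew": chew}


def bin_stream(events: list[LickEvent], session_duration: float) -> list[LickRecord]:
    """Emulate the device: aggregate beam breaks into 3-s windows.

    Events are counted in the window containing their onset; broken time
    is apportioned to the windows it overlaps.  Only occupied windows are
    stored, as on the hardware.
    """
    counts: dict[int, int] = {}
    durs: dict[int, float] = {}
    for e in events:
        if e.onset < 0 or e.onset + e.duration > session_duration + 1e-9:
            raise ValueError("event extends past the session end")
        w0 = int(e.onset // BIN_S)
        counts[w0] = counts.get(w0, 0) + 1
        t, remaining = e.onset, e.duration
        while remaining > 1e-12:
            w = int(t // BIN_S)
            upper = (w + 1) * BIN_S
            d = min(remaining, upper - t)
            durs[w] = durs.get(w, 0.0) + d
            t += d
            remaining -= d
    windows = sorted(set(counts) | set(durs))
    return [
        LickRecord(w * BIN_S, counts.get(w, 0) or 1, min(durs.get(w, 0.0), BIN_S))
        for w in windows
        if counts.get(w, 0) >= 1 or durs.get(w, 0.0) > 0
    ]


def simulate_session(config: SimConfig
                     ) -> tuple[PhotometryRecording, PhotometryRecording, LickSession, GroundTruth]:
    """Generate one animal-session: left and right fiber recordings, the
    binned lick session and the latent ground truth."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (s_sched, s_art, s_amp, s_motion, s_noise_l, s_noise_r) = ss.spawn(6)

    events = make_lick_schedule(config.bout_model, config.session_duration, s_sched)
    events, injected = inject_artifacts(events, config.artifacts, s_art,
                                        session_duration=config.session_duration)
    records = bin_stream(events, config.session_duration)

    # transient onsets: first beam break of each bout (= drink start)
    onsets: dict[int, float] = {}
    for e in events:
        onsets.setdefault(e.bout, e.onset)
        onsets[e.bout] = min(onsets[e.bout], e.onset)
    drink_onsets = [onsets[b] for b in sorted(onsets)]

    n_frames = int(round(config.frame_rate * config.session_duration))
    t = np.arange(n_frames) / config.frame_rate
    b = config.bleach_415
    bleach = b.A1 * np.exp(-t / b.tau1) + b.A2 * np.exp(-t / b.tau2) + b.C
    kern = transient_kernel(config.kernel.rise_tau, config.kernel.decay_tau,
                            1.0 / config.frame_rate)

    rng_amp = np.random.default_rng(s_amp)
    rng_motion = np.random.default_rng(s_motion)
    amplitudes: dict[str, list[float]] = {}
    motion_windows: dict[str, list[tuple[float, float]]] = {}
    recs = {}
    for side, s_noise in zip(SIDES, (s_noise_l, s_noise_r)):
        mean_amp = config.amplitude_map[(config.sex, config.fluid, side)]
        amp = rng_amp.normal(mean_amp, config.amplitude_cv * mean_amp, len(drink_onsets))
        amp = np.maximum(amp, 0.0)
        amplitudes[side] = [float(a) for a in amp]

        transients = np.zeros(n_frames)
        for onset, a in zip(drink_onsets, amp):
            i0 = int(round(onset * config.frame_rate))
            seg = kern[: n_frames - i0]
            transients[i0 : i0 + len(seg)] += a * seg

        m = config.motion
        n_motion = rng_motion.poisson(m.rate_per_min / 60.0 * config.session_duration)
        motion = np.zeros(n_frames)
        wins = []
        for _ in range(n_motion):
            start = rng_motion.uniform(0.0, max(config.session_duration - m.duration, 0.0))
            i0 = int(round(start * config.frame_rate))
            i1 = min(i0 + int(round(m.duration * config.frame_rate)), n_frames)
            motion[i0:i1] += m.amplitude
            wins.append((float(start), float(m.duration)))
        motion_windows[side] = wins

        rng_noise = np.random.default_rng(s_noise)
        f415 = bleach + motion + rng_noise.normal(0.0, config.noise_sigma, n_frames)
        f470 = (config.channel_scale * bleach + motion + transients
                + rng_noise.normal(0.0, config.noise_sigma, n_frames))
        recs[side] = PhotometryRecording(
            side, t, f415, f470, config.frame_rate,
            meta={"animal_id": config.animal_id, "session_index": config.session_index},
        )

    lick = LickSession(
        animal_id=config.animal_id,
        sex=config.sex,
        fluid=config.fluid,
        session_index=config.session_index,
        week=config.week,
        duration=config.session_duration,
        records=records,
        bottle_pre=config.bottle_pre_g,
        bottle_post=config.bottle_pre_g - config.intake_g,
        body_weight=config.body_weight_g,
        homecage_pre=config.homecage_pre_g,
        homecage_post=config.homecage_pre_g - config.intersession_g,
    )
    lick.validate()

    truth = GroundTruth(
        bleach_415=b,
        channel_scale=config.channel_scale,
        drink_onsets=[float(x) for x in drink_onsets],
        amplitudes=amplitudes,
        motion_windows=motion_windows,
        leak_indices=injected["leak"],
        chew_indices=injected["chew"],
        intake_g=config.intake_g,
        n_frames=n_frames,
    )
    return recs["left"], recs["right"], lick, truth


def write_session(
    out_dir: str | Path,
    rec_left: PhotometryRecording,
    rec_right: PhotometryRecording,
    lick: LickSession,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write one simulated session to disk: lick CSV, per-fiber photometry
    CSVs and ground-truth JSON."""
    from .lickometer import write_lick_log
    from .photometry import write_photometry_csv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{lick.animal_id}_s{lick.session_index:02d}"
    paths = {
        "lick": out_dir / f"{stem}_lick.csv",
        "photometry_left": out_dir / f"{stem}_left.csv",
        "photometry_right": out_dir / f"{stem}_right.csv",
        "truth": out_dir / f"{stem}_truth.json",
    }
    write_lick_log(lick, paths["lick"])
    write_photometry_csv([rec_left], paths["photometry_left"])
    write_photometry_csv([rec_right], paths["photometry_right"])
    with open(paths["truth"], "w") as fh:
        json.dump(asdict(truth), fh, indent=1, sort_keys=True)
    return paths
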