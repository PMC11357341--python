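"""Two-channel fiber-photometry preprocessing: raw 415/470 nm frame series
to per-session z-scored ΔF/F with QC.

Stage order is fixed:

    trim -> biexponential bleach fit (415) -> [shared-artifact censoring]
         -> RANSAC scaling -> 6 Hz lowpass (470) -> ΔF/F -> session z-score

The 415 nm isosbestic channel is calcium-independent, so it carries only
photobleaching, shared motion artifacts and noise.  Bleaching is modelled
as a biexponential decay with offset; the fitted curve is robustly scaled
onto the 470 nm channel (RANSAC, so calcium transients and artifact frames
do not bias the scaling) and the 470 signal is divided by that scaled fit.
Frames where the isosbestic channel departs from its own bleach fit mark
shared artifacts (fiber motion, cable snags) and are censored from the 470
channel by interpolation before scaling and filtering.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, signal

__all__ = [
    "ControlFitError",
    "PhotometryRecording",
    "BleachFit",
    "ScaledControl",
    "DffTrace",
    "QCThresholds",
    "QCResult",
    "trim_frames",
    "fit_biexponential",
    "censor_shared_artifacts",
    "ransac_scale",
    "lowpass",
    "compute_dff",
    "zscore_session",
    "qc_recording",
    "process_recording",
    "read_photometry_csv",
    "write_photometry_csv",
    "write_dff_csv",
]


class ControlFitError(ValueError):
    """Raised when the scaled control fit is unusable (nonpositive)."""


@dataclass
class PhotometryRecording:
    """Paired 415/470 nm frame series from one fiber on a uniform clock."""

    fiber_side: str
    time: np.ndarray
    F415: np.ndarray
    F470: np.ndarray
    frame_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.F415 = np.asarray(self.F415, dtype=float)
        self.F470 = np.asarray(self.F470, dtype=float)
        if not (len(self.time) == len(self.F415) == len(self.F470)):
            raise ValueError("time, F415 and F470 must have equal length")
        if len(self.time) >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if np.ptp(dt) > 1e-6:
                raise ValueError("time grid not uniform within 1e-6 s")

    @property
    def n_frames(self) -> int:
        return len(self.time)


@dataclass
class BleachFit:
    """Biexponential bleach model F(t) = A1 e^(-t/τ1) + A2 e^(-t/τ2) + C
    with τ1 <= τ2, fitted to the isosbestic channel."""

    A1: float
    tau1: float
    A2: float
    tau2: float
    C: float
    r_squared: float
    curve: np.ndarray
    converged: bool = True
    reason: str = ""


@dataclass
class ScaledControl:
    slope: float
    intercept: float
    inlier_mask: np.ndarray
    scaled_fit: np.ndarray

    @property
    def inlier_fraction(self) -> float:
        return float(np.mean(self.inlier_mask))


@dataclass
class QCThresholds:
    """QC gates; the study's own exclusions (poor bleach fits, excessive
    motion, cable tangles) were manual, so every gate is configurable."""

    r2_min: float = 0.8
    inlier_fraction_min: float = 0.5
    excursion_z: float = 10.0
    excursion_dwell_s: float = 1.0


@dataclass
class QCResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)

    @property
    def reason(self) -> str:
        return "; ".join(self.reasons)


@dataclass
class DffTrace:
    """Corrected, filtered, session-z-scored ΔF/F for one fiber.
    ``clock_offset`` is the seconds removed by frame trimming, so event
    timestamps on the acquisition clock map onto ``time`` by subtraction."""

    time: np.ndarray
    dff: np.ndarray | None
    zdff: np.ndarray | None
    qc: QCResult
    clock_offset: float
    frame_rate: float


# ---------------------------------------------------------------------------
# Pipeline stages


def trim_frames(rec: PhotometryRecording, n: int = 300) -> PhotometryRecording:
    """Drop the first ``n`` frames of both channels; time is re-zeroed and
    the removed span is recorded in ``meta['clock_offset']``."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n >= rec.n_frames:
        raise ValueError(f"cannot trim {n} frames from a {rec.n_frames}-frame recording")
    if n == 0:
        return rec
    t = rec.time[n:]
    offset = float(t[0] - rec.time[0]) + float(rec.meta.get("clock_offset", 0.0))
    meta = dict(rec.meta)
    meta["clock_offset"] = offset
    return PhotometryRecording(
        rec.fiber_side, t - t[0], rec.F415[n:].copy(), rec.F470[n:].copy(),
        rec.frame_rate, meta,
    )


def _biexp(t: np.ndarray, A1: float, tau1: float, A2: float, tau2: float, C: float
           ) -> np.ndarray:
    return A1 * np.exp(-t / tau1) + A2 * np.exp(-t / tau2) + C


def fit_biexponential(time: np.ndarray, F415: np.ndarray,
                      max_points: int = 2000) -> BleachFit:
    """Nonlinear least-squares biexponential fit to the isosbestic channel.

    Deterministic: a fixed initialization heuristic (offset from the last
    decile's median, amplitudes split from the first frame, time constants
    at 5 % and 50 % of the trace span) and no random restarts.  The fit is
    evaluated on an evenly subsampled grid of at most ``max_points`` frames
    -- the bleach curve is smooth, so subsampling loses nothing -- while r²
    is computed on the full trace.  Non-convergence yields a flagged fit
    (``converged=False``) that downstream QC rejects.
    """
    time = np.asarray(time, dtype=float)
    F415 = np.asarray(F415, dtype=float)
    n = len(time)
    if n < 100:
        raise ValueError("need at least 100 frames to fit the bleach model")
    if not (np.all(np.isfinite(time)) and np.all(np.isfinite(F415))):
        raise ValueError("non-finite values in bleach-fit input")
    t0 = time - time[0]
    span = float(t0[-1]) if t0[-1] > 0 else 1.0
    sub = np.unique(np.round(np.linspace(0, n - 1, min(max_points, n))).astype(int))
    C0 = float(np.median(F415[int(0.9 * n):]))
    A0 = max(float(F415[0]) - C0, 1e-9)
    p0 = [A0 / 2, 0.05 * span, A0 / 2, 0.5 * span, max(C0, 0.0)]
    bounds = ([0.0, 1e-3, 0.0, 1e-3, 0.0],
              [np.inf, 100 * span, np.inf, 100 * span, np.inf])
    converged, reason = True, ""
    try:
        popt, _ = optimize.curve_fit(
            _biexp, t0[sub], F415[sub], p0=p0, bounds=bounds, max_nfev=5000,
        )
    except (RuntimeError, ValueError) as exc:
        converged, reason = False, f"bleach fit failed: {exc}"
        popt = np.array([0.0, 0.05 * span, 0.0, 0.5 * span, float(np.mean(F415))])
    A1, tau1, A2, tau2, C = (float(v) for v in popt)
    if tau1 > tau2:
        A1, tau1, A2, tau2 = A2, tau2, A1, tau1
    curve = _biexp(t0, A1, tau1, A2, tau2, C)
    ss_res = float(np.sum((F415 - curve) ** 2))
    ss_tot = float(np.sum((F415 - np.mean(F415)) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res < 1e-12 * n else 0.0
    return BleachFit(A1, tau1, A2, tau2, C, r2, curve, converged, reason)


def censor_shared_artifacts(
    F415: np.ndarray,
    bleach_curve: np.ndarray,
    F470: np.ndarray,
    nsigma: float = 4.0,
    close_samples: int = 7,
    pad_samples: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Censor channel-shared artifact frames from the 470 channel.

    The isosbestic residual ``F415 - bleach_curve`` carries no calcium
    signal, so frames where it exceeds ``nsigma`` robust standard
    deviations (1.4826 x MAD) flag shared artifacts.  Flagged runs are
    morphologically closed (to bridge gaps up to ``close_samples``),
    padded by ``pad_samples`` on each side and replaced in F470 by linear
    interpolation from the surrounding clean frames.

    Returns the censored F470 copy and the boolean censor mask.
    """
    resid = np.asarray(F415, dtype=float) - np.asarray(bleach_curve, dtype=float)
    med = np.median(resid)
    sigma = 1.4826 * np.median(np.abs(resid - med))
    F470 = np.asarray(F470, dtype=float)
    if sigma <= 0:
        return F470.copy(), np.zeros(len(F470), dtype=bool)
    mask = np.abs(resid - med) > nsigma * sigma
    if close_samples > 1:
        mask = ndimage.binary_closing(mask, structure=np.ones(close_samples, dtype=bool))
    if pad_samples > 0:
        mask = ndimage.binary_dilation(mask, structure=np.ones(2 * pad_samples + 1, dtype=bool))
    if mask.all():
        warnings.warn("all frames flagged as shared artifacts; censoring skipped",
                      stacklevel=2)
        return F470.copy(), np.zeros(len(F470), dtype=bool)
    if not mask.any():
        return F470.copy(), mask
    out = F470.copy()
    idx = np.arange(len(F470))
    out[mask] = np.interp(idx[mask], idx[~mask], F470[~mask])
    return out, mask


def ransac_scale(fitted_curve: np.ndarray, F470: np.ndarray, seed,
                 max_trials: int = 100, min_samples: int = 2) -> ScaledControl:
    """Robust linear scaling of the bleach fit onto the 470 nm channel.

    RANSAC with two-point minimal samples: the residual threshold is
    1.4826 x MAD of an initial OLS residual, ``max_trials`` candidate lines
    are scored by consensus size, and the winner is refit by OLS on its
    inliers.  Calcium transients and artifact frames land outside the
    consensus set, so they do not bias the scaling.  Deterministic given
    ``seed``.
    """
    x = np.asarray(fitted_curve, dtype=float)
    y = np.asarray(F470, dtype=float)
    if len(x) != len(y):
        raise ValueError("fitted_curve and F470 must have equal length")
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct fitted-curve values")
    if seed is None:
        raise ValueError("ransac_scale requires a seed")
    slope0, icpt0 = np.polyfit(x, y, 1)
    resid0 = y - (slope0 * x + icpt0)
    thr = 1.4826 * float(np.median(np.abs(resid0 - np.median(resid0))))
    thr = max(thr, 1e-12 * max(1.0, float(np.max(np.abs(y)))))
    rng = np.random.default_rng(seed)
    n = len(x)
    pairs = rng.integers(0, n, size=(max_trials, max(min_samples, 2)))
    best_count, best = -1, (float(slope0), float(icpt0))
    for i0, i1 in pairs[:, :2]:
        if x[i0] == x[i1]:
            continue
        s = (y[i1] - y[i0]) / (x[i1] - x[i0])
        c = y[i0] - s * x[i0]
        count = int(np.count_nonzero(np.abs(y - (s * x + c)) <= thr))
        if count > best_count:
            best_count, best = count, (float(s), float(c))
    inl = np.abs(y - (best[0] * x + best[1])) <= thr
    if inl.sum() >= 2 and np.ptp(x[inl]) > 0:
        slope, icpt = (float(v) for v in np.polyfit(x[inl], y[inl], 1))
    else:  # pathological consensus; keep the candidate line
        slope, icpt = best
    mask = np.abs(y - (slope * x + icpt)) <= thr
    return ScaledControl(slope, icpt, mask, slope * x + icpt)


def lowpass(x: np.ndarray, frame_rate: float, cutoff: float = 6.0) -> np.ndarray:
    """Zero-phase (forward-backward) second-order Butterworth lowpass with
    unit DC gain.  Skipped with a warning when the frame rate cannot
    support the cutoff (Nyquist)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in lowpass input")
    if frame_rate <= 2 * cutoff:
        warnings.warn(
            f"frame rate {frame_rate} Hz cannot support a {cutoff} Hz lowpass; skipped",
            stacklevel=2,
        )
        return x.copy()
    sos = signal.butter(2, cutoff, btype="low", fs=frame_rate, output="sos")
    return signal.sosfiltfilt(sos, x)


def compute_dff(F470_filtered: np.ndarray, scaled_fit: np.ndarray,
                mode: str = "ratio") -> np.ndarray:
    """ΔF/F of the corrected 470 channel against the scaled control fit.

    ``ratio`` is the literal quotient F470/fit; ``subtract`` is
    (F470 - fit)/fit.  The two differ by exactly 1.0 pointwise and are
    identical after session z-scoring.
    """
    scaled_fit = np.asarray(scaled_fit, dtype=float)
    if np.any(scaled_fit <= 0):
        raise ControlFitError("nonpositive control fit")
    ratio = np.asarray(F470_filtered, dtype=float) / scaled_fit
    if mode == "ratio":
        return ratio
    if mode == "subtract":
        return ratio - 1.0
    raise ValueError(f"unknown dff mode {mode!r}")


def zscore_session(dff: np.ndarray) -> np.ndarray:
    """z-score over the whole session trace for one fiber."""
    dff = np.asarray(dff, dtype=float)
    sd = float(np.std(dff))
    if sd == 0:
        raise ValueError("zero-variance trace cannot be z-scored")
    return (dff - np.mean(dff)) / sd


def qc_recording(fit: BleachFit, scaled: ScaledControl, dff: np.ndarray | None,
                 frame_rate: float, thresholds: QCThresholds | None = None) -> QCResult:
    """Machine-readable QC verdict for one recording."""
    thr = thresholds or QCThresholds()
    reasons: list[str] = []
    if not fit.converged or fit.r_squared < thr.r2_min:
        reasons.append("poor bleach fit")
    if scaled.inlier_fraction < thr.inlier_fraction_min:
        reasons.append("excessive motion artifacts")
    if dff is None:
        reasons.append("nonpositive control fit")
    else:
        sd = float(np.std(dff))
        if sd == 0:
            reasons.append("zero-variance trace")
        else:
            z = (dff - np.mean(dff)) / sd
            dwell = int(np.ceil(thr.excursion_dwell_s * frame_rate))
            exc = np.abs(z) > thr.excursion_z
            if exc.any():
                run = np.convolve(exc.astype(int), np.ones(dwell, dtype=int), mode="valid")
                if np.any(run == dwell):
                    reasons.append("excessive excursions")
    return QCResult(passed=not reasons, reasons=reasons)


def process_recording(
    rec: PhotometryRecording,
    seed,
    *,
    n_trim: int = 300,
    cutoff_hz: float = 6.0,
    dff_mode: str = "ratio",
    censor: bool = True,
    censor_nsigma: float = 4.0,
    fit_max_points: int = 2000,
    qc_thresholds: QCThresholds | None = None,
) -> tuple[DffTrace, dict]:
    """Full preprocessing chain for one recording.

    Returns the :class:`DffTrace` (``dff``/``zdff`` are None when the
    control fit is unusable) plus a diagnostics dict with the bleach fit,
    the scaled control and the censor mask.
    """
    trimmed = trim_frames(rec, n_trim)
    fit = fit_biexponential(trimmed.time, trimmed.F415, max_points=fit_max_points)
    f470 = trimmed.F470
    censored = np.zeros(trimmed.n_frames, dtype=bool)
    if censor:
        f470, censored = censor_shared_artifacts(
            trimmed.F415, fit.curve, f470, nsigma=censor_nsigma
        )
    scaled = ransac_scale(fit.curve, f470, seed)
    f470_filt = lowpass(f470, rec.frame_rate, cutoff_hz)
    dff: np.ndarray | None
    try:
        dff = compute_dff(f470_filt, scaled.scaled_fit, dff_mode)
    except ControlFitError:
        dff = None
    zdff = None
    if dff is not None and np.std(dff) > 0:
        zdff = zscore_session(dff)
    qc = qc_recording(fit, scaled, dff, rec.frame_rate, qc_thresholds)
    trace = DffTrace(
        time=trimmed.time,
        dff=dff,
        zdff=zdff,
        qc=qc,
        clock_offset=float(trimmed.meta.get("clock_offset", 0.0)),
        frame_rate=rec.frame_rate,
    )
    return trace, {"fit": fit, "scaled": scaled, "censored": censored}


# ---------------------------------------------------------------------------
# I/O


def write_photometry_csv(recordings: list[PhotometryRecording], path: str | Path) -> None:
    """Write one or more fibers' frames as long-format CSV
    (frame_index,time_s,region,channel_nm,fluorescence)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# frame_rate={recordings[0].frame_rate}\n")
        for key, value in sorted(recordings[0].meta.items()):
            fh.write(f"# {key}={value}\n")
        fh.write("frame_index,time_s,region,channel_nm,fluorescence\n")
        for rec in recordings:
            for channel, series in (("415", rec.F415), ("470", rec.F470)):
                for i, (t, f) in enumerate(zip(rec.time, series)):
                    fh.write(f"{i},{t:.10f},{rec.fiber_side},{channel},{f:.6f}\n")


def read_photometry_csv(path: str | Path) -> list[PhotometryRecording]:
    """Read a long-format photometry CSV into one recording per region."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line.lstrip("# ").strip()
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    required = {"frame_index", "time_s", "region", "channel_nm", "fluorescence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
    frame_rate = float(meta.pop("frame_rate", "nan"))
    if not np.isfinite(frame_rate):
        raise ValueError(f"{path.name}: missing frame_rate metadata")
    recs = []
    for region, sub in df.groupby("region", sort=True):
        channels = {}
        time = None
        for channel, chunk in sub.groupby("channel_nm"):
            chunk = chunk.sort_values("frame_index")
            channels[str(channel)] = chunk["fluorescence"].to_numpy()
            time = chunk["time_s"].to_numpy()
        if "415" not in channels or "470" not in channels:
            raise ValueError(f"{path.name}: region {region} lacks a 415 or 470 channel")
        recs.append(
            PhotometryRecording(str(region), time, channels["415"], channels["470"],
                                frame_rate, dict(meta))
        )
    return recs


def write_dff_csv(trace: DffTrace, region: str, path: str | Path) -> None:
    """Per-session ΔF/F CSV (time_s, region, dff, zdff)."""
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "region": region,
            "dff": trace.dff if trace.dff is not None else np.nan,
            "zdff": trace.zdff if trace.zdff is not None else np.nan,
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")
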