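"""Cohort-level aggregation: weekly means, pooled quartile binning, robust
(Shepherd) correlation and the inter-session-intake correlation.

Animal is the experimental unit throughout: weekly summaries average
within animal first, then across animals.  Inferential models (mixed
ANOVA, ANCOVA, post-hoc corrections) are deliberately not reimplemented;
the pipeline exports tidy tables any stats package can consume.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QuartileAssignment",
    "ShepherdResult",
    "weekly_aggregate",
    "quartile_bin",
    "shepherds_pi",
    "correlate_intersession",
    "build_cohort_table",
]


@dataclass
class QuartileAssignment:
    """Quartile labels over a pooled set of values.

    Breakpoints are the 25/50/75th percentiles (linear interpolation
    between order statistics, pooled over all water and alcohol sessions);
    values landing exactly on a breakpoint take the lower quartile.
    """

    breakpoints: np.ndarray
    labels: list[str]

    def counts(self) -> dict[str, int]:
        out = {f"Q{i}": 0 for i in range(1, 5)}
        for lab in self.labels:
            out[lab] += 1
        return out


@dataclass
class ShepherdResult:
    pi: float
    p: float
    outlier_mask: np.ndarray
    n_used: int


def weekly_aggregate(table: pd.DataFrame, measure: str
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weekly means of ``measure``: per (animal, week), then per (sex, week)
    mean ± SEM over animals (SEM NaN for single-animal groups)."""
    if table.empty:
        raise ValueError("empty cohort table")
    for col in ("animal", "sex", "week", measure):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    per_animal = (
        table.groupby(["animal", "sex", "week"], as_index=False)[measure]
        .mean()
        .rename(columns={measure: f"{measure}_mean"})
    )
    grouped = per_animal.groupby(["sex", "week"])[f"{measure}_mean"]
    per_group = grouped.agg(
        mean="mean",
        sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) >= 2 else np.nan,
        n="count",
    ).reset_index()
    return per_animal, per_group


def quartile_bin(values) -> QuartileAssignment:
    """Assign pooled values to quartiles Q1..Q4."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values for quartile binning")
    breakpoints = np.percentile(v, [25, 50, 75])  # linear interpolation
    if breakpoints[0] == breakpoints[2]:
        warnings.warn("degenerate quartiles (ties dominate); all values labelled Q1",
                      stacklevel=2)
    idx = np.searchsorted(breakpoints, v, side="left")  # ties -> lower quartile
    labels = [f"Q{i + 1}" for i in idx]
    return QuartileAssignment(breakpoints, labels)


def _bootstrap_mahalanobis(xy: np.ndarray, n_boot: int, rng: np.random.Generator
                           ) -> np.ndarray:
    """Mean squared Mahalanobis distance of every point from the center and
    covariance of bootstrap resamples (the Shepherd outlier statistic)."""
    n = xy.shape[0]
    d2 = np.zeros(n)
    for _ in range(n_boot):
        sample = xy[rng.integers(0, n, n)]
        mu = sample.mean(axis=0)
        cov = np.cov(sample, rowvar=False)
        inv = np.linalg.pinv(cov)  # pinv: collinear data stays finite
        diff = xy - mu
        d2 += np.einsum("ij,jk,ik->i", diff, inv, diff)
    return d2 / n_boot


def shepherds_pi(x, y, n_boot: int = 200, seed=None, threshold: float = 6.0
                 ) -> ShepherdResult:
    """Spearman correlation after removing bivariate outliers.

    Outliers are points whose bootstrapped squared Mahalanobis distance
    from the bivariate center exceeds ``threshold``; the Spearman
    correlation is computed on the retained pairs and its p-value doubled
    as the Shepherd correction for the data-driven exclusion.
    Deterministic given ``seed``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    finite = np.isfinite(x) & np.isfinite(y)
    if not finite.all():
        raise ValueError("x and y must be finite")
    if x.size < 10:
        raise ValueError("need at least 10 pairs")
    rng = np.random.default_rng(seed)
    xy = np.column_stack([x, y])
    d2 = _bootstrap_mahalanobis(xy, n_boot, rng)
    outlier = d2 > threshold
    keep = ~outlier
    if keep.sum() < 10:
        raise ValueError("fewer than 10 pairs retained after outlier removal")
    rho, p = stats.spearmanr(x[keep], y[keep])
    return ShepherdResult(float(rho), float(min(1.0, 2.0 * p)), outlier, int(keep.sum()))


def correlate_intersession(
    table: pd.DataFrame,
    fluid: str = "water",
    n_boot: int = 200,
    seed=None,
) -> dict[str, dict]:
    """Correlate the previous inter-session water intake with the next
    session's intake, overall and per sex.

    Expects one row per animal-session with ``intersession_intake`` (the
    home-cage water consumed since the last session, g/kg) and ``intake``
    (the session's g/kg) columns.  Returns per-stratum Shepherd's pi, its
    p-value and the pair count; strata with fewer than 10 pairs are
    reported with ``pi`` None.
    """
    needed = {"sex", "fluid", "intersession_intake", "intake"}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    sub = table[table["fluid"] == fluid]
    sub = sub[np.isfinite(sub["intersession_intake"]) & np.isfinite(sub["intake"])]
    if len(sub) < 10:
        raise ValueError(f"insufficient pairs for fluid {fluid!r} ({len(sub)})")
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(3)
    out: dict[str, dict] = {}
    for (name, block), child in zip(
        [("overall", sub), ("male", sub[sub["sex"] == "male"]),
         ("female", sub[sub["sex"] == "female"])],
        seeds,
    ):
        if len(block) < 10:
            out[name] = {"pi": None, "p": None, "n": int(len(block))}
            continue
        try:
            res = shepherds_pi(
                block["intersession_intake"].to_numpy(),
                block["intake"].to_numpy(),
                n_boot=n_boot,
                seed=child,
            )
        except ValueError as exc:
            out[name] = {"pi": None, "p": None, "n": int(len(block)), "error": str(exc)}
            continue
        out[name] = {"pi": res.pi, "p": res.p, "n": res.n_used}
    return out


def build_cohort_table(micro: pd.DataFrame, metrics: pd.DataFrame | None = None
                       ) -> pd.DataFrame:
    """Join per-session microstructure with per-session mean transient
    metrics into a tidy cohort table keyed by (animal, session, side).

    Sessions in the first half of the schedule are water weeks, the second
    half alcohol weeks; the join validates that ``week`` is consistent
    with the session index (5 sessions per drinking week).
    """
    micro = micro.copy()
    expected_week = (micro["session"] - 1) // 5 + 1
    bad = micro[expected_week != micro["week"]]
    if len(bad):
        raise ValueError(f"week inconsistent with session index for {len(bad)} rows")
    if metrics is None or metrics.empty:
        return micro
    per_side = (
        metrics.groupby(["animal", "session", "side"], as_index=False)
        .agg(
            mean_peak=("peak_amplitude", "mean"),
            mean_time_to_peak=("time_to_peak", "mean"),
            mean_auc=("auc", "mean"),
            n_events_aligned=("peak_amplitude", "count"),
        )
    )
    table = micro.merge(per_side, on=["animal", "session"], how="left")
    key = table[["animal", "session", "side"]].dropna()
    if key.duplicated().any():
        raise ValueError("(animal, session, side) not unique in cohort table")
    return table
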