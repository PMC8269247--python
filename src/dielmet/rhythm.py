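"""Detection of 24-h periodicity in time series sampled on a regular grid.

The detector is a nonparametric umbrella rank test: observations are pooled
into clock-phase classes and, for every candidate peak class, an
umbrella-ordered Jonckheere-Terpstra-type statistic (sum of pairwise
Mann-Whitney counts consistent with a rise to the peak followed by a fall)
is evaluated.  Per-candidate p-values come from an exact null distribution
(dynamic programming over rank placements) for small samples without ties,
from exhaustive permutation enumeration for small tied samples, or from a
normal approximation with tie correction otherwise.  Candidate phases are
combined conservatively (Bonferroni) or by a permutation-calibrated min-p.

Peak time and amplitude of significant signals are estimated separately by
cosinor (harmonic least-squares) regression, and the average daily fold
change is the mean over complete 24-h windows of max/min of the
per-time-point medians.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhaseGroupedSeries",
    "RhythmResult",
    "umbrella_rank_test",
    "bh_fdr",
    "cosinor_fit",
    "complete_windows",
    "daily_fold_change",
    "classify_signals",
]

# exact DP is used up to this many total observations (no ties)
_EXACT_N_MAX = 30
# exhaustive enumeration (tied data) up to this many distinct label arrangements
_ENUM_MAX = 200_000


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class PhaseGroupedSeries:
    """Observations grouped by clock-phase class.

    ``classes[k]`` holds all observations whose sampling time falls in the
    k-th phase class; ``class_hours[k]`` is the clock hour of that class.
    Classes must partition [0, 24) into equal bins aligned to the sampling
    grid.
    """

    signal_id: str
    class_hours: list[float]
    classes: list[np.ndarray]
    period_id: str = "1"

    def __post_init__(self) -> None:
        if len(self.class_hours) != len(self.classes):
            raise ValueError("class_hours and classes length mismatch")
        self.classes = [np.asarray(c, dtype=float) for c in self.classes]

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def n_total(self) -> int:
        return int(sum(len(c) for c in self.classes))


@dataclass
class RhythmResult:
    """Per-signal rhythmicity summary."""

    signal_id: str
    p_raw: float
    q_fdr: float = math.nan
    is_diel: bool = False
    peak_hour: float = math.nan
    amplitude: float = math.nan
    mesor: float = math.nan
    mean_fold_change: float = math.nan
    scope: str = "1"
    n_windows_used: int = 0


# ---------------------------------------------------------------------------
# umbrella statistic machinery
# ---------------------------------------------------------------------------

def _umbrella_weights(n_classes: int, peak: int) -> np.ndarray:
    """0/1 weight matrix for the cyclic umbrella with peak at class ``peak``.

    Class heights are K/2 minus the cyclic distance to the peak; the pair
    (i, j) counts toward the statistic when class i sits strictly lower on
    the umbrella than class j (observations in i are expected below those
    in j).  Classes at equal height contribute no pair.
    """
    k = n_classes
    idx = np.arange(k)
    dist = np.minimum((idx - peak) % k, (peak - idx) % k)
    height = k / 2.0 - dist
    w = (height[:, None] < height[None, :]).astype(np.int64)
    return w


def _statistic(classes: Sequence[np.ndarray], w: np.ndarray) -> float:
    """A = sum over weighted class pairs of Mann-Whitney counts (ties 0.5)."""
    total = 0.0
    k = len(classes)
    for i in range(k):
        for j in range(k):
            if w[i, j]:
                xi = classes[i][:, None]
                xj = classes[j][None, :]
                total += np.sum(xi < xj) + 0.5 * np.sum(xi == xj)
    return float(total)


@lru_cache(maxsize=512)
def _exact_null_sf(sizes: tuple[int, ...], w_bytes: bytes) -> np.ndarray:
    """Exact null survival function of the umbrella statistic (no ties).

    Dynamic programming over placements of observations in increasing rank
    order.  State = counts of observations per class still to be placed;
    placing one observation of class g contributes, for every class h with
    weight w[g, h] = 1, the number of h-observations still unplaced (all of
    which are larger).  Returns ``sf`` with ``sf[a] = P(A >= a)`` for
    integer statistic values a = 0..max.
    """
    k = len(sizes)
    w = np.frombuffer(w_bytes, dtype=np.int64).reshape(k, k)
    max_a = int(sum(w[i, j] * sizes[i] * sizes[j] for i in range(k) for j in range(k)))

    # dist maps remaining-count state -> float counts over statistic values
    start = tuple(sizes)
    dist: dict[tuple[int, ...], np.ndarray] = {
        start: np.concatenate(([1.0], np.zeros(max_a)))
    }
    n = sum(sizes)
    for _ in range(n):
        new: dict[tuple[int, ...], np.ndarray] = {}
        for state, arr in dist.items():
            for g in range(k):
                if state[g] == 0:
                    continue
                nxt = list(state)
                nxt[g] -= 1
                contrib = int(sum(w[g, h] * nxt[h] for h in range(k)))
                key = tuple(nxt)
                tgt = new.get(key)
                if tgt is None:
                    tgt = np.zeros(max_a + 1)
                    new[key] = tgt
                if contrib:
                    tgt[contrib:] += arr[:-contrib] if contrib <= max_a else 0.0
                else:
                    tgt += arr
        dist = new
    counts = dist[tuple([0] * k)]
    sf = counts[::-1].cumsum()[::-1] / counts.sum()
    return sf


def _exact_p(classes: Sequence[np.ndarray], w: np.ndarray) -> float:
    sizes = tuple(len(c) for c in classes)
    sf = _exact_null_sf(sizes, w.astype(np.int64).tobytes())
    a = _statistic(classes, w)
    # statistic is integral when there are no ties
    return float(sf[min(int(round(a)), len(sf) - 1)])


def _enum_p(classes: Sequence[np.ndarray], w: np.ndarray) -> float:
    """Exact permutation p by enumeration of distinct label arrangements.

    Conditional on the observed (possibly tied) values: every distinct way
    of distributing the pooled values over the class sizes is equally
    likely under the null.
    """
    sizes = [len(c) for c in classes]
    pooled = np.concatenate(classes)
    obs = _statistic(classes, w)
    ge = 0
    total = 0
    seen_orders = set()
    for perm in itertools.permutations(range(len(pooled))):
        vals = tuple(pooled[list(perm)])
        if vals in seen_orders:
            continue
        seen_orders.add(vals)
        split = []
        pos = 0
        for s in sizes:
            split.append(pooled[list(perm[pos:pos + s])])
            pos += s
        a = _statistic(split, w)
        total += 1
        if a >= obs - 1e-9:
            ge += 1
    return ge / total


def _n_arrangements(sizes: Sequence[int]) -> int:
    n = sum(sizes)
    out = math.factorial(n)
    for s in sizes:
        out //= math.factorial(s)
    return out


def _normal_p(classes: Sequence[np.ndarray], w: np.ndarray) -> float:
    """Normal approximation with tie correction for the umbrella statistic.

    Mean and variance follow from the exact permutation moments of sums of
    Mann-Whitney counts: Var(U_ij) = ninj(ni+nj+1)/12 and pair covariances
    +/- ninjnl/12 according to whether the shared class sits on the same or
    on opposite sides of the two pairs.  Tied data multiply the variance by
    the standard rank tie-correction factor.
    """
    sizes = np.array([len(c) for c in classes], dtype=float)
    pairs = [(i, j) for i in range(len(classes)) for j in range(len(classes)) if w[i, j]]
    mu = sum(sizes[i] * sizes[j] / 2.0 for i, j in pairs)
    var = 0.0
    for i, j in pairs:
        var += sizes[i] * sizes[j] * (sizes[i] + sizes[j] + 1) / 12.0
    for (i, j), (k_, l) in itertools.permutations(pairs, 2):
        if i == k_ and j == l:
            continue
        shared = {i, j} & {k_, l}
        if not shared:
            continue
        if i == k_ and j == l:  # pragma: no cover - excluded above
            continue
        if i == l and j == k_:
            var -= sizes[i] * sizes[j] * (sizes[i] + sizes[j] + 1) / 12.0
            continue
        groups = {i, j, k_, l}
        prod = np.prod([sizes[g] for g in groups])
        if i == k_ or j == l:
            var += prod / 12.0
        else:  # chain: j == k_ or i == l
            var -= prod / 12.0

    pooled = np.concatenate(classes)
    n = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    has_ties = tie_term > 0
    if n > 1:
        var *= 1.0 - tie_term / float(n**3 - n)
    if var <= 0:
        return 1.0
    a = _statistic(classes, w)
    cc = 0.0 if has_ties else 0.5
    z = (a - cc - mu) / math.sqrt(var)
    return float(stats.norm.sf(z))


def _single_phase_p(classes: Sequence[np.ndarray], w: np.ndarray) -> float:
    pooled = np.concatenate(classes)
    ties = len(np.unique(pooled)) < len(pooled)
    n = len(pooled)
    sizes = [len(c) for c in classes]
    if not ties and n <= _EXACT_N_MAX:
        return _exact_p(classes, w)
    if ties and _n_arrangements(sizes) <= _ENUM_MAX and n <= 10:
        return _enum_p(classes, w)
    return _normal_p(classes, w)


def umbrella_rank_test(
    series: PhaseGroupedSeries,
    combine: str = "bonferroni",
    return_details: bool = False,
):
    """Combined umbrella rank test across all candidate peak phases.

    Parameters
    ----------
    series
        Phase-grouped observations (>= 3 classes, >= 2 observations each).
    combine
        ``"bonferroni"``: p = min(1, K * min_k p_k) over the K candidate
        peak classes (conservative under the strong dependence between
        neighbouring umbrellas).
    return_details
        Also return the per-candidate p-values keyed by class hour.

    Returns
    -------
    float (or (float, dict)): combined p-value.
    """
    k = series.n_classes
    if k < 3:
        raise ValueError("need >= 3 phase classes")
    for c in series.classes:
        if len(c) < 2:
            raise ValueError("need >= 2 observations per phase class")
    pooled = np.concatenate(series.classes)
    if np.all(pooled == pooled[0]):
        return (1.0, {h: 1.0 for h in series.class_hours}) if return_details else 1.0

    per_phase = {}
    for peak in range(k):
        w = _umbrella_weights(k, peak)
        per_phase[series.class_hours[peak]] = _single_phase_p(series.classes, w)
    if combine != "bonferroni":
        raise ValueError(f"unknown combine method {combine!r}")
    p = min(1.0, k * min(per_phase.values()))
    if return_details:
        return p, per_phase
    return p


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order preserved)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# cosinor
# ---------------------------------------------------------------------------

def cosinor_fit(
    times: np.ndarray,
    values: np.ndarray,
    period: float = 24.0,
    harmonics: int = 1,
) -> dict:
    """Harmonic least-squares fit of a periodic curve.

    Model: mesor + sum_h a_h cos(2 pi h t / P) + b_h sin(2 pi h t / P).

    Returns a dict with ``mesor``, ``amplitude`` ((max-min)/2 of the fitted
    curve), ``peak_time`` (time of the fitted maximum, mod ``period``, in
    the coordinates of ``times``), and ``p_value`` of the F-test against an
    intercept-only model.  A flat fit returns amplitude 0 and NaN peak.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if harmonics not in (1, 2):
        raise ValueError("harmonics must be 1 or 2")
    if len(np.unique(t)) < 5:
        raise ValueError("need >= 5 distinct time points")
    cols = [np.ones_like(t)]
    for h in range(1, harmonics + 1):
        cols.append(np.cos(2 * np.pi * h * t / period))
        cols.append(np.sin(2 * np.pi * h * t / period))
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient cosinor design")
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    ssr = float(np.sum((y - fitted) ** 2))
    ss0 = float(np.sum((y - y.mean()) ** 2))
    df1 = x.shape[1] - 1
    df2 = len(y) - x.shape[1]
    if df2 > 0 and ssr > 0:
        f = ((ss0 - ssr) / df1) / (ssr / df2)
        p_value = float(stats.f.sf(f, df1, df2))
    else:
        p_value = math.nan

    mesor = float(beta[0])
    flat_tol = 1e-10 * max(1.0, float(np.max(np.abs(y))))
    if harmonics == 1:
        a, b = beta[1], beta[2]
        amplitude = float(math.hypot(a, b))
        if amplitude <= flat_tol:
            amplitude, peak = 0.0, math.nan
        else:
            peak = (math.atan2(b, a) * period / (2 * np.pi)) % period
    else:
        grid = np.arange(0.0, period, 0.1)
        gx = np.column_stack(
            [np.ones_like(grid)]
            + [f(2 * np.pi * h * grid / period) for h in (1, 2) for f in (np.cos, np.sin)]
        )
        curve = gx @ beta
        amplitude = float((curve.max() - curve.min()) / 2.0)
        if amplitude <= flat_tol:
            amplitude, peak = 0.0, math.nan
        else:
            peak = float(grid[np.argmax(curve)])
    return {"mesor": mesor, "amplitude": amplitude, "peak_time": peak, "p_value": p_value}


# ---------------------------------------------------------------------------
# fold change
# ---------------------------------------------------------------------------

def complete_windows(
    times: np.ndarray,
    samples_per_window: int,
    window_start_offset: float | None = None,
) -> list[np.ndarray]:
    """Index arrays of consecutive 24-h windows holding a full day of samples.

    Windows are half-open [start + 24m, start + 24(m+1)); a window is
    complete when it contains at least ``samples_per_window`` time points.
    """
    t = np.asarray(times, dtype=float)
    t0 = t.min() if window_start_offset is None else float(window_start_offset)
    win = np.floor((t - t0) / 24.0).astype(int)
    out = []
    for wi in np.unique(win):
        idx = np.nonzero(win == wi)[0]
        if wi >= 0 and len(idx) >= samples_per_window:
            out.append(idx)
    return out


def daily_fold_change(
    times: np.ndarray,
    medians: np.ndarray,
    samples_per_window: int,
    window_start_offset: float | None = None,
) -> tuple[float, int, int]:
    """Mean over complete 24-h windows of max/min of per-time-point medians.

    Parameters
    ----------
    times
        Hours since series start for each median.
    medians
        Per-time-point medians (one value per time point).
    samples_per_window
        Number of time points a complete window must contain (24/interval).
    window_start_offset
        Hours-since-start at which windows begin; defaults to the first
        sample time.

    Returns
    -------
    (mean_fold, n_windows_used, n_windows_zero_min)
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(medians, dtype=float)
    order = np.argsort(t)
    t, y = t[order], y[order]
    folds = []
    n_zero = 0
    for idx in complete_windows(t, samples_per_window, window_start_offset):
        lo, hi = y[idx].min(), y[idx].max()
        if lo <= 0:
            n_zero += 1
            continue
        folds.append(hi / lo)
    if not folds:
        raise ValueError("no complete 24-h window")
    return float(np.mean(folds)), len(folds), n_zero


# ---------------------------------------------------------------------------
# per-signal classification
# ---------------------------------------------------------------------------

def _norm_period(v) -> str:
    """Canonical string form of a period label (1.0 and 1 both -> "1")."""
    try:
        f = float(v)
        if f == int(f):
            return str(int(f))
    except (TypeError, ValueError):
        pass
    return str(v)


def _phase_group(medians: pd.DataFrame, interval: float) -> PhaseGroupedSeries:
    hours = sorted(medians["clock_hour"].unique())
    classes = [medians.loc[medians["clock_hour"] == h, "value"].to_numpy() for h in hours]
    return PhaseGroupedSeries(signal_id="", class_hours=list(hours), classes=classes)


def classify_signals(
    values: pd.DataFrame,
    samples: pd.DataFrame,
    interval: float = 4.0,
    alpha: float = 0.05,
    scopes: Sequence[str] | None = None,
    harmonics: int = 1,
    window_start_hour: float | None = None,
    fit_all: bool = False,
) -> pd.DataFrame:
    """Run the full rhythm analysis for every signal and period scope.

    Parameters
    ----------
    values
        Long table with columns ``signal_id``, ``sample_id``, ``value``.
    samples
        Metadata with ``sample_id``, ``t_hours``, ``clock_hour``, ``period``,
        ``replicate`` (field samples only).
    interval
        Sampling interval in hours (must divide 24).
    alpha
        FDR threshold for the diel flag.
    scopes
        Period scopes to analyze; default: each period present, plus
        ``"both"`` when more than one.
    harmonics
        Cosinor harmonics (1 or 2).
    window_start_hour
        Clock hour at which 24-h fold-change windows start; default is the
        first sample's clock hour of each scope.
    fit_all
        Fit cosinor for all signals, not only significant ones.

    Returns
    -------
    DataFrame with one row per signal x scope (RhythmResult fields).
    """
    if 24.0 % interval != 0:
        raise ValueError("sampling interval must divide 24")
    merged = values.merge(samples, on="sample_id", how="inner")
    if not merged.empty:
        merged = merged.assign(period=merged["period"].map(_norm_period))
    if merged.empty:
        return pd.DataFrame(
            columns=["signal_id", "scope", "p_raw", "q_fdr", "is_diel", "peak_hour",
                     "amplitude", "mesor", "fold_change", "n_windows_used"]
        )
    periods = sorted(merged["period"].astype(str).unique())
    if scopes is None:
        scopes = list(periods) + (["both"] if len(periods) > 1 else [])

    spw = int(round(24.0 / interval))
    rows = []
    for scope in scopes:
        sub = merged if scope == "both" else merged[merged["period"].astype(str) == scope]
        if sub.empty:
            continue
        med = (
            sub.groupby(["signal_id", "t_hours", "clock_hour"], as_index=False)["value"]
            .median()
        )
        scope_rows = []
        for sid, g in med.groupby("signal_id", sort=True):
            p = umbrella_rank_test(_phase_group(g, interval))
            scope_rows.append((sid, g, p))
        qs = bh_fdr([r[2] for r in scope_rows])
        for (sid, g, p), q in zip(scope_rows, qs):
            is_diel = bool(q < alpha)
            peak_hour = amplitude = mesor = math.nan
            if is_diel or fit_all:
                t = g["t_hours"].to_numpy()
                start_clock = g.sort_values("t_hours")["clock_hour"].iloc[0]
                fit = cosinor_fit(t - t.min(), g["value"].to_numpy(), 24.0, harmonics)
                amplitude, mesor = fit["amplitude"], fit["mesor"]
                if not math.isnan(fit["peak_time"]):
                    peak_hour = (start_clock + fit["peak_time"]) % 24.0
            t = g["t_hours"].to_numpy()
            offs = None
            if window_start_hour is not None:
                first_clock = g.sort_values("t_hours")["clock_hour"].iloc[0]
                offs = t.min() + ((window_start_hour - first_clock) % 24.0)
            try:
                fold, n_win, _ = daily_fold_change(
                    t, g["value"].to_numpy(), spw, window_start_offset=offs
                )
            except ValueError:
                fold, n_win = math.nan, 0
            rows.append(
                {
                    "signal_id": sid,
                    "scope": scope,
                    "p_raw": p,
                    "q_fdr": q,
                    "is_diel": is_diel,
                    "peak_hour": peak_hour,
                    "amplitude": amplitude,
                    "mesor": mesor,
                    "fold_change": fold,
                    "n_windows_used": n_win,
                }
            )
    return pd.DataFrame(rows)
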