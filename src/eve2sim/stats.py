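"""Statistics for nascent-transcript time series.

These are the operations applied identically to simulated and experimental
series: regularization to integer minutes, per-minute change rates,
autocorrelation with Bartlett significance bands (matching the display of
classical ACF tools), width-2 rate histograms with pooling, a Pearson
chi-squared comparison of two pooled histograms, and dwell/summary
fractions.

The two discriminating signatures of the bursting analysis are (a)
significant autocorrelation of the nascent count at 1-3 minute lags —
multi-minute bursts — and (b) no significant autocorrelation of the
per-minute *changes* — no persistence of a particular initiation rate.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MinuteSeries",
    "ChangeSeries",
    "AutocorrelationResult",
    "RateHistogram",
    "Chi2Result",
    "SummaryRecord",
    "regularize",
    "per_minute_change",
    "autocorrelation",
    "rate_histogram",
    "pool",
    "chi2_independence",
    "series_summary",
]


@dataclasses.dataclass
class MinuteSeries:
    """Nascent counts averaged per integer minute.

    ``minute`` is a contiguous integer range; minutes with no samples are
    flagged in ``is_gap`` and carry NaN values.
    """

    minute: np.ndarray
    value: np.ndarray
    is_gap: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.minute) <= 0):
            raise ValueError("minute indices must be strictly increasing")

    @property
    def n_observed(self) -> int:
        return int((~self.is_gap).sum())

    def filled_values(self) -> np.ndarray:
        """Values with interior gaps linearly interpolated (for ACF use)."""
        if not self.is_gap.any():
            return self.value
        obs = ~self.is_gap
        return np.interp(self.minute, self.minute[obs], self.value[obs])


@dataclasses.dataclass
class ChangeSeries:
    """Per-minute change rates between successive samples (transcripts/min)."""

    t_mid_min: np.ndarray
    rate: np.ndarray

    def __len__(self) -> int:
        return len(self.rate)

    @property
    def positive_fraction(self) -> float:
        return float(np.mean(self.rate > 0))


def regularize(times_s, counts) -> MinuteSeries:
    """Average samples into integer-minute bins.

    Samples with time in [m, m+1) minutes contribute to minute m; empty
    minutes inside the observed range are flagged as gaps.
    """
    times_s = np.asarray(times_s, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if times_s.size == 0:
        raise ValueError("empty input series")
    if np.any(np.diff(times_s) < 0):
        raise ValueError("sample times must be non-decreasing")
    m = np.floor(times_s / 60.0).astype(int)
    minutes = np.arange(m.min(), m.max() + 1)
    sums = np.zeros(minutes.size)
    nobs = np.zeros(minutes.size)
    np.add.at(sums, m - m.min(), counts)
    np.add.at(nobs, m - m.min(), 1.0)
    gap = nobs == 0
    value = np.full(minutes.size, np.nan)
    value[~gap] = sums[~gap] / nobs[~gap]
    return MinuteSeries(minute=minutes, value=value, is_gap=gap)


def per_minute_change(times_s, counts=None) -> ChangeSeries:
    """Change rates (transcripts/min) between successive samples.

    Accepts either raw sample arrays ``(times_s, counts)`` with times in
    seconds, or a :class:`MinuteSeries` — in which case gap minutes break
    the sequence (no change is computed across a gap, since the interval is
    not one minute of contiguous observation).
    """
    if isinstance(times_s, MinuteSeries):
        ms = times_s
        obs = ~ms.is_gap
        t = ms.minute[obs].astype(float)
        x = ms.value[obs]
        dt = np.diff(t)
        keep = dt == 1  # adjacent minutes only
        rates = np.diff(x)[keep] / dt[keep]
        mids = (t[:-1] + t[1:])[keep] / 2.0
        return ChangeSeries(t_mid_min=mids, rate=rates)
    t = np.asarray(times_s, dtype=float) / 60.0
    x = np.asarray(counts, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("sample times must be strictly increasing (no duplicates)")
    return ChangeSeries(t_mid_min=(t[:-1] + t[1:]) / 2.0, rate=np.diff(x) / dt)


@dataclasses.dataclass
class AutocorrelationResult:
    """Sample ACF with Bartlett 5% significance limits.

    ``limit[k]`` is ``t(0.975, df=n) * SE(r_k)`` with the cumulative
    Bartlett standard error ``SE(r_k) = sqrt((1 + 2*sum_{j<k} r_j^2)/n)``;
    a lag is flagged significant when ``|r_k|`` exceeds its limit.
    """

    lag: np.ndarray
    r: np.ndarray
    limit: np.ndarray
    significant: np.ndarray
    n: int

    def significant_lags(self) -> np.ndarray:
        return self.lag[self.significant]

    @property
    def any_significant(self) -> bool:
        return bool(self.significant[1:].any())

    def all_significant(self, lags: Iterable[int]) -> bool:
        want = set(int(k) for k in lags)
        got = set(int(k) for k in self.significant_lags())
        return want <= got

    def any_significant_in(self, lags: Iterable[int]) -> bool:
        return bool(set(int(k) for k in lags) & set(int(k) for k in self.significant_lags()))


def autocorrelation(series, max_lag: int | None = None, alpha: float = 0.05) -> AutocorrelationResult:
    """Sample autocorrelation function with Bartlett significance bands.

    ``series`` may be a :class:`MinuteSeries` (interior gaps interpolated),
    a :class:`ChangeSeries`, or a plain 1-d array of regularly spaced
    values.  The default ``max_lag`` is ``n // 4``.
    """
    if isinstance(series, MinuteSeries):
        x = series.filled_values()
    elif isinstance(series, ChangeSeries):
        x = series.rate
    else:
        x = np.asarray(series, dtype=float)
    n = x.size
    if max_lag is None:
        max_lag = n // 4
    if n < max_lag + 5:
        raise ValueError(f"series too short ({n}) for max_lag={max_lag}")
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        raise ValueError("constant series: autocorrelation undefined (zero variance)")
    r = np.empty(max_lag + 1)
    r[0] = 1.0
    for k in range(1, max_lag + 1):
        r[k] = float(np.dot(xc[:-k], xc[k:])) / denom
    cum = 1.0 + 2.0 * np.concatenate([[0.0], np.cumsum(r[1:-1] ** 2)]) if max_lag >= 1 else np.array([])
    se = np.sqrt(np.concatenate([[0.0], cum]) / n) if max_lag >= 1 else np.array([0.0])
    tval = sps.t.ppf(1.0 - alpha / 2.0, df=n)
    limit = tval * se
    sig = np.zeros(max_lag + 1, dtype=bool)
    sig[1:] = np.abs(r[1:]) > limit[1:]
    return AutocorrelationResult(
        lag=np.arange(max_lag + 1), r=r, limit=limit, significant=sig, n=n
    )


@dataclasses.dataclass
class RateHistogram:
    """Integer-aligned histogram of per-minute changes, class width 2.

    ``lower_limits`` are the class lower bounds (…,-2, 0, 2,…): a change x
    falls in the class ``width * floor(x / width)``, so the class labeled 0
    covers [0, 2) — the "0-1 additions per minute" bar.
    """

    lower_limits: np.ndarray
    counts: np.ndarray
    class_width: int = 2
    n_pooled: int = 1

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def count_at(self, lower: int) -> int:
        idx = np.nonzero(self.lower_limits == lower)[0]
        return int(self.counts[idx[0]]) if idx.size else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"class_lower": self.lower_limits, "count": self.counts})


def rate_histogram(changes, class_width: int = 2) -> RateHistogram:
    """Bin change rates into integer-aligned classes of the given width."""
    if class_width <= 0:
        raise ValueError("class width must be positive")
    x = changes.rate if isinstance(changes, ChangeSeries) else np.asarray(changes, dtype=float)
    if x.size == 0:
        return RateHistogram(lower_limits=np.array([0]), counts=np.array([0]),
                             class_width=class_width)
    lows = (class_width * np.floor(x / class_width)).astype(int)
    grid = np.arange(lows.min(), lows.max() + class_width, class_width)
    counts = np.zeros(grid.size, dtype=int)
    np.add.at(counts, (lows - lows.min()) // class_width, 1)
    return RateHistogram(lower_limits=grid, counts=counts, class_width=class_width)


def pool(histograms: Iterable[RateHistogram]) -> RateHistogram:
    """Sum histograms class-wise after aligning their class grids."""
    hists = list(histograms)
    if not hists:
        raise ValueError("nothing to pool")
    width = hists[0].class_width
    if any(h.class_width != width for h in hists):
        raise ValueError("histograms have mismatched class widths")
    lo = min(int(h.lower_limits.min()) for h in hists)
    hi = max(int(h.lower_limits.max()) for h in hists)
    grid = np.arange(lo, hi + width, width)
    counts = np.zeros(grid.size, dtype=int)
    for h in hists:
        idx = (h.lower_limits - lo) // width
        counts[idx] += h.counts
    return RateHistogram(lower_limits=grid, counts=counts, class_width=width,
                         n_pooled=sum(h.n_pooled for h in hists))


@dataclasses.dataclass
class Chi2Result:
    statistic: float
    df: int
    pvalue: float
    class_lowers: np.ndarray  # retained classes
    contributions: np.ndarray  # per retained class, summed over both rows


def chi2_independence(hist_a: RateHistogram, hist_b: RateHistogram,
                      min_count: int = 5) -> Chi2Result:
    """Pearson chi-squared test of independence on two pooled histograms.

    Classes are aligned on their lower limits and retained only where the
    count exceeds ``min_count`` in *both* histograms; the test is Pearson's
    on the resulting 2 x K table with K - 1 degrees of freedom.
    """
    if hist_a.class_width != hist_b.class_width:
        raise ValueError("histograms have mismatched class widths")
    lowers = np.union1d(hist_a.lower_limits, hist_b.lower_limits)
    a = np.array([hist_a.count_at(l) for l in lowers], dtype=float)
    b = np.array([hist_b.count_at(l) for l in lowers], dtype=float)
    keep = (a > min_count) & (b > min_count)
    if keep.sum() < 2:
        raise ValueError(f"fewer than 2 classes with counts > {min_count} in both histograms")
    a, b, lowers = a[keep], b[keep], lowers[keep]
    table = np.vstack([a, b])
    col = table.sum(axis=0)
    row = table.sum(axis=1)
    expected = np.outer(row, col) / table.sum()
    cells = (table - expected) ** 2 / expected
    stat = float(cells.sum())
    df = len(lowers) - 1
    p = float(sps.chi2.sf(stat, df))
    return Chi2Result(statistic=stat, df=df, pvalue=p, class_lowers=lowers,
                      contributions=cells.sum(axis=0))


@dataclasses.dataclass
class SummaryRecord:
    """Summary fractions of one trajectory or series.

    Dwell fractions are exact time-in-state-class fractions from the event
    log; minute-class fractions classify each minute by its dominant state
    class.  Both are reported because "fraction of time at the LOW rate"
    can be read either way.
    """

    positive_change_fraction: float | None
    dwell_fractions: dict | None
    minute_class_fractions: dict | None
    bcd_bound_fraction: float | None


def series_summary(obj, duration: float | None = None) -> SummaryRecord:
    """Summarize a trajectory (with event log) or a bare change/minute series."""
    if hasattr(obj, "dwell_fractions_by_class"):  # NucleusTrajectory
        from .ssa import extract_minute_series

        times, counts = extract_minute_series(obj)
        changes = per_minute_change(times, counts)
        dwell = obj.dwell_fractions_by_class()
        minute_frac = _minute_class_fractions(obj)
        return SummaryRecord(
            positive_change_fraction=changes.positive_fraction,
            dwell_fractions=dwell,
            minute_class_fractions=minute_frac,
            bcd_bound_fraction=obj.bcd_bound_fraction(),
        )
    if isinstance(obj, ChangeSeries):
        return SummaryRecord(obj.positive_fraction, None, None, None)
    if isinstance(obj, MinuteSeries):
        return SummaryRecord(per_minute_change(obj).positive_fraction, None, None, None)
    raise TypeError(f"cannot summarize {type(obj).__name__}")


def _minute_class_fractions(traj) -> dict:
    """Classify each whole minute by the state class occupying most of it."""
    from .model import RegulatoryState, state_class

    if traj.copies is not None:
        traj = traj.copies[0]  # per-copy classification; merged states are ill-defined
    class_of = np.array([state_class(RegulatoryState.from_index(i)) for i in range(16)])
    n_min = int(traj.duration // 60)
    counts = {"off": 0, "low": 0, "high": 0}
    edges = np.append(traj.event_times, traj.duration)
    for m in range(n_min):
        t0, t1 = 60.0 * m, 60.0 * (m + 1)
        i0 = np.searchsorted(edges, t0, side="right") - 1
        i1 = min(np.searchsorted(edges, t1, side="right") - 1, len(edges) - 2)
        dwell = {"off": 0.0, "low": 0.0, "high": 0.0}
        for i in range(i0, i1 + 1):
            seg = min(edges[i + 1], t1) - max(edges[i], t0)
            if seg > 0:
                dwell[class_of[traj.state_index[i]]] += seg
        counts[max(dwell, key=dwell.get)] += 1
    total = max(sum(counts.values()), 1)
    return {k: v / total for k, v in counts.items()}
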