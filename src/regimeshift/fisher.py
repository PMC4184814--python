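"""Windowed Fisher Information for multivariate regime-shift detection.

The record is divided into overlapping windows of ``w`` time steps.
Within a window, two time points are *indistinguishable* — occupy the
same system state — when every variable differs by at most its size of
states ``sost_i``, a per-species uncertainty estimated from the least
variable window of the whole record.  Binning the window's points into
states gives state probabilities ``p(s)`` with amplitudes
``q(s) = sqrt(p(s))``, and the numeric Fisher Information of the window is

    FI = 4 * sum_{s=0}^{m} [q(s) - q(s+1)]**2,   q(0) = q(m+1) = 0,

with interior states in order of first appearance.  A single recurring
state gives the maximum FI = 8 (high dynamic order); ``w`` all-distinct
states give the minimum 8/w (disorder).  Within a regime the smoothed
mean FI track is roughly flat; a sustained decline signals loss of order
and resilience, and a regime shift is identified at the FI minimum
between two stable regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CommunityTimeSeries

__all__ = [
    "SostVector",
    "StatePartition",
    "FISeries",
    "RegimeSegmentation",
    "estimate_size_of_states",
    "partition_states",
    "fi_from_partition",
    "fi_series",
    "mean_fi",
    "segment_regimes",
]


@dataclass
class SostVector:
    """Per-species size of states (state tolerance, percent units)."""

    sost: np.ndarray
    source_window: tuple[int, int]  # [start, stop) of the least-variable window
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.sost = np.asarray(self.sost, dtype=float)
        if (self.sost < 0).any():
            raise ValueError("sost must be non-negative")


@dataclass
class StatePartition:
    """Binning of one window's points into states."""

    window_start_index: int
    assignments: np.ndarray  # state id (0-based, first-appearance order) per point
    m: int                   # number of states
    p: np.ndarray            # probability per state
    q: np.ndarray            # amplitude per state, q = sqrt(p)


@dataclass
class FISeries:
    """FI per window plus the smoothed mean-FI track."""

    ages: np.ndarray            # anchor age (last age in window)
    fi: np.ndarray
    window: int
    step: int = 1
    mean_fi: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"age": self.ages, "fi": self.fi})
        if self.mean_fi is not None:
            df["mean_fi"] = self.mean_fi
        return df


@dataclass
class RegimeSegmentation:
    """Piecewise classification of the mean-FI track."""

    segments: list[tuple[float, float, str]]  # (start age, end age, label), BP
    shift_ages: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.segments, columns=["start_age", "end_age", "label"])


def estimate_size_of_states(
    cts: CommunityTimeSeries, window: int = 10, scale: float = 1.0
) -> SostVector:
    """Size of states from the least-variable window of the record.

    A window of ``window`` steps slides over the whole record; the window
    minimizing the normalized total variability — the sum over species of
    (within-window sample s.d.) / (whole-record sample s.d.), species with
    zero record-wide s.d. excluded — is selected (earliest on ties), and
    ``sost_i = scale *`` the within-that-window sample s.d. of species i.
    """
    n, _ = cts.abundance.shape
    if window > n:
        raise ValueError(f"window {window} exceeds record length {n}")
    rec_sd = cts.abundance.std(axis=0, ddof=1)
    active = rec_sd > 0

    n_windows = n - window + 1
    sds = np.empty((n_windows, cts.n_species))
    for k in range(n_windows):
        sds[k] = cts.abundance[k : k + window].std(axis=0, ddof=1)
    if active.any():
        score = (sds[:, active] / rec_sd[active]).sum(axis=1)
    else:
        score = sds.sum(axis=1)
    best = int(np.argmin(score))  # argmin takes the earliest tie
    return SostVector(scale * sds[best], (best, best + window), scale)


def partition_states(points: np.ndarray, sost: SostVector | np.ndarray) -> StatePartition:
    """Greedy temporal-order binning of one window into states.

    The first point founds state 0.  Each subsequent point is compared, in
    state-creation order, against the *founding* point of each existing
    state and joins the first state whose founder is within ``sost`` on
    every variable (``|x_i - x_j| <= sost_i`` for all i); otherwise it
    founds a new state.  Always succeeds.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tol = sost.sost if isinstance(sost, SostVector) else np.asarray(sost, dtype=float)
    if pts.shape[1] != len(tol):
        raise ValueError("sost length does not match number of variables")
    w = pts.shape[0]
    founders: list[np.ndarray] = []
    assign = np.empty(w, dtype=int)
    for t in range(w):
        for s, f in enumerate(founders):
            if np.all(np.abs(pts[t] - f) <= tol):
                assign[t] = s
                break
        else:
            assign[t] = len(founders)
            founders.append(pts[t])
    counts = np.bincount(assign, minlength=len(founders))
    p = counts / w
    return StatePartition(0, assign, len(founders), p, np.sqrt(p))


def fi_from_partition(part: StatePartition) -> float:
    """Numeric Fisher Information of a state partition.

    ``FI = 4 * sum_{s=0}^{m} (q(s) - q(s+1))**2`` with boundary amplitudes
    ``q(0) = q(m+1) = 0`` and interior amplitudes in first-appearance
    order.  One state gives 8; m equiprobable states give 8/m.
    """
    q = np.concatenate(([0.0], part.q, [0.0]))
    return float(4.0 * np.sum(np.diff(q) ** 2))


def fi_series(
    cts: CommunityTimeSeries,
    window: int = 10,
    step: int = 1,
    sost: SostVector | None = None,
    sost_scale: float = 1.0,
) -> FISeries:
    """FI for every window start 0, step, 2*step, ... over the record.

    The anchor age of each window is its last (youngest) age so the value
    never reflects future data.  If ``sost`` is omitted it is estimated
    from the record with :func:`estimate_size_of_states`.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if sost is None:
        sost = estimate_size_of_states(cts, window=window, scale=sost_scale)
    n = cts.n_steps
    starts = range(0, n - window + 1, step)
    fi = np.array(
        [
            fi_from_partition(partition_states(cts.abundance[s : s + window], sost))
            for s in starts
        ]
    )
    ages = cts.ages[[s + window - 1 for s in starts]]
    meta = {
        "window": window,
        "step": step,
        "sost_scale": sost.scale,
        "sost_window": list(sost.source_window),
        "binning_rule": "founder-point, first-appearance order",
    }
    return FISeries(ages=ages, fi=fi, window=window, step=step, meta=meta)


def mean_fi(fs: FISeries, span: int = 5) -> FISeries:
    """Centered moving average of FI over ``span`` windows (mean FI track).

    ``span`` must be odd; at the edges the averaging window shrinks to the
    available windows.  ``span=1`` returns ``mean_fi = fi``.
    """
    if span < 1 or span % 2 == 0:
        raise ValueError("span must be odd and >= 1")
    L = len(fs.fi)
    if span > L:
        raise ValueError(f"span {span} exceeds series length {L}")
    h = span // 2
    smoothed = np.array(
        [fs.fi[max(0, i - h) : min(L, i + h + 1)].mean() for i in range(L)]
    )
    meta = dict(fs.meta, smoothing_span=span)
    return FISeries(fs.ages, fs.fi, fs.window, fs.step, mean_fi=smoothed, meta=meta)


def _local_slopes(ages: np.ndarray, y: np.ndarray, half: int) -> np.ndarray:
    """Slope of y against forward time (FI per kyr) in a centered span."""
    t = -ages / 1000.0  # kyr, increasing toward the present
    L = len(y)
    slopes = np.empty(L)
    for i in range(L):
        lo, hi = max(0, i - half), min(L, i + half + 1)
        tt, yy = t[lo:hi], y[lo:hi]
        tc = tt - tt.mean()
        denom = (tc**2).sum()
        slopes[i] = (tc * (yy - yy.mean())).sum() / denom if denom > 0 else 0.0
    return slopes


def _interval_sse(t: np.ndarray, y: np.ndarray) -> tuple:
    """Cumulative sums enabling O(1) linear-fit SSE of any interval."""
    one = np.concatenate(([0.0], np.cumsum(np.ones_like(t))))
    st = np.concatenate(([0.0], np.cumsum(t)))
    sy = np.concatenate(([0.0], np.cumsum(y)))
    stt = np.concatenate(([0.0], np.cumsum(t * t)))
    sty = np.concatenate(([0.0], np.cumsum(t * y)))
    syy = np.concatenate(([0.0], np.cumsum(y * y)))

    def sse(lo, hi: int):
        """(SSE, slope) of the least-squares line on points [lo, hi).

        ``lo`` may be an integer or an integer array (vectorized).
        """
        lo = np.asarray(lo)
        n = one[hi] - one[lo]
        vt = st[hi] - st[lo]
        vy = sy[hi] - sy[lo]
        ctt = (stt[hi] - stt[lo]) - vt * vt / n
        cty = (sty[hi] - sty[lo]) - vt * vy / n
        cyy = (syy[hi] - syy[lo]) - vy * vy / n
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(ctt > 0, cty / np.where(ctt > 0, ctt, 1.0), 0.0)
        out = np.maximum(cyy - slope * cty, 0.0)
        if lo.ndim == 0:
            return float(out), float(slope)
        return out, slope

    return sse


def segment_regimes(
    fs: FISeries,
    slope_tol: float = 0.5,
    min_len: int = 101,
    presmooth: int = 61,
    max_segments: int = 6,
) -> RegimeSegmentation:
    """Segment the mean-FI track into stable / declining / rising spans.

    The mean-FI track is smoothed with a centered moving average
    (segment-scale features are what matter; the raw track fluctuates
    episodically within regimes) and then fitted by
    a piecewise-linear model: breakpoints are placed by dynamic
    programming minimizing the residual sum of squares, each piece at
    least ``min_len`` windows long, and the number of pieces (up to
    ``max_segments``) chosen by BIC.  ``presmooth`` is the width (in
    windows) of the centered moving average applied before fitting.  Each fitted piece is classified by
    its slope against forward time (units: FI per kyr): ``|slope| <=
    slope_tol`` is stable, below ``-slope_tol`` declining, above rising;
    adjacent same-label pieces are merged.  Each maximal
    declining-then-rising sequence contributes one regime shift at the age
    of the mean-FI minimum between the bracketing stable segments (or
    between the decline start and rise end when no stable bracket exists).
    """
    if fs.mean_fi is None:
        raise ValueError("mean_fi not filled; call mean_fi() first")
    L = len(fs.mean_fi)
    if L < min_len:
        raise ValueError(f"record of {L} windows shorter than min_len {min_len}")

    half = presmooth // 2
    y = np.array(
        [fs.mean_fi[max(0, i - half) : min(L, i + half + 1)].mean() for i in range(L)]
    )
    t = -fs.ages / 1000.0  # kyr, increasing toward the present
    sse = _interval_sse(t, y)

    kmax = max(1, min(max_segments, L // min_len))
    # dp[k][i]: best SSE for the first i points in k pieces
    INF = np.inf
    dp = np.full((kmax + 1, L + 1), INF)
    back = np.zeros((kmax + 1, L + 1), dtype=int)
    dp[0, 0] = 0.0
    for k in range(1, kmax + 1):
        for i in range(k * min_len, L + 1):
            js = np.arange((k - 1) * min_len, i - min_len + 1)
            cost = dp[k - 1, js] + sse(js, i)[0]
            a = int(np.argmin(cost))
            dp[k, i] = cost[a]
            back[k, i] = js[a]

    # BIC over the number of pieces: 3 parameters per piece
    bics = []
    for k in range(1, kmax + 1):
        if dp[k, L] == INF:
            bics.append(INF)
            continue
        bics.append(L * np.log(max(dp[k, L], 1e-12) / L) + 3 * k * np.log(L))
    k_best = int(np.argmin(bics)) + 1

    bounds = [L]
    k = k_best
    while k > 0:
        bounds.append(int(back[k, bounds[-1]]))
        k -= 1
    bounds = bounds[::-1]  # 0 = b0 < b1 < ... < b_kbest = L

    name = {0: "stable", -1: "declining", 1: "rising"}
    merged: list[list[int]] = []  # [label, lo, hi)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        slope = sse(lo, hi)[1]
        lab = 0 if abs(slope) <= slope_tol else (-1 if slope < 0 else 1)
        if merged and merged[-1][0] == lab:
            merged[-1][2] = hi
        else:
            merged.append([lab, lo, hi])

    segments = [
        (float(fs.ages[lo]), float(fs.ages[hi - 1]), name[lab])
        for lab, lo, hi in merged
    ]

    # a decline followed by a recovery (an FI rise of at least a quarter of
    # the decline's drop, whether labeled rising or an abrupt jump to a
    # higher stable level) marks a regime shift at the FI minimum between
    # the pre-decline stable span and the recovery point
    shift_ages: list[float] = []
    for k, (lab, lo, hi) in enumerate(merged):
        if lab != -1:
            continue
        drop = y[lo] - y[hi - 1]
        if drop <= 0:
            continue
        k_rise = next(
            (j for j in range(k + 1, len(merged)) if merged[j][0] == 1), None
        )
        if k_rise is not None:
            right = merged[k_rise][2] - 1
            for m in merged[k_rise + 1 :]:
                if m[0] == 0:
                    right = m[1]
                    break
        else:
            after = y[hi - 1 :]
            rec = np.flatnonzero(after >= y[hi - 1] + 0.25 * drop)
            if rec.size == 0:
                continue
            right = min(hi - 1 + int(rec[0]), L - 1)
        left = lo
        for m in reversed(merged[:k]):
            if m[0] == 0:
                left = m[2] - 1
                break
        i_min = left + int(np.argmin(fs.mean_fi[left : right + 1]))
        shift_ages.append(float(fs.ages[i_min]))
    return RegimeSegmentation(segments, shift_ages)
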