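"""Pupillometry preprocessing and event-related listening-effort metrics.

Raw input is a two-eye pupil/gaze trace sampled nominally at 120 Hz over a
trial window covering at least [-1.0, +6.5] s around stimulus onset.  Zero
pupil diameter encodes a blink or tracking loss.  The pipeline, in order:

1. eye selection — per subject, the eye with the most valid (nonzero)
   diameter samples across all trials; ties go to the left eye;
2. blink detection — maximal zero runs intersecting the [-1, 6.5] s window;
3. trial exclusion — 20% or more blink samples within the window;
4. blink interpolation — straight line between the sample 10 before and the
   sample 16 after each blink (pupil and both gaze channels);
5. trial exclusion — any in-window gaze sample outside the screen bounds
   (a saccade off the display), evaluated after interpolation;
6. smoothing — 11-point moving average;
7. baseline correction — subtract the mean over [-1, 0) s;
8. metrics over [0, 6.5] s — MPD (mean dilation), PPD (peak dilation), and
   PPDL (peak latency in ms, first maximum on ties).

Traces averaged per subject and condition feed the same metric definitions,
and a block-mean downsampler (120 -> 30 Hz) prepares time-course exports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PreprocConfig",
    "PupilTrace",
    "EyeTrace",
    "PupilMetrics",
    "TrialDisposition",
    "select_eye",
    "detect_blinks",
    "blink_fraction",
    "screen_trial",
    "interpolate_blinks",
    "smooth",
    "baseline_correct",
    "compute_metrics",
    "downsample",
    "preprocess_trial",
    "preprocess_subject",
    "condition_average",
]


@dataclass(frozen=True)
class PreprocConfig:
    """Windows, thresholds and filter lengths of the preprocessing chain."""

    blink_window: tuple[float, float] = (-1.0, 6.5)
    blink_trial_threshold: float = 0.20
    interp_pre: int = 10
    interp_post: int = 16
    smooth_points: int = 11
    baseline_window: tuple[float, float] = (-1.0, 0.0)  # closed-open
    metrics_window: tuple[float, float] = (0.0, 6.5)  # closed-closed
    screen_bounds: tuple[float, float, float, float] = (0.0, 1920.0, 0.0, 1080.0)
    downsample_to: float = 30.0

    def __post_init__(self) -> None:
        if not 0 < self.blink_trial_threshold <= 1:
            raise ValueError("blink_trial_threshold must be in (0, 1]")
        for lo, hi in (self.blink_window, self.baseline_window, self.metrics_window):
            if lo >= hi:
                raise ValueError("windows must be well-ordered (lo < hi)")


@dataclass
class EyeTrace:
    """Single-eye trial trace: time, diameter (mm, 0 = missing), gaze."""

    t: np.ndarray
    d: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    rate: float = 120.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.gaze_x = np.asarray(self.gaze_x, dtype=float)
        self.gaze_y = np.asarray(self.gaze_y, dtype=float)
        n = len(self.t)
        if not (len(self.d) == len(self.gaze_x) == len(self.gaze_y) == n):
            raise ValueError("all channels must have equal length")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if np.any(self.d < 0):
            raise ValueError("pupil diameters must be >= 0 (0 encodes missing)")


@dataclass
class PupilTrace:
    """Two-eye trial trace as recorded by the tracker."""

    t: np.ndarray
    d_left: np.ndarray
    d_right: np.ndarray
    gaze_x_left: np.ndarray
    gaze_y_left: np.ndarray
    gaze_x_right: np.ndarray
    gaze_y_right: np.ndarray
    rate: float = 120.0

    def eye(self, label: str) -> EyeTrace:
        if label not in ("left", "right"):
            raise ValueError("eye label must be 'left' or 'right'")
        if label == "left":
            return EyeTrace(self.t, self.d_left, self.gaze_x_left, self.gaze_y_left, self.rate)
        return EyeTrace(self.t, self.d_right, self.gaze_x_right, self.gaze_y_right, self.rate)


@dataclass
class PupilMetrics:
    """Event-related pupil measures of one (possibly averaged) trace."""

    baseline_mm: float
    ppd_mm: float
    mpd_mm: float
    ppdl_ms: float


@dataclass
class TrialDisposition:
    kept: bool
    reason: str = "none"  # none | blink_fraction | offscreen_gaze | unrecoverable


def _window_mask(t: np.ndarray, window: tuple[float, float], closed_hi: bool = True) -> np.ndarray:
    lo, hi = window
    return (t >= lo) & ((t <= hi) if closed_hi else (t < hi))


def select_eye(traces: list[PupilTrace]) -> str:
    """Pick the higher-quality eye for one subject: more valid samples wins,
    ties go left."""
    if not traces:
        raise ValueError("need at least one trial trace")
    left = sum(int(np.count_nonzero(tr.d_left)) for tr in traces)
    right = sum(int(np.count_nonzero(tr.d_right)) for tr in traces)
    if left == 0 and right == 0:
        raise ValueError("no valid samples in either eye")
    return "right" if right > left else "left"


def detect_blinks(trace: EyeTrace, cfg: PreprocConfig | None = None) -> list[tuple[int, int]]:
    """Maximal runs of zero diameter whose extent intersects the blink window.

    Returns inclusive (start, stop) sample-index pairs.
    """
    cfg = cfg or PreprocConfig()
    z = trace.d == 0
    if not z.any():
        return []
    padded = np.concatenate(([False], z, [False]))
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:]) - 1
    runs = [(int(s), int(e)) for s, e in zip(starts, ends)]
    lo, hi = cfg.blink_window
    return [(s, e) for s, e in runs if trace.t[e] >= lo and trace.t[s] <= hi]


def blink_fraction(trace: EyeTrace, cfg: PreprocConfig | None = None) -> float:
    """Fraction of blink (zero) samples within the blink window."""
    cfg = cfg or PreprocConfig()
    m = _window_mask(trace.t, cfg.blink_window)
    if not m.any():
        raise ValueError("trace does not cover the blink window")
    return float(np.count_nonzero(trace.d[m] == 0) / np.count_nonzero(m))


def interpolate_blinks(
    trace: EyeTrace,
    blinks: list[tuple[int, int]] | None = None,
    cfg: PreprocConfig | None = None,
) -> EyeTrace:
    """Bridge each blink with a straight line between guard-band anchors.

    For a blink spanning samples [i, j] the anchors are i - interp_pre and
    j + interp_post; every sample strictly between them (including valid
    samples inside the guard bands) is replaced on the pupil and both gaze
    channels.  Anchors falling outside the trace, or on another blink, are
    moved to the nearest valid sample on that side; if a side has none, the
    fill is constant from the other side's anchor.  A blink with no valid
    anchor on either side raises ``ValueError`` (unrecoverable trial).
    """
    cfg = cfg or PreprocConfig()
    if blinks is None:
        blinks = detect_blinks(trace, cfg)
    n = len(trace.t)
    valid = trace.d != 0
    d = trace.d.copy()
    gx = trace.gaze_x.copy()
    gy = trace.gaze_y.copy()
    for i, j in blinks:
        lo = i - cfg.interp_pre
        hi = j + cfg.interp_post
        while lo >= 0 and not valid[max(lo, 0)]:
            lo -= 1
        while hi < n and not valid[min(hi, n - 1)]:
            hi += 1
        has_lo = 0 <= lo < n
        has_hi = 0 <= hi < n
        if not has_lo and not has_hi:
            raise ValueError("blink with no valid anchor on either side; trial unrecoverable")
        if has_lo and has_hi:
            span = np.arange(lo + 1, hi)
            frac = (span - lo) / (hi - lo)
            for ch in (d, gx, gy):
                ch[span] = ch[lo] + frac * (ch[hi] - ch[lo])
        elif has_hi:  # one-sided at trace start: constant fill from the right anchor
            for ch in (d, gx, gy):
                ch[:hi] = ch[hi]
        else:  # one-sided at trace end
            for ch in (d, gx, gy):
                ch[lo + 1:] = ch[lo]
    return EyeTrace(trace.t, d, gx, gy, trace.rate)


def screen_trial(
    trace: EyeTrace,
    blinks: list[tuple[int, int]] | None = None,
    cfg: PreprocConfig | None = None,
) -> TrialDisposition:
    """Decide whether a trial survives the blink-fraction and gaze rules.

    A trial is excluded if 20% or more of its blink-window samples are
    blinks; otherwise, if any in-window gaze sample (after blink
    interpolation) falls outside the screen bounds.
    """
    cfg = cfg or PreprocConfig()
    if blinks is None:
        blinks = detect_blinks(trace, cfg)
    if blink_fraction(trace, cfg) >= cfg.blink_trial_threshold:
        return TrialDisposition(kept=False, reason="blink_fraction")
    try:
        clean = interpolate_blinks(trace, blinks, cfg)
    except ValueError:
        return TrialDisposition(kept=False, reason="unrecoverable")
    m = _window_mask(clean.t, cfg.blink_window)
    x0, x1, y0, y1 = cfg.screen_bounds
    off = (clean.gaze_x[m] < x0) | (clean.gaze_x[m] > x1) | (clean.gaze_y[m] < y0) | (clean.gaze_y[m] > y1)
    if off.any():
        return TrialDisposition(kept=False, reason="offscreen_gaze")
    return TrialDisposition(kept=True)


def smooth(d: np.ndarray, n_points: int = 11) -> np.ndarray:
    """Centered moving average; the window shrinks symmetrically at the edges."""
    if n_points % 2 != 1 or n_points < 1:
        raise ValueError("n_points must be odd and positive")
    d = np.asarray(d, dtype=float)
    half = n_points // 2
    c = np.concatenate(([0.0], np.cumsum(d)))
    idx = np.arange(len(d))
    k = np.minimum(half, np.minimum(idx, len(d) - 1 - idx))
    lo = idx - k
    hi = idx + k + 1
    return (c[hi] - c[lo]) / (hi - lo)


def baseline_correct(
    d: np.ndarray, t: np.ndarray, cfg: PreprocConfig | None = None
) -> tuple[np.ndarray, float]:
    """Subtract the mean over the pre-stimulus second; returns (trace, baseline)."""
    cfg = cfg or PreprocConfig()
    m = _window_mask(np.asarray(t), cfg.baseline_window, closed_hi=False)
    if not m.any():
        raise ValueError("baseline window not covered by the trace")
    baseline = float(np.mean(np.asarray(d, dtype=float)[m]))
    return np.asarray(d, dtype=float) - baseline, baseline


def compute_metrics(
    d_corrected: np.ndarray,
    t: np.ndarray,
    cfg: PreprocConfig | None = None,
    baseline_mm: float = np.nan,
) -> PupilMetrics:
    """PPD / MPD / PPDL over the metrics window of a baseline-corrected trace."""
    cfg = cfg or PreprocConfig()
    t = np.asarray(t, dtype=float)
    d = np.asarray(d_corrected, dtype=float)
    m = _window_mask(t, cfg.metrics_window)
    if not m.any():
        raise ValueError("metrics window not covered by the trace")
    dw, tw = d[m], t[m]
    i = int(np.argmax(dw))  # first maximum on ties
    return PupilMetrics(
        baseline_mm=baseline_mm,
        ppd_mm=float(dw[i]),
        mpd_mm=float(np.mean(dw)),
        ppdl_ms=float((tw[i] - cfg.metrics_window[0]) * 1000.0),
    )


def downsample(
    d: np.ndarray, t: np.ndarray, rate: float, target: float = 30.0
) -> tuple[np.ndarray, np.ndarray]:
    """Block-mean downsampling (e.g. 120 -> 30 Hz); timestamps at block centers."""
    ratio = rate / target
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("rate must be an integer multiple of the target rate")
    f = int(round(ratio))
    n = (len(d) // f) * f
    d2 = np.asarray(d, dtype=float)[:n].reshape(-1, f).mean(axis=1)
    t2 = np.asarray(t, dtype=float)[:n].reshape(-1, f).mean(axis=1)
    return d2, t2


@dataclass
class ProcessedTrial:
    """Outcome of the per-trial chain for the selected eye."""

    disposition: TrialDisposition
    t: np.ndarray | None = None
    d_corrected: np.ndarray | None = None
    baseline_mm: float | None = None
    metrics: PupilMetrics | None = None


def preprocess_trial(trace: EyeTrace, cfg: PreprocConfig | None = None) -> ProcessedTrial:
    """Run detection, screening, interpolation, smoothing, baseline correction
    and metrics for one trial of the selected eye."""
    cfg = cfg or PreprocConfig()
    blinks = detect_blinks(trace, cfg)
    disp = screen_trial(trace, blinks, cfg)
    if not disp.kept:
        return ProcessedTrial(disposition=disp)
    clean = interpolate_blinks(trace, blinks, cfg)
    d = smooth(clean.d, cfg.smooth_points)
    d, baseline = baseline_correct(d, clean.t, cfg)
    metrics = compute_metrics(d, clean.t, cfg, baseline_mm=baseline)
    return ProcessedTrial(disp, clean.t, d, baseline, metrics)


def preprocess_subject(
    trials: list[tuple[dict, PupilTrace]],
    cfg: PreprocConfig | None = None,
) -> tuple[str, list[tuple[dict, ProcessedTrial]]]:
    """Select the subject's eye and preprocess every trial with it.

    ``trials`` is a list of (metadata dict, two-eye trace).  Returns the eye
    label and per-trial results paired with the metadata.
    """
    cfg = cfg or PreprocConfig()
    eye = select_eye([tr for _, tr in trials])
    return eye, [(meta, preprocess_trial(tr.eye(eye), cfg)) for meta, tr in trials]


def condition_average(
    processed: list[tuple[dict, ProcessedTrial]],
    keys: tuple[str, ...],
    cfg: PreprocConfig | None = None,
) -> pd.DataFrame:
    """Average kept baseline-corrected traces within groups and re-derive metrics.

    Groups are defined by the metadata fields in ``keys`` (e.g. subject and
    condition factors).  PPD/MPD/PPDL come from the pointwise-mean trace;
    the reported baseline is the mean of the per-trial baselines.  Returns a
    tidy frame with one row per group (the averaged trace is held in the
    ``t``/``trace`` object columns); groups with no kept trial are flagged
    with ``n_trials == 0``.
    """
    cfg = cfg or PreprocConfig()
    groups: dict[tuple, list[ProcessedTrial]] = {}
    for meta, pt in processed:
        groups.setdefault(tuple(meta[k] for k in keys), []).append(pt)
    rows = []
    for gkey, pts in groups.items():
        kept = [p for p in pts if p.disposition.kept]
        row = dict(zip(keys, gkey))
        row["n_trials"] = len(kept)
        if kept:
            t = kept[0].t
            stack = np.vstack([p.d_corrected for p in kept])
            mean_trace = stack.mean(axis=0)
            base = float(np.mean([p.baseline_mm for p in kept]))
            met = compute_metrics(mean_trace, t, cfg, baseline_mm=base)
            row.update(
                baseline_mm=base,
                ppd_mm=met.ppd_mm,
                mpd_mm=met.mpd_mm,
                ppdl_ms=met.ppdl_ms,
                t=t,
                trace=mean_trace,
            )
        else:
            row.update(baseline_mm=np.nan, ppd_mm=np.nan, mpd_mm=np.nan, ppdl_ms=np.nan, t=None, trace=None)
        rows.append(row)
    return pd.DataFrame(rows)
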