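"""Synthetic experiments with known ground truth for every pipeline stage.

The generator emulates the study design: 16 subjects, each measured in the
full 2 (voice training) x 2 (vocoder) x 2 (item variability) within-subject
factorial.  Per-condition true just-noticeable differences (JNDs) are drawn
from log-normal distributions whose condition means and SDs equal the
bundled emulation targets, so staircase-recovered JNDs can be checked
against known truth.  Pupil traces are built at 120 Hz over [-3, +6.5] s
around stimulus onset from

* a tonic baseline level (plus a small anticipatory shift in variable-item
  conditions, applied from trial start),
* an event-related dilation: a gamma-density-shaped kernel, onset-locked,
  scaled by a per-condition amplitude (vocoded > non-vocoded), and
* AR(1) noise shared between the eyes plus eye-specific measurement noise,

with injected artifacts: shared blinks and eye-specific tracking dropouts
(zero runs), occasional trial-killing long blinks, and off-screen gaze
excursions (saccades).  Every trial's intended keep/exclude disposition
under the 20%-blink and off-screen rules is recorded as ground truth.

The gamma kernel and the noise/artifact rates are generator choices, not
claims about pupil physiology; see docs/methods.md.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy.stats import gamma as _gamma

from .pupil import PreprocConfig, PupilTrace, select_eye
from .staircase import StaircaseConfig, WeibullListener, run_staircase

__all__ = [
    "CONDITIONS",
    "SubjectSpec",
    "DatasetSpec",
    "load_jnd_targets",
    "default_population",
    "generate_behavior",
    "generate_pupil_trial",
    "generate_subject_pupil",
    "generate_experiment",
    "generate_dataset",
    "load_dataset",
]

TRAININGS = ("untrained", "trained")
VOCODERS = ("non-vocoded", "vocoded")
VARIABILITIES = ("fixed", "variable")

#: the eight within-subject conditions, as (training, vocoder, variability)
CONDITIONS: tuple[tuple[str, str, str], ...] = tuple(
    (tr, vo, va) for tr in TRAININGS for vo in VOCODERS for va in VARIABILITIES
)

RATE_HZ = 120.0
TRIAL_SPAN_S = (-3.0, 6.5)  # pupillometry starts in the pre-stimulus silence
_N_SAMPLES = int(round((TRIAL_SPAN_S[1] - TRIAL_SPAN_S[0]) * RATE_HZ)) + 1
_ONSET_IDX = int(round(-TRIAL_SPAN_S[0] * RATE_HZ))


def load_jnd_targets() -> pd.DataFrame:
    """Condition-mean JND emulation targets (mean and SD in st per condition)."""
    with importlib.resources.files("voicecue.data").joinpath("jnd_condition_targets.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


@dataclass
class SubjectSpec:
    """Ground-truth parameters of one simulated subject."""

    subject_id: str
    true_jnd_st: dict[tuple[str, str, str], float]
    pupil_amp_mm: dict[tuple[str, str, str], float]
    tonic_mm: float = 3.03
    variable_baseline_shift_mm: float = 0.04
    noise_sd_mm: float = 0.03
    ar1: float = 0.95
    blink_rate: float = 2.0  # shared blink events per trial
    blink_dur_mean: float = 25.0  # samples (~200 ms at 120 Hz)
    blink_dur_sd: float = 8.0
    long_blink_prob: float = 0.04  # trial-killing blink (>= 20% of the window)
    saccade_prob: float = 0.04
    dropout_rate_left: float = 0.3  # eye-specific zero runs per trial
    dropout_rate_right: float = 0.8
    listener_slope: float = 1.5

    def __post_init__(self) -> None:
        if not 2.0 <= self.tonic_mm <= 8.0:
            raise ValueError("tonic pupil level must be physiological (2-8 mm)")
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError("AR(1) coefficient must be in [0, 1)")
        if any(a < 0 for a in self.pupil_amp_mm.values()):
            raise ValueError("pupil amplitudes must be >= 0")


@dataclass
class DatasetSpec:
    """Shape of one synthetic experiment."""

    n_subjects: int = 16
    n_pupil_trials: int = 10  # pupil trials generated per condition
    seed: int = 0
    amp_nonvocoded_mm: float = 0.20
    amp_vocoded_mm: float = 0.40
    amp_subject_sd_mm: float = 0.05

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    # moment-match a log-normal: E=mean, SD=sd
    var = sd**2
    sigma2 = np.log1p(var / mean**2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def default_population(
    seed: int | np.random.Generator | None = 0,
    spec: DatasetSpec | None = None,
) -> list[SubjectSpec]:
    """Draw a population of subjects matching the condition-mean JND targets.

    True JNDs are log-normal per condition with the bundled means/SDs; pupil
    response amplitudes depend on the vocoder factor (vocoded larger) with
    subject-level variation.
    """
    spec = spec or DatasetSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    targets = {
        (r.training, r.vocoder, r.variability): (r.jnd_mean_st, r.jnd_sd_st)
        for r in load_jnd_targets().itertuples()
    }
    amp_base = {"non-vocoded": spec.amp_nonvocoded_mm, "vocoded": spec.amp_vocoded_mm}
    subjects = []
    for i in range(spec.n_subjects):
        jnd = {}
        for cond in CONDITIONS:
            mu, sig = _lognormal_params(*targets[cond])
            jnd[cond] = float(rng.lognormal(mu, sig))
        amp_dev = {vo: rng.normal(0.0, spec.amp_subject_sd_mm) for vo in VOCODERS}
        amp = {
            cond: float(max(0.02, amp_base[cond[1]] + amp_dev[cond[1]]))
            for cond in CONDITIONS
        }
        subjects.append(SubjectSpec(subject_id=f"S{i + 1:02d}", true_jnd_st=jnd, pupil_amp_mm=amp))
    return subjects


def generate_behavior(
    subject: SubjectSpec,
    cfg: StaircaseConfig | None = None,
    seed: int | np.random.Generator | None = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run one adaptive staircase per condition against the subject's oracle.

    Returns (jnd table, full per-trial trace table).
    """
    cfg = cfg or StaircaseConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    jnd_rows, trace_rows = [], []
    for cond in CONDITIONS:
        listener = WeibullListener(threshold_st=subject.true_jnd_st[cond], slope=subject.listener_slope)
        trace: list[dict] = []
        res = run_staircase(listener, cfg, seed=rng, trace=trace)
        training, vocoder, variability = cond
        jnd_rows.append(
            {
                "subject": subject.subject_id,
                "training": training,
                "vocoder": vocoder,
                "variability": variability,
                "true_jnd_st": subject.true_jnd_st[cond],
                "jnd_st": res.jnd_st,
                "status": res.status,
                "n_trials": res.n_trials,
                "n_reversals": len(res.reversal_levels),
            }
        )
        for row in trace:
            trace_rows.append(
                {"subject": subject.subject_id, "training": training, "vocoder": vocoder, "variability": variability, **row}
            )
    return pd.DataFrame(jnd_rows), pd.DataFrame(trace_rows)


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    eps = rng.standard_normal(n) * sd * np.sqrt(max(1.0 - phi**2, 1e-12))
    return _signal.lfilter([1.0], [1.0, -phi], eps)


def _pupil_kernel(t: np.ndarray, shape: float = 4.0, scale: float = 0.5) -> np.ndarray:
    """Gamma-density event-related kernel, peak-normalized (mode at 1.5 s)."""
    k = _gamma.pdf(np.clip(t, 0.0, None), a=shape, scale=scale)
    peak = _gamma.pdf((shape - 1.0) * scale, a=shape, scale=scale)
    out = np.where(t > 0, k / peak, 0.0)
    return out


def _zero_runs(d: np.ndarray) -> list[tuple[int, int]]:
    z = d == 0
    padded = np.concatenate(([False], z, [False]))
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:]) - 1
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


def generate_pupil_trial(
    subject: SubjectSpec,
    condition: tuple[str, str, str],
    seed: int | np.random.Generator | None = 0,
    cfg: PreprocConfig | None = None,
) -> tuple[PupilTrace, dict]:
    """One raw two-eye trial trace plus its ground-truth record.

    The truth dict records the injected artifacts, per-eye blink fractions
    within the analysis window, and the intended disposition rule inputs.
    """
    cfg = cfg or PreprocConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    training, vocoder, variability = condition
    n = _N_SAMPLES
    t = (np.arange(n) - _ONSET_IDX) / RATE_HZ

    level = subject.tonic_mm + (subject.variable_baseline_shift_mm if variability == "variable" else 0.0)
    amp = subject.pupil_amp_mm[condition]
    sig = level + amp * _pupil_kernel(t) + _ar1_noise(rng, n, subject.noise_sd_mm, subject.ar1)
    d_left = sig + rng.standard_normal(n) * 0.01
    d_right = sig + rng.standard_normal(n) * 0.01

    cx, cy = 960.0, 540.0
    gaze = {
        eye: (cx + rng.standard_normal(n) * 25.0, cy + rng.standard_normal(n) * 25.0)
        for eye in ("left", "right")
    }

    win_lo, win_hi = cfg.blink_window
    wlo = int(round((win_lo - TRIAL_SPAN_S[0]) * RATE_HZ))
    whi = int(round((win_hi - TRIAL_SPAN_S[0]) * RATE_HZ))
    n_window = whi - wlo + 1

    def zero_out(d: np.ndarray, start: int, dur: int) -> None:
        d[max(0, start):min(n, start + dur)] = 0.0

    # shared blinks (both eyes)
    blink_spans: list[tuple[int, int]] = []
    for _ in range(rng.poisson(subject.blink_rate)):
        dur = max(3, int(round(rng.normal(subject.blink_dur_mean, subject.blink_dur_sd))))
        start = int(rng.integers(wlo - 15, whi - 5))
        blink_spans.append((start, dur))
    long_blink = bool(rng.random() < subject.long_blink_prob)
    if long_blink:
        dur = int(np.ceil(0.25 * n_window))
        start = int(rng.integers(wlo, whi - dur))
        blink_spans.append((start, dur))
    for start, dur in blink_spans:
        zero_out(d_left, start, dur)
        zero_out(d_right, start, dur)
    # eye-specific tracking dropouts
    for d, rate in ((d_left, subject.dropout_rate_left), (d_right, subject.dropout_rate_right)):
        for _ in range(rng.poisson(rate)):
            dur = max(3, int(round(rng.normal(15.0, 5.0))))
            zero_out(d, int(rng.integers(0, n - dur)), dur)
    # trackers lose gaze during zero-diameter runs
    for d, eye in ((d_left, "left"), (d_right, "right")):
        gx, gy = gaze[eye]
        gx[d == 0] = 0.0
        gy[d == 0] = 0.0

    # off-screen gaze excursion, placed clear of every zero run and of the
    # interpolation guard bands so screening sees it after de-blinking
    saccade = False
    if rng.random() < subject.saccade_prob:
        margin = cfg.interp_post + cfg.interp_pre + 14
        runs = _zero_runs(d_left) + _zero_runs(d_right)
        dur = 6
        for _ in range(50):
            start = int(rng.integers(_ONSET_IDX + 30, whi - 60))
            if all(start - margin > e or start + dur + margin < s for s, e in runs):
                for eye in ("left", "right"):
                    gaze[eye][0][start:start + dur] = cfg.screen_bounds[1] + 300.0
                saccade = True
                break

    frac_left = float(np.count_nonzero(d_left[wlo:whi + 1] == 0) / n_window)
    frac_right = float(np.count_nonzero(d_right[wlo:whi + 1] == 0) / n_window)

    trace = PupilTrace(
        t=t,
        d_left=d_left,
        d_right=d_right,
        gaze_x_left=gaze["left"][0],
        gaze_y_left=gaze["left"][1],
        gaze_x_right=gaze["right"][0],
        gaze_y_right=gaze["right"][1],
        rate=RATE_HZ,
    )
    truth = {
        "training": training,
        "vocoder": vocoder,
        "variability": variability,
        "true_amp_mm": amp,
        "true_level_mm": level,
        "n_blinks": len(blink_spans),
        "long_blink": long_blink,
        "saccade_injected": saccade,
        "blink_frac_left": frac_left,
        "blink_frac_right": frac_right,
    }
    return trace, truth


def _intended_disposition(truth: dict, eye: str, threshold: float) -> str:
    frac = truth[f"blink_frac_{eye}"]
    if frac >= threshold:
        return "blink_fraction"
    if truth["saccade_injected"]:
        return "offscreen_gaze"
    return "none"


def generate_subject_pupil(
    subject: SubjectSpec,
    n_trials_per_condition: int = 10,
    seed: int | np.random.Generator | None = 0,
    cfg: PreprocConfig | None = None,
) -> tuple[list[tuple[dict, PupilTrace]], pd.DataFrame]:
    """All pupil trials of one subject plus the ground-truth table.

    The intended disposition is resolved for the eye that eye selection will
    pick (computed from the generated traces themselves).
    """
    cfg = cfg or PreprocConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trials: list[tuple[dict, PupilTrace]] = []
    truths: list[dict] = []
    k = 0
    for cond in CONDITIONS:
        for j in range(n_trials_per_condition):
            trace, truth = generate_pupil_trial(subject, cond, seed=rng, cfg=cfg)
            meta = {
                "subject": subject.subject_id,
                "trial": k,
                "training": cond[0],
                "vocoder": cond[1],
                "variability": cond[2],
            }
            trials.append((meta, trace))
            truths.append({**meta, **truth})
            k += 1
    eye = select_eye([tr for _, tr in trials])
    for row in truths:
        reason = _intended_disposition(row, eye, cfg.blink_trial_threshold)
        row["selected_eye"] = eye
        row["intended_reason"] = reason
        row["intended_kept"] = reason == "none"
    return trials, pd.DataFrame(truths)


def generate_experiment(
    spec: DatasetSpec | None = None,
    seed: int | None = None,
    staircase_cfg: StaircaseConfig | None = None,
    preproc_cfg: PreprocConfig | None = None,
):
    """Generate a full in-memory experiment.

    Returns (subjects, jnd table, staircase trace table, pupil trials keyed
    by subject, ground-truth table).
    """
    spec = spec or DatasetSpec()
    root_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(root_seed)
    pop_rng, beh_rng, pup_rng = rng.spawn(3)
    subjects = default_population(pop_rng, spec)
    jnd_tables, trace_tables, truth_tables = [], [], []
    pupil_by_subject: dict[str, list[tuple[dict, PupilTrace]]] = {}
    for subject, brng, prng in zip(subjects, beh_rng.spawn(len(subjects)), pup_rng.spawn(len(subjects))):
        jnd, trace = generate_behavior(subject, staircase_cfg, seed=brng)
        trials, truth = generate_subject_pupil(subject, spec.n_pupil_trials, seed=prng, cfg=preproc_cfg)
        jnd_tables.append(jnd)
        trace_tables.append(trace)
        truth_tables.append(truth)
        pupil_by_subject[subject.subject_id] = trials
    return (
        subjects,
        pd.concat(jnd_tables, ignore_index=True),
        pd.concat(trace_tables, ignore_index=True),
        pupil_by_subject,
        pd.concat(truth_tables, ignore_index=True),
    )


# --------------------------------------------------------------------------
# on-disk dataset layout


def _traces_frame(trials: list[tuple[dict, PupilTrace]]) -> pd.DataFrame:
    frames = []
    for meta, tr in trials:
        frames.append(
            pd.DataFrame(
                {
                    "subject": meta["subject"],
                    "trial": meta["trial"],
                    "t": tr.t,
                    "d_left": tr.d_left,
                    "d_right": tr.d_right,
                    "gaze_x_left": tr.gaze_x_left,
                    "gaze_y_left": tr.gaze_y_left,
                    "gaze_x_right": tr.gaze_x_right,
                    "gaze_y_right": tr.gaze_y_right,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_dataset(spec: DatasetSpec | None = None, out_dir: str | Path = "dataset", seed: int | None = None) -> Path:
    """Write a complete synthetic dataset to ``out_dir``.

    Layout: manifest.json, jnd.tsv, staircase_trials.tsv, ground_truth.tsv,
    and traces/<subject>.tsv (long format, one row per sample).
    Deterministic under the seed.
    """
    spec = spec or DatasetSpec()
    out = Path(out_dir)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    subjects, jnd, trace, pupil, truth = generate_experiment(spec, seed=seed)
    jnd.to_csv(out / "jnd.tsv", sep="\t", index=False)
    trace.to_csv(out / "staircase_trials.tsv", sep="\t", index=False)
    truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    for sid, trials in pupil.items():
        _traces_frame(trials).to_csv(out / "traces" / f"{sid}.tsv", sep="\t", index=False, float_format="%.6f")
    manifest = {
        "seed": spec.seed if seed is None else seed,
        "spec": asdict(spec),
        "n_conditions": len(CONDITIONS),
        "rate_hz": RATE_HZ,
        "trial_span_s": list(TRIAL_SPAN_S),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def load_dataset(path: str | Path):
    """Read a dataset written by :func:`generate_dataset`.

    Returns (manifest, jnd table, ground-truth table, pupil trials keyed by
    subject).
    """
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    jnd = pd.read_csv(path / "jnd.tsv", sep="\t")
    truth = pd.read_csv(path / "ground_truth.tsv", sep="\t")
    meta_cols = truth.set_index(["subject", "trial"])
    pupil: dict[str, list[tuple[dict, PupilTrace]]] = {}
    for f in sorted((path / "traces").glob("*.tsv")):
        df = pd.read_csv(f, sep="\t")
        sid = df["subject"].iloc[0]
        trials = []
        for trial, g in df.groupby("trial", sort=True):
            row = meta_cols.loc[(sid, trial)]
            meta = {
                "subject": sid,
                "trial": int(trial),
                "training": row["training"],
                "vocoder": row["vocoder"],
                "variability": row["variability"],
            }
            trials.append(
                (
                    meta,
                    PupilTrace(
                        t=g["t"].to_numpy(),
                        d_left=g["d_left"].to_numpy(),
                        d_right=g["d_right"].to_numpy(),
                        gaze_x_left=g["gaze_x_left"].to_numpy(),
                        gaze_y_left=g["gaze_y_left"].to_numpy(),
                        gaze_x_right=g["gaze_x_right"].to_numpy(),
                        gaze_y_right=g["gaze_y_right"].to_numpy(),
                        rate=float(manifest["rate_hz"]),
                    ),
                )
            )
        pupil[sid] = trials
    return manifest, jnd, truth, pupil
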