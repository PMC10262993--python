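"""Aggregation and inference for the 2 x 2 x 2 within-subject design.

Responses (log-JNDs or pupil metrics) are analyzed with a fully
within-subject repeated-measures ANOVA over voice training, vocoder and
item variability (two levels each).  For every effect E the test is
F(1, n-1) = MS_E / MS_{E x subject}, equivalent to a one-sample t-test on
per-subject contrast scores.  Effect sizes are generalized eta-squared,

    eta2_g = SS_E / (SS_E + SS_subjects + sum of all error SS),

the standard form for designs where every factor is manipulated within
subjects.  Pairwise follow-ups are paired t-tests with Benjamini-Hochberg
false-discovery-rate correction across the requested family.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

FACTORS = ("training", "vocoder", "variability")
LEVELS = {
    "training": ("untrained", "trained"),
    "vocoder": ("non-vocoded", "vocoded"),
    "variability": ("fixed", "variable"),
}

__all__ = [
    "FACTORS",
    "LEVELS",
    "AnovaResult",
    "PairwiseResult",
    "round_half_up",
    "log_transform_jnds",
    "marginal_means",
    "rm_anova_2x2x2",
    "pairwise_fdr",
    "export_gamm_table",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, matching how printed tables are rounded."""
    q = Decimal(10) ** -ndigits
    # 12 significant digits first, so float artifacts (1.7349999...9) do not
    # masquerade as genuine below-half digits
    return float(Decimal(f"{float(x):.12g}").quantize(q, rounding=ROUND_HALF_UP))


def log_transform_jnds(table: pd.DataFrame, column: str = "jnd_st") -> pd.DataFrame:
    """Append a natural-log JND column (``log_jnd``) to reduce skewness.

    The log base does not affect F, p or eta2_g.
    """
    if (table[column] <= 0).any():
        raise ValueError("JNDs must be strictly positive to log-transform")
    out = table.copy()
    out["log_jnd"] = np.log(table[column].to_numpy(dtype=float))
    return out


def marginal_means(
    cell_means: dict[tuple[str, str, str], float],
    margin: dict[str, str],
) -> float:
    """Unweighted average of the condition cells matching ``margin``.

    ``cell_means`` maps (training, vocoder, variability) to a mean (st);
    ``margin`` fixes one or two factors, e.g. ``{"vocoder": "vocoded"}``.
    All eight cells must be present.
    """
    for f, lv in margin.items():
        if f not in FACTORS or lv not in LEVELS[f]:
            raise ValueError(f"unknown factor/level {f}={lv}")
    cells = [
        (tr, vo, va)
        for tr in LEVELS["training"]
        for vo in LEVELS["vocoder"]
        for va in LEVELS["variability"]
    ]
    missing = [c for c in cells if c not in cell_means]
    if missing:
        raise ValueError(f"missing cells: {missing}")
    idx = dict(zip(FACTORS, range(3)))
    sel = [c for c in cells if all(c[idx[f]] == lv for f, lv in margin.items())]
    return float(np.mean([cell_means[c] for c in sel]))


@dataclass
class AnovaResult:
    """Repeated-measures ANOVA table for the seven within-subject effects."""

    table: pd.DataFrame  # effect, F, df1, df2, p, eta2_g, ss_effect, ss_error
    ss_subjects: float

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


def _pivot_cells(table: pd.DataFrame, response: str, subject: str) -> np.ndarray:
    """Arrange the response as Y[subject, training, vocoder, variability]."""
    subs = sorted(table[subject].unique())
    n = len(subs)
    Y = np.full((n, 2, 2, 2), np.nan)
    pos = {f: {lv: k for k, lv in enumerate(LEVELS[f])} for f in FACTORS}
    sub_pos = {s: i for i, s in enumerate(subs)}
    for r in table.itertuples():
        i = sub_pos[getattr(r, subject)]
        a = pos["training"][getattr(r, "training")]
        b = pos["vocoder"][getattr(r, "vocoder")]
        c = pos["variability"][getattr(r, "variability")]
        Y[i, a, b, c] = getattr(r, response)
    if np.isnan(Y).any():
        raise ValueError("incomplete factorial: every subject needs all 8 cells")
    return Y


def rm_anova_2x2x2(
    table: pd.DataFrame,
    response: str,
    subject: str = "subject",
) -> AnovaResult:
    """Fully within-subject 2x2x2 ANOVA with generalized eta-squared.

    ``table`` is long format with columns ``subject``, the three factor
    columns (levels as in :data:`LEVELS`) and the response.  Each effect is
    tested against its own interaction-with-subject error term on
    (1, n-1) degrees of freedom.
    """
    Y = _pivot_cells(table, response, subject)
    n = Y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    grand = Y.mean()
    ss_subjects = 8.0 * float(((Y.mean(axis=(1, 2, 3)) - grand) ** 2).sum())

    factor_axes = {"training": 1, "vocoder": 2, "variability": 3}
    effects = []
    for k in (1, 2):
        effects += [tuple(c) for c in combinations(FACTORS, k)]
    effects.append(tuple(FACTORS))

    rows = []
    for eff in effects:
        axes = {factor_axes[f] for f in eff}
        M = Y
        for ax in (1, 2, 3):
            if ax in axes:
                M = M - M.mean(axis=ax, keepdims=True)
            else:
                M = M.mean(axis=ax, keepdims=True)
        pop = M.mean(axis=0, keepdims=True)  # population effect array
        reps = 8.0 / 2 ** len(axes)  # observations per effect cell per subject
        ss_eff = float(n * reps * (pop**2).sum())
        ss_err = float(reps * ((M - pop) ** 2).sum())
        df1, df2 = 1, n - 1
        if ss_err > 0:
            F = (ss_eff / df1) / (ss_err / df2)
            p = float(sps.f.sf(F, df1, df2))
        else:
            F = np.inf if ss_eff > 0 else np.nan
            p = 0.0 if ss_eff > 0 else np.nan
        rows.append(
            {
                "effect": " x ".join(eff),
                "F": F,
                "df1": df1,
                "df2": df2,
                "p": p,
                "ss_effect": ss_eff,
                "ss_error": ss_err,
            }
        )
    tab = pd.DataFrame(rows)
    denom_common = ss_subjects + tab["ss_error"].sum()
    tab["eta2_g"] = tab["ss_effect"] / (tab["ss_effect"] + denom_common)
    return AnovaResult(table=tab, ss_subjects=ss_subjects)


@dataclass
class PairwiseResult:
    contrast: str
    t: float
    df: int
    p_raw: float
    p_fdr: float


def pairwise_fdr(
    table: pd.DataFrame,
    response: str,
    factor: str,
    within: str | None = None,
    subject: str = "subject",
) -> list[PairwiseResult]:
    """Paired t-tests on a two-level factor, optionally within the levels of
    another factor, with Benjamini-Hochberg correction over the family.

    Observations are per-subject means over any remaining factors.
    """
    lv = LEVELS[factor]
    strata = LEVELS[within] if within is not None else (None,)
    raw = []
    for s in strata:
        sub = table if s is None else table[table[within] == s]
        cellA = sub[sub[factor] == lv[0]].groupby(subject)[response].mean()
        cellB = sub[sub[factor] == lv[1]].groupby(subject)[response].mean()
        common = cellA.index.intersection(cellB.index)
        if len(common) < 2:
            raise ValueError("need at least 2 paired subjects per contrast")
        diff = cellB.loc[common].to_numpy() - cellA.loc[common].to_numpy()
        if np.var(diff, ddof=1) == 0.0:
            # degenerate pairs: no evidence either way (t=0, p=1) unless the
            # shared difference is itself nonzero
            t, p = (0.0, 1.0) if np.allclose(diff, 0.0) else (np.inf, 0.0)
        else:
            t, p = sps.ttest_rel(cellB.loc[common], cellA.loc[common])
        label = f"{factor}: {lv[1]} - {lv[0]}" + (f" | {within}={s}" if s is not None else "")
        raw.append((label, float(t), len(common) - 1, float(p)))
    _, p_adj, _, _ = multipletests([r[3] for r in raw], method="fdr_bh")
    return [
        PairwiseResult(contrast=l, t=t, df=df, p_raw=p, p_fdr=float(q))
        for (l, t, df, p), q in zip(raw, p_adj)
    ]


def export_gamm_table(
    avg_traces: pd.DataFrame,
    time_col: str = "t",
    pupil_col: str = "pupil_mm",
) -> pd.DataFrame:
    """Long-format export for time-course (GAMM) modelling.

    Input: one row per sample of per-subject, per-(training, vocoder)
    averaged traces already pooled over item variability, with columns
    ``subject``, ``training``, ``vocoder``, ``t`` and the pupil value.
    Output columns: ``Pupil``, ``Time`` (s), ``Condition`` (4-level
    training.vocoder factor) and ``Event`` (one averaged curve = one event).
    """
    req = {"subject", "training", "vocoder", time_col, pupil_col}
    missing = req - set(avg_traces.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = pd.DataFrame(
        {
            "Pupil": avg_traces[pupil_col].to_numpy(dtype=float),
            "Time": avg_traces[time_col].to_numpy(dtype=float),
            "Condition": (
                avg_traces["training"].astype(str) + "." + avg_traces["vocoder"].astype(str)
            ),
            "Event": (
                avg_traces["subject"].astype(str)
                + "_"
                + avg_traces["training"].astype(str)
                + "_"
                + avg_traces["vocoder"].astype(str)
            ),
        }
    )
    return out
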