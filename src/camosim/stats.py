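"""Reaction-time analysis pipeline.

Stages, in order: participant exclusion (error rate > mean + 4 s.d.),
removal of no-response and incorrect trials (percentages logged against
the post-participant-exclusion trial count), reciprocal transform
(1 / RT-in-seconds) with a pooled 3 s.d. outlier screen, collapse to
per-participant cell means over the 2 x 2 x 2 condition crossing, a
fully-within repeated-measures ANOVA with generalized eta squared, and
paired simple-effects t-tests with Cohen's d.

In a balanced fully-within 2 x 2 x 2 design every effect has one degree
of freedom, so each effect reduces to a per-subject difference score: for
contrast c over the 8 cells, ``d_s = mean(cells with c=+1) - mean(cells
with c=-1)``, giving ``SS_effect = 2 n dbar^2`` and
``SS_error = 2 sum_s (d_s - dbar)^2`` (the subject-by-effect term).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .experiment import (
    ENHANCEMENT_LEVELS,
    ILLUMINATION_LEVELS,
    VIEWING_LEVELS,
)

__all__ = [
    "FACTOR_LEVELS",
    "EFFECTS",
    "CleanedData",
    "AnovaTable",
    "SimpleEffect",
    "exclude_participants",
    "filter_trials",
    "reciprocal_transform_and_screen",
    "cell_mean_matrix",
    "rm_anova_2x2x2",
    "generalized_eta_squared",
    "simple_effect",
    "default_simple_effects",
    "analyze",
]

FACTORS = ("enhancement", "illumination", "viewing")
FACTOR_LEVELS = {
    "enhancement": ENHANCEMENT_LEVELS,
    "illumination": ILLUMINATION_LEVELS,
    "viewing": VIEWING_LEVELS,
}

#: Canonical order of the 8 design cells (enhancement, illumination, viewing).
CELLS = tuple(
    itertools.product(ENHANCEMENT_LEVELS, ILLUMINATION_LEVELS, VIEWING_LEVELS)
)

EFFECTS = (
    "enhancement",
    "illumination",
    "viewing",
    "enhancement:illumination",
    "enhancement:viewing",
    "illumination:viewing",
    "enhancement:illumination:viewing",
)


def effect_contrast(effect: str) -> np.ndarray:
    """+/-1 contrast over the 8 canonical cells for a named effect."""
    terms = effect.split(":")
    codes = np.ones(len(CELLS))
    for f in terms:
        pos = FACTORS.index(f)
        level1 = FACTOR_LEVELS[f][1]
        codes *= np.array([1.0 if c[pos] == level1 else -1.0 for c in CELLS])
    return codes


class DataError(ValueError):
    """Raised for data violating a pipeline precondition."""


# ---------------------------------------------------------------------------
# Exclusions and transformation


def exclude_participants(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop participants whose error rate exceeds mean + 4 s.d.

    Error rate is the proportion of trials without a correct response
    (incorrect or no response).  A single pass is applied.  With zero
    spread no participant is removed.
    """
    if df["participant"].nunique() < 3:
        raise DataError("need at least 3 participants")
    rates = 1.0 - df.groupby("participant")["correct"].mean()
    sd = rates.std(ddof=1)
    cutoff = rates.mean() + 4.0 * sd
    removed = [] if sd == 0 else sorted(rates.index[rates > cutoff])
    log = {
        "participants_before": int(rates.size),
        "participants_removed": [int(p) for p in removed],
        "error_rate_cutoff": float(cutoff),
    }
    return df[~df["participant"].isin(removed)].copy(), log


def filter_trials(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Remove no-response then incorrect trials, logging their percentages.

    Percentages are computed on the trial count entering this stage (i.e.
    after participant exclusion, before any trial removal).
    """
    n0 = len(df)
    if n0 == 0:
        raise DataError("no trials to filter")
    no_resp = df["response"] == "none"
    incorrect = ~df["correct"] & ~no_resp
    kept = df[~no_resp & ~incorrect].copy()
    log = {
        "trials_before": int(n0),
        "no_response_removed": int(no_resp.sum()),
        "no_response_pct": 100.0 * float(no_resp.sum()) / n0,
        "incorrect_removed": int(incorrect.sum()),
        "incorrect_pct": 100.0 * float(incorrect.sum()) / n0,
    }
    return kept, log


@dataclass
class CleanedData:
    """Per-participant cell means on the transformed and ms scales."""

    cell_means: pd.DataFrame  # participants x 8 cells, 1/RT(s) scale
    cell_means_ms: pd.DataFrame  # same shape, raw ms scale
    log: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.cell_means)

    def matrix(self) -> np.ndarray:
        return self.cell_means.to_numpy(dtype=float)


def reciprocal_transform_and_screen(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Add the 1/RT(s) column and remove pooled 3 s.d. outliers on it."""
    if (df["rt_ms"] <= 0).any() or df["rt_ms"].isna().any():
        raise DataError("all retained trials must have rt_ms > 0")
    out = df.copy()
    out["rt_recip"] = 1000.0 / out["rt_ms"]
    mu = out["rt_recip"].mean()
    sd = out["rt_recip"].std(ddof=1)
    if sd > 0:
        outlier = (out["rt_recip"] - mu).abs() > 3.0 * sd
    else:
        outlier = pd.Series(False, index=out.index)
    log = {
        "outliers_removed": int(outlier.sum()),
        "outlier_pct": 100.0 * float(outlier.sum()) / len(out) if len(out) else 0.0,
    }
    return out[~outlier].copy(), log


def cell_mean_matrix(df: pd.DataFrame, value: str = "rt_recip") -> pd.DataFrame:
    """Collapse trials to per-participant means over the 8 design cells.

    Participants missing any cell are dropped (and listed in the frame's
    ``attrs['incomplete_participants']``).
    """
    piv = df.pivot_table(
        index="participant",
        columns=["enhancement", "illumination", "viewing"],
        values=value,
        aggfunc="mean",
    )
    piv = piv.reindex(columns=pd.MultiIndex.from_tuples(CELLS))
    incomplete = piv.index[piv.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"dropping participants with empty cells: {list(incomplete)}",
            stacklevel=2,
        )
    out = piv.drop(index=incomplete)
    out.attrs["incomplete_participants"] = [int(p) for p in incomplete]
    return out


def clean_and_collapse(df: pd.DataFrame) -> CleanedData:
    """Run the full exclusion/transform/collapse pipeline."""
    df1, log_p = exclude_participants(df)
    df2, log_t = filter_trials(df1)
    df3, log_o = reciprocal_transform_and_screen(df2)
    cm = cell_mean_matrix(df3, "rt_recip")
    cm_ms = cell_mean_matrix(df3, "rt_ms")
    log = {**log_p, **log_t, **log_o,
           "incomplete_participants": cm.attrs["incomplete_participants"]}
    return CleanedData(cell_means=cm, cell_means_ms=cm_ms.loc[cm.index], log=log)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA


@dataclass
class AnovaTable:
    """Fully-within 2 x 2 x 2 decomposition, one row per effect."""

    table: pd.DataFrame  # index EFFECTS; ss_effect ss_error df_effect df_error F p
    ss_subjects: float
    ss_total: float
    n: int

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.loc[effect]


def rm_anova_2x2x2(cell_means) -> AnovaTable:
    """Repeated-measures ANOVA on an n x 8 cell-mean matrix.

    Accepts a :class:`CleanedData`, the pivot produced by
    :func:`cell_mean_matrix`, or a plain array in canonical cell order.
    Each effect is tested against its own subject-by-effect error term
    with (1, n-1) degrees of freedom.
    """
    if isinstance(cell_means, CleanedData):
        Y = cell_means.matrix()
    elif isinstance(cell_means, pd.DataFrame):
        Y = cell_means.reindex(columns=pd.MultiIndex.from_tuples(CELLS)).to_numpy(
            dtype=float
        )
    else:
        Y = np.asarray(cell_means, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != 8:
        raise DataError("cell-mean matrix must be n x 8")
    if np.isnan(Y).any():
        raise DataError("cell-mean matrix contains missing cells")
    n = Y.shape[0]
    if n < 2:
        raise DataError("need at least 2 participants for the ANOVA")
    grand = Y.mean()
    ss_subjects = 8.0 * float(((Y.mean(axis=1) - grand) ** 2).sum())
    ss_total = float(((Y - grand) ** 2).sum())
    rows = {}
    for eff in EFFECTS:
        c = effect_contrast(eff)
        d = Y[:, c > 0].mean(axis=1) - Y[:, c < 0].mean(axis=1)
        dbar = d.mean()
        ss_e = 2.0 * n * dbar**2
        ss_err = 2.0 * float(((d - dbar) ** 2).sum())
        df_err = n - 1
        if ss_err == 0:
            if ss_e == 0:
                F, p = 0.0, 1.0
            else:
                warnings.warn(f"zero error SS for {eff}; F reported as inf",
                              stacklevel=2)
                F, p = np.inf, 0.0
        else:
            F = (ss_e / 1.0) / (ss_err / df_err)
            p = float(sps.f.sf(F, 1, df_err))
        rows[eff] = {
            "ss_effect": ss_e,
            "ss_error": ss_err,
            "df_effect": 1,
            "df_error": df_err,
            "F": F,
            "p": p,
        }
    table = pd.DataFrame(rows).T.loc[list(EFFECTS)]
    table[["df_effect", "df_error"]] = table[["df_effect", "df_error"]].astype(int)
    return AnovaTable(table=table, ss_subjects=ss_subjects, ss_total=ss_total, n=n)


def generalized_eta_squared(anova: AnovaTable) -> pd.Series:
    """Generalized eta squared per effect.

    For a fully-within design all measured variance is subject-related, so
    the denominator pools the effect's own SS with the subject SS and
    every error SS: ``SS_e / (SS_e + SS_subjects + sum of all SS_error)``.
    """
    total_err = float(anova.table["ss_error"].sum())
    denom = anova.table["ss_effect"] + anova.ss_subjects + total_err
    with np.errstate(invalid="ignore"):
        eta = anova.table["ss_effect"] / denom
    eta[denom == 0] = np.nan
    anova.table["eta_g_sq"] = eta
    return eta


# ---------------------------------------------------------------------------
# Simple effects


@dataclass
class SimpleEffect:
    """Paired contrast between two levels of a factor within a slice."""

    label: str
    mean_diff_ms: float  # level1 - level0 on the untransformed ms scale
    mean_diff_transformed: float  # level1 - level0 on the 1/RT scale
    t: float
    df: int
    p: float
    cohens_d: float  # d_z: mean diff / SD of paired differences
    cohens_d_av: float  # mean diff / mean of the two condition SDs


def _condition_means(
    cm: pd.DataFrame, factor: str, level: str, within: dict[str, str]
) -> pd.Series:
    sel = [
        c
        for c in cm.columns
        if c[FACTORS.index(factor)] == level
        and all(c[FACTORS.index(f)] == lv for f, lv in within.items())
    ]
    if not sel:
        raise DataError(f"no cells match {factor}={level}, within={within}")
    return cm[sel].mean(axis=1)


def simple_effect(
    cleaned: CleanedData,
    factor: str,
    within: dict[str, str] | None = None,
    label: str | None = None,
) -> SimpleEffect:
    """Paired t-test between the two levels of ``factor``.

    Cells are averaged over the factors not mentioned in ``within``; the
    test statistic and d are computed on the transformed scale, the mean
    difference is additionally reported on the millisecond scale.
    """
    within = within or {}
    lv0, lv1 = FACTOR_LEVELS[factor]
    a_t = _condition_means(cleaned.cell_means, factor, lv0, within)
    b_t = _condition_means(cleaned.cell_means, factor, lv1, within)
    a_ms = _condition_means(cleaned.cell_means_ms, factor, lv0, within)
    b_ms = _condition_means(cleaned.cell_means_ms, factor, lv1, within)
    diff = (b_t - a_t).to_numpy()
    n = diff.size
    sd = diff.std(ddof=1)
    dbar = diff.mean()
    if sd == 0:
        if dbar == 0:
            t, p, dz = 0.0, 1.0, 0.0
        else:
            warnings.warn("zero variance of paired differences; t undefined",
                          stacklevel=2)
            t = np.nan
            p = np.nan
            dz = np.nan
    else:
        t = dbar / (sd / np.sqrt(n))
        p = 2.0 * float(sps.t.sf(abs(t), n - 1))
        dz = dbar / sd
    sd_av = 0.5 * (a_t.std(ddof=1) + b_t.std(ddof=1))
    d_av = dbar / sd_av if sd_av > 0 else np.nan
    if label is None:
        ctx = ", ".join(f"{f}={lv}" for f, lv in within.items())
        label = f"{factor} ({ctx})" if ctx else factor
    return SimpleEffect(
        label=label,
        mean_diff_ms=float((b_ms - a_ms).mean()),
        mean_diff_transformed=float(dbar),
        t=float(t),
        df=n - 1,
        p=p,
        cohens_d=float(dz),
        cohens_d_av=float(d_av),
    )


def default_simple_effects(cleaned: CleanedData) -> list[SimpleEffect]:
    """The four contrasts the study reports: enhancement and illumination
    effects within each viewing condition."""
    out = []
    for factor in ("enhancement", "illumination"):
        for view in VIEWING_LEVELS:
            out.append(simple_effect(cleaned, factor, {"viewing": view}))
    return out


# ---------------------------------------------------------------------------
# Orchestration


def analyze(df: pd.DataFrame) -> dict:
    """Full pipeline on a trial-level frame; returns a JSON-able summary."""
    cleaned = clean_and_collapse(df)
    anova = rm_anova_2x2x2(cleaned)
    generalized_eta_squared(anova)
    simples = default_simple_effects(cleaned)
    return {
        "exclusions": cleaned.log,
        "n_participants": cleaned.n,
        "anova": {
            eff: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
            for eff, row in anova.table.iterrows()
        },
        "ss_subjects": anova.ss_subjects,
        "simple_effects": [
            {
                "label": s.label,
                "mean_diff_ms": s.mean_diff_ms,
                "t": None if np.isnan(s.t) else s.t,
                "df": s.df,
                "p": None if np.isnan(s.p) else s.p,
                "cohens_d": None if np.isnan(s.cohens_d) else s.cohens_d,
                "cohens_d_av": None if np.isnan(s.cohens_d_av) else s.cohens_d_av,
            }
            for s in simples
        ],
    }


def report(results: dict) -> str:
    """Plain-text summary mirroring the structure of the study's results."""
    lines = ["Reaction-time analysis", "=" * 22, ""]
    ex = results["exclusions"]
    lines.append(
        f"Participants analysed: {results['n_participants']} "
        f"(removed: {ex['participants_removed'] or 'none'})"
    )
    lines.append(
        f"Trials removed: {ex['no_response_pct']:.2f}% no response, "
        f"{ex['incorrect_pct']:.2f}% incorrect, "
        f"{ex['outliers_removed']} transformed-scale outliers"
    )
    lines.append("")
    lines.append("ANOVA (fully within, reciprocal-transformed cell means):")
    for eff, row in results["anova"].items():
        lines.append(
            f"  {eff:40s} F(1,{row['df_error']:.0f}) = {row['F']:8.2f}, "
            f"p = {row['p']:.4g}, etaG^2 = {row['eta_g_sq']:.4f}"
        )
    lines.append("")
    lines.append("Simple effects (paired t, transformed scale):")
    for s in results["simple_effects"]:
        lines.append(
            f"  {s['label']:40s} diff = {s['mean_diff_ms']:8.2f} ms, "
            f"t({s['df']}) = {s['t']:.2f}, p = {s['p']:.4g}, "
            f"d_z = {s['cohens_d']:.2f}"
        )
    return "\n".join(lines)
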