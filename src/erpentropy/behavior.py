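"""Go/No-Go flanker task: schedule, scoring, summaries and mixed ANOVA.

The task combines a Go/No-Go paradigm with an Eriksen flanker manipulation:
five-letter strings whose center letter is the target.  B and U demand a key
press (Go), D and V demand withholding (No Go); flankers either match the
target (congruent) or map to the opposite response (incongruent).

The behavioral analysis is a balanced mixed-design (split-plot) ANOVA with
one between-subject factor (fitness group) and two-level within-subject
factors (exercise, trial type, congruency).  Because every factor has two
levels, each effect carries 1 numerator df and its sum of squares follows
exactly from a +/-1 contrast coding: for contrast codes ``c_i`` and
observations ``y_i``, ``SS_effect = N * mean(c*y)^2``.  Each within effect
(and its interaction with the group factor) is tested against the
subject-within-group stratum of its own contrast; the group effect is tested
against the between-subject stratum.  This classical expected-mean-squares
computation is deterministic and reproducible against a direct
sums-of-squares oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "STIMULI",
    "TaskTiming",
    "generate_schedule",
    "score_points",
    "summarize_behavior",
    "mixed_anova",
    "simple_effects",
    "posthoc_contrast",
]

#: stimulus string -> (trialtype, congruency); Go targets are B and U.
STIMULI: dict[str, tuple[str, str]] = {
    "BBBBB": ("Go", "congruent"),
    "UUUUU": ("Go", "congruent"),
    "DDDDD": ("NoGo", "congruent"),
    "VVVVV": ("NoGo", "congruent"),
    "DDBDD": ("Go", "incongruent"),
    "VVUVV": ("Go", "incongruent"),
    "BBDBB": ("NoGo", "incongruent"),
    "UUVUU": ("NoGo", "incongruent"),
}


@dataclass(frozen=True)
class TaskTiming:
    """Trial timing constants (ms) and the per-trial stake in points."""

    fixation_ms: int = 600
    string_total_ms: int = 480
    target_delay_ms: int = 320
    target_duration_ms: int = 80
    feedback_latency_ms: int = 750
    feedback_duration_ms: int = 500
    iti_ms: int = 2600
    points_per_trial: int = 5

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")


def generate_schedule(
    n_blocks: int = 5,
    trials_per_block: int = 120,
    seed: int | np.random.Generator | None = None,
    balanced: bool = True,
) -> pd.DataFrame:
    """Randomized stimulus schedule: ``n_blocks`` blocks of
    ``trials_per_block`` trials.

    With ``balanced=True`` (default) each of the eight strings appears
    ``trials_per_block / 8`` times per block, giving exactly equal Go/No-Go
    totals; order is shuffled per block.  ``balanced=False`` samples strings
    uniformly at random instead.

    Returns a DataFrame with trial_index (0-based, global), block (1-based),
    stimulus_string, congruency, trialtype.
    """
    rng = np.random.default_rng(seed)
    strings = sorted(STIMULI)
    if balanced and trials_per_block % len(strings):
        raise ValueError(
            f"trials_per_block={trials_per_block} not divisible by "
            f"{len(strings)} stimulus strings"
        )
    rows = []
    for block in range(1, n_blocks + 1):
        if balanced:
            block_strings = np.repeat(strings, trials_per_block // len(strings))
            rng.shuffle(block_strings)
        else:
            block_strings = rng.choice(strings, size=trials_per_block)
        for s in block_strings:
            tt, cong = STIMULI[s]
            rows.append(
                {
                    "trial_index": len(rows),
                    "block": block,
                    "stimulus_string": s,
                    "congruency": cong,
                    "trialtype": tt,
                }
            )
    return pd.DataFrame(rows)


def score_points(trials: pd.DataFrame, points_per_trial: int = 5) -> int:
    """Total points: +``points_per_trial`` per correct trial, - per error."""
    correct = trials["correct"].to_numpy(dtype=bool)
    return int(points_per_trial * (correct.sum() - (~correct).sum()))


def summarize_behavior(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean hit RT and error rate.

    Cells are participant x session x congruency x trialtype.  ``mean_rt_ms``
    is computed over hits (correct Go responses) only, so it is missing in
    No-Go cells; ``error_rate_percent`` is 100 x errors / trials in the cell.
    """
    need = {"participant", "session", "congruency", "trialtype", "correct"}
    missing = need - set(trials.columns)
    if missing:
        raise ValueError(f"trial log lacks columns {sorted(missing)}")
    keys = ["participant", "session", "congruency", "trialtype"]
    rows = []
    for key, cell in trials.groupby(keys, sort=True):
        correct = cell["correct"].to_numpy(dtype=bool)
        er = 100.0 * float((~correct).sum()) / len(cell)
        rt = np.nan
        if key[3] == "Go":
            hits = cell[correct & (cell["trialtype"] == "Go")]
            if len(hits):
                rt = float(hits["rt_ms"].mean())
        rows.append(
            dict(zip(keys, key))
            | {"mean_rt_ms": rt, "error_rate_percent": er, "n_trials": len(cell)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed-design (split-plot) ANOVA for 2-level factors
# ---------------------------------------------------------------------------


def _codes(values: pd.Series, factor: str) -> np.ndarray:
    levels = sorted(values.unique())
    if len(levels) != 2:
        raise ValueError(
            f"factor {factor!r} must have exactly 2 levels, got {levels}"
        )
    return np.where(values.to_numpy() == levels[1], 1.0, -1.0)


def _check_balance(data, subject, between, within):
    """Complete, balanced split-plot layout or ValueError."""
    cell_counts = data.groupby([subject, *within], sort=False).size()
    if cell_counts.nunique() != 1:
        raise ValueError("design is unbalanced or has missing within-cells")
    n_cells = data[within].drop_duplicates().shape[0] if within else 1
    per_subject = data.groupby(subject).size()
    if per_subject.nunique() != 1:
        raise ValueError("subjects contribute unequal numbers of rows")
    if between is not None:
        g = data.groupby(subject)[between].nunique()
        if (g != 1).any():
            raise ValueError("a subject appears in more than one group")
    return int(per_subject.iloc[0]), n_cells


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str = "participant",
    between: str | None = "fitness_group",
    within: tuple = ("session", "trialtype", "congruency"),
) -> pd.DataFrame:
    """Balanced split-plot ANOVA with 2-level factors.

    Returns a table with one row per effect: ``effect``, ``df1``, ``df2``,
    ``ss_effect``, ``ss_error``, ``F``, ``p``.  The between effect is tested
    against the between-subject stratum; every within effect (alone or
    crossed with the between factor) against the subject-within-group
    stratum of its own contrast.  Rows with missing ``dv`` are rejected.
    """
    within = list(within)
    data = data[[c for c in {subject, between, *within, dv} if c]].copy()
    if data[dv].isna().any():
        raise ValueError(f"missing values in dv {dv!r}; no imputation is done")
    m_per_subject, _ = _check_balance(data, subject, between, within)
    n_total = len(data)
    n_subj = data[subject].nunique()

    if between is not None:
        group_of = data.groupby(subject)[between].first()
        n_groups = group_of.nunique()
    else:
        group_of = None
        n_groups = 1

    within_codes = {f: _codes(data[f], f) for f in within}
    results = []

    def _one_way(scores: pd.Series):
        """(ss_effect_of_grand_mean=None) group decomposition of per-subject
        scores: returns (ss_groups, ss_within_groups)."""
        if group_of is not None:
            gmeans = scores.groupby(group_of).transform("mean")
            counts = scores.groupby(group_of).size()
            overall = scores.mean()
            ss_g = float(
                (counts * (scores.groupby(group_of).mean() - overall) ** 2).sum()
            )
            ss_w = float(((scores - gmeans) ** 2).sum())
        else:
            ss_g = 0.0
            ss_w = float(((scores - scores.mean()) ** 2).sum())
        return ss_g, ss_w

    # between-subject stratum: one-way ANOVA on subject means, scaled by the
    # number of observations per subject
    if between is not None:
        subj_mean = data.groupby(subject)[dv].mean()
        ss_g, ss_w = _one_way(subj_mean)
        ss = m_per_subject * ss_g
        ss_err = m_per_subject * ss_w
        df_err = n_subj - n_groups
        if ss_err > 0:
            f = (ss / 1.0) / (ss_err / df_err)
        else:
            f = 0.0 if ss == 0 else np.inf
        results.append(
            {
                "effect": between,
                "df1": 1,
                "df2": df_err,
                "ss_effect": ss,
                "ss_error": ss_err,
                "F": f,
                "p": float(stats.f.sf(f, 1, df_err)),
            }
        )

    # within strata: per-subject contrast scores for every nonempty subset
    # of within factors; the effect tests the mean score, the interaction
    # with the group factor tests group differences in the score, both
    # against the subject-within-group stratum of that score
    err_df = n_subj - n_groups
    from itertools import combinations

    for k in range(1, len(within) + 1):
        for combo in combinations(within, k):
            code = np.prod([within_codes[f] for f in combo], axis=0)
            zs = (
                data.assign(_z=code * data[dv].to_numpy(dtype=float))
                .groupby(subject)["_z"]
                .mean()
            )
            ss_g, ss_w = _one_way(zs)
            ss_err = m_per_subject * ss_w
            ms_err = ss_err / err_df if err_df > 0 else np.nan
            entries = [
                (" * ".join(combo), m_per_subject * n_subj * float(zs.mean()) ** 2)
            ]
            if between is not None:
                entries.append(
                    (" * ".join([between, *combo]), m_per_subject * ss_g)
                )
            for name, ss in entries:
                if ss_err > 0:
                    f = ss / ms_err
                else:
                    f = 0.0 if ss == 0 else np.inf
                results.append(
                    {
                        "effect": name,
                        "df1": 1,
                        "df2": err_df,
                        "ss_effect": ss,
                        "ss_error": ss_err,
                        "F": f,
                        "p": float(stats.f.sf(f, 1, err_df)),
                    }
                )
    return pd.DataFrame(results)


def simple_effects(
    data: pd.DataFrame,
    dv: str,
    slice_factor: str,
    slice_level,
    subject: str = "participant",
    within: tuple = ("session", "trialtype"),
    error: str = "pooled",
    between: str | None = "fitness_group",
) -> pd.DataFrame:
    """Within-subject ANOVA on one slice of the between factor.

    ``error="pooled"`` (default) tests each within effect in the slice
    against the full sample's within-group stratum (df = n_subjects -
    n_groups, as in whole-sample follow-up contrasts); ``error="slice"``
    uses the slice's own stratum (df = n_slice - 1), matching per-group
    follow-up ANOVAs.
    """
    if error not in ("pooled", "slice"):
        raise ValueError("error must be 'pooled' or 'slice'")
    within = list(within)
    sliced = data[data[slice_factor] == slice_level]
    n_slice = sliced[subject].nunique()
    if n_slice < 2:
        raise ValueError(
            f"slice {slice_factor}={slice_level!r} has {n_slice} "
            "participants; need at least 2"
        )
    # numerators from the slice
    slice_tab = mixed_anova(sliced, dv, subject=subject, between=None,
                            within=within)
    if error == "slice":
        return slice_tab
    pooled_tab = mixed_anova(
        data, dv, subject=subject, between=between, within=within
    ).set_index("effect")
    out = []
    for _, row in slice_tab.iterrows():
        pooled = pooled_tab.loc[row["effect"]]
        ms_err = pooled["ss_error"] / pooled["df2"]
        f = row["ss_effect"] / ms_err
        out.append(
            {
                "effect": row["effect"],
                "df1": 1,
                "df2": int(pooled["df2"]),
                "ss_effect": row["ss_effect"],
                "ss_error": pooled["ss_error"],
                "F": f,
                "p": float(stats.f.sf(f, 1, pooled["df2"])),
            }
        )
    return pd.DataFrame(out)


def posthoc_contrast(
    data: pd.DataFrame,
    dv: str,
    effect_factor: str,
    slice_spec: dict | None = None,
    subject: str = "participant",
    between: str | None = "fitness_group",
    within: tuple = ("session", "trialtype"),
    pooled: bool = True,
) -> dict:
    """Paired two-level contrast inside a slice, e.g. No-Go vs Go at rest.

    Computes the per-subject difference of ``effect_factor`` levels within
    the rows selected by ``slice_spec`` and tests it against either the
    pooled full-design error stratum for the contrast's factors (default,
    df = n_subjects - n_groups) or the slice's own paired variance
    (``pooled=False``, df = n_slice - 1).  Returns a dict with levels,
    mean difference, F, dfs and p.
    """
    sliced = data
    slice_spec = slice_spec or {}
    for k, v in slice_spec.items():
        sliced = sliced[sliced[k] == v]
    levels = sorted(sliced[effect_factor].unique())
    if len(levels) != 2:
        raise ValueError(
            f"{effect_factor!r} must have 2 levels in the slice, got {levels}"
        )
    wide = sliced.groupby([subject, effect_factor])[dv].mean().unstack()
    diffs = (wide[levels[1]] - wide[levels[0]]).dropna()
    n = len(diffs)
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    mean_diff = float(diffs.mean())
    if pooled:
        # pooled error: within-group variance of the same paired difference
        # computed for every subject in the within-slice (both groups)
        within_slice = {k: v for k, v in slice_spec.items() if k != between}
        alldat = data
        for k, v in within_slice.items():
            alldat = alldat[alldat[k] == v]
        wide_all = (
            alldat.groupby([subject, effect_factor])[dv].mean().unstack()
        )
        d_all = (wide_all[levels[1]] - wide_all[levels[0]]).dropna()
        if between is not None:
            group_of = alldat.groupby(subject)[between].first()
            resid = d_all - d_all.groupby(group_of).transform("mean")
            df2 = len(d_all) - group_of.nunique()
        else:
            resid = d_all - d_all.mean()
            df2 = len(d_all) - 1
        var = float((resid**2).sum()) / df2
        f = n * mean_diff**2 / var if var > 0 else (
            0.0 if mean_diff == 0 else np.inf
        )
    else:
        var = float(diffs.var(ddof=1))
        df2 = n - 1
        f = n * mean_diff**2 / var if var > 0 else (0.0 if mean_diff == 0 else np.inf)
    return {
        "levels": tuple(levels),
        "mean_diff": mean_diff,
        "F": float(f),
        "df1": 1,
        "df2": int(df2),
        "p": float(stats.f.sf(f, 1, df2)),
        "n": n,
    }
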