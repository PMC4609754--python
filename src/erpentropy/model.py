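"""Mixed-effects trajectory models of binned entropy, with backward
elimination and Hochberg-adjusted inference.

One linear mixed model is fitted per region.  The response is the binned
regional entropy; time over the three 500 ms bins is coded with orthonormal
polynomial contrasts (linear ``(-1,0,1)/sqrt(2)``, quadratic
``(1,-2,1)/sqrt(6)``), and every two-level design factor is effect-coded
+/-0.5 so each coefficient is the average difference between its two levels:

* hemisphere: left = +0.5, right = -0.5 (a negative coefficient means lower
  entropy on the left),
* fitness: higher = +0.5, lower = -0.5,
* exercise: exercise = +0.5, rest = -0.5,
* trialtype: NoGo = +0.5, Go = -0.5,
* congruency: incongruent = +0.5, congruent = -0.5.

Random effects per participant: intercept, linear and quadratic time.  Fixed
effects: linear time, quadratic time, the configured factors, and all
factor-by-time products.  Backward elimination removes, one at a time, the
least significant highest-order term whose Hochberg-adjusted p exceeds
alpha, never removing a term while an interaction containing it is retained
(marginality; linear and quadratic time are treated as distinct orthogonal
components).  Post-hoc contrasts compare adjacent bins with paired t-tests
and fitness groups per bin with rank-sum Z statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "FACTOR_CODES",
    "Term",
    "LmmResult",
    "build_long_table",
    "fit_region_lmm",
    "backward_eliminate",
    "hochberg_adjust",
    "interval_contrasts",
    "group_contrasts",
]

_BIN_ORDER = ("0-500", "500-1000", "1000-1500")
_TIME_LIN = dict(zip(_BIN_ORDER, np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0)))
_TIME_QUAD = dict(zip(_BIN_ORDER, np.array([1.0, -2.0, 1.0]) / np.sqrt(6.0)))

#: canonical factor -> (column in the binned table, {level: +/-0.5 code})
FACTOR_CODES: dict[str, tuple[str, dict]] = {
    "hemisphere": ("hemisphere", {"left": 0.5, "right": -0.5}),
    "fitness": ("group", {"higher": 0.5, "lower": -0.5}),
    "exercise": ("session", {"exercise": 0.5, "rest": -0.5}),
    "trialtype": ("trialtype", {"NoGo": 0.5, "Go": -0.5}),
    "congruency": ("congruency", {"incongruent": 0.5, "congruent": -0.5}),
}

DEFAULT_FACTORS = ("hemisphere", "fitness", "exercise", "trialtype", "congruency")


@dataclass(frozen=True)
class Term:
    """One fixed-effect term: an optional time component (``None``, "lin" or
    "quad") crossed with a set of design factors."""

    time: str | None
    factors: frozenset = frozenset()

    @property
    def order(self) -> int:
        return len(self.factors) + (1 if self.time else 0)

    @property
    def label(self) -> str:
        parts = [f.capitalize() for f in sorted(self.factors)]
        if self.time == "lin":
            parts.insert(0, "Time")
        elif self.time == "quad":
            parts.insert(0, "Time Sq")
        return " x ".join(parts) if parts else "Intercept"

    def contains(self, other: "Term") -> bool:
        """True if ``other`` is marginal to (strictly contained in) self."""
        if self == other:
            return False
        if not other.factors <= self.factors:
            return False
        return other.time is None or other.time == self.time

    def __lt__(self, other):  # stable ordering for display
        return (self.order, self.label) < (other.order, other.label)


INTERCEPT = Term(None, frozenset())


def all_terms(factors=DEFAULT_FACTORS) -> list[Term]:
    """Intercept, linear/quadratic time, factors, and all products."""
    factors = list(factors)
    terms = []
    for t in (None, "lin", "quad"):
        for k in range(len(factors) + 1):
            for combo in combinations(factors, k):
                terms.append(Term(t, frozenset(combo)))
    return sorted(terms)


@dataclass
class LmmResult:
    """Fitted mixed-model summary: one row per retained fixed term, plus the
    elimination history when produced by :func:`backward_eliminate`."""

    table: pd.DataFrame
    eliminated: list = field(default_factory=list)
    converged: bool = True
    singular: bool = False
    region: str = ""


def build_long_table(
    binned: pd.DataFrame, factors=DEFAULT_FACTORS
) -> pd.DataFrame:
    """Attach orthonormal time codes and +/-0.5 factor codes to a binned
    entropy table.

    Adds ``time_lin``, ``time_quad`` and one ``<factor>_c`` column per
    configured factor; rows are otherwise passed through unchanged.
    """
    df = binned.copy()
    unknown = set(df["bin"].unique()) - set(_BIN_ORDER)
    if unknown:
        raise ValueError(f"unknown bin labels {sorted(unknown)}")
    df["time_lin"] = df["bin"].map(_TIME_LIN)
    df["time_quad"] = df["bin"].map(_TIME_QUAD)
    for f in factors:
        col, codes = FACTOR_CODES[f]
        vals = df[col].map(codes)
        if vals.isna().any():
            bad = sorted(set(df[col][vals.isna()]))
            raise ValueError(f"unknown levels {bad} for factor {f!r}")
        df[f"{f}_c"] = vals
    return df


def _design_matrix(table: pd.DataFrame, terms: list[Term]) -> np.ndarray:
    cols = []
    for t in terms:
        col = np.ones(len(table))
        if t.time == "lin":
            col = col * table["time_lin"].to_numpy()
        elif t.time == "quad":
            col = col * table["time_quad"].to_numpy()
        for f in sorted(t.factors):
            col = col * table[f"{f}_c"].to_numpy()
        cols.append(col)
    return np.column_stack(cols)


def _fit_mixedlm(y, X, groups, Z, reml=True):
    """Fit a MixedLM; on singular random-effects covariance, refit with a
    diagonal covariance (logged warning)."""
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import MixedLMParams

    model = sm.MixedLM(y, X, groups=groups, exog_re=Z)
    singular = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=reml, method="lbfgs", maxiter=500)
        except Exception:
            res = None
    if res is not None:
        ev = np.linalg.eigvalsh(np.atleast_2d(res.cov_re))
        if ev.min() < 1e-10 * max(ev.max(), 1e-12):
            singular = True
    if res is None or singular:
        logger.warning(
            "singular random-effects covariance; refitting with a diagonal "
            "covariance"
        )
        free = MixedLMParams.from_components(
            fe_params=np.ones(X.shape[1]), cov_re=np.eye(Z.shape[1])
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(free=free, reml=reml, method="lbfgs", maxiter=500)
        singular = True
    converged = bool(getattr(res, "converged", True))
    return res, converged, singular


def fit_region_lmm(
    table: pd.DataFrame,
    factors=DEFAULT_FACTORS,
    terms: list[Term] | None = None,
    response: str = "entropy",
    df_method: str = "normal",
    adjust: bool = True,
    region: str = "",
) -> LmmResult:
    """Fit the full mixed model for one region's binned entropy.

    Random structure: intercept + linear + quadratic time per participant
    (full covariance; diagonal fallback if singular).  ``df_method="normal"``
    computes p from the standard normal (the default, as the t statistics at
    these sample sizes are reported without df); ``"residual"`` uses a t
    distribution with ``n_obs - n_fixed`` df as a coarse finite-sample
    alternative.  With ``adjust=True`` the non-intercept p values are
    Hochberg-adjusted as one family.
    """
    if table["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    y = table[response].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("response contains non-finite values")
    if terms is None:
        terms = all_terms(factors)
    if "time_lin" not in table.columns:
        table = build_long_table(table, factors)
    X = _design_matrix(table, terms)
    Z = np.column_stack(
        [np.ones(len(table)), table["time_lin"], table["time_quad"]]
    )
    groups = table["participant"].to_numpy()
    res, converged, singular = _fit_mixedlm(y, X, groups, Z)
    b = np.asarray(res.fe_params, dtype=float)
    se = np.asarray(res.bse_fe, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where((se > 0) & np.isfinite(se), b / se, np.nan)
    # a zero coefficient with zero SE is a degenerate exact null
    tstat = np.where((se == 0) & (b == 0), 0.0, tstat)
    if df_method == "normal":
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    elif df_method == "residual":
        dof = max(len(y) - X.shape[1], 1)
        p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    else:
        raise ValueError("df_method must be 'normal' or 'residual'")
    out = pd.DataFrame(
        {
            "term": [t.label for t in terms],
            "b": b,
            "SE": se,
            "t": tstat,
            "p": p,
        }
    )
    out["p_adj"] = np.nan
    if adjust:
        mask = (out["term"] != "Intercept") & np.isfinite(out["p"])
        if mask.any():
            out.loc[mask, "p_adj"] = hochberg_adjust(
                out.loc[mask, "p"].to_numpy()
            )
    out.attrs["terms"] = terms
    return LmmResult(out, [], converged, singular, region)


def backward_eliminate(
    table: pd.DataFrame,
    factors=DEFAULT_FACTORS,
    alpha: float = 0.05,
    response: str = "entropy",
    df_method: str = "normal",
    family: str = "step",
    region: str = "",
) -> LmmResult:
    """Backward elimination of fixed effects under the marginality rule.

    At each step the currently removable terms (no retained interaction
    contains them; the intercept is never removable) are tested; their p
    values are Hochberg-adjusted — over the removable set per step
    (``family="step"``, the default) or over all non-intercept terms
    (``family="model"``) — and the highest-order term with the largest
    adjusted p above ``alpha`` is dropped.  The model is refitted after
    every removal; elimination stops when every removable term is
    significant.  The returned table describes the final model, with the
    elimination history in ``eliminated`` as (label, step) pairs.
    """
    if "time_lin" not in table.columns:
        table = build_long_table(table, factors)
    terms = all_terms(factors)
    eliminated: list[tuple[str, int]] = []
    step = 0
    while True:
        res = fit_region_lmm(
            table, factors, terms=terms, response=response,
            df_method=df_method, adjust=False, region=region,
        )
        tab = res.table.set_index("term")
        removable = [
            t
            for t in terms
            if t != INTERCEPT and not any(u.contains(t) for u in terms)
        ]
        if not removable:
            break
        if family == "step":
            fam_terms = removable
        elif family == "model":
            fam_terms = [t for t in terms if t != INTERCEPT]
        else:
            raise ValueError("family must be 'step' or 'model'")
        p_fam = tab.loc[[t.label for t in fam_terms], "p"].to_numpy()
        p_fam = np.nan_to_num(p_fam, nan=1.0)  # unestimable -> removable
        adj = dict(zip(fam_terms, hochberg_adjust(p_fam)))
        candidates = [t for t in removable if adj[t] > alpha]
        if not candidates:
            break
        drop = max(candidates, key=lambda t: (t.order, adj[t]))
        terms.remove(drop)
        eliminated.append((drop.label, step))
        step += 1
    final = fit_region_lmm(
        table, factors, terms=terms, response=response,
        df_method=df_method, adjust=True, region=region,
    )
    final.eliminated = eliminated
    return final


def hochberg_adjust(p) -> np.ndarray:
    """Hochberg step-up adjusted p values, returned in the input order.

    With ascending sorted p(1..m), ``adj(i) = min_{j >= i} (m - j + 1) *
    p(j)``, capped at 1.  Adjusted values are monotone non-decreasing in the
    raw values and never smaller than them.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = (m - np.arange(m)) * p[order]
    adj_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def _participant_bin_means(
    binned: pd.DataFrame, filters: dict
) -> pd.DataFrame:
    df = binned
    for k, v in filters.items():
        if v is not None:
            df = df[df[k] == v]
    if df.empty:
        raise ValueError(f"no rows match {filters}")
    return (
        df.groupby(["participant", "bin"])["entropy"].mean().unstack()
    )


def interval_contrasts(
    binned: pd.DataFrame,
    region: str,
    hemisphere: str | None = None,
    trialtype: str | None = None,
) -> pd.DataFrame:
    """Paired t-tests between adjacent bins on participant means.

    Participant means are taken over all conditions in the selected slice.
    Returns one row per adjacent-bin pair: contrast label, ``m_diff``
    (later minus earlier bin), ``t``, ``df`` (= n - 1), ``p``.
    """
    wide = _participant_bin_means(
        binned, {"region": region, "hemisphere": hemisphere, "trialtype": trialtype}
    )
    rows = []
    for earlier, later in zip(_BIN_ORDER[:-1], _BIN_ORDER[1:]):
        pair = wide[[earlier, later]].dropna()
        if len(pair) < 3:
            raise ValueError(
                f"fewer than 3 paired observations for {earlier} vs {later}"
            )
        diffs = pair[later] - pair[earlier]
        if np.allclose(diffs, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(pair[later], pair[earlier])
        rows.append(
            {
                "contrast": f"{later} vs {earlier}",
                "m_diff": float((pair[later] - pair[earlier]).mean()),
                "t": float(t),
                "df": len(pair) - 1,
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def group_contrasts(
    binned: pd.DataFrame,
    region: str,
    hemisphere: str,
    group_col: str = "group",
    statistic: str = "ranksum",
) -> pd.DataFrame:
    """Fitness-group comparison of participant mean entropy, per bin.

    Default statistic is the rank-sum (Wilcoxon/Mann-Whitney) normal
    approximation Z (higher minus lower fit); ``statistic="welch"`` gives a
    Welch t-test instead.  Returns one row per bin with the statistic and p.
    """
    df = binned[(binned["region"] == region) & (binned["hemisphere"] == hemisphere)]
    if df.empty:
        raise ValueError(f"no rows for {hemisphere} {region}")
    rows = []
    for b in _BIN_ORDER:
        sub = df[df["bin"] == b]
        means = sub.groupby(["participant", group_col])["entropy"].mean()
        means = means.reset_index()
        hi = means.loc[means[group_col] == "higher", "entropy"].to_numpy()
        lo = means.loc[means[group_col] == "lower", "entropy"].to_numpy()
        if len(hi) < 2 or len(lo) < 2:
            raise ValueError(f"bin {b}: need >= 2 participants per group")
        if statistic == "ranksum":
            z, p = stats.ranksums(hi, lo)
            rows.append({"bin": b, "Z": float(z), "p": float(p)})
        elif statistic == "welch":
            t, p = stats.ttest_ind(hi, lo, equal_var=False)
            rows.append({"bin": b, "Z": float(t), "p": float(p)})
        else:
            raise ValueError("statistic must be 'ranksum' or 'welch'")
    return pd.DataFrame(rows)
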