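"""Independent reference implementations used only by the tests.

Each oracle is deliberately written in the most literal way possible —
explicit loops over template pairs, Mobius sums over marginal means,
bisection over the sequential rejection rule — so that agreement with the
package's vectorized implementations is meaningful.
"""

from __future__ import annotations

import math
from itertools import combinations, product

import numpy as np
import pandas as pd


def sampen_bruteforce(x, m=2, r_multiplier=0.25, distance="chebyshev"):
    """O(N^2) template-comparison sample entropy.

    Returns (value, count_m, count_m1, sd, degenerate) with counts over
    ordered pairs i != j of the N - m templates at both lengths.
    """
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    n_templates = n - m
    n_pairs = n_templates * (n_templates - 1)
    if sd == 0.0:
        return 0.0, n_pairs, n_pairs, 0.0, True
    r = r_multiplier * sd

    def dist(i, j, length):
        if distance == "chebyshev":
            return max(abs(x[i + k] - x[j + k]) for k in range(length))
        return math.sqrt(sum((x[i + k] - x[j + k]) ** 2 for k in range(length)))

    count_m = 0
    count_m1 = 0
    for i in range(n_templates):
        for j in range(n_templates):
            if i == j:
                continue
            if dist(i, j, m) <= r:
                count_m += 1
            if dist(i, j, m + 1) <= r:
                count_m1 += 1
    if count_m == 0 or count_m1 == 0:
        return float("nan"), count_m, count_m1, sd, True
    return -math.log(count_m1 / count_m), count_m, count_m1, sd, False


def hochberg_stepup_oracle(p):
    """Adjusted p by bisection over the sequential step-up decision rule.

    For each hypothesis, the adjusted p is the smallest alpha at which the
    step-up procedure (find the largest k with p_(k) <= alpha / (m - k + 1);
    reject hypotheses 1..k) rejects it.
    """
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])

    def rejected_at(alpha):
        ks = [
            k
            for k in range(1, m + 1)
            if p[order[k - 1]] <= alpha / (m - k + 1)
        ]
        if not ks:
            return set()
        return set(order[: max(ks)])

    out = [None] * m
    for i in range(m):
        lo, hi = 0.0, 1.0
        if i not in rejected_at(1.0):
            out[i] = 1.0
            continue
        for _ in range(60):
            mid = (lo + hi) / 2.0
            if i in rejected_at(mid):
                hi = mid
            else:
                lo = mid
        out[i] = hi
    return out


def _marginal_mean(df, dv, factors, levels):
    sub = df
    for f, l in zip(factors, levels):
        sub = sub[sub[f] == l]
    return sub[dv].mean()


def _mobius_ss(df, dv, factors):
    """Sum of squares of the |factors|-way interaction via Mobius sums over
    marginal means (balanced design)."""
    n_total = len(df)
    level_sets = [sorted(df[f].unique()) for f in factors]
    n_cells = int(np.prod([len(ls) for ls in level_sets]))
    ss = 0.0
    for cell in product(*level_sets):
        est = 0.0
        k = len(factors)
        for r in range(k + 1):
            for idx in combinations(range(k), r):
                sub_factors = [factors[i] for i in idx]
                sub_levels = [cell[i] for i in idx]
                sign = (-1) ** (k - r)
                est += sign * _marginal_mean(df, dv, sub_factors, sub_levels)
        ss += est * est
    return (n_total / n_cells) * ss


def splitplot_anova_oracle(df, dv, subject, between, within):
    """Direct sums-of-squares split-plot ANOVA from cell/marginal means.

    Balanced designs, all factors 2-level, ``n`` subjects per group, one
    observation per subject x within-cell.  Returns {effect: (ss, ss_err,
    df_err, F)} with effect names matching behavior.mixed_anova.
    """
    within = list(within)
    m = df.groupby(subject).size().iloc[0]
    group_of = df.groupby(subject)[between].first()
    n_subj = len(group_of)
    n_groups = group_of.nunique()

    # between stratum
    subj_means = df.groupby(subject)[dv].mean()
    grand = df[dv].mean()
    group_means = df.groupby(between)[dv].mean()
    ss_between = m * sum(
        (group_means[g] - grand) ** 2 * (group_of == g).sum()
        for g in group_means.index
    )
    ss_subj_within = m * sum(
        (subj_means[s] - group_means[group_of[s]]) ** 2 for s in subj_means.index
    )
    out = {
        between: (
            ss_between,
            ss_subj_within,
            n_subj - n_groups,
            (ss_between / 1.0) / (ss_subj_within / (n_subj - n_groups)),
        )
    }

    for k in range(1, len(within) + 1):
        for combo in combinations(within, k):
            combo = list(combo)
            ss_w = _mobius_ss(df, dv, combo)
            ss_wb = _mobius_ss(df, dv, [between, *combo])
            # error: subject x combo within groups, by Mobius over
            # (subject, combo) minus (group, combo)
            level_sets = [sorted(df[f].unique()) for f in combo]
            ss_err = 0.0
            for s in subj_means.index:
                g = group_of[s]
                sdf = df[df[subject] == s]
                gdf = df[df[between] == g]
                for cell in product(*level_sets):
                    est = 0.0
                    kk = len(combo)
                    for r in range(kk + 1):
                        for idx in combinations(range(kk), r):
                            sub_f = [combo[i] for i in idx]
                            sub_l = [cell[i] for i in idx]
                            sign = (-1) ** (kk - r)
                            est += sign * (
                                _marginal_mean(sdf, dv, sub_f, sub_l)
                                - _marginal_mean(gdf, dv, sub_f, sub_l)
                            )
                    ss_err += est * est
            ss_err *= m / (2 ** len(combo))
            df_err = n_subj - n_groups
            out[" * ".join(combo)] = (
                ss_w, ss_err, df_err, ss_w / (ss_err / df_err)
            )
            out[" * ".join([between, *combo])] = (
                ss_wb, ss_err, df_err, ss_wb / (ss_err / df_err)
            )
    return out
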