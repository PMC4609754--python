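import numpy as np
import pandas as pd
import pytest

from erpentropy.model import (
    FACTOR_CODES,
    INTERCEPT,
    Term,
    all_terms,
    backward_eliminate,
    build_long_table,
    fit_region_lmm,
    group_contrasts,
    hochberg_adjust,
    interval_contrasts,
)
from oracles import hochberg_stepup_oracle

BINS = ("0-500", "500-1000", "1000-1500")


def make_binned_lmm_data(
    n_participants=30,
    seed=0,
    beta=None,
    intercept=0.46,
    re_sd=(0.02, 0.01, 0.005),
    noise_sd=0.01,
):
    """Participant x hemisphere x bin entropy table with known effects.

    ``beta`` maps term labels built from {"time_lin", "time_quad",
    "hemisphere_c", "fitness_c"} products (e.g. ("hemisphere_c",
    "fitness_c")) to coefficients on the coded scale.
    """
    rng = np.random.default_rng(seed)
    beta = beta or {}
    rows = []
    for i in range(n_participants):
        group = "higher" if i < n_participants // 2 else "lower"
        for hemi in ("left", "right"):
            for b in BINS:
                rows.append(
                    {
                        "participant": f"P{i:02d}",
                        "group": group,
                        "hemisphere": hemi,
                        "region": "frontal",
                        "bin": b,
                        "entropy": 0.0,
                    }
                )
    df = build_long_table(pd.DataFrame(rows), factors=("hemisphere", "fitness"))
    u = {
        p: rng.normal(0.0, re_sd) for p in df["participant"].unique()
    }
    y = np.full(len(df), float(intercept))
    for cols, coef in beta.items():
        y = y + coef * np.prod([df[c].to_numpy() for c in cols], axis=0)
    for j, row in df.iterrows():
        u0, u1, u2 = u[row["participant"]]
        y[j] += u0 + u1 * row["time_lin"] + u2 * row["time_quad"]
    y = y + rng.normal(0.0, noise_sd, len(df))
    df["entropy"] = y
    return df


class TestHochberg:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.04], [0.02, 0.04]),
            ([0.05, 0.05], [0.05, 0.05]),
        ],
    )
    def test_hand_enumerated_examples(self, p, expected):
        assert hochberg_adjust(p) == pytest.approx(expected, abs=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(30):
            p = rng.random(rng.integers(1, 10))
            _, adj, _, _ = multipletests(p, method="hommel")  # not hochberg
            got = hochberg_adjust(p)
            _, adj_h, _, _ = multipletests(p, method="simes-hochberg")
            assert got == pytest.approx(adj_h, abs=1e-12)

    def test_matches_stepup_oracle(self, rng):
        for _ in range(20):
            p = np.round(rng.random(rng.integers(1, 7)), 3)
            assert hochberg_adjust(p) == pytest.approx(
                hochberg_stepup_oracle(p), abs=1e-9
            )

    def test_monotone_and_bounded(self, rng):
        p = np.sort(rng.random(8))
        adj = hochberg_adjust(p)
        assert np.all(np.diff(adj) >= -1e-15)
        assert np.all(adj >= p) and np.all(adj <= 1.0)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            hochberg_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            hochberg_adjust([])


class TestLongTable:
    def _binned(self):
        rows = []
        for p in ("P01", "P02"):
            for hemi in ("left", "right"):
                for b in BINS:
                    rows.append(
                        {
                            "participant": p,
                            "group": "higher" if p == "P01" else "lower",
                            "hemisphere": hemi,
                            "region": "frontal",
                            "bin": b,
                            "entropy": 0.5,
                        }
                    )
        return pd.DataFrame(rows)

    def test_orthonormal_time_codes(self):
        df = build_long_table(self._binned(), factors=("hemisphere",))
        lin = df.drop_duplicates("bin").set_index("bin")["time_lin"]
        quad = df.drop_duplicates("bin").set_index("bin")["time_quad"]
        assert lin.loc[list(BINS)].to_numpy() == pytest.approx(
            np.array([-1, 0, 1]) / np.sqrt(2)
        )
        assert quad.loc[list(BINS)].to_numpy() == pytest.approx(
            np.array([1, -2, 1]) / np.sqrt(6)
        )
        v1, v2 = df["time_lin"].to_numpy(), df["time_quad"].to_numpy()
        assert v1 @ v2 == pytest.approx(0.0, abs=1e-12)
        assert v1.sum() == pytest.approx(0.0, abs=1e-12)

    def test_effect_codes_sum_to_zero(self):
        df = build_long_table(self._binned(), factors=("hemisphere", "fitness"))
        assert df["hemisphere_c"].sum() == 0.0
        assert df["fitness_c"].sum() == 0.0
        assert set(df["hemisphere_c"]) == {0.5, -0.5}

    def test_row_count_preserved(self):
        binned = self._binned()
        assert len(build_long_table(binned, ("hemisphere",))) == len(binned)

    def test_unknown_bin_rejected(self):
        binned = self._binned()
        binned.loc[0, "bin"] = "1500-2000"
        with pytest.raises(ValueError, match="bin"):
            build_long_table(binned)


class TestTermAlgebra:
    def test_labels_and_order(self):
        t = Term("quad", frozenset({"hemisphere", "fitness"}))
        assert t.label == "Time Sq x Fitness x Hemisphere"
        assert t.order == 3
        assert INTERCEPT.label == "Intercept"

    def test_containment_rules(self):
        hem = Term(None, frozenset({"hemisphere"}))
        hem_fit = Term(None, frozenset({"hemisphere", "fitness"}))
        lin_hem = Term("lin", frozenset({"hemisphere"}))
        quad_hem = Term("quad", frozenset({"hemisphere"}))
        assert hem_fit.contains(hem)
        assert lin_hem.contains(hem)
        assert not quad_hem.contains(lin_hem)  # distinct time components
        assert not hem.contains(hem_fit)

    def test_term_count(self):
        assert len(all_terms(("hemisphere", "fitness"))) == 12


class TestFitRegionLmm:
    def test_constant_response_intercept_only(self):
        df = make_binned_lmm_data(n_participants=8, seed=1,
                                  re_sd=(0, 0, 0), noise_sd=0.0)
        res = fit_region_lmm(df, factors=("hemisphere", "fitness"))
        tab = res.table.set_index("term")
        assert tab.loc["Intercept", "b"] == pytest.approx(0.46, abs=1e-8)
        others = tab.drop("Intercept")["b"]
        assert np.allclose(others, 0.0, atol=1e-8)

    def test_reduces_to_ols_without_participant_variance(self):
        import statsmodels.api as sm
        from erpentropy.model import _design_matrix

        df = make_binned_lmm_data(
            n_participants=20, seed=3, re_sd=(0, 0, 0), noise_sd=0.02,
            beta={("hemisphere_c", "fitness_c"): 0.03},
        )
        terms = all_terms(("hemisphere", "fitness"))
        res = fit_region_lmm(df, factors=("hemisphere", "fitness"))
        X = _design_matrix(df, terms)
        ols = sm.OLS(df["entropy"].to_numpy(), X).fit()
        assert res.table["b"].to_numpy() == pytest.approx(
            ols.params, abs=1e-6
        )

    def test_recovers_programmed_interaction(self):
        estimates = []
        for seed in range(5):
            df = make_binned_lmm_data(
                seed=seed, beta={("hemisphere_c", "fitness_c"): 0.03}
            )
            res = fit_region_lmm(df, factors=("hemisphere", "fitness"))
            tab = res.table.set_index("term")
            estimates.append(tab.loc["Fitness x Hemisphere", "b"])
        assert np.mean(estimates) == pytest.approx(0.03, rel=0.25)

    def test_too_few_participants_rejected(self):
        df = make_binned_lmm_data(n_participants=8, seed=0)
        solo = df[df["participant"] == "P00"]
        with pytest.raises(ValueError):
            fit_region_lmm(solo, factors=("hemisphere", "fitness"))


class TestBackwardElimination:
    def test_marginality_never_violated_and_intercept_kept(self):
        df = make_binned_lmm_data(
            seed=7, beta={("hemisphere_c", "fitness_c"): 0.03}
        )
        res = backward_eliminate(df, factors=("hemisphere", "fitness"))
        retained_labels = set(res.table["term"])
        assert "Intercept" in retained_labels
        retained = [
            t for t in all_terms(("hemisphere", "fitness"))
            if t.label in retained_labels
        ]
        # structural marginality: every retained term's marginal terms are
        # also retained
        for t in retained:
            for u in all_terms(("hemisphere", "fitness")):
                if t.contains(u):
                    assert u.label in retained_labels

    def test_null_three_way_removed_real_two_way_kept(self):
        kept_2way = removed_3way = 0
        n_rep = 8
        for seed in range(n_rep):
            df = make_binned_lmm_data(
                seed=100 + seed,
                beta={("hemisphere_c", "fitness_c"): 0.03},
            )
            res = backward_eliminate(df, factors=("hemisphere", "fitness"))
            labels = set(res.table["term"])
            elim = {lab for lab, _ in res.eliminated}
            kept_2way += "Fitness x Hemisphere" in labels
            removed_3way += (
                "Time x Fitness x Hemisphere" in elim
                and "Time Sq x Fitness x Hemisphere" in elim
            )
        assert kept_2way >= int(0.8 * n_rep)
        assert removed_3way >= int(0.8 * n_rep)


class TestContrasts:
    def _binned(self, values_by_bin, n=6):
        rows = []
        for i in range(n):
            for b in BINS:
                rows.append(
                    {
                        "participant": f"P{i}",
                        "group": "higher" if i < n // 2 else "lower",
                        "region": "frontal",
                        "hemisphere": "left",
                        "bin": b,
                        "entropy": values_by_bin[b][i],
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_bins_zero_t(self):
        vals = {b: np.full(6, 0.5) for b in BINS}
        out = interval_contrasts(self._binned(vals), "frontal", "left")
        assert np.allclose(out["m_diff"], 0.0)
        assert np.allclose(out["t"], 0.0)

    def test_hand_computed_paired_t(self):
        vals = {
            "0-500": np.array([0.5, 0.5, 0.5]),
            "500-1000": np.array([0.6, 0.7, 0.8]),
            "1000-1500": np.array([0.6, 0.7, 0.8]),
        }
        binned = self._binned(vals, n=3)
        out = interval_contrasts(binned, "frontal", "left").iloc[0]
        assert out["m_diff"] == pytest.approx(0.2)
        assert out["t"] == pytest.approx(0.2 / (0.1 / np.sqrt(3)), rel=1e-9)
        assert out["df"] == 2

    def test_too_few_pairs_rejected(self):
        vals = {b: np.full(2, 0.5) for b in BINS}
        with pytest.raises(ValueError):
            interval_contrasts(self._binned(vals, n=2), "frontal", "left")

    def test_group_contrast_detects_shift(self, rng):
        n = 20
        vals = {
            b: np.r_[rng.normal(0.42, 0.02, n // 2),
                     rng.normal(0.50, 0.02, n // 2)]
            for b in BINS
        }
        out = group_contrasts(self._binned(vals, n=n), "frontal", "left")
        assert (out["Z"] < 0).all()
        assert (out["p"] < 0.01).all()

    def test_welch_option(self, rng):
        n = 10
        vals = {b: rng.normal(0.5, 0.02, n) for b in BINS}
        out = group_contrasts(
            self._binned(vals, n=n), "frontal", "left", statistic="welch"
        )
        assert len(out) == 3
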