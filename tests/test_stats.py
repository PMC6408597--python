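import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import camosim as cs
from camosim.stats import (
    CELLS,
    EFFECTS,
    AnovaTable,
    DataError,
    cell_mean_matrix,
    clean_and_collapse,
    default_simple_effects,
    effect_contrast,
    exclude_participants,
    filter_trials,
    generalized_eta_squared,
    reciprocal_transform_and_screen,
    rm_anova_2x2x2,
    simple_effect,
)


def _trial_frame(n_participants=5, seed=0, **model_kw):
    model = cs.ObserverModel(**model_kw)
    return cs.simulate_experiment(n_participants, model, master_seed=seed)


# ---------------------------------------------------------------------------
# Exclusions


class TestExcludeParticipants:
    def test_equal_rates_none_removed(self):
        df = _trial_frame(4, error_rate=0.0, lapse_rate=0.0)
        out, log = exclude_participants(df)
        assert log["participants_removed"] == []
        assert len(out) == len(df)

    def test_outlier_removed(self):
        # 29 participants at ~3% errors, one at ~60%
        good = cs.simulate_experiment(
            29, cs.ObserverModel(error_rate=0.03, lapse_rate=0.0), master_seed=1
        )
        bad = cs.simulate_experiment(
            1, cs.ObserverModel(error_rate=0.60, lapse_rate=0.0), master_seed=2
        )
        bad["participant"] = 30
        df = pd.concat([good, bad], ignore_index=True)
        rates = 1.0 - df.groupby("participant")["correct"].mean()
        cutoff = rates.mean() + 4 * rates.std(ddof=1)
        assert rates[30] > cutoff  # direct mean + 4 SD computation
        out, log = exclude_participants(df)
        assert log["participants_removed"] == [30]
        assert 30 not in set(out["participant"])

    def test_too_few_participants(self):
        df = _trial_frame(2)
        with pytest.raises(DataError):
            exclude_participants(df)


class TestFilterTrials:
    def test_nothing_removed(self):
        df = _trial_frame(3, error_rate=0.0, lapse_rate=0.0)
        out, log = filter_trials(df)
        assert len(out) == len(df)
        assert log["no_response_pct"] == 0.0
        assert log["incorrect_pct"] == 0.0

    def test_percentage_arithmetic(self):
        df = _trial_frame(3, error_rate=0.0, lapse_rate=0.0).head(100).copy()
        df.loc[df.index[0], "response"] = "none"
        df.loc[df.index[0], "correct"] = False
        df.loc[df.index[0], "rt_ms"] = np.nan
        out, log = filter_trials(df)
        assert log["no_response_pct"] == pytest.approx(1.00)
        assert len(out) == 99

    def test_incorrect_and_none_separate(self):
        df = _trial_frame(3, error_rate=0.0, lapse_rate=0.0).head(200).copy()
        idx = df.index[:4]
        df.loc[idx[:2], "response"] = "none"
        df.loc[idx[:2], "rt_ms"] = np.nan
        df.loc[idx[:2], "correct"] = False
        df.loc[idx[2:], "response"] = df.loc[idx[2:], "quadrant"].map(
            {"TL": "TR", "TR": "TL", "BL": "BR", "BR": "BL"}
        )
        df.loc[idx[2:], "correct"] = False
        out, log = filter_trials(df)
        assert log["no_response_removed"] == 2
        assert log["incorrect_removed"] == 2
        assert log["no_response_pct"] == pytest.approx(1.0)
        assert log["incorrect_pct"] == pytest.approx(1.0)


class TestReciprocalTransform:
    def test_reciprocal_arithmetic(self):
        df = _trial_frame(3, error_rate=0.0, lapse_rate=0.0).head(10).copy()
        df["rt_ms"] = 500.0
        out, _ = reciprocal_transform_and_screen(df)
        assert np.allclose(out["rt_recip"], 2.0)
        df["rt_ms"] = 2000.0
        out, _ = reciprocal_transform_and_screen(df)
        assert np.allclose(out["rt_recip"], 0.5)

    def test_identical_rts_no_outliers(self):
        df = _trial_frame(3, error_rate=0.0, lapse_rate=0.0).copy()
        df["rt_ms"] = 1000.0
        out, log = reciprocal_transform_and_screen(df)
        assert log["outliers_removed"] == 0
        cm = cell_mean_matrix(out)
        assert np.allclose(cm.to_numpy(), 1.0)

    def test_nonpositive_rt_rejected(self):
        df = _trial_frame(3, error_rate=0.0, lapse_rate=0.0).head(5).copy()
        df.loc[df.index[0], "rt_ms"] = 0.0
        with pytest.raises(DataError):
            reciprocal_transform_and_screen(df)

    def test_extreme_outlier_screened(self):
        df = _trial_frame(5, error_rate=0.0, lapse_rate=0.0).copy()
        df.loc[df.index[0], "rt_ms"] = 160.0  # 1/0.16s = 6.25 per s, far out
        out, log = reciprocal_transform_and_screen(df)
        assert log["outliers_removed"] >= 1
        assert df.index[0] not in out.index


# ---------------------------------------------------------------------------
# ANOVA against a brute-force design-matrix projection oracle


def oracle_decomposition(Y: np.ndarray) -> dict:
    """Sequential-RSS sums of squares from explicit design matrices."""
    n, m = Y.shape
    assert m == 8
    y = Y.ravel()  # subject-major order
    subj = np.repeat(np.arange(n), m)
    blocks = [np.ones((n * m, 1))]
    # subject dummies
    blocks.append((subj[:, None] == np.arange(n)[None, :]).astype(float))
    # effect contrast columns
    for eff in EFFECTS:
        c = effect_contrast(eff)
        blocks.append(np.tile(c, n)[:, None])
    # subject-by-effect interaction columns
    for eff in EFFECTS:
        c = effect_contrast(eff)
        cols = (subj[:, None] == np.arange(n)[None, :]) * np.tile(c, n)[:, None]
        blocks.append(cols.astype(float))

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    out = {}
    X = blocks[0]
    prev = rss(X)
    X = np.hstack([X, blocks[1]])
    cur = rss(X)
    out["subjects"] = prev - cur
    prev = cur
    for i, eff in enumerate(EFFECTS):
        X = np.hstack([X, blocks[2 + i]])
        cur = rss(X)
        out[eff] = prev - cur
        prev = cur
    for i, eff in enumerate(EFFECTS):
        X = np.hstack([X, blocks[9 + i]])
        cur = rss(X)
        out[f"err:{eff}"] = prev - cur
        prev = cur
    return out


class TestRmAnovaOracle:
    @pytest.mark.parametrize("n,seed", [(3, 0), (5, 1), (8, 2), (10, 3)])
    def test_ss_match_design_matrix_projection(self, n, seed):
        Y = np.random.default_rng(seed).normal(2.0, 0.5, size=(n, 8))
        anova = rm_anova_2x2x2(Y)
        oracle = oracle_decomposition(Y)
        assert anova.ss_subjects == pytest.approx(oracle["subjects"], rel=1e-10)
        for eff in EFFECTS:
            row = anova[eff]
            assert row["ss_effect"] == pytest.approx(oracle[eff], rel=1e-10, abs=1e-12)
            assert row["ss_error"] == pytest.approx(
                oracle[f"err:{eff}"], rel=1e-10, abs=1e-12
            )

    @given(st.integers(0, 10_000), st.integers(3, 10))
    @settings(max_examples=25, deadline=None)
    def test_ss_match_property(self, seed, n):
        Y = np.random.default_rng(seed).normal(1.0, 1.0, size=(n, 8))
        anova = rm_anova_2x2x2(Y)
        oracle = oracle_decomposition(Y)
        for eff in EFFECTS:
            assert anova[eff]["ss_effect"] == pytest.approx(
                oracle[eff], rel=1e-9, abs=1e-10
            )

    def test_matches_statsmodels(self):
        Y = np.random.default_rng(7).normal(1.0, 0.3, size=(12, 8))
        anova = rm_anova_2x2x2(Y)
        from statsmodels.stats.anova import AnovaRM

        rows = []
        for s in range(12):
            for j, cell in enumerate(CELLS):
                rows.append((s, *cell, Y[s, j]))
        long = pd.DataFrame(
            rows, columns=["subject", "enhancement", "illumination", "viewing", "y"]
        )
        fit = AnovaRM(
            long, "y", "subject", within=["enhancement", "illumination", "viewing"]
        ).fit()
        for eff in EFFECTS:
            got = anova[eff]["F"]
            want = fit.anova_table.loc[eff, "F Value"]
            assert got == pytest.approx(want, rel=1e-8)

    def test_null_data_all_zero(self):
        Y = np.tile(np.random.default_rng(0).normal(size=(4, 1)), (1, 8))
        anova = rm_anova_2x2x2(Y)
        for eff in EFFECTS:
            assert anova[eff]["ss_effect"] == pytest.approx(0.0, abs=1e-20)
            assert anova[eff]["F"] == 0.0

    def test_decomposition_closes(self):
        Y = np.random.default_rng(11).normal(size=(7, 8))
        anova = rm_anova_2x2x2(Y)
        total = (
            anova.ss_subjects
            + anova.table["ss_effect"].sum()
            + anova.table["ss_error"].sum()
        )
        assert total == pytest.approx(anova.ss_total, rel=1e-10)

    def test_df_error(self):
        anova = rm_anova_2x2x2(np.random.default_rng(0).normal(size=(9, 8)))
        assert (anova.table["df_error"] == 8).all()
        assert (anova.table["df_effect"] == 1).all()

    def test_too_few_subjects(self):
        with pytest.raises(DataError):
            rm_anova_2x2x2(np.zeros((1, 8)))


class TestGeneralizedEtaSquared:
    def test_one_third_case(self):
        table = pd.DataFrame(
            {"ss_effect": [1.0], "ss_error": [1.0], "df_effect": [1],
             "df_error": [4], "F": [4.0], "p": [0.1]},
            index=["enhancement"],
        )
        anova = AnovaTable(table=table, ss_subjects=1.0, ss_total=3.0, n=5)
        eta = generalized_eta_squared(anova)
        assert eta["enhancement"] == pytest.approx(1.0 / 3.0)

    def test_zero_effect(self):
        table = pd.DataFrame(
            {"ss_effect": [0.0], "ss_error": [1.0], "df_effect": [1],
             "df_error": [4], "F": [0.0], "p": [1.0]},
            index=["enhancement"],
        )
        anova = AnovaTable(table=table, ss_subjects=1.0, ss_total=2.0, n=5)
        assert generalized_eta_squared(anova)["enhancement"] == 0.0

    def test_in_unit_interval_on_real_data(self):
        Y = np.random.default_rng(3).normal(2.0, 0.4, size=(10, 8))
        anova = rm_anova_2x2x2(Y)
        eta = generalized_eta_squared(anova)
        assert ((eta >= 0) & (eta <= 1)).all()
        assert anova.table["ss_effect"].sum() <= anova.ss_total + 1e-9


# ---------------------------------------------------------------------------
# Simple effects


class TestSimpleEffects:
    def _cleaned(self, Y, Yms=None):
        cm = pd.DataFrame(Y, columns=pd.MultiIndex.from_tuples(CELLS))
        cm.index.name = "participant"
        cms = pd.DataFrame(Yms if Yms is not None else Y * 1000.0,
                           columns=pd.MultiIndex.from_tuples(CELLS))
        return cs.CleanedData(cell_means=cm, cell_means_ms=cms)

    def test_identical_conditions_zero(self):
        Y = np.tile(np.random.default_rng(0).normal(size=(6, 1)), (1, 8))
        s = simple_effect(self._cleaned(Y), "enhancement",
                          {"viewing": "monoscopic"})
        assert s.t == 0.0
        assert s.cohens_d == 0.0

    def test_constant_difference_warns(self):
        Y = np.zeros((5, 8))
        for j, cell in enumerate(CELLS):
            if cell[0] == "present":
                Y[:, j] = 1.0
        with pytest.warns(UserWarning, match="zero variance"):
            s = simple_effect(self._cleaned(Y), "enhancement")
        assert np.isnan(s.t)

    def test_matches_brute_force_paired_t(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(1.0, 0.2, size=(5, 8))
        cleaned = self._cleaned(Y)
        s = simple_effect(cleaned, "enhancement", {"viewing": "monoscopic"})
        # brute force: per-subject means of the matching cells
        cols_a = [j for j, c in enumerate(CELLS)
                  if c[0] == "absent" and c[2] == "monoscopic"]
        cols_b = [j for j, c in enumerate(CELLS)
                  if c[0] == "present" and c[2] == "monoscopic"]
        d = Y[:, cols_b].mean(axis=1) - Y[:, cols_a].mean(axis=1)
        t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert s.t == pytest.approx(t, rel=1e-12)
        assert s.df == 4
        assert s.cohens_d == pytest.approx(d.mean() / d.std(ddof=1), rel=1e-12)
        assert np.sign(s.t) == np.sign(s.mean_diff_transformed)

    def test_default_contrasts_labels(self):
        Y = np.random.default_rng(1).normal(1.0, 0.1, size=(6, 8))
        effects = default_simple_effects(self._cleaned(Y))
        assert len(effects) == 4
        assert all(e.df == 5 for e in effects)


# ---------------------------------------------------------------------------
# Pipeline-level behaviour


class TestPipeline:
    def test_clean_and_collapse_shapes(self):
        df = _trial_frame(6, seed=3)
        cleaned = clean_and_collapse(df)
        assert cleaned.cell_means.shape == (6, 8)
        assert cleaned.cell_means_ms.shape == (6, 8)
        assert set(cleaned.log) >= {
            "no_response_pct", "incorrect_pct", "participants_removed",
        }

    def test_analyze_runs_end_to_end(self):
        df = _trial_frame(8, seed=4)
        results = cs.analyze(df)
        assert set(results["anova"]) == set(EFFECTS)
        text = cs.stats.report(results)
        assert "ANOVA" in text

    def test_recovers_sign_pattern(self):
        # parameter recovery: printed-difference deltas yield a large
        # monoscopic enhancement effect and a smaller stereoscopic one in
        # the majority of simulated experiments
        hits = 0
        runs = 10
        for seed in range(runs):
            df = _trial_frame(29, seed=100 + seed)
            cleaned = clean_and_collapse(df)
            effs = {e.label: e for e in default_simple_effects(cleaned)}
            mono = effs["enhancement (viewing=monoscopic)"]
            stereo = effs["enhancement (viewing=stereoscopic)"]
            if (
                mono.mean_diff_ms > 0
                and mono.p < 0.05
                and abs(stereo.mean_diff_ms) < mono.mean_diff_ms
            ):
                hits += 1
        assert hits > runs / 2
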