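"""Quickpred selection, chained PMM, Rubin pooling and MI stepwise selection."""

import numpy as np
import pandas as pd
import pytest

from gutdea.impute import (
    mice_pmm,
    pool_rubin,
    quickpred,
    rubin_combine,
    stepwise_backward_mi,
)
from gutdea.tobit import fit_tobit


def incomplete_table(n=300, seed=0, n_missing=60):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(0, 1, n)
    x2 = rng.normal(0, 1, n)
    target = 2.0 + 1.5 * x1 + rng.normal(0, 0.5, n)
    tab = pd.DataFrame({"target": target, "x1": x1, "x2": x2})
    complete = tab.copy()
    rows = rng.choice(n, size=n_missing, replace=False)
    tab.loc[rows, "target"] = np.nan
    return tab, complete


class TestQuickpred:
    def test_correlated_predictor_selected_uncorrelated_not(self):
        tab, _ = incomplete_table()
        matrix = quickpred(tab, mincor=0.1, minpuc=0.25)
        assert list(matrix.index) == ["target"]
        assert matrix.loc["target", "x1"] == 1  # corr ~ 0.95
        assert matrix.loc["target", "x2"] == 0  # corr ~ 0

    def test_forced_always_included(self):
        tab, _ = incomplete_table()
        matrix = quickpred(tab, forced=["x2"])
        assert matrix.loc["target", "x2"] == 1

    def test_fully_observed_table_empty_matrix(self):
        _, complete = incomplete_table()
        assert len(quickpred(complete)) == 0

    def test_all_missing_target_rejected(self):
        tab, _ = incomplete_table()
        tab["target"] = np.nan
        with pytest.raises(ValueError, match="no observed"):
            quickpred(tab)

    def test_weak_correlation_below_mincor_excluded(self):
        rng = np.random.default_rng(1)
        n = 2000
        a = rng.normal(size=n)
        t = 0.02 * a + rng.normal(size=n)  # corr ~ 0.02
        tab = pd.DataFrame({"t": t, "a": a})
        tab.loc[rng.choice(n, 200, replace=False), "t"] = np.nan
        assert quickpred(tab, mincor=0.1).loc["t", "a"] == 0


class TestMicePmm:
    def test_imputed_values_come_from_observed_support(self):
        tab, _ = incomplete_table()
        matrix = quickpred(tab, forced=["x1", "x2"])
        imp = mice_pmm(tab, matrix, m=3, maxit=3, seed=4)
        observed = set(tab["target"].dropna())
        for completed in imp:
            assert not completed.isna().any().any()
            imputed = completed.loc[tab["target"].isna(), "target"]
            assert set(imputed) <= observed

    def test_mcar_mean_recovered(self):
        tab, complete = incomplete_table(n=500, seed=2, n_missing=100)
        matrix = quickpred(tab, forced=["x1"])
        imp = mice_pmm(tab, matrix, m=5, maxit=5, seed=8)
        true_mean = complete["target"].mean()
        se = complete["target"].std() / np.sqrt(len(complete))
        means = [t["target"].mean() for t in imp]
        assert abs(np.mean(means) - true_mean) < 3 * se

    def test_deterministic_given_seed(self):
        tab, _ = incomplete_table()
        matrix = quickpred(tab, forced=["x1"])
        a = mice_pmm(tab, matrix, m=1, maxit=1, seed=5)
        b = mice_pmm(tab, matrix, m=1, maxit=1, seed=5)
        pd.testing.assert_frame_equal(a.tables[0], b.tables[0])

    def test_chains_differ(self):
        tab, _ = incomplete_table()
        matrix = quickpred(tab, forced=["x1"])
        imp = mice_pmm(tab, matrix, m=2, maxit=2, seed=6)
        assert not imp.tables[0].equals(imp.tables[1])

    def test_save_persists_tables_and_provenance(self, tmp_path):
        tab, _ = incomplete_table()
        matrix = quickpred(tab, forced=["x1"])
        imp = mice_pmm(tab, matrix, m=2, maxit=1, seed=7)
        imp.save(tmp_path / "imp")
        assert (tmp_path / "imp" / "imputation_01.csv").exists()
        assert (tmp_path / "imp" / "imputation_02.csv").exists()
        assert (tmp_path / "imp" / "provenance.json").exists()

    def test_fewer_observed_than_donors_rejected(self):
        tab = pd.DataFrame({"t": [1.0, 2.0, np.nan, np.nan], "a": [1.0, 2.0, 3.0, 4.0]})
        matrix = pd.DataFrame(1, index=["t"], columns=["a"])
        with pytest.raises(ValueError, match="donors"):
            mice_pmm(tab, matrix, m=1, maxit=1, donors=5, seed=0)


class TestRubinPooling:
    def test_two_imputation_hand_check(self):
        pooled = rubin_combine([[1.0], [2.0]], [[0.5], [0.5]])
        assert pooled.qbar[0] == pytest.approx(1.5)
        assert pooled.wbar[0] == pytest.approx(0.5)
        assert pooled.b[0] == pytest.approx(0.5)
        assert pooled.t[0] == pytest.approx(1.25)

    def test_identical_fits_no_between_variance(self):
        pooled = rubin_combine([[2.0], [2.0], [2.0]], [[0.3], [0.3], [0.3]])
        assert pooled.b[0] == pytest.approx(0.0)
        assert pooled.t[0] == pytest.approx(pooled.wbar[0])

    def test_single_imputation_warns(self):
        with pytest.warns(UserWarning, match="m=1"):
            pooled = rubin_combine([[1.0]], [[0.4]])
        assert pooled.t[0] == pytest.approx(0.4)

    def test_pool_tobit_fits(self):
        rng = np.random.default_rng(0)
        n = 400
        fits = []
        for _ in range(3):
            x = rng.normal(size=n)
            y = np.clip(0.7 + 0.1 * x + rng.normal(0, 0.1, n), 0, 1)
            fits.append(fit_tobit(y, x[:, None], names=["x"]))
        pooled = pool_rubin(fits)
        assert pooled.names == ["intercept", "x"]
        assert pooled.qbar[1] == pytest.approx(0.1, abs=0.03)
        assert np.all(pooled.t >= pooled.wbar)

    def test_mismatched_covariates_rejected(self):
        rng = np.random.default_rng(1)
        y = np.clip(rng.normal(0.5, 0.1, 200), 0, 1)
        f1 = fit_tobit(y, rng.normal(size=(200, 1)), names=["a"])
        f2 = fit_tobit(y, rng.normal(size=(200, 1)), names=["b"])
        with pytest.raises(ValueError, match="mismatched"):
            pool_rubin([f1, f2])


class TestStepwiseMI:
    @staticmethod
    def _datasets(m=5, n=500, seed=0):
        """Completed datasets with one strong covariate and noise covariates."""
        tables = []
        for chain in range(m):
            rng = np.random.default_rng(seed + chain)
            strong = rng.normal(size=n)
            frame = {"strong": strong}
            for k in range(4):
                frame[f"noise{k}"] = rng.normal(size=n)
            score = np.clip(0.7 + 0.08 * strong + rng.normal(0, 0.08, n), 0, 1)
            frame["score"] = score
            tables.append(pd.DataFrame(frame))
        return tables

    def test_true_effect_retained_noise_dropped(self):
        tables = self._datasets()
        candidates = ["strong", "noise0", "noise1", "noise2", "noise3"]
        sel = stepwise_backward_mi(tables, "score", candidates)
        assert sel.counts["strong"] == len(tables)
        assert "strong" in sel.selected
        for k in range(4):
            assert sel.counts[f"noise{k}"] < len(tables)
        assert sel.pooled is not None
        assert sel.pooled.p_values[sel.pooled.names.index("strong")] < 0.01

    def test_single_strong_candidate_kept_everywhere(self):
        tables = self._datasets(m=3)
        sel = stepwise_backward_mi(tables, "score", ["strong"])
        assert sel.counts == {"strong": 3}
        assert sel.selected == ["strong"]

    def test_all_noise_strict_alpha_empty_model(self):
        tables = self._datasets(m=3)
        sel = stepwise_backward_mi(tables, "score", ["noise0", "noise1"], alpha=1e-6)
        assert sel.selected == []
        assert sel.pooled is None

    def test_retained_iff_count_reaches_threshold(self):
        tables = self._datasets()
        sel = stepwise_backward_mi(tables, "score", ["strong", "noise0"], retain_frac=0.5)
        m = len(tables)
        for cand, cnt in sel.counts.items():
            assert (cand in sel.selected) == (cnt >= np.ceil(0.5 * m))
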