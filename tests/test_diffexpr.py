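import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from gravesomics import diffexpr
from gravesomics.datamodel import SampleSheet
from gravesomics.diffexpr import (
    NBFit,
    design_matrix,
    estimate_qvalues,
    fit_nb_glm,
    fit_protein_multinomial,
    log2_fold_changes,
    lrt_protein,
    lrt_status,
    predict_multinomial,
)


class TestNBGLM:
    def test_constant_counts_give_null_status_effects(self, tiny_sheet):
        y = np.full(12, 20.0)
        offsets = np.zeros(12)
        fit = fit_nb_glm(y, tiny_sheet, offsets)
        assert abs(fit.coefficients["status[GD]"]) < 1e-6
        assert abs(fit.coefficients["status[GO]"]) < 1e-6

    def test_poisson_limit_matches_statsmodels(self, tiny_sheet, rng):
        """At dispersion zero the NB log-likelihood equals the Poisson GLM's."""
        y = rng.poisson(15, size=12).astype(float)
        offsets = np.log(rng.uniform(0.8, 1.2, size=12))
        ours = fit_nb_glm(y, tiny_sheet, offsets, dispersion=0.0)
        X, _ = design_matrix(tiny_sheet)
        ref = sm.GLM(y, X, family=sm.families.Poisson(),
                     offset=offsets).fit()
        assert ours.log_likelihood == pytest.approx(ref.llf, abs=1e-6)
        np.testing.assert_allclose(ours.beta, ref.params, atol=1e-6)

    def test_recovers_planted_coefficient_on_average(self):
        """Mean estimated GD effect over replicates is close to ln 2
        (2-fold planted change, 50 per group)."""
        rng = np.random.default_rng(7)
        n = 150
        status = ["control"] * 50 + ["GD"] * 50 + ["GO"] * 50
        centre = (["Cardiff", "Essen", "Milan"] * 50)[:n]
        sheet = SampleSheet([f"S{i}" for i in range(n)], status, centre)
        offsets = np.zeros(n)
        mult = np.where(np.array(status) == "GD", 2.0, 1.0)
        phi = 0.15
        est = []
        for _ in range(120):
            mu = 40.0 * mult
            lam = rng.gamma(shape=1 / phi, scale=mu * phi)
            y = rng.poisson(lam).astype(float)
            est.append(fit_nb_glm(y, sheet, offsets).coefficients["status[GD]"])
        assert abs(np.mean(est) - np.log(2)) < 0.15

    def test_lrt_identical_fits_is_null(self):
        f = NBFit({}, 0.1, -50.0, True)
        stat, df, p = lrt_status(f, f)
        assert stat == 0.0 and df == 2 and p == pytest.approx(1.0)

    def test_lrt_chi_square_reference(self):
        f = NBFit({}, 0.1, -50.0, True)
        r = NBFit({}, 0.1, -50.0 - 5.99 / 2, True)
        _, _, p = lrt_status(f, r)
        assert p == pytest.approx(stats.chi2.sf(5.99, 2), abs=1e-12)
        assert p == pytest.approx(0.05, abs=2e-4)

    def test_dispersion_non_negative(self, filtered_blocks):
        counts = filtered_blocks["counts"]
        sheet = filtered_blocks["sheet"]
        offsets = np.log(counts.values.sum(axis=0))
        fit = fit_nb_glm(counts.values[0], sheet, offsets)
        assert fit.dispersion >= 0.0 and np.isfinite(fit.log_likelihood)


class TestProteinMultinomial:
    def test_constant_protein_gives_null_lrt(self, tiny_sheet):
        x = np.full(12, 3.0)
        full = fit_protein_multinomial(x, tiny_sheet)
        red = fit_protein_multinomial(x, tiny_sheet, include_protein=False)
        stat, df, p = lrt_protein(full, red)
        assert stat == pytest.approx(0.0, abs=1e-5)
        assert df == 2

    def test_probabilities_sum_to_one(self, tiny_sheet, rng):
        x = rng.normal(size=12)
        fit = fit_protein_multinomial(x, tiny_sheet)
        X, _ = design_matrix(tiny_sheet, include_status=False, extra=x)
        P = predict_multinomial(fit, X)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_two_class_reduction_matches_binary_logit(self, rng):
        """With two classes the multinomial MLE equals ordinary logistic
        regression (statsmodels oracle)."""
        n = 40
        sheet = SampleSheet([f"S{i}" for i in range(n)],
                            ["control"] * 20 + ["GD"] * 20,
                            ["Cardiff"] * n)
        x = rng.normal(size=n) + np.repeat([0.0, 1.0], 20)
        fit = fit_protein_multinomial(x, sheet)
        X, _ = design_matrix(sheet, include_status=False, extra=x)
        ref = sm.Logit((np.array(sheet.status) == "GD").astype(float),
                       X).fit(disp=0)
        np.testing.assert_allclose(fit.coefficients[0], ref.params,
                                   atol=1e-4)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-6)


class TestQValues:
    def test_all_ones_stay_ones(self):
        np.testing.assert_array_equal(estimate_qvalues([1.0] * 5),
                                      np.ones(5))

    def test_bh_hand_example(self):
        q = estimate_qvalues([0.01, 0.02, 0.03, 0.04], method="bh")
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_uniform_null_controls_discoveries(self):
        rng = np.random.default_rng(123)
        p = rng.uniform(size=5000)
        q = estimate_qvalues(p)
        assert (q < 0.05).mean() <= 0.07

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=400)
        q = estimate_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_matches_statsmodels_bh(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=200)
        ours = estimate_qvalues(p, method="bh")
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(Exception):
            estimate_qvalues([])


class TestLog2FoldChanges:
    def test_equal_means_zero(self):
        fc = log2_fold_changes({"control": 2.0, "GD": 2.0, "GO": 2.0})
        assert all(v == 0.0 for v in fc.values())

    def test_ln2_coefficient_is_one_doubling(self):
        fit = NBFit({"status[GD]": np.log(2), "status[GO]": 0.0}, 0.1,
                    -10.0, True)
        fc = log2_fold_changes(fit)
        assert fc["log2fc_GD_vs_control"] == pytest.approx(1.0)
        assert fc["log2fc_GO_vs_GD"] == pytest.approx(-1.0)

    def test_recovers_planted_eightfold_change(self):
        """An 8-fold planted effect is estimated near log2fc = 3."""
        rng = np.random.default_rng(11)
        n = 150
        status = ["control"] * 50 + ["GD"] * 50 + ["GO"] * 50
        sheet = SampleSheet([f"S{i}" for i in range(n)], status,
                            ["Cardiff"] * n)
        mult = np.where(np.array(status) == "GD", 8.0, 1.0)
        est = []
        for _ in range(40):
            lam = rng.gamma(shape=1 / 0.1, scale=30.0 * mult * 0.1)
            y = rng.poisson(lam).astype(float)
            fit = diffexpr.fit_nb_glm(y, sheet, np.zeros(n))
            est.append(log2_fold_changes(fit)["log2fc_GD_vs_control"])
        assert np.mean(est) == pytest.approx(3.0, abs=0.3)


class TestBlockDrivers:
    def test_planted_features_rank_top(self, filtered_blocks):
        """Truth-vs-rank AUC above 0.9: planted miRNAs concentrate at the
        top of the q-value ranking."""
        de = diffexpr.run_de_mirna(filtered_blocks["counts"],
                                   filtered_blocks["sheet"])
        truth = filtered_blocks["truth"]
        labels = de["feature_id"].isin(truth.de_mirna_ids).to_numpy()
        ranks = np.arange(len(de))[::-1]  # best rank = highest score
        from sklearn.metrics import roc_auc_score
        assert roc_auc_score(labels, ranks) > 0.9

    def test_protein_driver_recovers_signal(self, filtered_blocks):
        de = diffexpr.run_de_protein(filtered_blocks["protein_log"],
                                     filtered_blocks["sheet"])
        truth = filtered_blocks["truth"]
        hits = set(de.loc[de.q_value < 0.05, "feature_id"])
        planted = truth.de_protein_ids & set(de.feature_id)
        assert len(hits & planted) >= 0.5 * len(planted)

    def test_qvalues_follow_pvalues(self, filtered_blocks):
        de = diffexpr.run_de_mirna(filtered_blocks["counts"],
                                   filtered_blocks["sheet"])
        ok = de.dropna(subset=["p_value"])
        order = np.argsort(ok["p_value"].to_numpy())
        assert (np.diff(ok["q_value"].to_numpy()[order]) >= -1e-12).all()
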