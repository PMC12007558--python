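"""ComBat/CovBat correctness: analytic constructions and parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata
from sklearn.base import clone

from harmony_bench import (
    ComBatHarmonizer,
    CovBatHarmonizer,
    apply_combat,
    evaluate_harmonisation,
    fit_apply_covbat,
    fit_combat,
)
from harmony_bench.tables import ContractError


def _random_batched_data(seed=0, n_per_batch=(12, 15, 10), p=25, shift_sd=1.0, scale_range=(0.6, 1.6)):
    """Known location/scale batch effects on top of shared structure."""
    rng = np.random.default_rng(seed)
    blocks, batches = [], []
    base_mean = rng.normal(0, 3, p)
    for b, n in enumerate(n_per_batch):
        shift = rng.normal(0, shift_sd, p)
        scale = rng.uniform(*scale_range, p)
        blocks.append(base_mean + shift + rng.normal(size=(n, p)) * scale)
        batches += [f"b{b}"] * n
    return np.vstack(blocks), np.array(batches)


class TestComBatCore:
    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(1)
        X = rng.normal(10, 2, size=(30, 8))
        out = ComBatHarmonizer().fit_transform(X, batch=np.repeat("a", 30))
        np.testing.assert_allclose(out, X, rtol=1e-8)

    def test_batch_of_size_one_rejected(self):
        X = np.random.default_rng(0).normal(size=(4, 3))
        with pytest.raises(ContractError, match="size 1"):
            ComBatHarmonizer().fit(X, batch=np.array(["a", "a", "a", "b"]))

    def test_constant_feature_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        X[:, 1] = 5.0
        with pytest.raises(ContractError, match="constant"):
            ComBatHarmonizer().fit(X, batch=np.repeat(["a", "b"], 3))

    def test_pure_shift_construction(self):
        # batch 2 = batch 1 + c featurewise: gamma* differs by c/sigma and the
        # shift is removed exactly (the prior is degenerate, so EB shrinkage
        # reduces to the raw estimates)
        rng = np.random.default_rng(2)
        p, n = 10, 14
        base = rng.normal(0, 1.5, size=(n, p))
        c = 3.7
        X = np.vstack([base, base + c])
        batch = np.repeat(["b1", "b2"], n)
        model = ComBatHarmonizer().fit(X, batch=batch)
        sigma = np.sqrt(model.pooled_var_)
        np.testing.assert_allclose(
            model.gamma_star_[1] - model.gamma_star_[0], c / sigma, rtol=1e-6
        )
        out = model.transform(X, batch=batch)
        gap = out[:n].mean(axis=0) - out[n:].mean(axis=0)
        scale = np.abs(X).max()
        assert np.abs(gap).max() < 1e-6 * scale

    def test_within_batch_ranking_preserved_without_covariates(self):
        X, batch = _random_batched_data(seed=3)
        out = ComBatHarmonizer().fit_transform(X, batch=batch)
        for b in np.unique(batch):
            m = batch == b
            np.testing.assert_array_equal(
                rankdata(out[m], axis=0), rankdata(X[m], axis=0)
            )

    def test_idempotence_without_shrinkage(self):
        X, batch = _random_batched_data(seed=4)
        once = ComBatHarmonizer(empirical_bayes=False).fit_transform(X, batch=batch)
        twice = ComBatHarmonizer(empirical_bayes=False).fit_transform(once, batch=batch)
        np.testing.assert_allclose(twice, once, rtol=1e-6, atol=1e-6 * np.abs(once).max())

    def test_grand_mean_preserved(self):
        # exact without shrinkage (the weighted zero-sum constraint); EB
        # shrinkage perturbs batch means slightly, so only approximately there
        X, batch = _random_batched_data(seed=5)
        out = ComBatHarmonizer(empirical_bayes=False).fit_transform(X, batch=batch)
        np.testing.assert_allclose(out.mean(axis=0), X.mean(axis=0), atol=1e-8)
        out_eb = ComBatHarmonizer().fit_transform(X, batch=batch)
        sd = X.std(axis=0)
        assert np.max(np.abs(out_eb.mean(axis=0) - X.mean(axis=0)) / sd) < 0.1

    def test_eb_shrinks_towards_prior_mean(self):
        X, batch = _random_batched_data(seed=6)
        eb = ComBatHarmonizer().fit(X, batch=batch)
        raw = ComBatHarmonizer(empirical_bayes=False).fit(X, batch=batch)
        assert not eb.eb_skipped_.any()
        for b in range(eb.n_batches_):
            spread_eb = np.std(eb.gamma_star_[b] - eb.prior_gamma_bar_[b])
            spread_raw = np.std(raw.gamma_star_[b] - eb.prior_gamma_bar_[b])
            assert spread_eb < spread_raw

    def test_unseen_batch_label_raises(self):
        X, batch = _random_batched_data(seed=7)
        model = ComBatHarmonizer().fit(X, batch=batch)
        with pytest.raises(ContractError, match="unseen"):
            model.transform(X[:2], batch=np.array(["zz", "zz"]))

    def test_sklearn_protocol(self):
        model = ComBatHarmonizer(empirical_bayes=False, tol=1e-5)
        params = model.get_params()
        assert params["empirical_bayes"] is False and params["tol"] == 1e-5
        cloned = clone(model).set_params(max_iter=7)
        assert cloned.get_params()["max_iter"] == 7


class TestComBatCovariates:
    def test_covariate_signal_preserved_while_batch_removed(self):
        rng = np.random.default_rng(8)
        n, p = 40, 12
        # identical age distribution in both batches, so any surviving batch
        # mean gap is a harmonisation failure, not covariate signal
        age = np.tile(rng.uniform(20, 60, n // 2), 2)
        batch = np.repeat(["b1", "b2"], n // 2)
        slope = rng.normal(0, 0.5, p)
        X = (
            10.0
            + np.outer(age - age.mean(), slope)
            + np.where(batch == "b2", 4.0, 0.0)[:, None]
            + rng.normal(size=(n, p)) * 0.3
        )
        out = ComBatHarmonizer().fit_transform(X, batch=batch, covariates=age)
        # batch shift removed
        gap = out[batch == "b1"].mean(axis=0) - out[batch == "b2"].mean(axis=0)
        assert np.abs(gap).max() < 0.5
        # age association survives harmonisation
        for j in np.flatnonzero(np.abs(slope) > 0.3):
            r = np.corrcoef(age, out[:, j])[0, 1]
            assert np.sign(r) == np.sign(slope[j]) and abs(r) > 0.5

    def test_covariate_count_mismatch_raises(self):
        X, batch = _random_batched_data(seed=9)
        model = ComBatHarmonizer().fit(X, batch=batch)
        with pytest.raises(ContractError, match="covariate"):
            model.transform(X, batch=batch, covariates=np.ones(len(batch)))


class TestComBatOnStudy:
    def test_parameter_recovery_on_matched_model(self, preset_study, preset_truth):
        model = fit_combat(preset_study, covariates=("age", "sex"))
        est = model.gamma_star_ * np.sqrt(model.pooled_var_)
        truth = preset_truth.gamma.loc[list(model.batches_)].to_numpy()
        # compare against the identifiable projection: batch effects are only
        # determined up to the weighted zero-sum constraint
        w = model.batch_counts_ / model.batch_counts_.sum()
        truth_centred = truth - w @ truth
        corr = np.corrcoef(est.ravel(), truth_centred.ravel())[0, 1]
        assert corr >= 0.9

    def test_between_scanner_cov_collapses_to_noise_floor(self, preset_study):
        harmonised = apply_combat(fit_combat(preset_study), preset_study)
        ev = evaluate_harmonisation(preset_study, harmonised)
        assert ev.summary["median_cov_ratio_before"] >= 3
        assert 0.7 <= ev.summary["median_cov_ratio_after"] <= 1.5
        assert ev.summary["fraction_idps_cov_reduced"] >= 0.9

    def test_no_covariate_harmonisation_keeps_within_scanner_ranking(
        self, preset_study
    ):
        model = fit_combat(preset_study, covariates=())
        harmonised = apply_combat(model, preset_study)
        sess = preset_study.sessions
        for scanner in sess["scanner_id"].unique():
            ids = sess.loc[sess["scanner_id"] == scanner, "session_id"]
            np.testing.assert_array_equal(
                rankdata(preset_study.idps.loc[ids].to_numpy(), axis=0),
                rankdata(harmonised.idps.loc[ids].to_numpy(), axis=0),
            )

    def test_evaluation_of_identical_tables_is_all_zero_delta(self, preset_study):
        ev = evaluate_harmonisation(preset_study, preset_study)
        assert np.nanmax(np.abs(ev.cov_delta.to_numpy())) == 0


class TestCovBat:
    def test_no_batch_effects_gives_near_identity(self):
        rng = np.random.default_rng(10)
        X = rng.normal(5, 1, size=(200, 10))
        batch = np.repeat(["a", "b"], 100)
        out = CovBatHarmonizer(empirical_bayes=False).fit_transform(X, batch=batch)
        # deviations bounded by the sampling error of the batch estimates
        # (~10% location / ~7% scale error at n=100 acting on ~3.5 sd tails)
        np.testing.assert_allclose(out, X, atol=0.5)

    def test_score_variance_aligned_across_batches(self):
        # batches share the mean/scale but differ 4:1 in the variance of the
        # leading principal direction -> CovBat must equalise it
        rng = np.random.default_rng(11)
        n, p = 60, 8
        direction = np.ones(p) / np.sqrt(p)
        s1 = rng.normal(0, 2.0, n)
        s2 = rng.normal(0, 1.0, n)
        noise = rng.normal(size=(2 * n, p)) * 0.1
        X = np.vstack([np.outer(s1, direction), np.outer(s2, direction)]) + noise
        batch = np.repeat(["a", "b"], n)
        model = CovBatHarmonizer(empirical_bayes=False).fit(X, batch=batch)
        out = model.transform(X, batch=batch)
        proj = out @ direction
        v1, v2 = proj[:n].var(ddof=1), proj[n:].var(ddof=1)
        assert abs(v1 / v2 - 1) < 0.1

    def test_full_retention_with_q_equal_one(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(15, 6))
        batch = np.repeat(["a", "b", "c"], 5)
        model = CovBatHarmonizer(variance_fraction=1.0).fit(X, batch=batch)
        assert model.n_components_retained_ == min(15 - 1, 6)

    def test_invalid_variance_fraction_raises(self):
        X = np.random.default_rng(0).normal(size=(8, 3))
        with pytest.raises(ContractError):
            CovBatHarmonizer(variance_fraction=1.5).fit(X, batch=np.repeat(["a", "b"], 4))

    def test_study_wrapper_runs(self, preset_study):
        model, harmonised = fit_apply_covbat(preset_study)
        assert harmonised.idps.shape == preset_study.idps.shape
        assert model.n_components_retained_ >= 1
        ev = evaluate_harmonisation(preset_study, harmonised)
        assert ev.summary["median_cov_ratio_after"] < ev.summary["median_cov_ratio_before"]


def _fit(X, batch):
    model = CovBatHarmonizer().fit(X, batch=batch)
    return model, model.transform(X, batch=batch)
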