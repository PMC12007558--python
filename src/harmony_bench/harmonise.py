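"""Parametric empirical-Bayes ComBat and CovBat, as scikit-learn transformers.

ComBat models each feature v in batch (scanner) b as

    y = alpha_v + x . beta_v + sigma_v * (gamma_bv + delta_bv * eps)

and removes the per-batch location ``gamma`` and scale ``delta`` while
preserving the covariate signal ``x . beta``:

    y* = sigma_v * (z - gamma*_bv) / delta*_bv + alpha_v + x . beta_v,
    z  = (y - alpha_v - x . beta_v) / sigma_v.

The batch estimates are stabilised by empirical-Bayes shrinkage across
features: a normal prior on the standardised batch means (hyperparameters by
method of moments) and an inverse-gamma prior on the batch variances, solved
by alternating conditional posterior means.  The batch offsets in the mean
model carry a sample-size-weighted zero-sum constraint, so the grand mean is
preserved.

Within a (feature, batch) cell the adjustment is a strictly increasing
affine map, so with no covariates the within-batch subject ordering of every
feature is exactly preserved.

CovBat additionally aligns the *covariance* of the batches: after ComBat it
decomposes the covariate-adjusted residuals into principal components,
re-centres and re-scales each retained score per batch, and reconstructs.

Numerical conventions chosen here: per-batch variances use the divisor
``n_b`` (matching the divisor-``N`` pooled variance), which makes the
degenerate cases exact — a single-batch fit is the identity and the
no-shrinkage transform is idempotent.  Empirical-Bayes shrinkage is skipped
for a batch when the across-feature variance of its batch variances is ~0
(single batch, tiny feature sets), where the inverse-gamma moment equations
degenerate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .tables import ContractError, StudyData

__all__ = [
    "ComBatHarmonizer",
    "CovBatHarmonizer",
    "fit_combat",
    "apply_combat",
    "fit_apply_covbat",
    "evaluate_harmonisation",
    "HarmonisationEvaluation",
]


def _as_2d_float(X) -> tuple[np.ndarray, Optional[pd.Index]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), X.columns
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ContractError(f"X must be 2-d, got shape {arr.shape}")
    return arr, None


def _covariate_matrix(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    if isinstance(covariates, pd.DataFrame):
        arr = covariates.to_numpy(dtype=float)
    else:
        arr = np.asarray(covariates, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
    if arr.shape[0] != n:
        raise ContractError(
            f"covariates have {arr.shape[0]} rows, expected {n}"
        )
    if not np.isfinite(arr).all():
        raise ContractError("covariate values must be present (no missing)")
    return arr


class ComBatHarmonizer(TransformerMixin, BaseEstimator):
    """Remove additive and multiplicative batch effects from a feature matrix.

    Parameters
    ----------
    empirical_bayes : bool, default True
        Shrink per-batch location/scale estimates across features under the
        parametric normal / inverse-gamma priors.  With ``False`` the raw
        per-batch estimates are used (exact removal, no pooling; this
        variant is exactly idempotent).
    tol, max_iter :
        Convergence control of the alternating posterior-mean iteration
        (maximum relative parameter change below ``tol``, capped at
        ``max_iter`` sweeps).
    eps : float
        Relative threshold under which the across-feature variance of the
        batch variances counts as degenerate and shrinkage is skipped.

    The batch labels (and optional covariates) are passed to :meth:`fit` and
    :meth:`transform` rather than carried in ``X``, mirroring how batch is a
    property of the acquisition rather than of the features.

    Attributes
    ----------
    alpha_ : (p,) grand mean per feature
    beta_ : (c, p) covariate effects (covariates are centred internally)
    pooled_var_ : (p,) pooled residual variance, divisor N
    gamma_hat_, delta_hat_sq_ : (B, p) raw standardised batch means/variances
    gamma_star_, delta_star_sq_ : (B, p) EB-adjusted location/scale
    prior_gamma_bar_, prior_tau_sq_, prior_a_, prior_b_ : (B,) hyperparameters
    eb_skipped_ : (B,) bool, True where shrinkage was not applicable
    n_iter_ : (B,) iterations used by the EB solver
    """

    def __init__(
        self,
        empirical_bayes: bool = True,
        tol: float = 1e-4,
        max_iter: int = 100,
        eps: float = 1e-12,
    ):
        self.empirical_bayes = empirical_bayes
        self.tol = tol
        self.max_iter = max_iter
        self.eps = eps

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y=None, *, batch, covariates=None):
        X, feature_names = _as_2d_float(X)
        n, p = X.shape
        if not np.isfinite(X).all():
            raise ContractError("ComBat requires a complete feature matrix")
        batch = np.asarray(batch)
        if batch.shape[0] != n:
            raise ContractError(f"batch has {batch.shape[0]} labels, expected {n}")
        cov = _covariate_matrix(covariates, n)

        labels, inverse = np.unique(batch, return_inverse=True)
        counts = np.bincount(inverse)
        if (counts < 2).any():
            small = labels[counts < 2].tolist()
            raise ContractError(f"batch(es) of size 1 are not allowed: {small}")

        self.batches_ = labels
        self.n_batches_ = len(labels)
        self.batch_counts_ = counts
        self.feature_names_in_ = feature_names
        self.n_features_in_ = p
        self.covariate_means_ = cov.mean(axis=0) if cov.shape[1] else np.empty(0)
        cov_c = cov - self.covariate_means_

        # one-hot batch design plus centred covariates; the batch block spans
        # the intercept, so the weighted batch coefficients are batch means
        # adjusted for covariates
        design = np.zeros((n, self.n_batches_ + cov_c.shape[1]))
        design[np.arange(n), inverse] = 1.0
        design[:, self.n_batches_:] = cov_c
        coef, *_ = np.linalg.lstsq(design, X, rcond=None)
        batch_coef = coef[: self.n_batches_]
        self.beta_ = coef[self.n_batches_:]

        weights = counts / n
        self.alpha_ = weights @ batch_coef

        resid_full = X - design @ coef
        self.pooled_var_ = (resid_full**2).mean(axis=0)
        scale2 = np.maximum((X**2).mean(axis=0), 1.0)
        degenerate = self.pooled_var_ <= self.eps * scale2
        if degenerate.any():
            bad = np.flatnonzero(degenerate)
            raise ContractError(
                "feature(s) with (near-)zero pooled residual variance — "
                f"constant overall or perfectly fit: {bad[:5].tolist()}"
            )
        pooled_sd = np.sqrt(self.pooled_var_)

        stand_mean = self.alpha_[None, :] + cov_c @ self.beta_
        z = (X - stand_mean) / pooled_sd

        B = self.n_batches_
        gamma_hat = np.empty((B, p))
        delta_hat_sq = np.empty((B, p))
        for b in range(B):
            zb = z[inverse == b]
            gamma_hat[b] = zb.mean(axis=0)
            # divisor n_b, matching the divisor-N pooled variance
            delta_hat_sq[b] = zb.var(axis=0, ddof=0)
        self.gamma_hat_ = gamma_hat
        self.delta_hat_sq_ = delta_hat_sq

        self._fit_eb(z, inverse)
        return self

    def _fit_eb(self, z: np.ndarray, inverse: np.ndarray) -> None:
        B, p = self.gamma_hat_.shape
        self.prior_gamma_bar_ = self.gamma_hat_.mean(axis=1)
        self.prior_tau_sq_ = (
            self.gamma_hat_.var(axis=1, ddof=1) if p > 1 else np.zeros(B)
        )
        self.prior_a_ = np.full(B, np.nan)
        self.prior_b_ = np.full(B, np.nan)
        self.eb_skipped_ = np.zeros(B, dtype=bool)
        self.n_iter_ = np.zeros(B, dtype=int)
        gamma_star = self.gamma_hat_.copy()
        delta_star_sq = self.delta_hat_sq_.copy()

        for b in range(B):
            m = self.delta_hat_sq_[b].mean()
            s2 = self.delta_hat_sq_[b].var(ddof=1) if p > 1 else 0.0
            degenerate = s2 < self.eps * max(1.0, m**2)
            if not self.empirical_bayes or degenerate:
                self.eb_skipped_[b] = True
                continue
            a = (2 * s2 + m**2) / s2
            bb = (m * s2 + m**3) / s2
            self.prior_a_[b] = a
            self.prior_b_[b] = bb
            n_b = self.batch_counts_[b]
            zb = z[inverse == b]
            g_hat = self.gamma_hat_[b]
            g_bar = self.prior_gamma_bar_[b]
            t2 = self.prior_tau_sq_[b]
            g_old = g_hat.copy()
            d_old = self.delta_hat_sq_[b].copy()
            for it in range(1, self.max_iter + 1):
                g_new = (n_b * t2 * g_hat + d_old * g_bar) / (n_b * t2 + d_old)
                ssq = ((zb - g_new[None, :]) ** 2).sum(axis=0)
                d_new = (bb + 0.5 * ssq) / (n_b / 2.0 + a - 1.0)
                change = max(
                    np.max(np.abs(g_new - g_old) / (np.abs(g_old) + self.eps)),
                    np.max(np.abs(d_new - d_old) / (np.abs(d_old) + self.eps)),
                )
                g_old, d_old = g_new, d_new
                if change < self.tol:
                    break
            self.n_iter_[b] = it
            gamma_star[b] = g_old
            delta_star_sq[b] = d_old

        if (delta_star_sq <= 0).any():
            raise ContractError("non-positive adjusted batch variance")
        self.gamma_star_ = gamma_star
        self.delta_star_sq_ = delta_star_sq

    # -- transforming ----------------------------------------------------

    def transform(self, X, *, batch, covariates=None):
        if not hasattr(self, "alpha_"):
            raise ContractError("transform called before fit")
        X, feature_names = _as_2d_float(X)
        n, p = X.shape
        if p != self.n_features_in_:
            raise ContractError(f"X has {p} features, model expects {self.n_features_in_}")
        batch = np.asarray(batch)
        unseen = set(batch) - set(self.batches_)
        if unseen:
            raise ContractError(f"unseen batch label(s): {sorted(map(str, unseen))}")
        lookup = {lab: i for i, lab in enumerate(self.batches_)}
        b_idx = np.array([lookup[lab] for lab in batch])
        cov = _covariate_matrix(covariates, n)
        if cov.shape[1] != len(self.covariate_means_):
            raise ContractError(
                f"expected {len(self.covariate_means_)} covariate column(s), "
                f"got {cov.shape[1]}"
            )
        cov_c = cov - self.covariate_means_

        pooled_sd = np.sqrt(self.pooled_var_)
        stand_mean = self.alpha_[None, :] + cov_c @ self.beta_
        z = (X - stand_mean) / pooled_sd
        adj = (z - self.gamma_star_[b_idx]) / np.sqrt(self.delta_star_sq_[b_idx])
        out = adj * pooled_sd + stand_mean
        if feature_names is not None:
            return pd.DataFrame(out, columns=feature_names)
        return out

    def fit_transform(self, X, y=None, **fit_params):
        self.fit(X, y, **fit_params)
        return self.transform(
            X,
            batch=fit_params["batch"],
            covariates=fit_params.get("covariates"),
        )


class CovBatHarmonizer(TransformerMixin, BaseEstimator):
    """ComBat plus per-batch alignment of principal-component score scale.

    After the inner ComBat pass, covariate-adjusted residuals are decomposed
    with PCA across features; the smallest K components whose cumulative
    explained variance reaches ``variance_fraction`` have their scores
    re-centred and re-scaled per batch (a plain location/scale adjustment —
    no covariates, no shrinkage), the remaining scores pass through, and
    the residuals are reconstructed under the fitted mean structure.
    """

    def __init__(
        self,
        variance_fraction: float = 0.95,
        empirical_bayes: bool = True,
        tol: float = 1e-4,
        max_iter: int = 100,
    ):
        self.variance_fraction = variance_fraction
        self.empirical_bayes = empirical_bayes
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None, *, batch, covariates=None):
        if not (0 < self.variance_fraction <= 1):
            raise ContractError("variance_fraction must lie in (0, 1]")
        X_arr, feature_names = _as_2d_float(X)
        n, p = X_arr.shape
        self.feature_names_in_ = feature_names
        self.combat_ = ComBatHarmonizer(
            empirical_bayes=self.empirical_bayes, tol=self.tol, max_iter=self.max_iter
        ).fit(X_arr, batch=batch, covariates=covariates)

        harmonised = self.combat_.transform(X_arr, batch=batch, covariates=covariates)
        cov = _covariate_matrix(covariates, n)
        cov_c = cov - self.combat_.covariate_means_
        mean_structure = self.combat_.alpha_[None, :] + cov_c @ self.combat_.beta_
        resid = harmonised - mean_structure

        n_comp = min(n - 1, p)
        if n_comp < 1:
            raise ContractError("need >= 2 sessions for the residual decomposition")
        self.pca_ = PCA(n_components=n_comp, svd_solver="full").fit(resid)
        cum = np.cumsum(self.pca_.explained_variance_ratio_)
        self.n_components_retained_ = int(np.searchsorted(cum, self.variance_fraction) + 1)
        self.n_components_retained_ = min(self.n_components_retained_, n_comp)

        scores = self.pca_.transform(resid)
        labels = self.combat_.batches_
        lookup = {lab: i for i, lab in enumerate(labels)}
        b_idx = np.array([lookup[lab] for lab in np.asarray(batch)])
        K = self.n_components_retained_
        B = len(labels)
        self.score_means_ = np.zeros((B, K))
        self.score_sds_ = np.ones((B, K))
        self.score_pooled_mean_ = scores[:, :K].mean(axis=0)
        pooled_var = np.zeros(K)
        for b in range(B):
            sb = scores[b_idx == b, :K]
            self.score_means_[b] = sb.mean(axis=0)
            sd = sb.std(axis=0, ddof=0)
            self.score_sds_[b] = np.where(sd > 0, sd, 1.0)
            pooled_var += sb.shape[0] * sb.var(axis=0, ddof=0)
        self.score_pooled_sd_ = np.sqrt(pooled_var / n)
        self.score_pooled_sd_ = np.where(
            self.score_pooled_sd_ > 0, self.score_pooled_sd_, 1.0
        )
        return self

    def transform(self, X, *, batch, covariates=None):
        if not hasattr(self, "combat_"):
            raise ContractError("transform called before fit")
        X_arr, feature_names = _as_2d_float(X)
        harmonised = self.combat_.transform(X_arr, batch=batch, covariates=covariates)
        cov = _covariate_matrix(covariates, X_arr.shape[0])
        cov_c = cov - self.combat_.covariate_means_
        mean_structure = self.combat_.alpha_[None, :] + cov_c @ self.combat_.beta_
        resid = harmonised - mean_structure

        labels = self.combat_.batches_
        lookup = {lab: i for i, lab in enumerate(labels)}
        batch = np.asarray(batch)
        unseen = set(batch) - set(labels)
        if unseen:
            raise ContractError(f"unseen batch label(s): {sorted(map(str, unseen))}")
        b_idx = np.array([lookup[lab] for lab in batch])

        scores = self.pca_.transform(resid)
        K = self.n_components_retained_
        adj = (scores[:, :K] - self.score_means_[b_idx]) / self.score_sds_[b_idx]
        scores[:, :K] = adj * self.score_pooled_sd_ + self.score_pooled_mean_
        resid_adj = self.pca_.inverse_transform(scores)
        out = resid_adj + mean_structure
        if feature_names is not None:
            return pd.DataFrame(out, columns=feature_names)
        return out

    def fit_transform(self, X, y=None, **fit_params):
        self.fit(X, y, **fit_params)
        return self.transform(
            X,
            batch=fit_params["batch"],
            covariates=fit_params.get("covariates"),
        )


# -- study-level wrappers ------------------------------------------------


def _study_covariates(
    study: StudyData, covariates: Sequence[str]
) -> Optional[pd.DataFrame]:
    """Build the numeric covariate matrix: age as-is, sex as 0/1 (sorted labels)."""
    if not covariates:
        return None
    cols = {}
    for name in covariates:
        if name == "age":
            cols["age"] = study.sessions["age"].astype(float).to_numpy()
        elif name == "sex":
            levels = sorted(study.sessions["sex"].unique())
            if len(levels) > 2:
                raise ContractError(f"sex has {len(levels)} levels; expected <= 2")
            cols["sex"] = (study.sessions["sex"] == levels[-1]).astype(float).to_numpy()
        else:
            raise ContractError(f"unsupported covariate {name!r}")
    return pd.DataFrame(cols, index=study.sessions["session_id"])


def fit_combat(
    study: StudyData,
    batch_key: str = "scanner_id",
    covariates: Sequence[str] = ("age", "sex"),
    fit_sessions: str = "primary",
    **kwargs,
) -> ComBatHarmonizer:
    """Fit ComBat on a study's IDP table with the scanner as batch.

    The default ``fit_sessions="primary"`` estimates the model on the
    repeat_index-0 sessions only: in a travelling-heads design these form a
    balanced subject-by-scanner grid, so batch means are estimated without
    subject-composition bias (a repeat set would otherwise give its subject
    several-fold weight on that one scanner, leaking that subject's
    biological deviation into the scanner effect).  ``"all"`` fits on the
    whole cohort.  The fitted model is applied to all sessions either way.
    """
    if fit_sessions not in ("all", "primary"):
        raise ContractError(f"fit_sessions must be 'all' or 'primary'")
    mask = (
        np.ones(len(study.sessions), dtype=bool)
        if fit_sessions == "all"
        else (study.sessions["repeat_index"] == 0).to_numpy()
    )
    cov = _study_covariates(study, covariates)
    model = ComBatHarmonizer(**kwargs)
    model.fit(
        study.idps.to_numpy(float)[mask],
        batch=study.sessions[batch_key].to_numpy()[mask],
        covariates=None if cov is None else cov.to_numpy()[mask],
    )
    model.batch_key_ = batch_key
    model.covariate_names_ = tuple(covariates)
    return model


def apply_combat(model: ComBatHarmonizer, study: StudyData) -> StudyData:
    """Apply a fitted ComBat model to a study, returning a harmonised copy."""
    cov = _study_covariates(study, getattr(model, "covariate_names_", ()))
    out = model.transform(
        study.idps.to_numpy(float),
        batch=study.sessions[getattr(model, "batch_key_", "scanner_id")].to_numpy(),
        covariates=None if cov is None else cov.to_numpy(),
    )
    idps = pd.DataFrame(out, index=study.idps.index, columns=study.idps.columns)
    return study.with_idps(idps)


def fit_apply_covbat(
    study: StudyData,
    batch_key: str = "scanner_id",
    covariates: Sequence[str] = ("age", "sex"),
    variance_fraction: float = 0.95,
    **kwargs,
) -> tuple[CovBatHarmonizer, StudyData]:
    """Fit CovBat on a study and return the model plus the harmonised copy."""
    cov = _study_covariates(study, covariates)
    model = CovBatHarmonizer(variance_fraction=variance_fraction, **kwargs)
    batch = study.sessions[batch_key].to_numpy()
    cov_arr = None if cov is None else cov.to_numpy()
    out = model.fit_transform(
        study.idps.to_numpy(float), batch=batch, covariates=cov_arr
    )
    model.batch_key_ = batch_key
    model.covariate_names_ = tuple(covariates)
    idps = pd.DataFrame(out, index=study.idps.index, columns=study.idps.columns)
    return model, study.with_idps(idps)


@dataclass
class HarmonisationEvaluation:
    """Pre/post comparison of reliability and ranking statistics."""

    cov_before: pd.DataFrame
    cov_after: pd.DataFrame
    cov_delta: pd.DataFrame  # after - before, per IDP
    ranking_before: pd.Series  # median Q per IDP, all scanners
    ranking_after: pd.Series
    summary: dict


def evaluate_harmonisation(
    before: StudyData,
    after: StudyData,
    ddof: int = 1,
    between_policy: str = "first",
    vendor_subset: Optional[Sequence[str]] = None,
) -> HarmonisationEvaluation:
    """Run the CoV and ranking statistics on both tables and pair them.

    The headline summary reports the median over IDPs of the
    between-scanner / within-scanner CoV ratio before and after, and the
    median ranking consistency before and after (all scanners, plus a
    vendor-restricted subset when given).
    """
    from .ranking import ranking_consistency
    from .reliability import class_cov_profile

    if before.session_ids != after.session_ids:
        raise ContractError("before/after studies must share the same sessions")
    if list(before.idps.columns) != list(after.idps.columns):
        raise ContractError("before/after studies must share the same IDPs")

    rep_b = class_cov_profile(before, ddof=ddof, between_policy=between_policy).per_idp
    rep_a = class_cov_profile(after, ddof=ddof, between_policy=between_policy).per_idp
    delta = rep_a - rep_b

    rank_b = ranking_consistency(before).values_per_idp()
    rank_a = ranking_consistency(after).values_per_idp()

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio_b = rep_b["cov_between_scanner"] / rep_b["cov_within_scanner"]
        ratio_a = rep_a["cov_between_scanner"] / rep_a["cov_within_scanner"]
    summary = {
        "median_cov_ratio_before": float(np.nanmedian(ratio_b)),
        "median_cov_ratio_after": float(np.nanmedian(ratio_a)),
        "median_ranking_before": float(np.nanmedian(rank_b)),
        "median_ranking_after": float(np.nanmedian(rank_a)),
        "fraction_idps_cov_reduced": float(
            np.nanmean(
                (
                    rep_a["cov_between_scanner"] < rep_b["cov_between_scanner"]
                ).to_numpy(float)
            )
        ),
    }
    if vendor_subset is not None:
        rank_bv = ranking_consistency(
            before, scanner_subset=vendor_subset, subset_label="vendor"
        ).values_per_idp()
        rank_av = ranking_consistency(
            after, scanner_subset=vendor_subset, subset_label="vendor"
        ).values_per_idp()
        summary["median_ranking_vendor_before"] = float(np.nanmedian(rank_bv))
        summary["median_ranking_vendor_after"] = float(np.nanmedian(rank_av))

    return HarmonisationEvaluation(
        cov_before=rep_b,
        cov_after=rep_a,
        cov_delta=delta,
        ranking_before=rank_b,
        ranking_after=rank_a,
        summary=summary,
    )
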