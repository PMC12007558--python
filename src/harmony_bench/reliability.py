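"""Three-baseline coefficient-of-variation framework, scanner bias and IQM z-scores.

For every IDP three coefficients of variation (CoV = sd / |mean|) are
compared:

* **within-scanner, within-subject** — over a subject's repeat sessions on a
  single scanner, averaged across the qualifying (subject, scanner) sets;
  the noise floor.
* **between-scanner, within-subject** — over a subject's primary
  (repeat_index 0) sessions, one per scanner, averaged across subjects; the
  scanner effect plus noise.
* **within-scanner, between-subject** — across subjects' primary sessions on
  one scanner, averaged across scanners; the biological yardstick.

The relative difference 100*(between - within)/within summarises how far
between-scanner variability exceeds the noise floor.  Scanner *bias* is the
relative difference of the mean of a subject's between-scanner sessions from
the mean of their within-scanner repeat set.  IQM z-score heatmaps flag
outlying scanners or subjects in raw data quality.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .tables import CategoryMap, ContractError, StudyData

__all__ = [
    "ReliabilityReport",
    "BiasReport",
    "coefficient_of_variation",
    "class_cov_profile",
    "relative_difference",
    "scanner_bias",
    "aggregate_by_group",
    "zscore_iqms",
    "select_top_edges",
]

# relative threshold below which a mean counts as zero and the CoV as undefined
EPS_COV = 1e-12


@dataclass
class ReliabilityReport:
    """Per-IDP CoVs for the three repeat classes, plus relative differences."""

    per_idp: pd.DataFrame  # index IDP; cov_within_scanner, cov_between_scanner,
    #                         cov_biological, relative_difference_pct
    ddof: int = 1
    between_policy: str = "first"


@dataclass
class BiasReport:
    """Between- vs within-scanner mean disagreement, per subject and aggregated."""

    per_subject: pd.DataFrame  # subjects-with-repeats x IDP, all scanners
    per_subject_same_vendor: pd.DataFrame  # between-mean restricted to the
    #                                         repeat scanner's vendor
    group: pd.Series  # mean across qualifying subjects
    group_same_vendor: pd.Series


def _cov_1d(values: np.ndarray, ddof: int) -> float:
    ok = values[np.isfinite(values)]
    if len(ok) < 2:
        return float("nan")
    m = ok.mean()
    scale = max(np.abs(ok).max(), 1.0)
    if abs(m) < EPS_COV * scale:
        return float("nan")
    return float(ok.std(ddof=ddof) / abs(m))


def coefficient_of_variation(values: Sequence[float], ddof: int = 1) -> float:
    """Sample sd divided by absolute mean; NaN for < 2 values or a ~zero mean.

    A mean within ``EPS_COV`` of zero relative to the data's own scale makes
    the CoV numerically meaningless, so the undefined marker is returned
    instead of an exploding ratio.
    """
    return _cov_1d(np.asarray(values, dtype=float), ddof)


def _cov_columns(block: np.ndarray, ddof: int) -> np.ndarray:
    """Columnwise CoV of a (sessions x IDPs) block, NaN-aware."""
    n_ok = np.isfinite(block).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(block, axis=0)
        sd = np.nanstd(block, axis=0, ddof=ddof)
        scale = np.fmax(np.nanmax(np.abs(block), axis=0), 1.0)
    out = sd / np.abs(mean)
    bad = (n_ok < 2) | (np.abs(mean) < EPS_COV * scale)
    out[bad] = np.nan
    return out


def _nanmean_rows(rows: list[np.ndarray]) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(np.vstack(rows), axis=0)


def class_cov_profile(
    study: StudyData, ddof: int = 1, between_policy: str = "first"
) -> ReliabilityReport:
    """Per-IDP CoVs of the three repeat classes, averaged over their units.

    ``between_policy`` chooses which session represents a scanner the
    subject was scanned on repeatedly: ``"first"`` uses the repeat_index-0
    session only (repeats never leak into the between-scanner class);
    ``"mean-of-repeats"`` collapses each (subject, scanner) repeat set to
    its mean first.
    """
    if between_policy not in ("first", "mean-of-repeats"):
        raise ContractError(f"unknown between_policy {between_policy!r}")
    sess = study.sessions
    vals = study.idps.to_numpy(float)
    idx = {s: i for i, s in enumerate(study.idps.index)}
    n_idp = vals.shape[1]

    # within-scanner, within-subject: every (subject, scanner) set with >= 2 sessions
    within_rows = []
    for (_, _), grp in sess.groupby(["subject_id", "scanner_id"], sort=False):
        if len(grp) < 2:
            continue
        block = vals[[idx[s] for s in grp["session_id"]]]
        within_rows.append(_cov_columns(block, ddof))
    if within_rows:
        cov_within = _nanmean_rows(within_rows)
    else:
        warnings.warn(
            "no subject has >= 2 sessions on one scanner; "
            "within-scanner CoV is undefined",
            stacklevel=2,
        )
        cov_within = np.full(n_idp, np.nan)

    # between-scanner, within-subject: one value per scanner per subject
    between_rows = []
    for _, grp in sess.groupby("subject_id", sort=False):
        if between_policy == "first":
            chosen = grp[grp["repeat_index"] == 0]
            block = vals[[idx[s] for s in chosen["session_id"]]]
        else:
            parts = []
            for _, sg in grp.groupby("scanner_id", sort=False):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    parts.append(
                        np.nanmean(vals[[idx[s] for s in sg["session_id"]]], axis=0)
                    )
            block = np.vstack(parts)
        if block.shape[0] >= 2:
            between_rows.append(_cov_columns(block, ddof))
    cov_between = (
        _nanmean_rows(between_rows) if between_rows else np.full(n_idp, np.nan)
    )

    # within-scanner, between-subject (biological): primary sessions per scanner
    bio_rows = []
    primary = sess[sess["repeat_index"] == 0]
    for _, grp in primary.groupby("scanner_id", sort=False):
        if len(grp) < 2:
            continue
        block = vals[[idx[s] for s in grp["session_id"]]]
        bio_rows.append(_cov_columns(block, ddof))
    cov_bio = _nanmean_rows(bio_rows) if bio_rows else np.full(n_idp, np.nan)

    rel = relative_difference(cov_between, cov_within)
    per_idp = pd.DataFrame(
        {
            "cov_within_scanner": cov_within,
            "cov_between_scanner": cov_between,
            "cov_biological": cov_bio,
            "relative_difference_pct": rel,
        },
        index=study.idps.columns,
    )
    return ReliabilityReport(per_idp=per_idp, ddof=ddof, between_policy=between_policy)


def relative_difference(between, within):
    """100 * (between - within) / within; missing where within <= 0."""
    between = np.asarray(between, dtype=float)
    within = np.asarray(within, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * (between - within) / within
    out = np.where(within > 0, out, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def scanner_bias(study: StudyData) -> BiasReport:
    """Disagreement of between- vs within-scanner means, per qualifying subject.

    For each subject with within-scanner repeats: 100 * (mean over the
    subject's primary sessions across scanners - mean over their repeat
    set) / the latter.  The vendor-restricted variant limits the
    between-scanner mean to scanners sharing the repeat scanner's vendor.
    """
    sess = study.sessions
    vals = study.idps.to_numpy(float)
    idx = {s: i for i, s in enumerate(study.idps.index)}
    rep_counts = sess[sess["repeat_index"] > 0].groupby("subject_id").size()
    if rep_counts.empty:
        raise ContractError("no subject has within-scanner repeats")

    def _mean(block_ids: list[str]) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(vals[[idx[s] for s in block_ids]], axis=0)

    rows_all, rows_vendor, subjects = [], [], []
    for sub in rep_counts.index:
        grp = sess[sess["subject_id"] == sub]
        rep_scanner = grp.loc[grp["repeat_index"] > 0, "scanner_id"].iloc[0]
        rep_vendor = grp.loc[grp["scanner_id"] == rep_scanner, "vendor"].iloc[0]
        within_ids = grp.loc[grp["scanner_id"] == rep_scanner, "session_id"].tolist()
        primary = grp[grp["repeat_index"] == 0]
        between_ids = primary["session_id"].tolist()
        vendor_ids = primary.loc[
            primary["vendor"] == rep_vendor, "session_id"
        ].tolist()

        within_mean = _mean(within_ids)
        scale = np.fmax(np.abs(within_mean), 1.0)
        ok = np.abs(within_mean) >= EPS_COV * scale
        with np.errstate(invalid="ignore", divide="ignore"):
            bias_all = 100.0 * (_mean(between_ids) - within_mean) / within_mean
            bias_vendor = 100.0 * (_mean(vendor_ids) - within_mean) / within_mean
        bias_all[~ok] = np.nan
        bias_vendor[~ok] = np.nan
        subjects.append(sub)
        rows_all.append(bias_all)
        rows_vendor.append(bias_vendor)

    per_subject = pd.DataFrame(rows_all, index=subjects, columns=study.idps.columns)
    per_subject_vendor = pd.DataFrame(
        rows_vendor, index=subjects, columns=study.idps.columns
    )
    return BiasReport(
        per_subject=per_subject,
        per_subject_same_vendor=per_subject_vendor,
        group=per_subject.mean(axis=0),
        group_same_vendor=per_subject_vendor.mean(axis=0),
    )


def aggregate_by_group(
    per_idp: pd.DataFrame, categories: CategoryMap, statistic: str = "mean"
) -> pd.DataFrame:
    """Group-level mean or median of a per-IDP table, missing-aware."""
    if statistic not in ("mean", "median"):
        raise ContractError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    unknown = set(per_idp.index) - set(categories.entries.index)
    if unknown:
        raise ContractError(f"IDP(s) not in the category map: {sorted(unknown)[:5]}")
    groups = categories.entries.loc[per_idp.index, "group"]
    agg = per_idp.groupby(groups).agg(statistic)
    agg.index.name = "group"
    return agg


def zscore_iqms(study: StudyData, axis: str = "across_scanners") -> pd.DataFrame:
    """Averaged z-score heatmap of the IQMs, excluding within-scanner repeats.

    ``across_scanners``: each metric is z-scored over the scanners within a
    subject, then averaged over subjects -> scanner x IQM (how a scanner's
    quality sits relative to the others).  ``across_subjects``: z over
    subjects within a scanner, averaged over scanners -> subject x IQM.
    Entries are missing where the z-axis is constant.
    """
    if study.iqms is None:
        raise ContractError("study has no IQM table")
    if axis not in ("across_scanners", "across_subjects"):
        raise ContractError(f"unknown axis {axis!r}")
    sess = study.sessions
    primary = sess[sess["repeat_index"] == 0]
    iqms = study.iqms.loc[primary["session_id"]]
    z_axis, avg_axis = (
        ("scanner_id", "subject_id")
        if axis == "across_scanners"
        else ("subject_id", "scanner_id")
    )
    frames = []
    meta = primary.set_index("session_id")[[z_axis, avg_axis]]
    for col in iqms.columns:
        wide = (
            pd.concat([iqms[col], meta], axis=1)
            .pivot(index=z_axis, columns=avg_axis, values=col)
            .astype(float)
        )
        sd = wide.std(axis=0, ddof=1)
        dev = wide - wide.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = dev / sd
        # an exactly constant column has zero deviations: z -> 0 in the limit
        for c in sd.index[~(sd > 0)]:
            z[c] = np.where(dev[c].abs() == 0, 0.0, np.nan)
        frames.append(z.mean(axis=1).rename(col))
    out = pd.concat(frames, axis=1)
    out.index.name = z_axis
    return out


def select_top_edges(
    study: StudyData,
    edge_category: str,
    fraction: float = 0.05,
    k_override: Optional[int] = None,
) -> list[str]:
    """Retain the strongest connectivity edges by |mean| over repeat sessions.

    The mean edge weight is pooled over all within-scanner repeat sessions
    (every session of each repeated subject on their designated scanner);
    edges are ranked by absolute mean — partial correlations are signed, so
    a strongly negative edge is as "strong" as a positive one — with ties
    broken lexicographically by edge name.  ``k_override`` bypasses the
    fraction (round-half-up of fraction * n_edges).
    """
    cols = study.categories.idps_in_category(edge_category)
    cols = [c for c in cols if c in study.idps.columns]
    if not cols:
        raise ContractError(f"no IDPs found for category {edge_category!r}")
    if not (0 < fraction <= 1):
        raise ContractError("fraction must lie in (0, 1]")
    sess = study.sessions
    rep_subjects = sess.loc[sess["repeat_index"] > 0, ["subject_id", "scanner_id"]]
    if rep_subjects.empty:
        raise ContractError("edge selection needs >= 1 subject with repeats")
    pairs = set(map(tuple, rep_subjects.itertuples(index=False)))
    in_repeat_set = [
        (r.subject_id, r.scanner_id) in pairs for r in sess.itertuples(index=False)
    ]
    ids = sess.loc[in_repeat_set, "session_id"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = study.idps.loc[ids, cols].mean(axis=0)

    k = k_override if k_override is not None else int(math.floor(fraction * len(cols) + 0.5))
    if not (1 <= k <= len(cols)):
        raise ContractError(f"k={k} outside [1, {len(cols)}]")
    order = sorted(cols, key=lambda c: (-abs(means[c]), c))
    return order[:k]
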