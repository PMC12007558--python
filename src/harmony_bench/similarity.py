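"""Between-session similarity: per-category Spearman matrices and their median.

For each IDP category m, the Spearman rank correlation is computed between
the category's feature vectors of every pair of sessions, giving a matrix
R_m.  The between-session similarity P is the entrywise median of the R_m
across categories:

    P[i, j] = median_m rcorr(f[i, m], f[j, m])

so each category contributes with equal weight regardless of how many IDPs
it holds.  Session pairs are classified by whether they share subject and/or
scanner; comparing the class-wise distributions of P is the benchmark's
first-line picture of scanner effects (within-scanner repeats of a subject
should look more alike than the same subject on different scanners).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .tables import ContractError, SessionRecord, StudyData, rank_correlation
from .reliability import select_top_edges

__all__ = [
    "PAIR_CLASSES",
    "category_correlation_matrices",
    "similarity_matrix",
    "classify_pairs",
    "pair_class_distributions",
]

#: the four labels partitioning all unordered session pairs
PAIR_CLASSES = (
    "within_scanner_within_subject",
    "between_scanner_within_subject",
    "within_scanner_between_subject",
    "between_scanner_between_subject",
)


def _spearman_matrix(values: np.ndarray) -> np.ndarray:
    """All-pairs Spearman between the rows of ``values`` (sessions x features).

    Fast path (rank once, then a single correlation product) when no value is
    missing; otherwise falls back to pairwise-complete correlation per pair.
    Constant rows yield NaN off-diagonal; the diagonal is 1 by definition.
    """
    n = values.shape[0]
    if np.isfinite(values).all():
        ranks = rankdata(values, axis=1)
        centred = ranks - ranks.mean(axis=1, keepdims=True)
        norms = np.sqrt((centred**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (centred @ centred.T) / np.outer(norms, norms)
        corr[~np.isfinite(corr)] = np.nan
    else:
        corr = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(i + 1, n):
                corr[i, j] = corr[j, i] = rank_correlation(values[i], values[j])
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def category_correlation_matrices(
    study: StudyData,
    edge_category: Optional[str] = None,
    edge_fraction: float = 0.05,
    edge_k: Optional[int] = None,
) -> dict[str, pd.DataFrame]:
    """One session-by-session Spearman matrix per IDP category.

    If ``edge_category`` names a connectivity-edge category, only the edges
    retained by :func:`~harmony_bench.reliability.select_top_edges` (ranked
    by absolute mean over within-scanner repeat sessions) enter that
    category's correlations.
    """
    ids = study.session_ids
    out: dict[str, pd.DataFrame] = {}
    for cat in study.categories.categories:
        cols = study.categories.idps_in_category(cat)
        cols = [c for c in cols if c in study.idps.columns]
        if len(cols) < 2:
            raise ContractError(f"category {cat!r} has < 2 IDPs present in the table")
        if edge_category is not None and cat == edge_category:
            cols = select_top_edges(
                study, cat, fraction=edge_fraction, k_override=edge_k
            )
        mat = _spearman_matrix(study.idps[cols].to_numpy(float))
        out[cat] = pd.DataFrame(mat, index=ids, columns=ids)
    return out


def similarity_matrix(
    category_matrices: Mapping[str, pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Entrywise median across categories, plus the count of contributing ones.

    An entry is missing only when every category is missing for that pair.
    The diagonal is exactly 1.
    """
    if not category_matrices:
        raise ContractError("need at least one category matrix")
    mats = list(category_matrices.values())
    ids = mats[0].index
    stack = np.stack([m.to_numpy(float) for m in mats])
    with np.errstate(all="ignore"):
        med = np.nanmedian(stack, axis=0)
    counts = np.isfinite(stack).sum(axis=0)
    med[counts == 0] = np.nan
    np.fill_diagonal(med, 1.0)
    P = pd.DataFrame(med, index=ids, columns=ids)
    n_cat = pd.DataFrame(counts, index=ids, columns=ids)
    return P, n_cat


def classify_pairs(sessions: Sequence[SessionRecord] | pd.DataFrame) -> pd.DataFrame:
    """Label every unordered session pair by shared subject / shared scanner."""
    if isinstance(sessions, pd.DataFrame):
        frame = sessions
    else:
        frame = pd.DataFrame([r.as_dict() for r in sessions])
    ids = frame["session_id"].to_numpy()
    subj = frame["subject_id"].to_numpy()
    scan = frame["scanner_id"].to_numpy()
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    same_subj = subj[iu] == subj[ju]
    same_scan = scan[iu] == scan[ju]
    labels = np.where(
        same_subj,
        np.where(same_scan, PAIR_CLASSES[0], PAIR_CLASSES[1]),
        np.where(same_scan, PAIR_CLASSES[2], PAIR_CLASSES[3]),
    )
    return pd.DataFrame(
        {"session_a": ids[iu], "session_b": ids[ju], "pair_class": labels}
    )


def pair_class_distributions(
    P: pd.DataFrame, classes: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Order statistics of the similarity entries within each pair class.

    Returns a summary table (count, missing count, quartiles, mean) and the
    raw values per class.  Missing P entries are excluded but counted; an
    empty class yields an all-NaN summary row rather than an error.
    """
    loc = {s: i for i, s in enumerate(P.index)}
    vals = P.to_numpy(float)
    ia = classes["session_a"].map(loc).to_numpy()
    ib = classes["session_b"].map(loc).to_numpy()
    entries = vals[ia, ib]

    rows = []
    raw: dict[str, np.ndarray] = {}
    for cls in PAIR_CLASSES:
        v = entries[classes["pair_class"].to_numpy() == cls]
        ok = v[np.isfinite(v)]
        raw[cls] = ok
        if len(ok):
            q25, q50, q75 = np.percentile(ok, [25, 50, 75])
            rows.append((cls, len(v), len(v) - len(ok), q25, q50, q75, ok.mean()))
        else:
            rows.append((cls, len(v), len(v), *([np.nan] * 4)))
    summary = pd.DataFrame(
        rows,
        columns=["pair_class", "n_pairs", "n_missing", "q25", "median", "q75", "mean"],
    ).set_index("pair_class")
    return summary, raw
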