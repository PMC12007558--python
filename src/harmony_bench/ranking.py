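"""Between-scanner consistency of subject ranking, with a random-ranking null.

For every IDP d and every unordered scanner pair (l, k):

    Q[l, k, d] = rcorr(v[l, d], v[k, d])

where v[l, d] holds one value per subject (the subject's primary session on
scanner l) and rcorr is Spearman's rank correlation.  Q = 1 means the two
scanners order the subjects identically on that phenotype.  The indicative
null band is the interquartile range of the Spearman correlation between two
independent random rankings of the same number of subjects, obtained either
by Monte-Carlo draws or (for small n) exact enumeration of all n!
permutations against a fixed reference — valid by exchangeability.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .tables import ContractError, StudyData, rank_correlation

__all__ = [
    "RankingReport",
    "NullBaseline",
    "subject_vectors",
    "ranking_consistency",
    "null_baseline",
]

# scanner pairs with fewer complete subjects than this report a missing Q
MIN_COMPLETE_SUBJECTS = 3


@dataclass
class RankingReport:
    """Q values for every (scanner pair, IDP) in a scanner subset."""

    Q: pd.DataFrame  # MultiIndex (scanner_a, scanner_b) x IDP columns
    subset_label: str

    def values_per_idp(self) -> pd.Series:
        """Median Q across scanner pairs, per IDP."""
        return self.Q.median(axis=0)

    def all_values(self) -> np.ndarray:
        v = self.Q.to_numpy(float).ravel()
        return v[np.isfinite(v)]


@dataclass
class NullBaseline:
    """Quartiles of the random-ranking Spearman distribution."""

    n_subjects: int
    n_draws: int
    seed: Optional[int]
    mode: str
    q25: float
    q50: float
    q75: float


def subject_vectors(
    study: StudyData, scanner: str, policy: str = "first"
) -> pd.DataFrame:
    """Per-IDP subject vectors for one scanner (subjects x IDPs).

    ``policy="first"`` takes each subject's repeat_index-0 session so repeat
    sessions never contribute; ``"mean-of-repeats"`` averages all of the
    subject's sessions on that scanner.  Subjects without a session on the
    scanner get a missing row, keeping the vector length constant.
    """
    sess = study.sessions
    if scanner not in set(sess["scanner_id"]):
        raise ContractError(f"unknown scanner {scanner!r}")
    if policy not in ("first", "mean-of-repeats"):
        raise ContractError(f"unknown policy {policy!r}")
    subjects = list(dict.fromkeys(sess["subject_id"]))
    on_scanner = sess[sess["scanner_id"] == scanner]
    rows = []
    for sub in subjects:
        grp = on_scanner[on_scanner["subject_id"] == sub]
        if policy == "first":
            grp = grp[grp["repeat_index"] == 0]
        if grp.empty:
            rows.append(pd.Series(np.nan, index=study.idps.columns))
        elif policy == "first":
            rows.append(study.idps.loc[grp["session_id"].iloc[0]].astype(float))
        else:
            rows.append(study.idps.loc[grp["session_id"]].astype(float).mean(axis=0))
    out = pd.DataFrame(rows, index=subjects)
    out.index.name = "subject_id"
    return out


def _columnwise_spearman(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman per column between two (subjects x IDPs) matrices, NaN-aware."""
    n_idp = a.shape[1]
    out = np.full(n_idp, np.nan)
    complete = np.isfinite(a) & np.isfinite(b)
    all_complete = complete.all(axis=0)
    # fast path: columns with no missing entries, ranked jointly
    if all_complete.any():
        ar = rankdata(a[:, all_complete], axis=0)
        br = rankdata(b[:, all_complete], axis=0)
        ac = ar - ar.mean(axis=0)
        bc = br - br.mean(axis=0)
        denom = np.sqrt((ac**2).sum(axis=0) * (bc**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (ac * bc).sum(axis=0) / denom
        out[all_complete] = rho
    for j in np.flatnonzero(~all_complete):
        if complete[:, j].sum() >= MIN_COMPLETE_SUBJECTS:
            out[j] = rank_correlation(a[:, j], b[:, j])
    return np.clip(out, -1.0, 1.0)


def ranking_consistency(
    study: StudyData,
    scanner_subset: Optional[Sequence[str]] = None,
    policy: str = "first",
    subset_label: Optional[str] = None,
) -> RankingReport:
    """Q[l, k, d] for all unordered scanner pairs in the subset.

    With six scanners the full subset yields 15 pairs; restricting to one
    vendor's three scanners yields 3.  Scanner pairs with fewer than
    ``MIN_COMPLETE_SUBJECTS`` jointly observed subjects for an IDP report a
    missing Q.
    """
    scanners = (
        list(scanner_subset)
        if scanner_subset is not None
        else list(dict.fromkeys(study.sessions["scanner_id"]))
    )
    if len(scanners) < 2:
        raise ContractError("scanner subset must contain >= 2 scanners")
    vectors = {s: subject_vectors(study, s, policy).to_numpy(float) for s in scanners}
    rows, index = [], []
    for l, k in itertools.combinations(scanners, 2):
        rows.append(_columnwise_spearman(vectors[l], vectors[k]))
        index.append((l, k))
    Q = pd.DataFrame(
        np.vstack(rows),
        index=pd.MultiIndex.from_tuples(index, names=["scanner_a", "scanner_b"]),
        columns=study.idps.columns,
    )
    return RankingReport(Q=Q, subset_label=subset_label or "all")


def _spearman_of_permutations(perms: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Spearman of each permutation row against the reference ranking."""
    n = len(reference)
    ref_c = reference - reference.mean()
    denom = (ref_c**2).sum()
    centred = perms - perms.mean(axis=1, keepdims=True)
    return (centred @ ref_c) / denom


def null_baseline(
    n_subjects: int,
    n_draws: int = 10_000,
    seed: Optional[int] = None,
    mode: str = "montecarlo",
) -> NullBaseline:
    """Quartiles of Spearman correlation between independent random rankings.

    ``exact`` enumerates all n! rank orderings against a fixed reference
    (n <= 8; identical in distribution to two independent permutations by
    exchangeability).  ``montecarlo`` draws ``n_draws`` independent
    permutation pairs with the given seed.
    """
    if n_subjects < 2:
        raise ContractError("n_subjects must be >= 2")
    ref = np.arange(1.0, n_subjects + 1)
    if mode == "exact":
        if n_subjects > 8:
            raise ContractError("exact enumeration is limited to n_subjects <= 8")
        perms = np.array(
            list(itertools.permutations(range(1, n_subjects + 1))), dtype=float
        )
        corr = _spearman_of_permutations(perms, ref)
        n_eff = len(perms)
    elif mode == "montecarlo":
        if seed is None:
            raise ContractError("montecarlo mode requires a seed")
        rng = np.random.default_rng(seed)
        perms = np.argsort(
            rng.random((n_draws, n_subjects)), axis=1
        ).astype(float) + 1.0
        other = np.argsort(rng.random((n_draws, n_subjects)), axis=1).astype(float) + 1.0
        centred_a = perms - perms.mean(axis=1, keepdims=True)
        centred_b = other - other.mean(axis=1, keepdims=True)
        denom = (centred_a[0] ** 2).sum()  # constant for permutations of 1..n
        corr = (centred_a * centred_b).sum(axis=1) / denom
        n_eff = n_draws
    else:
        raise ContractError(f"unknown mode {mode!r}")
    q25, q50, q75 = np.percentile(corr, [25, 50, 75])
    return NullBaseline(
        n_subjects=n_subjects,
        n_draws=n_eff,
        seed=seed,
        mode=mode,
        q25=float(q25),
        q50=float(q50),
        q75=float(q75),
    )
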