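"""Data model, TSV I/O and the shared Spearman primitive.

A *study* is a session table (one row per scan session, carrying subject,
scanner, site, vendor, repeat index and demographics), a wide table of
imaging-derived phenotypes (IDPs; sessions x features), an IDP category map,
and optionally a wide table of image-quality metrics (IQMs).  Every
downstream statistic indexes into this structure.

All tables are plain TSV: tab-separated, UTF-8, header row mandatory,
missing values written as ``NA``, '.' decimal.  Floats are written at full
repr precision so that write -> read round-trips are exact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HarmonyError",
    "SchemaError",
    "ReferentialError",
    "CategoryError",
    "ContractError",
    "SessionRecord",
    "CategoryMap",
    "StudyData",
    "SESSION_COLUMNS",
    "load_study",
    "write_table",
    "read_table",
    "rank_correlation",
]


class HarmonyError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(HarmonyError):
    """A required column is missing or has the wrong type."""


class ReferentialError(HarmonyError):
    """A table refers to a session that does not exist."""


class CategoryError(HarmonyError):
    """An IDP has no category, or a category is too small to rank."""


class ContractError(HarmonyError):
    """An operation was called with arguments violating its contract."""


#: required columns of the session table, in canonical order
SESSION_COLUMNS = (
    "session_id",
    "subject_id",
    "scanner_id",
    "site",
    "vendor",
    "repeat_index",
    "age",
    "sex",
)

#: sentinel written to TSV for missing values
NA_TOKEN = "NA"


@dataclass(frozen=True)
class SessionRecord:
    """One scan session.

    ``repeat_index`` 0 marks the subject's primary session on a scanner;
    values >= 1 are within-scanner repeats of that (subject, scanner) pair.
    """

    session_id: str
    subject_id: str
    scanner_id: str
    site: str
    vendor: str
    repeat_index: int
    age: float
    sex: str

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class CategoryMap:
    """Maps each IDP name to a correlation category, a display group and a modality.

    The *category* is the grouping over which per-session feature vectors are
    rank-correlated; the *group* is the coarser label used when aggregating
    reliability statistics for display.
    """

    entries: pd.DataFrame  # index: idp_name; columns: category, group, modality

    def __post_init__(self) -> None:
        required = {"category", "group", "modality"}
        missing = required - set(self.entries.columns)
        if missing:
            raise SchemaError(f"category map missing column(s): {sorted(missing)}")
        if self.entries.index.has_duplicates:
            dupes = self.entries.index[self.entries.index.duplicated()].tolist()
            raise SchemaError(f"duplicate IDP names in category map: {dupes[:5]}")

    @property
    def categories(self) -> list[str]:
        return sorted(self.entries["category"].unique())

    @property
    def groups(self) -> list[str]:
        return sorted(self.entries["group"].unique())

    def idps_in_category(self, category: str) -> list[str]:
        sel = self.entries.index[self.entries["category"] == category]
        return list(sel)

    def category_of(self, idp: str) -> str:
        return str(self.entries.at[idp, "category"])

    def group_of(self, idp: str) -> str:
        return str(self.entries.at[idp, "group"])

    def validate(self) -> None:
        counts = self.entries["category"].value_counts()
        if len(counts) < 1:
            raise CategoryError("category map is empty")
        small = counts[counts < 2]
        if len(small):
            raise CategoryError(
                "every category needs >= 2 IDPs (rank correlation over one point "
                f"is undefined); too small: {sorted(small.index.tolist())}"
            )


@dataclass
class StudyData:
    """Session metadata joined with the wide IDP (and optional IQM) matrix."""

    sessions: pd.DataFrame  # columns SESSION_COLUMNS, one row per session
    idps: pd.DataFrame  # index session_id, one column per IDP
    categories: CategoryMap
    iqms: Optional[pd.DataFrame] = None  # index session_id, one column per IQM

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    @property
    def session_ids(self) -> list[str]:
        return self.sessions["session_id"].tolist()

    def session_records(self) -> list[SessionRecord]:
        return [
            SessionRecord(
                session_id=str(r.session_id),
                subject_id=str(r.subject_id),
                scanner_id=str(r.scanner_id),
                site=str(r.site),
                vendor=str(r.vendor),
                repeat_index=int(r.repeat_index),
                age=float(r.age),
                sex=str(r.sex),
            )
            for r in self.sessions.itertuples(index=False)
        ]

    def with_idps(self, idps: pd.DataFrame) -> "StudyData":
        """Copy of the study with the IDP matrix replaced (same sessions)."""
        if not idps.index.equals(self.idps.index):
            raise ContractError("replacement IDP table must keep the session index")
        return StudyData(
            sessions=self.sessions.copy(),
            idps=idps.copy(),
            categories=self.categories,
            iqms=None if self.iqms is None else self.iqms.copy(),
        )

    def validate(self) -> None:
        missing_cols = [c for c in SESSION_COLUMNS if c not in self.sessions.columns]
        if missing_cols:
            raise SchemaError(f"session table missing column(s): {missing_cols}")
        sid = self.sessions["session_id"]
        if sid.duplicated().any():
            raise SchemaError(
                f"duplicate session_id: {sid[sid.duplicated()].tolist()[:5]}"
            )
        key = self.sessions[["subject_id", "scanner_id", "repeat_index"]]
        if key.duplicated().any():
            raise SchemaError("duplicate (subject_id, scanner_id, repeat_index)")
        # repeat indices must form 0..k with no gaps per (subject, scanner)
        for (sub, scan), grp in self.sessions.groupby(
            ["subject_id", "scanner_id"], sort=False
        ):
            reps = sorted(int(r) for r in grp["repeat_index"])
            if reps != list(range(len(reps))):
                raise SchemaError(
                    f"repeat_index for ({sub}, {scan}) is {reps}, expected "
                    f"0..{len(reps) - 1} with no gaps"
                )
        # referential integrity of the wide tables
        known = set(sid)
        for name, table in (("idps", self.idps), ("iqms", self.iqms)):
            if table is None:
                continue
            if table.index.has_duplicates:
                raise ReferentialError(f"duplicate session_id rows in {name}")
            unknown = set(table.index) - known
            if unknown:
                raise ReferentialError(
                    f"{name} rows reference unknown session(s): "
                    f"{sorted(unknown)[:5]}"
                )
        self.categories.validate()
        uncategorised = set(self.idps.columns) - set(self.categories.entries.index)
        if uncategorised:
            raise CategoryError(
                f"IDP column(s) absent from the category map: "
                f"{sorted(uncategorised)[:5]}"
            )


def _read_tsv(path: Path, index_col: Optional[int] = None) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        index_col=index_col,
        na_values=[NA_TOKEN],
        keep_default_na=False,
        float_precision="round_trip",
        dtype_backend="numpy_nullable",
    )


def load_study(
    sessions_path: str | Path,
    idps_path: str | Path,
    categories_path: str | Path,
    iqms_path: str | Path | None = None,
) -> StudyData:
    """Load and validate a study from its TSV tables.

    Rows of the IDP (and IQM) tables are reordered to match the session
    table; ``NA`` cells become missing values and survive round-trips.
    """
    sessions = pd.read_csv(
        Path(sessions_path),
        sep="\t",
        na_values=[NA_TOKEN],
        keep_default_na=False,
        float_precision="round_trip",
        dtype={
            "session_id": str,
            "subject_id": str,
            "scanner_id": str,
            "site": str,
            "vendor": str,
            "sex": str,
        },
    )
    missing_cols = [c for c in SESSION_COLUMNS if c not in sessions.columns]
    if missing_cols:
        raise SchemaError(f"session table missing column(s): {missing_cols}")
    sessions = sessions[list(SESSION_COLUMNS)]

    idps = _read_tsv(Path(idps_path), index_col=0).astype(float)
    cats = _read_tsv(Path(categories_path), index_col=0)
    cats.index = cats.index.astype(str)
    cats = cats.astype(str)
    categories = CategoryMap(entries=cats)

    iqms = None
    if iqms_path is not None:
        iqms = _read_tsv(Path(iqms_path), index_col=0).astype(float)

    study = StudyData(sessions=sessions, idps=idps, categories=categories, iqms=iqms)
    study.validate()
    order = sessions["session_id"].tolist()
    study.idps = study.idps.reindex(order)
    if study.iqms is not None:
        study.iqms = study.iqms.reindex(order)
    return study


def write_table(table: pd.DataFrame | pd.Series, path: str | Path) -> None:
    """Write a rectangular result as TSV in the package dialect.

    Tab-separated, ``NA`` for missing, '.' decimal, full repr precision so a
    read-back reproduces the written values bit-for-bit.
    """
    if isinstance(table, pd.Series):
        table = table.to_frame()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # %.17g round-trips any double exactly
    table.to_csv(path, sep="\t", na_rep=NA_TOKEN, index=True, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table` (first column = labels)."""
    return pd.read_csv(
        Path(path),
        sep="\t",
        index_col=0,
        na_values=[NA_TOKEN],
        keep_default_na=False,
        float_precision="round_trip",
    )


def write_study(study: StudyData, out_dir: str | Path) -> dict[str, Path]:
    """Write the study's tables under ``out_dir``; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sessions": out / "sessions.tsv",
        "idps": out / "idps.tsv",
        "idp_categories": out / "idp_categories.tsv",
    }
    study.sessions.to_csv(
        paths["sessions"], sep="\t", na_rep=NA_TOKEN, index=False, float_format="%.17g"
    )
    idps = study.idps.copy()
    idps.index.name = "session_id"
    write_table(idps, paths["idps"])
    cats = study.categories.entries.copy()
    cats.index.name = "idp_name"
    write_table(cats, paths["idp_categories"])
    if study.iqms is not None:
        paths["iqms"] = out / "iqms.tsv"
        iqms = study.iqms.copy()
        iqms.index.name = "session_id"
        write_table(iqms, paths["iqms"])
    return paths


def load_study_dir(study_dir: str | Path) -> StudyData:
    """Load a study written by :func:`write_study`."""
    d = Path(study_dir)
    iqms = d / "iqms.tsv"
    return load_study(
        d / "sessions.tsv",
        d / "idps.tsv",
        d / "idp_categories.tsv",
        iqms if iqms.exists() else None,
    )


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Pairs where either value is missing are dropped before ranking
    (pairwise-complete deletion).  Returns NaN (the undefined marker) when
    fewer than two complete pairs remain or when either sequence is constant
    after dropping, so a degenerate input propagates as missing rather than
    masquerading as "no association".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError(
            f"rank_correlation needs two equal-length 1-d sequences, "
            f"got shapes {x.shape} and {y.shape}"
        )
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 2:
        return float("nan")
    xs, ys = x[mask], y[mask]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan")
    rho = stats.spearmanr(xs, ys).statistic
    return float(rho)
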