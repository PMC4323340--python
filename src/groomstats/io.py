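"""Readers and writers for observation logs, rosters and sociometric matrices.

All files are plain UTF-8 CSV with fixed headers and "." as the decimal
separator. Times are seconds from session start (floats). Seasons are opaque
string labels, never parsed as dates. Readers validate and reject rather than
coerce; every writer produces files its reader accepts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MatrixFormatError, SchemaError

__all__ = [
    "BEHAVIORS",
    "SCAN_STATES",
    "SociometricMatrix",
    "read_event_log",
    "write_event_log",
    "read_scan_log",
    "write_scan_log",
    "read_roster",
    "write_roster",
    "read_sessions",
    "write_sessions",
    "read_matrix",
    "write_matrix",
    "observation_time",
]

#: Closed vocabulary of focal-continuous behaviors.
BEHAVIORS = frozenset({"approach", "displacement", "groom", "aggression"})

#: Closed vocabulary of instantaneous-scan states.
SCAN_STATES = frozenset({"contact", "proximity", "co-provisioning"})

EVENT_COLUMNS = [
    "season",
    "session_id",
    "focal_id",
    "actor_id",
    "recipient_id",
    "behavior",
    "start",
    "end",
]
SCAN_COLUMNS = ["season", "session_id", "focal_id", "partner_id", "state", "scan_time"]
ROSTER_COLUMNS = ["individual_id", "age", "matriline_id", "mother_id"]
SESSION_COLUMNS = ["season", "session_id", "focal_id", "duration_min"]

_STR_DTYPES = {
    "season": str,
    "session_id": str,
    "focal_id": str,
    "actor_id": str,
    "recipient_id": str,
    "partner_id": str,
    "behavior": str,
    "state": str,
    "individual_id": str,
    "matriline_id": str,
    "mother_id": str,
}


def _read_csv(path, columns) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={c: _STR_DTYPES[c] for c in columns if c in _STR_DTYPES})
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df[columns]


def _row(i: int) -> str:
    # 1-based data-row number as a user would count it in the file body
    return f"row {i + 1}"


def read_event_log(path) -> pd.DataFrame:
    """Read a focal-continuous event log.

    Columns: season, session_id, focal_id, actor_id, recipient_id,
    behavior, start, end. ``end`` is required for groom rows (seconds) and
    may be empty otherwise.
    """
    df = _read_csv(path, EVENT_COLUMNS)
    for i, rec in enumerate(df.itertuples(index=False)):
        if rec.behavior not in BEHAVIORS:
            raise SchemaError(
                f"{path}: unknown behavior {rec.behavior!r} at {_row(i)}"
            )
        if rec.actor_id == rec.recipient_id:
            raise SchemaError(f"{path}: actor == recipient at {_row(i)}")
        if pd.isna(rec.start):
            raise SchemaError(f"{path}: missing start at {_row(i)}")
        if rec.behavior == "groom":
            if pd.isna(rec.end):
                raise SchemaError(f"{path}: groom row missing end at {_row(i)}")
            if rec.end < rec.start:
                raise SchemaError(f"{path}: end < start at {_row(i)}")
        elif not pd.isna(rec.end) and rec.end < rec.start:
            raise SchemaError(f"{path}: end < start at {_row(i)}")
    return df.reset_index(drop=True)


def write_event_log(log: pd.DataFrame, path) -> None:
    log[EVENT_COLUMNS].to_csv(path, index=False)


def read_scan_log(path) -> pd.DataFrame:
    """Read an instantaneous-scan log (one row per non-alone scan)."""
    df = _read_csv(path, SCAN_COLUMNS)
    for i, rec in enumerate(df.itertuples(index=False)):
        if rec.state not in SCAN_STATES:
            raise SchemaError(f"{path}: unknown state {rec.state!r} at {_row(i)}")
        if rec.focal_id == rec.partner_id:
            raise SchemaError(f"{path}: focal == partner at {_row(i)}")
        if pd.isna(rec.scan_time):
            raise SchemaError(f"{path}: missing scan_time at {_row(i)}")
    return df.reset_index(drop=True)


def write_scan_log(log: pd.DataFrame, path) -> None:
    log[SCAN_COLUMNS].to_csv(path, index=False)


def read_roster(path) -> pd.DataFrame:
    """Read the individual roster (id, age, matriline, optional mother)."""
    df = _read_csv(path, ROSTER_COLUMNS)
    if df["individual_id"].duplicated().any():
        dup = df.loc[df["individual_id"].duplicated(), "individual_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate individual_id {dup!r}")
    if (df["age"] < 0).any():
        i = int(np.argmax(df["age"].to_numpy() < 0))
        raise SchemaError(f"{path}: negative age at {_row(i)}")
    return df.reset_index(drop=True)


def write_roster(roster: pd.DataFrame, path) -> None:
    roster[ROSTER_COLUMNS].to_csv(path, index=False)


def read_sessions(path) -> pd.DataFrame:
    """Read the focal-session table (one row per 30-min follow)."""
    df = _read_csv(path, SESSION_COLUMNS)
    if (df["duration_min"] <= 0).any():
        i = int(np.argmax(df["duration_min"].to_numpy() <= 0))
        raise SchemaError(f"{path}: non-positive duration at {_row(i)}")
    return df.reset_index(drop=True)


def write_sessions(sessions: pd.DataFrame, path) -> None:
    sessions[SESSION_COLUMNS].to_csv(path, index=False)


@dataclass
class SociometricMatrix:
    """Square actor x recipient matrix of counts or minutes.

    Rows are actors (or focals), columns recipients (or partners). The
    diagonal is stored as zero and never read.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise MatrixFormatError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if (self.values < 0).any():
            raise MatrixFormatError("negative entry in sociometric matrix")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def reindex(self, ids: list[str]) -> "SociometricMatrix":
        """Return the same matrix with rows/columns in a new id order."""
        pos = {x: i for i, x in enumerate(self.ids)}
        try:
            idx = np.array([pos[x] for x in ids])
        except KeyError as e:
            raise KeyError(f"id {e.args[0]!r} not present in matrix") from None
        return SociometricMatrix(list(ids), self.values[np.ix_(idx, idx)])


def read_matrix(path) -> SociometricMatrix:
    """Read a square CSV with an id header row and id first column.

    Row/column id order is preserved exactly as in the file.
    """
    df = pd.read_csv(path, index_col=0)
    col_ids = [str(c) for c in df.columns]
    row_ids = [str(r) for r in df.index]
    if len(col_ids) != len(row_ids):
        raise MatrixFormatError(
            f"{path}: {len(row_ids)} rows but {len(col_ids)} columns"
        )
    if col_ids != row_ids:
        raise MatrixFormatError(f"{path}: row ids do not match column ids")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise MatrixFormatError(f"{path}: non-numeric or missing entry")
    if (values < 0).any():
        raise MatrixFormatError(f"{path}: negative entry")
    return SociometricMatrix(row_ids, values)


def write_matrix(matrix: SociometricMatrix, path) -> None:
    matrix.to_dataframe().to_csv(path)


def observation_time(sessions: pd.DataFrame, roster: pd.DataFrame | None = None) -> pd.Series:
    """Focal observation hours per individual per season.

    Returns a Series indexed by (season, individual_id). When a roster is
    supplied every session focal must appear in it, and individuals with no
    sessions get explicit zeros.
    """
    if roster is not None:
        known = set(roster["individual_id"])
        unknown = set(sessions["focal_id"]) - known
        if unknown:
            raise KeyError(
                f"session focal(s) absent from roster: {sorted(unknown)}"
            )
    hours = (
        sessions.groupby(["season", "focal_id"])["duration_min"].sum() / 60.0
    )
    hours.index = hours.index.set_names(["season", "individual_id"])
    if roster is not None and len(sessions):
        seasons = sessions["season"].unique()
        full = pd.MultiIndex.from_product(
            [seasons, sorted(known)], names=["season", "individual_id"]
        )
        hours = hours.reindex(full, fill_value=0.0)
    return hours.rename("hours")
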