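"""Directed affiliation measures from focal event and scan logs.

Grooming segments of the same directed pair in the same session are merged
into *acts* whenever the pause between them is shorter than 20 s (a grooming
act counts as terminated once it stops for >= 20 s); act duration sums the
active segments only, never the pauses.

Rates are normalized by the *combined* focal observation time of the two
individuals in a dyad, because a directed interaction A->B is observable
whenever either member is the focal animal:

* grooming_rate  = acts(A->B) / (hours_A + hours_B)   [acts per hour]
* grooming_time  = minutes(A->B) / (hours_A + hours_B) [min per hour]
* aggression received on the (A, B) row = acts(B->A) / (hours_A + hours_B)

Scan-derived time uses count x scan interval, summing both focal
perspectives of a dyad; co-provisioning is expressed as a percentage of all
scans in which either member was the focal.

The friendship index of A toward B is A's contact time with B divided by
A's mean contact time with all other females — an asymmetric matrix whose
rows (where defined) average 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError
from .io import SociometricMatrix

__all__ = [
    "BOUT_TERMINATION_S",
    "FriendshipMatrix",
    "merge_grooming_bouts",
    "grooming_measures",
    "aggression_rate",
    "scan_time_matrices",
    "interaction_matrix",
    "friendship_index",
    "friendship_measure_correlations",
]

#: A grooming act is terminated once it pauses for at least this many seconds.
BOUT_TERMINATION_S = 20.0


@dataclass
class FriendshipMatrix:
    """Asymmetric dyadic friendship index; row off-diagonal means are 1."""

    ids: list[str]
    values: np.ndarray
    basis: str = "contact"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def merge_grooming_bouts(events: pd.DataFrame) -> pd.DataFrame:
    """Merge groom segments into acts using the 20 s termination rule.

    Segments of the same directed pair within the same session, sorted by
    start time, are chained while the gap to the previous segment is < 20 s.
    Returns one row per act: season, session_id, groomer_id, groomee_id,
    start, end, duration_s (sum of segment lengths), n_segments.

    Raises ``DataError`` on overlapping segments for the same directed pair.
    """
    groom = events[events["behavior"] == "groom"]
    acts = []
    keys = ["season", "session_id", "actor_id", "recipient_id"]
    for (season, session, actor, recipient), g in groom.groupby(keys, sort=True):
        g = g.sort_values("start", kind="mergesort")
        cur = None
        for rec in g.itertuples(index=False):
            if rec.end < rec.start:
                raise DataError(
                    f"groom segment with end < start for {actor}->{recipient} "
                    f"in session {session}"
                )
            if cur is None:
                cur = [rec.start, rec.end, rec.end - rec.start, 1]
                continue
            gap = rec.start - cur[1]
            if gap < 0:
                raise DataError(
                    f"overlapping groom segments for {actor}->{recipient} "
                    f"in session {session}"
                )
            if gap < BOUT_TERMINATION_S:
                cur[1] = rec.end
                cur[2] += rec.end - rec.start
                cur[3] += 1
            else:
                acts.append((season, session, actor, recipient, *cur))
                cur = [rec.start, rec.end, rec.end - rec.start, 1]
        if cur is not None:
            acts.append((season, session, actor, recipient, *cur))
    return pd.DataFrame(
        acts,
        columns=[
            "season", "session_id", "groomer_id", "groomee_id",
            "start", "end", "duration_s", "n_segments",
        ],
    )


def _combined_hours(obs_hours: pd.Series, season: str, a: str, b: str) -> float:
    return float(obs_hours[(season, a)] + obs_hours[(season, b)])


def _directed_index(obs_hours: pd.Series, ids: list[str]) -> pd.DataFrame:
    seasons = sorted(obs_hours.index.get_level_values("season").unique())
    rows = [
        (s, a, b)
        for s in seasons
        for a in ids
        for b in ids
        if a != b
    ]
    return pd.DataFrame(rows, columns=["season", "groomer_id", "groomee_id"])


def grooming_measures(
    bouts: pd.DataFrame, obs_hours: pd.Series, ids: list[str]
) -> pd.DataFrame:
    """Directed grooming rate and time per season, zeros included.

    ``bouts`` is the output of :func:`merge_grooming_bouts`; ``obs_hours``
    the Series from :func:`groomstats.io.observation_time`.
    """
    out = _directed_index(obs_hours, ids)
    agg = (
        bouts.groupby(["season", "groomer_id", "groomee_id"])
        .agg(n_acts=("duration_s", "size"), seconds=("duration_s", "sum"))
        .reset_index()
    )
    out = out.merge(agg, how="left", on=["season", "groomer_id", "groomee_id"])
    out[["n_acts", "seconds"]] = out[["n_acts", "seconds"]].fillna(0.0)
    hours = np.array(
        [
            _combined_hours(obs_hours, s, a, b)
            for s, a, b in zip(out["season"], out["groomer_id"], out["groomee_id"])
        ]
    )
    if (hours <= 0).any():
        raise DataError("zero combined observation time for some dyad/season")
    out["grooming_rate"] = out["n_acts"] / hours
    out["grooming_time"] = out["seconds"] / 60.0 / hours
    return out.drop(columns=["seconds"])


def aggression_rate(
    events: pd.DataFrame, obs_hours: pd.Series, ids: list[str]
) -> pd.DataFrame:
    """Aggression *received* per directed dyad row.

    The (A, B) row carries the rate of aggression B->A — what the groomer A
    receives from the groomee B — per combined observation hour.
    """
    out = _directed_index(obs_hours, ids)
    aggr = events[events["behavior"] == "aggression"]
    counts = (
        aggr.groupby(["season", "actor_id", "recipient_id"])
        .size()
        .rename("k")
        .reset_index()
        # B->A aggression belongs on the (A, B) row
        .rename(columns={"actor_id": "groomee_id", "recipient_id": "groomer_id"})
    )
    out = out.merge(counts, how="left", on=["season", "groomer_id", "groomee_id"])
    out["k"] = out["k"].fillna(0.0)
    hours = np.array(
        [
            _combined_hours(obs_hours, s, a, b)
            for s, a, b in zip(out["season"], out["groomer_id"], out["groomee_id"])
        ]
    )
    if (hours <= 0).any():
        raise DataError("zero combined observation time for some dyad/season")
    out["aggression_received"] = out["k"] / hours
    return out.drop(columns=["k"])


def scan_time_matrices(
    scans: pd.DataFrame,
    scan_interval: float,
    sessions: pd.DataFrame,
    ids: list[str],
) -> dict[str, dict[str, SociometricMatrix]]:
    """Symmetric scan-state matrices per season.

    ``contact`` and ``proximity`` are minutes (scan count x interval, both
    focal perspectives summed); ``co_provisioning_pct`` is 100 x the dyad's
    co-provisioning scans over all scans in which either member was focal.
    """
    if scan_interval <= 0:
        raise ConfigurationError("scan_interval must be > 0")
    pos = {x: i for i, x in enumerate(ids)}
    n = len(ids)
    seasons = sorted(sessions["season"].unique())
    scans_per_focal = (
        sessions.groupby(["season", "focal_id"])["duration_min"].sum() / scan_interval
    )
    out: dict[str, dict[str, SociometricMatrix]] = {}
    for season in seasons:
        sub = scans[scans["season"] == season]
        mats = {
            "contact": np.zeros((n, n)),
            "proximity": np.zeros((n, n)),
            "co-provisioning": np.zeros((n, n)),
        }
        for rec in sub.itertuples(index=False):
            if rec.focal_id not in pos or rec.partner_id not in pos:
                continue
            mats[rec.state][pos[rec.focal_id], pos[rec.partner_id]] += 1
        result: dict[str, SociometricMatrix] = {}
        for state in ("contact", "proximity"):
            sym = (mats[state] + mats[state].T) * scan_interval
            result[state] = SociometricMatrix(list(ids), sym)
        denom = np.zeros((n, n))
        for a in ids:
            for b in ids:
                if a == b:
                    continue
                denom[pos[a], pos[b]] = float(
                    scans_per_focal.get((season, a), 0.0)
                    + scans_per_focal.get((season, b), 0.0)
                )
        cop = mats["co-provisioning"] + mats["co-provisioning"].T
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(denom > 0, 100.0 * cop / np.where(denom > 0, denom, 1), 0.0)
        np.fill_diagonal(pct, 0.0)
        result["co_provisioning_pct"] = SociometricMatrix(list(ids), pct)
        out[season] = result
    return out


def interaction_matrix(
    events: pd.DataFrame,
    behavior: str,
    season: str,
    ids: list[str],
    weight: str = "count",
) -> SociometricMatrix:
    """Symmetrized dyadic totals of a focal-continuous behavior.

    ``weight="count"`` sums event counts; ``weight="minutes"`` sums groom
    durations. Both directions of a dyad are pooled (the matrix is
    symmetric), matching how the scan-based time matrices are built.
    """
    pos = {x: i for i, x in enumerate(ids)}
    n = len(ids)
    sub = events[(events["behavior"] == behavior) & (events["season"] == str(season))]
    m = np.zeros((n, n))
    for rec in sub.itertuples(index=False):
        if rec.actor_id not in pos or rec.recipient_id not in pos:
            continue
        if weight == "minutes":
            w = (rec.end - rec.start) / 60.0
        else:
            w = 1.0
        m[pos[rec.actor_id], pos[rec.recipient_id]] += w
    sym = m + m.T
    return SociometricMatrix(list(ids), sym)


def friendship_index(
    time_matrix: SociometricMatrix, basis: str = "contact"
) -> FriendshipMatrix:
    """Asymmetric friendship index from a dyadic time (or count) matrix.

    F(A, B) = time(A, B) / mean over C != A of time(A, C). Rows with no
    recorded time at all get F = 0 everywhere and trigger a warning.
    """
    if time_matrix.n < 2:
        raise DataError("friendship index needs at least 2 individuals")
    m = time_matrix.values.copy()
    np.fill_diagonal(m, 0.0)
    n = time_matrix.n
    denom = m.sum(axis=1) / (n - 1)
    zero_rows = denom == 0
    if zero_rows.any():
        bad = [time_matrix.ids[i] for i in np.flatnonzero(zero_rows)]
        warnings.warn(
            f"no recorded {basis} time for {bad}; their friendship rows are 0",
            stacklevel=2,
        )
    f = np.where(zero_rows[:, None], 0.0, m / np.where(zero_rows, 1.0, denom)[:, None])
    np.fill_diagonal(f, 0.0)
    return FriendshipMatrix(list(time_matrix.ids), f, basis)


def friendship_measure_correlations(
    matrices: dict[str, FriendshipMatrix]
) -> pd.DataFrame:
    """Spearman correlations between friendship bases over directed dyads."""
    names = list(matrices)
    n = matrices[names[0]].values.shape[0]
    mask = ~np.eye(n, dtype=bool)
    vecs = {k: matrices[k].values[mask] for k in names}
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            if np.ptp(vecs[a]) == 0 or np.ptp(vecs[b]) == 0:
                warnings.warn(
                    f"spearman rho undefined for constant basis ({a} vs {b})",
                    stacklevel=2,
                )
                rho = np.nan
            else:
                rho = stats.spearmanr(vecs[a], vecs[b]).statistic
            out.loc[a, b] = out.loc[b, a] = rho
    return out
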