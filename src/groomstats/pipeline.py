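"""End-to-end chain: logs -> dominance -> affiliation -> dyad table -> fits."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import affiliation, dominance, model
from .io import observation_time

__all__ = ["StudyResult", "analyze_study"]


@dataclass
class StudyResult:
    obs_hours: pd.Series
    dominance: dict[str, dominance.DominanceSummary]
    measures: pd.DataFrame
    friendship: dict[str, affiliation.FriendshipMatrix]
    dyad_table: pd.DataFrame
    fits: dict[str, model.ModelFit] = field(default_factory=dict)


def analyze_study(
    events: pd.DataFrame,
    scans: pd.DataFrame,
    sessions: pd.DataFrame,
    roster: pd.DataFrame,
    *,
    scan_interval: float = 2.0,
    n_randomizations: int = 1000,
    seed: int | None = 0,
    responses: tuple[str, ...] = ("rate",),
    split: bool = False,
    offset: float | None = None,
    lrt: bool = True,
    friendship_basis: str = "contact",
) -> StudyResult:
    """Run the full analysis on one study's logs.

    ``responses`` selects which grooming measures to model; with
    ``split=True`` each response is additionally refitted on the low/high
    rank-distance subsets (threshold = pooled mean rank distance).
    """
    ids = list(roster["individual_id"])
    seasons = sorted(sessions["season"].unique())
    hours = observation_time(sessions, roster)

    dom: dict[str, dominance.DominanceSummary] = {}
    nds: dict[str, pd.Series] = {}
    for season in seasons:
        m = dominance.build_displacement_matrix(events, season, roster=roster)
        summary = dominance.summarize_dominance(
            m, n_randomizations=n_randomizations, seed=seed
        )
        dom[season] = summary
        nds[season] = summary.scores.set_index("id")["NDS"]

    bouts = affiliation.merge_grooming_bouts(events)
    measures = affiliation.grooming_measures(bouts, hours, ids)
    aggr = affiliation.aggression_rate(events, hours, ids)
    scan_mats = affiliation.scan_time_matrices(scans, scan_interval, sessions, ids)

    friendship: dict[str, affiliation.FriendshipMatrix] = {}
    coprov: dict[str, object] = {}
    for season in seasons:
        basis_key = "contact" if friendship_basis == "contact" else friendship_basis
        if friendship_basis in ("contact", "proximity"):
            basis_matrix = scan_mats[season][friendship_basis]
        elif friendship_basis == "approach":
            basis_matrix = affiliation.interaction_matrix(
                events, "approach", season, ids
            )
        elif friendship_basis == "grooming":
            basis_matrix = affiliation.interaction_matrix(
                events, "groom", season, ids, weight="minutes"
            )
        else:
            raise ValueError(f"unknown friendship basis {friendship_basis!r}")
        friendship[season] = affiliation.friendship_index(basis_matrix, basis_key)
        coprov[season] = scan_mats[season]["co_provisioning_pct"]

    table = model.assemble_dyad_table(measures, aggr, friendship, nds, coprov, roster)

    fits: dict[str, model.ModelFit] = {}
    for resp in responses:
        fits[resp] = model.fit_lmm(table, response=resp, offset=offset, lrt=lrt)
        if split:
            low, high, _thr = model.split_by_rank_distance(table)
            fits[f"{resp}_low_rank_distance"] = model.fit_lmm(
                low, response=resp, offset=offset, lrt=lrt
            )
            fits[f"{resp}_high_rank_distance"] = model.fit_lmm(
                high, response=resp, offset=offset, lrt=lrt
            )

    return StudyResult(
        obs_hours=hours,
        dominance=dom,
        measures=measures,
        friendship=friendship,
        dyad_table=table,
        fits=fits,
    )
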