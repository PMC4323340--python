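"""Focal-sampling simulator with known ground-truth social structure.

The generator emulates the observation design of a semi-free-ranging troop
of adult female macaques: continuous focal sessions (default 30 min, tiled
to an exact per-season focal-hour budget) during which directed events
(approach, displacement, groom, aggression) are recorded, plus instantaneous
scans of the focal's spatial state (contact / proximity / co-provisioning)
every 2 minutes.

Ground truth consists of a latent linear dominance hierarchy, a maternal kin
structure (matrilines), and a symmetric positive dyadic affinity matrix.
Directed grooming is a homogeneous count process whose log-rate is linear in
kinship, the groomer's relative rank, and the affinity-derived friendship
index, plus crossed actor/receiver intercepts and a symmetric dyadic effect
(the reciprocity channel). Displacements run down the latent hierarchy with
configurable directional consistency; aggression and approaches scale with
affinity; scan states are sampled per scan with probability proportional to
affinity.

Every draw comes from one of several RNG streams seeded from the master seed
by fixed offsets, so adding a behavior never shifts existing draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EffectConfig, GroupConfig
from .errors import ConfigurationError

__all__ = [
    "GroundTruth",
    "generate_group",
    "simulate_study",
    "friendship_from_affinity",
    "write_ground_truth",
    "read_ground_truth",
]

# RNG stream offsets (fixed; see module docstring)
_STREAM_GROUP = 1
_STREAM_DISPLACEMENT = 2
_STREAM_GROOM = 3
_STREAM_SCAN = 4
_STREAM_AGGRESSION = 5
_STREAM_APPROACH = 6

# Scan-state composition: fraction of scans in any social state, and the
# split of social scans among the three mutually exclusive states. Contact
# dominates so that the contact-based friendship index is well estimated;
# co-provisioning is rare (a single provisioned food patch).
_SOCIAL_SCAN_FRACTION = 0.3
_STATE_PROBS = {"contact": 0.5, "proximity": 0.4, "co-provisioning": 0.1}

# Affinity model: log-affinity = kin boost + symmetric Gaussian noise.
_KIN_AFFINITY = 1.0
_AFFINITY_SD = 0.8

# Acts of the same directed pair placed in one session keep at least this
# gap so the >=20 s termination rule never merges distinct simulated acts.
_ACT_GAP_S = 21.0


@dataclass
class GroundTruth:
    """Latent structure behind a simulated study."""

    latent_rank: list[str]  # ids from most dominant to least
    kin_pairs: set[frozenset]
    affinity: pd.DataFrame  # symmetric, positive off-diagonal
    true_betas: EffectConfig

    def rank_position(self) -> dict[str, int]:
        """1-based rank position per id (1 = most dominant)."""
        return {x: i + 1 for i, x in enumerate(self.latent_rank)}


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


def friendship_from_affinity(affinity: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize an affinity matrix into the asymmetric friendship index.

    F(A,B) = affinity(A,B) / mean over C != A of affinity(A,C); each row's
    off-diagonal mean is 1 by construction.
    """
    a = affinity.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    denom = a.sum(axis=1) / (n - 1)
    f = a / denom[:, None]
    np.fill_diagonal(f, 0.0)
    return pd.DataFrame(f, index=affinity.index, columns=affinity.columns)


def generate_group(config: GroupConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Create a roster and its latent social structure.

    The roster holds one adult female per row (id, age, matriline, mother).
    Within each matriline the oldest female is the mother of the rest, so
    every within-matriline pair is maternal kin (mother-daughter or
    sister-sister). The latent rank order lists matrilines in blocks —
    the nepotistic pattern in which maternal kin hold adjacent ranks —
    and kin therefore tend to be close in rank, as in real macaque troops.
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_GROUP)
    n = config.n_females
    ids = [f"F{i + 1:02d}" for i in range(n)]

    if config.ages is not None:
        ages = list(config.ages)
    else:
        ages = sorted(rng.integers(3, 27, size=n).tolist(), reverse=True)

    rows = []
    kin_pairs: set[frozenset] = set()
    k = 0
    for m, size in enumerate(config.matriline_sizes):
        members = ids[k : k + size]
        member_ages = sorted(ages[k : k + size], reverse=True)
        mother = members[0]
        for j, (ind, age) in enumerate(zip(members, member_ages)):
            rows.append(
                {
                    "individual_id": ind,
                    "age": float(age),
                    "matriline_id": f"M{m + 1}",
                    "mother_id": "" if j == 0 else mother,
                }
            )
        for a in range(size):
            for b in range(a + 1, size):
                kin_pairs.add(frozenset((members[a], members[b])))
        k += size
    roster = pd.DataFrame(rows)

    # Matriline-block rank order, matriline precedence randomized.
    order = rng.permutation(len(config.matriline_sizes))
    latent_rank: list[str] = []
    starts = np.concatenate([[0], np.cumsum(config.matriline_sizes)])
    for m in order:
        latent_rank.extend(ids[starts[m] : starts[m + 1]])

    kin = np.zeros((n, n))
    pos = {x: i for i, x in enumerate(ids)}
    for pair in kin_pairs:
        a, b = sorted(pair)
        kin[pos[a], pos[b]] = kin[pos[b], pos[a]] = 1.0
    noise = rng.normal(0.0, _AFFINITY_SD, size=(n, n))
    log_aff = _KIN_AFFINITY * kin + (noise + noise.T) / np.sqrt(2.0)
    affinity = np.exp(log_aff)
    np.fill_diagonal(affinity, 0.0)
    affinity_df = pd.DataFrame(affinity, index=ids, columns=ids)

    truth = GroundTruth(
        latent_rank=latent_rank,
        kin_pairs=kin_pairs,
        affinity=affinity_df,
        true_betas=EffectConfig(),
    )
    return roster, truth


def _place_point_events(rng, counts, ids, focal, season, behavior, n_sessions,
                        session_len_s, session_label):
    """Scatter point events (no duration) uniformly over the focal's sessions."""
    rows = []
    for (a, b), k in counts:
        if k == 0:
            continue
        sess = rng.integers(0, n_sessions, size=k)
        starts = rng.uniform(0.0, session_len_s, size=k)
        for s, t in zip(sess, starts):
            rows.append(
                (season, session_label(s), focal, a, b, behavior,
                 float(t), np.nan)
            )
    return rows


def _place_groom_events(rng, counts, focal, season, mean_bout_s, n_sessions,
                        session_len_s, session_label):
    """Place grooming acts in sessions, same-pair acts in disjoint slots.

    Acts of one directed pair falling in the same session are laid out in
    equal sub-slots with a >=21 s trailing margin, so distinct acts are never
    closer than the 20 s termination threshold.
    """
    rows = []
    for (a, b), k in counts:
        if k == 0:
            continue
        sess = rng.integers(0, n_sessions, size=k)
        for s in np.unique(sess):
            m = int((sess == s).sum())
            slot = session_len_s / m
            for q in range(m):
                lo = q * slot
                hi = (q + 1) * slot - _ACT_GAP_S
                start = float(rng.uniform(lo, max(lo + 1.0, hi - 1.0)))
                dur = float(rng.exponential(mean_bout_s))
                end = min(start + max(dur, 1.0), hi)
                if end <= start:
                    end = start + 1.0
                rows.append(
                    (season, session_label(s), focal, a, b, "groom",
                     start, end)
                )
    return rows


def simulate_study(
    roster: pd.DataFrame,
    truth: GroundTruth,
    effects: EffectConfig,
    config: GroupConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate focal event and scan logs for the whole study.

    Returns ``(events, scans, sessions)``. Directed events involving a dyad
    are generated during the focal time of *either* member, so a dyad's total
    exposure is the sum of both members' focal hours — matching how observed
    rates are normalized downstream. Reproducible given ``config.seed``.
    """
    config.validate()
    effects.validate()
    ids = list(roster["individual_id"])
    n = len(ids)
    pos = {x: i for i, x in enumerate(ids)}

    rankpos = truth.rank_position()
    sub = np.zeros((n, n))  # sub[i, j] = 1 if i subordinate to j
    for i in ids:
        for j in ids:
            if i != j and rankpos[i] > rankpos[j]:
                sub[pos[i], pos[j]] = 1.0
    kin = np.zeros((n, n))
    for pair in truth.kin_pairs:
        a, b = sorted(pair)
        kin[pos[a], pos[b]] = kin[pos[b], pos[a]] = 1.0
    f_true = friendship_from_affinity(truth.affinity).to_numpy()

    rng_groom = _rng(config.seed, _STREAM_GROOM)
    a_eff = rng_groom.normal(0.0, effects.actor_sd, size=n)
    r_eff = rng_groom.normal(0.0, effects.receiver_sd, size=n)
    d_noise = rng_groom.normal(0.0, effects.dyad_reciprocity_sd, size=(n, n))
    d_eff = np.triu(d_noise, 1)
    d_eff = d_eff + d_eff.T

    log_lam = (
        effects.beta0
        + effects.beta_kin * kin
        + effects.beta_sub * sub
        + effects.beta_friend * f_true
        + d_eff
        + a_eff[:, None]
        + r_eff[None, :]
    )
    lam = np.exp(log_lam)  # acts per dyad-hour observed
    np.fill_diagonal(lam, 0.0)

    aggr = effects.aggression_affinity_coupling * f_true
    appr = effects.approach_rate * f_true
    total_rate = lam + aggr + appr + effects.displacement_rate
    if np.nanmax(total_rate) > 3600.0:
        raise ConfigurationError(
            "simulated event rates exceed one expected event per second; "
            "check beta0 and the per-behavior rates"
        )

    rng_disp = _rng(config.seed, _STREAM_DISPLACEMENT)
    rng_aggr = _rng(config.seed, _STREAM_AGGRESSION)
    rng_appr = _rng(config.seed, _STREAM_APPROACH)
    rng_scan = _rng(config.seed, _STREAM_SCAN)

    n_sessions = config.sessions_per_season
    session_len_s = config.session_length * 60.0
    scans_per_session = config.scans_per_session
    hours = config.focal_hours_per_female

    mean_bout_s = effects.mean_groom_bout_min * 60.0
    state_names = list(_STATE_PROBS)
    state_p = np.array([_STATE_PROBS[s] for s in state_names])

    event_rows: list[tuple] = []
    scan_rows: list[tuple] = []
    session_rows: list[dict] = []

    for season_idx in range(config.seasons):
        season = str(season_idx + 1)
        for f in ids:
            fi = pos[f]
            label = lambda s, f=f, season=season: f"{season}-{f}-{s + 1:03d}"
            for s in range(n_sessions):
                session_rows.append(
                    {
                        "season": season,
                        "session_id": label(s),
                        "focal_id": f,
                        "duration_min": config.session_length,
                    }
                )
            partners = [j for j in ids if j != f]

            # grooming in both directions while f is focal
            counts = []
            for j in partners:
                ji = pos[j]
                counts.append(((f, j), int(rng_groom.poisson(lam[fi, ji] * hours))))
                counts.append(((j, f), int(rng_groom.poisson(lam[ji, fi] * hours))))
            event_rows.extend(
                _place_groom_events(
                    rng_groom, counts, f, season, mean_bout_s,
                    n_sessions, session_len_s, label,
                )
            )

            # displacements: one undirected count per dyad, direction down
            # the latent hierarchy with probability `consistency`
            disp_counts = []
            for j in partners:
                k = int(rng_disp.poisson(effects.displacement_rate * hours))
                if k == 0:
                    continue
                dominant, subordinate = (
                    (f, j) if rankpos[f] < rankpos[j] else (j, f)
                )
                down = int(rng_disp.binomial(k, effects.consistency))
                if down:
                    disp_counts.append(((dominant, subordinate), down))
                if k - down:
                    disp_counts.append(((subordinate, dominant), k - down))
            event_rows.extend(
                _place_point_events(
                    rng_disp, disp_counts, ids, f, season, "displacement",
                    n_sessions, session_len_s, label,
                )
            )

            aggr_counts = []
            appr_counts = []
            for j in partners:
                ji = pos[j]
                aggr_counts.append(((f, j), int(rng_aggr.poisson(aggr[fi, ji] * hours))))
                aggr_counts.append(((j, f), int(rng_aggr.poisson(aggr[ji, fi] * hours))))
                appr_counts.append(((f, j), int(rng_appr.poisson(appr[fi, ji] * hours))))
                appr_counts.append(((j, f), int(rng_appr.poisson(appr[ji, fi] * hours))))
            event_rows.extend(
                _place_point_events(
                    rng_aggr, aggr_counts, ids, f, season, "aggression",
                    n_sessions, session_len_s, label,
                )
            )
            event_rows.extend(
                _place_point_events(
                    rng_appr, appr_counts, ids, f, season, "approach",
                    n_sessions, session_len_s, label,
                )
            )

            # instantaneous scans: at most one partner/state per scan
            n_scans = n_sessions * scans_per_session
            aff_row = truth.affinity.to_numpy()[fi].copy()
            aff_row[fi] = 0.0
            p_partner = _SOCIAL_SCAN_FRACTION * aff_row / aff_row.sum()
            probs = np.concatenate([[1.0 - _SOCIAL_SCAN_FRACTION], np.delete(p_partner, fi)])
            draws = rng_scan.multinomial(n_scans, probs)
            social_total = int(draws[1:].sum())
            if social_total:
                slots = rng_scan.choice(n_scans, size=social_total, replace=False)
                si = 0
                for j, c in zip(partners, draws[1:]):
                    if c == 0:
                        continue
                    states = rng_scan.multinomial(int(c), state_p)
                    for st, sc in zip(state_names, states):
                        for _ in range(int(sc)):
                            slot = int(slots[si])
                            si += 1
                            scan_rows.append(
                                (
                                    season,
                                    label(slot // scans_per_session),
                                    f,
                                    j,
                                    st,
                                    (slot % scans_per_session)
                                    * config.scan_interval * 60.0,
                                )
                            )

    events = pd.DataFrame(
        event_rows,
        columns=[
            "season", "session_id", "focal_id", "actor_id", "recipient_id",
            "behavior", "start", "end",
        ],
    )
    events = events.sort_values(
        ["season", "session_id", "start"], kind="mergesort"
    ).reset_index(drop=True)
    scans = pd.DataFrame(
        scan_rows,
        columns=["season", "session_id", "focal_id", "partner_id", "state", "scan_time"],
    )
    scans = scans.sort_values(
        ["season", "session_id", "scan_time"], kind="mergesort"
    ).reset_index(drop=True)
    sessions = pd.DataFrame(session_rows)
    return events, scans, sessions


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "latent_rank": truth.latent_rank,
        "kin_pairs": sorted(sorted(p) for p in truth.kin_pairs),
        "true_betas": truth.true_betas.to_dict(),
        "affinity": {
            "ids": list(truth.affinity.index),
            "values": truth.affinity.to_numpy().tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    aff = pd.DataFrame(
        payload["affinity"]["values"],
        index=payload["affinity"]["ids"],
        columns=payload["affinity"]["ids"],
    )
    return GroundTruth(
        latent_rank=payload["latent_rank"],
        kin_pairs={frozenset(p) for p in payload["kin_pairs"]},
        affinity=aff,
        true_betas=EffectConfig(**payload["true_betas"]),
    )
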