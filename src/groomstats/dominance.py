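"""Dominance-hierarchy statistics from a displacement matrix.

Given a square wins matrix ``M`` (entry ``M[i, j]`` = number of times *i*
displaced *j*), this module computes:

* the dyadic dominance index corrected for chance,
  ``Dij = Pij - (Pij - 0.5) / (nij + 1)`` with ``Pij = wins_ij / nij``,
  which shrinks the raw win proportion toward 0.5 for sparsely observed
  dyads; unobserved dyads are assigned ``Dij = 0.5`` (no information);
* David's scores ``DS = w + w2 - l - l2`` and their normalization
  ``NDS = (DS + N(N-1)/2) / N``, a cardinal dominance value in
  ``[0, N-1]`` that weights wins by the strength of the opponents;
* hierarchy steepness: the absolute OLS slope of NDS against the rank
  positions ``1..N`` after sorting NDS in descending order, with a
  randomization test that redraws each dyad's wins as
  ``Binomial(nij, 0.5)``;
* Landau's linearity index
  ``h = 12/(N^3 - N) * sum_i (V_i - (N-1)/2)^2`` where ``V_i`` counts the
  individuals that *i* dominates (strict win majority), and the improved
  index ``h'``: the mean of ``h`` over random resolutions of unknown and
  tied dyads, with a randomization p-value against fully random
  dominance structures;
* the directional consistency index
  ``DCI = sum(H - L) / sum(H + L)`` over observed dyads, where ``H``/``L``
  are the counts in the more/less frequent direction.

Randomization tests take an explicit seed and are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .io import SociometricMatrix

__all__ = [
    "DijMatrix",
    "SteepnessResult",
    "LinearityResult",
    "DominanceSummary",
    "build_displacement_matrix",
    "dyadic_dominance_index",
    "davids_scores",
    "rank_order",
    "steepness",
    "linearity",
    "directional_consistency",
    "summarize_dominance",
]


@dataclass
class DijMatrix:
    """Dyadic dominance indices with their interaction counts."""

    ids: list[str]
    dij: np.ndarray  # off-diagonal in [0, 1]; diagonal stored 0, never read
    n_ij: np.ndarray  # symmetric interaction counts

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_unknown_dyads(self) -> int:
        iu = np.triu_indices(self.n, 1)
        return int((self.n_ij[iu] == 0).sum())


@dataclass
class SteepnessResult:
    slope: float
    steepness: float
    p_value: float | None
    n_randomizations: int
    seed: int | None


@dataclass
class LinearityResult:
    h: float  # Landau index, ties/unknowns contributing 1/2
    u: int  # number of unknown dyads
    h_prime: float  # improved index (mean h over random resolutions)
    p_value: float | None
    n_randomizations: int
    seed: int | None


@dataclass
class DominanceSummary:
    ids: list[str]
    matrix: SociometricMatrix
    dij: DijMatrix
    scores: pd.DataFrame
    order: list[str]
    tied: bool
    steepness: SteepnessResult
    linearity: LinearityResult
    dci: float
    known_dyads: int = 0
    unknown_dyads: int = 0
    extra: dict = field(default_factory=dict)


def build_displacement_matrix(
    events: pd.DataFrame,
    season: str,
    roster: pd.DataFrame | None = None,
    ids: list[str] | None = None,
) -> SociometricMatrix:
    """Count displacements per directed pair for one season.

    When ``roster`` (or an explicit ``ids`` list) is given, only interactions
    among those individuals are kept and the matrix covers all of them even
    if uninvolved; unknown actors then raise ``KeyError``.
    """
    if ids is None and roster is not None:
        ids = list(roster["individual_id"])
    disp = events[
        (events["behavior"] == "displacement") & (events["season"] == str(season))
    ]
    if ids is None:
        ids = sorted(set(disp["actor_id"]) | set(disp["recipient_id"]))
    pos = {x: i for i, x in enumerate(ids)}
    m = np.zeros((len(ids), len(ids)))
    for rec in disp.itertuples(index=False):
        if rec.actor_id not in pos:
            raise KeyError(f"actor {rec.actor_id!r} not in roster")
        if rec.recipient_id not in pos:
            raise KeyError(f"recipient {rec.recipient_id!r} not in roster")
        m[pos[rec.actor_id], pos[rec.recipient_id]] += 1
    return SociometricMatrix(list(ids), m)


def _dij_from_wins(wins: np.ndarray) -> np.ndarray:
    """Chance-corrected dyadic index for a (..., N, N) wins array."""
    n_ij = wins + np.swapaxes(wins, -1, -2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_ij > 0, wins / np.where(n_ij > 0, n_ij, 1), 0.5)
    d = p - (p - 0.5) / (n_ij + 1)
    d = np.where(n_ij > 0, d, 0.5)
    n = wins.shape[-1]
    eye = np.eye(n, dtype=bool)
    d = np.where(eye, 0.0, d)
    return d


def dyadic_dominance_index(M: SociometricMatrix) -> DijMatrix:
    """Compute Dij with the 0.5 convention for unobserved dyads."""
    wins = np.asarray(M.values, dtype=float)
    d = _dij_from_wins(wins)
    n_ij = wins + wins.T
    np.fill_diagonal(n_ij, 0.0)
    return DijMatrix(list(M.ids), d, n_ij)


def _nds_from_dij(d: np.ndarray) -> np.ndarray:
    """Normalized David's scores for a (..., N, N) Dij array (diag zero)."""
    n = d.shape[-1]
    w = d.sum(axis=-1)
    w2 = np.einsum("...ij,...j->...i", d, w)
    l = d.sum(axis=-2)
    l2 = np.einsum("...ji,...j->...i", d, l)
    ds = w + w2 - l - l2
    return (ds + n * (n - 1) / 2.0) / n


def davids_scores(D: DijMatrix) -> pd.DataFrame:
    """Per-individual David's score components, DS and NDS.

    Zero-sum DS and NDS mean ``(N-1)/2`` hold for any valid Dij matrix.
    """
    if D.n < 2:
        raise DataError("David's scores need at least 2 individuals")
    d = D.dij
    w = d.sum(axis=1)
    w2 = d @ w
    l = d.sum(axis=0)
    l2 = d.T @ l
    ds = w + w2 - l - l2
    nds = (ds + D.n * (D.n - 1) / 2.0) / D.n
    return pd.DataFrame(
        {"id": D.ids, "w": w, "w2": w2, "l": l, "l2": l2, "DS": ds, "NDS": nds}
    )


def rank_order(scores: pd.DataFrame) -> tuple[list[str], bool]:
    """Descending-NDS rank order; ties broken lexicographically by id.

    Returns ``(ordered ids, tie flag)``.
    """
    s = scores.sort_values(["NDS", "id"], ascending=[False, True], kind="mergesort")
    tied = bool(scores["NDS"].round(12).duplicated().any())
    return list(s["id"]), tied


def _steepness_from_nds(nds: np.ndarray) -> np.ndarray:
    """|OLS slope| of descending-sorted NDS on positions 1..N (batched)."""
    n = nds.shape[-1]
    y = -np.sort(-nds, axis=-1)
    x = np.arange(1, n + 1, dtype=float)
    xc = x - x.mean()
    slope = (y * xc).sum(axis=-1) / (xc**2).sum()
    return np.abs(slope)


def _check_randomizations(n_randomizations: int) -> None:
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    if n_randomizations < 100:
        warnings.warn(
            f"only {n_randomizations} randomizations; p-values will be coarse",
            stacklevel=3,
        )


def steepness(
    D: DijMatrix, n_randomizations: int = 10_000, seed: int | None = None
) -> SteepnessResult:
    """Hierarchy steepness with a wins-resampling randomization test.

    The null keeps each dyad's interaction count ``nij`` but redraws wins as
    ``Binomial(nij, 0.5)``; the one-tailed p-value is the proportion of null
    matrices whose steepness is at least the observed one.
    """
    if D.n < 3:
        raise DataError("steepness needs at least 3 individuals")
    nds = _nds_from_dij(D.dij[None])[0]
    y = -np.sort(-nds)
    x = np.arange(1, D.n + 1, dtype=float)
    xc = x - x.mean()
    slope = float((y * xc).sum() / (xc**2).sum())
    observed = abs(slope)

    p = None
    if n_randomizations:
        _check_randomizations(n_randomizations)
        rng = np.random.default_rng(seed)
        iu = np.triu_indices(D.n, 1)
        n_dyads = D.n_ij[iu].astype(int)
        wins_u = rng.binomial(n_dyads[None, :], 0.5, size=(n_randomizations, len(n_dyads)))
        wins = np.zeros((n_randomizations, D.n, D.n))
        wins[:, iu[0], iu[1]] = wins_u
        wins[:, iu[1], iu[0]] = n_dyads[None, :] - wins_u
        null = _steepness_from_nds(_nds_from_dij(_dij_from_wins(wins)))
        p = float((null >= observed).mean())
    return SteepnessResult(slope, observed, p, n_randomizations, seed)


def _landau_h(V: np.ndarray) -> np.ndarray:
    n = V.shape[-1]
    return 12.0 / (n**3 - n) * ((V - (n - 1) / 2.0) ** 2).sum(axis=-1)


def linearity(
    M: SociometricMatrix, n_randomizations: int = 10_000, seed: int | None = None
) -> LinearityResult:
    """Landau's h and the improved linearity index h'.

    ``h`` is reported with tied and unknown dyads contributing 1/2 to each
    member's dominated count; ``h'`` is the mean of ``h`` over
    ``n_randomizations`` random resolutions of those dyads, and the p-value
    is the proportion of fully random dominance structures whose ``h``
    reaches ``h'``. With ``n_randomizations=0`` the expectation is taken in
    closed form, ``h' = h + 6(u + t)/(N^3 - N)`` for ``u + t`` undecided
    dyads, and no p-value is computed.
    """
    if M.n < 3:
        raise DataError("linearity needs at least 3 individuals")
    if n_randomizations:
        _check_randomizations(n_randomizations)
    wins = np.asarray(M.values, dtype=float)
    n = M.n
    iu = np.triu_indices(n, 1)
    wij = wins[iu]
    wji = wins.T[iu]
    decided_i = wij > wji  # i (row index of triu) dominates j
    decided_j = wji > wij
    undecided = ~(decided_i | decided_j)  # ties and unknowns
    u = int(((wij + wji) == 0).sum())

    # h with half-credit for undecided dyads
    V_half = np.zeros(n)
    np.add.at(V_half, iu[0][decided_i], 1.0)
    np.add.at(V_half, iu[1][decided_j], 1.0)
    np.add.at(V_half, iu[0][undecided], 0.5)
    np.add.at(V_half, iu[1][undecided], 0.5)
    h = float(_landau_h(V_half[None])[0])

    n_und = int(undecided.sum())
    if n_randomizations == 0:
        # E[h] over fair resolutions: each undecided dyad adds Var = 1/4 to
        # two V_i terms, i.e. 12/(N^3-N) * n_und/2 in total
        h_prime = h + 6.0 * n_und / (n**3 - n)
        return LinearityResult(h, u, h_prime, None, 0, seed)

    rng = np.random.default_rng(seed)
    if n_und == 0:
        h_prime = h
    else:
        # resolve each undecided dyad by a fair coin, per replicate
        coin = rng.integers(0, 2, size=(n_randomizations, n_und))
        V = np.zeros((n_randomizations, n))
        base = np.zeros(n)
        np.add.at(base, iu[0][decided_i], 1.0)
        np.add.at(base, iu[1][decided_j], 1.0)
        V += base
        rows_i = iu[0][undecided]
        rows_j = iu[1][undecided]
        for k in range(n_und):  # n_und small in practice
            V[:, rows_i[k]] += coin[:, k]
            V[:, rows_j[k]] += 1 - coin[:, k]
        h_prime = float(_landau_h(V).mean())

    # null: every dyad decided at random
    n_dyads = len(iu[0])
    coin = rng.integers(0, 2, size=(n_randomizations, n_dyads))
    Vn = np.zeros((n_randomizations, n))
    for k in range(n_dyads):
        Vn[:, iu[0][k]] += coin[:, k]
        Vn[:, iu[1][k]] += 1 - coin[:, k]
    h_null = _landau_h(Vn)
    p = float((h_null >= h_prime).mean())
    return LinearityResult(h, u, h_prime, p, n_randomizations, seed)


def directional_consistency(M: SociometricMatrix) -> float:
    """DCI = sum(H - L) / sum(H + L) over dyads with at least one interaction."""
    wins = np.asarray(M.values, dtype=float)
    iu = np.triu_indices(M.n, 1)
    a = wins[iu]
    b = wins.T[iu]
    tot = a + b
    known = tot > 0
    if not known.any():
        raise DataError("DCI undefined: no dyad has any interaction")
    h = np.maximum(a, b)[known]
    l = np.minimum(a, b)[known]
    return float((h - l).sum() / (h + l).sum())


def summarize_dominance(
    M: SociometricMatrix,
    n_randomizations: int = 10_000,
    seed: int | None = None,
) -> DominanceSummary:
    """Full dominance suite for one season's displacement matrix."""
    dij = dyadic_dominance_index(M)
    scores = davids_scores(dij)
    order, tied = rank_order(scores)
    steep = steepness(dij, n_randomizations=n_randomizations, seed=seed)
    lin = linearity(M, n_randomizations=n_randomizations, seed=seed)
    dci = directional_consistency(M)
    n_dyads = M.n * (M.n - 1) // 2
    unknown = dij.n_unknown_dyads
    return DominanceSummary(
        ids=list(M.ids),
        matrix=M,
        dij=dij,
        scores=scores,
        order=order,
        tied=tied,
        steepness=steep,
        linearity=lin,
        dci=dci,
        known_dyads=n_dyads - unknown,
        unknown_dyads=unknown,
    )
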