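"""Dyadic grooming models with crossed groomer/groomee random effects.

The analysis table has one row per *directed* dyad per season (N(N-1) rows
per season). Each row carries the log-transformed response (grooming rate or
grooming time) and nine predictors: age difference, kinship (reference kin,
reported level "non-kin"), rank distance (|NDS difference|, cardinal),
relative rank of the groomer (reference dominant, reported level
"subordinate"), friendship F(groomer, groomee), grooming received (the raw
reverse-direction measure), co-provisioning percentage, aggression received,
and season (reference "1").

Fitting is a Gaussian linear mixed model by REML with two crossed random
intercepts — one for the groomer identity, one for the groomee — via
``statsmodels`` variance components. Confidence intervals are Wald,
``b +/- 1.96 * SE``. A likelihood-ratio test against the
intercept-plus-random-effects null (both refitted by ML) summarizes whole-
model significance. Effect sizes on the log scale translate to percent
changes as ``(exp(b * delta) - 1) * 100``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .errors import AssemblyError, ConfigurationError, DataError

__all__ = [
    "FIXED_EFFECTS",
    "FixedEffect",
    "ModelFit",
    "assemble_dyad_table",
    "log_transform",
    "fit_lmm",
    "effect_interpretation",
    "split_by_rank_distance",
    "report",
]

#: Design columns, in reporting order, with their display names.
FIXED_EFFECTS = {
    "age_difference": "Age difference",
    "kinship_nonkin": "Kinship (non-kin)",
    "rank_distance": "Rank distance",
    "relative_rank_sub": "Relative rank (subordinate)",
    "friendship": "Friendship",
    "groom_received": "Groom received",
    "co_provisioning_pct": "Co-provisioning",
    "aggression_received": "Aggression received",
    "season_2": "Season (2)",
}

_Z95 = 1.96  # Wald critical value, fixed so CI width is exactly 2*1.96*SE


@dataclass
class FixedEffect:
    name: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    reference: str | None = None

    @property
    def significant(self) -> bool:
        """CI excludes zero."""
        return self.ci_low > 0 or self.ci_high < 0


@dataclass
class ModelFit:
    response: str
    offset: float
    fixed_effects: list[FixedEffect]
    groomer_var: float
    groomee_var: float
    resid_var: float
    loglike: float
    null_lr_stat: float | None = None
    null_lr_df: int | None = None
    null_lr_p: float | None = None
    n_obs: int = 0
    converged: bool = True
    notes: list[str] = field(default_factory=list)

    def effect(self, name: str) -> FixedEffect:
        for fe in self.fixed_effects:
            if fe.name == name:
                return fe
        raise KeyError(name)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def assemble_dyad_table(
    measures: pd.DataFrame,
    aggression: pd.DataFrame,
    friendship: dict[str, "pd.DataFrame | object"],
    nds: dict[str, pd.Series],
    co_provisioning: dict[str, "object"],
    roster: pd.DataFrame,
) -> pd.DataFrame:
    """Build the directed-dyad model table (N(N-1) rows per season).

    Parameters are per-season mappings: ``friendship`` and
    ``co_provisioning`` map season -> matrix (FriendshipMatrix,
    SociometricMatrix or DataFrame), ``nds`` maps season -> Series of
    normalized David's scores indexed by id. ``measures`` and ``aggression``
    come from :mod:`groomstats.affiliation`. Kinship is maternal kin:
    same-matriline pairs of the roster.

    Row order is deterministic: season, groomer, groomee.
    """
    ids = list(roster["individual_id"])
    ages = dict(zip(roster["individual_id"], roster["age"]))
    matriline = dict(zip(roster["individual_id"], roster["matriline_id"]))
    seasons = sorted(measures["season"].unique())

    for season in seasons:
        if season not in nds:
            raise AssemblyError(f"no NDS available for season {season!r}")
        missing = [i for i in ids if i not in nds[season].index]
        if missing:
            raise AssemblyError(f"NDS missing for ids {missing} in season {season!r}")
        if season not in friendship:
            raise AssemblyError(f"no friendship matrix for season {season!r}")

    def _as_df(m) -> pd.DataFrame:
        return m if isinstance(m, pd.DataFrame) else m.to_dataframe()

    meas = measures.set_index(["season", "groomer_id", "groomee_id"])
    aggr = aggression.set_index(["season", "groomer_id", "groomee_id"])

    rows = []
    for season in seasons:
        f_df = _as_df(friendship[season])
        cop_df = _as_df(co_provisioning[season])
        s_nds = nds[season]
        for a in ids:
            for b in ids:
                if a == b:
                    continue
                try:
                    m_ab = meas.loc[(season, a, b)]
                    m_ba = meas.loc[(season, b, a)]
                    ag_ab = aggr.loc[(season, a, b)]
                except KeyError as e:
                    raise AssemblyError(
                        f"measures missing for dyad {e.args[0]}"
                    ) from None
                rows.append(
                    {
                        "season": season,
                        "groomer_id": a,
                        "groomee_id": b,
                        "grooming_rate": float(m_ab["grooming_rate"]),
                        "grooming_time": float(m_ab["grooming_time"]),
                        "groom_received_rate": float(m_ba["grooming_rate"]),
                        "groom_received_time": float(m_ba["grooming_time"]),
                        "kinship": "kin" if matriline[a] == matriline[b] else "non-kin",
                        "relative_rank": (
                            "subordinate" if s_nds[a] < s_nds[b] else "dominant"
                        ),
                        "rank_distance": abs(float(s_nds[a] - s_nds[b])),
                        "friendship": float(f_df.loc[a, b]),
                        "co_provisioning_pct": float(cop_df.loc[a, b]),
                        "aggression_received": float(ag_ab["aggression_received"]),
                        "age_difference": abs(float(ages[a]) - float(ages[b])),
                    }
                )
    return pd.DataFrame(rows)


def log_transform(x, offset: float | None = None) -> tuple[np.ndarray, float]:
    """log(x + offset); default offset = half the smallest positive value.

    Returns ``(transformed, offset used)``. With zeros present the offset
    must be positive.
    """
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise DataError("log transform requires non-negative values")
    if offset is None:
        pos = x[x > 0]
        if len(pos) == 0:
            raise DataError("no positive values; cannot choose a default offset")
        offset = float(pos.min() / 2.0)
    if offset <= 0 and (x == 0).any():
        raise ConfigurationError("offset must be > 0 when zeros are present")
    return np.log(x + offset), float(offset)


def _design(table: pd.DataFrame) -> pd.DataFrame:
    d = pd.DataFrame(index=table.index)
    d["age_difference"] = table["age_difference"]
    d["kinship_nonkin"] = (table["kinship"] == "non-kin").astype(float)
    d["rank_distance"] = table["rank_distance"]
    d["relative_rank_sub"] = (table["relative_rank"] == "subordinate").astype(float)
    d["friendship"] = table["friendship"]
    d["co_provisioning_pct"] = table["co_provisioning_pct"]
    d["aggression_received"] = table["aggression_received"]
    d["season_2"] = (table["season"].astype(str) != "1").astype(float)
    return d


_REFERENCES = {
    "kinship_nonkin": "kin",
    "relative_rank_sub": "dominant",
    "season_2": "season 1",
}


def fit_lmm(
    table: pd.DataFrame,
    response: str = "rate",
    offset: float | None = None,
    lrt: bool = True,
    random_effects: bool = True,
) -> ModelFit:
    """Fit the crossed-random-effects LMM for grooming rate or time.

    ``response`` selects ``grooming_rate`` or ``grooming_time``; the matching
    reverse-direction raw measure enters as the grooming-received covariate.
    The response is log-transformed (offset reported in the fit). Random
    intercepts for groomer and groomee identity are crossed variance
    components; estimation is REML. When ``lrt`` is true, both the full and
    the intercept-only null model are refitted by ML for a likelihood-ratio
    test. With ``random_effects=False`` the variance components are pinned
    at (numerically) zero — the degenerate limit in which the estimator
    coincides with ordinary least squares.
    """
    if response not in ("rate", "time"):
        raise ConfigurationError("response must be 'rate' or 'time'")
    col = f"grooming_{response}"
    y, used_offset = log_transform(table[col].to_numpy(), offset)

    d = _design(table)
    d["groom_received"] = table[f"groom_received_{response}"].to_numpy()
    cols = list(FIXED_EFFECTS)
    notes: list[str] = []
    constant = [c for c in cols if d[c].nunique() <= 1]
    if constant:
        # e.g. the season dummy on single-season data
        notes.append(f"dropped constant predictor(s): {constant}")
        cols = [c for c in cols if c not in constant]
    X = d[cols].to_numpy()
    Xc = np.column_stack([np.ones(len(X)), X])

    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # identify aliased columns by checking rank without each one
        aliased = []
        for j, name in enumerate(cols, start=1):
            keep = [k for k in range(Xc.shape[1]) if k != j]
            if np.linalg.matrix_rank(Xc[:, keep]) == rank:
                aliased.append(name)
        raise DataError(f"rank-deficient design; aliased terms: {aliased}")

    groups = np.ones(len(table), dtype=int)
    vc = {
        "groomer": pd.get_dummies(table["groomer_id"], dtype=float).to_numpy(),
        "groomee": pd.get_dummies(table["groomee_id"], dtype=float).to_numpy(),
    }
    def _fit(endog, exog, reml):
        model = sm.MixedLM(
            endog,
            exog,
            groups=groups,
            exog_vc=sm.regression.mixed_linear_model.VCSpec(
                names=list(vc),
                colnames=[[f"{k}{i}" for i in range(v.shape[1])] for k, v in vc.items()],
                mats=[[v] for v in vc.values()],
            ),
        )
        fit_kwargs: dict = {}
        if not random_effects:
            from statsmodels.regression.mixed_linear_model import MixedLMParams

            k = exog.shape[1]
            fit_kwargs["start_params"] = MixedLMParams.from_components(
                fe_params=np.zeros(k), cov_re=np.empty((0, 0)),
                vcomp=np.full(len(vc), 1e-10),
            )
            fit_kwargs["free"] = MixedLMParams.from_components(
                fe_params=np.ones(k), cov_re=np.empty((0, 0)),
                vcomp=np.zeros(len(vc)),
            )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = model.fit(reml=reml, method="lbfgs", maxiter=500, **fit_kwargs)
            if not res.converged and random_effects:
                res = model.fit(reml=reml, method="powell", maxiter=1000)
        for w in caught:
            if "singular" in str(w.message).lower() or "boundary" in str(
                w.message
            ).lower():
                notes.append(f"variance component at boundary: {w.message}")
        return res

    res = _fit(y, Xc, reml=True)

    params = res.fe_params
    ses = res.bse_fe
    effects = []
    for j, name in enumerate(cols, start=1):
        b = float(params[j])
        se = float(ses[j])
        effects.append(
            FixedEffect(
                name=name,
                estimate=b,
                se=se,
                ci_low=b - _Z95 * se,
                ci_high=b + _Z95 * se,
                reference=_REFERENCES.get(name),
            )
        )

    vcomp = dict(zip(list(vc), np.atleast_1d(res.vcomp).astype(float)))
    if random_effects and min(vcomp.values(), default=0.0) < 1e-10:
        notes.append("singular fit: a random-effect variance is at the zero floor")
    if not random_effects:
        notes.append("variance components pinned at zero (degenerate limit)")

    lr_stat = lr_df = lr_p = None
    if lrt:
        full_ml = _fit(y, Xc, reml=False)
        null_ml = _fit(y, np.ones((len(y), 1)), reml=False)
        lr_stat = float(2.0 * (full_ml.llf - null_ml.llf))
        lr_df = len(cols)
        lr_p = float(sps.chi2.sf(max(lr_stat, 0.0), lr_df))

    return ModelFit(
        response=col,
        offset=used_offset,
        fixed_effects=effects,
        groomer_var=float(vcomp.get("groomer", 0.0)),
        groomee_var=float(vcomp.get("groomee", 0.0)),
        resid_var=float(res.scale),
        loglike=float(res.llf),
        null_lr_stat=lr_stat,
        null_lr_df=lr_df,
        null_lr_p=lr_p,
        n_obs=len(table),
        converged=bool(res.converged),
        notes=notes,
    )


def effect_interpretation(b: float, delta: float = 1.0) -> tuple[float, str]:
    """Percent change in the response per ``delta`` units of a predictor.

    For a log-scale coefficient ``b``, the response changes by
    ``(exp(b * delta) - 1) * 100`` percent. Returns the exact percentage and
    a rounded label such as ``"22% higher"`` or ``"71% lower"``.
    """
    if not np.isfinite(b):
        raise ValueError("coefficient must be finite")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    pct = (np.exp(b * delta) - 1.0) * 100.0
    r = int(round(abs(pct)))
    if pct < 0:
        label = f"{r}% lower"
    elif pct > 0:
        label = f"{r}% higher"
    else:
        label = "0%"
    return float(pct), label


def split_by_rank_distance(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Split dyad rows at the pooled mean rank distance.

    Rows strictly above the mean form the high-distance subset; the rest the
    low-distance subset. Returns ``(low, high, threshold)``.
    """
    threshold = float(table["rank_distance"].mean())
    high = table[table["rank_distance"] > threshold]
    low = table[table["rank_distance"] <= threshold]
    if len(high) == 0:
        raise DataError(
            "empty high-rank-distance subset (all rank distances equal?)"
        )
    if len(low) == 0:
        raise DataError("empty low-rank-distance subset")
    return low.copy(), high.copy(), threshold


def report(fits: dict[str, ModelFit]) -> str:
    """Plain-text results tables, one per fitted model.

    Significant terms (CI excluding zero) are marked ``*`` and accompanied
    by exp-scale interpretations; continuous covariates measured per 0.1
    unit (grooming and aggression received) are interpreted at delta = 0.1.
    """
    small_delta = {"groom_received", "aggression_received"}
    lines = []
    for label, fit in fits.items():
        lines.append(f"== {label} (response: {fit.response}, offset {fit.offset:g}) ==")
        lines.append(
            f"{'term':<28}{'estimate':>10}{'SE':>8}{'CI low':>9}{'CI high':>9}  sig"
        )
        for fe in fit.fixed_effects:
            disp = FIXED_EFFECTS.get(fe.name, fe.name)
            lines.append(
                f"{disp:<28}{fe.estimate:>10.3f}{fe.se:>8.3f}"
                f"{fe.ci_low:>9.3f}{fe.ci_high:>9.3f}  {'*' if fe.significant else ''}"
            )
        lines.append(
            f"random-effect variances: groomer {fit.groomer_var:.4f}, "
            f"groomee {fit.groomee_var:.4f}, residual {fit.resid_var:.4f}"
        )
        if fit.null_lr_stat is not None:
            lines.append(
                f"null-model LRT: chi2({fit.null_lr_df}) = {fit.null_lr_stat:.2f}, "
                f"p = {fit.null_lr_p:.3g}"
            )
        for fe in fit.fixed_effects:
            if not fe.significant:
                continue
            delta = 0.1 if fe.name in small_delta else 1.0
            _, lo_label = effect_interpretation(fe.ci_low, delta)
            _, hi_label = effect_interpretation(fe.ci_high, delta)
            disp = FIXED_EFFECTS.get(fe.name, fe.name)
            unit = f"per {delta:g} unit" if delta != 1.0 else "per unit"
            lines.append(f"  {disp}: response {lo_label} to {hi_label} ({unit})")
        lines.append("")
    return "\n".join(lines)
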