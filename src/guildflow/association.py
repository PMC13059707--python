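"""Guild-treatment, guild-SCFA and chemistry-treatment models.

Per-guild differential abundance follows the "log-transform + linear mixed
model + BH" recipe: log guild relative abundance is regressed on treatment
indicators (Control as reference) with a donor random intercept, and
q-values are Benjamini-Hochberg across the whole guild x level family.
Guild-SCFA associations use the same mixed model with a z-scored SCFA
predictor and z-scored response, so the coefficient is a standardized
(scale-free) effect.  Chemistry outcomes (pH and individual SCFAs) are
compared between treatments with a donor-random-intercept mixed model and
all pairwise contrasts adjusted by Tukey's studentized-range method.

Mixed models are fit by REML via :class:`statsmodels` ``MixedLM``; when the
fit fails to converge the model is refit with donor as a fixed effect and
the affected rows are flagged (three-donor designs make variance
components fragile, and the fixed-effect fallback preserves coefficient
signs on balanced designs).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import SCFA_COLUMNS, TREATMENTS

__all__ = [
    "bh_qvalues",
    "fit_guild_treatment",
    "fit_guild_scfa",
    "fit_chem_treatment",
]

logger = logging.getLogger(__name__)


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    Equivalent to ``q_(i) = min_{j >= i} (m * p_(j) / j)`` on the sorted
    p-values.  NaN entries are excluded from the family and returned as NaN.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


@dataclass
class _Fit:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov: pd.DataFrame
    resid_df: float
    fallback: bool


def _fit_mixed(y: np.ndarray, x: pd.DataFrame, donors: pd.Series) -> _Fit:
    """Random-intercept fit with donor-fixed-effect fallback."""
    import statsmodels.api as sm
    import statsmodels.formula.api  # noqa: F401  (registers formula machinery)

    n_donors = donors.nunique()
    if n_donors >= 2:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, x, groups=donors.to_numpy())
                res = model.fit(reml=True, method="lbfgs")
            if res.converged and np.isfinite(res.bse[: x.shape[1]]).all():
                params = pd.Series(res.params[: x.shape[1]], index=x.columns)
                bse = pd.Series(res.bse[: x.shape[1]], index=x.columns)
                pv = pd.Series(res.pvalues[: x.shape[1]], index=x.columns)
                cov = pd.DataFrame(
                    np.asarray(res.cov_params())[: x.shape[1], : x.shape[1]],
                    index=x.columns,
                    columns=x.columns,
                )
                resid_df = len(y) - x.shape[1] - (n_donors - 1)
                return _Fit(params, bse, pv, cov, resid_df, fallback=False)
        except Exception:  # noqa: BLE001 - any numerical failure triggers the fallback
            pass
    else:
        logger.warning("fewer than 2 donors: falling back to a fixed-effects model")
    design = pd.concat(
        [x, pd.get_dummies(donors, prefix="donor", drop_first=True, dtype=float)], axis=1
    )
    ols = sm.OLS(y, design).fit()
    params = ols.params[x.columns]
    return _Fit(
        params=params,
        bse=ols.bse[x.columns],
        pvalues=ols.pvalues[x.columns],
        cov=ols.cov_params().loc[x.columns, x.columns],
        resid_df=float(ols.df_resid),
        fallback=True,
    )


def _treatment_design(meta: pd.DataFrame, reference: str) -> tuple[pd.DataFrame, list[str]]:
    levels = [t for t in TREATMENTS if t in set(meta["treatment"])]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} absent from the data")
    others = [t for t in levels if t != reference]
    x = pd.DataFrame({"Intercept": np.ones(len(meta))}, index=meta.index)
    for t in others:
        x[t] = (meta["treatment"] == t).astype(float)
    return x, others


def _log_guild(gt: pd.DataFrame, pseudo: float | str = "half-min") -> pd.DataFrame:
    from .preprocess import log_transform

    return log_transform(gt, pseudo=pseudo)


def _select_samples(meta: pd.DataFrame, timepoints) -> pd.Index:
    if timepoints is None:  # default: all post-baseline samples
        return meta.index[meta["time_h"] > 0]
    wanted = set(float(t) for t in timepoints)
    return meta.index[meta["time_h"].isin(wanted)]


def fit_guild_treatment(
    gt: pd.DataFrame,
    meta: pd.DataFrame,
    reference: str = "Control",
    timepoints=None,
    pseudo: float | str = "half-min",
) -> pd.DataFrame:
    """Per-guild mixed model of log abundance on treatment.

    Returns one row per (guild, non-reference treatment level) with the
    coefficient (log-fold difference from the reference), a standardized
    coefficient (response z-scored), standard error, p and BH q computed
    jointly across the whole family.  Zero-variance guilds are flagged
    degenerate and excluded from the FDR family.
    """
    samples = _select_samples(meta, timepoints)
    gt = gt.loc[samples]
    meta = meta.loc[samples]
    if meta["treatment"].nunique() < 2:
        raise ValueError("need at least 2 treatment levels")
    x, others = _treatment_design(meta, reference)
    logged = _log_guild(gt, pseudo=pseudo)
    rows = []
    for guild in gt.columns:
        y = logged[guild].to_numpy()
        sd = y.std(ddof=1)
        if sd < 1e-12:
            for t in others:
                rows.append((guild, t, np.nan, np.nan, np.nan, np.nan, True, False))
            continue
        fit = _fit_mixed(y, x, meta["donor"])
        for t in others:
            rows.append(
                (
                    guild,
                    t,
                    float(fit.params[t]),
                    float(fit.params[t] / sd),
                    float(fit.bse[t]),
                    float(fit.pvalues[t]),
                    False,
                    fit.fallback,
                )
            )
    out = pd.DataFrame(
        rows,
        columns=["guild", "term", "coef", "std_coef", "se", "p", "degenerate", "fallback"],
    )
    out["q"] = bh_qvalues(out["p"].to_numpy())
    return out


def fit_guild_scfa(
    gt: pd.DataFrame,
    chem: pd.DataFrame,
    meta: pd.DataFrame,
    scfas=SCFA_COLUMNS,
    timepoints=None,
    pseudo: float | str = "half-min",
) -> pd.DataFrame:
    """Per-guild mixed models of log abundance on each SCFA concentration.

    Both the log abundance and the SCFA are z-scored, so ``std_coef`` is
    invariant to the measurement units of either variable; ``coef`` is on
    the original (log-abundance per uM) scale.
    """
    samples = _select_samples(meta, timepoints)
    missing = [s for s in samples if s not in chem.index]
    if missing:
        raise ValueError(f"chemistry table missing sample(s): {missing}")
    gt = gt.loc[samples]
    meta = meta.loc[samples]
    chem = chem.loc[samples]
    logged = _log_guild(gt, pseudo=pseudo)
    rows = []
    for scfa in scfas:
        xs = chem[scfa].to_numpy(dtype=float)
        sx = xs.std(ddof=1)
        if sx < 1e-12:
            raise ValueError(f"SCFA column {scfa!r} is constant")
        zx = (xs - xs.mean()) / sx
        design = pd.DataFrame({"Intercept": np.ones(len(samples)), scfa: zx}, index=samples)
        for guild in gt.columns:
            y = logged[guild].to_numpy()
            sy = y.std(ddof=1)
            if sy < 1e-12:
                rows.append((guild, scfa, np.nan, np.nan, np.nan, np.nan, True, False))
                continue
            zy = (y - y.mean()) / sy
            fit = _fit_mixed(zy, design, meta["donor"])
            rows.append(
                (
                    guild,
                    scfa,
                    float(fit.params[scfa] * sy / sx),  # original scale
                    float(fit.params[scfa]),
                    float(fit.bse[scfa]),
                    float(fit.pvalues[scfa]),
                    False,
                    fit.fallback,
                )
            )
    out = pd.DataFrame(
        rows,
        columns=["guild", "term", "coef", "std_coef", "se", "p", "degenerate", "fallback"],
    )
    out["q"] = bh_qvalues(out["p"].to_numpy())
    return out


def fit_chem_treatment(
    chem: pd.DataFrame,
    meta: pd.DataFrame,
    response: str,
    timepoints=None,
) -> pd.DataFrame:
    """Mixed model of a chemistry outcome on treatment with Tukey contrasts.

    Fits ``response ~ treatment`` with a donor random intercept, then forms
    all C(levels, 2) pairwise contrasts of estimated marginal means and
    adjusts them family-wise with the studentized-range (Tukey) distribution
    at the model's residual degrees of freedom.
    """
    if response not in chem.columns:
        raise ValueError(f"unknown response {response!r}; chem columns: {list(chem.columns)}")
    samples = _select_samples(meta, timepoints)
    samples = samples.intersection(chem.index)
    meta = meta.loc[samples]
    chem = chem.loc[samples]
    levels = [t for t in TREATMENTS if t in set(meta["treatment"])]
    if len(levels) < 2:
        raise ValueError("need at least 2 treatment levels")
    # cell-means coding -> estimated marginal mean per treatment
    x = pd.DataFrame(
        {t: (meta["treatment"] == t).astype(float) for t in levels}, index=meta.index
    )
    y = chem[response].to_numpy(dtype=float)
    fit = _fit_mixed(y, x, meta["donor"])
    k = len(levels)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        est = float(fit.params[a] - fit.params[b])
        var = float(fit.cov.loc[a, a] + fit.cov.loc[b, b] - 2.0 * fit.cov.loc[a, b])
        se = np.sqrt(max(var, 1e-300))
        tval = est / se
        q = abs(tval) * np.sqrt(2.0)
        p_adj = float(stats.studentized_range.sf(q, k, max(fit.resid_df, 2.0)))
        rows.append((a, b, est, se, tval, min(max(p_adj, 0.0), 1.0), fit.fallback))
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "estimate", "se", "t", "p_adj", "fallback"]
    )
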