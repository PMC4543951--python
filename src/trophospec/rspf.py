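"""Logistic resource selection probability functions (use-availability design).

Each prey item found in a stomach is one "used" observation carrying its
predator's covariates (sex, season, site, SVL, SMI, FORI); each item of
the focal prey sampled in the environment is one "available" observation.
Because availability rows have no predator, predator-level covariates are
attached to them by a documented, switchable strategy: resampled from the
empirical predator covariate distribution of the same season/site
(default) or set to season/site means.

Two estimators are provided.  ``naive_logistic`` maximizes the ordinary
Bernoulli likelihood of used-vs-available with a logit link (an
exponential approximation to the RSPF, standard practice and stable).
``weighted_mle`` maximizes the use-availability weighted-distribution
log-likelihood

    l(beta) = sum_used ln pi(x; beta)
              - n_used * ln[ (1/n_avail) * sum_avail pi(x; beta) ]

with pi = expit(beta0 + beta'x); it is only identifiable with at least one
continuous covariate.  Continuous covariates are z-scored before fitting,
so coefficients are on the standardized scale.

Model search is forward-stepwise, ranked by AIC with the usual rule that
models more than 2 units above the best have substantially less support;
calibration is assessed with the Hosmer-Lemeshow test on deciles of fitted
probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

import statsmodels.api as sm
from statsmodels.tools.numdiff import approx_hess2

from .data_model import AvailabilityTable, CovariateTable, DietMatrix, PreyTaxon

logger = logging.getLogger("trophospec")

CONTINUOUS = ("svl", "smi", "fori")
CATEGORICAL = ("sex", "season", "site")
COVARIATE_POOL = CONTINUOUS + CATEGORICAL


class SeparationError(RuntimeError):
    """Complete separation: the likelihood has no finite maximizer."""


@dataclass
class UseAvailabilityTable:
    """Long-format used/available rows for one focal prey taxon."""

    focal_taxon: PreyTaxon
    table: pd.DataFrame  # response, taxon, season, site, sex, svl, smi, fori, weight

    @property
    def n_used(self) -> int:
        return int((self.table["response"] == 1).sum())

    @property
    def n_available(self) -> int:
        return int((self.table["response"] == 0).sum())


def assemble_use_availability(
    diet: DietMatrix,
    availability: AvailabilityTable,
    covariates: CovariateTable,
    focal_taxon: PreyTaxon,
    strategy: str = "resample",
    seed: int | None = None,
) -> UseAvailabilityTable:
    """Expand stomach items and environmental items into a used/available table.

    strategy: how predator-level covariates (sex, svl, smi, fori) attach to
    available rows — "resample" draws them from the empirical predator
    distribution of the same season/site; "mean" uses covariate means (sex
    set to the modal sex).
    """
    from .condition import condition_table

    if strategy not in ("resample", "mean"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if strategy == "resample" and seed is None:
        raise ValueError("strategy='resample' requires a seed")

    try:
        j = diet.taxa.index(focal_taxon)
        used_counts = diet.counts[:, j]
    except ValueError:
        used_counts = np.zeros(diet.n_individuals, dtype=int)
    n_avail_items = availability.count_for(focal_taxon)
    if used_counts.sum() == 0 and n_avail_items == 0:
        raise ValueError(
            f"focal taxon {focal_taxon.label!r} absent from both diet "
            "and environment"
        )

    cond = condition_table(diet, covariates)
    cov = covariates.aligned_to(diet)
    predators = pd.DataFrame(
        {
            "season": cov["season"],
            "site": cov["site"],
            "sex": cov["sex"],
            "svl": cov["svl"].astype(float),
            "smi": cond.table["smi"],
            "fori": cond.table["fori"].astype(float),
        }
    )

    used = predators.loc[predators.index.repeat(used_counts)].copy()
    used["response"] = 1

    if strategy == "resample":
        rng = np.random.default_rng(seed)
        picks = rng.integers(0, len(predators), size=n_avail_items)
        avail = predators.iloc[picks].copy()
    else:
        avail = pd.DataFrame(
            {
                "season": availability.season or predators["season"].mode().iat[0],
                "site": predators["site"].mode().iat[0],
                "sex": predators["sex"].mode().iat[0],
                "svl": predators["svl"].mean(),
                "smi": predators["smi"].mean(),
                "fori": predators["fori"].mean(),
            },
            index=range(n_avail_items),
        )
    if availability.season is not None:
        avail["season"] = availability.season
    avail["response"] = 0

    table = pd.concat([used, avail], ignore_index=True)
    table["taxon"] = focal_taxon.label
    table["weight"] = 1.0
    return UseAvailabilityTable(focal_taxon=focal_taxon, table=table)


@dataclass
class RSPFModel:
    focal_taxon: PreyTaxon
    method: str
    terms: list[str]
    columns: list[str]           # design columns incl. intercept
    beta: np.ndarray
    se: np.ndarray
    ci: np.ndarray               # (k, 2)
    aic: float
    llf: float
    fitted: np.ndarray           # probability of use per row
    response: np.ndarray
    mean_use: float = 0.0
    sd_use: float = 0.0
    hl_stat: float | None = None
    hl_p: float | None = None
    delta_aic: float | None = None

    def as_dict(self) -> dict:
        return {
            "focal_taxon": self.focal_taxon.label,
            "method": self.method,
            "terms": self.terms,
            "beta": dict(zip(self.columns, map(float, self.beta))),
            "se": dict(zip(self.columns, map(float, self.se))),
            "ci": {c: [float(lo), float(hi)]
                   for c, (lo, hi) in zip(self.columns, self.ci)},
            "aic": self.aic,
            "delta_aic": self.delta_aic,
            "hl_stat": self.hl_stat,
            "hl_p": self.hl_p,
            "mean_use": self.mean_use,
            "sd_use": self.sd_use,
            "n_used": int(self.response.sum()),
            "n_avail": int((1 - self.response).sum()),
        }


def _design(table: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + z-scored continuous terms + treatment-coded categoricals."""
    cols: list[np.ndarray] = [np.ones(len(table))]
    names = ["intercept"]
    for t in terms:
        if t in CONTINUOUS:
            v = table[t].to_numpy(dtype=float)
            sd = v.std(ddof=0)
            if sd == 0:
                raise ValueError(f"covariate {t!r} is constant")
            cols.append((v - v.mean()) / sd)
            names.append(t)
        elif t in CATEGORICAL:
            levels = sorted(pd.unique(table[t].astype(str)))
            for lev in levels[1:]:  # first level is the reference
                cols.append((table[t].astype(str) == lev).to_numpy(float))
                names.append(f"{t}[{lev}]")
        else:
            raise ValueError(f"unknown covariate {t!r}")
    return np.column_stack(cols), names


def fit_rspf(
    ua: UseAvailabilityTable,
    terms: list[str],
    method: str = "naive_logistic",
) -> RSPFModel:
    """Fit a resource selection probability function for one prey taxon."""
    y = ua.table["response"].to_numpy(dtype=float)
    if y.sum() == 0 or (1 - y).sum() == 0:
        raise ValueError("need at least one used and one available row")
    x, names = _design(ua.table, terms)

    if method == "naive_logistic":
        beta, se, llf, fitted = _fit_naive(y, x)
    elif method == "weighted_mle":
        if not any(t in CONTINUOUS for t in terms):
            raise ValueError(
                "weighted_mle needs at least one continuous covariate "
                "(identifiability condition)"
            )
        beta, se, llf, fitted = _fit_weighted(y, x)
    else:
        raise ValueError(f"unknown method {method!r}")

    k = len(beta)
    aic = 2 * k - 2 * llf
    ci = np.column_stack([beta - 1.96 * se, beta + 1.96 * se])
    used_fit = fitted[y == 1]
    return RSPFModel(
        focal_taxon=ua.focal_taxon, method=method, terms=list(terms),
        columns=names, beta=beta, se=se, ci=ci, aic=float(aic),
        llf=float(llf), fitted=fitted, response=y,
        mean_use=float(used_fit.mean()), sd_use=float(used_fit.std(ddof=0)),
    )


def _fit_naive(y, x):
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        model = sm.GLM(y, x, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=200)
        except PerfectSeparationWarning as exc:
            raise SeparationError(
                "complete separation: the response is perfectly predicted"
            ) from exc
        except Exception as exc:  # pragma: no cover - statsmodels variants
            raise SeparationError(f"logistic fit failed: {exc}") from exc
    beta = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    if not np.all(np.isfinite(se)) or np.max(np.abs(beta)) > 50:
        raise SeparationError(
            "complete separation suspected: unbounded coefficient estimates"
        )
    fitted = expit(x @ beta)
    return beta, se, float(res.llf), fitted


def _weighted_loglik(beta, y, x):
    eta = x @ beta
    pi = expit(eta)
    used = y == 1
    # log pi on used rows, computed stably via -log1p(exp(-eta))
    ll_used = -np.logaddexp(0.0, -eta[used]).sum()
    mean_avail = pi[~used].mean()
    if mean_avail <= 0:
        return -np.inf
    return ll_used - used.sum() * np.log(mean_avail)


def _fit_weighted(y, x):
    start, _, _, _ = _fit_naive(y, x)
    nll = lambda b: -_weighted_loglik(b, y, x)
    res = optimize.minimize(nll, start, method="BFGS",
                            options={"gtol": 1e-7, "maxiter": 500})
    beta = res.x
    if np.max(np.abs(beta)) > 50:
        raise SeparationError("weighted MLE diverged (separation?)")
    hess = approx_hess2(beta, nll)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError as exc:
        raise SeparationError("singular Hessian in weighted MLE") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    fitted = expit(x @ beta)
    return beta, se, float(-res.fun), fitted


def stepwise_aic(
    ua: UseAvailabilityTable,
    covariate_pool: list[str] | None = None,
    method: str = "naive_logistic",
) -> list[RSPFModel]:
    """Forward-stepwise model building ranked by AIC.

    Starts from the single-covariate models, repeatedly adds the covariate
    that lowers AIC most, and returns every model fitted along the way
    sorted by AIC, with delta_aic filled in (best model has 0; models with
    delta <= 2 share empirical support).
    """
    pool = list(covariate_pool or COVARIATE_POOL)
    # drop covariates that are constant in this table (e.g. single season)
    usable = []
    for t in pool:
        if t in CONTINUOUS and ua.table[t].std(ddof=0) == 0:
            continue
        if t in CATEGORICAL and ua.table[t].astype(str).nunique() < 2:
            continue
        usable.append(t)

    models: list[RSPFModel] = []
    current: list[str] = []
    if method == "naive_logistic":
        models.append(fit_rspf(ua, [], method=method))  # intercept-only
        best_aic = models[-1].aic
    else:
        best_aic = np.inf
    while True:
        candidates = []
        for t in usable:
            if t in current:
                continue
            try:
                m = fit_rspf(ua, current + [t], method=method)
            except (SeparationError, ValueError) as exc:
                logger.debug("skipping %s + %s: %s", current, t, exc)
                continue
            candidates.append((t, m))
        if not candidates:
            break
        t_best, m_best = min(candidates, key=lambda tm: tm[1].aic)
        models.extend(m for _, m in candidates)
        if m_best.aic < best_aic:
            best_aic = m_best.aic
            current = current + [t_best]
        else:
            break
    models.sort(key=lambda m: m.aic)
    for m in models:
        m.delta_aic = m.aic - models[0].aic
    return models


def hosmer_lemeshow(model: RSPFModel, g: int = 10) -> tuple[float, float]:
    """Hosmer-Lemeshow goodness of fit on g groups of fitted probability.

    Groups are deciles (quantile bins) of fitted probability; groups with a
    zero expected count are merged with their neighbor.  The statistic is
    compared with chi-square on (g_effective - 2) df.
    """
    if g < 3:
        raise ValueError("Hosmer-Lemeshow needs g >= 3 (df = g - 2 > 0)")
    fitted, y = model.fitted, model.response
    edges = np.quantile(fitted, np.linspace(0, 1, g + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    idx = np.searchsorted(edges, fitted, side="right") - 1
    groups = []
    for b in range(g):
        mask = idx == b
        if mask.any():
            groups.append((y[mask], fitted[mask]))
    # merge groups whose expected used or unused count is ~0
    merged: list[tuple[np.ndarray, np.ndarray]] = []
    for obs, fit in groups:
        if merged and (fit.sum() < 1e-9 or (1 - fit).sum() < 1e-9):
            po, pf = merged[-1]
            merged[-1] = (np.concatenate([po, obs]), np.concatenate([pf, fit]))
            logger.warning("Hosmer-Lemeshow: merged a group with zero expectation")
        else:
            merged.append((obs, fit))
    stat = 0.0
    for obs, fit in merged:
        e1, e0 = fit.sum(), (1 - fit).sum()
        o1 = obs.sum()
        o0 = len(obs) - o1
        if e1 > 0:
            stat += (o1 - e1) ** 2 / e1
        if e0 > 0:
            stat += (o0 - e0) ** 2 / e0
    df = len(merged) - 2
    if df <= 0:
        raise ValueError("too few Hosmer-Lemeshow groups after merging (df <= 0)")
    p = float(stats.chi2.sf(stat, df))
    model.hl_stat, model.hl_p = float(stat), p
    return float(stat), p


def mean_probability_of_use(model: RSPFModel) -> tuple[float, float]:
    """Mean and SD of fitted use probability over the used rows."""
    used = model.fitted[model.response == 1]
    return float(used.mean()), float(used.std(ddof=0))
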