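"""Negative-binomial mixed model with a facility random intercept.

Model
-----
Counts y_ij (resident j in facility i, or one row per facility) follow

    y_ij | b_i ~ NB2(mu_ij, k),   mu_ij = exp(x_ij' beta + o_ij + b_i),
    b_i ~ Normal(0, sigma_b^2),

with NB2 variance mu + mu^2/k (k is the size/dispersion parameter; k -> inf
recovers Poisson). The offset o_ij is log person-time by default, making
exp(x'beta) a rate per person-year. The marginal likelihood integrates the
random intercept out facility by facility with adaptive Gauss-Hermite
quadrature centred and scaled at the per-facility posterior mode (one node
gives the Laplace approximation).

Estimation maximises the marginal log-likelihood over (beta, log sigma_b,
log k) by L-BFGS-B; standard errors come from the inverse observed
information (central-difference Hessian), and Wald p-values are two-sided
normal. Backward elimination repeatedly drops the covariate with the
largest Wald p until all retained covariates meet the significance
threshold.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import ModelError
from .exposure import FacilityAggregate

logger = logging.getLogger("pahrank")

_ETA_MAX = 300.0  # clip linear predictor before exp to keep arithmetic finite
_Y_LOOP_MAX = 64  # exact product form of the NB gamma ratio up to this count


@dataclass(frozen=True)
class NBMMSpec:
    """Specification of the mixed model.

    ``covariates`` name columns of the data frame; an intercept is always
    included first and never eliminated. ``quadrature_points=1`` is the
    Laplace approximation.
    """

    covariates: tuple[str, ...] = ()
    response: str = "pah_count"
    group: str = "facility_id"
    exposure: str = "person_years"
    offset_mode: str = "log_person_time"  # or "none"
    quadrature_points: int = 15

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if self.offset_mode not in ("log_person_time", "none"):
            raise ModelError(f"unknown offset_mode {self.offset_mode!r}")
        if self.quadrature_points < 1:
            raise ModelError("quadrature_points must be >= 1")


@dataclass
class FittedNBMM:
    """A fitted model: coefficients, variance components and inference."""

    names: tuple[str, ...]  # "intercept" first, then covariates
    beta: np.ndarray
    sigma_b: float
    dispersion_k: float
    se: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    converged: bool
    n_facilities: int
    n_units: int
    spec: NBMMSpec
    elimination_trace: list[tuple[str, float]] = field(default_factory=list)

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def summary_dict(self) -> dict:
        return {
            "coefficients": {
                n: {"estimate": float(b), "se": float(s), "p": float(p)}
                for n, b, s, p in zip(self.names, self.beta, self.se, self.p_values)
            },
            "sigma_b": float(self.sigma_b),
            "dispersion_k": float(self.dispersion_k),
            "log_likelihood": float(self.log_likelihood),
            "converged": bool(self.converged),
            "n_facilities": int(self.n_facilities),
            "n_units": int(self.n_units),
            "offset_mode": self.spec.offset_mode,
            "elimination_trace": [
                {"covariate": n, "p": float(p)} for n, p in self.elimination_trace
            ],
        }


# ---------------------------------------------------------------------------
# NB2 log pmf

def nb_log_pmf(y, mu, k):
    """Log NB2 probability mass, gamma form, continuous in mu and k.

    Uses the product form of Gamma(y+k)/Gamma(k) for small counts so the
    Poisson limit (k -> inf) is reached without catastrophic cancellation.
    Raises on non-positive mu or k.
    """
    y_arr = np.atleast_1d(np.asarray(y))
    mu_arr = np.atleast_1d(np.asarray(mu, dtype=float))
    k = float(k)
    if k <= 0:
        raise ModelError("dispersion k must be > 0")
    if np.any(mu_arr <= 0):
        raise ModelError("mean mu must be > 0")
    if np.any(y_arr < 0) or np.any(y_arr != np.floor(y_arr)):
        raise ModelError("counts y must be nonnegative integers")
    y_arr, mu_arr = np.broadcast_arrays(y_arr.astype(float), mu_arr)
    out = _nb_log_pmf_core(y_arr, mu_arr, k)
    return float(out[0]) if np.isscalar(y) and np.isscalar(mu) else out


def _nb_log_pmf_core(y: np.ndarray, mu: np.ndarray, k: float) -> np.ndarray:
    l1p = np.log1p(mu / k)
    ymax = int(y.max(initial=0))
    if ymax <= _Y_LOOP_MAX:
        t1 = np.zeros_like(mu)
        for j in range(ymax):
            m = y > j
            t1[m] += math.log1p(j / k) - l1p[m]
    else:
        t1 = special.gammaln(y + k) - special.gammaln(k) - y * math.log(k) - y * l1p
    return t1 + y * np.log(mu) - k * l1p - special.gammaln(y + 1.0)


# ---------------------------------------------------------------------------
# data container

class _ModelData:
    """Design matrix, response, offset and group index, sorted by group."""

    def __init__(self, X, y, offset, gidx, n_groups, unit_ids, group_ids):
        self.X, self.y, self.offset = X, y, offset
        self.gidx, self.n_groups = gidx, n_groups
        self.unit_ids, self.group_ids = unit_ids, group_ids
        self.n_units, self.p = X.shape

    @classmethod
    def from_frame(cls, data: pd.DataFrame, spec: NBMMSpec) -> "_ModelData":
        for col in (spec.response, spec.group, *spec.covariates):
            if col not in data.columns:
                raise ModelError(f"data is missing column {col!r}")
        df = data.sort_values(spec.group, kind="stable").reset_index(drop=True)
        y = df[spec.response].to_numpy(dtype=float)
        if np.any(y < 0):
            raise ModelError("response counts must be nonnegative")
        if spec.offset_mode == "log_person_time":
            if spec.exposure not in df.columns:
                raise ModelError(f"data is missing exposure column {spec.exposure!r}")
            expo = df[spec.exposure].to_numpy(dtype=float)
            zero = expo <= 0
            if np.any(zero & (y > 0)):
                bad = df.loc[zero & (y > 0)].iloc[0]
                raise ModelError(
                    f"unit {bad.get('resident_id', bad[spec.group])!r} has events "
                    "but zero exposure"
                )
            if np.any(zero):
                logger.warning("stage=fit dropped_zero_exposure_units=%d", int(zero.sum()))
                df = df.loc[~zero].reset_index(drop=True)
                y = y[~zero]
                expo = expo[~zero]
            offset = np.log(expo)
        else:
            offset = np.zeros(len(df))
        groups, gidx = np.unique(df[spec.group].to_numpy(), return_inverse=True)
        X = np.column_stack(
            [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in spec.covariates]
        )
        unit_ids = (
            df["resident_id"].to_numpy()
            if "resident_id" in df.columns
            else df[spec.group].to_numpy()
        )
        return cls(X, y, offset, gidx, len(groups), unit_ids, groups)

    def gsum(self, values: np.ndarray) -> np.ndarray:
        return np.bincount(self.gidx, weights=values, minlength=self.n_groups)


# ---------------------------------------------------------------------------
# marginal likelihood

def _check_eta(md: _ModelData, eta: np.ndarray) -> None:
    if not np.all(np.isfinite(eta)):
        i = int(np.argmax(~np.isfinite(eta)))
        raise ModelError(
            f"non-finite linear predictor for unit {md.unit_ids[i]!r} "
            f"in facility {md.group_ids[md.gidx[i]]!r}"
        )


def _find_modes(md: _ModelData, eta0: np.ndarray, k: float, sb2: float,
                tol: float = 1e-11, maxit: int = 200):
    """Vectorised per-facility Newton for the posterior mode of b_i.

    The joint log-density is strictly concave in b (NB log-pmf curvature is
    negative, Gaussian prior adds -1/sigma^2), so damped Newton converges;
    steps are clipped for global safety.
    """
    y = md.y
    b = np.zeros(md.n_groups)
    info = np.full(md.n_groups, 1.0 / sb2)
    for _ in range(maxit):
        mu = np.exp(np.clip(eta0 + b[md.gidx], -_ETA_MAX, _ETA_MAX))
        score = md.gsum(y - (y + k) * mu / (k + mu)) - b / sb2
        info = md.gsum((y + k) * k * mu / (k + mu) ** 2) + 1.0 / sb2
        step = np.clip(score / info, -2.0, 2.0)
        b += step
        if np.max(np.abs(step)) < tol:
            break
    return b, info


def _group_loglik(md: _ModelData, eta0: np.ndarray, b: np.ndarray, k: float) -> np.ndarray:
    mu = np.exp(np.clip(eta0 + b[md.gidx], -_ETA_MAX, _ETA_MAX))
    return md.gsum(_nb_log_pmf_core(md.y, mu, k))


def marginal_log_likelihood(spec: NBMMSpec, params, data) -> float:
    """Marginal log-likelihood at ``params = (beta, log_sigma_b, log_k)``.

    ``log_sigma_b = -inf`` (sigma_b = 0) degenerates to the sum of
    independent NB log-pmfs at b = 0. ``data`` may be a prepared data frame
    or an internal compiled container.
    """
    beta, log_sigma_b, log_k = params
    md = data if isinstance(data, _ModelData) else _ModelData.from_frame(data, spec)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (md.p,):
        raise ModelError(f"beta has length {beta.shape}, expected {md.p}")
    k = math.exp(log_k) if np.isfinite(log_k) else math.inf
    sigma_b = 0.0 if log_sigma_b == -math.inf else math.exp(log_sigma_b)

    eta0 = md.X @ beta + md.offset
    _check_eta(md, eta0)

    if sigma_b == 0.0:
        return float(_group_loglik(md, eta0, np.zeros(md.n_groups), k).sum())

    sb2 = sigma_b * sigma_b
    b_hat, info = _find_modes(md, eta0, k, sb2)
    scale = 1.0 / np.sqrt(info)  # adaptive scale per facility

    z, w = np.polynomial.hermite.hermgauss(spec.quadrature_points)
    logw = np.log(w) + z * z
    lg = np.empty((spec.quadrature_points, md.n_groups))
    sqrt2 = math.sqrt(2.0)
    for q in range(spec.quadrature_points):
        bq = b_hat + sqrt2 * scale * z[q]
        lg[q] = (
            _group_loglik(md, eta0, bq, k)
            - 0.5 * math.log(2.0 * math.pi * sb2)
            - bq * bq / (2.0 * sb2)
        )
    ll_groups = special.logsumexp(lg + logw[:, None], axis=0)
    ll_groups += 0.5 * math.log(2.0) + np.log(scale)
    return float(ll_groups.sum())


# ---------------------------------------------------------------------------
# fitting

def _num_hessian(fun, x: np.ndarray, h_rel: float = 5e-4) -> np.ndarray:
    p = len(x)
    h = h_rel * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            if i == j:
                H[i, i] = (fun(x + ei) - 2.0 * fun(x) + fun(x - ei)) / (h[i] * h[i])
            else:
                H[i, j] = H[j, i] = (
                    fun(x + ei + ej) - fun(x + ei - ej)
                    - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4.0 * h[i] * h[j])
    return H


def fit(
    spec: NBMMSpec,
    data: pd.DataFrame,
    init: tuple | None = None,
    fix_sigma_b: float | None = None,
    fix_k: float | None = None,
) -> FittedNBMM:
    """Maximise the marginal likelihood and return a :class:`FittedNBMM`.

    ``fix_sigma_b``/``fix_k`` pin a variance component (``fix_sigma_b=0``
    drops the random effect entirely — the plain NB/Poisson limit used by
    oracle tests). ``init`` optionally supplies (beta, log_sigma_b, log_k)
    starting values; the default start is a closed-form intercept with
    zero slopes.
    """
    md = _ModelData.from_frame(data, spec)
    if md.n_groups < 2 and fix_sigma_b is None:
        raise ModelError("need >= 2 facilities to estimate a random intercept")
    p = md.p

    if init is not None:
        beta0 = np.asarray(init[0], dtype=float).copy()
        ls0, lk0 = float(init[1]), float(init[2])
    else:
        expo = np.exp(md.offset) if spec.offset_mode == "log_person_time" else np.full(md.n_units, 1.0)
        beta0 = np.zeros(p)
        beta0[0] = math.log((md.y.sum() + 0.5) / expo.sum())
        ls0, lk0 = math.log(0.3), math.log(2.0)

    free_sigma = fix_sigma_b is None
    free_k = fix_k is None
    if not free_sigma and fix_sigma_b < 0:
        raise ModelError("fix_sigma_b must be >= 0")
    if not free_k and fix_k <= 0:
        raise ModelError("fix_k must be > 0")

    def unpack(theta: np.ndarray):
        beta = theta[:p]
        pos = p
        if free_sigma:
            ls = theta[pos]; pos += 1
        else:
            ls = -math.inf if fix_sigma_b == 0 else math.log(fix_sigma_b)
        lk = theta[pos] if free_k else math.log(fix_k)
        return beta, ls, lk

    x0 = np.concatenate([beta0, [ls0] if free_sigma else [], [lk0] if free_k else []])
    bounds = [(None, None)] * p
    if free_sigma:
        bounds.append((math.log(1e-6), math.log(50.0)))
    if free_k:
        bounds.append((math.log(1e-6), math.log(1e9)))

    def nll(theta: np.ndarray) -> float:
        try:
            val = -marginal_log_likelihood(spec, unpack(theta), md)
        except (FloatingPointError, OverflowError):
            return 1e12
        return val if np.isfinite(val) else 1e12

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", jac="3-point", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-5},
        )
        theta = res.x
        beta, ls, lk = unpack(theta)
        ll = -nll(theta)
        converged = bool(res.success) and np.isfinite(ll)
        if not converged:
            warnings.warn(f"NBMM fit did not converge: {res.message}", stacklevel=2)

        # Wald inference from the observed information of the free parameters.
        se = np.full(p, np.nan)
        rank_deficient = np.linalg.matrix_rank(md.X) < p
        if rank_deficient:
            warnings.warn(
                "design matrix is rank-deficient (singular information); "
                "standard errors unavailable",
                stacklevel=2,
            )
        else:
            H = _num_hessian(nll, theta)
            try:
                cov = np.linalg.inv(H)
                dvar = np.diag(cov)[:p]
                if np.any(~np.isfinite(dvar)) or np.any(dvar <= 0):
                    raise np.linalg.LinAlgError("non-positive variance")
                se = np.sqrt(dvar)
            except np.linalg.LinAlgError:
                warnings.warn(
                    "singular observed information; standard errors unavailable",
                    stacklevel=2,
                )
    with np.errstate(invalid="ignore", divide="ignore"):
        zval = np.asarray(beta) / se
        p_values = 2.0 * stats.norm.sf(np.abs(zval))

    model = FittedNBMM(
        names=("intercept", *spec.covariates),
        beta=np.asarray(beta, dtype=float),
        sigma_b=0.0 if ls == -math.inf else math.exp(ls),
        dispersion_k=math.exp(lk),
        se=se,
        p_values=p_values,
        log_likelihood=ll,
        converged=converged,
        n_facilities=md.n_groups,
        n_units=md.n_units,
        spec=spec,
    )
    logger.info(
        "stage=fit n_units=%d n_facilities=%d loglik=%.4f sigma_b=%.4f k=%.4g converged=%s",
        md.n_units, md.n_groups, ll, model.sigma_b, model.dispersion_k, converged,
    )
    return model


# ---------------------------------------------------------------------------
# backward elimination

def backward_eliminate(
    spec: NBMMSpec,
    data: pd.DataFrame,
    alpha: float = 0.05,
    **fit_kwargs,
) -> tuple[FittedNBMM, list[tuple[str, float]]]:
    """Backward elimination on Wald p-values.

    Repeatedly refits after removing the covariate with the largest p-value
    (ties broken by the smaller absolute standardized effect, then name)
    until every retained covariate has p <= alpha. The intercept is never
    a candidate. The candidate list is canonicalised (sorted) first, so the
    retained set does not depend on the order covariates were listed.
    Returns the final fit and the removal trace [(name, p), ...].
    """
    if not 0 < alpha <= 1:
        raise ModelError("alpha must be in (0, 1]")
    if not spec.covariates:
        raise ModelError("candidate covariate list is empty")
    cands = sorted(spec.covariates)
    trace: list[tuple[str, float]] = []
    while True:
        cur = replace(spec, covariates=tuple(cands))
        model = fit(cur, data, **fit_kwargs)
        if not cands:
            logger.info("stage=eliminate note=all_covariates_eliminated")
            break
        pv = model.p_values[1:]
        zabs = np.abs(model.beta[1:] / model.se[1:])
        # NaN p (singular information) is treated as maximally removable.
        order = sorted(
            range(len(cands)),
            key=lambda i: (
                -(1.1 if np.isnan(pv[i]) else pv[i]),
                np.inf if np.isnan(zabs[i]) else zabs[i],
                cands[i],
            ),
        )
        worst = order[0]
        worst_p = pv[worst]
        if not np.isnan(worst_p) and worst_p <= alpha:
            break
        trace.append((cands[worst], float(worst_p)))
        logger.info("stage=eliminate removed=%s p=%.4g remaining=%d",
                    cands[worst], worst_p, len(cands) - 1)
        del cands[worst]
    model.elimination_trace = list(trace)
    return model, trace


# ---------------------------------------------------------------------------
# prediction

def predict_facility_counts(
    model: FittedNBMM,
    aggregates: "list[FacilityAggregate] | pd.DataFrame",
) -> pd.Series:
    """Population-level expected PAH count per facility (random effect 0).

    expected = exposure * exp(x'beta), with exposure the facility
    person-years under the log offset, or 1 under ``offset_mode='none'``.
    The facility covariate values are the resident-level proportions/means,
    mirroring how a resident-level model is applied at facility level.
    """
    df = aggregates_frame(aggregates) if not isinstance(aggregates, pd.DataFrame) else aggregates
    missing = [c for c in model.names[1:] if c not in df.columns]
    if missing:
        raise ModelError(f"aggregates are missing model covariate(s) {missing}")
    X = np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in model.names[1:]]
    )
    eta = X @ model.beta
    if model.spec.offset_mode == "log_person_time":
        expo = df["person_years"].to_numpy(dtype=float)
    else:
        expo = np.ones(len(df))
    pred = expo * np.exp(eta)
    return pd.Series(pred, index=pd.Index(df["facility_id"], name="facility_id"),
                     name="predicted")


# ---------------------------------------------------------------------------
# frame builders

def resident_frame(
    residents,
    pah_counts: dict[str, int],
    window,
) -> pd.DataFrame:
    """Per-resident model rows: response, exposure, facility and covariates."""
    from .exposure import person_time

    rows = []
    for r in residents:
        row = {
            "resident_id": r.resident_id,
            "facility_id": r.facility_id,
            "pah_count": pah_counts.get(r.resident_id, 0),
            "person_years": person_time(r, window),
            "age_years": r.age_years,
        }
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def aggregates_frame(aggregates: Sequence[FacilityAggregate]) -> pd.DataFrame:
    """Per-facility model rows from :class:`FacilityAggregate` records."""
    rows = []
    for a in aggregates:
        row = {
            "facility_id": a.facility_id,
            "n_residents": a.n_residents,
            "pah_count": a.pah_count,
            "person_years": a.person_years,
            "n_beds": a.n_beds,
            "stratum": a.stratum,
            "flagged": a.flagged,
        }
        row.update(a.covariate_props)
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "NBMMSpec", "FittedNBMM", "nb_log_pmf", "marginal_log_likelihood", "fit",
    "backward_eliminate", "predict_facility_counts", "resident_frame",
    "aggregates_frame",
]
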