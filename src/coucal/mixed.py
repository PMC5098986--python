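"""Hierarchical models for incubation, provisioning and off-time behaviour.

Three estimation engines live here:

* a generalized linear mixed model (GLMM) with random intercepts for one or
  two (possibly crossed) grouping factors, binomial-logit or Poisson-log
  family, fitted by Laplace-approximate maximum likelihood — the random
  effects and fixed effects are profiled at their joint penalized mode
  (penalized IRLS) and the variance parameters maximize the Laplace
  marginal likelihood;
* a Gaussian linear mixed model fitted by dense marginal (restricted)
  maximum likelihood, with optional case weights (used for the off-time
  model, where the perched proportion of a watch is weighted by the watch
  duration);
* flat-prior posterior simulation: draws from a multivariate normal centred
  at the estimates with the estimated covariance, whose 2.5/97.5 percentiles
  are the 95% credible intervals, plus marginal/conditional R-squared by
  variance partitioning (fixed-effect variance vs. random-effect variance
  vs. the family-specific residual variance).

All fits are deterministic given the data (optimizers start from ordinary
GLM estimates); posterior simulation is deterministic given its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.linalg import cho_factor, cho_solve

_SD_FLOOR = 1e-8
_BOUNDARY_TOL = 1e-5


# --------------------------------------------------------------------------
# families
# --------------------------------------------------------------------------


class _Binomial:
    name = "binomial"

    @staticmethod
    def loglik(y, eta):
        # logistic log-likelihood, numerically safe for large |eta|
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    @staticmethod
    def mu(eta):
        return special.expit(eta)

    @staticmethod
    def weight(eta):
        p = special.expit(eta)
        return p * (1.0 - p)


class _Poisson:
    name = "poisson"

    @staticmethod
    def loglik(y, eta):
        return float(np.sum(y * eta - np.exp(eta) - special.gammaln(y + 1.0)))

    @staticmethod
    def mu(eta):
        return np.exp(eta)

    @staticmethod
    def weight(eta):
        return np.exp(eta)


_FAMILIES = {"binomial": _Binomial, "poisson": _Poisson}


# --------------------------------------------------------------------------
# fit container
# --------------------------------------------------------------------------


@dataclass
class ModelFit:
    """Fitted-model container shared by all model types.

    ``params``/``cov`` are the fixed effects and their Wald covariance
    (conditional on the variance parameters, the convention of mixed-model
    software).  ``re_sd`` holds the random-intercept SD per grouping factor
    (link scale), ``resid_sd`` the Gaussian residual SD (None otherwise).
    ``scaler`` stores the mean/SD used to standardize each covariate so
    slopes can be back-transformed to natural units.
    """

    family: str
    param_names: list
    params: np.ndarray
    cov: np.ndarray
    re_sd: dict
    loglik: float
    resid_sd: float | None = None
    method: str = ""
    scaler: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)
    var_fixed: float = np.nan
    mean_eta_fixed: float = np.nan
    draws: np.ndarray | None = None
    cri: dict = field(default_factory=dict)
    n_obs: int = 0

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov))
        out = pd.DataFrame(
            {"estimate": self.params, "se": se}, index=self.param_names
        )
        if self.cri:
            out["cri_lo"] = [self.cri[p][0] for p in self.param_names]
            out["cri_hi"] = [self.cri[p][1] for p in self.param_names]
        return out

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": dict(zip(self.param_names, map(float, self.params))),
            "se": dict(zip(self.param_names, map(float, np.sqrt(np.diag(self.cov))))),
            "re_sd": {k: float(v) for k, v in self.re_sd.items()},
            "resid_sd": None if self.resid_sd is None else float(self.resid_sd),
            "loglik": float(self.loglik),
            "method": self.method,
            "flags": self.flags,
            "cri": {k: [float(a), float(b)] for k, (a, b) in self.cri.items()},
            "n_obs": int(self.n_obs),
        }


# --------------------------------------------------------------------------
# GLMM engine (binomial / Poisson, Laplace)
# --------------------------------------------------------------------------


def _group_codes(groups: list) -> tuple[list[np.ndarray], list[int]]:
    codes, sizes = [], []
    for g in groups:
        c, levels = pd.factorize(np.asarray(g))
        codes.append(c.astype(int))
        sizes.append(len(levels))
    return codes, sizes


def _eta_of(X, codes, sizes, u, offset):
    p = X.shape[1]
    eta = X @ u[:p] + offset
    j = p
    for c, m in zip(codes, sizes):
        eta = eta + u[j : j + m][c]
        j += m
    return eta


def _grad_of(X, codes, sizes, r):
    """[X | Z1 | Z2]' r without materializing the indicator columns."""
    parts = [X.T @ r]
    for c, m in zip(codes, sizes):
        parts.append(np.bincount(c, weights=r, minlength=m))
    return np.concatenate(parts)


def _hessian_of(X, codes, sizes, w):
    """[X | Z]' W [X | Z] assembled from group indices.

    Indicator structure makes every Z'WZ block either diagonal (same
    factor) or a scatter-add cross table (two crossed factors), so the
    assembly is O(n) instead of a dense n x (p+q) product.
    """
    p = X.shape[1]
    tot = p + sum(sizes)
    H = np.zeros((tot, tot))
    Xw = X * w[:, None]
    H[:p, :p] = Xw.T @ X
    offs = []
    j = p
    for c, m in zip(codes, sizes):
        offs.append(j)
        for a in range(p):
            col = np.bincount(c, weights=Xw[:, a], minlength=m)
            H[a, j : j + m] = col
            H[j : j + m, a] = col
        idx = j + np.arange(m)
        H[idx, idx] = np.bincount(c, weights=w, minlength=m)
        j += m
    if len(codes) == 2:
        (c1, c2), (m1, m2) = codes, sizes
        cross = np.zeros((m1, m2))
        np.add.at(cross, (c1, c2), w)
        H[offs[0] : offs[0] + m1, offs[1] : offs[1] + m2] = cross
        H[offs[1] : offs[1] + m2, offs[0] : offs[0] + m1] = cross.T
    return H


def _penalized_mode(
    y, X, codes, sizes, fam, offset, sds, beta0=None, ridge=0.0, max_iter=200, u0=None
):
    """Joint penalized-likelihood mode over (beta, b) by damped Newton.

    Returns (u, pen_loglik, pen).  ``u0`` warm starts the Newton iteration
    (e.g. the mode at nearby variance values).
    """
    p = X.shape[1]
    q = sum(sizes)
    pen = np.zeros(p + q)
    pen[:p] = ridge
    j = p
    for sd, m in zip(sds, sizes):
        pen[j : j + m] = 1.0 / max(sd, _SD_FLOOR) ** 2 if sd > 0 else 1.0 / _SD_FLOOR**2
        j += m
    # exact-zero SD: random effects pinned at 0 via huge penalty above
    if u0 is not None:
        u = u0.copy()
    else:
        u = np.zeros(p + q)
        if beta0 is not None:
            u[:p] = beta0

    def objective(u):
        eta = _eta_of(X, codes, sizes, u, offset)
        return fam.loglik(y, eta) - 0.5 * float(np.sum(pen * u**2))

    obj = objective(u)
    for _ in range(max_iter):
        eta = _eta_of(X, codes, sizes, u, offset)
        w = fam.weight(eta)
        grad = _grad_of(X, codes, sizes, y - fam.mu(eta)) - pen * u
        H = _hessian_of(X, codes, sizes, w)
        H[np.diag_indices_from(H)] += pen + 1e-12
        step = cho_solve(cho_factor(H, lower=True), grad)
        t = 1.0
        for _ in range(40):
            new = objective(u + t * step)
            if new >= obj - 1e-12:
                break
            t *= 0.5
        u = u + t * step
        if abs(new - obj) <= 1e-10 * (1.0 + abs(obj)):
            obj = new
            break
        obj = new
    return u, obj, pen


def _laplace_at_mode(y, X, codes, sizes, fam, offset, sds, u):
    """Laplace marginal log-likelihood given the joint mode u."""
    p = X.shape[1]
    eta = _eta_of(X, codes, sizes, u, offset)
    ll = fam.loglik(y, eta)
    b = u[p:]
    j = 0
    logdet_pen = 0.0
    quad = 0.0
    for sd, m in zip(sds, sizes):
        s2 = max(sd, _SD_FLOOR) ** 2
        quad += float(np.sum(b[j : j + m] ** 2)) / s2
        logdet_pen += m * np.log(s2)
        j += m
    # -0.5 log det(I + D Zt W Z) == -0.5 [log det(ZtWZ + D^-1) + log det D]
    w = fam.weight(eta)
    Hbb = _hessian_of(np.empty((len(y), 0)), codes, sizes, w)
    jj = 0
    for sd, m in zip(sds, sizes):
        s2 = max(sd, _SD_FLOOR) ** 2
        Hbb[np.arange(jj, jj + m), np.arange(jj, jj + m)] += 1.0 / s2
        jj += m
    sign, logdet_H = np.linalg.slogdet(Hbb)
    return ll - 0.5 * quad - 0.5 * (logdet_H + logdet_pen)


def laplace_loglik(y, X, groups, family, beta, sds, offset=None) -> float:
    """Laplace marginal log-likelihood at fixed (beta, sds).

    The random effects are set to their conditional mode given ``beta``.
    Used by the test suite to compare against adaptive-free Gauss-Hermite
    quadrature on single-factor problems.
    """
    fam = _FAMILIES[family]
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    offset = np.zeros(len(y)) if offset is None else np.asarray(offset, dtype=float)
    codes, sizes = _group_codes(groups)
    # profile only b: fold X beta into the offset
    off2 = offset + X @ np.asarray(beta, dtype=float)
    X0 = np.empty((len(y), 0))
    u, _, _ = _penalized_mode(y, X0, codes, sizes, fam, off2, list(sds), max_iter=200)
    ub = np.concatenate([np.asarray(beta, dtype=float), u])
    return float(_laplace_at_mode(y, X, codes, sizes, fam, offset, list(sds), ub))


def fit_glmm(
    y,
    X,
    groups: list,
    family: str,
    offset=None,
    param_names: list | None = None,
    group_names: list | None = None,
    fix_sd: dict | None = None,
    ridge: float = 0.0,
) -> ModelFit:
    """Random-intercept GLMM by Laplace-approximate maximum likelihood.

    ``groups`` is a list of 1-2 label arrays (e.g. parent id and nest id,
    treated as crossed).  Variance parameters are optimized on the log-SD
    scale (Nelder-Mead over at most two parameters); fixed effects sit at
    the joint penalized mode given the variance parameters, then the Wald
    covariance is the beta-block of the inverse joint Hessian.  ``fix_sd``
    pins named factors' SDs (e.g. to 0, collapsing the model to an ordinary
    GLM).  ``ridge`` adds an L2 penalty on the fixed effects — the fallback
    used under complete separation.
    """
    fam = _FAMILIES[family]
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    codes, sizes = _group_codes(groups)
    group_names = group_names or [f"group{i}" for i in range(len(groups))]
    param_names = param_names or [f"b{i}" for i in range(p)]
    fix_sd = fix_sd or {}

    # starting values from the ordinary GLM
    import statsmodels.api as sm

    sm_fam = sm.families.Binomial() if family == "binomial" else sm.families.Poisson()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            glm = sm.GLM(y, X, family=sm_fam, offset=offset).fit(maxiter=200)
            beta0 = np.asarray(glm.params, dtype=float)
            separated = bool(np.any(np.abs(beta0) > 15))
        except Exception:
            beta0 = np.zeros(p)
            separated = True
    flags = {}
    if separated and ridge == 0.0:
        ridge = 1e-2
        flags["separation"] = True

    free = [i for i, nm in enumerate(group_names) if nm not in fix_sd]

    def sds_from(theta):
        sds = []
        k = 0
        for i, nm in enumerate(group_names):
            if nm in fix_sd:
                sds.append(float(fix_sd[nm]))
            else:
                sds.append(float(np.exp(np.clip(theta[k], -10, 4))))
                k += 1
        return sds

    cache = {}
    warm = {"u": None}

    def neg_laplace(theta):
        key = tuple(np.round(theta, 12))
        if key in cache:
            return cache[key]
        sds = sds_from(theta)
        u, _, _ = _penalized_mode(
            y, X, codes, sizes, fam, offset, sds, beta0=beta0, ridge=ridge, u0=warm["u"]
        )
        warm["u"] = u
        val = -_laplace_at_mode(y, X, codes, sizes, fam, offset, sds, u)
        if ridge > 0:
            val += 0.5 * ridge * float(np.sum(u[:p] ** 2))
        cache[key] = (val, u)
        return cache[key]

    if free:
        theta0 = np.full(len(free), np.log(0.5))
        res = optimize.minimize(
            lambda t: neg_laplace(t)[0],
            theta0,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400},
        )
        theta_hat = res.x
    else:
        theta_hat = np.zeros(0)
    sds = sds_from(theta_hat)
    nll, u = neg_laplace(theta_hat)

    # Wald covariance: beta block of the inverse joint Hessian at the mode
    eta = _eta_of(X, codes, sizes, u, offset)
    w = fam.weight(eta)
    H = _hessian_of(X, codes, sizes, w)
    pen = np.zeros(p + sum(sizes))
    pen[:p] = ridge
    j = p
    for sd, m in zip(sds, sizes):
        pen[j : j + m] = 1.0 / max(sd, _SD_FLOOR) ** 2
        j += m
    H[np.diag_indices_from(H)] += pen + 1e-12
    Hinv = np.linalg.inv(H)
    cov = Hinv[:p, :p]

    re_sd = dict(zip(group_names, sds))
    for nm, sd in re_sd.items():
        if nm not in fix_sd and sd < _BOUNDARY_TOL:
            flags[f"boundary_{nm}"] = True

    beta = u[:p]
    eta_fix = X @ beta + offset  # offset is a known fixed term (exposure)
    return ModelFit(
        family=family,
        param_names=list(param_names),
        params=beta,
        cov=cov,
        re_sd=re_sd,
        loglik=-nll,
        method="laplace-ml",
        flags=flags,
        var_fixed=float(np.var(eta_fix)),
        mean_eta_fixed=float(np.mean(eta_fix)),
        n_obs=n,
    )


# --------------------------------------------------------------------------
# Gaussian LMM (dense marginal REML/ML, optional case weights)
# --------------------------------------------------------------------------


def fit_gaussian_lmm(
    y,
    X,
    groups: list,
    weights=None,
    reml: bool = True,
    param_names: list | None = None,
    group_names: list | None = None,
) -> ModelFit:
    """Gaussian linear mixed model with random intercepts.

    Maximizes the dense marginal (restricted) likelihood
    ``y ~ N(X beta, sigma_e^2 diag(1/w) + sum_k sigma_k^2 Z_k Z_k')``
    over log-SD parameters; beta is profiled by GLS.  Problem sizes in this
    study are a few hundred rows, so dense n x n algebra is the simplest
    reliable route.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    w = w / w.mean()
    codes, sizes = _group_codes(groups)
    group_names = group_names or [f"group{i}" for i in range(len(groups))]
    param_names = param_names or [f"b{i}" for i in range(p)]
    q = sum(sizes)
    Z = np.zeros((n, q))
    off = 0
    col_factor = np.empty(q, dtype=int)
    for fi, (c, m) in enumerate(zip(codes, sizes)):
        Z[np.arange(n), off + c] = 1.0
        col_factor[off : off + m] = fi
        off += m

    # Woodbury pieces: V0 = diag(1/w) + Z Lam Z' with Lam_k = (sd_k/sd_e)^2;
    # beta and sd_e are profiled out, the optimizer sees only log Lam.
    ZtWZ = (Z.T * w) @ Z
    ZtWX = (Z.T * w) @ X
    ZtWy = (Z.T * w) @ y
    XtWX = (X.T * w) @ X
    XtWy = (X.T * w) @ y
    ytWy = float(y @ (w * y))
    sum_log_w = float(np.sum(np.log(w)))

    def profile(log_lam):
        lam = np.exp(np.clip(log_lam, -24, 12))
        s = np.sqrt(lam[col_factor])
        B = (s[:, None] * ZtWZ) * s[None, :]
        B[np.diag_indices_from(B)] += 1.0
        ch = cho_factor(B, lower=True)
        logdet_V0 = -sum_log_w + 2.0 * float(np.sum(np.log(np.diag(ch[0]))))
        SX, Sy = s[:, None] * ZtWX, s * ZtWy
        Bi_SX, Bi_Sy = cho_solve(ch, SX), cho_solve(ch, Sy)
        XtViX = XtWX - SX.T @ Bi_SX
        XtViy = XtWy - SX.T @ Bi_Sy
        ytViy = ytWy - float(Sy @ Bi_Sy)
        beta = np.linalg.solve(XtViX, XtViy)
        rss = max(ytViy - float(beta @ XtViy), 1e-12)
        dof = n - p if reml else n
        s2_e = rss / dof
        ll = -0.5 * (logdet_V0 + n * np.log(s2_e) + rss / s2_e + n * np.log(2 * np.pi))
        if reml:
            sign, ld2 = np.linalg.slogdet(XtViX / s2_e)
            ll -= 0.5 * ld2 - 0.5 * p * np.log(2 * np.pi)
        return ll, beta, XtViX, s2_e

    def neg_ll(log_lam):
        try:
            return -profile(log_lam)[0]
        except np.linalg.LinAlgError:
            return 1e10

    theta0 = np.full(len(sizes), np.log(0.5))
    res = optimize.minimize(
        neg_ll,
        theta0,
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000, "maxfev": 4000},
    )
    ll_hat, beta, XtViX, s2_e = profile(res.x)
    s_e = float(np.sqrt(s2_e))
    cov = np.linalg.inv(XtViX) * s2_e
    lam_hat = np.exp(np.clip(res.x, -24, 12))
    sds = [float(np.sqrt(lk) * s_e) for lk in lam_hat]
    sd_y = float(np.std(y)) or 1.0
    flags = {}
    for nm, sd in zip(group_names, sds):
        if sd < _BOUNDARY_TOL * sd_y:
            flags[f"boundary_{nm}"] = True
    eta_fix = X @ beta
    return ModelFit(
        family="gaussian",
        param_names=list(param_names),
        params=beta,
        cov=cov,
        re_sd=dict(zip(group_names, sds)),
        resid_sd=float(s_e),
        loglik=-float(res.fun),
        method="reml" if reml else "ml",
        flags=flags,
        var_fixed=float(np.var(eta_fix)),
        mean_eta_fixed=float(np.mean(eta_fix)),
        n_obs=n,
    )


# --------------------------------------------------------------------------
# design-matrix helpers
# --------------------------------------------------------------------------


def _standardize(s: pd.Series) -> tuple[np.ndarray, dict]:
    mu, sd = float(s.mean()), float(s.std())
    sd = sd if sd > 0 else 1.0
    return ((s - mu) / sd).to_numpy(), {"mean": mu, "sd": sd}


def _species_sex_design(df: pd.DataFrame) -> tuple[np.ndarray, list[str], dict]:
    """Intercept + species + sex (+ interaction when estimable).

    Reference cell: black-coucal male (the uniparental carer).  Collinear
    columns (e.g. the interaction when a stratum is absent) are dropped.
    """
    n = len(df)
    cols = {"intercept": np.ones(n)}
    sp = (df["species"] == "white-browed").to_numpy(float)
    sx = (df["sex"] == "female").to_numpy(float)
    if sp.var() > 0:
        cols["species_wb"] = sp
    if sx.var() > 0:
        cols["sex_female"] = sx
    if sp.var() > 0 and sx.var() > 0:
        cols["species_wb:sex_female"] = sp * sx
    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    # QR rank check; drop trailing collinear columns
    while np.linalg.matrix_rank(X) < X.shape[1]:
        X = X[:, :-1]
        names = names[:-1]
    return X, names, {}


# --------------------------------------------------------------------------
# model wrappers
# --------------------------------------------------------------------------


def fit_binomial_glmm(checks: pd.DataFrame) -> ModelFit:
    """Which sex incubates: binomial GLMM of check outcomes.

    Response is male-incubating (1/0), covariate the centred time of day,
    random intercept per nest.  The back-transformed intercept is the
    population-median probability that the male is the incubating bird.
    Complete separation triggers a ridge-penalized fallback, flagged in
    ``fit.flags``.
    """
    if checks["nest_id"].nunique() < 2:
        raise ValueError("need >= 2 nests to estimate a nest random effect")
    y = (checks["sex_incubating"] == "male").to_numpy(float)
    t_c, scal = _standardize(checks["time_of_day"])
    X = np.column_stack([np.ones(len(y)), t_c])
    fit = fit_glmm(
        y,
        X,
        [checks["nest_id"].to_numpy()],
        family="binomial",
        param_names=["intercept", "time_c"],
        group_names=["nest"],
    )
    fit.scaler = {"time_of_day": scal}
    fit.flags["p_male_median"] = float(special.expit(fit.params[0]))
    return fit


def _validate_focal(obs: pd.DataFrame) -> pd.DataFrame:
    if (obs["duration_min"] <= 0).any():
        raise ValueError("watch duration must be positive")
    bad = obs["perch_min"] > obs["duration_min"] if "perch_min" in obs else None
    if bad is not None and bad.any():
        raise ValueError(f"{int(bad.sum())} rows have perch time exceeding watch duration")
    if (obs["feeding_visits"] < 0).any():
        raise ValueError("feeding visits must be non-negative")
    return obs


def fit_poisson_glmm(obs: pd.DataFrame, covariate_set: str = "brood_mass") -> ModelFit:
    """Feeding-visit rate: Poisson GLMM with log watch duration as offset.

    Fixed effects: species, sex, their interaction (when estimable) and, per
    ``covariate_set``, either standardized brood mass or standardized
    nestling number plus mean nestling age; time of day always enters
    standardized.  Random intercepts: feeding parent and nest (crossed).
    A species-sex stratum whose visit counts are all zero (female black
    coucals) is dropped with a flag — their non-provisioning is a
    descriptive fact, not a rate to estimate.
    """
    obs = _validate_focal(obs).copy()
    zero = obs.groupby(["species", "sex"])["feeding_visits"].transform("max") == 0
    dropped = sorted(set(map(tuple, obs.loc[zero, ["species", "sex"]].to_numpy())))
    if zero.all():
        raise ValueError("all strata have zero feeding visits")
    obs = obs.loc[~zero].reset_index(drop=True)

    X, names, _ = _species_sex_design(obs)
    scaler = {}
    if covariate_set == "brood_mass":
        z, scaler["brood_mass_g"] = _standardize(obs["brood_mass_g"])
        X = np.column_stack([X, z])
        names = names + ["brood_mass_z"]
    elif covariate_set == "nestlings_age":
        z1, scaler["n_nestlings"] = _standardize(obs["n_nestlings"])
        z2, scaler["mean_age_d"] = _standardize(obs["mean_age_d"])
        X = np.column_stack([X, z1, z2])
        names = names + ["n_nestlings_z", "mean_age_z"]
    else:
        raise ValueError(f"unknown covariate_set {covariate_set!r}")
    zt, scaler["time_of_day"] = _standardize(obs["time_of_day"])
    X = np.column_stack([X, zt])
    names = names + ["time_z"]

    fit = fit_glmm(
        obs["feeding_visits"].to_numpy(float),
        X,
        [obs["parent_id"].to_numpy(), obs["nest_id"].to_numpy()],
        family="poisson",
        offset=np.log(obs["duration_min"].to_numpy(float)),
        param_names=names,
        group_names=["parent", "nest"],
    )
    fit.scaler = scaler
    if dropped:
        fit.flags["dropped_zero_strata"] = [list(d) for d in dropped]
        warnings.warn(
            f"dropped all-zero feeding strata: {dropped}", UserWarning, stacklevel=2
        )
    return fit


def fit_lmm(daily: pd.DataFrame, response: str = "n_bouts") -> ModelFit:
    """Species comparison of daily incubation summaries (Gaussian LMM).

    ``response`` is ``n_bouts`` or ``total_absence`` (one row per nest-day;
    species fixed effect, nest random intercept) or ``bout_duration``
    (per-bin mean durations stacked long, adding time-of-day bin fixed
    effects).
    """
    df = daily.copy()
    if df.groupby("species")["nest_id"].nunique().min() < 2:
        raise ValueError("need >= 2 nests per species")
    names = ["intercept", "species_wb"]
    if response in ("n_bouts", "total_absence"):
        col = {"n_bouts": "n_bouts", "total_absence": "total_absence_min"}[response]
        y = df[col].to_numpy(float)
        X = np.column_stack(
            [np.ones(len(df)), (df["species"] == "white-browed").to_numpy(float)]
        )
        nests = df["nest_id"].to_numpy()
    elif response == "bout_duration":
        longs = []
        for name in ("morning", "noon", "afternoon"):
            sub = df[["nest_id", "species", f"mean_dur_{name}"]].dropna()
            sub = sub.rename(columns={f"mean_dur_{name}": "dur"})
            sub["tod"] = name
            longs.append(sub)
        long = pd.concat(longs, ignore_index=True)
        y = long["dur"].to_numpy(float)
        X = np.column_stack(
            [
                np.ones(len(long)),
                (long["species"] == "white-browed").to_numpy(float),
                (long["tod"] == "noon").to_numpy(float),
                (long["tod"] == "afternoon").to_numpy(float),
            ]
        )
        names = names + ["tod_noon", "tod_afternoon"]
        nests = long["nest_id"].to_numpy()
    else:
        raise ValueError(f"unknown response {response!r}")
    return fit_gaussian_lmm(
        y, X, [nests], reml=True, param_names=names, group_names=["nest"]
    )


def fit_offtime_model(obs: pd.DataFrame) -> ModelFit:
    """Off-time: weighted Gaussian mixed model of the perched proportion.

    The response is ``perch_min / duration_min`` (share of the watch spent
    perched high), weighted by watch duration so long watches carry more
    information — a proportion-scale formulation of "perch time with the
    watch duration as exposure".  Fixed effects as in the feeding model;
    random intercepts for parent and nest.
    """
    obs = _validate_focal(obs).copy()
    X, names, _ = _species_sex_design(obs)
    scaler = {}
    zb, scaler["brood_mass_g"] = _standardize(obs["brood_mass_g"])
    zt, scaler["time_of_day"] = _standardize(obs["time_of_day"])
    X = np.column_stack([X, zb, zt])
    names = names + ["brood_mass_z", "time_z"]
    fit = fit_gaussian_lmm(
        (obs["perch_min"] / obs["duration_min"]).to_numpy(float),
        X,
        [obs["parent_id"].to_numpy(), obs["nest_id"].to_numpy()],
        weights=obs["duration_min"].to_numpy(float),
        reml=True,
        param_names=names,
        group_names=["parent", "nest"],
    )
    fit.scaler = scaler
    return fit


# --------------------------------------------------------------------------
# posterior simulation and R-squared
# --------------------------------------------------------------------------


def posterior_sim(fit: ModelFit, n_draws: int = 10000, seed: int = 0) -> ModelFit:
    """Flat-prior posterior simulation of the fixed effects.

    Draws ``n_draws`` samples from ``N(beta_hat, cov)`` — the asymptotic
    posterior under an uninformative prior — and stores the empirical
    2.5/97.5 percentiles as 95% credible intervals on the fit.
    """
    rng = np.random.default_rng(seed)
    cov = 0.5 * (fit.cov + fit.cov.T)
    w, v = np.linalg.eigh(cov)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    fit.draws = fit.params + rng.standard_normal((n_draws, len(fit.params))) @ root.T
    lo, hi = np.percentile(fit.draws, [2.5, 97.5], axis=0)
    fit.cri = {nm: (float(a), float(b)) for nm, a, b in zip(fit.param_names, lo, hi)}
    fit.flags["posterior_seed"] = int(seed)
    return fit


def r_squared_components(
    var_fixed: float, var_random: float, var_resid: float
) -> tuple[float, float]:
    """Marginal and conditional R^2 from variance components.

    Marginal = fixed / (fixed + random + residual); conditional adds the
    random-effect variance to the numerator.
    """
    total = var_fixed + var_random + var_resid
    return var_fixed / total, (var_fixed + var_random) / total


def r_squared(fit: ModelFit) -> tuple[float, float]:
    """Marginal/conditional R^2 by link-scale variance partitioning.

    The residual variance is family specific: the Gaussian residual
    variance; pi^2/3 for binomial-logit; and the lognormal approximation
    ``ln(1 + 1/lambda)`` for Poisson-log, with lambda the typical rate
    ``exp(mean linear predictor + half the random variance)``.
    """
    var_u = float(sum(sd**2 for sd in fit.re_sd.values()))
    if fit.family == "gaussian":
        var_e = float(fit.resid_sd**2)
    elif fit.family == "binomial":
        var_e = np.pi**2 / 3.0
    elif fit.family == "poisson":
        lam = np.exp(fit.mean_eta_fixed + 0.5 * var_u)
        var_e = float(np.log1p(1.0 / lam))
    else:
        raise ValueError(f"unknown family {fit.family!r}")
    return r_squared_components(fit.var_fixed, var_u, var_e)


__all__ = [
    "ModelFit",
    "fit_binomial_glmm",
    "fit_gaussian_lmm",
    "fit_glmm",
    "fit_lmm",
    "fit_offtime_model",
    "fit_poisson_glmm",
    "laplace_loglik",
    "posterior_sim",
    "r_squared",
    "r_squared_components",
]
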