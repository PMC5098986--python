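"""Logistic growth curves with nestling-within-nest random effects.

Nestling size follows ``mass(t) = A / (1 + exp(-K (t - I)))`` with asymptote
``A`` (g), growth constant ``K`` (1/day) and inflection point ``I`` (day,
the age of fastest growth, where mass equals A/2).  Fits are per species-sex
group.  Random effects shift ``A`` and ``I`` — bivariate normal at the nest
level and, nested inside it, at the nestling level; ``K`` carries no random
effect (the between-brood and between-chick variation in these data loads on
size and timing, not on the rate constant).

Estimation is an alternating-linearization scheme in the Lindstrom-Bates
tradition: (1) given variance parameters, the fixed effects and random
effects are updated by penalized Gauss-Newton on the joint objective;
(2) the model is linearized at that mode and the variance parameters
maximize the marginal likelihood of the linearized mixed model, computed
nest-block by nest-block.  The two steps alternate until the marginal
log-likelihood is stable.  Wald 95% confidence intervals come from the GLS
covariance (fixed effects) and the numeric Hessian over the unconstrained
variance parameterization (log SDs, atanh correlations) via the delta
method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

_Z975 = 1.959963984540054


def predict_mass(A: float, K: float, I: float, t) -> np.ndarray | float:
    """Logistic growth curve; strictly increasing in age for K > 0, with
    ``predict_mass(A, K, I, I) == A / 2`` at the inflection point."""
    return A / (1.0 + np.exp(-K * (np.asarray(t, dtype=float) - I)))


def relative_fledging_mass(A: float, adult_mass: float) -> float:
    """Asymptotic mass as a percentage of adult body mass (1 decimal)."""
    if A <= 0 or adult_mass <= 0:
        raise ValueError("masses must be positive")
    return round(100.0 * A / adult_mass, 1)


class GrowthConvergenceError(RuntimeError):
    """Raised when the alternating fit fails; carries the last iterate."""

    def __init__(self, message: str, last_iterate: dict):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass
class GrowthFit:
    """Per-group growth-curve fit (fixed effects, variance components)."""

    group: tuple
    response: str
    params: dict  # A, K, I
    ci: dict  # name -> (lo, hi)
    ranef: dict  # level -> {sd_A, sd_I, corr, ci_sd_A, ci_sd_I, ci_corr}
    resid_sd: float
    loglik: float
    n_obs: int
    n_nests: int
    n_nestlings: int
    converged: bool
    hessian_pd: bool
    flags: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = [
            {"param": k, "estimate": self.params[k], "lo": self.ci[k][0], "hi": self.ci[k][1]}
            for k in ("K", "I", "A")
        ]
        return pd.DataFrame(rows)


def _theta_to_vc(theta: np.ndarray, scale: float) -> tuple:
    """Unconstrained 7-vector -> (Psi_nest, Psi_chick, sigma_e)."""

    def psi(ls_a, ls_i, zr):
        sa = np.exp(np.clip(ls_a, -10, 6)) * scale
        si = np.exp(np.clip(ls_i, -10, 6))
        r = np.tanh(zr)
        return np.array([[sa**2, r * sa * si], [r * sa * si, si**2]])

    s_e = np.exp(np.clip(theta[6], -10, 6)) * scale
    return psi(theta[0], theta[1], theta[2]), psi(theta[3], theta[4], theta[5]), s_e


def _curve_and_jac(beta, b, t, nest_of, chick_of, nest_of_chick):
    """Mean curve and derivatives w.r.t. (A, K, I) and the RE entries.

    ``b`` is laid out as [nest A | nest I | chick A | chick I].
    """
    A, K, I = beta
    J, Kc = len(np.unique(nest_of)), len(np.unique(chick_of))
    aN, iN = b[:J], b[J : 2 * J]
    aC, iC = b[2 * J : 2 * J + Kc], b[2 * J + Kc :]
    a = A + aN[nest_of] + aC[chick_of]
    i = I + iN[nest_of] + iC[chick_of]
    E = np.exp(-K * (t - i))
    S = 1.0 / (1.0 + E)
    f = a * S
    dA = S
    dK = a * S * S * E * (t - i)
    dI = -a * S * S * E * K
    return f, dA, dK, dI


def _pnls(beta, b, theta, y, t, nest_of, chick_of, nest_of_chick, scale, max_iter=60):
    """Penalized Gauss-Newton over (beta, b) at fixed variance parameters."""
    Psi_n, Psi_c, s_e = _theta_to_vc(theta, scale)
    J = len(np.unique(nest_of))
    Kc = len(np.unique(chick_of))
    Pn = np.linalg.inv(Psi_n + 1e-10 * np.eye(2) * scale)
    Pc = np.linalg.inv(Psi_c + 1e-10 * np.eye(2) * scale)
    n = len(y)

    def pen(b):
        aN, iN = b[:J], b[J : 2 * J]
        aC, iC = b[2 * J : 2 * J + Kc], b[2 * J + Kc :]
        qn = Pn[0, 0] * aN**2 + 2 * Pn[0, 1] * aN * iN + Pn[1, 1] * iN**2
        qc = Pc[0, 0] * aC**2 + 2 * Pc[0, 1] * aC * iC + Pc[1, 1] * iC**2
        return float(qn.sum() + qc.sum())

    def objective(beta, b):
        f, *_ = _curve_and_jac(beta, b, t, nest_of, chick_of, nest_of_chick)
        return float(np.sum((y - f) ** 2)) / s_e**2 + pen(b)

    obj = objective(beta, b)
    p = 3
    for _ in range(max_iter):
        f, dA, dK, dI = _curve_and_jac(beta, b, t, nest_of, chick_of, nest_of_chick)
        r = y - f
        # dense Jacobian [beta | nest A | nest I | chick A | chick I]
        C = np.zeros((n, p + 2 * J + 2 * Kc))
        C[:, 0], C[:, 1], C[:, 2] = dA, dK, dI
        rows = np.arange(n)
        C[rows, p + nest_of] = dA
        C[rows, p + J + nest_of] = dI
        C[rows, p + 2 * J + chick_of] = dA
        C[rows, p + 2 * J + Kc + chick_of] = dI
        H = (C.T @ C) / s_e**2
        g = (C.T @ r) / s_e**2
        # add penalty blocks and gradient contributions
        u = np.concatenate([beta, b])
        for (P, off, m) in ((Pn, p, J), (Pc, p + 2 * J, Kc)):
            idx_a = np.arange(off, off + m)
            idx_i = idx_a + m
            H[idx_a, idx_a] += P[0, 0]
            H[idx_i, idx_i] += P[1, 1]
            H[idx_a, idx_i] += P[0, 1]
            H[idx_i, idx_a] += P[0, 1]
            g[idx_a] -= P[0, 0] * u[idx_a] + P[0, 1] * u[idx_i]
            g[idx_i] -= P[0, 1] * u[idx_a] + P[1, 1] * u[idx_i]
        H[np.diag_indices_from(H)] += 1e-10
        try:
            step = cho_solve(cho_factor(H, lower=True), g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        tstep = 1.0
        for _ in range(30):
            nb, nbb = beta + tstep * step[:p], b + tstep * step[p:]
            new = objective(nb, nbb)
            if new <= obj + 1e-12:
                break
            tstep *= 0.5
        beta, b = beta + tstep * step[:p], b + tstep * step[p:]
        if abs(obj - new) <= 1e-10 * (1.0 + abs(obj)):
            obj = new
            break
        obj = new
    return beta, b


def _linearized_ml_factory(w, Xl, dA, dI, chick_of, nests_rows, chick_ids_per_nest, scale):
    """Build the marginal log-likelihood of the linearized mixed model.

    The marginal covariance is block diagonal over nests:
    ``V_ij = u_i' Psi_nest u_j + [same nestling] u_i' Psi_chick u_j
    + sigma_e^2 delta_ij`` with ``u_i = (dA_i, dI_i)``.  Nests with the same
    (rows, nestlings) shape are batched so each likelihood evaluation is a
    handful of vectorized cholesky factorizations.  Returns
    ``ml(theta) -> (loglik, beta_gls, cov_beta)`` with beta profiled by GLS.
    """
    p = Xl.shape[1]
    n = len(w)
    sig_groups: dict[tuple[int, int], list] = {}
    for rows, chicks in zip(nests_rows, chick_ids_per_nest):
        sig_groups.setdefault((len(rows), len(chicks)), []).append((rows, chicks))
    batches = []
    for (nj, m), items in sig_groups.items():
        B = len(items)
        Xb = np.empty((B, nj, p))
        wb = np.empty((B, nj))
        Ub = np.empty((B, nj, 2))
        same = np.empty((B, nj, nj))
        for bi, (rows, chicks) in enumerate(items):
            Xb[bi] = Xl[rows]
            wb[bi] = w[rows]
            Ub[bi, :, 0] = dA[rows]
            Ub[bi, :, 1] = dI[rows]
            c = chick_of[rows]
            same[bi] = (c[:, None] == c[None, :]).astype(float)
        rhs = np.concatenate([Xb, wb[:, :, None]], axis=2)
        batches.append((nj, Xb, wb, Ub, same, rhs))

    def ml(theta):
        Psi_n, Psi_c, s_e = _theta_to_vc(theta, scale)
        XtViX = np.zeros((p, p))
        XtViw = np.zeros(p)
        logdet = 0.0
        wtViw = 0.0
        for nj, Xb, wb, Ub, same, rhs in batches:
            Ut = Ub.transpose(0, 2, 1)
            V = (Ub @ Psi_n) @ Ut + ((Ub @ Psi_c) @ Ut) * same
            idx = np.arange(nj)
            V[:, idx, idx] += s_e**2
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return -1e12, None, None
            logdet += 2.0 * float(np.sum(np.log(np.diagonal(L, axis1=1, axis2=2))))
            sol = np.linalg.solve(V, rhs)
            ViX, Viw = sol[:, :, :p], sol[:, :, p]
            XtViX += Xb.reshape(-1, p).T @ ViX.reshape(-1, p)
            XtViw += Xb.reshape(-1, p).T @ Viw.reshape(-1)
            wtViw += float(wb.reshape(-1) @ Viw.reshape(-1))
        try:
            cov = np.linalg.inv(XtViX)
        except np.linalg.LinAlgError:
            return -1e12, None, None
        beta = cov @ XtViw
        quad = wtViw - float(beta @ XtViw)
        ll = -0.5 * (logdet + quad + n * np.log(2 * np.pi))
        return ll, beta, cov

    return ml


def fit_logistic_growth(
    data: pd.DataFrame,
    response: str = "mass",
    start: tuple | None = None,
    age_cap: float = 16.0,
    max_outer: int = 12,
) -> GrowthFit:
    """Fit the logistic growth curve to one species-sex subset.

    ``data`` needs columns ``nestling_id, nest_id, age_d`` and the response
    column (``mass_g`` or ``tarsus_mm``); tarsus runs through the identical
    code path.  Measurements beyond ``age_cap`` days are excluded (post-
    fledging mass losses are not modelled).  ``start`` overrides the default
    starting values (A0 = 95th percentile of the response, K0 = 0.37,
    I0 = 6).  Raises :class:`GrowthConvergenceError` (carrying the last
    iterate) if the alternating scheme does not stabilize.
    """
    col = {"mass": "mass_g", "tarsus": "tarsus_mm"}[response]
    df = data.loc[data["age_d"] <= age_cap, ["nestling_id", "nest_id", "age_d", col]].dropna()
    if df["nest_id"].nunique() < 5:
        raise ValueError("need >= 5 nests for a growth fit")
    y = df[col].to_numpy(float)
    t = df["age_d"].to_numpy(float)
    nest_of, nest_levels = pd.factorize(df["nest_id"])
    chick_of, chick_levels = pd.factorize(df["nestling_id"])
    nest_of = nest_of.astype(int)
    chick_of = chick_of.astype(int)
    # every nestling must belong to exactly one nest
    chick_nest = {}
    for c, nj in zip(chick_of, nest_of):
        if chick_nest.setdefault(c, nj) != nj:
            raise ValueError("a nestling appears in more than one nest")
    J, Kc = len(nest_levels), len(chick_levels)
    nests_rows = [np.where(nest_of == j)[0] for j in range(J)]
    chick_ids_per_nest = [
        sorted(set(chick_of[rows])) for rows in nests_rows
    ]

    scale = float(np.percentile(y, 95))
    beta = np.array(start if start is not None else (scale, 0.37, 6.0), dtype=float)
    b = np.zeros(2 * J + 2 * Kc)
    # initial variance parameters: modest heterogeneity, residual from a
    # crude curve fit at the starting values
    resid0 = float(np.std(y - predict_mass(*beta, t))) or 1e-3
    theta = np.array(
        [
            np.log(0.10),  # nest sd_A / scale (~10% of the asymptote)
            np.log(0.5),  # nest sd_I (days)
            0.0,
            np.log(0.10),
            np.log(0.5),
            0.0,
            np.log(max(0.5 * resid0 / scale, 1e-6)),
        ]
    )

    ll_prev = -np.inf
    last_change = np.inf
    converged = False
    beta_cov = None
    ll = -np.inf
    perfect = False
    for outer in range(max_outer):
        beta, b = _pnls(beta, b, theta, y, t, nest_of, chick_of, chick_nest, scale)
        f, dA, dK, dI = _curve_and_jac(beta, b, t, nest_of, chick_of, chick_nest)
        if float(np.sqrt(np.mean((y - f) ** 2))) < 1e-7 * scale:
            # data lie exactly on a curve: the nonlinear-LS limit, where the
            # residual variance degenerates and the marginal ML is unbounded
            perfect = converged = True
            break
        Xl = np.column_stack([dA, dK, dI])
        w = y - f + Xl @ beta + dA * (b[:J][nest_of] + b[2 * J : 2 * J + Kc][chick_of]) + dI * (
            b[J : 2 * J][nest_of] + b[2 * J + Kc :][chick_of]
        )
        ml = _linearized_ml_factory(
            w, Xl, dA, dI, chick_of, nests_rows, chick_ids_per_nest, scale
        )
        if outer == 0:
            # diverse variance starts; the first search otherwise risks a
            # spurious boundary basin (correlation pinned at +-1)
            starts = [
                theta,
                np.array([np.log(0.10), np.log(0.5), 0, np.log(0.10), np.log(1.2), 0, theta[6]]),
                np.array([np.log(0.03), np.log(0.2), 0, np.log(0.03), np.log(0.2), 0, theta[6]]),
            ]
        else:
            starts = [theta]
        best_th, best_ll = None, -np.inf
        for th0 in starts:
            cand = _nm_with_restarts(
                lambda th: -ml(th)[0],
                th0,
                maxiter=800 if outer == 0 else 300,
                n_restarts=1 if outer == 0 else 0,
            )
            val = ml(cand)[0]
            if val > best_ll:
                best_th, best_ll = cand, val
        theta = best_th
        ll, beta_gls, beta_cov = ml(theta)
        beta = beta_gls
        last_change = abs(ll - ll_prev) / (1.0 + abs(ll))
        ll_prev = ll
        if last_change <= 1e-8:
            converged = True
            break
    if not converged and last_change > 1e-6:
        raise GrowthConvergenceError(
            "alternating linearization did not stabilize",
            {"beta": beta, "theta": theta, "loglik": ll},
        )

    beta, b = _pnls(beta, b, theta, y, t, nest_of, chick_of, chick_nest, scale)
    Psi_n, Psi_c, s_e = _theta_to_vc(theta, scale)
    if perfect:
        beta_cov = np.zeros((3, 3))
        s_e = 0.0

    # fixed-effect CIs from the GLS covariance at the final linearization
    se = np.sqrt(np.clip(np.diag(beta_cov), 0.0, None))
    names = ("A", "K", "I")
    params = dict(zip(names, map(float, beta)))
    ci = {
        nm: (float(est - _Z975 * s), float(est + _Z975 * s))
        for nm, est, s in zip(names, beta, se)
    }

    # variance-parameter CIs from the numeric Hessian on the theta scale
    f, dA, dK, dI = _curve_and_jac(beta, b, t, nest_of, chick_of, chick_nest)
    Xl = np.column_stack([dA, dK, dI])
    w = y - f + Xl @ beta + dA * (b[:J][nest_of] + b[2 * J : 2 * J + Kc][chick_of]) + dI * (
        b[J : 2 * J][nest_of] + b[2 * J + Kc :][chick_of]
    )
    ml = _linearized_ml_factory(w, Xl, dA, dI, chick_of, nests_rows, chick_ids_per_nest, scale)
    hess = _numeric_hessian(lambda th: -ml(th)[0], theta)
    hess = 0.5 * (hess + hess.T)
    # perturbed evaluations that hit a non-PD corner poison the Hessian
    usable = bool(np.isfinite(hess).all() and np.abs(hess).max() < 1e10)
    hessian_pd = usable and bool(np.linalg.eigvalsh(hess).min() > 0)
    theta_se = np.full(7, np.nan)
    if hessian_pd:
        try:
            theta_se = np.sqrt(np.clip(np.diag(np.linalg.inv(hess)), 0.0, None))
        except np.linalg.LinAlgError:
            hessian_pd = False

    def level(out_off: int, Psi: np.ndarray) -> dict:
        sd_a, sd_i = np.sqrt(Psi[0, 0]), np.sqrt(Psi[1, 1])
        corr = Psi[0, 1] / (sd_a * sd_i) if sd_a > 0 and sd_i > 0 else 0.0
        ls_a, ls_i, zr = theta[out_off], theta[out_off + 1], theta[out_off + 2]
        se_a, se_i, se_z = theta_se[out_off], theta_se[out_off + 1], theta_se[out_off + 2]
        return {
            "sd_A": float(sd_a),
            "sd_I": float(sd_i),
            "corr": float(corr),
            "ci_sd_A": (float(sd_a * np.exp(-_Z975 * se_a)), float(sd_a * np.exp(_Z975 * se_a))),
            "ci_sd_I": (float(sd_i * np.exp(-_Z975 * se_i)), float(sd_i * np.exp(_Z975 * se_i))),
            "ci_corr": (float(np.tanh(zr - _Z975 * se_z)), float(np.tanh(zr + _Z975 * se_z))),
        }

    ranef = {"nest": level(0, Psi_n), "nestling": level(3, Psi_c)}
    flags = {"perfect_fit": True} if perfect else {}
    for lvl, d in ranef.items():
        if d["sd_A"] < 1e-4 * scale or d["sd_I"] < 1e-4:
            flags[f"boundary_{lvl}"] = True
    group = (
        str(df.attrs.get("species", data["species"].iloc[0] if "species" in data else "?")),
        str(data["sex"].iloc[0] if "sex" in data else "?"),
    )
    return GrowthFit(
        group=group,
        response=response,
        params=params,
        ci=ci,
        ranef=ranef,
        resid_sd=float(s_e),
        loglik=float(ll_prev),
        n_obs=len(y),
        n_nests=J,
        n_nestlings=Kc,
        converged=converged,
        hessian_pd=hessian_pd,
        flags=flags,
    )


def _nm_with_restarts(fun, x0: np.ndarray, maxiter: int, n_restarts: int = 1) -> np.ndarray:
    """Nelder-Mead with simplex restarts.

    A fresh simplex around the incumbent escapes the degenerate simplexes
    that otherwise strand the 7-parameter variance search at spurious
    boundary solutions (e.g. a correlation pinned at 1).
    """
    best = optimize.minimize(
        fun, x0, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": maxiter},
    )
    for _ in range(n_restarts):
        res = optimize.minimize(
            fun, best.x, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": maxiter},
        )
        if res.fun < best.fun - 1e-8:
            best = res
        else:
            break
    return best.x


def _numeric_hessian(fn, x0: np.ndarray, h: float = 1e-3) -> np.ndarray:
    k = len(x0)
    H = np.zeros((k, k))
    f0 = fn(x0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h
            ej[j] = h
            if i == j:
                H[i, i] = (fn(x0 + ei) - 2 * f0 + fn(x0 - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    fn(x0 + ei + ej) - fn(x0 + ei - ej) - fn(x0 - ei + ej) + fn(x0 - ei - ej)
                ) / (4 * h**2)
    return H


def re_correlations(fit: GrowthFit) -> pd.DataFrame:
    """Random-effect SDs of A and I and their correlation per level.

    One row per level (nest, nestling); ``meaningful`` flags correlations
    whose 95% CI excludes zero.
    """
    rows = []
    for lvl in ("nest", "nestling"):
        d = fit.ranef[lvl]
        lo, hi = d["ci_corr"]
        rows.append(
            {
                "level": lvl,
                "sd_A": d["sd_A"],
                "sd_A_lo": d["ci_sd_A"][0],
                "sd_A_hi": d["ci_sd_A"][1],
                "sd_I": d["sd_I"],
                "sd_I_lo": d["ci_sd_I"][0],
                "sd_I_hi": d["ci_sd_I"][1],
                "corr": d["corr"],
                "corr_lo": lo,
                "corr_hi": hi,
                "meaningful": bool(lo > 0 or hi < 0),
            }
        )
    return pd.DataFrame(rows)


def fit_growth_by_group(
    data: pd.DataFrame, response: str = "mass", age_cap: float = 16.0
) -> dict[tuple, GrowthFit]:
    """Fit every (species, sex) subset present in the data."""
    out = {}
    for (sp, sx), sub in data.groupby(["species", "sex"]):
        out[(sp, sx)] = fit_logistic_growth(sub, response=response, age_cap=age_cap)
    return out


__all__ = [
    "GrowthConvergenceError",
    "GrowthFit",
    "fit_growth_by_group",
    "fit_logistic_growth",
    "predict_mass",
    "re_correlations",
    "relative_fledging_mass",
]
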