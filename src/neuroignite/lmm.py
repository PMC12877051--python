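"""REML linear mixed model for the region-level analysis.

Model: delta ~ TumorPercentage + (TumorPercentage | SubID) + (1 | RegionID),
i.e. a fixed intercept and tumor-involvement slope, a correlated random
intercept/slope per subject, and a crossed random intercept per region.
Estimation is restricted maximum likelihood with an lme4-style relative
Cholesky parametrisation; the profiled REML criterion is evaluated through
the Woodbury identity on the (small) random-effects dimension, so fits
scale to thousands of rows. Fixed-effect t-tests use Satterthwaite's
degrees-of-freedom approximation computed from finite-difference gradients
of the contrast variance and the curvature of the REML criterion in
(theta, sigma).

Fits are attempted with the full random structure; on a singular fit the
slope-intercept correlation is dropped, then the random slope, and every
simplification is logged on the returned fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from scipy.sparse import csr_matrix

logger = logging.getLogger(__name__)

FORMULA = (
    "delta ~ TumorPercentage + (TumorPercentage | SubID) + (1 | RegionID)"
)

_SINGULAR_TOL = 1e-3
_MAX_CORR = 0.995


class LmmError(RuntimeError):
    """Structured non-convergence error carrying the optimizer trace."""

    def __init__(self, message: str, trace: object = None):
        super().__init__(message)
        self.trace = trace


@dataclass
class _Design:
    """Precomputed sufficient statistics of the model."""

    y: np.ndarray
    X: np.ndarray
    Z: csr_matrix
    sub_index: np.ndarray
    reg_index: np.ndarray
    n_sub: int
    n_reg: int
    ZtZ: np.ndarray = None
    ZtX: np.ndarray = None
    Zty: np.ndarray = None
    XtX: np.ndarray = None
    Xty: np.ndarray = None
    yty: float = 0.0

    def __post_init__(self) -> None:
        Zd = self.Z
        self.ZtZ = (Zd.T @ Zd).toarray()
        self.ZtX = Zd.T @ self.X
        self.Zty = Zd.T @ self.y
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]


@dataclass
class LmmFit:
    """Fitted mixed model: fixed effects, random SDs, diagnostics hooks."""

    formula: str
    response: str
    structure: str  # "full" | "no_corr" | "no_slope" | "degenerate"
    params: dict
    se: dict
    tvalues: dict
    df: dict
    pvalues: dict
    re_sd: dict
    corr_subject: float
    sigma: float
    reml_criterion: float
    converged: bool
    n_obs: int
    n_subjects: int
    n_regions: int
    fitted: np.ndarray
    residuals: np.ndarray
    messages: list = field(default_factory=list)
    _design: _Design = None
    _theta: np.ndarray = None


def _build_design(
    table: pd.DataFrame, response: str, tumor_col: str
) -> _Design:
    subs = pd.Categorical(table["sub_id"])
    regs = pd.Categorical(table["region_id"])
    n_sub, n_reg = len(subs.categories), len(regs.categories)
    n = len(table)
    y = table[response].to_numpy(dtype=float)
    x = table[tumor_col].to_numpy(dtype=float)
    X = np.column_stack([np.ones(n), x])
    si = np.asarray(subs.codes, dtype=int)
    ri = np.asarray(regs.codes, dtype=int)
    # Z columns: [sub intercepts | sub slopes | region intercepts]
    rows = np.concatenate([np.arange(n)] * 3)
    cols = np.concatenate([si, n_sub + si, 2 * n_sub + ri])
    vals = np.concatenate([np.ones(n), x, np.ones(n)])
    Z = csr_matrix((vals, (rows, cols)), shape=(n, 2 * n_sub + n_reg))
    return _Design(y=y, X=X, Z=Z, sub_index=si, reg_index=ri, n_sub=n_sub, n_reg=n_reg)


def _lambda_parts(theta: np.ndarray, structure: str) -> tuple[np.ndarray, float]:
    """(2x2 lower-triangular subject block, region scale) from theta."""
    lam = np.zeros((2, 2))
    if structure == "full":
        lam[0, 0], lam[1, 0], lam[1, 1] = theta[0], theta[1], theta[2]
        g = theta[3]
    elif structure == "no_corr":
        lam[0, 0], lam[1, 1] = theta[0], theta[1]
        g = theta[2]
    elif structure == "no_slope":
        lam[0, 0] = theta[0]
        g = theta[1]
    else:
        raise ValueError(f"unknown structure {structure!r}")
    return lam, g


def _theta_init(structure: str) -> tuple[np.ndarray, list]:
    if structure == "full":
        return np.array([1.0, 0.0, 1.0, 1.0]), [(0, None), (None, None), (0, None), (0, None)]
    if structure == "no_corr":
        return np.array([1.0, 1.0, 1.0]), [(0, None), (0, None), (0, None)]
    return np.array([1.0, 1.0]), [(0, None), (0, None)]


def _expand_lambda(des: _Design, lam: np.ndarray, g: float) -> np.ndarray:
    """Dense relative-covariance factor Lambda (q x q, block structure)."""
    q, S = des.q, des.n_sub
    L = np.zeros((q, q))
    idx = np.arange(S)
    L[idx, idx] = lam[0, 0]
    L[S + idx, idx] = lam[1, 0]
    L[S + idx, S + idx] = lam[1, 1]
    ridx = np.arange(2 * S, q)
    L[ridx, ridx] = g
    return L


def _core(des: _Design, L: np.ndarray, ridge: float = 1.0):
    """Shared pieces: A = L'Z'ZL + ridge*I, GLS solution on the V* scale."""
    A = L.T @ des.ZtZ @ L + ridge * np.eye(des.q)
    cf = linalg.cho_factor(A, lower=True)
    logdetA = 2.0 * np.log(np.diag(cf[0])).sum()
    LtZtX = L.T @ des.ZtX
    LtZty = L.T @ des.Zty
    AiX = linalg.cho_solve(cf, LtZtX)
    Aiy = linalg.cho_solve(cf, LtZty)
    XtVX = des.XtX - LtZtX.T @ AiX
    XtVy = des.Xty - LtZtX.T @ Aiy
    ytVy = des.yty - LtZty @ Aiy
    beta = linalg.solve(XtVX, XtVy, assume_a="pos")
    quad = ytVy - beta @ XtVy
    sign, logdetXtVX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        raise linalg.LinAlgError("X'V*X not positive definite")
    return A, cf, beta, quad, XtVX, logdetA, logdetXtVX


def _profiled_deviance(theta: np.ndarray, des: _Design, structure: str) -> float:
    lam, g = _lambda_parts(theta, structure)
    L = _expand_lambda(des, lam, g)
    try:
        _, _, _, quad, _, logdetA, logdetXtVX = _core(des, L)
    except linalg.LinAlgError:
        return 1e12
    n, p = des.n, des.p
    quad = max(quad, 1e-300)
    s2 = quad / (n - p)
    return logdetA + logdetXtVX + (n - p) * (np.log(2 * np.pi * s2) + 1.0)


def _deviance_theta_sigma(par: np.ndarray, des: _Design, structure: str) -> float:
    """Unprofiled REML deviance as a function of (theta, sigma)."""
    theta, sigma = par[:-1], par[-1]
    if sigma <= 0:
        return 1e12
    lam, g = _lambda_parts(theta, structure)
    L = _expand_lambda(des, lam, g)
    try:
        _, _, _, quad, _, logdetA, logdetXtVX = _core(des, L)
    except linalg.LinAlgError:
        return 1e12
    n, p = des.n, des.p
    s2 = sigma**2
    return (
        (n - p) * np.log(2 * np.pi * s2)
        + logdetA
        + logdetXtVX
        + quad / s2
    )


def _contrast_var(par: np.ndarray, des: _Design, structure: str, k: int) -> float:
    """Var(beta_k) as a function of (theta, sigma), for Satterthwaite."""
    theta, sigma = par[:-1], par[-1]
    lam, g = _lambda_parts(theta, structure)
    L = _expand_lambda(des, lam, g)
    _, _, _, _, XtVX, _, _ = _core(des, L)
    C = sigma**2 * np.linalg.inv(XtVX)
    return float(C[k, k])


def _fd_grad(f, x: np.ndarray) -> np.ndarray:
    g = np.zeros_like(x)
    for i in range(x.size):
        h = 1e-4 * max(abs(x[i]), 1e-2)
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2 * h)
    return g


def _fd_hessian(f, x: np.ndarray) -> np.ndarray:
    m = x.size
    H = np.zeros((m, m))
    hs = np.array([1e-4 * max(abs(v), 1e-2) for v in x])
    f0 = f(x)
    for i in range(m):
        for j in range(i, m):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += hs[i]
                xm[i] -= hs[i]
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / hs[i] ** 2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[[i, j]] += [hs[i], hs[j]]
                xpm[i] += hs[i]
                xpm[j] -= hs[j]
                xmp[i] -= hs[i]
                xmp[j] += hs[j]
                xmm[[i, j]] -= [hs[i], hs[j]]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                    4 * hs[i] * hs[j]
                )
    return H


def _is_singular(theta: np.ndarray, structure: str) -> bool:
    lam, g = _lambda_parts(theta, structure)
    diag = [lam[0, 0], g] + ([lam[1, 1]] if structure in ("full", "no_corr") else [])
    if any(d < _SINGULAR_TOL for d in diag):
        return True
    if structure == "full" and lam[1, 1] >= _SINGULAR_TOL:
        denom = np.hypot(lam[1, 0], lam[1, 1])
        if denom > 0 and abs(lam[1, 0]) / denom > _MAX_CORR:
            return True
    return False


def _fit_structure(des: _Design, structure: str):
    theta0, bounds = _theta_init(structure)
    res = optimize.minimize(
        _profiled_deviance,
        theta0,
        args=(des, structure),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success:
        res2 = optimize.minimize(
            _profiled_deviance,
            res.x,
            args=(des, structure),
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12},
        )
        if res2.fun <= res.fun:
            res = res2
    return res


def _finalize(des: _Design, theta: np.ndarray, structure: str, response: str,
              reml: float, messages: list, converged: bool) -> LmmFit:
    lam, g = _lambda_parts(theta, structure)
    L = _expand_lambda(des, lam, g)
    _, cf, beta, quad, XtVX, _, _ = _core(des, L)
    n, p, S = des.n, des.p, des.n_sub
    s2 = quad / (n - p)
    sigma = float(np.sqrt(s2))
    C = s2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(C))

    # unscaled random-effect covariance
    G = s2 * (lam @ lam.T)
    sd_int = float(np.sqrt(G[0, 0]))
    sd_slope = float(np.sqrt(G[1, 1]))
    sd_reg = float(sigma * g)
    corr = float("nan")
    if structure == "full" and sd_int > 0 and sd_slope > 0:
        corr = float(G[0, 1] / (sd_int * sd_slope))

    # Satterthwaite df per fixed effect
    par_hat = np.append(theta, sigma)
    dfs, pvals, tvals = {}, {}, {}
    names = ["Intercept", "TumorPercentage"]
    try:
        H = _fd_hessian(lambda v: _deviance_theta_sigma(v, des, structure), par_hat)
        cov_par = 2.0 * np.linalg.pinv(H)
        for k, name in enumerate(names):
            grad = _fd_grad(lambda v: _contrast_var(v, des, structure, k), par_hat)
            denom = float(grad @ cov_par @ grad)
            var_k = float(C[k, k])
            df_k = 2.0 * var_k**2 / denom if denom > 0 else float(n - p)
            df_k = min(max(df_k, 1.0), float(n - p))
            dfs[name] = df_k
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate curvature
        messages.append("Satterthwaite curvature singular; residual df used")
        for name in names:
            dfs[name] = float(n - p)
    for k, name in enumerate(names):
        t = beta[k] / se[k] if se[k] > 0 else 0.0
        tvals[name] = float(t)
        pvals[name] = float(2 * stats.t.sf(abs(t), dfs[name]))

    # conditional (BLUP) fitted values and residuals
    u = L @ linalg.cho_solve(cf, L.T @ (des.Zty - des.ZtX @ beta))
    fitted = des.X @ beta + des.Z @ u
    residuals = des.y - fitted

    return LmmFit(
        formula=FORMULA,
        response=response,
        structure=structure,
        params={n_: float(b) for n_, b in zip(names, beta)},
        se={n_: float(s) for n_, s in zip(names, se)},
        tvalues=tvals,
        df=dfs,
        pvalues=pvals,
        re_sd={
            "subject_intercept": sd_int,
            "subject_slope": sd_slope if structure != "no_slope" else 0.0,
            "region_intercept": sd_reg,
        },
        corr_subject=corr,
        sigma=sigma,
        reml_criterion=float(reml),
        converged=converged,
        n_obs=n,
        n_subjects=S,
        n_regions=des.n_reg,
        fitted=np.asarray(fitted),
        residuals=np.asarray(residuals),
        messages=messages,
        _design=des,
        _theta=theta,
    )


def fit_lmm(
    delta_table: pd.DataFrame,
    response: str = "delta_ignition",
    tumor_col: str = "tumor_fraction",
) -> LmmFit:
    """REML fit of ``delta ~ TumorPercentage + (TumorPercentage | SubID) +
    (1 | RegionID)`` for one patient group.

    Requires >= 5 subjects, >= 20 regions and nonzero variance in the tumor
    covariate. Rows with undefined response values are dropped. On singular
    convergence the random structure is simplified (drop correlation, then
    the random slope) and each step is recorded in ``fit.messages``.
    """
    table = delta_table.dropna(subset=[response]).copy()
    n_sub = table["sub_id"].nunique()
    n_reg = table["region_id"].nunique()
    if n_sub < 5:
        raise ValueError(f"need >= 5 subjects, got {n_sub}")
    if n_reg < 20:
        raise ValueError(f"need >= 20 regions, got {n_reg}")
    x = table[tumor_col].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(
            "TumorPercentage has zero variance; slope not identifiable"
        )
    y = table[response].to_numpy(dtype=float)
    if np.allclose(y, 0.0):
        n = len(table)
        zero = {"Intercept": 0.0, "TumorPercentage": 0.0}
        return LmmFit(
            formula=FORMULA,
            response=response,
            structure="degenerate",
            params=dict(zero),
            se=dict(zero),
            tvalues=dict(zero),
            df={k: float("nan") for k in zero},
            pvalues={k: float("nan") for k in zero},
            re_sd={
                "subject_intercept": 0.0,
                "subject_slope": 0.0,
                "region_intercept": 0.0,
            },
            corr_subject=float("nan"),
            sigma=0.0,
            reml_criterion=float("-inf"),
            converged=True,
            n_obs=n,
            n_subjects=n_sub,
            n_regions=n_reg,
            fitted=np.zeros(n),
            residuals=np.zeros(n),
            messages=["response identically zero; degenerate fit"],
        )

    des = _build_design(table, response, tumor_col)
    messages: list = []
    last_res = None
    for structure in ("full", "no_corr", "no_slope"):
        res = _fit_structure(des, structure)
        last_res = res
        if res.success or res.fun < 1e11:
            if _is_singular(res.x, structure) and structure != "no_slope":
                messages.append(
                    f"singular fit with structure '{structure}'; simplifying"
                )
                logger.info(messages[-1])
                continue
            return _finalize(
                des, res.x, structure, response, res.fun, messages, bool(res.success)
            )
        messages.append(f"structure '{structure}' failed: {res.message}")
    raise LmmError(
        "REML fit failed to converge after structure simplification",
        trace=last_res,
    )


# -- simulation and diagnostics --------------------------------------------


def simulate_delta_table(
    n_subjects: int = 10,
    n_regions: int = 40,
    beta: tuple = (0.0, -0.03),
    sd_subject_intercept: float = 0.025,
    sd_subject_slope: float = 0.01,
    corr: float = -0.4,
    sd_region: float = 0.007,
    sigma: float = 0.01,
    involvement_prob: float = 0.3,
    rng: np.random.Generator | None = None,
    response: str = "delta_ignition",
) -> pd.DataFrame:
    """Draw one long-format table from the mixed model's own equations.

    The tumor design mirrors real overlap tables: most region fractions are
    zero, a random subset per subject carries fractions in (0, 1).
    """
    rng = rng or np.random.default_rng()
    cov = np.array(
        [
            [sd_subject_intercept**2, corr * sd_subject_intercept * sd_subject_slope],
            [corr * sd_subject_intercept * sd_subject_slope, sd_subject_slope**2],
        ]
    )
    u_sub = rng.multivariate_normal(np.zeros(2), cov, size=n_subjects)
    u_reg = rng.normal(0.0, sd_region, n_regions)
    rows = []
    for j in range(n_subjects):
        frac = np.zeros(n_regions)
        involved = rng.random(n_regions) < involvement_prob
        frac[involved] = rng.uniform(0.0, 1.0, involved.sum())
        mu = (
            beta[0]
            + u_sub[j, 0]
            + (beta[1] + u_sub[j, 1]) * frac
            + u_reg
            + rng.normal(0.0, sigma, n_regions)
        )
        for i in range(n_regions):
            rows.append(
                {
                    "sub_id": f"s{j:02d}",
                    "region_id": f"r{i:03d}",
                    response: mu[i],
                    "tumor_fraction": frac[i],
                }
            )
    return pd.DataFrame(rows)


def simulate_from_fit(fit: LmmFit, rng: np.random.Generator) -> np.ndarray:
    """One response vector drawn from the fitted model's parameters."""
    des = fit._design
    if des is None:
        raise ValueError("fit carries no design (degenerate fit?)")
    sd = fit.re_sd
    rho = fit.corr_subject if np.isfinite(fit.corr_subject) else 0.0
    cov = np.array(
        [
            [sd["subject_intercept"] ** 2, rho * sd["subject_intercept"] * sd["subject_slope"]],
            [rho * sd["subject_intercept"] * sd["subject_slope"], sd["subject_slope"] ** 2],
        ]
    )
    u_sub = rng.multivariate_normal(np.zeros(2), cov, size=des.n_sub)
    u_reg = rng.normal(0.0, sd["region_intercept"], des.n_reg)
    beta = np.array([fit.params["Intercept"], fit.params["TumorPercentage"]])
    x = des.X[:, 1]
    mu = (
        des.X @ beta
        + u_sub[des.sub_index, 0]
        + u_sub[des.sub_index, 1] * x
        + u_reg[des.reg_index]
        + rng.normal(0.0, fit.sigma, des.n)
    )
    return mu


def lmm_diagnostics(
    fit: LmmFit, n_sims: int = 200, rng: np.random.Generator | None = None
) -> dict:
    """Numeric arrays behind the three standard panels.

    Returns residual-vs-fitted points, QQ quantile pairs of standardized
    residuals, and observed vs posterior-simulated density curves (the
    simulated curve averages >= ``n_sims`` draws from the fitted
    parameters). Densities integrate to 1.
    """
    if not fit.converged and fit.structure != "degenerate":
        raise ValueError("diagnostics require a converged fit")
    rng = rng or np.random.default_rng(0)
    resid = fit.residuals
    scale = resid.std(ddof=1) if resid.size > 1 else 1.0
    std_resid = resid / scale if scale > 0 else resid
    n = resid.size
    probs = (np.arange(1, n + 1) - 0.5) / n
    qq = {
        "theoretical": stats.norm.ppf(probs),
        "sample": np.sort(std_resid),
    }
    y = fit._design.y if fit._design is not None else fit.fitted + resid
    kde = stats.gaussian_kde(y)
    pad = 6 * kde.factor * y.std(ddof=1) + 1e-12
    grid = np.linspace(y.min() - pad, y.max() + pad, 512)
    observed = kde(grid)
    sims = np.empty((n_sims, grid.size))
    for s in range(n_sims):
        ysim = simulate_from_fit(fit, rng)
        sims[s] = stats.gaussian_kde(ysim)(grid)
    return {
        "fitted": fit.fitted,
        "residuals": resid,
        "qq": qq,
        "density_grid": grid,
        "density_observed": observed,
        "density_simulated_mean": sims.mean(axis=0),
        "density_simulated": sims,
    }
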