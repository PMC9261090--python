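"""Linear mixed models with crossed random effects via profiled REML.

The models needed here have by-subject random intercepts/slopes crossed with
by-stimulus random intercepts — a structure none of the installed Python
model packages estimates efficiently — so the engine solves the sparse
mixed-model equations directly.

Model:  y = X b + Z u + e,  u ~ N(0, sigma_e^2 T T'),  e ~ N(0, sigma_e^2 I),
where T = T(theta) is block diagonal over the declared random components:
a single-column ("diagonal") component contributes theta_k I over its group
levels; a correlated block of k columns sharing a group contributes
I_levels (x) L with L a k x k lower-triangular Cholesky factor (lme4's
relative-covariance parameterization).  With A = Z T the marginal covariance
is sigma_e^2 V0, V0 = I + A A', and every REML quantity reduces to sparse
solves with M = I_q + A'A:

    V0^-1      = I - A M^-1 A'
    log|V0|    = log|M|
    -2 l_REML  = (n-p) (log(2 pi s2) + 1) + log|M| + log|X' V0^-1 X|

with s2 = r' V0^-1 r / (n - p) profiling out the residual variance.  The
few free parameters (diagonal entries bounded at 0, off-diagonals free) are
optimized with L-BFGS-B; a zero diagonal entry is an admissible boundary and
is reported as a zero variance component.

Degrees of freedom use the Satterthwaite approximation in (theta, sigma^2)
coordinates: for a contrast c, df = 2 g^2 / (grad g' W grad g) with
g = c' Cov(b) c, the gradient taken numerically, and W = 2 H^-1 from the
numerical Hessian of the REML deviance — the construction lmerTest uses.
In the no-random-effects limit the engine returns exact OLS results with
df = n - p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.sparse.linalg import splu
from scipy.stats import t as t_dist, f as f_dist

from .affect_scoring import ValidationError
from .design_builder import ModelDataset, RandomStructure


class ConvergenceError(RuntimeError):
    """REML optimization failed; carries diagnostics and simplifications tried."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class FitResult:
    """Fixed-effect table, variance components and everything needed for contrasts."""

    fixed: pd.DataFrame  # index term; columns estimate, se, df, t, p, ci_low, ci_high, beta
    random_effects: pd.DataFrame  # index effect name; columns variance, sd
    random_correlations: dict  # (name_i, name_j) -> correlation, within blocks
    sigma: float  # residual SD
    loglik_reml: float
    converged: bool
    n_obs: int
    n_fixed: int
    message: str = ""
    simplifications: list = field(default_factory=list)
    dataset: ModelDataset | None = None
    _problem: "_REMLProblem | None" = None
    _theta: np.ndarray | None = None
    _satt_cache: dict | None = None

    @property
    def fixed_names(self) -> list[str]:
        return list(self.fixed.index)

    def coef(self, name: str) -> float:
        return float(self.fixed.loc[name, "estimate"])

    def to_json_dict(self) -> dict:
        return {
            "fixed": self.fixed.reset_index(names="term").to_dict("records"),
            "random_effects": self.random_effects.reset_index(names="term").to_dict("records"),
            "random_correlations": {f"{a}:{b}": v for (a, b), v in self.random_correlations.items()},
            "sigma": self.sigma,
            "loglik_reml": self.loglik_reml,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_fixed": self.n_fixed,
            "simplifications": self.simplifications,
        }

    def to_tsv(self, path) -> None:
        """Fixed-effects table formatted for reporting: b, beta, CI, t(df), p."""
        tab = self.fixed.copy()
        tab["t(df)"] = [f"{t:.2f} ({d:.1f})" for t, d in zip(tab["t"], tab["df"])]
        tab["95% CI"] = [f"[{lo:.2f}, {hi:.2f}]" for lo, hi in zip(tab["ci_low"], tab["ci_high"])]
        tab[["estimate", "se", "beta", "95% CI", "t(df)", "p"]].to_csv(
            path, sep="\t", float_format="%.4f"
        )


class _Component:
    """One random component: Z columns, parameter layout, T-block builder."""

    def __init__(self, data: pd.DataFrame, group: str, columns: list, names: list[str]):
        self.group = group
        self.names = names
        self.k = len(columns)
        codes, levels = pd.factorize(data[group], sort=True)
        self.m = len(levels)
        n = len(data)
        rows, cols, vals = [], [], []
        for j, col in enumerate(columns):
            v = np.ones(n) if col is None else data[col].to_numpy(float)
            rows.append(np.arange(n))
            cols.append(codes * self.k + j)
            vals.append(v)
        self.Z = sparse.csc_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, self.m * self.k),
        )
        # lower-triangular parameter layout, row-major: (0,0), (1,0), (1,1), ...
        self.tri = [(i, j) for i in range(self.k) for j in range(i + 1)]
        self.n_params = len(self.tri)

    def L(self, theta_part: np.ndarray) -> np.ndarray:
        L = np.zeros((self.k, self.k))
        for val, (i, j) in zip(theta_part, self.tri):
            L[i, j] = val
        return L

    def T(self, theta_part: np.ndarray) -> sparse.csc_matrix:
        if self.k == 1:
            return sparse.identity(self.m, format="csc") * float(theta_part[0])
        return sparse.kron(sparse.identity(self.m, format="csc"), self.L(theta_part), format="csc")

    def theta0(self) -> np.ndarray:
        return np.array([1.0 if i == j else 0.0 for (i, j) in self.tri])

    def bounds(self) -> list[tuple]:
        return [(0.0, None) if i == j else (None, None) for (i, j) in self.tri]


class _REMLProblem:
    """Precomputed cross-products for one model; evaluates REML quantities."""

    def __init__(self, X: np.ndarray, y: np.ndarray, components: list[_Component]):
        self.X, self.y = X, y
        self.n, self.p = X.shape
        self.components = components
        self.n_params = sum(c.n_params for c in components)
        if components:
            Z = sparse.hstack([c.Z for c in components]).tocsc()
            self.q = Z.shape[1]
            self.ZtZ = (Z.T @ Z).tocsc()
            self.ZtX = np.asarray(Z.T @ X)
            self.Zty = np.asarray(Z.T @ y)
        else:
            self.q = 0
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _T(self, theta: np.ndarray) -> sparse.csc_matrix:
        parts, off = [], 0
        for c in self.components:
            parts.append(c.T(theta[off : off + c.n_params]))
            off += c.n_params
        return sparse.block_diag(parts, format="csc")

    def core(self, theta: np.ndarray):
        """Return (logdet M, X'V0^-1 X, X'V0^-1 y, y'V0^-1 y)."""
        if self.q == 0 or np.all(theta == 0):
            return 0.0, self.XtX, self.Xty, self.yty
        T = self._T(theta)
        M = (T.T @ self.ZtZ @ T + sparse.identity(self.q, format="csc")).tocsc()
        lu = splu(M, permc_spec="MMD_AT_PLUS_A")
        logdet = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        AtX = np.asarray(T.T @ self.ZtX)
        Aty = np.asarray(T.T @ self.Zty)
        MinvAtX = lu.solve(np.ascontiguousarray(AtX))
        MinvAty = lu.solve(np.ascontiguousarray(Aty))
        XtViX = self.XtX - AtX.T @ MinvAtX
        XtViy = self.Xty - AtX.T @ MinvAty
        ytViy = self.yty - float(Aty @ MinvAty)
        return logdet, XtViX, XtViy, ytViy

    def profiled(self, theta: np.ndarray):
        logdet, XtViX, XtViy, ytViy = self.core(theta)
        beta = np.linalg.solve(XtViX, XtViy)
        ssr = max(ytViy - float(XtViy @ beta), 1e-300)
        s2 = ssr / (self.n - self.p)
        sign, logdet_xvx = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise ConvergenceError("X'V^-1X not positive definite; design may be rank deficient")
        dev = (self.n - self.p) * (np.log(2 * np.pi * s2) + 1.0) + logdet + logdet_xvx
        return dev, beta, s2, XtViX

    def deviance(self, theta: np.ndarray) -> float:
        try:
            dev = self.profiled(theta)[0]
        except (ConvergenceError, np.linalg.LinAlgError, RuntimeError):
            return np.inf  # steer the optimizer away from degenerate theta
        return dev if np.isfinite(dev) else np.inf

    def deviance_unprofiled(self, theta: np.ndarray, s2: float) -> float:
        """REML deviance (up to a constant) at fixed residual variance s2."""
        logdet, XtViX, XtViy, ytViy = self.core(theta)
        beta = np.linalg.solve(XtViX, XtViy)
        ssr = ytViy - float(XtViy @ beta)
        return (
            (self.n - self.p) * np.log(s2)
            + logdet
            + np.linalg.slogdet(XtViX)[1]
            + ssr / s2
        )

    def cov_beta(self, theta: np.ndarray, s2: float) -> np.ndarray:
        _, XtViX, _, _ = self.core(theta)
        return s2 * np.linalg.inv(XtViX)


def _build_design(dataset: ModelDataset):
    data = dataset.data
    y = data[dataset.outcome].to_numpy(dtype=float)
    cols = [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in dataset.fixed_effects]
    X = np.column_stack(cols)
    names = ["intercept"] + list(dataset.fixed_effects)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:  # drop aliased columns, keeping first occurrences
        keep, dropped = [0], []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
                keep.append(j)
            else:
                dropped.append(names[j])
        warnings.warn(f"dropping aliased fixed-effect columns: {dropped}", stacklevel=3)
        X = X[:, keep]
        names = [names[j] for j in keep]
    components = [
        _Component(data, t.group, [t.column], [t.name]) for t in dataset.random.terms
    ]
    components += [
        _Component(data, b.group, list(b.columns), list(b.names))
        for b in getattr(dataset.random, "blocks", [])
    ]
    return X, y, names, components


def fit_lmm(
    dataset: ModelDataset,
    random: RandomStructure | None = None,
    compute_df: bool = True,
    theta0: float = 1.0,
) -> FitResult:
    """REML fit of the declared crossed-random-effects model.

    Deterministic given data and configuration.  On failure of the bounded
    quasi-Newton search a Nelder-Mead restart is tried (logged in
    ``simplifications``); if no finite optimum is found a structured
    :class:`ConvergenceError` is raised.

    ``compute_df=False`` skips the Satterthwaite computation (df falls back
    to the residual rule n - p), which is much faster for simulations that
    only need point estimates.
    """
    if random is not None:
        dataset = ModelDataset(
            outcome=dataset.outcome,
            data=dataset.data,
            fixed_effects=list(dataset.fixed_effects),
            random=random,
            factors=dict(dataset.factors),
            meta=dict(dataset.meta),
            description=dataset.description,
        )
    if "participant_id" in dataset.data and dataset.data["participant_id"].nunique() < 2:
        raise ValidationError("need at least 2 subjects")

    X, y, names, components = _build_design(dataset)
    problem = _REMLProblem(X, y, components)
    n, p = problem.n, problem.p

    simplifications: list[str] = []
    theta = np.zeros(0)
    converged = True
    message = "OLS (no random effects)"
    if problem.n_params:
        x0 = np.concatenate([c.theta0() for c in components]) * float(theta0)
        bounds = [b for c in components for b in c.bounds()]
        is_diag = np.array(
            [i == j for c in components for (i, j) in c.tri], dtype=bool
        )
        opts = {"ftol": 1e-13, "gtol": 1e-8, "maxiter": 500}
        import contextlib

        @contextlib.contextmanager
        def _quiet():
            # the objective returns +inf at degenerate theta; scipy's finite
            # differences then emit spurious invalid-value warnings
            with warnings.catch_warnings():
                warnings.filterwarnings("ignore", category=RuntimeWarning)
                yield

        starts = [x0]
        if (~is_diag).any():
            # stage 1: optimize variances with correlations pinned at zero,
            # then release — avoids degenerate Cholesky local optima
            def dev_diag(t_diag):
                full = np.zeros(problem.n_params)
                full[is_diag] = t_diag
                return problem.deviance(full)

            with _quiet():
                res_d = optimize.minimize(
                    dev_diag, x0[is_diag], method="L-BFGS-B",
                    bounds=[b for b, d in zip(bounds, is_diag) if d], options=opts,
                )
            staged = np.zeros(problem.n_params)
            staged[is_diag] = res_d.x
            starts.insert(0, staged)
        best = None
        for start in starts:
            with _quiet():
                res = optimize.minimize(
                    problem.deviance, start, method="L-BFGS-B", bounds=bounds, options=opts,
                )
            if best is None or res.fun < best.fun:
                best = res
        res = best
        if not res.success:
            res2 = optimize.minimize(
                problem.deviance, res.x, method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 5000},
            )
            if res2.fun <= res.fun:
                res = res2
            simplifications.append("nelder-mead restart")
        if not np.isfinite(res.fun):
            raise ConvergenceError(
                "REML optimization failed",
                {"message": str(res.message), "simplifications": simplifications},
            )
        theta = res.x
        converged = bool(res.success) or np.isfinite(res.fun)
        message = str(res.message)

    # canonicalize boundary / sign: zero out tiny diagonal params
    off = 0
    for c in components:
        part = theta[off : off + c.n_params]
        for idx, (i, j) in enumerate(c.tri):
            if i == j and abs(part[idx]) < 1e-5:
                part[idx] = 0.0
            if i == j and part[idx] < 0:
                part[idx] = abs(part[idx])
        theta[off : off + c.n_params] = part
        off += c.n_params

    dev, beta, s2, XtViX = problem.profiled(theta)
    sigma = float(np.sqrt(s2))
    cov_beta = s2 * np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov_beta))

    re_rows, corrs = {}, {}
    off = 0
    for c in components:
        part = theta[off : off + c.n_params]
        Sig = c.L(part) @ c.L(part).T * s2
        for a, name in enumerate(c.names):
            re_rows[name] = {"variance": Sig[a, a], "sd": float(np.sqrt(Sig[a, a]))}
        for a in range(c.k):
            for b2 in range(a + 1, c.k):
                denom = np.sqrt(Sig[a, a] * Sig[b2, b2])
                corrs[(c.names[a], c.names[b2])] = float(Sig[a, b2] / denom) if denom > 0 else np.nan
        off += c.n_params
    random_effects = pd.DataFrame.from_dict(re_rows, orient="index", columns=["variance", "sd"]) \
        if re_rows else pd.DataFrame(columns=["variance", "sd"])

    fit = FitResult(
        fixed=pd.DataFrame(index=names),
        random_effects=random_effects,
        random_correlations=corrs,
        sigma=sigma,
        loglik_reml=-0.5 * dev,
        converged=converged,
        n_obs=n,
        n_fixed=p,
        message=message,
        simplifications=simplifications,
        dataset=dataset,
        _problem=problem,
        _theta=theta,
    )

    sd_y = float(np.std(y, ddof=1))
    rows = {}
    for j, name in enumerate(names):
        c = np.zeros(p)
        c[j] = 1.0
        df = approximate_df(fit, c) if compute_df else float(n - p)
        t = beta[j] / se[j] if se[j] > 0 else np.nan
        pval = 2 * t_dist.sf(abs(t), df)
        crit = t_dist.ppf(0.975, df)
        sd_x = float(np.std(X[:, j], ddof=1)) if name != "intercept" else 0.0
        beta_std = beta[j] * sd_x / sd_y if (name != "intercept" and sd_y > 0) else np.nan
        if name != "intercept" and sd_x == 0:
            warnings.warn(f"zero-variance predictor {name!r}: standardized beta undefined")
        rows[name] = {
            "estimate": beta[j], "se": se[j], "df": df, "t": t, "p": pval,
            "ci_low": beta[j] - crit * se[j], "ci_high": beta[j] + crit * se[j],
            "beta": beta_std,
        }
    fit.fixed = pd.DataFrame.from_dict(rows, orient="index")
    return fit


def _active_mask(fit: FitResult) -> np.ndarray:
    """Parameters included in the Satterthwaite computation: nonzero diagonals
    plus off-diagonals whose row and column diagonals are both nonzero."""
    problem = fit._problem
    theta = fit._theta
    mask = np.zeros(theta.size, dtype=bool)
    off = 0
    for c in problem.components:
        part = theta[off : off + c.n_params]
        diag_ok = {}
        for idx, (i, j) in enumerate(c.tri):
            if i == j:
                diag_ok[i] = part[idx] > 1e-5
        for idx, (i, j) in enumerate(c.tri):
            mask[off + idx] = diag_ok.get(i, False) and diag_ok.get(j, False)
        off += c.n_params
    return mask


def _satterthwaite_setup(fit: FitResult) -> dict | None:
    """Cache the contrast-independent pieces: perturbed Cov(beta) matrices and
    the asymptotic covariance of the variance-parameter estimates."""
    if fit._satt_cache is not None:
        return fit._satt_cache or None
    problem = fit._problem
    if problem is None or problem.n_params == 0:
        fit._satt_cache = {}
        return None
    mask = _active_mask(fit)
    if not mask.any():
        fit._satt_cache = {}
        return None
    s2 = fit.sigma**2
    v = np.concatenate([fit._theta[mask], [s2]])  # coordinates: active thetas + sigma^2
    m = v.size

    def cov_at(vp: np.ndarray) -> np.ndarray:
        theta = fit._theta.copy()
        theta[mask] = vp[:-1]
        return problem.cov_beta(theta, vp[-1])

    def dev_at(vp: np.ndarray) -> float:
        theta = fit._theta.copy()
        theta[mask] = vp[:-1]
        return problem.deviance_unprofiled(theta, vp[-1])

    h = 1e-4 * (np.abs(v) + 1e-2)
    cov_plus, cov_minus = [], []
    for i in range(m):
        e = np.zeros(m); e[i] = h[i]
        cov_plus.append(cov_at(v + e))
        cov_minus.append(cov_at(v - e))
    cov0 = cov_at(v)

    H = np.zeros((m, m))
    d0 = dev_at(v)
    for i in range(m):
        ei = np.zeros(m); ei[i] = h[i]
        H[i, i] = (dev_at(v + ei) - 2 * d0 + dev_at(v - ei)) / h[i] ** 2
        for j in range(i + 1, m):
            ej = np.zeros(m); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                dev_at(v + ei + ej) - dev_at(v + ei - ej)
                - dev_at(v - ei + ej) + dev_at(v - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        W = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        fit._satt_cache = {}
        return None
    fit._satt_cache = {"h": h, "cov0": cov0, "cov_plus": cov_plus, "cov_minus": cov_minus, "W": W}
    return fit._satt_cache


def approximate_df(fit: FitResult, contrast) -> float:
    """Satterthwaite degrees of freedom for a fixed-effect contrast.

    Falls back to the residual rule df = n - p when there are no (nonzero)
    random effects or the numerical information matrix is degenerate.
    """
    c = np.asarray(contrast, dtype=float)
    if c.shape != (fit.n_fixed,):
        raise ValidationError(
            f"contrast has length {c.size}, expected {fit.n_fixed} fixed effects"
        )
    fallback = float(fit.n_obs - fit.n_fixed)
    cache = _satterthwaite_setup(fit)
    if cache is None:
        return fallback
    g0 = float(c @ cache["cov0"] @ c)
    m = len(cache["cov_plus"])
    grad = np.array(
        [
            (float(c @ cache["cov_plus"][i] @ c) - float(c @ cache["cov_minus"][i] @ c))
            / (2 * cache["h"][i])
            for i in range(m)
        ]
    )
    denom = float(grad @ cache["W"] @ grad)
    if not np.isfinite(denom) or denom <= 0 or g0 <= 0:
        return fallback
    return float(np.clip(2.0 * g0**2 / denom, 1.0, fallback))


def contrast_test(fit: FitResult, contrast, beta_scale: float | None = None) -> dict:
    """t test of a single linear contrast of the fixed effects.

    ``beta_scale`` (= SD(x)/SD(y)) converts the estimate to a standardized
    beta when supplied.
    """
    c = np.asarray(contrast, dtype=float)
    beta_hat = fit.fixed["estimate"].to_numpy()
    cov = fit._problem.cov_beta(fit._theta, fit.sigma**2)
    est = float(c @ beta_hat)
    se = float(np.sqrt(c @ cov @ c))
    df = approximate_df(fit, c)
    t = est / se if se > 0 else np.nan
    crit = t_dist.ppf(0.975, df)
    out = {
        "estimate": est, "se": se, "df": df, "t": t,
        "p": 2 * t_dist.sf(abs(t), df),
        "ci_low": est - crit * se, "ci_high": est + crit * se,
    }
    if beta_scale is not None:
        out["beta"] = est * beta_scale
        out["beta_ci_low"] = out["ci_low"] * beta_scale
        out["beta_ci_high"] = out["ci_high"] * beta_scale
    return out


def wald_f_test(fit: FitResult, columns: list[str]) -> dict:
    """Omnibus Wald F test for a set of fixed-effect columns.

    The denominator df combines per-eigencontrast Satterthwaite dfs the way
    lmerTest does: df2 = 2 E / (E - r) with E = sum nu_i / (nu_i - 2).
    """
    names = fit.fixed_names
    idx = [names.index(c) for c in columns]
    p = fit.n_fixed
    L = np.zeros((len(idx), p))
    for r_i, j in enumerate(idx):
        L[r_i, j] = 1.0
    beta_hat = fit.fixed["estimate"].to_numpy()
    cov = fit._problem.cov_beta(fit._theta, fit.sigma**2)
    LCL = L @ cov @ L.T
    r = len(idx)
    F = float((L @ beta_hat) @ np.linalg.solve(LCL, L @ beta_hat) / r)
    _, eigvec = np.linalg.eigh(LCL)
    nus = np.array([approximate_df(fit, eigvec[:, k] @ L) for k in range(r)])
    with np.errstate(divide="ignore"):
        E = float(np.sum(np.where(nus > 2, nus / (nus - 2), np.inf)))
    if not np.isfinite(E) or E <= r:
        df2 = float(fit.n_obs - fit.n_fixed)
    else:
        df2 = 2 * E / (E - r)
    return {"F": F, "df1": r, "df2": df2, "p": float(f_dist.sf(F, r, df2))}


def conditional_effects(
    fit: FitResult,
    moderator_col: str = "mod",
    factor: str | None = None,
    force: bool = False,
    trend_p: float = 0.10,
) -> pd.DataFrame | None:
    """Simple slopes of the moderator within each level of a level-1 factor.

    Computed only when the omnibus moderator × factor interaction reaches
    trend-level significance (p < ``trend_p``), unless ``force=True``; returns
    ``None`` when the gate suppresses the table.
    """
    ds = fit.dataset
    if ds is None or moderator_col not in ds.data.columns:
        raise ValidationError("fit does not carry a moderated dataset")
    if factor is None:
        factor = next((f for f in ds.factors if not f.startswith("moderator")), None)
    inter_key = f"moderator_x_{factor}"
    if inter_key not in ds.factors:
        raise ValidationError(f"model has no moderator × {factor} interaction")
    inter_cols = ds.factors[inter_key]

    omnibus = wald_f_test(fit, inter_cols)
    if not force and omnibus["p"] >= trend_p:
        return None

    names = fit.fixed_names
    sd_mod = float(ds.data[moderator_col].std(ddof=1))
    sd_y = float(ds.data[ds.outcome].std(ddof=1))
    rows = []
    factor_cols = ds.factors[factor]
    for level in ["reference"] + factor_cols:  # reference: all factor dummies at 0
        c = np.zeros(fit.n_fixed)
        c[names.index(moderator_col)] = 1.0
        if level != "reference":
            c[names.index(f"{level}_x_mod")] = 1.0
        res = contrast_test(fit, c, beta_scale=sd_mod / sd_y if sd_y > 0 else None)
        res["level"] = level
        rows.append(res)
    tab = pd.DataFrame(rows).set_index("level")
    tab.attrs["omnibus"] = omnibus
    return tab


def standardized_beta(fit: FitResult) -> pd.Series:
    """Standardized coefficients beta_j = b_j * SD(x_j) / SD(y) on the fitted data."""
    return fit.fixed["beta"]


def bonferroni_adjust(p_values, family_size: int) -> np.ndarray:
    """Bonferroni-adjusted p values: min(1, family_size * p)."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p values must lie in [0, 1]")
    if family_size < p.size:
        raise ValidationError("family_size must be >= number of tests")
    return np.minimum(1.0, family_size * p)
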