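"""Gamma mixed-effects model of msRMR with identity link.

The response y_ij (msRMR of animal i, record j) is modelled as

    y_ij ~ Gamma(shape k, mean mu_ij),   mu_ij = x_ij' beta + u_i,
    u_i ~ Normal(0, sigma_u^2),

i.e. the mean is linear in the fixed effects (identity link) with an
additive per-animal random intercept, and the Gamma variance is mu^2 / k
(CV = k^{-1/2}). The marginal likelihood integrates u_i out by adaptive
Gauss-Hermite quadrature centred on the per-animal posterior mode; with a
single node this is exactly the Laplace approximation. All free parameters
(beta, log k, sigma_u) are estimated jointly by maximum likelihood;
standard errors come from the observed information (numerical Hessian).

Identity-link positivity: any parameter vector with a fitted mean below a
small floor is rejected by a smooth barrier, so the optimizer never
evaluates an invalid Gamma mean silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

MU_FLOOR = 1e-6
_LOG_K_BOUNDS = (-5.0, 20.0)   # shape k capped; a cap is hit only for
                               # (near-)degenerate zero-variance responses


class DesignRankError(ValueError):
    """Design matrix is rank deficient for the requested terms."""


class ConvergenceError(RuntimeError):
    """Marginal-likelihood optimization failed to converge."""


# ---------------------------------------------------------------------------
# Design matrices

def _term_columns(df: pd.DataFrame, term: str) -> dict[str, np.ndarray]:
    if term in ("1", "Intercept"):
        return {}
    if term == "status":
        levels = sorted(df["status"].unique())
        if levels not in (["NR", "R"], ["NR"], ["R"]):
            # generic treatment coding, first level is the reference
            return {
                f"status[{lv}]": (df["status"] == lv).to_numpy(float)
                for lv in levels[1:]
            }
        return {"status[R]": (df["status"] == "R").to_numpy(float)}
    if term == "ta_factor":
        levels = np.sort(df["ta_c"].unique())
        return {
            f"ta[{lv:g}]": (df["ta_c"] == lv).to_numpy(float)
            for lv in levels[1:]
        }
    if term == "sqrt_body_mass":
        # centred: sqrt(mass) is nearly constant relative to its mean, and
        # leaving it raw ill-conditions the likelihood surface
        col = np.sqrt(df["body_mass_g"].to_numpy(float))
        return {"sqrt_body_mass": col - col.mean()}
    if term == "age":
        col = df["age_y"].to_numpy(float)
        return {"age_y": col - col.mean()}
    if term in df.columns:
        return {term: df[term].to_numpy(float)}
    raise KeyError(f"unknown model term {term!r}")


def build_design(df: pd.DataFrame, terms, interactions: bool = False):
    """Fixed-effect design matrix (always includes an intercept).

    ``interactions=True`` additionally crosses every pair of non-intercept
    terms (all pairwise products of their columns)."""
    terms = [t for t in terms if t not in ("1", "Intercept")]
    per_term: list[dict[str, np.ndarray]] = [_term_columns(df, t) for t in terms]
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(df))}
    for tc in per_term:
        cols.update(tc)
    if interactions:
        for a in range(len(per_term)):
            for b in range(a + 1, len(per_term)):
                for na, va in per_term[a].items():
                    for nb, vb in per_term[b].items():
                        cols[f"{na}:{nb}"] = va * vb
    names = list(cols)
    X = np.column_stack([cols[n] for n in names])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignRankError(
            f"design for terms {terms} is rank deficient "
            f"({X.shape[1]} columns, rank {np.linalg.matrix_rank(X)})"
        )
    return X, names


# ---------------------------------------------------------------------------
# Fit container

@dataclass
class GlmmFit:
    coef: pd.Series
    se: pd.Series
    sigma_u: float
    gamma_shape: float
    loglik: float
    aic: float
    nparams: int
    n_obs: int
    n_groups: int
    terms: tuple[str, ...]
    design_columns: tuple[str, ...]
    converged: bool
    n_quad: int
    cov: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    sigma_u_fixed: bool = False
    message: str = ""

    def summary(self) -> str:
        lines = [
            f"Gamma GLMM (identity link), AGQ nodes={self.n_quad}",
            f"n_obs={self.n_obs}, animals={self.n_groups}, "
            f"logL={self.loglik:.3f}, AIC={self.aic:.3f}",
            f"shape k={self.gamma_shape:.3f} (CV={self.gamma_shape**-0.5:.3f}), "
            f"sigma_u={self.sigma_u:.4f}{' (fixed)' if self.sigma_u_fixed else ''}",
            "coefficients (response scale):",
        ]
        for name in self.coef.index:
            lines.append(f"  {name:>18s}  {self.coef[name]: .4f} "
                         f"+/- {self.se[name]:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "coef": {k: float(v) for k, v in self.coef.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "sigma_u": self.sigma_u,
            "gamma_shape": self.gamma_shape,
            "loglik": self.loglik,
            "aic": self.aic,
            "nparams": self.nparams,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "terms": list(self.terms),
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# Marginal likelihood machinery

def _gamma_logpdf_terms(y, mu, k, logy):
    return k * np.log(k) - k * np.log(mu) + (k - 1.0) * logy - k * y / mu \
        - special.gammaln(k)


class _Marginal:
    """Negative marginal log-likelihood of (beta, log k, sigma_u)."""

    def __init__(self, y, X, group_idx, n_groups, n_quad):
        self.y = y
        self.logy = np.log(y)
        self.X = X
        self.gi = group_idx
        self.G = n_groups
        self.nodes, self.weights = np.polynomial.hermite.hermgauss(n_quad)
        self.logw = np.log(self.weights)
        self.u_hat = np.zeros(n_groups)  # warm start across evaluations

    def _group_sum(self, values):
        return np.bincount(self.gi, weights=values, minlength=self.G)

    def _mode(self, eta, k, sig2):
        """Per-animal posterior mode of u by damped Newton (vectorized)."""
        y, gi = self.y, self.gi
        min_eta = np.full(self.G, np.inf)
        np.minimum.at(min_eta, gi, eta)
        lo = MU_FLOOR - min_eta + 1e-10          # u > lo keeps all mu > floor
        u = np.clip(self.u_hat, lo + 1e-8, None)
        for _ in range(200):
            mu = eta + u[gi]
            g = self._group_sum(k * (y - mu) / mu**2) - u / sig2
            h = self._group_sum(k * (mu - 2.0 * y) / mu**3) - 1.0 / sig2
            h = np.minimum(h, -1e-10)
            step = np.clip(g / -h, -1.0, 1.0)
            u_new = np.maximum(u + step, lo + 1e-8)
            if np.max(np.abs(u_new - u)) < 1e-10:
                u = u_new
                break
            u = u_new
        mu = eta + u[gi]
        h = self._group_sum(k * (mu - 2.0 * y) / mu**3) - 1.0 / sig2
        return u, np.minimum(h, -1e-10)

    def _group_h(self, eta, u, k, sig2):
        """h_i(u) = joint log density of (y_i, u_i), summed within animal."""
        mu = eta + u[self.gi]
        bad = mu <= MU_FLOOR
        mu = np.where(bad, MU_FLOOR, mu)
        lp = _gamma_logpdf_terms(self.y, mu, k, self.logy)
        h = self._group_sum(np.where(bad, -1e8, lp))
        return h - 0.5 * np.log(2.0 * np.pi * sig2) - u**2 / (2.0 * sig2)

    def loglik(self, beta, k, sigma):
        eta = self.X @ beta
        if eta.min() <= MU_FLOOR:
            return -1e8 * (1.0 + MU_FLOOR - eta.min())
        if sigma < 1e-8:
            return float(np.sum(_gamma_logpdf_terms(self.y, eta, k, self.logy)))
        sig2 = sigma * sigma
        u_hat, h2 = self._mode(eta, k, sig2)
        self.u_hat = u_hat
        scale = np.sqrt(2.0 / -h2)               # AGQ scale per animal
        contrib = np.empty((self.nodes.size, self.G))
        for m, (x, lw) in enumerate(zip(self.nodes, self.logw)):
            um = u_hat + scale * x
            contrib[m] = lw + x * x + self._group_h(eta, um, k, sig2)
        ll = special.logsumexp(contrib, axis=0) + np.log(scale)
        return float(np.sum(ll))

    def make_objective(self, p, fix_sigma):
        def nll(theta):
            beta = theta[:p]
            k = np.exp(theta[p])
            sigma = fix_sigma if fix_sigma is not None else theta[p + 1]
            return -self.loglik(beta, k, max(sigma, 0.0))
        return nll


def _start_values(y, X):
    """GLM (Gamma, identity) starting values; OLS fallback."""
    import statsmodels.api as sm

    beta0 = None
    k0 = 10.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(y, X, family=sm.families.Gamma(
                link=sm.families.links.Identity()))
            res = glm.fit(maxiter=200)
        if np.all(np.isfinite(res.params)) and (X @ res.params).min() > MU_FLOOR:
            beta0 = np.asarray(res.params)
            k0 = float(np.clip(1.0 / max(res.scale, 1e-8), 0.1, 1e6))
    except Exception:
        beta0 = None
    if beta0 is None:
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        if (X @ beta0).min() <= MU_FLOOR:
            beta0 = np.zeros(X.shape[1])
            beta0[0] = y.mean()
        resid = y - X @ beta0
        cv2 = max(np.var(resid) / y.mean() ** 2, 1e-4)
        k0 = float(np.clip(1.0 / cv2, 0.1, 1e6))
    return beta0, k0


def fit_gamma_glmm(
    data: pd.DataFrame,
    fixed_terms=("status",),
    group_col: str = "animal_id",
    response_col: str = "msrmr",
    n_quad: int = 11,
    fix_sigma_u: float | None = None,
    interactions: bool = False,
) -> GlmmFit:
    """Maximum-likelihood fit of the identity-link Gamma GLMM.

    Parameters
    ----------
    data : tidy records with the response, the grouping column (animal id)
        and any covariate columns the terms need.
    fixed_terms : model terms among ``{"status", "ta_factor",
        "sqrt_body_mass", "age"}`` or raw column names; the intercept is
        always included.
    n_quad : adaptive Gauss-Hermite nodes; 1 gives the plain Laplace
        approximation.
    fix_sigma_u : fix the random-intercept SD instead of estimating it
        (``0.0`` reduces the model to an independent Gamma GLM).
    """
    y = data[response_col].to_numpy(float)
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise ValueError("response must be finite and positive")
    X, names = build_design(data, fixed_terms, interactions=interactions)
    codes, uniques = pd.factorize(data[group_col])
    marg = _Marginal(y, X, codes, len(uniques), n_quad)
    p = X.shape[1]

    beta0, k0 = _start_values(y, X)
    if fix_sigma_u is None:
        resid = y - X @ beta0
        gm = np.bincount(codes, weights=resid) / np.bincount(codes)
        sigma0 = float(np.clip(np.std(gm), 0.01, None))
        x0 = np.concatenate([beta0, [np.log(k0)], [sigma0]])
        bounds = [(None, None)] * p + [_LOG_K_BOUNDS] + [(0.0, None)]
    else:
        x0 = np.concatenate([beta0, [np.log(k0)]])
        bounds = [(None, None)] * p + [_LOG_K_BOUNDS]

    nll = marg.make_objective(p, fix_sigma_u)
    opts = {"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8}
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                            options=opts)
    if fix_sigma_u is None:
        # second start at the sigma_u = 0 boundary guards against flat
        # ridges when the random effect is weakly identified
        x0b = np.concatenate([x0[:p + 1], [0.0]])
        res_b = optimize.minimize(nll, x0b, method="L-BFGS-B", bounds=bounds,
                                  options=opts)
        if res_b.fun < res.fun:
            res = res_b
    if not res.success:
        # one retry from a perturbed start; report status either way
        res2 = optimize.minimize(nll, res.x * 1.0 + 1e-3, method="L-BFGS-B",
                                 bounds=bounds,
                                 options={"maxiter": 500, "ftol": 1e-12})
        if res2.fun <= res.fun:
            res = res2

    theta = res.x
    beta = theta[:p]
    k = float(np.exp(theta[p]))
    sigma = float(fix_sigma_u if fix_sigma_u is not None else max(theta[p + 1], 0.0))
    loglik = -float(res.fun)
    nparams = p + 1 + (0 if fix_sigma_u is not None else 1)
    aic = 2.0 * nparams - 2.0 * loglik

    from statsmodels.tools.numdiff import approx_hess

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            H = approx_hess(theta, nll)
            cov = np.linalg.pinv(H)
            se_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except Exception:
            cov = np.full((theta.size, theta.size), np.nan)
            se_all = np.full(theta.size, np.nan)

    return GlmmFit(
        coef=pd.Series(beta, index=names),
        se=pd.Series(se_all[:p], index=names),
        sigma_u=sigma,
        gamma_shape=k,
        loglik=loglik,
        aic=aic,
        nparams=nparams,
        n_obs=len(y),
        n_groups=len(uniques),
        terms=tuple(t for t in fixed_terms if t not in ("1", "Intercept")),
        design_columns=tuple(names),
        converged=bool(res.success),
        n_quad=n_quad,
        cov=cov,
        sigma_u_fixed=fix_sigma_u is not None,
        message=str(res.message),
    )


# ---------------------------------------------------------------------------
# Inference on fits

def compare_models(fit_small: GlmmFit, fit_big: GlmmFit,
                   slack: float = 1e-6) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits: chi2 = 2 (logL_big - logL_small),
    df = parameter-count difference, p from the chi-square upper tail."""
    if fit_small.n_obs != fit_big.n_obs:
        raise ValueError("fits are on different data")
    if not set(fit_small.design_columns) <= set(fit_big.design_columns):
        raise ValueError("models are not nested")
    chi2 = 2.0 * (fit_big.loglik - fit_small.loglik)
    if chi2 < 0:
        if chi2 < -slack * max(1.0, abs(fit_big.loglik)):
            warnings.warn(
                f"larger model has lower likelihood (chi2={chi2:.3g}); "
                "optimizer slack exceeded", stacklevel=2)
        chi2 = 0.0
    df = fit_big.nparams - fit_small.nparams
    if df == 0:
        if chi2 > 1e-6:
            raise ValueError("zero df with positive chi2: invalid nesting")
        return 0.0, 0, 1.0
    if df < 0:
        raise ValueError("larger model has fewer parameters")
    return float(chi2), int(df), float(stats.chi2.sf(chi2, df))


@dataclass
class ContrastResult:
    difference: float
    se: float
    t: float
    p: float
    reference: str = "normal"


def status_contrast(fit: GlmmFit, df: float | None = None) -> ContrastResult:
    """Reproductive minus non-reproductive level on the response scale.

    With treatment coding (NR reference) this is the ``status[R]``
    coefficient; the Wald statistic is referred to the standard normal by
    default (denominator df for a GLMM are contested) or to a t with
    user-chosen df.
    """
    name = next((c for c in fit.coef.index if c.startswith("status[")), None)
    if name is None:
        raise ValueError("fit contains no status term")
    diff = float(fit.coef[name])
    se = float(fit.se[name])
    if se == 0 or not np.isfinite(se):
        tval = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        tval = diff / se
    if df is None:
        pval = 2.0 * stats.norm.sf(abs(tval))
        ref = "normal"
    else:
        pval = 2.0 * stats.t.sf(abs(tval), df)
        ref = f"t({df:g})"
    return ContrastResult(diff, se, float(tval), float(pval), ref)


# ---------------------------------------------------------------------------
# Forward selection

@dataclass
class SelectionStep:
    term: str
    aic: float
    chi2: float
    df: int
    p: float
    accepted: bool


def forward_select(
    data: pd.DataFrame,
    candidates=("sqrt_body_mass", "ta_factor", "status"),
    alpha: float = 0.05,
    group_col: str = "animal_id",
    response_col: str = "msrmr",
    n_quad: int = 11,
) -> tuple[GlmmFit, list[SelectionStep], GlmmFit | None]:
    """AIC / likelihood-ratio forward selection of fixed effects.

    Starting from the intercept-plus-random-intercept null model, each round
    fits every remaining candidate added to the current model and accepts
    the one with the lowest AIC, provided it both lowers the AIC and has a
    significant likelihood-ratio test (p < alpha) against the current model;
    otherwise selection stops. Candidates whose design is rank deficient or
    whose fit fails are skipped with a warning. When two or more terms are
    accepted, the all-interactions model is returned as a supplementary fit.

    Returns ``(final_fit, trace, interaction_fit_or_None)``.
    """
    def fit(terms, **kw):
        return fit_gamma_glmm(data, terms, group_col=group_col,
                              response_col=response_col, n_quad=n_quad, **kw)

    current = fit(())
    accepted: list[str] = []
    remaining = list(candidates)
    trace: list[SelectionStep] = []
    while remaining:
        round_fits: list[tuple[str, GlmmFit, float, int, float]] = []
        for cand in remaining:
            try:
                f = fit(tuple(accepted) + (cand,))
            except (DesignRankError, KeyError, ValueError) as exc:
                warnings.warn(f"candidate {cand!r} skipped: {exc}", stacklevel=2)
                continue
            if not f.converged:
                warnings.warn(f"candidate {cand!r} skipped: fit did not "
                              "converge", stacklevel=2)
                continue
            chi2, dof, p = compare_models(current, f)
            round_fits.append((cand, f, chi2, dof, p))
        if not round_fits:
            break
        round_fits.sort(key=lambda r: r[1].aic)
        best_cand, best_fit, chi2, dof, p = round_fits[0]
        ok = best_fit.aic < current.aic and p < alpha
        for cand, f, c2, d, pv in round_fits:
            trace.append(SelectionStep(cand, f.aic, c2, d, pv,
                                       accepted=ok and cand == best_cand))
        if not ok:
            break
        accepted.append(best_cand)
        remaining.remove(best_cand)
        current = best_fit

    interaction_fit = None
    if len(accepted) >= 2:
        try:
            interaction_fit = fit_gamma_glmm(
                data, tuple(accepted), group_col=group_col,
                response_col=response_col, n_quad=n_quad, interactions=True)
        except (DesignRankError, ValueError) as exc:
            warnings.warn(f"interaction model skipped: {exc}", stacklevel=2)
    return current, trace, interaction_fit


def selection_table(trace: list[SelectionStep]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [s.term for s in trace],
            "aic": [s.aic for s in trace],
            "chi2": [s.chi2 for s in trace],
            "df": [s.df for s in trace],
            "p": [s.p for s in trace],
            "accepted": [s.accepted for s in trace],
        }
    )


def filter_to_tnz(table: pd.DataFrame, tnz_by_status: dict) -> pd.DataFrame:
    """Restrict a tidy msRMR table to each status's own TNZ (closed
    interval [LCT, UCT]); records at the boundaries are kept."""
    parts = []
    for status, est in tnz_by_status.items():
        if est is None:
            continue
        sub = table[table["status"] == status]
        parts.append(sub[(sub["ta_c"] >= est.lct_c) & (sub["ta_c"] <= est.uct_c)])
    if not parts:
        raise ValueError("no status has a TNZ estimate")
    return pd.concat(parts, ignore_index=True)
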