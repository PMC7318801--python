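"""Weighted binomial logit models for the PD parameters.

Two fitting routes:

* :func:`fit_mixed_logit` — a maximum-likelihood binomial logit mixed model
  with a per-participant random intercept and (optionally) a by-participant
  random slope for parameter type, the within-subject factor.  The marginal
  likelihood integrates the random effects out with a Laplace approximation
  (per-subject mode found by Newton iterations; the approximation is exact
  when the random-effect variance is zero).  Responses are grid proportions
  entering as (successes, failures) = (weight*p, weight*(1-p)) integer
  pairs, which is why the estimates are rounded to the 1/weight grid
  upstream.

* :func:`fit_glm` — per-parameter follow-up GLMs through statsmodels, with
  either the binomial family or, when the data are overdispersed, the
  quasibinomial variant (dispersion estimated as Pearson X^2 / df, standard
  errors scaled by its square root, and drop-in-deviance tests scaled by
  the dispersion).

Factors are treatment (dummy) coded.  Default reference levels: parameter D
(so the "parameter (U)" coefficient is the D-to-U shift), instrumentality
side-effect, personal force impersonal, sex female — matching the sign
conventions of the published coefficient tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from scipy.special import gammaln

DEFAULT_REFERENCES = {
    "parameter": "D",
    "instrumentality": "side_effect",
    "personal_force": "impersonal",
    "sex": "female",
    "congruency": "congruent",
}


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of a weighted logit model.

    ``terms`` are factor names or colon-joined interactions, e.g.
    ``["parameter", "instrumentality", "parameter:instrumentality"]``.
    """

    terms: tuple
    weight: int = 20
    family: str = "binomial"  # "binomial" | "quasibinomial"
    references: dict = field(default_factory=lambda: dict(DEFAULT_REFERENCES))

    def __post_init__(self):
        if self.family not in ("binomial", "quasibinomial"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class FitResult:
    """Coefficient table plus fit diagnostics for any fitted logit model."""

    table: pd.DataFrame  # term, b, se, z, p, odds_ratio, ci_low, ci_high
    loglik: float
    deviance: float
    dispersion: float
    converged: bool
    n_obs: int
    spec: ModelSpec
    design_columns: tuple
    response_fingerprint: tuple
    # mixed-model extras
    re_sd: tuple | None = None
    re_corr: float | None = None
    singular: bool = False
    n_groups: int | None = None

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.table["b"].to_numpy(), index=self.table["term"])


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p: float
    full_terms: tuple
    reduced_terms: tuple


# ------------------------------------------------------------- design build

def build_design(
    df: pd.DataFrame, terms, references: dict | None = None
) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix (with intercept) for the given terms."""
    refs = dict(DEFAULT_REFERENCES)
    if references:
        refs.update(references)

    def factor_columns(name: str) -> list[tuple[str, np.ndarray]]:
        values = df[name].astype(str)
        levels = sorted(values.unique())
        ref = refs.get(name, levels[0])
        if ref in levels:
            levels = [lv for lv in levels if lv != ref]
        else:
            levels = levels[1:]
        return [
            (f"{name}[{lv}]", (values == lv).to_numpy(dtype=float)) for lv in levels
        ]

    cols: list[tuple[str, np.ndarray]] = [("Intercept", np.ones(len(df)))]
    for term in terms:
        parts = term.split(":")
        for combo in itertools.product(*(factor_columns(p) for p in parts)):
            name = ":".join(c[0] for c in combo)
            col = np.ones(len(df))
            for c in combo:
                col = col * c[1]
            cols.append((name, col))
    X = np.column_stack([c[1] for c in cols])
    return X, [c[0] for c in cols]


def pd_long_table(
    estimates: pd.DataFrame,
    participants: pd.DataFrame,
    weight: int = 20,
) -> pd.DataFrame:
    """Long format for the mixed model: one row per participant x parameter.

    Successes are the grid values scaled to integer counts.  Participants
    whose D is undefined contribute only their U row.
    """
    cols = [c for c in ("instrumentality", "personal_force", "sex")
            if c in participants.columns]
    merged = estimates.merge(
        participants[["participant_id", *cols]], on="participant_id", how="left"
    )
    rows = []
    for rec in merged.to_dict("records"):
        for param, grid in (("D", rec["grid_D"]), ("U", rec["grid_U"])):
            if param == "D" and rec.get("d_undefined", False):
                continue
            if pd.isna(grid):
                continue
            rows.append(
                {
                    "participant_id": rec["participant_id"],
                    "parameter": param,
                    "successes": int(round(grid * weight)),
                    "trials": int(weight),
                    **{c: rec[c] for c in cols},
                }
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------- mixed model

def _pack_groups(df, X, Z, y, m):
    """Pad each participant's rows to a common count with zero-trial rows."""
    codes, uniques = pd.factorize(df["participant_id"], sort=True)
    n_groups = len(uniques)
    counts = np.bincount(codes, minlength=n_groups)
    R = int(counts.max())
    p, q = X.shape[1], Z.shape[1]
    Xs = np.zeros((n_groups, R, p))
    Zs = np.zeros((n_groups, R, q))
    ys = np.zeros((n_groups, R))
    ms = np.zeros((n_groups, R))
    slot = np.zeros(n_groups, dtype=int)
    for i, g in enumerate(codes):
        j = slot[g]
        Xs[g, j], Zs[g, j], ys[g, j], ms[g, j] = X[i], Z[i], y[i], m[i]
        slot[g] = j + 1
    return Xs, Zs, ys, ms, n_groups


def _theta_to_chol(theta: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    L[np.tril_indices(q)] = theta
    return L


def _subject_joint(off, ZL, u, ys, ms):
    """Per-subject joint log-density (binomial log-lik + N(0,I) penalty)."""
    eta = off + np.einsum("nij,nj->ni", ZL, u)
    return (ys * eta - ms * np.logaddexp(0.0, eta)).sum(axis=1) - 0.5 * (
        u * u
    ).sum(axis=1)


def _laplace_negll(beta, theta, Xs, Zs, ys, ms, const, q, u_start=None, u_out=None):
    """Negative Laplace marginal log-likelihood (vectorized over subjects).

    The per-subject random-effect modes are found by damped Newton
    iterations (step-halving keeps the joint density monotone, so the inner
    problem cannot diverge even for extreme responses).  ``u_start`` warm
    starts the modes; ``u_out`` (a one-element list) receives them for reuse.
    """
    L = _theta_to_chol(theta, q)
    ZL = Zs @ L.T
    off = Xs @ beta
    n_groups = Xs.shape[0]
    u = np.zeros((n_groups, q)) if u_start is None else u_start.copy()
    eye = np.eye(q)
    f = _subject_joint(off, ZL, u, ys, ms)
    for _ in range(100):
        eta = off + np.einsum("nij,nj->ni", ZL, u)
        mu = special.expit(eta)
        grad = np.einsum("nij,ni->nj", ZL, ys - ms * mu) - u
        W = ms * mu * (1.0 - mu)
        H = np.einsum("nij,ni,nik->njk", ZL, W, ZL) + eye
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        # step-halving: accept only non-decreasing subject joints
        scale = np.ones((n_groups, 1))
        for _half in range(30):
            u_new = u + scale * step
            f_new = _subject_joint(off, ZL, u_new, ys, ms)
            bad = f_new < f - 1e-12
            if not bad.any():
                break
            scale[bad] *= 0.5
        u, f = u_new, np.maximum(f, f_new)
        if np.abs(scale * step).max() < 1e-11:
            break
    if u_out is not None:
        u_out[0] = u
    eta = off + np.einsum("nij,nj->ni", ZL, u)
    mu = special.expit(eta)
    ll = float(np.sum(ys * eta - ms * np.logaddexp(0.0, eta))) + const
    W = ms * mu * (1.0 - mu)
    H = np.einsum("nij,ni,nik->njk", ZL, W, ZL) + eye
    _, logdet = np.linalg.slogdet(H)
    return -(ll - 0.5 * float(np.sum(u * u)) - 0.5 * float(logdet.sum()))


def fit_mixed_logit(
    data: pd.DataFrame,
    spec: ModelSpec,
    random_slope: str | None = "parameter",
    fix_theta: tuple | None = None,
    gtol: float = 1e-8,
) -> FitResult:
    """Laplace-ML fit of the weighted logit mixed model.

    ``data`` is the long table (``successes``/``trials`` response columns,
    one row per participant per within-subject level).  The random structure
    is a per-participant intercept plus, unless ``random_slope`` is None, a
    by-participant slope for the named within-subject factor with an
    unstructured 2x2 covariance.  ``fix_theta`` pins the Cholesky factor of
    the random-effect covariance (e.g. all zeros reduces the model to a
    plain weighted logistic regression); otherwise it is estimated.

    Non-convergence is reported through ``converged``; near-zero estimated
    random-effect SDs raise the ``singular`` flag.
    """
    X, names = build_design(data, spec.terms, spec.references)
    y = data["successes"].to_numpy(dtype=float)
    m = data["trials"].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y > m):
        raise ValueError("successes must lie in [0, trials]")
    if random_slope is not None:
        refs = dict(DEFAULT_REFERENCES)
        refs.update(spec.references)
        vals = data[random_slope].astype(str)
        levels = sorted(vals.unique())
        ref = refs.get(random_slope, levels[0])
        nonref = [lv for lv in levels if lv != ref]
        if len(nonref) != 1:
            raise ValueError("random slope factor must have exactly 2 levels")
        Z = np.column_stack([np.ones(len(data)), (vals == nonref[0]).astype(float)])
    else:
        Z = np.ones((len(data), 1))
    q = Z.shape[1]
    n_theta = q * (q + 1) // 2

    Xs, Zs, ys, ms, n_groups = _pack_groups(data, X, Z, y, m)
    const = float(np.sum(gammaln(m + 1) - gammaln(y + 1) - gammaln(m - y + 1)))

    start_glm = sm.GLM(
        np.column_stack([y, m - y]), X, family=sm.families.Binomial()
    ).fit()
    beta0 = np.asarray(start_glm.params, dtype=float)
    p = len(beta0)

    theta_fixed = None if fix_theta is None else np.asarray(fix_theta, dtype=float)
    if theta_fixed is not None and len(theta_fixed) != n_theta:
        raise ValueError(f"fix_theta must have length {n_theta}")

    if theta_fixed is not None and not theta_fixed.any():
        # Zero random-effect variance: the Laplace objective is exactly the
        # binomial GLM log-likelihood; solve by Newton/IRLS to high precision.
        beta = beta0.copy()
        converged = False
        for _ in range(100):
            eta = X @ beta
            mu = special.expit(eta)
            grad = X.T @ (y - m * mu)
            H = (X * (m * mu * (1 - mu))[:, None]).T @ X
            step = np.linalg.solve(H, grad)
            beta = beta + step
            if np.abs(step).max() < 1e-13:
                converged = True
                break
        theta = theta_fixed
        negll = _laplace_negll(beta, theta, Xs, Zs, ys, ms, const, q)
    else:
        warm = [None]

        def obj_full(beta_v, theta_v):
            val = _laplace_negll(
                beta_v, theta_v, Xs, Zs, ys, ms, const, q,
                u_start=warm[0], u_out=warm,
            )
            return val

        if theta_fixed is not None:
            def obj(params):
                return obj_full(params, theta_fixed)
            x0 = beta0
        else:
            theta0 = np.zeros(n_theta)
            theta0[np.cumsum([0, *range(1, q)])] = 1.0  # unit diagonal start

            def obj(params):
                return obj_full(params[:p], params[p:])
            x0 = np.concatenate([beta0, theta0])

        # BFGS with restarts: line searches on this objective can stall on
        # finite-difference noise, so re-launch from the incumbent until the
        # log-likelihood stops improving, with a Nelder-Mead escape in between.
        res = optimize.minimize(
            obj, x0, method="BFGS", jac="3-point",
            options={"gtol": gtol, "maxiter": 1000},
        )
        for _ in range(4):
            if res.success:
                break
            res_nm = optimize.minimize(
                obj, res.x, method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
            )
            restart = optimize.minimize(
                obj, res_nm.x, method="BFGS", jac="3-point",
                options={"gtol": gtol, "maxiter": 1000},
            )
            improved = restart.fun < res.fun - 1e-9
            res = restart if restart.fun <= res.fun else res
            if not improved:
                break
        beta = res.x[:p]
        theta = theta_fixed if theta_fixed is not None else res.x[p:]
        converged = bool(res.success or np.max(np.abs(res.jac)) < 1e-4)
        negll = float(res.fun)

    # Wald covariance: inverse Hessian of the Laplace log-likelihood in beta
    # at the estimated variance components (the usual mixed-logit practice).
    def negll_beta(b):
        return _laplace_negll(b, theta, Xs, Zs, ys, ms, const, q)

    Hb = _numeric_hessian(negll_beta, beta)
    cov = np.linalg.inv(Hb)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

    Lc = _theta_to_chol(theta, q)
    V = Lc @ Lc.T
    re_sd = tuple(float(s) for s in np.sqrt(np.diag(V)))
    re_corr = (
        float(V[0, 1] / (re_sd[0] * re_sd[1]))
        if q == 2 and re_sd[0] > 0 and re_sd[1] > 0
        else None
    )
    singular = bool(
        theta_fixed is None and np.min(np.abs(np.diag(Lc))) < 1e-3
    )

    eta = X @ beta
    mu = special.expit(eta)
    dev_resid = 2 * (
        special.xlogy(y, np.where(mu > 0, y / np.maximum(m * mu, 1e-300), 1))
        + special.xlogy(m - y, np.where(mu < 1, (m - y) / np.maximum(m * (1 - mu), 1e-300), 1))
    )
    table = _coef_table(names, beta, se)
    return FitResult(
        table=table,
        loglik=-negll,
        deviance=float(np.sum(dev_resid)),
        dispersion=1.0,
        converged=converged,
        n_obs=int(len(data)),
        spec=spec,
        design_columns=tuple(names),
        response_fingerprint=(int(len(data)), float(y.sum()), float(m.sum())),
        re_sd=re_sd,
        re_corr=re_corr,
        singular=singular,
        n_groups=n_groups,
    )


def _numeric_hessian(f, x, h: float = 1e-4):
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    H = np.zeros((n, n))
    steps = h * (1.0 + np.abs(x))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = steps[i]
        for j in range(i, n):
            ej = np.zeros(n)
            ej[j] = steps[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * steps[i] * steps[j])
    return H


def _coef_table(names, beta, se) -> pd.DataFrame:
    z = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "term": names,
            "b": beta,
            "se": se,
            "z": z,
            "p": p,
            "odds_ratio": np.exp(beta),
            "ci_low": np.exp(beta - 1.96 * se),
            "ci_high": np.exp(beta + 1.96 * se),
        }
    )


def lrt(full: FitResult, reduced: FitResult) -> LRTResult:
    """Likelihood ratio test of nested weighted-logit fits on the same data."""
    if not set(reduced.design_columns) <= set(full.design_columns):
        raise ValueError("reduced model is not nested in the full model")
    if reduced.response_fingerprint != full.response_fingerprint:
        raise ValueError("models were fitted to different data")
    df = len(full.design_columns) - len(reduced.design_columns)
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    if df == 0 and chi2 <= 1e-8:
        p = 1.0
    return LRTResult(
        chi2=float(chi2), df=df, p=p,
        full_terms=full.spec.terms, reduced_terms=reduced.spec.terms,
    )


# --------------------------------------------------------------- plain GLM

def fit_glm(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Weighted logistic GLM (binomial or quasibinomial) via statsmodels.

    For the quasibinomial family the dispersion is Pearson X^2 / df and
    standard errors are scaled by its square root; coefficients are
    unchanged.  Complete separation is reported through ``converged``.
    """
    X, names = build_design(data, spec.terms, spec.references)
    y = data["successes"].to_numpy(dtype=float)
    m = data["trials"].to_numpy(dtype=float)
    model = sm.GLM(np.column_stack([y, m - y]), X, family=sm.families.Binomial())
    res = model.fit(scale=1.0)
    if spec.family == "quasibinomial":
        df_resid = len(data) - X.shape[1]
        if df_resid <= 0:
            raise ValueError("no residual degrees of freedom for dispersion")
        dispersion = float(res.pearson_chi2 / df_resid)
        res = model.fit(scale=dispersion)
    else:
        dispersion = 1.0
    separation = bool(np.max(np.abs(res.params)) > 15)
    table = _coef_table(names, np.asarray(res.params), np.asarray(res.bse))
    return FitResult(
        table=table,
        loglik=float(res.llf),
        deviance=float(res.deviance),
        dispersion=dispersion,
        converged=bool(res.converged) and not separation,
        n_obs=int(len(data)),
        spec=spec,
        design_columns=tuple(names),
        response_fingerprint=(int(len(data)), float(y.sum()), float(m.sum())),
    )


def drop_term_test(full: FitResult, reduced: FitResult) -> LRTResult:
    """Scaled drop-in-deviance test for (quasi)binomial GLMs.

    chi^2 = (deviance_reduced - deviance_full) / dispersion_full with df the
    difference in coefficient counts; for the binomial family (dispersion 1)
    this is the ordinary likelihood-ratio test.
    """
    if not set(reduced.design_columns) <= set(full.design_columns):
        raise ValueError("reduced model is not nested in the full model")
    if reduced.response_fingerprint != full.response_fingerprint:
        raise ValueError("models were fitted to different data")
    df = len(full.design_columns) - len(reduced.design_columns)
    chi2 = max(0.0, (reduced.deviance - full.deviance) / full.dispersion)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return LRTResult(
        chi2=float(chi2), df=df, p=p,
        full_terms=full.spec.terms, reduced_terms=reduced.spec.terms,
    )


def overdispersion_check(
    data: pd.DataFrame, spec: ModelSpec, threshold: float = 1.5
) -> tuple[bool, float]:
    """Pearson dispersion of a binomial-family fit, flagged above threshold.

    The flag motivates switching the follow-up GLMs to the quasibinomial
    family; the threshold is a package decision exposed in configuration.
    """
    X, _ = build_design(data, spec.terms, spec.references)
    y = data["successes"].to_numpy(dtype=float)
    m = data["trials"].to_numpy(dtype=float)
    df_resid = len(data) - X.shape[1]
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    res = sm.GLM(
        np.column_stack([y, m - y]), X, family=sm.families.Binomial()
    ).fit()
    dispersion = float(res.pearson_chi2 / df_resid)
    return dispersion > threshold, dispersion
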