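"""Random-intercept generalized linear mixed models via the Laplace
approximation.

This is a self-contained estimation engine for the model class the analysis
needs: GLMMs with a log, logit or identity link, one or two Gaussian
random-intercept batches (a cohort intercept, or squirrel identity nested
within cohort), and Poisson, negative-binomial (NB2, variance
``mu + mu^2/theta``), Bernoulli or Gaussian responses.

Estimation follows the standard two-level scheme: for fixed variance
parameters the joint mode of the fixed effects and the spherical random
effects ``u`` (random intercepts are ``b = s * u`` with ``u ~ N(0, I)``) is
found by penalized iteratively reweighted least squares (PIRLS); the
Laplace-approximated marginal log-likelihood

    ll(s, ...) = log f(y | beta_hat, u_hat) - ||u_hat||^2 / 2
                 - log det(H_u) / 2

(with ``H_u`` the penalized Fisher information of ``u`` at the mode) is then
maximized over the random-effect standard deviations — and the Gaussian
residual SD or the NB size parameter where applicable — by a bounded
quasi-Newton outer optimizer. Standard deviations are parameterized
directly with a lower bound of zero so boundary fits (variance exactly 0)
are reachable, as in lme4.

The nested two-batch structure is exploited throughout: the fine
(per-female) block of every linear system is diagonal and is eliminated by
a Schur complement, so each PIRLS step costs O(n) plus a dense solve of
size (number of cohorts + number of fixed effects).

Quadratic terms are written ``"x^2"`` and interactions ``"a:b"``; both are
built from the *scaled* component columns when the component is listed in
``scaled_vars`` (scale-then-square).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .families import Family, get_family
from .lifehistory import ScalingInfo, scale_predictors

RANDOM_STRUCTURES = ("none", "cohort_intercept", "female_in_cohort_intercepts")

_PIRLS_TOL = 1e-12
_PIRLS_MAXIT = 200
_OUTER_TOL = 1e-9
_OUTER_FD_EPS = 1e-5  # finite-difference step; must dominate PIRLS noise


# ---------------------------------------------------------------------------
# Model specification and terms


def parse_term(term: str) -> tuple[str, tuple[str, ...]]:
    """Classify a term string: linear, quadratic (``v^2``) or pairwise
    interaction (``a:b``)."""
    if ":" in term:
        parts = tuple(p.strip() for p in term.split(":"))
        if len(parts) != 2 or not all(parts):
            raise ValueError(f"malformed interaction term {term!r}")
        return "inter", parts
    if term.endswith("^2"):
        base = term[:-2].strip()
        if not base:
            raise ValueError(f"malformed quadratic term {term!r}")
        return "quad", (base,)
    return "lin", (term.strip(),)


def term_base_vars(term: str) -> tuple[str, ...]:
    return parse_term(term)[1]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixed model.

    ``fixed_terms`` lists predictors by name, with ``"v^2"`` for quadratics
    and ``"a:b"`` for interactions; ``scaled_vars`` names the continuous
    predictors standardized (mean 0, unit SD) before any squaring.
    """

    response: str
    family: str
    fixed_terms: tuple[str, ...]
    random_structure: str = "cohort_intercept"
    scaled_vars: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))
        object.__setattr__(self, "scaled_vars", tuple(self.scaled_vars))
        get_family(self.family)  # validates family name (link is implied)
        if self.random_structure not in RANDOM_STRUCTURES:
            raise ValueError(f"unknown random structure {self.random_structure!r}")
        lin = {t for t in self.fixed_terms if parse_term(t)[0] == "lin"}
        for t in self.fixed_terms:
            kind, bases = parse_term(t)
            if kind == "quad" and bases[0] not in lin:
                raise ValueError(f"quadratic {t!r} requires its linear term")
            if kind == "inter" and not set(bases) <= lin:
                raise ValueError(f"interaction {t!r} requires both main effects")

    def without(self, term: str) -> "ModelSpec":
        if term not in self.fixed_terms:
            raise ValueError(f"{term!r} not in spec")
        return replace(self, fixed_terms=tuple(t for t in self.fixed_terms if t != term))

    def removable_terms(self) -> list[str]:
        """Terms that may be dropped without violating marginality: a linear
        term is protected while its quadratic or any interaction using it
        remains."""
        protected: set[str] = set()
        for t in self.fixed_terms:
            kind, bases = parse_term(t)
            if kind in ("quad", "inter"):
                protected.update(bases)
        return [t for t in self.fixed_terms
                if parse_term(t)[0] != "lin" or term_base_vars(t)[0] not in protected]


def build_design(
    spec: ModelSpec,
    data: pd.DataFrame,
    scaling: dict[str, ScalingInfo] | None = None,
) -> tuple[np.ndarray, list[str], dict[str, ScalingInfo]]:
    """Design matrix (intercept first) plus the scaling constants used.

    Pass ``scaling`` to reuse a previous fit's standardization (prediction,
    bootstrap refits); otherwise it is computed from ``data``.
    """
    base_vars = sorted({v for t in spec.fixed_terms for v in term_base_vars(t)})
    missing = [v for v in base_vars if v not in data.columns]
    if missing:
        raise ValueError(f"data lacks model variables: {missing}")
    cols: dict[str, np.ndarray] = {}
    infos: dict[str, ScalingInfo] = {}
    for v in base_vars:
        x = np.asarray(data[v], dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"variable {v!r} contains missing values")
        if v in spec.scaled_vars:
            if scaling is not None:
                info = scaling[v]
                x = (x - info.mean) / info.sd
            else:
                x, info = scale_predictors(x)
            infos[v] = info
        cols[v] = x
    columns = [np.ones(len(data))]
    names = ["(Intercept)"]
    for t in spec.fixed_terms:
        kind, bases = parse_term(t)
        if kind == "lin":
            columns.append(cols[bases[0]])
        elif kind == "quad":
            columns.append(cols[bases[0]] ** 2)
        else:
            columns.append(cols[bases[0]] * cols[bases[1]])
        names.append(t)
    return np.column_stack(columns), names, infos


# ---------------------------------------------------------------------------
# Random-effect bookkeeping


class _Grouping:
    """Integer-coded random-intercept batches; at most two, nested."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.n_batches = 0
        self.names: list[str] = []
        if spec.random_structure == "none":
            return
        if spec.random_structure == "cohort_intercept":
            fine_col, coarse_col = "cohort", None
        else:
            fine_col, coarse_col = "female_id", "cohort"
        for col in filter(None, (fine_col, coarse_col)):
            if col not in data.columns:
                raise ValueError(f"random structure needs column {col!r}")
        self.g1, levels1 = pd.factorize(data[fine_col], sort=True)
        self.q1 = len(levels1)
        self.names = [fine_col]
        self.n_batches = 1
        self.g2 = None
        if coarse_col is not None:
            self.g2, levels2 = pd.factorize(data[coarse_col], sort=True)
            self.q2 = len(levels2)
            self.names.append(coarse_col)
            self.n_batches = 2
            # nested: each fine level sits inside exactly one coarse level
            map12 = np.full(self.q1, -1, dtype=int)
            for j, k in zip(self.g1, self.g2):
                if map12[j] == -1:
                    map12[j] = k
                elif map12[j] != k:
                    raise ValueError(
                        f"{fine_col!r} is not nested within {coarse_col!r}")
            self.map12 = map12
        for nm, q in zip(self.names, (self.q1, getattr(self, "q2", None))):
            if q is not None and q < 2:
                raise ValueError(f"grouping factor {nm!r} has fewer than 2 levels")


def _penalized_wls(X, w, z, grp: _Grouping, sds):
    """One penalized weighted-LS solve; returns (beta, u1, u2, logdet_Hu,
    cov_beta_factors) with the fine batch eliminated analytically."""
    p = X.shape[1]
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    XtWz = Xw.T @ z
    if grp.n_batches == 0:
        beta = np.linalg.solve(XtWX, XtWz)
        return beta, None, None, 0.0, XtWX
    s1 = sds[0]
    q1, g1 = grp.q1, grp.g1
    Sw1 = np.bincount(g1, weights=w, minlength=q1)
    Sz1 = np.bincount(g1, weights=w * z, minlength=q1)
    Sx1 = np.empty((q1, p))
    for k in range(p):
        Sx1[:, k] = np.bincount(g1, weights=Xw[:, k], minlength=q1)
    d1 = s1 * s1 * Sw1 + 1.0
    logdet = float(np.sum(np.log(d1)))

    if grp.n_batches == 1:
        A = XtWX - (s1 * s1) * (Sx1.T @ (Sx1 / d1[:, None]))
        r = XtWz - (s1 * s1) * (Sx1.T @ (Sz1 / d1))
        beta = np.linalg.solve(A, r)
        u1 = s1 * (Sz1 - Sx1 @ beta) / d1
        return beta, u1, None, logdet, A

    s2 = sds[1]
    q2, map12 = grp.q2, grp.map12
    Sw2 = np.bincount(map12, weights=Sw1, minlength=q2)
    Sz2 = np.bincount(map12, weights=Sz1, minlength=q2)
    Sx2 = np.empty((q2, p))
    for k in range(p):
        Sx2[:, k] = np.bincount(map12, weights=Sx1[:, k], minlength=q2)
    cross = s1 * s2 * Sw1                       # H_u fine-coarse entries
    # Schur complement onto (u2, beta); the u1 block is diagonal
    Acc = s2 * s2 * Sw2 + 1.0 - np.bincount(
        map12, weights=cross * cross / d1, minlength=q2)
    Acb = s2 * Sx2.copy()
    for k in range(p):
        Acb[:, k] -= np.bincount(
            map12, weights=cross * s1 * Sx1[:, k] / d1, minlength=q2)
    rc = s2 * Sz2 - np.bincount(map12, weights=cross * s1 * Sz1 / d1, minlength=q2)
    Abb = XtWX - (s1 * s1) * (Sx1.T @ (Sx1 / d1[:, None]))
    rb = XtWz - (s1 * s1) * (Sx1.T @ (Sz1 / d1))
    M = np.zeros((q2 + p, q2 + p))
    M[np.arange(q2), np.arange(q2)] = Acc
    M[:q2, q2:] = Acb
    M[q2:, :q2] = Acb.T
    M[q2:, q2:] = Abb
    sol = np.linalg.solve(M, np.concatenate([rc, rb]))
    u2, beta = sol[:q2], sol[q2:]
    u1 = (s1 * Sz1 - cross * u2[map12] - s1 * (Sx1 @ beta)) / d1
    logdet += float(np.sum(np.log(Acc)))
    cov_factor = Abb - (Acb.T / Acc) @ Acb      # beta information after u2
    return beta, u1, u2, logdet, cov_factor


def _eta_of(X, beta, grp, sds, u1, u2):
    eta = X @ beta
    if grp.n_batches >= 1 and u1 is not None:
        eta = eta + sds[0] * u1[grp.g1]
    if grp.n_batches == 2 and u2 is not None:
        eta = eta + sds[1] * u2[grp.g2]
    return eta


def _pirls(y, X, grp, sds, family: Family, aux, state=None):
    """Joint (beta, u) mode by penalized IRLS with step-halving.

    Returns a dict with the mode, the Laplace log-likelihood, and the beta
    information matrix. ``state`` carries a warm start between successive
    outer evaluations; random effects are stored on the ``b = s*u`` scale,
    which is invariant to the variance parameters being optimized (storing
    spherical ``u`` would rescale the linear predictor catastrophically
    when the outer step moves ``s``). A warm run that fails or stalls
    triggers a cold restart."""

    def run(beta, u1, u2, eta):
        def pen_of(e, a, b):
            return -2.0 * family.loglik(y, e, aux) + _usq(a) + _usq(b)

        pen_old = pen_of(eta, u1, u2) if beta is not None else np.inf
        converged = False
        logdet, cov_factor = 0.0, None
        for _ in range(_PIRLS_MAXIT):
            mu = family.mean(eta)
            w = family.weights(mu, aux)
            z = family.working_response(y, eta, mu)
            cand = _penalized_wls(X, w, z, grp, sds)
            cbeta, cu1, cu2, logdet, cov_factor = cand
            nbeta, nu1, nu2 = cbeta, cu1, cu2
            neta = _eta_of(X, nbeta, grp, sds, nu1, nu2)
            pen = pen_of(neta, nu1, nu2)
            if beta is not None:
                step = 1.0
                while (not np.isfinite(pen) or pen > pen_old + 1e-10) and step > 1e-10:
                    step *= 0.5
                    nbeta = (1 - step) * beta + step * cbeta
                    nu1 = None if cu1 is None else (1 - step) * u1 + step * cu1
                    nu2 = None if cu2 is None else (1 - step) * u2 + step * cu2
                    neta = _eta_of(X, nbeta, grp, sds, nu1, nu2)
                    pen = pen_of(neta, nu1, nu2)
            if not np.isfinite(pen):
                return {"ok": False}
            beta, u1, u2, eta = nbeta, nu1, nu2, neta
            if abs(pen - pen_old) < _PIRLS_TOL * (abs(pen) + 1.0):
                converged = True
                break
            pen_old = pen
        ll = family.loglik(y, eta, aux) - 0.5 * (_usq(u1) + _usq(u2)) - 0.5 * logdet
        return {
            "ok": True, "beta": beta, "u1": u1, "u2": u2, "eta": eta,
            "loglik": ll, "cov_factor": cov_factor, "converged": converged,
        }

    def scale_from_b(b, s):
        if b is None:
            return None
        return b / s if s > 1e-10 else np.zeros_like(b)

    res = None
    if state is not None and state.get("beta") is not None:
        beta = state["beta"]
        u1 = scale_from_b(state.get("b1"), sds[0]) if grp.n_batches >= 1 else None
        u2 = scale_from_b(state.get("b2"), sds[1]) if grp.n_batches == 2 else None
        warm = run(beta, u1, u2, _eta_of(X, beta, grp, sds, u1, u2))
        if warm["ok"] and warm["converged"]:
            res = warm
    if res is None:
        res = run(None, None, None, _initial_eta(y, family))
    if state is not None and res["ok"]:
        state["beta"] = res["beta"]
        state["b1"] = None if res["u1"] is None else sds[0] * res["u1"]
        state["b2"] = None if res["u2"] is None else sds[1] * res["u2"]
    return res


def _usq(u):
    return 0.0 if u is None else float(u @ u)


_THETA_GRID = np.log(np.array([0.3, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0,
                               64.0, 256.0, 2048.0]))


def _lbfgs(negll, x0, bounds, ftol=_OUTER_TOL, maxiter=500):
    """Bounded quasi-Newton with a one-shot retry at a coarser
    finite-difference step — line searches occasionally abort on the
    ~1e-9-level PIRLS noise and the retry recovers those."""
    opt = optimize.minimize(
        negll, np.asarray(x0, dtype=float), method="L-BFGS-B", bounds=bounds,
        options={"ftol": ftol, "gtol": 1e-7, "maxiter": maxiter,
                 "eps": _OUTER_FD_EPS})
    if not opt.success:
        opt2 = optimize.minimize(
            negll, opt.x, method="L-BFGS-B", bounds=bounds,
            options={"ftol": ftol, "gtol": 1e-6, "maxiter": maxiter,
                     "eps": 10 * _OUTER_FD_EPS})
        if opt2.fun <= opt.fun:
            opt = opt2
    return opt


def _seed_theta(negll, x: np.ndarray) -> np.ndarray:
    """Replace the trailing log(theta) entry with the best point of a
    coarse profile grid (other outer parameters held fixed)."""
    x = np.asarray(x, dtype=float).copy()
    best, best_val = x[-1], np.inf
    for lt in _THETA_GRID:
        xt = x.copy()
        xt[-1] = lt
        v = negll(xt)
        if v < best_val:
            best, best_val = lt, v
    cur = x.copy()
    if negll(cur) <= best_val:
        return cur
    x[-1] = best
    return x


def _initial_eta(y, family: Family):
    y = np.asarray(y, dtype=float)
    if family.link == "log":
        return np.log(y + 0.5)
    if family.link == "logit":
        return np.log((y + 0.5) / (1.5 - y))
    return y.copy()


# ---------------------------------------------------------------------------
# Fit result


@dataclass
class FitResult:
    """Fitted mixed model: coefficients on the link scale in
    scaled-predictor units, Wald tests, CIs (Wald by default; replaced by
    parametric-bootstrap percentiles when :func:`bootstrap_ci` is run),
    variance components and fit diagnostics."""

    spec: ModelSpec
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    test_stat: np.ndarray
    p_value: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    ci_method: str
    variance_components: dict[str, float]
    nb_dispersion: float | None
    sigma: float | None
    log_likelihood: float
    converged: bool
    n_obs: int
    n_groups: dict[str, int]
    scaling_info: dict[str, ScalingInfo]
    df: np.ndarray | None = None          # Satterthwaite df (Gaussian only)
    df_method: str | None = None
    vcov: np.ndarray = field(default=None, repr=False)
    notes: list[str] = field(default_factory=list, repr=False)
    _ctx: dict = field(default=None, repr=False)

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "term": self.terms, "beta": self.beta, "se": self.se,
            "stat": self.test_stat, "p": self.p_value,
            "ci_2.5": self.ci_low, "ci_97.5": self.ci_high,
        })
        return out


# ---------------------------------------------------------------------------
# Fitting


def fit_glmm(
    spec: ModelSpec,
    data: pd.DataFrame,
    fix_sd: dict[str, float] | None = None,
    fix_theta: float | None = None,
    scaling: dict[str, ScalingInfo] | None = None,
    satterthwaite: bool = True,
) -> FitResult:
    """Fit a random-intercept GLMM by Laplace-approximated ML.

    Parameters
    ----------
    spec
        Model description (response, family, terms, random structure).
    data
        Long- or per-female table containing every model variable.
    fix_sd
        Optional ``{batch name: sd}`` freezing a random-effect SD (``0``
        collapses the batch, reducing the model to a fixed-effects GLM —
        useful for oracle checks).
    fix_theta
        Freeze the NB size parameter instead of estimating it (e.g. a very
        large value to force the Poisson limit).
    scaling
        Reuse these standardization constants instead of computing them
        from ``data`` (bootstrap refits, resampling nulls, prediction).
    satterthwaite
        For Gaussian models, compute Satterthwaite degrees of freedom for
        the t-tests (otherwise, and whenever the computation fails,
        residual df are used and recorded).
    """
    if spec.response not in data.columns:
        raise ValueError(f"response {spec.response!r} not in data")
    if len(data) == 0:
        raise ValueError("empty data")
    y = np.asarray(data[spec.response], dtype=float)
    if np.isnan(y).any():
        raise ValueError("response contains missing values")
    family = get_family(spec.family)
    if family.name == "binomial" and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binomial response must be binary 0/1")
    if np.ptp(y) == 0.0:
        raise ValueError("degenerate response: no variation")
    if family.link == "log" and (y < 0).any():
        raise ValueError("count response must be non-negative")

    X, terms, infos = build_design(spec, data, scaling=scaling)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    grp = _Grouping(spec, data)

    # --- outer parameter vector: free RE sds, then log sigma / log theta
    fix_sd = dict(fix_sd or {})
    for nm in fix_sd:
        if nm not in grp.names:
            raise ValueError(f"fix_sd names unknown batch {nm!r}")
    free_sd_idx = [i for i, nm in enumerate(grp.names) if nm not in fix_sd]
    x0, lb, ub = [], [], []
    for i in free_sd_idx:
        x0.append(0.3)
        lb.append(0.0)
        ub.append(20.0)
    if family.has_sigma:
        x0.append(math.log(max(np.std(y), 1e-3)))
        lb.append(-12.0)
        ub.append(12.0)
    theta_free = family.has_theta and fix_theta is None
    if theta_free:
        mu0, v0 = float(np.mean(y)), float(np.var(y))
        theta0 = mu0 * mu0 / (v0 - mu0) if v0 > mu0 else 20.0
        x0.append(math.log(min(max(theta0, 0.2), 50.0)))
        lb.append(math.log(1e-3))
        ub.append(math.log(1e5))

    state: dict = {}

    def unpack(x):
        sds = []
        j = 0
        for i, nm in enumerate(grp.names):
            if nm in fix_sd:
                sds.append(float(fix_sd[nm]))
            else:
                sds.append(float(x[j]))
                j += 1
        aux = {}
        if family.has_sigma:
            aux["sigma"] = math.exp(float(x[j])); j += 1
        if theta_free:
            aux["theta"] = math.exp(float(x[j])); j += 1
        elif family.has_theta:
            aux["theta"] = float(fix_theta)
        return sds, aux

    def negll(x):
        sds, aux = unpack(x)
        res = _pirls(y, X, grp, sds, family, aux, state=state)
        if not res["ok"]:
            return 1e12
        return -res["loglik"]

    converged_outer = True
    if x0:
        x_start = np.array(x0, dtype=float)
        if theta_free:
            x_start = _seed_theta(negll, x_start)
        opt = _lbfgs(negll, x_start, list(zip(lb, ub)))
        if theta_free:
            # the NB->Poisson limit is a flat plateau in log(theta); if the
            # optimizer stalled on it, restart from the best grid point
            x_check = _seed_theta(negll, opt.x)
            if negll(x_check) < opt.fun - 1e-3:
                opt2 = _lbfgs(negll, x_check, list(zip(lb, ub)))
                if opt2.fun < opt.fun:
                    opt = opt2
        converged_outer = bool(opt.success)
        x_hat = opt.x
    else:
        x_hat = np.array([])
    sds, aux = unpack(x_hat)
    state.pop("beta", None)  # final polish from a cold start for determinism
    res = _pirls(y, X, grp, sds, family, aux)
    if not res["ok"]:
        raise RuntimeError("PIRLS failed at the optimum — model is degenerate")

    beta = res["beta"]
    cov = np.linalg.inv(res["cov_factor"])
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    variance_components = {nm: float(s * s) for nm, s in zip(grp.names, sds)}
    n_groups = {nm: int(q) for nm, q in zip(
        grp.names, (getattr(grp, "q1", None), getattr(grp, "q2", None))) if q}

    fit = FitResult(
        spec=spec, terms=terms, beta=beta, se=se,
        test_stat=np.full_like(beta, np.nan),
        p_value=np.full_like(beta, np.nan),
        ci_low=beta - 1.959963984540054 * se,
        ci_high=beta + 1.959963984540054 * se,
        ci_method="wald",
        variance_components=variance_components,
        nb_dispersion=aux.get("theta"),
        sigma=aux.get("sigma"),
        log_likelihood=float(res["loglik"]),
        converged=bool(converged_outer and res["converged"]),
        n_obs=len(y), n_groups=n_groups, scaling_info=infos,
        vcov=cov,
        _ctx={
            "X": X, "y": y, "grp": grp, "sds": sds, "aux": aux,
            "family": family, "fix_sd": fix_sd, "fix_theta": fix_theta,
            "x_hat": x_hat, "data_index": data.index, "negll": negll,
        },
    )
    if not fit.converged:
        fit.notes.append("outer or inner optimization did not fully converge")
    _fill_wald(fit, satterthwaite=satterthwaite)
    return fit


def fit_negative_binomial(spec: ModelSpec, data: pd.DataFrame, **kw) -> FitResult:
    """Convenience wrapper enforcing the NB family (theta estimated jointly)."""
    if spec.family != "negative_binomial":
        spec = replace(spec, family="negative_binomial")
    return fit_glmm(spec, data, **kw)


# ---------------------------------------------------------------------------
# Inference


def _fill_wald(fit: FitResult, satterthwaite: bool = True) -> None:
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(fit.se > 0, fit.beta / fit.se, np.nan)
    fit.test_stat = stat
    if (fit.se == 0).any():
        fit.notes.append("zero standard error: undefined Wald test for some term")
    if fit.spec.family == "gaussian":
        df = None
        if satterthwaite:
            df = _satterthwaite_df(fit)
        if df is None:
            df = np.full_like(fit.beta, max(fit.n_obs - len(fit.terms), 1))
            fit.df_method = "residual"
        else:
            fit.df_method = "satterthwaite"
        fit.df = df
        fit.p_value = 2.0 * stats.t.sf(np.abs(stat), df)
    else:
        fit.p_value = 2.0 * stats.norm.sf(np.abs(stat))
    # exact-zero coefficients give p = 1 by construction (sf(0) = 0.5)


def wald_tests(fit: FitResult) -> pd.DataFrame:
    """Per-term Wald statistic and p-value (z for GLMMs; t with
    Satterthwaite df for the Gaussian LMM, residual df as recorded
    fallback)."""
    out = pd.DataFrame({
        "term": fit.terms, "beta": fit.beta, "se": fit.se,
        "stat": fit.test_stat, "p": fit.p_value,
    })
    if fit.df is not None:
        out["df"] = fit.df
    return out


def _variance_of_beta_at(fit: FitResult, vpars: np.ndarray) -> np.ndarray:
    """Diag of Cov(beta) as a function of the variance parameters (free RE
    sds + sigma), for the Satterthwaite gradient. Gaussian only."""
    ctx = fit._ctx
    grp, family, fix_sd = ctx["grp"], ctx["family"], ctx["fix_sd"]
    free = [nm for nm in grp.names if nm not in fix_sd]
    sds = [vpars[free.index(nm)] if nm in free else fix_sd[nm] for nm in grp.names]
    aux = {"sigma": float(vpars[-1])}
    res = _pirls(ctx["y"], ctx["X"], grp, sds, family, aux)
    if not res["ok"]:
        raise FloatingPointError("PIRLS failure in Satterthwaite step")
    return np.diag(np.linalg.inv(res["cov_factor"]))


def _satterthwaite_df(fit: FitResult) -> np.ndarray | None:
    """Numeric Satterthwaite df: 2 Var(beta_j)^2 / Var(hat Var(beta_j)),
    with the variance-parameter covariance from the observed information of
    the Laplace (here exact) Gaussian log-likelihood."""
    ctx = fit._ctx
    grp, fix_sd = ctx["grp"], ctx["fix_sd"]
    free = [nm for nm in grp.names if nm not in fix_sd]
    v0 = np.array([math.sqrt(fit.variance_components[nm]) for nm in free]
                  + [fit.sigma])
    try:
        h = 1e-4 * (np.abs(v0) + 1e-2)
        k = len(v0)

        def nll(v):
            if (v[:-1] < 0).any() or v[-1] <= 0:
                raise FloatingPointError
            sds = [v[free.index(nm)] if nm in free else fix_sd[nm]
                   for nm in grp.names]
            res = _pirls(ctx["y"], ctx["X"], grp, sds, ctx["family"],
                         {"sigma": float(v[-1])})
            if not res["ok"]:
                raise FloatingPointError
            return -res["loglik"]

        H = np.zeros((k, k))
        f0 = nll(v0)
        for a in range(k):
            for b in range(a, k):
                ea, eb = np.eye(k)[a] * h[a], np.eye(k)[b] * h[b]
                if a == b:
                    H[a, a] = (nll(v0 + ea) - 2 * f0 + nll(v0 - ea)) / h[a] ** 2
                else:
                    H[a, b] = H[b, a] = (
                        nll(v0 + ea + eb) - nll(v0 + ea - eb)
                        - nll(v0 - ea + eb) + nll(v0 - ea - eb)
                    ) / (4 * h[a] * h[b])
        cov_v = np.linalg.inv(H)
        grad = np.zeros((len(fit.beta), k))
        for a in range(k):
            ea = np.eye(k)[a] * h[a]
            grad[:, a] = (
                _variance_of_beta_at(fit, v0 + ea)
                - _variance_of_beta_at(fit, v0 - ea)
            ) / (2 * h[a])
        var_beta = fit.se ** 2
        denom = np.einsum("ja,ab,jb->j", grad, cov_v, grad)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = 2.0 * var_beta ** 2 / denom
        resid_df = max(fit.n_obs - len(fit.terms), 1)
        df = np.where(np.isfinite(df) & (df > 0), np.minimum(df, 1e6), resid_df)
        return df
    except (FloatingPointError, np.linalg.LinAlgError):
        return None


def variance_param_ci(fit: FitResult, level: float = 0.95) -> dict[str, tuple[float, float]]:
    """Wald CIs for the non-beta parameters (random-effect variances, NB
    theta, Gaussian sigma) from the numeric observed information of the
    Laplace log-likelihood over the outer parameter vector.

    SD-scale parameters get symmetric Wald intervals truncated at zero and
    are returned on the *variance* scale; log-scale parameters (theta,
    sigma) get intervals symmetric on the log scale. Boundary fits
    (variance 0) return a degenerate ``(0, inf)`` upper-bound-free
    interval for that component.
    """
    ctx = fit._ctx
    grp, fix_sd, family = ctx["grp"], ctx["fix_sd"], ctx["family"]
    x_hat = np.asarray(ctx["x_hat"], dtype=float)
    names = [nm for nm in grp.names if nm not in fix_sd]
    kinds = ["sd"] * len(names)
    if family.has_sigma:
        names.append("sigma"); kinds.append("log")
    if family.has_theta and ctx.get("fix_theta") is None:
        names.append("theta"); kinds.append("log")
    if len(x_hat) == 0:
        return {}
    negll = ctx["negll"]
    k = len(x_hat)
    h = 1e-3 * (np.abs(x_hat) + 0.1)
    H = np.zeros((k, k))
    f0 = negll(x_hat)
    for a in range(k):
        ea = np.eye(k)[a] * h[a]
        H[a, a] = (negll(x_hat + ea) - 2 * f0 + negll(x_hat - ea)) / h[a] ** 2
        for b in range(a + 1, k):
            eb = np.eye(k)[b] * h[b]
            H[a, b] = H[b, a] = (
                negll(x_hat + ea + eb) - negll(x_hat + ea - eb)
                - negll(x_hat - ea + eb) + negll(x_hat - ea - eb)
            ) / (4 * h[a] * h[b])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(k, np.inf)
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    out: dict[str, tuple[float, float]] = {}
    for j, (nm, kind) in enumerate(zip(names, kinds)):
        if kind == "sd":
            if x_hat[j] <= 1e-8 or not np.isfinite(se[j]) or se[j] == 0:
                out[nm] = (0.0, math.inf)
            else:
                lo = max(x_hat[j] - zcrit * se[j], 0.0)
                hi = x_hat[j] + zcrit * se[j]
                out[nm] = (lo * lo, hi * hi)
        else:
            out[nm] = (math.exp(x_hat[j] - zcrit * se[j]),
                       math.exp(x_hat[j] + zcrit * se[j]))
    return out


def backward_select(
    spec: ModelSpec,
    data: pd.DataFrame,
    alpha: float = 0.05,
    fit_fn=fit_glmm,
    **fit_kw,
) -> tuple[ModelSpec, FitResult, list[dict]]:
    """Backward elimination at threshold ``alpha``, respecting marginality.

    At each step the removable term (quadratics and interactions before
    the main effects they contain) with the largest p-value >= ``alpha``
    is dropped and the model refitted; the trace records every step.
    """
    trace: list[dict] = []
    current = spec
    fit = fit_fn(current, data, **fit_kw)
    while True:
        removable = current.removable_terms()
        pvals = {t: float(fit.p_value[fit.terms.index(t)]) for t in removable}
        candidates = {t: p for t, p in pvals.items() if not (p < alpha)}
        if not candidates:
            break
        drop = max(candidates, key=candidates.get)
        trace.append({"dropped": drop, "p": candidates[drop],
                      "loglik_before": fit.log_likelihood})
        current = current.without(drop)
        fit = fit_fn(current, data, **fit_kw)
    return current, fit, trace


def bootstrap_ci(
    fit: FitResult,
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Parametric-bootstrap percentile CIs for the fixed effects.

    Responses are simulated from the fitted model — fresh spherical random
    intercepts included — and the model refitted to each replicate; the
    2.5/97.5 percentiles of each coefficient form the interval. The fit's
    ``ci_low``/``ci_high`` are updated in place. A warning note is recorded
    when more than 10% of replicates fail to converge.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    if seed is None:
        raise ValueError("bootstrap requires an explicit seed")
    ctx = fit._ctx
    X, grp, family, aux, sds = ctx["X"], ctx["grp"], ctx["family"], ctx["aux"], ctx["sds"]
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, len(fit.beta)))
    n_bad = 0
    for b in range(n_boot):
        eta = X @ fit.beta
        if grp.n_batches >= 1:
            eta = eta + sds[0] * rng.standard_normal(grp.q1)[grp.g1]
        if grp.n_batches == 2:
            eta = eta + sds[1] * rng.standard_normal(grp.q2)[grp.g2]
        ystar = family.simulate(rng, eta, aux).astype(float)
        try:
            if np.ptp(ystar) == 0.0:
                raise ValueError("degenerate bootstrap response")
            res = _refit_same_design(fit, ystar)
            if not res["converged"]:
                raise ValueError("non-convergence")
            draws[b] = res["beta"]
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            draws[b] = np.nan
            n_bad += 1
    good = draws[~np.isnan(draws).any(axis=1)]
    if len(good) == 0:
        raise RuntimeError("all bootstrap replicates failed")
    if n_bad > 0.10 * n_boot:
        fit.notes.append(f"bootstrap: {n_bad}/{n_boot} replicates failed")
        warnings.warn(f"bootstrap: {n_bad}/{n_boot} replicates failed",
                      stacklevel=2)
    a = (1.0 - level) / 2.0
    lo = np.percentile(good, 100 * a, axis=0)
    hi = np.percentile(good, 100 * (1 - a), axis=0)
    fit.ci_low, fit.ci_high, fit.ci_method = lo, hi, "parametric_bootstrap"
    return pd.DataFrame({"term": fit.terms, "ci_2.5": lo, "ci_97.5": hi})


def _refit_same_design(fit: FitResult, ystar: np.ndarray) -> dict:
    """Refit the model to a new response on the identical design (same
    scaling), warm-started at the original variance parameters."""
    ctx = fit._ctx
    grp, family, fix_sd = ctx["grp"], ctx["family"], ctx["fix_sd"]
    fix_theta = ctx.get("fix_theta")
    theta_free = family.has_theta and fix_theta is None
    X = ctx["X"]
    free_names = [nm for nm in grp.names if nm not in fix_sd]
    x0 = list(ctx["x_hat"])
    state: dict = {}

    def unpack(x):
        sds, j = [], 0
        for nm in grp.names:
            if nm in fix_sd:
                sds.append(float(fix_sd[nm]))
            else:
                sds.append(float(x[j])); j += 1
        aux = {}
        if family.has_sigma:
            aux["sigma"] = math.exp(float(x[j])); j += 1
        if theta_free:
            aux["theta"] = math.exp(float(x[j])); j += 1
        elif family.has_theta:
            aux["theta"] = float(fix_theta)
        return sds, aux

    def negll(x):
        sds, aux = unpack(x)
        res = _pirls(ystar, X, grp, sds, family, aux, state=state)
        if not res["ok"]:
            return 1e12
        return -res["loglik"]

    if x0:
        lb = [0.0] * len(free_names) + [-12.0] * family.has_sigma \
            + [math.log(1e-3)] * theta_free
        ub = [20.0] * len(free_names) + [12.0] * family.has_sigma \
            + [math.log(1e5)] * theta_free
        opt = _lbfgs(negll, np.array(x0), list(zip(lb, ub)),
                     ftol=1e-8, maxiter=200)
        if theta_free:
            x_check = _seed_theta(negll, opt.x)
            if negll(x_check) < opt.fun - 1e-3:
                opt2 = _lbfgs(negll, x_check, list(zip(lb, ub)),
                              ftol=1e-8, maxiter=200)
                if opt2.fun < opt.fun:
                    opt = opt2
        sds, aux = unpack(opt.x)
        outer_ok = bool(opt.success)
    else:
        sds, aux = unpack(np.array([]))
        outer_ok = True
    res = _pirls(ystar, X, grp, sds, family, aux)
    if not res["ok"]:
        raise RuntimeError("refit PIRLS failure")
    return {"beta": res["beta"], "converged": outer_ok and res["converged"],
            "loglik": res["loglik"], "sds": sds, "aux": aux,
            "cov_factor": res["cov_factor"]}


# ---------------------------------------------------------------------------
# Prediction and the quadratic optimum


def predict_curve(
    fit: FitResult,
    term: str,
    grid: np.ndarray,
    at: dict[str, float] | None = None,
    natural_grid: bool = False,
) -> pd.DataFrame:
    """Predicted response along ``term`` with delta-method standard errors.

    ``grid`` is in scaled units unless ``natural_grid`` is set (then it is
    converted with the fit's scaling constants). Covariates in ``at`` are
    given in natural units; scaled covariates not mentioned sit at their
    mean (scaled 0) and unscaled ones at 0.
    """
    at = dict(at or {})
    base_vars = sorted({v for t in fit.spec.fixed_terms for v in term_base_vars(t)})
    unknown = set(at) - set(base_vars)
    if unknown:
        raise ValueError(f"unknown covariates: {sorted(unknown)}")
    if term not in base_vars:
        raise ValueError(f"{term!r} is not a model variable")
    grid = np.asarray(grid, dtype=float)
    vals: dict[str, np.ndarray] = {}
    for v in base_vars:
        if v == term:
            x = grid.copy()
            if natural_grid:
                info = fit.scaling_info.get(v)
                x = (x - info.mean) / info.sd if info else x
        else:
            raw = float(at.get(v, np.nan))
            if v in fit.scaling_info:
                info = fit.scaling_info[v]
                x = np.full_like(grid, (raw - info.mean) / info.sd
                                 if not math.isnan(raw) else 0.0)
            else:
                x = np.full_like(grid, 0.0 if math.isnan(raw) else raw)
        vals[v] = x
    cols = [np.ones_like(grid)]
    for t in fit.spec.fixed_terms:
        kind, bases = parse_term(t)
        if kind == "lin":
            cols.append(vals[bases[0]])
        elif kind == "quad":
            cols.append(vals[bases[0]] ** 2)
        else:
            cols.append(vals[bases[0]] * vals[bases[1]])
    Xg = np.column_stack(cols)
    eta = Xg @ fit.beta
    se_eta = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, fit.vcov, Xg), 0.0))
    family = get_family(fit.spec.family)
    mu = family.mean(eta)
    if family.link == "log":
        dmu = mu
    elif family.link == "logit":
        dmu = mu * (1 - mu)
    else:
        dmu = np.ones_like(mu)
    return pd.DataFrame({
        term: grid, "eta": eta, "se_eta": se_eta,
        "response": mu, "se_response": np.abs(dmu) * se_eta,
    })


@dataclass(frozen=True)
class VertexResult:
    """Interior optimum of a quadratic term; ``has_maximum`` is False when
    the quadratic coefficient is non-negative (no interior maximum)."""

    term: str
    has_maximum: bool
    scaled_vertex: float
    natural_vertex: float


def vertex_in_natural_units(fit: FitResult, term: str) -> VertexResult:
    """Peak of the fitted parabola ``b1*x + b2*x^2`` on the predictor's
    natural scale: ``x* = -b1/(2 b2)`` (scaled), then unscaled."""
    quad = f"{term}^2"
    if term not in fit.terms or quad not in fit.terms:
        raise ValueError(f"fit lacks {term!r} and/or {quad!r}")
    b1, b2 = fit.coef(term), fit.coef(quad)
    if b2 >= 0:
        return VertexResult(term, False, math.nan, math.nan)
    xs = -b1 / (2.0 * b2)
    info = fit.scaling_info.get(term)
    xn = float(info.unscale(xs)) if info else xs
    return VertexResult(term, True, float(xs), xn)
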