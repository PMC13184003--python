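"""Univariate and bivariate liability ACE models fitted by weighted least squares.

The observed moments are latent (tetrachoric) correlations per sibling
kinship group g with additive-genetic sharing alpha_g and common-
environment sharing gamma_g:

    same-trait:          r_g(t)  = alpha_g * a_t^2 + gamma_g * c_t^2
    cross-person/trait:  rx_g    = alpha_g * a1 a2 rA + gamma_g * c1 c2 rC
    within-person:       r_ph    = a1 a2 rA + c1 c2 rC + e1 e2 rE

with e_t = sqrt(1 - a_t^2 - c_t^2) enforcing unit liability variance.
The univariate model is linear in (a^2, c^2) and solved in closed form,
unconstrained.  The bivariate correlated-factors model is minimized over
theta = (a1, c1, a2, c2, rA, rC, rE) with non-negative loadings and
factor correlations in [-1, 1], by multi-start SLSQP; parameter
covariance comes from the WLS sandwich, and derived quantities (r_ph,
bivA/bivC/bivE) get delta-method Wald intervals that are deliberately
not truncated to the parameter space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .params import Kinship, KinshipCoefficients, KINSHIP_COEFFICIENTS

__all__ = [
    "AceUnivariateFit",
    "AceBivariateFit",
    "expected_pair_correlation",
    "expected_cross_trait_correlation",
    "implied_moments",
    "fit_univariate_ace",
    "fit_bivariate_ace",
    "decompose_phenotypic_correlation",
    "screen_phenotypes",
    "ScreeningDecision",
]

Z95 = 1.96
SIB_GROUPS = (Kinship.FULL_SIB, Kinship.MATERNAL_HALF_SIB, Kinship.PATERNAL_HALF_SIB)


def expected_pair_correlation(a2: float, c2: float, coeffs: KinshipCoefficients) -> float:
    """Model-implied same-trait sibling correlation alpha*a2 + gamma*c2."""
    return coeffs.alpha * a2 + coeffs.gamma * c2


def expected_cross_trait_correlation(params, coeffs: KinshipCoefficients | None = None) -> float:
    """Cross-trait correlation: within-person when ``coeffs`` is None,
    else the cross-person version alpha*a1*a2*rA + gamma*c1*c2*rC."""
    t1, t2 = params.trait1, params.trait2
    if coeffs is None:
        return params.r_ph
    return (
        coeffs.alpha * t1.a * t2.a * params.rA
        + coeffs.gamma * t1.c * t2.c * params.rC
    )


# ---------------------------------------------------------------- univariate


@dataclass
class AceUnivariateFit:
    a2: float
    c2: float
    e2: float
    se: pd.Series  # a2, c2, e2
    ci: pd.DataFrame  # rows a2/c2/e2, cols low/high
    objective: float
    groups: list
    correlations: np.ndarray


def fit_univariate_ace(
    correlations: dict, variances: dict | None = None
) -> AceUnivariateFit:
    """Unconstrained WLS fit of (a2, c2) to same-trait sibling correlations.

    ``correlations`` maps Kinship (or its value) to the observed latent
    correlation; ``variances`` to asymptotic variances (defaults to equal
    weights).  e2 = 1 - a2 - c2 by construction; estimates may be
    negative, as in the classic unconstrained variance-component fit.
    """
    groups = list(correlations)
    if len(groups) < 2:
        raise ValueError("need at least 2 kinship groups")
    co = [KINSHIP_COEFFICIENTS[Kinship(g)] for g in groups]
    X = np.array([[c.alpha, c.gamma] for c in co])
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError("kinship groups do not identify a2 and c2 (identical alpha, gamma)")
    r = np.array([correlations[g] for g in groups], dtype=float)
    if variances is None:
        v = np.ones(len(groups))
    else:
        v = np.array([variances[g] for g in groups], dtype=float)
    W = np.diag(1.0 / v)

    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ W @ r)
    resid = r - X @ beta
    objective = float(resid @ W @ resid)

    # WLS sandwich with Sigma = diag(v): (X'WX)^-1 X'W Sigma W X (X'WX)^-1
    bread = np.linalg.inv(xtwx)
    meat = X.T @ W @ np.diag(v) @ W @ X
    cov = bread @ meat @ bread
    grad_e2 = np.array([-1.0, -1.0])
    var_e2 = float(grad_e2 @ cov @ grad_e2)
    a2, c2 = float(beta[0]), float(beta[1])
    e2 = 1.0 - a2 - c2
    se = pd.Series(
        [np.sqrt(cov[0, 0]), np.sqrt(cov[1, 1]), np.sqrt(var_e2)],
        index=["a2", "c2", "e2"],
    )
    est = pd.Series([a2, c2, e2], index=["a2", "c2", "e2"])
    ci = pd.DataFrame(
        {"low": est - Z95 * se, "high": est + Z95 * se}, index=est.index
    )
    return AceUnivariateFit(a2, c2, e2, se, ci, objective, groups, r)


# ----------------------------------------------------------------- bivariate

_PARAM_NAMES = ["a1", "c1", "a2", "c2", "rA", "rC", "rE"]
_DERIVED = ["r_ph", "bivA", "bivC", "bivE", "h2_1", "c2_1", "h2_2", "c2_2"]


@dataclass
class AceBivariateFit:
    """Bivariate correlated-factors fit over sibling-group latent correlations."""

    params: pd.Series  # a1, c1, a2, c2, rA, rC, rE (rC NaN when fixed_c)
    se: pd.Series
    ci: pd.DataFrame
    derived: pd.Series  # r_ph, bivA/bivC/bivE, per-trait variance shares
    derived_se: pd.Series
    derived_ci: pd.DataFrame
    objective: float
    fixed_c: bool
    converged: bool
    n_starts: int
    multistart_objectives: list
    ci_available: bool = True

    @property
    def r_ph(self) -> float:
        return float(self.derived["r_ph"])

    @property
    def rA(self) -> float:
        return float(self.params["rA"])


def _free_names(fix_c: bool) -> list:
    return ["a1", "a2", "rA", "rE"] if fix_c else _PARAM_NAMES


def _theta_to_full(theta: np.ndarray, fix_c: bool) -> np.ndarray:
    """Map the free vector to (a1, c1, a2, c2, rA, rC, rE)."""
    if not fix_c:
        return np.asarray(theta, dtype=float)
    a1, a2, rA, rE = theta
    return np.array([a1, 0.0, a2, 0.0, rA, 0.0, rE])


def implied_moments(full: np.ndarray, groups=SIB_GROUPS) -> np.ndarray:
    """Model-implied moment vector ordered (same1_g, same2_g, cross_g, within_g)."""
    a1, c1, a2, c2, rA, rC, rE = full
    e1 = np.sqrt(max(1.0 - a1 * a1 - c1 * c1, 0.0))
    e2 = np.sqrt(max(1.0 - a2 * a2 - c2 * c2, 0.0))
    r_ph = a1 * a2 * rA + c1 * c2 * rC + e1 * e2 * rE
    out = []
    for g in groups:
        co = KINSHIP_COEFFICIENTS[g]
        out.append(co.alpha * a1 * a1 + co.gamma * c1 * c1)
    for g in groups:
        co = KINSHIP_COEFFICIENTS[g]
        out.append(co.alpha * a2 * a2 + co.gamma * c2 * c2)
    for g in groups:
        co = KINSHIP_COEFFICIENTS[g]
        out.append(co.alpha * a1 * a2 * rA + co.gamma * c1 * c2 * rC)
    out.extend([r_ph] * len(groups))
    return np.array(out)


def _multistart_grid(fix_c: bool) -> list:
    """8 deterministic starts: rA sign x loading magnitude x rE magnitude."""
    starts = []
    for sa, load, re_ in itertools.product((0.5, -0.5), (0.3, 0.65), (0.1, 0.4)):
        if fix_c:
            starts.append(np.array([load, load, sa, re_]))
        else:
            starts.append(np.array([load, 0.25, load, 0.25, sa, sa / 2, re_]))
    return starts


def fit_bivariate_ace(
    moments: np.ndarray,
    moment_variances: np.ndarray | None = None,
    fix_c: bool = False,
    groups=SIB_GROUPS,
    auto_fix_c: bool = True,
    moment_covariance: np.ndarray | None = None,
) -> AceBivariateFit:
    """WLS fit of the bivariate correlated-factors ACE model.

    ``moments`` is the observed latent-correlation vector ordered as
    ``implied_moments``: same-trait-1 per group, same-trait-2 per group,
    cross-person cross-trait per group, within-person per group.
    Diagonal inverse-variance weights; 8 deterministic multi-starts of
    SLSQP under the constraints a_t, c_t >= 0, a_t^2 + c_t^2 <= 1 and
    factor correlations in [-1, 1].  When the free fit fails to converge
    and ``auto_fix_c`` holds with non-positive implied c2 estimates, the
    model is automatically re-fitted with the C paths fixed to zero.

    ``moment_covariance`` optionally supplies the full covariance of the
    moment vector (moments within a kinship group are estimated from the
    same pairs and co-vary); it enters only the sandwich covariance of
    the parameter estimates, not the fitting weights.
    """
    r = np.asarray(moments, dtype=float)
    n_mom = 4 * len(groups)
    if r.shape != (n_mom,):
        raise ValueError(f"expected {n_mom} moments, got {r.shape}")
    if moment_variances is None:
        v = np.ones(n_mom)
    else:
        v = np.asarray(moment_variances, dtype=float)
        if np.any(~np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("moment variances must be finite and positive")
    w = 1.0 / v

    names = _free_names(fix_c)
    k = len(names)

    def objective(theta):
        full = _theta_to_full(theta, fix_c)
        d = r - implied_moments(full, groups)
        return float(d @ (w * d))

    if fix_c:
        bounds = [(0.0, 1.0), (0.0, 1.0), (-1.0, 1.0), (-1.0, 1.0)]
        constraints = []
    else:
        bounds = [(0.0, 1.0)] * 4 + [(-1.0, 1.0)] * 3
        constraints = [
            {"type": "ineq", "fun": lambda t: 1.0 - t[0] ** 2 - t[1] ** 2},
            {"type": "ineq", "fun": lambda t: 1.0 - t[2] ** 2 - t[3] ** 2},
        ]

    best = None
    objs = []
    for x0 in _multistart_grid(fix_c):
        res = minimize(
            objective,
            x0,
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"maxiter": 500, "ftol": 1e-16},
        )
        objs.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success) and np.isfinite(best.fun)

    # polish with a bounded least-squares pass when the unit-variance
    # constraint is inactive (tightens zero-residual recovery)
    theta = np.asarray(best.x, dtype=float)
    theta = _polish(objective, theta, bounds, constraints)
    theta = _ls_polish(theta, fix_c, r, w, groups, bounds, objective)
    obj = objective(theta)

    if not converged and auto_fix_c and not fix_c:
        # mirror the study's fallback: if free optimization fails and the
        # univariate C components are ~0, drop the C paths
        uni_c_nonpos = theta[1] < 0.02 and theta[3] < 0.02
        if uni_c_nonpos:
            return fit_bivariate_ace(
                r, v, fix_c=True, groups=groups, auto_fix_c=False,
                moment_covariance=moment_covariance,
            )

    Sigma = np.diag(v) if moment_covariance is None else np.asarray(moment_covariance, float)
    full = _theta_to_full(theta, fix_c)
    se, ci, derived, dse, dci, ci_ok = _wald_machinery(full, theta, fix_c, r, Sigma, w, groups)
    params = pd.Series(full, index=_PARAM_NAMES)
    if fix_c:
        params[["c1", "c2", "rC"]] = np.nan
    return AceBivariateFit(
        params=params,
        se=se,
        ci=ci,
        derived=derived,
        derived_se=dse,
        derived_ci=dci,
        objective=obj,
        fixed_c=fix_c,
        converged=converged,
        n_starts=len(objs),
        multistart_objectives=objs,
        ci_available=ci_ok,
    )


def _ls_polish(theta, fix_c, r, w, groups, bounds, objective):
    from scipy.optimize import least_squares

    if not fix_c:
        slack1 = 1.0 - theta[0] ** 2 - theta[1] ** 2
        slack2 = 1.0 - theta[2] ** 2 - theta[3] ** 2
        if min(slack1, slack2) < 1e-6:
            return theta  # constraint active; keep the SLSQP solution
    sw = np.sqrt(w)

    def resid(t):
        return sw * (r - implied_moments(_theta_to_full(t, fix_c), groups))

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    res = least_squares(
        resid, np.clip(theta, lo, hi), bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15
    )
    return res.x if objective(res.x) <= objective(theta) else theta


def _polish(objective, theta, bounds, constraints, eps: float = 1e-9):
    res = minimize(
        objective,
        theta,
        method="SLSQP",
        bounds=bounds,
        constraints=constraints,
        options={"maxiter": 500, "ftol": 1e-18},
    )
    return np.asarray(res.x) if res.fun <= objective(theta) else theta


def _derived_quantities(full: np.ndarray) -> pd.Series:
    a1, c1, a2, c2, rA, rC, rE = full
    e1 = np.sqrt(max(1.0 - a1 * a1 - c1 * c1, 0.0))
    e2 = np.sqrt(max(1.0 - a2 * a2 - c2 * c2, 0.0))
    contribs = np.array([a1 * a2 * rA, c1 * c2 * rC, e1 * e2 * rE])
    r_ph = contribs.sum()
    if r_ph != 0.0:
        biv = contribs / r_ph
    else:
        biv = np.full(3, np.nan)
    return pd.Series(
        [r_ph, *biv, a1 * a1, c1 * c1, a2 * a2, c2 * c2], index=_DERIVED
    )


def _wald_machinery(full, theta, fix_c, r, Sigma, w, groups):
    """WLS sandwich parameter covariance + delta-method CIs for derived values."""
    names = _free_names(fix_c)
    k = len(theta)
    h = 1e-6

    def moments_of(t):
        return implied_moments(_theta_to_full(t, fix_c), groups)

    J = np.empty((len(r), k))
    for j in range(k):
        e = np.zeros(k)
        e[j] = h
        J[:, j] = (moments_of(theta + e) - moments_of(theta - e)) / (2 * h)

    W = np.diag(w)
    ok = True
    try:
        jtwj = J.T @ W @ J
        bread = np.linalg.inv(jtwj)
        cov = bread @ (J.T @ W @ Sigma @ W @ J) @ bread
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        ok = False

    se_free = pd.Series(np.sqrt(np.clip(np.diag(cov), 0, None)), index=names)
    se = pd.Series(np.nan, index=_PARAM_NAMES)
    se[names if not fix_c else ["a1", "a2", "rA", "rE"]] = se_free.to_numpy()
    params = pd.Series(full, index=_PARAM_NAMES)
    ci = pd.DataFrame(
        {"low": params - Z95 * se, "high": params + Z95 * se}, index=_PARAM_NAMES
    )

    derived = _derived_quantities(full)

    def derived_of(t):
        return _derived_quantities(_theta_to_full(t, fix_c)).to_numpy()

    G = np.empty((len(_DERIVED), k))
    for j in range(k):
        e = np.zeros(k)
        e[j] = h
        G[:, j] = (derived_of(theta + e) - derived_of(theta - e)) / (2 * h)
    if ok:
        dvar = np.einsum("ij,jk,ik->i", G, cov, G)
        dse = pd.Series(np.sqrt(np.clip(dvar, 0, None)), index=_DERIVED)
    else:
        dse = pd.Series(np.nan, index=_DERIVED)
    dci = pd.DataFrame(
        {"low": derived - Z95 * dse, "high": derived + Z95 * dse}, index=_DERIVED
    )
    return se, ci, derived, dse, dci, ok


def decompose_phenotypic_correlation(fit: AceBivariateFit) -> tuple:
    """(bivA, bivC, bivE): shares of r_ph through the A, C and E paths.

    Shares sum to 1 and may individually be negative (a path working
    against the net correlation).  Undefined when r_ph = 0.
    """
    if fit.r_ph == 0.0 or not np.isfinite(fit.r_ph):
        raise ValueError("phenotypic correlation is zero; proportions undefined")
    biv = fit.derived[["bivA", "bivC", "bivE"]].to_numpy(dtype=float)
    biv = np.where(np.isnan(biv), 0.0, biv)
    return tuple(float(x) for x in biv)


# ----------------------------------------------------------------- screening


@dataclass
class ScreeningDecision:
    include: bool
    reasons: list = field(default_factory=list)


def screen_phenotypes(
    within_person_tetrachoric: float,
    n_concordant: int,
    n_discordant: int,
    min_correlation: float = 0.1,
    min_pairs: int = 5,
) -> ScreeningDecision:
    """Inclusion rule for the bivariate models.

    Include iff the within-person tetrachoric correlation with the
    exposure trait is >= 0.1 and there are >= 5 concordant and >= 5
    discordant sibling pairs (boundaries inclusive).
    """
    reasons = []
    if not within_person_tetrachoric >= min_correlation:
        reasons.append("correlation")
    if n_concordant < min_pairs or n_discordant < min_pairs:
        reasons.append("sparsity")
    return ScreeningDecision(include=not reasons, reasons=reasons)
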