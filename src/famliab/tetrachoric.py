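"""Thresholds and tetrachoric correlations for binary liability traits.

Estimation is two-step: per-trait thresholds come from a marginal probit
model (person-specific threshold = minus the linear predictor, so the
binary-data likelihood stays exact under covariate adjustment), then the
latent correlation is profiled by maximum likelihood over bivariate-
normal rectangle probabilities.  Asymptotic variances use the observed
information, with a jackknife-over-pairs fallback when the information
is degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .bvn import bvn_quadrant_probability

__all__ = [
    "TetrachoricEstimate",
    "ThresholdModel",
    "estimate_thresholds",
    "tetrachoric_from_table",
    "tetrachoric_from_pairs",
    "PairCorrelationStructure",
    "pair_polychoric_structure",
]

_BOUND = 1.0 - 1e-6
_EPS_CELL = 1e-12


@dataclass
class TetrachoricEstimate:
    """Latent correlation of a binary pair with thresholds and asymptotic SE."""

    rho: float
    tau1: float
    tau2: float
    se: float
    n: int
    boundary: bool = False

    def implied_cells(self) -> np.ndarray:
        """2x2 cell probabilities [[p11, p10], [p01, p00]] implied by the fit."""
        p11 = bvn_quadrant_probability(self.tau1, self.tau2, self.rho)
        p1 = norm.sf(self.tau1)
        p2 = norm.sf(self.tau2)
        return np.array([[p11, p1 - p11], [p2 - p11, 1.0 - p1 - p2 + p11]])


@dataclass
class ThresholdModel:
    """Probit threshold model: person threshold = -(x' beta)."""

    params: pd.Series
    cov: np.ndarray
    column_names: list

    @property
    def intercept_threshold(self) -> float:
        """Threshold at covariates = 0 (with no covariates: Phi^-1(1 - prevalence))."""
        return -float(self.params.iloc[0])

    def thresholds(self, X) -> np.ndarray:
        return -(np.asarray(X, dtype=float) @ self.params.to_numpy())


def estimate_thresholds(y, X=None) -> ThresholdModel:
    """Probit regression of a binary outcome; thresholds are -linear predictor.

    With ``X`` = None an intercept-only model is fitted, giving the single
    threshold Phi^-1(1 - prevalence).
    """
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome is degenerate (all 0 or all 1)")
    if X is None:
        X = pd.DataFrame({"const": np.ones(len(y))})
    res = sm.GLM(y, np.asarray(X, float), family=sm.families.Binomial(sm.families.links.Probit())).fit(
        maxiter=200, tol=1e-10
    )
    cols = list(X.columns) if hasattr(X, "columns") else [f"x{i}" for i in range(np.shape(X)[1])]
    return ThresholdModel(
        params=pd.Series(np.asarray(res.params), index=cols),
        cov=np.asarray(res.cov_params()),
        column_names=cols,
    )


def _cells_from_counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table [[n11, n10], [n01, n00]]")
    if (c < 0).any():
        raise ValueError("negative cell counts")
    if c.sum() < 1:
        raise ValueError("empty table")
    return c


def _table_loglik(counts: np.ndarray, tau1: float, tau2: float, rho: float) -> float:
    p11 = bvn_quadrant_probability(tau1, tau2, rho)
    p1 = norm.sf(tau1)
    p2 = norm.sf(tau2)
    p = np.array([p11, p1 - p11, p2 - p11, 1.0 - p1 - p2 + p11])
    p = np.clip(p, _EPS_CELL, 1.0)
    n = counts.ravel()
    return float(n @ np.log(p))


def tetrachoric_from_table(
    counts, thresholds: tuple | None = None
) -> TetrachoricEstimate:
    """ML tetrachoric correlation from a 2x2 table [[n11, n10], [n01, n00]].

    Rows index the first trait (affected first), columns the second.
    Thresholds are profiled from the margins unless given.  The SE comes
    from the observed information — the full 3-parameter information when
    thresholds are free, so threshold uncertainty propagates.
    """
    c = _cells_from_counts(counts)
    n = c.sum()
    p1 = (c[0, 0] + c[0, 1]) / n
    p2 = (c[0, 0] + c[1, 0]) / n
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        raise ValueError("empty margin: tetrachoric correlation undefined")
    free = thresholds is None
    if free:
        tau1 = float(norm.isf(p1))
        tau2 = float(norm.isf(p2))
    else:
        tau1, tau2 = float(thresholds[0]), float(thresholds[1])

    if c[0, 1] == 0 and c[1, 0] == 0:
        return TetrachoricEstimate(1.0, tau1, tau2, np.nan, int(n), boundary=True)
    if c[0, 0] == 0 and c[1, 1] == 0:
        return TetrachoricEstimate(-1.0, tau1, tau2, np.nan, int(n), boundary=True)

    def nll(r):
        return -_table_loglik(c, tau1, tau2, r)

    res = minimize_scalar(nll, bounds=(-_BOUND, _BOUND), method="bounded",
                          options={"xatol": 1e-12})
    rho = float(res.x)
    boundary = abs(rho) >= _BOUND

    se = _se_from_information(c, tau1, tau2, rho, free)
    return TetrachoricEstimate(rho, tau1, tau2, se, int(n), boundary=boundary)


def _se_from_information(c, tau1, tau2, rho, free_thresholds: bool) -> float:
    h = 1e-5

    def ll(r, t1, t2):
        return _table_loglik(c, t1, t2, r)

    if not free_thresholds:
        d2 = (ll(rho + h, tau1, tau2) - 2 * ll(rho, tau1, tau2) + ll(rho - h, tau1, tau2)) / h**2
        info = -d2
        return float(1.0 / np.sqrt(info)) if info > 0 else np.nan

    theta = np.array([rho, tau1, tau2])

    def llv(t):
        return ll(t[0], t[1], t[2])

    H = np.zeros((3, 3))
    for i in range(3):
        for j in range(i, 3):
            ei = np.eye(3)[i] * h
            ej = np.eye(3)[j] * h
            H[i, j] = H[j, i] = (
                llv(theta + ei + ej) - llv(theta + ei - ej) - llv(theta - ei + ej) + llv(theta - ei - ej)
            ) / (4 * h * h)
    info = -H
    try:
        cov = np.linalg.inv(info)
        var = cov[0, 0]
    except np.linalg.LinAlgError:
        var = np.nan
    return float(np.sqrt(var)) if var > 0 else np.nan


def tetrachoric_from_pairs(
    y1,
    y2,
    tau1,
    tau2,
    cluster_ids=None,
    return_influence: bool = False,
    _jackknife_fallback: bool = True,
):
    """ML latent correlation for paired binaries with person-specific thresholds.

    ``tau1``/``tau2`` are per-observation thresholds (from a covariate-
    adjusted probit model), held fixed while rho is profiled.  When rows
    are not independent (e.g. both orientations of double-entered pairs
    stacked), pass ``cluster_ids``: the SE then uses the robust sandwich
    with per-row scores summed within clusters.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    t1 = np.broadcast_to(np.asarray(tau1, dtype=float), y1.shape).copy()
    t2 = np.broadcast_to(np.asarray(tau2, dtype=float), y2.shape).copy()
    n = len(y1)
    if n == 0:
        raise ValueError("no pairs")
    n_eff = n if cluster_ids is None else len(np.unique(cluster_ids))

    s1 = 2.0 * y1 - 1.0  # +1 if affected: P uses upper quadrant of (s*x > s*tau)
    s2 = 2.0 * y2 - 1.0
    const_thresholds = np.ptp(t1) == 0.0 and np.ptp(t2) == 0.0

    def row_probs(rho):
        """Per-row probability of the observed cell."""
        p = np.empty(n)
        if const_thresholds:
            # only 4 distinct cells: evaluate each quadrant once
            for sa in (-1.0, 1.0):
                for sb in (-1.0, 1.0):
                    m = (s1 == sa) & (s2 == sb)
                    if m.any():
                        p[m] = bvn_quadrant_probability(
                            float(sa * t1[0]), float(sb * t2[0]), float(sa * sb * rho)
                        )
        else:
            for sa in (-1.0, 1.0):
                for sb in (-1.0, 1.0):
                    m = (s1 == sa) & (s2 == sb)
                    if m.any():
                        p[m] = bvn_quadrant_probability(
                            sa * t1[m], sb * t2[m], float(sa * sb * rho)
                        )
        return np.clip(p, _EPS_CELL, 1.0)

    def loglik(rho):
        return float(np.log(row_probs(rho)).sum())

    res = minimize_scalar(lambda r: -loglik(r), bounds=(-_BOUND, _BOUND),
                          method="bounded", options={"xatol": 1e-10})
    rho = float(res.x)
    boundary = abs(rho) >= _BOUND

    h = 1e-5
    lp_plus = np.log(row_probs(rho + h))
    lp_mid = np.log(row_probs(rho))
    lp_minus = np.log(row_probs(rho - h))
    info = -float((lp_plus - 2 * lp_mid + lp_minus).sum()) / h**2
    influence = None
    if info > 0 and np.isfinite(info):
        scores = (lp_plus - lp_minus) / (2 * h)
        if cluster_ids is None:
            g = scores
        else:
            _, inv = np.unique(np.asarray(cluster_ids), return_inverse=True)
            g = np.bincount(inv, weights=scores)
        influence = g / info  # per-cluster first-order effect on rho_hat
        se = float(np.sqrt((g * g).sum()) / info)
    elif _jackknife_fallback:
        se = _jackknife_se(y1, y2, t1, t2, rho)
    else:
        se = np.nan
    est = TetrachoricEstimate(
        rho, float(np.mean(t1)), float(np.mean(t2)), se, n_eff, boundary=boundary
    )
    return (est, influence) if return_influence else est


def _jackknife_se(y1, y2, t1, t2, rho_hat, n_blocks: int = 20) -> float:
    """Delete-one-block jackknife over pairs (fallback for degenerate information)."""
    n = len(y1)
    blocks = np.arange(n) % n_blocks
    est = []
    for b in range(n_blocks):
        m = blocks != b
        if m.sum() < 4:
            continue
        try:
            e = tetrachoric_from_pairs(y1[m], y2[m], t1[m], t2[m], _jackknife_fallback=False)
            est.append(e.rho)
        except Exception:
            continue
    if len(est) < 3:
        return np.nan
    est = np.asarray(est)
    k = len(est)
    return float(np.sqrt((k - 1) / k * ((est - est.mean()) ** 2).sum()))


@dataclass
class PairCorrelationStructure:
    """Observed latent-correlation moments per kinship group for two traits.

    For each kinship group: the within-person cross-trait correlation,
    the two cross-person same-trait correlations and the (symmetrized)
    cross-person cross-trait correlation, with asymptotic variances and
    concordant/discordant pair counts per trait.
    """

    groups: list  # kinship names in order
    correlations: pd.DataFrame  # index (kinship, moment), cols rho/var/n
    counts: pd.DataFrame  # per kinship and trait: concordant / discordant
    covariance: pd.DataFrame | None = None  # full moment covariance (influence-based)

    def _index(self, order):
        rows = []
        for mom in order:
            for g in self.groups:
                rows.append((g, mom))
        return pd.MultiIndex.from_tuples(rows)

    def moment_vector(self, order=("same1", "same2", "cross", "within")) -> tuple:
        idx = self._index(order)
        r = self.correlations.loc[idx, "rho"].to_numpy()
        v = self.correlations.loc[idx, "var"].to_numpy()
        return r, v, idx

    def moment_covariance(self, order=("same1", "same2", "cross", "within")):
        """Full covariance of the moment vector (None if influence data missing)."""
        if self.covariance is None:
            return None
        idx = self._index(order)
        return self.covariance.loc[idx, idx].to_numpy()


def pair_polychoric_structure(
    pair_data: dict,
    thresholds: dict,
) -> PairCorrelationStructure:
    """Estimate the 4 latent correlations per kinship group.

    Parameters
    ----------
    pair_data : {kinship: DataFrame} with columns y1_a, y2_a, y1_b, y2_b
        (binary indicators of traits 1 and 2 for members A and B).
        Optionally per-person threshold columns tau1_a, tau2_a, tau1_b,
        tau2_b; absent columns fall back to the scalar thresholds.
    thresholds : {"tau1": float, "tau2": float} marginal thresholds used
        when no person-specific columns are present.
    """
    rows = []
    count_rows = []
    groups = []
    cov_blocks: dict = {}
    for kin, df in pair_data.items():
        groups.append(kin)
        t1a = df["tau1_a"].to_numpy() if "tau1_a" in df else np.full(len(df), thresholds["tau1"])
        t1b = df["tau1_b"].to_numpy() if "tau1_b" in df else np.full(len(df), thresholds["tau1"])
        t2a = df["tau2_a"].to_numpy() if "tau2_a" in df else np.full(len(df), thresholds["tau2"])
        t2b = df["tau2_b"].to_numpy() if "tau2_b" in df else np.full(len(df), thresholds["tau2"])
        y1a = df["y1_a"].to_numpy(float)
        y1b = df["y1_b"].to_numpy(float)
        y2a = df["y2_a"].to_numpy(float)
        y2b = df["y2_b"].to_numpy(float)
        n = len(df)

        pair_idx = np.arange(n)
        both = np.concatenate([pair_idx, pair_idx])
        # within-person cross-trait: both members pooled, pair-clustered SE
        e_w, inf_w = tetrachoric_from_pairs(
            np.concatenate([y1a, y1b]),
            np.concatenate([y2a, y2b]),
            np.concatenate([t1a, t1b]),
            np.concatenate([t2a, t2b]),
            cluster_ids=both,
            return_influence=True,
        )
        # cross-person same-trait
        e_s1, inf_s1 = tetrachoric_from_pairs(y1a, y1b, t1a, t1b, return_influence=True)
        e_s2, inf_s2 = tetrachoric_from_pairs(y2a, y2b, t2a, t2b, return_influence=True)
        # cross-person cross-trait: both orientations stacked (symmetrized),
        # SE pair-clustered since the orientations share pairs
        e_x, inf_x = tetrachoric_from_pairs(
            np.concatenate([y1a, y1b]),
            np.concatenate([y2b, y2a]),
            np.concatenate([t1a, t1b]),
            np.concatenate([t2b, t2a]),
            cluster_ids=both,
            return_influence=True,
        )
        ests = (("within", e_w, inf_w), ("same1", e_s1, inf_s1),
                ("same2", e_s2, inf_s2), ("cross", e_x, inf_x))
        for mom, est, _ in ests:
            rows.append((kin, mom, est.rho, est.se**2 if np.isfinite(est.se) else np.nan, n, est.boundary))
        # within-group covariance of the 4 moment estimates via influences
        # (moments of the same kinship group share the same pairs)
        if all(i is not None for _, _, i in ests):
            for mi, ei, ii in ests:
                for mj, ej, ij in ests:
                    cov_blocks[(kin, mi, mj)] = float((ii * ij).sum())
        for trait, (ya, yb) in (("trait1", (y1a, y1b)), ("trait2", (y2a, y2b))):
            both = int(((ya == 1) & (yb == 1)).sum())
            one = int(((ya + yb) == 1).sum())
            count_rows.append((kin, trait, both, one))

    corr = pd.DataFrame(
        rows, columns=["kinship", "moment", "rho", "var", "n", "boundary"]
    ).set_index(["kinship", "moment"])
    counts = pd.DataFrame(
        count_rows, columns=["kinship", "trait", "concordant", "discordant"]
    )
    covariance = None
    if cov_blocks:
        idx = corr.index
        cov = pd.DataFrame(0.0, index=idx, columns=idx)
        for (kin, mi, mj), val in cov_blocks.items():
            cov.loc[(kin, mi), (kin, mj)] = val
        # fall back to the marginal variance on the diagonal where the
        # influence-based entry is missing/degenerate
        diag = np.diag(cov.to_numpy())
        fix = ~np.isfinite(diag) | (diag <= 0)
        if fix.any():
            d = cov.to_numpy().copy()
            d[np.diag_indices_from(d)] = np.where(fix, corr["var"].to_numpy(), diag)
            cov = pd.DataFrame(d, index=idx, columns=idx)
        covariance = cov
    return PairCorrelationStructure(
        groups=groups, correlations=corr, counts=counts, covariance=covariance
    )
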