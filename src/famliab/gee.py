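"""Logistic GEE with cluster-robust sandwich variance, plus descriptives.

Point estimates come from ordinary logistic maximum likelihood (the GEE
with an independence working correlation has identical estimating
equations), and the covariance is the sandwich estimator with scores
summed within family clusters, so ORs carry Wald 95% confidence
intervals that are valid under arbitrary within-family dependence —
including the double-entered relative pairs used in the co-aggregation
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .registry import PhenotypeDefinition, extended_family_clusters
from .splines import natural_cubic_spline_basis

__all__ = [
    "GeeFit",
    "SeparationError",
    "fit_logistic_gee",
    "within_individual_or",
    "familial_coaggregation_or",
    "descriptive_table",
]

Z95 = 1.96  # conventional 95% normal quantile
_BETA_CAP = 15.0  # |log-odds| beyond this signals separation
_MIN_INFORMATIVE = 5  # sparse-cell suppression threshold


class SeparationError(RuntimeError):
    """Raised when the logistic fit drifts to a separated solution."""


@dataclass
class GeeFit:
    """Logistic GEE result: log-odds coefficients with cluster-robust Wald CIs."""

    params: pd.Series
    robust_cov: pd.DataFrame
    nobs: int
    n_clusters: int
    converged: bool
    suppressed: bool = False
    suppression_reason: str = ""

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.robust_cov)), index=self.params.index)

    def or_table(self) -> pd.DataFrame:
        se = self.se
        return pd.DataFrame(
            {
                "beta": self.params,
                "se": se,
                "OR": np.exp(self.params),
                "ci_low": np.exp(self.params - Z95 * se),
                "ci_high": np.exp(self.params + Z95 * se),
            }
        )

    def odds_ratio(self, term: str):
        row = self.or_table().loc[term]
        return float(row["OR"]), float(row["ci_low"]), float(row["ci_high"])


def _suppressed(reason: str, columns) -> GeeFit:
    idx = pd.Index(columns)
    nan = pd.Series(np.nan, index=idx)
    return GeeFit(
        params=nan,
        robust_cov=pd.DataFrame(np.nan, index=idx, columns=idx),
        nobs=0,
        n_clusters=0,
        converged=False,
        suppressed=True,
        suppression_reason=reason,
    )


def fit_logistic_gee(
    y,
    X: pd.DataFrame,
    clusters,
    freq_weights=None,
) -> GeeFit:
    """Logistic regression with a cluster-robust sandwich covariance.

    Parameters
    ----------
    y : binary outcome vector.
    X : design matrix (include the intercept column explicitly).
    clusters : cluster labels; scores are summed within clusters before
        forming the meat of the sandwich.  With all-singleton clusters the
        result is the ordinary heteroskedasticity-robust covariance.
    freq_weights : optional row multiplicities for aggregated data; a row
        with weight w contributes as w independent singleton observations
        within its cluster.
    """
    y = np.asarray(y, dtype=float)
    Xm = np.asarray(X, dtype=float)
    clusters = np.asarray(clusters)
    w = np.ones(len(y)) if freq_weights is None else np.asarray(freq_weights, float)

    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise ValueError("design matrix is rank deficient")

    model = sm.GLM(y, Xm, family=sm.families.Binomial(), freq_weights=w)
    try:
        res = model.fit(maxiter=100, tol=1e-10)
        converged = bool(res.converged)
    except Exception:
        return GeeFit(
            params=pd.Series(np.nan, index=X.columns),
            robust_cov=pd.DataFrame(np.nan, index=X.columns, columns=X.columns),
            nobs=int(w.sum()),
            n_clusters=len(np.unique(clusters)),
            converged=False,
        )
    beta = res.params
    if np.max(np.abs(beta)) > _BETA_CAP:
        raise SeparationError(
            f"|beta| = {np.max(np.abs(beta)):.2f} exceeds cap; data likely separated"
        )

    mu = res.fittedvalues
    v = mu * (1.0 - mu)
    bread = np.linalg.inv(Xm.T @ (Xm * (w * v)[:, None]))  # (X' W X)^-1

    resid = w * (y - mu)
    scores = Xm * resid[:, None]  # per-row (weighted) score contributions
    if freq_weights is not None:
        # an aggregated row of weight w is w independent singletons: its meat
        # contribution is w * s s' with s the per-unit score
        unit = Xm * (y - mu)[:, None]
        meat_rows = unit[:, :, None] * unit[:, None, :] * w[:, None, None]
        meat = meat_rows.sum(axis=0)
        # rows sharing a cluster additionally get cross terms
        order = np.argsort(clusters, kind="stable")
        cl_sorted = clusters[order]
        uniq, counts = np.unique(cl_sorted, return_counts=True)
        if np.any(counts > 1):
            g = pd.DataFrame(scores).groupby(clusters).sum().to_numpy()
            within = np.zeros_like(meat)
            for cid in uniq[counts > 1]:
                mask = clusters == cid
                s = scores[mask]
                gc = s.sum(axis=0)
                within += np.outer(gc, gc) - s.T @ s
            meat = meat + within
    else:
        g = pd.DataFrame(scores).groupby(clusters).sum().to_numpy()
        meat = g.T @ g

    cov = bread @ meat @ bread
    cov = (cov + cov.T) / 2.0
    cols = list(X.columns)
    return GeeFit(
        params=pd.Series(beta, index=cols),
        robust_cov=pd.DataFrame(cov, index=cols, columns=cols),
        nobs=int(round(w.sum())),
        n_clusters=len(np.unique(clusters)),
        converged=converged,
    )


def _drop_collinear(X: pd.DataFrame, tol: float = 1e-9) -> pd.DataFrame:
    """Keep a maximal linearly independent subset of columns, in order.

    Twin pairs share a birth year, so the two relatives' spline blocks can
    coincide exactly; earlier columns (const, exposure) take precedence.
    """
    mat = X.to_numpy(dtype=float)
    keep: list[int] = []
    for j in range(mat.shape[1]):
        cand = mat[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(cand).max())) == len(keep) + 1:
            keep.append(j)
    return X.iloc[:, keep]


def _spline_frame(values, prefix: str, df: int = 5, basis=None):
    values = np.asarray(values, dtype=float)
    if basis is None:
        basis = natural_cubic_spline_basis(values, df)
        mat = basis.basis
    else:
        mat = basis.evaluate(values)
    frame = pd.DataFrame(mat, columns=[f"{prefix}_ns{i+1}" for i in range(mat.shape[1])])
    return frame, basis


def within_individual_or(
    cohort: pd.DataFrame,
    bpd_indicator,
    outcome_indicator,
    definition: PhenotypeDefinition | None = None,
    clusters=None,
    spline_df: int = 5,
    adjust: bool = True,
) -> GeeFit:
    """OR for the outcome given exposure-trait status within individuals.

    Adjusted for sex and a natural-cubic birth-year spline (5 df);
    clusters default to singletons per person (use family ids to absorb
    relatedness).  Rows with unascertainable outcome (males for
    female-only phenotypes) are dropped.
    """
    df = pd.DataFrame(
        {
            "bpd": np.asarray(bpd_indicator, dtype=float),
            "y": np.asarray(outcome_indicator, dtype=float),
            "female": (cohort["sex"] == "female").astype(float).to_numpy(),
            "birth_year": cohort["birth_date"].dt.year.to_numpy()
            + cohort["birth_date"].dt.dayofyear.to_numpy() / 365.25,
        }
    )
    df["cluster"] = (
        np.asarray(clusters) if clusters is not None else np.arange(len(df))
    )
    if definition is not None and definition.female_only:
        df = df[df["female"] == 1.0]
    df = df.dropna(subset=["y", "bpd"]).reset_index(drop=True)

    tab = pd.crosstab(df["bpd"], df["y"])
    if tab.shape != (2, 2) or tab.to_numpy().min() < _MIN_INFORMATIVE:
        return _suppressed("fewer than 5 informative observations in a cell", ["const", "bpd"])

    X = pd.DataFrame({"const": 1.0, "bpd": df["bpd"]})
    if adjust:
        if definition is None or not definition.female_only:
            X["female"] = df["female"]
        spl, _ = _spline_frame(df["birth_year"], "by", spline_df)
        X = pd.concat([X.reset_index(drop=True), spl], axis=1)
    return fit_logistic_gee(df["y"], X, df["cluster"].to_numpy())


def familial_coaggregation_or(
    pairs: pd.DataFrame,
    bpd: pd.Series,
    outcome: pd.Series,
    persons: pd.DataFrame,
    definition: PhenotypeDefinition | None = None,
    spline_df: int = 5,
    adjust: bool = True,
) -> dict:
    """Per-kinship ORs for relative B's outcome given relative A's exposure trait.

    ``pairs`` must be double-entered for within-generation kinship types.
    ``bpd`` and ``outcome`` are person-indexed indicator Series; clusters
    are connected components over all relative pairs so overlapping and
    double-entered pairs share a cluster.  Sparse cells give a suppressed
    fit (rendered "NA" downstream).
    """
    info = persons.set_index("person_id")
    clusters = extended_family_clusters(pairs)
    out: dict[str, GeeFit] = {}
    for kin, sub in pairs.groupby("kinship", sort=True):
        if definition is not None and definition.within_generation_only:
            sub = sub[sub["generation_relation"] == "within"]
        if sub.empty:
            continue
        d = pd.DataFrame(
            {
                "exposure": sub["id_a"].map(bpd).to_numpy(dtype=float),
                "y": sub["id_b"].map(outcome).to_numpy(dtype=float),
                "sex_a": (info.loc[sub["id_a"], "sex"] == "female").to_numpy(dtype=float),
                "sex_b": (info.loc[sub["id_b"], "sex"] == "female").to_numpy(dtype=float),
                "by_a": info.loc[sub["id_a"], "birth_date"].dt.year.to_numpy(dtype=float),
                "by_b": info.loc[sub["id_b"], "birth_date"].dt.year.to_numpy(dtype=float),
                "cluster": sub["id_a"].map(clusters).to_numpy(),
            }
        )
        if definition is not None and definition.female_only:
            d = d[d["sex_b"] == 1.0]
        d = d.dropna(subset=["exposure", "y"]).reset_index(drop=True)
        if d.empty:
            out[kin] = _suppressed("no informative pairs", ["const", "exposure"])
            continue
        tab = pd.crosstab(d["exposure"], d["y"])
        if tab.shape != (2, 2) or tab.to_numpy().min() < _MIN_INFORMATIVE:
            out[kin] = _suppressed(
                "fewer than 5 informative pairs in a cell", ["const", "exposure"]
            )
            continue
        X = pd.DataFrame({"const": 1.0, "exposure": d["exposure"]})
        if adjust:
            X["sex_a"] = d["sex_a"]
            if definition is None or not definition.female_only:
                X["sex_b"] = d["sex_b"]
            for col, pref in (("by_a", "bya"), ("by_b", "byb")):
                if d[col].nunique() > spline_df:
                    spl, _ = _spline_frame(d[col], pref, spline_df)
                    X = pd.concat([X, spl], axis=1)
        X = X.loc[:, X.std(axis=0).gt(0) | (X.columns == "const")]
        X = _drop_collinear(X)
        try:
            out[kin] = fit_logistic_gee(d["y"], X, d["cluster"].to_numpy())
        except SeparationError:
            out[kin] = _suppressed("separation", list(X.columns))
    return out


def descriptive_table(
    counts: pd.DataFrame | None = None,
    cohort: pd.DataFrame | None = None,
    phenotype_indicators: dict | None = None,
    bpd_indicator=None,
) -> pd.DataFrame:
    """Descriptive counts and percentages by exposure-trait status.

    Either pass precomputed ``counts`` (columns: label, group, n_without,
    n_with) or a cohort plus indicator vectors.  For phenotype rows the
    percentage is taken within the with/without column totals; for
    stratum rows (sex, birth-year band) percentages are row-wise.
    """
    if counts is None:
        if cohort is None or phenotype_indicators is None or bpd_indicator is None:
            raise ValueError("need either counts or cohort + indicators")
        bpd = np.asarray(bpd_indicator, dtype=float)
        rows = []
        rows.append(("total", "overall", float((bpd == 0).sum()), float((bpd == 1).sum())))
        female = (cohort["sex"] == "female").to_numpy()
        for label, mask in (("male", ~female), ("female", female)):
            rows.append(
                (label, "sex", float(((bpd == 0) & mask).sum()), float(((bpd == 1) & mask).sum()))
            )
        for name, ind in phenotype_indicators.items():
            ind = np.asarray(ind, dtype=float)
            ok = ~np.isnan(ind)
            rows.append(
                (
                    name,
                    "phenotype",
                    float(((bpd == 0) & (ind == 1) & ok).sum()),
                    float(((bpd == 1) & (ind == 1) & ok).sum()),
                )
            )
        counts = pd.DataFrame(rows, columns=["label", "group", "n_without", "n_with"])

    counts = counts.copy()
    totals = counts[counts["group"] == "overall"]
    if len(totals):
        tot_without = float(totals["n_without"].iloc[0])
        tot_with = float(totals["n_with"].iloc[0])
    else:
        tot_without = counts.loc[counts["group"] == "phenotype", "n_without"].max()
        tot_with = counts.loc[counts["group"] == "phenotype", "n_with"].max()
    counts["n_total"] = counts["n_without"] + counts["n_with"]

    def pct(num, den):
        den = np.asarray(den, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(den > 0, 100.0 * np.asarray(num, float) / den, 0.0)
        return out

    is_pheno = counts["group"] == "phenotype"
    # female-only phenotypes carry explicit denominators (female totals)
    den_wo = (
        counts["denom_without"].fillna(tot_without)
        if "denom_without" in counts
        else pd.Series(tot_without, index=counts.index)
    )
    den_wi = (
        counts["denom_with"].fillna(tot_with)
        if "denom_with" in counts
        else pd.Series(tot_with, index=counts.index)
    )
    counts["pct_without"] = np.where(
        is_pheno,
        pct(counts["n_without"], den_wo),
        pct(counts["n_without"], counts["n_total"]),
    )
    counts["pct_with"] = np.where(
        is_pheno,
        pct(counts["n_with"], den_wi),
        pct(counts["n_with"], counts["n_total"]),
    )
    grand = tot_without + tot_with
    counts["prevalence_pct"] = pct(counts["n_total"], grand if grand else np.nan)
    return counts
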