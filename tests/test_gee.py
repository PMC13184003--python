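"""Natural-spline covariate basis and logistic GEE with cluster-robust variance."""

import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from famliab.gee import (
    SeparationError,
    descriptive_table,
    familial_coaggregation_or,
    fit_logistic_gee,
    within_individual_or,
)
from famliab.params import AceParams, BivariateAceParams, Kinship
from famliab.splines import natural_cubic_spline_basis


class TestNaturalSpline:
    def test_df_columns(self):
        sb = natural_cubic_spline_basis(np.arange(1973, 2002), df=5)
        assert sb.basis.shape == (29, 5)

    def test_linear_beyond_boundary(self):
        sb = natural_cubic_spline_basis(np.arange(1973, 2002), df=5)
        xx = np.linspace(2002, 2012, 40)
        y = sb.evaluate(xx) @ np.arange(1, 6, dtype=float)
        assert np.abs(np.diff(y, 2)).max() < 1e-8

    def test_linear_functions_reproduced(self):
        x = np.arange(1973, 2002, dtype=float)
        sb = natural_cubic_spline_basis(x, df=5)
        X = np.column_stack([np.ones(len(x)), sb.basis])
        beta, *_ = np.linalg.lstsq(X, x, rcond=None)
        assert np.abs(X @ beta - x).max() < 1e-8

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError, match="distinct"):
            natural_cubic_spline_basis(np.array([1.0, 2.0, 3.0]), df=5)

    def test_span_matches_r_ns(self):
        """Column span agrees with R's splines::ns on the same knots."""
        x = np.arange(1973, 2002)
        sb = natural_cubic_spline_basis(x.astype(float), df=5)
        rcode = (
            "x <- 1973:2001; b <- splines::ns(x, df=5); X <- cbind(1, b);"
            "P <- X %*% solve(t(X) %*% X) %*% t(X);"
            "write.table(P, stdout(), row.names=FALSE, col.names=FALSE)"
        )
        proc = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, timeout=120
        )
        if proc.returncode != 0:
            pytest.skip(f"Rscript unavailable: {proc.stderr[:200]}")
        P_r = np.array(
            [[float(v) for v in line.split()] for line in proc.stdout.strip().splitlines()]
        )
        X = np.column_stack([np.ones(len(x)), sb.basis])
        P = X @ np.linalg.solve(X.T @ X, X.T)
        assert np.abs(P - P_r).max() < 1e-8


class TestLogisticGee:
    def test_saturated_2x2_equals_cross_product_ratio(self):
        y = np.array([1] * 20 + [0] * 80 + [1] * 10 + [0] * 190, float)
        x = np.array([1] * 100 + [0] * 200, float)
        X = pd.DataFrame({"const": 1.0, "exposure": x})
        fit = fit_logistic_gee(y, X, np.arange(300))
        assert np.exp(fit.params["exposure"]) == pytest.approx(4.75, abs=1e-10)

    def test_singleton_clusters_equal_hc0(self):
        rng = np.random.default_rng(0)
        n = 400
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(0.4 - 0.9 * x))
        y = (rng.random(n) < p).astype(float)
        X = pd.DataFrame({"const": 1.0, "x": x})
        fit = fit_logistic_gee(y, X, np.arange(n))
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit(cov_type="HC0")
        assert np.abs(fit.robust_cov.to_numpy() - np.asarray(ref.cov_params())).max() < 1e-10

    def test_within_cluster_duplication_invariance(self):
        rng = np.random.default_rng(1)
        n = 300
        x = rng.normal(size=n)
        cl = rng.integers(0, 60, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(float)
        X = pd.DataFrame({"const": 1.0, "x": x})
        f1 = fit_logistic_gee(y, X, cl)
        f2 = fit_logistic_gee(
            np.concatenate([y, y]),
            pd.concat([X, X], ignore_index=True),
            np.concatenate([cl, cl]),
        )
        assert np.abs(f1.params - f2.params).max() < 1e-8
        assert np.abs(f1.se - f2.se).max() < 1e-8

    def test_agrees_with_statsmodels_gee(self):
        """Independent cross-check against the reference GEE implementation."""
        rng = np.random.default_rng(2)
        n = 600
        x = rng.normal(size=n)
        cl = rng.integers(0, 120, n)
        y = (rng.random(n) < 1 / (1 + np.exp(0.2 - 0.7 * x))).astype(float)
        X = pd.DataFrame({"const": 1.0, "x": x})
        mine = fit_logistic_gee(y, X, cl)
        ref = sm.GEE(
            y, X, groups=cl, family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Independence(),
        ).fit()
        assert np.abs(np.asarray(ref.params) - mine.params.to_numpy()).max() < 1e-6
        assert np.abs(np.asarray(ref.bse) - mine.se.to_numpy()).max() < 1e-6

    def test_separation_detected(self):
        y = np.array([0.0] * 20 + [1.0] * 20)
        x = np.array([0.0] * 20 + [1.0] * 20)
        X = pd.DataFrame({"const": 1.0, "x": x})
        with pytest.raises(SeparationError):
            fit_logistic_gee(y, X, np.arange(40))

    def test_wald_ci_excludes_one_iff_z_above_196(self):
        rng = np.random.default_rng(3)
        n = 500
        x = rng.integers(0, 2, n).astype(float)
        y = (rng.random(n) < 0.3 + 0.1 * x).astype(float)
        X = pd.DataFrame({"const": 1.0, "x": x})
        fit = fit_logistic_gee(y, X, np.arange(n))
        o, lo, hi = fit.odds_ratio("x")
        z = abs(fit.params["x"]) / fit.se["x"]
        assert (lo > 1 or hi < 1) == (z > 1.96)

    def test_freq_weights_match_expanded_data(self):
        w = np.array([20, 80, 10, 190], float)
        yw = np.array([1, 0, 1, 0], float)
        ew = np.array([1, 1, 0, 0], float)
        Xw = pd.DataFrame({"const": 1.0, "exposure": ew})
        fw = fit_logistic_gee(yw, Xw, np.arange(4), freq_weights=w)
        y = np.repeat(yw, w.astype(int))
        e = np.repeat(ew, w.astype(int))
        fe = fit_logistic_gee(y, pd.DataFrame({"const": 1.0, "exposure": e}), np.arange(300))
        assert np.abs(fw.params - fe.params).max() < 1e-8
        assert np.abs(fw.se - fe.se).max() < 1e-8


class TestNullCalibration:
    def test_null_or_ci_covers_one_95pct(self):
        """With outcome independent of exposure, the Wald CI for the OR
        should cover 1.0 in about 95% of replicates."""
        rng = np.random.default_rng(10)
        n = 800
        cover = 0
        reps = 200
        for _ in range(reps):
            x = rng.integers(0, 2, n).astype(float)
            y = (rng.random(n) < 0.25).astype(float)
            X = pd.DataFrame({"const": 1.0, "x": x})
            fit = fit_logistic_gee(y, X, np.arange(n))
            _, lo, hi = fit.odds_ratio("x")
            cover += lo <= 1.0 <= hi
        assert 0.90 <= cover / reps <= 0.99


class TestCoaggregationOrientation:
    def test_double_entry_orientation_symmetric(self):
        """Swapping the two orientations of every double-entered pair
        leaves the stacked-data fit unchanged."""
        rng = np.random.default_rng(4)
        n = 400
        ids_a = np.arange(n)
        ids_b = np.arange(n) + n
        bpd = pd.Series(rng.integers(0, 2, 2 * n).astype(float), index=np.arange(2 * n))
        out = pd.Series(rng.integers(0, 2, 2 * n).astype(float), index=np.arange(2 * n))
        persons = pd.DataFrame(
            {
                "person_id": np.arange(2 * n),
                "sex": rng.choice(["male", "female"], 2 * n),
                "birth_date": pd.to_datetime("1980-01-01"),
            }
        )
        base = pd.DataFrame(
            {
                "id_a": np.concatenate([ids_a, ids_b]),
                "id_b": np.concatenate([ids_b, ids_a]),
                "kinship": "full_sib",
                "alpha": 0.5,
                "gamma": 1.0,
                "generation_relation": "within",
            }
        )
        swapped = base.iloc[np.r_[n : 2 * n, 0:n]].reset_index(drop=True)
        f1 = familial_coaggregation_or(base, bpd, out, persons, adjust=False)
        f2 = familial_coaggregation_or(swapped, bpd, out, persons, adjust=False)
        k = "full_sib"
        assert np.abs(f1[k].params - f2[k].params).max() < 1e-10
        assert np.abs(f1[k].se - f2[k].se).max() < 1e-10

    def test_kinship_or_gradient_under_shared_etiology(self):
        """With shared genetic etiology, closer relatives show larger ORs
        (checked in expectation over replicates)."""
        from famliab.recovery import simulate_pair_study

        t = AceParams(0.6, 0.0, 0.4)
        params = BivariateAceParams(t, t, rA=0.9, rC=0.0, rE=0.0)
        groups = (Kinship.MZ_TWIN, Kinship.FULL_SIB, Kinship.COUSIN)
        lors = {g.value: [] for g in groups}
        for rep in range(25):
            data = simulate_pair_study(params, (0.2, 0.2), 3000, seed=rep + 1, groups=groups)
            for kin, df in data.items():
                y = np.concatenate([df["y2_b"], df["y2_a"]])
                x = np.concatenate([df["y1_a"], df["y1_b"]])
                tab = pd.crosstab(x, y).to_numpy() + 0.5
                lors[kin].append(np.log(tab[1, 1] * tab[0, 0] / (tab[0, 1] * tab[1, 0])))
        mz, fs, cz = (np.mean(lors[g.value]) for g in groups)
        assert mz > fs > cz > 0


class TestWithinIndividual:
    def test_unadjusted_or_from_reference_counts(self):
        """The published cohort's depressive-disorder cross-product ratio."""
        from famliab.pipeline import published_descriptives

        desc = published_descriptives()
        total = desc[desc["group"] == "overall"].iloc[0]
        dep = desc[desc["label"] == "depressive_disorder"].iloc[0]
        a = dep["n_with"]  # exposed with outcome
        b = total["n_with"] - dep["n_with"]
        c = dep["n_without"]
        d = total["n_without"] - dep["n_without"]
        w = np.array([a, b, c, d], float)
        y = np.array([1, 0, 1, 0], float)
        x = np.array([1, 1, 0, 0], float)
        X = pd.DataFrame({"const": 1.0, "exposure": x})
        fit = fit_logistic_gee(y, X, np.arange(4), freq_weights=w)
        assert np.exp(fit.params["exposure"]) == pytest.approx(36.17, abs=0.01)

    def test_sparse_exposure_suppressed(self):
        cohort = pd.DataFrame(
            {
                "person_id": np.arange(100),
                "sex": ["female"] * 100,
                "birth_date": pd.to_datetime("1990-06-01"),
            }
        )
        bpd = np.zeros(100)
        bpd[:2] = 1  # too few exposed
        out = np.random.default_rng(0).integers(0, 2, 100).astype(float)
        fit = within_individual_or(cohort, bpd, out)
        assert fit.suppressed


class TestDescriptives:
    def test_reference_cohort_percentages(self):
        from famliab.pipeline import published_descriptives

        desc = descriptive_table(counts=published_descriptives())
        total = desc[desc["group"] == "overall"].iloc[0]
        assert total["prevalence_pct"] == pytest.approx(100.0)
        # exposure prevalence 0.9% and female share among cases 85.8%
        prev = 100 * total["n_with"] / (total["n_with"] + total["n_without"])
        assert round(prev, 1) == 0.9
        female = desc[desc["label"] == "female"].iloc[0]
        dep = desc[desc["label"] == "depressive_disorder"].iloc[0]
        assert round(dep["pct_with"], 1) == 76.6
        assert round(dep["pct_without"], 1) == 8.3

    def test_zero_case_phenotype_no_division_error(self):
        counts = pd.DataFrame(
            {
                "label": ["total", "empty"],
                "group": ["overall", "phenotype"],
                "n_without": [100, 0],
                "n_with": [10, 0],
            }
        )
        desc = descriptive_table(counts=counts)
        row = desc[desc["label"] == "empty"].iloc[0]
        assert row["pct_with"] == 0.0 and row["pct_without"] == 0.0
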