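"""Pipeline orchestration: simulate -> build cohort -> co-aggregate -> ACE fit.

Each stage reads/writes plain TSV/JSON under an output directory and
drops a provenance record (config hash, seed) so a rerun with the same
config reproduces every stochastic output byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ace import (
    SIB_GROUPS,
    fit_bivariate_ace,
    fit_univariate_ace,
    screen_phenotypes,
)
from .gee import GeeFit, descriptive_table, familial_coaggregation_or, within_individual_or
from .params import Kinship
from .registry import (
    apply_cohort_exclusions,
    ascertain_phenotype,
    enumerate_relative_pairs,
    family_clusters,
    load_phenotype_definitions,
    read_registry,
    select_unique_sibling_pairs,
)
from .simulate import SimulationConfig, simulate_registry
from .splines import natural_cubic_spline_basis
from .tetrachoric import estimate_thresholds, pair_polychoric_structure

log = logging.getLogger("famliab")

__all__ = ["RunConfig", "run_pipeline", "render_tables", "default_phenotype_path"]


def default_phenotype_path():
    return resources.files("famliab.data") / "phenotypes.yaml"


def published_descriptives() -> pd.DataFrame:
    """Reference descriptive counts from a national register birth-cohort
    study of BPD comorbidity, used for worked examples."""
    path = resources.files("famliab.data") / "birth_cohort_descriptives.tsv"
    return pd.read_csv(path, sep="\t")


@dataclass
class RunConfig:
    output_dir: str = "results/run"
    registry_dir: str | None = None  # use an existing registry instead of simulating
    simulation: dict = field(default_factory=dict)  # kwargs for SimulationConfig
    phenotype_file: str | None = None
    exposure: str = "bpd"
    outcome: str = "depressive_disorder"
    run_within_individual: bool = True
    run_coaggregation: bool = True
    run_ace: bool = True
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _provenance(config: RunConfig, stage: str) -> dict:
    return {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "famliab_version": __version__,
    }


def _write_provenance(path: pathlib.Path, config: RunConfig, stage: str) -> None:
    with open(path, "w") as fh:
        json.dump(_provenance(config, stage), fh, indent=2)


def _spline_or_none(values: np.ndarray, df: int = 5):
    if len(np.unique(values)) <= df:
        return None
    return natural_cubic_spline_basis(values, df)


def build_threshold_frame(cohort: pd.DataFrame, indicator: np.ndarray):
    """Covariate-adjusted probit thresholds per cohort member (sex + birth-year spline)."""
    by = cohort["birth_date"].dt.year.to_numpy(dtype=float)
    female = (cohort["sex"] == "female").to_numpy(dtype=float)
    cols = {"const": np.ones(len(cohort)), "female": female}
    sb = _spline_or_none(by)
    if sb is not None:
        for i in range(sb.basis.shape[1]):
            cols[f"by_ns{i+1}"] = sb.basis[:, i]
    X = pd.DataFrame(cols)
    ok = ~np.isnan(np.asarray(indicator, dtype=float))
    model = estimate_thresholds(np.asarray(indicator, float)[ok], X[ok])
    tau = np.full(len(cohort), np.nan)
    tau[ok] = model.thresholds(X[ok])
    return tau, model


def ace_analysis(
    tables: dict,
    cohort: pd.DataFrame,
    pairs: pd.DataFrame,
    exposure_ind: np.ndarray,
    outcome_ind: np.ndarray,
    seed: int = 0,
    adjust: bool = True,
    screen: bool = True,
) -> dict:
    """Quantitative-genetic stage: unique sibling pairs -> latent correlation
    structure -> univariate and bivariate ACE fits plus the screening rule."""
    selected = select_unique_sibling_pairs(pairs, tables["persons"], seed=seed)
    cid = {p: i for i, p in enumerate(cohort["person_id"].to_numpy())}

    if adjust:
        tau1, _ = build_threshold_frame(cohort, exposure_ind)
        tau2, _ = build_threshold_frame(cohort, outcome_ind)
    else:
        from scipy.stats import norm

        e = np.asarray(exposure_ind, float)
        o = np.asarray(outcome_ind, float)
        tau1 = np.full(len(cohort), norm.isf(np.nanmean(e)))
        tau2 = np.full(len(cohort), norm.isf(np.nanmean(o)))

    exposure_ind = np.asarray(exposure_ind, dtype=float)
    outcome_ind = np.asarray(outcome_ind, dtype=float)

    pair_data = {}
    for kin in SIB_GROUPS:
        sub = selected[selected["kinship"] == kin.value]
        if sub.empty:
            continue
        rows = []
        for a, b in sub[["id_a", "id_b"]].itertuples(index=False):
            ia, ib = cid.get(a), cid.get(b)
            if ia is None or ib is None:
                continue
            row = (
                exposure_ind[ia], outcome_ind[ia], exposure_ind[ib], outcome_ind[ib],
                tau1[ia], tau2[ia], tau1[ib], tau2[ib],
            )
            if np.any(np.isnan(row)):
                continue
            rows.append(row)
        if rows:
            pair_data[kin.value] = pd.DataFrame(
                rows,
                columns=["y1_a", "y2_a", "y1_b", "y2_b", "tau1_a", "tau2_a", "tau1_b", "tau2_b"],
            )

    if len(pair_data) < 2:
        return {"error": "insufficient sibling pair groups", "n_groups": len(pair_data)}

    structure = pair_polychoric_structure(pair_data, thresholds={"tau1": np.nan, "tau2": np.nan})

    result: dict = {"n_pairs": {k: len(v) for k, v in pair_data.items()}}

    # screening on the pooled within-person correlation and pair counts
    within = structure.correlations.xs("within", level="moment")
    wvar = within["var"].replace(0, np.nan)
    w = 1.0 / wvar
    pooled_within = float((within["rho"] * w).sum() / w.sum())
    cnt = structure.counts.groupby("trait")[["concordant", "discordant"]].sum()
    n_conc = int(cnt.loc["trait2", "concordant"])
    n_disc = int(cnt.loc["trait2", "discordant"])
    decision = screen_phenotypes(pooled_within, n_conc, n_disc)
    result["screening"] = {
        "within_person_tetrachoric": pooled_within,
        "concordant_pairs": n_conc,
        "discordant_pairs": n_disc,
        "included": bool(decision.include),
        "reasons": decision.reasons,
    }
    if screen and not decision.include:
        return result

    groups = [Kinship(k) for k in pair_data]
    # univariate fits per trait
    for trait, mom in (("exposure", "same1"), ("outcome", "same2")):
        sub = structure.correlations.xs(mom, level="moment")
        corr = {Kinship(k): float(sub.loc[k, "rho"]) for k in pair_data}
        var = {Kinship(k): float(sub.loc[k, "var"]) for k in pair_data}
        if any(not np.isfinite(v) or v <= 0 for v in var.values()):
            var = None
        uni = fit_univariate_ace(corr, var)
        result[f"univariate_{trait}"] = {
            "a2": uni.a2, "c2": uni.c2, "e2": uni.e2,
            "se": uni.se.to_dict(), "objective": uni.objective,
        }

    r, v, _ = structure.moment_vector()
    v = np.where(np.isfinite(v) & (v > 0), v, np.nanmedian(v[np.isfinite(v) & (v > 0)]))
    cov = structure.moment_covariance()
    if cov is not None and not np.all(np.isfinite(cov)):
        cov = None
    fit = fit_bivariate_ace(r, v, groups=tuple(groups), moment_covariance=cov)
    result["bivariate"] = {
        "params": fit.params.to_dict(),
        "se": fit.se.to_dict(),
        "ci": fit.ci.to_dict(orient="index"),
        "derived": fit.derived.to_dict(),
        "derived_se": fit.derived_se.to_dict(),
        "derived_ci": fit.derived_ci.to_dict(orient="index"),
        "objective": fit.objective,
        "fixed_c": fit.fixed_c,
        "converged": fit.converged,
        "multistart_objectives": fit.multistart_objectives,
    }
    result["moments"] = {
        "rho": structure.correlations["rho"].unstack().to_dict(),
        "var": structure.correlations["var"].unstack().to_dict(),
    }
    return result


def run_pipeline(config: RunConfig) -> pathlib.Path:
    """Execute enabled stages; returns the output directory."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = pathlib.Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    pheno_path = config.phenotype_file or default_phenotype_path()
    definitions = load_phenotype_definitions(pheno_path)
    defs = {d.name: d for d in definitions}
    if config.exposure not in defs:
        raise FileNotFoundError(f"exposure phenotype {config.exposure!r} not defined")

    # stage: simulate (or point at an existing registry)
    if config.registry_dir is None:
        sim_cfg = SimulationConfig(**{"seed": config.seed, **config.simulation})
        registry_dir = out / "registry"
        log.info("simulating registry (%d families) -> %s", sim_cfg.n_families, registry_dir)
        simulate_registry(sim_cfg, registry_dir)
        _write_provenance(registry_dir / "provenance.json", config, "simulate")
    else:
        registry_dir = pathlib.Path(config.registry_dir)

    # stage: build cohort + pairs
    tables = read_registry(registry_dir)
    cohort = apply_cohort_exclusions(tables)
    pairs = enumerate_relative_pairs(tables, cohort)
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
    log.info("cohort: %d persons; %d oriented pairs", len(cohort), len(pairs))

    indicators = {}
    for name, d in defs.items():
        asc = ascertain_phenotype(cohort, d, tables["diagnoses"])
        indicators[name] = asc["indicator"].to_numpy(dtype=float)

    exposure = indicators[config.exposure]
    clusters = family_clusters(pairs, ids=cohort["person_id"]).reindex(
        cohort["person_id"]
    ).to_numpy()

    desc = descriptive_table(
        cohort=cohort,
        phenotype_indicators={k: v for k, v in indicators.items() if k != config.exposure},
        bpd_indicator=exposure,
    )
    desc.to_csv(out / "descriptives.tsv", sep="\t", index=False)

    # stage: within-individual + familial co-aggregation ORs
    if config.run_within_individual or config.run_coaggregation:
        rows = []
        for name, d in defs.items():
            if name == config.exposure:
                continue
            if config.run_within_individual:
                fit = within_individual_or(cohort, exposure, indicators[name], d, clusters)
                rows.append(_or_row(name, "within_individual", "", fit, "bpd"))
            if config.run_coaggregation:
                fits = familial_coaggregation_or(
                    pairs, _series(cohort, exposure), _series(cohort, indicators[name]), tables["persons"], d
                )
                for kin, f in fits.items():
                    rows.append(_or_row(name, "coaggregation", kin, f, "exposure"))
        coag = pd.DataFrame(
            rows,
            columns=["phenotype", "analysis", "kinship", "OR", "ci_low", "ci_high",
                     "n", "clusters", "suppressed", "reason"],
        )
        coag.to_csv(out / "coaggregation.tsv", sep="\t", index=False)
        _write_provenance(out / "coaggregation.provenance.json", config, "coaggregate")

    # stage: ACE models for the configured outcome
    if config.run_ace:
        res = ace_analysis(
            tables, cohort, pairs, exposure, indicators[config.outcome], seed=config.seed
        )
        with open(out / "ace.json", "w") as fh:
            json.dump(res, fh, indent=2, default=_jsonify)
        _write_provenance(out / "ace.provenance.json", config, "ace_fit")

    render_tables(out)
    return out


def _series(cohort, values):
    return pd.Series(np.asarray(values, dtype=float), index=cohort["person_id"].to_numpy())


def _or_row(phenotype, analysis, kinship, fit: GeeFit, term: str):
    if fit.suppressed or term not in fit.params.index or not np.isfinite(fit.params[term]):
        return (phenotype, analysis, kinship, np.nan, np.nan, np.nan,
                fit.nobs, fit.n_clusters, True, fit.suppression_reason)
    o, lo, hi = fit.odds_ratio(term)
    return (phenotype, analysis, kinship, o, lo, hi, fit.nobs, fit.n_clusters, False, "")


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    return str(obj)


def _fmt(x, nd=2):
    return "NA" if x is None or not np.isfinite(x) else f"{x:.{nd}f}"


def render_tables(out_dir) -> pathlib.Path:
    """Render the result bundle as a plain-text report (report.md)."""
    out = pathlib.Path(out_dir)
    lines = ["# famliab report", ""]

    desc_path = out / "descriptives.tsv"
    if desc_path.exists():
        desc = pd.read_csv(desc_path, sep="\t")
        lines += ["## Descriptives (counts and % by exposure status)", ""]
        lines.append("| label | group | n without | n with | % without | % with |")
        lines.append("|---|---|---|---|---|---|")
        for _, r in desc.iterrows():
            lines.append(
                f"| {r['label']} | {r['group']} | {int(r['n_without'])} | {int(r['n_with'])} "
                f"| {_fmt(r['pct_without'], 1)} | {_fmt(r['pct_with'], 1)} |"
            )
        lines.append("")

    coag_path = out / "coaggregation.tsv"
    if coag_path.exists():
        coag = pd.read_csv(coag_path, sep="\t")
        lines += ["## Odds ratios (within individuals and relative pairs)", ""]
        lines.append("| phenotype | analysis | kinship | OR (95% CI) | n | clusters |")
        lines.append("|---|---|---|---|---|---|")
        for _, r in coag.iterrows():
            if r["suppressed"]:
                cell = "NA"
            else:
                cell = f"{r['OR']:.2f} ({r['ci_low']:.2f}-{r['ci_high']:.2f})"
            lines.append(
                f"| {r['phenotype']} | {r['analysis']} | {r['kinship'] or ''} "
                f"| {cell} | {int(r['n'])} | {int(r['clusters'])} |"
            )
        lines.append("")

    ace_path = out / "ace.json"
    if ace_path.exists():
        with open(ace_path) as fh:
            ace = json.load(fh)
        lines += ["## ACE decomposition", ""]
        if "bivariate" in ace:
            d = ace["bivariate"]["derived"]
            ci = ace["bivariate"]["derived_ci"]
            lines.append("| quantity | estimate | 95% CI |")
            lines.append("|---|---|---|")
            order = sorted(
                ["bivA", "bivC", "bivE"],
                key=lambda k: -abs(d.get(k) if d.get(k) is not None else 0),
            )
            show = ["r_ph"] + order + ["h2_1", "c2_1", "h2_2", "c2_2"]
            for k in show:
                val = d.get(k)
                c = ci.get(k, {})
                val_s = _fmt(val if val is not None else np.nan)
                lo_ = c.get("low"); hi_ = c.get("high")
                lo_s = _fmt(lo_ if lo_ is not None else np.nan)
                hi_s = _fmt(hi_ if hi_ is not None else np.nan)
                lines.append(f"| {k} | {val_s} | {lo_s} to {hi_s} |")
            rA = ace["bivariate"]["params"].get("rA")
            rA_ci = ace["bivariate"]["ci"].get("rA", {})
            lines.append(
                f"| rA | {_fmt(rA if rA is not None else np.nan)} "
                f"| {_fmt(rA_ci.get('low', np.nan))} to {_fmt(rA_ci.get('high', np.nan))} |"
            )
        elif "screening" in ace:
            lines.append(f"Excluded by screening: {ace['screening']['reasons']}")
        lines.append("")

    report = out / "report.md"
    report.write_text("\n".join(lines))
    return report
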