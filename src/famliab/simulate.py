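"""Synthetic multigenerational registry generator.

Families are simulated so that the latent structure of the binary
diagnoses matches the liability-threshold ACE model assumed by the
downstream estimators: bivariate additive-genetic values are gene-dropped
through the pedigree (founders ~ N(0, R_A), children receive the parental
mean plus segregation noise with covariance R_A/2, MZ co-twins share one
genetic draw), common-environment values are drawn once per household
(all children of the same mother) and unique-environment values per
person.  Binary lifetime diagnoses arise by thresholding the liabilities,
with probit-scale shifts of the threshold for sex and birth year, and the
result is written as register-style delimited tables (persons, parent
links, twin zygosity, diagnosis events).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .params import BivariateAceParams, Kinship, KINSHIP_COEFFICIENTS

__all__ = [
    "SimulationConfig",
    "simulate_pedigrees",
    "simulate_liabilities",
    "simulate_pair_liabilities",
    "threshold_for_prevalence",
    "liabilities_to_registry",
    "write_registry",
    "simulate_registry",
    "pair_liability_covariance",
]

# RNG stage offsets: each pipeline stage gets its own child stream so that
# stages are independently reproducible under one config seed.
_STAGE_PEDIGREE = 1
_STAGE_LIABILITY = 2
_STAGE_REGISTRY = 3


@dataclass
class SimulationConfig:
    """Study-conditions container for the synthetic registry.

    Defaults emulate the register birth cohort the estimators were built
    for: probands born 1973-2001, a rare exposure trait (lifetime
    prevalence 0.9%) strongly skewed towards females, and a common
    comorbid outcome trait.
    """

    n_families: int = 1000
    family_mix: dict = field(
        default_factory=lambda: {
            "full_sib": 0.55,
            "maternal_half_sib": 0.12,
            "paternal_half_sib": 0.12,
            "mz_twin": 0.02,
            "dz_twin": 0.04,
            "cousin": 0.15,
        }
    )
    prevalence: tuple = (0.009, 0.083)  # (exposure trait, outcome trait)
    ace: BivariateAceParams | None = None
    # probit-scale threshold shift added for females per trait; negative
    # lowers the female threshold (raises female prevalence)
    sex_threshold_shift: tuple = (-0.6, 0.0)
    birth_year_range: tuple = (1973, 2001)
    # linear probit drift of the threshold per decade of birth year
    birth_year_drift: tuple = (0.0, 0.0)
    death_rate_per_year: float = 0.0005
    emigration_rate_per_year: float = 0.002
    trait_names: tuple = ("bpd", "depressive_disorder")
    icd9_codes: tuple = (("301D", "301J"), ("311",))
    icd10_codes: tuple = (("F60.3",), ("F32", "F33"))
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.family_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"family_mix proportions must sum to 1, got {total}")
        for p in self.prevalence:
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence targets must lie in (0,1), got {p}")
        if self.ace is None:
            from .params import AceParams

            self.ace = BivariateAceParams(
                AceParams(0.5, 0.05, 0.45), AceParams(0.5, 0.05, 0.45), 0.74, 0.5, 0.2
            )


def _rng(config_seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config_seed), stage]))


def threshold_for_prevalence(p: float) -> float:
    """Liability threshold tau with upper-tail probability ``p``.

    A person is diagnosed iff liability > tau, so P(diagnosis) = 1 - Phi(tau).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"prevalence must lie in (0, 1), got {p}")
    return float(norm.isf(p))


def simulate_pedigrees(config: SimulationConfig):
    """Generate person, parent-link and zygosity tables for synthetic families.

    Each family of the configured mix yields two focal children in the
    proband generation (full sibs, half sibs by re-partnering, MZ/DZ twins,
    or first cousins via two sibling parents), with parent birth years
    placed a generation earlier.  Deterministic given the config seed.
    """
    rng = _rng(config.seed, _STAGE_PEDIGREE)
    y0, y1 = config.birth_year_range

    types = list(config.family_mix)
    probs = np.array([config.family_mix[t] for t in types])
    fam_types = rng.choice(types, size=config.n_families, p=probs)

    persons = []  # (person_id, sex, birth_year, generation, family_id)
    links = []  # (person_id, mother_id, father_id)
    zygosity = []  # (person_id, twin_pair_id, zygosity)
    focal = []  # (family_id, person_id, role)
    next_id = 1

    def new_person(sex, birth_year, gen, fam):
        nonlocal next_id
        pid = next_id
        next_id += 1
        persons.append((pid, sex, int(birth_year), gen, fam))
        return pid

    def child_sex():
        return "female" if rng.random() < 0.5 else "male"

    for fam_id, ftype in enumerate(fam_types):
        parent_by = rng.integers(y0 - 32, y0 - 20)
        cy = rng.integers(y0, y1 + 1, size=2)
        cy.sort()
        if ftype in ("mz_twin", "dz_twin"):
            cy[1] = cy[0]
        if ftype in ("full_sib", "mz_twin", "dz_twin"):
            m = new_person("female", parent_by, 0, fam_id)
            f = new_person("male", parent_by + rng.integers(-3, 4), 0, fam_id)
            c1 = new_person(child_sex(), cy[0], 1, fam_id)
            c2 = new_person(child_sex(), cy[1], 1, fam_id)
            links += [(c1, m, f), (c2, m, f)]
            if ftype in ("mz_twin", "dz_twin"):
                zy = "MZ" if ftype == "mz_twin" else "DZ"
                zygosity += [(c1, fam_id, zy), (c2, fam_id, zy)]
            focal += [(fam_id, c1, ftype), (fam_id, c2, ftype)]
        elif ftype == "maternal_half_sib":
            m = new_person("female", parent_by, 0, fam_id)
            f1 = new_person("male", parent_by + rng.integers(-3, 4), 0, fam_id)
            f2 = new_person("male", parent_by + rng.integers(-3, 4), 0, fam_id)
            c1 = new_person(child_sex(), cy[0], 1, fam_id)
            c2 = new_person(child_sex(), cy[1], 1, fam_id)
            links += [(c1, m, f1), (c2, m, f2)]
            focal += [(fam_id, c1, ftype), (fam_id, c2, ftype)]
        elif ftype == "paternal_half_sib":
            f = new_person("male", parent_by, 0, fam_id)
            m1 = new_person("female", parent_by + rng.integers(-3, 4), 0, fam_id)
            m2 = new_person("female", parent_by + rng.integers(-3, 4), 0, fam_id)
            c1 = new_person(child_sex(), cy[0], 1, fam_id)
            c2 = new_person(child_sex(), cy[1], 1, fam_id)
            links += [(c1, m1, f), (c2, m2, f)]
            focal += [(fam_id, c1, ftype), (fam_id, c2, ftype)]
        elif ftype == "cousin":
            # grandparents -> two full-sib parents -> one child each
            gby = parent_by - rng.integers(20, 33)
            gm = new_person("female", gby, -1, fam_id)
            gf = new_person("male", gby + rng.integers(-3, 4), -1, fam_id)
            p1 = new_person(child_sex(), parent_by, 0, fam_id)
            p2 = new_person(child_sex(), parent_by + rng.integers(1, 5), 0, fam_id)
            links += [(p1, gm, gf), (p2, gm, gf)]
            s1 = new_person("male" if persons[-2][1] == "female" else "female", parent_by, 0, fam_id)
            s2 = new_person("male" if persons[-2][1] == "female" else "female", parent_by, 0, fam_id)
            for par, sp, cyv in ((p1, s1, cy[0]), (p2, s2, cy[1])):
                c = new_person(child_sex(), cyv, 1, fam_id)
                mother, father = (par, sp) if _sex_of(persons, par) == "female" else (sp, par)
                links.append((c, mother, father))
                focal.append((fam_id, c, ftype))
        else:  # pragma: no cover - guarded by config validation
            raise ValueError(f"unknown family type {ftype}")

    person_df = pd.DataFrame(
        persons, columns=["person_id", "sex", "birth_year", "generation", "family_id"]
    )
    link_df = pd.DataFrame(links, columns=["person_id", "mother_id", "father_id"])
    zyg_df = pd.DataFrame(zygosity, columns=["person_id", "twin_pair_id", "zygosity"])
    return person_df, link_df, zyg_df


def _sex_of(persons_list, pid):
    # persons are appended with sequential ids starting at 1
    return persons_list[pid - 1][1]


def simulate_liabilities(
    person_df: pd.DataFrame,
    link_df: pd.DataFrame,
    zyg_df: pd.DataFrame,
    params: BivariateAceParams,
    seed: int,
) -> np.ndarray:
    """Gene-drop bivariate liabilities through the pedigree.

    Returns an (n_persons, 2) array aligned with ``person_df`` rows; each
    trait's marginal liability variance is 1.
    """
    rng = _rng(seed, _STAGE_LIABILITY)
    n = len(person_df)
    idx = {pid: i for i, pid in enumerate(person_df["person_id"].to_numpy())}

    for which in "ACE":
        m = params.factor_correlation_matrix(which)
        if np.linalg.eigvalsh(m).min() < -1e-12:
            raise ValueError(f"factor correlation matrix R_{which} is not PSD")

    def chol(r):
        return np.linalg.cholesky(np.array([[1.0, r], [r, 1.0]]) + 1e-15 * np.eye(2))

    La, Lc, Le = chol(params.rA), chol(params.rC), chol(params.rE)

    mother = np.full(n, -1, dtype=int)
    father = np.full(n, -1, dtype=int)
    for pid, mid, fid in link_df.itertuples(index=False):
        mother[idx[pid]] = idx[mid]
        father[idx[pid]] = idx[fid]

    # MZ co-twin map: second twin copies the first twin's genetic vector
    mz_of = {}
    mz = zyg_df[zyg_df["zygosity"] == "MZ"]
    for _, grp in mz.groupby("twin_pair_id"):
        ids = grp["person_id"].tolist()
        for other in ids[1:]:
            mz_of[idx[other]] = idx[ids[0]]

    # topological order: founders first (generation field is a valid order)
    order = np.argsort(person_df["generation"].to_numpy(), kind="stable")

    A = np.zeros((n, 2))
    founder_noise = rng.standard_normal((n, 2))
    seg_noise = rng.standard_normal((n, 2)) / np.sqrt(2.0)
    for i in order:
        if i in mz_of:
            A[i] = A[mz_of[i]]
        elif mother[i] < 0:
            A[i] = La @ founder_noise[i]
        else:
            A[i] = (A[mother[i]] + A[father[i]]) / 2.0 + La @ seg_noise[i]

    # common environment: one draw per household = all children of one mother;
    # persons with unknown mother get their own draw
    house_key = np.where(mother >= 0, mother, np.arange(n) + n)
    uniq, inv = np.unique(house_key, return_inverse=True)
    C = (Lc @ rng.standard_normal((len(uniq), 2)).T).T[inv]
    E = (Le @ rng.standard_normal((n, 2)).T).T

    t1, t2 = params.trait1, params.trait2
    load_a = np.array([t1.a, t2.a])
    load_c = np.array([t1.c, t2.c])
    load_e = np.array([t1.e, t2.e])
    return A * load_a + C * load_c + E * load_e


def pair_liability_covariance(params: BivariateAceParams, kinship: Kinship) -> np.ndarray:
    """4x4 covariance of (trait1_a, trait2_a, trait1_b, trait2_b) for a pair."""
    co = KINSHIP_COEFFICIENTS[kinship]
    t1, t2 = params.trait1, params.trait2
    r_ph = params.r_ph
    same1 = co.alpha * t1.a2 + co.gamma * t1.c2
    same2 = co.alpha * t2.a2 + co.gamma * t2.c2
    cross = co.alpha * t1.a * t2.a * params.rA + co.gamma * t1.c * t2.c * params.rC
    return np.array(
        [
            [1.0, r_ph, same1, cross],
            [r_ph, 1.0, cross, same2],
            [same1, cross, 1.0, r_ph],
            [cross, same2, r_ph, 1.0],
        ]
    )


def simulate_pair_liabilities(
    params: BivariateAceParams, kinship: Kinship, n_pairs: int, seed: int
) -> np.ndarray:
    """Draw pair liabilities directly from the closed-form 4-variate normal.

    Equivalent in distribution to gene-dropping a two-child pedigree of the
    given kinship (a property verified in the test suite) but much faster
    for large recovery studies.  Returns (n_pairs, 4) columns
    (t1_a, t2_a, t1_b, t2_b).
    """
    cov = pair_liability_covariance(params, kinship)
    w = np.linalg.eigvalsh(cov)
    if w.min() < -1e-10:
        raise ValueError("pair covariance not PSD for these parameters")
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(4))
    kin_id = list(Kinship).index(kinship)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17, kin_id]))
    return rng.standard_normal((n_pairs, 4)) @ L.T


def liabilities_to_registry(
    person_df: pd.DataFrame,
    liabilities: np.ndarray,
    config: SimulationConfig,
):
    """Threshold liabilities into diagnosis events and complete the person table.

    Thresholds are probit-shifted by sex and (linearly) by birth year; the
    event date is uniform within the person's follow-up window, with the
    ICD revision (9 before 1997, 10 after) deciding which configured code
    set the synthetic code is drawn from.  Death and emigration dates are
    sampled from per-year exponential censoring rates.
    """
    rng = _rng(config.seed, _STAGE_REGISTRY)
    n = len(person_df)
    female = (person_df["sex"] == "female").to_numpy()
    by = person_df["birth_year"].to_numpy().astype(float)
    mid_year = float(np.mean(config.birth_year_range))

    follow_start_y = np.maximum(by, 1987.0)
    follow_end_y = np.full(n, 2020.99)

    # censoring: exponential waiting time from age 18 (cohort members must
    # survive to 18 anyway; simpler and sufficient for plumbing)
    death_y = by + 18.0 + rng.exponential(1.0 / max(config.death_rate_per_year, 1e-12), n)
    emig_y = by + 18.0 + rng.exponential(1.0 / max(config.emigration_rate_per_year, 1e-12), n)
    death_y = np.where(death_y < 2021.0, death_y, np.nan)
    emig_y = np.where(emig_y < 2021.0, emig_y, np.nan)

    events = []
    diagnosed = np.zeros((n, 2), dtype=bool)
    for t in range(2):
        shifts = (
            config.sex_threshold_shift[t] * female
            + config.birth_year_drift[t] * (by - mid_year) / 10.0
        )
        # recentre the base threshold so the population-average prevalence
        # hits the target despite the covariate shifts
        target = config.prevalence[t]

        def mean_prev(tau0):
            return float(np.mean(norm.sf(tau0 + shifts))) - target

        from scipy.optimize import brentq

        tau = brentq(mean_prev, -10.0, 10.0, xtol=1e-12)
        diagnosed[:, t] = liabilities[:, t] > tau + shifts

    end_candidates = np.nanmin(
        np.column_stack([follow_end_y, death_y, emig_y]), axis=1
    )
    u = rng.random((n, 2))
    for t in range(2):
        icd9 = config.icd9_codes[t]
        icd10 = config.icd10_codes[t]
        for i in np.nonzero(diagnosed[:, t])[0]:
            lo, hi = follow_start_y[i], end_candidates[i]
            if hi <= lo:
                continue  # censored before any follow-up; no event recorded
            ev_y = lo + u[i, t] * (hi - lo)
            if ev_y < 1997.0:
                rev, codes = 9, icd9
            else:
                rev, codes = 10, icd10
            code = codes[i % len(codes)]
            events.append(
                (
                    int(person_df["person_id"].iloc[i]),
                    rev,
                    code,
                    _year_to_date(ev_y),
                    "inpatient" if (i + t) % 2 else "outpatient",
                )
            )

    diag_df = pd.DataFrame(
        events, columns=["person_id", "icd_revision", "code", "date", "source"]
    )
    out = person_df.copy()
    out["birth_date"] = [
        _year_to_date(y + frac) for y, frac in zip(by, rng.random(n) * 0.999)
    ]
    out["death_date"] = [
        _year_to_date(y) if np.isfinite(y) else "" for y in death_y
    ]
    out["immigration_date"] = ""
    out["emigration_date"] = [
        _year_to_date(y) if np.isfinite(y) else "" for y in emig_y
    ]
    out["malformation_flag"] = 0
    return out, diag_df


def _year_to_date(y: float) -> str:
    year = int(y)
    day_of_year = int((y - year) * 364) + 1
    ts = pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(days=day_of_year - 1)
    return ts.strftime("%Y-%m-%d")


def write_registry(tables: dict, directory) -> None:
    """Write the registry tables as tab-delimited UTF-8 files.

    ``tables`` maps {"persons", "parents", "zygosity", "diagnoses"} to
    DataFrames following the schema read back by ``famliab.registry``.
    """
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = {
        "persons": ["person_id", "sex", "birth_date", "death_date", "immigration_date", "emigration_date", "malformation_flag"],
        "parents": ["person_id", "mother_id", "father_id"],
        "zygosity": ["person_id", "twin_pair_id", "zygosity"],
        "diagnoses": ["person_id", "icd_revision", "code", "date", "source"],
    }
    for key, cols in names.items():
        df = tables[key]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"table {key} missing columns {missing}")
        df[cols].to_csv(directory / f"{key}.tsv", sep="\t", index=False)


def simulate_registry(config: SimulationConfig, directory=None):
    """Full generator run: pedigrees -> liabilities -> registry tables.

    Returns the table dict; writes TSVs when ``directory`` is given.
    """
    person_df, link_df, zyg_df = simulate_pedigrees(config)
    liab = simulate_liabilities(person_df, link_df, zyg_df, config.ace, config.seed)
    completed, diagnoses = liabilities_to_registry(person_df, liab, config)
    tables = {
        "persons": completed,
        "parents": link_df,
        "zygosity": zyg_df,
        "diagnoses": diagnoses,
    }
    if directory is not None:
        write_registry(tables, directory)
    return tables
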