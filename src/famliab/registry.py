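"""Register-style cohort construction, phenotype ascertainment and relative pairs.

Rebuilds the study machinery from delimited register tables: a birth
cohort with exclusions (known mother, no malformation, alive and in the
country at 18), lifetime ICD-coded phenotype indicators with revision-era
matching, follow-up windows, kinship-classified relative pairs with
double entry for within-generation analyses, and the unique
sibling-pair-per-family-cluster selection used by the quantitative
genetic models.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .params import Kinship, KINSHIP_COEFFICIENTS

__all__ = [
    "PhenotypeDefinition",
    "load_phenotype_definitions",
    "RegistryValidationError",
    "read_registry",
    "apply_cohort_exclusions",
    "ascertain_phenotype",
    "compute_follow_up",
    "enumerate_relative_pairs",
    "select_unique_sibling_pairs",
    "family_clusters",
]

FOLLOW_UP_START = pd.Timestamp("1987-01-01")
FOLLOW_UP_END = pd.Timestamp("2020-12-31")
BIRTH_WINDOW = (pd.Timestamp("1973-01-01"), pd.Timestamp("2001-12-31"))
OLDER_GENERATION_CUTOFF = pd.Timestamp("1933-01-01")


class RegistryValidationError(ValueError):
    """Raised when a registry file violates the schema or referential integrity."""


@dataclass(frozen=True)
class PhenotypeDefinition:
    """One binary lifetime phenotype defined by ICD code prefixes per revision."""

    name: str
    domain: str = "psychiatric"  # psychiatric | somatic | behavioral
    icd9: tuple = ()
    icd10: tuple = ()
    female_only: bool = False
    within_generation_only: bool = False
    cause_of_death_source: bool = False

    def __post_init__(self) -> None:
        if not (self.icd9 or self.icd10):
            raise ValueError(f"phenotype {self.name} has no ICD codes")
        if self.domain not in ("psychiatric", "somatic", "behavioral"):
            raise ValueError(f"unknown domain {self.domain}")


def load_phenotype_definitions(path) -> list[PhenotypeDefinition]:
    """Load phenotype definitions from YAML (list of mappings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    defs = []
    for item in raw:
        defs.append(
            PhenotypeDefinition(
                name=item["name"],
                domain=item.get("domain", "psychiatric"),
                icd9=tuple(str(c) for c in item.get("icd9", [])),
                icd10=tuple(str(c) for c in item.get("icd10", [])),
                female_only=bool(item.get("female_only", False)),
                within_generation_only=bool(item.get("within_generation_only", False)),
                cause_of_death_source=bool(item.get("cause_of_death_source", False)),
            )
        )
    return defs


_PERSON_COLS = [
    "person_id",
    "sex",
    "birth_date",
    "death_date",
    "immigration_date",
    "emigration_date",
    "malformation_flag",
]


def _parse_dates(df: pd.DataFrame, cols, table: str) -> pd.DataFrame:
    for c in cols:
        parsed = pd.to_datetime(df[c], format="%Y-%m-%d", errors="coerce")
        bad = df[c].notna() & (df[c].astype(str).str.len() > 0) & parsed.isna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise RegistryValidationError(
                f"{table}: malformed date {df[c].iloc[row]!r} in row {row}"
            )
        df[c] = parsed
    return df


def read_registry(directory) -> dict:
    """Read and validate the four registry tables from ``directory``.

    Checks column presence, ISO date parsing, referential integrity of
    parent links and diagnosis person ids, and date ordering within
    persons.  Returns {"persons", "parents", "zygosity", "diagnoses"}.
    """
    directory = pathlib.Path(directory)
    tables = {}
    expected = {
        "persons": _PERSON_COLS,
        "parents": ["person_id", "mother_id", "father_id"],
        "zygosity": ["person_id", "twin_pair_id", "zygosity"],
        "diagnoses": ["person_id", "icd_revision", "code", "date", "source"],
    }
    for name, cols in expected.items():
        path = directory / f"{name}.tsv"
        if not path.exists():
            raise RegistryValidationError(f"missing registry file {path}")
        df = pd.read_csv(path, sep="\t", dtype={"code": str})
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise RegistryValidationError(f"{name}.tsv missing columns {missing}")
        tables[name] = df

    persons = _parse_dates(
        tables["persons"],
        ["birth_date", "death_date", "immigration_date", "emigration_date"],
        "persons",
    )
    tables["diagnoses"] = _parse_dates(tables["diagnoses"], ["date"], "diagnoses")

    ids = set(persons["person_id"])
    for col in ("mother_id", "father_id"):
        dangling = ~tables["parents"][col].isin(ids)
        if dangling.any():
            bad = tables["parents"].loc[dangling, col].iloc[0]
            raise RegistryValidationError(f"parents.tsv: dangling {col} {bad}")
    dangling = ~tables["diagnoses"]["person_id"].isin(ids)
    if dangling.any():
        bad = tables["diagnoses"].loc[dangling, "person_id"].iloc[0]
        raise RegistryValidationError(f"diagnoses.tsv: unknown person_id {bad}")

    for c in ("death_date", "emigration_date"):
        bad = persons[c].notna() & (persons[c] < persons["birth_date"])
        if bad.any():
            pid = persons.loc[bad, "person_id"].iloc[0]
            raise RegistryValidationError(f"persons.tsv: {c} before birth for {pid}")
    return tables


def apply_cohort_exclusions(
    tables: dict, birth_window=BIRTH_WINDOW
) -> pd.DataFrame:
    """Proband cohort: born in the window, known mother, no malformation,
    and neither death nor first emigration before the 18th birthday."""
    persons = tables["persons"]
    parents = tables["parents"]
    has_mother = persons["person_id"].isin(parents["person_id"])
    in_window = persons["birth_date"].between(birth_window[0], birth_window[1])
    no_malformation = persons["malformation_flag"].fillna(0).astype(int) == 0
    age18 = persons["birth_date"] + pd.DateOffset(years=18)
    died_young = persons["death_date"].notna() & (persons["death_date"] < age18)
    left_young = persons["emigration_date"].notna() & (
        persons["emigration_date"] < age18
    )
    keep = in_window & has_mother & no_malformation & ~died_young & ~left_young
    return persons[keep].reset_index(drop=True)


def _code_matches(codes: pd.Series, prefixes: tuple) -> pd.Series:
    if not prefixes:
        return pd.Series(False, index=codes.index)
    norm = codes.astype(str).str.replace(".", "", regex=False).str.upper()
    out = pd.Series(False, index=codes.index)
    for p in prefixes:
        out |= norm.str.startswith(str(p).replace(".", "").upper())
    return out


def ascertain_phenotype(
    persons: pd.DataFrame,
    definition: PhenotypeDefinition,
    diagnoses: pd.DataFrame,
) -> pd.DataFrame:
    """Lifetime indicator and first matching diagnosis date per person.

    A diagnosis matches when its code starts with one of the definition's
    prefixes for the event's ICD revision era (revision 9 for events up to
    1996, revision 10 from 1997).  Phenotypes sourced from the cause-of-
    death register match only rows with source ``cause_of_death``.
    Returns a frame indexed like ``persons`` with columns
    ``indicator`` (0/1) and ``first_date``.
    """
    d = diagnoses
    era9 = (d["icd_revision"] == 9) & (d["date"] < pd.Timestamp("1997-01-01"))
    era10 = (d["icd_revision"] == 10) & (d["date"] >= pd.Timestamp("1997-01-01"))
    match = (era9 & _code_matches(d["code"], definition.icd9)) | (
        era10 & _code_matches(d["code"], definition.icd10)
    )
    if definition.cause_of_death_source:
        match &= d["source"] == "cause_of_death"
    else:
        match &= d["source"].isin(("inpatient", "outpatient"))
    hits = d[match]
    first = hits.groupby("person_id")["date"].min()
    out = pd.DataFrame(index=persons.index)
    out["person_id"] = persons["person_id"].to_numpy()
    out["first_date"] = out["person_id"].map(first)
    out["indicator"] = out["first_date"].notna().astype(int)
    if definition.female_only:
        male = (persons["sex"] != "female").to_numpy()
        out.loc[male, "indicator"] = np.nan  # not ascertainable, excluded downstream
        out.loc[male, "first_date"] = pd.NaT
    return out[["person_id", "indicator", "first_date"]]


def compute_follow_up(
    persons: pd.DataFrame,
    ascertained: pd.DataFrame,
) -> pd.DataFrame:
    """Follow-up windows [start, end] per person for one phenotype.

    start = max(birth, first immigration, 1987-01-01); end = min(first
    emigration, first matching diagnosis, death, 2020-12-31), event = 1
    iff the diagnosis is the earliest terminator.  Persons whose window is
    degenerate (start > end) are flagged and should be dropped from that
    phenotype's analysis.
    """
    start = persons["birth_date"].copy()
    start = start.where(start >= FOLLOW_UP_START, FOLLOW_UP_START)
    imm = persons["immigration_date"]
    start = start.where(~(imm.notna() & (imm > start)), imm)

    ends = pd.concat(
        [
            persons["emigration_date"],
            ascertained["first_date"].set_axis(persons.index),
            persons["death_date"],
            pd.Series(FOLLOW_UP_END, index=persons.index),
        ],
        axis=1,
    )
    end = ends.min(axis=1)
    event = (
        ascertained["first_date"].set_axis(persons.index).notna()
        & (ascertained["first_date"].set_axis(persons.index) <= end)
    ).astype(int)
    degenerate = start > end
    return pd.DataFrame(
        {
            "person_id": persons["person_id"].to_numpy(),
            "start": start.to_numpy(),
            "end": end.to_numpy(),
            "event": event.to_numpy(),
            "degenerate": degenerate.to_numpy(),
        }
    )


def _sibling_frames(parents: pd.DataFrame) -> pd.DataFrame:
    """All sibling pairs (id_a < id_b) classified full/maternal/paternal."""
    p = parents
    merged = p.merge(p, how="inner", on="mother_id", suffixes=("_a", "_b"))
    mat = merged[merged["person_id_a"] < merged["person_id_b"]][
        ["person_id_a", "person_id_b", "father_id_a", "father_id_b"]
    ]
    same_father = mat["father_id_a"] == mat["father_id_b"]
    full = mat[same_father][["person_id_a", "person_id_b"]].assign(kind="full")
    mhalf = mat[~same_father][["person_id_a", "person_id_b"]].assign(kind="maternal_half")

    merged_f = p.merge(p, how="inner", on="father_id", suffixes=("_a", "_b"))
    pat = merged_f[merged_f["person_id_a"] < merged_f["person_id_b"]][
        ["person_id_a", "person_id_b", "mother_id_a", "mother_id_b"]
    ]
    phalf = pat[pat["mother_id_a"] != pat["mother_id_b"]][
        ["person_id_a", "person_id_b"]
    ].assign(kind="paternal_half")
    return pd.concat([full, mhalf, phalf], ignore_index=True)


def enumerate_relative_pairs(
    tables: dict, cohort: pd.DataFrame
) -> pd.DataFrame:
    """Classify relative pairs from parent links and the zygosity table.

    Within-generation pairs (twins, full/half siblings, first cousins;
    both members in the proband cohort) are emitted in both orientations
    (double entry).  Between-generation pairs (parent-child, aunt/uncle)
    are emitted once with the older relative as ``id_a`` (the exposure
    side), restricted to older relatives born on/after 1933.  Twin pairs
    with unknown zygosity are kept as full siblings but appear in neither
    the MZ nor the DZ set.

    Returns columns id_a, id_b, kinship, alpha, gamma, generation_relation.
    """
    parents = tables["parents"]
    persons = tables["persons"]
    zyg = tables["zygosity"]
    cohort_ids = set(cohort["person_id"])
    birth = persons.set_index("person_id")["birth_date"]

    # cycle check: a person may not be its own ancestor
    g = nx.DiGraph()
    for pid, mid, fid in parents[["person_id", "mother_id", "father_id"]].itertuples(index=False):
        g.add_edge(mid, pid)
        g.add_edge(fid, pid)
    if not nx.is_directed_acyclic_graph(g):
        raise RegistryValidationError("parent links contain a cycle")

    sibs = _sibling_frames(parents)
    twin_pair_of = dict(zip(zyg["person_id"], zyg["twin_pair_id"]))
    zygosity_of = dict(zip(zyg["person_id"], zyg["zygosity"]))

    rows = []

    def add_within(a, b, kin: Kinship):
        if a in cohort_ids and b in cohort_ids:
            co = KINSHIP_COEFFICIENTS[kin]
            rows.append((a, b, kin.value, co.alpha, co.gamma, "within"))
            rows.append((b, a, kin.value, co.alpha, co.gamma, "within"))

    for a, b, kind in sibs.itertuples(index=False):
        if kind == "full":
            za = twin_pair_of.get(a)
            zb = twin_pair_of.get(b)
            if za is not None and zb is not None and za == zb:
                zy = zygosity_of.get(a)
                if zy == "MZ":
                    add_within(a, b, Kinship.MZ_TWIN)
                elif zy == "DZ":
                    add_within(a, b, Kinship.DZ_TWIN)
                # unknown zygosity twins: excluded from twin sets, but they
                # remain eligible as full siblings below
            add_within(a, b, Kinship.FULL_SIB)
        elif kind == "maternal_half":
            add_within(a, b, Kinship.MATERNAL_HALF_SIB)
        else:
            add_within(a, b, Kinship.PATERNAL_HALF_SIB)

    # parent-child and aunt/uncle (between generation, emitted once,
    # older relative first, born >= 1933)
    child_of = parents.set_index("person_id")[["mother_id", "father_id"]]
    sib_lookup: dict[int, list[int]] = {}
    full_sibs = sibs[sibs["kind"] == "full"]
    for a, b, _ in full_sibs.itertuples(index=False):
        sib_lookup.setdefault(a, []).append(b)
        sib_lookup.setdefault(b, []).append(a)

    def add_between(older, younger, kin: Kinship):
        if younger not in cohort_ids:
            return
        bd = birth.get(older)
        if bd is None or pd.isna(bd) or bd < OLDER_GENERATION_CUTOFF:
            return
        co = KINSHIP_COEFFICIENTS[kin]
        rows.append((older, younger, kin.value, co.alpha, co.gamma, "between"))

    for child, mid, fid in parents[["person_id", "mother_id", "father_id"]].itertuples(index=False):
        add_between(mid, child, Kinship.PARENT_CHILD)
        add_between(fid, child, Kinship.PARENT_CHILD)
        for parent in (mid, fid):
            for au in sib_lookup.get(parent, []):
                add_between(au, child, Kinship.AUNT_UNCLE)

    # first cousins: children of full-sib parents, within generation
    children_of = parents.groupby("mother_id")["person_id"].apply(list).to_dict()
    children_of_f = parents.groupby("father_id")["person_id"].apply(list).to_dict()

    def kids(pid):
        return sorted(set(children_of.get(pid, []) + children_of_f.get(pid, [])))

    seen = set()
    for a, b, _ in full_sibs.itertuples(index=False):
        for ca in kids(a):
            for cb in kids(b):
                if ca == cb:
                    continue
                key = (min(ca, cb), max(ca, cb))
                if key in seen:
                    continue
                seen.add(key)
                add_within(key[0], key[1], Kinship.COUSIN)

    return pd.DataFrame(
        rows,
        columns=["id_a", "id_b", "kinship", "alpha", "gamma", "generation_relation"],
    )


def family_clusters(pairs: pd.DataFrame, ids=None) -> pd.Series:
    """Connected components over full- and half-sibling edges.

    Returns a Series mapping person_id -> cluster id.  ``ids`` optionally
    adds isolated persons so singletons get their own cluster.
    """
    sib_kin = {
        Kinship.FULL_SIB.value,
        Kinship.MATERNAL_HALF_SIB.value,
        Kinship.PATERNAL_HALF_SIB.value,
        Kinship.MZ_TWIN.value,
        Kinship.DZ_TWIN.value,
    }
    g = nx.Graph()
    sub = pairs[pairs["kinship"].isin(sib_kin)]
    g.add_edges_from(zip(sub["id_a"], sub["id_b"]))
    if ids is not None:
        g.add_nodes_from(ids)
    mapping = {}
    for cid, comp in enumerate(sorted(nx.connected_components(g), key=min)):
        for pid in comp:
            mapping[pid] = cid
    return pd.Series(mapping, name="cluster")


def extended_family_clusters(pairs: pd.DataFrame, ids=None) -> pd.Series:
    """Connected components over *all* relative-pair edges (for GEE clustering)."""
    g = nx.Graph()
    g.add_edges_from(zip(pairs["id_a"], pairs["id_b"]))
    if ids is not None:
        g.add_nodes_from(ids)
    mapping = {}
    for cid, comp in enumerate(sorted(nx.connected_components(g), key=min)):
        for pid in comp:
            mapping[pid] = cid
    return pd.Series(mapping, name="cluster")


_SEM_KINSHIPS = (
    Kinship.FULL_SIB.value,
    Kinship.MATERNAL_HALF_SIB.value,
    Kinship.PATERNAL_HALF_SIB.value,
)


def select_unique_sibling_pairs(
    pairs: pd.DataFrame, persons: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """One pair per sibling kinship type per independent family cluster.

    Selection within a cluster and type: (1) the pair closest in age,
    (2) among ties the pair whose older member is born earliest,
    (3) remaining ties broken by a seeded uniform draw.  Deterministic
    given the seed.
    """
    birth = persons.set_index("person_id")["birth_date"]
    sub = pairs[
        pairs["kinship"].isin(_SEM_KINSHIPS) & (pairs["id_a"] < pairs["id_b"])
    ].copy()
    if sub.empty:
        return sub.assign(cluster=pd.Series(dtype=int))
    clusters = family_clusters(pairs)
    sub["cluster"] = sub["id_a"].map(clusters)
    ba = sub["id_a"].map(birth)
    bb = sub["id_b"].map(birth)
    sub["age_gap_days"] = (ba - bb).abs().dt.days
    sub["older_birth"] = pd.concat([ba, bb], axis=1).min(axis=1)
    rng = np.random.default_rng(seed)
    sub["tie_break"] = rng.random(len(sub))
    sub = sub.sort_values(
        ["cluster", "kinship", "age_gap_days", "older_birth", "tie_break"],
        kind="stable",
    )
    selected = sub.groupby(["cluster", "kinship"], as_index=False).head(1)
    return selected.drop(columns=["tie_break"]).reset_index(drop=True)
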