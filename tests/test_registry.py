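"""Cohort construction, ascertainment, follow-up and relative-pair machinery."""

import numpy as np
import pandas as pd
import pytest

from famliab.registry import (
    PhenotypeDefinition,
    RegistryValidationError,
    apply_cohort_exclusions,
    ascertain_phenotype,
    compute_follow_up,
    enumerate_relative_pairs,
    read_registry,
    select_unique_sibling_pairs,
)

BPD = PhenotypeDefinition("bpd", "psychiatric", icd9=("301D", "301J"), icd10=("F60.3",))


def _persons(rows):
    df = pd.DataFrame(
        rows,
        columns=["person_id", "sex", "birth_date", "death_date",
                 "immigration_date", "emigration_date", "malformation_flag"],
    )
    for c in ("birth_date", "death_date", "immigration_date", "emigration_date"):
        df[c] = pd.to_datetime(df[c])
    return df


def _diag(rows):
    df = pd.DataFrame(rows, columns=["person_id", "icd_revision", "code", "date", "source"])
    df["date"] = pd.to_datetime(df["date"])
    return df


class TestReadRegistry:
    def test_simulator_output_parses(self, small_registry):
        directory, _, _ = small_registry
        tables = read_registry(directory)
        assert set(tables) == {"persons", "parents", "zygosity", "diagnoses"}

    def test_unknown_person_in_diagnoses_rejected(self, small_registry, tmp_path):
        directory, tables, _ = small_registry
        import shutil

        for f in directory.iterdir():
            shutil.copy(f, tmp_path / f.name)
        with open(tmp_path / "diagnoses.tsv", "a") as fh:
            fh.write("99999999\t10\tF60.3\t2001-01-01\tinpatient\n")
        with pytest.raises(RegistryValidationError, match="unknown person_id"):
            read_registry(tmp_path)

    def test_malformed_date_rejected(self, small_registry, tmp_path):
        directory, _, _ = small_registry
        import shutil

        for f in directory.iterdir():
            shutil.copy(f, tmp_path / f.name)
        text = (tmp_path / "diagnoses.tsv").read_text().splitlines()
        parts = text[1].split("\t")
        parts[3] = "1987-13-01"
        text[1] = "\t".join(parts)
        (tmp_path / "diagnoses.tsv").write_text("\n".join(text) + "\n")
        with pytest.raises(RegistryValidationError, match="malformed date"):
            read_registry(tmp_path)


class TestCohortExclusions:
    def _tables(self, persons):
        parents = pd.DataFrame(
            {"person_id": persons["person_id"], "mother_id": 900, "father_id": 901}
        )
        base = _persons(
            [
                (900, "female", "1950-01-01", None, None, None, 0),
                (901, "male", "1950-01-01", None, None, None, 0),
            ]
        )
        return {"persons": pd.concat([persons, base], ignore_index=True), "parents": parents}

    def test_death_before_18_excluded(self):
        persons = _persons(
            [
                (1, "female", "1980-06-01", "1998-05-31", None, None, 0),  # 17.99y
                (2, "female", "1980-06-01", "1998-06-02", None, None, 0),  # past 18th bday
            ]
        )
        cohort = apply_cohort_exclusions(self._tables(persons))
        assert cohort["person_id"].tolist() == [2]

    def test_emigration_then_return_retained(self):
        persons = _persons(
            [(1, "male", "1980-01-01", None, None, "2000-01-01", 0)]  # left at 20
        )
        cohort = apply_cohort_exclusions(self._tables(persons))
        assert cohort["person_id"].tolist() == [1]

    def test_malformation_excluded(self):
        persons = _persons([(1, "male", "1980-01-01", None, None, None, 1)])
        assert apply_cohort_exclusions(self._tables(persons)).empty

    def test_birth_window_enforced(self):
        persons = _persons(
            [
                (1, "male", "1972-12-31", None, None, None, 0),
                (2, "male", "1973-01-01", None, None, None, 0),
                (3, "male", "2001-12-31", None, None, None, 0),
                (4, "male", "2002-01-01", None, None, None, 0),
            ]
        )
        cohort = apply_cohort_exclusions(self._tables(persons))
        assert cohort["person_id"].tolist() == [2, 3]


class TestAscertainment:
    def test_icd10_era_event_detected(self):
        persons = _persons([(1, "female", "1980-01-01", None, None, None, 0)])
        diag = _diag([(1, 10, "F60.3", "1999-05-01", "outpatient")])
        out = ascertain_phenotype(persons, BPD, diag)
        assert out["indicator"].tolist() == [1]

    def test_icd9_era_event_detected(self):
        persons = _persons([(1, "female", "1975-01-01", None, None, None, 0)])
        diag = _diag([(1, 9, "301D", "1995-03-01", "inpatient")])
        out = ascertain_phenotype(persons, BPD, diag)
        assert out["indicator"].tolist() == [1]

    def test_wrong_era_code_ignored(self):
        persons = _persons([(1, "female", "1975-01-01", None, None, None, 0)])
        # ICD-9 code recorded in the ICD-10 era does not match
        diag = _diag([(1, 9, "301D", "1999-03-01", "inpatient")])
        out = ascertain_phenotype(persons, BPD, diag)
        assert out["indicator"].tolist() == [0]

    def test_suicide_requires_cause_of_death_source(self):
        suicide = PhenotypeDefinition(
            "suicide", "behavioral", icd10=("X6",), cause_of_death_source=True
        )
        persons = _persons([(1, "male", "1975-01-01", "2005-01-01", None, None, 0)])
        inpatient = _diag([(1, 10, "X60", "2004-12-01", "inpatient")])
        cod = _diag([(1, 10, "X60", "2005-01-01", "cause_of_death")])
        assert ascertain_phenotype(persons, suicide, inpatient)["indicator"].tolist() == [0]
        assert ascertain_phenotype(persons, suicide, cod)["indicator"].tolist() == [1]

    def test_female_only_blanks_males(self):
        pcos = PhenotypeDefinition("pcos", "somatic", icd10=("E28.2",), female_only=True)
        persons = _persons(
            [
                (1, "male", "1980-01-01", None, None, None, 0),
                (2, "female", "1980-01-01", None, None, None, 0),
            ]
        )
        diag = _diag([(2, 10, "E28.2", "2005-01-01", "outpatient")])
        out = ascertain_phenotype(persons, pcos, diag)
        assert np.isnan(out["indicator"].iloc[0])
        assert out["indicator"].iloc[1] == 1

    def test_idempotent(self):
        persons = _persons([(1, "female", "1980-01-01", None, None, None, 0)])
        diag = _diag([(1, 10, "F60.3", "1999-05-01", "outpatient")])
        a = ascertain_phenotype(persons, BPD, diag)
        b = ascertain_phenotype(persons, BPD, diag)
        pd.testing.assert_frame_equal(a, b)


class TestFollowUp:
    def test_default_window(self):
        persons = _persons([(1, "male", "1980-06-01", None, None, None, 0)])
        asc = pd.DataFrame({"person_id": [1], "indicator": [0], "first_date": [pd.NaT]})
        w = compute_follow_up(persons, asc)
        assert w["start"].iloc[0] == pd.Timestamp("1987-01-01")
        assert w["end"].iloc[0] == pd.Timestamp("2020-12-31")
        assert w["event"].iloc[0] == 0

    def test_diagnosis_terminates_with_event(self):
        persons = _persons([(1, "male", "1990-01-01", None, None, None, 0)])
        asc = pd.DataFrame(
            {"person_id": [1], "indicator": [1], "first_date": [pd.Timestamp("2005-03-02")]}
        )
        w = compute_follow_up(persons, asc)
        assert w["end"].iloc[0] == pd.Timestamp("2005-03-02")
        assert w["event"].iloc[0] == 1

    def test_emigration_before_diagnosis_censors(self):
        persons = _persons([(1, "male", "1990-01-01", None, None, "2004-06-01", 0)])
        asc = pd.DataFrame(
            {"person_id": [1], "indicator": [1], "first_date": [pd.Timestamp("2005-03-02")]}
        )
        w = compute_follow_up(persons, asc)
        assert w["end"].iloc[0] == pd.Timestamp("2004-06-01")
        assert w["event"].iloc[0] == 0

    def test_windows_never_pass_administrative_end(self, small_registry):
        directory, tables, _ = small_registry
        from famliab.registry import read_registry as rr

        t = rr(directory)
        cohort = apply_cohort_exclusions(t)
        asc = ascertain_phenotype(cohort, BPD, t["diagnoses"])
        w = compute_follow_up(cohort, asc)
        ok = ~w["degenerate"]
        assert (w.loc[ok, "end"] <= pd.Timestamp("2020-12-31")).all()
        assert (w.loc[ok, "start"] <= w.loc[ok, "end"]).all()


def _pair_tables(persons, parents, zygosity=None):
    zyg = zygosity if zygosity is not None else pd.DataFrame(
        columns=["person_id", "twin_pair_id", "zygosity"]
    )
    return {"persons": persons, "parents": parents, "zygosity": zyg}


class TestRelativePairs:
    def test_paternal_half_sibs_double_entered(self):
        persons = _persons(
            [
                (1, "male", "1980-01-01", None, None, None, 0),
                (2, "female", "1982-01-01", None, None, None, 0),
                (10, "female", "1950-01-01", None, None, None, 0),
                (11, "female", "1951-01-01", None, None, None, 0),
                (12, "male", "1950-01-01", None, None, None, 0),
            ]
        )
        parents = pd.DataFrame(
            {"person_id": [1, 2], "mother_id": [10, 11], "father_id": [12, 12]}
        )
        tables = _pair_tables(persons, parents)
        cohort = persons[persons["person_id"].isin([1, 2])]
        pairs = enumerate_relative_pairs(tables, cohort)
        phs = pairs[pairs["kinship"] == "paternal_half_sib"]
        assert len(phs) == 2  # both orientations
        assert set(map(tuple, phs[["id_a", "id_b"]].to_numpy())) == {(1, 2), (2, 1)}
        assert (phs["alpha"] == 0.25).all() and (phs["gamma"] == 0.0).all()

    def test_parent_born_before_1933_excluded(self):
        persons = _persons(
            [
                (1, "male", "1980-01-01", None, None, None, 0),
                (10, "female", "1930-01-01", None, None, None, 0),
                (11, "male", "1940-01-01", None, None, None, 0),
            ]
        )
        parents = pd.DataFrame({"person_id": [1], "mother_id": [10], "father_id": [11]})
        cohort = persons[persons["person_id"] == 1]
        pairs = enumerate_relative_pairs(_pair_tables(persons, parents), cohort)
        pc = pairs[pairs["kinship"] == "parent_child"]
        assert pc["id_a"].tolist() == [11]  # only the 1940 father
        assert (pc["generation_relation"] == "between").all()

    def test_unknown_zygosity_twins_absent_from_twin_sets(self):
        persons = _persons(
            [
                (1, "male", "1980-01-01", None, None, None, 0),
                (2, "male", "1980-01-01", None, None, None, 0),
                (10, "female", "1950-01-01", None, None, None, 0),
                (11, "male", "1950-01-01", None, None, None, 0),
            ]
        )
        parents = pd.DataFrame(
            {"person_id": [1, 2], "mother_id": [10, 10], "father_id": [11, 11]}
        )
        zyg = pd.DataFrame(
            {"person_id": [1, 2], "twin_pair_id": [1, 1], "zygosity": ["UN", "UN"]}
        )
        cohort = persons[persons["person_id"].isin([1, 2])]
        pairs = enumerate_relative_pairs(_pair_tables(persons, parents, zyg), cohort)
        assert not (pairs["kinship"].isin(["MZ_twin", "DZ_twin"])).any()
        assert (pairs["kinship"] == "full_sib").sum() == 2  # still full sibs

    def test_double_entry_count_invariant(self, small_registry):
        directory, _, _ = small_registry
        t = read_registry(directory)
        cohort = apply_cohort_exclusions(t)
        pairs = enumerate_relative_pairs(t, cohort)
        within = pairs[pairs["generation_relation"] == "within"]
        # each unordered within-generation pair appears exactly twice
        key = within.apply(
            lambda r: (min(r.id_a, r.id_b), max(r.id_a, r.id_b), r.kinship), axis=1
        )
        assert (key.value_counts() == 2).all()

    def test_kinship_matches_generating_structure(self, small_registry):
        directory, _, cfg = small_registry
        t = read_registry(directory)
        cohort = apply_cohort_exclusions(t)
        pairs = enumerate_relative_pairs(t, cohort)
        # reconstruct truth from parent links directly
        par = t["parents"].set_index("person_id")
        sub = pairs[pairs["kinship"].isin(["full_sib", "maternal_half_sib", "paternal_half_sib"])]
        for row in sub.itertuples(index=False):
            ma, fa = par.loc[row.id_a, ["mother_id", "father_id"]]
            mb, fb = par.loc[row.id_b, ["mother_id", "father_id"]]
            if row.kinship == "full_sib":
                assert ma == mb and fa == fb
            elif row.kinship == "maternal_half_sib":
                assert ma == mb and fa != fb
            else:
                assert ma != mb and fa == fb

    def test_cycle_detection(self):
        persons = _persons(
            [
                (1, "male", "1980-01-01", None, None, None, 0),
                (2, "female", "1981-01-01", None, None, None, 0),
            ]
        )
        parents = pd.DataFrame(
            {"person_id": [1, 2], "mother_id": [2, 1], "father_id": [2, 1]}
        )
        with pytest.raises(RegistryValidationError, match="cycle"):
            enumerate_relative_pairs(_pair_tables(persons, parents), persons)


class TestSiblingPairSelection:
    def _sib_setup(self, birth_years):
        rows = [(i + 1, "male", f"{y}-01-01", None, None, None, 0) for i, y in enumerate(birth_years)]
        rows += [(90, "female", "1950-01-01", None, None, None, 0),
                 (91, "male", "1950-01-01", None, None, None, 0)]
        persons = _persons(rows)
        n = len(birth_years)
        parents = pd.DataFrame(
            {"person_id": range(1, n + 1), "mother_id": 90, "father_id": 91}
        )
        tables = _pair_tables(persons, parents)
        cohort = persons[persons["person_id"] <= n]
        pairs = enumerate_relative_pairs(tables, cohort)
        return persons, pairs

    def test_closest_in_age_wins(self):
        persons, pairs = self._sib_setup([1980, 1983, 1984])
        sel = select_unique_sibling_pairs(pairs, persons, seed=0)
        assert len(sel) == 1
        assert {sel["id_a"].iloc[0], sel["id_b"].iloc[0]} == {2, 3}  # 1983 & 1984

    def test_oldest_breaks_gap_ties(self):
        # equal 4-year gaps (each spanning exactly one leap day): the pair
        # whose older member is born earliest wins
        persons, pairs = self._sib_setup_dates(["1980-06-01", "1984-06-01", "1988-06-01"])
        sel = select_unique_sibling_pairs(pairs, persons, seed=0)
        assert {sel["id_a"].iloc[0], sel["id_b"].iloc[0]} == {1, 2}

    def _sib_setup_dates(self, dates):
        rows = [(i + 1, "male", d, None, None, None, 0) for i, d in enumerate(dates)]
        rows += [(90, "female", "1950-01-01", None, None, None, 0),
                 (91, "male", "1950-01-01", None, None, None, 0)]
        persons = _persons(rows)
        n = len(dates)
        parents = pd.DataFrame(
            {"person_id": range(1, n + 1), "mother_id": 90, "father_id": 91}
        )
        cohort = persons[persons["person_id"] <= n]
        pairs = enumerate_relative_pairs(_pair_tables(persons, parents), cohort)
        return persons, pairs

    def test_single_child_cluster_yields_nothing(self):
        persons, pairs = self._sib_setup([1980])
        sel = select_unique_sibling_pairs(pairs, persons, seed=0)
        assert sel.empty

    def test_at_most_one_pair_per_type_per_cluster(self, small_registry):
        directory, _, _ = small_registry
        t = read_registry(directory)
        cohort = apply_cohort_exclusions(t)
        pairs = enumerate_relative_pairs(t, cohort)
        sel = select_unique_sibling_pairs(pairs, t["persons"], seed=1)
        assert sel.groupby(["cluster", "kinship"]).size().max() == 1

    def test_selection_deterministic(self, small_registry):
        directory, _, _ = small_registry
        t = read_registry(directory)
        cohort = apply_cohort_exclusions(t)
        pairs = enumerate_relative_pairs(t, cohort)
        a = select_unique_sibling_pairs(pairs, t["persons"], seed=5)
        b = select_unique_sibling_pairs(pairs, t["persons"], seed=5)
        pd.testing.assert_frame_equal(a, b)
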