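"""Rebuild the birth cohort and relative pairs from the synthetic registry.

Applies the cohort rules (born 1973-2001 with a known mother, no
congenital malformation, alive and in-country at 18), classifies every
relative pair from the parent links and zygosity table, and reports the
pair counts per kinship the way a register study would.
"""

import pathlib
import sys

from famliab.registry import (
    apply_cohort_exclusions,
    enumerate_relative_pairs,
    read_registry,
    select_unique_sibling_pairs,
)

OUT = pathlib.Path("results")


def main(registry: str = "results/registry") -> None:
    tables = read_registry(registry)
    cohort = apply_cohort_exclusions(tables)
    pairs = enumerate_relative_pairs(tables, cohort)
    selected = select_unique_sibling_pairs(pairs, tables["persons"], seed=1)

    cohort.to_csv(OUT / "cohort.tsv", sep="\t", index=False)
    pairs.to_csv(OUT / "pairs.tsv", sep="\t", index=False)
    selected.to_csv(OUT / "sem_pairs.tsv", sep="\t", index=False)

    print(f"cohort: {len(cohort)} of {len(tables['persons'])} persons retained")
    within = pairs[pairs["generation_relation"] == "within"]
    print("unique within-generation pairs (double-entered / 2):")
    print((within.groupby("kinship").size() // 2).to_string())
    print("between-generation pairs:")
    print(
        pairs[pairs["generation_relation"] == "between"].groupby("kinship").size().to_string()
    )
    print(f"unique SEM sibling pairs selected: {len(selected)}")
    print(selected.groupby("kinship").size().to_string())


if __name__ == "__main__":
    main(sys.argv[1] if len(sys.argv) > 1 else "results/registry")
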