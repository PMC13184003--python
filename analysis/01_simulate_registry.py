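"""Generate the synthetic registries used by the downstream analyses.

Two designs are written under results/:

* ``registry/`` — register-emulating conditions: exposure-trait lifetime
  prevalence 0.9% skewed towards females, a common comorbid outcome
  (8.3%), sibling/half-sibling/twin/cousin family mix, 20,000 families.
* ``registry_scaled/`` — a desk-scale quantitative-genetics design with
  common traits (5% / 8.3%) so the sibling 2x2 tables that feed the SEM
  stay informative at this family count.
"""

import pathlib
import sys

from famliab.simulate import SimulationConfig, simulate_registry

OUT = pathlib.Path("results")


def main(seed: int = 1) -> None:
    for name, kwargs in (
        ("registry", {"n_families": 20_000}),
        ("registry_scaled", {"n_families": 8_000, "prevalence": (0.05, 0.083)}),
    ):
        cfg = SimulationConfig(seed=seed, **kwargs)
        tables = simulate_registry(cfg, OUT / name)
        n_cases = tables["diagnoses"]["person_id"].nunique()
        print(
            f"{name}: {len(tables['persons'])} persons, "
            f"{len(tables['diagnoses'])} diagnosis events ({n_cases} diagnosed persons) "
            f"-> {OUT / name}"
        )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
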