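"""Liability ACE models on the scaled synthetic registry.

Runs the quantitative-genetic stage end to end: unique sibling-pair
selection, covariate-adjusted probit thresholds, tetrachoric moment
structure per kinship group, the screening rule, and the univariate and
bivariate (correlated-factors) WLS fits with Wald CIs.
"""

import json
import pathlib
import sys

from famliab.pipeline import RunConfig, run_pipeline

OUT = pathlib.Path("results")


def main(registry: str = "results/registry_scaled", seed: int = 1) -> None:
    cfg = RunConfig(
        output_dir=str(OUT / "ace_run"),
        registry_dir=registry,
        run_within_individual=False,
        run_coaggregation=False,
        seed=seed,
    )
    out = run_pipeline(cfg)
    ace = json.loads((out / "ace.json").read_text())

    print("pairs per kinship:", ace["n_pairs"])
    s = ace["screening"]
    print(
        f"screening: within-person tetrachoric {s['within_person_tetrachoric']:.3f}, "
        f"{s['concordant_pairs']} concordant / {s['discordant_pairs']} discordant "
        f"-> {'included' if s['included'] else 'excluded ' + str(s['reasons'])}"
    )
    if "bivariate" in ace:
        for trait in ("exposure", "outcome"):
            u = ace[f"univariate_{trait}"]
            print(
                f"univariate {trait}: a2={u['a2']:.3f} c2={u['c2']:.3f} e2={u['e2']:.3f}"
            )
        b = ace["bivariate"]
        d = b["derived"]
        ci = b["derived_ci"]
        print(
            f"bivariate: r_ph={d['r_ph']:.3f}, rA={b['params']['rA']:.3f} "
            f"({b['ci']['rA']['low']:.2f} to {b['ci']['rA']['high']:.2f})"
        )
        for k in ("bivA", "bivC", "bivE"):
            print(f"  {k} = {d[k]:.3f} ({ci[k]['low']:.2f} to {ci[k]['high']:.2f})")
        print(f"  shares sum to {d['bivA'] + d['bivC'] + d['bivE']:.10f}")
        print(f"  fixed_c retry used: {b['fixed_c']}")


if __name__ == "__main__":
    main(sys.argv[1] if len(sys.argv) > 1 else "results/registry_scaled")
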