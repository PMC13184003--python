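import pytest

from famliab.params import AceParams, BivariateAceParams
from famliab.pipeline import RunConfig, run_pipeline
from famliab.simulate import SimulationConfig, simulate_registry


@pytest.fixture(scope="session")
def default_biv_params():
    """Generating parameters shared by several estimator tests."""
    return BivariateAceParams(
        AceParams(0.5, 0.05, 0.45), AceParams(0.5, 0.05, 0.45), rA=0.74, rC=0.5, rE=0.2
    )


@pytest.fixture(scope="session")
def small_registry(tmp_path_factory):
    """A modest synthetic registry written to disk once per session."""
    directory = tmp_path_factory.mktemp("registry")
    cfg = SimulationConfig(n_families=1500, seed=42)
    tables = simulate_registry(cfg, directory)
    return directory, tables, cfg


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run reused by the end-to-end assertions."""
    out = tmp_path_factory.mktemp("run")
    # common-trait prevalences keep the sibling 2x2 tables informative at
    # this desk-scale family count
    cfg = RunConfig(
        output_dir=str(out),
        simulation={"n_families": 4000, "prevalence": (0.05, 0.083)},
        seed=7,
    )
    run_pipeline(cfg)
    return out, cfg
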