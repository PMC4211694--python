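import numpy as np
import pytest

from mirfish.pipeline import RunConfig, run_pipeline
from mirfish.preprocess import FilterParams
from mirfish.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A reduced (20k reads/library) noiseless synthetic study + pipeline run."""
    simdir = tmp_path_factory.mktemp("sim_small")
    outdir = tmp_path_factory.mktemp("out_small")
    config = SimulationConfig(
        seed=42, reads_per_library=20_000, isomir_rate=0.0, mutation_rate=0.0
    )
    truth = simulate_all(config, simdir)
    run_config = RunConfig(
        samplesheet=str(simdir / "samplesheet.tsv"),
        reference=str(simdir / "mature.fa"),
        outdir=str(outdir),
        ct_table=str(simdir / "ct.tsv"),
        filter_params=FilterParams(adapter_3p=config.adapter_3p),
    )
    report = run_pipeline(run_config)
    return {
        "config": config,
        "truth": truth,
        "simdir": simdir,
        "outdir": outdir,
        "run_config": run_config,
        "report": report,
    }


@pytest.fixture(scope="session")
def noiseless_full(tmp_path_factory):
    """Default-scale run with isomiR/mutation noise off (planted reads exact)."""
    simdir = tmp_path_factory.mktemp("sim_noiseless")
    outdir = tmp_path_factory.mktemp("out_noiseless")
    config = SimulationConfig(seed=1001, isomir_rate=0.0, mutation_rate=0.0)
    truth = simulate_all(config, simdir)
    report = run_pipeline(
        RunConfig(
            samplesheet=str(simdir / "samplesheet.tsv"),
            reference=str(simdir / "mature.fa"),
            outdir=str(outdir),
            filter_params=FilterParams(adapter_3p=config.adapter_3p),
        )
    )
    return {"config": config, "truth": truth, "outdir": outdir, "report": report}


@pytest.fixture(scope="session")
def noisy_full(tmp_path_factory):
    """Default-scale run with the default isomiR (0.2) and mutation (0.01) noise."""
    simdir = tmp_path_factory.mktemp("sim_noisy")
    outdir = tmp_path_factory.mktemp("out_noisy")
    config = SimulationConfig(seed=1002)
    truth = simulate_all(config, simdir)
    report = run_pipeline(
        RunConfig(
            samplesheet=str(simdir / "samplesheet.tsv"),
            reference=str(simdir / "mature.fa"),
            outdir=str(outdir),
            filter_params=FilterParams(adapter_3p=config.adapter_3p),
        )
    )
    return {"config": config, "truth": truth, "outdir": outdir, "report": report}
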