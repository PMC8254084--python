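import numpy as np
import pytest

from gocentric import default_scenario
from gocentric.matrix import CountMatrix
from gocentric.pipeline import RunConfig, run_pipeline
from gocentric.synthetic import write_scenario


def small_matrix(counts, timepoints=None, genes=None):
    """Hand-sized CountMatrix helper for fixtures."""
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    if timepoints is None:
        timepoints = [f"t{j}" for j in range(n_samples)]
    reps = {}
    replicates = []
    for t in timepoints:
        reps[t] = reps.get(t, 0) + 1
        replicates.append(reps[t])
    samples = [f"{t}_r{r}" for t, r in zip(timepoints, replicates)]
    return CountMatrix(genes, counts, samples, list(timepoints), replicates)


@pytest.fixture(scope="session")
def scenario():
    """The default synthetic study, generated once per session."""
    return default_scenario(seed=0)


@pytest.fixture(scope="session")
def pipeline_run(scenario, tmp_path_factory):
    """Full pipeline result on the default scenario (seed 0)."""
    outdir = tmp_path_factory.mktemp("scenario")
    paths = write_scenario(scenario, outdir / "inputs")
    cfg = RunConfig(seed=0)
    cfg.counts = str(paths["counts"])
    cfg.meta = str(paths["meta"])
    cfg.obo = str(paths["obo"])
    cfg.annotations = str(paths["annotations"])
    cfg.fasta = str(paths["fasta"])
    cfg.bed = str(paths["bed"])
    cfg.jaspar = str(paths["jaspar"])
    return run_pipeline(cfg, outdir / "run")
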