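import pandas as pd
import pytest

from lhnet import synthdata


@pytest.fixture(scope="session")
def default_cfg() -> synthdata.SimulationConfig:
    return synthdata.SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def study(default_cfg):
    """One default simulated study shared across tests: (matrix, annotation, truth)."""
    return synthdata.simulate_expression(default_cfg)


@pytest.fixture(scope="session")
def study_files(tmp_path_factory, default_cfg):
    """All study inputs written to disk once per session."""
    out = tmp_path_factory.mktemp("study")
    return synthdata.generate_study(default_cfg, out)


@pytest.fixture()
def toy_annotation() -> pd.DataFrame:
    rows = [
        ("t1", "g1", "chr1", 100, 200, "+", "lincRNA"),
        ("t2", "g1", "chr1", 150, 400, "+", "lincRNA"),
        ("t3", "g2", "chr1", 1000, 2000, "-", "protein_coding"),
        ("t4", "g3", "chr2", 500, 900, "+", "antisense"),
        ("t5", "g4", "chr2", 5000, 9000, "-", "pseudogene"),
    ]
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "gene_id", "chromosome", "start", "end", "strand", "biotype"],
    )
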