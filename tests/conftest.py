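import numpy as np
import pandas as pd
import pytest

from scnome.config import AnalysisConfig
from scnome.simulate import PhaseSpec, SimConfig, simulate_cohort


def _make_calls(records):
    """Build a call table from (chrom, pos, strand, context, n_meth, n_unmeth)."""
    return pd.DataFrame(
        records,
        columns=["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"],
    )


@pytest.fixture(scope="session")
def make_calls():
    return _make_calls


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 3-phase synthetic cohort with distinct open promoters per phase."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = SimConfig(
        seed=7,
        chrom_len=120_000,
        n_genes=12,
        phases=[
            PhaseSpec("mitotic", 10, 0.15, [f"gene{i:03d}" for i in range(4)],
                      "fgc", "F", 10),
            PhaseSpec("meiotic", 10, 0.08, [f"gene{i:03d}" for i in range(4, 8)],
                      "fgc", "F", 17),
            PhaseSpec("soma", 10, 0.67, [], "soma", "F", 10),
        ],
    )
    truth = simulate_cohort(cfg, out)
    return {"dir": out, "cfg": cfg, "truth": truth}


@pytest.fixture()
def relaxed_cfg():
    """Analysis config with QC count gates scaled to synthetic genome size."""
    cfg = AnalysisConfig()
    cfg.qc_scbs.min_cpg_sites = 100
    cfg.qc_cool.min_wcg = 100
    cfg.qc_cool.min_gch = 100
    cfg.var_min_cells = 5
    return cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)
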