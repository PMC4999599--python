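import numpy as np
import pytest

import velvetchip as vc
from velvetchip.tags import clonal_filter


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def default_study():
    """One default-configuration synthetic study shared across tests."""
    cfg = vc.SyntheticConfig(seed=1)
    genome, genes, truth, libs, expression = vc.simulate_study(cfg)
    return {
        "config": cfg,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "chip1": libs[0],
        "chip2": libs[1],
        "input": libs[2],
        "expression": expression,
    }


@pytest.fixture(scope="session")
def default_peaks(default_study):
    """Filtered libraries and the replicate-1 peak call for the shared study."""
    cfg = default_study["config"]
    chip = clonal_filter(default_study["chip1"])
    input_lib = clonal_filter(default_study["input"])
    result = vc.call_peaks(
        chip, input_lib, cfg.chrom_lengths, vc.PeakCallParams(seed=1), cfg.fragment_length
    )
    return {"chip": chip, "input": input_lib, "result": result}
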