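import numpy as np
import pytest

from psocid_id import (
    BarcodeLibrary,
    SequenceRecord,
    center_star_msa,
    distance_matrix,
    gap_summary,
    simulate_library,
    specificity_matrix,
    spike_unknown,
)
from psocid_id.primer_design import design_all
from psocid_id.synthetic_data import SimulationConfig


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_library():
    """Two species, two records each, fully divergent at column 5."""
    return BarcodeLibrary([
        SequenceRecord("a1", "ACGTGACGTACGTACG", species="spA"),
        SequenceRecord("a2", "ACGTGACGTACGTACG", species="spA"),
        SequenceRecord("b1", "ACGTAACGTACGTACG", species="spB"),
        SequenceRecord("b2", "ACGTAACGTACGTACG", species="spB"),
    ])


@pytest.fixture(scope="session")
def default_pipeline():
    """The full default-scale study run, shared across acceptance tests:
    simulate -> distances -> barcode gap -> MSA -> design -> specificity."""
    sim = simulate_library(SimulationConfig(seed=1))
    lib = sim.library
    dm = distance_matrix(lib, model="k2p")
    summary = gap_summary(dm, lib)
    msa = center_star_msa(lib, dm=dm)
    designs = design_all(msa, lib)
    pairs = [r.pair for r in designs.values() if r.pair is not None]
    matrix = specificity_matrix(pairs, lib)
    unknown = spike_unknown(sim, "L. decolor", noise_rate=0.01, seed=11)
    return {
        "sim": sim, "lib": lib, "dm": dm, "summary": summary, "msa": msa,
        "designs": designs, "pairs": pairs, "matrix": matrix,
        "unknown": unknown,
    }
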