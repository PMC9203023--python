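import numpy as np
import pandas as pd
import pytest

from baculorate.model_core import ExperimentDesign, SimulationParams
from baculorate.selection_spectrum import RegionAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Reduced-scale demography for fast simulator tests."""
    return SimulationParams(mu=1e-5, rho=1.0, lam=10.0, zeta=2.0, kappa=1e5, sigma=101, g=500)


@pytest.fixture
def small_design():
    return ExperimentDesign(n_passages=2, larvae_per_passage=2, final_larvae=3)


@pytest.fixture
def toy_annotation():
    """30-base reference: intergenic(1-6), +CDS(7-15), insert(16-24), intergenic(25-30).

    The CDS reads TTT GCA AAA (Phe-Ala-Lys), stop-free.
    """
    reference = "ACGTAC" + "TTTGCAAAA" + "GGGCCCTTTA" [:9] + "ACGTAA"
    return RegionAnnotation(
        reference=reference,
        intervals=(
            (1, 6, "intergenic", "+", 0),
            (7, 15, "CDS", "+", 0),
            (16, 24, "neutral-insert", "+", 0),
            (25, 30, "intergenic", "+", 0),
        ),
    )


def make_records(rows):
    """Variant DataFrame from (lineage, position, ref, alt, freq, rc, frb, type) tuples."""
    return pd.DataFrame(
        rows,
        columns=["lineage", "position", "ref", "alt", "frequency",
                 "read_count", "fr_balance", "type"],
    )


@pytest.fixture
def toy_records():
    return make_records(
        [
            ("A", 3, "G", "T", 0.010, 50, 0.30, "SNV"),
            ("A", 17, "G", "A", 0.020, 40, 0.25, "SNV"),
            ("B", 17, "G", "A", 0.015, 60, 0.35, "SNV"),
            ("B", 20, "C", "T", 0.008, 30, 0.40, "SNV"),
        ]
    )
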