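import numpy as np
import pandas as pd
import pytest

from cerna_emt.circuit import EmtCircuit, load_preset
from cerna_emt.circuit.params import IDX, N_SPECIES
from cerna_emt.io_formats import ExpressionTimeCourse, SiteAnnotation
from cerna_emt.synthetic import SynthConfig, generate_expression, paper_anchor_fixture


@pytest.fixture(scope="session")
def default_params():
    return load_preset("default")


@pytest.fixture(scope="session")
def a549_params():
    return load_preset("a549_like")


@pytest.fixture(scope="session")
def circuit(default_params):
    return EmtCircuit(default_params)


@pytest.fixture(scope="session")
def anchors():
    return paper_anchor_fixture()


@pytest.fixture
def small_expression():
    return ExpressionTimeCourse(
        ["A", "B"], [0.0, 24.0, 96.0], [[10.0, 20.0, 40.0], [5.0, 5.0, 5.0]], "TPM"
    )


@pytest.fixture
def small_sites():
    return SiteAnnotation(
        pd.DataFrame(
            [
                ("A", "miR-X", "8mer", 2, "targetscan"),
                ("B", "miR-X", "8mer", 1, "targetscan"),
                ("B", "miR-X", "7mer-m8", 3, "targetscan"),
            ],
            columns=["gene_id", "mirna_id", "site_class", "n_sites", "source"],
        )
    )


@pytest.fixture(scope="session")
def a549_like_synth():
    """Noiseless A549-like synthetic course with ground truth."""
    cfg = SynthConfig(seed=7)
    return cfg, *generate_expression(cfg)


def mesenchymal_init():
    x = np.zeros(N_SPECIES)
    x[IDX["SNAIL1"]] = 4.0
    x[IDX["zeb1_mrna"]] = 1.0
    x[IDX["ZEB1"]] = 4.0
    x[IDX["cerna_mrna"]] = 5.0
    return x
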