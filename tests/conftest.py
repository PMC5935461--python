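import numpy as np
import pytest

import chemogimap as cg
from chemogimap.io import score_pipeline

CLASS_MAP = {"drugA1": "A", "drugA2": "A", "drugB1": "B", "drugB2": "B"}
CLASS_SIGNATURES = {
    "A": {"GENE0001": 0.40, "GENE0002": 0.50, "GENE0003": 2.20},
    "B": {"GENE0010": 2.50, "GENE0011": 0.45},
}


@pytest.fixture(scope="session")
def class_screen():
    """Small screen with two 2-drug classes carrying planted signatures."""
    config = cg.SimConfig(seed=7, n_genes=80, n_gfp_controls=20,
                          class_map=CLASS_MAP, class_signatures=CLASS_SIGNATURES)
    plates, truth = cg.generate_screen(config)
    records, matrix = score_pipeline(plates)
    annotation = cg.DrugClassAnnotation.from_mapping(CLASS_MAP)
    return {"config": config, "plates": plates, "truth": truth,
            "records": records, "matrix": matrix, "annotation": annotation}


@pytest.fixture(scope="session")
def null_screen():
    """Screen with zero planted effects: every gene behaves like GFP."""
    config = cg.SimConfig(seed=29, n_genes=150, n_gfp_controls=50, n_treatments=3)
    plates, truth = cg.generate_screen(config)
    _, matrix = score_pipeline(plates)
    return {"config": config, "truth": truth, "matrix": matrix}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
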