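import numpy as np
import pandas as pd
import pytest

from ciberdyn import (
    SimConfig,
    default_design,
    generate_constructs,
    generate_guide_library,
    generate_truth,
)
from ciberdyn.simulate import simulate_screen


@pytest.fixture(scope="session")
def small_screen():
    """A modest simulated screen shared by read-level and dynamics tests."""
    library = generate_guide_library(60, 6, 50, seed=21)
    constructs = generate_constructs(library, n_pairs=600, seed=22)
    truth = generate_truth(library, seed=23)
    design = default_design()
    cfg = SimConfig(rng_seed=24, library_size_per_sample=100_000)
    sim = simulate_screen(library, constructs, truth, design, cfg)
    return {
        "library": library,
        "constructs": constructs,
        "truth": truth,
        "design": design,
        "cfg": cfg,
        "sim": sim,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_truth_frame(rows):
    """Hand-built truth table for targeted closed-form tests."""
    defaults = {
        "class_label": "neutral",
        "growth_effect": 0.0,
        "basal_isr": 0.0,
        "amplitude": 0.0,
        "ec50": 0.5,
        "hill": 1.0,
        "onset_h": 0.5,
        "adaptation": 0.0,
    }
    recs = []
    for guide_id, overrides in rows.items():
        rec = {"guide_id": guide_id, **defaults, **overrides}
        recs.append(rec)
    return pd.DataFrame(recs).set_index("guide_id", drop=False)
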