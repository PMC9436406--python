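import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_cohort():
    """Two-patient noise-free outgrowth cohort for fast structural tests."""
    from slicequant.config import SyntheticConfig
    from slicequant.synth import generate_cohort

    cfg = SyntheticConfig(n_patients=2, area_mode_patients=0, noise_sd=0.0, seed=7)
    table, truth = generate_cohort(cfg)
    return cfg, table, truth


@pytest.fixture
def de_table():
    from slicequant.synth import generate_de_table

    return generate_de_table(n_genes=2000, n_signal=50, seed=11)


def make_slice_records(
    perimeter=10_000.0,
    culture="DT1",
    condition="control_72h",
    slice_id="s1",
    **class_lengths,
):
    """Hand-built annotation records for one outgrowth-mode slice."""
    rows = [
        {
            "culture_id": culture,
            "slice_id": slice_id,
            "replicate": 1,
            "condition": condition,
            "annotation_class": "perimeter",
            "measure_kind": "perimeter",
            "value": perimeter,
            "unit": "um",
        }
    ]
    for cls, length in class_lengths.items():
        rows.append(
            {
                "culture_id": culture,
                "slice_id": slice_id,
                "replicate": 1,
                "condition": condition,
                "annotation_class": cls,
                "measure_kind": "length",
                "value": length,
                "unit": "um",
            }
        )
    return pd.DataFrame(rows)
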