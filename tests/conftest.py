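import numpy as np
import pytest

from llps_pscreen import SyntheticSpec, featurize_records, generate_condition_dataset, generate_dataset


@pytest.fixture(scope="session")
def behavior_dataset():
    """n=500 planted-rule behavior dataset, featurized once per session."""
    records, truth = generate_dataset(SyntheticSpec(n=500, seed=3))
    X, y, groups, kept, excluded = featurize_records(records)
    return {
        "records": records,
        "truth": truth,
        "X": X,
        "y": y,
        "groups": groups,
        "kept": kept,
        "excluded": excluded,
    }


@pytest.fixture(scope="session")
def condition_dataset():
    """n=400 liquid-only dataset with the planted chain dependency."""
    records, truth = generate_condition_dataset(SyntheticSpec(n=400, seed=2))
    X, y, groups, kept, excluded = featurize_records(records)
    return {
        "records": records,
        "truth": truth,
        "X": X,
        "groups": groups,
        "kept": kept,
    }


@pytest.fixture(scope="session")
def condition_null_dataset():
    """Liquid-only dataset with conditions independent of the sequences."""
    records, truth = generate_condition_dataset(
        SyntheticSpec(n=400, seed=5, condition_signal=False)
    )
    X, y, groups, kept, excluded = featurize_records(records)
    return {"records": records, "truth": truth, "X": X, "groups": groups, "kept": kept}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
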