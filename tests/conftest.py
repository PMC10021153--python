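import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from morbnet.codebook import CODES, Cohort

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_frame(indicators, genders=None, ages=None, weights=None) -> pd.DataFrame:
    """Cohort DataFrame from an (n, 16) indicator array plus optional columns."""
    ind = np.asarray(indicators, dtype=int)
    n = ind.shape[0]
    assert ind.shape == (n, 16)
    df = pd.DataFrame(ind, columns=list(CODES))
    df.insert(0, "weight", np.ones(n) if weights is None else np.asarray(weights, float))
    df.insert(0, "age", np.full(n, 60.0) if ages is None else np.asarray(ages, float))
    df.insert(0, "gender", ["women"] * n if genders is None else list(genders))
    df.insert(0, "person_id", [f"P{i:04d}" for i in range(n)])
    return df


def make_cohort(indicators, **kwargs) -> Cohort:
    return Cohort(make_frame(indicators, **kwargs))


def indicators_from_pairs(pairs) -> np.ndarray:
    """One record per entry of ``pairs``; each entry is a set of codes."""
    ind = np.zeros((len(pairs), 16), dtype=int)
    idx = {c: i for i, c in enumerate(CODES)}
    for r, present in enumerate(pairs):
        for code in present:
            ind[r, idx[code]] = 1
    return ind


@pytest.fixture
def tiny_cohort() -> Cohort:
    """Three equal-weight records: {HYP,DM}, {HYP,DM}, {HYP,MKS}."""
    return make_cohort(indicators_from_pairs([
        {"HYP", "DM"}, {"HYP", "DM"}, {"HYP", "MKS"}]))
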