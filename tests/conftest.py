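import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rusfresp.synthetic import EffectSpec, generate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort shared across tests (read-only)."""
    return generate_cohort(EffectSpec(), seed=1)


@pytest.fixture(scope="session")
def wasted_pre(cohort):
    """Pre-intervention ASV counts + labels for responders vs nonresponders."""
    counts = cohort.asv.at_timepoint(9)
    subj = counts.data.index.get_level_values("subject_id")
    mask = cohort.labels["group"].reindex(subj).isin(["responder", "nonresponder"]).to_numpy()
    counts = type(counts)(counts.data[mask])
    y = (
        cohort.labels["group"]
        .reindex(counts.data.index.get_level_values("subject_id"))
        .to_numpy()
    )
    return counts, y


def keyed_frame(values, subjects=None, timepoint=9, columns=None):
    """Small helper: build a (subject, timepoint)-keyed DataFrame."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    subjects = subjects or [f"S{i:02d}" for i in range(n)]
    columns = columns or [f"f{j}" for j in range(values.shape[1])]
    idx = pd.MultiIndex.from_tuples(
        [(s, timepoint) for s in subjects], names=["subject_id", "timepoint"]
    )
    return pd.DataFrame(values, index=idx, columns=columns)
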