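import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_survival(rng):
    """60 patients with exponential event and censoring times."""
    n = 60
    t_event = rng.exponential(25.0, size=n)
    t_cens = rng.exponential(50.0, size=n)
    times = np.minimum(t_event, t_cens)
    events = (t_event <= t_cens).astype(int)
    return times, events


def make_counts(rng, n_genes=30, n_samples=40, alpha=0.3, mean_range=(20, 800)):
    """NB counts with lognormal library sizes; returns (counts df, size factors)."""
    mu = rng.uniform(*mean_range, size=n_genes)
    s = np.exp(rng.normal(0, 0.2, size=n_samples))
    r = 1.0 / alpha
    m = mu[:, None] * s[None, :]
    counts = rng.negative_binomial(r, r / (r + m))
    df = pd.DataFrame(counts,
                      index=[f"G{i:03d}" for i in range(n_genes)],
                      columns=[f"S{j:03d}" for j in range(n_samples)])
    return df, s
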