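import numpy as np
import pandas as pd
import pytest

from hlascore.io import load_example_annotation, load_example_matrix


@pytest.fixture(scope="session")
def example_matrix() -> pd.DataFrame:
    return load_example_matrix()


@pytest.fixture(scope="session")
def example_annotation() -> pd.DataFrame:
    return load_example_annotation()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_mixture_matrix(
    rng,
    n_samples: int = 47,
    n_bimodal: int = 20,
    n_unimodal: int = 500,
    separation_sd: float = 4.0,
    minor_fraction: float = 0.3,
    sd: float = 1.0,
    balanced: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Log2-scale matrix with planted two-mode probes over unimodal noise.

    Each planted probe draws per-sample states Bernoulli(minor_fraction)
    (or exactly ``round(minor_fraction * n)`` minor samples when
    ``balanced``); the two modes sit ``separation_sd`` component standard
    deviations apart.  Returns (probes x samples DataFrame on the log2
    scale, planted probe ids).
    """
    mid = 8.0
    rows, names = [], []
    for i in range(n_bimodal):
        if balanced:
            state = np.zeros(n_samples, bool)
            state[rng.choice(n_samples, int(round(minor_fraction * n_samples)), replace=False)] = True
        else:
            state = rng.random(n_samples) < minor_fraction
        mu = np.where(state, mid + separation_sd * sd, mid)
        rows.append(rng.normal(mu, sd))
        names.append(f"planted_{i:03d}")
    for i in range(n_unimodal):
        rows.append(rng.normal(mid, sd, n_samples))
        names.append(f"null_{i:03d}")
    cols = [f"S{j:03d}" for j in range(n_samples)]
    return pd.DataFrame(rows, index=names, columns=cols), names[:n_bimodal]
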