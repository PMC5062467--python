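import numpy as np
import pandas as pd
import pytest

from pancanmet.signature import MetabolicSignature


@pytest.fixture
def toy_signature():
    return MetabolicSignature(
        {
            "P1": ("gA", "gB"),
            "P2": ("gB", "gC"),
            "P3": ("gB",),
        }
    )


@pytest.fixture
def random_signature():
    """A moderately sized random signature with promiscuous genes."""
    rng = np.random.default_rng(42)
    genes = [f"g{i:03d}" for i in range(120)]
    pathways = {}
    for p in range(12):
        size = int(rng.integers(4, 15))
        members = rng.choice(genes, size=size, replace=False)
        pathways[f"PW{p:02d}"] = tuple(sorted(members))
    return MetabolicSignature(pathways)


def make_counts(rng, n_genes, samples, mu_range=(5, 500), alpha=0.1):
    """NB counts with known dispersion, one DataFrame column per sample."""
    mu = rng.uniform(*mu_range, size=n_genes)
    lam = rng.gamma(1.0 / alpha, alpha * mu[:, None], size=(n_genes, len(samples)))
    y = rng.poisson(lam)
    return pd.DataFrame(y, index=[f"g{i:04d}" for i in range(n_genes)],
                        columns=samples)
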