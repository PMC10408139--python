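import numpy as np
import pandas as pd
import pytest

from oxsig.signature import GeneSignature


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_expr(rng):
    """A 200-gene x 50-sample random log-scale expression matrix."""
    genes = [f"Sim{i:05d}" for i in range(200)]
    samples = [f"S{j:02d}" for j in range(50)]
    values = rng.normal(8.0, 2.0, size=(200, 50))
    return pd.DataFrame(values, index=genes, columns=samples)


@pytest.fixture
def random_signatures(rng, random_expr):
    """Five random disjoint-up/down signatures over the 200-gene universe."""
    genes = np.array(random_expr.index)
    sigs = []
    for k in range(5):
        chosen = rng.choice(genes, size=30, replace=False)
        sigs.append(
            GeneSignature(name=f"sig{k}", up=frozenset(chosen[:15]),
                          down=frozenset(chosen[15:]))
        )
    return sigs
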