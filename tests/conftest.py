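import numpy as np
import pandas as pd
import pytest

from badgers import GenotypePanel, SummaryStatsTable, WeightMatrix
from badgers.genio import two_sided_p


def make_variants(m, chrom="1", spacing=1000, a1="A", a2="G"):
    return pd.DataFrame({
        "id": [f"rs{j}" for j in range(m)],
        "chrom": chrom,
        "pos": np.arange(1, m + 1, dtype=np.int64) * spacing,
        "a1": a1, "a2": a2,
    })


def make_panel(n=40, m=12, seed=0, maf=0.3, **kw) -> GenotypePanel:
    rng = np.random.default_rng(seed)
    dosages = rng.binomial(2, maf, size=(n, m)).astype(float)
    return GenotypePanel(make_variants(m, **kw), dosages)


def make_sumstats(beta, se, variants=None, n=1000, trait="t") -> SummaryStatsTable:
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    df = variants.copy() if variants is not None else make_variants(len(beta))
    df["beta"] = beta
    df["se"] = se
    df["z"] = beta / se
    df["p"] = two_sided_p(df["z"].to_numpy())
    df["n"] = n
    return SummaryStatsTable(df, trait_id=trait)


def make_weights(weights, variants=None, trait_ids=None) -> WeightMatrix:
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    if W.shape[0] == 1 and W.shape[1] > 1 and variants is not None \
            and len(variants) == W.shape[1]:
        W = W.T
    if W.ndim == 1:
        W = W[:, None]
    v = variants.copy() if variants is not None else make_variants(W.shape[0])
    ids = trait_ids or [f"trait{k}" for k in range(W.shape[1])]
    return WeightMatrix(v, W, ids)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def small_panel():
    return make_panel()
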