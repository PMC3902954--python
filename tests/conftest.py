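import numpy as np
import pandas as pd
import pytest

from trapfe.catalog import CODING, LONG_NONCODING, SHORT_NONCODING
from trapfe.mixture import PopulationProfile, TissueModel


def make_catalog(lengths, biotypes=None):
    """Small explicit catalog for worked examples."""
    n = len(lengths)
    if biotypes is None:
        biotypes = [CODING] * n
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "length_nt": list(lengths),
            "biotype": list(biotypes),
        }
    )


def make_tissue(fractions, transcription, translation=None, catalog=None):
    """Tissue from explicit per-population arrays (rows = populations)."""
    transcription = np.asarray(transcription, dtype=float)
    n_pop, n_genes = transcription.shape
    if catalog is None:
        catalog = make_catalog([1000] * n_genes)
    if translation is None:
        translation = np.ones_like(transcription)
    pops = [
        PopulationProfile(
            name=f"p{i}",
            fraction=float(fractions[i]),
            transcription=transcription[i],
            translation_efficiency=np.asarray(translation[i], dtype=float),
        )
        for i in range(n_pop)
    ]
    return TissueModel(catalog=catalog, populations=pops)


@pytest.fixture
def two_pop_tissue():
    """The worked two-gene mixture: f=(0.5,0.5), x_A=(10,10), x_B=(0,20)."""
    return make_tissue([0.5, 0.5], [[10.0, 10.0], [0.0, 20.0]])


@pytest.fixture
def rng():
    return np.random.default_rng(101)
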