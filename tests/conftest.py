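import numpy as np
import pytest

from corecollect import simulate
from corecollect.genotypes import (
    GenotypeMatrix,
    filter_maf,
    kinship_vanraden,
    rogers_distance,
)
from corecollect import structure as st


def make_g(dosage, chrom=None, pos=None, ids=None, marker_ids=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a plain nested list / array."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    return GenotypeMatrix(
        ids or [f"a{i}" for i in range(n)],
        marker_ids or [f"s{j}" for j in range(m)],
        np.asarray(chrom if chrom is not None else ["1"] * m, dtype=object),
        np.asarray(pos if pos is not None else range(1, m + 1)),
        dosage,
    )


@pytest.fixture(scope="session")
def small_panel():
    """80 accessions x 200 markers, 3 clusters, for fast cross-module tests."""
    spec = simulate.PanelSpec(n_per_cluster=[30, 30, 20], fst=0.2, m=200,
                              n_chrom=4, seed=3)
    g, truth = simulate.generate_panel(spec)
    return filter_maf(g, 0.01), truth


@pytest.fixture(scope="session")
def fixture600():
    """The canonical desk-scale panel (6 clusters, n=600, m=3000)."""
    return simulate.standard_fixture(seed=1)


@pytest.fixture(scope="session")
def g600(fixture600):
    return filter_maf(fixture600.genotypes, 0.01)


@pytest.fixture(scope="session")
def pca600(g600):
    return st.pca_with_tw(g600)


@pytest.fixture(scope="session")
def aux600(g600, pca600):
    return {
        "distance": rogers_distance(g600),
        "kinship": kinship_vanraden(g600),
        "pca": pca600,
    }


@pytest.fixture(scope="session")
def clusters600(pca600):
    cm = st.kmeans_bic(pca600, range(1, 11), seed=0, force_k=6)
    return st.dapc_covariates(pca600, cm)
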