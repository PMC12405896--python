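import numpy as np
import pytest

from minegwas.genomatrix import VariantTable
from minegwas.mcmc import Ensemble
from minegwas.models import TraitData


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_variant_table():
    """2 chromosomes, 6 SNPs, 4 accessions, one missing genotype."""
    ref = np.array(
        [
            [2, 1, 0, 2, 2, 1],
            [0, 0, 1, 1, 2, 2],
            [2, 2, 2, 2, 2, 2],
            [1, 1, 1, 0, 0, 0],
        ],
        dtype=np.int8,
    )
    miss = np.zeros_like(ref, dtype=bool)
    miss[1, 2] = True
    return VariantTable(
        accession_ids=["a1", "a2", "a3", "a4"],
        chrom=np.array(["1", "1", "1", "1", "2", "2"], dtype=object),
        pos=np.array([100, 30_000, 60_000, 90_000, 500, 40_000]),
        ref_count=ref,
        missing_mask=miss,
    )


def make_ensemble(n_samples: int, n_beta: int, seed: int = 0,
                  samples: np.ndarray | None = None) -> Ensemble:
    rng = np.random.default_rng(seed)
    if samples is None:
        samples = rng.normal(size=(n_samples, n_beta))
    return Ensemble(
        samples=np.asarray(samples, dtype=float),
        hamiltonians=np.zeros(len(samples)),
        model="linear",
        n_beta=n_beta,
    )


@pytest.fixture
def ensemble_factory():
    return make_ensemble


def make_trait_data(y, accession_ids=None):
    y = np.asarray(y, dtype=float)
    n = len(y)
    if accession_ids is None:
        accession_ids = [f"acc{i}" for i in range(n)]
    return TraitData(
        y=y,
        plant_ids=[f"plant{i}" for i in range(n)],
        accession_ids=list(accession_ids),
    )


@pytest.fixture
def trait_factory():
    return make_trait_data
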