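import numpy as np
import pytest

from hashdemux import synthetic
from hashdemux.classification import DemuxResult
from hashdemux.clustering import ClusterModel
from hashdemux.normalization import ClrMatrix


@pytest.fixture(scope="session")
def standard_sim():
    """Clean bimodal dataset with known labels (shared across tests)."""
    cfg = synthetic.SimConfig(n_cells=1500, n_hashtags=4, seed=42)
    data, truth = synthetic.simulate(cfg)
    return cfg, data, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dataset(rng, c=50, n=5, high=200, mrna=False):
    """Seeded random integer dataset for structural tests."""
    counts = rng.integers(0, high, size=(c, n))
    sizes = rng.integers(100, 10000, size=c).astype(float) if mrna else None
    return synthetic.HashingDataset(
        hto_counts=counts,
        hashtag_names=[f"H{i}" for i in range(n)],
        barcodes=[f"B{i}" for i in range(c)],
        mrna_library_size=sizes,
    )


def make_result(categories, best=None, second=None, min_md=None, second_md=None,
                hashtags=("A", "B")):
    """Hand-built DemuxResult for unit tests of the later pipeline stages."""
    c = len(categories)
    cat = np.array(categories, dtype=object)
    singlet_names = [h for h in cat if h not in ("Negative", "Doublet")]
    default_best = singlet_names[0] if singlet_names else hashtags[0]
    return DemuxResult(
        barcodes=[f"B{i}" for i in range(c)],
        hashtag_names=list(hashtags),
        category=cat,
        best_hashtag=np.array(
            best if best is not None else [default_best] * c, dtype=object
        ),
        second_hashtag=np.array(
            second if second is not None else [hashtags[1]] * c, dtype=object
        ),
        min_md=np.asarray(min_md if min_md is not None else np.ones(c), float),
        second_md=np.asarray(
            second_md if second_md is not None else np.full(c, 2.0), float
        ),
        is_outlier_initial=np.isin(cat, ("Negative", "Doublet")),
        reclassified_by_mrna=np.zeros(c, dtype=bool),
        doublet_first=np.full(c, "", dtype=object),
        doublet_second=np.full(c, "", dtype=object),
        cutoff_used=1.0,
        cutoff_mode="quantile",
        split_done=True,
    )


def manual_cluster_model(clr_values, assignment, medoid_indices):
    """ClusterModel over explicit values without running k-medoids."""
    assignment = np.asarray(assignment)
    medoid_indices = np.asarray(medoid_indices)
    return ClusterModel(
        k=int(assignment.max()),
        assignment=assignment,
        medoid_indices=medoid_indices,
        centroids=np.asarray(clr_values, float)[medoid_indices],
        core_flag=np.ones(len(assignment), dtype=bool),
    )


@pytest.fixture
def clr_of(standard_sim):
    from hashdemux.normalization import local_clr

    return local_clr(standard_sim[1])


def as_clr(values):
    return ClrMatrix(values=np.asarray(values, dtype=float))
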