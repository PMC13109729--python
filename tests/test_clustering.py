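import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import as_clr, manual_cluster_model
from hashdemux import normalization
from hashdemux.clustering import (
    flag_core_cells,
    kmedoids_cluster,
    label_clusters,
    select_k,
)
from hashdemux.errors import DegenerateInputError


def three_blobs(rng, n_per=100):
    centers = np.array([[4.0, -2.0, -2.0], [-2.0, 4.0, -2.0], [-2.0, -2.0, 4.0]])
    pts = np.concatenate(
        [c + rng.normal(0, 0.3, size=(n_per, 3)) for c in centers]
    )
    labels = np.repeat([0, 1, 2], n_per)
    return as_clr(pts), labels


def test_kmedoids_recovers_separated_blobs(rng):
    clr, labels = three_blobs(rng)
    model = kmedoids_cluster(clr, k=3, mode="pam", seed=0)
    assert adjusted_rand_score(labels, model.assignment) == 1.0
    for l in range(1, 4):
        assert model.assignment[model.medoid_indices[l - 1]] == l


def test_kmedoids_two_repeated_profiles():
    vals = np.array([[1.0, -1.0], [-1.0, 1.0]] * 5)
    model = kmedoids_cluster(as_clr(vals), k=2, mode="pam", seed=0)
    medoid_rows = vals[model.medoid_indices]
    assert {tuple(r) for r in medoid_rows} == {(1.0, -1.0), (-1.0, 1.0)}
    # zero within-cluster distance
    for l in (1, 2):
        members = vals[model.assignment == l]
        assert np.ptp(members, axis=0).max() == 0.0


def test_kmedoids_deterministic_and_clara_close_to_pam(rng):
    clr, labels = three_blobs(rng)
    a = kmedoids_cluster(clr, k=3, mode="clara", seed=9)
    b = kmedoids_cluster(clr, k=3, mode="clara", seed=9)
    np.testing.assert_array_equal(a.assignment, b.assignment)
    assert adjusted_rand_score(labels, a.assignment) == 1.0


def test_kmedoids_degenerate_k():
    vals = np.array([[1.0, -1.0], [-1.0, 1.0]] * 3)
    with pytest.raises(DegenerateInputError):
        kmedoids_cluster(as_clr(vals), k=3, mode="pam", seed=0)


def test_select_k_prefers_k1_when_split_adds_nothing(standard_sim):
    _, data, _ = standard_sim
    clr = normalization.local_clr(data)
    assert select_k(clr, 4, 5, mode="pam", seed=0) == 4


def test_select_k_prefers_k2_when_hashtag_buried(rng):
    """A hashtag whose singlets hide inside a big mixed cluster at k1 but get
    their own cluster at k2 gains > 1 in top-cluster median CLR."""
    from hashdemux.synthetic import SimConfig, simulate

    cfg = SimConfig(n_cells=1500, n_hashtags=4, archetype="contaminated",
                    contamination_fraction=0.3, seed=5)
    data, _ = simulate(cfg)
    clr = normalization.local_clr(data)
    assert select_k(clr, 4, 5, mode="pam", seed=0) == 5


def test_select_k_requires_increasing_k(clr_of):
    with pytest.raises(ValueError):
        select_k(clr_of, 4, 4)


def test_flag_core_quantile_arithmetic(rng):
    # 10 droplets at distinct distances from the medoid along one axis
    base = np.zeros((10, 3))
    base[:, 0] = np.arange(10) * 0.1
    base[:, 1] = -base[:, 0]
    model = manual_cluster_model(base, np.ones(10, dtype=int), [0])
    model = flag_core_cells(model, as_clr(base), quantile=0.9)
    assert model.core_flag.sum() == 9
    assert not model.core_flag[9]  # farthest droplet is non-core
    model = flag_core_cells(model, as_clr(base), quantile=1.0)
    assert model.core_flag.all()


def test_flag_core_ties_inclusive():
    vals = np.array([[1.0, -1.0]] * 8)  # all equidistant (distance 0)
    model = manual_cluster_model(vals, np.ones(8, dtype=int), [0])
    model = flag_core_cells(model, as_clr(vals), quantile=0.5)
    assert model.core_flag.all()


def test_flag_core_fraction_at_least_quantile(standard_sim):
    _, data, _ = standard_sim
    clr = normalization.local_clr(data)
    model = kmedoids_cluster(clr, k=4, mode="pam", seed=0)
    model = flag_core_cells(model, clr, quantile=0.9)
    for l in range(1, 5):
        members = model.members(l)
        frac = model.core_flag[members].mean()
        assert 0.9 <= frac <= 1.0


def test_label_clusters_bijective_on_standard(standard_sim):
    _, data, truth = standard_sim
    clr = normalization.local_clr(data)
    model = kmedoids_cluster(clr, k=4, mode="pam", seed=0)
    model = flag_core_cells(model, clr)
    model = label_clusters(model, clr, data.hashtag_names,
                           hto_library_size=data.hto_library_size)
    assert sorted(model.label_map) == sorted(data.hashtag_names)
    assert len(set(model.label_map.values())) == 4
    # labels match the generator's ground truth: in each labelled cluster the
    # dominant true singlet identity is the assigned hashtag
    for h, l in model.label_map.items():
        members = model.members(l)
        true_here = truth.category[members]
        singlet_mask = ~np.isin(true_here, ("Doublet", "Negative"))
        vals, counts = np.unique(true_here[singlet_mask], return_counts=True)
        assert vals[counts.argmax()] == h


def test_label_conflict_resolved_by_average_mode():
    """Two hashtags peak at the same medoid, but cluster-median CLR separates
    them, so medoid labelling falls back to average labelling."""
    vals = np.array([
        [2.0, 1.0, -3.0], [2.0, 0.0, -2.0], [2.0, -1.0, -1.0],   # cluster 1
        [0.0, -1.0, 1.0], [-1.0, 1.0, 0.0], [-2.0, 3.0, -1.0],   # cluster 2
        [-1.0, -1.0, 2.0], [-1.0, -1.0, 2.0], [-2.0, 0.0, 2.0],  # cluster 3
    ])
    model = manual_cluster_model(vals, [1, 1, 1, 2, 2, 2, 3, 3, 3], [0, 3, 6])
    # medoid scores: A -> cluster1, B -> cluster1 (conflict), C -> cluster3
    model = label_clusters(model, as_clr(vals), ["A", "B", "C"])
    assert model.label_map == {"A": 1, "B": 2, "C": 3}


def test_unclaimed_low_size_cluster_becomes_negative(rng):
    """At k = N+1 on the empty-droplet archetype, the empty cluster is claimed
    by no hashtag and has low library size, so it is flagged negative and all
    its droplets are non-core."""
    from hashdemux.synthetic import SimConfig, simulate

    cfg = SimConfig(n_cells=1500, n_hashtags=4, archetype="empty_cluster", seed=11)
    data, truth = simulate(cfg)
    clr = normalization.local_clr(data)
    model = kmedoids_cluster(clr, k=5, mode="pam", seed=0)
    model = flag_core_cells(model, clr)
    model = label_clusters(model, clr, data.hashtag_names,
                           hto_library_size=data.hto_library_size)
    assert len(model.negative_cluster_ids) == 1
    neg = next(iter(model.negative_cluster_ids))
    members = model.members(neg)
    assert not model.core_flag[members].any()
    # the negative cluster is dominated by true negatives (empty droplets
    # plus ordinary low-signal negatives)
    assert (truth.category[members] == "Negative").mean() > 0.8
    assert truth.is_empty[members].mean() > 0.5
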