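import numpy as np
import pytest
from scipy import stats

from conftest import make_result
from hashdemux.classification import (
    doublet_identities,
    initial_classify,
    mrna_reclassify,
    rescue_weak_hashtag,
    split_outliers,
)
from hashdemux.clustering import flag_core_cells, kmedoids_cluster, label_clusters
from hashdemux.dataset import HashingDataset
from hashdemux.errors import ConfigurationError
from hashdemux.mahalanobis import DistanceMatrix, mahalanobis_distances, pooled_covariance
from hashdemux.normalization import local_clr


def synthetic_md_setup(min_md_values, n_hashtags=2):
    """A labelled 2-cluster model plus a distance matrix whose per-droplet
    minimum equals the given values (second column larger)."""
    c = len(min_md_values)
    md = np.column_stack([np.asarray(min_md_values, float),
                          np.asarray(min_md_values, float) + 100.0])
    from conftest import manual_cluster_model

    vals = np.zeros((c, n_hashtags))
    model = manual_cluster_model(vals, np.ones(c, dtype=int), [0, 1][:1] * 1)
    model.k = 2
    model.medoid_indices = np.array([0, 1])
    model.centroids = vals[:2].copy()
    model.assignment = np.ones(c, dtype=int)
    model.label_map = {"A": 1, "B": 2}
    data = HashingDataset(
        np.ones((c, 2), dtype=int), ["A", "B"], [f"B{i}" for i in range(c)]
    )
    return DistanceMatrix(md=md), model, data


def test_quantile_cutoff_exact_outlier_count(rng):
    values = rng.permutation(np.linspace(0.001, 50, 1000))
    md, model, data = synthetic_md_setup(values)
    res = initial_classify(md, model, data, cutoff_mode="quantile", q=0.95)
    assert int(res.is_outlier_initial.sum()) == 50
    # the 50 outliers are exactly the 50 largest minima
    assert set(np.flatnonzero(res.is_outlier_initial)) == set(
        np.argsort(values)[-50:]
    )
    # all non-outliers are singlets of the nearest hashtag
    assert (res.category[~res.is_outlier_initial] == "A").all()


def test_chisq_cutoff_value():
    md, model, data = synthetic_md_setup(np.linspace(0, 1, 40))
    # N = 2 hashtags here, but the cutoff only depends on the df argument;
    # check the df = N-1 rule on a 4-hashtag distance matrix instead
    md4 = DistanceMatrix(md=np.tile(np.linspace(0, 1, 40)[:, None], (1, 4)))
    from conftest import manual_cluster_model

    model4 = manual_cluster_model(np.zeros((40, 4)), np.ones(40, dtype=int), [0])
    model4.k = 4
    model4.centroids = np.zeros((4, 4))
    model4.label_map = {f"H{i}": i + 1 for i in range(4)}
    data4 = HashingDataset(
        np.ones((40, 4), dtype=int), [f"H{i}" for i in range(4)],
        [f"B{i}" for i in range(40)],
    )
    res = initial_classify(md4, model4, data4, cutoff_mode="chisq", chisq_p=0.975)
    # 0.975 quantile of chi-square with 3 df, frozen reference value
    assert res.cutoff_used == pytest.approx(9.348403604505589, abs=1e-9)


def test_unlabelled_hashtag_is_configuration_error():
    md, model, data = synthetic_md_setup(np.linspace(0, 1, 20))
    model.label_map = {"A": 1}
    with pytest.raises(ConfigurationError):
        initial_classify(md, model, data)


def test_min_and_second_ordering_with_ties():
    md, model, data = synthetic_md_setup(np.zeros(4))
    md.md[:] = [[0.5, 0.2], [0.2, 0.5], [0.3, 0.3], [0.0, 0.0]]
    res = initial_classify(md, model, data, q=0.99)
    assert res.best_hashtag[0] == "B" and res.second_hashtag[0] == "A"
    assert res.best_hashtag[1] == "A"
    assert res.best_hashtag[2] == "A"  # tie -> hashtag input order
    assert (res.min_md <= res.second_md).all()
    assert ((0 <= res.md_ratio) & (res.md_ratio <= 1)).all()


def outlier_dataset(rng, n=400, mrna=None):
    """All-outlier result over droplets with bimodal log library sizes:
    half ~ N(3, 0.3) (negatives), half ~ N(7, 0.3) (doublets)."""
    comp = rng.integers(0, 2, size=n)
    log_lib = np.where(comp == 0, rng.normal(3, 0.3, n), rng.normal(7, 0.3, n))
    lib = np.maximum(np.round(np.exp(log_lib) - 1), 0).astype(int)
    counts = np.column_stack([lib, np.zeros(n, dtype=int)])
    data = HashingDataset(
        counts, ["A", "B"], [f"B{i}" for i in range(n)],
        mrna_library_size=mrna,
    )
    res = make_result(["Negative"] * n, best=["A"] * n, second=["B"] * n)
    return res, data, comp


def test_antimode_split_recovers_mixture_components(rng):
    res, data, comp = outlier_dataset(rng)
    res = split_outliers(res, data)
    assert 4 < res.antimode < 6
    pred_doublet = res.category == "Doublet"
    misassigned = pred_doublet != (comp == 1)
    assert misassigned.mean() < 0.01


def test_split_no_outliers_is_identity():
    res = make_result(["A", "A", "B"])
    data = HashingDataset(np.ones((3, 2), dtype=int), ["A", "B"],
                          ["B0", "B1", "B2"])
    before = res.category.copy()
    res = split_outliers(res, data)
    np.testing.assert_array_equal(res.category, before)
    assert res.antimode is None


def test_split_fallback_on_degenerate_library_sizes():
    """All outliers share one library size: fall back to the median singlet
    library size; outliers below it become negatives, at/above doublets."""
    cats = ["A"] * 6 + ["Negative"] * 12
    counts = np.ones((18, 2), dtype=int)
    counts[:6] = 50  # singlets: log lib ~ 4.6
    counts[6:] = 2   # outliers all identical, below the singlet median
    data = HashingDataset(counts, ["A", "B"], [f"B{i}" for i in range(18)])
    res = make_result(cats)
    res = split_outliers(res, data)
    assert (res.category[6:] == "Negative").all()


def test_doublet_identities_pairs_and_singlets():
    res = make_result(["Doublet", "A", "Negative"],
                      best=["B", "A", "A"], second=["A", "B", "B"])
    res = doublet_identities(res)
    assert (res.doublet_first[0], res.doublet_second[0]) == ("B", "A")
    assert res.doublet_first[1] == "" and res.doublet_first[2] == ""


def test_mrna_reclassify_rules():
    cats = ["A", "A", "A", "Negative", "Doublet", "Doublet"]
    mrna = np.array([100.0, 100.0, 100.0, 500.0, 100.0, 20.0])
    data = HashingDataset(
        np.ones((6, 2), dtype=int), ["A", "B"], [f"B{i}" for i in range(6)],
        mrna_library_size=mrna,
    )
    res = make_result(cats, best=["A"] * 6)
    res = mrna_reclassify(res, data)
    # T = median log(100+1) of singlets; negative at 500 > T -> singlet
    assert res.category[3] == "A" and res.reclassified_by_mrna[3]
    # doublet exactly at T stays a doublet (strict inequality)
    assert res.category[4] == "Doublet" and not res.reclassified_by_mrna[4]
    # doublet below T -> singlet
    assert res.category[5] == "A" and res.reclassified_by_mrna[5]
    # no singlet is ever converted away
    assert (res.category[:3] == "A").all()


def test_mrna_reclassify_skips_without_sizes():
    res = make_result(["A", "Negative"])
    data = HashingDataset(np.ones((2, 2), dtype=int), ["A", "B"], ["B0", "B1"])
    before = res.category.copy()
    res = mrna_reclassify(res, data)
    np.testing.assert_array_equal(res.category, before)


def test_rescue_rule_application():
    from conftest import as_clr

    counts = np.array([[20, 1, 1], [1, 1, 1], [30, 1, 1]])
    data = HashingDataset(counts, ["T", "X", "Y"], ["B0", "B1", "B2"])
    clr = local_clr(data)
    res = make_result(["Negative", "Negative", "Y"], hashtags=("T", "X", "Y"))
    # droplet 0: log(21) ~ 3.04 >= 2.5 and CLR margin ~ 2.0 >= 1.0 -> rescued
    res = rescue_weak_hashtag(res, clr, data, "T",
                              min_log_count=2.5, min_clr_margin=1.0)
    assert res.category[0] == "T"
    assert res.category[1] == "Negative"  # fails both thresholds
    assert res.category[2] == "Y"  # singlets untouched
    with pytest.raises(ValueError):
        rescue_weak_hashtag(res, clr, data, "missing", 1.0, 1.0)


def test_rescue_weak_archetype_precision():
    """On the weak-signal archetype, rescued negatives are overwhelmingly true
    members of the weakened hashtag (thresholds: log count 3.0, margin 0.5)."""
    from hashdemux.pipeline import RunConfig, run_demux
    from hashdemux.synthetic import SimConfig, simulate

    data, truth = simulate(
        SimConfig(n_cells=2000, n_hashtags=4, archetype="weak_signal", seed=2)
    )
    res, art = run_demux(data, RunConfig(cutoff_mode="chisq"))
    was_negative = res.category == "Negative"
    res = rescue_weak_hashtag(res, art.clr, data, "HTO1",
                              min_log_count=3.0, min_clr_margin=0.5)
    rescued = was_negative & (res.category == "HTO1")
    assert rescued.sum() > 0
    assert (truth.category[rescued] == "HTO1").mean() >= 0.8


def test_category_partition_and_quantile_monotonicity(standard_sim):
    _, data, _ = standard_sim
    clr = local_clr(data)
    model = kmedoids_cluster(clr, k=4, mode="pam", seed=0)
    model = flag_core_cells(model, clr)
    model = label_clusters(model, clr, data.hashtag_names,
                           hto_library_size=data.hto_library_size)
    cov = pooled_covariance(clr, model)
    md = mahalanobis_distances(clr, model, cov)
    singlet_counts = []
    for q in (0.80, 0.90, 0.95, 0.99):
        res = initial_classify(md, model, data, cutoff_mode="quantile", q=q)
        assert len(res.category) == data.n_droplets
        singlet_counts.append(int(res.is_singlet().sum()))
    assert singlet_counts == sorted(singlet_counts)
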