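"""PCA, SOM training, elbow k-means and reference-system classification."""

import numpy as np
import pandas as pd
import pytest

from scutemark.multivariate import (
    FeatureMatrix,
    classify_new,
    cluster_som,
    feature_matrix,
    kmeans_elbow,
    pca,
    sample_clusters,
    som_train,
)
from scutemark.psm_model import apply_marker_cutoffs, assign_markers
from scutemark.synthetic_data import default_config_for_species, generate_cohort

GENUS_SPECIES = ["Chelonia mydas", "Caretta caretta", "Eretmochelys imbricata",
                 "Lepidochelys olivacea"]


def _reference(full_db, seed=0, n=5, **overrides):
    cfgs = [default_config_for_species(sp, n_specimens=n, seed=seed * 100 + j,
                                       **overrides)
            for j, sp in enumerate(GENUS_SPECIES)]
    cohort, truths = generate_cohort(cfgs, full_db)
    cohort = assign_markers(cohort, full_db)
    filtered, _ = apply_marker_cutoffs(cohort, full_db)
    return feature_matrix(filtered, full_db), truths


# -- PCA -------------------------------------------------------------------

def test_rank_one_matrix_has_single_component():
    X = np.outer([1.0, 2.0, 3.0, 4.0], [2.0, 0.5, 1.0])
    res = pca(X)
    assert res.explained_variance_ratio[0] == pytest.approx(1.0)


def test_duplicated_samples_share_coordinates():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(4, 6))
    X = np.vstack([X, X[1]])
    res = pca(X)
    assert np.allclose(res.scores[1], res.scores[-1])


def test_pca_agrees_with_eigendecomposition_oracle():
    rng = np.random.default_rng(42)
    for _ in range(5):
        X = rng.normal(size=(6, 10))
        res = pca(X)
        C = np.cov(X, rowvar=False, ddof=1)
        evals = np.sort(np.linalg.eigvalsh(C))[::-1]
        sv_var = (res.scores ** 2).sum(axis=0) / (X.shape[0] - 1)
        assert np.allclose(sv_var, evals[:len(sv_var)], atol=1e-8)
        frac = evals[evals > 1e-12]
        assert np.allclose(res.explained_variance_ratio[:len(frac)],
                           frac / frac.sum(), atol=1e-8)


def test_pca_reconstruction():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(8, 12))
    res = pca(X)
    back = res.scores @ res.loadings.T + res.mean
    assert np.allclose(back, X, atol=1e-8)


def test_pca_needs_two_samples():
    with pytest.raises(ValueError):
        pca(np.ones((1, 3)))


# -- SOM -------------------------------------------------------------------

def test_som_deterministic_for_fixed_seed():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(10, 5))
    a = som_train(X, iterations=500, seed=3)
    b = som_train(X, iterations=500, seed=3)
    assert np.array_equal(a.codebooks, b.codebooks)


def test_single_sample_attracts_all_codebooks():
    X = np.tile([3.0, -1.0, 2.0], (1, 1))
    model = som_train(X, grid=(2, 2), iterations=2000, seed=0)
    # centred data is the zero vector; all codebooks collapse onto it
    assert np.abs(model.codebooks).max() < 0.05


def test_separated_clusters_map_to_disjoint_nodes():
    rng = np.random.default_rng(5)
    a = rng.normal(0.0, 0.1, size=(10, 4))
    b = rng.normal(8.0, 0.1, size=(10, 4))
    X = np.vstack([a, b])
    model = som_train(X, grid=(3, 3), iterations=3000, seed=2)
    Xc = X - model.mean
    bmus_a = {model.bmu(x) for x in Xc[:10]}
    bmus_b = {model.bmu(x) for x in Xc[10:]}
    assert not (bmus_a & bmus_b)


def test_zero_radius_som_is_online_kmeans_step():
    """With a collapsed neighbourhood only the BMU moves, by lr*(x - w)."""
    X = np.array([[4.0, 0.0]])
    lr = 0.05
    model = som_train(X, grid=(2, 2), iterations=1, seed=9,
                      learning_rate=(lr, lr), radius=(1e-9, 1e-9))
    ref = som_train(X, grid=(2, 2), iterations=0, seed=9)  # init only
    x = X[0] - ref.mean
    bmu = int(np.argmin(((ref.codebooks - x) ** 2).sum(axis=1)))
    expect = ref.codebooks.copy()
    expect[bmu] += lr * (x - expect[bmu])
    assert np.allclose(model.codebooks, expect)


def test_som_model_json_round_trip():
    from scutemark.multivariate import SOMModel
    rng = np.random.default_rng(0)
    model = cluster_som(som_train(rng.normal(size=(6, 3)), grid=(2, 2),
                                  iterations=100, seed=1))
    again = SOMModel.from_json(model.to_json())
    assert np.allclose(again.codebooks, model.codebooks)
    assert again.n_clusters == model.n_clusters
    assert np.array_equal(again.node_clusters, model.node_clusters)


# -- elbow k-means ---------------------------------------------------------

def test_elbow_recovers_three_line_clusters():
    cb = np.array([[0.0], [0.1], [10.0], [10.1], [20.0], [20.1]])
    k, labels = kmeans_elbow(cb, k_max=5, seed=0)
    assert k == 3
    assert len(set(labels[:2])) == 1 and len(set(labels[2:4])) == 1


def test_identical_codebooks_collapse_to_one_cluster():
    k, labels = kmeans_elbow(np.ones((8, 3)), seed=0)
    assert k == 1 and set(labels) == {0}


def test_elbow_matches_wcss_curve_inspection():
    """The chosen k maximises the second difference of the WCSS curve."""
    from sklearn.cluster import KMeans
    rng = np.random.default_rng(3)
    cb = np.vstack([rng.normal(c, 0.05, size=(4, 2))
                    for c in ((0, 0), (5, 0), (0, 5), (5, 5))])
    k, _ = kmeans_elbow(cb, k_max=8, seed=0)
    wcss = {kk: KMeans(n_clusters=kk, n_init=10, random_state=0).fit(cb).inertia_
            for kk in range(1, 9)}
    lw = {kk: np.log(w) for kk, w in wcss.items()}
    dd = {kk: lw[kk - 1] - 2 * lw[kk] + lw[kk + 1] for kk in range(2, 8)}
    assert k == max(dd, key=dd.get) == 4


# -- reference classification ---------------------------------------------

def test_four_genus_reference_clusters_by_genus(full_db):
    X, truths = _reference(full_db, seed=0)
    som = cluster_som(som_train(X, iterations=10_000, seed=0), seed=0)
    assert som.n_clusters == 4
    labels = sample_clusters(som, X)
    genus = {sid: full_db.genus_map[truths[sid].species] for sid in labels.index}
    # each genus lands in exactly one cluster
    for g in set(genus.values()):
        members = [labels[sid] for sid in labels.index if genus[sid] == g]
        assert len(set(members)) == 1


def test_reference_sample_reassigned_to_its_cluster(full_db):
    X, _ = _reference(full_db, seed=1)
    som = cluster_som(som_train(X, iterations=5000, seed=1), seed=1)
    basis = pca(X)
    report = classify_new(som, basis, X)
    labels = sample_clusters(som, X)
    assert list(report["cluster"]) == list(labels.values)


def test_unknown_marker_columns_rejected(full_db):
    X, _ = _reference(full_db, seed=2, n=2)
    som = cluster_som(som_train(X, iterations=500, seed=2), seed=2)
    bogus = FeatureMatrix(pd.DataFrame([[1.0]], index=["q"], columns=["NOPE-1"]))
    with pytest.raises(ValueError, match="unknown markers"):
        classify_new(som, pca(X), bogus)


def test_missing_markers_zero_filled_and_zero_vector_flagged(full_db):
    X, _ = _reference(full_db, seed=3, n=2)
    som = cluster_som(som_train(X, iterations=500, seed=3), seed=3)
    q = FeatureMatrix(pd.DataFrame([[0.0]], index=["empty"],
                                   columns=[X.marker_ids[0]]))
    report = classify_new(som, pca(X), q)
    assert bool(report.loc[0, "low_information"])
    assert report.loc[0, "cluster"] in set(som.node_clusters)


def test_degraded_hawksbill_queries_join_hawksbill_cluster(full_db):
    """Archaeological-style queries at d=0.6 land in the E. imbricata cluster."""
    X, truths = _reference(full_db, seed=4)
    som = cluster_som(som_train(X, iterations=10_000, seed=4), seed=4)
    basis = pca(X)
    labels = sample_clusters(som, X)
    ei_ids = [sid for sid in labels.index
              if truths[sid].species == "Eretmochelys imbricata"]
    ei_cluster = set(labels[ei_ids])
    assert len(ei_cluster) == 1
    (ei_cluster,) = ei_cluster

    hits = 0
    n_rep = 20
    for rep in range(n_rep):
        cfg = default_config_for_species("Eretmochelys imbricata",
                                         n_specimens=1, d=0.6,
                                         sample_prefix="COMB", seed=9000 + rep)
        cohort, _ = generate_cohort([cfg], full_db)
        cohort = assign_markers(cohort, full_db)
        filtered, _ = apply_marker_cutoffs(cohort, full_db)
        q = feature_matrix(filtered, full_db)
        report = classify_new(som, basis, q)
        hits += int(report.loc[0, "cluster"] == ei_cluster)
    assert hits >= 0.9 * n_rep
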