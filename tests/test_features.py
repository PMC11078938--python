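"""Scaling, background-PC exclusion, silhouettes and panel subsampling."""

import numpy as np
import pandas as pd
import pytest

from cycliq import (
    pca_embed,
    scale_features,
    silhouette,
    spatial_silhouette,
    subsample_silhouette,
)

from _oracles import silhouette_loop


def _panel(rng, n=120, p=30, shift=3.0):
    """Two-condition feature table with a mean shift between conditions."""
    labels = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, p)) + shift * labels[:, None]
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(p)]), labels


def test_scale_is_z_then_arcsinh(rng):
    table = pd.DataFrame({"a": rng.normal(3, 2, 200), "b": rng.uniform(0, 9, 200)})
    scaled = scale_features(table)
    # undo the arcsinh: what remains must be the plain z-scores
    z = np.sinh(scaled)
    np.testing.assert_allclose(z.mean(0), 0.0, atol=1e-10)
    np.testing.assert_allclose(z.std(0, ddof=0), 1.0, atol=1e-10)
    # a value at the column mean maps to arcsinh(0) = 0
    at_mean = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
    out = scale_features(at_mean)
    assert out.iloc[1, 0] == pytest.approx(0.0, abs=1e-12)
    # a z-score of exactly 1 maps to arcsinh(1) = ln(1 + sqrt(2))
    unit = scale_features(pd.DataFrame({"a": [0.0, 0.0, 1.0, 1.0]}))
    assert unit.iloc[2, 0] == pytest.approx(np.log(1 + np.sqrt(2)), abs=1e-12)


def test_scale_constant_column_becomes_zero_with_warning(caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="cycliq.features"):
        out = scale_features(pd.DataFrame({"flat": [2.0, 2.0, 2.0], "v": [1.0, 2.0, 3.0]}))
    assert (out["flat"] == 0).all()
    assert "zero-variance" in caplog.text


def test_scale_missing_values_propagate():
    out = scale_features(pd.DataFrame({"a": [1.0, np.nan, 3.0, 5.0]}))
    assert np.isnan(out["a"].iloc[1])
    assert out["a"].notna().sum() == 3


def test_scale_order_flag_changes_result(rng):
    table = pd.DataFrame({"a": rng.lognormal(0, 1, 100)})
    default = scale_features(table)
    flipped = scale_features(table, arcsinh_first=True)
    assert not np.allclose(default["a"], flipped["a"])
    # the arcsinh-first variant ends z-scored
    np.testing.assert_allclose(flipped["a"].mean(), 0.0, atol=1e-10)


def test_pca_drops_background_component(rng):
    """With an additive global factor, PC1 tracks per-cell totals."""
    n, p = 300, 20
    background = rng.normal(0, 3, n)
    X = rng.normal(size=(n, p)) + background[:, None]
    emb = pca_embed(pd.DataFrame(X), k=6)
    assert emb.pc1_total_correlation > 0.9
    assert emb.scores.shape == (n, 5)
    # surviving components mutually orthogonal
    gram = emb.scores.T @ emb.scores
    np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)


def test_pca_k_bounds(rng):
    X = pd.DataFrame(rng.normal(size=(30, 5)))
    with pytest.raises(ValueError):
        pca_embed(X, k=6)
    with pytest.raises(ValueError):
        pca_embed(X, k=1)


def test_silhouette_well_separated_clusters(rng):
    a = rng.normal(0, 0.05, (40, 3))
    b = rng.normal(5, 0.05, (40, 3))
    res = silhouette(np.vstack([a, b]), np.repeat([0, 1], 40))
    assert res.mean > 0.9
    assert np.all(res.samples >= -1) and np.all(res.samples <= 1)


def test_silhouette_singleton_cluster_scores_zero(rng):
    X = np.vstack([rng.normal(0, 1, (10, 2)), [[50.0, 50.0]]])
    labels = np.array([0] * 10 + [1])
    res = silhouette(X, labels)
    assert res.samples[-1] == 0.0


def test_silhouette_single_cluster_errors(rng):
    with pytest.raises(ValueError):
        silhouette(rng.normal(size=(10, 2)), np.zeros(10))


@pytest.mark.parametrize("seed", range(5))
def test_silhouette_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 40))
    X = rng.normal(size=(n, 3))
    labels = rng.integers(0, 3, n)
    if len(np.unique(labels)) < 2:
        labels[0] = (labels[0] + 1) % 3
    got = silhouette(X, labels).samples
    np.testing.assert_allclose(got, silhouette_loop(X, labels), atol=1e-10)


def test_silhouette_invariant_to_rigid_motion_and_relabeling(rng):
    X = rng.normal(size=(30, 2))
    labels = rng.integers(0, 2, 30)
    labels[:2] = [0, 1]
    base = silhouette(X, labels).samples
    theta = 0.8
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = X @ R.T + np.array([10.0, -4.0])
    np.testing.assert_allclose(silhouette(moved, labels).samples, base, atol=1e-9)
    np.testing.assert_allclose(silhouette(X, 1 - labels).samples, base, atol=1e-12)


def test_spatial_silhouette_is_silhouette_on_coordinates(rng):
    coords = rng.uniform(0, 100, (40, 2))
    labels = rng.integers(0, 2, 40)
    labels[:2] = [0, 1]
    a = spatial_silhouette(coords, labels)
    b = silhouette(coords, labels)
    np.testing.assert_allclose(a.samples, b.samples)


def test_subsample_shapes_reproducibility_and_full_panel(rng):
    table, labels = _panel(rng, n=80, p=30)
    res = subsample_silhouette(table, labels, sizes=(10, 30), reps=5,
                               pc_range=(2, 6), seed=3)
    assert set(res.means) == {10, 30}
    assert all(len(v) == 5 for v in res.means.values())
    again = subsample_silhouette(table, labels, sizes=(10, 30), reps=5,
                                 pc_range=(2, 6), seed=3)
    for size in res.means:
        np.testing.assert_array_equal(res.means[size], again.means[size])
    # the full panel is always the same draw -> identical values every rep
    np.testing.assert_allclose(res.means[30], res.means[30][0])


def test_subsample_size_exceeding_panel_errors(rng):
    table, labels = _panel(rng, n=40, p=12)
    with pytest.raises(ValueError):
        subsample_silhouette(table, labels, sizes=(25,), reps=2, seed=0)
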