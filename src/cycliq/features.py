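"""Feature scaling, background-PC exclusion and silhouette analyses.

Per-cell marker intensities are z-transformed per feature (mean 0, sd 1)
and then arcsinh-transformed, in that order.  PCA is run on the scaled
matrix and the first component is dropped: in cyclic immunofluorescence it
tracks the per-cell total signal (staining efficiency / background) rather
than biology, which is verified by reporting its correlation with the
per-cell feature totals.

Silhouette coefficients (Euclidean, sample labels as clusters) quantify
cluster cohesion; the antibody-subsampling analysis repeats the
scale-PCA-silhouette pipeline on randomly drawn feature panels to measure
how separation performance depends on panel size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

__all__ = [
    "scale_features",
    "pca_embed",
    "EmbeddingPCs",
    "silhouette",
    "SilhouetteResult",
    "subsample_silhouette",
    "SubsampleResult",
    "spatial_silhouette",
]

log = logging.getLogger(__name__)


def scale_features(
    table: pd.DataFrame, arcsinh_first: bool = False
) -> pd.DataFrame:
    """Per-feature z-transform followed by arcsinh (the pipeline default).

    Missing values propagate.  A zero-variance column maps to all zeros with
    a warning rather than an error.  ``arcsinh_first=True`` gives the more
    conventional arcsinh-then-z order for comparison runs.
    """
    X = table.astype(float).copy()

    def _z(df: pd.DataFrame) -> pd.DataFrame:
        mean = df.mean(axis=0)
        sd = df.std(axis=0, ddof=0)
        flat = sd == 0
        if flat.any():
            log.warning("zero-variance feature(s) mapped to 0: %s",
                        list(df.columns[flat]))
        sd = sd.mask(flat, 1.0)
        return (df - mean) / sd

    if arcsinh_first:
        return _z(np.arcsinh(X))
    return np.arcsinh(_z(X))


@dataclass
class EmbeddingPCs:
    """PCA scores with the first (background) component removed."""

    scores: np.ndarray             # cells x (k - 1), components 2..k
    explained_variance: np.ndarray  # variances of components 2..k
    pc1_total_correlation: float   # |corr| of dropped PC1 with row totals


def pca_embed(scaled: pd.DataFrame | np.ndarray, k: int) -> EmbeddingPCs:
    """Standard PCA scores with component 1 dropped.

    ``k`` counts components *including* the dropped first one, so the
    result has k - 1 columns.  Component signs are fixed by making the
    largest-magnitude loading of each component positive.  The correlation
    between PC1 and per-cell totals is computed and logged as evidence that
    PC1 is the global background factor.
    """
    X = scaled.to_numpy(dtype=float) if isinstance(scaled, pd.DataFrame) else np.asarray(scaled, float)
    if k < 2:
        raise ValueError("k must be >= 2 (component 1 is dropped)")
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds the {X.shape[1]} available features")
    if X.shape[0] < k:
        raise ValueError("need at least k observations")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(k):
        comp = pca.components_[j]
        i = np.argmax(np.abs(comp))
        if comp[i] < 0:
            scores[:, j] *= -1
    totals = X.sum(axis=1)
    if np.std(totals) == 0 or np.std(scores[:, 0]) == 0:
        corr = 0.0
    else:
        corr = float(abs(np.corrcoef(scores[:, 0], totals)[0, 1]))
    log.info("dropped PC1; |corr(PC1, per-cell totals)| = %.3f", corr)
    return EmbeddingPCs(
        scores=scores[:, 1:],
        explained_variance=pca.explained_variance_[1:].copy(),
        pc1_total_correlation=corr,
    )


@dataclass
class SilhouetteResult:
    """Per-point silhouettes s(i) in [-1, 1] and their mean."""

    samples: np.ndarray
    mean: float
    labels: np.ndarray


def silhouette(X: np.ndarray, labels: np.ndarray) -> SilhouetteResult:
    """Classical silhouette with Euclidean distance.

    s(i) = (b - a) / max(a, b) with a the mean distance to the own cluster
    and b the smallest mean distance to another cluster; points in singleton
    clusters get s = 0 by convention.  Requires >= 2 distinct labels.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    s = silhouette_samples(X, labels, metric="euclidean")
    return SilhouetteResult(samples=s, mean=float(s.mean()), labels=labels)


def spatial_silhouette(coords: np.ndarray, labels: np.ndarray) -> SilhouetteResult:
    """Silhouette of cluster labels in tissue space (2-D cell coordinates)."""
    return silhouette(np.asarray(coords, dtype=float), labels)


@dataclass
class SubsampleResult:
    """Mean silhouettes of repeatedly subsampled feature panels."""

    sizes: tuple[int, ...]
    means: dict[int, np.ndarray]  # size -> reps values
    seed: int
    pc_range: tuple[int, int]
    notes: list[str] = field(default_factory=list)


def subsample_silhouette(
    table: pd.DataFrame,
    labels: np.ndarray,
    sizes: tuple[int, ...] = (25, 50, 100),
    reps: int = 100,
    pc_range: tuple[int, int] = (2, 20),
    seed: int = 0,
) -> SubsampleResult:
    """Silhouette of random feature panels, repeated ``reps`` times per size.

    Each repetition samples ``size`` features without replacement, rescales
    them, runs PCA and scores the silhouette on components
    ``pc_range[0]..pc_range[1]`` (fewer when the panel limits the rank,
    which is recorded in ``notes``).  Per-repetition RNG substreams derive
    deterministically from ``seed``.
    """
    n_features = table.shape[1]
    if max(sizes) > n_features:
        raise ValueError(
            f"requested panel of {max(sizes)} from only {n_features} features"
        )
    pc_lo, pc_hi = pc_range
    if pc_lo < 2:
        raise ValueError("pc_range must start at component 2 or later")
    ss = np.random.SeedSequence(seed)
    means: dict[int, np.ndarray] = {}
    notes: list[str] = []
    columns = np.array(table.columns)
    for si, size in enumerate(sizes):
        vals = np.empty(reps)
        for rep in range(reps):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(si, rep))
            )
            panel = columns[rng.choice(n_features, size=size, replace=False)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # tiny panels can be rank-deficient
                scaled = scale_features(table[panel])
                k = min(pc_hi, size, scaled.shape[0] - 1)
                emb = pca_embed(scaled, k)
            if k < pc_hi:
                notes.append(f"size {size} rep {rep}: only PCs 2..{k} available")
            pcs = emb.scores[:, pc_lo - 2 : pc_hi - 1]
            vals[rep] = silhouette(pcs, labels).mean
        means[size] = vals
    return SubsampleResult(sizes=tuple(sizes), means=means, seed=seed,
                           pc_range=pc_range, notes=notes)
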