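"""Manifold embedding of methylomes: 2 coordinates for visualization,
5 for classification.

The reducer is a neighbor-graph manifold approximation algorithm (UMAP)
consumed as a dependency; this module owns the probe-order contract, the
seeding, and out-of-sample transform semantics.  A weighted k-NN
interpolation of training coordinates is available as a fallback transform
for single-specimen clinical inference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datamodel import BetaMatrix, ValidationError


def _as_array(X, probe_order=None):
    if isinstance(X, BetaMatrix):
        if not X.is_complete():
            raise ValidationError("embedding requires a complete matrix; impute first")
        if probe_order is not None and X.probe_ids != probe_order:
            raise ValidationError("probe order does not match the fitted embedding")
        return X.values, X.probe_ids, X.sample_ids
    if isinstance(X, pd.DataFrame):
        if X.isna().to_numpy().any():
            raise ValidationError("embedding requires a complete matrix; impute first")
        if probe_order is not None and list(X.columns) != probe_order:
            raise ValidationError("probe order does not match the fitted embedding")
        return X.to_numpy(dtype=float), list(X.columns), list(X.index)
    arr = np.asarray(X, dtype=float)
    if np.isnan(arr).any():
        raise ValidationError("embedding requires a complete matrix; impute first")
    if probe_order is not None and arr.shape[1] != len(probe_order):
        raise ValidationError("probe count does not match the fitted embedding")
    return arr, probe_order, None


class ManifoldEmbedding(BaseEstimator, TransformerMixin):
    """Seeded neighbor-graph embedding with out-of-sample transform.

    Parameters
    ----------
    n_dims : int
        Output dimensionality (2 for visualization, 5 for classification).
    seed : int
        Random seed; fit and transform are deterministic given the seed.
    n_neighbors, min_dist : reducer hyperparameters at their published defaults.
    oos_strategy : {"native", "knn"}
        Out-of-sample transform: the reducer's native transform, or weighted
        k-NN interpolation of training coordinates in probe space.
    """

    def __init__(self, n_dims: int = 5, seed: int = 0, n_neighbors: int = 15,
                 min_dist: float = 0.1, oos_strategy: str = "native",
                 knn_k: int = 10):
        self.n_dims = n_dims
        self.seed = seed
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.oos_strategy = oos_strategy
        self.knn_k = knn_k

    def fit(self, X, y=None):
        arr, probes, samples = _as_array(X)
        if arr.shape[0] < 10 * self.n_dims:
            raise ValidationError(
                f"need at least {10 * self.n_dims} samples to fit a "
                f"{self.n_dims}-dimensional embedding (got {arr.shape[0]})"
            )
        import umap

        self.reducer_ = umap.UMAP(
            n_components=self.n_dims,
            n_neighbors=self.n_neighbors,
            min_dist=self.min_dist,
            random_state=self.seed,
        )
        self.embedding_ = np.asarray(self.reducer_.fit_transform(arr), dtype=float)
        if not np.isfinite(self.embedding_).all():
            raise ValidationError("embedding produced non-finite coordinates")
        self.probe_order_ = probes
        self.sample_ids_ = samples
        self.training_data_ = arr
        return self

    def transform(self, X):
        check_is_fitted(self, "embedding_")
        arr, _, _ = _as_array(X, probe_order=self.probe_order_)
        if arr.shape[0] == 0:
            return np.empty((0, self.n_dims))
        if self.oos_strategy == "knn":
            return self._knn_transform(arr)
        coords = np.asarray(self.reducer_.transform(arr), dtype=float)
        return coords

    def _knn_transform(self, arr: np.ndarray) -> np.ndarray:
        """Inverse-distance weighted average of the k nearest training coordinates."""
        from sklearn.metrics import pairwise_distances

        d = pairwise_distances(arr, self.training_data_)
        k = min(self.knn_k, d.shape[1])
        idx = np.argsort(d, axis=1)[:, :k]
        out = np.empty((arr.shape[0], self.n_dims))
        for i in range(arr.shape[0]):
            dists = d[i, idx[i]]
            w = 1.0 / np.maximum(dists, 1e-12)
            w /= w.sum()
            out[i] = (w[:, None] * self.embedding_[idx[i]]).sum(axis=0)
        return out

    # the fitted reducer caches numba-compiled distance functions whose pickle
    # embeds per-process UUIDs; strip them so serialized models are
    # byte-reproducible, and rebuild them from the metric registry on load
    _VOLATILE_REDUCER_ATTRS = (
        "_input_distance_func", "_output_distance_func", "_inverse_distance_func",
    )

    def __getstate__(self):
        state = self.__dict__.copy()
        reducer = state.pop("reducer_", None)
        if reducer is not None:
            rstate = reducer.__dict__.copy()
            for key in self._VOLATILE_REDUCER_ATTRS:
                rstate.pop(key, None)
            state["_reducer_state"] = rstate
        return state

    def __setstate__(self, state):
        rstate = state.pop("_reducer_state", None)
        self.__dict__.update(state)
        if rstate is not None:
            import umap
            from umap import distances as dist

            reducer = object.__new__(umap.UMAP)
            reducer.__dict__.update(rstate)
            reducer._input_distance_func = dist.named_distances[reducer.metric]
            reducer._inverse_distance_func = dist.named_distances_with_gradients.get(
                reducer.metric)
            reducer._output_distance_func = dist.named_distances_with_gradients[
                reducer.output_metric]
            self.reducer_ = reducer

    def coordinates_frame(self, coords=None, sample_ids=None) -> pd.DataFrame:
        """Coordinates as a DataFrame (sample_id, dim1..dimd) for export."""
        check_is_fitted(self, "embedding_")
        if coords is None:
            coords, sample_ids = self.embedding_, self.sample_ids_
        cols = [f"dim{i + 1}" for i in range(self.n_dims)]
        return pd.DataFrame(np.asarray(coords), index=sample_ids, columns=cols)


def fit_embedding(matrix, n_dims: int = 5, seed: int = 0, **kwargs) -> ManifoldEmbedding:
    """Fit a seeded embedding on a complete beta matrix."""
    return ManifoldEmbedding(n_dims=n_dims, seed=seed, **kwargs).fit(matrix)


def transform(model: ManifoldEmbedding, new_samples) -> np.ndarray:
    """Map new samples onto a fitted embedding (one coordinate row per sample)."""
    return model.transform(new_samples)
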