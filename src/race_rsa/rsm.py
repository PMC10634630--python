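"""Representational similarity matrices from labelled feature arrays.

A :class:`FeatureSet` holds the activation matrix of one network layer
(images x features) together with a race label, an identity label and a
unique id per image.  The representational geometry of the layer is
summarised by the Pearson correlation between the feature vectors of every
pair of images (:class:`SimilarityMatrix`).  Trial-level pair tables
(same/different-identity face pairs) are plain :class:`pandas.DataFrame`
objects with a fixed column schema, validated by :func:`validate_pair_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "FeatureSet",
    "SimilarityMatrix",
    "PAIR_COLUMNS",
    "flatten_features",
    "build_similarity_matrix",
    "pair_similarity",
    "validate_pair_table",
]

#: Required columns of a pair table.  ``prop_same`` (behavioural proportion of
#: "same identity" responses) is optional and added by behaviour aggregation.
PAIR_COLUMNS = ("trial_id", "image_id_a", "image_id_b", "race", "same_identity")


def _as_str_array(x, name: str, n: int) -> np.ndarray:
    arr = np.asarray(x, dtype=object)
    if arr.ndim != 1 or arr.shape[0] != n:
        raise DataError(f"{name} must be a length-{n} 1-D sequence, got shape {arr.shape}")
    return np.asarray([str(v) for v in arr], dtype=object)


@dataclass
class FeatureSet:
    """Activation matrix for one layer with per-image labels.

    Parameters
    ----------
    layer_name
        Free-text layer identifier (e.g. ``"Conv5.3"``, ``"Fc7"``).
    activations
        ``(n_images, n_features)`` real matrix, arbitrary units.
    race_labels, identity_labels, image_ids
        Length ``n_images`` per-image annotations; ``image_ids`` must be unique.
    """

    layer_name: str
    activations: np.ndarray
    race_labels: np.ndarray
    identity_labels: np.ndarray
    image_ids: np.ndarray

    def __post_init__(self) -> None:
        self.activations = np.asarray(self.activations, dtype=np.float64)
        if self.activations.ndim != 2:
            raise DataError(
                f"activations must be 2-D (images x features), got ndim={self.activations.ndim}"
            )
        n = self.activations.shape[0]
        if n < 2:
            raise DataError("a FeatureSet needs at least 2 images")
        if self.activations.shape[1] < 2:
            raise DataError(
                "a FeatureSet needs at least 2 features per image "
                "(Pearson correlation is undefined otherwise)"
            )
        self.race_labels = _as_str_array(self.race_labels, "race_labels", n)
        self.identity_labels = _as_str_array(self.identity_labels, "identity_labels", n)
        self.image_ids = _as_str_array(self.image_ids, "image_ids", n)
        if len(set(self.image_ids)) != n:
            raise DataError("image_ids must be unique")

    @property
    def n_images(self) -> int:
        return self.activations.shape[0]

    @property
    def n_features(self) -> int:
        return self.activations.shape[1]


@dataclass
class SimilarityMatrix:
    """Symmetric image x image Pearson-correlation matrix with unit diagonal."""

    values: np.ndarray
    image_ids: np.ndarray
    race_labels: np.ndarray
    identity_labels: np.ndarray
    layer_name: str = "layer"
    _index: dict = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise DataError(f"similarity values must be square, got shape {self.values.shape}")
        n = self.values.shape[0]
        self.image_ids = _as_str_array(self.image_ids, "image_ids", n)
        self.race_labels = _as_str_array(self.race_labels, "race_labels", n)
        self.identity_labels = _as_str_array(self.identity_labels, "identity_labels", n)
        if len(set(self.image_ids)) != n:
            raise DataError("image_ids must be unique")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise DataError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-8):
            raise DataError("similarity matrix diagonal must be 1")
        if np.nanmax(np.abs(self.values)) > 1 + 1e-8:
            raise DataError("correlations must lie in [-1, 1]")
        self._index = {im: i for i, im in enumerate(self.image_ids)}

    @property
    def n_images(self) -> int:
        return self.values.shape[0]

    def index_of(self, image_id: str) -> int:
        try:
            return self._index[str(image_id)]
        except KeyError:
            raise DataError(f"unknown image_id {image_id!r}") from None


def flatten_features(
    raw: Sequence[np.ndarray],
    image_ids: Sequence[str],
    race_labels: Sequence[str],
    identity_labels: Sequence[str],
    layer_name: str = "layer",
) -> FeatureSet:
    """Flatten per-image activation tensors (any shape) into a FeatureSet.

    Every image's tensor must have the same shape; flattening is row-major
    (C order), so a ``224 x 224 x 64`` convolutional map becomes a
    3 211 264-long vector.  Row order follows input order.
    """
    raw = [np.asarray(a) for a in raw]
    if len(raw) == 0:
        raise DataError("no images supplied")
    ids = [str(i) for i in image_ids]
    if len(ids) != len(raw):
        raise DataError("image_ids length does not match number of images")
    ref_shape = raw[0].shape
    for im, a in zip(ids, raw):
        if a.shape != ref_shape:
            raise DataError(
                f"activation shape mismatch for image {im!r}: {a.shape} != {ref_shape}"
            )
    mat = np.stack([a.ravel(order="C") for a in raw])
    return FeatureSet(
        layer_name=layer_name,
        activations=mat,
        race_labels=np.asarray(race_labels, dtype=object),
        identity_labels=np.asarray(identity_labels, dtype=object),
        image_ids=np.asarray(ids, dtype=object),
    )


def build_similarity_matrix(fs: FeatureSet) -> SimilarityMatrix:
    """Pearson-correlate every pair of image feature vectors.

    Computed in double precision; the diagonal is forced to exactly 1 and the
    matrix symmetrised to remove last-bit asymmetry.  Raises
    :class:`DataError` naming the offending image if any feature row has zero
    variance (correlation undefined).
    """
    X = fs.activations
    sd = X.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DataError(
            f"zero-variance feature vector for image {fs.image_ids[bad[0]]!r}; "
            "Pearson correlation undefined"
        )
    C = np.corrcoef(X)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return SimilarityMatrix(
        values=C,
        image_ids=fs.image_ids,
        race_labels=fs.race_labels,
        identity_labels=fs.identity_labels,
        layer_name=fs.layer_name,
    )


def validate_pair_table(pairs: pd.DataFrame, require_prop_same: bool = False) -> pd.DataFrame:
    """Check a pair table has the required columns and sane values."""
    missing = [c for c in PAIR_COLUMNS if c not in pairs.columns]
    if missing:
        raise DataError(f"pair table missing columns: {missing}")
    if require_prop_same:
        if "prop_same" not in pairs.columns:
            raise DataError("pair table missing column: ['prop_same']")
        p = pairs["prop_same"].to_numpy(dtype=float)
        if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
            raise DataError("prop_same must lie in [0, 1]")
    return pairs


def pair_similarity(sm: SimilarityMatrix, pairs: pd.DataFrame) -> np.ndarray:
    """Look up the correlation for each trial's image pair, order preserved."""
    validate_pair_table(pairs)
    ia = np.fromiter((sm.index_of(i) for i in pairs["image_id_a"]), dtype=np.intp,
                     count=len(pairs))
    ib = np.fromiter((sm.index_of(i) for i in pairs["image_id_b"]), dtype=np.intp,
                     count=len(pairs))
    return sm.values[ia, ib]
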