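"""Readers and writers for the pipeline's on-disk formats.

Tables are CSV (long/tidy schemas with fixed column names), feature and
voxel-pattern arrays are HDF5, statistical maps and ROI masks are NIfTI.
Round-trips preserve values to double precision, grids/affines, and mask
bits.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import DataError
from .mvpa import VoxelPatternSet
from .rsm import FeatureSet, SimilarityMatrix, validate_pair_table

__all__ = [
    "save_feature_sets", "load_feature_sets",
    "save_similarity_matrix", "load_similarity_matrix",
    "save_labels", "load_labels",
    "save_pair_table", "load_pair_table",
    "save_voxel_patterns", "load_voxel_patterns",
    "voxel_patterns_to_long", "voxel_patterns_from_long",
]

_STR = h5py.string_dtype(encoding="utf-8")


def _write_str(group, name, values) -> None:
    group.create_dataset(name, data=np.asarray(values, dtype=object), dtype=_STR)


def _read_str(group, name) -> np.ndarray:
    return np.asarray([v.decode() if isinstance(v, bytes) else str(v)
                       for v in group[name][()]], dtype=object)


# -- FeatureSet (HDF5: one group per layer) ---------------------------------

def save_feature_sets(feature_sets, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["layer_order"] = [fs.layer_name for fs in feature_sets]
        for fs in feature_sets:
            g = f.create_group(fs.layer_name)
            g.create_dataset("activations", data=fs.activations)
            _write_str(g, "image_ids", fs.image_ids)
            _write_str(g, "race_labels", fs.race_labels)
            _write_str(g, "identity_labels", fs.identity_labels)


def load_feature_sets(path) -> list:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    out = []
    with h5py.File(path, "r") as f:
        order = [n if isinstance(n, str) else n.decode()
                 for n in f.attrs.get("layer_order", list(f.keys()))]
        for name in order:
            if name not in f:
                raise DataError(f"{path}: layer {name!r} listed but missing")
            g = f[name]
            out.append(FeatureSet(
                layer_name=name,
                activations=g["activations"][()],
                race_labels=_read_str(g, "race_labels"),
                identity_labels=_read_str(g, "identity_labels"),
                image_ids=_read_str(g, "image_ids"),
            ))
    return out


# -- SimilarityMatrix (CSV matrix + CSV labels) -----------------------------

def save_similarity_matrix(sm: SimilarityMatrix, path) -> None:
    """Matrix CSV with image_id header row and column."""
    pd.DataFrame(sm.values, index=sm.image_ids, columns=sm.image_ids).to_csv(
        path, index_label="image_id"
    )


def save_labels(sm_or_fs, path) -> None:
    pd.DataFrame({
        "image_id": sm_or_fs.image_ids,
        "race": sm_or_fs.race_labels,
        "identity": sm_or_fs.identity_labels,
    }).to_csv(path, index=False)


def load_labels(path) -> pd.DataFrame:
    df = _read_csv(path, ["image_id", "race", "identity"])
    return df.astype(str)


def load_similarity_matrix(matrix_path, labels_path, layer_name=None) -> SimilarityMatrix:
    try:
        df = pd.read_csv(matrix_path, index_col=0)
    except Exception as exc:  # noqa: BLE001 — surface parse context
        raise DataError(f"cannot parse similarity matrix {matrix_path}: {exc}") from exc
    if df.shape[0] != df.shape[1] or not (df.index.astype(str) == df.columns.astype(str)).all():
        raise DataError(f"{matrix_path}: matrix must be square with matching id row/column")
    labels = load_labels(labels_path).set_index("image_id")
    ids = df.index.astype(str)
    missing = [i for i in ids if i not in labels.index]
    if missing:
        raise DataError(f"{labels_path}: labels missing for images {missing[:5]}")
    labels = labels.loc[ids]
    return SimilarityMatrix(
        values=df.to_numpy(dtype=np.float64),
        image_ids=np.asarray(ids, dtype=object),
        race_labels=labels["race"].to_numpy(dtype=object),
        identity_labels=labels["identity"].to_numpy(dtype=object),
        layer_name=layer_name or Path(str(matrix_path)).stem,
    )


# -- pair tables ------------------------------------------------------------

def _read_csv(path, required_columns) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise DataError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    return df


def save_pair_table(pairs: pd.DataFrame, path) -> None:
    validate_pair_table(pairs)
    pairs.to_csv(path, index=False)


def load_pair_table(path) -> pd.DataFrame:
    df = _read_csv(path, ["trial_id", "image_id_a", "image_id_b", "race", "same_identity"])
    df["same_identity"] = df["same_identity"].astype(bool)
    return validate_pair_table(df)


# -- VoxelPatternSet (HDF5 or long CSV) -------------------------------------

def save_voxel_patterns(vps: VoxelPatternSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("responses", data=vps.responses)
        _write_str(f, "participant_group", vps.participant_group)
        _write_str(f, "condition_labels", vps.condition_labels)
        _write_str(f, "participant_ids", vps.participant_ids)


def load_voxel_patterns(path) -> VoxelPatternSet:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    with h5py.File(path, "r") as f:
        for key in ("responses", "participant_group", "condition_labels"):
            if key not in f:
                raise DataError(f"{path}: missing dataset {key!r}")
        return VoxelPatternSet(
            responses=f["responses"][()],
            participant_group=_read_str(f, "participant_group"),
            condition_labels=_read_str(f, "condition_labels"),
            participant_ids=_read_str(f, "participant_ids") if "participant_ids" in f else None,
        )


def voxel_patterns_to_long(vps: VoxelPatternSet) -> pd.DataFrame:
    n_p, n_c, n_v = vps.responses.shape
    return pd.DataFrame({
        "participant": np.repeat(vps.participant_ids, n_c * n_v),
        "group": np.repeat(vps.participant_group, n_c * n_v),
        "condition": np.tile(np.repeat(vps.condition_labels, n_v), n_p),
        "voxel": np.tile(np.arange(n_v), n_p * n_c),
        "value": vps.responses.ravel(),
    })


def voxel_patterns_from_long(df: pd.DataFrame) -> VoxelPatternSet:
    for col in ("participant", "group", "condition", "voxel", "value"):
        if col not in df.columns:
            raise DataError(f"long-format pattern table missing column {col!r}")
    pids = df["participant"].drop_duplicates().to_numpy(dtype=object)
    conds = df["condition"].drop_duplicates().to_numpy(dtype=object)
    voxels = np.sort(df["voxel"].unique())
    cube = (
        df.set_index(["participant", "condition", "voxel"])["value"]
        .unstack(["condition", "voxel"])
    )
    if cube.isna().any().any():
        raise DataError("long-format pattern table is incomplete")
    groups = df.drop_duplicates("participant").set_index("participant")["group"]
    responses = np.empty((len(pids), len(conds), len(voxels)))
    for ci, c in enumerate(conds):
        responses[:, ci, :] = cube[c].loc[pids, voxels].to_numpy()
    return VoxelPatternSet(
        responses=responses,
        participant_group=groups.loc[pids].to_numpy(dtype=object),
        condition_labels=conds,
        participant_ids=pids,
    )
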