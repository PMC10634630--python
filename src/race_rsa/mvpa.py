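"""Leave-one-participant-out pattern similarity and fMR adaptation.

A :class:`VoxelPatternSet` holds per-participant, per-condition voxel
response patterns (GLM parameter estimates) for one ROI, plus a participant
group label (participant race).  The MVPA pipeline:

1. normalise patterns by subtracting, per voxel and participant, the mean
   response across the analysed conditions;
2. for every participant and ordered condition pair (i, j), correlate the
   participant's pattern for i with the group template for j — the voxelwise
   mean over the *remaining* participants of their group (leave one
   participant out, LOPO) — and Fisher-z the correlation;
3. average z over pair types to form the factorial contrasts: same-race vs
   different-race faces, the own-race (Face x ParticipantGroup) interaction,
   and face-face vs face-object category similarity.

Adaptation is a univariate magnitude, not a pattern: the mean unnormalised
ROI response to Different-Identity blocks minus Same-Identity blocks
(positive = repetition suppression).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .behaviour import fisher_transform
from .decoding import cohens_d
from .errors import DataError

__all__ = [
    "VoxelPatternSet",
    "OwnRaceBiasResult",
    "normalize_patterns",
    "lopo_similarity",
    "race_similarity_contrast",
    "own_race_bias_contrast",
    "category_contrast",
    "adaptation_index",
]


@dataclass
class VoxelPatternSet:
    """participants x conditions x voxels response array with labels.

    ``condition_labels`` are free text; by convention the synthetic
    generator and pipeline use ``"<race>/different"`` and ``"<race>/same"``
    for the two block arrangements, and ``"Object/..."`` for pareidolic
    objects.
    """

    responses: np.ndarray
    participant_group: np.ndarray
    condition_labels: np.ndarray
    participant_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=np.float64)
        if self.responses.ndim != 3:
            raise DataError("responses must be 3-D (participants x conditions x voxels)")
        n_p, n_c, _ = self.responses.shape
        self.participant_group = np.asarray(
            [str(g) for g in np.asarray(self.participant_group)], dtype=object
        )
        self.condition_labels = np.asarray(
            [str(c) for c in np.asarray(self.condition_labels)], dtype=object
        )
        if self.participant_group.shape[0] != n_p:
            raise DataError("participant_group length does not match responses")
        if self.condition_labels.shape[0] != n_c:
            raise DataError("condition_labels length does not match responses")
        if n_c < 2:
            raise DataError("need at least 2 conditions")
        if len(set(self.condition_labels)) != n_c:
            raise DataError("condition labels must be unique")
        if self.participant_ids is None:
            self.participant_ids = np.asarray(
                [f"p{i:03d}" for i in range(n_p)], dtype=object
            )
        else:
            self.participant_ids = np.asarray(
                [str(p) for p in np.asarray(self.participant_ids)], dtype=object
            )
            if self.participant_ids.shape[0] != n_p:
                raise DataError("participant_ids length does not match responses")

    @property
    def n_participants(self) -> int:
        return self.responses.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.responses.shape[2]

    def condition_index(self, label: str) -> int:
        hits = np.flatnonzero(self.condition_labels == str(label))
        if hits.size == 0:
            raise DataError(f"unknown condition {label!r}")
        return int(hits[0])


def normalize_patterns(
    vps: VoxelPatternSet, condition_subset: Sequence[str]
) -> VoxelPatternSet:
    """Subtract the per-voxel mean over the given conditions, per participant.

    Only the conditions in the subset are normalised (and returned); after
    normalisation their per-voxel mean is ~0 for every participant.
    """
    if len(condition_subset) == 0:
        raise DataError("condition subset must be non-empty")
    idx = [vps.condition_index(c) for c in condition_subset]
    sub = vps.responses[:, idx, :]
    centred = sub - sub.mean(axis=1, keepdims=True)
    return VoxelPatternSet(
        responses=centred,
        participant_group=vps.participant_group,
        condition_labels=np.asarray(condition_subset, dtype=object),
        participant_ids=vps.participant_ids,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd @ xd) * (yd @ yd))
    if denom == 0:
        raise DataError("zero-variance pattern; correlation undefined")
    return float(np.clip((xd @ yd) / denom, -1.0, 1.0))


def lopo_similarity(
    vps: VoxelPatternSet, conditions: Sequence[str] | None = None
) -> pd.DataFrame:
    """Leave-one-participant-out pattern correlations for all ordered pairs.

    For each participant p and ordered condition pair (i, j): Pearson r
    between p's pattern for i and the mean pattern for j over the other
    participants of p's group, plus its Fisher z.  Each group needs >= 2
    participants.
    """
    if conditions is None:
        conditions = list(vps.condition_labels)
    cidx = np.asarray([vps.condition_index(c) for c in conditions])
    groups = vps.participant_group
    for g in set(groups):
        if (groups == g).sum() < 2:
            raise DataError(f"group {g!r} has a single participant; LOPO needs >= 2")
    R = vps.responses[:, cidx, :]
    rows = []
    for g in sorted(set(groups)):
        members = np.flatnonzero(groups == g)
        gsum = R[members].sum(axis=0)  # (n_cond, n_voxels)
        for p in members:
            template = (gsum - R[p]) / (members.size - 1)  # excludes participant p
            for i, ci in enumerate(conditions):
                for j, cj in enumerate(conditions):
                    r = _pearson(R[p, i], template[j])
                    rows.append(
                        dict(participant=vps.participant_ids[p], group=g,
                             cond_a=ci, cond_b=cj, r=r, z=fisher_transform(r))
                    )
    return pd.DataFrame(rows)


def race_similarity_contrast(
    ps: pd.DataFrame, face_conditions: Sequence[str]
) -> pd.DataFrame:
    """Per-participant mean z for same-race vs different-race face pairs.

    Same-race pairs are the diagonal condition pairs (Asian-Asian, ...);
    different-race pairs are all ordered cross-race pairs.  All face pair
    types must be present for every participant.
    """
    faces = [str(c) for c in face_conditions]
    sub = ps[ps["cond_a"].isin(faces) & ps["cond_b"].isin(faces)]
    rows = []
    for (pid, grp), d in sub.groupby(["participant", "group"], sort=False):
        have = set(zip(d["cond_a"], d["cond_b"]))
        need = {(a, b) for a in faces for b in faces}
        if have < need:
            raise DataError(
                f"participant {pid!r} missing condition pairs: {sorted(need - have)}"
            )
        same = d[d["cond_a"] == d["cond_b"]]["z"].mean()
        diff = d[d["cond_a"] != d["cond_b"]]["z"].mean()
        rows.append(dict(participant=pid, group=grp, same_race=same,
                         different_race=diff, difference=same - diff))
    return pd.DataFrame(rows)


@dataclass
class OwnRaceBiasResult:
    """2x2 Face x ParticipantGroup cell means with the own-race interaction."""

    cell_means: pd.DataFrame  # index: face condition, columns: participant group
    interaction: float        # mean over groups of (own-race z - other-race z)
    per_participant: pd.DataFrame
    group_tests: pd.DataFrame


def own_race_bias_contrast(
    ps: pd.DataFrame,
    face_conditions: Sequence[str] = ("Asian", "White"),
    groups: Sequence[str] = ("Asian", "White"),
    face_to_group: Mapping[str, str] | None = None,
) -> OwnRaceBiasResult:
    """Own-race consistency advantage from same-condition LOPO similarities.

    Restricts to the diagonal (face-face) pairs of the two given face
    conditions and forms the Face x ParticipantGroup table of mean z.  The
    interaction contrast is (own-race - other-race) averaged over groups;
    per group, a one-tailed paired t (own > other) and Cohen's d are
    attached.  ``face_to_group`` maps face condition -> owning group
    (defaults to same name).
    """
    faces = [str(f) for f in face_conditions]
    groups = [str(g) for g in groups]
    if face_to_group is None:
        face_to_group = {f: f for f in faces}
    sub = ps[(ps["cond_a"] == ps["cond_b"]) & ps["cond_a"].isin(faces)
             & ps["group"].isin(groups)]
    for g in groups:
        for f in faces:
            if sub[(sub["group"] == g) & (sub["cond_a"] == f)].empty:
                raise DataError(f"missing cell: face {f!r} x group {g!r}")
    per = (
        sub.pivot_table(index=["participant", "group"], columns="cond_a", values="z")
        .reset_index()
    )
    own = np.where(
        [face_to_group[faces[0]] == g for g in per["group"]],
        per[faces[0]], per[faces[1]],
    )
    other = np.where(
        [face_to_group[faces[0]] == g for g in per["group"]],
        per[faces[1]], per[faces[0]],
    )
    per = per.assign(own_race=own, other_race=other,
                     own_minus_other=own - other)
    cell_means = sub.pivot_table(index="cond_a", columns="group", values="z")
    interaction = float(per.groupby("group")["own_minus_other"].mean().mean())
    tests = []
    for g in groups:
        d = per[per["group"] == g]
        t, p = stats.ttest_rel(d["own_race"], d["other_race"], alternative="greater")
        tests.append(dict(group=g, n=len(d), t=float(t), p_one_tailed=float(p),
                          cohens_d=cohens_d(d["own_race"], d["other_race"], paired=True)))
    return OwnRaceBiasResult(
        cell_means=cell_means,
        interaction=interaction,
        per_participant=per,
        group_tests=pd.DataFrame(tests),
    )


def category_contrast(
    ps: pd.DataFrame,
    face_conditions: Sequence[str],
    object_condition: str = "Object",
) -> pd.DataFrame:
    """Per-participant mean z for face-face vs face-object pattern similarity.

    Face-face pairs are the ordered cross-race face pairs; face-object pairs
    correlate each face pattern with the object template (and vice versa).
    """
    faces = [str(c) for c in face_conditions]
    obj = str(object_condition)
    if not ((ps["cond_a"] == obj) | (ps["cond_b"] == obj)).any():
        raise DataError(f"object condition {obj!r} absent from similarity records")
    ff = ps[ps["cond_a"].isin(faces) & ps["cond_b"].isin(faces)
            & (ps["cond_a"] != ps["cond_b"])]
    fo = ps[(ps["cond_a"].isin(faces) & (ps["cond_b"] == obj))
            | ((ps["cond_a"] == obj) & ps["cond_b"].isin(faces))]
    if ff.empty:
        raise DataError("no cross-race face-face pairs present")
    rows = []
    for (pid, grp), d in ff.groupby(["participant", "group"], sort=False):
        d_fo = fo[fo["participant"] == pid]
        if d_fo.empty:
            raise DataError(f"participant {pid!r} has no face-object pairs")
        rows.append(dict(participant=pid, group=grp,
                         face_face=d["z"].mean(), face_object=d_fo["z"].mean(),
                         difference=d["z"].mean() - d_fo["z"].mean()))
    return pd.DataFrame(rows)


def adaptation_index(
    vps: VoxelPatternSet,
    condition_pairs: Mapping[str, tuple],
    roi: str = "ROI",
) -> pd.DataFrame:
    """Repetition-suppression index per participant and face race.

    ``condition_pairs`` maps face race -> (same-identity condition label,
    different-identity condition label).  The response per condition is the
    mean unnormalised parameter estimate over ROI voxels;
    ``adaptation = response_different - response_same`` (positive =
    suppression by identity repetition).
    """
    if not condition_pairs:
        raise DataError("condition_pairs must be non-empty")
    rows = []
    for race, pair in condition_pairs.items():
        if len(pair) != 2:
            raise DataError(f"race {race!r}: need (same, different) condition labels")
        i_same = vps.condition_index(pair[0])
        i_diff = vps.condition_index(pair[1])
        resp_same = vps.responses[:, i_same, :].mean(axis=1)
        resp_diff = vps.responses[:, i_diff, :].mean(axis=1)
        for p in range(vps.n_participants):
            rows.append(
                dict(participant=vps.participant_ids[p],
                     group=vps.participant_group[p], roi=roi, face_race=str(race),
                     response_same=float(resp_same[p]),
                     response_different=float(resp_diff[p]),
                     adaptation=float(resp_diff[p] - resp_same[p]))
            )
    return pd.DataFrame(rows)
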