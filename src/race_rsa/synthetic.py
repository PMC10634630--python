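"""Synthetic inputs with the statistical structure the analyses assume.

The generators emulate, at the feature / parameter-estimate level, the data
a face-race experiment produces:

* ``gen_layer_features`` — layered feature arrays for a stimulus set of
  3 races x 180 face images (90 identities x 2 images each, 540 images at
  the defaults), with race and identity signal that grows across the 16
  layers the way categorical structure emerges across a deep network, plus
  the same/different-identity pair table of the matching tasks (45 same and
  45 different pairs per race at the defaults).
* ``gen_behaviour`` — binary same/different judgements per participant whose
  "same" probability follows the pair correlation of a chosen layer through
  a logistic link with a guessing floor.
* ``gen_voxel_patterns`` — per-participant condition patterns built from
  group-shared race templates (within-race template similarity above
  cross-race), an own-race consistency boost for the participant's own
  race, and an identity-repetition attenuation of Same-arrangement blocks.
* ``gen_statmap`` — blob-shaped z maps (sums of Gaussian bumps) for ROI
  flood-fill extraction.

Every generator is a pure function of (config, seed): reruns are
bit-identical.  With all effects switched off, every downstream statistic
sits at its null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import DataError
from .mvpa import VoxelPatternSet
from .roi import StatMap
from .rsm import FeatureSet

__all__ = [
    "FeatureGenConfig",
    "PatternGenConfig",
    "default_layer_names",
    "gen_layer_features",
    "gen_behaviour",
    "gen_voxel_patterns",
    "gen_statmap",
]

VGG_LAYER_NAMES = (
    "Conv1.1", "Conv1.2", "Conv2.1", "Conv2.2", "Conv3.1", "Conv3.2", "Conv3.3",
    "Conv4.1", "Conv4.2", "Conv4.3", "Conv5.1", "Conv5.2", "Conv5.3",
    "Fc6", "Fc7", "Fc8",
)


def default_layer_names(n_layers: int) -> list:
    if n_layers == len(VGG_LAYER_NAMES):
        return list(VGG_LAYER_NAMES)
    return [f"layer{i:02d}" for i in range(n_layers)]


def _sigmoid_profile(n_layers: int, midpoint: float, width: float) -> np.ndarray:
    x = np.arange(n_layers, dtype=np.float64)
    return expit((x - midpoint) / width)


@dataclass
class FeatureGenConfig:
    """Study conditions for the layered feature generator.

    Defaults reproduce the stimulus-set geometry of the face matching
    tasks: 3 races x 90 identities x 2 images = 540 images, 16 layers, and
    90 trials (45 same + 45 different identity) per race.  The default
    signal profiles are logistic ramps over layer index — race signal
    rising through the late convolutional stages, identity signal rising in
    the fully connected stages — and the White signal multiplier of 1.3
    plants the own-training-distribution advantage of face networks.
    """

    n_races: int = 3
    race_names: Sequence[str] = ("Asian", "Black", "White")
    identities_per_race: int = 90
    images_per_identity: int = 2
    n_layers: int = 16
    feature_dims: int | Sequence[int] = 200
    race_signal_profile: np.ndarray | None = None
    identity_signal_profile: np.ndarray | None = None
    noise_sd: float = 1.0
    per_race_signal_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"Asian": 1.0, "Black": 1.0, "White": 1.3}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.race_names) != self.n_races:
            raise DataError("race_names length must equal n_races")
        if self.identities_per_race < 4 or self.identities_per_race % 2:
            raise DataError(
                "identities_per_race must be even and >= 4 "
                "(half form same-identity pairs, half different)"
            )
        if self.images_per_identity < 2:
            raise DataError("need >= 2 images per identity to define same-identity pairs")
        if np.isscalar(self.feature_dims):
            self.feature_dims = [int(self.feature_dims)] * self.n_layers
        else:
            self.feature_dims = [int(d) for d in self.feature_dims]
        if len(self.feature_dims) != self.n_layers:
            raise DataError("feature_dims length must equal n_layers")
        if self.race_signal_profile is None:
            self.race_signal_profile = _sigmoid_profile(self.n_layers, 9.0, 1.5)
        self.race_signal_profile = np.asarray(self.race_signal_profile, dtype=np.float64)
        if self.identity_signal_profile is None:
            self.identity_signal_profile = _sigmoid_profile(self.n_layers, 12.0, 1.0)
        self.identity_signal_profile = np.asarray(
            self.identity_signal_profile, dtype=np.float64
        )
        for prof, name in ((self.race_signal_profile, "race_signal_profile"),
                           (self.identity_signal_profile, "identity_signal_profile")):
            if prof.shape != (self.n_layers,):
                raise DataError(f"{name} must have one entry per layer")
            if (prof < 0).any():
                raise DataError(f"{name} must be non-negative")
        missing = [r for r in self.race_names if r not in self.per_race_signal_multipliers]
        if missing:
            raise DataError(f"per_race_signal_multipliers missing races: {missing}")


def gen_layer_features(cfg: FeatureGenConfig) -> tuple:
    """Generate one FeatureSet per layer plus the matching-task pair table.

    Image vector at layer l:
    ``race_signal[l] * m_race * mu_race + identity_signal[l] * mu_identity
    + noise_sd * eps``, with ``mu`` prototypes drawn once per race/identity
    per layer from a standard normal and ``eps`` i.i.d. standard normal.

    The pair table assigns the first half of each race's identities to
    same-identity pairs (the identity's two images) and the second half to
    different-identity pairs (adjacent identities, first image vs second).
    """
    rng = np.random.default_rng(cfg.seed)
    names = default_layer_names(cfg.n_layers)
    n_id = cfg.identities_per_race
    image_ids, race_labels, identity_labels = [], [], []
    for race in cfg.race_names:
        for k in range(n_id):
            for c in range(cfg.images_per_identity):
                image_ids.append(f"{race}_{k:03d}_{c}")
                race_labels.append(race)
                identity_labels.append(f"{race}_{k:03d}")
    n_images = len(image_ids)
    race_idx = np.repeat(np.arange(cfg.n_races), n_id * cfg.images_per_identity)
    ident_idx = np.repeat(np.arange(cfg.n_races * n_id), cfg.images_per_identity)
    mult = np.asarray(
        [cfg.per_race_signal_multipliers[r] for r in cfg.race_names], dtype=np.float64
    )

    feature_sets = []
    for li in range(cfg.n_layers):
        d = cfg.feature_dims[li]
        mu_race = rng.standard_normal((cfg.n_races, d))
        mu_id = rng.standard_normal((cfg.n_races * n_id, d))
        noise = rng.standard_normal((n_images, d))
        X = (
            cfg.race_signal_profile[li] * mult[race_idx, None] * mu_race[race_idx]
            + cfg.identity_signal_profile[li] * mu_id[ident_idx]
            + cfg.noise_sd * noise
        )
        feature_sets.append(
            FeatureSet(layer_name=names[li], activations=X,
                       race_labels=race_labels, identity_labels=identity_labels,
                       image_ids=image_ids)
        )

    rows = []
    half = n_id // 2
    for race in cfg.race_names:
        t = 0
        for k in range(half):  # same-identity pairs
            rows.append(dict(trial_id=f"{race}_t{t:02d}",
                             image_id_a=f"{race}_{k:03d}_0",
                             image_id_b=f"{race}_{k:03d}_1",
                             race=race, same_identity=True))
            t += 1
        for k in range(half, n_id):  # different-identity pairs
            k2 = half + (k - half + 1) % (n_id - half)
            rows.append(dict(trial_id=f"{race}_t{t:02d}",
                             image_id_a=f"{race}_{k:03d}_0",
                             image_id_b=f"{race}_{k2:03d}_1",
                             race=race, same_identity=False))
            t += 1
    pairs = pd.DataFrame(rows)
    return feature_sets, pairs


def gen_behaviour(
    pair_r: np.ndarray,
    trial_ids: Sequence[str],
    slope: float = 8.0,
    guess_rate: float = 0.1,
    n_participants: int = 70,
    seed: int = 0,
    group: str = "all",
) -> pd.DataFrame:
    """Simulate binary same/different judgements driven by pair similarity.

    P(same) = guess_rate + (1 - 2 * guess_rate) * logistic(slope * (r - mean r));
    judgements are i.i.d. across participants.  Returns a long table with
    columns participant / trial_id / same_response (+ group).
    """
    if slope < 0:
        raise DataError("slope must be >= 0")
    if not 0 <= guess_rate < 0.5:
        raise DataError("guess_rate must be in [0, 0.5)")
    pair_r = np.asarray(pair_r, dtype=np.float64)
    if len(trial_ids) != pair_r.size:
        raise DataError("trial_ids length must match pair_r")
    rng = np.random.default_rng(seed)
    p_same = guess_rate + (1.0 - 2.0 * guess_rate) * expit(slope * (pair_r - pair_r.mean()))
    draws = rng.random((n_participants, pair_r.size)) < p_same[None, :]
    rows = pd.DataFrame(
        {
            "participant": np.repeat([f"{group}_s{i:03d}" for i in range(n_participants)],
                                     pair_r.size),
            "trial_id": np.tile(np.asarray(trial_ids, dtype=object), n_participants),
            "same_response": draws.ravel().astype(int),
            "group": group,
        }
    )
    return rows


@dataclass
class PatternGenConfig:
    """Study conditions for the voxel-pattern generator.

    Defaults mirror the fMRI sample (28 Asian + 29 White participants) at a
    reduced voxel count.  ``rho_within`` is the variance share of a race
    template carried by race-specific structure plus the shared face
    component; ``rho_between`` is the shared-face share, so cross-race
    template correlation is rho_between / rho_within.  ``own_race_boost``
    scales the template weight for a participant's own-race conditions;
    ``adaptation_effect`` subtracts a uniform offset from Same-arrangement
    responses (repetition suppression).
    """

    n_participants: Mapping[str, int] = field(
        default_factory=lambda: {"Asian": 28, "White": 29}
    )
    n_voxels: int = 300
    face_races: Sequence[str] = ("Asian", "Black", "White")
    include_object: bool = True
    rho_within: float = 0.5
    rho_between: float = 0.25
    own_race_boost: float = 0.2
    adaptation_effect: float | Mapping[str, float] = 0.4
    baseline_amplitude: float = 1.0
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho_between <= self.rho_within:
            raise DataError("need 0 <= rho_between <= rho_within")
        if self.rho_within <= 0:
            raise DataError("rho_within must be positive")
        if not np.isfinite(self.own_race_boost):
            raise DataError("own_race_boost must be finite")
        if np.isscalar(self.adaptation_effect):
            self.adaptation_effect = {r: float(self.adaptation_effect)
                                      for r in self.face_races}
        missing = [r for r in self.face_races if r not in self.adaptation_effect]
        if missing:
            raise DataError(f"adaptation_effect missing races: {missing}")


def gen_voxel_patterns(cfg: PatternGenConfig) -> VoxelPatternSet:
    """Generate an ROI's participants x conditions x voxels response array.

    Conditions are ``"<race>/different"`` and ``"<race>/same"`` per face
    race (plus ``Object/...`` when enabled).  Participant p's pattern for a
    face condition is ``(1 + boost * own_race) * T_race + baseline + noise``;
    the Same arrangement additionally subtracts the adaptation effect.  The
    object template carries no race and no own-race boost.
    """
    rng = np.random.default_rng(cfg.seed)
    V = cfg.n_voxels
    shared = rng.standard_normal(V)
    templates = {}
    for race in cfg.face_races:
        unique = rng.standard_normal(V)
        templates[race] = (
            np.sqrt(cfg.rho_between) * shared
            + np.sqrt(cfg.rho_within - cfg.rho_between) * unique
        )
    if cfg.include_object:
        templates["Object"] = np.sqrt(cfg.rho_within) * rng.standard_normal(V)

    cond_labels = []
    for name in templates:
        cond_labels += [f"{name}/different", f"{name}/same"]
    groups, pids = [], []
    for g in cfg.n_participants:
        for i in range(cfg.n_participants[g]):
            groups.append(g)
            pids.append(f"{g}_p{i:03d}")
    n_p = len(groups)
    responses = np.empty((n_p, len(cond_labels), V))
    for p, g in enumerate(groups):
        for ci, label in enumerate(cond_labels):
            name, arrangement = label.split("/")
            boost = cfg.own_race_boost if name == g else 0.0
            pattern = (
                (1.0 + boost) * templates[name]
                + cfg.baseline_amplitude
                + cfg.noise_sd * rng.standard_normal(V)
            )
            if arrangement == "same":
                s = cfg.adaptation_effect.get(name, 0.0) if name != "Object" else (
                    cfg.adaptation_effect.get("Object", 0.0)
                )
                pattern = pattern - s
            responses[p, ci] = pattern
    return VoxelPatternSet(
        responses=responses,
        participant_group=np.asarray(groups, dtype=object),
        condition_labels=np.asarray(cond_labels, dtype=object),
        participant_ids=np.asarray(pids, dtype=object),
    )


def gen_statmap(
    shape: Sequence[int] = (40, 48, 40),
    centres: Sequence[Sequence[float]] = ((20, 24, 20),),
    amplitudes: Sequence[float] = (6.0,),
    widths: Sequence[float] = (3.0,),
    noise_sd: float = 0.0,
    seed: int = 0,
    affine: np.ndarray | None = None,
) -> StatMap:
    """Sum-of-Gaussian-bumps z map on a 3-D grid (default 3 mm MNI-like affine)."""
    shape = tuple(int(s) for s in shape)
    if not (len(centres) == len(amplitudes) == len(widths)):
        raise DataError("centres, amplitudes and widths must have equal length")
    grid = np.stack(
        np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij"),
        axis=-1,
    )
    values = np.zeros(shape)
    for c, a, w in zip(centres, amplitudes, widths):
        c = np.asarray(c, dtype=np.float64)
        if (c < 0).any() or (c >= np.asarray(shape)).any():
            raise DataError(f"blob centre {c} outside grid {shape}")
        sq = ((grid - c) ** 2).sum(axis=-1)
        values += a * np.exp(-sq / (2.0 * w**2))
    if noise_sd > 0:
        values += noise_sd * np.random.default_rng(seed).standard_normal(shape)
    if affine is None:
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = -1.5 * np.asarray(shape)  # roughly centre the origin
    return StatMap(values=values, affine=np.asarray(affine, dtype=np.float64))
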