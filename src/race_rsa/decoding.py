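"""Race and identity decoding from similarity structure.

Decoding follows a signal-detection recipe rather than a trained
classifier.  For race, a one-versus-rest score is computed for every image:
its mean correlation to the target-race images (self excluded).  Target-race
images form the positive class, all other images the negative class; the
separation of the two score distributions is summarised by the ROC area
(Mann-Whitney form) and converted to sensitivity d' = sqrt(2) * Phi^-1(AUC).
Identity decoding applies the same AUC/d' machinery to the correlations of
same-identity versus different-identity face pairs.

Significance against chance uses a maximum-statistic permutation test:
class labels are permuted identically across all layers, d' recomputed per
layer, and the maximum over layers recorded, which controls the familywise
error rate over layers.  One-tailed p-values use the add-one estimator
(k + 1) / (n_perm + 1) and are optionally Bonferroni-corrected over the
three races.  Parametric companions (within>between contrasts with Holm
correction, Cohen's d) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .rsm import SimilarityMatrix

__all__ = [
    "DecodingResult",
    "PermutationConfig",
    "within_class_score",
    "auc_from_scores",
    "auc_to_dprime",
    "race_decoding",
    "identity_decoding",
    "max_stat_permutation",
    "race_decoding_fwer",
    "identity_decoding_fwer",
    "within_between_difference",
    "holm_adjust",
    "contrast_t_holm",
    "cohens_d",
]

SQRT2 = np.sqrt(2.0)


@dataclass
class DecodingResult:
    layer_name: str
    target_class: str
    auc: float
    dprime: float
    p_fwer: float = np.nan
    p_bonferroni: float = np.nan


@dataclass
class PermutationConfig:
    """Settings for the maximum-statistic permutation test.

    ``statistic`` selects what is permuted: ``"race_dprime"`` permutes the
    image race labels, ``"identity_dprime"`` permutes the same/different
    flags over the pairs of one matching task.
    """

    n_perm: int = 10_000
    seed: int = 0
    statistic: str = "race_dprime"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise DataError("n_perm must be >= 1")
        if self.statistic not in ("race_dprime", "identity_dprime"):
            raise DataError(f"unknown permutation statistic {self.statistic!r}")


# ---------------------------------------------------------------------------
# scores, AUC, d'
# ---------------------------------------------------------------------------

def within_class_score(sm: SimilarityMatrix, target_race: str) -> np.ndarray:
    """Mean correlation of every image to the target-race images, self excluded."""
    z = (sm.race_labels == str(target_race))
    if not z.any():
        raise DataError(f"target race {target_race!r} not present among labels")
    if z.sum() < 2:
        raise DataError(f"target race {target_race!r} has a single image; need >= 2")
    zf = z.astype(np.float64)
    # diagonal entries are exactly 1, so subtracting the indicator removes self
    numer = sm.values @ zf - zf
    denom = zf.sum() - zf
    return numer / denom


def _auc_from_ranks(rank_sum_pos: np.ndarray, n_pos: int, n_neg: int) -> np.ndarray:
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auc_from_scores(scores: np.ndarray, positive_mask: np.ndarray) -> float:
    """ROC area as the Mann-Whitney probability P(score+ > score-) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=np.float64)
    pos = np.asarray(positive_mask, dtype=bool)
    if scores.shape != pos.shape or scores.ndim != 1:
        raise DataError("scores and positive_mask must be matching 1-D vectors")
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("need at least one positive and one negative score")
    ranks = stats.rankdata(scores, method="average")
    return float(_auc_from_ranks(ranks[pos].sum(), n_pos, n_neg))


def auc_to_dprime(
    auc,
    n_pos: int | None = None,
    n_neg: int | None = None,
    eps: float | None = None,
):
    """Convert ROC area to sensitivity d' = sqrt(2) * Phi^-1(AUC).

    AUC of 0 or 1 maps to infinite d'; to keep permutation statistics finite
    the AUC is clipped into ``[eps, 1 - eps]`` first.  When the class sizes
    are known, ``eps = 1 / (2 * n_pos * n_neg)`` (half the AUC resolution);
    otherwise a fixed 1e-6.  Accepts scalars or arrays.
    """
    if eps is None:
        eps = 1.0 / (2.0 * n_pos * n_neg) if (n_pos and n_neg) else 1e-6
    a = np.clip(np.asarray(auc, dtype=np.float64), eps, 1.0 - eps)
    d = SQRT2 * stats.norm.ppf(a)
    return float(d) if np.isscalar(auc) or np.ndim(auc) == 0 else d


def race_decoding(sm: SimilarityMatrix, target_race: str) -> DecodingResult:
    """One-versus-rest race decoding on a single layer's similarity matrix."""
    scores = within_class_score(sm, target_race)
    pos = sm.race_labels == str(target_race)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    auc = auc_from_scores(scores, pos)
    return DecodingResult(
        layer_name=sm.layer_name,
        target_class=str(target_race),
        auc=auc,
        dprime=auc_to_dprime(auc, n_pos, n_neg),
    )


def identity_decoding(
    pair_r: np.ndarray, same_flags: np.ndarray, layer_name: str = "layer",
    target_class: str = "same_identity",
) -> DecodingResult:
    """Decode same- vs different-identity pairs from their correlations."""
    pair_r = np.asarray(pair_r, dtype=np.float64)
    same = np.asarray(same_flags, dtype=bool)
    auc = auc_from_scores(pair_r, same)
    return DecodingResult(
        layer_name=layer_name,
        target_class=target_class,
        auc=auc,
        dprime=auc_to_dprime(auc, int(same.sum()), int((~same).sum())),
    )


# ---------------------------------------------------------------------------
# maximum-statistic permutation test
# ---------------------------------------------------------------------------

def _check_aligned_layers(sms: Sequence[SimilarityMatrix]) -> None:
    ref = sms[0].image_ids
    for sm in sms[1:]:
        if not np.array_equal(sm.image_ids, ref):
            raise DataError("all layers must share the same images in the same order")


def _permutation_indices(rng: np.random.Generator, n: int, n_perm: int) -> np.ndarray:
    idx = np.empty((n, n_perm), dtype=np.intp)
    for p in range(n_perm):
        idx[:, p] = rng.permutation(n)
    return idx


def _race_null_dprimes(
    sms: Sequence[SimilarityMatrix], target_race: str, cfg: PermutationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Observed d' per layer and the (n_layers, n_perm) permutation nulls."""
    labels = sms[0].race_labels
    z_true = (labels == str(target_race)).astype(np.float64)
    n = labels.size
    n_pos = int(z_true.sum())
    n_neg = n - n_pos
    if n_pos < 2 or n_neg < 1:
        raise DataError("degenerate race labels for permutation test")
    rng = np.random.default_rng(cfg.seed)
    Z = z_true[_permutation_indices(rng, n, cfg.n_perm)]  # (n, n_perm)
    obs = np.empty(len(sms))
    null = np.empty((len(sms), cfg.n_perm))
    for li, sm in enumerate(sms):
        obs[li] = race_decoding(sm, target_race).dprime
        numer = sm.values @ Z - Z
        scores = numer / (n_pos - Z)
        ranks = stats.rankdata(scores, method="average", axis=0)
        auc = _auc_from_ranks((ranks * Z).sum(axis=0), n_pos, n_neg)
        null[li] = auc_to_dprime(auc, n_pos, n_neg)
    return obs, null


def _identity_null_dprimes(
    pair_r_by_layer: np.ndarray, same_flags: np.ndarray, cfg: PermutationConfig
) -> tuple[np.ndarray, np.ndarray]:
    R = np.atleast_2d(np.asarray(pair_r_by_layer, dtype=np.float64))
    same = np.asarray(same_flags, dtype=bool)
    n = same.size
    if R.shape[1] != n:
        raise DataError("pair_r_by_layer and same_flags disagree on the number of pairs")
    n_pos = int(same.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError("degenerate same/different flags for permutation test")
    rng = np.random.default_rng(cfg.seed)
    Z = same.astype(np.float64)[_permutation_indices(rng, n, cfg.n_perm)]
    obs = np.empty(R.shape[0])
    null = np.empty((R.shape[0], cfg.n_perm))
    for li in range(R.shape[0]):
        obs[li] = identity_decoding(R[li], same).dprime
        ranks = stats.rankdata(R[li], method="average")  # scores fixed; flags permuted
        auc = _auc_from_ranks(ranks @ Z, n_pos, n_neg)
        null[li] = auc_to_dprime(auc, n_pos, n_neg)
    return obs, null


def max_stat_permutation(per_layer_inputs, config: PermutationConfig) -> np.ndarray:
    """Familywise-error-controlled one-tailed p-value per layer.

    ``per_layer_inputs`` is ``(sms, target_race)`` for ``race_dprime`` or
    ``(pair_r_by_layer, same_flags)`` for ``identity_dprime``.  Within each
    permutation the labels are shuffled identically across layers, the d'
    recomputed per layer and the maximum across layers recorded;
    ``p = (1 + #{null_max >= observed}) / (n_perm + 1)``.
    """
    if config.statistic == "race_dprime":
        sms, target = per_layer_inputs
        _check_aligned_layers(sms)
        obs, null = _race_null_dprimes(sms, target, config)
    else:
        pair_r, same = per_layer_inputs
        obs, null = _identity_null_dprimes(pair_r, same, config)
    null_max = null.max(axis=0)
    exceed = (null_max[None, :] >= obs[:, None]).sum(axis=1)
    return (1.0 + exceed) / (config.n_perm + 1.0)


def race_decoding_fwer(
    sms: Sequence[SimilarityMatrix],
    races: Sequence[str] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Race decoding over layers with max-statistic FWER control.

    Each race is tested one-versus-rest in turn; p-values are additionally
    Bonferroni-corrected over the races tested.  Returns a tidy table with
    one row per layer x race.
    """
    _check_aligned_layers(sms)
    if races is None:
        races = sorted(set(sms[0].race_labels))
    n_races = len(races)
    rows = []
    for ri, race in enumerate(races):
        cfg = PermutationConfig(n_perm=n_perm, seed=seed + ri, statistic="race_dprime")
        p_fwer = max_stat_permutation((sms, race), cfg)
        for li, sm in enumerate(sms):
            res = race_decoding(sm, race)
            rows.append(
                dict(layer=sm.layer_name, target=race, auc=res.auc, dprime=res.dprime,
                     p_fwer=p_fwer[li], p_bonferroni=min(1.0, n_races * p_fwer[li]))
            )
    return pd.DataFrame(rows)


def identity_decoding_fwer(
    pair_r_by_layer: np.ndarray,
    same_flags: np.ndarray,
    layer_names: Sequence[str],
    target: str = "same_identity",
    n_races_for_bonferroni: int = 3,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Identity decoding over layers for one matching task, FWER-controlled."""
    cfg = PermutationConfig(n_perm=n_perm, seed=seed, statistic="identity_dprime")
    p_fwer = max_stat_permutation((pair_r_by_layer, same_flags), cfg)
    R = np.atleast_2d(pair_r_by_layer)
    rows = []
    for li, name in enumerate(layer_names):
        res = identity_decoding(R[li], same_flags, layer_name=name)
        rows.append(
            dict(layer=name, target=target, auc=res.auc, dprime=res.dprime,
                 p_fwer=p_fwer[li],
                 p_bonferroni=min(1.0, n_races_for_bonferroni * p_fwer[li]))
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parametric contrasts
# ---------------------------------------------------------------------------

def within_between_difference(sm: SimilarityMatrix) -> pd.DataFrame:
    """Per-image mean within-race minus mean between-race correlation.

    ``within_mean`` averages correlations to own-race images (self excluded),
    ``between_mean`` to all other-race images.  Every race needs >= 2 images.
    """
    races = np.asarray(sm.race_labels)
    for race in set(races):
        if (races == race).sum() < 2:
            raise DataError(f"race {race!r} has a single image; need >= 2")
    rows = []
    for i, im in enumerate(sm.image_ids):
        own = races == races[i]
        own_excl = own.copy()
        own_excl[i] = False
        within = sm.values[i, own_excl].mean()
        between = sm.values[i, ~own].mean()
        rows.append(dict(image_id=im, race=races[i], within_mean=within,
                         between_mean=between, difference=within - between))
    return pd.DataFrame(rows)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, >= raw, capped at 1)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise DataError("p_values must be a non-empty 1-D vector")
    if (p < 0).any() or (p > 1).any():
        raise DataError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="holm")
    return adjusted


def contrast_t_holm(
    values_by_cell: Mapping,
    paired: bool = True,
    alternative: str = "greater",
) -> pd.DataFrame:
    """One-tailed t-test per cell with Holm step-down correction over cells.

    ``values_by_cell`` maps a cell key, e.g. ``(layer, race)``, to a pair of
    sample vectors ``(a, b)``.  Paired cells test ``mean(a - b) > 0``
    (within > between); unpaired cells use an independent-samples t
    (same > different identity).  Holm-adjusted p-values are monotone in the
    raw p-values and never exceed 1.
    """
    keys, ts, ps = [], [], []
    for key, (a, b) in values_by_cell.items():
        a = np.asarray(a, dtype=np.float64)
        b = np.asarray(b, dtype=np.float64)
        if paired:
            if a.shape != b.shape:
                raise DataError(f"cell {key!r}: paired samples must match in length")
            if a.size < 3:
                raise DataError(f"cell {key!r}: need n >= 3 observations")
            if np.std(a - b, ddof=1) == 0:
                raise DataError(f"cell {key!r}: zero-variance differences")
            t, p = stats.ttest_rel(a, b, alternative=alternative)
        else:
            if a.size < 3 or b.size < 3:
                raise DataError(f"cell {key!r}: need n >= 3 observations per sample")
            if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
                raise DataError(f"cell {key!r}: zero-variance samples")
            t, p = stats.ttest_ind(a, b, alternative=alternative)
        keys.append(key)
        ts.append(float(t))
        ps.append(float(p))
    return pd.DataFrame(
        {"cell": keys, "t": ts, "p_raw": ps, "p_holm": holm_adjust(ps)}
    )


def cohens_d(a, b, paired: bool = False) -> float:
    """Standardised mean difference.

    Paired: ``mean(a - b) / sd(a - b)``.  Independent: pooled-SD Cohen's d.
    Identical samples give 0; a non-zero mean difference with zero SD is an
    error (the statistic is undefined).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise DataError("need n >= 2 per sample for Cohen's d")
    if paired:
        if a.shape != b.shape:
            raise DataError("paired samples must match in length")
        diff = a - b
        sd = diff.std(ddof=1)
        if sd == 0:
            if diff.mean() == 0:
                return 0.0
            raise DataError("zero-SD differences with non-zero mean: d undefined")
        return float(diff.mean() / sd)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    if pooled == 0:
        if a.mean() == b.mean():
            return 0.0
        raise DataError("zero pooled SD with non-zero mean difference: d undefined")
    return float((a.mean() - b.mean()) / pooled)
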