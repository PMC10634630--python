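"""Behavioural similarity and brain/network-behaviour RSA.

Behavioural similarity for a matching task is the proportion of "same
identity" responses per trial, averaged over participants.  Layer-wise RSA
correlates those proportions with the feature correlations of the same face
pairs; significance uses the one-tailed critical r at alpha = 0.05 from the
t-distribution with n_pairs - 2 df.  Fisher's z-transform and the
independent-samples Fisher z comparison of two correlations are provided for
downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .rsm import SimilarityMatrix, pair_similarity, validate_pair_table

__all__ = [
    "RsaResult",
    "behaviour_similarity",
    "critical_r",
    "layer_behaviour_correlation",
    "fisher_transform",
    "fisher_z_compare",
]

FISHER_CLAMP = 1.0 - 1e-7


@dataclass
class RsaResult:
    layer_name: str
    race: str
    participant_group: str
    r: float
    n_pairs: int
    critical_r: float
    significant: bool


def behaviour_similarity(
    judgements: pd.DataFrame, pairs: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Proportion of "same" responses per trial across participants.

    ``judgements`` is long-format with columns ``participant``, ``trial_id``
    and binary ``same_response``; every participant must have judged every
    trial exactly once.  Returns ``trial_id``/``prop_same``/``n_participants``
    or, when ``pairs`` is given, the pair table with ``prop_same`` merged in.
    """
    for col in ("participant", "trial_id", "same_response"):
        if col not in judgements.columns:
            raise DataError(f"judgement table missing column {col!r}")
    resp = judgements["same_response"].to_numpy()
    if not np.isin(resp, [0, 1, True, False]).all():
        raise DataError("same_response must be binary (0/1)")
    wide = judgements.pivot_table(
        index="participant", columns="trial_id", values="same_response",
        aggfunc="count", fill_value=0,
    )
    incomplete = wide.columns[(wide != 1).any(axis=0)].tolist()
    if incomplete:
        raise DataError(f"missing or duplicated judgements for trials: {incomplete}")
    agg = (
        judgements.groupby("trial_id", sort=False)["same_response"]
        .agg(prop_same="mean", n_participants="count")
        .reset_index()
    )
    if pairs is None:
        return agg
    validate_pair_table(pairs)
    extra = set(agg["trial_id"]) - set(pairs["trial_id"])
    missing = set(pairs["trial_id"]) - set(agg["trial_id"])
    if extra or missing:
        raise DataError(
            f"trial ids do not match pair table (missing={sorted(missing)}, "
            f"unknown={sorted(extra)})"
        )
    return pairs.merge(agg, on="trial_id", how="left")


def critical_r(n_pairs: int, alpha: float = 0.05) -> float:
    """One-tailed critical Pearson r at the given alpha with n_pairs - 2 df."""
    if n_pairs < 4:
        raise DataError("need n_pairs >= 4 for a critical r")
    df = n_pairs - 2
    tc = stats.t.ppf(1.0 - alpha, df)
    return float(tc / np.sqrt(tc**2 + df))


def layer_behaviour_correlation(
    sm: SimilarityMatrix,
    pairs: pd.DataFrame,
    alpha: float = 0.05,
    race: str = "all",
    participant_group: str = "all",
) -> RsaResult:
    """Correlate behavioural prop_same with the layer's pair correlations.

    ``significant`` follows the one-tailed convention (positive correlations
    expected): r strictly greater than the critical r at ``alpha``.
    """
    validate_pair_table(pairs, require_prop_same=True)
    if len(pairs) < 4:
        raise DataError("need at least 4 pairs for RSA")
    pair_r = pair_similarity(sm, pairs)
    prop = pairs["prop_same"].to_numpy(dtype=float)
    if np.std(pair_r) == 0 or np.std(prop) == 0:
        raise DataError("zero variance in pair correlations or behaviour")
    r = float(np.corrcoef(pair_r, prop)[0, 1])
    rc = critical_r(len(pairs), alpha)
    return RsaResult(
        layer_name=sm.layer_name,
        race=race,
        participant_group=participant_group,
        r=r,
        n_pairs=len(pairs),
        critical_r=rc,
        significant=bool(r > rc),
    )


def fisher_transform(r, clamp: float = FISHER_CLAMP):
    """Fisher z = atanh(r), with |r| clamped to 1 - 1e-7 so r = +-1 stays finite."""
    r_arr = np.clip(np.asarray(r, dtype=np.float64), -clamp, clamp)
    z = np.arctanh(r_arr)
    return float(z) if np.ndim(r) == 0 else z


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Independent-samples Fisher z comparison of two correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-tailed normal
    p.  Assumes the two correlations come from independent samples.
    """
    if n1 <= 3 or n2 <= 3:
        raise DataError("Fisher z comparison needs n > 3 in both samples")
    z = (fisher_transform(r1) - fisher_transform(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
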