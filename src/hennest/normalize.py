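"""Pre-analysis normalisation of whole-period traits.

Skewed behavioural traits inflate REML residual variances, so each
continuous trait is taken through a rank-based inverse-normal transform
(a deterministic, strictly monotone map: average ranks, Blom-free offset
(r - 0.5)/n, then the standard-normal quantile) and scaled to exactly
zero mean and unit variance.  The binary nest-acceptance trait passes
through untouched.  Rank-based transforms are invariant to any strictly
monotone re-expression of the input, which is what makes heritability
recovery on link-transformed latents exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("hennest")


@dataclass
class NormalizedTrait:
    """Transformed values aligned to the input rows (missing preserved)."""

    values: np.ndarray
    transform: str


class NormalizationError(ValueError):
    """Vector unusable for normalisation (constant or too short)."""


def rank_inverse_normal(values) -> NormalizedTrait:
    """Rank-based inverse-normal transform, then exact centring/scaling.

    Ties receive average ranks; missing entries are carried through
    untouched.  Raises :class:`NormalizationError` on vectors with fewer
    than 3 non-missing values or no variation.
    """
    x = np.asarray(values, float)
    mask = np.isfinite(x)
    n = int(mask.sum())
    if n < 3:
        raise NormalizationError(f"need >= 3 non-missing values, got {n}")
    obs = x[mask]
    if np.nanmax(obs) == np.nanmin(obs):
        raise NormalizationError("constant vector cannot be normalised")
    ranks = stats.rankdata(obs, method="average")
    z = stats.norm.ppf((ranks - 0.5) / n)
    z = (z - z.mean()) / z.std(ddof=0)
    out = np.full_like(x, np.nan)
    out[mask] = z
    return NormalizedTrait(values=out, transform="rank_inverse_normal")


def passthrough_binary(values) -> NormalizedTrait:
    """Identity transform for 0/1 traits (no centring or scaling)."""
    x = np.asarray(values, float)
    obs = x[np.isfinite(x)]
    if not np.isin(obs, (0.0, 1.0)).all():
        raise NormalizationError("binary passthrough requires 0/1 values")
    return NormalizedTrait(values=x.copy(), transform="passthrough_binary")


#: traits analysed on the observed 0/1 scale
BINARY_TRAITS = ("NAL",)


def normalize_traits(table: pd.DataFrame,
                     columns: list[str]) -> pd.DataFrame:
    """Normalise the listed trait columns of a trait table.

    Continuous traits get the rank-based transform; binary traits pass
    through.  A trait that cannot be normalised is dropped with a log
    line rather than aborting the whole analysis.
    """
    out = table.copy()
    for col in columns:
        try:
            if col in BINARY_TRAITS:
                nt = passthrough_binary(out[col].to_numpy(float))
            else:
                nt = rank_inverse_normal(out[col].to_numpy(float))
        except NormalizationError as err:
            logger.warning("normalize drop trait=%s reason=%s", col, err)
            out = out.drop(columns=[col])
            continue
        out[col] = nt.values
        logger.info("normalize trait=%s transform=%s n=%d", col,
                    nt.transform, int(np.isfinite(nt.values).sum()))
    return out
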