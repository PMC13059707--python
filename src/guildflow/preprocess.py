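"""Rarefaction, prevalence filtering and abundance transforms.

Order of operations mirrors standard amplicon practice: rarefy the count
table to a common depth (default 28,000 reads), keep features exceeding a
prevalence threshold (default: present in strictly more than 30% of
samples), convert to relative abundance, and log-transform with a
pseudocount before correlation analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "rarefy",
    "prevalence_filter",
    "to_relative",
    "log_transform",
    "DEFAULT_RAREFACTION_DEPTH",
    "DEFAULT_MIN_PREVALENCE",
]

logger = logging.getLogger(__name__)

DEFAULT_RAREFACTION_DEPTH = 28_000
DEFAULT_MIN_PREVALENCE = 0.30


def rarefy(
    table: pd.DataFrame, depth: int = DEFAULT_RAREFACTION_DEPTH, seed: int | None = None
) -> pd.DataFrame:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (with a logged
    warning); a sample at exactly ``depth`` is returned unchanged.  Draws are
    multivariate hypergeometric, so rarefied column sums equal ``depth``
    exactly and the procedure is deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    totals = table.sum(axis=1)
    keep = totals >= depth
    dropped = table.index[~keep].tolist()
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s", len(dropped), depth, dropped
        )
    if not keep.any():
        raise ValueError(f"all {len(table)} samples have fewer than {depth} reads")
    kept = table.loc[keep]
    out = np.empty(kept.shape, dtype="int64")
    values = kept.to_numpy()
    for i, row in enumerate(values):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return pd.DataFrame(out, index=kept.index, columns=kept.columns)


def prevalence_filter(
    table: pd.DataFrame, min_prevalence: float = DEFAULT_MIN_PREVALENCE
) -> tuple[pd.DataFrame, float]:
    """Keep features detected in strictly more than ``min_prevalence`` of samples.

    Presence means count > 0.  Returns the filtered table and the coverage:
    the fraction of total reads retained by the kept features.
    """
    if not 0.0 <= min_prevalence < 1.0:
        raise ValueError("min_prevalence must be in [0, 1)")
    prevalence = (table > 0).mean(axis=0)
    keep = prevalence > min_prevalence
    if not keep.any():
        raise ValueError(
            f"no features exceed prevalence {min_prevalence}; most prevalent is "
            f"{prevalence.max():.3f}"
        )
    filtered = table.loc[:, keep]
    total = float(table.to_numpy().sum())
    coverage = float(filtered.to_numpy().sum()) / total if total > 0 else 0.0
    return filtered, coverage


def to_relative(table: pd.DataFrame) -> pd.DataFrame:
    """Convert counts to per-sample relative abundances (rows sum to 1).

    Samples with zero total stay all-zero rather than dividing by zero.
    """
    if (table.to_numpy() < 0).any():
        raise ValueError("count table contains negative values")
    totals = table.sum(axis=1).to_numpy().astype(float)
    safe = np.where(totals > 0, totals, 1.0)
    return table.div(safe, axis=0).astype(float)


def log_transform(rel: pd.DataFrame, pseudo: float | str = "half-min") -> pd.DataFrame:
    """Natural log of abundance plus a pseudocount.

    ``pseudo="half-min"`` uses half the smallest nonzero value in the whole
    table, the conventional choice when zeros come from detection limits.
    """
    values = rel.to_numpy(dtype=float)
    if isinstance(pseudo, str):
        if pseudo != "half-min":
            raise ValueError(f"pseudo must be a positive number or 'half-min', got {pseudo!r}")
        nonzero = values[values > 0]
        if nonzero.size == 0:
            raise ValueError("cannot infer half-min pseudocount from an all-zero table")
        pseudo = float(nonzero.min()) / 2.0
    if pseudo <= 0:
        raise ValueError("pseudo must be > 0")
    return pd.DataFrame(np.log(values + pseudo), index=rel.index, columns=rel.columns)
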