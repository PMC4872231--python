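"""Quality-control filters applied before any inference stage.

Three concerns live here: dropping probes whose array detection p-value is
not convincingly below threshold in every sample, aligning the expression
and methylation matrices onto a common ordered set of timepoints, and the
Shapiro–Wilk normality report used for descriptive QC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigError

logger = logging.getLogger("methdyn")


def filter_probes(
    meth: pd.DataFrame,
    detection_p: pd.DataFrame | None,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Retain probes whose detection p-value is < ``p_threshold`` in every sample.

    ``detection_p`` must cover all (probe, sample) cells of ``meth``. When it
    is ``None`` the matrix passes through unchanged (with a logged notice),
    for inputs whose upstream processing already applied the filter.
    """
    if not 0 < p_threshold <= 1:
        raise ConfigError(f"detection p threshold must lie in (0, 1], got {p_threshold}")
    if detection_p is None:
        logger.info("filter_probes: no detection p-values supplied; matrix unchanged")
        return meth
    missing_probes = meth.index.difference(detection_p.index)
    missing_samples = meth.columns.difference(detection_p.columns)
    if len(missing_probes) or len(missing_samples):
        raise ValueError(
            "detection p-value matrix does not cover the methylation matrix "
            f"(missing probes: {list(missing_probes[:5])}, "
            f"missing samples: {list(missing_samples[:5])})"
        )
    dp = detection_p.loc[meth.index, meth.columns].to_numpy()
    keep = (dp < p_threshold).all(axis=1)
    out = meth.loc[keep]
    logger.info(
        "filter_probes: retained %d/%d probes at detection p < %g in all %d samples",
        out.shape[0], meth.shape[0], p_threshold, meth.shape[1],
    )
    return out


def align_samples(
    expr: pd.DataFrame, meth: pd.DataFrame, min_common: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both matrices to their common samples, in expression order.

    The expression matrix's column order is authoritative. At least
    ``min_common`` shared timepoints are required — the regression stages
    are meaningless below that.
    """
    common = [s for s in expr.columns if s in set(meth.columns)]
    if len(common) < min_common:
        raise ValueError(
            f"only {len(common)} samples shared between expression and methylation; "
            f"need >= {min_common}"
        )
    dropped_e = [s for s in expr.columns if s not in common]
    dropped_m = [s for s in meth.columns if s not in common]
    if dropped_e:
        logger.info("align_samples: dropping expression-only samples %s", dropped_e)
    if dropped_m:
        logger.info("align_samples: dropping methylation-only samples %s", dropped_m)
    return expr[common], meth[common]


@dataclass
class NormalityResult:
    statistic: float
    p_value: float
    degenerate: bool = False  # constant input: W undefined, reported non-normal


def qc_normality(series: np.ndarray | pd.Series) -> NormalityResult:
    """Shapiro–Wilk normality check of one series (reporting only, never a filter)."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or not 3 <= x.size <= 5000:
        raise ValueError(f"qc_normality needs a 1-d series of length 3..5000, got {x.shape}")
    if np.ptp(x) == 0:
        logger.warning("qc_normality: constant series; W undefined, flagged non-normal")
        return NormalityResult(statistic=float("nan"), p_value=0.0, degenerate=True)
    stat, p = stats.shapiro(x)
    return NormalityResult(statistic=float(stat), p_value=float(p))
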