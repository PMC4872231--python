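"""Detection of dynamically expressed genes as within-bin CV outliers.

A gene is "dynamic" when its coefficient of variation over the time course
is an outlier among genes of comparable abundance. Genes are binned by mean
log10(FPKM+1) in fixed-width intervals (default 0.05), and within each bin
the Smirnov–Grubbs test is applied iteratively to the CVs: at each pass the
most extreme CV is flagged and removed if its studentized deviation exceeds
the Grubbs critical value, until no rejection occurs.

The Grubbs critical value at sample size N and level alpha is

    G_crit = (N - 1) / sqrt(N) * sqrt(t^2 / (N - 2 + t^2))

with t the upper alpha/N quantile of Student's t on N-2 degrees of freedom
for the one-sided (upper) test, or alpha/(2N) for the two-sided test.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig

logger = logging.getLogger("methdyn")


def bin_by_mean_log_expression(expr: pd.DataFrame, bin_width: float = 0.05) -> pd.Series:
    """Map each gene to its bin of mean log10(FPKM+1).

    Bins are left-closed, right-open: ``bin = floor(mean / width)``, so a
    mean lying exactly on a left edge belongs to the bin it opens.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    mean_log = np.log10(expr.to_numpy(dtype=float) + 1.0).mean(axis=1)
    idx = np.floor(mean_log / bin_width).astype(int)
    return pd.Series(idx, index=expr.index, name="bin_index")


def compute_cv(series: np.ndarray | pd.Series, scale: str = "log") -> float:
    """Coefficient of variation (sample SD / mean) of one gene's series.

    ``scale="log"`` computes the CV of log10(FPKM+1); ``"raw"`` uses FPKM
    directly. The mean on the chosen scale must be positive.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least 2 timepoints")
    if scale == "log":
        x = np.log10(x + 1.0)
    elif scale != "raw":
        raise ValueError(f"unknown CV scale {scale!r}")
    m = x.mean()
    if m <= 0:
        raise ValueError("CV undefined: mean of the series on the analysis scale is <= 0")
    return float(x.std(ddof=1) / m)


def grubbs_critical_value(n: int, alpha: float, one_sided: bool = True) -> float:
    """Critical value of the Grubbs outlier statistic at sample size ``n``."""
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    tail = alpha / n if one_sided else alpha / (2 * n)
    t = stats.t.ppf(1.0 - tail, n - 2)
    return float((n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t)))


def grubbs_outliers(
    values: np.ndarray,
    alpha: float = 0.05,
    one_sided_upper: bool = True,
    min_bin_size: int = 3,
    iterative: bool = True,
) -> list[tuple[int, int, float]]:
    """Iterative Smirnov–Grubbs outlier detection.

    Returns ``(index, pass_number, G)`` triples in flagging order, where
    ``index`` refers to the input vector, ``pass_number`` starts at 1, and
    ``G`` is the studentized deviation of the flagged value at that pass.
    With ``one_sided_upper`` only the maximum is tested at each pass;
    otherwise the value farthest from the mean is tested against the
    two-sided critical value. Ties at the extreme are broken toward the
    lowest input index (deterministic for id-sorted input).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("grubbs_outliers expects a 1-d vector")
    active = np.arange(x.size)
    flagged: list[tuple[int, int, float]] = []
    pass_no = 0
    while active.size >= min_bin_size:
        pass_no += 1
        sub = x[active]
        sd = sub.std(ddof=1)
        if sd == 0:  # all remaining values equal: no outlier is definable
            break
        mean = sub.mean()
        if one_sided_upper:
            local = int(np.argmax(sub))
            g = (sub[local] - mean) / sd
        else:
            local = int(np.argmax(np.abs(sub - mean)))
            g = abs(sub[local] - mean) / sd
        crit = grubbs_critical_value(active.size, alpha, one_sided=one_sided_upper)
        if g <= crit:
            break
        flagged.append((int(active[local]), pass_no, float(g)))
        active = np.delete(active, local)
        if not iterative:
            break
    return flagged


def detect_dynamic_genes(expr: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Run the full binned-CV Grubbs screen over an expression matrix.

    Returns one row per gene with columns ``gene_id``, ``mean_log_expr``,
    ``bin_index``, ``cv``, ``grubbs_statistic``, ``is_dynamic`` and
    ``pass_index`` (0 for genes never flagged). Genes with zero expression
    at every timepoint have no defined CV and are excluded (logged).
    """
    config = config or RunConfig()
    vals = expr.to_numpy(dtype=float)
    logx = np.log10(vals + 1.0)
    mean_log = logx.mean(axis=1)

    expressed = mean_log > 0  # all-zero genes have mean log10(FPKM+1) == 0
    n_dropped = int((~expressed).sum())
    if n_dropped:
        logger.info("detect_dynamic_genes: excluding %d genes with zero expression", n_dropped)

    if config.cv_scale == "log":
        basis = logx
    else:
        basis = vals
    with np.errstate(invalid="ignore", divide="ignore"):
        means = basis.mean(axis=1)
        cv = np.where(expressed & (means > 0), basis.std(axis=1, ddof=1) / means, np.nan)

    bin_index = np.floor(mean_log / config.bin_width).astype(int)

    out = pd.DataFrame(
        {
            "gene_id": expr.index.astype(str),
            "mean_log_expr": mean_log,
            "bin_index": bin_index,
            "cv": cv,
            "grubbs_statistic": np.nan,
            "is_dynamic": False,
            "pass_index": 0,
        }
    )

    testable = out.index[expressed & np.isfinite(cv)]
    for _, members in out.loc[testable].groupby("bin_index").groups.items():
        # lexicographic gene-id order makes tie-breaking deterministic
        members = members[np.argsort(out.loc[members, "gene_id"].to_numpy())]
        if len(members) < config.min_bin_size:
            logger.debug("bin with %d genes skipped (< min_bin_size)", len(members))
            continue
        cvs = out.loc[members, "cv"].to_numpy()
        hits = grubbs_outliers(
            cvs,
            alpha=config.grubbs_alpha,
            one_sided_upper=config.grubbs_one_sided,
            min_bin_size=config.min_bin_size,
            iterative=config.grubbs_iterative,
        )
        for local_idx, pass_no, g in hits:
            row = members[local_idx]
            out.loc[row, ["grubbs_statistic", "is_dynamic", "pass_index"]] = [g, True, pass_no]

    n_dyn = int(out["is_dynamic"].sum())
    n_tested = int(len(testable))
    logger.info(
        "detect_dynamic_genes: %d dynamic genes of %d tested (%.1f%%), bin width %g",
        n_dyn, n_tested, 100.0 * n_dyn / max(n_tested, 1), config.bin_width,
    )
    return out
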