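"""Reference-based cell-type deconvolution from methylation beta values.

Each sample's beta values at a panel of signature CpGs are projected onto
the reference signature matrix by non-negative least squares:

    w_t = argmin_{w >= 0} || S w - m_t ||^2

where S holds the mean beta of each signature CpG in each purified cell
type and m_t is the sample's observed betas at those CpGs. This is the
constrained-projection estimator used for whole-blood composition
estimation from 450K data; the non-negativity constraint alone is imposed
during optimisation, and rescaling the raw projection to sum to 1 is an
optional post-hoc step (off by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

logger = logging.getLogger("methdyn")

# per-sample raw proportion sums outside this band get a QC flag
QC_SUM_BAND = (0.8, 1.2)


def _check_signature(sig: pd.DataFrame) -> None:
    if sig.shape[1] < 2:
        raise ValueError("reference signature needs >= 2 cell types")
    S = sig.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(S)
    if rank < sig.shape[1]:
        # identify columns involved in the dependency for the error message
        _, r = np.linalg.qr(S)
        diag = np.abs(np.diag(r))
        dependent = [sig.columns[i] for i in np.where(diag < 1e-10 * diag.max())[0]]
        raise ValueError(
            f"reference signature is rank-deficient (rank {rank} < {sig.shape[1]} "
            f"cell types); linearly dependent columns: {dependent or 'unresolved'}"
        )


def estimate_composition(
    meth: pd.DataFrame,
    signature: pd.DataFrame,
    normalize: bool = False,
    min_overlap: float = 0.9,
) -> pd.DataFrame:
    """Estimate per-sample cell-type proportions by NNLS projection.

    Parameters
    ----------
    meth : DataFrame
        Probes x samples beta values; must contain at least ``min_overlap``
        of the signature probes.
    signature : DataFrame
        Signature CpGs x cell types mean beta values.
    normalize : bool
        If True, rescale each sample's raw projection to sum to 1
        (when its raw sum is positive).

    Returns
    -------
    DataFrame
        Samples x cell types estimated proportions.
    """
    overlap = signature.index.intersection(meth.index)
    frac = len(overlap) / len(signature.index)
    if frac < min_overlap:
        raise ValueError(
            f"only {len(overlap)}/{len(signature.index)} signature probes present in "
            f"the methylation matrix ({frac:.1%} < {min_overlap:.0%})"
        )
    sig = signature.loc[overlap]
    _check_signature(sig)
    S = sig.to_numpy(dtype=float)
    M = meth.loc[overlap].to_numpy(dtype=float)
    W = np.empty((meth.shape[1], signature.shape[1]))
    for j in range(meth.shape[1]):
        W[j], _ = nnls(S, M[:, j])
    if normalize:
        sums = W.sum(axis=1)
        pos = sums > 0
        W[pos] /= sums[pos, None]
    comp = pd.DataFrame(W, index=meth.columns, columns=signature.columns)
    logger.info(
        "estimate_composition: %d samples x %d cell types from %d signature probes "
        "(normalize=%s)", comp.shape[0], comp.shape[1], len(overlap), normalize,
    )
    return comp


@dataclass
class CompositionQC:
    """Per-sample sum and per-type mean ± SD summary with out-of-band flags."""

    per_sample_sum: pd.Series
    per_type_mean: pd.Series
    per_type_sd: pd.Series
    flagged_samples: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.per_type_mean, "sd": self.per_type_sd})


def composition_qc(comp: pd.DataFrame) -> CompositionQC:
    """Summarise a composition matrix and flag samples with implausible sums."""
    sums = comp.sum(axis=1)
    lo, hi = QC_SUM_BAND
    flagged = sums.index[(sums < lo) | (sums > hi)].tolist()
    if flagged:
        logger.warning(
            "composition_qc: %d samples with proportion sum outside [%g, %g]: %s",
            len(flagged), lo, hi, flagged[:5],
        )
    return CompositionQC(
        per_sample_sum=sums,
        per_type_mean=comp.mean(axis=0),
        per_type_sd=comp.std(axis=0, ddof=1),
        flagged_samples=flagged,
    )
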