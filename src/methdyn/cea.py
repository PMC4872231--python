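"""Cell-type composition / expression association (CEA) analysis.

For each gene, the log-scale expression series E_t (log10[FPKM+1]) is
regressed on the estimated cell-type proportions and the fit is compared
with an intercept-only null by an ANOVA F-test:

    M1: E_t = b0 + sum_c b_c P_ct        M0: E_t = b0

    F = ((RSS0 - RSS1) / q) / (RSS1 / (n - r1)),  q = r1 - 1

where r1 is the *rank* of the M1 design matrix. Proportions summing to ~1
make the design near-collinear with the intercept; fitting by pseudo-inverse
with rank-aware degrees of freedom keeps the ANOVA exact without arbitrarily
dropping a cell type. A gene with p below the configured level is classified
CEA (composition-associated); its most associated single cell type (smallest
univariate regression p) is recorded for downstream covariate adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig

logger = logging.getLogger("methdyn")

_RANK_TOL = 1e-8  # relative singular-value cutoff for the design rank


@dataclass
class CEAResult:
    gene_id: str
    f_statistic: float
    p_value: float
    df_num: int
    df_den: int
    is_cea: bool
    per_type_p: dict[str, float]
    best_cell_type: str


def _rank_aware_lstsq(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """Least squares via SVD pseudo-inverse; returns (fitted values, rank)."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    keep = s > _RANK_TOL * s[0]
    rank = int(keep.sum())
    coeff = (Vt[keep].T / s[keep]) @ (U[:, keep].T @ y)
    return X @ coeff, rank


def cea_test(
    gene_series: np.ndarray | pd.Series,
    comp: pd.DataFrame,
    alpha: float = 0.05,
    gene_id: str = "",
    per_type: bool = True,
) -> CEAResult:
    """Nested-model ANOVA of one gene's log-expression on cell composition.

    ``gene_series`` is E_t on the log10(FPKM+1) scale, aligned with the rows
    of ``comp`` (samples x cell types).
    """
    y = np.asarray(gene_series, dtype=float)
    n = y.size
    if n != comp.shape[0]:
        raise ValueError(f"series length {n} != {comp.shape[0]} composition samples")
    W = comp.to_numpy(dtype=float)
    X = np.column_stack([np.ones(n), W])

    fitted, r1 = _rank_aware_lstsq(X, y)
    if n <= r1:
        raise ValueError(f"n = {n} samples <= rank {r1} of the design; F-test undefined")

    rss0 = float(np.sum((y - y.mean()) ** 2))
    rss1 = float(np.sum((y - fitted) ** 2))
    q = r1 - 1
    df_den = n - r1

    if rss0 <= 0 or q == 0:  # constant expression: nothing to explain
        f_stat, p = 0.0, 1.0
    elif rss1 <= _RANK_TOL * rss0:  # numerically perfect fit
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = ((rss0 - rss1) / q) / (rss1 / df_den)
        p = float(stats.f.sf(f_stat, q, df_den))

    per_type_p: dict[str, float] = {}
    if per_type:
        for c, col in zip(comp.columns, W.T):
            if np.ptp(col) == 0 or rss0 <= 0:
                per_type_p[str(c)] = 1.0
            else:
                per_type_p[str(c)] = float(stats.linregress(col, y).pvalue)
    best = min(per_type_p, key=per_type_p.get) if per_type_p else str(comp.columns[0])

    return CEAResult(
        gene_id=gene_id,
        f_statistic=float(f_stat),
        p_value=p,
        df_num=q,
        df_den=df_den,
        is_cea=bool(p < alpha),
        per_type_p=per_type_p,
        best_cell_type=best,
    )


def run_cea(expr: pd.DataFrame, comp: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """CEA test for every gene of an aligned expression matrix.

    Expression is put on the log10(FPKM+1) scale here; ``expr`` holds FPKM.
    Returns one row per gene with the F statistic, ANOVA p, CEA flag,
    per-cell-type univariate p-values and the best (smallest-p) cell type.
    """
    config = config or RunConfig()
    if list(expr.columns) != list(comp.index):
        raise ValueError("expression samples and composition samples are not aligned")
    logx = np.log10(expr.to_numpy(dtype=float) + 1.0)
    rows = []
    for gid, y in zip(expr.index.astype(str), logx):
        res = cea_test(y, comp, alpha=config.cea_alpha, gene_id=gid)
        row = {
            "gene_id": res.gene_id,
            "f_statistic": res.f_statistic,
            "p_value": res.p_value,
            "df_num": res.df_num,
            "df_den": res.df_den,
            "is_cea": res.is_cea,
            "best_cell_type": res.best_cell_type,
        }
        row.update({f"p_{c}": v for c, v in res.per_type_p.items()})
        rows.append(row)
    out = pd.DataFrame(rows)
    logger.info(
        "run_cea: %d/%d genes CEA at p < %g",
        int(out["is_cea"].sum()), len(out), config.cea_alpha,
    )
    return out


def stratify_genes(cea_results: pd.DataFrame, dynamic_results: pd.DataFrame) -> pd.DataFrame:
    """Cross-classify the gene universe: CEA/non-CEA x dynamic/non-dynamic.

    Both inputs must cover exactly the same genes. Returns a 2x2 count table
    (rows: dynamic status, columns: CEA status).
    """
    cea_ids = set(cea_results["gene_id"])
    dyn_ids = set(dynamic_results["gene_id"])
    if cea_ids != dyn_ids:
        diff = sorted(cea_ids.symmetric_difference(dyn_ids))
        raise ValueError(f"gene universes differ between CEA and dynamic results: {diff[:10]}")
    merged = cea_results[["gene_id", "is_cea"]].merge(
        dynamic_results[["gene_id", "is_dynamic"]], on="gene_id"
    )
    table = pd.crosstab(
        merged["is_dynamic"].map({True: "dynamic", False: "non-dynamic"}),
        merged["is_cea"].map({True: "CEA", False: "non-CEA"}),
    ).reindex(index=["dynamic", "non-dynamic"], columns=["CEA", "non-CEA"], fill_value=0)
    table.index.name = "expression"
    table.columns.name = "association"
    logger.info("stratify_genes:\n%s", table.to_string())
    return table
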