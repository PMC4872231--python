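"""Methylation / expression association (MEA) analysis.

For each gene paired with a CpG near its transcription start site (within a
fixed window, SNP-overlapping probes excluded), both series are first made
relative to the reference day ("Day 1"): the log-scale expression series
log10(FPKM+1) and the beta series are each divided by their value at the
reference timepoint. Two regressions are then fitted per pair:

    Model 1:  E_t = b0 + b_m M_t
    Model 2:  E_t = b0 + b_m M_t + b_CT CT_t

where CT_t is the proportion series of the cell type most associated with
the gene (smallest univariate CEA p). Model-1 R^2 is the ordinary
coefficient of determination (the squared Pearson correlation). Model-2's
methylation-attributed R^2 is the squared correlation between the
composition-adjusted partial residual E_t - b0 - b_CT*CT_t and the fitted
methylation term b_m*M_t — the partial-R^2 reading of "variance explained
by methylation after adjustment".

Significance per pair comes from a permutation test on the Spearman rank
correlation: the expression vector is permuted B times (default 1000) and
the add-one-corrected two-sided p is (1 + #{|rho_b| >= |rho|}) / (B + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig

logger = logging.getLogger("methdyn")


# ---------------------------------------------------------------------------
# pair extraction

def extract_pairs(
    genes: pd.DataFrame, cpgs: pd.DataFrame, window: int = 5000
) -> pd.DataFrame:
    """All same-chromosome (gene, CpG) pairs with |position - TSS| <= window.

    SNP-overlapping probes are excluded first. ``tss_distance`` is signed and
    strand-adjusted (positive = downstream of the TSS in the gene's reading
    direction); the window filter itself uses the absolute distance, and the
    boundary is inclusive.
    """
    usable = cpgs.loc[~cpgs["snp_overlap"].astype(bool)]
    n_snp = len(cpgs) - len(usable)
    rows = []
    for chrom, gsub in genes.groupby("chromosome", sort=False):
        csub = usable.loc[usable["chromosome"] == chrom]
        if csub.empty:
            continue
        pos = csub["position"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos_sorted = pos[order]
        pids = csub["probe_id"].to_numpy()[order]
        for gid, tss, strand in zip(gsub["gene_id"], gsub["tss"], gsub["strand"]):
            lo = np.searchsorted(pos_sorted, tss - window, side="left")
            hi = np.searchsorted(pos_sorted, tss + window, side="right")
            sign = 1 if strand == "+" else -1
            for p, pid in zip(pos_sorted[lo:hi], pids[lo:hi]):
                rows.append((gid, pid, sign * (int(p) - int(tss))))
    out = pd.DataFrame(rows, columns=["gene_id", "probe_id", "tss_distance"])
    logger.info(
        "extract_pairs: %d gene-CpG pairs within %d bp of a TSS "
        "(%d SNP-overlapping probes excluded)", len(out), window, n_snp,
    )
    if out.empty:
        logger.warning("extract_pairs: no pairs found")
    return out


# ---------------------------------------------------------------------------
# per-pair statistics

def relative_to_reference(
    series: np.ndarray | pd.Series, ref_index: int = 0, min_ref: float = 1e-6
) -> np.ndarray | None:
    """Divide a series by its value at the reference timepoint.

    Returns the ratio series (exactly 1 at ``ref_index``), or ``None`` when
    the reference value is below ``min_ref`` — such series are excluded from
    the analysis rather than divided by ~0.
    """
    x = np.asarray(series, dtype=float)
    if not 0 <= ref_index < x.size:
        raise ValueError(f"ref_index {ref_index} out of range for length {x.size}")
    ref = x[ref_index]
    if ref < min_ref:
        return None
    out = x / ref
    out[ref_index] = 1.0
    return out


def mea_model1(e_rel: np.ndarray, m_rel: np.ndarray) -> tuple[float, float]:
    """Simple regression of relative expression on relative methylation.

    Returns ``(beta_m, r2)``. A constant predictor or constant response has
    nothing to fit/explain: ``(0.0, 0.0)`` by convention.
    """
    e = np.asarray(e_rel, dtype=float)
    m = np.asarray(m_rel, dtype=float)
    if e.size != m.size or e.size < 3:
        raise ValueError("mea_model1 needs equal-length series of length >= 3")
    if np.ptp(m) == 0 or np.ptp(e) == 0:
        return 0.0, 0.0
    slope, _, r, _, _ = stats.linregress(m, e)
    return float(slope), float(r * r)


def mea_model2(
    e_rel: np.ndarray, m_rel: np.ndarray, ct: np.ndarray, partial: bool = True
) -> tuple[float, float, float]:
    """Composition-adjusted regression of relative expression on methylation.

    Fits ``E = b0 + b_m M + b_ct CT`` by pseudo-inverse least squares and
    returns ``(beta_m, beta_ct, r2_meth)``. With ``partial`` (default) the
    methylation-attributed R^2 is the squared Pearson correlation between
    the partial residual ``E - b0 - b_ct*CT`` and the fitted term ``b_m*M``;
    otherwise the joint model's plain R^2 is returned.
    """
    e = np.asarray(e_rel, dtype=float)
    m = np.asarray(m_rel, dtype=float)
    c = np.asarray(ct, dtype=float)
    n = e.size
    if not (m.size == c.size == n) or n < 4:
        raise ValueError("mea_model2 needs equal-length series of length >= 4")
    X = np.column_stack([np.ones(n), m, c])
    coef, _, rank, _ = np.linalg.lstsq(X, e, rcond=None)
    if rank < 3:
        logger.debug("mea_model2: collinear design (rank %d); pseudo-inverse fit", rank)
    b0, bm, bct = (float(v) for v in coef)
    if not partial:
        fitted = X @ coef
        tss = float(np.sum((e - e.mean()) ** 2))
        rss = float(np.sum((e - fitted) ** 2))
        r2 = 0.0 if tss <= 0 else max(0.0, 1.0 - rss / tss)
        return bm, bct, r2
    partial_resid = e - b0 - bct * c
    term = bm * m
    if np.ptp(term) == 0 or np.ptp(partial_resid) == 0:
        return bm, bct, 0.0
    r = np.corrcoef(partial_resid, term)[0, 1]
    return bm, bct, float(r * r)


def spearman_permutation(
    e_rel: np.ndarray,
    m_rel: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    two_sided: bool = True,
) -> tuple[float, float]:
    """Spearman correlation with an empirical permutation p-value.

    The expression vector is permuted ``n_perm`` times; the add-one-corrected
    p is ``(1 + #{b : |rho_b| >= |rho|}) / (n_perm + 1)`` (two-sided) or the
    analogous upper-tail count. A constant series has no defined rank
    correlation and reports ``(0.0, 1.0)``.
    """
    e = np.asarray(e_rel, dtype=float)
    m = np.asarray(m_rel, dtype=float)
    if e.size != m.size or e.size < 3:
        raise ValueError("spearman_permutation needs equal-length series of length >= 3")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if np.ptp(e) == 0 or np.ptp(m) == 0:
        logger.debug("spearman_permutation: constant series; rho undefined, p = 1")
        return 0.0, 1.0
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    re = stats.rankdata(e)  # average ranks for ties
    rm = stats.rankdata(m)
    re_c = re - re.mean()
    rm_c = rm - rm.mean()
    denom = np.sqrt(np.sum(re_c**2) * np.sum(rm_c**2))
    rho = float(np.dot(re_c, rm_c) / denom)

    # ranks of a permuted vector are the permuted ranks, so permute re directly
    perms = rng.permuted(np.broadcast_to(re_c, (n_perm, re_c.size)), axis=1)
    rho_b = perms @ rm_c / denom
    if two_sided:
        count = int(np.sum(np.abs(rho_b) >= abs(rho) - 1e-12))
    else:
        count = int(np.sum(rho_b >= rho - 1e-12))
    perm_p = (1 + count) / (n_perm + 1)
    return rho, float(perm_p)


def methylation_sd(beta_series: np.ndarray | pd.Series) -> float:
    """Sample SD (n-1 denominator) of a raw (not Day-1-relative) beta series."""
    x = np.asarray(beta_series, dtype=float)
    if x.size < 2:
        raise ValueError("methylation_sd needs length >= 2")
    return float(x.std(ddof=1))


def compare_distributions(
    values_a: np.ndarray, values_b: np.ndarray, test: str = "mannwhitney"
) -> dict:
    """Two-sample comparison of a statistic between gene groups.

    Default is the two-sided Mann–Whitney U test (normal approximation with
    tie correction); ``test="ks"`` uses the two-sample Kolmogorov–Smirnov
    test. Medians and IQRs of both groups are always reported; the p-value
    is omitted (None, with a flag) when either group has fewer than 2 values.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")

    def _summ(x: np.ndarray) -> dict:
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return {"n": int(x.size), "median": float(med), "iqr": (float(q1), float(q3))}

    out = {"group_a": _summ(a), "group_b": _summ(b), "test": test,
           "statistic": None, "p_value": None, "degenerate": False}
    if a.size < 2 or b.size < 2:
        out["degenerate"] = True
        return out
    if test == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    elif test == "ks":
        res = stats.ks_2samp(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    out["statistic"] = float(res.statistic)
    out["p_value"] = float(min(res.pvalue, 1.0))
    return out


# ---------------------------------------------------------------------------
# pipeline driver

@dataclass
class MEASummary:
    """Fig.-4-style report: per-group medians/IQRs and significance fractions."""

    n_pairs: int
    n_excluded_cea: int
    n_excluded_reference: int
    by_group: dict
    frac_perm_significant: float
    r2_comparison: dict | None
    perm_p_comparison: dict | None
    sd_comparison: dict | None


def run_mea(
    expr: pd.DataFrame,
    meth: pd.DataFrame,
    pairs: pd.DataFrame,
    cea_results: pd.DataFrame,
    dynamic_results: pd.DataFrame,
    config: RunConfig | None = None,
    composition: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, MEASummary]:
    """Per-pair MEA statistics plus the stratified summary report.

    With ``config.mea_stratified`` (default) pairs whose gene is CEA are
    removed before the per-pair analysis, so composition-driven expression
    cannot masquerade as methylation-driven. Model 2 is fitted when a
    ``composition`` matrix is supplied, using each gene's best CEA cell type
    as the adjustment covariate.
    """
    config = config or RunConfig()
    if list(expr.columns) != list(meth.columns):
        raise ValueError("expression and methylation matrices are not sample-aligned")
    if composition is not None and list(composition.index) != list(expr.columns):
        raise ValueError("composition matrix is not sample-aligned with expression")

    cea_map = cea_results.set_index("gene_id")
    dyn_map = dynamic_results.set_index("gene_id")
    rng = np.random.default_rng(config.rng_seed)

    work = pairs.loc[pairs["gene_id"].isin(expr.index) & pairs["probe_id"].isin(meth.index)]
    n_in = len(work)
    n_cea_excluded = 0
    if config.mea_stratified:
        is_cea = work["gene_id"].map(cea_map["is_cea"]).fillna(False).astype(bool)
        n_cea_excluded = int(is_cea.sum())
        work = work.loc[~is_cea]
        logger.info(
            "run_mea: excluded %d/%d pairs at CEA genes (stratified analysis)",
            n_cea_excluded, n_in,
        )

    logx = pd.DataFrame(
        np.log10(expr.to_numpy(dtype=float) + 1.0), index=expr.index, columns=expr.columns
    )

    rows = []
    n_ref_excluded = 0
    e_rel_cache: dict[str, np.ndarray | None] = {}
    for gid, pid, dist in work[["gene_id", "probe_id", "tss_distance"]].itertuples(index=False):
        if gid not in e_rel_cache:
            e_rel_cache[gid] = relative_to_reference(
                logx.loc[gid].to_numpy(), config.reference_day_index, config.min_ref_value
            )
        e_rel = e_rel_cache[gid]
        beta = meth.loc[pid].to_numpy(dtype=float)
        m_rel = relative_to_reference(beta, config.reference_day_index, config.min_ref_value)
        if e_rel is None or m_rel is None:
            n_ref_excluded += 1
            continue

        bm, r2_1 = mea_model1(e_rel, m_rel)
        if composition is not None:
            best_ct = cea_map.loc[gid, "best_cell_type"] if gid in cea_map.index else None
            if best_ct is not None and best_ct in composition.columns:
                ct = composition[best_ct].to_numpy(dtype=float)
                _, _, r2_2 = mea_model2(e_rel, m_rel, ct, partial=config.mea_r2_partial)
            else:
                r2_2 = np.nan
        else:
            r2_2 = np.nan
        rho, perm_p = spearman_permutation(
            e_rel, m_rel, config.n_permutations, rng, two_sided=config.mea_two_sided
        )
        is_dyn = bool(dyn_map.loc[gid, "is_dynamic"]) if gid in dyn_map.index else False
        is_cea_g = bool(cea_map.loc[gid, "is_cea"]) if gid in cea_map.index else False
        rows.append(
            {
                "gene_id": gid,
                "probe_id": pid,
                "tss_distance": dist,
                "r2_model1": r2_1,
                "r2_model2": r2_2,
                "beta_m": bm,
                "spearman_rho": rho,
                "perm_p": perm_p,
                "meth_sd": methylation_sd(beta),
                "is_dynamic": is_dyn,
                "is_cea": is_cea_g,
            }
        )
    if n_ref_excluded:
        logger.info(
            "run_mea: excluded %d pairs whose reference-day value was below %g",
            n_ref_excluded, config.min_ref_value,
        )

    results = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "probe_id", "tss_distance", "r2_model1", "r2_model2", "beta_m",
            "spearman_rho", "perm_p", "meth_sd", "is_dynamic", "is_cea",
        ],
    )

    by_group: dict = {}
    for name, grp in (
        ("dynamic", results.loc[results["is_dynamic"]]),
        ("non-dynamic", results.loc[~results["is_dynamic"]]),
    ):
        if len(grp) == 0:
            by_group[name] = None
            continue
        q = lambda col: tuple(float(v) for v in np.percentile(grp[col], [25, 50, 75]))
        r2q, ppq, sdq = q("r2_model1"), q("perm_p"), q("meth_sd")
        by_group[name] = {
            "n_pairs": int(len(grp)),
            "r2_median": r2q[1], "r2_iqr": (r2q[0], r2q[2]),
            "perm_p_median": ppq[1], "perm_p_iqr": (ppq[0], ppq[2]),
            "meth_sd_median": sdq[1], "meth_sd_iqr": (sdq[0], sdq[2]),
            "frac_perm_significant": float((grp["perm_p"] < 0.05).mean()),
        }

    def _cmp(col: str) -> dict | None:
        dyn = results.loc[results["is_dynamic"], col].to_numpy()
        non = results.loc[~results["is_dynamic"], col].to_numpy()
        if dyn.size == 0 or non.size == 0:
            return None
        return compare_distributions(dyn, non, test=config.compare_test)

    summary = MEASummary(
        n_pairs=len(results),
        n_excluded_cea=n_cea_excluded,
        n_excluded_reference=n_ref_excluded,
        by_group=by_group,
        frac_perm_significant=float((results["perm_p"] < 0.05).mean()) if len(results) else 0.0,
        r2_comparison=_cmp("r2_model1"),
        perm_p_comparison=_cmp("perm_p"),
        sd_comparison=_cmp("meth_sd"),
    )
    logger.info(
        "run_mea: %d pairs analysed; %.1f%% with permutation p < 0.05",
        summary.n_pairs, 100 * summary.frac_perm_significant,
    )
    return results, summary
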