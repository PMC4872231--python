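"""End-to-end orchestration of the four analysis stages.

``run_pipeline`` wires QC/alignment → deconvolution → dynamic-gene
detection → CEA → stratified MEA, asserting sample-order equality at every
stage boundary, and returns one bundle with every intermediate result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .cea import run_cea, stratify_genes
from .config import RunConfig
from .deconvolution import composition_qc, estimate_composition
from .dynamic import detect_dynamic_genes
from .mea import MEASummary, extract_pairs, run_mea
from .qc import align_samples, filter_probes

logger = logging.getLogger("methdyn")


@dataclass
class PipelineResult:
    composition: pd.DataFrame
    dynamic: pd.DataFrame
    cea: pd.DataFrame
    strata: pd.DataFrame
    pairs: pd.DataFrame
    mea: pd.DataFrame
    mea_summary: MEASummary


def run_pipeline(
    expr: pd.DataFrame,
    meth: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    cpg_annotation: pd.DataFrame,
    signature: pd.DataFrame,
    config: RunConfig | None = None,
    detection_p: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run every stage on aligned matrices and return all results."""
    config = config or RunConfig()

    meth = filter_probes(meth, detection_p, p_threshold=0.01)
    expr, meth = align_samples(expr, meth)
    assert list(expr.columns) == list(meth.columns)

    if config.min_mean_fpkm > 0:
        keep = expr.mean(axis=1) >= config.min_mean_fpkm
        logger.info(
            "expression filter: retaining %d/%d genes with mean FPKM >= %g",
            int(keep.sum()), len(keep), config.min_mean_fpkm,
        )
        expr = expr.loc[keep]

    composition = estimate_composition(
        meth, signature, normalize=config.normalize_composition
    )
    composition_qc(composition)
    assert list(composition.index) == list(expr.columns)

    dynamic = detect_dynamic_genes(expr, config)
    cea = run_cea(expr, composition, config)
    strata = stratify_genes(cea, dynamic)

    pairs = extract_pairs(gene_annotation, cpg_annotation, window=config.tss_window_bp)
    mea, mea_summary = run_mea(
        expr, meth, pairs, cea, dynamic, config, composition=composition
    )
    return PipelineResult(
        composition=composition,
        dynamic=dynamic,
        cea=cea,
        strata=strata,
        pairs=pairs,
        mea=mea,
        mea_summary=mea_summary,
    )
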