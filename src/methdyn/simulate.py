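"""Synthetic longitudinal expression/methylation data with planted structure.

The generator emulates a single individual sampled repeatedly over a short
time course (default 24 timepoints): a mixed leukocyte sample whose
cell-type composition drifts from day to day, bulk expression formed by
mixing cell-type-specific expression through that composition, and a
methylome that is very stable in time (per-CpG temporal SD ~ 0.01 on the
beta scale, matching the stability of repeated-sampling array data).

Three kinds of structure are planted, recorded in a :class:`GroundTruth`
so that every inference stage can be scored against known answers:

* **dynamic genes** — a multiplicative fold-change spike on one or more
  "stimulus" days, mimicking transient inflammatory responses;
* **CEA genes** — expression concentrated in a single cell type, so the
  bulk series tracks that cell type's proportion;
* **MEA pairs** — a gene whose log-scale expression is linearly driven by
  a slowly drifting CpG beta series, with the variance split chosen to hit
  a target regression R^2.

A reference signature (cell-type-specific CpGs) is generated alongside so
the deconvolution stage can estimate the composition the generator used.
All randomness flows from one seed via deterministically spawned child
generators, so identical parameters + seed give bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio

logger = logging.getLogger("methdyn")

DEFAULT_CELL_TYPES = ("CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran")
# whole-blood-like mean proportions for the default leukocyte panel
DEFAULT_DIRICHLET_BASE = (0.08, 0.15, 0.07, 0.05, 0.10, 0.55)


@dataclass
class SimulationParams:
    """Generative settings; defaults mirror the 24-timepoint study design."""

    n_timepoints: int = 24
    n_genes: int = 5000
    n_cpgs: int = 20000
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    dirichlet_base: tuple[float, ...] = DEFAULT_DIRICHLET_BASE
    dirichlet_concentration: float = 100.0
    n_dynamic_genes: int = 50
    dynamic_fold: float = 4.0
    spike_days: tuple[int, ...] = (12,)
    n_cea_genes: int = 100
    cea_effect: float = 50.0
    n_mea_pairs: int = 50
    mea_target_r2: float = 0.5
    meth_temporal_sd: float = 0.01
    expr_noise_sd: float = 0.05
    n_signature_cpgs_per_type: int = 100
    # marginal beta-value mixture: hypo + hyper modes plus a uniform shelf
    beta_mix_weights: tuple[float, float, float] = (0.45, 0.45, 0.10)
    beta_modes: tuple[float, float] = (0.1, 0.9)
    mea_drift_sd: float = 0.05
    mea_signal_sd: float = 0.15
    snp_overlap_fraction: float = 0.05
    cpgs_per_gene: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cell_types) != len(self.dirichlet_base):
            raise ValueError("cell_types and dirichlet_base lengths differ")
        if abs(sum(self.dirichlet_base) - 1.0) > 1e-9:
            raise ValueError("dirichlet_base must sum to 1")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")
        if not 0.0 <= self.mea_target_r2 <= 1.0:
            raise ValueError("mea_target_r2 must lie in [0, 1]")
        planted = self.n_dynamic_genes + self.n_cea_genes + self.n_mea_pairs
        if planted > self.n_genes:
            raise ValueError(
                f"{planted} planted genes exceed n_genes = {self.n_genes}"
            )
        if any(not 0 <= d < self.n_timepoints for d in self.spike_days):
            raise ValueError("spike_days must be valid timepoint indices")

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)


@dataclass
class GroundTruth:
    """Record of everything the generator planted."""

    true_composition: pd.DataFrame
    dynamic_gene_ids: list[str] = field(default_factory=list)
    cea_genes: dict[str, str] = field(default_factory=dict)  # gene -> driving cell type
    mea_pairs: list[dict] = field(default_factory=list)  # gene_id, probe_id, target_r2
    signature_cpg_ids: dict[str, list[str]] = field(default_factory=dict)

    def validate_disjoint(self) -> None:
        dyn = set(self.dynamic_gene_ids)
        cea = set(self.cea_genes)
        mea = {p["gene_id"] for p in self.mea_pairs}
        if dyn & cea or dyn & mea or cea & mea:
            raise AssertionError("planted gene categories overlap")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id": g, "category": "dynamic", "detail": ""} for g in self.dynamic_gene_ids
        ]
        rows += [
            {"id": g, "category": "cea", "detail": ct} for g, ct in self.cea_genes.items()
        ]
        rows += [
            {"id": p["gene_id"], "category": "mea",
             "detail": f"{p['probe_id']}:r2={p['target_r2']}"}
            for p in self.mea_pairs
        ]
        for ct, probes in self.signature_cpg_ids.items():
            rows += [{"id": pr, "category": "signature", "detail": ct} for pr in probes]
        return pd.DataFrame(rows, columns=["id", "category", "detail"])


@dataclass
class SimulatedDataset:
    expression: pd.DataFrame
    methylation: pd.DataFrame
    gene_annotation: pd.DataFrame
    cpg_annotation: pd.DataFrame
    signature: pd.DataFrame
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mio.write_expression_matrix(self.expression, out / "expression.tsv")
        mio.write_methylation_matrix(self.methylation, out / "methylation.tsv")
        mio.write_gene_annotation(self.gene_annotation, out / "genes.tsv")
        mio.write_cpg_annotation(self.cpg_annotation, out / "cpgs.tsv")
        mio.write_signature_matrix(self.signature, out / "signature.tsv")
        self.truth.to_frame().to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        mio.write_composition_matrix(self.truth.true_composition, out / "true_composition.tsv")


# ---------------------------------------------------------------------------
# stage generators

def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_composition(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw one Dirichlet composition vector per timepoint.

    Per-type means equal ``dirichlet_base``; ``dirichlet_concentration`` is
    the total Dirichlet mass, so larger values give a more stable
    composition over time.
    """
    rng = rng or _child_rngs(params.rng_seed, 1)[0]
    alpha = np.asarray(params.dirichlet_base) * params.dirichlet_concentration
    W = rng.dirichlet(alpha, size=params.n_timepoints)
    sample_ids = [f"Day{t + 1}" for t in range(params.n_timepoints)]
    return pd.DataFrame(W, index=sample_ids, columns=list(params.cell_types))


def _assign_planted(params: SimulationParams, rng: np.random.Generator):
    gene_ids = [f"gene{g:05d}" for g in range(params.n_genes)]
    order = rng.permutation(params.n_genes)
    n_dyn, n_cea, n_mea = params.n_dynamic_genes, params.n_cea_genes, params.n_mea_pairs
    dyn = sorted(gene_ids[i] for i in order[:n_dyn])
    cea = sorted(gene_ids[i] for i in order[n_dyn:n_dyn + n_cea])
    mea = sorted(gene_ids[i] for i in order[n_dyn + n_cea:n_dyn + n_cea + n_mea])
    return gene_ids, dyn, cea, mea


def simulate_expression(
    params: SimulationParams,
    composition: pd.DataFrame,
    truth: GroundTruth,
    rng: np.random.Generator,
    gene_ids: list[str],
) -> pd.DataFrame:
    """Bulk FPKM from cell-type-specific expression mixed through composition.

    Baseline: FPKM_gt = sum_k w_tk * e_gk * exp(eps_gt), with e_gk log-normal
    per (gene, cell type) and eps ~ N(0, expr_noise_sd^2). Dynamic genes get
    a multiplicative ``dynamic_fold`` at each spike day; CEA genes have their
    expression concentrated in one cell type (scaled by ``cea_effect``), so
    the bulk series tracks that type's proportion. MEA-pair genes are filled
    in separately by :func:`simulate_methylation_coupled`.
    """
    W = composition.to_numpy()
    T = W.shape[0]
    G = len(gene_ids)
    K = params.n_cell_types

    base_level = rng.lognormal(mean=np.log(5.0), sigma=1.2, size=G)
    type_mult = rng.lognormal(mean=0.0, sigma=0.3, size=(G, K))
    e_gk = base_level[:, None] * type_mult

    idx = {g: i for i, g in enumerate(gene_ids)}
    for gid, ct in truth.cea_genes.items():
        k = list(params.cell_types).index(ct)
        g = idx[gid]
        # expression almost exclusively from the driving cell type
        lvl = rng.lognormal(mean=np.log(50.0), sigma=0.5)
        e_gk[g, :] = lvl * 0.01
        e_gk[g, k] = lvl * params.cea_effect / 10.0

    eps = rng.normal(0.0, params.expr_noise_sd, size=(G, T))
    fpkm = (e_gk @ W.T) * np.exp(eps)

    for gid in truth.dynamic_gene_ids:
        g = idx[gid]
        for d in params.spike_days:
            fpkm[g, d] *= params.dynamic_fold

    return pd.DataFrame(fpkm, index=gene_ids, columns=composition.index)


def _draw_baseline_betas(params: SimulationParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Bimodal marginal beta levels: hypo/hyper Beta modes plus a uniform shelf."""
    w = np.asarray(params.beta_mix_weights, dtype=float)
    w = w / w.sum()
    comp = rng.choice(3, size=n, p=w)
    lo, hi = params.beta_modes
    # Beta(a, b) with mode m at concentration c: a = 1 + m*c, b = 1 + (1-m)*c
    c = 30.0
    out = np.empty(n)
    sel = comp == 0
    out[sel] = rng.beta(1 + lo * c, 1 + (1 - lo) * c, size=int(sel.sum()))
    sel = comp == 1
    out[sel] = rng.beta(1 + hi * c, 1 + (1 - hi) * c, size=int(sel.sum()))
    sel = comp == 2
    out[sel] = rng.uniform(0.2, 0.8, size=int(sel.sum()))
    return out


def simulate_methylation(
    params: SimulationParams,
    truth: GroundTruth,
    rng: np.random.Generator,
    probe_ids: list[str],
    signature_pure: pd.DataFrame,
) -> pd.DataFrame:
    """Beta matrix: stable baseline CpGs plus composition-mixed signature CpGs.

    Baseline probes: beta_ct = clip(beta_c + eta_ct, 0, 1) with a bimodal
    per-probe level beta_c and iid temporal noise eta ~ N(0, temporal_sd^2).
    Signature probes mix the pure cell-type betas through the composition,
    then add the same temporal noise. MEA probes are overwritten later by
    :func:`simulate_methylation_coupled`.
    """
    W = truth.true_composition.to_numpy()
    T = W.shape[0]
    P = len(probe_ids)
    levels = _draw_baseline_betas(params, P, rng)
    beta = np.repeat(levels[:, None], T, axis=1)

    sig_idx = {p: i for i, p in enumerate(probe_ids)}
    if len(signature_pure):
        mixed = signature_pure.to_numpy() @ W.T  # (n_sig, T)
        for row, pid in enumerate(signature_pure.index):
            beta[sig_idx[pid]] = mixed[row]

    beta = beta + rng.normal(0.0, params.meth_temporal_sd, size=(P, T))
    beta = np.clip(beta, 0.0, 1.0)
    return pd.DataFrame(beta, index=probe_ids, columns=truth.true_composition.index)


def simulate_methylation_coupled(
    params: SimulationParams,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression and methylation series for the planted MEA pairs.

    The CpG drifts slowly (smoothed random walk rescaled to
    ``mea_drift_sd`` on the beta scale); the gene's log10(FPKM+1) series is
    ``a + b*M_t + xi_t`` with b and var(xi) split so the realised population
    R^2 of E on M equals ``mea_target_r2`` exactly. A target of 1 requires
    (and gets) zero noise; FPKM is recovered as 10^E - 1.
    """
    T = params.n_timepoints
    r2 = params.mea_target_r2
    e_rows, m_rows, e_ids, m_ids = [], [], [], []
    for pair in truth.mea_pairs:
        center = rng.uniform(0.3, 0.7)
        walk = np.cumsum(rng.normal(0.0, 1.0, size=T))
        walk = np.convolve(walk, np.ones(3) / 3, mode="same")  # slow drift
        sd = walk.std(ddof=1)
        m = center + (walk - walk.mean()) / (sd if sd > 0 else 1.0) * params.mea_drift_sd
        m = np.clip(m, 0.02, 0.98)

        a = rng.uniform(0.8, 1.5)  # log10(FPKM+1) working point
        var_m = m.var(ddof=1)
        sign = rng.choice([-1.0, 1.0])
        if var_m <= 0 or r2 == 0:
            b = 0.0
            noise_sd = params.mea_signal_sd
        else:
            b = sign * params.mea_signal_sd * np.sqrt(r2) / np.sqrt(var_m)
            noise_sd = params.mea_signal_sd * np.sqrt(1.0 - r2)
        e_log = a + b * (m - m.mean()) + rng.normal(0.0, noise_sd, size=T)
        e_log = np.maximum(e_log, 0.0)
        fpkm = np.power(10.0, e_log) - 1.0

        e_rows.append(fpkm)
        m_rows.append(m)
        e_ids.append(pair["gene_id"])
        m_ids.append(pair["probe_id"])

    cols = truth.true_composition.index
    expr = pd.DataFrame(np.asarray(e_rows).reshape(len(e_ids), T), index=e_ids, columns=cols)
    meth = pd.DataFrame(np.asarray(m_rows).reshape(len(m_ids), T), index=m_ids, columns=cols)
    return expr, meth


def _build_signature(params: SimulationParams, rng: np.random.Generator) -> pd.DataFrame:
    """Pure cell-type betas at discriminative signature CpGs.

    Each cell type gets ``n_signature_cpgs_per_type`` probes that are highly
    methylated in that type and lowly methylated in the others.
    """
    K = params.n_cell_types
    n_per = params.n_signature_cpgs_per_type
    rows, ids = [], []
    for k, ct in enumerate(params.cell_types):
        high = rng.uniform(0.70, 0.95, size=n_per)
        low = rng.uniform(0.05, 0.30, size=(n_per, K))
        block = low
        block[:, k] = high
        rows.append(block)
        ids.extend(f"sig_{ct}_{j:03d}" for j in range(n_per))
    return pd.DataFrame(np.vstack(rows), index=ids, columns=list(params.cell_types))


def _layout_annotations(
    params: SimulationParams,
    gene_ids: list[str],
    truth: GroundTruth,
    sig_ids: list[str],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Place genes and CpGs on a toy genome.

    Genes sit every 100 kb (no cross-gene window overlap at the default
    5 kb window); each gene carries ``cpgs_per_gene`` CpGs within the
    window, a fraction of which are SNP-flagged. MEA probes are placed near
    their own gene's TSS; signature probes and any remaining probes go to
    intergenic positions so they never enter the cis pair list.
    """
    spacing = 100_000
    genes_per_chrom = 250
    g_rows = []
    gene_pos = {}
    for i, gid in enumerate(gene_ids):
        chrom = f"chr{i // genes_per_chrom + 1}"
        tss = (i % genes_per_chrom) * spacing + 50_000
        strand = "+" if rng.random() < 0.5 else "-"
        g_rows.append((gid, chrom, tss, strand))
        gene_pos[gid] = (chrom, tss)
    gene_annot = pd.DataFrame(g_rows, columns=mio.GENE_ANNOTATION_COLUMNS)

    mea_probe_of_gene = {p["gene_id"]: p["probe_id"] for p in truth.mea_pairs}
    c_rows = []
    probe_ids: list[str] = []
    counter = 0
    for gid in gene_ids:
        chrom, tss = gene_pos[gid]
        if gid in mea_probe_of_gene:
            pid = mea_probe_of_gene[gid]
            offset = int(rng.integers(-2000, 2001))
            c_rows.append((pid, chrom, max(1, tss + offset), False))
            probe_ids.append(pid)
        for _ in range(params.cpgs_per_gene):
            pid = f"cg{counter:07d}"
            counter += 1
            offset = int(rng.integers(-5000, 5001))
            snp = bool(rng.random() < params.snp_overlap_fraction)
            c_rows.append((pid, chrom, max(1, tss + offset), snp))
            probe_ids.append(pid)

    # signature probes: intergenic, never within a TSS window
    for j, pid in enumerate(sig_ids):
        chrom = f"chr{j % 20 + 30}"
        c_rows.append((pid, chrom, 10_000 + j * 1000, False))
        probe_ids.append(pid)

    # fill the remaining probe budget with distal baseline CpGs
    while len(probe_ids) < params.n_cpgs:
        pid = f"cg{counter:07d}"
        counter += 1
        chrom = f"chr{int(rng.integers(30, 50))}"
        c_rows.append((pid, chrom, int(rng.integers(1, 5_000_000)), False))
        probe_ids.append(pid)

    cpg_annot = pd.DataFrame(c_rows, columns=mio.CPG_ANNOTATION_COLUMNS)
    return gene_annot, cpg_annot, probe_ids


def simulate_dataset(params: SimulationParams | None = None) -> SimulatedDataset:
    """Generate a complete synthetic study with its ground truth."""
    params = params or SimulationParams()
    rngs = _child_rngs(params.rng_seed, 6)
    r_comp, r_assign, r_expr, r_meth, r_mea, r_layout = rngs

    composition = simulate_composition(params, r_comp)
    gene_ids, dyn, cea, mea = _assign_planted(params, r_assign)

    truth = GroundTruth(true_composition=composition)
    truth.dynamic_gene_ids = dyn
    cea_types = r_assign.choice(params.n_cell_types, size=len(cea))
    truth.cea_genes = {g: params.cell_types[k] for g, k in zip(cea, cea_types)}
    truth.mea_pairs = [
        {"gene_id": g, "probe_id": f"mea_cg{j:05d}", "target_r2": params.mea_target_r2}
        for j, g in enumerate(mea)
    ]

    signature = _build_signature(params, r_meth)
    truth.signature_cpg_ids = {
        ct: [p for p in signature.index if p.startswith(f"sig_{ct}_")]
        for ct in params.cell_types
    }

    gene_annot, cpg_annot, probe_ids = _layout_annotations(
        params, gene_ids, truth, list(signature.index), r_layout
    )

    expr = simulate_expression(params, composition, truth, r_expr, gene_ids)
    meth = simulate_methylation(params, truth, r_meth, probe_ids, signature)

    expr_mea, meth_mea = simulate_methylation_coupled(params, truth, r_mea)
    for gid in expr_mea.index:
        expr.loc[gid] = expr_mea.loc[gid]
    for pid in meth_mea.index:
        meth.loc[pid] = meth_mea.loc[pid]

    truth.validate_disjoint()
    logger.info(
        "simulate_dataset: %d genes x %d timepoints, %d CpGs; planted %d dynamic, "
        "%d CEA, %d MEA (seed %d)",
        params.n_genes, params.n_timepoints, len(probe_ids),
        len(dyn), len(cea), len(truth.mea_pairs), params.rng_seed,
    )
    return SimulatedDataset(
        expression=expr,
        methylation=meth,
        gene_annotation=gene_annot,
        cpg_annotation=cpg_annot,
        signature=signature,
        truth=truth,
    )
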