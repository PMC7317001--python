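"""Synthetic multi-omics cohorts with planted ground truth for every stage.

The generator emulates the study design the pipeline expects: a tumor cohort
with mutation, CNV, methylation, miRNA, lncRNA and gene-expression layers, a
normal expression cohort, regulator catalogs, and a protein interaction
network. Ground truth is planted at every stage:

* key genes carry combined mutation+CNV events in a fixed fraction of
  samples and a large expression shift between variant and non-variant
  samples, so they pass the candidate filter by construction;
* each key gene owns private target genes whose expression follows the
  linear regulator model; on *dysregulated* TF edges the regulator acts only
  in the key gene's variant samples (the TF is transcriptionally flat at its
  baseline elsewhere, so its weight is non-zero in the variant group and
  unidentifiable-zero in the non-variant group), while *stable* edges carry
  one weight everywhere — the XOR of the fitted group networks should
  recover exactly the dysregulated edges;
* target genes are 4-fold over-expressed in tumor vs normal so they pass the
  training-gene filter;
* the PPIN is a planted-partition graph: each module's TFs and targets form
  a dense block, blocks are sparsely interconnected, and key genes attach
  loosely to a background block. Module structure is therefore recoverable
  only when the dysregulation networks are, which makes recovery degrade as
  the model noise grows.

Methylation is Beta-distributed, CNV states are multinomial over {-2..2} and
mutations Bernoulli — simple marginals that exercise the pipeline without
mimicking real tumor-cohort distributions. The same seed always yields a
bit-identical cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .dysreg import RegressionInputs
from .io import EdgeList, OmicsMatrix, RegulatorCatalog, write_edge_list, write_matrix
from .links import MirnaTargetEvidence

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_candidate_cohort",
    "generate_differential_expression",
    "make_regression_problem",
    "mirna_evidence_for",
]

# per-target covariates: methylation, CNV, 2 TFs, 1 miRNA, 1 lncRNA
_COVARIATES_PER_TARGET = 6
_CNV_STATES = np.array([-2, -1, 0, 1, 2])
_CNV_PROBS = np.array([0.01, 0.04, 0.90, 0.04, 0.01])


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of one synthetic cohort.

    Defaults mirror the scale of the real study where one is stated
    (19 key genes in modules of 8/5/6; >10%% variant fraction planted at
    0.3; a 3-SD candidate expression shift) and otherwise use values a
    small tumor-cohort simulation would: 100 tumor / 50 normal samples,
    unit-variance expression noise around the regulator signal, dense
    intra-module PPIN blocks with sparse inter-block wiring.
    """

    seed: int
    n_samples: int = 150
    n_normal_samples: int = 50
    module_sizes: tuple = (8, 5, 6)
    targets_per_key: int = 2
    mutated_fraction: float = 0.4
    candidate_shift_sd: float = 3.0   # expression shift of key genes, in SD units
    candidate_noise_sd: float = 1.0
    stable_tf_weight: float = 2.0
    dysreg_effect: float = 3.0        # TF weight difference between sample groups
    mir_weight: float = -0.4
    lnc_weight: float = -0.4
    dm_weight: float = -0.5
    cn_weight: float = 0.5
    noise_sd: float = 0.1             # residual SD of the target-gene linear model
    training_fold_change: float = 4.0
    n_background_genes: int = 60
    background_mutation_rate: float = 0.02
    n_noise_key_genes: int = 1        # key genes planted outside every module
    noise_relay_length: int = 3       # PPIN relay chain from a noise island to a module
    ppin_p_within: float = 0.3
    ppin_p_between: float = 0.0       # inter-block wiring (0 = fully separated modules)
    ppin_p_background: float = 0.01
    key_attach_edges: int = 2         # shared background anchors per module

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_normal_samples < 2:
            raise ValueError("sample counts must be positive (>=2 normals)")
        if not self.module_sizes or any(s < 1 for s in self.module_sizes):
            raise ValueError("module_sizes must be positive")
        if self.targets_per_key < 1:
            raise ValueError("targets_per_key must be positive")
        if not 0.0 < self.mutated_fraction < 1.0:
            raise ValueError("mutated_fraction must be in (0, 1)")
        for name in ("ppin_p_within", "ppin_p_between", "ppin_p_background",
                     "background_mutation_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability")
        n_var = round(self.mutated_fraction * self.n_samples)
        min_fit = _COVARIATES_PER_TARGET + 1
        if n_var < min_fit or self.n_samples - n_var < min_fit:
            raise ValueError(
                f"infeasible config: group sizes {n_var}/{self.n_samples - n_var} "
                f"below the minimum fit size {min_fit}"
            )

    @property
    def n_key_genes(self) -> int:
        return int(sum(self.module_sizes)) + self.n_noise_key_genes


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth for every pipeline stage."""

    key_genes: tuple
    noise_key_genes: tuple     # planted key genes belonging to no module
    module_of: dict            # key gene -> module index (0-based; -1 = none)
    variant_samples: dict      # key gene -> tuple of sample ids
    dysregulated_edges: dict   # key gene -> frozenset of (tf, target)
    stable_edges: dict         # key gene -> frozenset of (tf, target)
    training_genes: tuple      # all planted differential target genes
    lncrna_gene_pairs: frozenset  # planted (lncrna, gene) links

    def module_labels(self) -> dict:
        return dict(self.module_of)


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    expression: OmicsMatrix
    expression_normal: OmicsMatrix
    methylation: OmicsMatrix
    cnv: OmicsMatrix
    mutation: OmicsMatrix
    mirna: OmicsMatrix
    lncrna: OmicsMatrix
    catalog: RegulatorCatalog
    ppin_edges: EdgeList
    truth: GroundTruth
    _graph: nx.Graph | None = field(default=None, repr=False)

    @property
    def ppin(self) -> nx.Graph:
        if self._graph is None:
            self._graph = self.ppin_edges.to_graph()
        return self._graph

    def layers(self) -> dict:
        return {
            "expression": self.expression,
            "methylation": self.methylation,
            "cnv": self.cnv,
            "mirna": self.mirna,
            "lncrna": self.lncrna,
        }

    def write(self, outdir: str | Path) -> None:
        """Write every standard pipeline input plus truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, matrix in (
            ("expression", self.expression),
            ("expression_normal", self.expression_normal),
            ("methylation", self.methylation),
            ("cnv", self.cnv),
            ("mutation", self.mutation),
            ("mirna_expression", self.mirna),
            ("lncrna_expression", self.lncrna),
        ):
            write_matrix(matrix, outdir / f"{name}.tsv")
        write_edge_list(self.catalog.tf_gene, outdir / "tf_gene.tsv")
        write_edge_list(self.catalog.mirna_gene, outdir / "mirna_gene.tsv")
        write_edge_list(self.catalog.lncrna_gene, outdir / "lncrna_gene.tsv")
        if self.catalog.mirna_lncrna is not None:
            write_edge_list(self.catalog.mirna_lncrna, outdir / "mirna_lncrna.tsv")
        write_edge_list(self.ppin_edges, outdir / "ppin.tsv")
        truth = {
            "key_genes": list(self.truth.key_genes),
            "noise_key_genes": list(self.truth.noise_key_genes),
            "module_of": self.truth.module_of,
            "variant_samples": {k: list(v) for k, v in self.truth.variant_samples.items()},
            "dysregulated_edges": {
                k: sorted(map(list, v)) for k, v in self.truth.dysregulated_edges.items()
            },
            "stable_edges": {
                k: sorted(map(list, v)) for k, v in self.truth.stable_edges.items()
            },
            "training_genes": list(self.truth.training_genes),
            "lncrna_gene_pairs": sorted(map(list, self.truth.lncrna_gene_pairs)),
            "config": asdict(self.config),
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def _block_edges(rng: np.random.Generator, nodes: list, p: float) -> set:
    edges = set()
    n = len(nodes)
    if p <= 0 or n < 2:
        return edges
    mask = rng.random((n, n)) < p
    for i in range(n):
        for j in range(i + 1, n):
            if mask[i, j]:
                edges.add((nodes[i], nodes[j]))
    return edges


def _cross_edges(rng: np.random.Generator, a: list, b: list, p: float) -> set:
    edges = set()
    if p <= 0:
        return edges
    mask = rng.random((len(a), len(b))) < p
    for i, u in enumerate(a):
        for j, v in enumerate(b):
            if mask[i, j]:
                edges.add((u, v))
    return edges


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a complete synthetic cohort from the configured conditions."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    samples = [f"T{i + 1:03d}" for i in range(config.n_samples)]
    normal_samples = [f"N{i + 1:03d}" for i in range(config.n_normal_samples)]

    key_genes, module_of = [], {}
    for m, size in enumerate(config.module_sizes):
        for _ in range(size):
            gene = f"KG{len(key_genes) + 1:02d}"
            key_genes.append(gene)
            module_of[gene] = m
    noise_keys = [f"KN{i + 1:02d}" for i in range(config.n_noise_key_genes)]
    for gene in noise_keys:  # planted outside every module (-1 = no module)
        key_genes.append(gene)
        module_of[gene] = -1

    t_per = config.targets_per_key
    dys_tf_of = {k: [f"TFD_{k}_{i + 1}" for i in range(t_per)] for k in key_genes}
    sta_tf_of = {k: [f"TFS_{k}_{i + 1}" for i in range(t_per)] for k in key_genes}
    tf_of = {k: dys_tf_of[k] + sta_tf_of[k] for k in key_genes}
    target_of = {k: [f"TG_{k}_{i + 1}" for i in range(t_per)] for k in key_genes}
    mir_of = {k: [f"MIR_{k}_{i + 1}" for i in range(t_per)] for k in key_genes}
    lnc_of = {k: [f"LNC_{k}_{i + 1}" for i in range(t_per)] for k in key_genes}
    background = [f"BG{i + 1:03d}" for i in range(config.n_background_genes)]

    all_tfs = [t for k in key_genes for t in tf_of[k]]
    all_targets = [t for k in key_genes for t in target_of[k]]
    all_mirs = [m for k in key_genes for m in mir_of[k]]
    all_lncs = [l for k in key_genes for l in lnc_of[k]]
    protein_genes = key_genes + all_tfs + all_targets + background
    n, n_norm = config.n_samples, config.n_normal_samples

    # --- variant structure -------------------------------------------------
    n_var = round(config.mutated_fraction * n)
    variant_idx = {k: np.sort(rng.choice(n, n_var, replace=False)) for k in key_genes}

    mutation = (rng.random((len(protein_genes), n)) < config.background_mutation_rate)
    mutation = mutation.astype(int)
    cnv = rng.choice(_CNV_STATES, p=_CNV_PROBS, size=(len(protein_genes), n))
    gene_pos = {g: i for i, g in enumerate(protein_genes)}
    for k in key_genes:
        row = gene_pos[k]
        mutation[row, :] = 0
        mutation[row, variant_idx[k]] = 1
        cnv[row, variant_idx[k]] = rng.choice(np.array([-2, -1, 1, 2]), size=n_var)

    methylation = rng.beta(2.0, 5.0, size=(len(protein_genes), n))

    # --- regulator expression ---------------------------------------------
    def expr_block(ids: list, n_cols: int, mus: np.ndarray | None = None):
        if mus is None:
            mus = rng.uniform(5.0, 10.0, size=len(ids))
        return mus, mus[:, None] + rng.standard_normal((len(ids), n_cols))

    tf_mu, tf_expr = expr_block(all_tfs, n)
    mir_mu, mir_expr = expr_block(all_mirs, n)
    lnc_mu, lnc_expr = expr_block(all_lncs, n)
    tf_pos = {g: i for i, g in enumerate(all_tfs)}
    mir_pos = {g: i for i, g in enumerate(all_mirs)}
    lnc_pos = {g: i for i, g in enumerate(all_lncs)}

    # Dysregulated TFs act only where their key gene is altered: outside the
    # key's variant samples they sit flat at baseline, so their regulatory
    # weight exists in the variant group and vanishes in the non-variant one.
    if config.dysreg_effect != 0:
        for k in key_genes:
            flat = np.setdiff1d(np.arange(n), variant_idx[k])
            for tf in dys_tf_of[k]:
                tf_expr[tf_pos[tf], flat] = tf_mu[tf_pos[tf]]

    # --- edge truth ---------------------------------------------------------
    tf_gene_edges, mirna_gene_edges, mirna_lncrna_edges, lncrna_gene_edges = (
        set(), set(), set(), set())
    dysregulated, stable = {}, {}
    for k in key_genes:
        dys, sta = set(), set()
        for i, target in enumerate(target_of[k]):
            tf_dys, tf_sta = dys_tf_of[k][i], sta_tf_of[k][i]
            dys.add((tf_dys, target))
            sta.add((tf_sta, target))
            tf_gene_edges.update({(tf_dys, target), (tf_sta, target)})
            mirna_gene_edges.add((mir_of[k][i], target))
            mirna_lncrna_edges.add((mir_of[k][i], lnc_of[k][i]))
            lncrna_gene_edges.add((lnc_of[k][i], target))
        dysregulated[k] = frozenset(dys)
        stable[k] = frozenset(sta)

    # --- tumor expression ----------------------------------------------------
    expression = np.empty((len(protein_genes), n))
    base = rng.uniform(8.0, 12.0, size=len(protein_genes))
    dm_centered = methylation - 2.0 / 7.0  # Beta(2,5) mean
    for g, row in gene_pos.items():
        expression[row] = base[row] + rng.standard_normal(n)  # background / key default
    for tf in all_tfs:  # TF covariates seen by the pipeline are the TF rows
        expression[gene_pos[tf]] = tf_expr[tf_pos[tf]]
        base[gene_pos[tf]] = tf_mu[tf_pos[tf]]

    for k in key_genes:
        row = gene_pos[k]
        shift = np.zeros(n)
        shift[variant_idx[k]] = config.candidate_shift_sd * config.candidate_noise_sd
        expression[row] = (
            base[row] + shift + config.candidate_noise_sd * rng.standard_normal(n)
        )

    target_base = {}
    for k in key_genes:
        for i, target in enumerate(target_of[k]):
            row = gene_pos[target]
            tf_dys, tf_sta = dys_tf_of[k][i], sta_tf_of[k][i]
            signal = (
                config.dysreg_effect * (tf_expr[tf_pos[tf_dys]] - tf_mu[tf_pos[tf_dys]])
                + config.stable_tf_weight * (tf_expr[tf_pos[tf_sta]] - tf_mu[tf_pos[tf_sta]])
                + config.mir_weight * (mir_expr[mir_pos[mir_of[k][i]]] - mir_mu[mir_pos[mir_of[k][i]]])
                + config.lnc_weight * (lnc_expr[lnc_pos[lnc_of[k][i]]] - lnc_mu[lnc_pos[lnc_of[k][i]]])
                + config.dm_weight * dm_centered[row]
                + config.cn_weight * cnv[row]
            )
            target_base[target] = base[row]
            expression[row] = base[row] + signal + config.noise_sd * rng.standard_normal(n)

    # --- normal expression (targets 1/fold of tumor baseline) ---------------
    expression_normal = np.empty((len(protein_genes), n_norm))
    for g, row in gene_pos.items():
        expression_normal[row] = base[row] + rng.standard_normal(n_norm)
    for target, b in target_base.items():
        row = gene_pos[target]
        expression_normal[row] = (
            b / config.training_fold_change + 0.5 * rng.standard_normal(n_norm)
        )

    # --- PPIN ----------------------------------------------------------------
    # Planted-partition layout: each module's TFs and targets form one dense
    # block; blocks interconnect only sparsely; key genes hang off shared
    # background anchors rather than sitting inside their block, so module
    # structure is recoverable only through the dysregulation networks. Each
    # noise key gene gets a private island tied to one module by a relay
    # chain: far from every module at a finite distance.
    block_nodes: list[list[str]] = [[] for _ in config.module_sizes]
    for k in key_genes:
        if module_of[k] >= 0:
            block_nodes[module_of[k]].extend(tf_of[k] + target_of[k])
    ppin = set()
    for nodes in block_nodes:
        ppin |= _block_edges(rng, nodes, config.ppin_p_within)
    for i in range(len(block_nodes)):
        for j in range(i + 1, len(block_nodes)):
            ppin |= _cross_edges(rng, block_nodes[i], block_nodes[j],
                                 config.ppin_p_between)

    # Each module (and each noise key) owns a private chunk of background
    # anchor nodes; its key genes hang off those anchors. Background genes
    # beyond the anchor chunks stay outside the PPIN, standing in for the
    # real-data situation where many genes never map into the network.
    n_anchors = max(1, config.key_attach_edges)
    next_anchor = 0

    def take_anchors():
        nonlocal next_anchor
        if next_anchor + n_anchors > len(background):
            raise ValueError("n_background_genes too small for the anchor layout")
        chosen = background[next_anchor:next_anchor + n_anchors]
        next_anchor += n_anchors
        ppin.update(_block_edges(rng, chosen, config.ppin_p_background))
        return chosen

    module_anchors = [take_anchors() for _ in config.module_sizes]
    noise_anchors = {k: take_anchors() for k in noise_keys}
    for k in key_genes:
        anchors = module_anchors[module_of[k]] if module_of[k] >= 0 else noise_anchors[k]
        for a in anchors:
            ppin.add((k, a))

    first_key_of_module = [
        next(k for k in key_genes if module_of[k] == m) for m in range(len(config.module_sizes))
    ]
    for i, k in enumerate(noise_keys):
        island = tf_of[k] + target_of[k]
        for a, b in zip(island, island[1:] + island[:1]):  # connected ring
            ppin.add((a, b))
        ppin |= _block_edges(rng, island, config.ppin_p_within)
        target_module = i % len(config.module_sizes)
        relays = [f"RLY_{k}_{j + 1}" for j in range(max(1, config.noise_relay_length))]
        # chain ends at a stable-TF node, which is never a dysregulation seed
        chain = [island[0], *relays, sta_tf_of[first_key_of_module[target_module]][0]]
        for a, b in zip(chain, chain[1:]):
            ppin.add((a, b))

    def omics(layer: str, ids: list, values: np.ndarray, cols: list) -> OmicsMatrix:
        return OmicsMatrix(layer, pd.DataFrame(values, index=ids, columns=cols))

    catalog = RegulatorCatalog(
        tf_gene=EdgeList("tf_gene", frozenset(tf_gene_edges)),
        mirna_gene=EdgeList("mirna_gene", frozenset(mirna_gene_edges)),
        lncrna_gene=EdgeList("lncrna_gene", frozenset(lncrna_gene_edges)),
        mirna_lncrna=EdgeList("mirna_lncrna", frozenset(mirna_lncrna_edges)),
    )
    truth = GroundTruth(
        key_genes=tuple(key_genes),
        noise_key_genes=tuple(noise_keys),
        module_of=module_of,
        variant_samples={k: tuple(samples[i] for i in variant_idx[k]) for k in key_genes},
        dysregulated_edges=dysregulated,
        stable_edges=stable,
        training_genes=tuple(all_targets),
        lncrna_gene_pairs=frozenset(lncrna_gene_edges),
    )
    return SyntheticCohort(
        config=config,
        expression=omics("expression", protein_genes, expression, samples),
        expression_normal=omics("expression", protein_genes, expression_normal,
                                normal_samples),
        methylation=omics("methylation", protein_genes, methylation, samples),
        cnv=omics("cnv", protein_genes, cnv, samples),
        mutation=omics("mutation", protein_genes, mutation, samples),
        mirna=omics("mirna_expression", all_mirs, mir_expr, samples),
        lncrna=omics("lncrna_expression", all_lncs, lnc_expr, samples),
        catalog=catalog,
        ppin_edges=EdgeList("ppi", frozenset(ppin)),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# focused generators for single pipeline stages


def generate_candidate_cohort(
    *,
    n_key: int = 10,
    n_null: int = 200,
    n_samples: int = 100,
    mutated_fraction: float = 0.3,
    shift_sd: float = 3.0,
    noise_sd: float = 1.0,
    null_mutation_rate: float = 0.02,
    seed: int,
) -> tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix, list]:
    """Mutation/CNV/expression matrices with planted candidate genes.

    Returns ``(mutation, cnv, expression, planted_genes)``. Planted genes
    carry combined events in ``mutated_fraction`` of samples and a
    ``shift_sd``-SD expression shift in variant samples; null genes mutate
    at a low background rate.
    """
    rng = np.random.default_rng(seed)
    samples = [f"T{i + 1:03d}" for i in range(n_samples)]
    planted = [f"KEY{i + 1:02d}" for i in range(n_key)]
    nulls = [f"NULL{i + 1:03d}" for i in range(n_null)]
    genes = planted + nulls

    mutation = (rng.random((len(genes), n_samples)) < null_mutation_rate).astype(int)
    cnv = rng.choice(_CNV_STATES, p=_CNV_PROBS, size=(len(genes), n_samples))
    expression = rng.uniform(8.0, 12.0, size=len(genes))[:, None] + \
        noise_sd * rng.standard_normal((len(genes), n_samples))

    n_var = round(mutated_fraction * n_samples)
    for i, gene in enumerate(planted):
        idx = rng.choice(n_samples, n_var, replace=False)
        mutation[i, :] = 0
        mutation[i, idx] = 1
        cnv[i, idx] = rng.choice(np.array([-2, -1, 1, 2]), size=n_var)
        expression[i, idx] += shift_sd * noise_sd

    frame = lambda layer, vals: OmicsMatrix(layer, pd.DataFrame(vals, index=genes, columns=samples))
    return frame("mutation", mutation), frame("cnv", cnv), frame("expression", expression), planted


def generate_differential_expression(
    *,
    n_genes: int = 500,
    n_planted: int = 50,
    fold: float = 4.0,
    n_tumor: int = 60,
    n_normal: int = 40,
    noise_sd: float = 0.5,
    seed: int,
) -> tuple[OmicsMatrix, OmicsMatrix, list]:
    """Tumor/normal expression pair with planted fold-change genes."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    planted = genes[:n_planted]
    base = rng.uniform(8.0, 12.0, size=n_genes)
    tumor = base[:, None] + noise_sd * rng.standard_normal((n_genes, n_tumor))
    normal = base[:, None] + noise_sd * rng.standard_normal((n_genes, n_normal))
    normal[:n_planted] = base[:n_planted, None] / fold + noise_sd * rng.standard_normal(
        (n_planted, n_normal)
    )
    t_cols = [f"T{i + 1:03d}" for i in range(n_tumor)]
    n_cols = [f"N{i + 1:03d}" for i in range(n_normal)]
    return (
        OmicsMatrix("expression", pd.DataFrame(tumor, index=genes, columns=t_cols)),
        OmicsMatrix("expression", pd.DataFrame(normal, index=genes, columns=n_cols)),
        planted,
    )


def make_regression_problem(
    *,
    n_samples: int = 150,
    n_tfs: int = 3,
    n_mirnas: int = 2,
    n_lncrnas: int = 1,
    noise_sd: float = 0.1,
    weight_range: tuple = (-1.0, 1.0),
    seed: int,
) -> tuple[RegressionInputs, dict]:
    """One gene's regression design with known raw-scale weights.

    Returns ``(inputs, true_weights)`` where the keys of ``true_weights``
    match :class:`~modminer.dysreg.RegressionWeights` (``dm``, ``cn``,
    ``tf:<id>``, ...).
    """
    rng = np.random.default_rng(seed)
    lo, hi = weight_range
    dm = rng.beta(2.0, 5.0, size=n_samples)
    cn = rng.choice(_CNV_STATES, p=_CNV_PROBS, size=n_samples).astype(float)
    tf = {f"TF{i + 1}": rng.standard_normal(n_samples) for i in range(n_tfs)}
    mir = {f"MIR{i + 1}": rng.standard_normal(n_samples) for i in range(n_mirnas)}
    lnc = {f"LNC{i + 1}": rng.standard_normal(n_samples) for i in range(n_lncrnas)}

    true: dict[str, float] = {"dm": float(rng.uniform(lo, hi)), "cn": float(rng.uniform(lo, hi))}
    ge = true["dm"] * dm + true["cn"] * cn
    for prefix, mapping in (("tf", tf), ("mir", mir), ("lnc", lnc)):
        for name in sorted(mapping):
            w = float(rng.uniform(lo, hi))
            true[f"{prefix}:{name}"] = w
            ge = ge + w * mapping[name]
    ge = ge + noise_sd * rng.standard_normal(n_samples)
    inputs = RegressionInputs(gene_id="G", ge=ge, dm=dm, cn=cn, tf=tf, mir=mir, lnc=lnc)
    return inputs, true


def mirna_evidence_for(cohort: SyntheticCohort, *, n_decoys: int = 20) -> list[MirnaTargetEvidence]:
    """Evidence table in which exactly the cohort's true miRNA targets qualify.

    True edges get CLIP support, three negative cancer correlations and one
    predictor flag; decoys each fail one of the three criteria.
    """
    rng = np.random.default_rng(cohort.config.seed + 1)
    qualifying_corr = tuple(
        (c, -0.5, 0.01) for c in ("LUSC", "LUAD", "BRCA")
    )
    records = [
        MirnaTargetEvidence(
            mirna_id=mirna, target_id=gene, clip_support=int(rng.integers(1, 5)),
            cancer_correlations=qualifying_corr, predictor_flags=frozenset({"RNA22"}),
        )
        for mirna, gene in sorted(cohort.catalog.mirna_gene.edges)
    ]
    for i in range(n_decoys):
        mode = i % 3
        records.append(
            MirnaTargetEvidence(
                mirna_id=f"MIR_DECOY_{i + 1}",
                target_id=f"DECOY_{i + 1}",
                clip_support=0 if mode == 0 else 3,
                cancer_correlations=(("LUSC", -0.5, 0.01),) if mode == 1 else qualifying_corr,
                predictor_flags=frozenset() if mode == 2 else frozenset({"PITA"}),
            )
        )
    return records
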