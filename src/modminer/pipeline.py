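"""End-to-end orchestration: candidates -> networks -> XOR -> groups -> CCRS -> modules."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .candidates import CandidateResult, VariationMatrix, build_variation_matrix, \
    select_key_candidates
from .ccrs import DistanceMatrix, distance_matrix
from .clustering import ClusteringParams, ModuleAssignment, auto_parameters, cluster_modules
from .dysreg import DysregulationNetwork, RegulatoryNetwork, build_group_network, \
    filter_training_genes, xor_networks
from .grouping import GeneGroup, dysregulation_seeds, expand_group
from .io import OmicsMatrix, RegulatorCatalog, align_samples

__all__ = ["PipelineResult", "run_pipeline", "adjusted_rand_index"]


@dataclass
class PipelineResult:
    """Everything the pipeline computed, stage by stage."""

    variation: VariationMatrix
    candidates: list
    key_genes: list              # selected candidate genes, in matrix order
    training_genes: list
    group_networks: dict         # key gene -> (mutated net, non-mutated net)
    dysregulation: dict          # key gene -> DysregulationNetwork
    groups: list                 # non-empty GeneGroups, one per clustered key gene
    empty_group_keys: list       # key genes whose group did not map into the PPIN
    skipped_key_genes: list      # key genes with a sample group too small to fit
    distances: DistanceMatrix | None
    params: ClusteringParams | None
    assignment: ModuleAssignment | None

    def module_members(self) -> dict:
        return self.assignment.modules() if self.assignment is not None else {}


def run_pipeline(
    *,
    expression: OmicsMatrix,
    expression_normal: OmicsMatrix,
    methylation: OmicsMatrix | None,
    cnv: OmicsMatrix,
    mutation: OmicsMatrix,
    mirna: OmicsMatrix | None,
    lncrna: OmicsMatrix | None,
    catalog: RegulatorCatalog,
    ppin: nx.Graph,
    min_fraction: float = 0.10,
    candidate_fdr: float = 0.01,
    fold_change: float = 2.0,
    training_fdr: float = 0.05,
    weight_threshold: float = 0.3,
    steps: int = 2,
    params: ClusteringParams | None = None,
    min_group_size: int = 5,
) -> PipelineResult:
    """Run the full module-mining pipeline on sample-aligned or alignable inputs.

    Tumor layers are aligned to their shared samples first; the normal
    expression matrix is only used for the training-gene contrast. Clustering
    parameters are determined automatically unless ``params`` is given.
    """
    tumor_layers = [l for l in (expression, mutation, cnv, methylation, mirna, lncrna)
                    if l is not None]
    aligned = align_samples(tumor_layers)
    aligned_by_id = dict(zip([id(l) for l in tumor_layers], aligned))

    def take(layer):
        return aligned_by_id[id(layer)] if layer is not None else None

    expression_a = take(expression)
    layers = {
        "expression": expression_a,
        "methylation": take(methylation),
        "cnv": take(cnv),
        "mirna": take(mirna),
        "lncrna": take(lncrna),
    }
    layers = {k: v for k, v in layers.items() if v is not None}

    variation = build_variation_matrix(take(mutation), take(cnv))
    candidates = select_key_candidates(
        variation, expression_a, min_fraction=min_fraction, fdr=candidate_fdr
    )
    key_genes = [c.gene_id for c in candidates if c.selected]
    training = filter_training_genes(
        expression, expression_normal, fold_change=fold_change, fdr=training_fdr
    )

    group_networks, dysregulation = {}, {}
    groups, empty_keys, skipped = [], [], []
    for key in key_genes:
        try:
            net_mut = build_group_network(
                key, "mutated", variation, layers, catalog, training,
                weight_threshold=weight_threshold, min_group_size=min_group_size,
            )
            net_non = build_group_network(
                key, "non_mutated", variation, layers, catalog, training,
                weight_threshold=weight_threshold, min_group_size=min_group_size,
            )
        except ValueError as err:
            warnings.warn(f"key gene {key!r} skipped: {err}", stacklevel=2)
            skipped.append(key)
            continue
        group_networks[key] = (net_mut, net_non)
        dysreg = xor_networks(net_mut, net_non)
        dysregulation[key] = dysreg
        group = expand_group(dysregulation_seeds(key, dysreg), ppin, steps, key_gene_id=key)
        if group.is_empty:
            empty_keys.append(key)
        else:
            groups.append(group)

    distances = assignment = None
    chosen = params
    if len(groups) >= 2:
        distances = distance_matrix(groups, ppin)
        if chosen is None:
            try:
                chosen = auto_parameters(distances)
            except ValueError as err:
                warnings.warn(f"clustering skipped: {err}", stacklevel=2)
        if chosen is not None:
            assignment = cluster_modules(distances, chosen)
    return PipelineResult(
        variation=variation,
        candidates=candidates,
        key_genes=key_genes,
        training_genes=training,
        group_networks=group_networks,
        dysregulation=dysregulation,
        groups=groups,
        empty_group_keys=empty_keys,
        skipped_key_genes=skipped,
        distances=distances,
        params=chosen,
        assignment=assignment,
    )


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings of the same items.

    1 means identical partitions (up to label names), 0 the chance level.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must cover the same items")
    cats_a = {v: i for i, v in enumerate(dict.fromkeys(a.tolist()))}
    cats_b = {v: i for i, v in enumerate(dict.fromkeys(b.tolist()))}
    table = np.zeros((len(cats_a), len(cats_b)), dtype=np.int64)
    for x, y in zip(a.tolist(), b.tolist()):
        table[cats_a[x], cats_b[y]] += 1

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_cells = comb2(table).sum()
    sum_rows = comb2(table.sum(axis=1)).sum()
    sum_cols = comb2(table.sum(axis=0)).sum()
    n_pairs = comb2(len(a))
    expected = sum_rows * sum_cols / n_pairs if n_pairs else 0.0
    max_index = (sum_rows + sum_cols) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))
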