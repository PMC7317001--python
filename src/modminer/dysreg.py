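"""Per-gene regulatory models and dysregulation networks.

For each key candidate gene, cancer samples split into variant and
non-variant groups (row of the variation matrix). Within each group, every
training gene's expression is modelled as a linear combination of its
methylation, copy-number state and the expression of its catalogued TF,
miRNA and lncRNA regulators:

    GE_g ~ w_DM * DM_g + w_CN * CN_g + sum_t w_TF_t * TF_t
           + sum_m w_miR_m * miR_m + sum_l w_lnc_l * lncR_l

fitted without intercept on standardized variables. TF edges whose
standardized |weight| exceeds a threshold form the group's regulatory
network; the symmetric difference (XOR) of the two group networks is the key
gene's dysregulation network. miRNA and lncRNA covariates only adjust the
fit — network edges are drawn from TF weights alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .candidates import VariationMatrix
from .io import OmicsMatrix, RegulatorCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionInputs",
    "RegressionWeights",
    "RegulatoryNetwork",
    "DysregulationNetwork",
    "filter_training_genes",
    "fit_gene_model",
    "build_group_network",
    "xor_networks",
]

SAMPLE_GROUPS = ("mutated", "non_mutated")


def filter_training_genes(
    expr_tumor: OmicsMatrix,
    expr_normal: OmicsMatrix,
    *,
    fold_change: float = 2.0,
    fdr: float = 0.05,
    equal_var: bool = True,
) -> list[str]:
    """Genes differentially expressed between tumor and normal samples.

    Keeps genes whose mean-expression fold-change (tumor/normal) exceeds
    ``fold_change`` or falls below its reciprocal AND whose t-test q-value
    (Benjamini-Hochberg over all testable genes) is below ``fdr``. Genes with
    zero mean normal expression have no defined fold-change and are skipped
    with a warning.
    """
    shared = [g for g in expr_tumor.feature_ids if g in set(expr_normal.feature_ids)]
    ratios: dict[str, float] = {}
    pvals: dict[str, float] = {}
    for gene in shared:
        t_vec = expr_tumor.row(gene)
        n_vec = expr_normal.row(gene)
        n_mean = n_vec.mean()
        if n_mean == 0:
            warnings.warn(
                f"gene {gene!r}: zero mean normal expression; fold-change undefined, skipped",
                stacklevel=2,
            )
            continue
        t, p = stats.ttest_ind(t_vec, n_vec, equal_var=equal_var)
        if np.isnan(p):
            warnings.warn(f"gene {gene!r}: degenerate expression, t-test undefined, skipped",
                          stacklevel=2)
            continue
        ratios[gene] = t_vec.mean() / n_mean
        pvals[gene] = float(p)

    if not pvals:
        return []
    genes = list(pvals)
    qvals = stats.false_discovery_control([pvals[g] for g in genes], method="bh")
    kept = [
        g
        for g, q in zip(genes, qvals)
        if (ratios[g] > fold_change or ratios[g] < 1.0 / fold_change) and q < fdr
    ]
    return kept


# ---------------------------------------------------------------------------
# per-gene linear model


@dataclass(frozen=True)
class RegressionInputs:
    """Design of one gene's expression model within one sample group.

    All vectors share a single sample ordering. The regulator covariates are
    determined solely by the regulator catalog.
    """

    gene_id: str
    ge: np.ndarray
    dm: np.ndarray | None = None
    cn: np.ndarray | None = None
    tf: Mapping[str, np.ndarray] = field(default_factory=dict)
    mir: Mapping[str, np.ndarray] = field(default_factory=dict)
    lnc: Mapping[str, np.ndarray] = field(default_factory=dict)

    def covariate_items(self) -> list[tuple[str, np.ndarray]]:
        items: list[tuple[str, np.ndarray]] = []
        if self.dm is not None:
            items.append(("dm", np.asarray(self.dm, dtype=float)))
        if self.cn is not None:
            items.append(("cn", np.asarray(self.cn, dtype=float)))
        for prefix, mapping in (("tf", self.tf), ("mir", self.mir), ("lnc", self.lnc)):
            for name in sorted(mapping):
                items.append((f"{prefix}:{name}", np.asarray(mapping[name], dtype=float)))
        return items

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_items())


@dataclass(frozen=True)
class RegressionWeights:
    """Fitted coefficients of one gene model.

    ``weights`` are on the standardized scale (response and covariates
    z-scored); ``raw_weights`` are de-standardized back to the original
    units (w_std * sd(GE) / sd(x)). Keys are ``"dm"``, ``"cn"``,
    ``"tf:<id>"``, ``"mir:<id>"``, ``"lnc:<id>"``.
    """

    gene_id: str
    weights: dict[str, float]
    raw_weights: dict[str, float]
    residual_variance: float
    n_samples: int

    def tf_weights(self) -> dict[str, float]:
        return {k.split(":", 1)[1]: w for k, w in self.weights.items() if k.startswith("tf:")}


def _standardize(x: np.ndarray) -> tuple[np.ndarray, float]:
    sd = float(x.std())
    if sd == 0:
        return np.zeros_like(x), 0.0
    return (x - x.mean()) / sd, sd


def fit_gene_model(inputs: RegressionInputs, *, ridge_penalty: float = 1e-8) -> RegressionWeights:
    """Least-squares fit of one gene's expression model.

    Response and covariates are standardized to zero mean / unit variance;
    the model has no intercept (standardization removes the mean). Constant
    covariates get weight 0. A rank-deficient design falls back to ridge
    regression with the logged ``ridge_penalty``.
    """
    y = np.asarray(inputs.ge, dtype=float)
    n = len(y)
    if n < inputs.n_covariates + 1:
        raise ValueError(
            f"gene {inputs.gene_id!r}: {n} samples cannot identify "
            f"{inputs.n_covariates} covariates"
        )
    items = inputs.covariate_items()
    y_std, y_sd = _standardize(y)

    names: list[str] = []
    columns: list[np.ndarray] = []
    sds: dict[str, float] = {}
    weights = {name: 0.0 for name, _ in items}
    for name, x in items:
        if len(x) != n:
            raise ValueError(f"covariate {name!r} has length {len(x)} != {n}")
        z, sd = _standardize(x)
        sds[name] = sd
        if sd > 0:
            names.append(name)
            columns.append(z)

    if y_sd == 0 or not columns:
        raw = {name: 0.0 for name in weights}
        return RegressionWeights(inputs.gene_id, weights, raw, float(np.var(y_std)), n)

    X = np.column_stack(columns)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning(
            "gene %r: rank-deficient design (rank %d < %d); ridge fallback, penalty %g",
            inputs.gene_id, rank, X.shape[1], ridge_penalty,
        )
        beta = np.linalg.solve(X.T @ X + ridge_penalty * np.eye(X.shape[1]), X.T @ y_std)
    else:
        beta, *_ = np.linalg.lstsq(X, y_std, rcond=None)

    for name, b in zip(names, beta):
        weights[name] = float(b)
    residuals = y_std - X @ beta
    raw = {
        name: (weights[name] * y_sd / sds[name]) if sds[name] > 0 else 0.0
        for name in weights
    }
    return RegressionWeights(inputs.gene_id, weights, raw, float(np.var(residuals)), n)


# ---------------------------------------------------------------------------
# group networks and XOR


@dataclass(frozen=True)
class RegulatoryNetwork:
    """TF -> gene edges retained within one sample group of one key gene."""

    key_gene_id: str
    sample_group: str
    edges: frozenset  # of (regulator, target, weight)

    def __post_init__(self) -> None:
        if self.sample_group not in SAMPLE_GROUPS:
            raise ValueError(f"sample_group must be one of {SAMPLE_GROUPS}")

    def edge_pairs(self) -> frozenset:
        return frozenset((reg, tgt) for reg, tgt, _ in self.edges)

    def nodes(self) -> frozenset:
        return frozenset(x for reg, tgt, _ in self.edges for x in (reg, tgt))


@dataclass(frozen=True)
class DysregulationNetwork:
    """Edges regulated in exactly one of the two sample groups."""

    key_gene_id: str
    edges: frozenset  # of (regulator, target)

    def nodes(self) -> frozenset:
        return frozenset(x for edge in self.edges for x in edge)


def build_group_network(
    key_gene: str,
    group: str,
    M: VariationMatrix,
    layers: Mapping[str, OmicsMatrix],
    catalog: RegulatorCatalog,
    training_genes: Sequence[str],
    *,
    weight_threshold: float = 0.3,
    min_group_size: int = 5,
) -> RegulatoryNetwork:
    """Fit every training gene's model within one sample group of a key gene.

    ``layers`` must hold sample-aligned matrices under the keys
    ``expression``, ``methylation``, ``cnv``, ``mirna`` and ``lncrna``
    (methylation/cnv/mirna/lncrna optional). Membership in the group follows
    row ``key_gene`` of the variation matrix. TF edges with standardized
    |weight| > ``weight_threshold`` are retained.
    """
    if group not in SAMPLE_GROUPS:
        raise ValueError(f"group must be one of {SAMPLE_GROUPS}")
    expr = layers["expression"]
    if M.sample_ids != expr.sample_ids:
        raise ValueError("layers must be sample-aligned with the variation matrix")

    member = M.row(key_gene).astype(bool)
    if group == "non_mutated":
        member = ~member
    idx = np.flatnonzero(member)
    if len(idx) < min_group_size:
        raise ValueError(
            f"key gene {key_gene!r}: {group} group has {len(idx)} samples "
            f"(< minimum fit size {min_group_size})"
        )

    methyl = layers.get("methylation")
    cnv = layers.get("cnv")
    mirna = layers.get("mirna")
    lncrna = layers.get("lncrna")
    expr_features = set(expr.feature_ids)

    edges = set()
    for gene in training_genes:
        if gene not in expr_features:
            continue
        tf_ids = sorted(t for t in catalog.tfs_of(gene) if t in expr_features and t != gene)
        if not tf_ids:
            continue  # no TF covariates -> no edges to threshold
        mir_ids = sorted(
            m for m in catalog.mirnas_of(gene)
            if mirna is not None and m in set(mirna.feature_ids)
        )
        lnc_ids = sorted(
            l for l in catalog.lncrnas_of(gene)
            if lncrna is not None and l in set(lncrna.feature_ids)
        )
        inputs = RegressionInputs(
            gene_id=gene,
            ge=expr.row(gene)[idx],
            dm=methyl.row(gene)[idx] if methyl is not None and gene in set(methyl.feature_ids) else None,
            cn=cnv.row(gene)[idx] if cnv is not None and gene in set(cnv.feature_ids) else None,
            tf={t: expr.row(t)[idx] for t in tf_ids},
            mir={m: mirna.row(m)[idx] for m in mir_ids},
            lnc={l: lncrna.row(l)[idx] for l in lnc_ids},
        )
        if len(idx) < inputs.n_covariates + 1:
            warnings.warn(
                f"gene {gene!r}: {group} group of key gene {key_gene!r} too small for "
                f"{inputs.n_covariates} covariates; model skipped",
                stacklevel=2,
            )
            continue
        fit = fit_gene_model(inputs)
        for tf_id, w in fit.tf_weights().items():
            if abs(w) > weight_threshold:
                edges.add((tf_id, gene, w))
    return RegulatoryNetwork(key_gene, group, frozenset(edges))


def xor_networks(net_a: RegulatoryNetwork, net_b: RegulatoryNetwork) -> DysregulationNetwork:
    """Symmetric difference of two group networks (edge = regulator/target pair).

    Edges present in exactly one network are the dysregulated links; weights
    play no role in membership.
    """
    if net_a.key_gene_id != net_b.key_gene_id:
        raise ValueError(
            f"cannot XOR networks of different key genes "
            f"({net_a.key_gene_id!r} vs {net_b.key_gene_id!r})"
        )
    diff = net_a.edge_pairs() ^ net_b.edge_pairs()
    return DysregulationNetwork(net_a.key_gene_id, frozenset(diff))
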