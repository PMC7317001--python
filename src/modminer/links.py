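"""Evidence screening for miRNA targets and miRNA-mediated lncRNA-gene links.

A miRNA-target edge is kept only when three independent lines of evidence
agree: the target site has CLIP-Seq support, the pair is negatively
co-expressed across several cancer types, and at least one sequence-based
predictor calls the site. Genes and lncRNAs regulated by the same miRNA are
then linked whenever their expression is significantly anti-correlated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io import EdgeList, FormatError, OmicsMatrix

__all__ = [
    "PREDICTOR_PROGRAMS",
    "MirnaTargetEvidence",
    "filter_mirna_targets",
    "infer_lncrna_gene_links",
    "read_evidence_table",
    "write_evidence_table",
]

PREDICTOR_PROGRAMS = frozenset({"TargetScan", "PicTar", "PITA", "miRanda/mirSVR", "RNA22"})


@dataclass(frozen=True)
class MirnaTargetEvidence:
    """Evidence record for one putative miRNA -> target-gene interaction."""

    mirna_id: str
    target_id: str
    clip_support: int
    cancer_correlations: tuple = field(default_factory=tuple)  # (cancer, r, p)
    predictor_flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.clip_support < 0:
            raise ValueError("clip_support must be a non-negative count")
        for cancer, r, p in self.cancer_correlations:
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"pearson r {r} out of [-1, 1] for cancer {cancer!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p-value {p} out of [0, 1] for cancer {cancer!r}")
        unknown = set(self.predictor_flags) - PREDICTOR_PROGRAMS
        if unknown:
            raise ValueError(f"unknown predictor program(s): {sorted(unknown)}")


def filter_mirna_targets(
    evidence: Iterable[MirnaTargetEvidence],
    *,
    min_clip: int = 1,
    min_negative_cancers: int = 3,
    alpha: float = 0.05,
) -> EdgeList:
    """Screen miRNA-target evidence into a high-confidence edge list.

    An edge is kept iff all of:

    1. at least ``min_clip`` CLIP-Seq experiments support the target site;
    2. expression is negatively correlated (r < 0, p < ``alpha``) in at least
       ``min_negative_cancers`` cancer types;
    3. at least one prediction program flags the interaction.
    """
    kept = set()
    for rec in evidence:
        if rec.clip_support < min_clip:
            continue
        n_negative = sum(1 for _, r, p in rec.cancer_correlations if r < 0 and p < alpha)
        if n_negative < min_negative_cancers:
            continue
        if not rec.predictor_flags:
            continue
        kept.add((rec.mirna_id, rec.target_id))
    return EdgeList("mirna_gene", frozenset(kept))


def infer_lncrna_gene_links(
    mirna_gene: EdgeList,
    mirna_lncrna: EdgeList,
    expr_genes: OmicsMatrix,
    expr_lncrna: OmicsMatrix,
    *,
    alpha: float = 0.05,
) -> EdgeList:
    """Infer lncRNA-gene links through shared miRNA regulators.

    For every (gene, lncRNA) pair regulated by at least one common miRNA, the
    Pearson correlation of their expression profiles is computed over the
    shared sample ordering; the link is kept iff r < 0 with two-sided
    p < ``alpha``. Pairs with constant expression are skipped with a warning.
    """
    if expr_genes.sample_ids != expr_lncrna.sample_ids:
        raise ValueError("expression matrices must share one sample ordering; align first")
    if mirna_gene.edge_type != "mirna_gene" or mirna_lncrna.edge_type != "mirna_lncrna":
        raise ValueError("expected mirna_gene and mirna_lncrna edge lists")

    genes_by_mirna: dict[str, set[str]] = {}
    for mirna, gene in mirna_gene.edges:
        genes_by_mirna.setdefault(mirna, set()).add(gene)
    lncs_by_mirna: dict[str, set[str]] = {}
    for mirna, lnc in mirna_lncrna.edges:
        lncs_by_mirna.setdefault(mirna, set()).add(lnc)

    gene_features = set(expr_genes.feature_ids)
    lnc_features = set(expr_lncrna.feature_ids)

    pairs = set()
    for mirna, genes in genes_by_mirna.items():
        for lnc in lncs_by_mirna.get(mirna, ()):
            for gene in genes:
                pairs.add((gene, lnc))

    kept = set()
    for gene, lnc in sorted(pairs):
        if gene not in gene_features or lnc not in lnc_features:
            continue
        x = expr_genes.row(gene)
        y = expr_lncrna.row(lnc)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(
                f"constant expression for pair ({gene!r}, {lnc!r}); correlation undefined, "
                "pair skipped",
                stacklevel=2,
            )
            continue
        r, p = stats.pearsonr(x, y)
        if r < 0 and p < alpha:
            kept.add((lnc, gene))
    return EdgeList("lncrna_gene", frozenset(kept))


# ---------------------------------------------------------------------------
# evidence table TSV
#
# columns: mirna, target, clip_support, correlations, predictors
# correlations serialized as semicolon-delimited cancer:r:p triplets,
# predictors as semicolon-delimited program names; empty lists as "".

_HEADER = ["mirna", "target", "clip_support", "correlations", "predictors"]


def write_evidence_table(records: Sequence[MirnaTargetEvidence], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for rec in records:
            corr = ";".join(f"{c}:{r:.6g}:{p:.6g}" for c, r, p in rec.cancer_correlations)
            preds = ";".join(sorted(rec.predictor_flags))
            fh.write(f"{rec.mirna_id}\t{rec.target_id}\t{rec.clip_support}\t{corr}\t{preds}\n")


def read_evidence_table(path: str | Path) -> list[MirnaTargetEvidence]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _HEADER:
            raise FormatError(f"{path}: expected header {_HEADER}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            mirna, target, clip, corr, preds = parts
            correlations = []
            if corr:
                for triplet in corr.split(";"):
                    cancer, r, p = triplet.split(":")
                    correlations.append((cancer, float(r), float(p)))
            flags = frozenset(preds.split(";")) if preds else frozenset()
            records.append(
                MirnaTargetEvidence(
                    mirna_id=mirna,
                    target_id=target,
                    clip_support=int(clip),
                    cancer_correlations=tuple(correlations),
                    predictor_flags=flags,
                )
            )
    return records
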