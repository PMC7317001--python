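"""Key candidate gene selection from mutation, CNV and expression data.

A gene is a key candidate when (1) it carries a combined variation event —
somatic mutation plus non-zero copy-number state — in more than 10% of
samples, and (2) its expression differs between variant and non-variant
samples at FDR < 0.01 (two-sample t-test, Benjamini-Hochberg correction over
the genes passing the frequency criterion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import OmicsMatrix

__all__ = [
    "VariationMatrix",
    "CandidateResult",
    "build_variation_matrix",
    "select_key_candidates",
    "candidates_to_frame",
]


@dataclass(frozen=True, eq=False)
class VariationMatrix:
    """Binary genes x samples matrix; 1 marks mutation AND |CNV| >= 1."""

    data: pd.DataFrame  # int {0,1}

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def row(self, gene: str) -> np.ndarray:
        return self.data.loc[gene].to_numpy(dtype=int)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariationMatrix):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass(frozen=True)
class CandidateResult:
    gene_id: str
    mutated_fraction: float
    t_statistic: float
    p_value: float
    q_value: float
    selected: bool


def build_variation_matrix(mutations: OmicsMatrix, cnv: OmicsMatrix) -> VariationMatrix:
    """Conjoin mutation calls and CNV states into the binary variation matrix.

    ``m[i, j] = 1`` iff gene i is mutated in sample j AND its copy-number
    state there is non-zero. The gene universe is the intersection of the two
    feature sets; samples must already be aligned.
    """
    if mutations.sample_ids != cnv.sample_ids:
        raise ValueError("mutation and CNV matrices must be sample-aligned (use align_samples)")
    shared = [g for g in mutations.feature_ids if g in set(cnv.feature_ids)]
    if not shared:
        raise ValueError("mutation and CNV matrices share no genes")
    mut = mutations.data.loc[shared].to_numpy() == 1
    cn = cnv.data.loc[shared].to_numpy() != 0
    values = (mut & cn).astype(int)
    return VariationMatrix(pd.DataFrame(values, index=shared, columns=mutations.sample_ids))


def select_key_candidates(
    M: VariationMatrix,
    expr: OmicsMatrix,
    *,
    min_fraction: float = 0.10,
    fdr: float = 0.01,
    equal_var: bool = True,
) -> list[CandidateResult]:
    """Select key candidate genes from the variation matrix and expression.

    Genes with a variant fraction above ``min_fraction`` are tested for
    differential expression between their variant and non-variant samples
    (Student's t by default, Welch when ``equal_var=False``); q-values are
    Benjamini-Hochberg over the tested genes. Genes with fewer than two
    samples on either side, or zero variance in both groups, are excluded
    with a warning.
    """
    if M.sample_ids != expr.sample_ids:
        raise ValueError("expression must be sample-aligned with the variation matrix")
    expr_features = set(expr.feature_ids)

    rows: list[dict] = []
    tested: list[int] = []  # indices into rows with a defined p-value
    for gene in M.feature_ids:
        if gene not in expr_features:
            continue
        m_row = M.row(gene).astype(bool)
        fraction = float(m_row.mean())
        rec = {
            "gene_id": gene,
            "mutated_fraction": fraction,
            "t_statistic": np.nan,
            "p_value": np.nan,
            "q_value": np.nan,
        }
        if fraction > min_fraction:
            e = expr.row(gene)
            mutated, wild = e[m_row], e[~m_row]
            if len(mutated) < 2 or len(wild) < 2:
                warnings.warn(
                    f"gene {gene!r}: fewer than 2 samples in a group; "
                    "differential test untestable, gene excluded",
                    stacklevel=2,
                )
            else:
                t, p = stats.ttest_ind(mutated, wild, equal_var=equal_var)
                if np.isnan(p):
                    warnings.warn(
                        f"gene {gene!r}: zero variance in both groups; p undefined, "
                        "gene excluded",
                        stacklevel=2,
                    )
                else:
                    rec["t_statistic"] = float(t)
                    rec["p_value"] = float(p)
                    tested.append(len(rows))
        rows.append(rec)

    if tested:
        pvals = np.array([rows[i]["p_value"] for i in tested])
        qvals = stats.false_discovery_control(pvals, method="bh")
        for i, q in zip(tested, qvals):
            rows[i]["q_value"] = float(q)

    return [
        CandidateResult(
            gene_id=r["gene_id"],
            mutated_fraction=r["mutated_fraction"],
            t_statistic=r["t_statistic"],
            p_value=r["p_value"],
            q_value=r["q_value"],
            selected=bool(
                r["mutated_fraction"] > min_fraction
                and np.isfinite(r["q_value"])
                and r["q_value"] < fdr
            ),
        )
        for r in rows
    ]


def candidates_to_frame(results: list[CandidateResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "mutated_fraction": [r.mutated_fraction for r in results],
            "t_statistic": [r.t_statistic for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "selected": [r.selected for r in results],
        }
    )
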