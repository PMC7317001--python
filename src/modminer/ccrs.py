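"""Corrected Cumulative Rank Score (CCRS) between gene groups over a PPIN.

The functional distance between two genes is their shortest-path length in
the unweighted PPIN; pairs with no connecting path have no distance. CCRS
between groups G1 and G2 with intersection G = G1 n G2 averages the
distances over four pair blocks:

    (G x G) + (G x (G1-G)) + (G x (G2-G)) + ((G1-G) x (G2-G))

divided by N, the number of pairs whose distance exists. Two corrections
apply to the three blocks whose pairs share a parent group: every gene is at
distance 1 from itself (a direct interaction), and two connected genes of
one group count distance 1 regardless of path length. Path-less pairs are
excluded from N rather than counted as zero, so disconnected pairs cannot
deflate the score. A score of 1 therefore means "functionally identical";
larger scores mean farther apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .grouping import GeneGroup

__all__ = [
    "CcrsResult",
    "DistanceMatrix",
    "functional_distance",
    "ccrs",
    "distance_matrix",
]

#: distance assigned to same-group pairs (self-pairs and connected pairs)
SAME_GROUP_DISTANCE = 1.0


def functional_distance(p: str, q: str, ppin: nx.Graph) -> int | None:
    """Shortest-path length between two genes; None when no path exists."""
    if p not in ppin:
        raise ValueError(f"gene {p!r} not in the PPIN")
    if q not in ppin:
        raise ValueError(f"gene {q!r} not in the PPIN")
    try:
        return nx.shortest_path_length(ppin, p, q)
    except nx.NetworkXNoPath:
        return None


@dataclass(frozen=True)
class CcrsResult:
    group_a_id: str
    group_b_id: str
    score: float | None  # None when no pair has an existing distance
    n_pairs: int

    @property
    def is_absent(self) -> bool:
        return self.score is None


def _component_index(ppin: nx.Graph) -> dict[str, int]:
    comp = {}
    for i, nodes in enumerate(nx.connected_components(ppin)):
        for node in nodes:
            comp[node] = i
    return comp


def ccrs(
    g1: GeneGroup,
    g2: GeneGroup,
    ppin: nx.Graph,
    *,
    shared_parent_correction: bool = True,
) -> CcrsResult:
    """Corrected cumulative rank score between two gene groups.

    With ``shared_parent_correction`` (default) the constant same-group
    distance applies to all three blocks whose pairs share a parent group —
    (G, G), (G, G1-G) and (G, G2-G); the alternative restricts the
    correction to (G, G) and is kept for sensitivity analysis. The fourth
    block always uses true shortest-path lengths. Pairs iterate over the
    literal Cartesian products, including p = q inside G.
    """
    for group in (g1, g2):
        missing = [m for m in group.members if m not in ppin]
        if missing:
            raise ValueError(
                f"group {group.key_gene_id!r} has members outside the PPIN: {missing[:5]}"
            )
    comp = _component_index(ppin)

    shared = g1.members & g2.members
    only1 = g1.members - shared
    only2 = g2.members - shared

    total = 0.0
    n_pairs = 0

    def corrected_block(left, right, include_self_pairs):
        nonlocal total, n_pairs
        for p in left:
            for q in right:
                if p == q:
                    if include_self_pairs:
                        total += SAME_GROUP_DISTANCE
                        n_pairs += 1
                    continue
                if comp[p] == comp[q]:
                    total += SAME_GROUP_DISTANCE
                    n_pairs += 1
                # no path: distance absent, excluded from N

    def path_block(left, right):
        nonlocal total, n_pairs
        right_set = set(right)
        for p in left:
            lengths = nx.single_source_shortest_path_length(ppin, p)
            for q in right_set:
                d = lengths.get(q)
                if d is not None:
                    total += float(d)
                    n_pairs += 1

    corrected_block(shared, shared, include_self_pairs=True)
    if shared_parent_correction:
        corrected_block(shared, only1, include_self_pairs=False)
        corrected_block(shared, only2, include_self_pairs=False)
    else:
        path_block(shared, only1)
        path_block(shared, only2)
    path_block(only1, only2)

    if n_pairs == 0:
        return CcrsResult(g1.key_gene_id, g2.key_gene_id, None, 0)
    return CcrsResult(g1.key_gene_id, g2.key_gene_id, total / n_pairs, n_pairs)


@dataclass(frozen=True, eq=False)
class DistanceMatrix:
    """Symmetric key-gene distance matrix of pairwise CCRS scores.

    ``values`` holds NaN where the score is absent (no existing functional
    distance between the two groups); ``mask`` is True there.
    """

    key_gene_ids: list
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.key_gene_ids)
        if self.values.shape != (n, n) or self.mask.shape != (n, n):
            raise ValueError("distance matrix shape does not match key gene count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.key_gene_ids, columns=self.key_gene_ids)

    def write(self, path) -> None:
        """Square TSV; masked entries written as the sentinel 'NA'."""
        self.to_frame().to_csv(path, sep="\t", index_label="key_gene", na_rep="NA")

    @classmethod
    def read(cls, path) -> "DistanceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        values = frame.to_numpy(dtype=float)
        return cls(list(frame.index), values, np.isnan(values))


def distance_matrix(groups: list[GeneGroup], ppin: nx.Graph, **ccrs_kwargs) -> DistanceMatrix:
    """All pairwise CCRS scores among gene groups (Dis_ij of the clustering step)."""
    if len(groups) < 2:
        raise ValueError("need at least two gene groups")
    n = len(groups)
    values = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            result = ccrs(groups[i], groups[j], ppin, **ccrs_kwargs)
            if not result.is_absent:
                values[i, j] = values[j, i] = result.score
    return DistanceMatrix([g.key_gene_id for g in groups], values, np.isnan(values))
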