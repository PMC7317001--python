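"""Abnormal regulatory gene groups: two-step PPIN neighborhoods.

The seeds of a key gene's group are the key gene itself plus every node of
its dysregulation network; the group is the set of PPIN nodes within graph
distance <= 2 (by default) of any seed that maps into the PPIN. Seeds absent
from the PPIN (e.g. miRNA/lncRNA entities, unmapped symbols) are dropped
with a warning; if no seed maps, the group is empty and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import networkx as nx

__all__ = ["GeneGroup", "expand_group", "dysregulation_seeds"]


@dataclass(frozen=True)
class GeneGroup:
    """A named gene set anchored to a key gene (operand of the CCRS distance)."""

    key_gene_id: str
    members: frozenset

    def __len__(self) -> int:
        return len(self.members)

    @property
    def is_empty(self) -> bool:
        return not self.members


def dysregulation_seeds(key_gene: str, dysreg_net) -> frozenset:
    """Seed set for group expansion: the key gene plus its dysregulated nodes."""
    return frozenset({key_gene}) | dysreg_net.nodes()


def expand_group(
    seed_genes: Iterable[str],
    ppin: nx.Graph,
    steps: int = 2,
    *,
    key_gene_id: str | None = None,
) -> GeneGroup:
    """All PPIN nodes within graph distance ``steps`` of any retained seed.

    Seeds themselves are members (distance 0). Returns an empty, flagged
    group when no seed maps into the PPIN.
    """
    if steps < 0:
        raise ValueError("steps must be non-negative")
    seeds = sorted(set(seed_genes))
    retained = [s for s in seeds if s in ppin]
    dropped = [s for s in seeds if s not in ppin]
    name = key_gene_id if key_gene_id is not None else (seeds[0] if seeds else "")
    if dropped:
        warnings.warn(
            f"group {name!r}: {len(dropped)} seed(s) not in the PPIN dropped "
            f"(e.g. {dropped[:3]})",
            stacklevel=2,
        )
    if not retained:
        warnings.warn(f"group {name!r}: no seed maps into the PPIN; empty group", stacklevel=2)
        return GeneGroup(key_gene_id=name, members=frozenset())

    members: set[str] = set()
    for seed in retained:
        reachable = nx.single_source_shortest_path_length(ppin, seed, cutoff=steps)
        members.update(reachable)
    return GeneGroup(key_gene_id=name, members=frozenset(members))
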