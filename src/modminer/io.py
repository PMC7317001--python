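"""Containers and readers/writers for multi-omics matrices and interaction data.

All tabular inputs are plain TSV:

* omics matrices — one header row of sample ids, first column of feature ids;
* edge lists — two columns (source, target), optionally a third weight column
  that is ignored when reading plain interaction lists;
* gene groups — GMT (set name, description = key gene, then member genes).

Feature and sample identifiers are treated as opaque, case-sensitive strings;
no symbol normalisation is attempted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "DomainError",
    "OmicsMatrix",
    "EdgeList",
    "RegulatorCatalog",
    "read_matrix",
    "write_matrix",
    "align_samples",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
]


class FormatError(ValueError):
    """Malformed input: duplicate identifiers, non-numeric cells, bad columns."""


class DomainError(ValueError):
    """A value outside the layer's admissible domain (e.g. CNV state not in -2..2)."""


#: tokens interpreted as missing when parsing matrix cells
_MISSING_TOKENS = {"", "NA", "N/A", "NAN", "NaN", "nan", "null", "NULL"}

#: directed regulator layers; everything else (ppi) is undirected
REGULATOR_EDGE_TYPES = frozenset({"tf_gene", "mirna_gene", "mirna_lncrna", "lncrna_gene"})
EDGE_TYPES = REGULATOR_EDGE_TYPES | {"ppi"}


def _domain_violation(layer_name: str, values: np.ndarray) -> tuple[int, int] | None:
    """Return the (row, col) index of the first domain violation, or None.

    NaN cells always violate: missing values are handled before this check.
    """
    bad = ~np.isfinite(values)
    if layer_name == "methylation":
        bad |= (values < 0.0) | (values > 1.0)
    elif layer_name == "cnv":
        bad |= (values != np.round(values)) | (np.abs(values) > 2)
    elif layer_name == "mutation":
        bad |= (values != 0) & (values != 1)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        return int(r), int(c)
    return None


@dataclass(frozen=True, eq=False)
class OmicsMatrix:
    """A named numeric matrix (features x samples) with axis labels.

    Value domains are enforced per layer on construction: methylation betas in
    [0, 1], CNV integers in {-2..2}, mutation calls in {0, 1}; any other layer
    (expression-like) only requires finite numbers.
    """

    layer_name: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise FormatError(f"duplicate feature ids in layer {self.layer_name!r}: {dupes[:5]}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids in layer {self.layer_name!r}: {dupes[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError(f"non-numeric values in layer {self.layer_name!r}")
        hit = _domain_violation(self.layer_name, values.astype(float))
        if hit is not None:
            r, c = hit
            raise DomainError(
                f"layer {self.layer_name!r}: value {values[r, c]!r} out of domain at "
                f"feature {self.data.index[r]!r}, sample {self.data.columns[c]!r}"
            )

    # -- accessors ---------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def row(self, feature_id: str) -> np.ndarray:
        return self.data.loc[feature_id].to_numpy(dtype=float)

    def restrict_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.layer_name, self.data.loc[:, list(sample_ids)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OmicsMatrix):
            return NotImplemented
        return (
            self.layer_name == other.layer_name
            and self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self.data.shape
        return f"OmicsMatrix(layer={self.layer_name!r}, features={n}, samples={m})"


def read_matrix(path: str | Path, layer_name: str, missing: str = "error") -> OmicsMatrix:
    """Read a features x samples TSV into a validated :class:`OmicsMatrix`.

    Parameters
    ----------
    path : path to a TSV with one header row of sample ids and a first column
        of feature ids.
    layer_name : layer label; determines the value-domain check.
    missing : ``"error"`` raises a :class:`DomainError` naming the first
        missing cell; ``"drop"`` removes features containing missing values
        and emits a warning.
    """
    if missing not in ("error", "drop"):
        raise ValueError("missing must be 'error' or 'drop'")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)

    def parse_cell(token: str, feature: str, sample: str) -> float:
        token = token.strip()
        if token in _MISSING_TOKENS:
            return np.nan
        try:
            return float(token)  # correctly-rounded, exact round trip
        except ValueError:
            raise FormatError(
                f"{path}: non-numeric cell {token!r} at feature {feature!r}, "
                f"sample {sample!r}"
            ) from None

    parsed = pd.DataFrame(
        [
            [parse_cell(raw.iat[i, j], raw.index[i], raw.columns[j])
             for j in range(raw.shape[1])]
            for i in range(raw.shape[0])
        ],
        index=raw.index,
        columns=raw.columns,
        dtype=float,
    )

    has_missing = parsed.isna()
    if has_missing.to_numpy().any():
        if missing == "error":
            r, c = np.argwhere(has_missing.to_numpy())[0]
            raise DomainError(
                f"{path}: missing value in layer {layer_name!r} at "
                f"feature {parsed.index[r]!r}, sample {parsed.columns[c]!r}"
            )
        dropped = parsed.index[has_missing.any(axis=1)].tolist()
        warnings.warn(
            f"layer {layer_name!r}: dropping {len(dropped)} feature(s) with missing "
            f"values (e.g. {dropped[:3]})",
            stacklevel=2,
        )
        parsed = parsed.loc[~has_missing.any(axis=1)]
    return OmicsMatrix(layer_name, parsed)


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="feature_id")


def align_samples(matrices: Sequence[OmicsMatrix]) -> list[OmicsMatrix]:
    """Restrict every matrix to the shared samples, in one common order.

    The common order is the first matrix's sample order filtered to the
    intersection, which makes the operation idempotent.
    """
    if len(matrices) < 2:
        raise ValueError("align_samples needs at least two matrices")
    common = set(matrices[0].sample_ids)
    for m in matrices[1:]:
        common &= set(m.sample_ids)
    if not common:
        raise ValueError("no samples shared across all layers")
    order = [s for s in matrices[0].sample_ids if s in common]
    logger.info("align_samples: %d shared samples across %d layers", len(order), len(matrices))
    return [m.restrict_samples(order) for m in matrices]


# ---------------------------------------------------------------------------
# edge lists


@dataclass(frozen=True, eq=False)
class EdgeList:
    """A set of interaction edges of one type.

    Regulator layers (tf_gene, mirna_gene, mirna_lncrna, lncrna_gene) are
    directed and reject self-loops; ppi is undirected with edges stored as
    canonically ordered pairs (self-loops permitted, deduplicated).
    """

    edge_type: str
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {self.edge_type!r}")
        canonical = set()
        for src, dst in self.edges:
            if self.directed:
                if src == dst:
                    raise FormatError(f"self-loop {src!r} in directed layer {self.edge_type!r}")
                canonical.add((src, dst))
            else:
                canonical.add((src, dst) if src <= dst else (dst, src))
        object.__setattr__(self, "edges", frozenset(canonical))

    @property
    def directed(self) -> bool:
        return self.edge_type != "ppi"

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        src, dst = pair
        if self.directed:
            return (src, dst) in self.edges
        return ((src, dst) if src <= dst else (dst, src)) in self.edges

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EdgeList):
            return NotImplemented
        return self.edge_type == other.edge_type and self.edges == other.edges

    def targets_of(self, source: str) -> set[str]:
        if not self.directed:
            raise ValueError("targets_of applies to directed layers")
        return {t for s, t in self.edges if s == source}

    def sources_of(self, target: str) -> set[str]:
        if not self.directed:
            raise ValueError("sources_of applies to directed layers")
        return {s for s, t in self.edges if t == target}

    def to_graph(self):
        """Return the edge list as a networkx (Di)Graph."""
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_edges_from(self.edges)
        return g


def read_edge_list(path: str | Path, edge_type: str) -> EdgeList:
    edges = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected >=2 tab-separated columns")
            edges.add((parts[0], parts[1]))
    return EdgeList(edge_type, frozenset(edges))


def write_edge_list(edge_list: EdgeList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for src, dst in sorted(edge_list.edges):
            fh.write(f"{src}\t{dst}\n")


@dataclass
class RegulatorCatalog:
    """Regulator -> target adjacency for the TF, miRNA and lncRNA layers.

    Determines which covariates enter each gene's expression model: the TFs,
    miRNAs and lncRNAs catalogued as regulating that gene.
    """

    tf_gene: EdgeList
    mirna_gene: EdgeList
    lncrna_gene: EdgeList
    mirna_lncrna: EdgeList | None = None

    def __post_init__(self) -> None:
        self._tf_by_gene: dict[str, set[str]] = {}
        self._mir_by_gene: dict[str, set[str]] = {}
        self._lnc_by_gene: dict[str, set[str]] = {}
        for reg, gene in self.tf_gene.edges:
            self._tf_by_gene.setdefault(gene, set()).add(reg)
        for reg, gene in self.mirna_gene.edges:
            self._mir_by_gene.setdefault(gene, set()).add(reg)
        for reg, gene in self.lncrna_gene.edges:
            self._lnc_by_gene.setdefault(gene, set()).add(reg)

    def tfs_of(self, gene: str) -> set[str]:
        return set(self._tf_by_gene.get(gene, set()))

    def mirnas_of(self, gene: str) -> set[str]:
        return set(self._mir_by_gene.get(gene, set()))

    def lncrnas_of(self, gene: str) -> set[str]:
        return set(self._lnc_by_gene.get(gene, set()))


# ---------------------------------------------------------------------------
# GMT gene groups


def write_gmt(groups: Iterable, path: str | Path) -> None:
    """Write gene groups as GMT: name, description (= key gene), members."""
    with open(path, "w") as fh:
        for group in groups:
            members = "\t".join(sorted(group.members))
            line = f"{group.key_gene_id}\t{group.key_gene_id}"
            fh.write(line + ("\t" + members if members else "") + "\n")


def read_gmt(path: str | Path) -> list:
    from .grouping import GeneGroup

    groups = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: GMT lines need name and description")
            _, key_gene, *members = parts
            groups.append(GeneGroup(key_gene_id=key_gene, members=frozenset(members)))
    return groups
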