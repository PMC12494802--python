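"""Reading, writing, and graph construction for TF-target interaction tables.

The on-disk layout is the TRRUST v2 four-column TSV: transcription factor,
target gene, regulation mode (``Activation`` / ``Repression`` / ``Unknown``),
and a ``;``-separated list of PubMed ids.  Duplicate (tf, target) rows are
legal in the table (one row per piece of literature evidence) and are
collapsed into a single directed edge when the graph is built, with all
contributing regulation labels retained as edge annotations.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Regulation",
    "RegulatoryInteraction",
    "RegulatoryGraph",
    "parse_interaction_table",
    "build_graph",
    "write_interaction_table",
]

_HEADER = ("TF", "Target_Gene", "Regulation", "PMID")


class Regulation(str, Enum):
    """Direction of a regulatory interaction."""

    ACTIVATION = "Activation"
    REPRESSION = "Repression"
    UNKNOWN = "Unknown"


@dataclass(frozen=True)
class RegulatoryInteraction:
    """One annotation row: a TF regulating a target gene.

    Attributes
    ----------
    tf : str
        Gene symbol of the transcription factor (nonempty).
    target : str
        Gene symbol of the regulated gene (nonempty).
    regulation : Regulation
        Mode of regulation.
    pmids : tuple of str
        Supporting PubMed ids; may be empty.
    """

    tf: str
    target: str
    regulation: Regulation
    pmids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.tf or not self.target:
            raise ValueError("tf and target symbols must be nonempty")
        if not isinstance(self.regulation, Regulation):
            object.__setattr__(self, "regulation", Regulation(self.regulation))


@dataclass
class RegulatoryGraph:
    """Directed regulatory graph with a deterministic node ordering.

    Nodes are ordered by first appearance: every TF in row order first,
    then targets not already seen as a TF.  This makes one-hot features
    and edge splits reproducible across runs.

    Attributes
    ----------
    nodes : list of str
        Unique gene symbols in canonical order.
    node_index : dict
        Symbol -> 0-based position in ``nodes``.
    edges : list of (int, int)
        Unique directed (source_index, target_index) pairs, in order of
        first appearance.
    edge_annotations : dict
        (source_index, target_index) -> list of Regulation labels from all
        contributing rows (a multiset; duplicates preserved).
    is_tf, is_target : list of bool
        Role flags per node; a symbol may carry both.
    """

    nodes: list[str]
    node_index: dict[str, int]
    edges: list[tuple[int, int]]
    edge_annotations: dict[tuple[int, int], list[Regulation]]
    is_tf: list[bool]
    is_target: list[bool]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[int, int]]:
        return set(self.edges)


def _looks_like_path(source: str | os.PathLike) -> bool:
    if isinstance(source, os.PathLike):
        return True
    if "\n" in source or "\t" in source:
        return False
    return os.path.exists(source)


def _split_row(line: str) -> list[str]:
    """Split one row into cells.

    Tab-separated rows split on tabs; otherwise whitespace-separated, with
    everything after the third column rejoined into a single PMID cell so
    that "18483242; 23349129" survives the split.
    """
    if "\t" in line:
        return [c.strip() for c in line.split("\t")]
    parts = line.split()
    if len(parts) <= 4:
        return parts
    return parts[:3] + [" ".join(parts[3:])]


def parse_interaction_table(
    source: str | os.PathLike,
    dialect: str = "auto",
) -> list[RegulatoryInteraction]:
    """Parse a TRRUST-layout table from a path or an in-memory string.

    Parameters
    ----------
    source : path or str
        Path to a TSV file, or the table text itself.
    dialect : {"auto", "header", "no_header"}
        Whether the first row is a header.  ``auto`` detects a header by
        the literal first cell ``TF``.

    Returns
    -------
    list of RegulatoryInteraction, one per data row in file order.

    Raises
    ------
    ValueError
        On rows with fewer than 3 columns or an unrecognized regulation
        label (the error names the offending row).
    """
    if dialect not in ("auto", "header", "no_header"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    if _looks_like_path(source):
        text = Path(source).read_text()
    else:
        text = str(source)

    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []

    start = 0
    first_cells = _split_row(lines[0])
    if dialect == "header" or (dialect == "auto" and first_cells and first_cells[0] == "TF"):
        start = 1

    records: list[RegulatoryInteraction] = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        cells = _split_row(line)
        if len(cells) < 3:
            raise ValueError(f"row {lineno}: expected >=3 columns, got {len(cells)}: {line!r}")
        tf, target, reg_label = cells[0].strip(), cells[1].strip(), cells[2].strip()
        try:
            regulation = Regulation(reg_label)
        except ValueError:
            raise ValueError(
                f"row {lineno}: unrecognized regulation label {reg_label!r}"
            ) from None
        pmids: tuple[str, ...] = ()
        if len(cells) >= 4 and cells[3].strip():
            pmids = tuple(p.strip() for p in cells[3].split(";") if p.strip())
        records.append(RegulatoryInteraction(tf, target, regulation, pmids))
    return records


def build_graph(interactions: Sequence[RegulatoryInteraction]) -> RegulatoryGraph:
    """Build the directed graph, collapsing duplicate (tf, target) rows.

    Node order: all TFs by first appearance in row order, then targets not
    already present.  All regulation labels of duplicate rows are kept in
    ``edge_annotations``.
    """
    if not interactions:
        raise ValueError("cannot build a graph from an empty interaction list")

    nodes: list[str] = []
    node_index: dict[str, int] = {}

    def _add(symbol: str) -> int:
        idx = node_index.get(symbol)
        if idx is None:
            idx = len(nodes)
            node_index[symbol] = idx
            nodes.append(symbol)
        return idx

    for rec in interactions:
        _add(rec.tf)
    for rec in interactions:
        _add(rec.target)

    tf_symbols = {rec.tf for rec in interactions}
    target_symbols = {rec.target for rec in interactions}

    edges: list[tuple[int, int]] = []
    edge_annotations: dict[tuple[int, int], list[Regulation]] = {}
    for rec in interactions:
        pair = (node_index[rec.tf], node_index[rec.target])
        if pair not in edge_annotations:
            edge_annotations[pair] = []
            edges.append(pair)
        edge_annotations[pair].append(rec.regulation)

    return RegulatoryGraph(
        nodes=nodes,
        node_index=node_index,
        edges=edges,
        edge_annotations=edge_annotations,
        is_tf=[s in tf_symbols for s in nodes],
        is_target=[s in target_symbols for s in nodes],
    )


def write_interaction_table(
    interactions: Iterable[RegulatoryInteraction],
    path: str | os.PathLike,
) -> None:
    """Write records as a header-ed TSV that round-trips through the parser."""
    lines = ["\t".join(_HEADER)]
    for rec in interactions:
        lines.append(
            "\t".join([rec.tf, rec.target, rec.regulation.value, "; ".join(rec.pmids)])
        )
    Path(path).write_text("\n".join(lines) + "\n")
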