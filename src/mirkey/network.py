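"""Bipartite miRNA-gene network construction, degree ranking, and export."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd


@dataclass(frozen=True)
class BipartiteNetwork:
    """miRNA regulator nodes, gene target nodes, and regulator->target edges."""

    mirna_nodes: frozenset[str]
    gene_nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        collisions = self.mirna_nodes & self.gene_nodes
        if collisions:
            raise ValueError(
                f"identifier collision between miRNA and gene namespaces: {sorted(collisions)}"
            )
        for mirna, gene in self.edges:
            if mirna not in self.mirna_nodes or gene not in self.gene_nodes:
                raise ValueError(f"edge ({mirna}, {gene}) has an endpoint outside the node sets")

    def degree(self, node: str) -> int:
        if node in self.mirna_nodes:
            return sum(1 for m, _ in self.edges if m == node)
        if node in self.gene_nodes:
            return sum(1 for _, g in self.edges if g == node)
        raise KeyError(node)

    def mirna_degrees(self) -> dict[str, int]:
        deg = {m: 0 for m in self.mirna_nodes}
        for m, _ in self.edges:
            deg[m] += 1
        return deg

    def gene_degrees(self) -> dict[str, int]:
        deg = {g: 0 for g in self.gene_nodes}
        for _, g in self.edges:
            deg[g] += 1
        return deg


@dataclass(frozen=True)
class KeyMiRNAReport:
    """Degree-ranked miRNAs; rows tied with the top_n-th count are all kept."""

    table: pd.DataFrame  # columns: mirna_id, target_count, rank, selected
    top_n: int

    @property
    def key_mirnas(self) -> list[str]:
        return list(self.table.loc[self.table["selected"], "mirna_id"])


def build_network(per_mirna_targets: Mapping[str, Iterable[str]]) -> BipartiteNetwork:
    """Build the bipartite network; nodes are endpoints of >= 1 edge."""
    edges: set[tuple[str, str]] = set()
    for mirna, genes in per_mirna_targets.items():
        for gene in genes:
            edges.add((mirna, gene))
    mirnas = frozenset(m for m, _ in edges)
    genes_ = frozenset(g for _, g in edges)
    return BipartiteNetwork(mirna_nodes=mirnas, gene_nodes=genes_, edges=frozenset(edges))


def rank_key_mirnas(network: BipartiteNetwork, top_n: int = 3) -> KeyMiRNAReport:
    """Rank miRNAs by target-gene degree; return the top_n plus boundary ties.

    Sorted by target_count descending, ties by miRNA id ascending; ranks are
    dense (equal counts share a rank).
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    degrees = network.mirna_degrees()
    if not degrees:
        raise ValueError("empty network")
    rows = sorted(degrees.items(), key=lambda r: (-r[1], r[0]))
    table = pd.DataFrame(rows, columns=["mirna_id", "target_count"])
    table["rank"] = (
        table["target_count"].rank(method="dense", ascending=False).astype(int)
    )
    if len(table) <= top_n:
        cutoff = table["target_count"].min()
    else:
        cutoff = int(table["target_count"].iloc[top_n - 1])
    table["selected"] = table["target_count"] >= cutoff
    return KeyMiRNAReport(table=table, top_n=top_n)


def export_network(
    network: BipartiteNetwork, path: str | Path, format: Literal["sif", "tsv"] = "sif"
) -> None:
    """Write the edge list; SIF lines read ``mirna targets gene``."""
    if not network.edges:
        raise ValueError("refusing to export an empty-edge network")
    edges = sorted(network.edges)
    with open(path, "w") as fh:
        if format == "sif":
            for mirna, gene in edges:
                fh.write(f"{mirna}\ttargets\t{gene}\n")
        elif format == "tsv":
            fh.write("mirna\tgene\n")
            for mirna, gene in edges:
                fh.write(f"{mirna}\t{gene}\n")
        else:
            raise ValueError(f"unknown format {format!r}")


def import_network(path: str | Path, format: Literal["sif", "tsv"] = "sif") -> BipartiteNetwork:
    """Inverse of :func:`export_network`; round-trips exactly."""
    per_mirna: dict[str, list[str]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if format == "tsv":
        lines = lines[1:]  # header
    for line in lines:
        parts = line.split("\t")
        if format == "sif":
            if len(parts) != 3 or parts[1] != "targets":
                raise ValueError(f"malformed SIF line: {line!r}")
            mirna, gene = parts[0], parts[2]
        elif format == "tsv":
            if len(parts) != 2:
                raise ValueError(f"malformed TSV line: {line!r}")
            mirna, gene = parts
        else:
            raise ValueError(f"unknown format {format!r}")
        per_mirna.setdefault(mirna, []).append(gene)
    return build_network(per_mirna)
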