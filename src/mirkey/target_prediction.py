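"""Canonical seed-match target prediction and regulator-count ranking.

The engine scans 3'UTRs for the reverse complement of miRNA positions 2-7
(the seed match) and classifies each occurrence into the canonical site
taxonomy:

* ``8mer``     seed match extended by a match to miRNA position 8 on the 5'
               side AND an adenine opposite miRNA position 1 on the 3' side;
* ``7mer-m8``  seed match plus the position-8 match only;
* ``7mer-A1``  seed match plus the adenine only;
* ``6mer``     the bare seed match.

Each genomic occurrence is reported once with its longest applicable type,
and reported 1-based inclusive coordinates span the full classified site
(so a 7mer-A1 span includes the target-side A). Sites overlapping ``N``
bases are suppressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

SiteType = Literal["6mer", "7mer-A1", "7mer-m8", "8mer"]

SITE_WIDTH = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}
CANONICAL_7PLUS = frozenset({"7mer-A1", "7mer-m8", "8mer"})

_RNA_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence, 5'->3', normalized to the RNA alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        if len(seq) < 8:
            raise ValueError(f"{self.id}: mature miRNA must be >= 8 nt")
        bad = set(seq) - set("ACGU")
        if bad:
            raise ValueError(f"{self.id}: invalid bases {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    @property
    def seed(self) -> str:
        """Positions 2-7 of the miRNA (RNA)."""
        return self.sequence[1:7]

    @property
    def seed_match(self) -> str:
        """DNA reverse complement of the seed, as found in a target UTR."""
        return _revcomp_rna_to_dna(self.seed)

    @property
    def m8_match(self) -> str:
        """DNA base in the UTR that pairs with miRNA position 8."""
        return _RNA_COMPLEMENT[self.sequence[7]].replace("U", "T")


@dataclass(frozen=True)
class UTRRecord:
    """A 3'UTR sequence keyed by transcript accession and gene symbol."""

    transcript_accession: str
    gene_symbol: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(
                f"{self.transcript_accession}: invalid bases {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class SeedSite:
    """A classified miRNA binding site, 1-based inclusive UTR coordinates."""

    mirna_id: str
    transcript_accession: str
    site_type: SiteType
    start: int
    end: int
    site_sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != SITE_WIDTH[self.site_type]:
            raise ValueError(
                f"span {self.start}-{self.end} inconsistent with {self.site_type}"
            )


@dataclass(frozen=True)
class TargetEdge:
    """Aggregated miRNA -> gene prediction supported by one or more sites."""

    mirna_id: str
    gene_symbol: str
    sites: tuple[SeedSite, ...]

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("TargetEdge requires at least one site")
        object.__setattr__(
            self,
            "sites",
            tuple(sorted(self.sites, key=lambda s: (s.transcript_accession, s.start))),
        )


def _revcomp_rna_to_dna(rna: str) -> str:
    return str(Seq(rna).back_transcribe().reverse_complement())


def seed_matches(mirna: MatureMiRNA, utr: UTRRecord) -> list[SeedSite]:
    """All canonical sites for one miRNA in one UTR, longest type per locus."""
    seq = utr.sequence
    if len(seq) < 8:
        return []
    core = mirna.seed_match  # 6-nt DNA seed match
    m8 = mirna.m8_match
    sites: list[SeedSite] = []
    pos = seq.find(core)
    while pos != -1:
        has_m8 = pos >= 1 and seq[pos - 1] == m8
        has_a1 = pos + 6 < len(seq) and seq[pos + 6] == "A"
        if has_m8 and has_a1:
            site_type, start0, end0 = "8mer", pos - 1, pos + 6
        elif has_m8:
            site_type, start0, end0 = "7mer-m8", pos - 1, pos + 5
        elif has_a1:
            site_type, start0, end0 = "7mer-A1", pos, pos + 6
        else:
            site_type, start0, end0 = "6mer", pos, pos + 5
        span = seq[start0 : end0 + 1]
        if "N" not in span:
            sites.append(
                SeedSite(
                    mirna_id=mirna.id,
                    transcript_accession=utr.transcript_accession,
                    site_type=site_type,
                    start=start0 + 1,
                    end=end0 + 1,
                    site_sequence=span,
                )
            )
        pos = seq.find(core, pos + 1)
    return sites


def predict_targets(
    mirnas: Sequence[MatureMiRNA],
    utr_db: Sequence[UTRRecord],
    min_site: Literal["6mer", "7mer"] = "7mer",
) -> list[TargetEdge]:
    """Aggregate seed matches into per-(miRNA, gene) target edges.

    A gene is called a target of a miRNA iff at least one site of a
    qualifying type exists in any of its transcripts; with the default
    ``min_site="7mer"`` a bare 6mer is recorded on the edge's site list only
    when a qualifying site also exists, but never suffices alone.
    """
    if not utr_db:
        raise ValueError("empty UTR database")
    qualifying = CANONICAL_7PLUS if min_site == "7mer" else frozenset(SITE_WIDTH)
    by_pair: dict[tuple[str, str], list[SeedSite]] = {}
    for mirna in mirnas:
        for utr in utr_db:
            found = seed_matches(mirna, utr)
            if found:
                by_pair.setdefault((mirna.id, utr.gene_symbol), []).extend(found)
    edges = []
    for (mirna_id, gene), sites in sorted(by_pair.items()):
        if any(s.site_type in qualifying for s in sites):
            edges.append(TargetEdge(mirna_id=mirna_id, gene_symbol=gene, sites=tuple(sites)))
    return edges


@dataclass(frozen=True)
class RankedTargets:
    """Genes ranked by distinct-regulator count with a top-fraction flag."""

    table: pd.DataFrame  # columns: gene_symbol, regulator_count, selected
    fraction: float

    @property
    def selected_genes(self) -> list[str]:
        return list(self.table.loc[self.table["selected"], "gene_symbol"])


def rank_by_regulator_count(
    edges: Iterable[TargetEdge],
    candidate_mirnas: Iterable[str] | None = None,
    fraction: float = 0.25,
) -> RankedTargets:
    """Sort genes by number of distinct upstream candidate miRNAs; take the top fraction.

    The cutoff is ``ceil(fraction * n_genes)`` genes; every gene tied with the
    boundary count is also selected, so the selection may exceed the ceiling.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    edges = list(edges)
    if not edges:
        raise ValueError("empty edge list")
    candidates = set(candidate_mirnas) if candidate_mirnas is not None else None
    regulators: dict[str, set[str]] = {}
    for e in edges:
        if candidates is not None and e.mirna_id not in candidates:
            continue
        regulators.setdefault(e.gene_symbol, set()).add(e.mirna_id)
    rows = sorted(
        ((gene, len(mirs)) for gene, mirs in regulators.items()),
        key=lambda r: (-r[1], r[0]),
    )
    n_top = math.ceil(fraction * len(rows))
    cutoff_count = rows[n_top - 1][1]
    table = pd.DataFrame(rows, columns=["gene_symbol", "regulator_count"])
    table["selected"] = table["regulator_count"] >= cutoff_count
    return RankedTargets(table=table, fraction=fraction)


def read_mirna_fasta(path: str | Path) -> list[MatureMiRNA]:
    return [
        MatureMiRNA(id=rec.id, sequence=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_utr_fasta(path: str | Path) -> list[UTRRecord]:
    """UTR FASTA with headers of the form ``accession|gene_symbol``."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        accession, _, gene = rec.id.partition("|")
        if not gene:
            raise ValueError(f"UTR header {rec.id!r} lacks '|gene_symbol'")
        records.append(
            UTRRecord(transcript_accession=accession, gene_symbol=gene, sequence=str(rec.seq))
        )
    return records


def sites_to_frame(edges: Iterable[TargetEdge], gene_by_accession: dict[str, str] | None = None) -> pd.DataFrame:
    rows = []
    for e in edges:
        for s in e.sites:
            rows.append(
                {
                    "mirna": e.mirna_id,
                    "accession": s.transcript_accession,
                    "gene": e.gene_symbol,
                    "type": s.site_type,
                    "start": s.start,
                    "end": s.end,
                    "sequence": s.site_sequence,
                }
            )
    return pd.DataFrame(
        rows, columns=["mirna", "accession", "gene", "type", "start", "end", "sequence"]
    )
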