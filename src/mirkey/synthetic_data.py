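"""Synthetic inputs for every pipeline stage, plus packaged table fixtures.

The study deposited no raw data, so testable stand-ins are generated here:
paired log-normal expression cohorts with planted fold changes, random UTR
corpora with planted seed sites (background cleaned of accidental matches),
and GMT annotation corpora with planted enrichment. Loaders for the packaged
``table1/2/3.tsv`` fixtures — per-grade differential miRNA lists, per-miRNA
cancer-pathway target lists, and candidate binding sites — live here too.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mirkey.diffexpr import ExpressionMatrix
from mirkey.enrichment import GeneSetAnnotation, write_gmt

_BASES = np.array(list("ACGT"))

#: Expected per-grade (up, down) list sizes of the table1 fixture.
TABLE1_EXPECTED_COUNTS = {"GI": (12, 12), "GII": (18, 17), "GIII": (19, 16)}


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the paired tumor/normal expression simulation.

    Normal-tissue log2 intensity is Normal(baseline_log2_mean,
    baseline_log2_sd) per (miRNA, patient); tumor log2 intensity adds the
    planted true log2 fold change plus Normal(0, noise_sd). Intensities are
    returned on the linear scale.
    """

    n_mirnas: int
    grades: Mapping[str, int]  # grade label -> number of tumor/normal pairs
    planted_up: Mapping[str, float] = field(default_factory=dict)
    planted_down: Mapping[str, float] = field(default_factory=dict)
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    noise_sd: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.planted_up) & set(self.planted_down)
        if overlap:
            raise ValueError(f"planted up/down sets overlap: {sorted(overlap)}")
        if any(fc <= 0 for fc in self.planted_up.values()):
            raise ValueError("planted_up log2 fold changes must be > 0")
        if any(fc >= 0 for fc in self.planted_down.values()):
            raise ValueError("planted_down log2 fold changes must be < 0")
        if self.n_mirnas < len(self.planted_up) + len(self.planted_down):
            raise ValueError("n_mirnas smaller than the planted sets")
        if self.baseline_log2_sd <= 0:
            raise ValueError("baseline_log2_sd must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not self.grades or any(n < 1 for n in self.grades.values()):
            raise ValueError("every grade needs at least one pair")


def simulate_expression(spec: SimulationSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a paired cohort; returns (matrix, truth table).

    The truth table has one row per miRNA with columns mirna_id, direction
    (up/down/null) and true_log2fc. Identical spec and seed give bit-identical
    output.
    """
    rng = np.random.default_rng(spec.rng_seed)
    planted_ids = sorted(spec.planted_up) + sorted(spec.planted_down)
    n_null = spec.n_mirnas - len(planted_ids)
    null_ids = [f"sim-miR-{i:04d}" for i in range(n_null)]
    mirna_ids = planted_ids + null_ids

    true_fc = np.zeros(spec.n_mirnas)
    direction = []
    for i, mid in enumerate(mirna_ids):
        if mid in spec.planted_up:
            true_fc[i] = spec.planted_up[mid]
            direction.append("up")
        elif mid in spec.planted_down:
            true_fc[i] = spec.planted_down[mid]
            direction.append("down")
        else:
            direction.append("null")
    truth = pd.DataFrame(
        {"mirna_id": mirna_ids, "direction": direction, "true_log2fc": true_fc}
    )

    columns: dict[str, np.ndarray] = {}
    sample_rows = []
    for grade in sorted(spec.grades):
        for p in range(1, spec.grades[grade] + 1):
            patient = f"{grade}-P{p}"
            normal_log2 = rng.normal(
                spec.baseline_log2_mean, spec.baseline_log2_sd, spec.n_mirnas
            )
            noise = (
                rng.normal(0.0, spec.noise_sd, spec.n_mirnas)
                if spec.noise_sd > 0
                else np.zeros(spec.n_mirnas)
            )
            tumor_log2 = normal_log2 + true_fc + noise
            columns[f"{patient}-T"] = np.exp2(tumor_log2)
            columns[f"{patient}-N"] = np.exp2(normal_log2)
            sample_rows.append((f"{patient}-T", patient, grade, "tumor"))
            sample_rows.append((f"{patient}-N", patient, grade, "normal"))

    intensities = pd.DataFrame(columns, index=pd.Index(mirna_ids, name="mirna_id"))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "patient_id", "grade", "tissue"]
    ).set_index("sample_id")
    return ExpressionMatrix(intensities=intensities, samples=samples), truth


def _motif_positions(seq: str, motif: str) -> list[int]:
    out, pos = [], seq.find(motif)
    while pos != -1:
        out.append(pos)
        pos = seq.find(motif, pos + 1)
    return out


def simulate_utrs(
    genes: Sequence[str],
    length: int,
    planted_sites: Sequence[tuple[str, int, str]],
    rng_seed: int,
    forbidden_motifs: Sequence[str] | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random UTRs with seed sites planted at fixed 1-based offsets.

    Background bases are i.i.d. uniform over {A,C,G,T}. Any occurrence of a
    forbidden motif that is not entirely inside a planted-site span is
    re-randomized, so the returned truth table (gene, offset, site_sequence)
    is exhaustive. ``forbidden_motifs`` defaults to every 6-mer substring of
    the planted site sequences; pass all site patterns of the miRNA under
    study to also guard against flank-extension upgrades.

    Returns ({gene: sequence}, truth table). Accessions for FASTA output are
    ``SYN_<gene>``.
    """
    rng = np.random.default_rng(rng_seed)
    by_gene: dict[str, list[tuple[int, str]]] = {g: [] for g in genes}
    for gene, offset, site_seq in planted_sites:
        if gene not in by_gene:
            raise ValueError(f"planted site references unknown gene {gene!r}")
        if offset < 1 or offset + len(site_seq) - 1 > length:
            raise ValueError(f"site at {gene}:{offset} does not fit in a {length}-nt UTR")
        by_gene[gene].append((offset, site_seq))
    for gene, sites in by_gene.items():
        spans = sorted((o, o + len(s) - 1) for o, s in sites)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping planted sites on gene {gene!r}")

    if forbidden_motifs is None:
        motifs = set()
        for _, _, site_seq in planted_sites:
            motifs.update(site_seq[i : i + 6] for i in range(len(site_seq) - 5))
        forbidden_motifs = sorted(motifs)

    sequences: dict[str, str] = {}
    for gene in genes:
        seq = rng.choice(_BASES, size=length)
        planted_mask = np.zeros(length, dtype=bool)
        for offset, site_seq in by_gene[gene]:
            seq[offset - 1 : offset - 1 + len(site_seq)] = list(site_seq)
            planted_mask[offset - 1 : offset - 1 + len(site_seq)] = True
        # clean accidental matches; redraw only non-planted positions
        for _ in range(1000):
            dirty = False
            s = "".join(seq)
            for motif in forbidden_motifs:
                for pos in _motif_positions(s, motif):
                    span = slice(pos, pos + len(motif))
                    if planted_mask[span].all():
                        continue
                    dirty = True
                    redraw = ~planted_mask[span]
                    window = seq[span]  # slice -> view on seq
                    window[redraw] = rng.choice(_BASES, size=int(redraw.sum()))
            if not dirty:
                break
        else:  # pragma: no cover - probabilistically unreachable
            raise RuntimeError(f"could not clean background for gene {gene!r}")
        sequences[gene] = "".join(seq)

    truth = pd.DataFrame(
        [
            {"gene": g, "offset": o, "site_sequence": s}
            for g, o, s in sorted(planted_sites)
        ],
        columns=["gene", "offset", "site_sequence"],
    )
    return sequences, truth


def write_utr_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    """Write UTRs with ``accession|gene_symbol`` headers (accession SYN_<gene>)."""
    with open(path, "w") as fh:
        for gene in sorted(sequences):
            fh.write(f">SYN_{gene}|{gene}\n{sequences[gene]}\n")


def simulate_annotations(
    n_terms: int,
    genes_per_term: int,
    enriched_terms: Mapping[str, float],
    rng_seed: int,
    query_genes: Sequence[str],
    universe_genes: Sequence[str],
    category: str = "GO",
) -> tuple[list[GeneSetAnnotation], pd.DataFrame]:
    """Annotation corpus with planted enrichment; returns (annotations, truth).

    Null terms draw ``genes_per_term`` genes uniformly from the universe. An
    enriched term first includes ``round(fraction * len(query_genes))`` query
    genes, then fills up with non-query genes. Term ids are ``TERM0000``...;
    keys of ``enriched_terms`` must be among them.
    """
    if genes_per_term < 1:
        raise ValueError("genes_per_term must be >= 1")
    if any(not 0 < f <= 1 for f in enriched_terms.values()):
        raise ValueError("enrichment fractions must be in (0, 1]")
    term_ids = [f"TERM{i:04d}" for i in range(n_terms)]
    unknown = set(enriched_terms) - set(term_ids)
    if unknown:
        raise ValueError(f"enriched term ids not in corpus: {sorted(unknown)}")
    query = list(dict.fromkeys(query_genes))
    universe = list(dict.fromkeys(universe_genes))
    non_query = [g for g in universe if g not in set(query)]

    rng = np.random.default_rng(rng_seed)
    annotations, truth_rows = [], []
    for term_id in term_ids:
        if term_id in enriched_terms:
            fraction = enriched_terms[term_id]
            n_query = min(int(round(fraction * len(query))), genes_per_term, len(query))
            chosen = list(rng.choice(query, size=n_query, replace=False))
            n_fill = min(genes_per_term - n_query, len(non_query))
            chosen += list(rng.choice(non_query, size=n_fill, replace=False))
        else:
            fraction = 0.0
            chosen = list(
                rng.choice(universe, size=min(genes_per_term, len(universe)), replace=False)
            )
        annotations.append(
            GeneSetAnnotation(
                term_id=term_id,
                term_name=f"synthetic term {term_id}",
                category=category,
                genes=frozenset(chosen),
            )
        )
        truth_rows.append(
            {"term_id": term_id, "enriched": fraction > 0, "fraction": fraction}
        )
    return annotations, pd.DataFrame(truth_rows)


def simulate_annotations_gmt(path: str | Path, **kwargs) -> pd.DataFrame:
    """Convenience wrapper: write the simulated corpus as a GMT file."""
    annotations, truth = simulate_annotations(**kwargs)
    write_gmt(annotations, path)
    return truth


# ---------------------------------------------------------------------------
# packaged table fixtures


@dataclass(frozen=True)
class TableFixture:
    """A transcribed table: T1 grade lists, T2 target lists, or T3 sites."""

    table_id: str
    frame: pd.DataFrame

    def grade_lists(self) -> dict[str, tuple[list[str], list[str]]]:
        """T1 only: grade -> (up list, down list) in transcription order."""
        if self.table_id != "T1":
            raise ValueError("grade_lists is only defined for T1")
        out = {}
        for grade, grp in self.frame.groupby("grade", sort=True):
            up = list(grp.loc[grp["direction"] == "up", "mirna"])
            down = list(grp.loc[grp["direction"] == "down", "mirna"])
            out[str(grade)] = (up, down)
        return out

    def target_lists(self) -> dict[str, list[str]]:
        """T2 only: miRNA -> predicted cancer-pathway target genes."""
        if self.table_id != "T2":
            raise ValueError("target_lists is only defined for T2")
        return {
            str(m): list(grp["gene"])
            for m, grp in self.frame.groupby("mirna", sort=True)
        }


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("mirkey").joinpath("fixtures", name)))


def load_table_fixture(table_id: str) -> TableFixture:
    """Load a packaged fixture (T1, T2 or T3) and verify its invariants."""
    if table_id not in ("T1", "T2", "T3"):
        raise ValueError(f"unknown table id {table_id!r}")
    path = _fixture_path(f"table{table_id[1]}.tsv")
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep="\t")

    if table_id == "T1":
        counts = {
            str(grade): (
                int((grp["direction"] == "up").sum()),
                int((grp["direction"] == "down").sum()),
            )
            for grade, grp in frame.groupby("grade")
        }
        if counts != TABLE1_EXPECTED_COUNTS:
            raise ValueError(f"table1 per-grade counts corrupted: {counts}")
    elif table_id == "T2":
        for mirna, grp in frame.groupby("mirna"):
            if grp["gene"].duplicated().any():
                raise ValueError(f"table2 row {mirna} contains duplicate gene symbols")
    else:
        widths = frame["end"] - frame["start"] + 1
        if not widths.isin([6, 7, 8]).all():
            raise ValueError("table3 spans must be 6-8 nt wide")
    return TableFixture(table_id=table_id, frame=frame)
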