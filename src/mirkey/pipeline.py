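"""End-to-end orchestration: config, deterministic artifacts, run report.

Two execution modes:

* ``fixture``    start from the packaged table fixtures (per-grade
  differential lists and per-miRNA cancer-pathway target lists) and run the
  intersection / exclusion / network stages. This is the exact path for
  table-derived numbers, because the study's raw intermediates were never
  deposited.
* ``simulation`` generate every input synthetically from one seed and run
  all stages: expression -> differential calls -> common set -> seed-match
  target prediction -> enrichment -> cancer-pathway screen -> network.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from mirkey import __version__
from mirkey.diffexpr import (
    DifferentialCallSet,
    apply_validation_exclusions,
    call_grade_differential,
    common_dysregulated,
    pairwise_log2fc,
)
from mirkey.enrichment import (
    CancerPathwaySet,
    GeneSetAnnotation,
    enrich,
    genes_in_both,
    screen_cancer_pathways,
    select_significant,
    write_gmt,
)
from mirkey.network import build_network, export_network, rank_key_mirnas
from mirkey.synthetic_data import (
    SimulationSpec,
    load_table_fixture,
    simulate_annotations,
    simulate_expression,
    simulate_utrs,
    write_utr_fasta,
)
from mirkey.target_prediction import (
    MatureMiRNA,
    UTRRecord,
    predict_targets,
    rank_by_regulator_count,
    sites_to_frame,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; prior-stage artifacts are left intact."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class SimulationSettings:
    n_mirnas: int = 300
    pairs_per_grade: int = 3
    n_up: int = 4
    n_down: int = 8
    planted_log2fc: float = 2.0
    noise_sd: float = 0.2
    n_genes: int = 60
    utr_length: int = 400
    site_probability: float = 0.35
    n_go_terms: int = 40
    n_kegg_terms: int = 20
    genes_per_term: int = 25
    n_background_genes: int = 200


@dataclass(frozen=True)
class PipelineConfig:
    mode: str = "fixture"  # "fixture" | "simulation"
    out_dir: str = "mirkey_run"
    rng_seed: int = 0
    threshold_fold: float = 2.0
    diffexpr_mode: str = "mean"
    min_site: str = "7mer"
    top_fraction: float = 0.25
    alpha: float = 0.05
    cancer_pathways: tuple[str, ...] = ("hsa05200",)
    top_n: int = 3
    excluded: tuple[str, ...] = ("hsa-miR-200c",)
    simulation: SimulationSettings = field(default_factory=SimulationSettings)

    def __post_init__(self) -> None:
        if self.mode not in ("fixture", "simulation"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.threshold_fold <= 1:
            raise ValueError("threshold_fold must be > 1")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = dict(raw)
        for key in ("cancer_pathways", "excluded"):
            if key in cfg and isinstance(cfg[key], list):
                cfg[key] = tuple(cfg[key])
        if sim is not None:
            cfg["simulation"] = SimulationSettings(**sim)
        return cls(**cfg)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _write_json(path: Path, payload: Mapping[str, Any]) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _random_mirna_sequence(rng: np.random.Generator, length: int = 22) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages, write artifacts under ``config.out_dir``, return the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "config_hash": config.digest(),
        "config": asdict(config),
        "stages": {},
    }
    if config.mode == "fixture":
        _run_fixture(config, out, report)
    else:
        _run_simulation(config, out, report)
    _write_json(out / "report.json", report)
    return report


def _run_fixture(config: PipelineConfig, out: Path, report: dict[str, Any]) -> None:
    try:
        t1 = load_table_fixture("T1")
        callset = DifferentialCallSet(
            calls={
                grade: (frozenset(up), frozenset(down))
                for grade, (up, down) in t1.grade_lists().items()
            },
            threshold_fold=config.threshold_fold,
        )
        callset.to_frame().to_csv(out / "calls.tsv", sep="\t", index=False)
        common = common_dysregulated(callset)
        audit = apply_validation_exclusions(common, config.excluded)
        final = audit.common
        with open(out / "common.tsv", "w") as fh:
            fh.write("mirna\tdirection\n")
            for m in sorted(final.up):
                fh.write(f"{m}\tup\n")
            for m in sorted(final.down):
                fh.write(f"{m}\tdown\n")
        report["stages"]["diffexpr"] = {
            "per_grade_counts": {
                g: [len(callset.up(g)), len(callset.down(g))] for g in callset.grades
            },
            "common_up": sorted(common.up),
            "common_down": sorted(common.down),
            "excluded": list(audit.removed),
            "final_up": sorted(final.up),
            "final_down": sorted(final.down),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("diffexpr", str(exc)) from exc

    try:
        t2 = load_table_fixture("T2")
        per_mirna = t2.target_lists()
        network = build_network(per_mirna)
        export_network(network, out / "network.sif", format="sif")
        key = rank_key_mirnas(network, top_n=config.top_n)
        key.table.to_csv(out / "key_mirnas.tsv", sep="\t", index=False)
        report["stages"]["network"] = {
            "n_edges": len(network.edges),
            "key_mirnas": {
                row.mirna_id: int(row.target_count)
                for row in key.table.itertuples(index=False)
                if row.selected
            },
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("network", str(exc)) from exc


def _run_simulation(config: PipelineConfig, out: Path, report: dict[str, Any]) -> None:
    sim = config.simulation
    seeds = np.random.SeedSequence(config.rng_seed).spawn(5)

    # --- expression + differential calls
    try:
        planted_up = {f"mir-up-{i:02d}": sim.planted_log2fc for i in range(sim.n_up)}
        planted_down = {
            f"mir-down-{i:02d}": -sim.planted_log2fc for i in range(sim.n_down)
        }
        spec = SimulationSpec(
            n_mirnas=sim.n_mirnas,
            grades={g: sim.pairs_per_grade for g in ("GI", "GII", "GIII")},
            planted_up=planted_up,
            planted_down=planted_down,
            noise_sd=sim.noise_sd,
            rng_seed=int(seeds[0].generate_state(1)[0]),
        )
        matrix, truth = simulate_expression(spec)
        matrix.to_tsv(out / "expression.tsv", out / "samples.tsv")
        truth.to_csv(out / "expression_truth.tsv", sep="\t", index=False)
        records = pairwise_log2fc(matrix)
        callset = call_grade_differential(
            records, threshold_fold=config.threshold_fold, mode=config.diffexpr_mode
        )
        callset.to_frame().to_csv(out / "calls.tsv", sep="\t", index=False)
        common = apply_validation_exclusions(
            common_dysregulated(callset), config.excluded
        ).common
        candidates = sorted(common.up) + sorted(common.down)
        report["stages"]["diffexpr"] = {
            "per_grade_counts": {
                g: [len(callset.up(g)), len(callset.down(g))] for g in callset.grades
            },
            "common_up": sorted(common.up),
            "common_down": sorted(common.down),
        }
        if not candidates:
            raise ValueError("no commonly dysregulated miRNAs recovered")
    except Exception as exc:  # noqa: BLE001
        raise StageError("diffexpr", str(exc)) from exc

    # --- seed-match target prediction on a planted UTR corpus
    try:
        rng = np.random.default_rng(seeds[1])
        mirnas = [
            MatureMiRNA(id=mid, sequence=_random_mirna_sequence(rng))
            for mid in candidates
        ]
        genes = [f"GENE{i:04d}" for i in range(sim.n_genes)]
        planted_sites = []
        slot = 0
        site_truth_edges: set[tuple[str, str]] = set()
        for gene in genes:
            offset = 10
            for m in mirnas:
                if rng.random() < sim.site_probability:
                    pattern = m.seed_match + "A"  # 7mer-A1
                    if offset + len(pattern) - 1 > sim.utr_length - 10:
                        break
                    planted_sites.append((gene, offset, pattern))
                    site_truth_edges.add((m.id, gene))
                    offset += len(pattern) + 12
            slot += 1
        forbidden = sorted(
            {m.seed_match for m in mirnas}
            | {m.m8_match + m.seed_match for m in mirnas}
        )
        sequences, site_truth = simulate_utrs(
            genes,
            sim.utr_length,
            planted_sites,
            rng_seed=int(seeds[2].generate_state(1)[0]),
            forbidden_motifs=forbidden,
        )
        write_utr_fasta(sequences, out / "utrs.fa")
        with open(out / "mirnas.fa", "w") as fh:
            for m in mirnas:
                fh.write(f">{m.id}\n{m.sequence}\n")
        utr_db = [
            UTRRecord(transcript_accession=f"SYN_{g}", gene_symbol=g, sequence=s)
            for g, s in sorted(sequences.items())
        ]
        edges = predict_targets(mirnas, utr_db, min_site=config.min_site)
        sites_to_frame(edges).to_csv(out / "sites.tsv", sep="\t", index=False)
        ranked = rank_by_regulator_count(
            edges, candidate_mirnas=candidates, fraction=config.top_fraction
        )
        ranked.table.to_csv(out / "ranked_targets.tsv", sep="\t", index=False)
        selected_genes = ranked.selected_genes
        report["stages"]["targets"] = {
            "n_edges": len(edges),
            "n_planted_edges": len(site_truth_edges),
            "n_genes_ranked": int(len(ranked.table)),
            "n_selected": len(selected_genes),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("targets", str(exc)) from exc

    # --- enrichment and cancer-pathway screen
    try:
        universe = genes + [f"BG{i:04d}" for i in range(sim.n_background_genes)]
        go_annotations, _ = simulate_annotations(
            n_terms=sim.n_go_terms,
            genes_per_term=sim.genes_per_term,
            enriched_terms={"TERM0000": 0.9, "TERM0001": 0.8},
            rng_seed=int(seeds[3].generate_state(1)[0]),
            query_genes=selected_genes,
            universe_genes=universe,
            category="GO",
        )
        kegg_annotations, _ = simulate_annotations(
            n_terms=sim.n_kegg_terms,
            genes_per_term=sim.genes_per_term,
            enriched_terms={"TERM0000": 0.9},
            rng_seed=int(seeds[4].generate_state(1)[0]),
            query_genes=selected_genes,
            universe_genes=universe,
            category="KEGG",
        )
        # designated cancer pathway: an explicitly planted KEGG term
        cancer_id = config.cancer_pathways[0]
        cancer_genes = frozenset(selected_genes) | frozenset(genes[: sim.n_genes // 2])
        kegg_annotations = [
            GeneSetAnnotation(
                term_id=cancer_id,
                term_name="pathways in cancer (synthetic)",
                category="KEGG",
                genes=cancer_genes,
            ),
            *kegg_annotations,
        ]
        write_gmt(go_annotations, out / "go.gmt")
        write_gmt(kegg_annotations, out / "kegg.gmt")
        query = set(selected_genes)
        go_results = enrich(query, go_annotations, universe=universe)
        kegg_results = enrich(query, kegg_annotations, universe=universe)
        sig_go = select_significant(go_results, alpha=config.alpha)
        sig_kegg = select_significant(kegg_results, alpha=config.alpha)
        both = genes_in_both(
            sig_go.gene_membership(go_annotations).values(),
            sig_kegg.gene_membership(kegg_annotations).values(),
        )
        per_mirna = {
            mid: [e.gene_symbol for e in edges if e.mirna_id == mid]
            for mid in candidates
        }
        screened = screen_cancer_pathways(
            both,
            kegg_annotations,
            CancerPathwaySet(term_ids=frozenset(config.cancer_pathways)),
            per_mirna,
        )
        with open(out / "cancer_targets.tsv", "w") as fh:
            fh.write("mirna\tn_targets\tgenes\n")
            for mid in candidates:
                fh.write(f"{mid}\t{len(screened[mid])}\t{','.join(screened[mid])}\n")
        report["stages"]["enrichment"] = {
            "n_sig_go": len(sig_go.significant),
            "n_sig_kegg": len(sig_kegg.significant),
            "n_genes_in_both": len(both),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("enrichment", str(exc)) from exc

    # --- network + key miRNAs
    try:
        nonempty = {m: g for m, g in screened.items() if g}
        if not nonempty:
            raise ValueError("no miRNA retained any cancer-pathway target")
        network = build_network(nonempty)
        export_network(network, out / "network.sif", format="sif")
        key = rank_key_mirnas(network, top_n=config.top_n)
        key.table.to_csv(out / "key_mirnas.tsv", sep="\t", index=False)
        report["stages"]["network"] = {
            "n_edges": len(network.edges),
            "key_mirnas": {
                row.mirna_id: int(row.target_count)
                for row in key.table.itertuples(index=False)
                if row.selected
            },
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("network", str(exc)) from exc
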