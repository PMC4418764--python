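# mirkey

Key-miRNA discovery from paired tumor/normal miRNA expression profiles.

The pipeline goes from a paired expression matrix to a ranked table of key
regulator miRNAs:

1. **diffexpr** — per-patient log2(tumor/normal) fold changes; per-grade
   differential calls at a strict more-than-two-fold rule; the commonly
   dysregulated set as the per-direction intersection across grades, with an
   audit-logged exclusion step for candidates contradicted by independent
   validation.
2. **target_prediction** — canonical seed-match engine (6mer / 7mer-A1 /
   7mer-m8 / 8mer, longest-type-wins, 1-based inclusive spans covering the
   full site); genes ranked by the number of distinct upstream candidate
   miRNAs, top fraction selected with boundary ties included.
3. **enrichment** — one-sided hypergeometric tests per GO/KEGG term,
   Benjamini–Hochberg FDR within each category, significant/top-k selection,
   the genes-in-both-significant-GO-and-KEGG screen, and a cancer-pathway
   filter producing per-miRNA target lists.
4. **network** — bipartite miRNA–gene network over cancer-pathway targets,
   degree-ranked key miRNAs (ties at the boundary all included), SIF/TSV
   export with exact round-trip import.
5. **validation** — 2^(−ΔΔCt) relative quantification against a U6
   reference, Renilla/Firefly luciferase normalization, pooled-variance
   Student's and Welch two-sample t-tests.
6. **synthetic_data** — deterministic generators for every input: paired
   log-normal expression cohorts with planted fold changes, UTR corpora with
   planted seed sites on a background cleaned of accidental matches, GMT
   annotation corpora with planted enrichment; plus loaders for the packaged
   `table1/2/3.tsv` fixtures (per-grade differential lists, per-miRNA
   cancer-pathway target lists, candidate miR-199a-5p sites).

## CLI

```sh
mirkey run --config run.yaml            # full pipeline (fixture or simulation mode)
mirkey simulate --n-mirnas 300 --out sim/
mirkey diffexpr --expr sim/expression.tsv --samples sim/samples.tsv --out de/
mirkey targets --mirnas m.fa --utrs u.fa --min-site 7mer --fraction 0.25 --out targets/
mirkey enrich --query genes.txt --go go.gmt --kegg kegg.gmt --alpha 0.05 --out enrich/
mirkey network --targets edges.tsv --top 3 --format sif --out net/
mirkey qpcr --ct ct.tsv --out qpcr.tsv
mirkey luc --in luc.tsv --out luc_norm.tsv
```

A minimal `run.yaml`:

```yaml
mode: fixture          # or: simulation
out_dir: mirkey_run
rng_seed: 1
threshold_fold: 2.0
diffexpr_mode: mean    # or: all_pairs
top_fraction: 0.25
alpha: 0.05
cancer_pathways: [hsa05200]
top_n: 3
excluded: [hsa-miR-200c]
```

File formats: expression as TSV (miRNA × sample) with a companion sample
sheet (`sample_id`, `patient_id`, `grade`, `tissue`); miRNAs and UTRs as
FASTA (UTR headers `accession|gene_symbol`); annotations as GMT; networks as
SIF (`mirna targets gene`) or TSV edge lists.

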