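"""Hypergeometric gene-set enrichment with Benjamini-Hochberg FDR.

One-sided (upper tail) hypergeometric tests per term, BH adjustment applied
within each category (GO and KEGG independently), a significant/top-k view,
the "genes in both significant GO terms and KEGG pathways" screen, and the
cancer-pathway filter that produces per-miRNA target lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class GeneSetAnnotation:
    """One annotation term (GO or KEGG) with its gene membership."""

    term_id: str
    term_name: str
    category: str  # "GO" | "KEGG"
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term_id}: empty gene set")
        if self.category not in ("GO", "KEGG"):
            raise ValueError(f"term {self.term_id}: unknown category {self.category!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    category: str
    k: int  # query genes in term
    K: int  # universe genes in term
    n: int  # query size
    N: int  # universe size
    p: float
    q: float = field(default=float("nan"))


@dataclass(frozen=True)
class CancerPathwaySet:
    """KEGG term ids treated as cancer-related (default: hsa05200)."""

    term_ids: frozenset[str] = frozenset({"hsa05200"})

    def validate_against(self, annotations: Iterable[GeneSetAnnotation]) -> None:
        known = {a.term_id for a in annotations}
        missing = self.term_ids - known
        if missing:
            raise ValueError(f"cancer pathway ids not in annotation: {sorted(missing)}")


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Computed via scipy's log-space survival function (numerically stable).
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric configuration k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return []
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()


def enrich(
    query: Iterable[str],
    annotations: Sequence[GeneSetAnnotation],
    universe: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Test every term with >= 1 query hit; BH-adjust per category.

    The universe defaults to all genes carrying at least one annotation.
    Results are sorted by p ascending, ties broken by term_id.
    """
    query_set = set(query)
    if not query_set:
        raise ValueError("empty query gene set")
    if universe is None:
        universe_set: set[str] = set()
        for a in annotations:
            universe_set |= a.genes
    else:
        universe_set = set(universe)
    offenders = query_set - universe_set
    if offenders:
        raise ValueError(f"query genes outside universe: {sorted(offenders)}")

    N, n = len(universe_set), len(query_set)
    raw: list[EnrichmentResult] = []
    for a in annotations:
        term_genes = a.genes & universe_set
        k = len(term_genes & query_set)
        if k == 0:
            continue
        K = len(term_genes)
        raw.append(
            EnrichmentResult(
                term_id=a.term_id,
                term_name=a.term_name,
                category=a.category,
                k=k,
                K=K,
                n=n,
                N=N,
                p=hypergeom_pvalue(k, K, n, N),
            )
        )

    adjusted: list[EnrichmentResult] = []
    for category in sorted({r.category for r in raw}):
        members = [r for r in raw if r.category == category]
        qvals = bh_adjust([r.p for r in members])
        adjusted.extend(
            EnrichmentResult(**{**r.__dict__, "q": qv}) for r, qv in zip(members, qvals)
        )
    return sorted(adjusted, key=lambda r: (r.p, r.term_id))


@dataclass(frozen=True)
class SignificantTerms:
    """Significance selection plus a Fig-2-style top-k reporting view."""

    significant: tuple[EnrichmentResult, ...]
    top: tuple[EnrichmentResult, ...]
    alpha: float

    def gene_membership(
        self, annotations: Sequence[GeneSetAnnotation]
    ) -> dict[str, frozenset[str]]:
        by_id = {a.term_id: a.genes for a in annotations}
        return {r.term_id: by_id[r.term_id] for r in self.significant}


def select_significant(
    results: Sequence[EnrichmentResult], alpha: float = 0.05, top_k: int = 10
) -> SignificantTerms:
    """Significant = q < alpha; the top-k view lists the best terms by p regardless."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    ordered = sorted(results, key=lambda r: (r.p, r.term_id))
    significant = tuple(r for r in ordered if r.q < alpha)
    return SignificantTerms(
        significant=significant, top=tuple(ordered[:top_k]), alpha=alpha
    )


def genes_in_both(
    sig_go_genes: Iterable[Iterable[str]], sig_kegg_genes: Iterable[Iterable[str]]
) -> frozenset[str]:
    """Genes in >= 1 significant GO term AND >= 1 significant KEGG pathway."""
    go_union: set[str] = set()
    for genes in sig_go_genes:
        go_union |= set(genes)
    kegg_union: set[str] = set()
    for genes in sig_kegg_genes:
        kegg_union |= set(genes)
    return frozenset(go_union & kegg_union)


def screen_cancer_pathways(
    genes: Iterable[str],
    annotations: Sequence[GeneSetAnnotation],
    cancer_set: CancerPathwaySet,
    per_mirna_targets: Mapping[str, Iterable[str]],
) -> dict[str, list[str]]:
    """Per-miRNA sorted lists of targets that pass the screen and sit in a cancer pathway.

    A target survives iff it is in ``genes`` (the genes-in-both screen output)
    and belongs to at least one designated cancer pathway. miRNAs with no
    survivors keep an empty row.
    """
    cancer_set.validate_against(annotations)
    cancer_genes: set[str] = set()
    for a in annotations:
        if a.term_id in cancer_set.term_ids:
            cancer_genes |= a.genes
    screen = set(genes)
    out: dict[str, list[str]] = {}
    for mirna, targets in per_mirna_targets.items():
        out[mirna] = sorted(set(targets) & screen & cancer_genes)
    return out


def read_gmt(path: str | Path, category: str) -> list[GeneSetAnnotation]:
    """Parse a GMT file (term id, description, tab-separated gene symbols)."""
    annotations = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: malformed GMT line")
            term_id, term_name, *genes = parts
            annotations.append(
                GeneSetAnnotation(
                    term_id=term_id,
                    term_name=term_name,
                    category=category,
                    genes=frozenset(g for g in genes if g),
                )
            )
    return annotations


def write_gmt(annotations: Sequence[GeneSetAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            fh.write("\t".join([a.term_id, a.term_name, *sorted(a.genes)]) + "\n")
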