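"""Independent brute-force oracles used by the test suite.

Deliberately slow and literal; they must not share code paths with the
package implementations they check.
"""

from __future__ import annotations

import math
from fractions import Fraction


def hypergeom_upper_tail_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) by explicit enumeration of the hypergeometric pmf."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for j in range(k, min(K, n) + 1):
        acc += Fraction(math.comb(K, j) * math.comb(N - K, n - j), total)
    return acc


def bh_stepup(pvalues: list[float]) -> tuple[list[float], list[bool]]:
    """Textbook Benjamini-Hochberg: adjusted p-values and rejections at 0.05.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1; reject all hypotheses
    ranked at or below the largest i with p_(i) <= i * alpha / m.
    """
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            m * pvalues[order[j - 1]] / j for j in range(rank_pos, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    alpha = 0.05
    max_i = 0
    for i in range(1, m + 1):
        if pvalues[order[i - 1]] <= i * alpha / m:
            max_i = i
    reject = [False] * m
    for i in range(max_i):
        reject[order[i]] = True
    return q, reject


_DNA_FOR_RNA = {"A": "A", "C": "C", "G": "G", "U": "T"}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def scan_sites_bruteforce(mirna_seq_rna: str, utr_seq_dna: str):
    """Position-by-position test of all four canonical patterns at every offset.

    Builds the literal DNA strings for 8mer / 7mer-m8 / 7mer-A1 / 6mer and
    compares them against every UTR window, longest pattern first; emits at
    most one site per seed-core position. Returns a list of
    (type, start_1based, end_1based, sequence).
    """
    rna = mirna_seq_rna.upper().replace("T", "U")
    seed_rna = rna[1:7]
    core = "".join(_COMPLEMENT[_DNA_FOR_RNA[b]] for b in seed_rna)[::-1]
    m8 = _COMPLEMENT[_DNA_FOR_RNA[rna[7]]]
    patterns = [
        ("8mer", m8 + core + "A", -1),
        ("7mer-m8", m8 + core, -1),
        ("7mer-A1", core + "A", 0),
        ("6mer", core, 0),
    ]
    utr = utr_seq_dna.upper().replace("U", "T")
    sites = []
    claimed_core_positions = set()
    for site_type, pattern, core_shift in patterns:
        for start0 in range(len(utr) - len(pattern) + 1):
            window = utr[start0 : start0 + len(pattern)]
            if window != pattern:
                continue
            core_pos = start0 - core_shift  # 0-based position of the 6-nt core
            if core_pos in claimed_core_positions:
                continue
            if "N" in window:
                continue
            claimed_core_positions.add(core_pos)
            sites.append((site_type, start0 + 1, start0 + len(pattern), window))
    return sorted(sites, key=lambda s: s[1])


def rank_genes_bruteforce(edges: list[tuple[str, str]], fraction: float):
    """Count-then-sort ranking with boundary-tie inclusion, done by hand."""
    counts: dict[str, set[str]] = {}
    for mirna, gene in edges:
        counts.setdefault(gene, set()).add(mirna)
    rows = sorted(((g, len(ms)) for g, ms in counts.items()), key=lambda r: (-r[1], r[0]))
    n_top = math.ceil(fraction * len(rows))
    cutoff = rows[n_top - 1][1]
    selected = {g for g, c in rows if c >= cutoff}
    return rows, selected


def student_t_bruteforce(a: list[float], b: list[float]) -> tuple[float, int]:
    """Pooled-variance two-sample t statistic from the textbook formula."""
    n1, n2 = len(a), len(b)
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    s1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    s2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t, n1 + n2 - 2
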