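"""GO-level STR enrichment testing.

Two designs are supported:

* between species: for each GO term and each unordered species pair,
  Fisher's exact test on [[A_with, A_without], [B_with, B_without]], where
  "with" counts genes in the term carrying at least one STR;
* within species: for each GO term, Fisher's exact test of the in-term
  with/without split against the rest of the genome.

All p-values in a family are corrected with the Benjamini-Yekutieli FDR
procedure, which controls the false discovery rate under arbitrary
dependence by inflating with c(m) = sum_{i=1..m} 1/i. Tests are two-sided;
the enrichment/purification direction is read from the sample odds ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import StrscapeWarning

__all__ = [
    "GOCountTable",
    "ContingencyResult",
    "FDRResult",
    "fisher_exact_2x2",
    "by_fdr",
    "count_table_from_flags",
    "pairwise_species_tests",
    "within_species_enrichment",
]


@dataclass
class GOCountTable:
    """Per-GO-term with/without-STR gene counts for one species."""

    species_id: str
    counts: dict[str, tuple[int, int]]  # term -> (n_with, n_without)

    @property
    def background(self) -> tuple[int, int]:
        w = sum(c[0] for c in self.counts.values())
        wo = sum(c[1] for c in self.counts.values())
        return w, wo


@dataclass
class ContingencyResult:
    go_id: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    direction: str  # enriched | purified | none
    label: str = ""  # e.g. the species pair


@dataclass
class FDRResult:
    m: int
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    rejected: np.ndarray
    alpha: float
    method: str = "benjamini-yekutieli"


def _direction(table) -> str:
    (a, b), (c, d) = table
    ad, bc = a * d, b * c
    if ad == bc:
        return "none"
    return "enriched" if ad > bc else "purified"


def fisher_exact_2x2(table) -> tuple[float, str]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns (p_value, direction). The two-sided p sums hypergeometric point
    probabilities <= that of the observed table (up to a small relative tie
    tolerance). Direction compares the sample odds ratio to 1: "enriched"
    means the first row has the larger with-proportion.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be nonnegative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table: test undefined")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(min(p, 1.0)), _direction(table)


def by_fdr(raw_p: Sequence[float], alpha: float = 0.05) -> FDRResult:
    """Benjamini-Yekutieli FDR adjustment.

    adjusted_(i) = min(1, min_{j>=rank(i)} p_(j) * m * c(m) / j) with
    c(m) = sum_{i=1..m} 1/i; a test is rejected when adjusted <= alpha.
    """
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return FDRResult(0, p, p.copy(), np.zeros(0, bool), alpha)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_by")
    return FDRResult(p.size, p, adjusted, rejected, alpha)


def count_table_from_flags(
    species_id: str,
    gene_go: Mapping[str, set[str]],
    str_flags: Mapping[str, bool],
) -> GOCountTable:
    """Build a GOCountTable from gene->GO sets and gene->has-STR flags."""
    counts: dict[str, list[int]] = {}
    for gene, terms in gene_go.items():
        w = bool(str_flags.get(gene, False))
        for t in terms:
            c = counts.setdefault(t, [0, 0])
            c[0 if w else 1] += 1
    return GOCountTable(species_id, {t: (c[0], c[1]) for t, c in counts.items()})


def pairwise_species_tests(
    tables: Sequence[GOCountTable],
    go_terms: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, FDRResult, set[str]]:
    """Between-species STR enrichment per GO term.

    Runs Fisher's exact test for every GO term and unordered species pair
    on [[A_with, A_without], [B_with, B_without]]. FDR is pooled over all
    term x pair tests. A term is significant if any of its pairwise tests
    survives BY at ``alpha``.

    Returns a long-format frame (term, species_a, species_b, the four
    cells, p, adjusted_p, direction, significant), the FDRResult, and the
    set of significant terms.
    """
    if len(tables) < 2:
        raise ValueError("need at least two species")
    by_species = {t.species_id: t for t in tables}
    if go_terms is None:
        go_terms = sorted(set().union(*(t.counts.keys() for t in tables)))
    rows = []
    n_skipped = 0
    for term in go_terms:
        for sa, sb in combinations(sorted(by_species), 2):
            ca = by_species[sa].counts.get(term)
            cb = by_species[sb].counts.get(term)
            if ca is None or cb is None or (sum(ca) == 0 and sum(cb) == 0):
                n_skipped += 1
                continue
            table = ((ca[0], ca[1]), (cb[0], cb[1]))
            p, direction = fisher_exact_2x2(table)
            rows.append(
                {
                    "term": term,
                    "species_a": sa,
                    "species_b": sb,
                    "a_with": ca[0],
                    "a_without": ca[1],
                    "b_with": cb[0],
                    "b_without": cb[1],
                    "p": p,
                    "direction": direction,
                }
            )
    if n_skipped:
        warnings.warn(
            f"{n_skipped} term/species-pair combinations skipped (term absent)",
            StrscapeWarning,
            stacklevel=2,
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df, by_fdr([], alpha), set()
    fdr = by_fdr(df["p"].to_numpy(), alpha)
    df["adjusted_p"] = fdr.adjusted_p
    df["significant"] = fdr.rejected
    significant_terms = set(df.loc[df["significant"], "term"])
    return df, fdr, significant_terms


def within_species_enrichment(
    gene_go: Mapping[str, set[str]],
    str_flags: Mapping[str, bool],
    alpha: float = 0.05,
    alpha_display: float = 0.01,
) -> tuple[list[ContingencyResult], FDRResult, pd.DataFrame]:
    """Within-species enrichment/purification of STR-carrying genes per term.

    For each GO term with at least one annotated gene, Fisher's exact test
    on [[in-term with, in-term without], [out-of-term with, out-of-term
    without]]; direction from the odds ratio (enriched = more STR genes in
    the term than background). BY-corrected over terms; ``alpha_display``
    is recorded in the output frame as the conventional display cut.
    """
    genes = list(gene_go)
    total_with = sum(bool(str_flags.get(g, False)) for g in genes)
    total_without = len(genes) - total_with
    terms = sorted(set().union(*gene_go.values())) if gene_go else []
    results: list[ContingencyResult] = []
    for term in terms:
        in_with = in_without = 0
        for g in genes:
            if term in gene_go[g]:
                if str_flags.get(g, False):
                    in_with += 1
                else:
                    in_without += 1
        table = (
            (in_with, in_without),
            (total_with - in_with, total_without - in_without),
        )
        p, direction = fisher_exact_2x2(table)
        results.append(ContingencyResult(term, table, p, direction))
    fdr = by_fdr([r.p_value for r in results], alpha)
    df = pd.DataFrame(
        {
            "term": [r.go_id for r in results],
            "in_with": [r.table[0][0] for r in results],
            "in_without": [r.table[0][1] for r in results],
            "out_with": [r.table[1][0] for r in results],
            "out_without": [r.table[1][1] for r in results],
            "p": [r.p_value for r in results],
            "adjusted_p": fdr.adjusted_p if results else [],
            "direction": [r.direction for r in results],
        }
    )
    if len(df):
        df["significant"] = fdr.rejected
        df["display"] = (df["adjusted_p"] <= alpha_display) & (df["direction"] != "none")
    return results, fdr, df
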