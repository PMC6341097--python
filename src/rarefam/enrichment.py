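"""Size-bounded gene-set overrepresentation analysis (ORA).

Given an input gene list (here: the genes carrying family VOIs) and a
collection of gene sets, each set is tested with the hypergeometric upper
tail: with a universe of N genes of which C belong to the set, and k input
genes, the observed overlap O is compared against the expectation
E = C*k/N, and p = P(X >= O) for X ~ Hypergeometric(N, C, k).  The
enrichment ratio R = O/E is the scale-free effect size.

Sets are filtered to a size window before testing (default 500-1500
member genes within the universe): very small categories are too specific
and very large ones too generic to say anything about a broad phenotype
driven by hundreds of genes.  Benjamini-Hochberg FDR is computed across
the surviving sets.

The default universe is the union of all genes in the gene-set collection;
an explicit universe can be supplied instead, and every p-value depends on
that choice.  Gene symbols are matched case-insensitively (upper-cased).
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import EnrichmentConfig, EnrichmentResult, GeneSet


def _upper(genes: Iterable[str]) -> set[str]:
    return {g.upper() for g in genes}


def ora_test(
    input_genes: set[str], gene_set: GeneSet, universe: set[str]
) -> EnrichmentResult:
    """Hypergeometric upper-tail overrepresentation test for one set.

    Input genes and set members are intersected with the universe first;
    unmatched input genes do not contribute to k.  With E = 0 the ratio is
    undefined and reported as NaN.
    """
    uni = _upper(universe)
    members = _upper(gene_set.members) & uni
    inputs = _upper(input_genes) & uni
    N, C, k = len(uni), len(members), len(inputs)
    overlap = sorted(inputs & members)
    O = len(overlap)
    E = C * k / N if N else 0.0
    R = O / E if E > 0 else math.nan
    p = float(hypergeom.sf(O - 1, N, C, k)) if N else 1.0
    return EnrichmentResult(
        set_id=gene_set.set_id,
        name=gene_set.name,
        C=C,
        O=O,
        E=E,
        R=R,
        p=p,
        overlap_genes=tuple(overlap),
    )


def filter_sets_by_size(
    sets: Iterable[GeneSet], cfg: EnrichmentConfig, universe: set[str]
) -> list[GeneSet]:
    """Keep sets whose member count within the universe lies in
    [min_set_size, max_set_size]."""
    uni = _upper(universe)
    kept = []
    for gs in sets:
        c = len(_upper(gs.members) & uni)
        if cfg.min_set_size <= c <= cfg.max_set_size:
            kept.append(gs)
    return kept


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    if len(pvalues) == 0:
        return []
    if any(not (0.0 < p <= 1.0) for p in pvalues):
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(pvalues, method="fdr_bh")
    return [float(q) for q in adjusted]


def default_universe(sets: Iterable[GeneSet]) -> set[str]:
    """Union of all genes appearing in any set."""
    uni: set[str] = set()
    for gs in sets:
        uni |= _upper(gs.members)
    return uni


def run_enrichment(
    input_genes: Iterable[str],
    gene_sets: Sequence[GeneSet],
    cfg: EnrichmentConfig = EnrichmentConfig(),
    universe: set[str] | None = None,
) -> list[EnrichmentResult]:
    """Size filter, per-set ORA, BH FDR across surviving sets; sorted by p.

    Significance at the configured FDR threshold is left to the caller
    (``r.fdr < cfg.fdr_alpha``); the full table is always returned.
    """
    input_genes = _upper(input_genes)
    if not input_genes:
        raise ValueError("input gene list is empty")
    if universe is None:
        universe = default_universe(gene_sets)
    tested = filter_sets_by_size(gene_sets, cfg, universe)
    results = [ora_test(input_genes, gs, universe) for gs in tested]
    if results:
        fdrs = bh_fdr([r.p for r in results])
        results = [
            EnrichmentResult(
                set_id=r.set_id, name=r.name, C=r.C, O=r.O, E=r.E, R=r.R,
                p=r.p, fdr=q, overlap_genes=r.overlap_genes,
            )
            for r, q in zip(results, fdrs)
        ]
    results.sort(key=lambda r: (r.p, r.set_id))
    return results
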