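"""Gene-based rare-variant burden association.

Qualifying variants (protein-altering and rare, or private, depending on
the filter mode) are collapsed per gene into a carrier indicator per
individual, giving a 2x2 carrier table against case/control status.  The
test is the one-sided Fisher exact test in the direction "greater burden
in cases": the upper tail P(X >= a) of the hypergeometric distribution of
the case-carrier cell under fixed margins.

Two odds-ratio conventions are provided:

* ``conditional`` (default) — the conditional maximum-likelihood estimate
  under the Fisher noncentral hypergeometric model, with the exact
  conditional 95% CI obtained by inverting the noncentral tails at 0.025
  each side (the convention of R's ``fisher.test``);
* ``wald`` — the sample cross-product odds ratio with the asymptotic
  Woolf (log-scale Wald) interval, the convention of most epidemiology
  tables.

The two can differ appreciably for sparse tables, so results always state
which convention produced them.
"""

from __future__ import annotations

import math
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import hypergeom, nchypergeom_fisher

from .prioritization import is_protein_altering, passes_frequency_filter
from .types import (
    AnnotatedVariant,
    BurdenResult,
    ContingencyTable,
    FilterConfig,
    GenotypeTable,
)

CIMethod = Literal["conditional", "wald"]


def fisher_one_sided(table: ContingencyTable) -> float:
    """Upper-tail Fisher exact p: P(case carriers >= a) given fixed margins."""
    a, b, c, d = table.a, table.b, table.c, table.d
    N = a + b + c + d
    if N == 0:
        return 1.0
    K = a + c  # total carriers
    n = a + b  # cases
    return float(hypergeom.sf(a - 1, N, K, n))


def _support(table: ContingencyTable) -> tuple[int, int]:
    K, n, N = table.a + table.c, table.n_cases, table.n_cases + table.n_controls
    return max(0, K + n - N), min(K, n)


def _solve_log_psi(func, lo: float = -1.0, hi: float = 1.0) -> float:
    """Bracket-expanding Brent solve on the log odds-ratio scale."""
    flo, fhi = func(lo), func(hi)
    for _ in range(60):
        if flo == 0.0:
            return lo
        if fhi == 0.0:
            return hi
        if flo * fhi < 0:
            return brentq(func, lo, hi, xtol=1e-12)
        lo, hi = lo * 2, hi * 2
        flo, fhi = func(lo), func(hi)
        if abs(lo) > 700:
            break
    raise RuntimeError("failed to bracket the noncentral hypergeometric root")


def odds_ratio_cmle(
    table: ContingencyTable, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Conditional-MLE odds ratio and exact conditional CI.

    The estimate is the odds ratio at which the mean of the Fisher
    noncentral hypergeometric distribution (margins fixed at the observed
    ones) equals the observed case-carrier cell.  The CI inverts the
    noncentral upper/lower tails at (1-confidence)/2 each.  When the
    observed cell sits at the boundary of its support the corresponding
    bound (and possibly the estimate) is 0 or infinite; with no carriers
    at all the estimate is undefined (NaN) with CI (0, inf).
    """
    a = table.a
    K, n = table.a + table.c, table.n_cases
    N = table.n_cases + table.n_controls
    lo, hi = _support(table)
    alpha = 1.0 - confidence

    if lo == hi:  # degenerate: cell determined by margins (e.g. no carriers)
        return math.nan, (0.0, math.inf)

    if a == hi:
        estimate = math.inf
    elif a == lo:
        estimate = 0.0
    else:
        log_psi = _solve_log_psi(
            lambda lp: nchypergeom_fisher.mean(N, K, n, math.exp(lp)) - a
        )
        estimate = math.exp(log_psi)

    if a == lo:
        lower = 0.0
    else:
        lower = math.exp(
            _solve_log_psi(
                lambda lp: nchypergeom_fisher.sf(a - 1, N, K, n, math.exp(lp))
                - alpha / 2
            )
        )
    if a == hi:
        upper = math.inf
    else:
        upper = math.exp(
            _solve_log_psi(
                lambda lp: nchypergeom_fisher.cdf(a, N, K, n, math.exp(lp))
                - alpha / 2
            )
        )
    return estimate, (lower, upper)


def odds_ratio_wald(
    table: ContingencyTable, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Sample cross-product odds ratio with the Woolf (log-Wald) interval.

    When any cell is zero the interval (and the estimate shown with it)
    uses the Haldane-Anscombe 0.5 continuity correction; an all-informative
    zero numerator/denominator yields 0 or infinity.
    """
    from scipy.stats import norm

    a, b, c, d = table.a, table.b, table.c, table.d
    z = norm.ppf(1 - (1 - confidence) / 2)
    if min(a, b, c, d) == 0:
        if a + c == 0 or (a == 0 and d == 0) or (b == 0 and c == 0):
            # no information about the odds ratio direction at all
            if a * d == 0 and b * c == 0:
                return math.nan, (0.0, math.inf)
        a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        est = math.inf if b * c == 0 and a * d > 0 else (
            0.0 if a * d == 0 else a * d / (b * c)
        )
        se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
        centre = a_ * d_ / (b_ * c_)
        return est, (centre * math.exp(-z * se), centre * math.exp(z * se))
    est = a * d / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return est, (est * math.exp(-z * se), est * math.exp(z * se))


def _odds_ratio(table: ContingencyTable, ci_method: CIMethod):
    if ci_method == "conditional":
        return odds_ratio_cmle(table)
    if ci_method == "wald":
        return odds_ratio_wald(table)
    raise ValueError(f"unknown ci_method {ci_method!r}")


def _check_disjoint(case_ids: Sequence[str], control_ids: Sequence[str]) -> None:
    overlap = set(case_ids) & set(control_ids)
    if overlap:
        raise ValueError(
            f"samples in both case and control lists: {sorted(overlap)[:10]}"
        )


def qualifying_variants(
    gene: str, variants: Iterable[AnnotatedVariant], cfg: FilterConfig
) -> list[AnnotatedVariant]:
    """Protein-altering variants of `gene` passing the frequency filter."""
    return [
        v
        for v in variants
        if v.gene == gene
        and is_protein_altering(v.functional_class)
        and passes_frequency_filter(v, cfg)
    ]


def aggregate_gene_carriers(
    gene: str,
    variants: Iterable[AnnotatedVariant],
    genotypes: GenotypeTable,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    cfg: FilterConfig,
) -> ContingencyTable:
    """Collapse qualifying variants of one gene into a 2x2 carrier table.

    An individual carrying any number of qualifying alleles counts once.
    Missing genotypes count as non-carrier: burden samples were sequenced,
    so sporadic missingness should not inflate carrier counts (this is the
    opposite of the conservative segregation policy, deliberately).
    """
    _check_disjoint(case_ids, control_ids)
    keys = [
        v.key
        for v in qualifying_variants(gene, variants, cfg)
        if genotypes.has_variant(v.key)
    ]
    a = int(genotypes.carrier_mask(keys, case_ids).sum())
    c = int(genotypes.carrier_mask(keys, control_ids).sum())
    return ContingencyTable(a=a, b=len(case_ids) - a, c=c,
                            d=len(control_ids) - c)


def _allele_table(
    keys: Sequence[str],
    genotypes: GenotypeTable,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
) -> ContingencyTable:
    def alt_alleles(samples: Sequence[str]) -> int:
        total = 0
        for k in keys:
            for s in samples:
                cnt = genotypes.get(s, k)
                if not math.isnan(cnt):
                    total += int(cnt)
        return total

    a = alt_alleles(case_ids)
    c = alt_alleles(control_ids)
    return ContingencyTable(a=a, b=2 * len(case_ids) - a, c=c,
                            d=2 * len(control_ids) - c)


def burden_test(
    table: ContingencyTable,
    gene: str = "",
    n_variants: int = 0,
    ci_method: CIMethod = "conditional",
) -> BurdenResult:
    """Fisher one-sided p plus odds ratio/CI for a prepared carrier table."""
    estimate, ci = _odds_ratio(table, ci_method)
    return BurdenResult(
        gene=gene,
        table=table,
        p_one_sided=fisher_one_sided(table),
        or_cmle=estimate,
        ci95=ci,
        n_variants=n_variants,
    )


def per_variant_test(
    variant: AnnotatedVariant,
    genotypes: GenotypeTable,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    ci_method: CIMethod = "conditional",
) -> BurdenResult:
    """Single-variant carrier table test (same machinery as the gene burden)."""
    _check_disjoint(case_ids, control_ids)
    keys = [variant.key] if genotypes.has_variant(variant.key) else []
    a = int(genotypes.carrier_mask(keys, case_ids).sum())
    c = int(genotypes.carrier_mask(keys, control_ids).sum())
    table = ContingencyTable(a=a, b=len(case_ids) - a, c=c,
                             d=len(control_ids) - c)
    return burden_test(table, gene=variant.gene, n_variants=1,
                       ci_method=ci_method)


def compare_to_reference_af(
    case_carriers: int,
    n_cases: int,
    ref_af: float,
    ref_n_alleles: int,
    ci_method: CIMethod = "conditional",
) -> BurdenResult:
    """Compare case carriers against an external reference allele frequency.

    The reference panel is reconstructed as round(ref_af * ref_n_alleles)
    alt alleles out of ``ref_n_alleles``; case carriers are treated as
    heterozygous so the case side contributes one alt allele per carrier
    out of ``2 * n_cases`` alleles, and the usual Fisher machinery runs on
    the resulting allele-count table.
    """
    if not (0.0 <= ref_af <= 1.0):
        raise ValueError(f"reference allele frequency outside [0,1]: {ref_af}")
    if case_carriers > n_cases:
        raise ValueError("more case carriers than cases")
    ref_alt = round(ref_af * ref_n_alleles)
    table = ContingencyTable(
        a=case_carriers,
        b=2 * n_cases - case_carriers,
        c=ref_alt,
        d=ref_n_alleles - ref_alt,
    )
    return burden_test(table, gene="", n_variants=1, ci_method=ci_method)


def run_burden_scan(
    genes: Sequence[str],
    variants: Iterable[AnnotatedVariant],
    genotypes: GenotypeTable,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    cfg: FilterConfig,
    count_mode: Literal["carrier", "allele"] = "carrier",
    ci_method: CIMethod = "conditional",
) -> list[BurdenResult]:
    """One burden test per gene, Bonferroni-adjusted over the panel size,
    sorted by p (an extension over the raw per-gene p-values)."""
    _check_disjoint(case_ids, control_ids)
    variants = list(variants)
    results = []
    m = len(genes)
    for gene in genes:
        quals = [
            v for v in qualifying_variants(gene, variants, cfg)
            if genotypes.has_variant(v.key)
        ]
        keys = [v.key for v in quals]
        if count_mode == "carrier":
            a = int(genotypes.carrier_mask(keys, case_ids).sum())
            c = int(genotypes.carrier_mask(keys, control_ids).sum())
            table = ContingencyTable(a=a, b=len(case_ids) - a, c=c,
                                     d=len(control_ids) - c)
        elif count_mode == "allele":
            table = _allele_table(keys, genotypes, case_ids, control_ids)
        else:
            raise ValueError(f"unknown count_mode {count_mode!r}")
        base = burden_test(table, gene=gene, n_variants=len(quals),
                           ci_method=ci_method)
        results.append(
            BurdenResult(
                gene=base.gene,
                table=base.table,
                p_one_sided=base.p_one_sided,
                or_cmle=base.or_cmle,
                ci95=base.ci95,
                n_variants=base.n_variants,
                p_bonferroni=min(1.0, base.p_one_sided * m),
            )
        )
    results.sort(key=lambda r: (r.p_one_sided, r.gene))
    return results
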