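"""Multistep prioritization of variants of interest (VOIs) in multiplex
families.

A VOI is a variant that survives three successive predicates, applied in
order but mutually independent:

1. functional-class filter — keep protein-altering classes only
   (nonsynonymous, splice, stop gain, stop loss);
2. frequency filter — in ``private`` mode the variant must be absent from
   all interrogated population databases (dbSNP, 1000 Genomes European,
   ESP European-American); in ``rare`` mode its reference-panel allele
   frequency must be below the configured threshold;
3. segregation filter — every affected member of the family must carry at
   least one copy.

Deleteriousness scores (SIFT, PolyPhen-2, GERP, CADD) are carried through
for reporting but never filtered on.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .types import (
    AnnotatedVariant,
    FilterConfig,
    FilterMode,
    FunctionalClass,
    GenotypeTable,
    MissingAffectedPolicy,
    Pedigree,
    PROTEIN_ALTERING,
    UnknownDbFlagPolicy,
    VOIRecord,
)


class SegregationError(ValueError):
    """An affected family member is missing from the genotype table."""


def is_protein_altering(functional_class: FunctionalClass) -> bool:
    """True for nonsynonymous, splice, stop-gain and stop-loss variants."""
    return functional_class in PROTEIN_ALTERING


def is_private(variant: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """Absent from dbSNP, 1KG European and ESP European-American.

    Tri-state flags: under ``treat_absent`` an unknown flag counts as
    absent; under ``fail_variant`` any unknown flag disqualifies.
    """
    flags = (variant.in_dbsnp, variant.in_1kg_eur, variant.in_esp_ea)
    if any(f is True for f in flags):
        return False
    if cfg.unknown_db_flag_policy is UnknownDbFlagPolicy.FAIL_VARIANT:
        return not any(f is None for f in flags)
    return True


def is_rare(variant: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """Reference allele frequency strictly below the threshold.

    A missing frequency means the allele was not observed in the panel and
    counts as rare.
    """
    af = variant.af_1kg_eur
    if af is None:
        return True
    return af < cfg.rare_af_threshold


def passes_frequency_filter(variant: AnnotatedVariant, cfg: FilterConfig) -> bool:
    if cfg.mode is FilterMode.PRIVATE:
        return is_private(variant, cfg)
    return is_rare(variant, cfg)


def segregates_in_family(
    variant: AnnotatedVariant,
    genotypes: GenotypeTable,
    pedigree: Pedigree,
    cfg: FilterConfig,
) -> bool:
    """True iff every affected member carries >= 1 alt allele.

    A missing genotype in an affected member fails the variant under the
    default ``fail_variant`` policy, or drops that individual from the
    requirement under ``ignore_individual``.  An affected member absent
    from the genotype table altogether is a hard error.
    """
    affected = pedigree.affected_ids
    if not affected:
        return False
    for iid in affected:
        if not genotypes.has_sample(iid):
            raise SegregationError(
                f"affected individual {iid} (family {pedigree.family_id}) "
                "not in genotype table"
            )
    seen_any = False
    for iid in affected:
        count = genotypes.get(iid, variant.key)
        if math.isnan(count):
            if cfg.missing_affected_policy is MissingAffectedPolicy.FAIL_VARIANT:
                return False
            continue  # ignore_individual
        if count < 1:
            return False
        seen_any = True
    return seen_any


@dataclass(frozen=True)
class GeneFamilyCount:
    gene: str
    n_families: int
    family_ids: tuple[str, ...]

    @property
    def shared(self) -> bool:
        """Gene carries a VOI in more than one family."""
        return self.n_families > 1


def identify_vois(
    cohort: Sequence[tuple[Pedigree, GenotypeTable]],
    variants: Iterable[AnnotatedVariant],
    cfg: FilterConfig,
) -> tuple[list[VOIRecord], dict[str, int], list[GeneFamilyCount]]:
    """Run the three-stage filter over every family.

    Returns the VOI records sorted by (family, chrom, pos), the per-family
    VOI counts (zero included), and per-gene counts of distinct families,
    flagging genes seen in more than one family.  A variant shared by
    several families yields one record per family.
    """
    variants = list(variants)
    candidates = [
        v
        for v in variants
        if is_protein_altering(v.functional_class)
        and passes_frequency_filter(v, cfg)
    ]
    records: list[VOIRecord] = []
    per_family: dict[str, int] = {}
    for pedigree, genotypes in cohort:
        fam_records = []
        for v in candidates:
            if not genotypes.has_variant(v.key):
                continue
            if segregates_in_family(v, genotypes, pedigree, cfg):
                carriers = tuple(
                    iid
                    for iid in pedigree.affected_ids
                    if not math.isnan(genotypes.get(iid, v.key))
                    and genotypes.get(iid, v.key) >= 1
                )
                fam_records.append(
                    VOIRecord(variant=v, family_id=pedigree.family_id,
                              carriers=carriers)
                )
        fam_records.sort(key=lambda r: (r.variant.chrom, r.variant.pos,
                                        r.variant.ref, r.variant.alt))
        records.extend(fam_records)
        per_family[pedigree.family_id] = len(fam_records)

    gene_families: dict[str, set[str]] = {}
    for r in records:
        gene_families.setdefault(r.variant.gene, set()).add(r.family_id)
    gene_counts = [
        GeneFamilyCount(gene=g, n_families=len(fams),
                        family_ids=tuple(sorted(fams)))
        for g, fams in sorted(gene_families.items())
    ]
    records.sort(key=lambda r: (r.family_id, r.variant.chrom, r.variant.pos,
                                r.variant.ref, r.variant.alt))
    return records, per_family, gene_counts
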