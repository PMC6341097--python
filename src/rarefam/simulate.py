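"""Synthetic pedigrees, cohorts and transmission data with recorded ground
truth.

The generator emulates the statistical structure of a familial
rare-variant study: multiplex three-generation families ascertained for an
affected first-cousin pair, an unrelated case-control cohort with one gene
carrying an excess of rare heterozygous protein-altering variants in
cases, and Bernoulli transmission events to affected siblings.  Every
dataset records its planted features (GroundTruth) so pipeline stages can
be validated exactly.

Default study conditions: 26 families, 1004 cases vs 1127 controls, a
13-gene panel with one planted risk gene, 37 sibling transmission events.
A single global seed is split into independent per-stage streams so stages
can be re-run in isolation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .types import (
    Affection,
    AnnotatedVariant,
    FunctionalClass,
    GeneSet,
    GenotypeTable,
    Individual,
    Pedigree,
    Sex,
    TransmissionEvent,
)

#: gene panel used by the default cohort simulation (13 candidate genes,
#: the first one carries the planted signal)
DEFAULT_PANEL = (
    "CEP41", "BAI2", "CEP250", "CEP78", "DCDC2", "NFATC1", "NTAN1",
    "SCN10A", "SH3BP4", "SNPH", "SPATA3", "TMEM82", "ZNF638",
)

FamilyStructure = Literal["first_cousin_pair", "cousin_pair_plus_sibs"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generator.

    The planted carrier rates default to 18/1004 (cases) and 2/1127
    (controls) — the magnitude of signal the case-control stage is built
    to detect.  Background variants are rare (default panel frequency
    2e-3) and identically distributed in both arms.
    """

    seed: int = 0
    n_families: int = 26
    family_structure: FamilyStructure = "cousin_pair_plus_sibs"
    n_cases: int = 1004
    n_controls: int = 1127
    n_genes: int = 13
    planted_gene: str = "CEP41"
    planted_case_carrier_rate: float = 18 / 1004
    planted_control_carrier_rate: float = 2 / 1127
    n_planted_variants: int = 8
    background_rare_af: float = 0.002
    n_background_variants_per_gene: int = 8
    transmission_prob: float = 0.5
    n_sibling_events: int = 37

    def __post_init__(self) -> None:
        for name in ("planted_case_carrier_rate", "planted_control_carrier_rate",
                     "background_rare_af", "transmission_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("n_families", "n_cases", "n_controls", "n_genes",
                     "n_planted_variants", "n_background_variants_per_gene",
                     "n_sibling_events"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def genes(self) -> tuple[str, ...]:
        base = [self.planted_gene]
        pool = [g for g in DEFAULT_PANEL if g != self.planted_gene]
        for i in itertools.count(2):
            if len(base) >= self.n_genes:
                break
            base.append(pool.pop(0) if pool else f"GENE{i:03d}")
        return tuple(base[: self.n_genes])


@dataclass
class GroundTruth:
    """Planted features of a synthetic dataset, for exact validation."""

    planted_vois: list[tuple[str, str, tuple[str, ...]]] = field(default_factory=list)
    decoy_keys: list[tuple[str, str]] = field(default_factory=list)
    planted_gene: str | None = None
    case_carriers: tuple[str, ...] = ()
    control_carriers: tuple[str, ...] = ()
    transmissions: tuple[bool, ...] = ()


def rng_streams(seed: int, names: Sequence[str] = (
        "pedigree", "cohort", "transmissions", "gene_sets")) -> dict[str, np.random.Generator]:
    """Split one global seed into named independent generator streams."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


# ---------------------------------------------------------------------------
# pedigree structure and gene dropping


def simulate_pedigree(
    family_id: str,
    structure: FamilyStructure = "first_cousin_pair",
) -> Pedigree:
    """Three-generation multiplex family with two affected first cousins.

    Layout: one shared grandparental couple, their two children each
    married to an unrelated founder spouse, and one affected child per
    nuclear family (the cousin pair).  ``cousin_pair_plus_sibs`` adds one
    affected sibling to each cousin.
    """
    f = family_id
    members = [
        Individual(f"{f}_gpf", f, sex=Sex.MALE, affected=Affection.UNAFFECTED),
        Individual(f"{f}_gpm", f, sex=Sex.FEMALE, affected=Affection.UNAFFECTED),
        Individual(f"{f}_p1", f, father_id=f"{f}_gpf", mother_id=f"{f}_gpm",
                   sex=Sex.MALE, affected=Affection.UNAFFECTED),
        Individual(f"{f}_s1", f, sex=Sex.FEMALE, affected=Affection.UNAFFECTED),
        Individual(f"{f}_p2", f, father_id=f"{f}_gpf", mother_id=f"{f}_gpm",
                   sex=Sex.FEMALE, affected=Affection.UNAFFECTED),
        Individual(f"{f}_s2", f, sex=Sex.MALE, affected=Affection.UNAFFECTED),
        Individual(f"{f}_c1", f, father_id=f"{f}_p1", mother_id=f"{f}_s1",
                   sex=Sex.MALE, affected=Affection.AFFECTED),
        Individual(f"{f}_c2", f, father_id=f"{f}_s2", mother_id=f"{f}_p2",
                   sex=Sex.FEMALE, affected=Affection.AFFECTED),
    ]
    if structure == "cousin_pair_plus_sibs":
        members += [
            Individual(f"{f}_c1s", f, father_id=f"{f}_p1", mother_id=f"{f}_s1",
                       sex=Sex.FEMALE, affected=Affection.AFFECTED),
            Individual(f"{f}_c2s", f, father_id=f"{f}_s2", mother_id=f"{f}_p2",
                       sex=Sex.MALE, affected=Affection.AFFECTED),
        ]
    elif structure != "first_cousin_pair":
        raise ValueError(f"unsupported family structure {structure!r}")
    return Pedigree(family_id=family_id, members=members)


def _topological_members(ped: Pedigree) -> list[Individual]:
    placed: set[str] = set()
    ordered: list[Individual] = []
    remaining = list(ped.members)
    while remaining:
        progress = False
        for m in list(remaining):
            parents = [p for p in (m.father_id, m.mother_id) if p is not None]
            if all(p in placed for p in parents):
                ordered.append(m)
                placed.add(m.individual_id)
                remaining.remove(m)
                progress = True
        if not progress:  # cycle — Pedigree validation should prevent this
            raise RuntimeError("pedigree is not acyclic")
    return ordered


def gene_drop(
    ped: Pedigree, rng: np.random.Generator, n_replicates: int = 1
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Drop founder alleles through the pedigree by Mendelian transmission.

    Each founder receives two unique integer allele labels; every meiosis
    passes one of the parent's two alleles with probability 1/2,
    independently across meioses and replicates.  Returns, per individual,
    the (paternal-slot, maternal-slot) allele-label arrays of shape
    ``(n_replicates,)``.
    """
    alleles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    next_label = 0
    for m in _topological_members(ped):
        slots = []
        for parent_id in (m.father_id, m.mother_id):
            if parent_id is None:
                slots.append(np.full(n_replicates, next_label))
                next_label += 1
            else:
                pa, pb = alleles[parent_id]
                pick = rng.integers(0, 2, size=n_replicates).astype(bool)
                slots.append(np.where(pick, pa, pb))
        alleles[m.individual_id] = (slots[0], slots[1])
    return alleles


def founder_allele_labels(ped: Pedigree) -> dict[str, tuple[int, int]]:
    """Allele labels assigned to each founder by :func:`gene_drop` (the
    labelling is deterministic in member order)."""
    labels: dict[str, tuple[int, int]] = {}
    next_label = 0
    for m in _topological_members(ped):
        pair = []
        for parent_id in (m.father_id, m.mother_id):
            if parent_id is None:
                pair.append(next_label)
                next_label += 1
        if m.is_founder:
            labels[m.individual_id] = (pair[0], pair[1])
    return labels


def cousin_coinheritance_rate(
    n_replicates: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo estimate of the probability that both first cousins
    inherit one specific allele of a shared grandparent (analytically
    1/16: each cousin receives it with probability 1/4, independently)."""
    ped = simulate_pedigree("MC", structure="first_cousin_pair")
    marked = founder_allele_labels(ped)["MC_gpf"][0]
    alleles = gene_drop(ped, rng, n_replicates)
    def carries(iid: str) -> np.ndarray:
        a, b = alleles[iid]
        return (a == marked) | (b == marked)
    both = carries("MC_c1") & carries("MC_c2")
    return float(both.mean())


# ---------------------------------------------------------------------------
# family VOI planting


def _ancestors(ped: Pedigree, iid: str) -> set[str]:
    out: set[str] = set()
    stack = [iid]
    while stack:
        m = ped.member(stack.pop())
        for pid in (m.father_id, m.mother_id):
            if pid is not None and pid not in out:
                out.add(pid)
                stack.append(pid)
    return out


def _path_to_ancestor(ped: Pedigree, iid: str, ancestor: str) -> list[str]:
    """One parent chain from `iid` up to `ancestor` (inclusive)."""
    chain = [iid]
    current = iid
    while current != ancestor:
        m = ped.member(current)
        nxt = None
        for pid in (m.father_id, m.mother_id):
            if pid is not None and (pid == ancestor or ancestor in _ancestors(ped, pid)):
                nxt = pid
                break
        if nxt is None:
            raise ValueError(f"{ancestor} is not an ancestor of {iid}")
        chain.append(nxt)
        current = nxt
    return chain


def plant_family_voi(
    ped: Pedigree,
    gene: str,
    chrom: str = "7",
    pos: int = 130_000_000,
    functional_class: FunctionalClass = FunctionalClass.NONSYNONYMOUS,
    private: bool = True,
) -> tuple[AnnotatedVariant, dict[str, float]]:
    """Insert a heterozygous variant carried by every affected member.

    The variant is introduced on a shared founder path: a common founder
    ancestor of all affected members carries it, and it is transmitted
    along one lineage chain to each affected individual, so segregation is
    Mendelian-consistent.  Raises when no founder is a common ancestor of
    all affecteds.
    """
    affected = ped.affected_ids
    if not affected:
        raise ValueError(f"family {ped.family_id} has no affected members")
    common: set[str] | None = None
    for iid in affected:
        anc = _ancestors(ped, iid) | {iid}
        common = anc if common is None else common & anc
    founder_ids = {m.individual_id for m in ped.founders}
    shared_founders = sorted((common or set()) & founder_ids)
    if not shared_founders:
        raise ValueError(
            f"family {ped.family_id}: no founder is a common ancestor of all "
            "affected members"
        )
    source = shared_founders[0]
    carriers: set[str] = set()
    for iid in affected:
        carriers |= set(_path_to_ancestor(ped, iid, source))
    variant = AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref="C",
        alt="G",
        gene=gene,
        functional_class=functional_class,
        in_dbsnp=not private,
        in_1kg_eur=False,
        in_esp_ea=False,
        af_1kg_eur=None if private else 0.05,
    )
    genotypes = {
        m.individual_id: (1.0 if m.individual_id in carriers else 0.0)
        for m in ped.members
    }
    return variant, genotypes


def simulate_families(
    cfg: SimConfig,
    rng: np.random.Generator,
    include_decoys: bool = True,
) -> tuple[list[tuple[Pedigree, GenotypeTable]], list[AnnotatedVariant], GroundTruth]:
    """Generate the multiplex-family arm of the study.

    Each family receives exactly one planted qualifying VOI in a
    family-specific gene; with ``include_decoys`` it also receives
    non-qualifying controls: a private synonymous segregating variant, a
    database-known protein-altering segregating variant, and a private
    protein-altering variant carried by only one affected member.  None of
    the decoys should survive the VOI filter.
    """
    truth = GroundTruth()
    cohort: list[tuple[Pedigree, GenotypeTable]] = []
    variants: dict[str, AnnotatedVariant] = {}
    for i in range(cfg.n_families):
        fam = f"FAM{i + 1:02d}"
        ped = simulate_pedigree(fam, cfg.family_structure)
        gene = f"VOIGENE{i + 1:02d}"
        base_pos = 1_000_000 * (i + 1)
        voi, gts = plant_family_voi(ped, gene, chrom=str(i % 22 + 1),
                                    pos=base_pos)
        fam_variants = [voi]
        fam_genotypes = [gts]
        truth.planted_vois.append(
            (fam, voi.key, tuple(sorted(set(ped.affected_ids)
                                        & {k for k, v in gts.items() if v >= 1})))
        )
        if include_decoys:
            syn, syn_gts = plant_family_voi(
                ped, gene, chrom=str(i % 22 + 1), pos=base_pos + 10,
                functional_class=FunctionalClass.SYNONYMOUS,
            )
            known, known_gts = plant_family_voi(
                ped, gene, chrom=str(i % 22 + 1), pos=base_pos + 20,
                private=False,
            )
            partial = AnnotatedVariant(
                chrom=str(i % 22 + 1), pos=base_pos + 30, ref="C", alt="G",
                gene=gene, functional_class=FunctionalClass.NONSYNONYMOUS,
                in_dbsnp=False, in_1kg_eur=False, in_esp_ea=False,
            )
            first_affected = ped.affected_ids[0]
            partial_gts = {
                m.individual_id: (1.0 if m.individual_id == first_affected else 0.0)
                for m in ped.members
            }
            fam_variants += [syn, known, partial]
            fam_genotypes += [syn_gts, known_gts, partial_gts]
            truth.decoy_keys += [(fam, syn.key), (fam, known.key),
                                 (fam, partial.key)]
        sample_ids = [m.individual_id for m in ped.members]
        counts = np.array(
            [[g[s] for s in sample_ids] for g in fam_genotypes]
        )
        table = GenotypeTable([v.key for v in fam_variants], sample_ids, counts)
        cohort.append((ped, table))
        for v in fam_variants:
            variants[v.key] = v
    return cohort, list(variants.values()), truth


# ---------------------------------------------------------------------------
# case-control cohort


def simulate_cohort(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[AnnotatedVariant], GenotypeTable, list[str], list[str], GroundTruth]:
    """Unrelated case-control cohort over the gene panel.

    Carrier status in the planted gene is Bernoulli per individual at the
    configured case/control rates, all carriers heterozygous for exactly
    one of the planted variants (chosen uniformly).  Background genes
    carry rare variants with identical per-individual heterozygote
    probability ``2 * background_rare_af`` in both arms (null genes).
    """
    case_ids = [f"case_{i + 1:04d}" for i in range(cfg.n_cases)]
    control_ids = [f"control_{i + 1:04d}" for i in range(cfg.n_controls)]
    samples = case_ids + control_ids
    variants: list[AnnotatedVariant] = []
    rows: list[np.ndarray] = []

    # planted signal gene
    planted_variants = [
        AnnotatedVariant(
            chrom="7",
            pos=130_000_000 + 100 * j,
            ref="C",
            alt="T",
            gene=cfg.planted_gene,
            functional_class=FunctionalClass.NONSYNONYMOUS,
            in_dbsnp=False, in_1kg_eur=False, in_esp_ea=False,
            af_1kg_eur=None,
        )
        for j in range(cfg.n_planted_variants)
    ]
    n_samp = len(samples)
    planted_counts = np.zeros((cfg.n_planted_variants, n_samp))
    carrier_rates = np.concatenate(
        [np.full(cfg.n_cases, cfg.planted_case_carrier_rate),
         np.full(cfg.n_controls, cfg.planted_control_carrier_rate)]
    )
    is_carrier = rng.random(n_samp) < carrier_rates
    which = rng.integers(0, max(cfg.n_planted_variants, 1), size=n_samp)
    for j in np.nonzero(is_carrier)[0]:
        planted_counts[which[j], j] = 1.0
    variants += planted_variants
    rows.append(planted_counts)

    # null background genes
    for g_index, gene in enumerate(cfg.genes):
        if gene == cfg.planted_gene:
            continue
        for j in range(cfg.n_background_variants_per_gene):
            variants.append(
                AnnotatedVariant(
                    chrom=str(g_index % 22 + 1),
                    pos=5_000_000 * (g_index + 1) + 100 * j,
                    ref="G",
                    alt="A",
                    gene=gene,
                    functional_class=FunctionalClass.NONSYNONYMOUS,
                    in_dbsnp=True, in_1kg_eur=True, in_esp_ea=True,
                    af_1kg_eur=cfg.background_rare_af,
                )
            )
        het_p = min(1.0, 2 * cfg.background_rare_af)
        block = (
            rng.random((cfg.n_background_variants_per_gene, n_samp)) < het_p
        ).astype(float)
        rows.append(block)

    counts = np.vstack(rows) if rows else np.empty((0, n_samp))
    table = GenotypeTable([v.key for v in variants], samples, counts)
    case_carriers = tuple(
        s for s, flag in zip(case_ids, is_carrier[: cfg.n_cases]) if flag
    )
    control_carriers = tuple(
        s for s, flag in zip(control_ids, is_carrier[cfg.n_cases:]) if flag
    )
    truth = GroundTruth(
        planted_gene=cfg.planted_gene,
        case_carriers=case_carriers,
        control_carriers=control_carriers,
    )
    return variants, table, case_ids, control_ids, truth


# ---------------------------------------------------------------------------
# sibling transmissions


def simulate_transmissions(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[TransmissionEvent], GroundTruth]:
    """Bernoulli(transmission_prob) transmission events to affected sibs."""
    draws = rng.random(cfg.n_sibling_events) < cfg.transmission_prob
    events = [
        TransmissionEvent(
            family_id=f"TFAM{i + 1:02d}",
            sibling_id=f"TFAM{i + 1:02d}_sib",
            variant_key=f"7:130041748:G:C",
            transmitted=bool(t),
        )
        for i, t in enumerate(draws)
    ]
    return events, GroundTruth(transmissions=tuple(bool(t) for t in draws))


# ---------------------------------------------------------------------------
# gene sets


def simulate_gene_sets(
    rng: np.random.Generator,
    n_sets: int = 300,
    universe_size: int = 5000,
    size_range: tuple[int, int] = (400, 1600),
) -> list[GeneSet]:
    """Random gene-set collection over a synthetic symbol universe."""
    universe = np.array([f"SYN{i + 1:05d}" for i in range(universe_size)])
    sets = []
    for i in range(n_sets):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = rng.choice(universe, size=min(size, universe_size),
                             replace=False)
        sets.append(
            GeneSet(set_id=f"SET{i + 1:04d}", name=f"synthetic set {i + 1}",
                    members=frozenset(members.tolist()))
        )
    return sets


def simulate_enrichment_input(
    gene_sets: Sequence[GeneSet],
    planted_set_id: str,
    n_input_genes: int,
    rng: np.random.Generator,
    overrepresentation: float = 3.0,
) -> list[str]:
    """Draw an input gene list over-representing one planted set.

    Members of the planted set receive ``overrepresentation`` times the
    sampling weight of other universe genes; sampling is without
    replacement.
    """
    universe = sorted({g for gs in gene_sets for g in gs.members})
    planted = next(gs for gs in gene_sets if gs.set_id == planted_set_id)
    weights = np.array(
        [overrepresentation if g in planted.members else 1.0 for g in universe]
    )
    weights = weights / weights.sum()
    chosen = rng.choice(len(universe), size=n_input_genes, replace=False,
                        p=weights)
    return [universe[i] for i in chosen]
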