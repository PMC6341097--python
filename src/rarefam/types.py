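"""Core domain types shared by every stage of the pipeline.

The analysis revolves around a handful of small value objects: pedigree
members, annotated variants, a genotype matrix, gene sets, and the result
records each statistical stage emits.  All of them are plain dataclasses so
they serialize naturally to the TSV outputs the pipeline writes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class FunctionalClass(enum.Enum):
    """Consequence category of a coding/near-coding variant.

    Protein-altering classes (nonsynonymous, splice, stop gain, stop loss)
    are the ones retained by the qualifying-variant filters; the rest exist
    so that input annotation rows can be represented without loss.
    """

    NONSYNONYMOUS = "nonsynonymous"
    SPLICE = "splice"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    SYNONYMOUS = "synonymous"
    UTR = "utr"
    INTRONIC_NONSPLICE = "intronic_nonsplice"
    INTERGENIC = "intergenic"
    OTHER = "other"


#: classes kept by the protein-altering filter
PROTEIN_ALTERING = frozenset(
    {
        FunctionalClass.NONSYNONYMOUS,
        FunctionalClass.SPLICE,
        FunctionalClass.STOP_GAIN,
        FunctionalClass.STOP_LOSS,
    }
)


class PedigreeError(ValueError):
    """Structural problem in a pedigree (unknown parent, ancestry cycle...)."""


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    affected: Affection = Affection.UNKNOWN

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """One family: a list of members with validated parent links."""

    family_id: str
    members: list[Individual]

    def __post_init__(self) -> None:
        ids = [m.individual_id for m in self.members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(
                f"family {self.family_id}: duplicate individual ids {dupes}"
            )
        known = set(ids)
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in known:
                    raise PedigreeError(
                        f"family {self.family_id}: {m.individual_id} references "
                        f"absent parent {pid}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = {
            m.individual_id: [p for p in (m.father_id, m.mother_id) if p is not None]
            for m in self.members
        }
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {i: WHITE for i in parents}
        for start in parents:
            if colour[start] != WHITE:
                continue
            stack: list[tuple[str, int]] = [(start, 0)]
            colour[start] = GREY
            while stack:
                node, idx = stack[-1]
                if idx < len(parents[node]):
                    stack[-1] = (node, idx + 1)
                    nxt = parents[node][idx]
                    if colour[nxt] == GREY:
                        raise PedigreeError(
                            f"family {self.family_id}: {nxt} is its own ancestor"
                        )
                    if colour[nxt] == WHITE:
                        colour[nxt] = GREY
                        stack.append((nxt, 0))
                else:
                    colour[node] = BLACK
                    stack.pop()

    def member(self, individual_id: str) -> Individual:
        for m in self.members:
            if m.individual_id == individual_id:
                return m
        raise KeyError(f"{individual_id} not in family {self.family_id}")

    @property
    def affected_ids(self) -> list[str]:
        return [m.individual_id for m in self.members if m.affected is Affection.AFFECTED]

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    def children_of(self, parent_id: str) -> list[Individual]:
        return [
            m for m in self.members if parent_id in (m.father_id, m.mother_id)
        ]

    def siblings_of(self, individual_id: str) -> list[Individual]:
        """Full siblings: both parents shared and non-null."""
        me = self.member(individual_id)
        if me.father_id is None or me.mother_id is None:
            return []
        return [
            m
            for m in self.members
            if m.individual_id != individual_id
            and m.father_id == me.father_id
            and m.mother_id == me.mother_id
        ]


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass(frozen=True)
class AnnotatedVariant:
    """A single bi-allelic variant with its functional annotation.

    Database-presence flags are tri-state (True / False / None=unknown) so
    the private-variant filter can treat missingness explicitly.  Positions
    follow the VCF convention (1-based).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    functional_class: FunctionalClass
    in_dbsnp: bool | None = None
    in_1kg_eur: bool | None = None
    in_esp_ea: bool | None = None
    af_1kg_eur: float | None = None
    sift: float | None = None
    polyphen2: float | None = None
    gerp: float | None = None
    cadd_phred: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.af_1kg_eur is not None and not (0.0 <= self.af_1kg_eur <= 1.0):
            raise ValueError(f"allele frequency outside [0,1]: {self.af_1kg_eur}")

    @property
    def key(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)


class GenotypeTable:
    """Allele-count matrix: variants x samples, values in {0,1,2} or missing.

    Backed by a float ndarray with NaN for missing calls; row/column lookup
    is by variant key and sample id.
    """

    def __init__(self, variant_keys: Sequence[str], sample_ids: Sequence[str],
                 counts: np.ndarray | None = None) -> None:
        self._vidx = {k: i for i, k in enumerate(variant_keys)}
        self._sidx = {s: j for j, s in enumerate(sample_ids)}
        if len(self._vidx) != len(variant_keys):
            raise ValueError("duplicate variant keys")
        if len(self._sidx) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        shape = (len(variant_keys), len(sample_ids))
        if counts is None:
            counts = np.full(shape, np.nan)
        counts = np.asarray(counts, dtype=float)
        if counts.shape != shape:
            raise ValueError(f"counts shape {counts.shape} != {shape}")
        valid = np.isnan(counts) | np.isin(counts, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = counts[~valid][0]
            raise ValueError(f"allele counts must be 0/1/2 or missing, got {bad}")
        self.counts = counts

    @property
    def variant_keys(self) -> list[str]:
        return list(self._vidx)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._sidx)

    def get(self, sample_id: str, key: str) -> float:
        """Allele count, NaN when missing."""
        return float(self.counts[self._vidx[key], self._sidx[sample_id]])

    def set(self, sample_id: str, key: str, count: float) -> None:
        if not (math.isnan(count) or count in (0.0, 1.0, 2.0)):
            raise ValueError(f"invalid allele count {count}")
        self.counts[self._vidx[key], self._sidx[sample_id]] = count

    def has_variant(self, key: str) -> bool:
        return key in self._vidx

    def has_sample(self, sample_id: str) -> bool:
        return sample_id in self._sidx

    def carrier_mask(self, keys: Iterable[str], samples: Sequence[str],
                     missing_as_noncarrier: bool = True) -> np.ndarray:
        """Boolean vector over `samples`: carries >=1 alt allele at any key.

        Missing genotypes count as non-carrier when
        ``missing_as_noncarrier`` (the burden convention).
        """
        rows = [self._vidx[k] for k in keys]
        cols = [self._sidx[s] for s in samples]
        if not rows:
            return np.zeros(len(cols), dtype=bool)
        sub = self.counts[np.ix_(rows, cols)]
        if missing_as_noncarrier:
            sub = np.nan_to_num(sub, nan=0.0)
        return (sub >= 1).any(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.variant_keys, columns=self.sample_ids
        )


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id} has no members")


# ---------------------------------------------------------------------------
# configuration and result records


class FilterMode(enum.Enum):
    PRIVATE = "private"
    RARE = "rare"


class MissingAffectedPolicy(enum.Enum):
    FAIL_VARIANT = "fail_variant"
    IGNORE_INDIVIDUAL = "ignore_individual"


class UnknownDbFlagPolicy(enum.Enum):
    TREAT_ABSENT = "treat_absent"
    FAIL_VARIANT = "fail_variant"


@dataclass(frozen=True)
class FilterConfig:
    """Qualifying-variant definition.

    ``private`` mode keeps variants absent from all population databases
    (the discovery-stage rule); ``rare`` mode keeps variants with reference
    allele frequency strictly below ``rare_af_threshold`` (the case-control
    stage rule, default 0.01).
    """

    mode: FilterMode = FilterMode.PRIVATE
    rare_af_threshold: float = 0.01
    splice_window: int = 2
    missing_affected_policy: MissingAffectedPolicy = MissingAffectedPolicy.FAIL_VARIANT
    unknown_db_flag_policy: UnknownDbFlagPolicy = UnknownDbFlagPolicy.TREAT_ABSENT

    def __post_init__(self) -> None:
        if not (0.0 < self.rare_af_threshold <= 1.0):
            raise ValueError("rare_af_threshold must be in (0, 1]")
        if self.splice_window < 1:
            raise ValueError("splice_window must be >= 1")


@dataclass(frozen=True)
class VOIRecord:
    """A variant of interest: private, protein-altering, shared by all
    affected members of one family."""

    variant: AnnotatedVariant
    family_id: str
    carriers: tuple[str, ...]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 carrier table: rows case/control, columns carrier/non-carrier."""

    a: int  # case carriers
    b: int  # case non-carriers
    c: int  # control carriers
    d: int  # control non-carriers

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class BurdenResult:
    gene: str
    table: ContingencyTable
    p_one_sided: float
    or_cmle: float  # may be inf; NaN when undefined (no carriers at all)
    ci95: tuple[float, float]
    n_variants: int
    p_bonferroni: float | None = None


@dataclass(frozen=True)
class TransmissionEvent:
    family_id: str
    sibling_id: str
    variant_key: str
    transmitted: bool


@dataclass(frozen=True)
class TDTResult:
    T: int
    U: int
    chi2: float  # NaN when T+U == 0
    p: float
    p_binomial: float | None = None


@dataclass(frozen=True)
class EnrichmentConfig:
    min_set_size: int = 500
    max_set_size: int = 1500
    fdr_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (1 <= self.min_set_size <= self.max_set_size):
            raise ValueError("need 1 <= min_set_size <= max_set_size")


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    name: str
    C: int  # reference genes in the category
    O: int  # observed input genes in the category
    E: float  # expected count under the hypergeometric null
    R: float  # enrichment ratio O/E (NaN when E == 0)
    p: float  # hypergeometric upper-tail probability
    fdr: float | None = None
    overlap_genes: tuple[str, ...] = ()
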