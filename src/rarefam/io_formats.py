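"""Readers and writers for the external formats the pipeline touches.

PED (6-column whitespace), VCF v4.x plus a sidecar annotation TSV, and GMT
gene-set files are normalized into the domain types; every stage's results
go out as TSV with a header row.  Coordinates are 1-based throughout.

The annotation TSV carries one row per bi-allelic variant with columns::

    chrom  pos  ref  alt  gene  functional_class  in_dbsnp  in_1kg_eur
    in_esp_ea  af_1kg_eur  sift  polyphen2  gerp  cadd_phred

Tri-state database flags are encoded ``1`` / ``0`` / ``.`` (unknown);
missing numeric scores are ``.``.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (
    Affection,
    AnnotatedVariant,
    BurdenResult,
    EnrichmentResult,
    FunctionalClass,
    GeneSet,
    GenotypeTable,
    Individual,
    Pedigree,
    Sex,
    TDTResult,
    VOIRecord,
    variant_key,
)


class ParseError(ValueError):
    """A malformed line in an input file (message names the line)."""


class JoinError(ValueError):
    """VCF records could not be matched to annotation rows."""


# ---------------------------------------------------------------------------
# PED

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}
_AFF_CODES = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED,
              "0": Affection.UNKNOWN, "-9": Affection.UNKNOWN}


def read_ped(path: str | Path) -> list[Pedigree]:
    """Parse a 6+-column whitespace-delimited PED file into pedigrees.

    Affection coding: 2 = affected, 1 = unaffected, 0/-9 = unknown.
    Parent id ``0`` means founder.  Structural problems (absent parents,
    an individual that is its own ancestor) raise :class:`PedigreeError`
    from the Pedigree constructor.
    """
    members: dict[str, list[Individual]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 6 columns, got {len(fields)}"
                )
            fam, iid, fat, mot, sex, pheno = fields[:6]
            members.setdefault(fam, []).append(
                Individual(
                    individual_id=iid,
                    family_id=fam,
                    father_id=None if fat == "0" else fat,
                    mother_id=None if mot == "0" else mot,
                    sex=_SEX_CODES.get(sex, Sex.UNKNOWN),
                    affected=_AFF_CODES.get(pheno, Affection.UNKNOWN),
                )
            )
    return [Pedigree(family_id=fam, members=ms) for fam, ms in members.items()]


def write_ped(pedigrees: Iterable[Pedigree], path: str | Path) -> None:
    sex_out = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    aff_out = {Affection.AFFECTED: "2", Affection.UNAFFECTED: "1",
               Affection.UNKNOWN: "0"}
    with open(path, "w") as fh:
        for ped in pedigrees:
            for m in ped.members:
                fh.write(
                    "\t".join(
                        [
                            ped.family_id,
                            m.individual_id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            sex_out[m.sex],
                            aff_out[m.affected],
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# VCF + annotation TSV

ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "functional_class",
    "in_dbsnp", "in_1kg_eur", "in_esp_ea", "af_1kg_eur",
    "sift", "polyphen2", "gerp", "cadd_phred",
]

_X_CHROMS = {"X", "chrX", "x", "chrx"}


def _tri_state(value) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s in (".", "", "NA"):
        return None
    return s in ("1", "1.0", "True", "true")


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s in (".", "", "NA"):
        return None
    return float(s)


def read_annotation(path: str | Path) -> dict[str, AnnotatedVariant]:
    """Annotation TSV -> variant-key -> AnnotatedVariant mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing annotation columns {missing}")
    out: dict[str, AnnotatedVariant] = {}
    for row in df.itertuples(index=False):
        v = AnnotatedVariant(
            chrom=row.chrom,
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            gene=row.gene,
            functional_class=FunctionalClass(row.functional_class),
            in_dbsnp=_tri_state(row.in_dbsnp),
            in_1kg_eur=_tri_state(row.in_1kg_eur),
            in_esp_ea=_tri_state(row.in_esp_ea),
            af_1kg_eur=_opt_float(row.af_1kg_eur),
            sift=_opt_float(row.sift),
            polyphen2=_opt_float(row.polyphen2),
            gerp=_opt_float(row.gerp),
            cadd_phred=_opt_float(row.cadd_phred),
        )
        out[v.key] = v
    return out


def read_variants(
    vcf_path: str | Path,
    annotation_tsv_path: str | Path,
    max_unannotated_frac: float = 0.0,
) -> tuple[list[AnnotatedVariant], GenotypeTable]:
    """Read a VCF, split multi-allelic records, join to the annotation TSV.

    The join key is (chrom, pos, ref, alt).  Records without an annotation
    row are dropped with a warning as long as their fraction stays at or
    below ``max_unannotated_frac``; otherwise a :class:`JoinError` lists the
    unmatched keys.  Genotypes are decoded to alt-allele counts (``./.`` ->
    missing).  chrX records are flagged with a warning: counts are kept
    exactly as written, no hemizygous adjustment is applied.
    """
    annotation = read_annotation(annotation_tsv_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)

    keys: list[str] = []
    rows: list[np.ndarray] = []
    matched: list[AnnotatedVariant] = []
    unmatched: list[str] = []
    saw_x = False
    n_records = 0
    for rec in vcf:
        n_records += 1
        if rec.CHROM in _X_CHROMS:
            saw_x = True
        gts = rec.genotypes  # [[a1, a2, phased], ...]
        for alt_index, alt in enumerate(rec.ALT, start=1):
            key = variant_key(rec.CHROM, rec.POS, rec.REF, alt)
            counts = np.empty(len(samples))
            for j, gt in enumerate(gts):
                alleles = gt[:-1]
                if any(a < 0 for a in alleles):
                    counts[j] = np.nan
                else:
                    counts[j] = sum(1 for a in alleles if a == alt_index)
            ann = annotation.get(key)
            if ann is None:
                unmatched.append(key)
                continue
            keys.append(key)
            rows.append(counts)
            matched.append(ann)
    vcf.close()

    total = len(matched) + len(unmatched)
    if unmatched:
        frac = len(unmatched) / total
        if frac > max_unannotated_frac:
            raise JoinError(
                f"{len(unmatched)}/{total} VCF entries lack annotation rows: "
                + ", ".join(unmatched[:20])
            )
        warnings.warn(
            f"dropped {len(unmatched)} unannotated VCF entries", stacklevel=2
        )
    if saw_x:
        warnings.warn(
            "chrX records present: allele counts kept as written, no "
            "hemizygous adjustment",
            stacklevel=2,
        )
    counts = np.vstack(rows) if rows else np.empty((0, len(samples)))
    return matched, GenotypeTable(keys, samples, counts)


def write_vcf(
    variants: Sequence[AnnotatedVariant],
    genotypes: GenotypeTable,
    path: str | Path,
) -> None:
    """Emit a minimal VCF v4.2 with GT-only genotype columns.

    Counts 0/1/2 become ``0/0``, ``0/1``, ``1/1``; missing becomes ``./.``.
    Each variant is written as its own bi-allelic record.
    """
    samples = genotypes.sample_ids
    gt_for = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for v in ordered:
            cells = []
            for s in samples:
                count = genotypes.get(s, v.key)
                cells.append("./." if math.isnan(count) else gt_for[count])
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
                + "\t".join(cells)
                + "\n"
            )


def _flag_out(flag: bool | None) -> str:
    return "." if flag is None else ("1" if flag else "0")


def _num_out(x: float | None) -> str:
    return "." if x is None else format(x, "g")


def write_annotation(variants: Sequence[AnnotatedVariant], path: str | Path) -> None:
    rows = [
        {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "functional_class": v.functional_class.value,
            "in_dbsnp": _flag_out(v.in_dbsnp),
            "in_1kg_eur": _flag_out(v.in_1kg_eur),
            "in_esp_ea": _flag_out(v.in_esp_ea),
            "af_1kg_eur": _num_out(v.af_1kg_eur),
            "sift": _num_out(v.sift),
            "polyphen2": _num_out(v.polyphen2),
            "gerp": _num_out(v.gerp),
            "cadd_phred": _num_out(v.cadd_phred),
        }
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Tab-delimited gene sets: id, description, member symbols.

    Duplicate members collapse; sets left with zero members are skipped
    with a warning.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated "
                    f"columns, got {len(fields)}"
                )
            set_id, name = fields[0], fields[1]
            members = frozenset(g for g in fields[2:] if g.strip())
            if not members:
                warnings.warn(
                    f"{path}: line {lineno}: gene set {set_id} has no "
                    "members, skipped",
                    stacklevel=2,
                )
                continue
            sets.append(GeneSet(set_id=set_id, name=name, members=members))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.set_id, gs.name, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# result TSVs


def _fmt(x: float | None) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    if isinstance(x, float) and math.isinf(x):
        return "inf" if x > 0 else "-inf"
    return format(x, ".6g")


def write_voi_records(records: Sequence[VOIRecord], path: str | Path) -> None:
    header = [
        "family_id", "chrom", "pos", "ref", "alt", "gene", "functional_class",
        "carriers", "sift", "polyphen2", "gerp", "cadd_phred",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in records:
            v = r.variant
            fh.write(
                "\t".join(
                    [
                        r.family_id, v.chrom, str(v.pos), v.ref, v.alt, v.gene,
                        v.functional_class.value, ",".join(r.carriers),
                        _fmt(v.sift), _fmt(v.polyphen2), _fmt(v.gerp),
                        _fmt(v.cadd_phred),
                    ]
                )
                + "\n"
            )


def write_burden_results(results: Sequence[BurdenResult], path: str | Path) -> None:
    header = ["gene", "case_carriers", "case_noncarriers", "control_carriers",
              "control_noncarriers", "n_variants", "p_one_sided", "or_cmle",
              "ci95_lower", "ci95_upper", "p_bonferroni"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in results:
            t = r.table
            fh.write(
                "\t".join(
                    [
                        r.gene, str(t.a), str(t.b), str(t.c), str(t.d),
                        str(r.n_variants), _fmt(r.p_one_sided), _fmt(r.or_cmle),
                        _fmt(r.ci95[0]), _fmt(r.ci95[1]), _fmt(r.p_bonferroni),
                    ]
                )
                + "\n"
            )


def write_tdt_result(result: TDTResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("T\tU\tchi2\tp_chi2\tp_binomial_exact\n")
        fh.write(
            "\t".join(
                [str(result.T), str(result.U), _fmt(result.chi2),
                 _fmt(result.p), _fmt(result.p_binomial)]
            )
            + "\n"
        )


def write_enrichment_results(
    results: Sequence[EnrichmentResult], path: str | Path
) -> None:
    header = ["set_id", "name", "C", "O", "E", "R", "p", "fdr", "overlap_genes"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.set_id, r.name, str(r.C), str(r.O), _fmt(r.E),
                        _fmt(r.R), _fmt(r.p), _fmt(r.fdr),
                        ",".join(r.overlap_genes),
                    ]
                )
                + "\n"
            )
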