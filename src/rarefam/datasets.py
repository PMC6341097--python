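"""Bundled worked example: CEP41 targeted-sequencing carrier observations.

Eight rare heterozygous protein-altering CEP41 variants observed in a
case-control resequencing panel of 1004 unrelated familial cases and 1127
controls; each observation is a distinct heterozygous individual.  The
per-variant deleteriousness scores (SIFT, PolyPhen-2, GERP, CADD) are
carried for reporting.  This tiny dataset exercises the whole burden
machinery: aggregating the case column gives 18 case carriers, the
control column 2 control carriers.
"""

from __future__ import annotations

import numpy as np

from .types import AnnotatedVariant, FunctionalClass, GenotypeTable

N_CASES = 1004
N_CONTROLS = 1127

#: (pos, ref, alt, aa_change, case_obs, control_obs, sift, polyphen2, gerp, cadd)
CEP41_OBSERVATIONS = (
    (130038866, "C", "G", "A330P", 1, 0, 0.12, 0.06, 2.66, 7.084),
    (130040580, "C", "T", "R242H", 1, 0, 0.04, 0.998, 6.03, 34.0),
    (130041748, "G", "C", "P206A", 12, 1, 0.14, 0.997, 5.54, 23.3),
    (130041754, "T", "C", "M204V", 1, 0, 0.15, 0.64, 5.54, 18.04),
    (130041762, "G", "C", "S201C", 1, 0, 0.03, 0.997, 5.54, 21.9),
    (130044507, "G", "C", "A107G", 0, 1, 0.39, 0.116, 0.835, 10.79),
    (130050987, "C", "G", "A85P", 1, 0, 0.28, 0.773, 3.18, 15.08),
    (130056798, "A", "G", "M36T", 1, 0, 0.0, 0.302, 5.71, 13.96),
)


def cep41_case_control(
    rng: np.random.Generator | None = None,
) -> tuple[list[AnnotatedVariant], GenotypeTable, list[str], list[str], dict[str, AnnotatedVariant]]:
    """Materialize the CEP41 worked example as package objects.

    Each observation becomes one distinct heterozygous individual; with an
    ``rng`` the carrier individuals are placed at random positions among
    the sample ids (carrier counts are invariant to the placement).

    Returns (variants, genotypes, case_ids, control_ids, by_aa_change).
    """
    case_ids = [f"case_{i + 1:04d}" for i in range(N_CASES)]
    control_ids = [f"control_{i + 1:04d}" for i in range(N_CONTROLS)]
    samples = case_ids + control_ids
    if rng is None:
        case_order = list(range(N_CASES))
        control_order = list(range(N_CONTROLS))
    else:
        case_order = rng.permutation(N_CASES).tolist()
        control_order = rng.permutation(N_CONTROLS).tolist()

    variants: list[AnnotatedVariant] = []
    by_aa: dict[str, AnnotatedVariant] = {}
    counts = np.zeros((len(CEP41_OBSERVATIONS), len(samples)))
    next_case = 0
    next_control = 0
    for i, (pos, ref, alt, aa, n_case, n_control, sift, pp2, gerp, cadd) in (
            enumerate(CEP41_OBSERVATIONS)):
        v = AnnotatedVariant(
            chrom="chr7", pos=pos, ref=ref, alt=alt, gene="CEP41",
            functional_class=FunctionalClass.NONSYNONYMOUS,
            in_dbsnp=False, in_1kg_eur=False, in_esp_ea=False,
            af_1kg_eur=None, sift=sift, polyphen2=pp2, gerp=gerp,
            cadd_phred=cadd,
        )
        variants.append(v)
        by_aa[aa] = v
        for _ in range(n_case):
            counts[i, case_order[next_case]] = 1.0
            next_case += 1
        for _ in range(n_control):
            counts[i, N_CASES + control_order[next_control]] = 1.0
            next_control += 1
    genotypes = GenotypeTable([v.key for v in variants], samples, counts)
    return variants, genotypes, case_ids, control_ids, by_aa
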