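"""Rare-variant transmission-disequilibrium burden test.

Instead of the classical trio TDT (which scores transmissions from
heterozygous parents), this sibling-based formulation asks: among affected
siblings of probands who carry a qualifying variant, how often is the
variant present in the sibling?  Under Mendelian expectation a rare
heterozygous variant reaches a sibling with probability 1/2, so an excess
of carrier siblings (T) over non-carrier siblings (U) indicates
over-transmission of the risk allele.

The statistic is the Yates-corrected chi-square goodness-of-fit against
the 50:50 expectation,

    chi2 = (max(|T - U| - 1, 0))^2 / (T + U),

referred to the chi-square distribution with 1 df.  An exact two-sided
binomial p (p = 0.5) is reported alongside for small counts.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

from scipy.stats import binomtest, chi2 as chi2_dist

from .types import (
    GenotypeTable,
    Pedigree,
    TDTResult,
    TransmissionEvent,
)


def count_transmission_events(
    proband_variants: Mapping[str, Sequence[str]],
    genotypes: GenotypeTable,
    pedigrees: Sequence[Pedigree],
    affected_only: bool = True,
) -> list[TransmissionEvent]:
    """Score carrier status of affected siblings at the probands' variants.

    ``proband_variants`` maps each proband id to the qualifying variant
    keys it carries.  One event is produced per (sibling, variant) pair:
    ``transmitted`` iff the sibling's allele count is >= 1.  Siblings with
    a missing genotype at the variant produce no event.  A proband with no
    affected siblings contributes nothing.
    """
    by_member: dict[str, Pedigree] = {}
    for ped in pedigrees:
        for m in ped.members:
            by_member[m.individual_id] = ped

    events: list[TransmissionEvent] = []
    for proband_id, keys in proband_variants.items():
        if proband_id not in by_member:
            raise ValueError(f"proband {proband_id} not in any pedigree")
        ped = by_member[proband_id]
        sibs = ped.siblings_of(proband_id)
        if affected_only:
            sibs = [s for s in sibs if s.individual_id in ped.affected_ids]
        for sib in sibs:
            if not genotypes.has_sample(sib.individual_id):
                raise ValueError(
                    f"sibling {sib.individual_id} has no genotypes"
                )
            for key in keys:
                count = genotypes.get(sib.individual_id, key)
                if math.isnan(count):
                    continue  # no event for missing calls
                events.append(
                    TransmissionEvent(
                        family_id=ped.family_id,
                        sibling_id=sib.individual_id,
                        variant_key=key,
                        transmitted=count >= 1,
                    )
                )
    return events


def tdt_chi2_yates(T: int, U: int) -> TDTResult:
    """Yates-corrected chi-square TDT statistic for T transmitted vs U
    untransmitted events.

    The continuity correction truncates at zero, so |T - U| <= 1 gives
    chi2 = 0 and p = 1.  With no events at all the statistic is undefined
    (NaN, p = 1).
    """
    if T < 0 or U < 0:
        raise ValueError("T and U must be non-negative")
    n = T + U
    if n == 0:
        return TDTResult(T=T, U=U, chi2=math.nan, p=1.0, p_binomial=1.0)
    chi2 = max(abs(T - U) - 1, 0) ** 2 / n
    p = float(chi2_dist.sf(chi2, df=1))
    p_binom = float(binomtest(T, n, 0.5).pvalue)
    return TDTResult(T=T, U=U, chi2=chi2, p=p, p_binomial=p_binom)


def ascertain_probands(
    pedigrees: Sequence[Pedigree],
    genotypes: GenotypeTable,
    qualifying_keys: Sequence[str],
) -> dict[str, list[str]]:
    """Pick one proband per family: the first affected member (by id)
    carrying any qualifying variant.  Returns proband -> carried keys."""
    out: dict[str, list[str]] = {}
    for ped in pedigrees:
        for iid in sorted(ped.affected_ids):
            if not genotypes.has_sample(iid):
                continue
            carried = [
                k
                for k in qualifying_keys
                if genotypes.has_variant(k)
                and not math.isnan(genotypes.get(iid, k))
                and genotypes.get(iid, k) >= 1
            ]
            if carried:
                out[iid] = carried
                break
    return out


def tdt_from_events(events: Iterable[TransmissionEvent]) -> TDTResult:
    events = list(events)
    T = sum(1 for e in events if e.transmitted)
    U = len(events) - T
    return tdt_chi2_yates(T, U)
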