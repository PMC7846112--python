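"""Co-segregation checking in the fully genotyped pedigree.

After the WES cascade narrows candidates using a handful of sequenced
members, each surviving variant is genotyped in every family member with
DNA.  Perfect co-segregation — every affected member a carrier, no
unaffected carrier — is the dominant-model pattern that retains a
candidate; a single discordant member eliminates it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .pedigree import Pedigree, Status
from .variants import AnnotatedVariant


@dataclass
class SegregationResult:
    """Carrier pattern of one candidate across the pedigree.

    Members with unknown status or missing genotype are excluded from the
    totals and listed in ``missing_ids``.  ``cosegregates`` requires a
    non-empty case group with all cases carriers and zero carrier controls;
    ``discordant_ids`` are the non-carrier cases plus carrier controls.
    """

    variant_id: str
    case_carriers: int
    case_total: int
    control_carriers: int
    control_total: int
    cosegregates: bool
    discordant_ids: list[str] = field(default_factory=list)
    missing_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variant_id": self.variant_id,
            "case_carriers": self.case_carriers,
            "case_total": self.case_total,
            "control_carriers": self.control_carriers,
            "control_total": self.control_total,
            "cosegregates": self.cosegregates,
            "discordant_ids": self.discordant_ids,
            "missing_ids": self.missing_ids,
        }


def check_cosegregation(variant: AnnotatedVariant, ped: Pedigree) -> SegregationResult:
    """Compare a variant's carrier pattern with affection status.

    Carrier means dosage >= 1 — heterozygous suffices under the dominant
    model.  Members with unknown status or without a (non-missing)
    genotype are excluded from both numerator and denominator and reported
    in ``missing_ids``.
    """
    case_carriers = case_total = control_carriers = control_total = 0
    discordant: list[str] = []
    missing: list[str] = []
    for ind in ped:
        if ind.status is Status.UNKNOWN:
            missing.append(ind.id)
            continue
        g = variant.genotypes.get(ind.id)
        if g is None:
            missing.append(ind.id)
            continue
        carrier = g >= 1
        if ind.status is Status.AFFECTED:
            case_total += 1
            case_carriers += carrier
            if not carrier:
                discordant.append(ind.id)
        else:
            control_total += 1
            control_carriers += carrier
            if carrier:
                discordant.append(ind.id)
    if case_total == 0 and control_total == 0:
        warnings.warn(
            f"no genotyped members with known status for {variant.id}", stacklevel=2
        )
    cosegregates = (
        case_total > 0 and case_carriers == case_total and control_carriers == 0
    )
    return SegregationResult(
        variant_id=variant.id,
        case_carriers=case_carriers,
        case_total=case_total,
        control_carriers=control_carriers,
        control_total=control_total,
        cosegregates=cosegregates,
        discordant_ids=sorted(discordant),
        missing_ids=sorted(missing),
    )


def rank_candidates(results: list[SegregationResult]) -> list[SegregationResult]:
    """Order candidates: co-segregating first, then by carrier-rate contrast.

    The contrast is case carrier rate minus control carrier rate (empty
    groups contribute rate 0); ties break on variant id.
    """

    def key(r: SegregationResult):
        case_rate = r.case_carriers / r.case_total if r.case_total else 0.0
        control_rate = r.control_carriers / r.control_total if r.control_total else 0.0
        return (not r.cosegregates, -(case_rate - control_rate), r.variant_id)

    return sorted(results, key=key)
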