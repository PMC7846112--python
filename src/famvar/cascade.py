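"""Dominant-model variant filtering cascade.

Five filters applied in the discovery order: shared by all sequenced cases,
absent from all sequenced controls, likely-functional consequence class,
rare in every reference panel (< 1 per mille by default), and predicted
deleterious in silico.  The last three are pure per-variant predicates and
commute; the order is fixed for the audit trail, which records input /
output counts and survivor ids per stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .variants import AnnotatedVariant, FunctionalClass, PolyPhenCall, SiftCall

logger = logging.getLogger(__name__)

DEFAULT_FUNCTIONAL_CLASSES = frozenset(
    {
        FunctionalClass.STOP_GAIN,
        FunctionalClass.STOP_LOSS,
        FunctionalClass.FRAMESHIFT_INDEL,
        FunctionalClass.NONSYNONYMOUS,
        FunctionalClass.SPLICING,
    }
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and policies of the cascade.

    ``missing_genotype_policy``: under ``strict`` a missing case genotype
    cannot confirm sharing (variant dropped) while a missing control
    genotype cannot confirm carriage (variant kept); ``permissive`` ignores
    missing calls in the case-sharing filter too.
    ``unknown_prediction_policy`` decides whether a variant with an unknown
    SIFT/PolyPhen/CADD annotation passes (``keep``) or fails (``drop``) the
    corresponding deleteriousness criterion.
    """

    functional_classes: frozenset[FunctionalClass] = DEFAULT_FUNCTIONAL_CLASSES
    max_panel_af: float = 0.001
    require_sift_deleterious: bool = True
    require_polyphen_damaging: bool = True
    min_cadd: float = 20.0
    unknown_prediction_policy: str = "keep"  # keep | drop
    missing_genotype_policy: str = "strict"  # strict | permissive

    def __post_init__(self):
        if not 0.0 <= self.max_panel_af <= 1.0:
            raise ValueError(f"max_panel_af {self.max_panel_af} outside [0, 1]")
        if self.unknown_prediction_policy not in ("keep", "drop"):
            raise ValueError("unknown_prediction_policy must be 'keep' or 'drop'")
        if self.missing_genotype_policy not in ("strict", "permissive"):
            raise ValueError("missing_genotype_policy must be 'strict' or 'permissive'")


@dataclass
class CascadeStage:
    name: str
    input_count: int
    output_count: int
    survivor_ids: list[str]


@dataclass
class CascadeReport:
    """Stage-by-stage audit trail of the cascade."""

    stages: list[CascadeStage] = field(default_factory=list)

    @property
    def final_candidates(self) -> list[str]:
        return list(self.stages[-1].survivor_ids) if self.stages else []

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": s.name,
                    "input_count": s.input_count,
                    "output_count": s.output_count,
                    "survivor_ids": s.survivor_ids,
                }
                for s in self.stages
            ],
            "final_candidates": self.final_candidates,
        }


def _require_ids(variant: AnnotatedVariant, ids: Iterable[str]) -> None:
    for i in ids:
        if i not in variant.genotypes:
            raise KeyError(f"individual {i!r} has no genotype at {variant.id}")


def filter_shared_by_cases(
    variants: Sequence[AnnotatedVariant],
    case_ids: Sequence[str],
    policy: str = "strict",
) -> list[AnnotatedVariant]:
    """Keep variants carried (dosage >= 1) by every case.

    Under ``strict`` a missing case genotype disqualifies the variant
    (sharing cannot be confirmed); under ``permissive`` that case is
    skipped.
    """
    if not case_ids:
        raise ValueError("case_ids must be non-empty")
    out = []
    for v in variants:
        _require_ids(v, case_ids)
        keep = True
        for c in case_ids:
            g = v.genotypes[c]
            if g is None:
                if policy == "strict":
                    keep = False
                    break
                continue
            if g < 1:
                keep = False
                break
        if keep:
            out.append(v)
    return out


def filter_absent_in_controls(
    variants: Sequence[AnnotatedVariant],
    control_ids: Sequence[str],
    policy: str = "strict",
) -> list[AnnotatedVariant]:
    """Drop variants carried by any control.

    A missing control genotype never excludes a variant (carriage cannot be
    confirmed) under either policy.
    """
    if not control_ids:
        raise ValueError("control_ids must be non-empty")
    out = []
    for v in variants:
        _require_ids(v, control_ids)
        if not any(
            v.genotypes[c] is not None and v.genotypes[c] >= 1 for c in control_ids
        ):
            out.append(v)
    return out


def filter_functional(
    variants: Sequence[AnnotatedVariant], config: FilterConfig
) -> list[AnnotatedVariant]:
    """Keep variants in a likely-functional consequence class."""
    return [v for v in variants if v.annotation.functional_class in config.functional_classes]


def filter_rare(
    variants: Sequence[AnnotatedVariant], config: FilterConfig
) -> list[AnnotatedVariant]:
    """Keep variants rare in every reference panel.

    The criterion is max recorded panel AF < ``config.max_panel_af``; a
    variant unobserved in every panel is retained — absence of frequency
    evidence must not exclude an allele that may simply be too rare to have
    been catalogued.
    """
    out = []
    for v in variants:
        max_af = v.annotation.max_panel_af()
        if max_af is None or max_af < config.max_panel_af:
            out.append(v)
    return out


def filter_deleterious(
    variants: Sequence[AnnotatedVariant], config: FilterConfig
) -> list[AnnotatedVariant]:
    """Keep variants satisfying every enabled in-silico deleteriousness criterion."""
    keep_unknown = config.unknown_prediction_policy == "keep"
    out = []
    for v in variants:
        ann = v.annotation
        ok = True
        if config.require_sift_deleterious:
            if ann.sift is SiftCall.UNKNOWN:
                ok = keep_unknown
            else:
                ok = ann.sift is SiftCall.DELETERIOUS
        if ok and config.require_polyphen_damaging:
            if ann.polyphen is PolyPhenCall.UNKNOWN:
                ok = keep_unknown
            else:
                ok = ann.polyphen is PolyPhenCall.PROBABLY_DAMAGING
        if ok and config.min_cadd is not None:
            if ann.cadd_phred is None:
                ok = keep_unknown
            else:
                ok = ann.cadd_phred >= config.min_cadd
        if ok:
            out.append(v)
    return out


def run_cascade(
    variants: Sequence[AnnotatedVariant],
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    config: FilterConfig | None = None,
) -> CascadeReport:
    """Apply the five filters in discovery order, recording the audit trail."""
    if not variants:
        raise ValueError("no variants to filter")
    config = config or FilterConfig()
    policy = config.missing_genotype_policy
    stages = [
        ("shared_by_cases", lambda vs: filter_shared_by_cases(vs, case_ids, policy)),
        ("absent_in_controls", lambda vs: filter_absent_in_controls(vs, control_ids, policy)),
        ("functional", lambda vs: filter_functional(vs, config)),
        ("rare", lambda vs: filter_rare(vs, config)),
        ("deleterious", lambda vs: filter_deleterious(vs, config)),
    ]
    report = CascadeReport()
    current = list(variants)
    for name, fn in stages:
        survivors = fn(current)
        report.stages.append(
            CascadeStage(name, len(current), len(survivors), [v.id for v in survivors])
        )
        logger.info("stage %-20s %6d -> %6d", name, len(current), len(survivors))
        current = survivors
    return report
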