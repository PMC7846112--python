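"""Cohort carrier screening and reference-panel allele-count aggregation.

The validation step of a family discovery: genotype the candidate in large
external case/control cohorts (no additional carriers expected for a
private allele) and aggregate its allele counts across public reference
panels to bound the population frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .variants import GenotypeCall


@dataclass
class CohortScreenResult:
    cohort_name: str
    n_cases: int
    n_controls: int
    case_carriers: int
    control_carriers: int
    n_missing: int = 0

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass(frozen=True)
class PanelCount:
    """Allele observations in one reference panel of diploid individuals."""

    name: str
    n_individuals: int
    alt_allele_count: int

    def __post_init__(self):
        if self.n_individuals < 0 or self.alt_allele_count < 0:
            raise ValueError("panel counts must be non-negative")
        if self.alt_allele_count > 2 * self.n_individuals:
            raise ValueError(
                f"panel {self.name!r}: {self.alt_allele_count} alt alleles exceed "
                f"2 x {self.n_individuals} chromosomes"
            )


@dataclass
class PanelAggregate:
    panels: list[PanelCount]
    total_individuals: int
    total_alt_alleles: int
    allele_frequency: float

    def to_dict(self) -> dict:
        return {
            "panels": [p.__dict__.copy() for p in self.panels],
            "total_individuals": self.total_individuals,
            "total_alt_alleles": self.total_alt_alleles,
            "allele_frequency": self.allele_frequency,
        }


def screen_cohort(
    genotypes: Mapping[str, GenotypeCall],
    status: Mapping[str, str],
    name: str = "cohort",
) -> CohortScreenResult:
    """Count carriers per group in an external cohort.

    ``status`` maps subject id to ``"case"`` or ``"control"``.  Missing
    genotypes are excluded from the denominators and counted in
    ``n_missing``.
    """
    n_cases = n_controls = case_carriers = control_carriers = n_missing = 0
    for subject, group in status.items():
        g = genotypes.get(subject)
        if g is None:
            n_missing += 1
            continue
        carrier = g >= 1
        if group == "case":
            n_cases += 1
            case_carriers += carrier
        elif group == "control":
            n_controls += 1
            control_carriers += carrier
        else:
            raise ValueError(f"subject {subject!r}: unknown group {group!r}")
    if n_cases == 0 and n_controls == 0:
        warnings.warn(f"cohort {name!r} has no genotyped subjects", stacklevel=2)
    return CohortScreenResult(name, n_cases, n_controls, case_carriers, control_carriers, n_missing)


def aggregate_panels(panels: Sequence[PanelCount]) -> PanelAggregate:
    """Sum allele observations over panels.

    The frequency denominator is diploid: 2 x total individuals.  With no
    individuals at all the frequency is reported as 0.
    """
    panels = list(panels)
    total_ind = sum(p.n_individuals for p in panels)
    total_alt = sum(p.alt_allele_count for p in panels)
    freq = total_alt / (2 * total_ind) if total_ind else 0.0
    return PanelAggregate(panels, total_ind, total_alt, freq)


def read_panel_table(path) -> list[PanelCount]:
    """Read panel counts from a TSV with columns name, n_individuals, alt_allele_count."""
    df = pd.read_csv(path, sep="\t")
    return [
        PanelCount(str(n), int(i), int(a))
        for n, i, a in zip(df["name"], df["n_individuals"], df["alt_allele_count"])
    ]


# Reference-panel roster used by the default pipeline run.  The total
# individual count (345,939) and the two observed alternate alleles (both in
# gnomAD) are the published aggregate for the study variant; the per-panel
# individual split is a synthetic allocation, as the exact per-panel sizes
# are not machine-readable here.
DEFAULT_REFERENCE_PANELS: list[PanelCount] = [
    PanelCount("100KGP", 166_050, 0),
    PanelCount("gnomAD", 141_456, 2),
    PanelCount("NIHR-BioResource", 13_037, 0),
    PanelCount("H3Africa", 23_657, 0),
    PanelCount("GenomeAsia100K", 1_739, 0),
]
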