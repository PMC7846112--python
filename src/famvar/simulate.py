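"""Synthetic family study generator.

Builds everything the discovery pipeline consumes — a three-generation
pedigree, a background of Mendelian gene-dropped rare variants with
realistic annotations, one planted fully penetrant dominant causal variant,
and per-member plasma coagulation phenotypes — so the whole analysis is
exercisable without any external data.

The generator's statistical shape mirrors the study design it emulates:
15 members across 3 generations with 5 affected; roughly 9.4% of
case-shared, control-absent variants in a likely-functional class; about 2%
of rare functional variants jointly predicted deleterious by SIFT /
PolyPhen / CADD; and group plasma moments (mean, SD) for f-TFPI, PAI-1,
ECLT, uPA and thrombomodulin taken from the published case/control
summaries of the family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Individual, Pedigree, Sex, Status, write_ped
from .variants import (
    AnnotatedVariant,
    FunctionalClass,
    PolyPhenCall,
    SiftCall,
    VariantAnnotation,
    VariantSite,
    write_annotated_vcf,
)

# -- configuration ----------------------------------------------------------


@dataclass(frozen=True)
class CausalSpec:
    """Annotation profile of the planted causal variant.

    Defaults emulate an extremely rare, nonsynonymous, uniformly
    deleterious-predicted missense allele (CADD PHRED ~30, essentially
    absent from reference panels).
    """

    chrom: str = "1"
    pos: int = 46_092_317
    ref: str = "G"
    alt: str = "A"
    id: str = "causal_1"
    functional_class: FunctionalClass = FunctionalClass.NONSYNONYMOUS
    panel_afs: tuple[tuple[str, float], ...] = (("gnomAD", 2.89e-06),)
    sift: SiftCall = SiftCall.DELETERIOUS
    polyphen: PolyPhenCall = PolyPhenCall.PROBABLY_DAMAGING
    cadd_phred: float = 30.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    ``af_beta_a``/``af_beta_b`` parameterise the Beta population allele
    frequency spectrum (truncated to [``af_min``, ``af_max``]); the default
    Beta(0.2, 2) puts most mass on rare alleles, as exome data do.
    ``functional_fraction`` is the probability that a background variant
    falls in a likely-functional consequence class, and
    ``rare_fraction_of_functional`` the probability that a functional
    variant draws a fully concordant deleterious prediction profile.
    ``penetrance``/``phenocopy_rate`` control the carrier→affected map; the
    defaults (1, 0) give the strict dominant full-penetrance model under
    which carrier status and affection status coincide exactly.
    """

    seed: int = 0
    n_background_variants: int = 20_000
    af_beta_a: float = 0.2
    af_beta_b: float = 2.0
    af_min: float = 1e-5
    af_max: float = 0.5
    functional_fraction: float = 0.094
    rare_fraction_of_functional: float = 0.02
    panel_names: tuple[str, ...] = ("gnomAD", "FrEx")
    panel_af_log_sd: float = 0.2
    penetrance: float = 1.0
    phenocopy_rate: float = 0.0
    causal: CausalSpec = field(default_factory=CausalSpec)

    def validate(self) -> None:
        if self.n_background_variants < 1:
            raise ValueError("n_background_variants must be >= 1")
        for name in ("functional_fraction", "rare_fraction_of_functional",
                     "penetrance", "phenocopy_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.af_min <= self.af_max <= 1.0:
            raise ValueError("require 0 < af_min <= af_max <= 1")
        if self.af_beta_a <= 0 or self.af_beta_b <= 0:
            raise ValueError("Beta spectrum parameters must be positive")


@dataclass(frozen=True)
class GroupMoments:
    case_mean: float
    case_sd: float
    control_mean: float
    control_sd: float
    units: str

    def __post_init__(self):
        if self.case_sd <= 0 or self.control_sd <= 0:
            raise ValueError("group SDs must be positive")


# Group moments per plasma parameter.  Means and SEM-derived SDs follow the
# published family summaries (cases n=3 on vitamin-K antagonists, controls
# n=7); uPA showed no case/control difference, so both groups share its
# moments.
DEFAULT_PLASMA_MODEL: dict[str, GroupMoments] = {
    "f-TFPI": GroupMoments(6.6, 3.37, 17.4, 3.23, "ng/mL"),
    "PAI-1": GroupMoments(21.7, 10.69, 3.3, 1.98, "IU/mL"),
    "ECLT": GroupMoments(1200.0, 519.6, 458.0, 238.1, "min"),
    "uPA": GroupMoments(1.2, 0.4, 1.1, 0.35, "ng/mL"),
    "thrombomodulin": GroupMoments(9.63, 5.35, 4.29, 0.45, "ng/mL"),
}


# -- pedigree template ------------------------------------------------------


def template_pedigree() -> Pedigree:
    """Deterministic 15-member, 3-generation pedigree with 5 affected.

    The affected set spans an index case, her affected mother, maternal
    uncle and aunt, and an affected maternal cousin — a transmission
    pattern consistent with autosomal-dominant inheritance from a shared
    grandparental founder.
    """
    M, F = Sex.MALE, Sex.FEMALE
    AFF, UN = Status.AFFECTED, Status.UNAFFECTED
    rows = [
        # generation I (founder grandparents)
        Individual("304000", None, None, M, UN),
        Individual("304001", None, None, F, UN),
        # generation II: sibship plus married-in spouses (founders)
        Individual("305001", "304000", "304001", F, AFF),   # mother of index
        Individual("305002", "304000", "304001", M, AFF),   # maternal uncle
        Individual("305003", "304000", "304001", F, AFF),   # maternal aunt
        Individual("305005", "304000", "304001", F, UN),    # unaffected sib
        Individual("305004", None, None, M, UN),            # husband of 305001
        Individual("305006", None, None, M, UN),            # husband of 305003
        Individual("305007", None, None, F, UN),            # wife of 305002
        # generation III
        Individual("305000", "305004", "305001", F, AFF),   # index case
        Individual("305015", "305004", "305001", F, UN),
        Individual("305010", "305002", "305007", M, UN),
        Individual("305012", "305002", "305007", F, AFF),   # affected cousin
        Individual("305013", "305006", "305003", F, UN),
        Individual("305014", "305006", "305003", M, UN),
    ]
    return Pedigree(rows, name="FAM1")


# -- gene dropping ----------------------------------------------------------


def gene_drop_matrix(ped: Pedigree, afs: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, list[str]]:
    """Drop ``len(afs)`` independent bi-allelic variants through ``ped``.

    Founders draw genotypes from Hardy–Weinberg proportions at each
    variant's frequency; every non-founder receives one gamete per parent,
    alt with probability (parental dosage)/2 — exactly Mendelian
    transmission for dosage coded 0/1/2.  Returns an (n_variants,
    n_members) int8 dosage matrix and the member id order (topological).
    """
    order = ped.topological_order()
    col = {ind_id: i for i, ind_id in enumerate(order)}
    n = len(afs)
    geno = np.zeros((n, len(order)), dtype=np.int8)
    for ind_id in order:
        ind = ped[ind_id]
        if ind.is_founder:
            geno[:, col[ind_id]] = rng.binomial(2, afs).astype(np.int8)
        else:
            gf = geno[:, col[ind.father_id]]
            gm = geno[:, col[ind.mother_id]]
            geno[:, col[ind_id]] = (
                (rng.random(n) < gf / 2.0).astype(np.int8)
                + (rng.random(n) < gm / 2.0).astype(np.int8)
            )
    return geno, order


def gene_drop(ped: Pedigree, af: float, rng: np.random.Generator) -> dict[str, int]:
    """Gene-drop a single variant at population frequency ``af``."""
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"allele frequency {af} outside [0, 1]")
    geno, order = gene_drop_matrix(ped, np.asarray([af]), rng)
    return {ind_id: int(geno[0, i]) for i, ind_id in enumerate(order)}


def estimate_kinship_mc(
    ped: Pedigree,
    n_drops: int = 200_000,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Monte-Carlo kinship via labelled-allele gene dropping.

    Each founder receives two unique allele labels; alleles descend by
    Mendelian segregation.  The kinship of a pair is estimated as the mean
    over drops of the allele-sharing probability (1/4 × number of identical
    label pairs between the two individuals).  Returns (estimate matrix,
    standard-error matrix, member order).  Entirely independent of the
    recursive kinship computation, so it serves as an oracle for it.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    order = ped.topological_order()
    col = {ind_id: i for i, ind_id in enumerate(order)}
    n_ind = len(order)
    alleles = np.empty((n_drops, n_ind, 2), dtype=np.int32)
    for ind_id in order:
        ind = ped[ind_id]
        c = col[ind_id]
        if ind.is_founder:
            alleles[:, c, 0] = 2 * c
            alleles[:, c, 1] = 2 * c + 1
        else:
            for slot, pid in ((0, ind.father_id), (1, ind.mother_id)):
                pick = rng.integers(0, 2, size=n_drops)
                alleles[:, c, slot] = alleles[np.arange(n_drops), col[pid], pick]
    est = np.empty((n_ind, n_ind))
    se = np.empty((n_ind, n_ind))
    for i in range(n_ind):
        for j in range(i, n_ind):
            share = np.zeros(n_drops)
            for a, b in itertools.product(range(2), range(2)):
                share += alleles[:, i, a] == alleles[:, j, b]
            share /= 4.0
            est[i, j] = est[j, i] = share.mean()
            se[i, j] = se[j, i] = share.std(ddof=1) / np.sqrt(n_drops)
    return est, se, order


# -- causal planting --------------------------------------------------------


def _drop_single_copy(ped: Pedigree, founder_id: str, rng: np.random.Generator) -> dict[str, int]:
    """Drop one copy of an allele introduced heterozygously in ``founder_id``."""
    order = ped.topological_order()
    geno: dict[str, int] = {}
    for ind_id in order:
        ind = ped[ind_id]
        if ind.is_founder:
            geno[ind_id] = 1 if ind_id == founder_id else 0
        else:
            geno[ind_id] = int(rng.random() < geno[ind.father_id] / 2.0) + int(
                rng.random() < geno[ind.mother_id] / 2.0
            )
    return geno


def causal_founder(ped: Pedigree) -> str:
    """The earliest-generation founder ancestral to every affected member.

    Falls back to the first founder in id order if no founder is ancestral
    to all affected (e.g. no affected members yet).
    """
    affected = ped.affected
    candidates = [
        f
        for f in sorted(ped.founders)
        if all(f in ped.ancestors(a) or f == a for a in affected)
    ]
    pool = candidates or sorted(ped.founders)
    return min(pool, key=lambda f: (ped.depth(f), f))


def plant_causal_and_assign_status(
    ped: Pedigree,
    penetrance: float = 1.0,
    phenocopy_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    founder_id: str | None = None,
    max_attempts: int = 10_000,
) -> tuple[dict[str, int], dict[str, Status]]:
    """Introduce one causal allele in a founder and derive affection status.

    The allele is gene-dropped from ``founder_id`` (default: the earliest
    founder ancestral to all currently affected members), re-drawing until
    at least 3 carriers spanning at least 2 generations exist — the minimal
    configuration in which dominant transmission is visible.  Each carrier
    is then affected with probability ``penetrance`` and each non-carrier
    with probability ``phenocopy_rate``; at the defaults (1, 0) carriers
    and affected coincide exactly.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    founder = founder_id or causal_founder(ped)
    if founder not in ped:
        raise KeyError(f"founder {founder!r} not in pedigree")
    for _ in range(max_attempts):
        geno = _drop_single_copy(ped, founder, rng)
        carriers = [i for i, g in geno.items() if g >= 1]
        generations = {ped.depth(i) for i in carriers}
        if len(carriers) >= 3 and len(generations) >= 2:
            break
    else:
        raise RuntimeError(
            f"no acceptable causal transmission after {max_attempts} attempts"
        )
    statuses = {}
    for ind_id, g in geno.items():
        p = penetrance if g >= 1 else phenocopy_rate
        statuses[ind_id] = Status.AFFECTED if rng.random() < p else Status.UNAFFECTED
    return geno, statuses


# -- full study simulation --------------------------------------------------


@dataclass
class StudyBundle:
    pedigree: Pedigree
    variants: list[AnnotatedVariant]
    plasma: pd.DataFrame
    causal_id: str


_FUNCTIONAL_CLASSES = [
    FunctionalClass.NONSYNONYMOUS,
    FunctionalClass.SPLICING,
    FunctionalClass.FRAMESHIFT_INDEL,
    FunctionalClass.STOP_GAIN,
    FunctionalClass.STOP_LOSS,
]
_FUNCTIONAL_WEIGHTS = [0.85, 0.06, 0.04, 0.03, 0.02]
_NEUTRAL_CLASSES = [
    FunctionalClass.SYNONYMOUS,
    FunctionalClass.OTHER,
    FunctionalClass.NONFRAMESHIFT_INDEL,
]
_NEUTRAL_WEIGHTS = [0.55, 0.35, 0.10]
_BASES = np.array(["A", "C", "G", "T"])


def simulate_study(config: SimulationConfig) -> StudyBundle:
    """Generate a complete synthetic study from one seed.

    Produces the pedigree (statuses re-derived from the planted causal
    transmission), ``n_background_variants`` independently gene-dropped
    annotated variants plus the causal variant, and a tidy plasma table
    with one Normal draw per member × parameter from the group moments in
    :data:`DEFAULT_PLASMA_MODEL` (floored at 0).  Bit-identical outputs for
    identical configs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ped0 = template_pedigree()

    causal_geno, statuses = plant_causal_and_assign_status(
        ped0, config.penetrance, config.phenocopy_rate, rng
    )
    ped = ped0.with_statuses(statuses)

    # background allele frequency spectrum
    n = config.n_background_variants
    afs = rng.beta(config.af_beta_a, config.af_beta_b, size=n)
    afs = np.clip(afs, config.af_min, config.af_max)

    geno, order = gene_drop_matrix(ped, afs, rng)

    # annotations, vectorised
    functional = rng.random(n) < config.functional_fraction
    func_idx = rng.choice(len(_FUNCTIONAL_CLASSES), size=n, p=_FUNCTIONAL_WEIGHTS)
    neut_idx = rng.choice(len(_NEUTRAL_CLASSES), size=n, p=_NEUTRAL_WEIGHTS)

    panel_noise = {
        p: np.clip(afs * rng.lognormal(0.0, config.panel_af_log_sd, size=n), 0.0, 1.0)
        for p in config.panel_names
    }
    # a sliver of genuinely unobserved-in-panel variants among the rarest
    unobserved = {p: rng.random(n) < np.where(afs < 1e-3, 0.05, 0.0) for p in config.panel_names}

    deleterious = rng.random(n) < config.rare_fraction_of_functional
    cadd_hi = rng.uniform(25.0, 35.0, size=n)
    cadd_lo = rng.uniform(0.0, 20.0, size=n)
    sift_classes = [SiftCall.TOLERATED, SiftCall.DELETERIOUS, SiftCall.UNKNOWN]
    sift_idx = rng.choice(len(sift_classes), size=n, p=[0.70, 0.25, 0.05])
    poly_classes = [
        PolyPhenCall.BENIGN,
        PolyPhenCall.POSSIBLY_DAMAGING,
        PolyPhenCall.PROBABLY_DAMAGING,
        PolyPhenCall.UNKNOWN,
    ]
    poly_idx = rng.choice(len(poly_classes), size=n, p=[0.55, 0.25, 0.15, 0.05])

    chroms = rng.integers(1, 23, size=n)
    positions = rng.integers(1, 250_000_000, size=n)
    ref_idx = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    refs = _BASES[ref_idx]
    alts = _BASES[(ref_idx + alt_shift) % 4]

    variants: list[AnnotatedVariant] = []
    for v in range(n):
        if functional[v]:
            fclass = _FUNCTIONAL_CLASSES[func_idx[v]]
        else:
            fclass = _NEUTRAL_CLASSES[neut_idx[v]]
        if deleterious[v]:
            sift, poly, cadd = SiftCall.DELETERIOUS, PolyPhenCall.PROBABLY_DAMAGING, cadd_hi[v]
        else:
            sift, poly, cadd = sift_classes[sift_idx[v]], poly_classes[poly_idx[v]], cadd_lo[v]
        panel_afs = {
            p: float(panel_noise[p][v])
            for p in config.panel_names
            if not unobserved[p][v]
        }
        site = VariantSite(
            chrom=str(chroms[v]),
            pos=int(positions[v]),
            ref=str(refs[v]),
            alt=str(alts[v]),
            id=f"bg{v:06d}",
        )
        ann = VariantAnnotation(
            functional_class=fclass,
            panel_afs=panel_afs,
            sift=sift,
            polyphen=poly,
            cadd_phred=float(cadd),
        )
        genotypes = {ind_id: int(geno[v, i]) for i, ind_id in enumerate(order)}
        variants.append(AnnotatedVariant(site, genotypes, ann))

    c = config.causal
    causal = AnnotatedVariant(
        VariantSite(c.chrom, c.pos, c.ref, c.alt, id=c.id),
        {i: causal_geno[i] for i in order},
        VariantAnnotation(
            functional_class=c.functional_class,
            panel_afs=dict(c.panel_afs),
            sift=c.sift,
            polyphen=c.polyphen,
            cadd_phred=c.cadd_phred,
        ),
    )
    variants.append(causal)

    plasma = _simulate_plasma(ped, rng)
    return StudyBundle(ped, variants, plasma, causal_id=c.id)


def _simulate_plasma(ped: Pedigree, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for ind in ped:
        if ind.status is Status.UNKNOWN:
            continue
        group = "case" if ind.status is Status.AFFECTED else "control"
        for param, m in DEFAULT_PLASMA_MODEL.items():
            mean, sd = (m.case_mean, m.case_sd) if group == "case" else (m.control_mean, m.control_sd)
            value = max(float(rng.normal(mean, sd)), 0.0)
            rows.append((ind.id, group, param, value, m.units))
    return pd.DataFrame(rows, columns=["subject_id", "status", "parameter", "value", "units"])


# -- serialisation ----------------------------------------------------------


def write_study(bundle: StudyBundle, out_dir) -> dict[str, Path]:
    """Write PED, VCF, annotation TSV and plasma CSV under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": out / "family.ped",
        "vcf": out / "variants.vcf",
        "annotations": out / "annotations.tsv",
        "plasma": out / "plasma.csv",
    }
    write_ped(bundle.pedigree, paths["ped"])
    samples = bundle.pedigree.topological_order()
    write_annotated_vcf(bundle.variants, samples, paths["vcf"])

    rows = []
    for v in bundle.variants:
        row = {
            "chrom": v.site.chrom,
            "pos": v.site.pos,
            "ref": v.site.ref,
            "alt": v.site.alt,
            "functional_class": v.annotation.functional_class.value,
            "sift": v.annotation.sift.value,
            "polyphen": v.annotation.polyphen.value,
            "cadd_phred": v.annotation.cadd_phred,
        }
        for p, af in v.annotation.panel_afs.items():
            row[f"af_{p}"] = af
        rows.append(row)
    pd.DataFrame(rows).to_csv(paths["annotations"], sep="\t", index=False)
    bundle.plasma.to_csv(paths["plasma"], index=False)
    return paths
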