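"""Annotated multi-sample variant model and VCF / annotation-table I/O.

The unit of work downstream is the :class:`AnnotatedVariant`: one bi-allelic
site (multi-allelic records are decomposed on read), a per-sample alternate
allele count, and the functional / frequency / in-silico annotations the
filtering cascade consumes.  Genotypes are unphased carrier dosages — the
dominant-model cascade only ever asks "does this person carry the allele".
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


class FunctionalClass(str, enum.Enum):
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    FRAMESHIFT_INDEL = "frameshift_indel"
    NONFRAMESHIFT_INDEL = "nonframeshift_indel"
    NONSYNONYMOUS = "nonsynonymous"
    SPLICING = "splicing"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class SiftCall(str, enum.Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"
    UNKNOWN = "unknown"


class PolyPhenCall(str, enum.Enum):
    PROBABLY_DAMAGING = "probably_damaging"
    POSSIBLY_DAMAGING = "possibly_damaging"
    BENIGN = "benign"
    UNKNOWN = "unknown"


class VariantFormatError(ValueError):
    """Raised for files that do not satisfy the expected VCF/TSV contract."""


@dataclass(frozen=True)
class VariantSite:
    """One bi-allelic site, 1-based VCF coordinates."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if not self.id:
            object.__setattr__(self, "id", f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}")


@dataclass
class VariantAnnotation:
    """Functional class, per-panel allele frequencies, and prediction scores.

    ``panel_afs`` maps reference-panel name to allele frequency; a panel in
    which the variant is unobserved is simply absent from the map (distinct
    from a recorded frequency of 0).  ``cadd_phred`` is ``None`` when no
    score is available.
    """

    functional_class: FunctionalClass = FunctionalClass.OTHER
    panel_afs: dict[str, float] = field(default_factory=dict)
    sift: SiftCall = SiftCall.UNKNOWN
    polyphen: PolyPhenCall = PolyPhenCall.UNKNOWN
    cadd_phred: float | None = None

    def __post_init__(self):
        for panel, af in self.panel_afs.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"panel {panel!r} AF {af} outside [0, 1]")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"CADD PHRED must be non-negative, got {self.cadd_phred}")

    def max_panel_af(self) -> float | None:
        """Largest recorded panel AF, or ``None`` if unobserved everywhere."""
        return max(self.panel_afs.values()) if self.panel_afs else None


# Genotypes are plain ``int | None``: the alternate-allele count 0/1/2,
# or None for a missing call (distinct from homozygous reference).
GenotypeCall = int | None


@dataclass
class AnnotatedVariant:
    site: VariantSite
    genotypes: dict[str, GenotypeCall]
    annotation: VariantAnnotation = field(default_factory=VariantAnnotation)

    @property
    def id(self) -> str:
        return self.site.id

    def carriers(self) -> set[str]:
        return {s for s, g in self.genotypes.items() if g is not None and g >= 1}


# -- VCF reading ------------------------------------------------------------

_INFO_KEYS = {
    "functional_class": "FUNC",
    "sift": "SIFT",
    "polyphen": "POLYPHEN",
    "cadd_phred": "CADD",
}
_AF_PREFIX = "AF_"


def _parse_enum(cls, value, default):
    if value is None:
        return default
    try:
        return cls(str(value))
    except ValueError:
        return default


def read_annotated_vcf(
    vcf_path,
    annotation_path=None,
    *,
    info_keys: Mapping[str, str] | None = None,
    af_prefix: str = _AF_PREFIX,
) -> list[AnnotatedVariant]:
    """Read a multi-sample VCF (v4.2, plain or bgzipped) into the data model.

    Multi-allelic records are decomposed into one :class:`AnnotatedVariant`
    per alternate allele, recoding each sample's alternate count for that
    allele alone; a genotype with any missing allele becomes a missing call.
    Annotations come from the INFO keys ``FUNC``/``SIFT``/``POLYPHEN``/
    ``CADD`` plus any ``AF_<panel>`` keys (names configurable via
    ``info_keys``/``af_prefix``); an optional sidecar TSV keyed on
    chrom,pos,ref,alt overrides the INFO values.  Per-allele INFO fields of
    multi-allelic records are indexed by allele; scalar fields are shared.
    """
    from cyvcf2 import VCF

    keys = dict(_INFO_KEYS)
    if info_keys:
        keys.update(info_keys)

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if not samples:
        raise VariantFormatError(f"{vcf_path}: no sample columns / GT data in VCF")

    variants: list[AnnotatedVariant] = []
    for rec in vcf:
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        info = dict(rec.INFO)
        for k, alt in enumerate(rec.ALT, start=1):

            def pick(val):
                if isinstance(val, tuple):
                    return val[k - 1] if k - 1 < len(val) else None
                return val

            ann = VariantAnnotation(
                functional_class=_parse_enum(
                    FunctionalClass, pick(info.get(keys["functional_class"])), FunctionalClass.OTHER
                ),
                sift=_parse_enum(SiftCall, pick(info.get(keys["sift"])), SiftCall.UNKNOWN),
                polyphen=_parse_enum(
                    PolyPhenCall, pick(info.get(keys["polyphen"])), PolyPhenCall.UNKNOWN
                ),
                cadd_phred=(
                    float(pick(info[keys["cadd_phred"]]))
                    if keys["cadd_phred"] in info and pick(info[keys["cadd_phred"]]) is not None
                    else None
                ),
                panel_afs={
                    key[len(af_prefix) :]: float(pick(val))
                    for key, val in info.items()
                    if key.startswith(af_prefix) and pick(val) is not None
                },
            )
            genotypes: dict[str, GenotypeCall] = {}
            for sample, gt in zip(samples, gts):
                alleles = gt[:-1]  # last element is the phased flag
                if any(a < 0 for a in alleles):
                    genotypes[sample] = None
                else:
                    genotypes[sample] = sum(1 for a in alleles if a == k)
            site = VariantSite(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=alt,
                id=rec.ID or "",
            )
            variants.append(AnnotatedVariant(site, genotypes, ann))
    vcf.close()

    if annotation_path is not None:
        apply_annotation_table(variants, annotation_path, af_prefix=af_prefix)
    return variants


def apply_annotation_table(
    variants: Sequence[AnnotatedVariant],
    annotation_path,
    *,
    af_prefix: str = _AF_PREFIX.lower(),
    column_map: Mapping[str, str] | None = None,
) -> int:
    """Join a sidecar annotation TSV onto ``variants`` in place.

    Expected columns (renameable through ``column_map``): ``chrom``, ``pos``,
    ``ref``, ``alt``, then any of ``functional_class``, ``sift``,
    ``polyphen``, ``cadd_phred`` and per-panel frequency columns named
    ``af_<panel>``.  TSV values override whatever came from the VCF INFO
    field.  Rows matching no variant are counted, logged as a warning, and
    the count returned.
    """
    cols = {"chrom": "chrom", "pos": "pos", "ref": "ref", "alt": "alt"}
    if column_map:
        cols.update(column_map)
    table = pd.read_csv(annotation_path, sep="\t", dtype={cols["chrom"]: str})
    af_prefix = af_prefix.lower()

    index = {(v.site.chrom, v.site.pos, v.site.ref, v.site.alt): v for v in variants}
    unmatched = 0
    for row in table.itertuples(index=False):
        row = row._asdict()
        key = (str(row[cols["chrom"]]), int(row[cols["pos"]]), row[cols["ref"]], row[cols["alt"]])
        variant = index.get(key)
        if variant is None:
            unmatched += 1
            continue
        ann = variant.annotation
        if not pd.isna(row.get("functional_class")):
            ann.functional_class = _parse_enum(
                FunctionalClass, row["functional_class"], FunctionalClass.OTHER
            )
        if not pd.isna(row.get("sift")):
            ann.sift = _parse_enum(SiftCall, row["sift"], SiftCall.UNKNOWN)
        if not pd.isna(row.get("polyphen")):
            ann.polyphen = _parse_enum(PolyPhenCall, row["polyphen"], PolyPhenCall.UNKNOWN)
        if "cadd_phred" in row and not pd.isna(row["cadd_phred"]):
            ann.cadd_phred = float(row["cadd_phred"])
        for col, val in row.items():
            if col.lower().startswith(af_prefix) and not pd.isna(val):
                ann.panel_afs[col[len(af_prefix) :]] = float(val)
    if unmatched:
        logger.warning("%d annotation rows matched no variant", unmatched)
    return unmatched


# -- VCF writing ------------------------------------------------------------

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}


def _fmt(x: float) -> str:
    return format(x, ".6g")


def write_annotated_vcf(
    variants: Sequence[AnnotatedVariant],
    samples: Sequence[str],
    path,
) -> None:
    """Write variants as a plain-text VCF v4.2 with annotations in INFO.

    Serialised keys: ``FUNC``, ``SIFT``, ``POLYPHEN``, ``CADD`` and one
    ``AF_<panel>`` per reference panel observed anywhere in ``variants``;
    unknown predictions and absent panels are omitted per record, so a
    read-back reconstructs the same data model (floats quantised to six
    significant digits).  Every variant must carry a genotype entry for
    every listed sample.
    """
    panels = sorted({p for v in variants for p in v.annotation.panel_afs})
    chroms: list[str] = []
    for v in variants:
        if v.site.chrom not in chroms:
            chroms.append(v.site.chrom)

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=famvar\n")
        fh.write('##INFO=<ID=FUNC,Number=1,Type=String,Description="Functional class">\n')
        fh.write('##INFO=<ID=SIFT,Number=1,Type=String,Description="SIFT category">\n')
        fh.write('##INFO=<ID=POLYPHEN,Number=1,Type=String,Description="PolyPhen category">\n')
        fh.write('##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD PHRED score">\n')
        for panel in panels:
            fh.write(
                f'##INFO=<ID=AF_{panel},Number=1,Type=Float,'
                f'Description="Allele frequency in panel {panel}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")

        for v in variants:
            ann = v.annotation
            info_parts = [f"FUNC={ann.functional_class.value}"]
            if ann.sift is not SiftCall.UNKNOWN:
                info_parts.append(f"SIFT={ann.sift.value}")
            if ann.polyphen is not PolyPhenCall.UNKNOWN:
                info_parts.append(f"POLYPHEN={ann.polyphen.value}")
            if ann.cadd_phred is not None:
                info_parts.append(f"CADD={_fmt(ann.cadd_phred)}")
            for panel in panels:
                if panel in ann.panel_afs:
                    info_parts.append(f"AF_{panel}={_fmt(ann.panel_afs[panel])}")
            gt_fields = []
            for s in samples:
                if s not in v.genotypes:
                    raise VariantFormatError(
                        f"sample {s!r} has no genotype at {v.site.id}"
                    )
                gt_fields.append(_GT_STRINGS[v.genotypes[s]])
            fh.write(
                "\t".join(
                    [
                        v.site.chrom,
                        str(v.site.pos),
                        v.site.id,
                        v.site.ref,
                        v.site.alt,
                        ".",
                        "PASS",
                        ";".join(info_parts),
                        "GT",
                    ]
                    + gt_fields
                )
                + "\n"
            )
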