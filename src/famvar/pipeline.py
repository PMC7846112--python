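"""End-to-end orchestration: simulate -> prioritize -> segregate -> screen -> phenostats.

``run_full_study`` executes the whole discovery analysis on either a
synthetic study (generated from a seed) or user-provided input files, and
emits a single JSON report carrying the cascade audit trail, segregation
results, cohort screen, reference-panel aggregation, group comparisons and
provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import metadata, resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import screen as screen_mod
from .cascade import FilterConfig, run_cascade
from .pedigree import (
    Pedigree,
    read_ped,
    select_cases_for_sequencing,
    select_controls_for_sequencing,
)
from .phenostats import compare_all
from .segregation import check_cosegregation, rank_candidates
from .simulate import SimulationConfig, simulate_study, write_study
from .variants import read_annotated_vcf

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    With no input paths the study is synthesised from ``simulation``; when
    ``vcf``/``ped`` (and optionally ``annotations``/``plasma``) are given,
    those files are analysed instead.  ``n_wes_cases``/``n_wes_controls``
    set the sequencing-subset sizes (capped at the available members).
    """

    seed: int = 0
    out_dir: str | Path = "famvar_out"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    n_wes_cases: int = 4
    n_wes_controls: int = 2
    vcf: str | None = None
    ped: str | None = None
    annotations: str | None = None
    plasma: str | None = None
    cohort_n_cases: int = 6790
    cohort_n_controls: int = 5970
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        filt = FilterConfig(**raw.pop("filters", {}))
        return cls(simulation=sim, filters=filt, **raw)

    # fields with no bearing on the analysis result, excluded from the hash
    _NON_ANALYTIC = frozenset({"out_dir", "log_level"})

    def to_canonical_yaml(self) -> str:
        def plain(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return {
                    k: plain(getattr(obj, k))
                    for k in obj.__dataclass_fields__
                    if k not in RunConfig._NON_ANALYTIC
                }
            if isinstance(obj, (frozenset, set, tuple, list)):
                return sorted(str(getattr(x, "value", x)) for x in obj)
            if isinstance(obj, Path):
                return str(obj)
            return getattr(obj, "value", obj)

        return yaml.safe_dump(plain(self), sort_keys=True)


def _package_version() -> str:
    try:
        return metadata.version("famvar")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def run_full_study(config: RunConfig) -> dict:
    """Execute every stage in order and return (and write) the JSON report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # -- inputs: synthetic or user-provided --------------------------------
    if config.vcf is None and config.ped is None:
        sim_config = SimulationConfig(
            **{
                **{
                    k: getattr(config.simulation, k)
                    for k in config.simulation.__dataclass_fields__
                },
                "seed": config.seed,
            }
        )
        bundle = simulate_study(sim_config)
        paths = write_study(bundle, out_dir / "inputs")
        logger.info("synthetic study written: %s", {k: str(v) for k, v in paths.items()})
        ped, variants, plasma = bundle.pedigree, bundle.variants, bundle.plasma
        causal_id = bundle.causal_id
    else:
        if config.vcf is None or config.ped is None:
            raise ValueError("user-supplied runs need both vcf and ped paths")
        for label in ("vcf", "ped", "annotations", "plasma"):
            p = getattr(config, label)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} path does not exist: {p}")
        ped = read_ped(config.ped)
        variants = read_annotated_vcf(config.vcf, config.annotations)
        plasma = pd.read_csv(config.plasma) if config.plasma else None
        causal_id = None

    # -- subject selection --------------------------------------------------
    k = min(config.n_wes_cases, len(ped.affected))
    m = min(config.n_wes_controls, len(ped.unaffected))
    cases = sorted(select_cases_for_sequencing(ped, k))
    controls = sorted(select_controls_for_sequencing(ped, set(cases), m))
    logger.info("WES subset: %d cases %s, %d controls %s", k, cases, m, controls)

    # -- cascade ------------------------------------------------------------
    report = run_cascade(variants, cases, controls, config.filters)

    # -- co-segregation of final candidates ---------------------------------
    by_id = {v.id: v for v in variants}
    seg_results = [
        check_cosegregation(by_id[vid], ped) for vid in report.final_candidates
    ]
    seg_results = rank_candidates(seg_results)

    # -- external cohort screen ---------------------------------------------
    # Carriers of a private familial allele are not expected outside the
    # family; cohort genotypes are drawn at the aggregated reference
    # frequency, which at ~3e-6 almost surely yields zero carriers.
    aggregate = screen_mod.aggregate_panels(screen_mod.DEFAULT_REFERENCE_PANELS)
    n_total = config.cohort_n_cases + config.cohort_n_controls
    draws = rng.binomial(2, aggregate.allele_frequency, size=n_total)
    cohort_genotypes = {f"S{i:06d}": int(g) for i, g in enumerate(draws)}
    cohort_status = {
        f"S{i:06d}": ("case" if i < config.cohort_n_cases else "control")
        for i in range(n_total)
    }
    cohort = screen_mod.screen_cohort(cohort_genotypes, cohort_status, "replication")

    # -- plasma statistics ---------------------------------------------------
    comparisons = compare_all(plasma) if plasma is not None else []

    report_doc = {
        "provenance": {
            "package_version": _package_version(),
            "seed": config.seed,
            "config_sha256": hashlib.sha256(
                config.to_canonical_yaml().encode()
            ).hexdigest(),
        },
        "subjects": {"wes_cases": cases, "wes_controls": controls},
        "cascade": report.to_dict(),
        "segregation": [r.to_dict() for r in seg_results],
        "cohort_screen": cohort.to_dict(),
        "panel_aggregate": aggregate.to_dict(),
        "group_comparisons": [c.to_dict() for c in comparisons],
    }
    if causal_id is not None:
        report_doc["simulation"] = {
            "causal_id": causal_id,
            "causal_in_final_candidates": causal_id in report.final_candidates,
            "causal_cosegregates": any(
                r.variant_id == causal_id and r.cosegregates for r in seg_results
            ),
        }
    validate_report(report_doc)
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report_doc, indent=2) + "\n")
    logger.info("report written to %s", report_path)
    return report_doc


# -- report schema -----------------------------------------------------------


def report_schema() -> dict:
    """The JSON schema the pipeline report conforms to."""
    schema_text = resources.files("famvar").joinpath("report.schema.json").read_text()
    return json.loads(schema_text)


def validate_report(report: dict) -> None:
    """Structural validation of a report against the shipped schema.

    Implements the subset of JSON Schema the shipped document uses:
    required keys and primitive ``type`` checks, recursing through
    ``properties``/``items``.
    """
    _check(report, report_schema(), "$")


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
    "null": type(None),
}


def _check(node, schema: dict, path: str) -> None:
    stype = schema.get("type")
    if stype is not None:
        expected = _TYPES[stype] if isinstance(stype, str) else tuple(
            _TYPES[t] for t in stype
        )
        if isinstance(node, bool) and stype in ("number", "integer"):
            raise ValueError(f"{path}: expected {stype}, got boolean")
        if not isinstance(node, expected):
            raise ValueError(f"{path}: expected {stype}, got {type(node).__name__}")
    for key in schema.get("required", []):
        if key not in node:
            raise ValueError(f"{path}: missing required key {key!r}")
    for key, subschema in schema.get("properties", {}).items():
        if isinstance(node, dict) and key in node:
            _check(node[key], subschema, f"{path}.{key}")
    if "items" in schema and isinstance(node, list):
        for i, item in enumerate(node):
            _check(item, schema["items"], f"{path}[{i}]")
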