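"""Filtering cascade: per-filter contracts, brute-force equivalence,
commutation of the pure predicates, and causal-variant recovery."""

import itertools

import pytest

from conftest import make_variant, random_variants

from famvar.cascade import (
    FilterConfig,
    filter_absent_in_controls,
    filter_deleterious,
    filter_functional,
    filter_rare,
    filter_shared_by_cases,
    run_cascade,
)
from famvar.simulate import SimulationConfig, simulate_study
from famvar.variants import FunctionalClass, PolyPhenCall, SiftCall

CASES = ["c1", "c2", "c3", "c4"]
CONTROLS = ["u1", "u2"]
SAMPLES = CASES + CONTROLS


def brute_force_candidates(variants, cases, controls, config):
    """Single-pass predicate evaluation, independent of the staged cascade."""
    out = []
    for v in variants:
        g = v.genotypes
        shared = all(
            (g[c] is not None and g[c] >= 1)
            if config.missing_genotype_policy == "strict"
            else (g[c] is None or g[c] >= 1)
            for c in cases
        )
        carried_by_control = any(g[c] is not None and g[c] >= 1 for c in controls)
        functional = v.annotation.functional_class in config.functional_classes
        afs = v.annotation.panel_afs
        rare = (not afs) or max(afs.values()) < config.max_panel_af
        keep_unknown = config.unknown_prediction_policy == "keep"
        ann = v.annotation
        sift_ok = (
            (keep_unknown if ann.sift is SiftCall.UNKNOWN else ann.sift is SiftCall.DELETERIOUS)
            if config.require_sift_deleterious
            else True
        )
        poly_ok = (
            (
                keep_unknown
                if ann.polyphen is PolyPhenCall.UNKNOWN
                else ann.polyphen is PolyPhenCall.PROBABLY_DAMAGING
            )
            if config.require_polyphen_damaging
            else True
        )
        cadd_ok = keep_unknown if ann.cadd_phred is None else ann.cadd_phred >= config.min_cadd
        if shared and not carried_by_control and functional and rare and sift_ok and poly_ok and cadd_ok:
            out.append(v.id)
    return out


def test_shared_by_cases_examples():
    kept = make_variant({s: 1 for s in SAMPLES}, vid="kept")
    dropped = make_variant({**{s: 1 for s in SAMPLES}, "c2": 0}, vid="dropped")
    result = filter_shared_by_cases([kept, dropped], CASES, "strict")
    assert [v.id for v in result] == ["kept"]


def test_shared_by_cases_missing_policy():
    v = make_variant({**{s: 1 for s in SAMPLES}, "c1": None}, vid="v")
    assert filter_shared_by_cases([v], CASES, "strict") == []
    assert [x.id for x in filter_shared_by_cases([v], CASES, "permissive")] == ["v"]


def test_absent_in_controls_examples():
    clean = make_variant({**{c: 1 for c in CASES}, "u1": 0, "u2": 0}, vid="clean")
    het_control = make_variant({**{c: 1 for c in CASES}, "u1": 1, "u2": 0}, vid="het")
    missing_control = make_variant({**{c: 1 for c in CASES}, "u1": None, "u2": 0}, vid="miss")
    result = filter_absent_in_controls([clean, het_control, missing_control], CONTROLS, "strict")
    assert [v.id for v in result] == ["clean", "miss"]


def test_unknown_case_id_raises():
    v = make_variant({"c1": 1})
    with pytest.raises(KeyError, match="ghost"):
        filter_shared_by_cases([v], ["c1", "ghost"], "strict")


def test_functional_filter():
    config = FilterConfig()
    syn = make_variant({"c1": 1}, vid="syn", functional_class=FunctionalClass.SYNONYMOUS)
    mis = make_variant({"c1": 1}, vid="mis", functional_class=FunctionalClass.NONSYNONYMOUS)
    assert [v.id for v in filter_functional([syn, mis], config)] == ["mis"]


def test_rare_filter_thresholds():
    config = FilterConfig()
    common = make_variant({"c1": 1}, vid="common", panel_afs={"gnomAD": 0.005})
    rare = make_variant({"c1": 1}, vid="rare", panel_afs={"gnomAD": 0.0005})
    unobserved = make_variant({"c1": 1}, vid="unobs", panel_afs={})
    borderline = make_variant({"c1": 1}, vid="edge", panel_afs={"gnomAD": 0.001})
    kept = [v.id for v in filter_rare([common, rare, unobserved, borderline], config)]
    assert kept == ["rare", "unobs"]  # strict < 1 per mille; unobserved retained


def test_deleterious_filter_policies():
    benign = make_variant({"c1": 1}, vid="benign", polyphen=PolyPhenCall.BENIGN)
    unknown = make_variant(
        {"c1": 1}, vid="unknown", sift=SiftCall.UNKNOWN, polyphen=PolyPhenCall.UNKNOWN, cadd=None
    )
    causal_like = make_variant({"c1": 1}, vid="causal")
    keep = FilterConfig(unknown_prediction_policy="keep")
    drop = FilterConfig(unknown_prediction_policy="drop")
    assert [v.id for v in filter_deleterious([benign, unknown, causal_like], keep)] == [
        "unknown",
        "causal",
    ]
    assert [v.id for v in filter_deleterious([benign, unknown, causal_like], drop)] == ["causal"]


def test_low_cadd_dropped():
    v = make_variant({"c1": 1}, vid="low", cadd=12.0)
    assert filter_deleterious([v], FilterConfig()) == []


def test_cascade_counts_non_increasing_and_chained():
    variants = random_variants(300, SAMPLES, seed=1)
    report = run_cascade(variants, CASES, CONTROLS, FilterConfig())
    assert [s.name for s in report.stages] == [
        "shared_by_cases",
        "absent_in_controls",
        "functional",
        "rare",
        "deleterious",
    ]
    for prev, cur in zip(report.stages, report.stages[1:]):
        assert cur.input_count == prev.output_count
    for s in report.stages:
        assert s.output_count <= s.input_count
        assert len(s.survivor_ids) == s.output_count


def test_cascade_survivors_are_nested_subsets():
    variants = random_variants(300, SAMPLES, seed=2)
    report = run_cascade(variants, CASES, CONTROLS, FilterConfig())
    previous = {v.id for v in variants}
    for s in report.stages:
        current = set(s.survivor_ids)
        assert current <= previous
        previous = current


@pytest.mark.parametrize("policy", ["strict", "permissive"])
@pytest.mark.parametrize("unknown_policy", ["keep", "drop"])
def test_cascade_equals_brute_force(policy, unknown_policy):
    config = FilterConfig(
        missing_genotype_policy=policy, unknown_prediction_policy=unknown_policy
    )
    variants = random_variants(1000, SAMPLES, seed=7)
    report = run_cascade(variants, CASES, CONTROLS, config)
    assert report.final_candidates == brute_force_candidates(variants, CASES, CONTROLS, config)


def test_pure_predicate_filters_commute():
    config = FilterConfig()
    variants = random_variants(400, SAMPLES, seed=4)
    filters = {
        "functional": lambda vs: filter_functional(vs, config),
        "rare": lambda vs: filter_rare(vs, config),
        "deleterious": lambda vs: filter_deleterious(vs, config),
    }
    results = set()
    for order in itertools.permutations(filters):
        vs = variants
        for name in order:
            vs = filters[name](vs)
        results.add(tuple(sorted(v.id for v in vs)))
    assert len(results) == 1


def test_control_carrying_everything_empties_stage_two():
    variants = [
        make_variant({**{s: 1 for s in SAMPLES}}, vid=f"v{i}") for i in range(5)
    ]
    report = run_cascade(variants, CASES, CONTROLS, FilterConfig())
    assert report.stages[1].output_count == 0
    assert report.final_candidates == []


def test_empty_variant_list_rejected():
    with pytest.raises(ValueError):
        run_cascade([], CASES, CONTROLS, FilterConfig())


def test_causal_variant_survives_default_study():
    """The planted causal variant reaches the final candidate list."""
    for seed in (0, 1, 2):
        bundle = simulate_study(SimulationConfig(seed=seed, n_background_variants=2000))
        ped = bundle.pedigree
        report = run_cascade(bundle.variants, ped.affected, ped.unaffected, FilterConfig())
        assert bundle.causal_id in report.final_candidates
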