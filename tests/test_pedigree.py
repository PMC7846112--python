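"""Pedigree parsing, validation, kinship, and subset selection."""

import itertools

import numpy as np
import pytest

from famvar.pedigree import (
    Individual,
    Pedigree,
    PedigreeError,
    Sex,
    Status,
    read_ped,
    select_cases_for_sequencing,
    select_controls_for_sequencing,
    write_ped,
)
from famvar.simulate import estimate_kinship_mc, template_pedigree


# -- construction and parsing ------------------------------------------------


def test_individual_requires_both_parents_or_neither():
    with pytest.raises(PedigreeError, match="one parent"):
        Individual("x", father_id="f", mother_id=None)


def test_duplicate_ids_rejected():
    rows = [Individual("a"), Individual("a")]
    with pytest.raises(PedigreeError, match="duplicate"):
        Pedigree(rows)


def test_dangling_parent_rejected():
    rows = [Individual("kid", father_id="ghost_f", mother_id="ghost_m")]
    with pytest.raises(PedigreeError, match="dangling"):
        Pedigree(rows)


def test_wrong_parental_sex_rejected():
    rows = [
        Individual("dad", sex=Sex.FEMALE),
        Individual("mom", sex=Sex.FEMALE),
        Individual("kid", father_id="dad", mother_id="mom"),
    ]
    with pytest.raises(PedigreeError, match="father"):
        Pedigree(rows)


def test_unknown_parental_sex_warns_not_errors():
    rows = [
        Individual("dad", sex=Sex.UNKNOWN),
        Individual("mom", sex=Sex.FEMALE),
        Individual("kid", father_id="dad", mother_id="mom"),
    ]
    with pytest.warns(UserWarning, match="unknown sex"):
        ped = Pedigree(rows)
    assert len(ped) == 3


def test_ped_round_trip(tmp_path, family):
    path = tmp_path / "fam.ped"
    write_ped(family, path)
    back = read_ped(path)
    assert back.ids == family.ids
    for ind in family:
        other = back[ind.id]
        assert (other.father_id, other.mother_id, other.sex, other.status) == (
            ind.father_id,
            ind.mother_id,
            ind.sex,
            ind.status,
        )
    assert len(back.affected) == 5


def test_ped_parse_error_names_line(tmp_path):
    path = tmp_path / "bad.ped"
    path.write_text("FAM a 0 0 1 1\nFAM b 0 0\n")
    with pytest.raises(PedigreeError, match="bad.ped:2"):
        read_ped(path)


def test_empty_ped_file_rejected(tmp_path):
    path = tmp_path / "empty.ped"
    path.write_text("")
    with pytest.raises(PedigreeError, match="no individuals"):
        read_ped(path)


def test_own_parent_cycle_rejected(tmp_path):
    path = tmp_path / "cycle.ped"
    path.write_text("FAM mom 0 0 2 1\nFAM a a mom 1 1\n")
    with pytest.raises(PedigreeError, match="cycle"):
        read_ped(path)


def test_ped_codes_map_to_model(tmp_path):
    path = tmp_path / "codes.ped"
    path.write_text("F1 p1 0 0 1 2\nF1 p2 0 0 2 -9\nF1 c1 p1 p2 0 0\n")
    ped = read_ped(path)
    assert ped["p1"].sex is Sex.MALE and ped["p1"].status is Status.AFFECTED
    assert ped["p2"].status is Status.UNKNOWN
    assert ped["c1"].sex is Sex.UNKNOWN and ped["c1"].status is Status.UNKNOWN


# -- kinship ----------------------------------------------------------------


def small_nuclear():
    return Pedigree(
        [
            Individual("dad", sex=Sex.MALE),
            Individual("mom", sex=Sex.FEMALE),
            Individual("kid1", "dad", "mom"),
            Individual("kid2", "dad", "mom"),
        ]
    )


def test_kinship_closed_forms(family):
    ped = small_nuclear()
    assert ped.kinship("dad", "dad") == 0.5  # non-inbred self
    assert ped.kinship("dad", "mom") == 0.0  # founders unrelated
    assert ped.kinship("dad", "kid1") == 0.25  # parent-offspring
    assert ped.kinship("kid1", "kid2") == 0.25  # full sibs
    assert family.kinship("305000", "305012") == 0.0625  # first cousins


def test_kinship_unknown_id_raises(family):
    with pytest.raises(KeyError):
        family.kinship("305000", "nobody")


def test_kinship_symmetric_and_bounded(family):
    ids = family.ids
    for i, j in itertools.combinations(ids, 2):
        pij, pji = family.kinship(i, j), family.kinship(j, i)
        assert pij == pji
        assert pij <= max(family.kinship(i, i), family.kinship(j, j))


def test_kinship_handles_inbreeding():
    # father x daughter mating: child of self-kinship 1/2(1 + 1/4)
    ped = Pedigree(
        [
            Individual("f", sex=Sex.MALE),
            Individual("m", sex=Sex.FEMALE),
            Individual("d", "f", "m", Sex.FEMALE),
            Individual("c", "f", "d"),
        ]
    )
    assert ped.kinship("c", "c") == pytest.approx(0.5 * (1 + 0.25))


def test_kinship_matches_gene_dropping_monte_carlo(family):
    """Recursive kinship equals labelled-allele gene-dropping within 3 SE."""
    est, se, order = estimate_kinship_mc(family, n_drops=60_000, rng=np.random.default_rng(7))
    for a, i in zip(order, range(len(order))):
        for b, j in zip(order, range(len(order))):
            phi = family.kinship(a, b)
            tol = 3 * se[i, j] + 1e-12
            assert abs(est[i, j] - phi) <= tol, (a, b, est[i, j], phi)


# -- subset selection --------------------------------------------------------


def exhaustive_cases(ped, k):
    """Independent brute-force enumerator for the case-selection rule."""
    best, best_key = None, None
    for subset in itertools.combinations(sorted(ped.affected), k):
        s = sum(ped.kinship(a, b) for a, b in itertools.combinations(subset, 2))
        key = (s, subset)
        if best_key is None or key < best_key:
            best_key, best = key, set(subset)
    return best


def exhaustive_controls(ped, cases, m):
    best, best_key = None, None
    for subset in itertools.combinations(sorted(ped.unaffected), m):
        s = sum(ped.kinship(u, c) for u in subset for c in cases)
        key = (-s, subset)
        if best_key is None or key < best_key:
            best_key, best = key, set(subset)
    return best


@pytest.mark.parametrize("k", [2, 3, 4, 5])
def test_case_selection_matches_enumeration(family, k):
    assert select_cases_for_sequencing(family, k) == exhaustive_cases(family, k)


@pytest.mark.parametrize("m", [1, 2, 3])
def test_control_selection_matches_enumeration(family, m):
    cases = select_cases_for_sequencing(family, 4)
    assert select_controls_for_sequencing(family, cases, m) == exhaustive_controls(
        family, cases, m
    )


def test_selecting_all_affected_returns_them(family):
    assert select_cases_for_sequencing(family, 5) == set(family.affected)


def test_selecting_all_unaffected_returns_them(family):
    cases = set(family.affected)
    assert select_controls_for_sequencing(family, cases, 10) == set(family.unaffected)


def test_k_exceeding_affected_count_raises(family):
    with pytest.raises(ValueError, match="exceeds"):
        select_cases_for_sequencing(family, 6)


def test_sibling_of_case_beats_unrelated_married_in(family):
    """A married-in spouse with no affected descendants is never preferred
    over a full sibling of the cases."""
    cases = set(family.affected)
    chosen = select_controls_for_sequencing(family, cases, 1)
    # 305006 married into the family and has only unaffected children
    assert chosen != {"305006"}
    (pick,) = chosen
    score = lambda u: sum(family.kinship(u, c) for c in cases)
    assert score(pick) >= score("305005")  # 305005 is a full sib of gen-II cases


def test_tie_break_is_lexicographic():
    # two unaffected members with identical kinship to the single case
    ped = Pedigree(
        [
            Individual("dad", sex=Sex.MALE, status=Status.UNAFFECTED),
            Individual("mom", sex=Sex.FEMALE, status=Status.UNAFFECTED),
            Individual("a_kid", "dad", "mom", Sex.FEMALE, Status.UNAFFECTED),
            Individual("b_kid", "dad", "mom", Sex.MALE, Status.UNAFFECTED),
            Individual("c_case", "dad", "mom", Sex.MALE, Status.AFFECTED),
        ]
    )
    assert select_controls_for_sequencing(ped, {"c_case"}, 1) == {"a_kid"}
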