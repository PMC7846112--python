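"""Pedigree parsing, validation, kinship, and sequencing-subset selection.

A :class:`Pedigree` is the backbone of a family study: it defines who is
affected, who is related to whom, and therefore which carrier patterns are
compatible with dominant inheritance.  Kinship coefficients (Wright's
:math:`\\varphi`) quantify genealogical closeness and drive the choice of
which affected members to exome-sequence ("most distant" cases maximise the
chance that shared variants are disease-related rather than simply familial)
and which unaffected members serve as sequenced controls ("genetically
close" controls remove the familial background most efficiently).
"""

from __future__ import annotations

import enum
import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Status(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class PedigreeError(ValueError):
    """Raised for malformed or internally inconsistent pedigrees."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id``/``mother_id`` are either both set or both ``None``
    (a founder); a single known parent is not representable.
    """

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    status: Status = Status.UNKNOWN

    def __post_init__(self) -> None:
        if not self.id:
            raise PedigreeError("individual id must be non-empty")
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"individual {self.id!r} has exactly one parent recorded; "
                "pedigrees require both parents or neither"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


class Pedigree:
    """An ordered, validated collection of :class:`Individual` records.

    Validation enforces: unique non-empty ids, parent references resolving
    within the pedigree, fathers male / mothers female where sex is known
    (unknown parental sex is accepted with a warning), and acyclicity of
    the parent relation.
    """

    def __init__(self, individuals: Iterable[Individual], name: str = "family"):
        self.name = name
        self._members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._members:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self._members[ind.id] = ind
        if not self._members:
            raise PedigreeError("pedigree contains no individuals")
        self._validate_parents()
        self._depth = self._compute_depths()  # also proves acyclicity
        self._kinship_memo: dict[tuple[str, str], float] = {}

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members.values())

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._members

    def __getitem__(self, ind_id: str) -> Individual:
        try:
            return self._members[ind_id]
        except KeyError:
            raise KeyError(f"no individual {ind_id!r} in pedigree {self.name!r}") from None

    @property
    def ids(self) -> list[str]:
        return list(self._members)

    @property
    def affected(self) -> list[str]:
        return [i.id for i in self if i.status is Status.AFFECTED]

    @property
    def unaffected(self) -> list[str]:
        return [i.id for i in self if i.status is Status.UNAFFECTED]

    @property
    def founders(self) -> list[str]:
        return [i.id for i in self if i.is_founder]

    def depth(self, ind_id: str) -> int:
        """Generation depth: 0 for founders, 1 + max(parent depths) otherwise."""
        return self._depth[ind_id]

    def topological_order(self) -> list[str]:
        """Ids sorted so every parent precedes its children."""
        return sorted(self._members, key=lambda i: (self._depth[i], i))

    def ancestors(self, ind_id: str) -> set[str]:
        """All strict ancestors of ``ind_id``."""
        out: set[str] = set()
        stack = [ind_id]
        while stack:
            ind = self._members[stack.pop()]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in out:
                    out.add(pid)
                    stack.append(pid)
        return out

    def with_statuses(self, statuses: Mapping[str, Status]) -> "Pedigree":
        """A copy of this pedigree with affection statuses replaced."""
        new = [
            Individual(i.id, i.father_id, i.mother_id, i.sex, statuses.get(i.id, i.status))
            for i in self
        ]
        return Pedigree(new, name=self.name)

    # -- validation ---------------------------------------------------------

    def _validate_parents(self) -> None:
        dangling = []
        for ind in self:
            for pid, role, want in (
                (ind.father_id, "father", Sex.MALE),
                (ind.mother_id, "mother", Sex.FEMALE),
            ):
                if pid is None:
                    continue
                parent = self._members.get(pid)
                if parent is None:
                    dangling.append(pid)
                    continue
                if parent.sex is Sex.UNKNOWN:
                    warnings.warn(
                        f"{role} {pid!r} of {ind.id!r} has unknown sex",
                        stacklevel=3,
                    )
                elif parent.sex is not want:
                    raise PedigreeError(
                        f"{role} {pid!r} of {ind.id!r} is recorded as {parent.sex.value}"
                    )
        if dangling:
            raise PedigreeError(f"dangling parent ids: {sorted(set(dangling))}")

    def _compute_depths(self) -> dict[str, int]:
        depth: dict[str, int] = {}
        in_progress: set[str] = set()

        def visit(ind_id: str) -> int:
            if ind_id in depth:
                return depth[ind_id]
            if ind_id in in_progress:
                raise PedigreeError(f"parent cycle involving individual {ind_id!r}")
            in_progress.add(ind_id)
            ind = self._members[ind_id]
            d = 0 if ind.is_founder else 1 + max(visit(ind.father_id), visit(ind.mother_id))
            in_progress.discard(ind_id)
            depth[ind_id] = d
            return d

        for i in self._members:
            visit(i)
        return depth

    # -- kinship ------------------------------------------------------------

    def kinship(self, i: str, j: str) -> float:
        """Wright's kinship coefficient :math:`\\varphi(i,j)`.

        The probability that one allele sampled at random from ``i`` and one
        from ``j`` are identical by descent, under the convention that
        founders are mutually unrelated and non-inbred.  Computed by the
        standard recursion

        .. math::
           \\varphi(i,i) = \\tfrac12\\,(1 + \\varphi(f_i, m_i)), \\qquad
           \\varphi(i,j) = \\tfrac12\\,(\\varphi(f_j, i) + \\varphi(m_j, i)),

        where in the second form ``j`` is chosen as the individual of
        greater generation depth (so it cannot be an ancestor of ``i``).
        Inbred pedigrees are handled by the recursion itself.
        """
        for x in (i, j):
            if x not in self._members:
                raise KeyError(f"no individual {x!r} in pedigree {self.name!r}")
        return self._phi(i, j)

    def _phi(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        memo = self._kinship_memo
        if key in memo:
            return memo[key]
        ind_a = self._members[a]
        if a == b:
            inb = 0.0 if ind_a.is_founder else self._phi(ind_a.father_id, ind_a.mother_id)
            val = 0.5 * (1.0 + inb)
        else:
            # Recurse on the deeper member; at equal depth neither is an
            # ancestor of the other, so either choice terminates.
            if self._depth[a] < self._depth[b]:
                a, b = b, a
                ind_a = self._members[a]
            if ind_a.is_founder:
                val = 0.0  # two founders, or a founder unrelated to b
            else:
                val = 0.5 * (self._phi(ind_a.father_id, b) + self._phi(ind_a.mother_id, b))
        memo[key] = val
        return val

    def kinship_matrix(self, ids: list[str] | None = None):
        """Dense kinship matrix over ``ids`` (default: all members, pedigree order)."""
        import numpy as np

        ids = ids if ids is not None else self.ids
        n = len(ids)
        phi = np.empty((n, n))
        for r, i in enumerate(ids):
            for c, j in enumerate(ids[r:], start=r):
                phi[r, c] = phi[c, r] = self.kinship(i, j)
        return phi


# -- PED I/O ----------------------------------------------------------------

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}
_STATUS_CODES = {"1": Status.UNAFFECTED, "2": Status.AFFECTED}


def read_ped(path, family: str | None = None) -> Pedigree:
    """Read a PLINK-style 6-column PED file into a :class:`Pedigree`.

    Columns: family, individual, father, mother, sex, phenotype
    (whitespace-delimited; extra columns ignored).  Codes: parent ``0`` =
    missing; sex ``1``/``2`` = male/female, anything else unknown;
    phenotype ``1``/``2`` = unaffected/affected, ``0``/``-9`` unknown.

    ``family`` selects one family id when the file holds several; with the
    default ``None`` the file must contain exactly one family.
    """
    rows: list[tuple[str, Individual]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeError(
                    f"{path}:{lineno}: expected >=6 whitespace-delimited fields, "
                    f"got {len(fields)}"
                )
            fam, ind_id, father, mother, sex, pheno = fields[:6]
            try:
                ind = Individual(
                    id=ind_id,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=_SEX_CODES.get(sex, Sex.UNKNOWN),
                    status=_STATUS_CODES.get(pheno, Status.UNKNOWN),
                )
            except PedigreeError as exc:
                raise PedigreeError(f"{path}:{lineno}: {exc}") from exc
            rows.append((fam, ind))
    families = {fam for fam, _ in rows}
    if not families:
        raise PedigreeError(f"{path}: no individuals found")
    if family is None:
        if len(families) > 1:
            raise PedigreeError(
                f"{path}: multiple families {sorted(families)}; pass family= to select one"
            )
        family = next(iter(families))
    elif family not in families:
        raise PedigreeError(f"{path}: family {family!r} not present")
    return Pedigree((ind for fam, ind in rows if fam == family), name=family)


def write_ped(ped: Pedigree, path) -> None:
    """Write a pedigree as a PLINK-style 6-column PED file."""
    sex_out = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    status_out = {Status.UNAFFECTED: "1", Status.AFFECTED: "2", Status.UNKNOWN: "0"}
    with open(path, "w") as fh:
        for ind in ped:
            fh.write(
                "\t".join(
                    [
                        ped.name,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        sex_out[ind.sex],
                        status_out[ind.status],
                    ]
                )
                + "\n"
            )


# -- sequencing-subset selection --------------------------------------------


def _best_subset(
    ped: Pedigree,
    candidates: list[str],
    k: int,
    score,
    *,
    minimize: bool,
) -> set[str]:
    """Exhaustively score all k-subsets of ``candidates``.

    Candidates are iterated in sorted-id order and only strict improvements
    replace the incumbent, so ties resolve to the lexicographically first
    sorted subset.
    """
    best: tuple[str, ...] | None = None
    best_score = None
    sign = 1.0 if minimize else -1.0
    for subset in itertools.combinations(sorted(candidates), k):
        s = sign * score(subset)
        if best_score is None or s < best_score:
            best_score, best = s, subset
    assert best is not None
    return set(best)


def select_cases_for_sequencing(ped: Pedigree, k: int) -> set[str]:
    """The ``k`` affected members minimising summed pairwise kinship.

    Operationalises "the most genealogically distant affected relatives":
    distant cases share the least background genome, so a variant carried by
    all of them is unlikely to be shared by chance.  Exhaustive over all
    C(n_affected, k) subsets; ties break to the lexicographically first
    sorted id set.
    """
    affected = ped.affected
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(affected):
        raise ValueError(f"k={k} exceeds affected count {len(affected)}")

    def score(subset: tuple[str, ...]) -> float:
        return sum(ped.kinship(a, b) for a, b in itertools.combinations(subset, 2))

    return _best_subset(ped, affected, k, score, minimize=True)


def select_controls_for_sequencing(ped: Pedigree, cases: set[str], m: int) -> set[str]:
    """The ``m`` unaffected members maximising summed kinship to ``cases``.

    Genetically close controls share the familial background with the cases,
    so subtracting their variants removes the most non-causal candidates.
    """
    unaffected = ped.unaffected
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > len(unaffected):
        raise ValueError(f"m={m} exceeds unaffected count {len(unaffected)}")
    for c in cases:
        if c not in ped:
            raise KeyError(f"case {c!r} not in pedigree")

    def score(subset: tuple[str, ...]) -> float:
        return sum(ped.kinship(u, c) for u in subset for c in cases)

    return _best_subset(ped, unaffected, m, score, minimize=False)
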