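"""Pedigree input/output, validation and the breadth-first expansion schedule.

A pedigree is a completely observed genealogy descending from exactly one
founding pair: every individual other than the two founders has both
parents recorded in the file.  Phenotypes are binary, sex-limited (female
only) and partially observed: a female is either affected, unaffected, or
unobserved; males are always unobserved.

File format: tab-separated with a header row and columns
``id  sire  dam  sex  first_year  last_year  phenotype``.
Missing parents are encoded ``0`` (PED convention); a missing phenotype is
``NA``.  Sex accepts ``F``/``female``/``2`` and ``M``/``male``/``1``.

The breadth-first expansion schedule is the nested sequence of
sub-pedigrees consumed by the sequential Monte Carlo likelihood: it starts
from the founding pair and at each level adds every individual whose
parents are both already included, so every individual appears exactly
once and after both parents even through inbreeding loops.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator

import networkx as nx
import pandas as pd

from .genetics import AFFECTED, FEMALE, MALE, UNAFFECTED, UNOBSERVED

COLUMNS = ["id", "sire", "dam", "sex", "first_year", "last_year", "phenotype"]

_MISSING_PARENT = "0"
_MISSING_PHENOTYPE = "NA"

_SEX_CODES = {
    "f": FEMALE, "female": FEMALE, "2": FEMALE,
    "m": MALE, "male": MALE, "1": MALE,
}
_PHENOTYPE_CODES = {
    "affected": AFFECTED, "2": AFFECTED,
    "unaffected": UNAFFECTED, "1": UNAFFECTED,
    "na": UNOBSERVED, "0": UNOBSERVED, "": UNOBSERVED,
}


class PedigreeError(ValueError):
    """Base class for pedigree validation errors."""


class NoIndividualsError(PedigreeError):
    pass


class MissingColumnError(PedigreeError):
    pass


class DuplicateIdError(PedigreeError):
    pass


class UnknownParentError(PedigreeError):
    pass


class PartialParentageError(PedigreeError):
    """An individual with exactly one recorded parent (immigrants and
    half-founders are rejected: the model space assumes one founding pair)."""


class ParentSexError(PedigreeError):
    pass


class MalePhenotypeError(PedigreeError):
    pass


class CycleError(PedigreeError):
    pass


class FounderCountError(PedigreeError):
    pass


class ChronologyError(PedigreeError):
    pass


class UnreachableIndividualError(PedigreeError):
    pass


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``sire``/``dam`` are ``None`` for the two founders.  ``first_year``
    and ``last_year`` bound the years the individual is present in the
    population (inclusive).  ``phenotype`` is one of ``affected``,
    ``unaffected``, ``unobserved``; males are always ``unobserved``.
    """

    id: str
    sire: str | None
    dam: str | None
    sex: str
    first_year: int
    last_year: int
    phenotype: str = UNOBSERVED

    @property
    def is_founder(self) -> bool:
        return self.sire is None and self.dam is None

    @property
    def observed(self) -> bool:
        return self.phenotype != UNOBSERVED


@dataclass(frozen=True)
class ExpansionSchedule:
    """Breadth-first nested sub-pedigree sequence.

    ``increments[k]`` is the pair (ids added at level k, subset of those
    ids with an observed phenotype); level 0 is the founding pair.
    """

    increments: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]

    def __iter__(self):
        return iter(self.increments)

    def __len__(self):
        return len(self.increments)

    @property
    def ids(self) -> list[str]:
        """All ids flattened in schedule order."""
        return [i for ids, _ in self.increments for i in ids]


class Pedigree:
    """A validated one-founding-pair pedigree with partial phenotypes."""

    def __init__(self, individuals: list[Individual]):
        self._individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._individuals:
                raise DuplicateIdError(f"duplicate individual id {ind.id!r}")
            self._individuals[ind.id] = ind
        self._validate()

    # -- container protocol -------------------------------------------------
    def __iter__(self) -> Iterator[Individual]:
        return iter(self._individuals.values())

    def __len__(self) -> int:
        return len(self._individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self._individuals

    def __getitem__(self, iid: str) -> Individual:
        return self._individuals[iid]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return self._individuals == other._individuals

    # -- derived views ------------------------------------------------------
    @property
    def founders(self) -> tuple[str, str]:
        """(founding female id, founding male id)."""
        f = [i for i in self if i.is_founder]
        female = next(i.id for i in f if i.sex == FEMALE)
        male = next(i.id for i in f if i.sex == MALE)
        return (female, male)

    @property
    def years(self) -> range:
        lo = min(i.first_year for i in self)
        hi = max(i.last_year for i in self)
        return range(lo, hi + 1)

    def females(self, observed_only: bool = False) -> list[Individual]:
        return [
            i for i in self
            if i.sex == FEMALE and (i.observed or not observed_only)
        ]

    def children_of(self, iid: str) -> list[Individual]:
        return [i for i in self if iid in (i.sire, i.dam)]

    def alive_in(self, year: int) -> list[Individual]:
        return [i for i in self if i.first_year <= year <= i.last_year]

    def with_phenotypes(self, phenotypes: dict[str, str]) -> "Pedigree":
        """A copy with the phenotype of selected individuals replaced."""
        return Pedigree([
            replace(i, phenotype=phenotypes.get(i.id, i.phenotype))
            for i in self
        ])

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        if not self._individuals:
            raise NoIndividualsError("no individuals in pedigree")
        founders = []
        for ind in self:
            if (ind.sire is None) != (ind.dam is None):
                raise PartialParentageError(
                    f"{ind.id}: exactly one parent recorded; individuals must "
                    "have both parents present or be founders"
                )
            if ind.is_founder:
                founders.append(ind)
                continue
            for parent_id, want_sex, role in (
                (ind.sire, MALE, "sire"),
                (ind.dam, FEMALE, "dam"),
            ):
                if parent_id not in self._individuals:
                    raise UnknownParentError(
                        f"{ind.id}: unknown {role} id {parent_id!r}"
                    )
                parent = self._individuals[parent_id]
                if parent.sex != want_sex:
                    raise ParentSexError(
                        f"{ind.id}: {role} {parent_id} is not {want_sex}"
                    )
        if len(founders) != 2 or {f.sex for f in founders} != {FEMALE, MALE}:
            raise FounderCountError(
                f"expected exactly one founding pair (one female, one male); "
                f"found founders {[f.id for f in founders]}"
            )
        for ind in self:
            if ind.sex == MALE and ind.phenotype != UNOBSERVED:
                raise MalePhenotypeError(
                    f"{ind.id}: male with non-missing phenotype "
                    f"{ind.phenotype!r} (trait is sex-limited to females)"
                )
            if ind.last_year < ind.first_year:
                raise ChronologyError(
                    f"{ind.id}: last_year {ind.last_year} precedes "
                    f"first_year {ind.first_year}"
                )
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise CycleError(f"parent links contain a cycle: {cyc}")
        for ind in self:
            if ind.is_founder:
                continue
            for pid in (ind.sire, ind.dam):
                if self._individuals[pid].first_year >= ind.first_year:
                    raise ChronologyError(
                        f"{ind.id}: parent {pid} first_year does not "
                        f"precede the offspring's first_year"
                    )

    def graph(self) -> nx.DiGraph:
        """Parent -> child directed graph."""
        g = nx.DiGraph()
        g.add_nodes_from(self._individuals)
        for ind in self:
            if not ind.is_founder:
                g.add_edge(ind.sire, ind.id)
                g.add_edge(ind.dam, ind.id)
        return g


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_row(row: pd.Series) -> Individual:
    iid = str(row["id"]).strip()
    sire = str(row["sire"]).strip()
    dam = str(row["dam"]).strip()
    sex_token = str(row["sex"]).strip().lower()
    if sex_token not in _SEX_CODES:
        raise PedigreeError(f"{iid}: unknown sex code {row['sex']!r}")
    phen_token = str(row["phenotype"]).strip().lower()
    if phen_token not in _PHENOTYPE_CODES:
        raise PedigreeError(f"{iid}: unknown phenotype code {row['phenotype']!r}")
    return Individual(
        id=iid,
        sire=None if sire == _MISSING_PARENT else sire,
        dam=None if dam == _MISSING_PARENT else dam,
        sex=_SEX_CODES[sex_token],
        first_year=int(row["first_year"]),
        last_year=int(row["last_year"]),
        phenotype=_PHENOTYPE_CODES[phen_token],
    )


def read_pedigree(path: str | Path | io.IOBase, sep: str = "\t") -> Pedigree:
    """Read and validate a pedigree-plus-phenotype table (TSV by default;
    ``sep`` admits other delimited dialects).

    Raises a named :class:`PedigreeError` subclass for each distinct
    violation (missing columns, unknown parents, cycles, male phenotypes,
    parent-sex inconsistencies, more or fewer than one founding pair...).
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"missing required columns: {missing}")
    if df.empty:
        raise NoIndividualsError("no individuals in pedigree file")
    return Pedigree([_parse_row(row) for _, row in df.iterrows()])


def to_frame(ped: Pedigree) -> pd.DataFrame:
    """Pedigree as a DataFrame in the on-disk column layout."""
    phen_out = {AFFECTED: "affected", UNAFFECTED: "unaffected",
                UNOBSERVED: _MISSING_PHENOTYPE}
    rows = [
        {
            "id": i.id,
            "sire": i.sire if i.sire is not None else _MISSING_PARENT,
            "dam": i.dam if i.dam is not None else _MISSING_PARENT,
            "sex": "F" if i.sex == FEMALE else "M",
            "first_year": i.first_year,
            "last_year": i.last_year,
            "phenotype": phen_out[i.phenotype],
        }
        for i in ped
    ]
    return pd.DataFrame(rows, columns=COLUMNS)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    """Write a pedigree TSV that round-trips through :func:`read_pedigree`."""
    to_frame(ped).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Breadth-first expansion schedule
# ---------------------------------------------------------------------------

def breadth_first_schedule(ped: Pedigree) -> ExpansionSchedule:
    """Breadth-first nested sub-pedigree schedule from the founding pair.

    Level 0 is the founding pair (female first); each subsequent level
    contains every not-yet-included individual both of whose parents are
    already included, sorted lexicographically by id within the level.
    The likelihood is invariant to the within-level order; the sort makes
    runs bit-reproducible.  An individual that can never be reached (not
    descended from the founding pair) raises
    :class:`UnreachableIndividualError` — the one-pair validation makes
    this unreachable in practice, but the check guards hand-built inputs.
    """
    included: set[str] = set()
    increments = []
    founders = ped.founders
    level: list[str] = list(founders)
    while level:
        observed = tuple(i for i in level if ped[i].observed)
        increments.append((tuple(level), observed))
        included.update(level)
        level = sorted(
            i.id for i in ped
            if i.id not in included
            and not i.is_founder
            and i.sire in included and i.dam in included
        )
    remaining = [i.id for i in ped if i.id not in included]
    if remaining:
        raise UnreachableIndividualError(
            f"individuals not reachable from the founding pair: {remaining}"
        )
    return ExpansionSchedule(tuple(increments))
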