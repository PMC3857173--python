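"""Single-locus genetics for a sex-limited binary trait in a ZW species.

A biallelic locus (alleles ``a`` and ``A``) is modelled either on an
autosome or on the Z chromosome.  Birds have ZW sex determination: males
are ZZ (two Z-linked alleles), females are ZW and therefore hemizygous at
a Z-linked locus (a single expressed allele; the W is assumed to carry no
copy of the locus).

Genotypes are *parentally ordered*: the first allele is the maternal one,
the second the paternal one, so ``aA`` and ``Aa`` are distinct states.
All observable quantities are invariant to this convention (mirror
symmetry, enforced by the test suite).

The trait is sex-limited: it is expressed only in females, with full
penetrance — a female's phenotype is a deterministic function of her
genotype under a given inheritance model.  Males carry and transmit the
alleles but never express the trait.

The model space is the cross product of the 4 x 4 ordered founder
genotype pairs, dominant vs recessive expression, and autosomal vs
Z-linked location: 64 models in total.  On the Z, a female founder is
hemizygous, so the two heterozygous female labels do not correspond to a
realisable state; those models are kept in the enumeration (preserving
the 64-model bookkeeping) but flagged invalid and carry zero likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

ALLELES = ("a", "A")

FEMALE = "female"
MALE = "male"

AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNOBSERVED = "unobserved"
NOT_EXPRESSED = "not_expressed"

DOMINANT = "dominant"
RECESSIVE = "recessive"

AUTOSOME = "autosome"
Z = "Z"

_DIPLOID_LABELS = ("aa", "aA", "Aa", "AA")


class GeneticsError(ValueError):
    """Invalid genotype/sex/location combination."""


@dataclass(frozen=True)
class OrderedGenotype:
    """A parentally ordered genotype.

    ``alleles`` has length 2 for diploid genotypes, ordered
    (maternal, paternal), or length 1 for hemizygous genotypes
    (females at a Z-linked locus).
    """

    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) not in (1, 2) or any(x not in ALLELES for x in self.alleles):
            raise GeneticsError(f"invalid genotype alleles: {self.alleles!r}")

    @classmethod
    def diploid(cls, maternal: str, paternal: str) -> "OrderedGenotype":
        return cls((maternal, paternal))

    @classmethod
    def hemizygous(cls, allele: str) -> "OrderedGenotype":
        return cls((allele,))

    @classmethod
    def from_label(cls, label: str) -> "OrderedGenotype":
        """Parse ``"aA"`` (ordered maternal-paternal) or ``"A"`` (hemizygous)."""
        return cls(tuple(label))

    @property
    def hemizygous_flag(self) -> bool:
        return len(self.alleles) == 1

    @property
    def label(self) -> str:
        return "".join(self.alleles)

    @property
    def n_copies_A(self) -> int:
        return sum(x == "A" for x in self.alleles)

    @property
    def code(self) -> int:
        """Integer state code: diploid 2*maternal + paternal, hemizygous the
        allele itself, with a=0 and A=1."""
        bits = [ALLELES.index(x) for x in self.alleles]
        if len(bits) == 1:
            return bits[0]
        return 2 * bits[0] + bits[1]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def genotype_from_code(code: int, hemizygous: bool) -> OrderedGenotype:
    if hemizygous:
        return OrderedGenotype.hemizygous(ALLELES[code])
    return OrderedGenotype.diploid(ALLELES[code >> 1], ALLELES[code & 1])


@dataclass(frozen=True)
class InheritanceModel:
    """One fully specified single-locus inheritance model.

    ``founder_female_label`` / ``founder_male_label`` record the ordered
    diploid labels used in the 4 x 4 enumeration.  For Z-linked models the
    female founder is hemizygous: homozygous labels collapse to the
    hemizygous state with the same allele, heterozygous labels have no
    realisable hemizygous counterpart and the model is flagged
    ``valid=False`` (zero prior mass, zero likelihood), keeping the model
    count at 64.
    """

    model_id: int
    mode: str  # dominant | recessive
    location: str  # autosome | Z
    founder_female_label: str
    founder_male_label: str

    @property
    def valid(self) -> bool:
        if self.location == AUTOSOME:
            return True
        return self.founder_female_label in ("aa", "AA")

    @property
    def founder_female_genotype(self) -> OrderedGenotype:
        if self.location == Z:
            if not self.valid:
                raise GeneticsError(
                    f"model {self.model_id}: heterozygous female founder label "
                    f"{self.founder_female_label!r} has no hemizygous state on Z"
                )
            return OrderedGenotype.hemizygous(self.founder_female_label[0])
        return OrderedGenotype.from_label(self.founder_female_label)

    @property
    def founder_male_genotype(self) -> OrderedGenotype:
        return OrderedGenotype.from_label(self.founder_male_label)

    @property
    def description(self) -> str:
        return (
            f"{self.founder_female_label}x{self.founder_male_label} "
            f"{self.mode} {self.location}"
        )


def enumerate_models() -> list[InheritanceModel]:
    """Enumerate the 64 inheritance models in a stable, documented order.

    model_id runs 1..64, iterating (slowest to fastest) over location
    (autosome, Z), mode (dominant, recessive), founder female ordered
    genotype (aa, aA, Aa, AA), founder male ordered genotype (same order).
    """
    models = []
    i = 1
    for location in (AUTOSOME, Z):
        for mode in (DOMINANT, RECESSIVE):
            for female in _DIPLOID_LABELS:
                for male in _DIPLOID_LABELS:
                    models.append(InheritanceModel(i, mode, location, female, male))
                    i += 1
    return models


def model_by_id(model_id: int) -> InheritanceModel:
    if not 1 <= model_id <= 64:
        raise GeneticsError(f"model_id must be in 1..64, got {model_id}")
    return enumerate_models()[model_id - 1]


def find_model(mode: str, location: str, female: str, male: str) -> InheritanceModel:
    """Look up the unique model with the given ordered founder labels."""
    for m in enumerate_models():
        if (m.mode, m.location, m.founder_female_label, m.founder_male_label) == (
            mode,
            location,
            female,
            male,
        ):
            return m
    raise GeneticsError(f"no such model: {female}x{male} {mode} {location}")


# ---------------------------------------------------------------------------
# Transmission probability tables (integer-coded, used by the SMC and the
# enumeration oracle).  Diploid codes: 0=aa, 1=aA, 2=Aa, 3=AA (maternal
# allele = high bit).  Hemizygous codes: 0=a, 1=A.
# ---------------------------------------------------------------------------

def _build_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    auto = np.zeros((4, 4, 4))
    for m in range(4):
        for f in range(4):
            for mat in (m >> 1, m & 1):
                for pat in (f >> 1, f & 1):
                    auto[m, f, 2 * mat + pat] += 0.25
    # Z-linked son: maternal Z allele is the mother's single allele,
    # paternal Z allele drawn uniformly from the father's two.
    zson = np.zeros((2, 4, 4))
    for hm in range(2):
        for f in range(4):
            for pat in (f >> 1, f & 1):
                zson[hm, f, 2 * hm + pat] += 0.5
    # Z-linked daughter: hemizygous, single Z allele drawn from the father;
    # the maternal contribution is the W, which carries no copy.
    zdau = np.zeros((2, 4, 2))
    for hm in range(2):
        for f in range(4):
            for pat in (f >> 1, f & 1):
                zdau[hm, f, pat] += 0.5
    return auto, zson, zdau


TRANS_AUTOSOME, TRANS_Z_SON, TRANS_Z_DAUGHTER = _build_tables()

#: number of A copies per diploid / hemizygous state code
A_COUNT_DIPLOID = np.array([0, 1, 1, 2], dtype=np.int64)
A_COUNT_HEMI = np.array([0, 1], dtype=np.int64)


def _affected_table(mode: str, hemizygous: bool) -> np.ndarray:
    """Boolean lookup (indexed by state code): is a female with that
    genotype affected under ``mode``?  Dominant: affected iff carrying at
    least one A.  Recessive: affected iff carrying no A."""
    counts = A_COUNT_HEMI if hemizygous else A_COUNT_DIPLOID
    if mode == DOMINANT:
        return counts > 0
    if mode == RECESSIVE:
        return counts == 0
    raise GeneticsError(f"unknown mode {mode!r}")


def transmission_distribution(
    mother: OrderedGenotype,
    father: OrderedGenotype,
    child_sex: str,
    location: str,
) -> dict[OrderedGenotype, float]:
    """Exact Mendelian transmission distribution over child genotypes.

    Autosome: the child receives one of the mother's two alleles and one
    of the father's two, each uniformly.  Z: a son receives the mother's
    single Z allele plus a uniform draw from the father's two; a daughter
    is hemizygous with a uniform draw from the father's two (her W comes
    from the mother and carries no copy of the locus).
    """
    if father.hemizygous_flag:
        raise GeneticsError("father cannot be hemizygous")
    if location == AUTOSOME:
        if mother.hemizygous_flag:
            raise GeneticsError("diploid mother required at an autosomal locus")
        table = TRANS_AUTOSOME[mother.code, father.code]
        hemi = False
    elif location == Z:
        if not mother.hemizygous_flag:
            raise GeneticsError("mother must be hemizygous at a Z-linked locus")
        if child_sex == MALE:
            table = TRANS_Z_SON[mother.code, father.code]
            hemi = False
        elif child_sex == FEMALE:
            table = TRANS_Z_DAUGHTER[mother.code, father.code]
            hemi = True
        else:
            raise GeneticsError(f"unknown sex {child_sex!r}")
    else:
        raise GeneticsError(f"unknown location {location!r}")
    return {
        genotype_from_code(c, hemi): p
        for c, p in enumerate(table)
        if p > 0
    }


def transmit(
    mother: OrderedGenotype,
    father: OrderedGenotype,
    child_sex: str,
    location: str,
    rng: np.random.Generator,
) -> OrderedGenotype:
    """Draw one child genotype from the Mendelian transmission distribution."""
    dist = transmission_distribution(mother, father, child_sex, location)
    genotypes = list(dist)
    probs = np.fromiter(dist.values(), dtype=float)
    idx = rng.choice(len(genotypes), p=probs)
    return genotypes[idx]


def phenotype_of(g: OrderedGenotype, sex: str, model: InheritanceModel) -> str:
    """Deterministic full-penetrance phenotype map.

    Males never express the trait (sex-limited).  Females are affected
    under a dominant model iff they carry at least one A; under a
    recessive model iff they carry no A (hemizygous females: dominant ->
    affected iff the single allele is A, recessive iff it is a).
    """
    if sex == MALE:
        return NOT_EXPRESSED
    if sex != FEMALE:
        raise GeneticsError(f"unknown sex {sex!r}")
    if model.location == Z and not g.hemizygous_flag:
        raise GeneticsError("female at a Z-linked locus must be hemizygous")
    if model.location == AUTOSOME and g.hemizygous_flag:
        raise GeneticsError("female at an autosomal locus must be diploid")
    affected = _affected_table(model.mode, g.hemizygous_flag)[g.code]
    return AFFECTED if affected else UNAFFECTED


def w_linkage_check(ped) -> list[tuple[str, str]]:
    """List (affected mother, unaffected daughter) pairs.

    Under strict W-linkage every daughter of an affected female would
    inherit the trait with her W chromosome, so a non-empty list excludes
    the W chromosome as the location of the locus.
    """
    pairs = []
    for ind in ped:
        if ind.sex != FEMALE or ind.phenotype != UNAFFECTED or ind.dam is None:
            continue
        mother = ped[ind.dam]
        if mother.phenotype == AFFECTED:
            pairs.append((mother.id, ind.id))
    return pairs


def iter_valid_models() -> Iterator[InheritanceModel]:
    return (m for m in enumerate_models() if m.valid)
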