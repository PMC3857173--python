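"""Independent reference oracles for the test suite.

``reference_likelihood`` recomputes the pedigree likelihood by plain
recursive enumeration over OrderedGenotype objects, deriving gamete
probabilities from first principles (uniform draws over parental
alleles) rather than from the package's transmission tables or the
vectorized enumeration, so it can stand as an independent check of both.
"""

from __future__ import annotations

from pedtrait.genetics import (
    AUTOSOME,
    FEMALE,
    MALE,
    AFFECTED,
    UNAFFECTED,
    InheritanceModel,
    OrderedGenotype,
    Z,
)
from pedtrait.pedio import Pedigree, breadth_first_schedule


def _child_options(mother: OrderedGenotype, father: OrderedGenotype,
                   sex: str, location: str):
    """(genotype, probability) options from uniform gamete draws."""
    if location == AUTOSOME:
        return [
            (OrderedGenotype((ma, pa)), 0.25)
            for ma in mother.alleles
            for pa in father.alleles
        ]
    if sex == MALE:  # ZZ: maternal single Z allele + one paternal Z allele
        ma = mother.alleles[0]
        return [(OrderedGenotype((ma, pa)), 0.5) for pa in father.alleles]
    # ZW daughter: hemizygous, one paternal Z allele
    return [(OrderedGenotype((pa,)), 0.5) for pa in father.alleles]


def _compatible(g: OrderedGenotype, ind, model: InheritanceModel) -> bool:
    if ind.phenotype not in (AFFECTED, UNAFFECTED):
        return True
    if ind.sex != FEMALE:
        return False
    carries_A = "A" in g.alleles
    if model.mode == "dominant":
        affected = carries_A
    else:
        affected = not carries_A
    return affected == (ind.phenotype == AFFECTED)


def reference_likelihood(ped: Pedigree, model: InheritanceModel) -> float:
    """Natural-scale likelihood by depth-first recursion (tiny pedigrees)."""
    if not model.valid:
        return 0.0
    order = breadth_first_schedule(ped).ids
    assign = {
        order[0]: model.founder_female_genotype,
        order[1]: model.founder_male_genotype,
    }
    for iid in order[:2]:
        if not _compatible(assign[iid], ped[iid], model):
            return 0.0

    def recurse(k: int) -> float:
        if k == len(order):
            return 1.0
        ind = ped[order[k]]
        total = 0.0
        for g, p in _child_options(assign[ind.dam], assign[ind.sire],
                                   ind.sex, model.location):
            if not _compatible(g, ind, model):
                continue
            assign[ind.id] = g
            total += p * recurse(k + 1)
            del assign[ind.id]
        return total

    return recurse(2)
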