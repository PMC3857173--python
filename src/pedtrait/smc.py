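"""Pedigree likelihood of a sex-limited trait by sequential Monte Carlo.

The likelihood of the observed phenotypes under a fully specified
inheritance model is a sum over every joint genotype assignment to the
pedigree of its Mendelian prior probability times a 0/1 phenotype
compatibility indicator (full penetrance, no phenocopies).  The SMC
estimator targets this sum over the nested breadth-first sub-pedigree
sequence: particles hold joint genotype configurations, founder genotypes
are fixed by the model, new individuals' genotypes are proposed from the
Mendelian transmission distribution given the particle's parental
genotypes, particles incompatible with a newly observed phenotype are
killed, and the product of per-step survival fractions estimates the
likelihood.  The estimator is unbiased on the natural scale whether or
not survivors are bootstrap-resampled back to the full particle count
after each step; resampling (the default) is what makes astronomically
small likelihoods reachable at feasible particle counts.

``exact_likelihood`` computes the same sum by exhaustive enumeration of
all joint configurations and serves as the independent oracle on small
pedigrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import genetics
from .genetics import (
    AFFECTED,
    AUTOSOME,
    FEMALE,
    InheritanceModel,
    TRANS_AUTOSOME,
    TRANS_Z_DAUGHTER,
    TRANS_Z_SON,
    Z,
    _affected_table,
    enumerate_models,
)
from .pedio import Pedigree, breadth_first_schedule

DEFAULT_N_PARTICLES = 2_000_000

#: zero survival below this particle count triggers a confirmation rerun
#: at 10x particles before zero likelihood is reported
_CONFIRM_THRESHOLD = 10_000

_PHEN_CODE = {genetics.UNOBSERVED: -1, genetics.UNAFFECTED: 0, AFFECTED: 1}


class SMCError(ValueError):
    pass


class EnumerationCapError(SMCError):
    """Pedigree too large for exhaustive enumeration; use smc_likelihood."""


@dataclass
class ParticlePopulation:
    """Retained joint genotype configurations over the full pedigree.

    ``genotypes[p, j]`` is the integer state code of individual
    ``ids[j]`` in particle ``p`` (diploid codes 0..3, hemizygous 0..1).
    ``weights`` are normalized posterior weights (uniform for SMC output,
    exact posterior probabilities for the enumeration oracle).
    """

    ids: list[str]
    hemizygous: np.ndarray  # bool per individual column
    model: InheritanceModel
    genotypes: np.ndarray  # (n_particles, n_individuals) int8
    weights: np.ndarray | None = None

    @property
    def n_particles(self) -> int:
        return self.genotypes.shape[0]


@dataclass
class LikelihoodResult:
    """Monte-Carlo (or exact) pedigree likelihood estimate.

    ``log_likelihood`` is the natural log of the product of per-step
    survival fractions; ``-inf`` iff some fraction is zero, with
    ``failed_step`` recording the first such step.  ``mc_standard_error``
    is the delta-approximation standard error of the log-likelihood from
    the per-step survival fractions (0 for exact results, ``inf`` for a
    zero estimate).
    """

    log_likelihood: float
    per_step_survival: tuple[float, ...]
    n_particles: int
    seed: int
    mc_standard_error: float
    resample: str = "always"
    failed_step: int | None = None
    final_particles: ParticlePopulation | None = None

    @property
    def minus2_loglik(self) -> float:
        return -2.0 * self.log_likelihood

    def to_dict(self) -> dict:
        return {
            "log_likelihood": self.log_likelihood,
            "minus2_loglik": self.minus2_loglik,
            "per_step_survival": list(self.per_step_survival),
            "n_particles": self.n_particles,
            "seed": self.seed,
            "mc_standard_error": self.mc_standard_error,
            "resample": self.resample,
            "failed_step": self.failed_step,
        }


# ---------------------------------------------------------------------------
# Compiled pedigree plan
# ---------------------------------------------------------------------------

class PedigreePlan:
    """Integer-indexed form of a pedigree and its expansion schedule.

    Building the plan once and reusing it across runs (with different
    phenotype vectors) is what makes the permutation test affordable: the
    topology, schedule and index arrays never change, only the phenotype
    codes do.
    """

    def __init__(self, ped: Pedigree):
        schedule = breadth_first_schedule(ped)
        self.ids: list[str] = schedule.ids
        index = {iid: j for j, iid in enumerate(self.ids)}
        n = len(self.ids)
        self.is_female = np.array(
            [ped[i].sex == FEMALE for i in self.ids], dtype=bool
        )
        self.mother_idx = np.full(n, -1, dtype=np.int64)
        self.father_idx = np.full(n, -1, dtype=np.int64)
        for j, iid in enumerate(self.ids):
            ind = ped[iid]
            if not ind.is_founder:
                self.mother_idx[j] = index[ind.dam]
                self.father_idx[j] = index[ind.sire]
        self.phenotype = np.array(
            [_PHEN_CODE[ped[i].phenotype] for i in self.ids], dtype=np.int8
        )
        # steps as (lo, hi) index ranges over the flattened schedule order
        self.steps: list[tuple[int, int]] = []
        lo = 0
        for ids, _ in schedule:
            self.steps.append((lo, lo + len(ids)))
            lo += len(ids)
        self.n_nonfounders = n - 2

    def hemizygous_columns(self, model: InheritanceModel) -> np.ndarray:
        if model.location == Z:
            return self.is_female.copy()
        return np.zeros(len(self.ids), dtype=bool)

    def phenotype_vector(self, phenotypes: dict[str, str]) -> np.ndarray:
        """Phenotype code vector with the given per-id overrides applied."""
        phen = self.phenotype.copy()
        index = {iid: j for j, iid in enumerate(self.ids)}
        for iid, p in phenotypes.items():
            phen[index[iid]] = _PHEN_CODE[p]
        return phen


def _founder_codes(model: InheritanceModel) -> tuple[int, int]:
    return model.founder_female_genotype.code, model.founder_male_genotype.code


def _founder_survival(
    plan: PedigreePlan, model: InheritanceModel, phen: np.ndarray
) -> float:
    """Deterministic 0/1 compatibility of the fixed founder genotypes."""
    female_id, male_id = plan.ids[0], plan.ids[1]
    aff = _affected_table(model.mode, model.location == Z)
    fcode, _ = _founder_codes(model)
    ok = True
    if phen[0] >= 0:  # founding female observed
        ok &= bool(aff[fcode]) == bool(phen[0])
    # founding male can never be observed (validation), but keep the guard
    if phen[1] >= 0:
        ok = False
    del female_id, male_id
    return 1.0 if ok else 0.0


# ---------------------------------------------------------------------------
# SMC core
# ---------------------------------------------------------------------------

def _propose_column(
    G: np.ndarray,
    j: int,
    plan: PedigreePlan,
    location: str,
    rng: np.random.Generator,
) -> None:
    """Fill column j of the particle genotype matrix with Mendelian draws."""
    m = G[:, plan.mother_idx[j]]
    f = G[:, plan.father_idx[j]]
    n = G.shape[0]
    if location == AUTOSOME:
        b0 = rng.integers(0, 2, size=n, dtype=np.int8)
        b1 = rng.integers(0, 2, size=n, dtype=np.int8)
        mat = np.where(b0 == 1, m & 1, m >> 1)
        pat = np.where(b1 == 1, f & 1, f >> 1)
        G[:, j] = 2 * mat + pat
    elif plan.is_female[j]:  # Z-linked daughter: one paternal Z allele
        b = rng.integers(0, 2, size=n, dtype=np.int8)
        G[:, j] = np.where(b == 1, f & 1, f >> 1)
    else:  # Z-linked son: maternal single Z allele + one paternal Z allele
        b = rng.integers(0, 2, size=n, dtype=np.int8)
        G[:, j] = 2 * m + np.where(b == 1, f & 1, f >> 1)


def run_smc(
    plan: PedigreePlan,
    model: InheritanceModel,
    n_particles: int,
    seed: int,
    resample: str = "always",
    store_particles: bool = False,
    phenotype: np.ndarray | None = None,
) -> LikelihoodResult:
    """SMC likelihood on a pre-compiled plan (optionally with a replacement
    phenotype vector, as used by the permutation test)."""
    if n_particles < 1:
        raise SMCError("n_particles must be >= 1")
    if resample not in ("always", "never"):
        raise SMCError(f"resample must be 'always' or 'never', got {resample!r}")
    phen = plan.phenotype if phenotype is None else phenotype

    def _result(loglik, survival, se, failed=None, particles=None):
        return LikelihoodResult(
            log_likelihood=loglik,
            per_step_survival=tuple(survival),
            n_particles=n_particles,
            seed=seed,
            mc_standard_error=se,
            resample=resample,
            failed_step=failed,
            final_particles=particles,
        )

    if not model.valid:
        # heterozygous female founder label on Z: zero prior mass
        return _result(-math.inf, [0.0], math.inf, failed=0)

    s0 = _founder_survival(plan, model, phen)
    if s0 == 0.0:
        return _result(-math.inf, [0.0], math.inf, failed=0)

    n_ind = len(plan.ids)
    rng = np.random.Generator(np.random.Philox(key=seed))
    G = np.empty((n_particles, n_ind), dtype=np.int8)
    fcode, mcode = _founder_codes(model)
    G[:, 0] = fcode
    G[:, 1] = mcode

    aff_dip = _affected_table(model.mode, hemizygous=False)
    aff_hemi = _affected_table(model.mode, hemizygous=True)
    hemi_col = plan.hemizygous_columns(model)

    # One filtering event per observed individual (rather than per BFS
    # level): the product of conditional survival fractions targets the
    # same likelihood for any refinement of the expansion order, and the
    # finer granularity keeps each fraction far from zero, which is what
    # makes astronomically small likelihoods reachable without depletion.
    survival = [s0]
    alive = np.ones(n_particles, dtype=bool)  # used in resample='never'
    n_alive = n_particles
    for lo, hi in plan.steps[1:]:
        for j in range(lo, hi):
            _propose_column(G, j, plan, model.location, rng)
            if phen[j] < 0:
                continue
            table = aff_hemi if hemi_col[j] else aff_dip
            ok = table[G[:, j]] == bool(phen[j])
            if resample == "always":
                k = int(ok.sum())
                p = k / n_particles
                survival.append(p)
                if k == 0:
                    return _result(-math.inf, survival, math.inf,
                                   failed=len(survival) - 1)
                surv_idx = np.flatnonzero(ok)
                G = G[surv_idx[rng.integers(0, k, size=n_particles)]]
            else:
                alive &= ok
                k = int(alive.sum())
                p = k / n_alive if n_alive else 0.0
                survival.append(p)
                if k == 0:
                    return _result(-math.inf, survival, math.inf,
                                   failed=len(survival) - 1)
                n_alive = k

    loglik = float(sum(math.log(p) for p in survival))
    if resample == "always":
        var = sum((1 - p) / (p * n_particles) for p in survival[1:])
    else:
        p_tot = n_alive / n_particles
        var = (1 - p_tot) / (p_tot * n_particles)
    se = math.sqrt(var)

    particles = None
    if store_particles:
        kept = G if resample == "always" else G[alive]
        particles = ParticlePopulation(
            ids=list(plan.ids),
            hemizygous=hemi_col,
            model=model,
            genotypes=kept.copy(),
        )
    return _result(loglik, survival, se, particles=particles)


def smc_likelihood(
    ped: Pedigree,
    model: InheritanceModel,
    n_particles: int = DEFAULT_N_PARTICLES,
    seed: int = 0,
    resample: str = "always",
    store_particles: bool = False,
    auto_confirm: bool = True,
    plan: PedigreePlan | None = None,
) -> LikelihoodResult:
    """Sequential Monte Carlo estimate of the phenotype likelihood.

    Identical inputs reproduce identical output bit-for-bit.  A zero
    survival fraction at a low particle count (< 10^4) triggers one
    confirmation rerun at 10x particles before zero likelihood is
    reported, to separate structural incompatibility from particle
    depletion; a structural founder-phenotype mismatch (step 0) is
    deterministic and never rerun.
    """
    if plan is None:
        plan = PedigreePlan(ped)
    res = run_smc(plan, model, n_particles, seed, resample, store_particles)
    if (
        auto_confirm
        and res.log_likelihood == -math.inf
        and res.failed_step is not None
        and res.failed_step > 0
        and n_particles < _CONFIRM_THRESHOLD
    ):
        confirm_seed = _derive_seed(seed, 1)
        rerun = run_smc(
            plan, model, 10 * n_particles, confirm_seed, resample, store_particles
        )
        if rerun.log_likelihood > -math.inf:
            return rerun
    return res


def _derive_seed(seed: int, stream: int) -> int:
    ss = np.random.SeedSequence([int(seed), int(stream)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle
# ---------------------------------------------------------------------------

def _enumeration(
    ped: Pedigree,
    model: InheritanceModel,
    cap: int,
    plan: PedigreePlan | None = None,
    order: Sequence[int] | None = None,
    phenotype: np.ndarray | None = None,
):
    """All joint configurations and their (unnormalized) probabilities.

    Returns ``(plan, cols, probs)`` where ``cols[j]`` is the state-code
    column of individual ``plan.ids[j]`` over all enumerated
    configurations, or ``None`` when the founder genotypes already
    contradict an observed founder phenotype.  ``order`` permutes the
    enumeration radices (the sum is order-invariant; used for
    cross-checks).
    """
    if plan is None:
        plan = PedigreePlan(ped)
    if plan.n_nonfounders > cap:
        raise EnumerationCapError(
            f"{plan.n_nonfounders} non-founders exceeds the enumeration cap "
            f"({cap}); use smc_likelihood"
        )
    phen = plan.phenotype if phenotype is None else phenotype
    if not model.valid:
        return None
    if _founder_survival(plan, model, phen) == 0.0:
        return None

    n_ind = len(plan.ids)
    hemi_col = plan.hemizygous_columns(model)
    radices = [2 if hemi_col[j] else 4 for j in range(2, n_ind)]
    nf = list(range(2, n_ind))
    if order is not None:
        nf = [nf[k] for k in order]
        radices = [2 if hemi_col[j] else 4 for j in nf]
    M = int(np.prod(radices, dtype=np.int64)) if radices else 1

    fcode, mcode = _founder_codes(model)
    cols: list[np.ndarray] = [None] * n_ind  # type: ignore[list-item]
    cols[0] = np.full(M, fcode, dtype=np.int8)
    cols[1] = np.full(M, mcode, dtype=np.int8)
    idx = np.arange(M, dtype=np.int64)
    stride = M
    for j, r in zip(nf, radices):
        stride //= r
        cols[j] = ((idx // stride) % r).astype(np.int8)

    probs = np.ones(M)
    aff_dip = _affected_table(model.mode, hemizygous=False)
    aff_hemi = _affected_table(model.mode, hemizygous=True)
    for j in range(2, n_ind):
        m = cols[plan.mother_idx[j]]
        f = cols[plan.father_idx[j]]
        c = cols[j]
        if model.location == AUTOSOME:
            probs *= TRANS_AUTOSOME[m, f, c]
        elif plan.is_female[j]:
            probs *= TRANS_Z_DAUGHTER[m, f, c]
        else:
            probs *= TRANS_Z_SON[m, f, c]
    for j in range(2, n_ind):
        if phen[j] < 0:
            continue
        table = aff_hemi if hemi_col[j] else aff_dip
        probs = probs * (table[cols[j]] == bool(phen[j]))
    return plan, cols, probs


def exact_likelihood(
    ped: Pedigree,
    model: InheritanceModel,
    cap: int = 12,
    order: Sequence[int] | None = None,
    plan: PedigreePlan | None = None,
    phenotype: np.ndarray | None = None,
) -> float:
    """Exact log-likelihood by exhaustive enumeration (small pedigrees).

    Sums the Mendelian prior probability of every joint genotype
    configuration compatible with all observed phenotypes.  Raises
    :class:`EnumerationCapError` above ``cap`` non-founders (the state
    space is 4^n).
    """
    enum = _enumeration(ped, model, cap, plan=plan, order=order,
                        phenotype=phenotype)
    if enum is None:
        return -math.inf
    _, _, probs = enum
    total = float(probs.sum())
    return math.log(total) if total > 0 else -math.inf


def exact_likelihood_result(ped: Pedigree, model: InheritanceModel,
                            cap: int = 12) -> LikelihoodResult:
    ll = exact_likelihood(ped, model, cap=cap)
    return LikelihoodResult(
        log_likelihood=ll,
        per_step_survival=(),
        n_particles=0,
        seed=0,
        mc_standard_error=0.0,
        resample="exact",
        failed_step=None,
    )


def exact_posterior(
    ped: Pedigree, model: InheritanceModel, cap: int = 12
) -> ParticlePopulation:
    """Exact posterior over joint genotype configurations given the
    observed phenotypes (enumeration oracle for the trajectory module)."""
    enum = _enumeration(ped, model, cap)
    if enum is None:
        raise SMCError("model has zero likelihood on this pedigree")
    plan, cols, probs = enum
    keep = probs > 0
    if not keep.any():
        raise SMCError("model has zero likelihood on this pedigree")
    G = np.stack([c[keep] for c in cols], axis=1).astype(np.int8)
    w = probs[keep]
    return ParticlePopulation(
        ids=list(plan.ids),
        hemizygous=plan.hemizygous_columns(model),
        model=model,
        genotypes=G,
        weights=w / w.sum(),
    )


# ---------------------------------------------------------------------------
# Model sweep
# ---------------------------------------------------------------------------

def positive_likelihood_models(
    ped: Pedigree,
    n_particles: int = DEFAULT_N_PARTICLES,
    seed: int = 0,
    models: Sequence[InheritanceModel] | None = None,
    confirm_with_exact: bool = True,
    exact_cap: int = 12,
) -> list[tuple[int, LikelihoodResult]]:
    """Run the SMC under every inheritance model; return those with a
    finite log-likelihood as (model_id, result) pairs.

    On pedigrees under the enumeration cap, zero-likelihood SMC
    determinations are confirmed against :func:`exact_likelihood`; a
    disagreement (particle depletion) triggers one rerun at 10x
    particles.
    """
    if models is None:
        models = enumerate_models()
    plan = PedigreePlan(ped)
    small = plan.n_nonfounders <= exact_cap
    ss = np.random.SeedSequence(int(seed)).spawn(len(models))
    out = []
    for model, child in zip(models, ss):
        run_seed = int(child.generate_state(1, dtype=np.uint32)[0])
        res = smc_likelihood(
            ped, model, n_particles=n_particles, seed=run_seed, plan=plan
        )
        if res.log_likelihood == -math.inf and confirm_with_exact and small:
            if exact_likelihood(ped, model, cap=exact_cap) > -math.inf:
                res = smc_likelihood(
                    ped, model, n_particles=10 * n_particles,
                    seed=_derive_seed(run_seed, 2), plan=plan,
                )
        if res.log_likelihood > -math.inf:
            out.append((model.model_id, res))
    return out


def trivial_phenotype_check(ped: Pedigree, model: InheritanceModel) -> bool:
    """True when the model's fixed founder genotypes are compatible with
    any observed founder phenotype (a zero here is structural)."""
    plan = PedigreePlan(ped)
    return model.valid and _founder_survival(plan, model, plan.phenotype) == 1.0
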