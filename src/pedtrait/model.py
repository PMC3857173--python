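"""Model/Results facade over the segregation-analysis pipeline.

:class:`MendelianSegregationModel` is built from a pedigree (or a
pedigree TSV); :meth:`fit` sweeps the 64-model space with the SMC
likelihood and returns :class:`SegregationResults`, which carries the
score table (AIC, relative likelihood, posterior model probability), the
per-model Monte-Carlo likelihood estimates with their standard errors,
and methods for the downstream inferences that condition on a fitted
model: allele-count trajectories and the phenotype permutation test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import permtest as _permtest
from . import smc as _smc
from . import trajectory as _trajectory
from .genetics import InheritanceModel, enumerate_models, model_by_id, w_linkage_check
from .pedio import Pedigree, read_pedigree
from .selection import score_models
from .smc import DEFAULT_N_PARTICLES, LikelihoodResult, PedigreePlan


class MendelianSegregationModel:
    """Single-locus segregation analysis of a sex-limited binary trait on
    a one-founding-pair pedigree.

    Parameters
    ----------
    pedigree : Pedigree
        Validated pedigree with partially observed female phenotypes.
    models : sequence of InheritanceModel, optional
        Candidate model space; defaults to the full 64-model enumeration.
    """

    def __init__(self, pedigree: Pedigree,
                 models: Sequence[InheritanceModel] | None = None):
        self.pedigree = pedigree
        self.models = list(models) if models is not None else enumerate_models()
        self.plan = PedigreePlan(pedigree)

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "MendelianSegregationModel":
        return cls(read_pedigree(path), **kwargs)

    def w_linkage_report(self) -> list[tuple[str, str]]:
        """(affected mother, unaffected daughter) pairs; non-empty excludes
        strict W-linkage of the locus."""
        return w_linkage_check(self.pedigree)

    def fit(
        self,
        n_particles: int = DEFAULT_N_PARTICLES,
        seed: int = 0,
        confirm_with_exact: bool = True,
    ) -> "SegregationResults":
        """Estimate the likelihood of every candidate model by SMC and
        score the model space."""
        positive = _smc.positive_likelihood_models(
            self.pedigree,
            n_particles=n_particles,
            seed=seed,
            models=self.models,
            confirm_with_exact=confirm_with_exact,
        )
        table = score_models(
            [(mid, res.log_likelihood) for mid, res in positive],
            models=self.models,
        )
        return SegregationResults(
            model=self,
            score_table=table,
            likelihoods=dict(positive),
            n_particles=n_particles,
            seed=seed,
        )


@dataclass
class SegregationResults:
    """Fitted model-space scores and the inferences that hang off them."""

    model: MendelianSegregationModel
    score_table: pd.DataFrame
    likelihoods: dict[int, LikelihoodResult]
    n_particles: int
    seed: int
    _particle_cache: dict = field(default_factory=dict, repr=False)

    # -- basic accessors ----------------------------------------------------
    @property
    def pedigree(self) -> Pedigree:
        return self.model.pedigree

    @property
    def best_model(self) -> InheritanceModel:
        return model_by_id(int(self.score_table.iloc[0]["model_id"]))

    @property
    def positive_models(self) -> list[int]:
        """model_ids with positive (finite log) likelihood."""
        return sorted(self.likelihoods)

    def posterior(self, model_id: int) -> float:
        row = self.score_table[self.score_table["model_id"] == model_id]
        return float(row["posterior"].iloc[0])

    def loglik(self, model_id: int) -> float:
        res = self.likelihoods.get(model_id)
        return res.log_likelihood if res is not None else -math.inf

    # -- downstream inference ----------------------------------------------
    def retained_particles(
        self,
        model_id: int | None = None,
        n_particles: int | None = None,
        min_survivors: int = 500,
    ) -> _smc.ParticlePopulation:
        """Compatible joint genotype configurations under a model.

        Tries a ``resample='never'`` pass first (surviving particles are
        independent posterior draws, avoiding the resampling path
        degeneracy that collapses early-year marginals); falls back to
        the resampled particle history when fewer than ``min_survivors``
        survive, which is the norm when the likelihood is tiny.
        """
        mid = model_id if model_id is not None else self.best_model.model_id
        n = n_particles or self.n_particles
        key = (mid, n)
        if key in self._particle_cache:
            return self._particle_cache[key]
        m = model_by_id(mid)
        res = _smc.smc_likelihood(
            self.pedigree, m, n_particles=n, seed=self.seed,
            resample="never", store_particles=True, plan=self.model.plan,
        )
        pop = res.final_particles
        if pop is None or pop.n_particles < min_survivors:
            res = _smc.smc_likelihood(
                self.pedigree, m, n_particles=n, seed=self.seed,
                resample="always", store_particles=True, plan=self.model.plan,
            )
            pop = res.final_particles
        if pop is None or pop.n_particles == 0:
            raise _smc.SMCError(
                f"model {mid} retains no compatible configurations"
            )
        self._particle_cache[key] = pop
        return pop

    def allele_trajectories(
        self,
        model_id: int | None = None,
        n_particles: int | None = None,
    ) -> _trajectory.TrajectorySummary:
        """Per-year posterior of the A-allele count under a fitted model
        (default: the posterior-best model)."""
        pop = self.retained_particles(model_id, n_particles)
        return _trajectory.allele_trajectories(self.pedigree, pop)

    def permutation_test(
        self,
        model_id: int | None = None,
        n_permutations: int = 10_000,
        n_particles: int = 10_000,
        seed: int | None = None,
    ) -> _permtest.PermutationResult:
        """Exact phenotype permutation test using the SMC log-likelihood
        under a fitted model (default: the posterior-best model) as the
        test statistic."""
        mid = model_id if model_id is not None else self.best_model.model_id
        return _permtest.permutation_test(
            self.pedigree,
            model_by_id(mid),
            n_permutations=n_permutations,
            n_particles=n_particles,
            seed=self.seed if seed is None else seed,
        )

    # -- presentation -------------------------------------------------------
    def summary(self, top: int = 8) -> str:
        """Plain-text summary: data scale, SMC settings, and the score
        table of the top models."""
        ped = self.pedigree
        females = ped.females(observed_only=True)
        affected = sum(i.phenotype == "affected" for i in females)
        t = self.score_table.head(top).copy()
        t["minus2_loglik"] = t["minus2_loglik"].map(
            lambda v: f"{v:.3f}" if math.isfinite(v) else "inf"
        )
        t["relative_likelihood"] = t["relative_likelihood"].map("{:.4g}".format)
        t["posterior"] = t["posterior"].map("{:.4f}".format)
        lines = [
            "Mendelian segregation analysis (sex-limited trait)",
            "=" * 58,
            f"Individuals: {len(ped)}   years: "
            f"{ped.years.start}-{ped.years.stop - 1}",
            f"Observed females: {len(females)}   affected: {affected}",
            f"Candidate models: {len(self.model.models)}   "
            f"positive likelihood: {len(self.likelihoods)}",
            f"SMC particles: {self.n_particles}   seed: {self.seed}",
            "-" * 58,
            t.to_string(index=False),
        ]
        best = self.best_model
        lines.append("-" * 58)
        lines.append(
            f"Best model: {best.model_id} ({best.description}), "
            f"posterior {self.posterior(best.model_id):.4f}"
        )
        return "\n".join(lines)
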