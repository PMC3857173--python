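import math

import numpy as np
import pytest

from pedtrait.genetics import (
    AUTOSOME,
    DOMINANT,
    FEMALE,
    MALE,
    RECESSIVE,
    enumerate_models,
    find_model,
)
from pedtrait.pedio import Pedigree
from pedtrait.smc import (
    EnumerationCapError,
    exact_likelihood,
    positive_likelihood_models,
    smc_likelihood,
)
from conftest import ind, random_small_studies, small_sim_config
from helpers import reference_likelihood
from pedtrait.synthdata import simulate_pedigree

N = 10_000


def _mirror_label(label):
    return {"aA": "Aa", "Aa": "aA"}.get(label, label)


class TestTrivialLikelihoods:
    def test_single_affected_daughter_is_half(self, trio_affected, model4):
        assert math.isclose(math.exp(exact_likelihood(trio_affected, model4)), 0.5)
        res = smc_likelihood(trio_affected, model4, n_particles=N, seed=3)
        assert abs(math.exp(res.log_likelihood) - 0.5) < 0.02

    def test_mixed_daughters_quarter(self, quartet_mixed, model4):
        assert math.isclose(math.exp(exact_likelihood(quartet_mixed, model4)), 0.25)
        res = smc_likelihood(quartet_mixed, model4, n_particles=N, seed=3)
        assert abs(math.exp(res.log_likelihood) - 0.25) < 0.02

    def test_impossible_phenotype_zero(self, trio_affected):
        no_A = find_model(DOMINANT, AUTOSOME, "aa", "aa")
        assert exact_likelihood(trio_affected, no_A) == -math.inf
        res = smc_likelihood(trio_affected, no_A, n_particles=N, seed=3)
        assert res.log_likelihood == -math.inf
        assert res.failed_step is not None

    def test_no_observed_phenotype_gives_one(self, model4):
        ped = Pedigree([
            ind("A1", None, None, FEMALE),
            ind("A2", None, None, MALE),
            ind("B3", "A2", "A1", FEMALE, first=1981),
        ])
        assert exact_likelihood(ped, model4) == 0.0
        res = smc_likelihood(ped, model4, n_particles=100, seed=0)
        assert res.log_likelihood == 0.0

    def test_survival_product_invariant(self, quartet_mixed, model4):
        res = smc_likelihood(quartet_mixed, model4, n_particles=N, seed=5)
        assert math.isclose(
            res.log_likelihood,
            sum(math.log(p) for p in res.per_step_survival),
        )


class TestExactOracle:
    def test_matches_reference_recursion(self):
        rng = np.random.default_rng(42)
        models = [m for m in enumerate_models() if m.valid]
        studies = random_small_studies(rng, 25, max_nonfounders=7)
        checked = 0
        for study in studies:
            test_model = models[rng.integers(0, len(models))]
            ref = reference_likelihood(study.pedigree, test_model)
            got = exact_likelihood(study.pedigree, test_model)
            if ref == 0.0:
                assert got == -math.inf
            else:
                assert math.isclose(math.exp(got), ref, rel_tol=1e-10)
                checked += 1
        assert checked >= 5

    def test_enumeration_order_invariance(self, model4):
        # inbreeding loop: founding male breeds with his own daughter
        ped = Pedigree([
            ind("A1", None, None, FEMALE, phen="unaffected"),
            ind("A2", None, None, MALE),
            ind("D1", "A2", "A1", FEMALE, first=1981, phen="unaffected"),
            ind("D2", "A2", "A1", MALE, first=1981),
            ind("E8", "A2", "D1", FEMALE, first=1983, phen="affected"),
            ind("E9", "A2", "D1", FEMALE, first=1983, phen="unaffected"),
            ind("F1", "D2", "E9", FEMALE, first=1985, phen="affected"),
            ind("F2", "D2", "E9", FEMALE, first=1985, phen="unaffected"),
        ])
        forward = exact_likelihood(ped, model4)
        n_nf = len(ped) - 2
        backward = exact_likelihood(ped, model4, order=list(range(n_nf))[::-1])
        assert math.isclose(forward, backward)
        assert math.isclose(
            math.exp(forward), reference_likelihood(ped, model4), rel_tol=1e-10
        )

    def test_cap_enforced(self, robin_fixture, model4):
        with pytest.raises(EnumerationCapError):
            exact_likelihood(robin_fixture.pedigree, model4, cap=12)

    def test_monotone_in_observed_phenotypes(self, model4):
        rng = np.random.default_rng(7)
        studies = random_small_studies(rng, 15, max_nonfounders=9)
        tested = 0
        for study in studies:
            ped = study.pedigree
            hidden = [i for i in ped
                      if i.sex == FEMALE and not i.observed and not i.is_founder]
            if not hidden:
                continue
            base = exact_likelihood(ped, model4)
            label = "affected" if rng.random() < 0.5 else "unaffected"
            more = ped.with_phenotypes({hidden[0].id: label})
            augmented = exact_likelihood(more, model4)
            assert augmented <= base + 1e-12
            tested += 1
        assert tested >= 5


class TestSMCEstimator:
    def test_bit_reproducible(self, quartet_mixed, model4):
        a = smc_likelihood(quartet_mixed, model4, n_particles=N, seed=123)
        b = smc_likelihood(quartet_mixed, model4, n_particles=N, seed=123)
        assert a.log_likelihood == b.log_likelihood
        assert a.per_step_survival == b.per_step_survival

    def test_within_three_se_of_exact(self, model4):
        rng = np.random.default_rng(5)
        studies = random_small_studies(rng, 30, max_nonfounders=10)
        fails = 0
        for study in studies:
            ex = exact_likelihood(study.pedigree, model4)
            res = smc_likelihood(study.pedigree, model4, n_particles=N,
                                 seed=int(rng.integers(2**30)))
            if ex == -math.inf:
                assert res.log_likelihood == -math.inf
            elif abs(res.log_likelihood - ex) > 3 * res.mc_standard_error:
                fails += 1
        assert fails <= 1

    @pytest.mark.parametrize("resample", ["always", "never"])
    def test_unbiased_on_natural_scale(self, quartet_mixed, model4, resample):
        exact = math.exp(exact_likelihood(quartet_mixed, model4))
        ests = np.array([
            math.exp(smc_likelihood(quartet_mixed, model4, n_particles=2000,
                                    seed=s, resample=resample).log_likelihood)
            for s in range(100)
        ])
        se = ests.std(ddof=1) / 10
        assert abs(ests.mean() - exact) < 3 * se

    def test_mirror_founder_symmetry(self):
        rng = np.random.default_rng(9)
        study = random_small_studies(rng, 1, max_nonfounders=9)[0]
        for mode, female, male in [(DOMINANT, "aa", "Aa"),
                                   (RECESSIVE, "Aa", "aA")]:
            m = find_model(mode, AUTOSOME, female, male)
            mm = find_model(mode, AUTOSOME, _mirror_label(female),
                            _mirror_label(male))
            e1 = exact_likelihood(study.pedigree, m)
            e2 = exact_likelihood(study.pedigree, mm)
            if e1 == -math.inf:
                assert e2 == -math.inf
                continue
            assert math.isclose(e1, e2)
            r1 = smc_likelihood(study.pedigree, m, n_particles=N, seed=1)
            r2 = smc_likelihood(study.pedigree, mm, n_particles=N, seed=2)
            tol = 3 * math.hypot(r1.mc_standard_error, r2.mc_standard_error)
            assert abs(r1.log_likelihood - r2.log_likelihood) <= tol

    def test_depletion_confirmation_rerun(self, model4):
        # a chain of generations, one observed daughter per level: per-step
        # survival is around 1/2, so a handful of particles routinely dies
        # out even though the likelihood is comfortably positive; the
        # automatic 10x confirmation rerun should usually rescue a finite
        # estimate
        members = [
            ind("A1", None, None, FEMALE, phen="unaffected"),
            ind("A2", None, None, MALE),
        ]
        dam, sire = "A1", "A2"
        for k in range(5):
            year = 1981 + k
            phen = "affected" if k % 2 == 0 else "unaffected"
            members.append(ind(f"C{k}", sire, dam, FEMALE, first=year,
                               phen=phen))
            members.append(ind(f"M{k}", sire, dam, MALE, first=year))
            dam, sire = f"C{k}", f"M{k}"
        ped = Pedigree(members)
        assert exact_likelihood(ped, model4) > -math.inf
        raw_inf = confirmed_finite = 0
        for seed in range(40):
            raw = smc_likelihood(ped, model4, n_particles=4, seed=seed,
                                 auto_confirm=False)
            if raw.log_likelihood == -math.inf:
                raw_inf += 1
                conf = smc_likelihood(ped, model4, n_particles=4, seed=seed,
                                      auto_confirm=True)
                if conf.log_likelihood > -math.inf:
                    confirmed_finite += 1
                    assert conf.n_particles == 40
        assert raw_inf > 5
        assert confirmed_finite > raw_inf / 2


class TestModelSweep:
    def test_structurally_impossible_models_absent(self, trio_affected):
        got = positive_likelihood_models(trio_affected, n_particles=2000, seed=0)
        ids = {mid for mid, _ in got}
        absent = find_model(DOMINANT, AUTOSOME, "aa", "aa")
        assert absent.model_id not in ids
        assert find_model(DOMINANT, AUTOSOME, "aa", "Aa").model_id in ids
        for mid, res in got:
            assert res.log_likelihood > -math.inf

    def test_generating_model_has_positive_likelihood(self, model4):
        study = simulate_pedigree(small_sim_config(model4, 9, n_years=5,
                                                   breeding_probability=0.95,
                                                   adult_survival=0.9,
                                                   mean_clutch=2.2,
                                                   offspring_survival=0.75))
        got = positive_likelihood_models(study.pedigree, n_particles=5000,
                                         seed=1)
        assert model4.model_id in {mid for mid, _ in got}
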