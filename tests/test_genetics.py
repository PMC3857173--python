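import math

import numpy as np
import pytest

from pedtrait.genetics import (
    AFFECTED,
    AUTOSOME,
    DOMINANT,
    FEMALE,
    MALE,
    NOT_EXPRESSED,
    RECESSIVE,
    UNAFFECTED,
    Z,
    GeneticsError,
    OrderedGenotype,
    enumerate_models,
    find_model,
    model_by_id,
    phenotype_of,
    transmission_distribution,
    transmit,
    w_linkage_check,
)
from conftest import ind, small_sim_config
from pedtrait.pedio import Pedigree
from pedtrait.synthdata import simulate_pedigree

G = OrderedGenotype.from_label


class TestModelSpace:
    def test_sixty_four_models(self):
        models = enumerate_models()
        assert len(models) == 64
        assert [m.model_id for m in models] == list(range(1, 65))

    def test_unique_dominant_autosomal_aa_Aa(self):
        hits = [
            m for m in enumerate_models()
            if (m.mode, m.location) == (DOMINANT, AUTOSOME)
            and m.founder_female_label == "aa"
            and m.founder_male_label == "Aa"
        ]
        assert len(hits) == 1

    def test_half_autosomal_half_z(self):
        models = enumerate_models()
        assert sum(m.location == AUTOSOME for m in models) == 32
        assert sum(m.location == Z for m in models) == 32

    def test_z_heterozygous_female_founders_flagged_invalid(self):
        invalid = [m for m in enumerate_models() if not m.valid]
        assert len(invalid) == 16
        assert all(m.location == Z for m in invalid)
        assert all(m.founder_female_label in ("aA", "Aa") for m in invalid)
        with pytest.raises(GeneticsError):
            invalid[0].founder_female_genotype

    def test_z_homozygous_female_labels_collapse_to_hemizygous(self):
        m = find_model(DOMINANT, Z, "AA", "aa")
        assert m.founder_female_genotype == OrderedGenotype.hemizygous("A")

    def test_model_by_id_round_trips(self):
        for m in enumerate_models():
            assert model_by_id(m.model_id) == m


class TestTransmission:
    @pytest.mark.parametrize("mother,father,sex,loc,expected", [
        ("aa", "Aa", FEMALE, AUTOSOME, {"aA": 0.5, "aa": 0.5}),
        ("AA", "AA", MALE, AUTOSOME, {"AA": 1.0}),
        ("a", "aA", FEMALE, Z, {"a": 0.5, "A": 0.5}),
        ("A", "aa", MALE, Z, {"Aa": 1.0}),  # ordered (maternal, paternal)
        ("aA", "Aa", FEMALE, AUTOSOME,
         {"aA": 0.25, "aa": 0.25, "AA": 0.25, "Aa": 0.25}),
    ])
    def test_exact_distributions(self, mother, father, sex, loc, expected):
        dist = transmission_distribution(G(mother), G(father), sex, loc)
        assert {g.label: p for g, p in dist.items()} == expected

    @pytest.mark.parametrize("mother,father", [
        ("aa", "aA"), ("aA", "aA"), ("AA", "aa"), ("Aa", "AA"),
    ])
    @pytest.mark.parametrize("sex", [FEMALE, MALE])
    def test_autosomal_distribution_sums_to_one(self, mother, father, sex):
        dist = transmission_distribution(G(mother), G(father), sex, AUTOSOME)
        assert math.isclose(sum(dist.values()), 1.0)

    @pytest.mark.parametrize("mother", ["a", "A"])
    @pytest.mark.parametrize("father", ["aa", "aA", "Aa", "AA"])
    @pytest.mark.parametrize("sex", [FEMALE, MALE])
    def test_z_distribution_sums_to_one(self, mother, father, sex):
        dist = transmission_distribution(G(mother), G(father), sex, Z)
        assert math.isclose(sum(dist.values()), 1.0)

    def test_invalid_parent_ploidy_rejected(self):
        with pytest.raises(GeneticsError):
            transmission_distribution(G("a"), G("A"), MALE, Z)  # hemi father
        with pytest.raises(GeneticsError):
            transmission_distribution(G("aA"), G("aA"), MALE, Z)  # diploid Z mother
        with pytest.raises(GeneticsError):
            transmission_distribution(G("a"), G("aA"), FEMALE, AUTOSOME)

    def test_transmit_matches_distribution(self):
        rng = np.random.default_rng(11)
        dist = transmission_distribution(G("aA"), G("Aa"), FEMALE, AUTOSOME)
        draws = [transmit(G("aA"), G("Aa"), FEMALE, AUTOSOME, rng).label
                 for _ in range(4000)]
        for g, p in dist.items():
            freq = draws.count(g.label) / len(draws)
            assert abs(freq - p) < 0.03


class TestPhenotypeMap:
    def test_dominant_heterozygous_female_affected(self, model4):
        assert phenotype_of(G("aA"), FEMALE, model4) == AFFECTED

    def test_dominant_homozygous_a_female_unaffected(self, model4):
        assert phenotype_of(G("aa"), FEMALE, model4) == UNAFFECTED

    def test_males_never_express(self, model4):
        assert phenotype_of(G("AA"), MALE, model4) == NOT_EXPRESSED

    def test_recessive_inverts_dominant_for_females(self):
        dom = find_model(DOMINANT, AUTOSOME, "aa", "Aa")
        rec = find_model(RECESSIVE, AUTOSOME, "aa", "Aa")
        for label in ("aa", "aA", "Aa", "AA"):
            d = phenotype_of(G(label), FEMALE, dom)
            r = phenotype_of(G(label), FEMALE, rec)
            assert {d, r} == {AFFECTED, UNAFFECTED}

    def test_hemizygous_females_on_z(self):
        dom = find_model(DOMINANT, Z, "aa", "Aa")
        rec = find_model(RECESSIVE, Z, "aa", "Aa")
        assert phenotype_of(G("A"), FEMALE, dom) == AFFECTED
        assert phenotype_of(G("a"), FEMALE, dom) == UNAFFECTED
        assert phenotype_of(G("a"), FEMALE, rec) == AFFECTED

    def test_total_on_valid_domain(self):
        outcomes = set()
        for m in enumerate_models():
            if not m.valid:
                continue
            codes = ("a", "A") if m.location == Z else ("aa", "aA", "Aa", "AA")
            for label in codes:
                outcomes.add(phenotype_of(G(label), FEMALE, m))
            outcomes.add(phenotype_of(G("aa"), MALE, m))
        assert outcomes == {AFFECTED, UNAFFECTED, NOT_EXPRESSED}


class TestWLinkage:
    def _ped(self, daughter_phen):
        return Pedigree([
            ind("A1", None, None, FEMALE, phen="affected"),
            ind("A2", None, None, MALE),
            ind("B3", "A2", "A1", FEMALE, first=1981, phen=daughter_phen),
        ])

    def test_all_daughters_affected_does_not_exclude(self):
        assert w_linkage_check(self._ped("affected")) == []

    def test_unaffected_daughter_of_affected_mother_listed(self):
        assert w_linkage_check(self._ped("unaffected")) == [("A1", "B3")]

    def test_exclusion_common_under_autosomal_dominance(self, model4):
        # affected mothers routinely have unaffected daughters when the
        # trait is autosomal, so W-linkage is excluded in most simulated
        # studies that contain informative mother-daughter pairs
        n_informative = 0
        n_excluded = 0
        for seed in range(120):
            study = simulate_pedigree(
                small_sim_config(model4, seed, n_years=6,
                                 breeding_probability=1.0)
            )
            ped = study.pedigree
            informative = any(
                ped[i.dam].phenotype == "affected" and i.observed
                for i in ped
                if i.sex == FEMALE and i.dam is not None
            )
            if informative:
                n_informative += 1
                pairs = w_linkage_check(ped)
                for mother, daughter in pairs:
                    assert ped[mother].phenotype == "affected"
                    assert ped[daughter].phenotype == "unaffected"
                if pairs:
                    n_excluded += 1
        assert n_informative > 20
        assert n_excluded / n_informative > 0.5
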