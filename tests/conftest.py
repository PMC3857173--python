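import pytest

from pedtrait.genetics import (
    AUTOSOME,
    DOMINANT,
    FEMALE,
    MALE,
    find_model,
)
from pedtrait.pedio import Individual, Pedigree
from pedtrait.synthdata import SimulationConfig, make_robin_like_fixture, simulate_pedigree


def ind(iid, sire, dam, sex, first=1980, last=1989, phen="unobserved"):
    return Individual(iid, sire, dam, sex, first, last, phen)


@pytest.fixture
def model4():
    """Autosomal dominant with founders aa (female) x Aa (male)."""
    return find_model(DOMINANT, AUTOSOME, "aa", "Aa")


@pytest.fixture
def trio_affected(model4):
    """Founders plus one affected daughter: likelihood 1/2 under model4."""
    return Pedigree([
        ind("A1", None, None, FEMALE, phen="unaffected"),
        ind("A2", None, None, MALE),
        ind("B3", "A2", "A1", FEMALE, first=1981, phen="affected"),
    ])


@pytest.fixture
def quartet_mixed(model4):
    """Founders plus one affected and one unaffected daughter: 1/4."""
    return Pedigree([
        ind("A1", None, None, FEMALE, phen="unaffected"),
        ind("A2", None, None, MALE),
        ind("B3", "A2", "A1", FEMALE, first=1981, phen="affected"),
        ind("B4", "A2", "A1", FEMALE, first=1981, phen="unaffected"),
    ])


def small_sim_config(true_model, seed, n_years=4, **overrides):
    """Small forward-simulation setting used for random test pedigrees."""
    kw = dict(
        true_model=true_model,
        seed=seed,
        n_years=n_years,
        mean_clutch=1.8,
        offspring_survival=0.7,
        adult_survival=0.85,
        breeding_probability=0.8,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


def random_small_studies(rng, n, max_nonfounders=10, min_size=5,
                         models=None, **overrides):
    """Yield n non-extinct simulated studies with <= max_nonfounders
    non-founders, drawing the true model at random."""
    from pedtrait.genetics import enumerate_models

    if models is None:
        models = [m for m in enumerate_models() if m.valid]
    out = []
    while len(out) < n:
        true = models[rng.integers(0, len(models))]
        cfg = small_sim_config(true, int(rng.integers(2**30)), **overrides)
        s = simulate_pedigree(cfg)
        if s.extinct:
            continue
        if not min_size <= len(s.pedigree) <= max_nonfounders + 2:
            continue
        out.append(s)
    return out


@pytest.fixture(scope="session")
def robin_fixture():
    return make_robin_like_fixture()
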