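"""Per-year trajectories of the count of allele A.

Given a population of compatible joint genotype configurations (from the
SMC or from the enumeration oracle), each configuration implies a
trajectory: for every calendar year, the number of copies of A among the
individuals present that year.  An individual is present in every year of
[first_year, last_year] and contributes 2 alleles at an autosomal locus;
at a Z-linked locus males (ZZ) contribute 2 and females (ZW, hemizygous)
contribute 1.  The summary reports the posterior mean and pointwise
equal-tailed 50% and 95% bands per year, together with the total allele
count (twice the population size for an autosomal locus) the trajectory
is bounded by.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetics import A_COUNT_DIPLOID, A_COUNT_HEMI
from .pedio import Pedigree
from .smc import ParticlePopulation


class TrajectoryError(ValueError):
    pass


@dataclass
class TrajectorySummary:
    """Posterior summary of the yearly A-allele count.

    ``table`` has one row per year with columns year, mean_A, lo50, hi50,
    lo95, hi95, total_alleles.
    """

    table: pd.DataFrame
    model_id: int
    n_particles: int

    @property
    def years(self) -> list[int]:
        return self.table["year"].tolist()

    def plot(self, ax=None):
        """Mean trajectory with shaded 50%/95% bands and the total allele
        count as a dash-dotted ceiling."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table
        ax.fill_between(t["year"], t["lo95"], t["hi95"], color="0.85",
                        label="95% band")
        ax.fill_between(t["year"], t["lo50"], t["hi50"], color="0.6",
                        label="50% band")
        ax.plot(t["year"], t["mean_A"], color="black", label="mean")
        ax.plot(t["year"], t["total_alleles"], color="black", ls="-.",
                label="total alleles")
        ax.set_xlabel("year")
        ax.set_ylabel("copies of A")
        ax.legend()
        return ax


def particle_allele_counts(
    ped: Pedigree, particles: ParticlePopulation, years: list[int] | None = None
) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Per-particle, per-year A counts.

    Returns (years, counts, totals) with ``counts[p, t]`` the A-copy
    count of particle p in year index t and ``totals[t]`` the total
    allele count that year.
    """
    if particles.n_particles == 0:
        raise TrajectoryError("empty particle population")
    if years is None:
        years = list(ped.years)
    idx = {iid: j for j, iid in enumerate(particles.ids)}
    G = particles.genotypes
    # per-individual A-copy count per particle
    a_per_ind = np.empty_like(G, dtype=np.int64)
    for j, iid in enumerate(particles.ids):
        table = A_COUNT_HEMI if particles.hemizygous[j] else A_COUNT_DIPLOID
        a_per_ind[:, j] = table[G[:, j]]
    counts = np.zeros((G.shape[0], len(years)), dtype=np.int64)
    totals = np.zeros(len(years), dtype=np.int64)
    for t, year in enumerate(years):
        cols = [idx[i.id] for i in ped.alive_in(year) if i.id in idx]
        if cols:
            counts[:, t] = a_per_ind[:, cols].sum(axis=1)
            totals[t] = sum(
                1 if particles.hemizygous[j] else 2 for j in cols
            )
    return years, counts, totals


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x, kind="mergesort")
    cw = np.cumsum(w[order])
    cw /= cw[-1]
    return float(x[order][np.searchsorted(cw, q, side="left")])


def allele_trajectories(
    ped: Pedigree,
    particles: ParticlePopulation,
    years: list[int] | None = None,
) -> TrajectorySummary:
    """Summarize the posterior A-count trajectory from retained particles.

    Bands are pointwise per-year equal-tailed quantile intervals of the
    particle counts (25-75% and 2.5-97.5%), reported on the integer count
    scale and extended by at most one count where needed so each interval
    contains the posterior mean (integer quantiles of a near-point-mass
    posterior can otherwise sit just below a fractional mean).  Weighted
    populations (enumeration oracle output) use weighted quantiles; SMC
    populations are uniform-weight.
    """
    years, counts, totals = particle_allele_counts(ped, particles, years)
    w = particles.weights
    rows = []
    for t, year in enumerate(years):
        x = counts[:, t]
        if w is None:
            mean = float(x.mean())
            lo50, hi50, lo95, hi95 = np.percentile(
                x, [25, 75, 2.5, 97.5], method="nearest"
            )
        else:
            mean = float(np.average(x, weights=w))
            lo50 = _weighted_quantile(x, w, 0.25)
            hi50 = _weighted_quantile(x, w, 0.75)
            lo95 = _weighted_quantile(x, w, 0.025)
            hi95 = _weighted_quantile(x, w, 0.975)
        lo_m, hi_m = int(np.floor(mean)), int(np.ceil(mean))
        rows.append(
            {
                "year": year,
                "mean_A": mean,
                "lo50": min(int(lo50), lo_m),
                "hi50": max(int(hi50), hi_m),
                "lo95": min(int(lo95), lo_m),
                "hi95": max(int(hi95), hi_m),
                "total_alleles": int(totals[t]),
            }
        )
    return TrajectorySummary(
        table=pd.DataFrame(rows),
        model_id=particles.model.model_id,
        n_particles=particles.n_particles,
    )
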