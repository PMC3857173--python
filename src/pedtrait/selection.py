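"""Model ranking: AIC and Bayesian posterior model probabilities.

Every inheritance model in the 64-model space is fully specified (founder
genotypes fixed, full penetrance, no free parameters), so the AIC penalty
term is a shared constant and AIC reduces to -2 log L; AIC ranking, raw
likelihood ranking and posterior ranking therefore coincide.  Posterior
model probabilities assume a uniform prior of 1/64 over the model space:
models with zero likelihood contribute zero mass, and the prior cancels
in the normalization.  Likelihoods here are astronomically small (order
e^-40), so normalization is done with log-sum-exp stabilization.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .genetics import InheritanceModel, enumerate_models


class NoCompatibleModelError(ValueError):
    """Every candidate model has zero likelihood."""


def score_models(
    results: Sequence[tuple[int, float]],
    models: Sequence[InheritanceModel] | None = None,
) -> pd.DataFrame:
    """Score table over the full model space from (model_id, log_likelihood)
    pairs.

    ``results`` lists the models with known log-likelihoods (natural log;
    ``-inf`` allowed); models of the space absent from ``results`` are
    treated as zero-likelihood.  Returns a DataFrame sorted by descending
    posterior with columns model_id, founder_female, founder_male, mode,
    location, minus2_loglik, aic, relative_likelihood, posterior.

    AIC = -2 log L + 2k with k = 0 shared by all models;
    relative_likelihood_i = exp((AIC_best - AIC_i)/2);
    posterior_i = L_i / sum_j L_j under the uniform 1/64 prior.
    """
    if models is None:
        models = enumerate_models()
    by_id = {m.model_id: m for m in models}
    loglik = {m.model_id: -math.inf for m in models}
    for model_id, ll in results:
        if model_id not in by_id:
            raise KeyError(f"unknown model_id {model_id}")
        loglik[model_id] = float(ll)

    lls = np.array([loglik[m.model_id] for m in models])
    finite = np.isfinite(lls)
    if not finite.any():
        raise NoCompatibleModelError(
            "no compatible model: all candidate models have zero likelihood"
        )
    best = lls[finite].max()
    rel = np.where(finite, np.exp(lls - best), 0.0)
    posterior = rel / rel.sum()  # log-sum-exp: shift by the best model

    table = pd.DataFrame(
        {
            "model_id": [m.model_id for m in models],
            "founder_female": [m.founder_female_label for m in models],
            "founder_male": [m.founder_male_label for m in models],
            "mode": [m.mode for m in models],
            "location": [m.location for m in models],
            "minus2_loglik": -2.0 * lls,
            "aic": -2.0 * lls,
            "relative_likelihood": rel,
            "posterior": posterior,
        }
    )
    table = table.sort_values(
        ["posterior", "model_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table
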