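"""Parameter-recovery studies on synthetic data.

These routines tie the generator and the REML engine together: simulate a
study-shaped population with known truth, fit the animal model exactly as
the analysis pipeline would, and summarise how well the configured
parameters are recovered.  They are used by the test suite and by the
reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from nutrieff.animal_model import (
    RandomTerm,
    fit_mixed_model,
    fixed_design,
    genetic_parameters,
)
from nutrieff.pedigree import additive_relationship
from nutrieff.simulate import (
    SimulationConfig,
    default_config,
    restrict_config,
    simulate_breeding_values,
    simulate_pedigree,
    simulate_phenotypes,
)

#: fixed effects the generator actually injects into every trait
GENERATOR_FIXED_TERMS = ["sex", "slaughter_bw", "temperature"]


@dataclass
class RecoveryResult:
    trait_pair: tuple[str, str]
    truth_rg: float
    estimates: list[float]
    h2_estimates: dict[str, list[float]]
    n_phenotyped: list[int]

    @property
    def mean_rg(self) -> float:
        return float(np.mean(self.estimates))

    @property
    def empirical_se(self) -> float:
        e = np.asarray(self.estimates)
        return float(e.std(ddof=1) / np.sqrt(e.size))


def fit_pair(
    traits: pd.DataFrame,
    A_sub: np.ndarray,
    pair: tuple[str, str],
    fixed_terms: list[str] = GENERATOR_FIXED_TERMS,
):
    """Bivariate animal model for two trait columns of a simulated table."""
    X, _ = fixed_design(traits, fixed_terms)
    lit = pd.Categorical(traits["litter_id"]).codes.astype(int)
    n = len(traits)
    y = traits[list(pair)].to_numpy()
    fit = fit_mixed_model(
        y, X,
        [RandomTerm("animal", np.arange(n), A_sub), RandomTerm("litter", lit)],
        trait_names=list(pair),
    )
    return fit


def recover_genetic_correlation(
    pair: tuple[str, str],
    n_replicates: int = 20,
    seed: int = 1,
    cfg: SimulationConfig | None = None,
) -> RecoveryResult:
    """Mean bivariate-REML genetic-correlation estimate over seeded replicates.

    Every replicate is a fully independent *bivariate* simulation of the
    pair — fresh pedigree, breeding values, litter effects, covariates
    and residuals drawn under the pair's marginal architecture — so the
    average integrates over pedigree-level sampling as well as
    effect-level sampling.
    """
    cfg = restrict_config(cfg or default_config(seed), list(pair))
    rng = np.random.default_rng(seed)
    G = cfg.covariance("a")
    truth = float(G[0, 1] / np.sqrt(G[0, 0] * G[1, 1]))
    names = [t.name for t in cfg.traits]
    estimates: list[float] = []
    h2_est: dict[str, list[float]] = {pair[0]: [], pair[1]: []}
    ns: list[int] = []
    for _ in range(n_replicates):
        ped, litters = simulate_pedigree(cfg, rng)
        A_full = additive_relationship(ped)
        Fv = np.diag(A_full.values) - 1.0
        bv = simulate_breeding_values(ped, G, rng, names, inbreeding_coeffs=Fv)
        traits = simulate_phenotypes(ped, litters, bv, cfg, rng)
        A_sub = A_full.submatrix(list(traits["animal_id"])).values
        fit = fit_pair(traits, A_sub, pair)
        gp = genetic_parameters(fit)
        estimates.append(gp.rg)
        for t in pair:
            h2_est[t].append(gp.h2[t])
        ns.append(len(traits))
    return RecoveryResult(pair, truth, estimates, h2_est, ns)


def recover_heritability(
    trait: str,
    n_replicates: int = 20,
    seed: int = 1,
    cfg: SimulationConfig | None = None,
) -> tuple[float, list[float]]:
    """Univariate h2 recovery: returns (truth, per-replicate estimates)."""
    cfg = restrict_config(cfg or default_config(seed), [trait])
    rng = np.random.default_rng(seed)
    spec = cfg.traits[0]
    truth = spec.v_a / spec.v_p
    names = [t.name for t in cfg.traits]
    G = cfg.covariance("a")
    estimates = []
    for _ in range(n_replicates):
        ped, litters = simulate_pedigree(cfg, rng)
        A_full = additive_relationship(ped)
        Fv = np.diag(A_full.values) - 1.0
        bv = simulate_breeding_values(ped, G, rng, names, inbreeding_coeffs=Fv)
        traits = simulate_phenotypes(ped, litters, bv, cfg, rng)
        A_sub = A_full.submatrix(list(traits["animal_id"])).values
        X, _ = fixed_design(traits, GENERATOR_FIXED_TERMS)
        lit = pd.Categorical(traits["litter_id"]).codes.astype(int)
        fit = fit_mixed_model(
            traits[trait].to_numpy(), X,
            [RandomTerm("animal", np.arange(len(traits)), A_sub),
             RandomTerm("litter", lit)],
        )
        gp = genetic_parameters(fit)
        estimates.append(gp.h2[fit.trait_names[0]])
    return truth, estimates
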