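"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from nutrieff.animal_model import REMLFit
from nutrieff.pedigree import Pedigree, PedigreeRecord


def manual_fit(theta, names, ai, traits=("t",)):
    """Assemble a REMLFit directly from known components (for ratio tests)."""
    comps: dict[str, np.ndarray] = {}
    n_traits = len(traits)
    for name in names:
        term = name.split("_", 1)[1].split("(")[0]
        comps.setdefault(term, np.zeros((n_traits, n_traits)))
    for pos, name in enumerate(names):
        term = name.split("_", 1)[1].split("(")[0]
        if n_traits == 1:
            comps[term][0, 0] = theta[pos]
    return REMLFit(
        trait_names=list(traits), components=comps,
        component_traits={k: tuple(range(n_traits)) for k in comps},
        param_names=list(names), theta=np.asarray(theta, float),
        beta=np.zeros(1), beta_names=["(Intercept)"], beta_cov=np.eye(1),
        loglik=0.0, converged=True, iterations=1,
        ai_matrix=np.asarray(ai, float), n_obs=100, residual_df=99,
        at_boundary=[],
    )


def random_pedigree(n_founders: int, n_offspring: int, rng: np.random.Generator) -> Pedigree:
    """Random overlapping-generation pedigree; parents always precede offspring."""
    records = [PedigreeRecord(f"F{i}") for i in range(n_founders)]
    sexes = {r.animal_id: ("m" if i % 2 == 0 else "f") for i, r in enumerate(records)}
    for k in range(n_offspring):
        males = [a for a, s in sexes.items() if s == "m"]
        females = [a for a, s in sexes.items() if s == "f"]
        aid = f"O{k}"
        records.append(
            PedigreeRecord(aid, str(rng.choice(males)), str(rng.choice(females)))
        )
        sexes[aid] = "m" if rng.random() < 0.5 else "f"
    return Pedigree(records)


def gene_drop_relationship(ped: Pedigree, n_drops: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo numerator relationships by gene dropping.

    Founders receive unique alleles; each offspring inherits one random
    allele from each parent (unknown parents contribute fresh alleles).
    ``a_ij`` is estimated as four times the probability that one random
    allele from *i* is identical by descent to one from *j* (and
    ``a_ii = 1 + P(autozygous)``).
    """
    n = len(ped)
    sire, dam = ped.parent_indices()
    alleles = np.empty((n, 2, n_drops), dtype=np.int32)
    next_allele = 0
    idx = np.arange(n_drops)
    for i in range(n):
        for slot, p in enumerate((sire[i], dam[i])):
            if p < 0:
                alleles[i, slot] = next_allele
                next_allele += 1
            else:
                pick = rng.integers(0, 2, n_drops)
                alleles[i, slot] = alleles[p, pick, idx]
    A = np.empty((n, n))
    for i in range(n):
        ai1, ai2 = alleles[i]
        A[i, i] = 1.0 + np.mean(ai1 == ai2)
        for j in range(i):
            aj1, aj2 = alleles[j]
            matches = ((ai1 == aj1).astype(np.int8) + (ai1 == aj2)
                       + (ai2 == aj1) + (ai2 == aj2))
            A[i, j] = A[j, i] = matches.mean() / 2.0
    return A


@pytest.fixture(scope="session")
def small_random_pedigree() -> Pedigree:
    rng = np.random.default_rng(42)
    return random_pedigree(10, 20, rng)


@pytest.fixture(scope="session")
def trio() -> Pedigree:
    return Pedigree.from_records(
        [
            PedigreeRecord("A"),
            PedigreeRecord("B"),
            PedigreeRecord("C", "A", "B"),
        ]
    )
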