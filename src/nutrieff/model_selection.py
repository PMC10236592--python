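"""All-subsets AIC screening of fixed-effect structures.

Before fitting the animal models, a plain fixed-effects linear model with
every candidate covariate and interaction is screened: all subsets of the
full term set that respect marginality (an interaction is admissible only
when both its main effects are present) are fitted by ordinary least
squares and ranked by AIC.  The terms of the single best model are carried
into the animal model; all models within delta-AIC < 2 of the best are
reported as the *top set*.

AIC uses the maximum-likelihood residual variance (RSS/n) and counts the
residual variance as a parameter, matching the usual definition for linear
models fitted by least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from nutrieff.animal_model import fixed_design

MAX_CANDIDATES = 2 ** 20
DEFAULT_DELTA = 2.0


class SelectionError(ValueError):
    """Model screening cannot proceed (degenerate data or too many terms)."""


@dataclass
class CandidateModel:
    terms: tuple[str, ...]
    k: int
    loglik: float
    aic: float
    delta_aic: float = np.nan

    def __str__(self) -> str:  # compact display for reports
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"{rhs}  (k={self.k}, AIC={self.aic:.2f})"


def fit_fixed(data: pd.DataFrame, response: str, terms: Sequence[str]):
    """OLS fit of ``response ~ terms``; returns (coefficients, loglik, k, aic).

    ``k`` counts the regression coefficients plus the residual variance.
    Aliased columns are dropped inside `fixed_design`.
    """
    X, names = fixed_design(data, terms)
    y = data[response].to_numpy(float)
    n = y.size
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ coef) ** 2))
    if rss <= 0 or not np.isfinite(rss):
        raise SelectionError(
            "zero residual variance: response is exactly fitted, AIC undefined"
        )
    sigma2 = rss / n
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    k = X.shape[1] + 1
    aic = -2.0 * loglik + 2.0 * k
    return pd.Series(coef, index=names), loglik, k, aic


def _respects_marginality(subset: frozenset[str]) -> bool:
    for t in subset:
        if ":" in t:
            if any(p not in subset for p in t.split(":")):
                return False
    return True


def admissible_subsets(full_terms: Sequence[str]) -> list[tuple[str, ...]]:
    """All marginality-respecting subsets, in the original term order."""
    terms = list(full_terms)
    if 2 ** len(terms) > MAX_CANDIDATES:
        raise SelectionError(
            f"{len(terms)} terms give more than {MAX_CANDIDATES} candidate "
            "models; reduce the term set"
        )
    out = []
    for r in range(len(terms) + 1):
        for combo in combinations(terms, r):
            if _respects_marginality(frozenset(combo)):
                out.append(combo)
    return out


def dredge(
    data: pd.DataFrame,
    response: str,
    full_terms: Sequence[str],
    delta_threshold: float = DEFAULT_DELTA,
) -> tuple[list[CandidateModel], list[CandidateModel], tuple[str, ...]]:
    """Rank every admissible fixed-effect subset by AIC.

    Returns ``(ranked, top_set, selected_terms)`` where ``top_set`` holds
    all models within ``delta_threshold`` of the best AIC and
    ``selected_terms`` are the terms of the single best model (ties broken
    by fewer parameters, then lexicographic term order).
    """
    candidates = []
    for combo in admissible_subsets(full_terms):
        _, ll, k, aic = fit_fixed(data, response, combo)
        candidates.append(CandidateModel(combo, k, ll, aic))
    candidates.sort(key=lambda m: (m.aic, m.k, m.terms))
    best = candidates[0].aic
    for m in candidates:
        m.delta_aic = m.aic - best
    top_set = [m for m in candidates if m.delta_aic < delta_threshold]
    return candidates, top_set, candidates[0].terms


def ranking_table(candidates: list[CandidateModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "terms": [" + ".join(m.terms) if m.terms else "1" for m in candidates],
            "k": [m.k for m in candidates],
            "loglik": [m.loglik for m in candidates],
            "aic": [m.aic for m in candidates],
            "delta_aic": [m.delta_aic for m in candidates],
        }
    )
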