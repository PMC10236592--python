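"""Mixed-model analysis of sensory-panel scores with Fisher's LSD post hoc.

Panel scores (0-10 line scale) for firmness, tenderness, juiciness and
flavour are modelled as

    score = mu + Session + Judge + Sex + PE-group + FatThickness + e

with session and judge as random effects (identity covariance) and the
remaining factors fixed.  Group comparisons use Fisher's least significant
difference on the adjusted (least-squares) means: a pair of groups differs
when the absolute difference of adjusted means exceeds
``t(1-alpha/2, df) * sqrt(2 * MS_error / n_eff)`` with ``n_eff`` the
harmonic mean of the two group sizes and ``df`` the residual degrees of
freedom of the fixed-effect projection.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from nutrieff.animal_model import REMLFit, RandomTerm, fit_mixed_model, fixed_design

logger = logging.getLogger(__name__)

ATTRIBUTES = ("firmness", "tenderness", "juiciness", "flavour")
FIXED_FACTORS = ("sex", "pe_group", "fat_thickness")
RANDOM_FACTORS = ("judge", "session")


@dataclass
class SensoryFit:
    """REML fit of one attribute plus the bookkeeping needed for LSD tests."""

    attribute: str
    fit: REMLFit
    data: pd.DataFrame
    fixed_factors: list[str]
    xnames: list[str]

    @property
    def ms_error(self) -> float:
        return float(self.fit.components["residual"][0, 0])

    def adjusted_means(self, factor: str) -> pd.Series:
        """Least-squares means: predictions averaged over the other factors."""
        levels = sorted(self.data[factor].astype(str).unique())
        means = {}
        for lv in levels:
            row = np.zeros(len(self.xnames))
            for j, name in enumerate(self.xnames):
                if name == "(Intercept)":
                    row[j] = 1.0
                else:
                    fac, flev = name[:-1].split("[")
                    if fac == factor:
                        row[j] = 1.0 if flev == lv else 0.0
                    else:
                        # equal weight over that factor's levels
                        n_levels = self.data[fac].astype(str).nunique()
                        row[j] = 1.0 / n_levels
            means[lv] = float(row @ self.fit.beta)
        return pd.Series(means, name=f"adjusted_mean_{factor}")


def fit_sensory(data: pd.DataFrame, attribute: str) -> SensoryFit:
    """Fit the sensory mixed model for one attribute.

    ``data`` is long format with columns ``judge, session, sex, pe_group,
    fat_thickness, attribute, score``.  Fixed factors with fewer than two
    observed levels are dropped with a warning.
    """
    if attribute not in set(data["attribute"].astype(str)):
        raise ValueError(f"attribute {attribute!r} not present in the score table")
    d = data[data["attribute"].astype(str) == attribute].reset_index(drop=True)
    fixed = []
    for f in FIXED_FACTORS:
        if d[f].astype(str).nunique() >= 2:
            fixed.append(f)
        else:
            logger.warning("factor %r has a single level; dropped", f)
    X, xnames = fixed_design(d, fixed)
    terms = []
    for f in RANDOM_FACTORS:
        codes = pd.Categorical(d[f].astype(str)).codes.astype(int)
        terms.append(RandomTerm(f, codes))
    fit = fit_mixed_model(d["score"].to_numpy(float), X, terms, beta_names=xnames)
    return SensoryFit(attribute, fit, d, fixed, xnames)


def _letters(levels: list[str], nonsig: dict[str, dict[str, bool]]) -> dict[str, str]:
    """Compact letter display from a non-significance adjacency matrix.

    ``levels`` must be ordered by descending mean; groups that share a
    letter do not differ.  Maximal runs of mutually non-different levels
    get one letter each.
    """
    n = len(levels)
    intervals = []
    for i in range(n):
        j = i
        while j + 1 < n and all(nonsig[levels[a]][levels[b]]
                                for a in range(i, j + 2)
                                for b in range(i, j + 2)):
            j += 1
        intervals.append((i, j))
    # drop intervals contained in earlier ones
    maximal = []
    for iv in intervals:
        if not any(o[0] <= iv[0] and iv[1] <= o[1] for o in maximal):
            maximal.append(iv)
    letters = {lv: "" for lv in levels}
    for letter, (i, j) in zip(string.ascii_lowercase, maximal):
        for k in range(i, j + 1):
            letters[levels[k]] += letter
    return letters


def fisher_lsd(
    sf: SensoryFit, factor: str = "pe_group", alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Pairwise LSD comparisons of adjusted means for one fixed factor.

    Returns a table with one row per unordered pair (difference, LSD
    threshold, significance flag) and a letters display where groups
    sharing a letter are not separated at level ``alpha``.
    """
    if factor not in sf.fixed_factors:
        raise ValueError(f"{factor!r} was not a fixed factor of the fit")
    means = sf.adjusted_means(factor)
    counts = sf.data[factor].astype(str).value_counts()
    df_resid = sf.fit.residual_df
    mse = sf.ms_error
    degenerate = mse <= 0
    if degenerate:
        logger.warning("zero residual variance; every nonzero difference separates")
    tcrit = stats.t.ppf(1 - alpha / 2, df_resid)
    rows = []
    levels = list(means.sort_values(ascending=False).index)
    nonsig = {a: {b: True for b in levels} for a in levels}
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            n_eff = 2.0 / (1.0 / counts[a] + 1.0 / counts[b])
            lsd = tcrit * np.sqrt(2.0 * mse / n_eff)
            diff = means[a] - means[b]
            sig = bool(abs(diff) > lsd)
            nonsig[a][b] = nonsig[b][a] = not sig
            rows.append(
                {"level_1": a, "level_2": b, "difference": diff,
                 "lsd": lsd, "significant": sig}
            )
    table = pd.DataFrame(rows)
    letters = _letters(levels, nonsig)
    return table, letters


def sensory_report(data: pd.DataFrame, alpha: float = 0.05) -> dict[str, dict]:
    """Fit all four attributes and collect LSD tables for the PE grouping."""
    out = {}
    for attr in ATTRIBUTES:
        sf = fit_sensory(data, attr)
        table, letters = fisher_lsd(sf, "pe_group", alpha)
        out[attr] = {
            "fit": sf,
            "judge_var": sf.fit.component("judge"),
            "session_var": sf.fit.component("session"),
            "residual_var": sf.ms_error,
            "adjusted_means": sf.adjusted_means("pe_group"),
            "lsd_table": table,
            "letters": letters,
        }
    return out
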