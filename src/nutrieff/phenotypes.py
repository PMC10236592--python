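"""Derivation of nutrient-efficiency, performance and water-holding phenotypes.

Protein efficiency (PE) is the fraction of dietary crude-protein intake that
a pig retains in its carcass between the start of the grower phase (~20 kg
live weight) and slaughter; phosphorus efficiency (PhE) is the analogous
fraction for phosphorus.  Retained protein and phosphorus are predicted from
a dual-energy X-ray absorptiometry (DXA) scan of the left cold carcass half
via published prediction equations; the starting content is approximated by
sex-specific per-kg carcass composition constants multiplied by the live
weight at entry.

All equation-level functions accept scalars or numpy arrays.  Table-level
derivation (`derive_phenotypes`) flags implausible values in a QC table
instead of dropping records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# DXA -> carcass composition prediction equations (grams)
CP_INTERCEPT = -482.745
CP_SLOPE = 0.23
PH_INTERCEPT = -6.388
PH_SLOPE_BMC = 0.109
PH_SLOPE_LEAN = 0.004

SEXES = ("female", "castrate", "entire_male")


class ImplausibleValueWarning(UserWarning):
    """A derived quantity fell outside its biologically plausible range."""


class DomainError(ValueError):
    """Input outside the mathematical domain of a derivation formula."""


@dataclass(frozen=True)
class BaselineComposition:
    """Per-kg carcass composition of ~20-kg piglets, by sex.

    The constants are calibration inputs estimated from a chemically
    analysed reference sample of piglets; the defaults below are plausible
    placeholder values for Swiss Large White piglets (g nutrient per kg
    live body weight at entry) and should be replaced with
    population-specific estimates when available.
    """

    protein_per_kg: dict[str, float] = field(
        default_factory=lambda: {s: 150.0 for s in SEXES}
    )
    phosphorus_per_kg: dict[str, float] = field(
        default_factory=lambda: {s: 5.5 for s in SEXES}
    )

    def __post_init__(self) -> None:
        for table in (self.protein_per_kg, self.phosphorus_per_kg):
            for sex, v in table.items():
                if v <= 0:
                    raise ValueError(f"non-positive per-kg content for sex {sex!r}")


def carcass_protein(lean_dxa, half_prop):
    """Crude protein retained in the carcass (g) from DXA lean mass.

    ``lean_dxa`` is the DXA lean tissue mass of the left cold carcass half
    (g); ``half_prop`` the weight of that half as a proportion of the total
    cold carcass weight.  Non-positive predictions are returned as-is with
    an `ImplausibleValueWarning`.
    """
    lean_dxa = np.asarray(lean_dxa, dtype=float)
    half_prop = np.asarray(half_prop, dtype=float)
    if np.any(lean_dxa < 0) or np.any(half_prop <= 0) or np.any(half_prop > 1):
        raise DomainError("lean_dxa must be >= 0 and 0 < half_prop <= 1")
    cp = CP_INTERCEPT + CP_SLOPE * (lean_dxa * half_prop)
    if np.any(cp <= 0):
        warnings.warn(
            f"non-positive predicted carcass protein (min {np.min(cp):.2f} g); "
            "check DXA inputs",
            ImplausibleValueWarning,
            stacklevel=2,
        )
    return cp[()] if cp.ndim == 0 else cp


def carcass_phosphorus(bmc_dxa, lean_dxa, half_prop):
    """Phosphorus retained in the carcass (g) from DXA bone mineral and lean mass."""
    bmc_dxa = np.asarray(bmc_dxa, dtype=float)
    lean_dxa = np.asarray(lean_dxa, dtype=float)
    half_prop = np.asarray(half_prop, dtype=float)
    if np.any(bmc_dxa < 0) or np.any(lean_dxa < 0) or np.any(half_prop <= 0) or np.any(half_prop > 1):
        raise DomainError("DXA masses must be >= 0 and 0 < half_prop <= 1")
    ph = (
        PH_INTERCEPT
        + PH_SLOPE_BMC * (bmc_dxa * half_prop)
        + PH_SLOPE_LEAN * (lean_dxa * half_prop)
    )
    if np.any(ph <= 0):
        warnings.warn(
            f"non-positive predicted carcass phosphorus (min {np.min(ph):.3f} g)",
            ImplausibleValueWarning,
            stacklevel=2,
        )
    return ph[()] if ph.ndim == 0 else ph


def baseline_content(sex, start_bw, base: BaselineComposition):
    """Protein and phosphorus content (g) at experiment entry.

    Multiplies the live body weight at entry by the sex-specific per-kg
    composition of the reference piglet sample.  A soft range check warns
    when the entry weight is far from the ~20-kg calibration point.
    """
    sexes = np.atleast_1d(np.asarray(sex, dtype=object))
    bw = np.asarray(start_bw, dtype=float)
    missing = sorted({s for s in sexes} - set(base.protein_per_kg))
    if missing:
        raise KeyError(f"no baseline composition configured for sex {missing[0]!r}")
    if np.any((bw < 15) | (bw > 30)):
        warnings.warn(
            "entry weight outside the 15-30 kg calibration range of the "
            "baseline composition",
            ImplausibleValueWarning,
            stacklevel=2,
        )
    prot_per_kg = np.array([base.protein_per_kg[s] for s in sexes], dtype=float)
    phos_per_kg = np.array([base.phosphorus_per_kg[s] for s in sexes], dtype=float)
    prot = prot_per_kg * bw
    phos = phos_per_kg * bw
    if np.isscalar(start_bw) and np.asarray(sex).ndim == 0:
        return float(prot[0]), float(phos[0])
    return prot, phos


def protein_efficiency(cp_slaughter, cp_start, cp_intake):
    """PE = retained carcass protein over total crude-protein intake."""
    cp_intake = np.asarray(cp_intake, dtype=float)
    if np.any(cp_intake <= 0):
        raise DomainError("crude-protein intake must be positive")
    pe = (np.asarray(cp_slaughter, float) - np.asarray(cp_start, float)) / cp_intake
    if np.any(pe < 0):
        warnings.warn(
            "negative protein efficiency (retained < baseline); not clipped",
            ImplausibleValueWarning,
            stacklevel=2,
        )
    return pe[()] if pe.ndim == 0 else pe


def phosphorus_efficiency(ph_slaughter, ph_start, p_intake):
    """PhE = retained carcass phosphorus over total phosphorus intake."""
    p_intake = np.asarray(p_intake, dtype=float)
    if np.any(p_intake <= 0):
        raise DomainError("phosphorus intake must be positive")
    phe = (np.asarray(ph_slaughter, float) - np.asarray(ph_start, float)) / p_intake
    if np.any(phe < 0):
        warnings.warn(
            "negative phosphorus efficiency (retained < baseline); not clipped",
            ImplausibleValueWarning,
            stacklevel=2,
        )
    return phe[()] if phe.ndim == 0 else phe


def performance_traits(start_bw, slaughter_bw, start_age, slaughter_age, feed_intake_total):
    """Average daily gain, average daily feed intake and feed conversion ratio.

    ADG = weight gain over the grower-finisher period divided by its length
    in days; ADFI = total feed over the same period; FCR = ADFI / ADG.
    """
    duration = np.asarray(slaughter_age, float) - np.asarray(start_age, float)
    if np.any(duration <= 0):
        raise DomainError("slaughter age must exceed start age")
    adg = (np.asarray(slaughter_bw, float) - np.asarray(start_bw, float)) / duration
    adfi = np.asarray(feed_intake_total, float) / duration
    fcr = adfi / adg
    if np.ndim(adg) == 0:
        return float(adg), float(adfi), float(fcr)
    return adg, adfi, fcr


def water_holding(w1, w2, w3):
    """Drip loss and cooking loss (%) from the three chop weights.

    ``w1`` is the chop weight after blooming, ``w2`` after 48 h storage at
    4 °C and ``w3`` after cooking.  Inverted weight orderings give negative
    losses, which are flagged rather than clipped.
    """
    w1 = np.asarray(w1, float)
    w2 = np.asarray(w2, float)
    w3 = np.asarray(w3, float)
    if np.any(w1 <= 0) or np.any(w2 <= 0) or np.any(w3 <= 0):
        raise DomainError("chop weights must be positive")
    dl = (w1 - w2) / w1 * 100.0
    cl = (w2 - w3) / w2 * 100.0
    if np.any(dl < 0) or np.any(cl < 0):
        warnings.warn(
            "negative drip or cooking loss (weight gain between stages)",
            ImplausibleValueWarning,
            stacklevel=2,
        )
    if np.ndim(dl) == 0:
        return float(dl), float(cl)
    return dl, cl


def residual_age(slaughter_age, slaughter_bw):
    """Residuals of slaughter age regressed on slaughter weight (rAgeLW).

    Replaces slaughter age as a covariate to break its collinearity with
    slaughter weight.  Residuals sum to zero and are orthogonal to weight.
    """
    age = np.asarray(slaughter_age, dtype=float)
    bw = np.asarray(slaughter_bw, dtype=float)
    if age.size < 3:
        raise DomainError("need at least 3 records to residualise age on weight")
    if np.ptp(bw) == 0:
        raise DomainError("slaughter weight is constant; regression is degenerate")
    X = np.column_stack([np.ones_like(bw), bw])
    coef, *_ = np.linalg.lstsq(X, age, rcond=None)
    return age - X @ coef


# ---------------------------------------------------------------------------
# table-level derivation

#: required columns of the animal-record table
RECORD_COLUMNS = [
    "animal_id", "sex", "treatment", "litter_id", "series", "year_of_change",
    "temperature", "start_bw", "start_age", "slaughter_bw", "slaughter_age",
    "feed_intake_total", "cp_intake", "p_intake", "dxa_lean", "dxa_bmc",
    "left_half_weight", "total_carcass_weight",
]


def derive_phenotypes(
    records: pd.DataFrame,
    base: BaselineComposition | None = None,
    meat: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive all phenotypes for a cohort of animal records.

    Parameters
    ----------
    records : table with `RECORD_COLUMNS`.  A ``measured_cp`` /
        ``measured_ph`` column, when present and non-missing, bypasses the
        DXA prediction equations for that animal (wet-chemistry subset).
    base : baseline composition constants (defaults used if omitted).
    meat : optional meat-quality table keyed by ``animal_id`` with chop
        weights ``w1, w2, w3`` and any directly measured traits.

    Returns
    -------
    (derived, qc) : one row per animal with pe, phe, adg, adfi, fcr,
        rAgeLW (plus drip/cooking loss when ``meat`` given), and a QC table
        of flagged records.
    """
    base = base or BaselineComposition()
    missing_cols = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing_cols:
        raise KeyError(f"animal-record table is missing columns {missing_cols}")
    r = records.reset_index(drop=True)
    qc_rows: list[dict] = []

    half_prop = (r["left_half_weight"] / r["total_carcass_weight"]).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ImplausibleValueWarning)
        cp_sl = carcass_protein(r["dxa_lean"].to_numpy(), half_prop)
        ph_sl = carcass_phosphorus(
            r["dxa_bmc"].to_numpy(), r["dxa_lean"].to_numpy(), half_prop
        )
        if "measured_cp" in r.columns:
            use = r["measured_cp"].notna().to_numpy()
            cp_sl = np.where(use, r["measured_cp"].to_numpy(float), cp_sl)
        if "measured_ph" in r.columns:
            use = r["measured_ph"].notna().to_numpy()
            ph_sl = np.where(use, r["measured_ph"].to_numpy(float), ph_sl)
        cp_start, ph_start = baseline_content(
            r["sex"].to_numpy(), r["start_bw"].to_numpy(), base
        )
        pe = protein_efficiency(cp_sl, cp_start, r["cp_intake"].to_numpy())
        phe = phosphorus_efficiency(ph_sl, ph_start, r["p_intake"].to_numpy())
        adg, adfi, fcr = performance_traits(
            r["start_bw"].to_numpy(), r["slaughter_bw"].to_numpy(),
            r["start_age"].to_numpy(), r["slaughter_age"].to_numpy(),
            r["feed_intake_total"].to_numpy(),
        )
    ragelw = residual_age(r["slaughter_age"].to_numpy(), r["slaughter_bw"].to_numpy())

    out = pd.DataFrame(
        {
            "animal_id": r["animal_id"],
            "pe": pe, "phe": phe, "adg": adg, "adfi": adfi, "fcr": fcr,
            "rAgeLW": ragelw,
        }
    )
    for col in ("sex", "treatment", "litter_id", "series", "year_of_change",
                "temperature", "slaughter_bw"):
        out[col] = r[col]

    for i, aid in enumerate(r["animal_id"]):
        if cp_sl[i] <= 0:
            qc_rows.append({"animal_id": aid, "flag": "nonpositive_carcass_protein"})
        if ph_sl[i] <= 0:
            qc_rows.append({"animal_id": aid, "flag": "nonpositive_carcass_phosphorus"})
        if not 0 < pe[i] < 1:
            qc_rows.append({"animal_id": aid, "flag": "pe_outside_unit_interval"})
        if not 0 < phe[i] < 1:
            qc_rows.append({"animal_id": aid, "flag": "phe_outside_unit_interval"})

    if meat is not None:
        m = meat.set_index("animal_id")
        if {"w1", "w2", "w3"}.issubset(m.columns):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ImplausibleValueWarning)
                dl, cl = water_holding(
                    m["w1"].to_numpy(), m["w2"].to_numpy(), m["w3"].to_numpy()
                )
            wh = pd.DataFrame({"drip_loss": dl, "cooking_loss": cl}, index=m.index)
            out = out.merge(wh, left_on="animal_id", right_index=True, how="left")
            for aid, d, c in zip(m.index, np.atleast_1d(dl), np.atleast_1d(cl)):
                if d < 0 or c < 0:
                    qc_rows.append({"animal_id": aid, "flag": "negative_water_loss"})
        direct = [c for c in m.columns if c not in ("w1", "w2", "w3")]
        if direct:
            out = out.merge(m[direct], left_on="animal_id", right_index=True, how="left")

    qc = pd.DataFrame(qc_rows, columns=["animal_id", "flag"])
    return out, qc
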