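"""Synthetic pedigreed populations with known genetic architecture.

The generator emulates the design of a Swiss Large White resource
population: a three-generation pedigree built from 39 sires and 79 dams
whose litters (one to three per dam) are spread over 14 farrowing series,
with roughly 1071 phenotyped offspring.  Breeding values follow the
additive infinitesimal model and are generated by recursive Mendelian
sampling — founders are drawn from ``N(0, G_a)`` and each non-founder is
the parent average plus a deviation with covariance
``0.5 * (1 - (F_s + F_d)/2) * G_a`` — so inbreeding is handled exactly and
cost scales linearly in pedigree size.  Phenotypes add normal litter
effects shared within litter, fixed effects from configured covariate
generators and correlated residuals.

Observation-level records (weights, ages, intakes, DXA masses) are
*back-generated* by inverting the derivation formulas, so running the
phenotype-derivation stage on the records returns the simulated trait
values to machine precision.  The trait-level targets (means, SDs and
variance components) default to the published estimates for this
population; because protein retention, growth and intake are inverted
from the traits rather than forward-modelled from growth physiology, the
records are internally consistent but not biologically mechanistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from nutrieff.pedigree import Pedigree, PedigreeRecord, inbreeding
from nutrieff.phenotypes import (
    BaselineComposition,
    CP_INTERCEPT,
    CP_SLOPE,
    PH_INTERCEPT,
    PH_SLOPE_BMC,
    PH_SLOPE_LEAN,
)

CORE_TRAITS = ("pe", "phe", "adg", "fcr", "adfi")


class ConfigError(ValueError):
    """Invalid or infeasible simulation configuration."""


@dataclass(frozen=True)
class TraitSpec:
    """True architecture of one trait: mean, components and fixed-effect variance."""

    name: str
    mean: float
    v_a: float
    v_ce: float
    v_r: float
    v_fixed: float = 0.0  # variance contributed by fixed effects / covariates

    @property
    def v_p(self) -> float:
        return self.v_a + self.v_ce + self.v_r

    @property
    def sd_total(self) -> float:
        return float(np.sqrt(self.v_p + self.v_fixed))


@dataclass
class SensoryConfig:
    """Judge/session variance structure and group effects for panel scores."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HPE": 12, "MPE": 13, "LPE": 14}
    )
    n_judges: int = 8
    n_sessions: int = 6
    judge_var: float = 1.0
    session_var: float = 0.25
    residual_var: float = 1.0
    base_mean: float = 5.0
    # per-attribute PE-group offsets; default emulates lower juiciness in
    # the most protein-efficient group
    group_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "firmness": {},
            "tenderness": {},
            "juiciness": {"HPE": -1.5},
            "flavour": {},
        }
    )


@dataclass
class SimulationConfig:
    """Design and true parameters of a simulated population."""

    seed: int = 0
    n_sires: int = 39
    n_dams: int = 79
    n_series: int = 14
    # dams having exactly 1, 2 and 3 litters (must sum to n_dams)
    dams_per_litter_count: tuple[int, int, int] = (48, 23, 8)
    litter_size_mean: float = 9.08
    n_grandsires: int = 60
    n_granddams: int = 160
    traits: tuple[TraitSpec, ...] = ()
    genetic_corr: np.ndarray | None = None
    litter_corr: np.ndarray | None = None
    residual_corr: np.ndarray | None = None
    sex_levels: tuple[str, ...] = ("castrate", "female", "entire_male")
    sex_probs: tuple[float, ...] = (0.44, 0.46, 0.10)
    treatment_levels: tuple[str, ...] = (
        "Control A", "Control B", "Control C", "Treatment A", "Treatment B",
    )
    treatment_probs: tuple[float, ...] = (0.12, 0.06, 0.02, 0.72, 0.08)
    years: tuple[int, ...] = tuple(range(2013, 2022))
    slaughter_bw_mean: float = 106.0
    slaughter_bw_sd: float = 5.0
    temperature_mean: float = 21.0
    temperature_sd: float = 3.0
    start_bw_mean: float = 22.3
    start_bw_sd: float = 1.6
    start_age_mean: float = 70.0
    start_age_sd: float = 5.0
    feed_cp_g_per_kg: float = 130.0
    feed_p_g_per_kg: float = 5.0
    carcass_yield: float = 0.79
    half_prop_mean: float = 0.5
    half_prop_sd: float = 0.004
    baseline: BaselineComposition = field(default_factory=BaselineComposition)
    sensory: SensoryConfig = field(default_factory=SensoryConfig)

    def __post_init__(self) -> None:
        if sum(self.dams_per_litter_count) != self.n_dams:
            raise ConfigError(
                "dams_per_litter_count must sum to n_dams "
                f"({sum(self.dams_per_litter_count)} != {self.n_dams})"
            )
        if abs(sum(self.sex_probs) - 1) > 1e-9 or abs(sum(self.treatment_probs) - 1) > 1e-9:
            raise ConfigError("sex and treatment probabilities must sum to 1")
        n = len(self.traits)
        for label in ("genetic_corr", "litter_corr", "residual_corr"):
            M = getattr(self, label)
            if M is not None:
                M = np.asarray(M, float)
                if M.shape != (n, n) or not np.allclose(M, M.T):
                    raise ConfigError(f"{label} must be a symmetric {n}x{n} matrix")
                if np.linalg.eigvalsh(M).min() < -1e-8:
                    raise ConfigError(f"{label} is not positive semi-definite")
                setattr(self, label, M)

    @property
    def n_litters(self) -> int:
        c1, c2, c3 = self.dams_per_litter_count
        return c1 + 2 * c2 + 3 * c3

    def trait_index(self, name: str) -> int:
        for i, t in enumerate(self.traits):
            if t.name == name:
                return i
        raise ConfigError(f"trait {name!r} not configured")

    def covariance(self, which: str) -> np.ndarray:
        """Component covariance matrix across traits ('a', 'ce' or 'r')."""
        v = np.array([getattr(t, f"v_{which}") for t in self.traits])
        corr = {"a": self.genetic_corr, "ce": self.litter_corr,
                "r": self.residual_corr}[which]
        if corr is None:
            corr = np.eye(len(self.traits))
        return corr * np.sqrt(np.outer(v, v))


def restrict_config(cfg: SimulationConfig, traits: Sequence[str]) -> SimulationConfig:
    """Config restricted to a subset of traits (marginal correlations kept)."""
    idx = [cfg.trait_index(t) for t in traits]
    sub = lambda M: None if M is None else np.asarray(M)[np.ix_(idx, idx)]
    return replace(
        cfg,
        traits=tuple(cfg.traits[i] for i in idx),
        genetic_corr=sub(cfg.genetic_corr),
        litter_corr=sub(cfg.litter_corr),
        residual_corr=sub(cfg.residual_corr),
    )


def _nearest_psd_corr(C: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Clip negative eigenvalues and rescale to unit diagonal."""
    w, Q = np.linalg.eigh(C)
    if w.min() >= eps:
        return C
    M = (Q * np.maximum(w, eps)) @ Q.T
    d = np.sqrt(np.diag(M))
    return M / np.outer(d, d)


def default_config(seed: int = 0) -> SimulationConfig:
    """Study-shaped defaults: published trait targets and variance components.

    Total-SD targets per trait exceed the phenotypic variance of the animal
    model because fixed effects (sex, diet, year, slaughter weight,
    temperature) also contribute; ``v_fixed`` absorbs the difference.  The
    residual cross-trait correlation is derived from the target phenotypic
    correlations minus the genetic covariance and projected to the nearest
    positive semi-definite matrix (the FCR/ADG/ADFI triangle is not jointly
    attainable because FCR is structurally their ratio).
    """
    targets = {  # name: (mean, total SD, V_A, V_CE, V_P)
        "pe": (0.39, 0.04, 5.2e-4, 5.8e-6, 9.6e-4),
        "phe": (0.43, 0.05, 5.6e-4, 1.2e-4, 2.1e-3),
        "adg": (0.85, 0.11, 1.3e-3, 4.2e-4, 2.9e-3),
        "fcr": (2.67, 0.23, 8.1e-3, 2.2e-3, 2.1e-2),
        "adfi": (2.26, 0.31, 1.2e-2, 2.7e-3, 2.3e-2),
    }
    traits = []
    for name, (mean, sd, v_a, v_ce, v_p) in targets.items():
        traits.append(
            TraitSpec(name, mean, v_a, v_ce, v_p - v_a - v_ce,
                      v_fixed=max(sd ** 2 - v_p, 0.0))
        )
    rg = np.eye(5)
    rp = np.eye(5)
    g_pairs = {(0, 1): 0.61, (0, 2): -0.19, (0, 3): -0.55, (0, 4): -0.53,
               (1, 2): -0.21, (1, 3): -0.15, (1, 4): -0.25,
               (2, 3): -0.12, (2, 4): 0.74, (3, 4): 0.57}
    p_pairs = {(0, 1): 0.53, (0, 2): 0.05, (0, 3): -0.50, (0, 4): -0.36,
               (1, 2): -0.003, (1, 3): -0.31, (1, 4): -0.27,
               (2, 3): -0.38, (2, 4): 0.59, (3, 4): 0.50}
    for (i, j), v in g_pairs.items():
        rg[i, j] = rg[j, i] = v
    for (i, j), v in p_pairs.items():
        rp[i, j] = rp[j, i] = v
    v_a = np.array([t.v_a for t in traits])
    v_r = np.array([t.v_r for t in traits])
    v_p = np.array([t.v_p for t in traits])
    cov_r = rp * np.sqrt(np.outer(v_p, v_p)) - rg * np.sqrt(np.outer(v_a, v_a))
    rr = cov_r / np.sqrt(np.outer(v_r, v_r))
    np.fill_diagonal(rr, 1.0)
    rr = _nearest_psd_corr(rr)
    return SimulationConfig(
        seed=seed,
        traits=tuple(traits),
        genetic_corr=rg,
        litter_corr=np.eye(5),
        residual_corr=rr,
    )


@dataclass
class SimulatedDataset:
    """Pedigree, true effects and record tables produced by one simulation."""

    pedigree: Pedigree
    breeding_values: pd.DataFrame     # per animal x trait
    traits: pd.DataFrame              # phenotyped animals: trait values + covariates
    records: pd.DataFrame             # back-generated observation-level records
    sensory: pd.DataFrame
    config: SimulationConfig


# ---------------------------------------------------------------------------
# pedigree


def simulate_pedigree(cfg: SimulationConfig, rng: np.random.Generator | None = None
                      ) -> tuple[Pedigree, pd.DataFrame]:
    """Three-generation pedigree plus a litter map for the phenotyped offspring.

    Returns ``(pedigree, litters)`` where ``litters`` has one row per
    offspring with its litter id and farrowing series.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    if cfg.n_litters <= 0 or cfg.n_sires <= 0:
        raise ConfigError("design needs at least one sire and one litter")
    records = []
    grandsires = [f"GS{i+1}" for i in range(cfg.n_grandsires)]
    granddams = [f"GD{i+1}" for i in range(cfg.n_granddams)]
    for gid in grandsires + granddams:
        records.append(PedigreeRecord(gid))
    sires = [f"S{i+1}" for i in range(cfg.n_sires)]
    dams = [f"D{i+1}" for i in range(cfg.n_dams)]
    for pid in sires + dams:
        if grandsires and granddams:
            records.append(
                PedigreeRecord(pid,
                               str(rng.choice(grandsires)),
                               str(rng.choice(granddams)))
            )
        else:
            records.append(PedigreeRecord(pid))
    # assign each dam its litter count (shuffled), each litter a sire/series
    counts = np.concatenate([
        np.full(cfg.dams_per_litter_count[0], 1),
        np.full(cfg.dams_per_litter_count[1], 2),
        np.full(cfg.dams_per_litter_count[2], 3),
    ])
    rng.shuffle(counts)
    litter_rows = []
    litter_no = 0
    for dam, c in zip(dams, counts):
        series_for_dam = rng.choice(cfg.n_series, size=c, replace=False)
        for k in range(c):
            litter_no += 1
            sire = str(rng.choice(sires))
            series = f"FS{int(series_for_dam[k]) + 1}"
            size = max(1, int(rng.poisson(cfg.litter_size_mean)))
            for _ in range(size):
                aid = f"P{len(litter_rows)+1}"
                records.append(PedigreeRecord(aid, sire, dam, series))
                litter_rows.append(
                    {"animal_id": aid, "litter_id": f"L{litter_no}",
                     "series": series, "sire": sire, "dam": dam}
                )
    ped = Pedigree.from_records(records)
    return ped, pd.DataFrame(litter_rows)


# ---------------------------------------------------------------------------
# genetic effects and phenotypes


def simulate_breeding_values(
    ped: Pedigree, G_a: np.ndarray, rng: np.random.Generator,
    trait_names: list[str] | None = None,
    inbreeding_coeffs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Multi-trait breeding values by recursive Mendelian sampling.

    ``inbreeding_coeffs`` (aligned with the pedigree order) can be passed
    to avoid recomputing the relationship matrix when the caller already
    has it.
    """
    G_a = np.atleast_2d(np.asarray(G_a, float))
    w = np.linalg.eigvalsh(G_a)
    if w.min() < -1e-10 * max(w.max(), 1):
        raise ConfigError("G_a is not positive semi-definite")
    n_traits = G_a.shape[0]
    # PSD square root (handles singular G_a, e.g. duplicated traits)
    wc, Q = np.linalg.eigh(G_a)
    L = Q * np.sqrt(np.maximum(wc, 0.0))
    n = len(ped)
    sire, dam = ped.parent_indices()
    if inbreeding_coeffs is None:
        F, _ = inbreeding(ped)
        Fv = F.to_numpy()
    else:
        Fv = np.asarray(inbreeding_coeffs, float)
    z = rng.standard_normal((n, n_traits)) @ L.T
    bv = np.zeros((n, n_traits))
    for i in range(n):
        s, d = sire[i], dam[i]
        mean = np.zeros(n_traits)
        factor = 1.0
        if s >= 0:
            mean += 0.5 * bv[s]
            factor -= 0.25 * (1.0 + Fv[s])
        if d >= 0:
            mean += 0.5 * bv[d]
            factor -= 0.25 * (1.0 + Fv[d])
        bv[i] = mean + np.sqrt(factor) * z[i]
    cols = trait_names or [f"t{k+1}" for k in range(n_traits)]
    return pd.DataFrame(bv, index=ped.ids, columns=cols)


def _sex_offsets(levels, probs, var_target: float) -> np.ndarray:
    """Mean-zero categorical offsets with a given variance under ``probs``."""
    base = np.linspace(-1.0, 1.0, len(levels))
    p = np.asarray(probs, float)
    base = base - p @ base
    v = p @ base ** 2
    return base * np.sqrt(var_target / v) if v > 0 else base * 0.0


def simulate_phenotypes(
    ped: Pedigree,
    litters: pd.DataFrame,
    bv: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Phenotypes for the offspring generation: fixed + a + litter + residual.

    Fixed-effect variance ``v_fixed`` of each trait is split equally over
    three mean-zero sources: a sex effect, a slaughter-weight slope and a
    temperature slope.
    """
    if not cfg.traits:
        raise ConfigError("no traits configured")
    n = len(litters)
    n_traits = len(cfg.traits)
    names = [t.name for t in cfg.traits]
    G_ce = cfg.covariance("ce")
    R = cfg.covariance("r")
    litter_ids = litters["litter_id"].unique()
    ce = {lid: np.linalg.cholesky(G_ce + 1e-15 * np.eye(n_traits))
          @ rng.standard_normal(n_traits) for lid in litter_ids}
    resid = rng.multivariate_normal(np.zeros(n_traits), R, size=n,
                                    method="eigh")
    sex = rng.choice(cfg.sex_levels, size=n, p=cfg.sex_probs)
    treatment = rng.choice(cfg.treatment_levels, size=n, p=cfg.treatment_probs)
    year = rng.choice(cfg.years, size=n)
    slaughter_bw = rng.normal(cfg.slaughter_bw_mean, cfg.slaughter_bw_sd, n)
    temperature = rng.normal(cfg.temperature_mean, cfg.temperature_sd, n)
    z_bw = (slaughter_bw - cfg.slaughter_bw_mean) / cfg.slaughter_bw_sd
    z_temp = (temperature - cfg.temperature_mean) / cfg.temperature_sd
    out = litters[["animal_id", "litter_id", "series"]].copy()
    out["sex"] = sex
    out["treatment"] = treatment
    out["year_of_change"] = year
    out["slaughter_bw"] = slaughter_bw
    out["temperature"] = temperature
    bv_ph = bv.loc[out["animal_id"], names].to_numpy()
    ce_ph = np.array([ce[lid] for lid in out["litter_id"]])
    for k, spec in enumerate(cfg.traits):
        vf = spec.v_fixed / 3.0
        sex_eff = _sex_offsets(cfg.sex_levels, cfg.sex_probs, vf)
        sex_map = dict(zip(cfg.sex_levels, sex_eff))
        fixed = (np.array([sex_map[s] for s in sex])
                 + np.sqrt(vf) * z_bw + np.sqrt(vf) * z_temp)
        out[spec.name] = spec.mean + fixed + bv_ph[:, k] + ce_ph[:, k] + resid[:, k]
    return out


# ---------------------------------------------------------------------------
# back-generation of observation-level records


def back_generate_observables(
    traits: pd.DataFrame, cfg: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Invert the derivation formulas to produce raw records.

    Weights, ages, intakes and DXA masses are chosen so the derivation
    stage reproduces the simulated pe, phe, adg and adfi exactly.  FCR is
    the identity ``adfi / adg`` at the record level, so the trait table's
    ``fcr`` column is superseded by that ratio in derived output.
    """
    for t in ("pe", "phe", "adg", "adfi"):
        if t not in traits.columns:
            raise ConfigError(f"trait table lacks required column {t!r}")
    n = len(traits)
    base = cfg.baseline
    start_bw = np.clip(rng.normal(cfg.start_bw_mean, cfg.start_bw_sd, n), 18, 28)
    start_age = np.clip(rng.normal(cfg.start_age_mean, cfg.start_age_sd, n), 55, 90)
    half_prop = np.clip(rng.normal(cfg.half_prop_mean, cfg.half_prop_sd, n),
                        0.47, 0.53)
    slaughter_bw = traits["slaughter_bw"].to_numpy()
    adg = traits["adg"].to_numpy()
    adfi = traits["adfi"].to_numpy()
    pe = traits["pe"].to_numpy()
    phe = traits["phe"].to_numpy()
    duration = (slaughter_bw - start_bw) / adg
    bad = duration <= 0
    if np.any(bad):  # implausible simulated growth; rare at default settings
        duration[bad] = np.abs(duration[bad]) + 1.0
        start_bw[bad] = slaughter_bw[bad] - adg[bad] * duration[bad]
    slaughter_age = start_age + duration
    feed = adfi * duration
    cp_intake = feed * cfg.feed_cp_g_per_kg
    p_intake = feed * cfg.feed_p_g_per_kg
    sexes = traits["sex"].to_numpy()
    cp_start = np.array([base.protein_per_kg[s] for s in sexes]) * start_bw
    ph_start = np.array([base.phosphorus_per_kg[s] for s in sexes]) * start_bw
    cp_slaughter = cp_start + pe * cp_intake
    ph_slaughter = ph_start + phe * p_intake
    lean = (cp_slaughter - CP_INTERCEPT) / (CP_SLOPE * half_prop)
    bmc = (ph_slaughter - PH_INTERCEPT - PH_SLOPE_LEAN * lean * half_prop) / (
        PH_SLOPE_BMC * half_prop
    )
    flagged = (lean <= 0) | (bmc <= 0)
    total_carcass = cfg.carcass_yield * slaughter_bw
    rec = pd.DataFrame(
        {
            "animal_id": traits["animal_id"],
            "sex": sexes,
            "treatment": traits["treatment"],
            "litter_id": traits["litter_id"],
            "series": traits["series"],
            "year_of_change": traits["year_of_change"],
            "temperature": traits["temperature"],
            "start_bw": start_bw,
            "start_age": start_age,
            "slaughter_bw": slaughter_bw,
            "slaughter_age": slaughter_age,
            "feed_intake_total": feed,
            "cp_intake": cp_intake,
            "p_intake": p_intake,
            "dxa_lean": lean,
            "dxa_bmc": bmc,
            "left_half_weight": half_prop * total_carcass,
            "total_carcass_weight": total_carcass,
            "flagged": flagged,
        }
    )
    return rec


# ---------------------------------------------------------------------------
# sensory scores


def simulate_sensory(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Long-format panel scores: every judge scores every sample once per attribute."""
    sc = cfg.sensory
    samples = []
    sid = 0
    for grp, n in sc.group_sizes.items():
        for _ in range(n):
            sid += 1
            samples.append(
                {"sample": f"M{sid}", "pe_group": grp,
                 "sex": str(rng.choice(["castrate", "female"])),
                 "fat_thickness": str(rng.choice(["<1.5cm", "1.5cm", "3cm"]))}
            )
    for i, s in enumerate(samples):
        s["session"] = f"ses{i % sc.n_sessions + 1}"
    judges = [f"J{j+1}" for j in range(sc.n_judges)]
    judge_eff = {j: rng.normal(0, np.sqrt(sc.judge_var)) for j in judges}
    sess_eff = {f"ses{k+1}": rng.normal(0, np.sqrt(sc.session_var))
                for k in range(sc.n_sessions)}
    sex_eff = {"castrate": 0.0, "female": 0.15}
    ft_eff = {"<1.5cm": 0.0, "1.5cm": -0.1, "3cm": -0.3}
    rows = []
    from nutrieff.sensory import ATTRIBUTES

    for attr in ATTRIBUTES:
        g_eff = sc.group_effects.get(attr, {})
        for s in samples:
            for j in judges:
                score = (sc.base_mean + judge_eff[j] + sess_eff[s["session"]]
                         + sex_eff[s["sex"]] + ft_eff[s["fat_thickness"]]
                         + g_eff.get(s["pe_group"], 0.0)
                         + rng.normal(0, np.sqrt(sc.residual_var)))
                rows.append({**s, "judge": j, "attribute": attr,
                             "score": float(np.clip(score, 0, 10))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-call dataset


def simulate_dataset(cfg: SimulationConfig | None = None, seed: int | None = None
                     ) -> SimulatedDataset:
    """Generate a full dataset (pedigree, traits, records, sensory scores)."""
    cfg = cfg or default_config(seed if seed is not None else 0)
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    ped, litters = simulate_pedigree(cfg, rng)
    names = [t.name for t in cfg.traits]
    bv = simulate_breeding_values(ped, cfg.covariance("a"), rng, names)
    traits = simulate_phenotypes(ped, litters, bv, cfg, rng)
    records = back_generate_observables(traits, cfg, rng)
    sens = simulate_sensory(cfg, rng)
    return SimulatedDataset(ped, bv, traits, records, sens, cfg)
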