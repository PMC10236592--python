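# nutrieff

Pedigree-based genetic analysis of nutrient efficiency in
growing-finishing pigs.

Breeding pigs that retain more of the protein they eat would cut both
feed cost and nitrogen pollution.  **Protein efficiency** (PE) — the
proportion of dietary crude-protein intake retained in the carcass
between ~20 kg and slaughter — can be phenotyped at scale by predicting
carcass protein from a DXA scan of the left carcass half.  This package
implements, for quantitative geneticists and breeding-programme analysts,
the full analysis pipeline around that phenotype:

* **`pedigree`** — pedigree parsing/validation, numerator relationship
  matrix **A** (tabular method) and inbreeding coefficients `F = a_ii − 1`;
* **`phenotypes`** — PE, phosphorus efficiency, ADG/ADFI/FCR, drip and
  cooking loss, and age-on-weight residualisation, from raw records;
* **`animal_model`** — from-scratch AI-REML for the animal model
  `y = Xb + Z_a a + Z_c c + e` with `a ~ N(0, A σ²_A)`, univariate and
  bivariate (unstructured 2×2 components, missing traits retained), with
  `h² = σ²_A/σ²_P`, litter ratio `CE² = σ²_CE/σ²_P`, genetic and
  phenotypic correlations, and delta-method standard errors;
* **`model_selection`** — all-subsets AIC screening of fixed effects
  respecting marginality (ΔAIC < 2 top set);
* **`sensory`** — mixed model for panel scores with random judge and
  session effects and Fisher's LSD mean separation;
* **`simulate`** — a synthetic-data generator that emulates the source
  population (39 sires, 79 dams, 14 farrowing series, ~1071 phenotyped
  pigs) with known genetic architecture, so every stage is testable
  without the embargoed raw data;
* **`cli`** — a `nutrieff` command with `simulate`, `derive`, `select`,
  `genetics`, `sensory` and `report` subcommands.

See `docs/methods.md` for the model details and numerical choices.

## Worked example

```python
import numpy as np, pandas as pd
from nutrieff.simulate import simulate_dataset
from nutrieff.phenotypes import derive_phenotypes
from nutrieff.pedigree import additive_relationship
from nutrieff.animal_model import RandomTerm, fit_mixed_model, genetic_parameters
from nutrieff.validation import fit_pair

ds = simulate_dataset(seed=3)                      # study-shaped population
derived, qc = derive_phenotypes(ds.records.drop(columns=["flagged"]),
                                ds.config.baseline)
print(len(derived), derived.pe.mean().round(3), derived.pe.std().round(3))
# 1067 0.385 0.041        <- ~1071 pigs, PE mean ~0.39, SD ~0.04

A = additive_relationship(ds.pedigree).submatrix(list(derived.animal_id)).values
lit = pd.Categorical(derived.litter_id).codes
fit = fit_mixed_model(
    derived.pe.to_numpy(), np.ones((len(derived), 1)),
    [RandomTerm("animal", np.arange(len(derived)), A), RandomTerm("litter", lit)],
)
gp = genetic_parameters(fit)
print(round(gp.h2["trait1"], 2), "+-", round(gp.h2_se["trait1"], 2))
# 0.42 +- 0.1             <- h2 of PE (intercept-only model; the generator's
#                            unmodelled fixed effects inflate V_P, so add
#                            sex/weight/temperature to X for the 0.54-scale truth)

biv = fit_pair(ds.traits, A, ("pe", "phe"))        # bivariate, full fixed effects
print(round(genetic_parameters(biv).rg, 2))
# 0.69                    <- genetic correlation PE-PhE for this one replicate
#                            (simulated truth 0.61; single-fit SE ~0.16)
```

Or from the shell:

```sh
nutrieff simulate --seed 3 --out run/
nutrieff derive --records run/records.csv --out run/
nutrieff genetics --data run/derived.csv --pedigree run/pedigree.csv \
    --traits pe,phe --pairs pe,phe --out run/
nutrieff report --run-dir run/
```

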