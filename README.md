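# amykit

Kinetic analysis and mechanistic classification of small-molecule inhibitors
of amyloid self-assembly.

Amyloid formation by peptides such as IAPP (amylin) proceeds by nucleated
polymerization: new fibrils arise by primary nucleation from free monomer
(rate νₙ, order n_c), grow by elongation at both ends (ν₊), and multiply
through secondary processes — fragmentation or fibril-surface secondary
nucleation (ν₂, order n₂, optionally saturating with Michaelis constant
K₂).  Two macroscopic rates summarize a mechanism at monomer concentration
m₀:

    λ = √(2·ν₊·νₙ/m₀)        (primary pathway, h⁻¹)
    κ = √(2·ν₊·ν₂)           (secondary pathway, h⁻¹)

and the normalized fibril mass follows closed forms built from them — the
exact Oosawa solution when κ = 0, and for κ > 0 the generalized-logistic
solution

    M(t)/m₀ = 1 − [1 + (λ²/(θκ²))·(cosh κt − 1)]^(−θ),

where θ sets the sensitivity of the secondary pathway to monomer depletion.
Both forms are validated in the test suite against brute-force integration
of the moment ODEs.

On top of the kinetics, `amykit` implements the full inhibitor-discovery
analysis chain for plate-based ThT screens and the orthogonal biophysics:

- **tht_screening** — blank subtraction, per-condition normalization,
  half-time extraction, and activity calls from half-time fold-change
  (0.8×/1.25× thresholds) plus a Mann–Whitney U test (p < 1e-4).
- **global_fitting** — global dose-series fits in which exactly one process
  (primary, secondary, elongation) varies with inhibitor concentration while
  the rest are shared; scenarios ranked by AICc; direct per-condition λ/κ
  extraction with fitting errors; monomer-series mechanism comparison.
- **biophysics** — Taylor dispersion fits and Stokes–Einstein radii, SPR
  biexponential and global 1:1 Langmuir kinetics (with unidentifiable-K_D
  detection), NMR chemical shift perturbations and intensity ratios,
  copelleting fractions from UV spectra, extinction coefficients, and Van
  Slyke buffer capacity.
- **capflex** — microfluidic elugram normalization, plateau quantification,
  and running-median spike detection (threshold 0.01 normalized units,
  window 15 samples).
- **synthetic_data** — seeded generators for every input modality with
  recorded ground truth, so the entire pipeline is testable offline.
- **io / cli** — delimited-text readers/writers, YAML manifests, and an
  `amykit` command with subcommands `simulate`, `screen`, `fit`, `extract`,
  `tda`, `spr`, `csp`, `capflex`, `copellet`.

See `docs/methods.md` for the model details, parameterizations, numerical
choices and limitations.

## Worked example

Classify the mechanism of a synthetic inhibitor that suppresses primary
nucleation (five concentrations, factors 1→0.1 on νₙ, three replicate
wells, noise σ = 0.01):

```python
import numpy as np
from amykit.synthetic_data import gen_dose_series
from amykit.global_fitting import compare_scenarios, extract_macroscopic

series, truth = gen_dose_series(seed=1, process="nu_n")
fits = compare_scenarios(series, seed=1)
for f in fits:
    print(f"{f.scenario:16s} {f.delta_aicc:10.1f}  {f.r2:.5f}")

best = fits[0]
lam = np.array([best.lam[c.label] for c in series.conditions])
print("recovered nu_n scaling:", np.round((lam / lam[0]) ** 2, 3))
```

prints

```
primary_only            0.0  0.99930
elongation_only      1865.0  0.99894
secondary_only       2583.5  0.99876
recovered nu_n scaling: [1.    0.699 0.401 0.201 0.1  ]
```

The primary-nucleation scenario wins by ~1900 AICc units, and the
recovered per-condition νₙ scaling factors (λ_c²/λ₀², since λ² ∝ νₙ)
reproduce the generating 1/0.7/0.4/0.2/0.1 dose response within 1%.
Extracting the macroscopic rates condition by condition,

```python
macro = extract_macroscopic(series, seed=1)
print(macro.lam)    # [0.0203 0.0163 0.0124 0.0089 0.0063]  (truth: 0.02·√f)
print(macro.kappa)  # [0.995 1.006 1.004 1.001 1.001]       (truth: 1.0)
```

shows λ falling as the square root of the inhibition factor while κ stays
at its uninhibited value — the λ/κ fingerprint of a primary-nucleation
inhibitor.

The same analysis runs from the shell:

```bash
amykit simulate --kind dose-series --seed 1 --out sim/
amykit fit --manifest sim/manifest.yaml --out results/ --seed 1
```

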