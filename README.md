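# iondetail

Nanodosimetric cluster statistics linked to cell-survival radiobiology.

When a charged particle crosses a DNA-sized volume (a cylinder of a few
nanometers), the number of ionizations it produces — the *ionization
cluster size* ν — is a random variable whose distribution P_ν (the ICSD)
characterizes the radiation far more sharply than the average linear
energy transfer (LET). `iondetail` is for physicists and radiobiologists
who want to compute the standard descriptors of such distributions, relate
them to measured cell survival, and test a graded damage model against the
classical step-weighted one:

* **M1** = Σ ν P_ν — mean cluster size;
* **Fk** = Σ_{ν≥k} P_ν — probability of a cluster of size ≥ k, the
  classical all-or-nothing radiation-quality parameter;
* **R2(p)** = Σ_ν P_ν [1 − (1−p)^ν − νp(1−p)^(ν−1)] — the probability
  that at least two *sub-lethal lesions* arise when each ionization
  independently becomes a lesion with probability p. Two such lesions in
  close range constitute severe, DSB-like damage. R2(1) = F2 exactly, and
  binomially thinning a spectrum at detector efficiency η = p turns
  measured F2 into R2(p), so R2 is directly measurable with a
  nanodosimeter.

On the biology side, from linear-quadratic survival parameters (α, β) the
package computes iso-survival doses (solving αD + βD² = −ln S), the RBE at
5% survival, and the inactivation cross section

σ_S = (k/ρ) · LET · √(α² − 4β ln S)   [µm², k = 0.1602, LET in keV/µm]

and then fits the proportional link **σ₅% ≈ K · R2(p; d)** over a grid of
lesion probabilities p and target sizes d, with the scale K (µm²)
optimized per grid point by least squares on the unweighted sum of squared
differences (χ²). Records fitted with a negative β are repaired to the
best purely linear curve preserving the 5%-survival dose.

Because curated survival databases and Geant4-class track-structure codes
are external resources, the package includes a synthetic stand-in for
both: a toy compound-Poisson track model (Monte Carlo and exact analytic
form) that generates realistic overdispersed ICSDs, and a survival-record
generator with known ground truth (σ = K·R2(p) plus optional lognormal
noise) for closed-loop parameter-recovery studies.

## Worked example

```python
import numpy as np
from iondetail import R2CrossSectionModel
from iondetail.synth import (
    SyntheticStudySpec, default_grid_set, generate_survival_dataset,
)

grids = default_grid_set()                      # 3 target sizes x 4 ions
records = generate_survival_dataset(SyntheticStudySpec(seed=1))
result = R2CrossSectionModel(records, grids).fit()
print(result.summary())
```

prints

```
Proportional cross-section model  sigma_S = K * R2(p; d)
==========================================================
records used                150
survival level              0.05
best lesion probability p   0.35
best target geometry        2.3 x 3.4 nm^2 (diameter x height)
best K                      57 um^2
min chi2 (raw)              0.00281986 um^4
coefficient of determination 1.0000
chi2-surface ties           1
```

The study was generated with ground truth p = 0.35, K = 57 µm² and a
2.3 × 3.4 nm target; the fit recovers all three from the survival records
alone. `result.chi2_surface` holds the (p, d) surface normalized to its
maximum, `result.compare_fk_models()` scores the rival σ ≈ K·Fk models —
on the example above the graded R2 model attains the highest coefficient
of determination (1.000), followed by F5 (0.994) and F2 (0.874), showing
why a single step weight cannot match a graded one.

## Command line

```sh
iondetail simulate --ions 1H,4He --diameters 2.3 --out icsd.csv
iondetail stats --icsd icsd.csv --out derived.csv
iondetail rbe --survival survival.csv --out rbe.csv
iondetail fit --icsd icsd.csv --survival survival.csv --out fitdir/
iondetail synth-study --out study/ --sigma-log 0.2 --seed 7
```

All commands are deterministic given their seed and write a JSON manifest
next to their primary output.

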