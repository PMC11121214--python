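# Methods

## The quantities

An ionization cluster size distribution (ICSD) is the discrete law P_ν of
the number ν of ionizations a single primary particle produces inside a
nanometric cylindrical target (diameter d, height h). ν = 0 events —
traversals that ionize nothing — are part of the sample space, and the
mean cluster size M1 = Σ_{ν≥0} ν P_ν averages over them. Distributions
are stored dense from ν = 0 to an explicit ν_max with zero tail beyond
it; no operation extrapolates the tail. On construction the probabilities
must close to 1 within 1e−9; sums off by at most 1e−6 (counts-to-
probability rounding) are renormalized, anything worse is rejected as a
data error.

The cumulative probability Fk = Σ_{ν≥k} P_ν weights every cluster of size
≥ k equally and ignores everything smaller. The graded alternative R2(p)
assumes each ionization independently converts into a sub-lethal lesion
with probability p, and that at least two such lesions constitute severe
(double-strand-break-like) damage:

    R2(p) = Σ_ν P_ν w(ν, p),   w(ν, p) = 1 − (1−p)^ν − ν p (1−p)^(ν−1).

w is the binomial survival function P(Bin(ν, p) ≥ 2) in closed form. It
is evaluated through log1p/expm1 so that neither the small-p regime
(w ≈ C(ν,2)p², obtained as a difference of two near-unit terms) nor
p → 1 loses precision; p = 1 is special-cased (w = 1 for ν ≥ 2), where
R2 reduces exactly to F2. p is validated to [0, 1] everywhere; the
narrower 0.2–1.0 scan range is a fit configuration, not a core
constraint.

Binomial thinning Q_m = Σ_ν P_ν C(ν,m) η^m (1−η)^{ν−m} models a detector
that registers each ionization with efficiency η. Two identities anchor
it: M1(thinned) = η·M1, and F2(thinned at η=p) = R2(p) — the reason a
nanodosimeter with tunable counting efficiency can measure R2 directly.
Both are asserted to 1e−10 in the tests.

## Linear-quadratic survival math

Survival is S(D) = exp(−αD − βD²). The iso-survival dose is the positive
root of αD + βD² = −ln S (closed form at β = 0), RBE is D_ref/D_ion at
the working level (default S = 0.05), and the inactivation cross section
is

    σ_S = (k/ρ) · LET · sqrt(α² − 4β ln S),

with k = 0.1602 (LET in keV/µm, α in Gy⁻¹, β in Gy⁻², ρ in g/cm³,
default 1). The printed grouping of this formula is ambiguous in some
sources; the square-root reading implemented here is the unique one that
(a) carries the stated units, (b) reduces to (k/ρ)·LET·α at β = 0, and
(c) equals (k/ρ)·LET·(α + 2βD_S), the local slope of −ln S at the
iso-survival dose — an identity the test suite verifies by brute-force
differentiation.

Records fitted with β < 0 (a statistical artifact of survival-curve
digitization) are repaired to the best purely linear curve by
α′ = α + β·D_S, β′ = 0, which preserves the dose at the working survival
level exactly and always lowers α. This endpoint-preserving rule is one
of several defensible conventions; it is exact at the only survival level
the downstream analysis uses, and corrected records carry a flag so
alternative rules can be compared. The survival level itself is a
parameter (5% by default, the level at which σ(LET) fits are reported to
become particle-independent for V79 cells).

## Interpolation

Quantities are tabulated on ~40 log-spaced energies (0.2–1000 MeV/u) per
ion and geometry. Queries use a local three-point Lagrange quadratic in
log10(E) through the nearest bracketing triple: grid nodes are reproduced
exactly and a global polynomial over nearly four decades (which would
oscillate) is avoided. Extrapolation outside the grid span is refused.
Species without direct grids are filled by a least-squares quadratic in
atomic number Z across ≥ 3 donor ions at fixed energy per nucleon,
validated by leave-one-out prediction on smooth synthetic Z-dependences.

## The proportional fit

The link model is σ₅% = K·R2(p; d). For each candidate (p, d) the scale
K is optimized against the records' cross sections by minimizing the
unweighted sum of squares Σ(σᵢ − K·rᵢ)² — unweighted because the survival
compilations being emulated do not publish uncertainties. K has the
closed-form minimizer Σσr/Σr²; an explicit K-grid scan (default 1–200
µm², step 1) is available and agrees within one step. The χ² surface is
reported normalized to its maximum (so the minimum is a fraction of the
worst fit); ties within a 1e−12 relative band are broken toward larger d
then smaller p and counted, because a shallow valley running from
(small p, large d) to (large p, small d) is an intrinsic degeneracy of
this model family: increasing the target size and decreasing the lesion
probability trade off almost exactly. Consequently p is only sharply
identified at a fixed geometry; recovery studies under noise therefore
fix d at its true value, while noise-free recovery is required to select
the true geometry from the full scan. Target size enters only through
which pre-computed grid is used; no geometric interpolation between
target sizes is attempted.

Model comparison uses the coefficient of determination 1 − SS_res/SS_tot
about the observed mean, computed identically for the R2-based model and
each σ = K·Fk rival (k = 2..7), making the graded and step weightings
directly comparable.

## The synthetic generator

The toy track model replaces full track-structure transport. One history
is one traversal along the cylinder axis: primary interaction sites form
a 1-D Poisson process of rate λ over the height h; each site spawns
1 + Geometric ionizations (mean multiplicity m, giving the overdispersion
real ICSDs show); each ionization is displaced laterally by an isotropic
2-D Gaussian (σ_r) and counted only if it lands inside the cylinder, an
escape process that thins each cluster binomially with
q = 1 − exp(−R²/2σ_r²). The per-traversal count is therefore compound
Poisson, and the exact distribution is computed by the Panjer recursion —
grids are built from this analytic form (deterministic, fast), while the
Monte-Carlo sampler is kept for calibration tests (mean within binomial
standard errors at 10⁵ histories, the default; variance/mean matching the
analytic Fano factor).

Defaults, chosen once as field-plausible conventions: mean energy per
ionization W = 30 eV (so λ·(1+m) = LET/W, using 1 keV/µm = 1 eV/nm);
cluster multiplicity m = 1.5; lateral σ_r = 1 nm; schematic LET(E) =
26·Z²·E^−0.78 keV/µm anchored to proton stopping in water at 1, 10 and
100 MeV with Z² velocity scaling. None of these claims fidelity to
liquid-water cross sections; they produce ICSDs with the right gross
features (ν = 0 mass, overdispersion, LET-driven mean) for exercising the
statistics.

The survival-study generator draws an ion (¹H, ⁴He, ¹²C, ²⁰Ne) and a
log-uniform energy in 0.25–800 MeV/u, rejecting draws with LET above
528 keV/µm (the LET coverage of the emulated compilations), computes the
true R2(p*=0.35) from the analytic track model at that exact energy, sets
σ = K*·R2 with K* = 57 µm² times lognormal noise (σ_log, default 0; 0.2
in the noisy studies), and inverts σ through the cross-section formula
into (α, β) at a fixed α/β = 5 Gy (V79-typical); the positive root always
exists, so the inversion is exact, and the round trip σ → (α, β) → σ is
verified to 1e−9. The photon reference is α = 0.18 Gy⁻¹, β = 0.036 Gy⁻²
(the same α/β ratio). Defaults n = 150 records, one integer seed drives
all randomness.

What the generator does *not* emulate: cell-cycle-phase heterogeneity and
lab-to-lab scatter beyond a single lognormal factor, correlated errors
between α and β, energy/LET inconsistencies between stated beam energy
and measured LET, and any real track-structure physics. Passing recovery
tests therefore show that the estimation machinery is correct and
well-conditioned under the stated noise model — not that the proportional
law or the parameter values are features of real data.

## Numerical choices and problem sizes

Grids use 40 log-spaced energies and the p-grid 0.2–1.0 step 0.01 (both
configurable); recovery and model-comparison studies use 150 records and
20 replicates; Monte-Carlo checks use 10⁵–10⁶ samples. The Panjer
recursion's ν_max is set data-driven at mean + 12 sd + 20 and the
truncated tail must be below 1e−9. With σ_log = 0.2 and n = 150 the
p-estimator at fixed geometry is unbiased with a replicate-to-replicate
spread of about 0.03 (standard deviation), so individual noisy replicates
occasionally miss the truth by more than 0.05; K is recovered within a
few percent. The χ² surface of any single noisy replicate still shows
the valley geometry described above.

## Known limitations

The fit treats the grid's p and d as exhaustive candidates (no continuous
optimization); σ uncertainties, had they existed, could not currently be
used as weights; the negative-β repair is a convention, not the original
database's (undocumented) formalism; and the toy LET model should never
be used where a real stopping-power table is available — LET is an input
column everywhere outside the synthetic module.
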