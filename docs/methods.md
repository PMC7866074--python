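# Methods

## Scope and data model

The package estimates binary (tracer) diffusion coefficients at infinite
dilution, D12, of a solute (subscript 2) in a solvent (subscript 1). A
*record* is one measurement (T, ρ₁, μ₁, D12) for a (solvent, solute)
*system*; records carry a polar/nonpolar label determined by the solvent.
Compound-level properties (M, Tc, Tb, Pc, Vc, ω, σ_LJ, ε_LJ/k_B) are joined
from a packaged table of 111 compounds transcribed from the literature,
with one provenance code per estimated value. Units are frozen across the
API — T in K, μ₁ in cP, ρ₁ in g cm⁻³, Pc in bar, Vc in cm³ mol⁻¹, σ in Å,
ε/k_B in K, D12 in cm² s⁻¹ — and every unit conversion happens inside an
operation, never at a call site.

## Classic models

**Wilke-Chang** (hydrodynamic, predictive):
D12 = 7.4×10⁻⁸ (φM₁)^0.5 T / (μ₁ V_bp,2^0.6), with the association factor
φ = 1.9 for methanol, 1.5 for ethanol, 1.0 otherwise, resolved from the
solvent identity and overridable per call. V_bp comes from the critical
volume via the Tyn-Calus power law V_bp = 0.285 Vc^1.048.

**Tyn-Calus** (hydrodynamic, predictive):
D12 = 8.93×10⁻⁸ (V_bp,1^0.267 / V_bp,2^0.433) T/μ₁. The exponent placement
(solvent volume in the numerator) follows the standard published form of
the equation.

**Per-system correlation** (Magalhães et al.): D12 = a·T/μ₁ + b, ordinary
least squares on the single regressor x = T/μ₁. A fit needs at least three
points with distinct x (two parameters plus one residual degree of
freedom); fewer points, or zero variance in x, is a fit error — mirroring
the practice of skipping under-sampled systems. Predictions may go negative
under extreme extrapolation; the value is returned as-is with a
RuntimeWarning rather than clipped, so the caller sees the correlation's
actual behavior.

**Hybrid Lennard-Jones model** (Zhu et al., nonpolar solvents):
D12 = D_kin · F1 · F2 · F3 with the dilute-gas (Chapman-Enskog-like)
prefactor D_kin = (3/8)·√(k_B T/(π m₁)) / (ρ_n,1 σ₁₂²) evaluated in CGS
internally, a free-volume factor F1 = 1 − ρ*^1.029079/T*^0.165377, a dense-
fluid correction F2 = 1 + ρ*^0.126978·[0.596103(ρ*−1)/(0.539292(ρ*−1) +
T*^(0.400152−0.41054ρ*)) + 0.68856], and an energy factor
F3 = exp(−ρ*²/(2T*)). Binary parameters come from combining rules with a
size-asymmetry correction k₁₂ᵈ = 0.7926(σ₂−σ₁)/(σ₂+σ₁):
σ₁₂ = (1−k₁₂ᵈ)(σ₁+σ₂)/2 and ε₁₂ = √(ε₁ε₂). The pure-component LJ
parameters are the model's own corresponding-states estimates — solute:
ε₂/k_B = Tc,2/1.313, σ₂ = (0.13 k_B Tc,2/1.313 / Pc,2)^{1/3}; solvent: the
same leading factors times polynomial corrections in the reduced density
ρ_r,1 = ρ₁/(M₁/Vc,1) and temperature T_r,1 = T/Tc,1 — not the tabulated LJ
values, which serve the data pipeline instead.

Typesetting of the source equations loses fraction bars and fractional
exponents; the groupings above were fixed by two requirements: every factor
must be dimensionless (which restores the cube roots in the σ estimators —
verified by the benzene check, σ₂ ≈ 5.40 Å from Tc = 562.2 K, Pc =
48.9 bar), and the ρ*→0 limit must equal the dilute-gas coefficient. The
constants sit in one table (`ZHU_EQ5_CONSTANTS`) so a correction against
the original source touches a single definition. One remaining ambiguity —
whether the solvent-ε bracket multiplies or divides, and whether F2's T*
term is a power — is resolved as multiply/power and pinned by frozen
regression values from an independent script evaluation. The reduced
density feeding the solvent estimator is a density ratio (ρ₁/ρc,1), not a
pressure ratio; the alternative reading is dimensionally unusable there.
F1 ≤ 0 (dense, cold states) is outside the model's validity; the value is
still returned, with a warning.

**Property estimators.** Klincewicz Tc = 50.2 − 0.16·M + 1.41·T_b is
implemented in its two-input molar-mass/boiling-point form only; it
reproduces the packaged organometallic critical temperatures to ±0.01 K
(the ferrocene Tc row is the known exception in the source table and is
packaged as printed). The Lee-Kesler acentric factor uses θ = T_b/Tc and
takes Pc in bar, converting to atmospheres internally — the convention that
reproduces the tabulated values to ±10⁻⁴. Group-contribution critical-
property methods and viscosity/density correlations are out of scope; the
table ships those values as data.

## Dataset handling

Data files are comma-delimited with a schema-version comment line; units
are frozen in the column names (`T_K`, `rho1_g_cm3`, `mu1_cP`,
`D12_cm2_s`). Floats are written with `%.17g` and parsed with round-trip
precision so write→read is bit-exact. Validation errors cite row and
column. The train/test split is record-level (a system may contribute to
both sides — required for per-system correlation fitting on training data
and scoring on test data), unstratified, seeded, with a floor(n·fraction)
train share: 1431 records at 70% give 1001 train / 430 test. The seed is a
required, logged input.

## Learning pipeline

Variable selection works on the absolute Pearson correlation matrix: while
any pair of kept variables exceeds the 0.50 collinearity threshold, the
worst-offending pair is processed and its member with the lower
|correlation with D12| is dropped; exact ties fall back on a caller-supplied
preference order (encoding ease of obtaining a variable). Processing pairs
in descending |r| makes the result deterministic. The procedure guarantees
post hoc that all kept pairwise |r| ≤ 0.50.

Inputs are normalized to [0,1] with bounds fitted on training rows only;
test rows may map outside [0,1] and are deliberately not clipped, so the
fitted models can extrapolate. Scaling a constant column is an error.

The five algorithms (multilinear regression, k-nearest neighbors, decision
tree, random forest, gradient boosting) are scikit-learn estimators behind
one train/predict contract. Hyper-parameters are tuned by exhaustive grid
search with 4-fold cross-validation — folds are contiguous blocks after one
seeded shuffle — scored by the validation coefficient of determination,
with ties resolved to the first candidate in grid order, and the winner
refit on the full training set. The grids are data, not code
(`data/grids.json`): mlr none; knn k ∈ {1,2,3,5,7,10,15}; tree depth
{2,3,4,6,8,∞} × min-leaf {1,3,5}; forest {100,300} trees × depth {4,8,∞} ×
feature subset {all, √p}; boosting {100,300,500} stages ×
learning rate {0.05,0.1,0.2} × depth {2,3,4}. These are declared defaults,
not a reconstruction of any published appendix, and any call may pass a
different grid. With the seed fixed, the whole train→predict path is
reproducible bit for bit. Models serialize to a JSON sidecar (algorithm,
grid point, selected variables, scaler bounds, seed) plus a joblib blob.

y-randomization reruns the identical grid-search build on shuffled training
targets and scores Q² on the untouched test set; a model capturing real
structure should beat every scrambled rebuild.

## Metrics

AARD(%) = 100/N·Σ|calc−exp|/exp; RMSE = √(mean squared deviation); R²/Q²
are 1 − SS_res/SS_tot about the mean of the evaluated set (Q² centers on
the test mean — the conventional external-validation choice; centering on
the train mean is the main alternative and gives slightly different
values). Reports aggregate AARD per system; the *global* AARD pools all
points and is algebraically the NDP-weighted mean of the per-system AARDs
(asserted to 10⁻¹² relative in the tests), while the *arithmetic* AARD
averages systems unweighted.

## Synthetic data generator

The generator emulates the structure of experimental D12 compilations:
per-system constant compound properties drawn log-uniformly within the
polar/nonpolar applicability domains (polar: T 268–554 K, μ₁ 0.0241–17.6 cP,
M₂ 17–674, Pc,2 4.1–221.2 bar, M₁ 20–113, ε₁/k_B 208–2121 K; nonpolar:
T 213–567 K, μ₁ 0.0229–2.92 cP, M₂ 2–461, Pc,2 12.5–96.3 bar, M₁ 30–395;
densities 0.30–1.65 g cm⁻³), a narrow per-system temperature window
(±10–40 K) and a viscosity series spanning a factor 5–12 (as temperature
series in real compilations do — and enough spread in the T/μ₁ regressor
for per-system fits to be identifiable). D12 comes from one of three
mechanisms — the Wilke-Chang equation itself, a per-system affine law with
recorded (a, b), or a smooth nonlinear positive function of the five
nonpolar model variables — times multiplicative lognormal noise
exp(ε), ε ~ N(0, √ln(1+cv²)), so the expected AARD of the true model is
approximately the noise coefficient of variation and pipeline benchmarks
are interpretable. Systems whose noiseless D12 would leave 2×10⁻⁷–5×10⁻⁴
cm² s⁻¹ (the physical decade span of liquid-phase tracer diffusivities) are
redrawn. Everything is deterministic under the seed, and a truth sidecar
records the per-system mechanism parameters.

What the generator does **not** emulate: the real marginal distributions of
the compilations, thermodynamically consistent ρ(T)/μ(T) relations within a
system (state variables are drawn independently), measurement-source
heterogeneity, or chemically meaningful correlation between a compound's
properties. Tests passing on synthetic data therefore demonstrate that the
pipeline machinery is correct and that the expected orderings (boosted
ensemble over linear baseline on nonlinear targets; original model over
all y-scrambled rebuilds) hold under controlled signal/noise — not that any
particular accuracy will be achieved on real measurements.

## Problem sizes and test conditions

The stochastic pipeline checks run at deliberately modest sizes: the
boosted-vs-linear ordering uses 60 systems / ≥600 points × 20 seeds with a
compact boosting grid ({100,300} stages × depth {2,3} at learning rate
0.1); y-randomization uses 200 permutations of a 25-system database with a
single-point grid (100 stages, depth 3). The parameter-recovery check for
the affine mechanism uses well-sampled systems (20–40 points): with 5%
multiplicative noise, ordinary least squares on 10–15 points recovers
slopes within 5% only ~80% of the time — an inherent property of
heteroscedastic noise on a skewed regressor, not a defect — while
well-measured systems recover ≥90%.

## Known limitations

* The Zhu-model equation groupings are reconstructions (see above); they
  are isolated in one constants table and pinned by regression tests.
* The packaged table is transcribed as printed, including two internal
  oddities of the source: the ferrocene Tc that does not follow the
  Klincewicz correlation its provenance code implies, and a hydrogen
  ε_LJ/k_B of 0.00 K (the loader accepts ≥ 0 for packaged data; estimator
  outputs remain strictly positive).
* Q² here is computed about the test-set mean; comparisons against numbers
  computed about the training mean will differ slightly.
* The per-system correlation is fit by unweighted OLS on raw D12, so
  high-diffusivity points dominate under relative noise; a weighted variant
  is deliberately not provided to keep the correlation in its standard
  form.
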