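# Methods

## Model and assumptions

Each of *k* barcoded subpopulations evolves as an independent linear
birth–death process with common division rate β and death rate δ (both
min⁻¹): the barcodes are assumed fitness-neutral, rates are constant in time
(exponential growth or decay only), and cells are well mixed. Under these
assumptions the first two moments of the subpopulation sizes are

    ⟨nᵢ(t)⟩ = nᵢ(0)e^{rt},   Var(nᵢ(t)) = nᵢ(0) (β+δ)/r · e^{rt}(e^{rt}−1),

with r = β − δ. Error propagation of fᵢ(t) = nᵢ(t)/N(t) gives the frequency
variance

    Var(fᵢ(t)) ≈ (β+δ)(1−e^{−rt}) / (r N(0)) · fᵢ(0)(1−fᵢ(0)),

which is what the founder-size statistic measures: the mean inverse founder
size equals the frequency-variance term averaged over tags. Substituting the
variance yields the closed form ⟨N_B(t)⟩ ≈ rN(0)/[(β+δ)(1−e^{−rt})], notable
for being independent of the tag distribution; inverting it together with
N(t) = N(0)e^{rt} gives the rate estimators in `restamp.core.estimate_rates`.
The approximations involved (⟨1/X⟩ ≈ 1/⟨X⟩, error propagation) are accurate
when N(0) is large and per-tag frequencies are small; the validation suite
quantifies the residual bias at census ~10⁶ (a few percent on the founder
size, well under the ensemble spread).

Technical bottlenecks are modeled as multinomial sampling events. Each event
of size S contributes an additive 1/S term to the mean inverse founder size
(law-of-total-variance decomposition), so the correction subtracts
Σ⟨Sⱼ⁻¹⟩ + Σ⟨Iⱼ⁻¹⟩ from the measured drift. When replicate sizes are given
for one bottleneck stage, the ledger averages the *inverses* (mean of 1/S),
which is what the decomposition calls for — not the inverse of the mean.

## Degenerate inputs and numerical choices

- **r → 0**: the closed forms for ⟨N_B⟩, Var(f), s_B and the rate inversion
  are 0/0 at β = δ. Whenever |r|·t < 10⁻⁸ the analytic series limits are used
  (e.g. ⟨N_B⟩ → N(0)/((β+δ)t)); tests verify continuity against r = ±10⁻⁶
  evaluations.
- **Uninformative tags**: tags with reference frequency exactly 0 or 1 carry
  no drift information and are excluded from the sums; the retained and
  excluded counts are recorded on every estimate.
- **Over-correction**: when the ledger terms exceed the measured drift the
  corrected founder size is non-positive. It is returned flagged, never
  clipped or raised, because negativity is itself diagnostic of bottlenecks
  stringent enough to drown the biological signal; the rate estimator
  refuses flagged inputs with an actionable message.
- **Identical profiles** (zero drift) give an infinite founder size, returned
  flagged for the same reason.
- **Volume convention**: founder sizes, N(0) and N(t) must refer to the same
  reference volume before rate inversion; estimates carry an explicit
  `volume_scale` (e.g. ×5 for a 200 µl sample against per-ml CFU counts).

## Bottleneck sensitivity

s_B(t) = Var_B(fᵢ)/Var_BD(fᵢ(t)) = rN(0)/[(β+δ)(1−e^{−rt})N_B] compares
sampling-induced to biologically induced variance; N(0) enters as CFU per ml.
The robustness threshold 0.17 is taken as a given constant, calibrated
empirically in controlled death experiments (the value of s_B at t = 35 min
in the low-death-rate control). `sensitivity_grid` scans (β, δ) designs —
by default over [0, 0.046] × [0, 0.14] min⁻¹, the ranges implied by a 15-min
minimum doubling time and 5-min minimum halving time — and flags cells above
threshold; sensitivity rises sharply as both rates approach zero, so slowly
turning-over populations need larger samples or longer observation.

## Death-process emulation

A pure death process can be emulated by sampling a volume Δv_t = Δv₀e^{−δt}
from a well-mixed culture. Sampling reproduces the *mean* per-tag survivor
count but its variance is binomial in the sampling fraction rather than in
the survival probability p = e^{−δt}; matching the two multiplies the founder
size by 1/(1−p) (for k ≫ 1 the residual (1−fᵢ(0)) factor is negligible and
is dropped, as in the 1000-tag experiments the utilities target).

## Plasmid-segregation comparator

With a conditionally non-replicative plasmid the marker-positive fraction
dilutes only through division, ⟨F(t)⟩ = F(0)e^{−βt}, giving
β = ln(F(0)/F(t))/t and δ = ln(F(0)N(0)/(F(t)N(t)))/t. It shares no code or
assumptions with the founder-size path beyond exponential dynamics, which is
why it serves as the cross-method consistency check in the tests.

## Tag-extinction forecasting

The probability that a lineage founded by one cell is extinct by t is
p₁ = δ(e^{rt}−1)/(βe^{rt}−δ) (limit δt/(1+δt) at β = δ); a tag with n₀
founder cells is extinct with probability p₁^{n₀}. `expected_surviving_tags`
reports the expected surviving fraction and count, used to decide whether k
should be increased before an experiment with heavy death.

## Simulator

The tau-leap advances all tags and all ensemble iterations in one array per
step: births ~ Poisson(β·n·dt) and deaths ~ Poisson(δ·n·dt), with deaths
capped at the current count so zero is absorbing. At the default dt = 0.01
min and rates ≤ 0.14 min⁻¹ the per-cell event probability per step is
< 0.002, making the cap bias negligible; the suite cross-checks means and
variances against an exact event-driven (Gillespie) oracle on instances with
N(0) ≤ 10³. A single numpy Generator seeded from the plan drives the whole
run — identical (seed, plan, initial state) reproduces trajectories
bit-exactly; there is no parallel execution, so no per-iteration stream
splitting is needed. Sampling bottlenecks are multinomial (with replacement)
even at large sampling fractions, consistent with the analytic correction
being derived for multinomial events. Rate heterogeneity draws per-tag
(βᵢ, δᵢ) once at t = 0 from truncated normals; estimates remain accurate
for relative SD below ~10% and inflate beyond that, which the tests check
qualitatively.

The canonical validation scenario mirrors the controlled in-silico
experiment: k = 1000 tags with geometric(1/1000) initial abundances (census
≈ 10⁶), t = 120 min, dt = 0.01, 100 iterations, reference-side bottlenecks
I₁ = I₂ = 10⁶ and sample-side S₁ = 10⁵, S₂ = 10⁶, for the dying
(β, δ) = (0.01, 0.03) and growing (0.03, 0.01) cases. Per iteration the
reference chain is one fresh multinomial cascade of the inoculum. The
growing-case *corrected* mean is not used as a point target: its ensemble SD
exceeds its mean (the S₁ = 10⁵ bottleneck is stringent relative to the
~10⁷ endpoint census), so only its order of magnitude is meaningful.

## Read pipeline

Reads follow a fixed layout — 30 bp random barcode then a 21 bp constant
strain barcode — and are kept only on an exact strain-barcode match. Under
position-independent substitution errors the pass rate is p^{N_S}, inverted
to estimate the per-base correct-call probability p (typically 0.98–0.99).
Mismatch counts in the random region are then Binomial(N_R, q), q = 1−p;
the expected read count per mismatch class m sets a per-class budget, and
m_max is the largest class expected to contribute ≥ 1 read. After exact
clustering, the k most abundant sequences are the true barcodes; every other
sequence is scored by Hamming distance to its *nearest* true barcode (the
mean distance to all k barcodes is ≈ 3N_R/4 for any sequence and cannot
discriminate, so nearest-distance is the operative reading of the class
assignment). Sequences beyond m_max are discarded as spurious; within each
class at most round(ñ_m) most-abundant sequences are retained and merged
into their nearest barcode's count (a flag keeps them separate for
diagnostics). The model is quality-blind and substitution-only — no indel
alignment, no PCR-bias modeling.

## Synthetic data generator

The generator emulates the targeted experimental regime: libraries of up to
k = 1000 distinct 30-mers (with a pairwise Hamming floor of 5 so error
classes up to m_max cannot collide between barcodes — a generator guarantee,
not a property of real libraries), uniform/geometric/explicit abundances,
i.i.d. substitutions at rate q uniform over the three alternative bases,
constant dummy qualities, and optional random-sequence contaminants. Default
test scales (depth 10⁴–10⁵, q = 0.01, k = 20–50) keep ensemble checks
tractable while matching the error regime of the real protocol. What it does
*not* emulate: position-dependent error profiles, indels, PCR duplicates and
amplification bias, chimeras, or quality-score structure — so passing tests
demonstrate correctness of the counting and filtering logic under the
stated error model, not robustness to those artifacts. Experiment bundles
(reference/timepoint tables, noiseless CFU series, ledger) are deterministic
given (plan, seed) and record full ground truth.

## Problem sizes in the test and validation suites

The validation suite runs the two canonical simulation cases at full scale
(k = 1000, 100 iterations, 12 000 steps each, ~1–2 min together) and keeps
oracle comparisons at small-instance scale: 500 Gillespie ensembles at
N(0) = 10³ for the variance formula, 2000 ensembles of 20 small lineages
for extinction, 200 multinomial replicates per sample size for the
founder-size oracle, and a 10⁵-read pipeline check. Monte-Carlo comparisons
use 3-standard-error bands computed from the ensembles themselves.

## Known limitations

- Constant rates only: no logistic growth, compartments or migration.
- All cells share the same rates; strong phenotypic heterogeneity
  (e.g. persisters) biases estimates upward.
- The founder-size approximations degrade for very small N(0) or very large
  per-tag frequencies.
- The read pipeline assumes the fixed layout and substitution-only errors.
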