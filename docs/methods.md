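# Methods

## The model

Population growth across a strain's biokinetic range is described as a
single rate-limiting, enzyme-catalysed reaction.  The reaction itself
follows an Arrhenius law; the enzyme that catalyses it is in equilibrium
between its folded (native, catalytically active) and unfolded states, and
it denatures at both low and high temperature because the Gibbs energy of
unfolding is concave in temperature.  The modelled rate at absolute
temperature `T` (K) is

    r(T) = c · T · exp(−ΔH‡ / RT) / (1 + exp(−n ΔG(T) / RT))

with the per-residue unfolding free energy in the convergence-temperature
(Murphy–Privalov) parameterisation

    ΔG(T) = ΔH* + ΔCp (T − T_H) − T [ΔS* + ΔCp ln(T / T_S)].

Parameters and units:

| symbol | meaning | units | scope |
|---|---|---|---|
| `c` | scaling constant (carries the rate units) | rate/K | per strain |
| `ΔH‡` | enthalpy of activation of the rate-limiting reaction | J/mol | per strain |
| `ΔCp` | heat-capacity change on unfolding | J/(K·mol-residue) | per strain |
| `n` | number of amino-acid residues of the enzyme (continuous) | — | per strain |
| `ΔH*`, `ΔS*` | unfolding enthalpy/entropy at the convergence temperatures | J/mol-residue, J/(K·mol-residue) | universal |
| `T_H`, `T_S` | convergence temperatures for enthalpy and entropy | K | universal |

`R = 8.314` J/(K·mol).  `1/(1 + exp(−nΔG/RT))` is the probability that
the enzyme is native (`P_native`); `d²ΔG/dT² = −ΔCp/T < 0`, so `ΔG` has a
unique maximum at the stability temperature `T* = T_S exp(−ΔS*/ΔCp)` and
at most two zeros `T_L < T* < T_U`, the temperatures of 50% cold and heat
denaturation.  The growth optimum `T_opt` sits between `T*` and `T_U`.
All rate evaluations go through a log-sum-exp form of the denominator and
are finite for any admissible parameters.

Derived quantities: `T*` (closed form), `T_opt` (coarse 1 K scan to
bracket, then bounded scalar refinement of `−log r`; a flag is raised if
the scan sees more than one local maximum), `T_L`/`T_U` (Brent root finds
on each side of `T*`; concavity guarantees at most one root per side),
the average number of non-polar hydrogen atoms per residue `Nh` (a linear
map of `ΔCp`, coefficients calibrated against published per-group derived
values and overridable in `constants.NH_COEFFICIENTS`), and the total
heat-capacity change `n·ΔCp`.

## Identifiability — why the universal priors are informative

The model is *exactly* invariant under

    (ΔH*, ΔS*, ΔCp_i) → λ (ΔH*, ΔS*, ΔCp_i),   n_i → n_i / λ,

because `ΔG` is homogeneous of degree one in `(ΔH*, ΔS*, ΔCp)` and enters
the rate only through `n·ΔG`.  Growth data therefore carry *no*
information about the absolute per-residue energy scale; only the prior
fixes it.  Beyond this exact ridge, the convergence temperatures are
identified (weakly) by consistency across strains with different
`ΔCp/n` ratios, which is why fitting many strains from all five thermal
groups jointly matters.  The default priors are:

* universal parameters — uniform boxes bracketing the published
  convergence-parameter estimates for globular proteins:
  `ΔH* ∈ [4600, 5200]` J/mol-residue, `ΔS* ∈ [16, 18.5]` J/(K·mol-residue),
  `T_H ∈ [371, 379]` K, `T_S ∈ [386, 394]` K (with `T_H < T_S`);
* group means — uniform: `ΔH‡ ∈ [20, 200]` kJ/mol, `ΔCp ∈ [20, 120]`,
  `n ∈ [50, 1000]`;
* strain parameters — Gaussian around their group mean with
  per-parameter-type precisions `τ_θ`, themselves uniform on wide
  intervals (effectively truncated at positivity: proposals with
  non-positive `ΔH‡`, `ΔCp` or `n` have zero posterior mass);
* `log c` — uniform on `[−10, 60]` (proper but vague; the two-stage
  standardisation removes `c`'s influence anyway);
* observational precision `τ_obs` on the square-root rate scale —
  gamma(0.001, 0.001).

All prior densities are normalised so marginal likelihoods of competing
group structures are comparable.

## Likelihood and standardisation

Observed rates are standardised per strain by the maximum observed rate;
the square root of the standardised rate is modelled as Gaussian around
the square root of the modelled rate with precision `τ_obs` (the square
root stabilises the variance of rate measurements).  The two-stage
procedure refits after dividing each strain's data by its *fitted*
maximum rate, pinning fitted maxima at one.

## Sampler

One sweep updates: each strain's `(log c, ΔH‡, ΔCp, n)` block and each
group-mean block with Haario-style adaptive Metropolis (proposal
covariance `2.38²/d` times the running empirical covariance plus
`10⁻¹⁰ I` jitter, with a Robbins–Monro global scale correction toward
23.4% acceptance; warm-up 1,000 iterations with diagonal proposals, after
which the warm-up history is discarded from the moments because the early
self-tempering phase is not stationary); a joint *translation* of each
group mean together with its member strains (the between-strain Gaussian
terms are invariant, so this move lets a whole group slide along the
likelihood); the log-precisions `τ_θ` as one Haario block; `τ_obs` by its
conjugate gamma Gibbs draw; and the universal parameters by (i) one
adaptive-direction ensemble sweep (moves along lines through pairs of
ensemble members, differential-evolution scaling `2.38/√(2d)`, plus a 5%
stepping-stone independence proposal from the prior box), (ii) a
Metropolis move along the exact λ-ridge above (likelihood-invariant;
Jacobian λ²), and (iii) four *compensated* scalar moves, one per
universal coordinate, which rescale every strain's `(ΔCp, n)` to keep
`n·ΔCp` and the matching `ΔG` coefficient exactly invariant and then
absorb the leftover log-rate change into `(log c, ΔH‡)` by a per-strain
linear projection (a unit-Jacobian shear).  Without the compensated
moves the conditional posterior of the universal parameters given the
strains is orders of magnitude sharper than their marginal posterior and
the chain freezes.

Every block draws from its own seeded random stream keyed by the strain
or group label, so runs are reproducible and permuting input rows or
strains changes nothing but labels.

Initialisation is deterministic: per-strain least squares (universal
parameters at the prior midpoints, multi-start over the residue count,
which is ridged per strain) followed by one joint least-squares polish of
the universal and all strain parameters.  Coordinate-wise initialisation
alone lands in a spurious low-`n` basin because the hot-side fit is
extremely sharp in `T_S`.  Group means start at member averages,
precisions at the geometric midpoint of their prior intervals, and the
chain falls back to prior midpoints if the least squares fails.

### Known limitation: effective sample size along the flat directions

The posterior valley along `(T_H, T_S)` — with full per-strain
re-compensation — is nearly flat over several kelvin, and no
fixed-Jacobian Metropolis move tracks it exactly.  At desk-scale run
lengths (the default 50,000 iterations; the full-scale analyses behind
the reference values used 10⁶) the chains traverse only ~0.2 K of it:
posterior *means* of the convergence temperatures are accurate to about
1%, but their 99% HPDIs reflect within-valley noise and are too narrow to
be calibrated.  HPDIs for the enthalpy change, the group means and the
strain parameters are informative at this run length.  Split-R̂ and ESS
are reported so the user can see this directly.

## Synthetic data

The generator emulates a literature compilation: strains grouped into the
five thermal groups (psychrophile, mesophile, Ascomycota, thermophile,
hyperthermophile) with group means at the reference posterior estimates;
strain parameters Gaussian around the means, truncated at zero
(between-strain SDs default to 2 kJ/mol for `ΔH‡`, 1 J/(K·mol-residue)
for `ΔCp`, 15 residues for `n` — chosen as a small but non-degenerate
spread, since published per-strain tables report only posterior SDs that
mix strain spread with estimation error); 14 temperatures per strain
spanning from the cold-side temperature where the modelled rate is 5% of
its maximum to just past `T_U`, clipped to the observable window
271–396 K and always containing `T_opt`; observation noise Gaussian on
the square-root scale with SD 0.02, floored so rates stay non-negative
(`rate = max(0, √r + ε)²`); per-strain standardisation to a maximum of
one.  Defaults produce 14 strains (2/6/2/2/2 across groups, mesophiles
most abundant, as in real compilations) × 14 points = 196 records,
matching the record density (~14 records/strain) of a large compilation.

What the generator does *not* emulate: heterogeneity of measurement
methods across source studies, non-Gaussian or temperature-dependent
error, unevenly sampled temperature designs, and taxonomic correlation
structure.  Passing recovery tests therefore demonstrates correctness of
the inference machinery under the model's own assumptions, not robustness
to real literature data.

## Model comparison

Five grouping structures are supported (single group; by domain; by
domain with Eukarya split by cellularity; by thermal group; by thermal
group with Ascomycota separate).  Thermal allocation thresholds on `T*`
default to 285/300/316 K — midpoints between the published per-group
stability temperatures — with ties going to the colder group; they are
configurable.

Marginal likelihoods: the default estimator is stepping-stone sampling
with a 24-rung ladder `β_j = (j/24)⁵`.  The ladder is deliberately fine
and concentrated near the prior: with a vague gamma prior on `τ_obs` the
log-likelihood variance explodes at small `β`, and coarse ladders (8–16
rungs) biased the estimate by several log units in validation runs.  A
product-space (pseudo-prior) sampler is also provided in two forms — a
generic one, validated against the closed-form Bayes factor of a
conjugate Gaussian toy, and a shared-parameter form specialised to
grouping structures in which only the group means and between-strain
precisions are model-specific (pseudo-priors are full-covariance
Gaussians fitted to pilot runs).  On realistic growth data the
product-space indicator is nonetheless absorbing in both directions
(each grouping reshapes the strain parameters through shrinkage, so the
current shared state is always implausible under the competing model);
the sampler detects this and warns.  Stepping-stone is therefore the
default, and the reported per-rung MC error ignores autocorrelation —
between-seed spread is the honest uncertainty gauge.

## Numerical choices

* Overflow policy: all rate evaluations in log space; the native-state
  logistic saturates to exactly 0/1 instead of producing NaN.
* `T_opt` tolerance 10⁻⁴ K (bounded Brent); root finds to 10⁻⁹ K.
* HPDI: shortest contiguous window over sorted retained samples; ties
  broken at the lowest start.
* Degenerate inputs: `ΔCp = 0` degrades `ΔG` to a line; `n = 0` gives
  `P_native = ½` everywhere; a protein with `max ΔG ≤ 0` has no 50%
  bounds and is reported as NaN with a flag.
* Single-strain fits are nonlinear least squares on the square-root
  scale (`scipy.optimize.least_squares`, trust-region reflective) with
  the classical fixing scheme (freeze `ΔS*`, `T_H`, `T_S`) by default
  and `c` optimised on the log scale.

## Desk-scale defaults

The default run length is 50,000 iterations with 50% burn-in (the
reference analyses used 10⁶); the acceptance script and the test suite
use 50,000 and smaller, respectively, with problem sizes of 14 strains ×
14 points (the generator default) down to 4 strains × 6 points for
smoke tests.  These sizes were chosen so a full verification pass runs on
a laptop-class single core in minutes while leaving every qualitative
conclusion intact.
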