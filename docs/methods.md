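# Methods

## The setting

`bellcog` analyzes bipartite two-outcome coincidence experiments of the
kind used in quantum cognition: a respondent is shown a combined concept
(*Two Different Wind Directions*) and selects one pair of outcomes per
joint measurement.  There are four joint measurements AB, AB′, A′B, A′B′,
built from two measurements per conceptual sub-system; every outcome is
one of the eight windrose directions, arranged as four antipodal axes
(A = North/South, A′ = East/West, B = Northeast/Southwest,
B′ = Southeast/Northwest).  The primitive data object is the
`JointProbabilityTable`: four 2×2 blocks p(X_i, Y_j), each nonnegative
and normalized.

Two statistics are computed on a table:

* **CHSH**: S = E(A,B) − E(A,B′) + E(A′,B) + E(A′,B′), with
  E(X,Y) = p11 − p12 − p21 + p22.  |S| ≤ 2 for experimentally separated
  sub-systems; singlet-state product measurements reach 2√2 (Tsirelson);
  the algebraic maximum is 4.  The literature permutes which term carries
  the minus sign, so `chsh(..., minus_term=...)` makes it explicit
  (default AB′) and |S| is always reported alongside S.
* **Marginal-law residuals**: the eight signed differences between a
  sub-system's outcome marginals under the two possible partner
  measurements (no-signaling conditions).  All zero for separated
  sub-systems and for any product-measurement quantum model.

The raw 85-participant windrose table (packaged as `wind_eq2.csv`)
violates both: |S| = 2.48 by exact arithmetic on the printed 2-decimal
probabilities, and marginal residuals up to 0.17.  (The original report
quotes |S| = 2.47 from unrounded raw data that are not available; the
package always computes from the data it is given and does not special-case
that value.)

## Rotation symmetrization

The marginal-law violation is attributed to the anisotropy of the *wind*
concept (North ≠ South in meaning).  The symmetrized protocols remove it
by uniformly mixing rotated replicas of the whole measurement
configuration: rotations by 180° only ("coin", `symmetrize_180`) or by
all eight multiples of 45° ("octahedral die", `symmetrize_octahedral`).

Under the **consistency assumption** — a respondent selects the same
unordered pair of compass directions whichever rotated configuration
offers it — a rotated replica's probabilities are a pure reindexing of
the unrotated table.  The general reindexing rule implemented matches
*unordered* direction pairs: rotated slot (m,(i,j)) with directions
(d₁,d₂) maps to the unique unrotated slot presenting {d₁,d₂}.  This is
the only bijection consistent with all the worked correspondences of the
published protocol, and it reproduces them (p₄₅(A₁,B₁) = p(A′₁,B₁),
p₉₀(A₁,B₁) = p(A′₁,B′₁), p₁₃₅(A₁,B₁) = p(A₂,B′₁), 180° = full index
swap).  Custom schemes are accepted if their eight outcomes tile the
compass; otherwise `MappingError`.

Two exact consequences, verified as properties on random tables:

* every marginal of a symmetrized table equals ½ exactly (each mixing
  group contains, for every slot, its index-swapped partner);
* S is exactly preserved (each rotated replica permutes the four E's
  with compensating signs; every E of the octahedral output is ±S/4).

Mixing is deterministic cellwise averaging of stored float values; the
stochastic version (actually rolling the die per respondent) lives in
the synthetic-respondents module.

## Singlet quantum model

The symmetrized table has the block symmetry p11 = p22, p12 = p21 and
obeys the marginal law, so it admits a standard quantum model: state
|Ψ⟩ = (|12⟩ − |21⟩)/√2 in C²⊗C², joint measurements as product spin
observables (σ·dL)⊗(σ·dR).  The Born rule gives
p(s_L, s_R) = ¼(1 − s_L s_R dL·dR) and E = −dL·dR.  Probabilities are
implemented both in this closed form and by explicit construction of the
product eigenvectors (half-angle convention, e^{±iφ/2} phases) and
|⟨·|Ψ⟩|² in C⁴; the two routes agree to 1e−12 and both are exposed.

`solve_directions` inverts the model.  The closed form fixes the gauge
θ_a = 0, φ_a = φ_b = 0, φ_a′ = φ_b′ and reads the four dot products off
the block expectations: θ_b = arccos(−E_AB), θ_b′ = arccos(−E_AB′),
θ_a′ = θ_b′ ∓ arccos(−E_A′B′) (the published branch, minus, is tried
first and recorded in the solution object), and φ_a′ from the A′B
condition.  For the octahedrally symmetrized experimental table this
yields θ_b = 51.68°, θ_b′ = 128.32°, θ_a′ = 76.63°, φ_a′ = φ_b′ = 51.36°
at full precision; the 2-decimal published chain (128.30°, 76.62°,
51.37°) differs only through intermediate rounding, and tests compare at
±0.02°.

The φ_a′ = φ_b′ gauge cannot represent every realizable quadruple of dot
products (example: (a·b, a·b′, a′·b, a′·b′) = (0,0,1,0), realized by
a = z, b = a′ = x, b′ = y, forces unequal azimuths).  The numerical
fallback therefore runs bounded least squares over the five parameters
(θ_b, θ_a′, θ_b′, φ_a′, φ_b′), eight multi-starts from a generator
seeded with 1729, tolerances 1e−15.  A target that still cannot be
reproduced within the caller's tolerance — asymmetric blocks,
marginal-law violation, or |S| > 2√2 — raises `InfeasibleTargetError`;
modeling such tables would require entangled (non-product) measurements,
which are out of scope.

## Rigid-rod mechanical model

The rod model shows the two violations have independent mechanisms
without any Hilbert-space machinery.  Each sub-system is a sphere whose
measurement is an (ε, d)-elastic band on a diameter: uniformly breakable
on [d−ε, d+ε] only, band coordinate +1 = outcome 1.  A particle at
coordinate x gets outcome 1 with probability (x − d + ε)/(2ε) (the
fraction of breakable band below it; a break exactly at the particle is
assigned to outcome 1 — a measure-zero tie fixed for determinism).
(1, 0) reproduces Born statistics.

The rod constraint: both particles start at their sphere centers; the
first measurement drags its particle to an end point and the rod forces
the partner particle to the antipodal point of its sphere, where it
falls onto the second band at coordinate −s₁·cos θ (s₁ the first
outcome sign, θ the relative band angle).  Closed forms implemented:
sequential probabilities for either order, their uniform order mixture,
the mixed marginals
p̄(A₁,·) = (ε_A−d_A)/(2ε_A) + d_B cosθ/(4ε_A ε_B), the equal-band
expectation E = −cosθ/ε + d²/ε², and the maximal-violation CHSH value
|S| = 2|√2/ε − d²/ε²|.  The order mixture is defined as the average of
the two sequential forms (the normative definition; a published expanded
form of the same quantity contains typographical sign slips in its third
terms).  All closed forms require the landing assumption
|cos θ| ≤ ε − |d| for the bands involved (`AssumptionError` otherwise),
which at the maximal-violation angles (cosines ±√2/2) means ε ≥ √2/2.

Consequences, all tested: d = 0 preserves the marginal law for any θ
while |S| = 2√2/ε ranges from 2√2 (ε = 1, the quantum value — the
closed-form table then equals the singlet prediction for coplanar
directions to 1e−12) up to the algebraic maximum 4 at ε = √2/2; band
asymmetry d ≠ 0 violates the marginal law but strictly *decreases* |S|.

`simulate_rod` is a direct Monte-Carlo of the mechanics (vectorized,
numpy PCG64, seed recorded in the result), not of the closed forms, and
agrees with them cellwise within 3σ binomial bounds at 10⁶ trials per
joint pair.  `fit_elastic` recovers a shared (ε, d) from an empirical
table by least squares on the 16 closed-form cells, parametrized as
(ε, d/(1−ε)) so the admissible region is a box.

## Synthetic respondents

The generator emulates the study design: n = 85 respondents by default
(the original cohort size), each answering all four joint measurements,
with one categorical draw per block from the generating table.  Choices
(not probabilities) are the primitive record; empirical tables are
derived counts/n.  Within-respondent dependence across the four blocks
is not specified by the study; the default is independence given the
table, with an optional comonotone "shared-pair preference" coupling
(one latent uniform per respondent through each block's inverse CDF,
probability `coupling`, default 0) documented as an extension.

`apply_consistency` maps each respondent's choices to the rotated
configuration deterministically through the slot correspondence, so the
empirical table of a rotated sample equals `rotated_table` of the
empirical table bit-exactly, for any seed.  `sample_mixed_protocol`
draws one rotation per respondent (coin: {0°, 180°}; die: all eight) and
records the consistency images of latent unrotated draws; its empirical
table is an unbiased estimate of the corresponding symmetrized table,
and realizes the protocol's point stochastically: marginal residuals at
sampling-noise level with |S| still above 2.

`bootstrap_statistic` resamples respondents with replacement
(within-subject units, matching the assumed design) and returns a
2.5/97.5 percentile interval; coverage for |S| is checked by simulation
(100 cohorts of n = 1000, 200 bootstrap replicates each, ≥ 90% coverage).

What the generator does *not* emulate: response times, question-order
effects, partial consistency of real respondents under rotation, or
cohort heterogeneity.  Passing tests therefore show correctness of the
estimators and protocols under the stated sampling model, not robustness
to those real-data features.

## Numerical choices

* Normalization tolerance 1e−9 for program-generated tables, 0.011 for
  hand-entered 2-decimal tables (worst-case accumulated rounding of four
  cells); marginal-law tolerance 1e−9, overridable.  Probabilities are
  never silently renormalized; validation failures name the offending
  block or cell.
* Probabilities are stored at full precision; printed comparisons round
  half-up to 2 decimals only at report time.
* Compass angles are integer degrees clockwise from North; Bloch
  directions are (θ, φ) radians with the z-axis as reference.
* Problem sizes: the Monte-Carlo cross-checks use 10⁶ rod trials per
  joint pair and 10⁵–5·10⁵ trials elsewhere, with 3σ binomial acceptance
  bands; property tests sweep 1000 random tables / direction pairs.

## Known limitations

* Marginal-law-violating tables have no product-measurement quantum
  model by construction; the entangled-measurement extension that could
  fit them is deliberately not implemented.
* The rod simulator assumes every landing hits a breakable segment, as
  the closed forms do; configurations outside that regime are rejected
  rather than modeled.
* Statistical inference is limited to the percentile bootstrap; no
  hypothesis tests of the CHSH violation are provided.
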