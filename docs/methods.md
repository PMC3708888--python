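# Methods

## Model

The estimator treats every measured reaction energy as a noisy linear
observation of per-compound formation energies:

    b = Sᵀ f + e,        e ~ N(0, σ²_rc I)

with S the m×n stoichiometric matrix of unique reactions (compounds × 
reactions) and b the replicate-aggregated, inverse-Legendre-transformed
observations in kJ/mol. The reactant-contribution (RC) layer solves this by
minimal-norm least squares, f̂ = (Sᵀ)⁺b. The group-contribution (GC) layer
replaces f by G·Δg — formation energies as sums of structural-subgroup
energies — giving the design Λ = SᵀG and Δĝ = Λ⁺b.

The component-contribution estimator decomposes a query x ∈ ℝᵐ with the
orthogonal projectors P_R (onto range(S)) and P_N = I − P_R, scoring the
in-span part with RC and the remainder with GC:

    ΔG°_cc(x) = xᵀ(P_R (Sᵀ)⁺ + P_N G Λ⁺) b = xᵀ w.

Linearity in x makes first-law consistency structural: Σᵢcᵢxᵢ = 0 implies
Σᵢcᵢ·ΔG°_cc(xᵢ) = 0 identically. On range(S) the estimate coincides with
pure RC; on null(Sᵀ) with pure GC.

### Uncertainty

Layer covariances are the standard least-squares forms scaled by estimated
error variances:

    Σ_rc = σ̂²_rc (Sᵀ)⁺(Sᵀ)⁺ᵀ,   Σ_gc = σ̂²_gc Λ⁺Λ⁺ᵀ,
    σ̂²_layer = RSS_layer / (n − rank(design)).

The squared standard error of a query is

    SE²(x) = xᵀ(P_R Σ_rc P_R + P_N G Σ_gc Gᵀ P_N)x + α²‖P_{N(Λ)}Gᵀ P_N x‖²,

where P_{N(Λ)} projects onto the null space of Λ in group space and
α = 10¹⁰ kJ/mol stands in for an infinite standard error: a query whose
group-space remainder has any component outside range(Λᵀ) involves a group
(or undecomposable compound) about which the data say nothing. Such queries
are reported `covered = False`. Confidence intervals use standard normal
quantiles, ΔG° ± z₍(1+γ)/2₎·SE. Prediction intervals for a *new measurement*
add the mixed residual variance

    σ̂²_cc(x) = (‖P_R x‖²·σ̂²_rc + ‖P_N x‖²·σ̂²_gc) / ‖x‖²,

with squared-norm fractions as weights — they sum to one exactly by the
Pythagorean identity (a plain-norm-fraction variant is available via
`CCConfig(squared_fraction_weights=False)`).

### Standardization of raw measurements

An apparent equilibrium constant K′ at temperature T becomes
ΔG′° = −RT ln K′ at the recorded T (no further temperature normalization;
metal-ion binding is likewise out of scope). The inverse Legendre transform
then subtracts, per compound, the energy of its pseudoisomer group relative
to the reference species: each microspecies j with proton count N_H and
charge z is shifted by

    N_H·RT·ln(10)·pH − (z² − N_H)·α_DH(T)·√I/(1 + β√I),

with β = 1.6 M^(−1/2) and α_DH(T) the Alberty cubic
(9.20483·10⁻³·T − 1.284668·10⁻⁵·T² + 4.95199·10⁻⁸·T³ kJ/mol/M^(1/2),
≈ 2.915 at 298.15 K), and the group energy is the stable log-sum-exp
−RT·ln Σⱼ exp(−ΔGⱼ/RT). Species tables accept explicit energy offsets or a
pKa ladder (adjacent species differ by one proton; the more-protonated
neighbour sits RT·ln(10)·pKa lower, with the proton's formation energy
conventionally zero).

### Replicates, canonicalization, projection

Observations of the same chemical reaction are merged by canonical key:
coefficients rescaled to coprime integers and oriented so the
lexicographically smallest compound is a substrate. The signed rescaling
factor is applied to the observed ΔG° as well, and the training value per
unique reaction is the **median** of the corrected replicates (robust to
outliers). Replicate counts and combined weights are retained; the default
regression is unweighted after aggregation, with optional per-row weighting
by row-scaling (`CCConfig(use_weights=True)`).

The aggregated observation vector is then projected onto range(Sᵀ) — the
subspace of first-law-consistent observation vectors — before training.
Projection does not change any least-squares estimate (the pseudoinverse
annihilates the orthogonal component), so the removed sum of squares is
carried along (`TrainingData.projected_ss`) and added back into both layers'
residual sums of squares; error variances therefore equal those of the
unprojected fit, while downstream consumers (e.g. cross-validation truth
values) see consistent observations.

## Numerical choices

* Dense SVD everywhere; rank cutoff `max(rows, cols)·eps·σ_max`,
  overridable. Projectors are explicitly symmetrized.
* The projector onto null(Λ) is built from an explicit null-space basis
  (trailing right singular vectors), so it is *exactly* zero at full column
  rank. The α² term is never folded into the dense uncertainty matrix:
  SE² evaluates it as α²·‖·‖² on a factored form, since α² ≈ 10²⁰ would
  amplify epsilon-level projector residue into kJ/mol-scale noise. Queries
  whose remainder norm falls below the coverage tolerance (10⁻¹⁰·‖x‖,
  configurable) are treated as covered and the term is dropped as numerical
  residue.
* Degrees of freedom n − rank must be positive in both layers; training
  refuses to estimate variances otherwise (and cross-validation marks such
  folds skipped).
* Unknown compounds at query time yield `covered = False` with SE = α rather
  than an exception, so batch scoring proceeds.
* A null net reaction (e.g. "A = A") scores exactly 0 ± 0.

## Synthetic worlds

The generator draws group contributions Δg ~ N(0, 30² kJ²/mol²), a
per-compound deviation from group additivity δ ~ N(0, 6.8²) — anchored at
the root-mean-square non-additivity error typical of curated group models —
and sets f_true = G·Δg + δ. Reactions are unique sparse integer
stoichiometries (coefficients in ±{1..3}, 2–5 compounds, emitted in
canonical coprime form so all observations carry noise at the same scale),
restricted to a "measured" subset of compounds (default 80 %) to mimic
corpora concentrated in central metabolism. Observations are
Sᵀf_true + N(0, 1²) with replicate counts 1 + Poisson(5); optional orphan
compounds carry a private group no reaction touches, exercising the
uncovered path. Worlds can be written as the same TSV dialects the readers
consume (K′ rows fall back to the ΔG′° dialect when the constant is not
representable in double precision, as measurement corpora do for reactions
far from equilibrium).

What the generator does **not** emulate: element balance and real chemistry,
inter-laboratory condition heterogeneity, correlated measurement errors, and
pKa estimation error. Passing tests therefore demonstrate the correctness of
the estimator's algebra and the calibration of its uncertainty under its own
error model, not the field accuracy achievable on curated measurement
corpora.

## Validation studies

* **Leave-one-out cross-validation** retrains from scratch per fold (no
  rank-one updates — correctness over speed at desk scale), excluding all
  replicates of the held-out reaction, and classifies folds by whether the
  held-out vector lies in the remainder's span (tolerance 10⁻⁸, exposed).
  The method comparison uses a paired sign test on absolute residuals — the
  choice of test is an implementation default.
* **Interval calibration** is assessed on single-replicate worlds with the
  full compound set measured, where the estimator's error model is exact;
  problem sizes are 60 worlds × (60 reactions, 20 compounds, 6 groups) with
  5 held-out reactions each. Under replicate medians the per-replicate
  interval coverage falls below nominal by construction — the interval
  targets a new observation at the aggregated noise scale — so the
  cross-validation report tracks hits both per raw replicate and for the
  aggregated value.
* **Parameter recovery** uses 500 single-replicate worlds without
  non-additivity for group-contribution recovery (counted elementwise
  against 3 estimated SEs) and ~1000 default-condition trials for RC-covered
  reaction estimates against 4 SEs.

## Limitations

* No Mg²⁺/pMg transforms, no temperature normalization of K′ beyond the
  measurement temperature, no multi-compartment transport energetics.
* No group-definition table ships with the package: the incidence matrix is
  an input (or produced by the pluggable RDKit SMARTS decomposer from
  user-supplied patterns). The estimator's mathematics is independent of the
  chemistry table.
* Normal (not Student-t) quantiles follow the interval definitions; at small
  residual degrees of freedom intervals are mildly anticonservative.
* Heteroscedastic replicate structure (varying replicate counts) is pooled
  into single per-layer variances; per-observation weighting is available
  but off by default.
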