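# ccgibbs

Component-contribution estimation of standard Gibbs energies of biochemical
reactions, with covariance-based uncertainty and guaranteed first-law
consistency.

## The problem

Thermodynamic constraints on metabolism — which direction a reaction can run,
which metabolite concentrations are feasible — need the standard Gibbs energy
ΔG° of every reaction in a model, but equilibrium constants have been measured
for well under 10 % of the reactions in genome-scale reconstructions. Two
classical remedies trade off against each other:

* **Reactant contributions (RC)** fit per-compound formation energies ΔGf to
  the measured reaction energies by least squares. Accurate, but only reaches
  reactions inside the span of what was measured.
* **Group contributions (GC)** regress the same measurements on counts of
  structural subgroups, so any decomposable compound is reachable — at the
  cost of the group-additivity approximation (several kJ/mol of extra error).

Mixing the two naively assigns formation energies from different reference
points to different compounds, so reaction cycles can acquire a nonzero net
energy — a first-law violation.

## The method

Let S be the m×n stoichiometric matrix of the n unique measured reactions
over m compounds, G the m×g group incidence matrix, Λ = SᵀG, and b the vector
of measured (inverse-Legendre-transformed, replicate-median) standard Gibbs
energies. A query reaction x is split orthogonally by the projectors P_R onto
range(S) and P_N = I − P_R; RC scores the first part, GC the remainder:

    ΔG°_cc(x) = xᵀ [ P_R (Sᵀ)⁺ + P_N G Λ⁺ ] b  =  xᵀ w

Because the estimate is a single linear functional of x, any combination of
reactions with zero net stoichiometry gets exactly zero total energy:
consistency is structural, not approximate. Uncertainty propagates through
the same map with the standard least-squares covariances
Σ_rc = σ̂²_rc·(Sᵀ)⁺(Sᵀ)⁺ᵀ and Σ_gc = σ̂²_gc·Λ⁺Λ⁺ᵀ:

    SE²(x) = xᵀ[P_R Σ_rc P_R + P_N G Σ_gc Gᵀ P_N]x + α²‖P_{N(Λ)} Gᵀ P_N x‖²

The α² term (α = 10¹⁰ kJ/mol) assigns an effectively infinite standard error
to queries whose group-space remainder leaves the training span (a novel
group): such reactions are *flagged uncovered*, never silently guessed.
Prediction intervals for a new measurement add the mixed residual variance
σ̂²_cc(x), the subspace-fraction-weighted mean of σ̂²_rc and σ̂²_gc.

Raw measurements (apparent K′ or ΔG′° at given T, pH, ionic strength) are
standardized to chemical ΔG° by the inverse Legendre transform over each
compound's pseudoisomer (protonation-state) group, with extended
Debye–Hückel activity corrections.

## Worked example

`python examples/02_train_and_score.py` trains on a generated world (40
unique reactions, 26 compounds, 8 groups, replicate noise 1 kJ/mol,
non-additivity 6.8 kJ/mol) and scores one query of each class:

```
trained on 250 raw observations -> 40 unique reactions over 26 compounds
rank(S) = 20, rank(Lambda) = 8; sigma_rc = 0.55 kJ/mol, sigma_gc = 26.75 kJ/mol

class           true  estimate        SE  covered  RC frac
in_range     2886.89   2888.65      3.20     True    1.000
mixed         954.85    963.25      6.52     True    0.997
gc_only      -215.41   -223.48      5.47     True    0.000
uncovered      10.30     46.05       inf    False    0.500
cycle           0.00      0.00      0.00     True    0.000
```

Reading the table: the `in_range` query lies wholly inside the measured span
(RC fraction 1) and reproduces the reactant-contribution fit within a few
kJ/mol; `gc_only` is orthogonal to every measurement and falls back on group
contributions; the `uncovered` query contains a group absent from all
training reactions and is flagged rather than estimated; the null net
reaction (`cycle`) scores exactly 0 ± 0. The other examples demonstrate the
K′ ↔ ΔG° transforms (`01`), confidence vs prediction intervals (`03`), and
leave-one-out cross-validation (`04`).

A thin CLI wraps the same library for shell pipelines:

```sh
ccgibbs simulate --out-dir world --seed 1
ccgibbs train --observations world/observations.tsv --groups world/groups.tsv \
              --model-out model.json
ccgibbs estimate --model model.json --reactions queries.txt --out scores.tsv
ccgibbs loocv --observations world/observations.tsv --groups world/groups.tsv \
              --out-prefix cv
```

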