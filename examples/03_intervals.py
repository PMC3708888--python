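"""Confidence and prediction intervals for an estimated reaction energy.

The confidence interval covers the *true* standard Gibbs energy; the
prediction interval additionally absorbs the residual error variance and so
covers a *new measurement* of the reaction.  Both use standard normal
quantiles on the covariance-propagated standard error.
"""

from ccgibbs import (
    SimConfig,
    confidence_interval,
    estimate,
    generate,
    prediction_interval,
    train,
)
from ccgibbs.dataset import format_reaction, project_observations

world = generate(SimConfig(seed=5))
td = project_observations(world.training_data())
model = train(td, world.incidence)

rxn = td.reaction_vector(0)
est = estimate(model, rxn)
print("reaction:", format_reaction(rxn))
print(f"dG0 = {est.dG0:.2f} +- {est.standard_error:.2f} kJ/mol (true {world.true_dg(rxn):.2f})")
print()
print(f"{'level':>6s} {'confidence interval':>24s} {'prediction interval':>24s}")
for level in (0.68, 0.90, 0.95, 0.99):
    lo_c, hi_c = confidence_interval(est, level)
    lo_p, hi_p = prediction_interval(model, rxn, level)
    print(
        f"{level:6.2f} [{lo_c:10.2f}, {hi_c:10.2f}] [{lo_p:10.2f}, {hi_p:10.2f}]"
    )
print()
print("Prediction intervals are wider: they add the mixed residual variance")
print("(RC/GC error variances weighted by the query's subspace fractions).")
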