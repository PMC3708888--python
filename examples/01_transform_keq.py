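"""Convert an apparent equilibrium constant to a chemical standard Gibbs energy.

An apparent K' measured at some pH and ionic strength reflects the whole
pseudoisomer group of each compound.  The inverse Legendre transform strips
the pH/ionic-strength dependence and returns the Gibbs energy of the reaction
written over single reference species - the quantity linear regression needs.
"""

import math

from ccgibbs import Conditions, SpeciesRecord, keq_to_dg, reverse_transform_reaction
from ccgibbs.thermo import R_KJ_PER_MOL_K, transform_reaction

RT = R_KJ_PER_MOL_K * 298.15
cond = Conditions(T=298.15, pH=7.0, ionic_strength=0.25)

# A -> B where B is protonatable with pKa 6.8 (two microspecies)
rt_ln10 = RT * math.log(10.0)
species_db = {
    "A": [SpeciesRecord("A", 0.0, n_h=5, z=-1, is_reference=True)],
    "B": [
        SpeciesRecord("B", 0.0, n_h=5, z=-2, is_reference=True),
        SpeciesRecord("B", -rt_ln10 * 6.8, n_h=6, z=-1),
    ],
}
reaction = {"A": -1.0, "B": 1.0}

k_prime = 2.75e3
dg_prime = keq_to_dg(k_prime, cond.T)
dg_standard = reverse_transform_reaction(reaction, dg_prime, cond, species_db)
dg_prime_back = transform_reaction(reaction, dg_standard, cond, species_db)

print(f"K' = {k_prime:.3g} at pH {cond.pH}, I = {cond.ionic_strength} M")
print(f"dG'0 (transformed)   = {dg_prime:8.3f} kJ/mol   # -RT ln K'")
print(f"dG0  (chemical)      = {dg_standard:8.3f} kJ/mol   # inverse Legendre transform")
print(f"dG'0 (round trip)    = {dg_prime_back:8.3f} kJ/mol   # forward transform restores it")
print()
print("The difference between dG'0 and dG0 is the per-compound pseudoisomer")
print("correction: proton binding and Debye-Huckel activity terms.")
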