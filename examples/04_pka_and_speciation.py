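"""Thermodynamic-cycle pKa and charge-state populations versus pH.

Builds solution Gibbs energies that encode chloroquine's published pKa
pair (7.51 / 12.34) via the deprotonation cycle with
G_aq(H+) = -1111.27 kJ/mol, recovers the pKa values, and maps them to the
fractions of M, [M+H]+ and [M+2H]2+ across pH.  Mefloquine (pKa1 = -7.31)
shows the contrast: essentially no diprotonation at any aqueous pH.
"""

import numpy as np

from driftchem import (
    PKaPair,
    crossover_ph,
    ph_of_max_monoprotonated,
    speciation,
)
from driftchem.synthetic import _thermo_from_pka

triple = _thermo_from_pka("CQ", 7.51, 12.34, 298.15)
pair = triple.pka_pair()
print(f"CQ: pKa1 {pair.pka1:.2f}, pKa2 {pair.pka2:.2f} "
      "(recovered from the Gibbs-energy cycle)")
print(f"    dication/monocation equal abundance at pH "
      f"{crossover_ph(pair, 'MH2-MH'):.2f}")
print(f"    monocation maximal at pH {ph_of_max_monoprotonated(pair):.3f}")
c = speciation(pair, [7.4])
print(f"    at physiological pH 7.4: alpha_MH2 {c.alpha_MH2[0]:.3f}, "
      f"alpha_MH {c.alpha_MH[0]:.3f}, alpha_M {c.alpha_M[0]:.2e}")

mq = PKaPair(-7.31, 7.96)
c = speciation(mq, np.array([0.0, 7.4]))
print(f"MQ: alpha_MH2 at pH 0 = {c.alpha_MH2[0]:.2e} "
      "(no diprotonation even in strong acid)")
print(f"    monocation/neutral crossover at pH {crossover_ph(mq, 'MH-M'):.2f}")
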