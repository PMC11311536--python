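# Default Lennard-Jones (12,6) parameters per element for the ion-N2
# interaction, derived from the UFF van-der-Waals set (well depth converted
# kcal->kJ; vdW minimum distance x converted to sigma = x / 2^(1/6)).
# Override any entry (or add elements) with your own table; these are
# generic starting values, not a calibrated N2 CCS parameterization.
# "X" is the synthetic bead element used by the scenario generator.
H:  {epsilon_kJmol: 0.184, sigma_A: 2.571}
C:  {epsilon_kJmol: 0.439, sigma_A: 3.431}
N:  {epsilon_kJmol: 0.289, sigma_A: 3.261}
O:  {epsilon_kJmol: 0.251, sigma_A: 3.118}
F:  {epsilon_kJmol: 0.209, sigma_A: 2.997}
P:  {epsilon_kJmol: 1.276, sigma_A: 3.695}
S:  {epsilon_kJmol: 1.146, sigma_A: 3.595}
Cl: {epsilon_kJmol: 0.950, sigma_A: 3.516}
Br: {epsilon_kJmol: 1.050, sigma_A: 3.732}
I:  {epsilon_kJmol: 1.420, sigma_A: 4.009}
X:  {epsilon_kJmol: 0.500, sigma_A: 3.400}
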