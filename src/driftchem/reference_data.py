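"""Published reference values for nine quinoline antimalarial drugs.

Transcribed constants from the drift-tube ion-mobility / DFT study of
amodiaquine (AQ), chloroquine (CQ), quinacrine (QR), pamaquine (PQ),
primaquine (PR), sitamaquine (SQ), quinine (QN), cinchonine (CIN) and
mefloquine (MQ):

* ``CCS_PAIRS`` — assigned (trajectory-method calculated, drift-tube
  experimental) nitrogen CCS pairs for the monoprotonated species, Å².
* ``PKA_TABLE`` — computed pKa1/pKa2 (deprotonation of [M+2H]²⁺ and
  [M+H]⁺ respectively) from the thermodynamic cycle in water.

These are *inputs* for worked examples and regression checks, not outputs
of this package; per-conformer quantum-chemistry energies behind them are
not reproducible at desk scale.
"""

from __future__ import annotations

from .acidbase import PKaPair

__all__ = ["CCS_PAIRS", "PKA_TABLE", "pka_pair"]

# molecule, assigned protonation site, CCS_calc (Å²), CCS_exp (Å²)
CCS_PAIRS: list[tuple[str, str, float, float]] = [
    ("AQ", "a", 192.9, 193.7),   # major peak, most stable conformer
    ("AQ", "a", 187.2, 186.1),   # minor peak, second conformer
    ("CQ", "b", 173.0, 175.3),
    ("QR", "a", 191.4, 195.3),
    ("PQ", "b", 175.5, 175.6),
    ("SQ", "b", 179.8, 182.9),
    ("PR", "a", 155.1, 159.1),   # minor high-resolution peak
    ("QN", "b", 174.5, 176.9),
    ("CIN", "b", 165.5, 166.8),
    ("QN", "other", 180.1, 183.9),   # OH-protonated gas-phase species
    ("CIN", "other", 174.5, 176.2),  # OH-protonated gas-phase species
]

# molecule -> (pKa1, pKa2)
PKA_TABLE: dict[str, tuple[float, float]] = {
    "AQ": (6.21, 10.27),
    "CQ": (7.51, 12.34),
    "QR": (8.78, 12.79),
    "PQ": (2.03, 12.54),
    "PR": (0.23, 10.69),
    "SQ": (3.11, 12.03),
    "QN": (3.46, 10.63),
    "CIN": (3.33, 9.74),
    "MQ": (-7.31, 7.96),
}


def pka_pair(molecule: str) -> PKaPair:
    """Reference :class:`~driftchem.acidbase.PKaPair` for a drug."""
    pka1, pka2 = PKA_TABLE[molecule]
    return PKaPair(pka1=pka1, pka2=pka2)
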