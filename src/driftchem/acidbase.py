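"""Thermodynamic-cycle pKa and diprotic charge-state speciation.

The pKa of an acid HA follows from solution-phase Gibbs energies via

    ΔG_deprot = G_aq(A) + G_aq(H⁺) − G_aq(HA),   pKa = ΔG_deprot / (RT ln 10)

with G_aq(H⁺) = −1111.27 kJ/mol (−265.6 kcal/mol).  The literature quotes
the magnitude of the aqueous proton free energy; the cycle requires the
negative value, which is what this module uses internally.

For a diprotic base M (species M, MH⁺, MH₂²⁺) the equilibrium fractions at
a given pH follow the classical closed form with h = 10^−pH,
K₁ = 10^−pKa1 (deprotonation of MH₂²⁺), K₂ = 10^−pKa2 (deprotonation of
MH⁺):

    D = h² + K₁h + K₁K₂
    α_MH2 = h²/D,  α_MH = K₁h/D,  α_M = K₁K₂/D

evaluated in log space so extreme pKa values (e.g. pKa1 ≈ −7) cannot
overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import KCAL_TO_KJ, PROTON_GAQ_KCAL, R_KJ

LN10 = np.log(10.0)

__all__ = [
    "PKaPair",
    "SpeciationCurve",
    "ThermoTriple",
    "crossover_ph",
    "ph_of_max_monoprotonated",
    "pka_from_gibbs",
    "proton_gaq_constant",
    "speciation",
]


def proton_gaq_constant(unit: str = "kJ") -> float:
    """Magnitude of the aqueous proton Gibbs energy, in 'kcal' or 'kJ'.

    The kJ value is the conventional 2-decimal rounding of
    265.6 kcal/mol × 4.184.
    """
    if unit == "kcal":
        return PROTON_GAQ_KCAL
    if unit == "kJ":
        return round(PROTON_GAQ_KCAL * KCAL_TO_KJ, 2)
    raise ValueError(f"unknown unit {unit!r}; use 'kcal' or 'kJ'")


def pka_from_gibbs(g_aq_conjbase: float, g_aq_acid: float, T: float = 298.15) -> float:
    """pKa of the acid from solution Gibbs energies of acid and conjugate base.

    Parameters are in kJ/mol; the aqueous proton free energy −1111.27 kJ/mol
    is added internally.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    g_proton_aq = -proton_gaq_constant("kJ")
    dg_deprot = g_aq_conjbase + g_proton_aq - g_aq_acid
    return dg_deprot / (R_KJ * T * LN10)


@dataclass
class ThermoTriple:
    """Solution Gibbs energies of M, MH⁺ and (optionally) MH₂²⁺, kJ/mol."""

    molecule: str
    g_aq_M: float
    g_aq_MH: float
    g_aq_MH2: float | None = None
    h_gas_prot: float | None = None
    g_gas_prot: float | None = None
    temperature: float = 298.15

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def pka_pair(self) -> "PKaPair":
        """Both dissociation constants; pKa1 requires the diprotonated G."""
        pka2 = pka_from_gibbs(self.g_aq_M, self.g_aq_MH, self.temperature)
        if self.g_aq_MH2 is None:
            raise ValueError(
                f"{self.molecule}: g_aq_MH2 missing, pKa1 not computable"
            )
        pka1 = pka_from_gibbs(self.g_aq_MH, self.g_aq_MH2, self.temperature)
        return PKaPair(pka1=pka1, pka2=pka2)


@dataclass(frozen=True)
class PKaPair:
    """pKa1 (deprotonation of MH₂²⁺) and pKa2 (deprotonation of MH⁺)."""

    pka1: float
    pka2: float

    def __post_init__(self):
        if not (np.isfinite(self.pka1) and np.isfinite(self.pka2)):
            raise ValueError("pKa values must be finite")


@dataclass
class SpeciationCurve:
    """Charge-state fractions over a pH grid; fractions sum to 1 pointwise."""

    ph: np.ndarray
    alpha_MH2: np.ndarray
    alpha_MH: np.ndarray
    alpha_M: np.ndarray

    def as_dict(self):
        return {
            "pH": self.ph,
            "alpha_MH2": self.alpha_MH2,
            "alpha_MH": self.alpha_MH,
            "alpha_M": self.alpha_M,
        }


def speciation(pka: PKaPair, ph) -> SpeciationCurve:
    """Diprotic α fractions on a pH grid, computed overflow-safe in log space."""
    ph = np.atleast_1d(np.asarray(ph, dtype=float))
    if not np.all(np.isfinite(ph)):
        raise ValueError("pH grid must be finite")
    # log10 of the three D terms: h², K₁h, K₁K₂
    t = np.stack(
        [
            -2.0 * ph,
            -pka.pka1 - ph,
            np.full_like(ph, -pka.pka1 - pka.pka2),
        ]
    ) * LN10
    log_d = logsumexp(t, axis=0)
    alphas = np.exp(t - log_d)
    return SpeciationCurve(
        ph=ph, alpha_MH2=alphas[0], alpha_MH=alphas[1], alpha_M=alphas[2]
    )


_CROSSOVER_PAIRS = ("MH2-MH", "MH-M", "MH2-M")


def crossover_ph(pka: PKaPair, pair: str) -> float:
    """pH where two species have equal abundance (analytic).

    'MH2-MH' → pKa1, 'MH-M' → pKa2, 'MH2-M' → (pKa1+pKa2)/2; all exact
    consequences of the α ratios (α_MH2/α_MH = h/K₁ etc.).
    """
    if pair == "MH2-MH":
        return pka.pka1
    if pair == "MH-M":
        return pka.pka2
    if pair == "MH2-M":
        return 0.5 * (pka.pka1 + pka.pka2)
    raise ValueError(f"unknown species pair {pair!r}; use one of {_CROSSOVER_PAIRS}")


def ph_of_max_monoprotonated(pka: PKaPair) -> float:
    """pH maximizing the monoprotonated fraction: (pKa1 + pKa2)/2."""
    return 0.5 * (pka.pka1 + pka.pka2)
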