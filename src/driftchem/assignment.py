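"""Match ion-mobility peaks to candidate protomers/conformers.

The assignment rule is "energy-first within a CCS gate": for each
experimental peak, candidates whose calculated CCS lies within a percent
bias threshold of the peak's experimental CCS are eligible, and the
eligible candidate with the lowest Gibbs energy (solution phase for
ESI-like data, gas phase for APCI-like data) wins.  Ties break on smaller
bias, then lexicographic candidate id.  Boltzmann weights over the whole
ensemble report each candidate's equilibrium population at the ensemble
temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_io import CandidateStructure, Ensemble
from .constants import R_KJ
from .mobility import IMPeak

__all__ = [
    "Assignment",
    "AssignmentReport",
    "assign",
    "boltzmann_weights",
    "percent_bias",
]


def percent_bias(ccs_calc: float, ccs_exp: float) -> float:
    """Unsigned percent deviation 100·|calc − exp|/exp of calculated from
    experimental CCS."""
    if ccs_calc <= 0 or ccs_exp <= 0:
        raise ValueError("CCS values must be positive")
    return 100.0 * abs(ccs_calc - ccs_exp) / ccs_exp


def boltzmann_weights(g_values, T: float = 298.15) -> np.ndarray:
    """Equilibrium population fractions exp(−ΔG/RT), normalized to 1.

    Invariant under adding a constant to all G values; lower G never gets
    a smaller weight.
    """
    g = np.asarray(list(g_values), dtype=float)
    if g.size == 0:
        raise ValueError("need at least one Gibbs energy")
    if not np.all(np.isfinite(g)):
        raise ValueError("Gibbs energies must be finite")
    if T <= 0:
        raise ValueError("temperature must be positive")
    x = -(g - g.min()) / (R_KJ * T)
    w = np.exp(x)
    return w / w.sum()


@dataclass
class Assignment:
    """One peak ↔ candidate link."""

    peak: IMPeak
    candidate_id: str
    bias_percent: float
    rank_by_energy: int          # 1 = most stable in the ensemble
    boltzmann_weight: float      # ensemble population fraction
    phase_used: str              # 'gas' or 'aq'

    def __post_init__(self):
        if not (0.0 <= self.boltzmann_weight <= 1.0):
            raise ValueError("boltzmann weight must lie in [0, 1]")
        if self.bias_percent < 0:
            raise ValueError("bias must be non-negative")


@dataclass
class AssignmentReport:
    """All peaks of one molecule, each assigned or explicitly unassigned."""

    molecule: str
    assignments: list[Assignment] = field(default_factory=list)
    unassigned_peaks: list[IMPeak] = field(default_factory=list)
    bias_min: float | None = None
    bias_max: float | None = None
    shared_candidates: list[str] = field(default_factory=list)

    @property
    def n_peaks(self) -> int:
        return len(self.assignments) + len(self.unassigned_peaks)


def _phase_g(c: CandidateStructure, phase: str) -> float:
    g = c.g_aq if phase == "aq" else c.g_gas
    if g is None:
        raise ValueError(
            f"candidate {c.id!r} has no {phase}-phase Gibbs energy"
        )
    return g


def assign(
    peaks: list[IMPeak],
    ensemble: Ensemble,
    bias_threshold: float = 3.0,
    phase: str = "aq",
) -> AssignmentReport:
    """Assign each peak to the most stable candidate within the CCS gate.

    Parameters
    ----------
    peaks:
        Picked peaks carrying experimental CCS values.
    ensemble:
        Candidates; every one must carry ``ccs_calc`` and the chosen
        phase's Gibbs energy.
    bias_threshold:
        CCS gate in percent (default 3.0, slightly above the bias range
        typical of trajectory-method calculations against drift-tube data).
    phase:
        'aq' ranks by solution Gibbs energy (thermodynamically controlled
        protonation, ESI-like), 'gas' by gas-phase energy (APCI-like).
    """
    if not peaks:
        raise ValueError("no peaks to assign")
    if phase not in ("gas", "aq"):
        raise ValueError("phase must be 'gas' or 'aq'")
    for c in ensemble:
        if c.ccs_calc is None:
            raise ValueError(
                f"candidate {c.id!r} has no calculated CCS; run the ccs stage first"
            )
    g_all = np.array([_phase_g(c, phase) for c in ensemble])
    weights = boltzmann_weights(g_all, ensemble.temperature)
    order = np.argsort(g_all, kind="stable")
    rank = {ensemble.candidates[int(i)].id: r + 1 for r, i in enumerate(order)}
    wmap = {c.id: float(w) for c, w in zip(ensemble, weights)}

    assignments: list[Assignment] = []
    unassigned: list[IMPeak] = []
    used: dict[str, int] = {}
    for peak in peaks:
        eligible = []
        for c in ensemble:
            bias = percent_bias(c.ccs_calc, peak.ccs_exp)
            if bias <= bias_threshold:
                eligible.append((_phase_g(c, phase), bias, c.id))
        if not eligible:
            unassigned.append(peak)
            continue
        g, bias, cid = min(eligible)  # lowest G, then smallest bias, then id
        used[cid] = used.get(cid, 0) + 1
        assignments.append(
            Assignment(
                peak=peak,
                candidate_id=cid,
                bias_percent=bias,
                rank_by_energy=rank[cid],
                boltzmann_weight=wmap[cid],
                phase_used=phase,
            )
        )
    biases = [a.bias_percent for a in assignments]
    return AssignmentReport(
        molecule=ensemble.molecule,
        assignments=assignments,
        unassigned_peaks=unassigned,
        bias_min=min(biases) if biases else None,
        bias_max=max(biases) if biases else None,
        shared_candidates=[cid for cid, n in used.items() if n > 1],
    )
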