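"""Synthetic inputs with the statistical structure the pipeline assumes.

Real inputs to this pipeline are quantum-chemistry outputs (optimized
protomer/conformer geometries, fitted charges, Gibbs energies) and
drift-tube arrival-time distributions.  This module emulates both at desk
scale: self-avoiding bead-chain "molecules" stand in for drug geometries,
conformer ensembles carry controlled energy gaps and CCS separations,
thermochemistry is planted by inverting the pKa cycle, and drift spectra
are sums of Gaussian peaks with seeded noise.  Every scenario ships a
truth record naming the generating candidate behind each peak, so
recovery tests never re-derive ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .acidbase import LN10, ThermoTriple, proton_gaq_constant
from .assignment import boltzmann_weights
from .chem_io import Atom, CandidateStructure, Ensemble
from .constants import R_KJ
from .mobility import DriftSpectrum, InstrumentConfig, drift_from_ccs

__all__ = ["ScenarioSpec", "make_bead_molecule", "make_scenario"]

SITE_CYCLE = ("a", "b", "c")


def make_bead_molecule(
    n_beads: int,
    bond_length: float = 1.5,
    radius_scale: float = 3.4,
    net_charge: float = 0.0,
    seed: int = 0,
    mode: str = "compact",
    molecule: str = "bead",
    structure_id: str = "bead-0",
    site_label: str = "none",
    max_retries: int = 2000,
) -> CandidateStructure:
    """Self-avoiding random bead chain of the synthetic element X.

    ``mode='extended'`` biases successive bond directions into a narrow
    forward cone (stretched chains); ``'compact'`` draws directions
    uniformly (collapsed coils).  Integer units of the net charge sit on
    well-separated beads; any fractional remainder is spread evenly.
    Deterministic for a given seed.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    rng = np.random.default_rng(seed)
    pos = np.zeros((n_beads, 3))
    direction = np.array([1.0, 0.0, 0.0])
    min_sep = 0.9 * bond_length
    for i in range(1, n_beads):
        placed = False
        for _ in range(max_retries):
            if mode == "extended":
                step = direction + 0.35 * rng.normal(size=3)
            elif mode == "compact":
                step = rng.normal(size=3)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            step /= np.linalg.norm(step)
            cand = pos[i - 1] + bond_length * step
            if i < 2 or np.min(
                np.linalg.norm(pos[: i - 1] - cand, axis=1)
            ) >= min_sep:
                pos[i] = cand
                direction = step
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"self-avoiding placement failed for bead {i} after "
                f"{max_retries} retries"
            )
    z = int(round(net_charge))
    charges = np.zeros(n_beads)
    if z > 0:
        carriers = np.linspace(0, n_beads - 1, num=min(z, n_beads)).astype(int)
        for c in carriers:
            charges[c] += 1.0
    charges += (net_charge - charges.sum()) / n_beads
    atoms = [
        Atom("X", tuple(map(float, pos[i])), float(charges[i]),
             lj_epsilon=0.5, lj_sigma=radius_scale)
        for i in range(n_beads)
    ]
    return CandidateStructure(
        id=structure_id,
        molecule=molecule,
        charge_state=max(z, 0),
        site_label=site_label,
        atoms=atoms,
    )


@dataclass
class ScenarioSpec:
    """Controls for one synthetic study: ensemble, spectra, thermochemistry.

    Defaults emulate the study conditions of the drug data this pipeline
    targets: a handful of protomers with ~10 conformers total, solution
    energy gaps of a few kJ/mol, CCS values near 150 Å² separated by a few
    percent, drift peaks at high signal-to-noise, and a weakly basic
    diprotic compound (pKa ≈ 7.5 / 12.3).
    """

    n_protomers: int = 2
    conformers_per_protomer: int = 2
    energy_gap_distribution: tuple[str, tuple[float, ...]] = ("uniform", (2.0, 8.0))
    ccs_base: float = 150.0        # Å²
    ccs_separation: float = 6.0    # Å² between adjacent candidates
    ccs_noise_sd: float = 0.5      # Å² noise on the *calculated* CCS
    planted_pka: tuple[float, float] = (7.51, 12.34)
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    snr: float = 100.0
    n_beads: int = 12
    molecule: str = "SYN"
    temperature: float = 298.15
    seed: int = 0

    def __post_init__(self):
        if self.n_protomers < 1 or self.conformers_per_protomer < 1:
            raise ValueError("counts must be >= 1")
        if self.ccs_noise_sd < 0:
            raise ValueError("ccs_noise_sd must be >= 0")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


def _draw_gap(rng, dist) -> float:
    kind, params = dist
    if kind == "fixed":
        return float(params[0])
    if kind == "uniform":
        return float(rng.uniform(params[0], params[1]))
    if kind == "exponential":
        return float(rng.exponential(params[0]))
    raise ValueError(f"unknown energy gap distribution {kind!r}")


def _thermo_from_pka(molecule: str, pka1: float, pka2: float,
                     T: float) -> ThermoTriple:
    """Invert the thermodynamic cycle: G values that reproduce the pKas."""
    g_proton = -proton_gaq_constant("kJ")
    rt_ln10 = R_KJ * T * LN10
    g_m = 0.0
    g_mh = g_m + g_proton - pka2 * rt_ln10
    g_mh2 = g_mh + g_proton - pka1 * rt_ln10
    return ThermoTriple(
        molecule=molecule, g_aq_M=g_m, g_aq_MH=g_mh, g_aq_MH2=g_mh2,
        temperature=T,
    )


def make_scenario(
    spec: ScenarioSpec,
) -> tuple[Ensemble, list[DriftSpectrum], ThermoTriple, dict[str, Any]]:
    """Build one synthetic study: ensemble + spectra + thermo + truth record.

    Each protomer's most stable conformer generates one drift peak with
    intensity proportional to the protomer's Boltzmann population.  True
    CCS values are planted analytically (base + index·separation); the
    candidates' *calculated* CCS carry Gaussian noise of sd
    ``ccs_noise_sd`` to mimic method error.  The truth record lists the
    generating candidate per peak and flags peaks too close to resolve.
    """
    rng = np.random.default_rng(spec.seed)
    candidates: list[CandidateStructure] = []
    true_ccs: dict[str, float] = {}
    generators: list[str] = []
    g_protomer = 0.0
    idx = 0
    for p in range(spec.n_protomers):
        if p > 0:
            g_protomer += _draw_gap(rng, spec.energy_gap_distribution)
        g_conf = g_protomer
        for c in range(spec.conformers_per_protomer):
            if c > 0:
                g_conf += _draw_gap(rng, spec.energy_gap_distribution)
            cid = f"p{p}c{c}"
            mol = make_bead_molecule(
                spec.n_beads,
                net_charge=1.0,
                seed=int(rng.integers(2**31 - 1)),
                molecule=spec.molecule,
                structure_id=cid,
                site_label=SITE_CYCLE[p % len(SITE_CYCLE)],
            )
            ccs_true = spec.ccs_base + idx * spec.ccs_separation
            ccs_noisy = ccs_true + rng.normal(0.0, spec.ccs_noise_sd)
            mol.g_aq = g_conf
            mol.g_gas = g_conf + float(rng.uniform(-1.0, 1.0))
            mol.ccs_calc = float(ccs_noisy)
            candidates.append(mol)
            true_ccs[cid] = ccs_true
            if c == 0:
                generators.append(cid)
            idx += 1
    ensemble = Ensemble(
        molecule=spec.molecule, candidates=candidates,
        temperature=spec.temperature,
    )

    # one [M+H]+ spectrum: a Gaussian peak per protomer's generator
    ion_mass = candidates[0].mass
    mz = ion_mass / 1.0
    times = np.arange(1.0, 60.0, 0.02)
    clean = np.zeros_like(times)
    peak_truth = []
    g_gen = np.array([ensemble.get(cid).g_aq for cid in generators])
    pops = boltzmann_weights(g_gen, spec.temperature)
    fwhm_rel = 0.02  # instrument resolving power ~50 in t-space
    centers = []
    for cid, pop in zip(generators, pops):
        td = drift_from_ccs(true_ccs[cid], spec.instrument, ion_mass, 1)
        sigma = fwhm_rel * td / 2.3548
        clean += 1000.0 * pop * np.exp(-0.5 * ((times - td) / sigma) ** 2)
        centers.append(td)
        peak_truth.append(
            {"candidate_id": cid, "ccs_true": true_ccs[cid],
             "drift_time_ms": float(td), "population": float(pop)}
        )
    noise_sd = clean.max() / spec.snr if clean.max() > 0 else 1.0
    for p in peak_truth:
        amp = 1000.0 * p["population"]
        p["amplitude"] = amp
        p["detectable"] = bool(amp > 5.0 * noise_sd)
    noisy = clean + rng.normal(0.0, noise_sd, size=times.size)
    spectrum = DriftSpectrum(
        times=times, intensities=np.clip(noisy, 0.0, None),
        mz=mz, charge_state=1, instrument=spec.instrument,
    )

    thermo = _thermo_from_pka(
        spec.molecule, spec.planted_pka[0], spec.planted_pka[1],
        spec.temperature,
    )

    warnings = []
    centers = sorted(centers)
    for a, b in zip(centers, centers[1:]):
        if (b - a) < fwhm_rel * b:
            warnings.append(
                f"peaks at {a:.3f} and {b:.3f} ms closer than one FWHM"
            )
    if spec.ccs_noise_sd > 0 and spec.ccs_separation < 3 * spec.ccs_noise_sd:
        warnings.append("CCS separation below 3x the planted CCS noise")
    truth = {
        "molecule": spec.molecule,
        "seed": spec.seed,
        "planted_pka": list(spec.planted_pka),
        "peaks": peak_truth,
        "true_ccs": true_ccs,
        "warnings": warnings,
    }
    return ensemble, [spectrum], thermo, truth
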