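"""Single-field drift-tube conversions and arrival-time-distribution peaks.

For a uniform-field drift tube the measured drift time gives the mobility
K = L²/(V·t_d); reduced to standard conditions,
K₀ = K·(P/760)·(273.15/T).  The Mason–Schamp relation then links mobility
to the momentum-transfer collision cross section:

    Ω = (3 z e / 16 N₀) · √(2π / (μ k_B T)) · 1/K₀

with μ the ion–buffer-gas reduced mass and N₀ the gas number density at
273.15 K / 760 Torr.  Drift length and voltage are instrument configuration
(they are not universal constants), and a constant non-drift residence time
t₀ may be subtracted from raw arrival times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .constants import (
    ATOMIC_MASS_KG,
    BOLTZMANN_SI,
    ELEMENTARY_CHARGE,
    N0_STANDARD,
)

__all__ = [
    "DriftSpectrum",
    "IMPeak",
    "InstrumentConfig",
    "ccs_from_drift",
    "drift_from_ccs",
    "pick_peaks",
    "read_spectrum",
    "write_spectrum",
]

N2_MASS_U = 28.0134


@dataclass(frozen=True)
class InstrumentConfig:
    """Drift-tube geometry and operating conditions.

    Defaults are typical of commercial ~78 cm single-field drift tubes run
    with nitrogen near 4 Torr; length and voltage must be set to the actual
    instrument values for quantitative work.
    """

    drift_length: float = 78.1    # cm
    drift_voltage: float = 1570.0  # V
    pressure: float = 3.94        # Torr
    temperature: float = 300.0    # K
    gas_mass: float = N2_MASS_U   # u
    t0: float = 0.0               # ms, non-drift residence time

    def __post_init__(self):
        if min(self.drift_length, self.drift_voltage, self.gas_mass) <= 0:
            raise ValueError("drift length, voltage and gas mass must be positive")
        if not (0.5 <= self.pressure <= 20.0):
            raise ValueError(f"pressure {self.pressure} Torr outside 0.5–20 Torr")
        if not (200.0 <= self.temperature <= 400.0):
            raise ValueError(f"temperature {self.temperature} K outside 200–400 K")


def _omega_prefactor(instrument: InstrumentConfig, ion_mass: float, z: int) -> float:
    """Ω·t_d⁻¹ proportionality (Å² per ms) for this instrument and ion."""
    mu_kg = (
        ion_mass * instrument.gas_mass / (ion_mass + instrument.gas_mass)
    ) * ATOMIC_MASS_KG
    # K for t_d = 1 ms, in cm²/(V s)
    k_unit = instrument.drift_length**2 / (instrument.drift_voltage * 1.0e-3)
    k0_unit = (
        k_unit
        * (instrument.pressure / 760.0)
        * (273.15 / instrument.temperature)
        * 1.0e-4  # m²/(V s)
    )
    omega_m2 = (
        (3.0 * z * ELEMENTARY_CHARGE / (16.0 * N0_STANDARD))
        * math.sqrt(2.0 * math.pi / (mu_kg * BOLTZMANN_SI * instrument.temperature))
        / k0_unit
    )
    return omega_m2 * 1.0e20  # Å² at t_d = 1 ms; Ω scales linearly with t_d


def ccs_from_drift(
    t_d: float, instrument: InstrumentConfig, ion_mass: float, z: int
) -> float:
    """CCS (Å²) from drift time (ms) via the Mason–Schamp chain.

    ``t_d`` is the true drift time (instrument t0 already subtracted by the
    caller or configured on the instrument as 0).
    """
    if t_d <= 0:
        raise ValueError("drift time must be positive")
    if z == 0:
        raise ValueError("charge state must be non-zero")
    return _omega_prefactor(instrument, ion_mass, z) * t_d


def drift_from_ccs(
    ccs: float, instrument: InstrumentConfig, ion_mass: float, z: int
) -> float:
    """Drift time (ms) producing the given CCS (Å²); exact inverse of
    :func:`ccs_from_drift`."""
    if ccs <= 0:
        raise ValueError("CCS must be positive")
    if z == 0:
        raise ValueError("charge state must be non-zero")
    return ccs / _omega_prefactor(instrument, ion_mass, z)


@dataclass
class DriftSpectrum:
    """An m/z-selected arrival-time distribution."""

    times: np.ndarray        # ms, strictly increasing
    intensities: np.ndarray  # counts, >= 0
    mz: float                # Th
    charge_state: int
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def ion_mass(self) -> float:
        """Ion mass in u (m/z times charge; electron mass neglected)."""
        return self.mz * self.charge_state


@dataclass
class IMPeak:
    """A picked arrival-time peak with its derived experimental CCS."""

    drift_time: float  # ms
    intensity: float
    fwhm: float        # ms
    ccs_exp: float     # Å²

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")


def _gaussian(t, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def pick_peaks(
    spectrum: DriftSpectrum,
    min_rel_intensity: float = 0.05,
    min_separation: float = 0.2,
) -> list[IMPeak]:
    """Detect and centroid Gaussian peaks in an arrival-time distribution.

    Local maxima above ``min_rel_intensity``·max and at least
    ``min_separation`` ms apart are refined by a Gaussian fit over a ±FWHM
    window; each peak is annotated with its Mason–Schamp CCS.  A flat or
    sub-threshold trace yields an empty list.
    """
    t, y = spectrum.times, spectrum.intensities
    ymax = float(y.max(initial=0.0))
    if ymax <= 0:
        return []
    dt = float(np.median(np.diff(t)))
    distance = max(1, int(round(min_separation / dt)))
    idx, _ = find_peaks(y, height=min_rel_intensity * ymax, distance=distance)
    peaks: list[IMPeak] = []
    for i in idx:
        # crude FWHM from half-max crossings around the apex
        half = y[i] / 2.0
        lo = i
        while lo > 0 and y[lo] > half:
            lo -= 1
        hi = i
        while hi < len(y) - 1 and y[hi] > half:
            hi += 1
        fwhm0 = max(t[hi] - t[lo], 2 * dt)
        sel = (t >= t[i] - fwhm0) & (t <= t[i] + fwhm0)
        sigma0 = fwhm0 / 2.3548
        try:
            popt, _ = curve_fit(
                _gaussian,
                t[sel],
                y[sel],
                p0=[y[i], t[i], sigma0],
                maxfev=2000,
            )
            amp, mu, sigma = popt[0], popt[1], abs(popt[2])
            if not (t[0] <= mu <= t[-1]) or amp <= 0:
                raise RuntimeError
        except RuntimeError:
            amp, mu, sigma = y[i], t[i], sigma0
        td = mu - spectrum.instrument.t0
        if td <= 0:
            continue
        ccs = ccs_from_drift(
            td, spectrum.instrument, spectrum.ion_mass, spectrum.charge_state
        )
        peaks.append(
            IMPeak(
                drift_time=float(mu),
                intensity=float(amp),
                fwhm=float(2.3548 * sigma),
                ccs_exp=float(ccs),
            )
        )
    peaks.sort(key=lambda p: p.drift_time)
    # merge refined centroids that collapsed onto the same peak
    merged: list[IMPeak] = []
    for p in peaks:
        if merged and p.drift_time - merged[-1].drift_time < min_separation:
            if p.intensity > merged[-1].intensity:
                merged[-1] = p
        else:
            merged.append(p)
    return merged


def write_spectrum(spectrum: DriftSpectrum, path: str | Path) -> None:
    """Write a spectrum as two-column text with a YAML header block."""
    header = {
        "mz": spectrum.mz,
        "z": spectrum.charge_state,
        "instrument": {
            "drift_length": spectrum.instrument.drift_length,
            "drift_voltage": spectrum.instrument.drift_voltage,
            "pressure": spectrum.instrument.pressure,
            "temperature": spectrum.instrument.temperature,
            "gas_mass": spectrum.instrument.gas_mass,
            "t0": spectrum.instrument.t0,
        },
    }
    lines = [
        "# " + ln for ln in yaml.safe_dump(header, sort_keys=True).strip().splitlines()
    ]
    for t, y in zip(spectrum.times, spectrum.intensities):
        lines.append(f"{t:.6f}\t{y:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum(path: str | Path) -> DriftSpectrum:
    """Read a spectrum written by :func:`write_spectrum`."""
    header_lines, data = [], []
    for ln in Path(path).read_text().splitlines():
        if ln.startswith("#"):
            # strip exactly the comment prefix; YAML nesting needs the indent
            header_lines.append(ln[2:] if ln.startswith("# ") else ln[1:])
        elif ln.strip():
            parts = ln.split()
            data.append((float(parts[0]), float(parts[1])))
    meta = yaml.safe_load("\n".join(header_lines)) or {}
    inst = InstrumentConfig(**meta.get("instrument", {}))
    arr = np.array(data)
    return DriftSpectrum(
        times=arr[:, 0],
        intensities=arr[:, 1],
        mz=float(meta["mz"]),
        charge_state=int(meta["z"]),
        instrument=inst,
    )
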