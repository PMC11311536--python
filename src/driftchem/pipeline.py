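"""End-to-end orchestration: ccs → peaks → assignment → pKa → speciation.

Every stage writes a tidy TSV/CSV/JSON artifact with floats formatted at 6
significant digits, so re-running with the same config and seed is
byte-identical.  Stage failures raise :class:`PipelineError` naming the
stage; partial outputs written before the failure are retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acidbase import PKaPair, ThermoTriple, speciation
from .assignment import AssignmentReport, assign
from .ccs_engine import TMSettings, nitrogen_gas, pa_ccs, tm_ccs
from .chem_io import Ensemble, read_ensemble
from .mobility import IMPeak, pick_peaks, read_spectrum

__all__ = ["PipelineError", "RunConfig", "run_all"]


class PipelineError(RuntimeError):
    """A stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class RunConfig:
    """Inputs, thresholds and toggles for one molecule-level run."""

    ensemble_path: str | Path
    out_dir: str | Path
    spectra_paths: list[str | Path] = field(default_factory=list)
    peaks_path: str | Path | None = None   # pre-picked peaks: skip calibrate
    thermo_path: str | Path | None = None  # CSV for the pKa stage
    compute_ccs: bool = False
    ccs_method: str = "pa"                 # 'pa' or 'tm'
    gas_temperature: float = 298.0
    bias_threshold: float = 3.0            # %
    phase: str = "aq"
    min_rel_intensity: float = 0.05
    min_separation: float = 0.2            # ms
    ph_grid: tuple[float, float, float] = (0.0, 14.0, 0.05)
    ph_of_interest: float = 7.4
    seed: int = 0

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        if not Path(self.ensemble_path).exists():
            raise FileNotFoundError(self.ensemble_path)


def _fmt(x) -> str:
    return f"{x:.6g}" if isinstance(x, float) else str(x)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df = df.copy()
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(lambda v: f"{v:.6g}")
    df.to_csv(path, sep="\t", index=False)


def _ccs_stage(ensemble: Ensemble, cfg: RunConfig) -> Ensemble:
    gas = nitrogen_gas(cfg.gas_temperature)
    rows = []
    for i, cand in enumerate(ensemble.candidates):
        if cfg.ccs_method == "pa":
            res = pa_ccs(cand, gas, seed=cfg.seed + i)
        elif cfg.ccs_method == "tm":
            res = tm_ccs(cand, gas, TMSettings(seed=cfg.seed + i))
        else:
            raise ValueError(f"unknown ccs method {cfg.ccs_method!r}")
        ensemble.candidates[i] = cand.with_ccs(res.ccs, res.stderr)
        rows.append(
            {"id": cand.id, "method": res.method, "ccs_A2": res.ccs,
             "stderr_A2": res.stderr, "n": res.n_samples, "seed": res.seed}
        )
    _write_tsv(pd.DataFrame(rows), cfg.out_dir / "ccs.tsv")
    return ensemble


def _peaks_stage(cfg: RunConfig) -> list[IMPeak]:
    peaks: list[IMPeak] = []
    if cfg.peaks_path is not None:
        df = pd.read_csv(cfg.peaks_path, sep="\t")
        for _, row in df.iterrows():
            peaks.append(
                IMPeak(
                    drift_time=float(row["t_d_ms"]),
                    intensity=float(row["intensity"]),
                    fwhm=float(row["fwhm_ms"]),
                    ccs_exp=float(row["ccs_A2"]),
                )
            )
        return peaks
    for sp in cfg.spectra_paths:
        spectrum = read_spectrum(sp)
        peaks.extend(
            pick_peaks(spectrum, cfg.min_rel_intensity, cfg.min_separation)
        )
    rows = [
        {"t_d_ms": p.drift_time, "intensity": p.intensity,
         "fwhm_ms": p.fwhm, "ccs_A2": p.ccs_exp}
        for p in peaks
    ]
    _write_tsv(pd.DataFrame(rows), cfg.out_dir / "peaks.tsv")
    return peaks


def _assign_stage(peaks, ensemble, cfg: RunConfig) -> AssignmentReport:
    report = assign(peaks, ensemble, cfg.bias_threshold, cfg.phase)
    rows = []
    for a in report.assignments:
        rows.append(
            {"t_d_ms": a.peak.drift_time, "ccs_exp_A2": a.peak.ccs_exp,
             "candidate_id": a.candidate_id, "bias_percent": a.bias_percent,
             "rank_by_energy": a.rank_by_energy,
             "boltzmann_weight": a.boltzmann_weight, "phase": a.phase_used}
        )
    for p in report.unassigned_peaks:
        rows.append(
            {"t_d_ms": p.drift_time, "ccs_exp_A2": p.ccs_exp,
             "candidate_id": "", "bias_percent": np.nan,
             "rank_by_energy": -1, "boltzmann_weight": np.nan,
             "phase": cfg.phase}
        )
    _write_tsv(pd.DataFrame(rows), cfg.out_dir / "assignments.tsv")
    return report


def _pka_stage(cfg: RunConfig) -> PKaPair | None:
    if cfg.thermo_path is None:
        return None
    df = pd.read_csv(cfg.thermo_path)
    row = df.iloc[0]
    triple = ThermoTriple(
        molecule=str(row["molecule"]),
        g_aq_M=float(row["g_aq_M"]),
        g_aq_MH=float(row["g_aq_MH"]),
        g_aq_MH2=float(row["g_aq_MH2"]) if "g_aq_MH2" in row else None,
        temperature=float(row.get("temperature", 298.15)),
    )
    pair = triple.pka_pair()
    _write_tsv(
        pd.DataFrame(
            [{"molecule": triple.molecule, "pka1": pair.pka1,
              "pka2": pair.pka2}]
        ),
        cfg.out_dir / "pka.tsv",
    )
    return pair


def _speciate_stage(pair: PKaPair, cfg: RunConfig):
    lo, hi, step = cfg.ph_grid
    ph = np.arange(lo, hi + 0.5 * step, step)
    curve = speciation(pair, ph)
    df = pd.DataFrame(
        {"pH": curve.ph, "alpha_MH2": curve.alpha_MH2,
         "alpha_MH": curve.alpha_MH, "alpha_M": curve.alpha_M}
    )
    _write_tsv(df, cfg.out_dir / "speciation.csv")
    return curve


def run_all(config: RunConfig) -> dict:
    """Execute all configured stages and write a molecule-level summary.

    Returns the summary dict (also written to ``summary.json``): assigned
    site label of the most intense peak, bias range, pKa pair, and whether
    a detectable diprotonated population is expected at the pH of
    interest.
    """
    config.out_dir.mkdir(parents=True, exist_ok=True)
    stage = "read"
    try:
        ensemble = read_ensemble(config.ensemble_path)
        stage = "ccs"
        if config.compute_ccs or any(c.ccs_calc is None for c in ensemble):
            ensemble = _ccs_stage(ensemble, config)
        stage = "calibrate"
        peaks = _peaks_stage(config)
        stage = "assign"
        report = _assign_stage(peaks, ensemble, config)
        stage = "pka"
        pair = _pka_stage(config)
        stage = "speciate"
        curve = None
        if pair is not None:
            curve = _speciate_stage(pair, config)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(stage, str(exc)) from exc

    site_label = None
    if report.assignments:
        top = max(report.assignments, key=lambda a: a.peak.intensity)
        site_label = ensemble.get(top.candidate_id).site_label
    summary = {
        "version": __version__,
        "seed": config.seed,
        "molecule": ensemble.molecule,
        "phase": config.phase,
        "bias_threshold_percent": config.bias_threshold,
        "n_peaks": report.n_peaks,
        "n_assigned": len(report.assignments),
        "assigned_site_label": site_label,
        "assignments": {
            a.candidate_id: float(f"{a.bias_percent:.6g}")
            for a in report.assignments
        },
        "bias_min_percent": (
            float(f"{report.bias_min:.6g}") if report.bias_min is not None else None
        ),
        "bias_max_percent": (
            float(f"{report.bias_max:.6g}") if report.bias_max is not None else None
        ),
    }
    if pair is not None:
        summary["pka1"] = float(f"{pair.pka1:.6g}")
        summary["pka2"] = float(f"{pair.pka2:.6g}")
        from .acidbase import speciation as _spec

        at_ph = _spec(pair, [config.ph_of_interest])
        summary["ph_of_interest"] = config.ph_of_interest
        summary["dication_expected"] = bool(at_ph.alpha_MH2[0] > 1e-3)
    (config.out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
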