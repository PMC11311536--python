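"""End-to-end pipeline on a generated scenario.

Generates a synthetic study (two protomers, two conformers each, planted
energies, CCS values and pKa pair), writes the files a real study would
provide, runs every stage through the pipeline orchestrator, and compares
the summary against the scenario's truth record.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

from driftchem import ScenarioSpec, make_scenario, write_ensemble, write_spectrum
from driftchem.pipeline import RunConfig, run_all

spec = ScenarioSpec(seed=42, planted_pka=(7.51, 12.34))
ensemble, spectra, thermo, truth = make_scenario(spec)

workdir = Path(tempfile.mkdtemp(prefix="driftchem-demo-"))
write_ensemble(ensemble, workdir / "ensemble.xyz")
write_spectrum(spectra[0], workdir / "spectrum.txt")
pd.DataFrame([{
    "molecule": thermo.molecule, "g_aq_M": thermo.g_aq_M,
    "g_aq_MH": thermo.g_aq_MH, "g_aq_MH2": thermo.g_aq_MH2,
    "temperature": thermo.temperature,
}]).to_csv(workdir / "thermo.csv", index=False)

summary = run_all(RunConfig(
    ensemble_path=workdir / "ensemble.xyz",
    spectra_paths=[workdir / "spectrum.txt"],
    thermo_path=workdir / "thermo.csv",
    out_dir=workdir / "out",
    seed=42,
))

print(json.dumps(summary, indent=2, sort_keys=True))
print()
print("truth:", {p["candidate_id"]: round(p["ccs_true"], 1)
                 for p in truth["peaks"]},
      "planted pKa:", truth["planted_pka"])
print("every peak should be assigned to its generating candidate and the "
      "pKa pair recovered exactly; outputs live in", workdir / "out")
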