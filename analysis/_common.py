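"""Shared loader for the analysis scripts: read the simulated cohort."""

from pathlib import Path

from tcrrep.io import read_manifest

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def load_samples():
    manifest = read_manifest(COHORT_DIR / "manifest.tsv")
    samples = [
        manifest.load_sample(row["patient_id"], row["compartment"])
        for _, row in manifest.table.iterrows()
    ]
    return manifest, samples
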