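"""Shared fixtures: tiny hand-built repertoires and a small simulated cohort."""

from __future__ import annotations

import numpy as np
import pytest

from tcrrep.repertoire import Clone, RepertoireSample
from tcrrep.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def toy_sample() -> RepertoireSample:
    clones = [
        Clone("CASSLGQAYEQYF", "TRBV9", "TRBJ2-7", 80),
        Clone("CASSPDRGAYEQYF", "TRBV6-5", "TRBJ2-7", 20),
        Clone("CASRQGAYNEQFF", "TRBV28", "TRBJ2-1", 5),
        Clone("CASSFSTCSANYGYTF", "TRBV27", "TRBJ1-2", 1),
        Clone("CASS*GHTEAFF", "TRBV19", "TRBJ1-1", 3, productive=False),
        Clone("CAWSVWGGETQYF", "TRBV30", "TRBJ2-5", 2, productive=False),
    ]
    return RepertoireSample.from_clones(
        "S1", clones, patient_id="P1", compartment="TUMOR", usable_input=500.0
    )


@pytest.fixture
def random_sample_factory():
    """Build random repertoires with reproducible content."""

    def _make(seed: int = 0, n: int = 40, sample_id: str = "R", **meta) -> RepertoireSample:
        rng = np.random.default_rng(seed)
        aas, seen = [], set()
        while len(aas) < n:
            s = "C" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=int(rng.integers(6, 18)))) + "F"
            if s not in seen:
                seen.add(s)
                aas.append(s)
        vs = [f"TRBV{int(v)}" for v in rng.choice([9, 13, 14, 15, 18, 19, 27, 28, 30], size=n)]
        js = [f"TRBJ{int(a)}-{int(b)}" for a, b in zip(rng.integers(1, 3, n), rng.integers(1, 6, n))]
        ts = rng.geometric(0.05, size=n)
        prod = rng.random(n) > 0.15
        aas = [a if p else a[:4] + "*" + a[5:] for a, p in zip(aas, prod)]
        return RepertoireSample(
            sample_id, cdr3_aa=aas, v_gene=vs, j_gene=js, templates=ts,
            productive=prod, **meta,
        )

    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """Six NSCLC patients with all three compartments, planted virals."""
    config = SimulationConfig(
        n_patients=6,
        clones_per_compartment={"PBMC": 300, "ADJACENT_LUNG": 200, "TUMOR": 250},
        depth={"PBMC": 6000, "ADJACENT_LUNG": 5000, "TUMOR": 5000},
        n_viral_public_clones=20,
        n_viral_motifs=4,
    )
    return simulate_cohort(config, seed=1234)
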