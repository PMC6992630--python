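"""Synthetic multi-compartment TCR repertoire cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes: each
patient carries latent clone populations per compartment (blood, adjacent
lung, tumor) with heavy-tailed clone-size distributions, configurable clone
sharing between compartments, planted viral-specific public clones carrying
known CDR3 motifs and a V-gene bias, multinomial template sampling at a
configurable depth, and survival times whose hazard is log-linear in
standardized repertoire features. Identical config + seed yields
byte-identical output files.

Clone sharing is parameterized by the *target true-set Jaccard index* of each
compartment pair. Planted viral public clones are shared between lung and
tumor on top of that pairwise sharing, so sharing-recovery experiments set
``n_viral_public_clones = 0``. Observed counts are multinomial draws with
replacement from the latent frequencies; no sequencing-error model is
applied because the pipeline operates on already-denoised clonotype tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_manifest, write_rearrangements
from .metrics import clonality_from_frequencies
from .repertoire import AA_ALPHABET, Compartment, RepertoireSample

PBMC = Compartment.PBMC.value
LUNG = Compartment.ADJACENT_LUNG.value
TUMOR = Compartment.TUMOR.value
HEALTHY = Compartment.HEALTHY_LUNG.value
COPD = Compartment.COPD_LUNG.value

#: canonical V/J pools used by the generator (IMGT-style names)
V_GENES = (
    "TRBV2", "TRBV4-1", "TRBV5-1", "TRBV6-1", "TRBV6-5", "TRBV7-2", "TRBV7-9",
    "TRBV9", "TRBV10-3", "TRBV11-2", "TRBV12-5", "TRBV13", "TRBV14", "TRBV15",
    "TRBV18", "TRBV19", "TRBV20-1", "TRBV24-1", "TRBV25-1", "TRBV27", "TRBV28",
    "TRBV29-1", "TRBV30",
)
J_GENES = (
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5", "TRBJ1-6",
    "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-4", "TRBJ2-5", "TRBJ2-6", "TRBJ2-7",
)

# mildly skewed background V usage (geometric decay, fixed, normalized lazily)
_V_WEIGHTS = 0.85 ** np.arange(len(V_GENES))

_EPITOPE_LABELS = ("CMV-pp65", "EBV-BMLF1", "FLU-M1", "EBV-BZLF1", "CMV-IE1")

#: survival features the generator can tie hazard to
SURVIVAL_FEATURES = (
    "pbmc_density",
    "adjacent_lung_density",
    "tumor_density",
    "adjacent_lung_clonality",
    "tumor_clonality",
    "lung_enriched_clonality",
)


class ConfigError(ValueError):
    """The simulation configuration is infeasible; nothing was written."""


def _default_clones():
    return {PBMC: 1500, LUNG: 600, TUMOR: 800}


def _default_sigma():
    # per-compartment lognormal sigma: adjacent lung most clonal, blood least,
    # mirroring the compartment ordering the analysis is built to detect
    return {PBMC: 0.8, LUNG: 1.4, TUMOR: 1.1, HEALTHY: 1.0, COPD: 1.2}


def _default_sharing():
    return {(LUNG, TUMOR): 0.12, (PBMC, LUNG): 0.03, (PBMC, TUMOR): 0.03}


def _default_depth():
    return {PBMC: 20000, LUNG: 10000, TUMOR: 10000, HEALTHY: 10000, COPD: 10000}


def _default_density():
    # mean T cell fraction per compartment; tumor mean 0.24 mirrors the
    # cohort-average tumor density the pipeline is expected to recover
    return {PBMC: 0.45, LUNG: 0.18, TUMOR: 0.24, HEALTHY: 0.12, COPD: 0.15}


def _default_viral_bias():
    return {"TRBV9": 0.5, "TRBV19": 0.3, "TRBV28": 0.2}


def _default_survival():
    # signs mirror the associations the analysis tests: more blood T cells
    # protective, more lung-restricted reactivity harmful
    return {
        "baseline_hazard": 1.0 / 1000.0,  # events per day
        "coefficients": {"pbmc_density": -0.4, "lung_enriched_clonality": 0.5},
        "censor_low": 300.0,
        "censor_high": 2500.0,
    }


def _default_effects():
    # EGFR-like subgroup with deflated tumor clonality (driver-mutation effect)
    return {"egfr_like": {"fraction": 0.15, "tumor_spread_factor": 0.7}}


@dataclass
class SimulationConfig:
    n_patients: int = 20
    n_copd: int = 0
    n_healthy: int = 0
    clones_per_compartment: dict = field(default_factory=_default_clones)
    clone_size_distribution: str = "lognormal"  # or "power_law"
    lognormal_sigma: dict = field(default_factory=_default_sigma)
    power_law_exponent: float = 2.0
    patient_spread_jitter: tuple = (0.7, 1.3)
    sharing_fractions: dict = field(default_factory=_default_sharing)
    depth: dict = field(default_factory=_default_depth)
    mean_t_cell_fraction: dict = field(default_factory=_default_density)
    density_concentration: float = 25.0
    nonproductive_fraction: float = 0.15
    n_viral_public_clones: int = 30
    n_viral_motifs: int = 5
    viral_v_bias: dict = field(default_factory=_default_viral_bias)
    viral_presence_prob: float = 0.7
    viral_boost: float = 2.0
    viral_reference_size: int = 400
    survival_model: dict = field(default_factory=_default_survival)
    effect_tags: dict = field(default_factory=_default_effects)
    seed: int = 0

    # ------------------------------------------------------------------ #

    def compartments(self) -> list[str]:
        return [c for c in (PBMC, LUNG, TUMOR) if c in self.clones_per_compartment]

    def pair_shared_count(self, a: str, b: str) -> int:
        j = self._sharing_lookup().get(frozenset((a, b)), 0.0)
        na = self.clones_per_compartment.get(a, 0)
        nb = self.clones_per_compartment.get(b, 0)
        return int(round(j / (1.0 + j) * (na + nb))) if j > 0 else 0

    def _sharing_lookup(self) -> dict:
        return {frozenset(k): v for k, v in self.sharing_fractions.items()}

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        for pair, j in self.sharing_fractions.items():
            if not 0.0 <= j <= 1.0:
                raise ConfigError(f"sharing fraction for {pair} outside [0, 1]")
        for c, d in self.depth.items():
            if d < 1:
                raise ConfigError(f"depth for {c} must be >= 1")
        if not 0.0 <= self.nonproductive_fraction < 1.0:
            raise ConfigError("nonproductive_fraction must be in [0, 1)")
        if self.n_viral_public_clones > self.viral_reference_size:
            raise ConfigError("viral_reference_size must cover all planted viral clones")
        if self.n_viral_public_clones > 0 and self.n_viral_motifs < 1:
            raise ConfigError("need >= 1 viral motif when planting viral clones")
        comps = self.compartments()
        for c in comps:
            shared_total = sum(
                self.pair_shared_count(c, other) for other in comps if other != c
            )
            if shared_total > self.clones_per_compartment[c]:
                raise ConfigError(
                    f"compartment {c}: {shared_total} shared clones exceed its "
                    f"{self.clones_per_compartment[c]} clones"
                )
        for feat in self.survival_model.get("coefficients", {}):
            if feat not in SURVIVAL_FEATURES:
                raise ConfigError(f"unknown survival feature {feat!r}")


# --------------------------------------------------------------------------- #
# CDR3 sequence generation
# --------------------------------------------------------------------------- #


def random_cdr3(rng: np.random.Generator, lmin: int = 8, lmax: int = 20) -> str:
    """Random valid CDR3: length uniform on [lmin, lmax], C...F framing."""
    length = int(rng.integers(lmin, lmax + 1))
    interior = "".join(rng.choice(list(AA_ALPHABET), size=length - 2))
    return "C" + interior + "F"


def _viral_cdr3(rng: np.random.Generator, motif: str) -> str:
    """CDR3 embedding ``motif`` where trimming (3 N-/2 C-terminal) keeps it."""
    n_pre = int(rng.integers(3, 6))
    n_post = int(rng.integers(2, 5))
    pre = "".join(rng.choice(list(AA_ALPHABET), size=n_pre))
    post = "".join(rng.choice(list(AA_ALPHABET), size=n_post))
    return "C" + pre + motif + post + "F"


def _unique_cdr3s(
    rng: np.random.Generator, count: int, taken: set, forbidden_motifs=()
) -> list[str]:
    out: list[str] = []
    while len(out) < count:
        s = random_cdr3(rng)
        if s in taken or any(m in s for m in forbidden_motifs):
            continue
        taken.add(s)
        out.append(s)
    return out


def make_naive_reference(size: int, seed=None, rng=None, forbidden_motifs=()) -> list[str]:
    """Synthetic naive background repertoire for motif-rate estimation."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return _unique_cdr3s(rng, size, set(), forbidden_motifs)


# --------------------------------------------------------------------------- #
# Cohort simulation
# --------------------------------------------------------------------------- #


@dataclass
class GroundTruth:
    latent_frequencies: dict  # sample_id -> {cdr3: frequency}
    clone_sets: dict  # sample_id -> set of cdr3
    shared_sets: dict  # (patient_id, compartment pair) -> set of cdr3
    viral_clones: pd.DataFrame  # cdr3_aa, motif, v_gene, j_gene
    motifs: list
    survival_coefficients: dict
    features: pd.DataFrame  # per patient, raw and standardized
    effect_assignments: dict  # tag -> list of patient_ids

    def true_jaccard(self, patient_id: str, comp_a: str, comp_b: str) -> float:
        a = self.clone_sets[f"{patient_id}_{comp_a}"]
        b = self.clone_sets[f"{patient_id}_{comp_b}"]
        return len(a & b) / len(a | b) if (a or b) else float("nan")


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    samples: list
    manifest: pd.DataFrame
    truth: GroundTruth
    viral_reference: pd.DataFrame

    def sample(self, patient_id: str, compartment: str) -> RepertoireSample:
        sid = f"{patient_id}_{Compartment(compartment).value}"
        for s in self.samples:
            if s.sample_id == sid:
                return s
        raise KeyError(sid)

    def nsclc_patients(self) -> list[str]:
        return sorted({s.patient_id for s in self.samples if s.patient_id.startswith("P")})


def _draw_weights(rng, n, config: SimulationConfig, sigma: float) -> np.ndarray:
    if config.clone_size_distribution == "lognormal":
        return np.exp(rng.normal(0.0, sigma, size=n)) if sigma > 0 else np.ones(n)
    if config.clone_size_distribution == "power_law":
        u = rng.random(n)
        return (1.0 - u) ** (-1.0 / (config.power_law_exponent - 1.0))
    raise ConfigError(f"unknown clone_size_distribution {config.clone_size_distribution!r}")


def _draw_genes(rng, n) -> tuple[list[str], list[str]]:
    pv = _V_WEIGHTS / _V_WEIGHTS.sum()
    vs = list(rng.choice(V_GENES, size=n, p=pv))
    js = list(rng.choice(J_GENES, size=n))
    return vs, js


def _make_viral_clones(rng, config: SimulationConfig) -> tuple[pd.DataFrame, list[str]]:
    motifs: list[str] = []
    taken_motifs: set[str] = set()
    while len(motifs) < config.n_viral_motifs:
        m = "".join(rng.choice(list(AA_ALPHABET), size=4))
        if m not in taken_motifs:
            taken_motifs.add(m)
            motifs.append(m)
    bias = config.viral_v_bias
    bias_genes = sorted(bias)
    bias_p = np.array([bias[g] for g in bias_genes], dtype=float)
    bias_p = bias_p / bias_p.sum()
    rows = []
    taken: set[str] = set()
    for i in range(config.n_viral_public_clones):
        motif = motifs[i % len(motifs)]
        while True:
            cdr3 = _viral_cdr3(rng, motif)
            if cdr3 not in taken:
                taken.add(cdr3)
                break
        rows.append(
            {
                "cdr3_aa": cdr3,
                "motif": motif,
                "v_gene": str(rng.choice(bias_genes, p=bias_p)),
                "j_gene": str(rng.choice(J_GENES)),
            }
        )
    cols = ["cdr3_aa", "motif", "v_gene", "j_gene"]
    return pd.DataFrame(rows, columns=cols), motifs


def make_viral_reference(
    config: SimulationConfig,
    viral_clones: pd.DataFrame,
    motifs: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Synthetic tetramer-defined viral CDR3 reference: every planted clone
    plus decoys free of the planted motifs."""
    rows = []
    for i, rec in viral_clones.iterrows():
        rows.append(
            {
                "cdr3_aa": rec["cdr3_aa"],
                "v_gene": rec["v_gene"],
                "epitope": _EPITOPE_LABELS[motifs.index(rec["motif"]) % len(_EPITOPE_LABELS)],
            }
        )
    n_decoys = config.viral_reference_size - len(viral_clones)
    taken = set(viral_clones["cdr3_aa"])
    decoys = _unique_cdr3s(rng, n_decoys, taken, forbidden_motifs=motifs)
    pv = _V_WEIGHTS / _V_WEIGHTS.sum()
    for i, cdr3 in enumerate(decoys):
        rows.append(
            {
                "cdr3_aa": cdr3,
                "v_gene": str(rng.choice(V_GENES, p=pv)),
                "epitope": _EPITOPE_LABELS[i % len(_EPITOPE_LABELS)],
            }
        )
    return pd.DataFrame(rows, columns=["cdr3_aa", "v_gene", "epitope"])


def _clinical_row(rng) -> dict:
    # marginals mirror an early-stage NSCLC surgical cohort
    return {
        "age": float(np.clip(np.round(rng.normal(66.3, 9.9), 1), 35, 90)),
        "sex": "F" if rng.random() < 0.45 else "M",
        "histology": str(rng.choice(["ADCA", "SCCA", "other"], p=[0.62, 0.37, 0.01])),
        "stage": str(rng.choice(["I", "II", "III"], p=[0.48, 0.33, 0.19])),
        "smoking": str(rng.choice(["current", "former", "never"], p=[0.43, 0.48, 0.09])),
        "tumor_size": float(np.round(np.exp(rng.normal(np.log(3.2), 0.4)), 1)),
    }


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> SimulatedCohort:
    """Draw a full cohort (repertoires + manifest + ground truth) in memory.

    ``seed`` overrides ``config.seed`` when given. Use :func:`write_cohort`
    to materialize the immunoSEQ-dialect files, manifest, viral reference and
    ground-truth JSON.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    comps = config.compartments()
    pairs = [
        (a, b)
        for i, a in enumerate(comps)
        for b in comps[i + 1 :]
        if config.pair_shared_count(a, b) > 0
    ]

    viral_clones, motifs = _make_viral_clones(rng, config)
    viral_ref = make_viral_reference(config, viral_clones, motifs, rng)

    samples: list[RepertoireSample] = []
    manifest_rows: list[dict] = []
    latent: dict = {}
    clone_sets: dict = {}
    shared_sets: dict = {}
    features_rows: list[dict] = []
    effect_assignments: dict = {tag: [] for tag in config.effect_tags}

    pad = max(3, len(str(config.n_patients)))
    patient_ids = [f"P{i + 1:0{pad}d}" for i in range(config.n_patients)]

    for pid in patient_ids:
        jitter = rng.uniform(*config.patient_spread_jitter)
        tags = {
            tag: rng.random() < spec.get("fraction", 0.0)
            for tag, spec in config.effect_tags.items()
        }
        for tag, on in tags.items():
            if on:
                effect_assignments[tag].append(pid)

        taken: set[str] = set(viral_clones["cdr3_aa"])
        pair_shared: dict = {}
        for a, b in pairs:
            m = config.pair_shared_count(a, b)
            pair_shared[(a, b)] = _unique_cdr3s(rng, m, taken, motifs)
            shared_sets[(pid, frozenset((a, b)))] = set(pair_shared[(a, b)])

        viral_present = (
            np.asarray(rng.random(len(viral_clones)) < config.viral_presence_prob)
            if len(viral_clones)
            else np.zeros(0, dtype=bool)
        )

        clin = _clinical_row(rng)
        patient_feats: dict = {"patient_id": pid}
        comp_freqs: dict = {}

        for comp in comps:
            n_c = config.clones_per_compartment[comp]
            shared_here = [
                s for (a, b), s in pair_shared.items() if comp in (a, b)
            ]
            n_shared = sum(len(s) for s in shared_here)
            privates = _unique_cdr3s(rng, n_c - n_shared, taken, motifs)
            cdr3s = privates + [c for s in shared_here for c in s]
            v_genes, j_genes = _draw_genes(rng, len(cdr3s))
            boost = np.ones(len(cdr3s))
            if comp in (LUNG, TUMOR) and viral_present.any():
                v_idx = np.flatnonzero(viral_present)
                cdr3s = cdr3s + viral_clones["cdr3_aa"].iloc[v_idx].tolist()
                v_genes = v_genes + viral_clones["v_gene"].iloc[v_idx].tolist()
                j_genes = j_genes + viral_clones["j_gene"].iloc[v_idx].tolist()
                boost = np.concatenate([boost, np.full(len(v_idx), config.viral_boost)])

            sigma = config.lognormal_sigma.get(comp, 1.0) * jitter
            if comp == TUMOR and tags.get("egfr_like"):
                sigma *= config.effect_tags["egfr_like"].get("tumor_spread_factor", 1.0)
            weights = _draw_weights(rng, len(cdr3s), config, sigma) * boost
            freqs = weights / weights.sum()
            comp_freqs[comp] = dict(zip(cdr3s, freqs))

            depth = config.depth[comp]
            observed = rng.multinomial(depth, freqs)
            keep = observed > 0
            obs_cdr3 = [c for c, k in zip(cdr3s, keep) if k]
            obs_v = [v for v, k in zip(v_genes, keep) if k]
            obs_j = [j for j, k in zip(j_genes, keep) if k]
            obs_t = observed[keep]

            # non-productive rearrangements (out-of-frame / stop-containing)
            n_np = int(round(config.nonproductive_fraction / (1 - config.nonproductive_fraction)
                             * len(obs_cdr3)))
            np_cdr3, np_v, np_j, np_t = [], [], [], []
            for _ in range(n_np):
                base = random_cdr3(rng)
                pos = int(rng.integers(1, len(base) - 1))
                np_cdr3.append(base[:pos] + "*" + base[pos + 1 :])
                np_t.append(int(rng.geometric(0.6)))
            if n_np:
                vv, jj = _draw_genes(rng, n_np)
                np_v, np_j = vv, jj

            sid = f"{pid}_{comp}"
            productive = np.concatenate(
                [np.ones(len(obs_cdr3), bool), np.zeros(n_np, bool)]
            )
            all_t = np.concatenate([obs_t, np.array(np_t, dtype=np.int64)])
            density_draw = rng.beta(
                config.mean_t_cell_fraction[comp] * config.density_concentration,
                (1 - config.mean_t_cell_fraction[comp]) * config.density_concentration,
            )
            usable = float(obs_t.sum()) / density_draw
            sample = RepertoireSample(
                sid,
                cdr3_aa=obs_cdr3 + np_cdr3,
                v_gene=obs_v + np_v,
                j_gene=obs_j + np_j,
                templates=all_t,
                productive=productive,
                patient_id=pid,
                compartment=comp,
                usable_input=usable,
            )
            samples.append(sample)
            latent[sid] = comp_freqs[comp]
            clone_sets[sid] = set(cdr3s)
            if comp == PBMC:
                patient_feats["pbmc_density"] = density_draw
            elif comp == LUNG:
                patient_feats["adjacent_lung_density"] = density_draw
                patient_feats["adjacent_lung_clonality"] = clonality_from_frequencies(
                    np.array(list(comp_freqs[comp].values()))
                )
            elif comp == TUMOR:
                patient_feats["tumor_density"] = density_draw
                patient_feats["tumor_clonality"] = clonality_from_frequencies(
                    np.array(list(comp_freqs[comp].values()))
                )
            manifest_rows.append(
                {
                    "patient_id": pid,
                    "sample_id": sid,
                    "compartment": comp,
                    "path": f"samples/{sid}.tsv",
                    "usable_input": round(usable, 3),
                    **clin,
                }
            )

        if PBMC in comp_freqs and LUNG in comp_freqs:
            blood = set(comp_freqs[PBMC])
            lung_only = {c: f for c, f in comp_freqs[LUNG].items() if c not in blood}
            if lung_only:
                w = np.array(list(lung_only.values()))
                patient_feats["lung_enriched_clonality"] = clonality_from_frequencies(
                    w / w.sum()
                )
        features_rows.append(patient_feats)

    # control subjects: one lung sample each, no survival follow-up
    for prefix, comp, count in (("C", COPD, config.n_copd), ("H", HEALTHY, config.n_healthy)):
        for i in range(count):
            pid = f"{prefix}{i + 1:03d}"
            n_c = config.clones_per_compartment.get(comp, 600)
            taken_local: set[str] = set(viral_clones["cdr3_aa"])
            cdr3s = _unique_cdr3s(rng, n_c, taken_local, motifs)
            v_genes, j_genes = _draw_genes(rng, n_c)
            sigma = config.lognormal_sigma.get(comp, 1.0)
            weights = _draw_weights(rng, n_c, config, sigma)
            freqs = weights / weights.sum()
            depth = config.depth.get(comp, 10000)
            observed = rng.multinomial(depth, freqs)
            keep = observed > 0
            sid = f"{pid}_{comp}"
            density_draw = rng.beta(
                config.mean_t_cell_fraction.get(comp, 0.15) * config.density_concentration,
                (1 - config.mean_t_cell_fraction.get(comp, 0.15)) * config.density_concentration,
            )
            obs_t = observed[keep]
            sample = RepertoireSample(
                sid,
                cdr3_aa=[c for c, k in zip(cdr3s, keep) if k],
                v_gene=[v for v, k in zip(v_genes, keep) if k],
                j_gene=[j for j, k in zip(j_genes, keep) if k],
                templates=obs_t,
                patient_id=pid,
                compartment=comp,
                usable_input=float(obs_t.sum()) / density_draw,
            )
            samples.append(sample)
            latent[sid] = dict(zip(cdr3s, freqs))
            clone_sets[sid] = set(cdr3s)
            manifest_rows.append(
                {
                    "patient_id": pid,
                    "sample_id": sid,
                    "compartment": comp,
                    "path": f"samples/{sid}.tsv",
                    "usable_input": round(sample.usable_input, 3),
                    "age": float(np.clip(np.round(rng.normal(50, 14), 1), 20, 90)),
                    "sex": "F" if rng.random() < 0.5 else "M",
                    "histology": "",
                    "stage": "",
                    "smoking": str(rng.choice(["current", "never"], p=[0.5, 0.5])),
                    "tumor_size": np.nan,
                }
            )

    features = pd.DataFrame(features_rows).set_index("patient_id")
    survival = config.survival_model
    coeffs = survival.get("coefficients", {})
    zcols = {}
    for feat in coeffs:
        if feat not in features.columns:
            raise ConfigError(
                f"survival coefficient on {feat!r} but the configured compartments "
                "cannot produce that feature"
            )
        col = features[feat].astype(float)
        sd = col.std(ddof=0)
        zcols[feat] = (col - col.mean()) / sd if sd > 0 else col * 0.0
    log_hr = sum(beta * zcols[f] for f, beta in coeffs.items()) if coeffs else 0.0
    hazard = survival.get("baseline_hazard", 1e-3) * np.exp(
        log_hr if coeffs else np.zeros(len(features))
    )
    event_time = rng.exponential(1.0 / np.asarray(hazard, dtype=float))
    censor_time = rng.uniform(
        survival.get("censor_low", 300.0), survival.get("censor_high", 2500.0),
        size=len(features),
    )
    os_time = np.minimum(event_time, censor_time)
    os_event = event_time <= censor_time
    lung_death = os_event & (rng.random(len(features)) < 0.7)
    relapse = rng.random(len(features)) < 0.35
    surv = pd.DataFrame(
        {
            "os_time": np.round(os_time, 1),
            "os_event": os_event.astype(int),
            "lung_cancer_death": lung_death.astype(int),
            "relapse": relapse.astype(int),
        },
        index=features.index,
    )

    manifest = pd.DataFrame(manifest_rows)
    manifest = manifest.merge(surv, left_on="patient_id", right_index=True, how="left")
    for feat, z in zcols.items():
        features[f"z_{feat}"] = z

    truth = GroundTruth(
        latent_frequencies=latent,
        clone_sets=clone_sets,
        shared_sets=shared_sets,
        viral_clones=viral_clones,
        motifs=motifs,
        survival_coefficients=dict(coeffs),
        features=features.reset_index(),
        effect_assignments=effect_assignments,
    )
    return SimulatedCohort(
        config=config,
        samples=samples,
        manifest=manifest,
        truth=truth,
        viral_reference=viral_ref,
    )


def write_cohort(cohort: SimulatedCohort, out_dir, dialect: str = "immunoseq") -> Path:
    """Write samples, manifest, viral reference and ground truth under out_dir."""
    out = Path(out_dir)
    (out / "samples").mkdir(parents=True, exist_ok=True)
    for sample in cohort.samples:
        write_rearrangements(sample, out / "samples" / f"{sample.sample_id}.tsv", dialect)
    write_manifest(cohort.manifest, out / "manifest.tsv")
    cohort.viral_reference.to_csv(
        out / "viral_reference.tsv", sep="\t", index=False, lineterminator="\n"
    )
    truth = cohort.truth
    payload = {
        "motifs": truth.motifs,
        "viral_clones": truth.viral_clones.to_dict(orient="records"),
        "survival_coefficients": truth.survival_coefficients,
        "effect_assignments": truth.effect_assignments,
        "features": truth.features.round(6).to_dict(orient="records"),
        "shared_sets": {
            f"{pid}:{'|'.join(sorted(pair))}": sorted(s)
            for (pid, pair), s in truth.shared_sets.items()
        },
        "latent_frequencies": {
            sid: {c: round(f, 10) for c, f in sorted(freqs.items())}
            for sid, freqs in sorted(truth.latent_frequencies.items())
        },
    }
    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=None, sort_keys=True, separators=(",", ":"))
    return out


# --------------------------------------------------------------------------- #
# Small paired-sample simulators for calibration and power studies
# --------------------------------------------------------------------------- #


def simulate_null_pair(n_clones: int, depth: int, rng, sigma: float = 1.0):
    """Two samples multinomially drawn from one latent frequency vector."""
    w = np.exp(rng.normal(0.0, sigma, size=n_clones)) if sigma > 0 else np.ones(n_clones)
    f = w / w.sum()
    return rng.multinomial(depth, f), rng.multinomial(depth, f), f


def simulate_enriched_pair(
    n_clones: int,
    depth: int,
    rng,
    n_enriched: int = 20,
    fold: float = 10.0,
    sigma: float = 1.0,
):
    """A pair where ``n_enriched`` clones are ``fold``-times more frequent in
    sample A; returns (counts_a, counts_b, enriched_index_array)."""
    w = np.exp(rng.normal(0.0, sigma, size=n_clones)) if sigma > 0 else np.ones(n_clones)
    f_b = w / w.sum()
    idx = rng.choice(n_clones, size=n_enriched, replace=False)
    w_a = w.copy()
    w_a[idx] *= fold
    f_a = w_a / w_a.sum()
    return rng.multinomial(depth, f_a), rng.multinomial(depth, f_b), np.sort(idx)
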