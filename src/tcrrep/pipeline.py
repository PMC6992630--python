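"""Cross-module recipes composing the per-sample operations into the
cohort-level analyses: metric tables, compartment overlap tables, and the
tissue-enriched sub-repertoire compositions (e.g. clonality of the lung
repertoire enriched versus paired blood)."""

from __future__ import annotations

import pandas as pd

from . import abundance, metrics, overlap
from .repertoire import Compartment, RepertoireSample

PBMC = Compartment.PBMC.value
LUNG = Compartment.ADJACENT_LUNG.value
TUMOR = Compartment.TUMOR.value


def metrics_table(
    samples,
    targets: dict | None = None,
    identity: str = "aa",
    min_templates: int = 100,
) -> pd.DataFrame:
    """One row of repertoire metrics per sample (productive clones only).

    ``targets`` maps "PBMC"/"tissue" to extrapolation depths (defaults
    400,000 / 120,000 templates).
    """
    targets = {**metrics.DEFAULT_EXTRAPOLATION_TARGETS, **(targets or {})}
    rows = []
    for s in samples:
        is_pbmc = s.compartment is not None and s.compartment.value == PBMC
        target = targets["PBMC"] if is_pbmc else targets["tissue"]
        m = metrics.repertoire_metrics(s, target, identity, min_templates)
        rows.append(
            {
                "sample_id": s.sample_id,
                "patient_id": s.patient_id,
                "compartment": s.compartment.value if s.compartment else None,
                "density": m.density,
                "richness_observed": m.richness_observed,
                "richness_extrapolated": m.richness_extrapolated,
                "extrapolation_target": m.extrapolation_target,
                "extrapolation_method": m.extrapolation_method,
                "clonality": m.clonality,
                "shannon_entropy": m.shannon_entropy,
            }
        )
    return pd.DataFrame(rows)


def _by_patient(samples) -> dict:
    out: dict = {}
    for s in samples:
        if s.compartment is None:
            continue
        out.setdefault(s.patient_id, {})[s.compartment.value] = s
    return out


def overlap_table(
    samples,
    pairs=((LUNG, TUMOR), (PBMC, TUMOR), (PBMC, LUNG)),
    identity: str = "aa",
    top_n: int = 100,
    productive_only: bool = True,
) -> pd.DataFrame:
    """Per-patient Jaccard / Morisita-Horn / top-N sharing for each
    compartment pair available in that patient."""
    rows = []
    for pid, comps in sorted(_by_patient(samples).items()):
        for a, b in pairs:
            if a not in comps or b not in comps:
                continue
            sa, sb = comps[a], comps[b]
            if productive_only:
                sa, sb = sa.productive_only(), sb.productive_only()
            res = overlap.overlap_pair(sa, sb, identity)
            top = overlap.top_n_sharing(sa, sb, top_n, identity)
            rows.append(
                {
                    "patient_id": pid,
                    "compartment_a": a,
                    "compartment_b": b,
                    "jaccard": res.jaccard,
                    "morisita": res.morisita,
                    "shared_clones": res.shared_clone_count,
                    "union_clones": res.union_clone_count,
                    f"top{top_n}_detected_in_partner": top.detected_in_partner,
                    f"top{top_n}_in_partner_top{top_n}": top.in_partner_top_n,
                }
            )
    return pd.DataFrame(rows)


def enriched_repertoire(
    sample: RepertoireSample,
    baseline: RepertoireSample,
    min_total: int = 5,
    alpha: float = 0.1,
) -> RepertoireSample:
    """The sub-repertoire of ``sample`` enriched versus ``baseline``."""
    results = abundance.call_enriched(sample, baseline, min_total, alpha)
    return abundance.enriched_subrepertoire(sample.productive_only(), results, side="A")


def lung_enriched_clonality_table(
    samples, baseline: str = PBMC, tissue: str = LUNG,
    min_total: int = 5, alpha: float = 0.1,
) -> pd.DataFrame:
    """Per-patient clonality of the tissue repertoire enriched versus the
    paired baseline compartment (the paper-facing survival variable)."""
    rows = []
    for pid, comps in sorted(_by_patient(samples).items()):
        if tissue not in comps or baseline not in comps:
            continue
        sub = enriched_repertoire(comps[tissue], comps[baseline], min_total, alpha)
        rows.append(
            {
                "patient_id": pid,
                "n_enriched_clones": sub.n_clones,
                "lung_enriched_clonality": metrics.clonality(sub) if sub.n_clones else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def enriched_overlap_table(
    samples, baseline: str = PBMC, pair=(LUNG, TUMOR),
    min_total: int = 5, alpha: float = 0.1, identity: str = "aa",
) -> pd.DataFrame:
    """Overlap between two tissue repertoires after restricting each to the
    clones enriched versus the patient's baseline compartment."""
    rows = []
    for pid, comps in sorted(_by_patient(samples).items()):
        if baseline not in comps or any(c not in comps for c in pair):
            continue
        subs = [
            enriched_repertoire(comps[c], comps[baseline], min_total, alpha) for c in pair
        ]
        if any(s.n_clones == 0 for s in subs):
            continue
        rows.append(
            {
                "patient_id": pid,
                "jaccard": overlap.jaccard(*subs, identity),
                "morisita": overlap.morisita(*subs, identity),
            }
        )
    return pd.DataFrame(rows)
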