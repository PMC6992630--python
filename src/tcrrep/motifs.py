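"""Motif-based antigen-specificity grouping of CDR3s, with viral classification.

The approach follows the paratope-hotspot idea: short amino-acid motifs
(k-mers, k in {2,3,4}) that are strongly over-represented in the analysis set
relative to a large reference repertoire mark TCRs likely to share antigen
specificity.  CDR3s are first trimmed (3 N-terminal and 2 C-terminal
residues removed) to focus on the antigen-contacting loop; motifs must occur
in at least two analysis CDR3s, reach a fold enrichment over the reference
rate (default >= 10) and a resampling p-value (default <= 0.001).  Two CDR3s
join the same specificity group when they share an enriched motif (local
similarity) or are of equal length at Hamming distance <= 1 after trimming
(global similarity); groups are connected components of that relation.

A group is classified *viral* when at least 3 of its members match
tetramer-defined viral reference CDR3s exactly and one V gene is enriched
within the group versus its cohort-wide usage (one-sided Fisher p < 0.05).
Per patient, viral and non-viral groups are normalized separately over the
three location categories (tumor-only / lung-only / shared) so the two motif
classes can be compared despite the reference database skew.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .nomenclature import UNRESOLVED
from .repertoire import Compartment

TRIM_N_TERMINAL = 3
TRIM_C_TERMINAL = 2
DEFAULT_K_VALUES = (2, 3, 4)

LOCATION_TUMOR_ONLY = "TUMOR_ONLY"
LOCATION_LUNG_ONLY = "LUNG_ONLY"
LOCATION_SHARED = "SHARED"


def trim_cdr3(cdr3: str) -> str | None:
    """Motif-analysis window: drop 3 N- and 2 C-terminal residues.

    Sequences shorter than 7 residues cannot be trimmed and are excluded
    (returns None); trimming is lossy and one-way.
    """
    if len(cdr3) < TRIM_N_TERMINAL + TRIM_C_TERMINAL + 2:
        return None
    return cdr3[TRIM_N_TERMINAL:-TRIM_C_TERMINAL]


def _kmer_set(seq: str, k_values=DEFAULT_K_VALUES) -> set[str]:
    out: set[str] = set()
    for k in k_values:
        for i in range(len(seq) - k + 1):
            out.add(seq[i : i + k])
    return out


@dataclass
class MotifHit:
    motif: str
    observed_count: int  # analysis CDR3s containing the motif
    analysis_size: int
    reference_rate: float
    fold_enrichment: float
    resample_p: float

    @property
    def k(self) -> int:
        return len(self.motif)


def enriched_motifs(
    cdr3_set,
    reference,
    k_values=DEFAULT_K_VALUES,
    fold_min: float = 10.0,
    p_max: float = 0.001,
    resamples: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[MotifHit]:
    """Motifs over-represented in ``cdr3_set`` versus ``reference``.

    Candidate motifs must occur in >= 2 unique analysis CDR3s. The fold
    enrichment compares containment rates (reference rate floored at
    0.5/|reference| when zero); the resampling p is the probability that a
    same-sized draw from the reference contains the motif at least as often,
    estimated over ``resamples`` draws with the add-one correction
    p = (1 + #{exceedances}) / (resamples + 1).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    analysis = sorted({t for s in set(cdr3_set) if (t := trim_cdr3(s)) is not None})
    ref = [t for s in reference for t in (trim_cdr3(s),) if t is not None]
    if not ref:
        raise ValueError("motif enrichment needs a non-empty reference repertoire")
    n_analysis = len(analysis)
    n_ref = len(ref)
    if n_analysis == 0:
        return []

    support: Counter[str] = Counter()
    for seq in analysis:
        support.update(_kmer_set(seq, k_values))
    candidates = sorted(m for m, c in support.items() if c >= 2)

    ref_count: Counter[str] = Counter()
    for seq in ref:
        ref_count.update(_kmer_set(seq, k_values))

    floor_rate = 0.5 / n_ref
    hits: list[MotifHit] = []
    fold_passers = []
    for m in candidates:
        rate = max(ref_count.get(m, 0) / n_ref, floor_rate)
        fold = (support[m] / n_analysis) / rate
        if fold >= fold_min:
            fold_passers.append((m, rate, fold))

    if fold_passers:
        idx = None
        for m, rate, fold in fold_passers:
            if ref_count.get(m, 0) == 0:
                # no reference sequence contains the motif: every resampled
                # draw contains it 0 times, below any observed count >= 2
                p = 1.0 / (resamples + 1)
            else:
                if idx is None:
                    idx = rng.integers(0, n_ref, size=(resamples, n_analysis))
                mask = np.fromiter((m in seq for seq in ref), dtype=bool, count=n_ref)
                draws = mask[idx].sum(axis=1)
                p = (1 + int((draws >= support[m]).sum())) / (resamples + 1)
            if p <= p_max:
                hits.append(
                    MotifHit(
                        motif=m,
                        observed_count=support[m],
                        analysis_size=n_analysis,
                        reference_rate=rate,
                        fold_enrichment=fold,
                        resample_p=p,
                    )
                )
    hits.sort(key=lambda h: (-h.fold_enrichment, h.motif))
    return hits


@dataclass
class SpecificityGroup:
    group_id: str
    members: pd.DataFrame  # columns: cdr3_aa, trimmed [, patient_id, compartment, v_gene]
    motifs: tuple[str, ...]
    n_viral_members: int | None = None
    v_gene_fisher_p: float | None = None
    is_viral: bool | None = None
    location: str | None = None
    unresolved_v_members: int = 0

    @property
    def member_cdr3s(self) -> list[str]:
        return sorted(self.members["cdr3_aa"].unique())

    def member_compartments(self, patient_id: str) -> set[str]:
        m = self.members
        if "patient_id" not in m.columns or "compartment" not in m.columns:
            return set()
        return set(m.loc[m["patient_id"] == patient_id, "compartment"])


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def build_groups(records, motifs: list[MotifHit]) -> list[SpecificityGroup]:
    """Connected components of the shared-motif / Hamming<=1 relation.

    ``records`` is a DataFrame with at least a ``cdr3_aa`` column (plus
    optional patient_id / compartment / v_gene metadata carried into the
    groups). Singleton components are discarded. The construction is a true
    equivalence closure: input order never changes the components.
    """
    records = pd.DataFrame(records)
    records = records.copy()
    records["trimmed"] = records["cdr3_aa"].map(trim_cdr3)
    records = records[records["trimmed"].notna()]
    nodes = sorted(records["cdr3_aa"].unique())
    trimmed = {c: trim_cdr3(c) for c in nodes}
    index = {c: i for i, c in enumerate(nodes)}
    uf = _UnionFind(len(nodes))

    motif_strings = [h.motif for h in motifs]
    for m in motif_strings:
        containing = [index[c] for c in nodes if m in trimmed[c]]
        for i in containing[1:]:
            uf.union(containing[0], i)

    # global rule: equal trimmed length, Hamming distance <= 1 — linked via
    # single-position wildcard patterns, which is exact for distance <= 1
    patterns: dict[str, int] = {}
    for c in nodes:
        t = trimmed[c]
        for pos in range(len(t)):
            pat = f"{pos}:{t[:pos]}*{t[pos + 1:]}"
            if pat in patterns:
                uf.union(patterns[pat], index[c])
            else:
                patterns[pat] = index[c]

    components: dict[int, list[str]] = {}
    for c in nodes:
        components.setdefault(uf.find(index[c]), []).append(c)

    groups: list[SpecificityGroup] = []
    for root in sorted(components, key=lambda r: nodes[r]):
        member_cdr3s = components[root]
        if len(member_cdr3s) < 2:
            continue
        sub = records[records["cdr3_aa"].isin(member_cdr3s)].reset_index(drop=True)
        gmotifs = tuple(
            sorted(m for m in motif_strings if any(m in trimmed[c] for c in member_cdr3s))
        )
        groups.append(
            SpecificityGroup(
                group_id=f"G{len(groups) + 1:04d}",
                members=sub,
                motifs=gmotifs,
            )
        )
    return groups


def classify_viral(
    group: SpecificityGroup,
    viral_reference: pd.DataFrame,
    cohort_v_usage,
    min_viral_members: int = 3,
    fisher_alpha: float = 0.05,
) -> SpecificityGroup:
    """Set the viral label: >= 3 exact viral-reference CDR3 matches AND a
    V gene enriched within the group vs cohort usage (one-sided Fisher p < 0.05).

    ``cohort_v_usage`` maps V gene -> clone count over the analysis universe.
    Unresolved V genes are excluded from the Fisher table (counted in
    ``unresolved_v_members``). Adding a viral-reference member can only raise
    the viral count, so the label is monotone in viral membership.
    """
    viral_set = set(viral_reference["cdr3_aa"])
    member_cdr3s = group.member_cdr3s
    group.n_viral_members = sum(c in viral_set for c in member_cdr3s)

    usage = dict(cohort_v_usage)
    usage.pop(UNRESOLVED, None)
    n_universe = sum(usage.values())
    if "v_gene" in group.members.columns:
        member_v = (
            group.members.drop_duplicates("cdr3_aa")[["cdr3_aa", "v_gene"]]
            .set_index("cdr3_aa")["v_gene"]
        )
    else:
        member_v = pd.Series(dtype=object)
    v_counts = Counter(v for v in member_v if v != UNRESOLVED)
    group.unresolved_v_members = int((member_v == UNRESOLVED).sum())
    n_group = sum(v_counts.values())

    best_p = 1.0
    if n_group > 0 and n_universe > n_group:
        for v, k in sorted(v_counts.items()):
            big_k = usage.get(v, k)
            table = [[k, n_group - k], [max(big_k - k, 0), (n_universe - big_k) - (n_group - k)]]
            if min(min(row) for row in table) < 0:
                continue
            _, p = fisher_exact(table, alternative="greater")
            best_p = min(best_p, float(p))
    group.v_gene_fisher_p = best_p
    group.is_viral = group.n_viral_members >= min_viral_members and best_p < fisher_alpha
    return group


def assign_location(group: SpecificityGroup) -> SpecificityGroup:
    """Tumor/lung location over all patients: SHARED iff some patient carries
    the group in both tumor and adjacent lung."""
    m = group.members
    if "patient_id" not in m.columns or "compartment" not in m.columns:
        group.location = None
        return group
    has_t = has_l = shared = False
    for pid in m["patient_id"].unique():
        comps = group.member_compartments(pid)
        t = Compartment.TUMOR.value in comps
        l = Compartment.ADJACENT_LUNG.value in comps
        shared = shared or (t and l)
        has_t, has_l = has_t or t, has_l or l
    if shared:
        group.location = LOCATION_SHARED
    elif has_t and not has_l:
        group.location = LOCATION_TUMOR_ONLY
    elif has_l and not has_t:
        group.location = LOCATION_LUNG_ONLY
    else:
        group.location = None
    return group


@dataclass
class LocationProportions:
    patient_id: str
    viral: dict | None  # {TUMOR_ONLY/LUNG_ONLY/SHARED: proportion}, sums to 1
    non_viral: dict | None
    fold_shared: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.fold_shared is None and self.viral and self.non_viral:
            denom = self.non_viral.get(LOCATION_SHARED, 0.0)
            num = self.viral.get(LOCATION_SHARED, 0.0)
            self.fold_shared = num / denom if denom > 0 else None


def location_proportions(groups, patient_id: str) -> LocationProportions:
    """Per-patient location proportions, viral and non-viral normalized
    separately (the reference database skews heavily non-viral, so raw motif
    counts are not comparable across the two classes)."""
    tallies = {True: Counter(), False: Counter()}
    for g in groups:
        if g.is_viral is None:
            raise ValueError("groups must be classified (classify_viral) first")
        comps = g.member_compartments(patient_id)
        t = Compartment.TUMOR.value in comps
        l = Compartment.ADJACENT_LUNG.value in comps
        if t and l:
            cat = LOCATION_SHARED
        elif t:
            cat = LOCATION_TUMOR_ONLY
        elif l:
            cat = LOCATION_LUNG_ONLY
        else:
            continue  # group not observed in this patient's tumor/lung pair
        tallies[bool(g.is_viral)][cat] += 1

    def _norm(counter: Counter) -> dict | None:
        total = sum(counter.values())
        if total == 0:
            return None
        return {
            cat: counter.get(cat, 0) / total
            for cat in (LOCATION_TUMOR_ONLY, LOCATION_LUNG_ONLY, LOCATION_SHARED)
        }

    return LocationProportions(
        patient_id=patient_id, viral=_norm(tallies[True]), non_viral=_norm(tallies[False])
    )


def cohort_v_usage(records) -> Counter:
    """V gene -> unique clone count over the analysis universe."""
    records = pd.DataFrame(records)
    uniq = records.drop_duplicates("cdr3_aa")
    return Counter(uniq["v_gene"])
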