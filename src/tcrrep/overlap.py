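"""Repertoire homology: Jaccard, Morisita-Horn, top-N sharing, public clones.

The Jaccard index is |A intersect B| / |A union B| over unique clone keys;
the Morisita overlap is computed in its bounded Morisita-Horn form

    MH = 2 sum_i x_i y_i / ((d_x + d_y) X Y),   d_x = sum x_i^2 / X^2,

with counts x_i, y_i over the union of clone keys (absent clone = 0) and
totals X, Y; both indices live in [0, 1]. ``set_sharing`` is the generic
three-way fraction utility used for per-tissue mutation identifier sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .repertoire import Compartment, RepertoireSample, as_counts


@dataclass
class OverlapResult:
    pair: tuple[str, str]
    jaccard: float
    morisita: float
    shared_clone_count: int
    union_clone_count: int


@dataclass
class TopSharingResult:
    n: int
    detected_in_partner: int
    in_partner_top_n: int


def jaccard(a, b, identity: str = "aa") -> float:
    """Shared unique clones over union; NaN (with warning) on empty input."""
    ka, kb = set(as_counts(a, identity)), set(as_counts(b, identity))
    if not ka or not kb:
        for s in (a, b):
            if isinstance(s, RepertoireSample):
                s.warnings.append("jaccard on empty repertoire")
        return float("nan")
    return len(ka & kb) / len(ka | kb)


def morisita(a, b, identity: str = "aa") -> float:
    """Morisita-Horn overlap in [0, 1]; NaN on empty input."""
    ca, cb = as_counts(a, identity), as_counts(b, identity)
    if not ca or not cb:
        return float("nan")
    keys = set(ca) | set(cb)
    x = np.array([ca.get(k, 0) for k in keys], dtype=float)
    y = np.array([cb.get(k, 0) for k in keys], dtype=float)
    bx, by = x.sum(), y.sum()
    dx = (x * x).sum() / (bx * bx)
    dy = (y * y).sum() / (by * by)
    return float(2.0 * (x * y).sum() / ((dx + dy) * bx * by))


def overlap_pair(a, b, identity: str = "aa") -> OverlapResult:
    ca, cb = as_counts(a, identity), as_counts(b, identity)
    ka, kb = set(ca), set(cb)
    ids = tuple(
        s.sample_id if isinstance(s, RepertoireSample) else "?" for s in (a, b)
    )
    return OverlapResult(
        pair=ids,
        jaccard=jaccard(ca, cb),
        morisita=morisita(ca, cb),
        shared_clone_count=len(ka & kb),
        union_clone_count=len(ka | kb),
    )


def _ranked_keys(counts: dict) -> list:
    """Clone keys by descending count, ties broken lexicographically."""
    return [k for k, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]


def top_n_sharing(source, partner, n: int = 100, identity: str = "aa") -> TopSharingResult:
    """How many of the source's top-n clones exist in (the top-n of) partner.

    Ranking is by template count with deterministic lexicographic tie-break;
    clones tied at the boundary beyond rank n are excluded.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cs, cp = as_counts(source, identity), as_counts(partner, identity)
    top_source = _ranked_keys(cs)[:n]
    partner_top = set(_ranked_keys(cp)[:n])
    detected = [k for k in top_source if k in cp]
    in_top = [k for k in detected if k in partner_top]
    return TopSharingResult(n=n, detected_in_partner=len(detected), in_partner_top_n=len(in_top))


def public_clones(
    cohort, min_patients: int = 2, identity: str = "aa"
) -> pd.DataFrame:
    """Tabulate clone keys observed in >= ``min_patients`` distinct patients.

    Returns one row per public clone with the number of patients carrying it
    and per-compartment occurrence counts.
    """
    samples = list(cohort)
    if len({s.patient_id for s in samples}) < 2:
        raise ValueError("public clone tabulation needs samples from >= 2 patients")
    per_key_patients: dict = {}
    per_key_comp: dict = {}
    for s in samples:
        comp = s.compartment.value if s.compartment else "UNKNOWN"
        for k in s.counts(identity):
            per_key_patients.setdefault(k, set()).add(s.patient_id)
            comp_counts = per_key_comp.setdefault(k, {})
            comp_counts[comp] = comp_counts.get(comp, 0) + 1
    comps = sorted({c for d in per_key_comp.values() for c in d})
    rows = []
    for k in sorted(per_key_patients, key=lambda k: (-len(per_key_patients[k]), str(k))):
        n_pat = len(per_key_patients[k])
        if n_pat < min_patients:
            continue
        row = {"clone": k, "n_patients": n_pat}
        for c in comps:
            row[f"n_samples_{c}"] = per_key_comp[k].get(c, 0)
        rows.append(row)
    cols = ["clone", "n_patients"] + [f"n_samples_{c}" for c in comps]
    return pd.DataFrame(rows, columns=cols)


def set_sharing(a, b) -> tuple[float, float, float]:
    """(fraction only in a, only in b, shared) over |a union b|; sums to 1.

    Returns NaNs when both sets are empty (the fractions are undefined).
    """
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        return (float("nan"),) * 3
    n = len(union)
    shared = len(sa & sb)
    return ((len(sa) - shared) / n, (len(sb) - shared) / n, shared / n)
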