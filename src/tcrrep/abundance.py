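"""Differential clone abundance between paired samples.

Each clone with combined template count >= ``min_total`` (default 5) is
tested on the 2x2 table [[count_a, total_a - count_a], [count_b,
total_b - count_b]] with a two-sided exact (Fisher) test; p-values are
Benjamini-Hochberg adjusted across the clones tested within the pair, and a
clone is called enriched on the side with the higher frequency when its
q-value is at or below ``alpha`` (default 0.1). Amino-acid clone identity is
used and only productive rearrangements enter, matching the assay framework
this stage mirrors.

The exact p-value is computed by direct enumeration of the conditional
hypergeometric distribution, which vectorizes across the thousands of clones
of a pair; a unit test pins it against ``scipy.stats.fisher_exact``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .repertoire import RepertoireSample, as_counts

_REL_EPS = 1.0 + 1e-7  # pmf comparison tolerance, as in the classical test


def _hypergeom_pmf(x, n, total_a, k) -> np.ndarray:
    """Vectorized central hypergeometric pmf via log-gamma (stable, fast)."""
    x = np.asarray(x, dtype=float)
    k = np.asarray(k, dtype=float)
    total_b = n - total_a

    def log_comb(nn, kk):
        return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

    return np.exp(log_comb(total_a, x) + log_comb(total_b, k - x) - log_comb(n, k))


def test_clone(count_a: int, total_a: int, count_b: int, total_b: int) -> float:
    """Two-sided exact p-value for one clone's 2x2 abundance table."""
    for c, t in ((count_a, total_a), (count_b, total_b)):
        if not (0 <= c <= t) or t <= 0:
            raise ValueError("need totals >= counts >= 0 and totals > 0")
    k = count_a + count_b
    n = total_a + total_b
    xs = np.arange(max(0, k - total_b), min(k, total_a) + 1)
    pm = _hypergeom_pmf(xs, n, total_a, k)
    p_obs = pm[xs == count_a][0]
    return float(min(1.0, pm[pm <= p_obs * _REL_EPS].sum()))


def _fisher_many(a: np.ndarray, b: np.ndarray, total_a: int, total_b: int) -> np.ndarray:
    """Vectorized two-sided exact p-values for many clones of one pair.

    All tables share the margins (total_a, total_b); tables are grouped by
    combined count k so each conditional distribution is enumerated once.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    k = a + b
    n = total_a + total_b
    p = np.empty(len(a), dtype=float)
    uk = np.unique(k)
    lows = np.maximum(0, uk - total_b)
    highs = np.minimum(uk, total_a)
    lens = highs - lows + 1
    offsets = np.concatenate([[0], np.cumsum(lens)])
    all_x = np.concatenate([np.arange(lo, hi + 1) for lo, hi in zip(lows, highs)])
    all_k = np.repeat(uk, lens)
    pm_all = _hypergeom_pmf(all_x, n, total_a, all_k)
    for i, kv in enumerate(uk):
        sel = k == kv
        pm = pm_all[offsets[i] : offsets[i + 1]]
        order = np.argsort(pm, kind="stable")
        cums = np.cumsum(pm[order])
        pm_sorted = pm[order]
        p_obs = pm[a[sel] - lows[i]]
        pos = np.searchsorted(pm_sorted, p_obs * _REL_EPS, side="right")
        p[sel] = np.where(pos > 0, cums[np.maximum(pos - 1, 0)], 0.0)
    return np.minimum(p, 1.0)


@dataclass
class EnrichmentConfig:
    min_total: int = 5
    alpha: float = 0.1
    identity: str = "aa"  # amino-acid clone identity is forced for this stage


def call_enriched(
    a,
    b,
    min_total: int = 5,
    alpha: float = 0.1,
    *,
    productive_only: bool = True,
) -> pd.DataFrame:
    """Test every clone of a paired comparison; return all tested clones.

    Parameters follow the differential abundance framework defaults
    (minTotal = 5, alpha = 0.1, productive-only, amino-acid counts). Returns
    a DataFrame with columns clone, count_a, count_b, total_a, total_b,
    p_value, q_value, enriched_in ('A' | 'B' | 'neither'); empty when no
    clone reaches ``min_total``.
    """
    if isinstance(a, RepertoireSample) and productive_only:
        a = a.productive_only()
    if isinstance(b, RepertoireSample) and productive_only:
        b = b.productive_only()
    ca = as_counts(a, "aa")
    cb = as_counts(b, "aa")
    total_a = sum(ca.values())
    total_b = sum(cb.values())
    keys = sorted(set(ca) | set(cb))
    xa = np.array([ca.get(k, 0) for k in keys], dtype=np.int64)
    xb = np.array([cb.get(k, 0) for k in keys], dtype=np.int64)
    mask = xa + xb >= min_total
    cols = ["clone", "count_a", "count_b", "total_a", "total_b", "p_value", "q_value", "enriched_in"]
    if total_a == 0 or total_b == 0 or not mask.any():
        return pd.DataFrame(columns=cols)
    keys = [k for k, m in zip(keys, mask) if m]
    xa, xb = xa[mask], xb[mask]
    p = _fisher_many(xa, xb, total_a, total_b)
    q = multipletests(p, method="fdr_bh")[1]
    freq_a = xa / total_a
    freq_b = xb / total_b
    called = q <= alpha
    direction = np.where(freq_a > freq_b, "A", np.where(freq_b > freq_a, "B", "neither"))
    enriched_in = np.where(called, direction, "neither")
    return pd.DataFrame(
        {
            "clone": keys,
            "count_a": xa,
            "count_b": xb,
            "total_a": total_a,
            "total_b": total_b,
            "p_value": p,
            "q_value": q,
            "enriched_in": enriched_in,
        },
        columns=cols,
    )


def enriched_keys(results: pd.DataFrame, side: str = "A") -> set:
    if side not in {"A", "B"}:
        raise ValueError("side must be 'A' or 'B'")
    if len(results) == 0:
        return set()
    return set(results.loc[results["enriched_in"] == side, "clone"])


def enriched_subrepertoire(
    sample: RepertoireSample, results: pd.DataFrame, side: str = "A"
) -> RepertoireSample:
    """Restrict ``sample`` to the clones called enriched on ``side``.

    Metrics (e.g. clonality) may then be computed on the restriction; an
    empty restriction is returned as an empty repertoire with a warning.
    """
    return sample.restrict_to_keys(enriched_keys(results, side), identity="aa")
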