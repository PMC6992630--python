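"""Core containers for TCR-beta CDR3 repertoire data.

A *clone* (clonotype) is one unique TCR-beta rearrangement, identified by its
CDR3 amino-acid sequence and, optionally, its V/J gene calls.  Its abundance
is the *template count*: the number of input TCR molecules observed for that
rearrangement.  A :class:`RepertoireSample` is the set of clones observed in
one tissue sample (blood, lung, or tumor) of one subject, together with the
normalization metadata needed for T cell density (the total usable input in
nucleated-cell equivalents).

For performance the sample stores its clones column-wise (parallel arrays);
``sample.clones`` materializes :class:`Clone` objects on demand.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
STOP_SYMBOL = "*"

#: identity keys for clones used pipeline-wide. "aa" collapses convergent
#: recombination onto the CDR3 amino-acid sequence; "aa_vj" keeps V/J calls.
IDENTITY_KEYS = ("aa", "aa_vj")


class Compartment(str, Enum):
    """Tissue compartment a repertoire sample was drawn from."""

    PBMC = "PBMC"
    ADJACENT_LUNG = "ADJACENT_LUNG"
    TUMOR = "TUMOR"
    HEALTHY_LUNG = "HEALTHY_LUNG"
    COPD_LUNG = "COPD_LUNG"


@dataclass(frozen=True)
class Clone:
    """One unique TCR-beta rearrangement and its template count."""

    cdr3_aa: str
    v_gene: str
    j_gene: str
    templates: int
    productive: bool = True
    cdr3_nt: str | None = None

    def __post_init__(self) -> None:
        if self.templates < 1:
            raise ValueError("retained clones must have templates >= 1")
        if self.productive:
            if not self.cdr3_aa:
                raise ValueError("productive clone with empty CDR3")
            if STOP_SYMBOL in self.cdr3_aa:
                raise ValueError("productive clone contains a stop symbol")

    def key(self, identity: str = "aa"):
        return clone_key(self.cdr3_aa, self.v_gene, self.j_gene, identity)


def clone_key(cdr3_aa: str, v_gene: str, j_gene: str, identity: str = "aa"):
    if identity == "aa":
        return cdr3_aa
    if identity == "aa_vj":
        return (cdr3_aa, v_gene, j_gene)
    raise ValueError(f"unknown identity key {identity!r}; use one of {IDENTITY_KEYS}")


class RepertoireSample:
    """Clones observed in one tissue sample, stored column-wise.

    Parameters
    ----------
    usable_input:
        Total nucleated-cell equivalents usable for TCR sequencing — the
        denominator of T cell density. ``None`` when the assay did not report
        it; density is then absent, never zero.
    """

    def __init__(
        self,
        sample_id: str,
        *,
        cdr3_aa: Sequence[str],
        v_gene: Sequence[str],
        j_gene: Sequence[str],
        templates: Sequence[int],
        productive: Sequence[bool] | None = None,
        cdr3_nt: Sequence[str | None] | None = None,
        patient_id: str | None = None,
        compartment: Compartment | str | None = None,
        usable_input: float | None = None,
        warnings: Iterable[str] = (),
    ) -> None:
        self.sample_id = sample_id
        self.patient_id = patient_id
        self.compartment = Compartment(compartment) if compartment is not None else None
        n = len(cdr3_aa)
        self.cdr3_aa = list(cdr3_aa)
        self.v_gene = list(v_gene)
        self.j_gene = list(j_gene)
        self.templates = np.asarray(templates, dtype=np.int64)
        if productive is None:
            productive = np.ones(n, dtype=bool)
        self.productive = np.asarray(productive, dtype=bool)
        self.cdr3_nt = list(cdr3_nt) if cdr3_nt is not None else None
        if usable_input is not None and usable_input <= 0:
            raise ValueError("usable_input must be positive when given")
        self.usable_input = usable_input
        self.warnings = list(warnings)
        for name, col in (("v_gene", self.v_gene), ("j_gene", self.j_gene)):
            if len(col) != n:
                raise ValueError(f"{name} length mismatch")
        if len(self.templates) != n or len(self.productive) != n:
            raise ValueError("column length mismatch")
        if n and self.templates.min() < 1:
            raise ValueError("retained clones must have templates >= 1")

    # ------------------------------------------------------------------ #

    @classmethod
    def from_clones(
        cls,
        sample_id: str,
        clones: Iterable[Clone],
        **meta,
    ) -> "RepertoireSample":
        clones = list(clones)
        return cls(
            sample_id,
            cdr3_aa=[c.cdr3_aa for c in clones],
            v_gene=[c.v_gene for c in clones],
            j_gene=[c.j_gene for c in clones],
            templates=[c.templates for c in clones],
            productive=[c.productive for c in clones],
            cdr3_nt=[c.cdr3_nt for c in clones],
            **meta,
        )

    @classmethod
    def from_counts(
        cls,
        sample_id: str,
        counts: Mapping[str, int] | Mapping[tuple, int],
        *,
        v_gene: str = "unresolved",
        j_gene: str = "unresolved",
        **meta,
    ) -> "RepertoireSample":
        """Build a sample from an ``{identity key: templates}`` mapping.

        Keys may be bare CDR3 strings or ``(cdr3_aa, v_gene, j_gene)`` tuples.
        """
        aas, vs, js, ts = [], [], [], []
        for key, t in counts.items():
            if t < 1:
                continue
            if isinstance(key, tuple):
                aa, v, j = key
            else:
                aa, v, j = key, v_gene, j_gene
            aas.append(aa)
            vs.append(v)
            js.append(j)
            ts.append(int(t))
        return cls(sample_id, cdr3_aa=aas, v_gene=vs, j_gene=js, templates=ts, **meta)

    # ------------------------------------------------------------------ #

    @property
    def n_clones(self) -> int:
        return len(self.cdr3_aa)

    @property
    def total_templates(self) -> int:
        """Sum of clone template counts (always recomputed, never trusted)."""
        return int(self.templates.sum()) if self.n_clones else 0

    @property
    def clones(self) -> list[Clone]:
        nt = self.cdr3_nt if self.cdr3_nt is not None else [None] * self.n_clones
        return [
            Clone(
                cdr3_aa=self.cdr3_aa[i],
                v_gene=self.v_gene[i],
                j_gene=self.j_gene[i],
                templates=int(self.templates[i]),
                productive=bool(self.productive[i]),
                cdr3_nt=nt[i],
            )
            for i in range(self.n_clones)
        ]

    def productive_only(self) -> "RepertoireSample":
        """Restrict to productive rearrangements (totals recomputed).

        An all-non-productive sample yields an empty repertoire carrying an
        ``"all clones non-productive"`` warning so downstream stages can decide.
        """
        mask = self.productive
        warnings = list(self.warnings)
        if self.n_clones and not mask.any():
            warnings.append("all clones non-productive")
        idx = np.flatnonzero(mask)
        return self._subset(idx, warnings=warnings)

    def _subset(self, idx: np.ndarray, warnings: list[str] | None = None) -> "RepertoireSample":
        return RepertoireSample(
            self.sample_id,
            cdr3_aa=[self.cdr3_aa[i] for i in idx],
            v_gene=[self.v_gene[i] for i in idx],
            j_gene=[self.j_gene[i] for i in idx],
            templates=self.templates[idx],
            productive=self.productive[idx],
            cdr3_nt=[self.cdr3_nt[i] for i in idx] if self.cdr3_nt is not None else None,
            patient_id=self.patient_id,
            compartment=self.compartment,
            usable_input=self.usable_input,
            warnings=self.warnings if warnings is None else warnings,
        )

    def restrict_to_keys(self, keys, identity: str = "aa") -> "RepertoireSample":
        """Restrict the sample to clones whose identity key is in ``keys``."""
        keyset = set(keys)
        idx = np.array(
            [
                i
                for i in range(self.n_clones)
                if clone_key(self.cdr3_aa[i], self.v_gene[i], self.j_gene[i], identity) in keyset
            ],
            dtype=np.int64,
        )
        out = self._subset(idx)
        if out.n_clones == 0:
            out.warnings.append("empty restriction")
        return out

    def counts(self, identity: str = "aa") -> dict:
        """Aggregate template counts by clone identity key."""
        out: dict = {}
        for i in range(self.n_clones):
            k = clone_key(self.cdr3_aa[i], self.v_gene[i], self.j_gene[i], identity)
            out[k] = out.get(k, 0) + int(self.templates[i])
        return out

    def __len__(self) -> int:
        return self.n_clones

    def __repr__(self) -> str:  # pragma: no cover
        comp = self.compartment.value if self.compartment else "?"
        return (
            f"RepertoireSample({self.sample_id!r}, {comp}, "
            f"{self.n_clones} clones, {self.total_templates} templates)"
        )


def as_counts(obj, identity: str = "aa") -> dict:
    """Coerce a sample or mapping into an ``{identity key: count}`` dict."""
    if isinstance(obj, RepertoireSample):
        return obj.counts(identity)
    if isinstance(obj, Mapping):
        return dict(obj)
    raise TypeError(f"cannot interpret {type(obj).__name__} as clone counts")
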