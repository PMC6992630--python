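"""Read/write rearrangement tables and the cohort manifest.

Two TSV dialects are supported out of the box, defined by the bundled
``data/dialects.yaml`` mapping: the immunoSEQ export dialect (``aminoAcid``,
``vGeneName``, ``count (templates)``, ``sequenceStatus`` ...) and an
AIRR-style dialect (``junction_aa``, ``v_call``, ``duplicate_count``,
``productive`` ...).  On read, gene names are normalized, rows with zero
templates are dropped, duplicate (cdr3_aa, v_gene, j_gene) rows are merged by
summing templates, and a parse report is attached to the returned sample.

The cohort manifest is one long-format TSV with one row per (patient,
compartment) sample plus the patient's clinical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .nomenclature import normalize_gene_name
from .repertoire import Compartment, RepertoireSample


class FormatError(ValueError):
    """A rearrangement table or manifest violates its dialect contract."""


@dataclass
class ParseReport:
    rows_read: int = 0
    rows_dropped_zero: int = 0
    rows_failed: int = 0
    rows_merged: int = 0


_DIALECTS: dict | None = None


def dialects() -> dict:
    global _DIALECTS
    if _DIALECTS is None:
        ref = resources.files("tcrrep.data").joinpath("dialects.yaml")
        with ref.open("r", encoding="utf-8") as fh:
            _DIALECTS = yaml.safe_load(fh)
    return _DIALECTS


def _dialect(name: str) -> dict:
    try:
        return dialects()[name]
    except KeyError:
        raise FormatError(f"unknown dialect {name!r}; known: {sorted(dialects())}") from None


def read_rearrangements(
    path,
    dialect: str = "immunoseq",
    *,
    sample_id: str | None = None,
    patient_id: str | None = None,
    compartment: Compartment | str | None = None,
    usable_input: float | None = None,
    max_bad_row_fraction: float = 0.01,
) -> RepertoireSample:
    """Read one rearrangement TSV into a validated :class:`RepertoireSample`.

    Raises :class:`FormatError` if a required column is missing, the data
    section is empty, or more than ``max_bad_row_fraction`` of rows carry an
    unparseable template count.
    """
    path = Path(path)
    spec = _dialect(dialect)
    colmap = spec["columns"]
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [c for c, f in colmap.items() if f != "cdr3_nt"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r} ({dialect} dialect)")
    if len(df) == 0:
        raise FormatError(f"{path.name}: no rearrangements")

    inverse = {f: c for c, f in colmap.items()}
    report = ParseReport(rows_read=len(df))

    raw_counts = pd.to_numeric(df[inverse["templates"]], errors="coerce")
    bad = raw_counts.isna() | (raw_counts % 1 != 0) | (raw_counts < 0)
    report.rows_failed = int(bad.sum())
    if report.rows_failed > max_bad_row_fraction * len(df):
        raise FormatError(
            f"{path.name}: {report.rows_failed}/{len(df)} rows have unparseable "
            f"template counts (> {max_bad_row_fraction:.0%} allowed)"
        )
    df = df.loc[~bad].copy()
    counts = raw_counts.loc[~bad].astype(np.int64)
    zero = counts == 0
    report.rows_dropped_zero = int(zero.sum())
    df = df.loc[~zero]
    counts = counts.loc[~zero]
    if len(df) == 0:
        raise FormatError(f"{path.name}: no rearrangements")

    true_token = str(spec["productive_true"]).lower()
    productive = df[inverse["productive"]].astype(str).str.strip().str.lower().isin(
        {true_token, "true", "t"} if true_token in {"t", "true"} else {true_token}
    )
    work = pd.DataFrame(
        {
            "cdr3_aa": df[inverse["cdr3_aa"]].astype(str).str.strip(),
            "v_gene": [normalize_gene_name(v) for v in df[inverse["v_gene"]]],
            "j_gene": [normalize_gene_name(j) for j in df[inverse["j_gene"]]],
            "templates": counts.to_numpy(),
            "productive": productive.to_numpy(),
        }
    )
    nt_col = inverse.get("cdr3_nt")
    has_nt = nt_col is not None and nt_col in df.columns
    if has_nt:
        work["cdr3_nt"] = df[nt_col].astype(str).str.strip()

    agg = {"templates": "sum", "productive": "max"}
    if has_nt:
        agg["cdr3_nt"] = "first"
    merged = (
        work.groupby(["cdr3_aa", "v_gene", "j_gene"], sort=True, as_index=False)
        .agg(agg)
    )
    report.rows_merged = len(work) - len(merged)

    sample = RepertoireSample(
        sample_id or path.stem,
        cdr3_aa=merged["cdr3_aa"].tolist(),
        v_gene=merged["v_gene"].tolist(),
        j_gene=merged["j_gene"].tolist(),
        templates=merged["templates"].to_numpy(),
        productive=merged["productive"].to_numpy(dtype=bool),
        cdr3_nt=merged["cdr3_nt"].tolist() if has_nt else None,
        patient_id=patient_id,
        compartment=compartment,
        usable_input=usable_input,
    )
    sample.parse_report = report
    return sample


def write_rearrangements(sample: RepertoireSample, path, dialect: str = "immunoseq") -> None:
    """Write a sample in the requested dialect with its fixed column order."""
    spec = _dialect(dialect)
    inverse = {f: c for c, f in spec["columns"].items()}
    nt = sample.cdr3_nt if sample.cdr3_nt is not None else [""] * sample.n_clones
    data = {
        inverse["cdr3_nt"]: ["" if x is None else x for x in nt],
        inverse["cdr3_aa"]: sample.cdr3_aa,
        inverse["v_gene"]: sample.v_gene,
        inverse["j_gene"]: sample.j_gene,
        inverse["templates"]: sample.templates,
        inverse["productive"]: [
            spec["productive_true"] if p else spec["productive_false"]
            for p in sample.productive
        ],
    }
    df = pd.DataFrame(data)[spec["write_order"]]
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def productive_filter(sample: RepertoireSample) -> RepertoireSample:
    """Retain productive clones only; totals recomputed (pipeline-wide rule)."""
    return sample.productive_only()


# --------------------------------------------------------------------------- #
# Cohort manifest
# --------------------------------------------------------------------------- #

MANIFEST_COLUMNS = [
    "patient_id",
    "sample_id",
    "compartment",
    "path",
    "usable_input",
    "age",
    "sex",
    "histology",
    "stage",
    "smoking",
    "tumor_size",
    "os_time",
    "os_event",
    "lung_cancer_death",
    "relapse",
]

CLINICAL_COLUMNS = MANIFEST_COLUMNS[5:]


@dataclass
class CohortManifest:
    """Patients x samples x clinical covariates, long format (one row/sample)."""

    table: pd.DataFrame
    base_dir: Path | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in ("patient_id", "compartment", "path") if c not in t.columns]
        if missing:
            raise FormatError(f"manifest missing required columns: {missing}")
        dup = t.duplicated(subset=["patient_id", "compartment"])
        if dup.any():
            pairs = t.loc[dup, ["patient_id", "compartment"]].to_records(index=False)
            raise FormatError(f"duplicate (patient, compartment) rows: {list(pairs)[:5]}")
        if "os_time" in t.columns:
            ost = pd.to_numeric(t["os_time"], errors="coerce")
            if (ost.dropna() < 0).any():
                raise FormatError("os_time must be >= 0")

    @property
    def patients(self) -> pd.DataFrame:
        """One row per patient with the clinical covariates."""
        cols = ["patient_id"] + [c for c in CLINICAL_COLUMNS if c in self.table.columns]
        return self.table[cols].drop_duplicates("patient_id").reset_index(drop=True)

    def sample_rows(self, compartment: Compartment | str | None = None) -> pd.DataFrame:
        t = self.table
        if compartment is not None:
            t = t[t["compartment"] == Compartment(compartment).value]
        return t.reset_index(drop=True)

    def resolve_path(self, path: str) -> Path:
        p = Path(path)
        if not p.is_absolute() and self.base_dir is not None:
            p = self.base_dir / p
        return p

    def load_sample(
        self, patient_id: str, compartment: Compartment | str, dialect: str = "immunoseq"
    ) -> RepertoireSample:
        comp = Compartment(compartment).value
        t = self.table
        row = t[(t["patient_id"] == patient_id) & (t["compartment"] == comp)]
        if len(row) == 0:
            raise KeyError(f"no sample for ({patient_id}, {comp})")
        row = row.iloc[0]
        key = (patient_id, comp)
        if key not in self._cache:
            usable = row.get("usable_input")
            self._cache[key] = read_rearrangements(
                self.resolve_path(row["path"]),
                dialect,
                sample_id=row.get("sample_id") or f"{patient_id}_{comp}",
                patient_id=patient_id,
                compartment=comp,
                usable_input=float(usable) if pd.notna(usable) else None,
            )
        return self._cache[key]


def read_manifest(path, check_files: bool = True) -> CohortManifest:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    table = pd.read_csv(path, sep=sep)
    manifest = CohortManifest(table=table, base_dir=path.parent)
    if check_files:
        for p in table["path"]:
            rp = manifest.resolve_path(p)
            if not rp.exists():
                raise FormatError(f"manifest references missing file: {rp}")
    return manifest


def write_manifest(table: pd.DataFrame, path) -> None:
    cols = [c for c in MANIFEST_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")
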