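"""TRBV/TRBJ gene nomenclature normalization.

immunoSEQ exports name genes as e.g. ``TCRBV09-01`` or ``TCRBV12-03/12-04``
while AIRR-style tables use IMGT names such as ``TRBV9`` or ``TRBV12-3``.
V-gene usage comparisons (e.g. the Fisher test behind viral motif
classification) require one canonical form, so both styles are mapped onto
IMGT-style names. Names that cannot be resolved map to the sentinel
``"unresolved"`` — never dropped silently.

The mapping is rule-based: strip the vendor prefix, drop leading zeros and
allele suffixes, and render single-member families without the ``-member``
part (IMGT convention, e.g. TRBV9 not TRBV9-1). A bundled two-column fixture
(``data/trbv_nomenclature.tsv``) doubles as a lookup table and a validation
oracle for the rules.
"""

from __future__ import annotations

import csv
import re
from functools import lru_cache
from importlib import resources

UNRESOLVED = "unresolved"

#: TRBV families with a single functional member, written dash-less by IMGT.
_DASHLESS_V_FAMILIES = {1, 2, 9, 13, 14, 15, 16, 17, 18, 19, 26, 27, 28, 30}

_GENE_RE = re.compile(
    r"^(?:TCRB|TRB)([VJ])0*(\d+)(?:[-.]0*(\d+))?(?:\*\d+)?$", re.IGNORECASE
)


@lru_cache(maxsize=1)
def _lookup_table() -> dict[str, str]:
    table: dict[str, str] = {}
    ref = resources.files("tcrrep.data").joinpath("trbv_nomenclature.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            table[row["immunoseq"].upper()] = row["imgt"]
    return table


@lru_cache(maxsize=4096)
def normalize_gene_name(raw: str) -> str:
    """Map an immunoSEQ- or IMGT-style gene name onto its canonical form.

    Idempotent: canonical names map to themselves. Unresolvable input
    (ambiguous ``/`` names, garbage, empty strings) yields ``"unresolved"``.
    """
    if raw is None:
        return UNRESOLVED
    name = str(raw).strip()
    if not name:
        return UNRESOLVED
    upper = name.upper()
    if upper == UNRESOLVED.upper():
        return UNRESOLVED
    if upper in _lookup_table():
        return _lookup_table()[upper]
    m = _GENE_RE.match(upper)
    if m is None:
        return UNRESOLVED
    segment, family, member = m.group(1), int(m.group(2)), m.group(3)
    if segment == "J":
        return f"TRBJ{family}-{int(member) if member else 1}"
    if family in _DASHLESS_V_FAMILIES:
        return f"TRBV{family}"
    return f"TRBV{family}-{int(member) if member else 1}"
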