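"""Post-search retention filtering of peptide-spectrum matches (PSMs).

PSMs were searched against a composite database of the canonical proteome,
an sORF peptide partition, and common contaminants.  A match supports an
sORF-encoded peptide only when it maps *solely* to the sORF partition, covers
at least 30% of the spectrum and passes FDR < 0.01.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

PARTITIONS = ("canonical_proteome", "sorf_db", "contaminants")


def _partition_set(value) -> frozenset:
    if isinstance(value, str):
        return frozenset(p for p in value.split(";") if p)
    return frozenset(value)


def filter_psms(records: pd.DataFrame, min_coverage: float = 0.30,
                max_fdr: float = 0.01) -> tuple[pd.DataFrame, dict[str, int]]:
    """Retain PSMs that uniquely support sORF peptides.

    A record is retained iff its ``matched_partitions`` equals ``{sorf_db}``
    exactly, ``spectrum_coverage`` >= ``min_coverage`` (inclusive) and
    ``fdr`` < ``max_fdr`` (strict).  ``matched_partitions`` may be a
    semicolon-joined string or an iterable of partition names.

    Returns ``(retained, rejection_counts)`` where each rejected record
    increments every rule it violates.
    """
    counts = {"not_solely_sorf": 0, "min_coverage": 0, "max_fdr": 0}
    keep = []
    for _, row in records.iterrows():
        parts = _partition_set(row["matched_partitions"])
        if not parts:
            raise ValueError(f"PSM {row.get('psm_id')!r} has empty matched_partitions")
        violated = []
        if parts != frozenset(("sorf_db",)):
            violated.append("not_solely_sorf")
        if row["spectrum_coverage"] < min_coverage:
            violated.append("min_coverage")
        if not (row["fdr"] < max_fdr):
            violated.append("max_fdr")
        keep.append(not violated)
        for rule in violated:
            counts[rule] += 1
    retained = records.loc[keep].copy() if len(records) else records.copy()
    return retained, counts
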