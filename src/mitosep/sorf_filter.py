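"""Ribo-seq quality filtering of small ORF (sORF) candidates.

Candidate sORFs come in four annotation classes — short coding sequences
(``cds``), long non-coding RNAs (``lncrna``), upstream ORFs (``uorf``) and
intergenic ORFs (``intergenic``) — each with its own set of ribosome-profiling
quality thresholds.  All classes require a minimum ORF-score (a 3-nt
periodicity statistic); the non-genic classes additionally require length,
FLOSS classification, replication across ribo-seq datasets and, for intergenic
ORFs, distance from neighbouring genes.

The quality metrics themselves (in-frame coverage, coverage uniformity, FLOSS
class) are consumed as input columns; they are catalog-level statistics, not
recomputed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

ANNOTATION_CLASSES = ("cds", "lncrna", "uorf", "intergenic")

#: Canonical rule names used in violation lists and rejection counts.
RULES = (
    "min_orf_score",
    "min_in_frame_coverage",
    "uniformity",
    "min_aa_length",
    "floss",
    "min_datasets",
    "min_gene_distance",
)


@dataclass(frozen=True)
class ClassThresholds:
    """Thresholds applied to one annotation class.

    ``None`` disables a rule for the class.  All numeric thresholds are
    inclusive (``>=`` / closed uniformity interval) except
    ``min_gene_distance_nt``, which is strict (``>``): gene distance is
    specified as "more than 1 kb".
    """

    min_orf_score: float = 6.0
    min_in_frame_coverage: float = 0.0
    uniformity_low: float = -1.0
    uniformity_high: float = 1.0
    min_aa_length: Optional[int] = None
    require_good_floss: bool = False
    min_datasets: Optional[int] = None
    min_gene_distance_nt: Optional[float] = None

    def __post_init__(self) -> None:
        if self.uniformity_low > self.uniformity_high:
            raise ValueError("uniformity_low must be <= uniformity_high")


def default_config() -> dict[str, ClassThresholds]:
    """Per-class default thresholds.

    cds: ORF-score >= 6, coverage >= 0.5, uniformity in [-1, 1] (the published
    window; vacuous for a statistic bounded in [-1, 1] but kept verbatim).
    lncrna: coverage >= 0.5, uniformity in [-0.5, 0.5].
    uorf: coverage >= 0.7, uniformity in [-0.3, 0.3], >= 20 aa, good FLOSS,
    detected in >= 10 ribo-seq datasets.
    intergenic: > 1000 nt from both neighbouring genes, coverage >= 0.9,
    uniformity in [-0.3, 0.3], >= 20 aa, good FLOSS, >= 1 dataset.
    """
    return {
        "cds": ClassThresholds(min_in_frame_coverage=0.5,
                               uniformity_low=-1.0, uniformity_high=1.0),
        "lncrna": ClassThresholds(min_in_frame_coverage=0.5,
                                  uniformity_low=-0.5, uniformity_high=0.5),
        "uorf": ClassThresholds(min_in_frame_coverage=0.7,
                                uniformity_low=-0.3, uniformity_high=0.3,
                                min_aa_length=20, require_good_floss=True,
                                min_datasets=10),
        "intergenic": ClassThresholds(min_in_frame_coverage=0.9,
                                      uniformity_low=-0.3, uniformity_high=0.3,
                                      min_aa_length=20, require_good_floss=True,
                                      min_datasets=1,
                                      min_gene_distance_nt=1000.0),
    }


@dataclass
class FilterConfig:
    """Bundle of per-annotation-class thresholds."""

    per_class: dict[str, ClassThresholds] = field(default_factory=default_config)

    def thresholds_for(self, annotation_class: str) -> ClassThresholds:
        try:
            return self.per_class[annotation_class]
        except KeyError:
            raise ValueError(
                f"unknown annotation class {annotation_class!r}; "
                f"expected one of {ANNOTATION_CLASSES}"
            ) from None


def _require(record: Mapping, fields: list[str]) -> None:
    for f in fields:
        if f not in record or record[f] is None or (
            isinstance(record[f], float) and pd.isna(record[f])
        ):
            raise ValueError(f"sORF record missing required field {f!r}")


def passes_filters(record: Mapping, config: Optional[FilterConfig] = None
                   ) -> tuple[bool, list[str]]:
    """Evaluate one sORF record against its class's thresholds.

    Returns ``(decision, violated_rules)``; the decision is True iff every
    applicable rule holds.  Raises :class:`ValueError` naming the field when a
    field required for the record's class is missing.
    """
    if config is None:
        config = FilterConfig()
    cls = record.get("annotation_class")
    thr = config.thresholds_for(cls)

    required = ["orf_score", "in_frame_coverage", "coverage_uniformity"]
    if thr.min_aa_length is not None:
        required.append("aa_length")
    if thr.require_good_floss:
        required.append("floss_class")
    if thr.min_datasets is not None:
        required.append("n_ribo_datasets")
    if thr.min_gene_distance_nt is not None:
        required += ["upstream_distance_nt", "downstream_distance_nt"]
    _require(record, required)

    violated: list[str] = []
    if record["orf_score"] < thr.min_orf_score:
        violated.append("min_orf_score")
    if record["in_frame_coverage"] < thr.min_in_frame_coverage:
        violated.append("min_in_frame_coverage")
    if not (thr.uniformity_low <= record["coverage_uniformity"]
            <= thr.uniformity_high):
        violated.append("uniformity")
    if thr.min_aa_length is not None and record["aa_length"] < thr.min_aa_length:
        violated.append("min_aa_length")
    if thr.require_good_floss and record["floss_class"] != "good":
        violated.append("floss")
    if thr.min_datasets is not None and record["n_ribo_datasets"] < thr.min_datasets:
        violated.append("min_datasets")
    if thr.min_gene_distance_nt is not None:
        # strict: "> 1 kb" from both neighbours
        if not (record["upstream_distance_nt"] > thr.min_gene_distance_nt
                and record["downstream_distance_nt"] > thr.min_gene_distance_nt):
            violated.append("min_gene_distance")
    return (not violated), violated


def filter_table(records: pd.DataFrame, config: Optional[FilterConfig] = None
                 ) -> tuple[pd.DataFrame, dict[str, int], dict[str, int]]:
    """Apply :func:`passes_filters` row-wise.

    Returns ``(kept, rejection_counts, summary)`` where ``rejection_counts``
    attributes each rejected record to *every* rule it violates and
    ``summary`` reports the retained sORF and distinct gene counts.
    """
    if config is None:
        config = FilterConfig()
    counts = {rule: 0 for rule in RULES}
    keep_mask = []
    for _, row in records.iterrows():
        ok, violated = passes_filters(row, config)
        keep_mask.append(ok)
        for rule in violated:
            counts[rule] += 1
    kept = records.loc[keep_mask].copy() if len(records) else records.copy()
    summary = {
        "n_sorfs": int(len(kept)),
        "n_genes": int(kept["gene_id"].nunique()) if len(kept) else 0,
    }
    return kept, counts, summary


def dedupe_isoforms(records: pd.DataFrame
                    ) -> tuple[pd.DataFrame, list[dict]]:
    """Remove redundant isoforms within each gene.

    Within a gene, the longest isoform (ties broken lexicographically by
    ``sorf_id``) is kept; any other isoform whose peptide sequence is an exact
    substring of that longest sequence is removed as redundant.  Isoforms not
    contained in the longest sequence are kept.
    """
    removal_log: list[dict] = []
    keep_idx: list = []
    for gene, grp in records.groupby("gene_id", sort=False):
        # longest first, ties broken by sorf_id ascending
        ordered = grp.assign(_len=grp["peptide_seq"].str.len()).sort_values(
            ["_len", "sorf_id"], ascending=[False, True]
        )
        longest = ordered.iloc[0]
        keep_idx.append(longest.name)
        for idx, row in ordered.iloc[1:].iterrows():
            if row["peptide_seq"] in longest["peptide_seq"]:
                removal_log.append({
                    "gene_id": gene,
                    "removed": row["sorf_id"],
                    "contained_in": longest["sorf_id"],
                })
            else:
                keep_idx.append(idx)
    kept = records.loc[[i for i in records.index if i in set(keep_idx)]].copy()
    return kept, removal_log
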