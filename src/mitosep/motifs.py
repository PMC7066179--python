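"""Mitochondrial targeting-motif classification of candidate peptides.

Three import signals are recognised:

* **MTS** — a cleavable N-terminal matrix-targeting sequence, called by
  consensus over external predictor outputs: TargetP says "mitochondria" at
  reliability class 1 or 2 AND (MitoFate > 0.8 OR MitoProt > 0.8).
* **TMD** — a transmembrane helix of *modest* hydrophobicity.  Mitochondrial
  TMDs are on average less hydrophobic than secretory ones, so a hydrophobicity
  cap (default 3 on the Kyte–Doolittle 19-residue window mean) excludes
  strongly hydrophobic secretory membrane proteins.
* **CXnC** — twin cysteine pairs of intermembrane-space proteins: two CX9C,
  two CX3C, or one CX9C plus one CX10C (non-overlapping occurrences).

External predictors (TargetP, MitoFate, MitoProt, TMHMM, SignalP) are never
executed; their scores arrive as optional input columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Kyte–Doolittle 19-residue window mean above which a span is helix-like.
KD_HELIX_THRESHOLD = 1.6

#: (label, number of X residues) for the twin-cysteine patterns.
CYS_PATTERNS = (("CX9C", 9), ("CX3C", 3), ("CX10C", 10))


@dataclass(frozen=True)
class PredictorScores:
    """External predictor outputs for one peptide; any field may be absent."""

    peptide_id: str = ""
    targetp_location: Optional[str] = None          # "mitochondria" / "other"
    targetp_reliability_class: Optional[int] = None  # 1 (best) .. 5
    mitofate_score: Optional[float] = None
    mitoprot_score: Optional[float] = None
    tmhmm_tmd: Optional[bool] = None
    signalp_call: Optional[bool] = None

    def __post_init__(self):
        rc = self.targetp_reliability_class
        if rc is not None and rc not in (1, 2, 3, 4, 5):
            raise ValueError(f"TargetP reliability class must be 1..5, got {rc}")


def mts_consensus(scores: PredictorScores) -> Optional[bool]:
    """Consensus MTS call over external predictor scores.

    True iff TargetP predicts mitochondria at reliability class 1 or 2 and
    either MitoFate or MitoProt exceeds 0.8 (strictly).  Absent MitoFate /
    MitoProt scores fail their clause.  Returns ``None`` ("insufficient
    evidence") when the TargetP fields themselves are missing.
    """
    if scores.targetp_location is None or scores.targetp_reliability_class is None:
        return None
    if scores.targetp_location != "mitochondria":
        return False
    if scores.targetp_reliability_class not in (1, 2):
        return False
    mf = scores.mitofate_score
    mp = scores.mitoprot_score
    return (mf is not None and mf > 0.8) or (mp is not None and mp > 0.8)


def _validate_seq(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")
    return seq


def _find_pattern(seq: str, n_x: int) -> list[tuple[int, int]]:
    """All (start, end) half-open spans of C-X{n_x}-C, overlaps included."""
    span = n_x + 2
    return [(i, i + span) for i in range(len(seq) - span + 1)
            if seq[i] == "C" and seq[i + span - 1] == "C"]


def _max_nonoverlapping(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Greedy left-to-right selection of non-overlapping fixed-length spans."""
    chosen: list[tuple[int, int]] = []
    for s, e in spans:
        if not chosen or s >= chosen[-1][1]:
            chosen.append((s, e))
    return chosen


def scan_twin_cysteine(seq: str) -> tuple[bool, dict[str, list[tuple[int, int]]]]:
    """Twin-cysteine-pair scan for intermembrane-space targeting.

    Returns ``(decision, positions)`` where positions maps each pattern label
    to its non-overlapping occurrences (0-based half-open, greedy
    left-to-right).  The decision is true iff the peptide carries two
    non-overlapping CX9C, two non-overlapping CX3C, or one CX9C plus one
    CX10C that do not overlap.
    """
    seq = _validate_seq(seq)
    all_spans = {label: _find_pattern(seq, nx) for label, nx in CYS_PATTERNS}
    nonover = {label: _max_nonoverlapping(spans)
               for label, spans in all_spans.items()}
    decision = (len(nonover["CX9C"]) >= 2 or len(nonover["CX3C"]) >= 2
                or _has_disjoint_pair(all_spans["CX9C"], all_spans["CX10C"]))
    return decision, nonover


def _has_disjoint_pair(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> bool:
    for s1, e1 in a:
        for s2, e2 in b:
            if e1 <= s2 or e2 <= s1:
                return True
    return False


def window_hydrophobicity(seq: str, window: int = 19,
                          scale: Optional[dict] = None) -> list[float]:
    """Sliding-window mean hydrophobicity (Kyte–Doolittle by default)."""
    scale = KYTE_DOOLITTLE if scale is None else scale
    vals = [scale[a] for a in seq]
    out = []
    s = sum(vals[:window])
    out.append(s / window)
    for i in range(window, len(vals)):
        s += vals[i] - vals[i - window]
        out.append(s / window)
    return out


@dataclass
class TmdResult:
    status: str                  # "called" | "rejected" | "none" | "too_short"
    decision: bool
    best_window: Optional[tuple[int, int]] = None  # 0-based half-open
    best_score: Optional[float] = None
    reason: str = ""


def tmd_call(seq: str, scores: Optional[PredictorScores] = None,
             window: int = 19, scale: Optional[dict] = None,
             max_hydrophobicity: float = 3.0,
             helix_threshold: float = KD_HELIX_THRESHOLD) -> TmdResult:
    """Transmembrane-domain call with a hydrophobicity cap.

    A TMD is called when an upstream predictor flags one (TMHMM or SignalP,
    when provided) or the best window mean exceeds ``helix_threshold``, AND
    the maximum window hydrophobicity does not exceed ``max_hydrophobicity``
    (strongly hydrophobic spans are secretory-like and rejected).
    """
    seq = _validate_seq(seq)
    if len(seq) < window:
        return TmdResult("too_short", False, reason="sequence shorter than window")
    means = window_hydrophobicity(seq, window=window, scale=scale)
    best_i = max(range(len(means)), key=lambda i: means[i])
    best = means[best_i]
    span = (best_i, best_i + window)
    flagged = scores is not None and (bool(scores.tmhmm_tmd)
                                      or bool(scores.signalp_call))
    helixlike = flagged or best > helix_threshold
    if not helixlike:
        return TmdResult("none", False, span, best, "no helix-like window or flag")
    if best > max_hydrophobicity:
        return TmdResult("rejected", False, span, best,
                         "window hydrophobicity above cap (secretory-like)")
    return TmdResult("called", True, span, best,
                     "predictor flag" if flagged else "window above helix threshold")


@dataclass
class MotifCall:
    peptide_id: str
    label: str                   # "MTS" | "TMD" | "CXnC" | "none"
    evidence: dict = field(default_factory=dict)


def motif_classify(seq: str, scores: Optional[PredictorScores] = None,
                   window: int = 19, scale: Optional[dict] = None,
                   max_hydrophobicity: float = 3.0,
                   helix_threshold: float = KD_HELIX_THRESHOLD) -> MotifCall:
    """Classify one peptide by targeting motif, precedence MTS > TMD > CXnC.

    An N-terminal cleavable presequence dominates; twin cysteine pairs are the
    fallback internal signal.
    """
    pid = scores.peptide_id if scores is not None else ""
    if scores is not None and mts_consensus(scores) is True:
        return MotifCall(pid, "MTS", {"rule": "targetp+mitofate/mitoprot consensus"})
    tmd = tmd_call(seq, scores, window=window, scale=scale,
                   max_hydrophobicity=max_hydrophobicity,
                   helix_threshold=helix_threshold)
    if tmd.decision:
        return MotifCall(pid, "TMD", {
            "rule": tmd.reason, "window": tmd.best_window,
            "window_hydrophobicity": tmd.best_score})
    cys, positions = scan_twin_cysteine(seq)
    if cys:
        return MotifCall(pid, "CXnC", {"rule": "twin cysteine pairs",
                                       "positions": positions})
    return MotifCall(pid, "none", {})
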