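"""Quantitative proteomics statistics for the 3 vs 3 TMT comparison.

Implements the normalization and testing route used to characterise the
knockout mitochondrial proteome: log2 transform and per-channel median
subtraction; filtering to proteins quantified in all six channels from more
than two unique peptides; re-normalization to the mitochondrial proteins (to
absorb variance introduced by mitochondrial isolation); per-protein two-sided
Student's t-test volcano statistics; per-complex summarization with an
intragroup-SD filter; plus paired metabolite fold-change tests and the
citrate-synthase activity formula used to normalise respirometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CONTROL, KO = "control", "ko"


def _split_groups(columns: pd.Index, groups: pd.Series) -> tuple[list, list]:
    ctrl = [c for c in columns if groups[c] == CONTROL]
    ko = [c for c in columns if groups[c] == KO]
    return ctrl, ko


def tmt_normalize(intensities: pd.DataFrame, n_unique_peptides: pd.Series,
                  already_log2: bool = False
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median-center log2 reporter intensities and filter identifications.

    Rows are kept only when all six channels have valid values and the
    quantification rests on more than 2 unique peptides.  Columns are centered
    by subtracting their median (computed on the retained rows), so every
    output column has median exactly 0.

    Returns ``(normalized, dropped_log)`` where the log records each dropped
    protein and the rule it failed.
    """
    m = intensities.astype(float)
    if not already_log2:
        if (m <= 0).any().any():
            bad = m.index[(m <= 0).any(axis=1)][:5].tolist()
            raise ValueError(f"raw intensities must be positive (e.g. {bad})")
        m = np.log2(m)
    valid = m.notna().all(axis=1)
    enough = n_unique_peptides.reindex(m.index) > 2
    dropped = []
    for pid in m.index[~(valid & enough)]:
        rules = []
        if not valid[pid]:
            rules.append("missing_values")
        if not bool(enough[pid]):
            rules.append("unique_peptides<=2")
        dropped.append({"protein": pid, "rules": ";".join(rules)})
    kept = m.loc[valid & enough]
    kept = kept - kept.median(axis=0)
    return kept, pd.DataFrame(dropped, columns=["protein", "rules"])


def mito_renormalize(normalized: pd.DataFrame, mito_flags: pd.Series
                     ) -> pd.DataFrame:
    """Subtract the per-channel mean of mitochondrial proteins from every row.

    Absorbs between-sample variance introduced by mitochondrial isolation;
    afterwards the mito-row mean of every column is exactly 0.
    """
    flags = mito_flags.reindex(normalized.index).fillna(False).astype(bool)
    if not flags.any():
        raise ValueError("no mitochondrial proteins present; cannot re-normalize")
    mito_mean = normalized.loc[flags].mean(axis=0)
    return normalized - mito_mean


@dataclass
class DEResult:
    protein: str
    log2fc: float
    p_value: float
    flagged: bool = False        # zero within-group variance in both groups


def volcano(matrix: pd.DataFrame, groups: pd.Series,
            welch: bool = False) -> pd.DataFrame:
    """Per-protein KO vs control differential statistics.

    log2 fold change is the difference of group means (values are already
    log2); the p-value is a two-sided unpaired Student's t-test with pooled
    variance (Welch's correction available behind ``welch``).  Rows where both
    groups have zero variance get an undefined p (NaN) and are flagged.
    """
    ctrl_cols, ko_cols = _split_groups(matrix.columns, groups)
    if not ctrl_cols or not ko_cols:
        raise ValueError("both control and ko channels are required")
    a = matrix[ko_cols].to_numpy(float)
    b = matrix[ctrl_cols].to_numpy(float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    t = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    p = np.asarray(t.pvalue, float)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p[zero_var] = np.nan
    # identical groups: define p = 1 rather than NaN when the difference is 0
    p[zero_var & (log2fc == 0)] = 1.0
    return pd.DataFrame({
        "log2fc": log2fc,
        "p_value": p,
        "flagged": zero_var & (log2fc != 0),
    }, index=matrix.index)


def summarize_by_complex(matrix: pd.DataFrame, groups: pd.Series,
                         complex_membership: pd.Series,
                         sd_threshold: float = 2.0,
                         subunit: Optional[pd.Series] = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median KO/control log2 ratios per respiratory-chain complex.

    Per protein, the KO-minus-control difference of group medians is computed;
    proteins whose intragroup standard deviation reaches ``sd_threshold`` in
    either group are excluded as too variable (2 for zebrafish-like runs, 0.6
    for mouse-like).  When ``subunit`` maps several isoforms to one subunit,
    the most altered retained isoform represents it.  Complexes with no
    retained protein are reported as missing (NaN).

    Returns ``(per_complex, per_protein)``.
    """
    ctrl_cols, ko_cols = _split_groups(matrix.columns, groups)
    med_ratio = (matrix[ko_cols].median(axis=1)
                 - matrix[ctrl_cols].median(axis=1))
    intrasd = pd.concat([matrix[ctrl_cols].std(axis=1, ddof=1),
                         matrix[ko_cols].std(axis=1, ddof=1)], axis=1).max(axis=1)
    retained = intrasd < sd_threshold
    per_protein = pd.DataFrame({
        "median_log2_ratio": med_ratio,
        "intragroup_sd": intrasd,
        "retained": retained,
        "complex": complex_membership.reindex(matrix.index),
    })
    rows = per_protein[per_protein["retained"]].copy()
    if subunit is not None:
        rows["subunit"] = subunit.reindex(rows.index)
        idx = (rows.assign(_a=rows["median_log2_ratio"].abs())
               .sort_values("_a", ascending=False)
               .drop_duplicates(subset=["complex", "subunit"]).index)
        rows = rows.loc[idx]
    per_complex = (rows.groupby("complex")["median_log2_ratio"].median()
                   .reindex(sorted(complex_membership.dropna().unique())))
    return per_complex.to_frame("median_log2_ratio"), per_protein


def metabolite_fold(wt: pd.DataFrame, ko: pd.DataFrame) -> pd.DataFrame:
    """Paired fold-change tests across metabolites.

    ``wt`` / ``ko`` are metabolites x replicate-clutch concentration tables
    with matching shapes (replicates paired by clutch, i.e. by column).
    Returns per-metabolite KO/WT mean fold change, the two-sided paired-t
    p-value and its Bonferroni-corrected version (multiplied by the number of
    metabolites, capped at 1).
    """
    if wt.shape != ko.shape or list(wt.index) != list(ko.index):
        raise ValueError("wt and ko tables must be paired: same metabolites "
                         "and same number of replicate clutches")
    m = len(wt.index)
    rows = []
    for met in wt.index:
        x, y = ko.loc[met].to_numpy(float), wt.loc[met].to_numpy(float)
        fold = x.mean() / y.mean()
        if np.allclose(x, y):
            p = 1.0
        else:
            p = float(stats.ttest_rel(x, y).pvalue)
        rows.append({"metabolite": met, "fold_change": fold, "p_value": p,
                     "p_bonferroni": min(1.0, p * m)})
    return pd.DataFrame(rows).set_index("metabolite")


def cs_activity(times: Sequence[float], absorbances: Sequence[float]) -> float:
    """Citrate synthase activity from a DTNB absorbance time series.

    activity = mean over i >= 1 of (A_i - A_0) / (t_i - t_0): the average of
    the secant slopes from the first point, in absorbance units per time unit.
    For an exactly linear series this equals the slope regardless of spacing.
    """
    t = np.asarray(times, float)
    a = np.asarray(absorbances, float)
    if t.ndim != 1 or t.shape != a.shape or len(t) < 2:
        raise ValueError("need matching 1-d series with at least 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    return float(np.mean((a[1:] - a[0]) / (t[1:] - t[0])))


def ocr_per_cs(ocr: float, cs: float) -> float:
    """Oxygen consumption normalised by citrate synthase activity."""
    if cs <= 0:
        raise ValueError("CS activity must be positive")
    return ocr / cs
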