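"""Co-expression classification of candidate genes as mitochondrial.

The procedure scores each candidate gene by how closely its co-expression
profile resembles that of known mitochondrial genes:

1. per test gene, rank every other expressed gene by Spearman correlation;
2. run preranked GSEA of a gene-set collection against each ranked list and
   assemble a gene x gene-set NES matrix (NES zeroed where the permutation
   p-value exceeds 0.05);
3. retain informative gene sets — those where many known-mitochondrial
   "classifier" genes show strong |NES| — and drop oversized sets;
4. PCA on the standardized NES matrix, then k-means for every cluster number
   k in 2..15; at each k, clusters are labelled positive/negative by a mito
   percentage threshold chosen to maximize accuracy on a small training set of
   short mitochondrial/non-mitochondrial proteins;
5. each candidate receives the fraction of cluster numbers in which it fell
   in a positive cluster (the "k-means score", -1 when not expressed), and is
   called mitochondrial when its score averaged over datasets reaches 0.75.

Roles: ``classifier_mito`` / ``classifier_nonmito`` define cluster labelling,
``training_mito_sep`` / ``training_nonmito_sep`` select the per-k threshold,
``candidate`` genes are the ones being scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .gsea import gsea_batch, ranked_from_correlations, spearman_matrix

ROLES = ("classifier_mito", "classifier_nonmito",
         "training_mito_sep", "training_nonmito_sep", "candidate")

NOT_EXPRESSED = -1.0


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix plus gene role labels."""

    expr: pd.DataFrame
    roles: pd.Series  # gene -> role
    dataset_id: str = "dataset"

    def genes_with_role(self, *roles: str) -> list[str]:
        wanted = set(roles)
        return [g for g in self.expr.index
                if self.roles.get(g) in wanted]


def clean_dataset(ds: ExpressionDataset, min_sample_fraction: float = 0.5
                  ) -> tuple[ExpressionDataset, pd.Series]:
    """Drop genes not expressed in more than ``min_sample_fraction`` of samples.

    A gene counts as expressed when it has at least one read (value >= 1) in
    strictly more than the given fraction of samples (default: half).
    """
    if not 0 < min_sample_fraction < 1:
        raise ValueError("min_sample_fraction must lie in (0, 1)")
    n = ds.expr.shape[1]
    frac = (ds.expr.to_numpy(dtype=float) >= 1).sum(axis=1) / n
    expressed = pd.Series(frac > min_sample_fraction, index=ds.expr.index)
    cleaned = ExpressionDataset(ds.expr.loc[expressed], ds.roles, ds.dataset_id)
    return cleaned, expressed


def retain_gene_sets(nes_by_classifier_mito: Mapping[str, Sequence[float]],
                     set_sizes: Mapping[str, int],
                     min_high_mito: int = 100,
                     abs_nes_threshold: float = 3.0,
                     max_set_size: int = 500) -> list[str]:
    """Keep gene sets informative about mitochondrial identity.

    A set is retained iff at least ``min_high_mito`` classifier-mito genes
    reach |NES| strictly above ``abs_nes_threshold`` and the set has at most
    ``max_set_size`` genes.  Defaults are the full-scale values; scale them
    down for small synthetic designs.
    """
    kept = []
    for name, nes_values in nes_by_classifier_mito.items():
        if set_sizes[name] > max_set_size:
            continue
        n_high = sum(1 for v in nes_values if abs(v) > abs_nes_threshold)
        if n_high >= min_high_mito:
            kept.append(name)
    return kept


def build_nes_matrix(ds: ExpressionDataset, gene_sets: Mapping[str, Sequence[str]],
                     n_perm: int = 1000, seed: int = 0,
                     p_zero: float = 0.05,
                     min_high_mito: int = 100,
                     abs_nes_threshold: float = 3.0,
                     max_set_size: int = 500) -> tuple[pd.DataFrame, list[str]]:
    """NES matrix over all analyzed genes and the retained gene sets.

    Analyzed genes are the expressed classifier, training and candidate genes.
    Entries are NES values, set to 0 wherever the underlying permutation
    p-value exceeds ``p_zero``.  Gene-set retention is decided from the
    classifier-mito rows before zeroing is applied to the returned matrix.
    Returns ``(matrix, retained_set_ids)``.
    """
    analyzed = ds.genes_with_role(*ROLES)
    corr = spearman_matrix(ds.expr)
    raw_nes: dict[str, dict[str, float]] = {}
    zeroed: dict[str, dict[str, float]] = {}
    for i, gene in enumerate(analyzed):
        ranked = ranked_from_correlations(corr[gene], gene)
        cache: dict = {}
        res = gsea_batch(ranked, dict(gene_sets), n_perm=n_perm,
                         seed=seed + i, _null_cache=cache)
        raw_nes[gene] = {s: r.nes for s, r in res.items()}
        zeroed[gene] = {s: (r.nes if r.p_value <= p_zero else 0.0)
                        for s, r in res.items()}
    mito_genes = ds.genes_with_role("classifier_mito")
    nes_by_set = {s: [zeroed[g][s] for g in mito_genes] for s in gene_sets}
    sizes = {s: len(set(members)) for s, members in gene_sets.items()}
    retained = retain_gene_sets(nes_by_set, sizes, min_high_mito,
                                abs_nes_threshold, max_set_size)
    mat = pd.DataFrame.from_dict(zeroed, orient="index").loc[analyzed, retained]
    return mat, retained


@dataclass
class ScoreReport:
    """Per-dataset diagnostics from :func:`score_dataset`."""

    n_components: int = 0
    variance_explained: float = 0.0
    thresholds_by_k: dict = field(default_factory=dict)
    skipped_k: list = field(default_factory=list)


def score_dataset(nes: pd.DataFrame, roles: pd.Series,
                  k_range: Iterable[int] = range(2, 16),
                  variance_fraction: float = 0.9,
                  seed: int = 0) -> tuple[pd.Series, ScoreReport]:
    """k-means scores over PCA of the NES matrix.

    For each k, clusters of all rows are labelled positive when their
    classifier-gene mito percentage reaches the threshold that maximizes
    training-set accuracy (ties resolved toward the lowest, most inclusive
    threshold; clusters with no classifier genes count as 0% mito).  Every
    row's score is the fraction of cluster numbers in which it sat in a
    positive cluster.
    """
    report = ScoreReport()
    genes = nes.index.to_numpy()
    role = roles.reindex(genes)
    is_cm = (role == "classifier_mito").to_numpy()
    is_cn = (role == "classifier_nonmito").to_numpy()
    is_tm = (role == "training_mito_sep").to_numpy()
    is_tn = (role == "training_nonmito_sep").to_numpy()
    if is_cm.sum() < 2 or is_cn.sum() < 2:
        raise ValueError("need at least 2 classifier genes of each role")

    X = StandardScaler().fit_transform(nes.to_numpy(dtype=float))
    pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1]), random_state=seed)
    Z = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    ncomp = int(np.searchsorted(cum, variance_fraction) + 1)
    ncomp = min(ncomp, Z.shape[1])
    Z = Z[:, :ncomp]
    report.n_components = ncomp
    report.variance_explained = float(cum[ncomp - 1])

    binaries = np.zeros(len(genes))
    n_used = 0
    for k in k_range:
        if k > len(genes):
            warnings.warn(f"k={k} exceeds number of rows; skipped")
            report.skipped_k.append(k)
            continue
        km = KMeans(n_clusters=k, n_init=10, random_state=seed + k)
        labels = km.fit_predict(Z)
        pct = np.zeros(k)
        for c in range(k):
            in_c = labels == c
            n_m, n_n = int((in_c & is_cm).sum()), int((in_c & is_cn).sum())
            pct[c] = n_m / (n_m + n_n) if (n_m + n_n) else 0.0
        best_t, best_acc = None, -1
        for t in sorted(set(pct)):
            positive = pct >= t
            pos_rows = positive[labels]
            acc = int((pos_rows & is_tm).sum()) + int((~pos_rows & is_tn).sum())
            if acc > best_acc or (acc == best_acc and (best_t is None or t < best_t)):
                best_acc, best_t = acc, t
        positive = pct >= best_t
        binaries += positive[labels].astype(float)
        n_used += 1
        report.thresholds_by_k[k] = {"threshold": float(best_t),
                                     "training_accuracy": int(best_acc)}
    if n_used == 0:
        raise ValueError("no usable cluster number in k_range")
    scores = pd.Series(binaries / n_used, index=genes, name="kmeans_score")
    return scores, report


def call_candidates(scores: pd.DataFrame, threshold: float = 0.75
                    ) -> pd.DataFrame:
    """Final mitochondrial calls from per-dataset k-means scores.

    ``scores``: candidates x datasets, with -1 marking "not expressed in this
    dataset".  The average is taken over datasets where the gene is expressed;
    a gene is predicted mitochondrial when the average reaches ``threshold``
    and called high-confidence when every expressed-dataset score does.
    Genes expressed nowhere are reported untestable (no call).
    """
    rows = []
    for gene, row in scores.iterrows():
        vals = row[row != NOT_EXPRESSED]
        if vals.empty:
            rows.append({"gene_id": gene, "average_score": np.nan,
                         "predicted_mito": False, "confidence": "low",
                         "untestable": True})
            continue
        avg = float(vals.mean())
        rows.append({
            "gene_id": gene,
            "average_score": avg,
            "predicted_mito": bool(avg >= threshold),
            "confidence": "high" if bool((vals >= threshold).all()) else "low",
            "untestable": False,
        })
    return pd.DataFrame(rows).set_index("gene_id")


def classify_candidates(datasets: Sequence[ExpressionDataset],
                        gene_sets: Mapping[str, Sequence[str]],
                        n_perm: int = 1000, seed: int = 0,
                        min_sample_fraction: float = 0.5,
                        min_high_mito: int = 100,
                        abs_nes_threshold: float = 3.0,
                        max_set_size: int = 500,
                        threshold: float = 0.75,
                        k_range: Iterable[int] = range(2, 16),
                        variance_fraction: float = 0.9
                        ) -> tuple[pd.DataFrame, dict]:
    """End-to-end co-expression classification across datasets.

    Runs cleaning, NES-matrix construction and k-means scoring per dataset,
    then averages scores (ignoring not-expressed sentinels) into final calls.
    Returns ``(calls, report)``.
    """
    per_dataset: dict[str, pd.Series] = {}
    report: dict = {"datasets": {}}
    all_candidates: list[str] = []
    k_range = list(k_range)
    for ds in datasets:
        cands = ds.genes_with_role("candidate")
        all_candidates.extend(c for c in cands if c not in all_candidates)
    for ds in datasets:
        cleaned, expressed = clean_dataset(ds, min_sample_fraction)
        nes, retained = build_nes_matrix(
            cleaned, gene_sets, n_perm=n_perm, seed=seed,
            min_high_mito=min_high_mito, abs_nes_threshold=abs_nes_threshold,
            max_set_size=max_set_size)
        sc, sc_report = score_dataset(nes, ds.roles, k_range=k_range,
                                      variance_fraction=variance_fraction,
                                      seed=seed)
        col = pd.Series(NOT_EXPRESSED, index=pd.Index(all_candidates), dtype=float)
        for g in all_candidates:
            if g in sc.index:
                col[g] = sc[g]
        per_dataset[ds.dataset_id] = col
        report["datasets"][ds.dataset_id] = {
            "retained_sets": retained,
            "n_components": sc_report.n_components,
            "variance_explained": sc_report.variance_explained,
            "thresholds_by_k": sc_report.thresholds_by_k,
        }
    score_mat = pd.DataFrame(per_dataset)
    calls = call_candidates(score_mat, threshold=threshold)
    return calls.join(score_mat), report
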