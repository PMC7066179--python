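"""Preranked gene-set enrichment with a same-size random-set null.

The enrichment score (ES) is the maximum deviation of the weighted
Kolmogorov–Smirnov running sum over a ranked gene list, with weight exponent 1
on the absolute ranking statistic.  The null distribution is built from random
gene sets of the same size drawn from the ranked universe; the normalized
enrichment score (NES) divides ES by the mean |null ES| of matching sign, and
the permutation p-value is the fraction of null ES at least as extreme in the
direction of the observed ES (signed tail, the convention of preranked GSEA
implementations; add-one correction when the null is sampled rather than
exhaustive).

When the number of distinct same-size subsets of the universe does not exceed
the requested permutation count, the null is enumerated exhaustively; the
observed set is then a member of its own null and no add-one correction is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass(frozen=True)
class EnrichmentResult:
    gene_set_id: str
    es: float
    nes: float
    p_value: float
    n_null: int
    exhaustive: bool


def rank_by_correlation(expr: pd.DataFrame, test_gene: str) -> pd.Series:
    """Rank all other genes by Spearman correlation with ``test_gene``.

    ``expr`` is a genes x samples matrix.  Returns a Series indexed by gene,
    sorted by correlation descending with ties broken by gene identifier.
    Raises :class:`ValueError` if the test gene has constant expression.
    """
    if test_gene not in expr.index:
        raise KeyError(f"test gene {test_gene!r} not in expression matrix")
    x = expr.loc[test_gene].to_numpy(dtype=float)
    if np.all(x == x[0]):
        raise ValueError(f"test gene {test_gene!r} has constant expression; "
                         "Spearman correlation undefined")
    others = expr.drop(index=test_gene)
    corr = _spearman_with(others.to_numpy(dtype=float), x)
    out = pd.Series(corr, index=others.index, name="spearman")
    order = pd.DataFrame({"c": -out, "g": out.index}).sort_values(["c", "g"])
    return out.loc[order["g"]]


def _spearman_with(mat: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Spearman correlation of each row of ``mat`` with vector ``x``."""
    rx = rankdata(x)
    rx = rx - rx.mean()
    nx = np.sqrt((rx ** 2).sum())
    rm = np.apply_along_axis(rankdata, 1, mat)
    rm = rm - rm.mean(axis=1, keepdims=True)
    nm = np.sqrt((rm ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (rm @ rx) / (nm * nx)
    return np.where(nm == 0, 0.0, c)  # constant rows: correlation set to 0


def spearman_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Spearman correlation of a genes x samples matrix."""
    r = np.apply_along_axis(rankdata, 1, expr.to_numpy(dtype=float))
    r = r - r.mean(axis=1, keepdims=True)
    norm = np.sqrt((r ** 2).sum(axis=1, keepdims=True))
    norm[norm == 0] = np.inf  # constant genes correlate 0 with everything
    r /= norm
    return pd.DataFrame(r @ r.T, index=expr.index, columns=expr.index)


def ranked_from_correlations(corr: pd.Series, test_gene: str) -> pd.Series:
    """Descending ranked list from a precomputed correlation column."""
    out = corr.drop(index=test_gene)
    order = pd.DataFrame({"c": -out, "g": out.index}).sort_values(["c", "g"])
    return out.loc[order["g"]]


def _es_from_positions(pos: np.ndarray, weights: np.ndarray, n: int) -> np.ndarray:
    """Enrichment scores for one or more hit-position sets.

    ``pos``: (m, k) sorted hit positions (0-based into the ranked list);
    ``weights``: length-n nonnegative weights (|statistic|).  Returns (m,) ES.
    When the positive and negative extremes of the running sum tie in absolute
    value, the positive one is taken (deterministic convention).
    """
    pos = np.atleast_2d(pos)
    m, k = pos.shape
    if k == n:
        return np.ones(m)
    w = weights[pos]
    nr = w.sum(axis=1, keepdims=True)
    flat = nr[:, 0] == 0
    if np.any(flat):  # all-zero statistics inside the set: fall back to equal weights
        w = np.where(flat[:, None], 1.0, w)
        nr = w.sum(axis=1, keepdims=True)
    hits = np.cumsum(w, axis=1) / nr
    miss = 1.0 / (n - k)
    j = np.arange(1, k + 1)
    after = hits - (pos + 1 - j) * miss          # running sum just after each hit
    before = hits - w / nr - (pos - (j - 1)) * miss  # just before each hit
    top = np.maximum(after.max(axis=1), 0.0)
    bot = np.minimum(before.min(axis=1), 0.0)
    # positive extreme wins ties (with a float-noise window)
    return np.where(top >= -bot - 1e-9, top, bot)


def _null_positions(n: int, k: int, n_perm: int, rng: np.random.Generator
                    ) -> tuple[np.ndarray, bool]:
    """Same-size null sets as sorted position arrays; exhaustive when small."""
    total = comb(n, k)
    if total <= n_perm:
        pos = np.array(list(combinations(range(n), k)), dtype=int)
        return pos, True
    u = rng.random((n_perm, n))
    pos = np.sort(np.argsort(u, axis=1)[:, :k], axis=1)
    return pos, False


def gsea(ranked: pd.Series, gene_set: Iterable[str], n_perm: int = 1000,
         seed: int = 0, gene_set_id: str = "") -> EnrichmentResult:
    """Preranked GSEA of one gene set against one ranked list.

    ``ranked`` is a gene-indexed Series of ranking statistics sorted
    descending.  Raises :class:`ValueError` when the gene set does not
    intersect the ranked universe.
    """
    genes = ranked.index.to_numpy()
    stats = ranked.to_numpy(dtype=float)
    n = len(genes)
    members = set(gene_set)
    hit_mask = np.fromiter((g in members for g in genes), bool, count=n)
    k = int(hit_mask.sum())
    if k == 0:
        raise ValueError(f"gene set {gene_set_id!r} not represented in the ranked list")
    weights = np.abs(stats)
    obs_pos = np.flatnonzero(hit_mask)
    es = float(_es_from_positions(obs_pos, weights, n)[0])
    if k == n:
        return EnrichmentResult(gene_set_id, es, 1.0 if es else 0.0, 1.0, 1, True)

    rng = np.random.default_rng(seed)
    null_pos, exhaustive = _null_positions(n, k, n_perm, rng)
    null_es = _es_from_positions(null_pos, weights, n)

    nes = _normalize_es(es, null_es)
    p = _tail_p(es, null_es, exhaustive)
    return EnrichmentResult(gene_set_id, es, nes, p, len(null_es), exhaustive)


def _tail_p(es: float, null_es: np.ndarray, exhaustive: bool,
            tol: float = 1e-12) -> float:
    """Signed-tail permutation p with a small tolerance for float near-ties."""
    if es >= 0:
        n_extreme = int(np.sum(null_es >= es - tol))
    else:
        n_extreme = int(np.sum(null_es <= es + tol))
    if exhaustive:
        return n_extreme / len(null_es)
    return (1 + n_extreme) / (1 + len(null_es))


def _normalize_es(es: float, null_es: np.ndarray) -> float:
    if es == 0:
        return 0.0
    same_sign = null_es[np.sign(null_es) == np.sign(es)]
    denom_pool = same_sign if same_sign.size else null_es[null_es != 0]
    if denom_pool.size == 0:
        return 0.0
    return float(es / np.abs(denom_pool).mean())


def gsea_batch(ranked: pd.Series, gene_sets: dict[str, Sequence[str]],
               n_perm: int = 1000, seed: int = 0,
               _null_cache: Optional[dict] = None) -> dict[str, EnrichmentResult]:
    """GSEA of many gene sets against one ranked list, sharing null draws.

    Null ES distributions depend only on the ranked list and the represented
    set size, so they are computed once per size (cached in ``_null_cache``
    when the caller reuses it across calls with the same ranked list).
    """
    genes = ranked.index.to_numpy()
    stats = ranked.to_numpy(dtype=float)
    n = len(genes)
    weights = np.abs(stats)
    index = {g: i for i, g in enumerate(genes)}
    cache: dict = _null_cache if _null_cache is not None else {}
    rng = np.random.default_rng(seed)
    out: dict[str, EnrichmentResult] = {}
    for name, members in gene_sets.items():
        pos = np.sort(np.fromiter(
            (index[g] for g in set(members) if g in index), int))
        k = pos.size
        if k == 0:
            raise ValueError(f"gene set {name!r} not represented in the ranked list")
        es = float(_es_from_positions(pos, weights, n)[0])
        if k == n:
            out[name] = EnrichmentResult(name, es, 1.0 if es else 0.0, 1.0, 1, True)
            continue
        if k not in cache:
            cache[k] = _null_positions(n, k, n_perm, rng)
        null_pos, exhaustive = cache[k]
        key = ("es", k)
        if key not in cache:
            cache[key] = _es_from_positions(null_pos, weights, n)
        null_es = cache[key]
        nes = _normalize_es(es, null_es)
        p = _tail_p(es, null_es, exhaustive)
        out[name] = EnrichmentResult(name, es, nes, p, len(null_es), exhaustive)
    return out
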