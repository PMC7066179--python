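"""Reaction-blockage / gene-deletion screen over a metabolic model.

The screen asks which single blockage best reproduces a lactate+succinate
overflow phenotype: each reaction is blocked in turn (bounds set to zero), the
ATP-production objective is constrained to at least 90% of the blocked model's
own maximum, the steady-state flux polytope is sampled uniformly with a
hit-and-run Markov chain, and the lactate / succinate export distributions are
compared against samples of the unchanged baseline model with a two-sided
Wilcoxon rank-sum test and pooled-SD Cohen's d.  Blockages with a negative
effect size for either export are discarded; the rest are ranked by the sum of
the two effect sizes.  The gene-deletion screen blocks, per gene, every
reaction whose GPR rule evaluates false without it, then reuses the same
workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.optimize import linprog
from scipy.stats import mannwhitneyu

from .metabolic_model import MetabolicModel, evaluate_gpr, fba_max

STEADY_STATE_TOL = 1e-6


# ---------------------------------------------------------------------------
# Blocking and ATP constraint
# ---------------------------------------------------------------------------

@dataclass
class ConstrainedModel:
    model: Optional[MetabolicModel]
    status: str                  # "ok" | "collapses_atp"
    blocked_reactions: tuple[str, ...]
    atp_capacity: Optional[float] = None  # blocked-model ATP maximum


def block_and_constrain(model: MetabolicModel, reaction_ids,
                        atp_fraction: float = 0.9) -> ConstrainedModel:
    """Zero out the target reaction(s) and pin ATP near the blocked capacity.

    The objective reaction's lower bound is first relaxed to 0 (the baseline
    model may carry a physiological ATP demand), the blocked maximum is
    computed, and the objective lower bound is then set to
    ``atp_fraction * maximum``.  Blockages under which the model is infeasible
    or has zero ATP capacity are reported with status ``"collapses_atp"`` and
    excluded from sampling.
    """
    if isinstance(reaction_ids, str):
        reaction_ids = [reaction_ids]
    reaction_ids = tuple(reaction_ids)
    m = model.copy()
    for rid in reaction_ids:
        r = m.reaction(rid)
        r.lower_bound = 0.0
        r.upper_bound = 0.0
    obj = m.reaction(m.objective_id)
    if obj.upper_bound > 0:
        obj.lower_bound = 0.0
    res = fba_max(m)
    if res.status != "optimal" or res.objective_value <= STEADY_STATE_TOL:
        return ConstrainedModel(None, "collapses_atp", reaction_ids,
                                res.objective_value if res.status == "optimal" else None)
    obj.lower_bound = atp_fraction * res.objective_value
    return ConstrainedModel(m, "ok", reaction_ids, res.objective_value)


# ---------------------------------------------------------------------------
# Uniform sampling of the flux polytope (hit-and-run)
# ---------------------------------------------------------------------------

@dataclass
class FluxSampleSet:
    samples: pd.DataFrame        # n x reactions
    seed: int
    model_tag: str

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def _fva_interior(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                  tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Relative-interior start point and effectively-fixed dimensions.

    Flux variability analysis (min/max per reaction) identifies dimensions the
    constraints pin to a single value even where the declared bounds are wide;
    the average of all FVA vertices is then strictly between the attainable
    extremes of every free dimension, i.e. in the relative interior of the
    box-and-equality polytope.
    """
    n = S.shape[1]
    b_eq = np.zeros(S.shape[0])
    box = list(zip(lb, ub))
    vertices = []
    vmin = np.empty(n)
    vmax = np.empty(n)
    for j in range(n):
        c = np.zeros(n)
        for sign, store in ((1.0, vmin), (-1.0, vmax)):
            c[j] = sign
            res = linprog(c, A_eq=S, b_eq=b_eq, bounds=box, method="highs")
            if not res.success:
                raise ValueError("flux polytope is empty; cannot sample")
            store[j] = sign * res.fun if sign > 0 else -res.fun
            vertices.append(res.x)
        c[j] = 0.0
    fixed = (vmax - vmin) <= tol
    if fixed.all():
        raise ValueError("flux polytope is a single point; nothing to sample")
    v0 = np.mean(vertices, axis=0)
    return v0, fixed


def sample_fluxes(model: MetabolicModel, n: int = 5000, seed: int = 0,
                  warmup: int = 1000, thinning: int = 100,
                  model_tag: str = "") -> FluxSampleSet:
    """Uniform samples of the steady-state flux polytope.

    Hit-and-run random walk: from the current point, pick a uniformly random
    direction within the null space of the (augmented) stoichiometric matrix,
    intersect the line with the bound box, and jump to a uniform point of the
    resulting chord.  Fixed reactions (lower bound == upper bound) are folded
    into the equality system.  ``warmup`` steps are discarded and one sample
    is recorded every ``thinning`` steps.
    """
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    nrxn = S.shape[1]
    v0, fixed = _fva_interior(S, lb, ub)
    A = S
    if fixed.any():
        extra = np.zeros((int(fixed.sum()), nrxn))
        extra[np.arange(int(fixed.sum())), np.flatnonzero(fixed)] = 1.0
        A = np.vstack([S, extra])
    N = null_space(A)
    if N.shape[1] == 0:
        raise ValueError("flux polytope is a single point; nothing to sample")

    rng = np.random.default_rng(seed)
    dim = N.shape[1]
    x = np.zeros(dim)
    eps = 1e-12
    samples = np.empty((n, nrxn))
    collected = 0
    step = 0
    margin = 1e-9
    while collected < n:
        g = rng.standard_normal(dim)
        d = N @ g
        nd = np.linalg.norm(d)
        if nd < eps:
            continue
        d /= nd
        v = v0 + N @ x
        with np.errstate(divide="ignore", invalid="ignore"):
            hi = np.where(d > eps, (ub - v) / d, np.inf)
            lo = np.where(d < -eps, (lb - v) / d, np.inf)
        alpha_max = min(np.min(hi), np.min(lo))
        with np.errstate(divide="ignore", invalid="ignore"):
            hi = np.where(d > eps, (lb - v) / d, -np.inf)
            lo = np.where(d < -eps, (ub - v) / d, -np.inf)
        alpha_min = max(np.max(hi), np.max(lo))
        if alpha_max <= alpha_min:
            step += 1
            continue
        span = alpha_max - alpha_min
        alpha = rng.uniform(alpha_min + margin * span, alpha_max - margin * span)
        x = x + alpha * (g / nd)
        step += 1
        if step > warmup and (step - warmup) % thinning == 0:
            v = np.clip(v0 + N @ x, lb, ub)
            samples[collected] = v
            collected += 1
    df = pd.DataFrame(samples, columns=model.reaction_ids)
    return FluxSampleSet(df, seed, model_tag or model.id)


# ---------------------------------------------------------------------------
# Export comparison and ranking
# ---------------------------------------------------------------------------

@dataclass
class BlockageComparison:
    target_id: str
    d_lactate: float
    d_succinate: float
    p_lactate: float
    p_succinate: float
    degenerate: bool = False
    rank: Optional[int] = None

    @property
    def sum_d(self) -> float:
        return self.d_lactate + self.d_succinate

    @property
    def discarded(self) -> bool:
        return self.d_lactate < 0 or self.d_succinate < 0


def cohens_d(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Pooled-SD Cohen's d of x vs y; (0, degenerate=True) when both SDs are 0."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    pooled_var = (((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
                  / (nx + ny - 2))
    if pooled_var <= 0:
        return 0.0, True
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var)), False


def ranksum_p(x: np.ndarray, y: np.ndarray, exact_max_n: int = 20) -> float:
    """Two-sided Wilcoxon rank-sum p; exact enumeration for small samples."""
    method = "exact" if max(len(x), len(y)) <= exact_max_n else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def compare_exports(blocked: FluxSampleSet, baseline: FluxSampleSet,
                    lactate_id: str, succinate_id: str,
                    target_id: Optional[str] = None) -> BlockageComparison:
    """Effect of a blockage on lactate / succinate export vs baseline.

    Cohen's d is oriented as (blocked - baseline); p-values come from the
    two-sided rank-sum test.
    """
    bl = blocked.samples[lactate_id].to_numpy()
    bs = blocked.samples[succinate_id].to_numpy()
    ol = baseline.samples[lactate_id].to_numpy()
    os_ = baseline.samples[succinate_id].to_numpy()
    d_lac, deg1 = cohens_d(bl, ol)
    d_suc, deg2 = cohens_d(bs, os_)
    return BlockageComparison(
        target_id=target_id or blocked.model_tag,
        d_lactate=d_lac, d_succinate=d_suc,
        p_lactate=ranksum_p(bl, ol), p_succinate=ranksum_p(bs, os_),
        degenerate=deg1 or deg2,
    )


def rank_blockages(comparisons: Sequence[BlockageComparison]
                   ) -> tuple[list[BlockageComparison], list[BlockageComparison]]:
    """Discard blockages with any negative effect size; rank the rest.

    Retained blockages are sorted by the sum of effect sizes descending, ties
    broken by target id; ``rank`` is assigned 1-based.  Returns
    ``(retained, discarded)``.
    """
    retained = [c for c in comparisons if not c.discarded]
    discarded = [c for c in comparisons if c.discarded]
    retained.sort(key=lambda c: (-c.sum_d, c.target_id))
    for i, c in enumerate(retained, start=1):
        c.rank = i
    return retained, discarded


# ---------------------------------------------------------------------------
# Screens
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    ranking: pd.DataFrame
    collapsed: list[tuple[str, ...]] = field(default_factory=list)
    comparisons: list[BlockageComparison] = field(default_factory=list)
    discarded: list[BlockageComparison] = field(default_factory=list)


_RANKING_COLUMNS = ["target_id", "rank", "d_lactate", "d_succinate", "sum_d",
                    "p_lactate", "p_succinate", "degenerate"]


def _comparisons_to_frame(retained: list[BlockageComparison]) -> pd.DataFrame:
    if not retained:
        return pd.DataFrame(columns=_RANKING_COLUMNS)
    return pd.DataFrame([{
        "target_id": c.target_id, "rank": c.rank,
        "d_lactate": c.d_lactate, "d_succinate": c.d_succinate,
        "sum_d": c.sum_d,
        "p_lactate": c.p_lactate, "p_succinate": c.p_succinate,
        "degenerate": c.degenerate,
    } for c in retained])


def _run_screen(model: MetabolicModel, targets: dict[str, Sequence[str]],
                n_samples: int, seed: int, atp_fraction: float,
                warmup: int, thinning: int) -> ScreenResult:
    lac, suc = model.lactate_export_id, model.succinate_export_id
    if lac is None or suc is None:
        raise ValueError("model must declare lactate and succinate export ids")
    baseline = sample_fluxes(model, n=n_samples, seed=seed,
                             warmup=warmup, thinning=thinning,
                             model_tag="baseline")
    comparisons: list[BlockageComparison] = []
    collapsed: list[tuple[str, ...]] = []
    for i, (name, rxns) in enumerate(targets.items()):
        cm = block_and_constrain(model, list(rxns), atp_fraction)
        if cm.status != "ok":
            collapsed.append((name,) + cm.blocked_reactions)
            continue
        blocked = sample_fluxes(cm.model, n=n_samples, seed=seed + 1 + i,
                                warmup=warmup, thinning=thinning,
                                model_tag=name)
        comparisons.append(compare_exports(blocked, baseline, lac, suc,
                                           target_id=name))
    retained, discarded = rank_blockages(comparisons)
    return ScreenResult(_comparisons_to_frame(retained), collapsed,
                        comparisons, discarded)


def reaction_blockage_screen(model: MetabolicModel,
                             reaction_ids: Optional[Sequence[str]] = None,
                             n_samples: int = 5000, seed: int = 0,
                             atp_fraction: float = 0.9,
                             warmup: int = 1000, thinning: int = 100
                             ) -> ScreenResult:
    """Block each reaction in turn and rank by lactate+succinate effect size.

    By default every reaction except the objective itself is screened.
    """
    if reaction_ids is None:
        reaction_ids = [r for r in model.reaction_ids if r != model.objective_id]
    targets = {rid: [rid] for rid in reaction_ids}
    return _run_screen(model, targets, n_samples, seed, atp_fraction,
                       warmup, thinning)


def gene_deletion_screen(model: MetabolicModel,
                         genes: Optional[Sequence[str]] = None,
                         n_samples: int = 5000, seed: int = 0,
                         atp_fraction: float = 0.9,
                         warmup: int = 1000, thinning: int = 100
                         ) -> ScreenResult:
    """Delete each gene and rank deletions by export effect sizes.

    A gene deletion blocks every reaction whose GPR evaluates false with that
    gene absent.  Genes whose deletion blocks no reaction yield a comparison
    with zero effect size, flagged degenerate.
    """
    if genes is None:
        genes = model.genes()
    targets: dict[str, Sequence[str]] = {}
    no_effect: list[str] = []
    for g in genes:
        blocked = [r.id for r in model.reactions
                   if r.gpr.strip() and not evaluate_gpr(r.gpr, {g})]
        if blocked:
            targets[g] = blocked
        else:
            no_effect.append(g)
    result = _run_screen(model, targets, n_samples, seed, atp_fraction,
                         warmup, thinning)
    for g in no_effect:
        result.comparisons.append(BlockageComparison(
            g, 0.0, 0.0, 1.0, 1.0, degenerate=True))
    return result
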