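# Methods

This note records the models, conventions and parameter choices behind each
pipeline stage, what the synthetic data emulate (and what they do not), and
the numerical decisions a maintainer would need to reproduce or change the
behaviour. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## sORF quality filtering

Ribo-seq quality metrics (ORF-score, in-frame coverage, coverage uniformity,
FLOSS class, dataset support) are consumed as catalog columns, never
recomputed from alignments: their definitions belong to the upstream catalog,
and the contribution here is the per-class decision rule. All numeric
thresholds are inclusive ("minimum", "at least"), except the intergenic gene
distance, which is strict ("more than 1 kb"). The coding-class uniformity
window [−1, 1] is vacuous for a statistic bounded in [−1, 1]; it is kept
verbatim so the configuration mirrors the published rule set, and the
generator consequently never plants a uniformity violation for that class.
Isoform redundancy is resolved deterministically: within a gene the longest
peptide (ties broken lexicographically by sORF id) is kept and any isoform
whose sequence is an exact substring of it is removed — a reproducible
rendering of what is otherwise a manual curation step.

## Preranked enrichment (GSEA) and the co-expression classifier

For a test gene, every other expressed gene is ranked by Spearman correlation,
descending, ties broken by gene identifier. The enrichment score of a gene
set is the maximum deviation of the weighted Kolmogorov–Smirnov running sum
with weight exponent 1 on |ρ|; when the positive and negative extremes tie in
absolute value (within 1e−9, to absorb float noise between algebraically
equivalent computations) the positive extreme is taken. The null is random
same-size gene sets from the ranked universe (default 1000 draws, seeded);
when the number of distinct same-size subsets does not exceed the requested
permutations the null is enumerated exhaustively, the observed set then being
a member of its own null. The p-value is a **signed tail**: the fraction of
null ES at least as extreme in the direction of the observed ES (add-one
corrected when sampled). NES divides ES by the mean |null ES| of matching
sign. One consequence of the signed tail: under a pure null, either tail can
fall below 0.05, so the expected fraction of NES-matrix entries surviving the
p ≤ 0.05 zeroing rule is ~10%, not 5% — the property tests assert the ~90%
zero rate.

Gene-set retention (≥ `min_high_mito` classifier-mito genes with |NES| above
`abs_nes_threshold`; sets larger than `max_set_size` dropped) defaults to the
full-scale values 100 / 3 / 500. NES magnitudes shrink with universe size —
in a ~280-gene synthetic universe a same-size random set overlaps the planted
mitochondrial module by chance, inflating the null — so the synthetic runs
use 1.2 / half-the-classifier-mito-genes / 500 (frozen in
`mitosep.pipelines.SYNTHETIC_CLASSIFIER_PARAMS`).

Scoring: NES columns are standardized; PCA keeps the smallest number of
components explaining ≥ 90% variance (the exact component count used
originally is not specified, so it is a configurable rule recorded per run in
the report); k-means (Lloyd, 10 restarts, seeded) runs for k = 2..15. A
cluster's mito percentage uses only classifier genes in the denominator —
training and candidate genes never influence cluster labelling — and clusters
containing no classifier genes count as 0%. Candidate thresholds are the
observed cluster percentages; the one maximizing training-set accuracy wins,
ties resolved toward the lowest (most inclusive) threshold. Cluster-label
permutation invariance is automatic because scoring is by cluster
composition. A k exceeding the row count is skipped with a warning and the
score denominator adjusted. The final call averages per-dataset scores over
datasets where the gene is expressed (score ≠ −1), calls mitochondrial at
≥ 0.75 (the boundary is inclusive), and flags high confidence when every
expressed-dataset score clears 0.75. Genes expressed nowhere are reported
untestable rather than called.

## Targeting motifs

External predictors are never executed; their outputs are optional input
columns, and a missing TargetP record yields an explicit
"insufficient evidence" outcome distinct from a negative call. The internal
TMD score is a 19-residue Kyte–Doolittle window mean with helix threshold 1.6
(the scale's conventional transmembrane cutoff); the hydrophobicity cap
defaults to 3 **in the configured scale's units** — the original cap's scale
is not stated, so both scale and cap are configurable, and on Kyte–Doolittle
the cap correctly rejects a poly-leucine window (mean 3.8). Twin-cysteine
patterns CX3C / CX9C / CX10C are matched with any residue as X;
non-overlapping occurrences are selected greedily left-to-right (optimal for
fixed-length intervals), and the mixed CX9C + CX10C rule accepts any disjoint
pair. Classification precedence is MTS > TMD > CXnC: an N-terminal cleavable
presequence dominates, and twin cysteine pairs are the fallback internal
signal — the precedence is a design choice, since upstream the motif scan was
applied only to peptides not already selected by co-expression.

## PSM retention

Retention is a pure conjunction: partitions exactly {sorf_db}, coverage
≥ 0.30 (inclusive, "at least 30%"), FDR < 0.01 (strict). "Spectrum coverage"
is stored as an opaque fraction from the search-engine output.

## Metabolic model, FBA and the blockage screen

Models carry dense stoichiometry, per-reaction bounds, GPR boolean rules, an
ATP-production objective and named lactate/succinate exports; they round-trip
through SBML Level 3 FBC v2 (libsbml) and an equivalent JSON dialect. FBA is
a single linear program (HiGHS via scipy); infeasibility is reported as a
status, never as a zero optimum. GPR rules are evaluated by a small
recursive-descent parser (genes true unless knocked out; empty rule = always
active); a gene deletion blocks every reaction whose rule evaluates false.

`block_and_constrain` zeroes the target bounds, relaxes the objective's lower
bound, computes the blocked model's own ATP maximum, and pins the objective
lower bound at 0.9 × that maximum (the fraction is configurable, boundary
inclusive). Blockages leaving the model infeasible or with zero ATP capacity
are reported in a separate "collapses ATP" category and excluded from
sampling and ranking.

Sampling targets the uniform distribution on {v : S·v = 0, lb ≤ v ≤ ub} with
hit-and-run: directions are isotropic in the null space of the equality
system, the chord through the current point is intersected with the bound box
and the next point is uniform on it. Dimensions the constraints pin to a
single value (found by flux variability analysis with tolerance 1e−9) are
folded into the equality system; the start point is the average of the FVA
vertices, which is strictly interior in every free dimension of a
box-and-equality polytope. Points are reconstructed as v₀ + N·x from reduced
coordinates, keeping steady-state residuals at machine precision (the
validity contract is |S·v| < 1e−6 and bounds for 100% of samples). Defaults
are 5000 samples, 1000 warm-up steps, thinning 100; the package's own tests
and the acceptance script use 1000 samples with the default warm-up/thinning,
which keeps the seed-to-seed spread of the smaller effect sizes well away
from sign flips while staying inside a desk-scale run time. No polytope
rounding is applied; at these dimensions (≈ 7 free directions in the toy
network) thinning substitutes for it.

Comparisons use pooled-SD Cohen's d oriented blocked − baseline (0 with a
degeneracy flag when both variances vanish) and a two-sided Wilcoxon
rank-sum p (exact enumeration when both groups have ≤ 20 samples, otherwise
the tie-corrected normal approximation). Blockages with d < 0 for either
export are discarded (d = 0 is retained); the rest are ranked by the sum of
the two effect sizes, ties broken by target id.

### The toy cardiomyocyte network

`gen_toy_metabolic_model` is a deterministic 22-reaction fixture: glucose
uptake; lumped glycolysis (2 ATP + 2 cytosolic NADH per glucose); lactate
dehydrogenase with lactate export (id `L_LACt2r`); pyruvate dehydrogenase,
pyruvate carboxylase and a lumped citrate-synthase→succinate TCA segment with
succinate export (`SUMt_MitoCore`); separate cytosolic/mitochondrial NAD(H)
pools linked by a malate shuttle (reversible cytosolic and mitochondrial
malate dehydrogenases + fumarase) and a glycerol-phosphate-like quinone
shuttle; lumped CI, CII (reversible succinate dehydrogenase, so fumarate can
serve as terminal electron acceptor), CIII, CIV, CV coupled through a
proton-motive currency; an oxygen exchange; a proton leak; small pyruvate and
acetyl-CoA overflow exchanges; and an ATP demand objective
(`OF_ATP_MitoCore`). Fluxes are unitless (nominally mmol·gDW⁻¹·h⁻¹); only
relative comparisons matter. The demand reaction carries a frozen lower
bound of 244.8 — 90% of the network's 272-unit ATP capacity — representing a
hard-working cardiomyocyte, so that the *unchanged* baseline sampled by the
screen is already physiologically constrained; `block_and_constrain` relaxes
this bound before computing each blocked model's own capacity. Gene rules
assign one gene per complex, with an AND pair on CIII (`gCIII_1 and gCIII_2`)
and an OR pair on CV (`gCV_a or gCV_b`) to exercise boolean semantics.

The network reproduces the diagnostic phenotype by construction of its
chemistry, not its parameters: blocking CIII (or CIV — the identical cut of
the same chain) leaves glycolysis plus fumarate respiration as the only
ATP routes, forcing lactate up and succinate export strongly up, while
blocking CII forces succinate export up but lactate *down* (oxidative
phosphorylation still runs), so the CII blockage is discarded on its negative
lactate effect size.

## Proteomics statistics

`tmt_normalize` log2-transforms raw reporter intensities, drops rows lacking
a valid value in any of the six channels or quantified from ≤ 2 unique
peptides (strict "more than 2"), and subtracts each column's median computed
on the retained rows — column medians are exactly 0 afterwards, and the
centering is idempotent. `mito_renormalize` subtracts the per-channel mean of
mitochondria-annotated rows from all rows (absorbing variance introduced by
mitochondrial isolation); the mito-row mean is exactly 0 afterwards. The
volcano uses log2 fold change from group means and a two-sided
pooled-variance Student's t (Welch behind a flag); rows with zero variance in
both groups get p = 1 when the difference is 0 and an undefined, flagged p
otherwise. Per-complex summaries use medians instead — the mean/median split
is deliberate, each where the original analysis states it — with proteins
excluded when their intragroup SD reaches the threshold (2 for
zebrafish-like, 0.6 for mouse-like runs) and, when several isoforms map to
one subunit, the most-altered retained isoform representing it; complexes
with nothing retained are reported missing, not zero. Metabolite tests are
two-sided paired t per metabolite with Bonferroni multiplication across
metabolites, capped at 1. Citrate synthase activity is the mean of secant
slopes (A_i − A_0)/(t_i − t_0), exact for linear series at any spacing;
OCR/CS is exposed as a plain ratio.

## Synthetic data: what it emulates, and what it does not

Every generator is deterministic under its seed and writes a sidecar truth
table the pipeline never reads.

* **sORF tables** plant pass/fail labels by sampling metrics inside or just
  outside each class's thresholds (including exact-boundary values such as a
  1000-nt gene distance, which must fail the strict rule). Metrics are drawn
  independently per record; real catalog metrics are correlated, so passing
  the recovery test shows rule fidelity, not realistic metric joint
  distributions.
* **Expression datasets** use a latent-factor model: mitochondrial-module
  genes (classifier, training and planted mito candidates) share one factor
  with loading √ρ (default ρ = 0.8, 40 samples), non-mito genes load on three
  independent factors, background genes are noise; values are a rounded
  exponential transform (count-like, nonnegative, monotone in the latent
  variable, so Spearman-based recovery is meaningful). Defaults: 60 + 60
  classifier genes, 10 + 10 training, 10 + 10 candidates, 120 background —
  roughly 1/20 of the real design in every role. Gene sets are five
  mito-like sets (60% classifier-mito members) and five random decoys. Real
  tissue data have batch structure, varying library depth and overlapping
  pathway sets; none of that is emulated, so classifier recovery here
  demonstrates the mechanism, not field performance.
* **Peptides** plant one motif class each: consensus-passing predictor scores
  for MTS; a 19-residue core with Kyte–Doolittle mean in [1.8, 2.8] inside
  hydrophilic flanks for TMD; qualifying cysteine-pair combinations for CXnC;
  cysteine-free hydrophilic fillers for "none". Predictor scores are
  sampled, not produced by the real predictors.
* **PSM tables** and **TMT matrices** plant retention labels and a complex-III
  depletion (default −2 log2, σ = 0.3, 3v3, 10–12 CIII rows) with a fraction
  of rows carrying missing values or ≤ 2 peptides so the validity filters are
  exercised. Reporter-ion interference and isotope-impurity structure are not
  simulated.

## Known limitations

* The sampler is plain hit-and-run without polytope rounding; on very
  elongated polytopes (hundreds of reactions) it would need rounding or much
  longer thinning to mix.
* The exact PCA dimensionality and the handling of the negative-control
  tissue in the original classifier are unspecified upstream; both are
  configuration here (components by 90% variance; any dataset can simply be
  left out of the averaged call).
* NES magnitudes are universe-size dependent, so retention thresholds must be
  rescaled when moving between designs; the package exposes them as
  parameters rather than constants.
* `summarize_by_complex` interprets the intragroup-SD rule as a per-protein
  retention filter, the most direct reading of the described procedure.
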