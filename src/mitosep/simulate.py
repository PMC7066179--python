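"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates the structure of one real input (an sORF catalog
slice, tissue expression matrices, candidate peptides with external predictor
scores, a miniature cardiomyocyte-like metabolic network, PSM tables, a 3v3
TMT proteomics matrix) and returns a sidecar truth table recording the planted
labels.  The pipeline never reads the truth; tests and the acceptance script
compare pipeline output against it.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coexpression import ExpressionDataset
from .metabolic_model import MetabolicModel, Reaction
from .motifs import KYTE_DOOLITTLE
from .sorf_filter import ANNOTATION_CLASSES, default_config

AA_ALPHABET = list("ACDEFGHIKLMNPQRSTVWY")
#: Strongly hydrophilic residues (all Kyte-Doolittle < 0), cysteine-free.
HYDROPHILIC = list("STNQEDKRGP")


# ---------------------------------------------------------------------------
# sORF tables
# ---------------------------------------------------------------------------

def gen_sorf_table(n: int, seed: int, pass_fraction: float = 0.5
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Candidate sORF records with known filter outcomes.

    Approximately ``pass_fraction`` of the records satisfy every quality rule
    of their annotation class; each remaining record violates at least one
    randomly chosen applicable rule.  The truth table records the violated
    rules per record.
    """
    if not 0 <= pass_fraction <= 1:
        raise ValueError("pass_fraction must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    config = default_config()
    rows, truths = [], []
    for i in range(n):
        cls = ANNOTATION_CLASSES[i % len(ANNOTATION_CLASSES)]
        thr = config[cls]
        should_pass = bool(rng.random() < pass_fraction)
        min_len = thr.min_aa_length or 7
        aa_length = int(rng.integers(min_len, 100))
        rec = {
            "sorf_id": f"sorf{i:05d}",
            "gene_id": f"gene{int(rng.integers(0, max(1, n // 2))):05d}",
            "annotation_class": cls,
            "aa_length": aa_length,
            "orf_score": float(rng.uniform(6.0, 25.0)),
            "in_frame_coverage": float(rng.uniform(thr.min_in_frame_coverage, 1.0)),
            "coverage_uniformity": float(rng.uniform(thr.uniformity_low,
                                                     thr.uniformity_high)),
            "floss_class": "good",
            "n_ribo_datasets": int(rng.integers(thr.min_datasets or 1, 31)),
            "upstream_distance_nt": np.nan,
            "downstream_distance_nt": np.nan,
            "peptide_seq": "".join(rng.choice(AA_ALPHABET, size=aa_length)),
        }
        if cls == "intergenic":
            rec["upstream_distance_nt"] = float(rng.uniform(1001.0, 50000.0))
            rec["downstream_distance_nt"] = float(rng.uniform(1001.0, 50000.0))
        violated: list[str] = []
        if not should_pass:
            applicable = ["min_orf_score", "min_in_frame_coverage"]
            if cls != "cds":        # the cds uniformity window [-1,1] is vacuous
                applicable.append("uniformity")
            if thr.min_aa_length is not None:
                applicable.append("min_aa_length")
            if thr.require_good_floss:
                applicable.append("floss")
            if thr.min_datasets is not None:
                applicable.append("min_datasets")
            if thr.min_gene_distance_nt is not None:
                applicable.append("min_gene_distance")
            n_viol = int(rng.integers(1, len(applicable) + 1))
            violated = sorted(rng.choice(applicable, size=n_viol, replace=False))
            for rule in violated:
                if rule == "min_orf_score":
                    rec["orf_score"] = float(rng.uniform(0.0, 5.999))
                elif rule == "min_in_frame_coverage":
                    rec["in_frame_coverage"] = float(
                        rng.uniform(0.0, thr.min_in_frame_coverage * 0.999))
                elif rule == "uniformity":
                    side = rng.random() < 0.5
                    lo, hi = thr.uniformity_low, thr.uniformity_high
                    rec["coverage_uniformity"] = float(
                        rng.uniform(hi + 0.001, 1.0) if side
                        else rng.uniform(-1.0, lo - 0.001))
                elif rule == "min_aa_length":
                    rec["aa_length"] = int(rng.integers(1, thr.min_aa_length))
                    rec["peptide_seq"] = rec["peptide_seq"][:rec["aa_length"]]
                elif rule == "floss":
                    rec["floss_class"] = "not_good"
                elif rule == "min_datasets":
                    rec["n_ribo_datasets"] = int(rng.integers(0, thr.min_datasets))
                elif rule == "min_gene_distance":
                    # boundary value 1000 fails the strict > rule
                    which = rng.integers(0, 3)
                    bad = float(1000.0 if rng.random() < 0.2
                                else rng.uniform(0.0, 1000.0))
                    if which in (0, 2):
                        rec["upstream_distance_nt"] = bad
                    if which in (1, 2):
                        rec["downstream_distance_nt"] = bad
        rows.append(rec)
        truths.append({"item_id": rec["sorf_id"],
                       "passes_filter": not violated,
                       "violated_rules": ";".join(violated)})
    return pd.DataFrame(rows), pd.DataFrame(truths)


# ---------------------------------------------------------------------------
# Expression datasets + gene sets
# ---------------------------------------------------------------------------

def gen_expression_dataset(n_samples: int = 40, rho: float = 0.8,
                           n_classifier_mito: int = 60,
                           n_classifier_nonmito: int = 60,
                           n_training: int = 20, n_candidates: int = 20,
                           mito_candidate_fraction: float = 0.5,
                           n_background: int = 120,
                           seed: int = 0, dataset_id: str = "synthetic"
                           ) -> tuple[ExpressionDataset, dict[str, list[str]],
                                      pd.DataFrame]:
    """Expression matrix with a planted mitochondrial co-expression module.

    Mitochondrial-module genes (classifier-mito, mito training genes and the
    planted mito candidates) share one latent factor with loading sqrt(rho),
    so their pairwise correlation is ~rho; non-mito classifier/training/
    candidate genes load equally strongly on three independent factors
    (transcription-factor-module-like); background genes are pure noise.
    Values are count-like (exponential transform of the latent Gaussian,
    rounded), hence nonnegative, and monotone in the latent variable so
    Spearman-based recovery is meaningful.

    Returns ``(dataset, gene_sets, truth)`` where the gene sets include
    mito-like sets overrepresenting classifier-mito genes and random decoys.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    if n_classifier_mito < 2 or n_classifier_nonmito < 2:
        raise ValueError("need at least 2 classifier genes per role")
    rng = np.random.default_rng(seed)

    n_tm = n_training // 2
    n_tn = n_training - n_tm
    n_cm_cand = int(round(mito_candidate_fraction * n_candidates))

    names, roles, is_mito_module, factor_idx = [], [], [], []

    def add(prefix, count, role, mito, factors):
        for i in range(count):
            names.append(f"{prefix}{i:03d}")
            roles.append(role)
            is_mito_module.append(mito)
            factor_idx.append(factors[i % len(factors)] if factors else -1)

    add("CM", n_classifier_mito, "classifier_mito", True, [0])
    add("CN", n_classifier_nonmito, "classifier_nonmito", False, [1, 2, 3])
    add("TM", n_tm, "training_mito_sep", True, [0])
    add("TN", n_tn, "training_nonmito_sep", False, [1, 2, 3])
    add("CAND_M", n_cm_cand, "candidate", True, [0])
    add("CAND_N", n_candidates - n_cm_cand, "candidate", False, [1, 2, 3])
    add("BG", n_background, None, False, [])

    factors = rng.standard_normal((4, n_samples))
    z = np.empty((len(names), n_samples))
    load = np.sqrt(rho)
    for gi, fi in enumerate(factor_idx):
        noise = rng.standard_normal(n_samples)
        if fi >= 0:
            z[gi] = load * factors[fi] + np.sqrt(1 - rho) * noise
        else:
            z[gi] = noise
    expr = pd.DataFrame(np.round(np.exp(2.5 + z)),
                        index=names,
                        columns=[f"s{j:02d}" for j in range(n_samples)])

    role_series = pd.Series({n: r for n, r in zip(names, roles) if r},
                            dtype=object)
    ds = ExpressionDataset(expr, role_series, dataset_id)

    mito_classifier = [n for n, r in zip(names, roles) if r == "classifier_mito"]
    background = [n for n, r in zip(names, roles) if r is None]
    nonmito_classifier = [n for n, r in zip(names, roles)
                          if r == "classifier_nonmito"]
    # with no background genes, pad sets from the non-mito classifier pool
    filler_pool = background if background else nonmito_classifier
    gene_sets: dict[str, list[str]] = {}
    set_size = 30
    for k in range(5):
        n_mito = min(int(0.6 * set_size), len(mito_classifier))
        members = (list(rng.choice(mito_classifier, n_mito, replace=False))
                   + list(rng.choice(filler_pool,
                                     min(set_size - n_mito, len(filler_pool)),
                                     replace=False)))
        gene_sets[f"mito_like_{k}"] = sorted(members)
    decoy_pool = background + nonmito_classifier
    for k in range(5):
        gene_sets[f"decoy_{k}"] = sorted(
            rng.choice(decoy_pool, min(set_size, len(decoy_pool)),
                       replace=False))

    truth = pd.DataFrame({
        "item_id": names,
        "role": [r or "background" for r in roles],
        "true_mito": is_mito_module,
    })
    return ds, gene_sets, truth


# ---------------------------------------------------------------------------
# Peptides with planted targeting motifs
# ---------------------------------------------------------------------------

MOTIF_CLASSES = ("MTS", "TMD", "CXnC", "none")


def _filler(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(HYDROPHILIC, size=length))


def _tmd_core(rng: np.random.Generator, lo: float = 1.8, hi: float = 2.8,
              window: int = 19) -> str:
    pool = list("LAVGSFT")
    while True:
        core = "".join(rng.choice(pool, size=window))
        mean = sum(KYTE_DOOLITTLE[a] for a in core) / window
        if lo <= mean <= hi:
            return core


def gen_peptides(n: int, seed: int,
                 class_mix: dict[str, float] | None = None
                 ) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Peptides with planted targeting-motif classes and predictor scores.

    Returns ``(sequences, predictor_scores, truth)``.  MTS peptides carry
    predictor scores satisfying the consensus rule; TMD peptides contain a
    19-residue window of modest hydrophobicity (above helix-like, below the
    secretory cap); CXnC peptides carry a qualifying twin-cysteine
    combination; "none" peptides satisfy no rule.
    """
    if class_mix is None:
        class_mix = {c: 0.25 for c in MOTIF_CLASSES}
    if not class_mix:
        raise ValueError("class_mix must not be empty")
    unknown = set(class_mix) - set(MOTIF_CLASSES)
    if unknown:
        raise ValueError(f"unknown motif classes {unknown}")
    if abs(sum(class_mix.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix fractions must sum to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(list(class_mix), size=n, p=list(class_mix.values()))

    seqs: dict[str, str] = {}
    score_rows, truth_rows = [], []
    for i, label in enumerate(labels):
        pid = f"pep{i:04d}"
        length = int(rng.integers(45, 80))
        scores = {"peptide_id": pid, "targetp_location": "other",
                  "targetp_reliability_class": int(rng.integers(3, 6)),
                  "mitofate_score": float(rng.uniform(0.0, 0.5)),
                  "mitoprot_score": float(rng.uniform(0.0, 0.5)),
                  "tmhmm_tmd": False, "signalp_call": False}
        if label == "MTS":
            seq = _filler(rng, length)
            scores["targetp_location"] = "mitochondria"
            scores["targetp_reliability_class"] = int(rng.integers(1, 3))
            if rng.random() < 0.5:
                scores["mitofate_score"] = float(rng.uniform(0.801, 0.999))
            else:
                scores["mitoprot_score"] = float(rng.uniform(0.801, 0.999))
        elif label == "TMD":
            core = _tmd_core(rng)
            start = int(rng.integers(0, length - len(core) + 1))
            seq = (_filler(rng, start) + core
                   + _filler(rng, length - start - len(core)))
            scores["tmhmm_tmd"] = bool(rng.random() < 0.5)
        elif label == "CXnC":
            variant = rng.integers(0, 3)
            motifs = {0: [9, 9], 1: [3, 3], 2: [9, 10]}[int(variant)]
            pieces = [_filler(rng, int(rng.integers(2, 8)))]
            for nx in motifs:
                pieces.append("C" + _filler(rng, nx) + "C")
                pieces.append(_filler(rng, int(rng.integers(2, 8))))
            seq = "".join(pieces)
            if len(seq) < length:
                seq += _filler(rng, length - len(seq))
        else:
            seq = _filler(rng, length)
        seqs[pid] = seq
        score_rows.append(scores)
        truth_rows.append({"item_id": pid, "motif_class": label})
    return seqs, pd.DataFrame(score_rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Toy cardiomyocyte-like metabolic model
# ---------------------------------------------------------------------------

#: Physiological ATP demand of the toy model (lower bound on the objective),
#: 90% of its unconstrained ATP capacity; computed once from the stoichiometry
#: below and frozen.  See docs/methods.md.
TOY_ATP_DEMAND = 244.8


def gen_toy_metabolic_model(atp_demand: float | None = None) -> MetabolicModel:
    """Deterministic miniature cardiomyocyte-like metabolic network.

    Glucose uptake feeds lumped glycolysis; pyruvate goes to lactate (with
    export), to acetyl-CoA and an explicit succinate node (with export), or to
    oxaloacetate (anaplerosis).  Separate cytosolic and mitochondrial NAD(H)
    pools are connected by a malate shuttle and a glycerol-phosphate-like
    quinone shuttle; the respiratory chain is lumped into CI, CII (reversible
    succinate dehydrogenase, enabling fumarate respiration), CIII, CIV and CV,
    coupled through a proton-motive currency metabolite.  The ATP demand
    reaction is the objective and carries a physiological lower bound near the
    model's capacity, representing a hard-working cardiomyocyte; blockage
    screening relaxes that bound before computing each blocked model's own
    capacity.

    The published export/objective naming is mirrored: lactate export
    ``L_LACt2r``, succinate export ``SUMt_MitoCore``, ATP objective
    ``OF_ATP_MitoCore``.
    """
    if atp_demand is None:
        atp_demand = TOY_ATP_DEMAND
    mets = ["glc", "pyr", "lac", "accoa", "oaa", "mal", "fum", "succ",
            "nadh_c", "nad_c", "nadh_m", "nad_m", "q", "qh2",
            "cytc_ox", "cytc_red", "o2", "atp", "adp", "h_psi"]
    rx = [
        Reaction("EX_glc", {"glc": 1}, 0, 10),
        Reaction("GLYC", {"glc": -1, "adp": -2, "nad_c": -2,
                          "pyr": 2, "atp": 2, "nadh_c": 2}, 0, 1000, "gGLYC"),
        Reaction("LDH", {"pyr": -1, "nadh_c": -1, "lac": 1, "nad_c": 1},
                 0, 1000, "gLDH"),
        Reaction("L_LACt2r", {"lac": -1}, 0, 1000),
        Reaction("EX_pyr", {"pyr": -1}, 0, 5),
        Reaction("PDH", {"pyr": -1, "nad_m": -1, "accoa": 1, "nadh_m": 1},
                 0, 1000, "gPDH"),
        Reaction("PC", {"pyr": -1, "atp": -1, "oaa": 1, "adp": 1},
                 0, 1000, "gPC"),
        Reaction("EX_accoa", {"accoa": -1}, 0, 5),
        Reaction("CS_TCA", {"accoa": -1, "oaa": -1, "nad_m": -2,
                            "succ": 1, "nadh_m": 2}, 0, 1000, "gCS"),
        Reaction("MDH_m", {"mal": -1, "nad_m": -1, "oaa": 1, "nadh_m": 1},
                 -1000, 1000, "gMDHm"),
        Reaction("MDH_c", {"oaa": -1, "nadh_c": -1, "mal": 1, "nad_c": 1},
                 -1000, 1000, "gMDHc"),
        Reaction("FH", {"fum": -1, "mal": 1}, -1000, 1000, "gFH"),
        # CII / succinate dehydrogenase; reversible (fumarate respiration)
        Reaction("CII_SDH", {"succ": -1, "q": -1, "fum": 1, "qh2": 1},
                 -1000, 1000, "gCII"),
        Reaction("SUMt_MitoCore", {"succ": -1}, 0, 1000),
        Reaction("GPS", {"nadh_c": -1, "q": -1, "nad_c": 1, "qh2": 1},
                 0, 1000, "gGPS"),
        Reaction("CI", {"nadh_m": -1, "q": -1, "nad_m": 1, "qh2": 1,
                        "h_psi": 4}, 0, 1000, "gCI"),
        Reaction("CIII", {"qh2": -1, "cytc_ox": -2, "q": 1, "cytc_red": 2,
                          "h_psi": 2}, 0, 1000, "gCIII_1 and gCIII_2"),
        Reaction("CIV", {"cytc_red": -4, "o2": -1, "cytc_ox": 4, "h_psi": 8},
                 0, 1000, "gCIV"),
        Reaction("CV", {"adp": -1, "h_psi": -3, "atp": 1}, 0, 1000,
                 "gCV_a or gCV_b"),
        Reaction("LEAK", {"h_psi": -1}, 0, 1000),
        Reaction("EX_o2", {"o2": 1}, 0, 40),
        Reaction("OF_ATP_MitoCore", {"atp": -1, "adp": 1}, atp_demand, 1000),
    ]
    return MetabolicModel(
        id="toy_cardiomyocyte",
        metabolites=mets,
        reactions=rx,
        objective_id="OF_ATP_MitoCore",
        lactate_export_id="L_LACt2r",
        succinate_export_id="SUMt_MitoCore",
    )


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

def gen_psm_table(n: int, seed: int, retained_fraction: float = 0.5
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PSM records varying in partition mapping, spectrum coverage and FDR."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= retained_fraction <= 1:
        raise ValueError("retained_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows, truths = [], []
    other_partitions = [["canonical_proteome"], ["contaminants"],
                        ["sorf_db", "canonical_proteome"],
                        ["sorf_db", "contaminants"],
                        ["canonical_proteome", "contaminants"]]
    for i in range(n):
        keep = bool(rng.random() < retained_fraction)
        length = int(rng.integers(7, 30))
        rec = {
            "psm_id": f"psm{i:05d}",
            "peptide_seq": "".join(rng.choice(AA_ALPHABET, size=length)),
            "matched_partitions": "sorf_db",
            # boundary value 0.30 is retained (inclusive threshold)
            "spectrum_coverage": float(0.30 if rng.random() < 0.1
                                       else rng.uniform(0.30, 1.0)),
            "fdr": float(rng.uniform(0.0, 0.0099)),
        }
        violated = []
        if not keep:
            choices = rng.choice(["partition", "coverage", "fdr"],
                                 size=int(rng.integers(1, 4)), replace=False)
            if "partition" in choices:
                rec["matched_partitions"] = ";".join(
                    other_partitions[int(rng.integers(0, len(other_partitions)))])
                violated.append("not_solely_sorf")
            if "coverage" in choices:
                rec["spectrum_coverage"] = float(rng.uniform(0.0, 0.2999))
                violated.append("min_coverage")
            if "fdr" in choices:
                # boundary value 0.01 fails the strict < rule
                rec["fdr"] = float(0.01 if rng.random() < 0.2
                                   else rng.uniform(0.01, 0.2))
                violated.append("max_fdr")
        rows.append(rec)
        truths.append({"item_id": rec["psm_id"], "retained": keep,
                       "violated_rules": ";".join(sorted(violated))})
    return pd.DataFrame(rows), pd.DataFrame(truths)


# ---------------------------------------------------------------------------
# TMT proteomics matrices
# ---------------------------------------------------------------------------

CHANNELS = ("ctrl_1", "ctrl_2", "ctrl_3", "ko_1", "ko_2", "ko_3")


def gen_proteomics_matrix(n_proteins: int = 400, seed: int = 0,
                          depletion_log2fc: float = -2.0, sigma: float = 0.3,
                          n_ciii: int = 10
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series,
                                     pd.DataFrame]:
    """3v3 TMT reporter-intensity matrix with a planted complex-III depletion.

    The first ``n_ciii`` proteins are complex III members whose KO channels
    are shifted by ``depletion_log2fc`` on the log2 scale; channel noise is
    N(0, sigma).  A small fraction of non-CIII rows carry missing values or
    <=2 unique peptides so the validity filters have work to do.

    Returns ``(intensities, annotations, groups, truth)`` with raw (linear)
    intensities; annotations carry mito flags, complex membership and
    unique-peptide counts.
    """
    if n_ciii >= n_proteins:
        raise ValueError("n_ciii must be smaller than n_proteins")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    ids = [f"P{i:05d}" for i in range(n_proteins)]
    base = rng.normal(20.0, 2.0, size=n_proteins)
    log2 = base[:, None] + rng.normal(0.0, sigma, size=(n_proteins, 6))
    log2[:n_ciii, 3:] += depletion_log2fc

    complexes = np.array(["other"] * n_proteins, dtype=object)
    complexes[:n_ciii] = "CIII"
    pool = rng.permutation(np.arange(n_ciii, n_proteins))
    extra = ["CI", "CII", "CIV", "CV", "AF"]
    per = max(1, (n_proteins - n_ciii) // 20)
    for k, cx in enumerate(extra):
        complexes[pool[k * per:(k + 1) * per]] = cx
    mito = (complexes != "other") | (rng.random(n_proteins) < 0.3)

    peptides = rng.integers(3, 30, size=n_proteins)
    modifiable = np.arange(n_ciii, n_proteins)
    low_pep = rng.choice(modifiable, size=max(1, int(0.08 * n_proteins)),
                         replace=False)
    peptides[low_pep] = rng.integers(1, 3, size=len(low_pep))
    with_nan = rng.choice(np.setdiff1d(modifiable, low_pep),
                          size=max(1, int(0.05 * n_proteins)), replace=False)
    for r in with_nan:
        log2[r, int(rng.integers(0, 6))] = np.nan

    intensities = pd.DataFrame(2.0 ** log2, index=ids, columns=list(CHANNELS))
    annotations = pd.DataFrame({
        "mito": mito, "complex": complexes, "n_unique_peptides": peptides,
    }, index=ids)
    groups = pd.Series(["control"] * 3 + ["ko"] * 3, index=list(CHANNELS))
    truth = pd.DataFrame({
        "item_id": ids,
        "depleted": [i < n_ciii for i in range(n_proteins)],
        "complex": complexes,
        "usable": (peptides > 2) & ~np.isnan(log2).any(axis=1),
    })
    return intensities, annotations, groups, truth
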