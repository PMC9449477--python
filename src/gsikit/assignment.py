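"""Hierarchical SVM population assignment with decision-table final calls.

The engine mirrors a supervised machine-learning genetic stock identification
workflow: balanced training sets drawn from the baseline, locus subsampling
(top-F_ST within the training split, or random), dosage-encoding -> PCA ->
radial-kernel SVM with Platt-calibrated probabilities, Monte Carlo and K-fold
cross-validation, and a two-approach x two-level hierarchy whose final calls
are a pure function of the level-wise probabilities, a decision table and a
probability threshold.

Level 1 separates the autumn-spawning group (6aN_Aut) from the combined
winter/spring group (6aS + 6aN_Sp); Level 2 splits that combined group.
Approach 1 uses predefined population labels; Approach 2 uses K-means
cluster proxies.  Each level is strictly binary.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .containers import BaselineDataset, GenotypeMatrix
from .popgen import perlocus_fst

# canonical group names (Approach 1)
L1_AUT = "6aN_Aut"
L1_MIX = "6aS/6aN_Sp"
L2_S = "6aS"
L2_SP = "6aN_Sp"
# Approach 2 cluster-proxy analogues
A2_L1_AUT = "6aN_Aut^A2"
A2_L1_MIX = "6aS/6aN_Sp^A2L1"
A2_L2_S = "6aS^A2L2"
A2_L2_MIX = "6aS/6aN_Sp^A2L2"

NA_LABEL = "NA"


@dataclass
class AssignerConfig:
    """Configuration of one binary assigner (one approach, one level)."""

    approach: int = 1  # 1 = predefined populations, 2 = cluster proxies
    level: int = 1
    n_train_per_group: int = 200
    loci_mode: str = "fst"  # "fst" | "random"
    loci_fraction: float = 1.0
    n_pcs: int = 40
    svm_cost: float = 1.0
    svm_gamma: float = 0.33
    n_iterations: int = 100
    threshold: float = 0.67
    seed: int = 0

    def __post_init__(self) -> None:
        if self.approach not in (1, 2):
            raise ValueError("approach must be 1 or 2")
        if self.level not in (1, 2):
            raise ValueError("level must be 1 or 2")
        if not (0 < self.loci_fraction <= 1):
            raise ValueError("loci_fraction must be in (0, 1]")
        if not (0.5 < self.threshold <= 1):
            raise ValueError("threshold must be in (0.5, 1]")
        if self.loci_mode not in ("fst", "random"):
            raise ValueError("loci_mode must be 'fst' or 'random'")


def level_labels(populations: pd.Series, level: int, approach: int = 1) -> pd.Series:
    """Collapse population labels to the binary contrast of a level.

    Level 1 contrasts the autumn group with everything else pooled; Level 2
    keeps only the two non-autumn groups (others come back as NaN and should
    be dropped by the caller).
    """
    aut, mix = (L1_AUT, L1_MIX) if approach == 1 else (A2_L1_AUT, A2_L1_MIX)
    if level == 1:
        return populations.map(lambda p: aut if p in (L1_AUT, A2_L1_AUT) else mix)
    if approach == 1:
        return populations.map(lambda p: p if p in (L2_S, L2_SP) else np.nan)
    return populations.map(lambda p: p if p in (A2_L2_S, A2_L2_MIX) else np.nan)


# ---------------------------------------------------------------------------
# Training-set construction and locus subsampling
# ---------------------------------------------------------------------------

def build_training_set(baseline: BaselineDataset, config: AssignerConfig, rng=None):
    """Balanced train/test split plus the locus subset for one iteration.

    Per group, ``n_train_per_group`` individuals are sampled without
    replacement (the remainder is the test set).  The locus subset is the top
    ceil(fraction x L) loci ranked by per-locus F_ST computed on the training
    split only (mode "fst"), or a uniform random subset (mode "random");
    at least one locus is always retained.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    labels = baseline.labels()
    groups = list(dict.fromkeys(labels))
    sizes = labels.value_counts()
    too_small = [g for g in groups if sizes[g] < config.n_train_per_group]
    if too_small:
        raise ValueError(
            f"n_train_per_group={config.n_train_per_group} exceeds group size for "
            f"{too_small} (smallest: {sizes.min()})"
        )
    train_ids, test_ids = [], []
    for g in groups:
        ids = np.asarray(labels.index[labels == g])
        pick = rng.choice(len(ids), size=config.n_train_per_group, replace=False)
        mask = np.zeros(len(ids), dtype=bool)
        mask[pick] = True
        train_ids.extend(ids[mask])
        test_ids.extend(ids[~mask])

    markers = baseline.genotypes.markers
    n_keep = max(1, math.ceil(config.loci_fraction * len(markers)))
    if n_keep >= len(markers):
        loci = list(markers)
    elif config.loci_mode == "random":
        loci = list(rng.choice(markers, size=n_keep, replace=False))
    else:
        train_dos = baseline.genotypes.dosage.loc[train_ids].to_numpy(dtype=float)
        train_labels = labels.loc[train_ids]
        per_group = [
            train_dos[(train_labels == g).to_numpy()] for g in groups
        ]
        theta = perlocus_fst(per_group)
        theta = np.where(np.isnan(theta), -np.inf, theta)
        order = np.argsort(-theta, kind="stable")  # ties keep panel order
        loci = [markers[i] for i in order[:n_keep]]
    return train_ids, test_ids, loci


# ---------------------------------------------------------------------------
# Feature pipeline + SVM
# ---------------------------------------------------------------------------

class _FeaturePipeline:
    """Impute (training column means) -> center -> PCA, fitted on training only."""

    def __init__(self, n_pcs: int):
        self.n_pcs = n_pcs

    def fit(self, dosage: pd.DataFrame):
        self.columns_ = list(dosage.columns)
        self.means_ = dosage.mean(axis=0)
        self.means_ = self.means_.fillna(0.0)  # all-missing training column
        x = dosage.fillna(self.means_).to_numpy(dtype=float) - self.means_.to_numpy()
        rank = min(x.shape[0] - 1, x.shape[1])
        self.n_pcs_used_ = min(self.n_pcs, rank)
        self.pca_ = PCA(n_components=self.n_pcs_used_, svd_solver="full").fit(x)
        return self

    def transform(self, dosage: pd.DataFrame) -> np.ndarray:
        d = dosage[self.columns_]
        x = d.fillna(self.means_).to_numpy(dtype=float) - self.means_.to_numpy()
        return self.pca_.transform(x)


@dataclass
class TrainedAssigner:
    """One fitted binary assigner: feature pipeline + Platt-calibrated RBF SVM."""

    config: AssignerConfig
    classes: list
    pipeline: _FeaturePipeline
    svm: CalibratedClassifierCV
    loci: list

    @property
    def support_vectors_(self) -> np.ndarray:
        return self.svm.calibrated_classifiers_[0].estimator.support_vectors_

    def predict_proba(self, genotypes: GenotypeMatrix) -> pd.DataFrame:
        dos = genotypes.dosage.reindex(columns=self.loci)
        scores = self.pipeline.transform(dos)
        proba = self.svm.predict_proba(scores)
        return pd.DataFrame(proba, index=genotypes.individuals, columns=self.svm.classes_)


def train_assigner(
    genotypes: GenotypeMatrix,
    labels: pd.Series,
    config: AssignerConfig,
    loci=None,
    random_state: int | None = None,
) -> TrainedAssigner:
    """Fit dosage -> PCA -> radial-kernel SVM with Platt-calibrated probabilities.

    ``labels`` must contain exactly two classes.  ``n_pcs`` larger than the
    training rank is clipped with a warning.
    """
    import warnings

    y = labels.loc[genotypes.individuals]
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValueError(f"training labels must have exactly 2 classes, got {classes}")
    loci = list(loci) if loci is not None else list(genotypes.markers)
    dos = genotypes.dosage[loci]
    pipe = _FeaturePipeline(config.n_pcs).fit(dos)
    if pipe.n_pcs_used_ < config.n_pcs:
        warnings.warn(
            f"n_pcs clipped from {config.n_pcs} to training rank {pipe.n_pcs_used_}"
        )
    x = pipe.transform(dos)
    counts = y.value_counts()
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 training individuals")
    rs = config.seed if random_state is None else random_state
    # Platt scaling on cross-validated decision values; the final RBF SVM is
    # refit on the full training set (ensemble=False)
    svm = CalibratedClassifierCV(
        SVC(kernel="rbf", C=config.svm_cost, gamma=config.svm_gamma),
        method="sigmoid",
        cv=StratifiedKFold(
            n_splits=min(5, int(counts.min())), shuffle=True, random_state=rs
        ),
        ensemble=False,
    ).fit(x, y)
    return TrainedAssigner(config, classes, pipe, svm, loci)


def tune_svm(
    genotypes: GenotypeMatrix,
    labels: pd.Series,
    cost_grid=(0.1, 1, 10),
    gamma_grid=(0.1, 0.33, 0.5, 1.0),
    cv_folds: int = 5,
    n_pcs: int = 40,
    seed: int = 0,
):
    """Grid search for (cost, gamma) by cross-validated accuracy.

    Ties resolve to the smallest cost, then the smallest gamma.  Returns
    ``((cost, gamma), DataFrame of accuracies)``.
    """
    y = labels.loc[genotypes.individuals].to_numpy()
    if len(set(y)) < 2:
        raise ValueError("degenerate single-class training data")
    if not len(cost_grid) or not len(gamma_grid):
        raise ValueError("grids must be nonempty")
    dos = genotypes.dosage
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(y)), y))
    records = []
    for cost in sorted(cost_grid):
        for gamma in sorted(gamma_grid):
            accs = []
            for tr, te in folds:
                pipe = _FeaturePipeline(n_pcs).fit(dos.iloc[tr])
                svm = SVC(kernel="rbf", C=cost, gamma=gamma, random_state=seed).fit(
                    pipe.transform(dos.iloc[tr]), y[tr]
                )
                accs.append(float((svm.predict(pipe.transform(dos.iloc[te])) == y[te]).mean()))
            records.append({"cost": cost, "gamma": gamma, "accuracy": float(np.mean(accs))})
    table = pd.DataFrame(records)
    best = table.loc[table["accuracy"].idxmax()]  # grid sorted -> first max wins ties
    return (float(best["cost"]), float(best["gamma"])), table


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _aggregate(per_iter: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean +/- s.d. of true-group membership probability and accuracy per group."""
    stacked = pd.concat(per_iter)
    out = stacked.groupby("group").agg(
        mean_probability=("probability", "mean"),
        sd_probability=("probability", "std"),
        accuracy=("correct", "mean"),
        n_tested=("correct", "size"),
    )
    out["sd_probability"] = out["sd_probability"].fillna(0.0)
    return out.reset_index()


def _score_split(
    baseline: BaselineDataset,
    binary_labels: pd.Series,
    train_ids,
    test_ids,
    loci,
    config: AssignerConfig,
    random_state: int,
) -> pd.DataFrame:
    model = train_assigner(
        baseline.genotypes.subset(individuals=train_ids),
        binary_labels,
        config,
        loci=loci,
        random_state=random_state,
    )
    proba = model.predict_proba(baseline.genotypes.subset(individuals=test_ids))
    truth = binary_labels.loc[test_ids]
    p_true = pd.Series(
        [proba.loc[i, truth.loc[i]] for i in test_ids], index=test_ids, dtype=float
    )
    pred = proba.idxmax(axis=1)
    return pd.DataFrame(
        {"group": truth, "probability": p_true, "correct": (pred == truth).astype(float)}
    )


def monte_carlo_cv(baseline: BaselineDataset, config: AssignerConfig) -> pd.DataFrame:
    """Monte Carlo cross-validation of one binary assigner.

    ``config.n_iterations`` independent balanced splits; each trains on the
    training part only (locus ranking included) and scores the held-out
    individuals.  Returns per-group mean +/- s.d. of the true-group
    membership probability and the argmax assignment accuracy.
    """
    binary = level_labels(baseline.labels(), config.level, config.approach)
    keep = binary.notna()
    base = baseline.subset(baseline.metadata.index[keep])
    binary = binary[keep]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    relabeled = BaselineDataset(
        base.genotypes, base.metadata.assign(population=binary.values)
    )
    per_iter = []
    for it in range(config.n_iterations):
        train_ids, test_ids, loci = build_training_set(relabeled, config, rng=rng)
        per_iter.append(
            _score_split(
                base, binary, train_ids, test_ids, loci, config,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return _aggregate(per_iter)


def kfold_cv(baseline: BaselineDataset, config: AssignerConfig, k_folds: int = 5) -> pd.DataFrame:
    """Stratified K-fold cross-validation; every individual tested exactly once."""
    if not (2 <= k_folds):
        raise ValueError("k_folds must be >= 2")
    binary = level_labels(baseline.labels(), config.level, config.approach)
    keep = binary.notna()
    base = baseline.subset(baseline.metadata.index[keep])
    binary = binary[keep]
    sizes = binary.value_counts()
    if (sizes < k_folds).any():
        raise ValueError(f"a group is smaller than k_folds={k_folds}: {dict(sizes)}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=config.seed)
    ids = np.asarray(base.genotypes.individuals)
    y = binary.loc[ids].to_numpy()
    markers = base.genotypes.markers
    n_keep = max(1, math.ceil(config.loci_fraction * len(markers)))
    per_iter = []
    for tr, te in skf.split(np.zeros(len(ids)), y):
        train_ids, test_ids = list(ids[tr]), list(ids[te])
        if n_keep >= len(markers):
            loci = list(markers)
        elif config.loci_mode == "random":
            loci = list(rng.choice(markers, size=n_keep, replace=False))
        else:
            dos_tr = base.genotypes.dosage.loc[train_ids].to_numpy(dtype=float)
            lab_tr = binary.loc[train_ids]
            theta = perlocus_fst(
                [dos_tr[(lab_tr == g).to_numpy()] for g in sorted(set(y))]
            )
            theta = np.where(np.isnan(theta), -np.inf, theta)
            loci = [markers[i] for i in np.argsort(-theta, kind="stable")[:n_keep]]
        per_iter.append(
            _score_split(
                base, binary, train_ids, test_ids, loci, config,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return _aggregate(per_iter)


def locus_sensitivity(
    baseline: BaselineDataset,
    config: AssignerConfig,
    fractions=tuple(f / 10 for f in range(2, 11)),
    mode: str = "random",
) -> pd.DataFrame:
    """Assignment accuracy as a function of the fraction of loci used.

    Runs Monte Carlo cross-validation at each fraction (random subsampling by
    default), yielding the accuracy-vs-fraction curve used to justify the
    missing-data tolerance for unknowns.
    """
    if any(not (0 < f <= 1) for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rows = []
    for frac in fractions:
        cfg = replace(config, loci_fraction=float(frac), loci_mode=mode)
        agg = monte_carlo_cv(baseline, cfg)
        rows.append(
            {
                "fraction": float(frac),
                "accuracy": float((agg["accuracy"] * agg["n_tested"]).sum() / agg["n_tested"].sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Decision table and final calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecisionRule:
    approach: int
    level: int
    group: str
    meets_threshold: bool  # True = P >= threshold row, False = P < threshold row
    action: str  # "assigned" | "move to level 2" | "not assigned"
    final: str | None  # final label, or None when moving to level 2


def decision_table(approach: int) -> list[DecisionRule]:
    """The explicit rule set mapping (level, group, >= / < threshold) to actions.

    Rows exhaust all combinations for the approach; above threshold the
    autumn group is final and the mixed group moves to Level 2; below
    threshold Level 1 is unassigned (NA) and Level 2 falls back to the mixed
    label of its approach.
    """
    if approach == 1:
        return [
            DecisionRule(1, 1, L1_AUT, True, "assigned", L1_AUT),
            DecisionRule(1, 1, L1_MIX, True, "move to level 2", None),
            DecisionRule(1, 1, L1_AUT, False, "not assigned", NA_LABEL),
            DecisionRule(1, 1, L1_MIX, False, "not assigned", NA_LABEL),
            DecisionRule(1, 2, L2_S, True, "assigned", L2_S),
            DecisionRule(1, 2, L2_SP, True, "assigned", L2_SP),
            DecisionRule(1, 2, L2_S, False, "not assigned", L1_MIX),
            DecisionRule(1, 2, L2_SP, False, "not assigned", L1_MIX),
        ]
    if approach == 2:
        return [
            DecisionRule(2, 1, A2_L1_AUT, True, "assigned", A2_L1_AUT),
            DecisionRule(2, 1, A2_L1_MIX, True, "move to level 2", None),
            DecisionRule(2, 1, A2_L1_AUT, False, "not assigned", NA_LABEL),
            DecisionRule(2, 1, A2_L1_MIX, False, "not assigned", NA_LABEL),
            DecisionRule(2, 2, A2_L2_S, True, "assigned", A2_L2_S),
            DecisionRule(2, 2, A2_L2_MIX, True, "assigned", A2_L2_MIX),
            DecisionRule(2, 2, A2_L2_S, False, "not assigned", A2_L1_MIX),
            DecisionRule(2, 2, A2_L2_MIX, False, "not assigned", A2_L1_MIX),
        ]
    raise ValueError("approach must be 1 or 2")


@dataclass
class AssignmentResult:
    """Per-individual probabilities at each level and the final call."""

    individual: str
    p_level1: dict
    p_level2: dict | None
    final: str
    reason: str | None  # None | below-threshold-L1 | below-threshold-L2 | insufficient-loci
    threshold: float


def final_call(p_level1: dict, p_level2: dict | None, table: list[DecisionRule], threshold: float):
    """Apply the decision table to one individual's probabilities.

    Returns ``(final label, reason, level-2 consulted flag)``.  The call is a
    pure function of (probabilities, table, threshold): re-deriving calls
    from stored probabilities reproduces stored labels exactly.
    """
    rules = {(r.level, r.group, r.meets_threshold): r for r in table}
    g1 = max(p_level1, key=lambda g: p_level1[g])
    meets = p_level1[g1] >= threshold
    rule = rules[(1, g1, meets)]
    if rule.action == "assigned":
        return rule.final, None, False
    if rule.action == "not assigned":
        return rule.final, "below-threshold-L1", False
    if p_level2 is None:
        raise ValueError("decision table requires Level 2 probabilities")
    g2 = max(p_level2, key=lambda g: p_level2[g])
    meets2 = p_level2[g2] >= threshold
    rule2 = rules[(2, g2, meets2)]
    reason = None if rule2.action == "assigned" else "below-threshold-L2"
    return rule2.final, reason, True


def assign_unknowns(
    assigner_l1: TrainedAssigner,
    assigner_l2: TrainedAssigner,
    genotypes: GenotypeMatrix,
    table: list[DecisionRule] | None = None,
    threshold: float = 0.67,
    min_loci_fraction: float = 0.6,
    panel_size: int | None = None,
) -> list[AssignmentResult]:
    """Hierarchical assignment of unknown individuals.

    Individuals whose called loci overlap the Level-1 assigner's retained
    loci by less than ``min_loci_fraction`` of the panel are unassigned with
    reason "insufficient-loci".  Everyone else gets Level-1 probabilities;
    the decision table routes them to a final label, consulting Level 2 when
    required.
    """
    if table is None:
        table = decision_table(assigner_l1.config.approach)
    if panel_size is None:
        panel_size = len(assigner_l1.loci)
    p1 = assigner_l1.predict_proba(genotypes)
    p2 = assigner_l2.predict_proba(genotypes)
    called = genotypes.dosage[assigner_l1.loci].notna().sum(axis=1)
    results = []
    for ind in genotypes.individuals:
        if called[ind] < min_loci_fraction * panel_size:
            results.append(
                AssignmentResult(ind, {}, None, NA_LABEL, "insufficient-loci", threshold)
            )
            continue
        probs1 = p1.loc[ind].to_dict()
        probs2 = p2.loc[ind].to_dict()
        final, reason, used_l2 = final_call(probs1, probs2, table, threshold)
        results.append(
            AssignmentResult(ind, probs1, probs2 if used_l2 else None, final, reason, threshold)
        )
    return results


def _call_consistent(final: str, truth: str) -> bool:
    """Is a final call consistent with the true origin?

    The mixed label is consistent with either of its constituent groups;
    NA is never consistent.
    """
    if final == NA_LABEL:
        return False
    if final in (L1_MIX, A2_L1_MIX, A2_L2_MIX):
        return truth in (L2_S, L2_SP, A2_L2_S, A2_L2_MIX)
    if final in (L1_AUT, A2_L1_AUT):
        return truth in (L1_AUT, A2_L1_AUT)
    if final in (L2_S, A2_L2_S):
        return truth in (L2_S, A2_L2_S)
    return final == truth


def hierarchical_self_assignment(
    baseline: BaselineDataset,
    config_l1: AssignerConfig,
    config_l2: AssignerConfig | None = None,
    n_iterations: int | None = None,
):
    """Monte Carlo self-assignment through the full two-level hierarchy.

    Each iteration draws one balanced training split per population, trains
    the Level-1 and Level-2 assigners on the training individuals only, runs
    the held-out individuals through the decision table, and scores the final
    call against the true origin (the mixed label counts as consistent with
    either constituent group; NA counts as wrong).

    Returns ``(overall accuracy, per-iteration DataFrame)``.
    """
    if config_l2 is None:
        config_l2 = replace(config_l1, level=2, svm_gamma=0.5)
    if n_iterations is None:
        n_iterations = config_l1.n_iterations
    table = decision_table(config_l1.approach)
    labels = baseline.labels()
    rng = np.random.default_rng(np.random.SeedSequence([config_l1.seed, 303]))
    rows = []
    for it in range(n_iterations):
        train_ids, test_ids, loci = build_training_set(baseline, config_l1, rng=rng)
        train_geno = baseline.genotypes.subset(individuals=train_ids, markers=loci)
        lab1 = level_labels(labels.loc[train_ids], 1, config_l1.approach)
        model_l1 = train_assigner(
            train_geno, lab1, config_l1,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        lab2 = level_labels(labels.loc[train_ids], 2, config_l2.approach)
        keep2 = lab2.notna()
        model_l2 = train_assigner(
            train_geno.subset(individuals=lab2.index[keep2]), lab2[keep2], config_l2,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        test_geno = baseline.genotypes.subset(individuals=test_ids, markers=loci)
        results = assign_unknowns(
            model_l1, model_l2, test_geno, table=table,
            threshold=config_l1.threshold, panel_size=len(loci),
        )
        correct = [
            _call_consistent(r.final, labels.loc[r.individual]) for r in results
        ]
        rows.append({"iteration": it, "accuracy": float(np.mean(correct)),
                     "n_tested": len(results)})
    per_iter = pd.DataFrame(rows)
    overall = float(
        (per_iter["accuracy"] * per_iter["n_tested"]).sum() / per_iter["n_tested"].sum()
    )
    return overall, per_iter


def composition_estimate(results: list[AssignmentResult]) -> pd.Series:
    """Counts of final labels over a set of assignment results."""
    return pd.Series([r.final for r in results]).value_counts()


def results_to_frame(results: list[AssignmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"individual": r.individual, "final": r.final, "reason": r.reason,
               "threshold": r.threshold}
        for g, p in r.p_level1.items():
            row[f"p_L1[{g}]"] = p
        for g, p in (r.p_level2 or {}).items():
            row[f"p_L2[{g}]"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def threshold_sweep(
    results: list[AssignmentResult],
    thresholds=(0.67, 0.7, 0.8, 0.9),
    sample_of: pd.Series | None = None,
) -> pd.DataFrame:
    """Proportion of individuals below threshold at each level, per threshold.

    Recomputes calls from the stored probabilities without retraining.  The
    Level-2 proportion is taken over individuals that reached Level 2.  With
    ``sample_of`` (individual -> sample id) the proportions are reported per
    sample and averaged; otherwise over the whole set.
    """
    rows = []
    scored = [r for r in results if r.reason != "insufficient-loci"]
    for t in thresholds:
        recs = []
        for r in scored:
            below1 = max(r.p_level1.values()) < t
            reached2 = r.p_level2 is not None
            below2 = reached2 and max(r.p_level2.values()) < t
            recs.append(
                {
                    "individual": r.individual,
                    "below_L1": below1,
                    "reached_L2": reached2,
                    "below_L2": below2,
                }
            )
        df = pd.DataFrame(recs).set_index("individual")
        if sample_of is not None:
            df["sample"] = sample_of.loc[df.index]
            per_sample = df.groupby("sample").agg(
                below_L1=("below_L1", "mean"),
                below_L2=(
                    "below_L2",
                    lambda s: s[df.loc[s.index, "reached_L2"]].mean()
                    if df.loc[s.index, "reached_L2"].any()
                    else 0.0,
                ),
            )
            l1 = float(per_sample["below_L1"].mean())
            l2 = float(per_sample["below_L2"].mean())
        else:
            l1 = float(df["below_L1"].mean())
            reached = df["reached_L2"]
            l2 = float(df.loc[reached, "below_L2"].mean()) if reached.any() else 0.0
        rows.append({"threshold": t, "below_L1": l1, "below_L2": l2})
    return pd.DataFrame(rows)
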