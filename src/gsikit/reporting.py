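"""Composition reports and the end-to-end pipeline driver.

The pipeline runs: simulate baseline -> simulate reads -> call genotypes ->
completeness filter -> baseline F_ST -> cluster discovery -> hierarchical
cross-validation -> assignment of a simulated mixed sample -> threshold sweep
-> per-quarter composition tables.  All randomness flows from the config
seed; rerunning the same config reproduces identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assignment import (
    AssignerConfig,
    AssignmentResult,
    assign_unknowns,
    monte_carlo_cv,
    results_to_frame,
    threshold_sweep,
    train_assigner,
    build_training_set,
    level_labels,
    decision_table,
)
from .containers import BaselineDataset, GenotypeMatrix
from .dapc import encode_genotypes, find_clusters, map_clusters_to_proxies
from .genotyping import call_matrix, filter_individuals
from .panel import default_panel
from .popgen import pairwise_fst
from .simulate import (
    MixtureSpec,
    ReadSimParams,
    simulate_allele_frequencies,
    simulate_baseline_genotypes,
    simulate_mixed_sample,
    simulate_read_counts,
    write_baseline_csv,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Composition reports
# ---------------------------------------------------------------------------

@dataclass
class CompositionReport:
    """Final-call composition of one sample in one quarter."""

    sample: str
    quarter: object
    n_individuals: int
    counts: dict  # final label -> count
    fractions: dict  # final label -> fraction (sums to 1)
    threshold: float


def composition_report(
    results: list[AssignmentResult],
    metadata: pd.DataFrame,
    group_by: str = "quarter",
) -> list[CompositionReport]:
    """Per-sample, per-quarter counts and fractions of each final label.

    ``metadata`` needs columns ``individual`` and ``sample`` plus the
    ``group_by`` column (missing quarter values group under "unknown" with a
    warning).  Empty samples are omitted with a warning.
    """
    meta = metadata.set_index("individual") if "individual" in metadata.columns else metadata
    finals = pd.Series({r.individual: r.final for r in results})
    thresholds = {r.threshold for r in results}
    threshold = thresholds.pop() if len(thresholds) == 1 else float("nan")
    meta = meta.loc[finals.index].copy()
    if group_by not in meta.columns:
        raise ValueError(f"metadata lacks column {group_by!r}")
    grouping = meta[group_by]
    if grouping.isna().any():
        logger.warning(
            "%d individuals without %s grouped under 'unknown'",
            int(grouping.isna().sum()), group_by,
        )
        grouping = grouping.fillna("unknown")
    sample_col = meta["sample"] if "sample" in meta.columns else pd.Series(
        "all", index=meta.index
    )
    reports = []
    for (sample, q), idx in finals.groupby([sample_col, grouping]).groups.items():
        sub = finals.loc[idx]
        if len(sub) == 0:
            logger.warning("empty sample %s/%s omitted", sample, q)
            continue
        counts = sub.value_counts().to_dict()
        n = int(len(sub))
        fractions = {k: v / n for k, v in counts.items()}
        reports.append(CompositionReport(str(sample), q, n, counts, fractions, threshold))
    return reports


def composition_frame(reports: list[CompositionReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        for label in sorted(r.counts):
            rows.append(
                {
                    "sample": r.sample,
                    "quarter": r.quarter,
                    "n_individuals": r.n_individuals,
                    "final": label,
                    "count": r.counts[label],
                    "fraction": r.fractions[label],
                    "threshold": r.threshold,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline configuration and driver
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 1,
    "simulate": {
        "n_per_pop": 300,
        "differentiation": 0.5,
        "missing_rate": 0.01,
        "mixture": {"6aN_Aut": 0.6, "6aS": 0.3, "6aN_Sp": 0.1},
        "n_mixture": 200,
        "reads": {"mean_depth": 100, "dispersion": 2.0, "error_rate": 0.005,
                  "missing_rate": 0.02},
    },
    "caller": {"min_depth": 10, "min_calls": 40},
    "fst": {"n_permutations": 200, "n_bootstrap": 200},
    "clusters": {"k_min": 1, "k_max": 8, "n_pcs": 10},
    "assignment": {
        "n_train_per_group": 200,
        "n_pcs": 20,
        "svm_cost": 1.0,
        "svm_gamma": 0.33,
        "svm_gamma_l2": 0.5,
        "n_iterations": 20,
        "threshold": 0.67,
    },
    "sweep_thresholds": [0.67, 0.7, 0.8, 0.9],
}

POPULATIONS = ["6aN_Aut", "6aS", "6aN_Sp"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see DEFAULT_CONFIG for the schema)."""

    raw: dict = field(default_factory=lambda: DEFAULT_CONFIG)

    def __post_init__(self) -> None:
        cfg = {**DEFAULT_CONFIG, **(self.raw or {})}
        for key in ("simulate", "caller", "fst", "clusters", "assignment"):
            cfg[key] = {**DEFAULT_CONFIG[key], **(cfg.get(key) or {})}
        if "seed" not in cfg or cfg["seed"] is None:
            raise ValueError("config requires a seed")
        if not isinstance(cfg["seed"], int):
            raise ValueError("seed must be an integer")
        fr = cfg["simulate"]["mixture"]
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError("mixture proportions must sum to 1")
        self.cfg = cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.cfg, sort_keys=True).encode()
        ).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str, index=False) -> None:
    """CSV writer stamping package version and config hash as a header comment."""
    with open(path, "w") as fh:
        fh.write(f"# gsikit {__version__}; config_hash={config_hash}\n")
        df.to_csv(fh, index=index)


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute every stage in order; returns the artifact directory.

    Any stage failure aborts with the stage name prepended to the cause.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.cfg
    seed = cfg["seed"]
    chash = config.hash()
    stage = "setup"
    try:
        panel = default_panel()

        stage = "simulate"
        sim = cfg["simulate"]
        specs = simulate_allele_frequencies(
            3, panel, sim["differentiation"], seed=seed,
            pop_names=POPULATIONS, n_individuals=sim["n_per_pop"],
        )
        baseline_true = simulate_baseline_genotypes(
            specs, missing_rate=sim["missing_rate"], seed=seed
        )
        params = ReadSimParams(**sim["reads"])
        counts = simulate_read_counts(baseline_true.genotypes, params, seed=seed)
        mix_geno, mix_truth = simulate_mixed_sample(
            specs, MixtureSpec(sim["mixture"], sim["n_mixture"]), seed=seed
        )
        write_baseline_csv(baseline_true, out / "baseline_true.csv")

        stage = "call"
        called = call_matrix(counts, panel)
        retained, dropped = filter_individuals(called, cfg["caller"]["min_calls"])
        baseline = BaselineDataset(
            retained, baseline_true.metadata.loc[retained.individuals].reset_index(drop=True)
        )
        logger.info("stage call: retained %d, dropped %d", retained.n_individuals, len(dropped))

        stage = "fst"
        fst = pairwise_fst(
            baseline,
            n_permutations=cfg["fst"]["n_permutations"],
            n_bootstrap=cfg["fst"]["n_bootstrap"],
            seed=seed,
        )
        _write_csv(fst.estimate, out / "fst_matrix.csv", chash, index=True)
        _write_csv(fst.p_value, out / "fst_pvalues.csv", chash, index=True)

        stage = "clusters"
        dosage = encode_genotypes(baseline.genotypes)
        solution = find_clusters(
            dosage,
            k_range=range(cfg["clusters"]["k_min"], cfg["clusters"]["k_max"] + 1),
            n_pcs=cfg["clusters"]["n_pcs"],
            seed=seed,
        )
        proxies, views = map_clusters_to_proxies(solution, baseline.labels())
        _write_csv(
            solution.bic.rename("BIC").rename_axis("K").reset_index(), out / "bic.csv", chash
        )
        _write_csv(
            views["populations_by_cluster"], out / "populations_by_cluster.csv", chash,
            index=True,
        )
        _write_csv(
            views["clusters_by_population"], out / "clusters_by_population.csv", chash,
            index=True,
        )

        stage = "cross-validation"
        asg = cfg["assignment"]
        cfg_l1 = AssignerConfig(
            approach=1, level=1,
            n_train_per_group=asg["n_train_per_group"],
            n_pcs=asg["n_pcs"], svm_cost=asg["svm_cost"], svm_gamma=asg["svm_gamma"],
            n_iterations=asg["n_iterations"], threshold=asg["threshold"], seed=seed,
        )
        mc_l1 = monte_carlo_cv(baseline, cfg_l1)
        _write_csv(mc_l1, out / "mc_cv_level1.csv", chash)

        stage = "train"
        labels1 = level_labels(baseline.labels(), 1)
        model_l1 = train_assigner(baseline.genotypes, labels1, cfg_l1)
        labels2 = level_labels(baseline.labels(), 2)
        keep2 = labels2.notna()
        cfg_l2 = AssignerConfig(
            approach=1, level=2,
            n_train_per_group=min(75, int(labels2[keep2].value_counts().min())),
            n_pcs=min(asg["n_pcs"], int(keep2.sum()) - 1),
            svm_cost=asg["svm_cost"], svm_gamma=asg["svm_gamma_l2"],
            n_iterations=asg["n_iterations"], threshold=asg["threshold"], seed=seed,
        )
        model_l2 = train_assigner(
            baseline.genotypes.subset(individuals=labels2.index[keep2]),
            labels2[keep2], cfg_l2,
        )

        stage = "assign"
        results = assign_unknowns(
            model_l1, model_l2, mix_geno, threshold=asg["threshold"],
            panel_size=panel.n_markers,
        )
        frame = results_to_frame(results)
        frame["true_origin"] = mix_truth.loc[frame["individual"]].to_numpy()
        _write_csv(frame, out / "assignments.csv", chash)

        stage = "sweep"
        sweep = threshold_sweep(results, tuple(cfg["sweep_thresholds"]))
        _write_csv(sweep, out / "threshold_sweep.csv", chash)

        stage = "report"
        meta = pd.DataFrame(
            {
                "individual": mix_geno.individuals,
                "sample": "mixed_sim",
                "quarter": 3,
            }
        )
        reports = composition_report(results, meta)
        _write_csv(composition_frame(reports), out / "composition.csv", chash)
    except Exception as exc:  # noqa: BLE001 - annotate stage then re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
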