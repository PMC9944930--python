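"""End-to-end experiment orchestration.

``run_experiment`` executes the full pipeline — simulate panel and cohort,
train per-annotator models, compute agreement, build the four consensus
models, validate everything on static and temporal sets — from a single
serialisable :class:`ExperimentConfig`.  Every output table carries the
config hash and master seed in a comment header, so a run is reproducible
(byte-identical) from the config alone.

The master seed fans out to per-stage seeds through ``numpy``'s
``SeedSequence`` spawning, so stages are statistically independent but fully
determined by the one number.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement as agr
from . import consensus as cns
from . import models as mdl
from . import simulate as sim
from . import validation as val
from .errors import ConfigurationError

log = logging.getLogger("icuconsensus")

STAGES = ("simulate", "train", "agree", "consensus", "validate")


@dataclass
class ExperimentConfig:
    """Complete, serialisable description of one experiment run."""

    seed: int = 42
    n_panel_records: int = 60
    n_cohort_patients: int = 1000
    n_validation_alive: int = 100
    n_validation_died: int = 100
    backend: str = "decision_tree"
    cv_folds: int = 5
    class_weighting: str = "off"
    consensus_threshold: float = 0.7
    tie_rule: str = "most_severe"
    cutoff_scheme: str = "neutral"
    outcome_high_quantile: float = 0.75
    outcome_low_quantile: float = 0.25
    annotator_regime: str = "mixed"  # mixed (4 consistent + 7 noisy) | consistent
    make_figures: bool = False

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def stage_seeds(self) -> dict[str, int]:
        children = np.random.SeedSequence(self.seed).spawn(len(STAGES))
        return {
            stage: int(child.generate_state(1)[0] % 2**31)
            for stage, child in zip(STAGES, children)
        }

    def model_spec(self, seed: int) -> mdl.ModelSpec:
        return mdl.ModelSpec(
            backend=self.backend,
            cv_folds=self.cv_folds,
            class_weighting=self.class_weighting,
            seed=seed,
        )


@dataclass
class ExperimentReport:
    """All tables produced by one experiment run."""

    config: ExperimentConfig
    learnability: pd.DataFrame
    agreement_training: agr.AgreementSummary
    agreement_predicted: agr.AgreementSummary
    validation_static: pd.DataFrame
    validation_temporal: pd.DataFrame
    importances: pd.DataFrame
    internal_external_r: float

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "learnability": self.learnability,
            "agreement_training": self.agreement_training.to_frame(),
            "agreement_predicted": self.agreement_predicted.to_frame(),
            "pairwise_kappa_predicted": self.agreement_predicted.pairwise_kappa.reset_index(
                names="annotator_id"
            ),
            "validation_static": self.validation_static,
            "validation_temporal": self.validation_temporal,
            "importances": self.importances.reset_index(names="annotator_id"),
            "correlation": pd.DataFrame({"internal_external_pearson_r": [self.internal_external_r]}),
        }
        for tag, summary in self.agreement_predicted.per_stratum.items():
            out[f"agreement_predicted_{tag}"] = summary.to_frame()
        return out


def _write_table(df: pd.DataFrame, path: Path, header: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def run_experiment(config: ExperimentConfig, outdir=None) -> ExperimentReport:
    """Run simulate → train → agree → consensus → validate and (optionally)
    write all report tables under ``outdir``."""
    seeds = config.stage_seeds()
    spec = config.model_spec(seeds["train"])

    # --- simulate ------------------------------------------------------
    log.info("stage simulate: panel %d records, cohort %d patients",
             config.n_panel_records, config.n_cohort_patients)
    try:
        if config.annotator_regime == "mixed":
            profiles = sim.default_profiles(seeds["simulate"])
        elif config.annotator_regime == "consistent":
            profiles = [
                sim.AnnotatorProfile(f"C{i + 1}", seed=(seeds["simulate"] * 10007 + i) % 2**31)
                for i in range(11)
            ]
        else:
            raise ConfigurationError(
                f"annotator_regime must be 'mixed' or 'consistent', got {config.annotator_regime!r}"
            )
        panel = sim.generate_annotated_panel(config.n_panel_records, profiles, seeds["simulate"])
        sim_config = sim.SimulationConfig(
            outcome_high_quantile=config.outcome_high_quantile,
            outcome_low_quantile=config.outcome_low_quantile,
        )
        cohort = sim.generate_cohort(config.n_cohort_patients, sim_config, seeds["simulate"] + 1)
        vset_static = sim.make_validation_sets(
            cohort, config.n_validation_alive, config.n_validation_died, "static",
            seeds["simulate"] + 2,
        )
        vset_temporal = sim.make_validation_sets(
            cohort, config.n_validation_alive, config.n_validation_died, "temporal",
            seeds["simulate"] + 2,
        )
    except Exception as err:
        raise ConfigurationError(f"stage 'simulate' failed: {err}") from err

    # --- train ---------------------------------------------------------
    log.info("stage train: %d annotator models (%s)", len(panel.annotator_ids), config.backend)
    report = mdl.assess_learnability(panel, spec)
    annotator_models = mdl.train_all_annotator_models(panel, spec)
    importances = mdl.feature_importance_table(annotator_models)

    # --- agree ---------------------------------------------------------
    log.info("stage agree: training-panel and predicted-label agreement")
    agreement_training = agr.agreement_summary(panel.labels)
    predicted = pd.DataFrame(
        {aid: m.predict(vset_static.feature_table()) for aid, m in annotator_models.items()},
        index=vset_static.records.index,
    )
    agreement_predicted = agr.agreement_summary(
        predicted, strata=vset_static.records["outcome"].to_numpy()
    )

    # --- consensus -----------------------------------------------------
    log.info("stage consensus: MV, TMV (threshold %.2f), FC, TFC", config.consensus_threshold)
    try:
        mv = cns.ConsensusClassifier("MV", tie_rule=config.tie_rule, model_spec=spec).fit(panel)
        tmv = cns.ConsensusClassifier(
            "TMV", threshold=config.consensus_threshold, tie_rule=config.tie_rule, model_spec=spec
        ).fit(panel, report)
        fc = cns.FuzzyConsensus(annotator_models)
        tfc = cns.FuzzyConsensus.top(annotator_models, report, config.consensus_threshold)
    except ConfigurationError as err:
        raise ConfigurationError(f"stage 'consensus' failed: {err}") from err

    # --- validate ------------------------------------------------------
    log.info("stage validate: static + temporal, scheme %r", config.cutoff_scheme)
    entries = [*annotator_models.items(), ("MV", mv), ("TMV", tmv), ("FC", fc), ("TFC", tfc)]
    static_results = [
        val.evaluate_static(m, vset_static, model_id=mid, scheme=config.cutoff_scheme)
        for mid, m in entries
    ]
    temporal_results = [
        val.evaluate_temporal(m, vset_temporal, scheme=config.cutoff_scheme, model_id=mid)
        for mid, m in entries
    ]
    annot_static = [r for r in static_results if r.model_id in annotator_models]
    pearson_r = val.internal_external_correlation(report, annot_static)

    static_table = val.results_table(static_results)
    static_table.insert(1, "internal_f1",
                        [report.scores.get(mid, np.nan) for mid, _ in entries])

    exp_report = ExperimentReport(
        config=config,
        learnability=report.to_frame(),
        agreement_training=agreement_training,
        agreement_predicted=agreement_predicted,
        validation_static=static_table,
        validation_temporal=val.results_table(temporal_results),
        importances=importances,
        internal_external_r=pearson_r,
    )

    if outdir is not None:
        outdir = Path(outdir)
        header = f"# config_hash={config.hash()} seed={config.seed}\n"
        panel_path = outdir / "panel.csv"
        panel_path.parent.mkdir(parents=True, exist_ok=True)
        with open(panel_path, "w") as fh:
            fh.write(header)
            panel_out = panel.features.copy()
            for col in panel.labels.columns:
                panel_out[f"label_{col}"] = panel.labels[col]
            panel_out.to_csv(fh, index_label="instance_id", float_format="%.10g",
                             lineterminator="\n")
        for name, table in exp_report.tables().items():
            _write_table(table, outdir / f"{name}.csv", header)
        if config.make_figures:
            import matplotlib

            matplotlib.use("Agg")
            ax = agr.plot_pairwise_kappa(agreement_predicted)
            ax.figure.savefig(outdir / "pairwise_kappa.png", dpi=150, bbox_inches="tight")
    return exp_report


def replicate_experiment(config: ExperimentConfig, n_seeds: int) -> dict:
    """Re-run the experiment across seeds and summarise MV-vs-TMV behaviour.

    The win rate counts seeds where the TMV static micro-F1 strictly exceeds
    MV's (ties are not wins).
    """
    if n_seeds < 2:
        raise ConfigurationError(f"n_seeds must be >= 2, got {n_seeds}")
    rows = []
    for k in range(n_seeds):
        cfg = dataclasses.replace(config, seed=config.seed + k)
        rep = run_experiment(cfg)
        stat = rep.validation_static.set_index("model_id")["micro_f1"]
        rows.append(
            {
                "seed": cfg.seed,
                "mv_f1": stat["MV"],
                "tmv_f1": stat["TMV"],
                "fc_f1": stat["FC"],
                "tfc_f1": stat["TFC"],
                "mean_annotator_f1": stat.drop(["MV", "TMV", "FC", "TFC"]).mean(),
                "internal_external_r": rep.internal_external_r,
            }
        )
    per_seed = pd.DataFrame(rows)
    return {
        "per_seed": per_seed,
        "tmv_win_rate": float((per_seed["tmv_f1"] > per_seed["mv_f1"]).mean()),
        "tfc_win_rate": float((per_seed["tfc_f1"] > per_seed["fc_f1"]).mean()),
        "mean_mv_f1": float(per_seed["mv_f1"].mean()),
        "mean_tmv_f1": float(per_seed["tmv_f1"].mean()),
    }
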