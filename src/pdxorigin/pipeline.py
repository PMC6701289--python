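"""End-to-end orchestration: data -> MCFS -> informative set -> rules & IFS/SVM.

One :class:`PipelineConfig` drives the whole analysis with a single master
seed that fans out deterministically to per-stage seeds.  Outputs are plain
text (TSV/JSON) plus a machine-readable manifest; identical configs produce
bit-identical files (wall-clock information goes to a separate run.log that
is excluded from that contract).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from .dataset import LabeledDataset
from .ifs import (
    ClassifierConfig,
    CVConfig,
    IFSCurve,
    OptimalFeatureSet,
    cv_evaluate,
    random_subset_significance,
    two_stage_ifs,
)
from .mcfs import (
    MCFSParams,
    RIThreshold,
    compute_relative_importance,
    grow_projection_trees,
    permutation_threshold,
    rank_features,
)
from .metrics import PerformanceReport
from .rules import RipperParams, RuleSet, Rule, evaluate_ruleset, johnson_reducer, ripper_induce, serialize_rules
from .simulate import GroundTruth, SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "ReportBundle",
    "PipelineStageError",
    "validate_config",
    "run_pipeline",
]

_STAGE_NAMES = ("data", "mcfs", "threshold", "rules", "ifs", "significance")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one full run."""

    out_dir: str
    master_seed: int = 0
    # input: either a synthetic world or a pair of files
    synthetic: SyntheticConfig | None = None
    matrix_path: str | None = None
    labels_path: str | None = None
    # stage parameters (seeds inside these are overridden by the master seed)
    mcfs: MCFSParams = field(default_factory=MCFSParams)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    ripper: RipperParams = field(default_factory=RipperParams)
    n_permutations: int = 20
    alpha: float = 0.05
    coarse_step: int = 10
    interval_halfwidth_steps: int = 10
    n_random_subsets: int = 100
    rule_cv_repeats: int = 3
    run_rules: bool = True
    run_ifs: bool = True

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds from the master seed."""
        state = np.random.SeedSequence(self.master_seed).generate_state(
            len(_STAGE_NAMES)
        )
        return {
            name: int(s % (2**31 - 1)) for name, s in zip(_STAGE_NAMES, state)
        }


@dataclass
class ReportBundle:
    """Outputs of one pipeline run: file paths plus in-memory results."""

    out_dir: Path
    manifest: dict
    dataset: LabeledDataset
    ground_truth: GroundTruth | None = None
    ri: np.ndarray | None = None
    ranking: np.ndarray | None = None
    threshold: RIThreshold | None = None
    informative: np.ndarray | None = None
    ruleset: RuleSet | None = None
    rule_self_report: PerformanceReport | None = None
    rule_cv_report: PerformanceReport | None = None
    optimal: OptimalFeatureSet | None = None
    stage1: IFSCurve | None = None
    stage2: IFSCurve | None = None
    random_p: float | None = None
    random_mccs: np.ndarray | None = None
    random_threshold: float | None = None


def validate_config(cfg: PipelineConfig) -> list[str]:
    """All diagnostics for a config (empty list means runnable)."""
    diags: list[str] = []
    if cfg.synthetic is None and (cfg.matrix_path is None or cfg.labels_path is None):
        diags.append("either a synthetic config or matrix_path+labels_path is required")
    if cfg.synthetic is not None and cfg.matrix_path is not None:
        diags.append("give a synthetic config or file paths, not both")
    if cfg.synthetic is not None:
        try:
            cfg.synthetic.validate()
        except ValueError as exc:
            diags.append(f"synthetic: {exc}")
        else:
            smallest = min(cfg.synthetic.class_sizes)
            smallest_name = cfg.synthetic.class_names[
                cfg.synthetic.class_sizes.index(smallest)
            ]
            if cfg.cv.folds > smallest:
                diags.append(
                    f"cv.folds={cfg.cv.folds} exceeds the smallest class "
                    f"{smallest_name!r} ({smallest} samples); folds will be reduced"
                )
            try:
                cfg.mcfs.validate(cfg.synthetic.n_genes)
            except ValueError as exc:
                diags.append(f"mcfs: {exc}")
    else:
        for path, what in ((cfg.matrix_path, "matrix"), (cfg.labels_path, "labels")):
            if path is not None and not Path(path).exists():
                diags.append(f"{what} file does not exist: {path}")
        try:
            cfg.mcfs.validate()
        except ValueError as exc:
            diags.append(f"mcfs: {exc}")
    for sub, name in ((cfg.classifier, "classifier"), (cfg.cv, "cv"), (cfg.ripper, "ripper")):
        try:
            sub.validate()
        except ValueError as exc:
            diags.append(f"{name}: {exc}")
    if cfg.n_permutations < 3:
        diags.append("n_permutations must be >= 3")
    if not (0 < cfg.alpha < 1):
        diags.append("alpha must be in (0, 1)")
    if cfg.coarse_step < 1 or cfg.interval_halfwidth_steps < 0:
        diags.append("coarse_step must be >= 1 and interval_halfwidth_steps >= 0")
    if cfg.n_random_subsets < 1:
        diags.append("n_random_subsets must be >= 1")
    return diags


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _curve_tsv(path: Path, curve: IFSCurve, classes: list[str]) -> None:
    with open(path, "w") as fh:
        acc_cols = "\t".join(f"ACC_{c}" for c in classes)
        fh.write(f"n_features\t{acc_cols}\tACC\tMCC\n")
        for k, rep in curve.points:
            accs = "\t".join(f"{a:.6f}" for a in rep.per_class_accuracy)
            fh.write(f"{k}\t{accs}\t{rep.overall_accuracy:.6f}\t{rep.mcc:.6f}\n")


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute all stages in order; a stage failure aborts with its name.

    Stage order: data (generate or load) -> MCFS ranking -> permutation
    threshold / informative set -> rule branch (Johnson reducer + RIPPER,
    self-consistency and CV reports) -> IFS/SVM branch (two-stage scan) ->
    random-subset significance.  Rule and IFS branches can be switched off;
    the manifest records every parameter, seed, and skipped stage.
    """
    diags = validate_config(cfg)
    hard = [d for d in diags if "will be reduced" not in d]
    if hard:
        raise ValueError("invalid pipeline config: " + "; ".join(hard))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = cfg.stage_seeds()
    manifest: dict = {
        "package": "pdxorigin",
        "master_seed": cfg.master_seed,
        "stage_seeds": seeds,
        "config": _config_dict(cfg),
        "stages": {},
        "files": {},
    }
    log_lines: list[str] = []
    bundle = ReportBundle(out_dir=out, manifest=manifest, dataset=None)  # type: ignore[arg-type]

    def _stage(name: str):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                manifest["stages"][name] = "failed"
                _write_json(out / "manifest.json", manifest)
                raise PipelineStageError(name, exc) from exc
            manifest["stages"][name] = "ok"
            log_lines.append(f"{name}: {time.perf_counter() - t0:.2f}s")

        return deco

    @_stage("data")
    def _data():
        if cfg.synthetic is not None:
            syn = dataclasses.replace(cfg.synthetic, seed=seeds["data"])
            ds, truth = generate_dataset(syn)
            bundle.ground_truth = truth
            pio.write_labeled_dataset(ds, out / "matrix.tsv", out / "labels.tsv")
            manifest["files"]["matrix"] = "matrix.tsv"
            manifest["files"]["labels"] = "labels.tsv"
        else:
            ds = pio.read_labeled_dataset(cfg.matrix_path, cfg.labels_path)
        bundle.dataset = ds
        manifest["data"] = {
            "n_genes": ds.n_genes,
            "n_samples": ds.n_samples,
            "classes": ds.classes,
            "class_counts": ds.class_counts(),
        }

    ds = bundle.dataset
    mcfs_params = dataclasses.replace(cfg.mcfs, seed=seeds["mcfs"])

    @_stage("mcfs")
    def _mcfs():
        ens = grow_projection_trees(ds, mcfs_params)
        bundle.ri = compute_relative_importance(ens)
        bundle.ranking = rank_features(bundle.ri)
        with open(out / "ranking.tsv", "w") as fh:
            fh.write("rank\tgene\tRI\n")
            for rank, gi in enumerate(bundle.ranking, start=1):
                fh.write(f"{rank}\t{ds.genes[gi]}\t{bundle.ri[gi]:.10g}\n")
        manifest["files"]["ranking"] = "ranking.tsv"
        manifest["mcfs"] = {"m": mcfs_params.resolve_m(ds.n_genes), "n_trees": len(ens)}

    @_stage("threshold")
    def _threshold():
        thr_params = dataclasses.replace(cfg.mcfs, seed=seeds["threshold"])
        bundle.threshold, bundle.informative = permutation_threshold(
            ds, thr_params, cfg.n_permutations, cfg.alpha, observed_ri=bundle.ri
        )
        with open(out / "informative_genes.tsv", "w") as fh:
            fh.write("gene\tRI\n")
            order = sorted(
                bundle.informative, key=lambda g: (-bundle.ri[g], g)
            )
            for gi in order:
                fh.write(f"{ds.genes[gi]}\t{bundle.ri[gi]:.10g}\n")
        manifest["files"]["informative"] = "informative_genes.tsv"
        manifest["threshold"] = {
            "value": bundle.threshold.threshold,
            "alpha": cfg.alpha,
            "n_permutations": cfg.n_permutations,
            "n_informative": int(bundle.informative.size),
        }

    if cfg.run_rules:

        @_stage("rules")
        def _rules():
            inf_genes = [ds.genes[g] for g in bundle.informative]
            ri_map = {ds.genes[g]: float(bundle.ri[g]) for g in bundle.informative}
            ripper = dataclasses.replace(cfg.ripper, seed=seeds["rules"])
            if inf_genes:
                reduct = johnson_reducer(ds, inf_genes, ri=ri_map, seed=seeds["rules"])
                bundle.ruleset = ripper_induce(ds, reduct or inf_genes, ripper)
            else:
                counts = ds.class_counts()
                default = max(ds.classes, key=lambda c: counts[c])
                bundle.ruleset = RuleSet([Rule((), default)])
                log_lines.append("rules: no informative genes, default-only rule set")
            (out / "rules.txt").write_text(serialize_rules(bundle.ruleset))
            manifest["files"]["rules"] = "rules.txt"
            bundle.rule_self_report = evaluate_ruleset(
                bundle.ruleset, ds, mode="self_consistency"
            )
            _write_json(out / "rule_self_report.json", bundle.rule_self_report.to_dict())
            manifest["files"]["rule_self_report"] = "rule_self_report.json"
            if inf_genes:
                cv_rules = CVConfig(
                    folds=cfg.cv.folds, repeats=cfg.rule_cv_repeats, seed=seeds["rules"]
                )
                bundle.rule_cv_report = evaluate_ruleset(
                    None,
                    ds,
                    mode="cv",
                    cv=cv_rules,
                    genes=inf_genes,
                    ripper=ripper,
                    ri=ri_map,
                )
                _write_json(
                    out / "rule_cv_report.json", bundle.rule_cv_report.to_dict()
                )
                manifest["files"]["rule_cv_report"] = "rule_cv_report.json"
            manifest["rules"] = {
                "n_rules": len(bundle.ruleset),
                "cv_evaluated": bool(inf_genes),
            }

    else:
        manifest["stages"]["rules"] = "skipped"

    if cfg.run_ifs:

        @_stage("ifs")
        def _ifs():
            cv_ifs = dataclasses.replace(cfg.cv, seed=seeds["ifs"])
            bundle.optimal, bundle.stage1, bundle.stage2 = two_stage_ifs(
                ds,
                bundle.ranking,
                cfg.classifier,
                cv_ifs,
                cfg.coarse_step,
                cfg.interval_halfwidth_steps,
            )
            _curve_tsv(out / "ifs_stage1.tsv", bundle.stage1, ds.classes)
            _curve_tsv(out / "ifs_stage2.tsv", bundle.stage2, ds.classes)
            (out / "optimal_genes.txt").write_text(
                "".join(f"{ds.genes[g]}\n" for g in bundle.optimal.feature_indices)
            )
            _write_json(out / "optimal_report.json", bundle.optimal.report.to_dict())
            manifest["files"].update(
                {
                    "ifs_stage1": "ifs_stage1.tsv",
                    "ifs_stage2": "ifs_stage2.tsv",
                    "optimal_genes": "optimal_genes.txt",
                    "optimal_report": "optimal_report.json",
                }
            )
            manifest["ifs"] = {
                "optimal_size": bundle.optimal.size,
                "optimal_mcc": bundle.optimal.report.mcc,
            }

        @_stage("significance")
        def _significance():
            cv_ifs = dataclasses.replace(cfg.cv, seed=seeds["ifs"])
            p, mccs, thr95 = random_subset_significance(
                ds,
                bundle.optimal.size,
                bundle.optimal.report.mcc,
                cfg.classifier,
                cv_ifs,
                n_subsets=cfg.n_random_subsets,
                seed=seeds["significance"],
            )
            bundle.random_p, bundle.random_mccs, bundle.random_threshold = p, mccs, thr95
            with open(out / "random_mcc.tsv", "w") as fh:
                fh.write("subset\tMCC\n")
                for i, v in enumerate(mccs, start=1):
                    fh.write(f"{i}\t{v:.6f}\n")
            _write_json(
                out / "random_significance.json",
                {
                    "observed_mcc": bundle.optimal.report.mcc,
                    "empirical_p": p,
                    "p05_threshold": thr95,
                    "n_subsets": cfg.n_random_subsets,
                },
            )
            manifest["files"]["random_mcc"] = "random_mcc.tsv"
            manifest["files"]["random_significance"] = "random_significance.json"

    else:
        manifest["stages"]["ifs"] = "skipped"
        manifest["stages"]["significance"] = "skipped"

    _write_json(out / "manifest.json", manifest)
    (out / "run.log").write_text(
        "\n".join([f"finished {time.strftime('%Y-%m-%dT%H:%M:%S')}"] + log_lines) + "\n"
    )
    return bundle


def _config_dict(cfg: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    d = {}
    for f in dataclasses.fields(cfg):
        d[f.name] = enc(getattr(cfg, f.name))
    return d
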