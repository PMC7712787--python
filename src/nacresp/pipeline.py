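"""End-to-end orchestration: simulate -> quantify -> ROC -> CNN -> report.

A single YAML config drives a fully seeded run. The report contains one ROC
row per conventional parameter per subgroup, one CNN metrics block per
modality/timepoint before and after rotation augmentation, the rank-test
p-values comparing per-fold metrics pre vs post augmentation, and enough
provenance (config hash, seeds, package versions) to regenerate every number
from the config alone. Timestamps live only under ``provenance`` so reports
from identical configs are otherwise byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cnn import ArchitectureConfig, EvalMetrics, evaluate, split_train_test, train_crossval
from .crops import MODALITY_TIMEPOINTS, build_dataset
from .phantom import CohortConfig, PatientStudy, generate_cohort, write_cohort
from .quant import QuantConfig, cohort_parameters
from .stats import rank_compare, roc_analysis, subgroup_filter

log = logging.getLogger("nacresp")

PARAMETERS = ("suv0", "suv1", "mtv0", "mtv1", "tlg0", "tlg1",
              "adc0", "adc1", "dsuv", "dmtv", "dtlg", "dadc")
SUBGROUPS = ("all", "HER2_negative", "triple_negative")


class PipelineStageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class CNNStageConfig:
    arch: ArchitectureConfig = field(default_factory=ArchitectureConfig)
    modalities: tuple[str, ...] = MODALITY_TIMEPOINTS
    folds: int = 3
    train_fraction: float = 0.8
    split_seed: int | None = None  # derived from the phantom seed when None
    fold_seed: int | None = None


@dataclass
class PipelineConfig:
    phantom: CohortConfig = field(default_factory=CohortConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)
    cnn: CNNStageConfig = field(default_factory=CNNStageConfig)
    subgroups: tuple[str, ...] = SUBGROUPS
    output_dir: str = "nacresp_out"
    log_level: str = "INFO"
    save_volumes: bool = False
    save_crops: bool = False

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        kwargs = {}
        if "phantom" in raw:
            kwargs["phantom"] = CohortConfig(**raw.pop("phantom"))
        if "quant" in raw:
            kwargs["quant"] = QuantConfig(**raw.pop("quant"))
        if "cnn" in raw:
            cnn_raw = dict(raw.pop("cnn"))
            arch = ArchitectureConfig(**cnn_raw.pop("arch", {}))
            kwargs["cnn"] = CNNStageConfig(arch=arch, **{
                k: tuple(v) if k == "modalities" else v for k, v in cnn_raw.items()})
        for key in ("subgroups",):
            if key in raw:
                raw[key] = tuple(raw[key])
        kwargs.update(raw)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def canonical(self) -> dict:
        """JSON-serializable, order-stable view used for hashing and provenance."""
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in sorted(dataclasses.asdict(obj).items())}
            if isinstance(obj, dict):
                return {str(k): conv(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (tuple, list)):
                return [conv(v) for v in obj]
            return obj
        return conv(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _roc_stage(params: pd.DataFrame, config: PipelineConfig) -> list[dict]:
    rows = []
    for subgroup in config.subgroups:
        sub = subgroup_filter(params, subgroup)
        for parameter in PARAMETERS:
            row = {"parameter": parameter, "subgroup": subgroup}
            scores = sub[parameter]
            mask = scores.notna()
            row["n"] = int(mask.sum())
            try:
                res = roc_analysis(scores[mask].to_numpy(), sub.loc[mask, "responder"].to_numpy())
                row.update(auc=res.auc, ci_low=res.ci_low, ci_high=res.ci_high,
                           p_value=res.p_value, cutoff=res.cutoff,
                           sensitivity=res.sensitivity, specificity=res.specificity,
                           direction=res.direction, n_pos=res.n_pos, n_neg=res.n_neg,
                           note="")
            except ValueError as err:
                if subgroup == "all":
                    raise PipelineStageError("roc", str(err)) from err
                row.update(auc=np.nan, ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
                           cutoff=np.nan, sensitivity=np.nan, specificity=np.nan,
                           direction="", n_pos=int(sub["responder"].sum()),
                           n_neg=int((~sub["responder"].astype(bool)).sum()),
                           note=str(err))
            rows.append(row)
    return rows


def _cnn_stage(cohort: list[PatientStudy], config: PipelineConfig) -> dict:
    cnn_cfg = config.cnn
    base_seed = config.phantom.seed
    split_seed = cnn_cfg.split_seed if cnn_cfg.split_seed is not None else base_seed + 101
    fold_seed = cnn_cfg.fold_seed if cnn_cfg.fold_seed is not None else base_seed + 202
    out: dict = {}
    for modality in cnn_cfg.modalities:
        block: dict = {}
        for augment in (False, True):
            tag = "post" if augment else "pre"
            t0 = time.perf_counter()
            crops = build_dataset(cohort, modality, augment=augment, config=config.quant)
            train, test = split_train_test(crops, cnn_cfg.train_fraction, seed=split_seed)
            models, val_metrics = train_crossval(
                train, cnn_cfg.arch, k=cnn_cfg.folds, seed=fold_seed)
            test_metrics = evaluate(models, test)
            block[tag] = {
                "n_crops": len(crops),
                "n_train": len(train),
                "validation": val_metrics.as_dict(),
                "validation_auc_median": float(np.median(
                    [fv["auc"] for fv in val_metrics.fold_values])),
                "test": test_metrics.as_dict(),
            }
            log.info("cnn %s %s-augmentation: test AUC %.3f (%.1f s)",
                     modality, tag, test_metrics.auc, time.perf_counter() - t0)
        compare = {}
        for metric in ("sensitivity", "specificity", "accuracy", "auc"):
            pre_vals = [fv[metric] for fv in block["pre"]["validation"]["fold_values"]]
            post_vals = [fv[metric] for fv in block["post"]["validation"]["fold_values"]]
            if np.isfinite(pre_vals).all() and np.isfinite(post_vals).all():
                compare[metric] = rank_compare(pre_vals, post_vals)
            else:
                compare[metric] = float("nan")
        block["augmentation_compare_p"] = compare
        out[modality] = block
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run report."""
    logging.basicConfig(level=config.log_level)
    os.makedirs(config.output_dir, exist_ok=True)
    report: dict = {
        "provenance": {
            "config_hash": config.config_hash(),
            "config": config.canonical(),
            "seed": config.phantom.seed,
            "versions": {"nacresp": __version__, "numpy": np.__version__},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
    }

    t0 = time.perf_counter()
    try:
        cohort = generate_cohort(config.phantom)
    except ValueError as err:
        raise PipelineStageError("simulate", str(err)) from err
    if not cohort:
        raise PipelineStageError("simulate", "empty cohort")
    n_resp = sum(s.true_response for s in cohort)
    report["cohort"] = {
        "n_patients": len(cohort),
        "n_responders": n_resp,
        "responder_percent": round(100.0 * n_resp / len(cohort)),
    }
    if config.save_volumes:
        write_cohort(cohort, os.path.join(config.output_dir, "volumes"))
    log.info("simulate: %d patients (%.1f s)", len(cohort), time.perf_counter() - t0)

    t0 = time.perf_counter()
    try:
        params = cohort_parameters(cohort, config.quant)
    except ValueError as err:
        raise PipelineStageError("quantify", str(err)) from err
    meta = pd.DataFrame({
        "patient_id": [s.patient_id for s in cohort],
        "grade": [s.grade for s in cohort],
        "responder": [s.grade >= 4 for s in cohort],
        "ER": [s.er_positive for s in cohort],
        "PR": [s.pr_positive for s in cohort],
        "HER2": [s.her2_positive for s in cohort],
    })
    params = params.merge(meta, on="patient_id")
    params.to_csv(os.path.join(config.output_dir, "parameters.csv"), index=False)
    log.info("quantify: %d records (%.1f s)", len(params), time.perf_counter() - t0)

    t0 = time.perf_counter()
    roc_rows = _roc_stage(params, config)
    pd.DataFrame(roc_rows).to_csv(os.path.join(config.output_dir, "roc_results.csv"), index=False)
    report["roc"] = roc_rows
    log.info("roc: %d rows (%.1f s)", len(roc_rows), time.perf_counter() - t0)

    try:
        report["cnn"] = _cnn_stage(cohort, config)
    except ValueError as err:
        raise PipelineStageError("cnn", str(err)) from err

    report_path = os.path.join(config.output_dir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    log.info("report written to %s", report_path)
    return report
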