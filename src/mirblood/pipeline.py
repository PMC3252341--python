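"""End-to-end orchestration: simulate -> normalize -> screen -> classify -> validate.

``run_pipeline`` executes the discovery and validation sequence on a
synthetic cohort and writes a deterministic artifact set (normalized matrix,
differential-expression table, CV sweep with per-sample log-odds and
permutation null, qPCR results) plus the resolved configuration, a MANIFEST,
and a log with seeds.  Every artifact is reproducible from the config+seed
written next to it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import io as mio
from .diffexp import rank_by_fold_change, run_diffexp, shapiro_median
from .preprocess import fit_vsn, summarize_replicates, transform_vsn
from .qpcr import qpcr_compare
from .signature import CVConfig, cv_evaluate, permutation_null, subset_sweep_summary
from .synthetic import SyntheticSpec, generate_cohort, generate_qpcr_cohort

logger = logging.getLogger("mirblood")


@dataclass
class QPCRSettings:
    n_pairs: int = 24
    targets: dict = field(default_factory=lambda: {"miR-202": 1.0, "miR-718": -1.2})
    ct_noise_sd: float = 0.25
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    """All stage parameters plus the global seed and output directory."""

    cohort: SyntheticSpec = field(default_factory=SyntheticSpec)
    trim_fraction: float = 0.9
    vsn_max_iter: int = 20
    alpha: float = 0.05
    cv: CVConfig = field(default_factory=CVConfig)
    n_permutations: int = 20
    run_classification: bool = True
    run_qpcr: bool = True
    qpcr: QPCRSettings = field(default_factory=QPCRSettings)
    seed: int = 0
    outdir: str = "results/pipeline"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        parsed = {}
        for fld, sub_cls in (("cohort", SyntheticSpec), ("cv", CVConfig), ("qpcr", QPCRSettings)):
            if fld in data:
                sub = dict(data.pop(fld))
                _reject_unknown(sub, sub_cls, fld)
                # YAML has no tuples; restore them for tuple-typed defaults
                for f in dataclasses.fields(sub_cls):
                    if isinstance(f.default, tuple) and isinstance(sub.get(f.name), list):
                        sub[f.name] = tuple(sub[f.name])
                parsed[fld] = sub_cls(**sub)
        _reject_unknown(data, cls, "pipeline")
        return cls(**parsed, **data)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _reject_unknown(data: dict, cls, where: str) -> None:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {where} config keys: {sorted(unknown)}")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run every enabled stage; returns the artifact path map.

    A stage failure aborts with a stage-named error; artifacts written up to
    that point stay on disk and the MANIFEST marks the run incomplete.
    """
    os.makedirs(config.outdir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(config.outdir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    artifacts: dict[str, str] = {}
    manifest = {"complete": False, "stages": []}

    def _save_manifest():
        with open(os.path.join(config.outdir, "MANIFEST.json"), "w") as fh:
            json.dump({**manifest, "artifacts": artifacts}, fh, indent=2)

    cfg_path = os.path.join(config.outdir, "config.yaml")
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    artifacts["config"] = cfg_path
    logger.info("resolved config written to %s (seed=%d)", cfg_path, config.seed)

    try:
        stage = "simulate"
        spec = dataclasses.replace(config.cohort, seed=config.seed)
        raw = generate_cohort(spec)
        artifacts.update(mio.write_raw_cohort(raw, os.path.join(config.outdir, "cohort")))
        manifest["stages"].append(stage)
        logger.info("simulated cohort: %d samples x %d features x %d replicates",
                    *raw.intensities.shape)

        stage = "normalize"
        summ = summarize_replicates(raw)
        params = fit_vsn(summ, trim_fraction=config.trim_fraction, max_iter=config.vsn_max_iter)
        expr = transform_vsn(summ, params, labels=raw.labels)
        p = os.path.join(config.outdir, "expression_normalized.tsv")
        mio.write_expression_tsv(expr.values, p)
        artifacts["expression"] = p
        p = os.path.join(config.outdir, "calibration.tsv")
        mio.write_calibration_tsv(params, p)
        artifacts["calibration"] = p
        manifest["stages"].append(stage)
        logger.info("VSN calibration: lam=%.3f converged=%s", params.lam, params.converged)

        stage = "diffexp"
        sw_median, _ = shapiro_median(expr)
        table = rank_by_fold_change(run_diffexp(expr, alpha=config.alpha))
        p = os.path.join(config.outdir, "diffexp.tsv")
        mio.write_diffexp_tsv(table, p)
        artifacts["diffexp"] = p
        manifest["stages"].append(stage)
        n_sig = int(table["significant"].sum())
        n_up = int((table["significant"] & (table["direction"] == "up")).sum())
        logger.info("diffexp: %d significant (%d up / %d down) at alpha=%.2f; "
                    "Shapiro-Wilk median p=%.3g",
                    n_sig, n_up, n_sig - n_up, config.alpha, sw_median)

        summary = {
            "seed": config.seed,
            "n_significant": n_sig,
            "n_up": n_up,
            "n_down": n_sig - n_up,
            "shapiro_median_p": sw_median,
            "vsn_lam": params.lam,
        }

        if config.run_classification:
            stage = "classify"
            cv_cfg = dataclasses.replace(config.cv, seed=config.seed)
            res = cv_evaluate(expr, config=cv_cfg)
            sweep = subset_sweep_summary(res)
            p = os.path.join(config.outdir, "cv_sweep.tsv")
            sweep.to_csv(p, sep="\t", index=False, float_format="%.6g")
            artifacts["cv_sweep"] = p
            p = os.path.join(config.outdir, "log_odds.tsv")
            res.log_odds.to_frame().join(raw.labels).to_csv(p, sep="\t", float_format="%.6g")
            artifacts["log_odds"] = p
            null = permutation_null(expr, config=cv_cfg, n_permutations=config.n_permutations)
            p = os.path.join(config.outdir, "permutation_null.tsv")
            np.savetxt(p, null.null_accuracies, header="null_accuracy", comments="")
            artifacts["permutation_null"] = p
            summary["cv_best"] = res.best
            summary["permutation_percentile"] = null.percentile
            manifest["stages"].append(stage)
            logger.info("classification best: %s (real acc %.3f at permutation "
                        "percentile %.1f)", res.best, null.real_accuracy, null.percentile)

        if config.run_qpcr:
            stage = "qpcr"
            qtable = generate_qpcr_cohort(
                n_pairs=config.qpcr.n_pairs,
                true_log2_fold=config.qpcr.targets,
                ct_noise_sd=config.qpcr.ct_noise_sd,
                seed=config.seed + 1,
            )
            p = os.path.join(config.outdir, "qpcr_ct.tsv")
            mio.write_qpcr_table(qtable, p)
            artifacts["qpcr_ct"] = p
            qrows = []
            for target in qtable.targets():
                r = qpcr_compare(qtable, target, alpha=config.qpcr.alpha)
                qrows.append(
                    {
                        "mirna_id": target,
                        "fold_magnitude": r.fold.magnitude,
                        "direction": r.fold.direction,
                        "ddct": r.fold.ddct,
                        "geometric_mean_fold": r.fold.geometric_mean_fold,
                        "arithmetic_mean_fold": r.fold.arithmetic_mean_fold,
                        "p_value": r.p_value,
                        "auc": r.auc,
                        "significant": r.significant,
                    }
                )
                dpath = os.path.join(config.outdir, f"qpcr_delta_ct_{target}.tsv")
                r.delta_ct_table.to_csv(dpath, sep="\t", float_format="%.6g")
                artifacts[f"qpcr_delta_ct_{target}"] = dpath
            import pandas as pd

            p = os.path.join(config.outdir, "qpcr_results.tsv")
            pd.DataFrame(qrows).to_csv(p, sep="\t", index=False, float_format="%.6g")
            artifacts["qpcr_results"] = p
            manifest["stages"].append(stage)
            logger.info("qPCR validation: %s", [f"{q['mirna_id']}: {q['fold_magnitude']:.2f}"
                                                f" ({q['direction']}), p={q['p_value']:.3g}"
                                                for q in qrows])

        p = os.path.join(config.outdir, "summary.json")
        with open(p, "w") as fh:
            json.dump(summary, fh, indent=2, default=_json_default)
        artifacts["summary"] = p
        manifest["complete"] = True
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        _save_manifest()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    _save_manifest()
    return artifacts
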