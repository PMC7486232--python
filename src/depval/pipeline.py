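"""End-to-end pipeline: simulate, filter, develop, validate, sensitivity.

One :class:`RunConfig` fully determines a run; rerunning with the same
config reproduces every numeric output. Artifacts are written under an
output directory:

    cohorts/dev.csv, cohorts/val.csv (+ eligibility audits)
    model.json                       (development risk model)
    table1.csv                       (stage comparison, 2-decimal rendering)
    reports/<stage>.json             (full-precision metric panels)
    curves/calibration_<stage>.csv, curves/roc_<stage>.csv
    figures/*.svg                    (optional)
    nri.json, interaction.csv, run_log.json
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import outcome as oc
from . import synthesis as syn
from .errors import DepvalError
from .metrics import flexible_calibration_curve, roc_curve_points
from .pmle import RiskModel, choose_penalty, fit_pmle, linear_predictor, predict_prob
from .reclassification import compare_models_auc, interaction_test, nri
from .validation import (
    DEFAULT_LAM_GRID,
    run_validation_suite,
    stage_table,
)


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one full pipeline run."""

    dev: syn.GeneratorConfig = field(default_factory=lambda: syn.development_config())
    val: syn.GeneratorConfig = field(default_factory=lambda: syn.validation_config())
    stages: tuple[str, ...] = ("standard", "adjusted", "refitted")
    lam_grid: tuple[float, ...] = DEFAULT_LAM_GRID
    refit_lam_strategy: str = "grid"
    bootstrap_B: int = 2000
    nri_threshold: float | None = None  # None -> observed prevalence
    smoother_span: float = 0.75
    precision: int = 2
    seed: int = 0
    figures: bool = True

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dev"]["wave_age_range"] = list(self.dev.wave_age_range)
        d["val"]["wave_age_range"] = list(self.val.wave_age_range)
        d["stages"] = list(self.stages)
        d["lam_grid"] = list(self.lam_grid)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("dev", "val"):
            sub = d.get(key, {})
            if "wave_age_range" in sub:
                sub["wave_age_range"] = tuple(sub["wave_age_range"])
            d[key] = syn.GeneratorConfig(**sub)
        for key in ("stages", "lam_grid"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def _figures(out: Path, stages, y: np.ndarray, span: float) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    made = []
    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    for st in stages:
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        roc = roc_curve_points(st.predictions.p, y)
        ax1.plot(roc["fpr"], roc["tpr"], color="black")
        ax1.plot([0, 1], [0, 1], color="grey", ls="--", lw=0.8)
        ax1.set_xlabel("False positive rate")
        ax1.set_ylabel("True positive rate")
        ax1.set_title(f"ROC — {st.label} (AUC {st.report.auc:.2f})")
        try:
            curve = flexible_calibration_curve(st.predictions.p, y, span=span)
            ax2.plot(curve.grid, curve.estimate, color="black")
            ax2.plot(curve.grid, curve.low, color="black", ls="--", lw=0.8)
            ax2.plot(curve.grid, curve.high, color="black", ls="--", lw=0.8)
        except DepvalError:
            pass
        lim = 1.0
        ax2.plot([0, lim], [0, lim], color="grey", lw=0.8)
        ax2.set_xlabel("Predicted probability")
        ax2.set_ylabel("Observed proportion")
        ax2.set_title(f"Calibration — {st.label}")
        fig.tight_layout()
        name = f"{st.label}.svg"
        fig.savefig(figdir / name)
        plt.close(fig)
        made.append(name)
    return made


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full analysis; returns the artifact directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress")
    try:
        artifacts = _run(config, out)
    except DepvalError as exc:
        marker.write_text(f"failed: {exc}")
        raise
    marker.unlink()
    return artifacts


def _run(config: RunConfig, out: Path) -> Path:
    for sub in ("cohorts", "reports", "curves"):
        (out / sub).mkdir(exist_ok=True)
    config.to_yaml(out / "config.yaml")

    # 1. cohorts + eligibility filter
    dev_raw, val_raw = syn.generate_miscalibrated_pair(config.dev, config.val)
    dev, dev_audit = oc.select_analysis_sample(dev_raw)
    val, val_audit = oc.select_analysis_sample(val_raw)
    dev = oc.attach_outcome(dev)
    val = oc.attach_outcome(val)
    syn.write_cohort(dev_raw, out / "cohorts" / "dev.csv")
    syn.write_cohort(val_raw, out / "cohorts" / "val.csv")
    dev_audit.to_csv(out / "cohorts" / "dev_audit.csv", index=False)
    val_audit.to_csv(out / "cohorts" / "val_audit.csv", index=False)

    # 2. development model (penalized fit, penalty chosen on the grid)
    schema = config.dev.predictor_names
    X_dev = dev[schema]
    lam = choose_penalty(X_dev, dev["y"], list(config.lam_grid))
    model = fit_pmle(X_dev, dev["y"], lam, provenance="development fit")
    model.to_json(out / "model.json")

    # 3. validation ladder on the target analysis sample
    stages = run_validation_suite(
        model,
        val,
        stages=config.stages,
        lam_strategy=config.refit_lam_strategy,
        B=config.bootstrap_B,
        seed=config.seed,
    )
    table = stage_table(stages, decimals=config.precision)
    table.to_csv(out / "table1.csv")
    y_val = val["y"].to_numpy(dtype=float)
    for st in stages:
        _write_json(out / "reports" / f"{st.label}.json", st.report.to_dict())
        roc_curve_points(st.predictions.p, y_val).to_csv(
            out / "curves" / f"roc_{st.label}.csv", index=False
        )
        try:
            flexible_calibration_curve(
                st.predictions.p, y_val, span=config.smoother_span
            ).to_frame().to_csv(out / "curves" / f"calibration_{st.label}.csv", index=False)
        except DepvalError:
            pass

    # 4. sensitivity analyses: soldier status added to the transferred score
    std = stages[0]
    lp = linear_predictor(std.model, val)
    soldier = val["soldier"].to_numpy(dtype=float)
    ext = fit_pmle(
        pd.DataFrame({"lp": lp, "soldier": soldier}),
        y_val,
        0.0,
        provenance="soldier-extended",
    )
    p_new = predict_prob(ext, pd.DataFrame({"lp": lp, "soldier": soldier})).p
    nri_res = nri(
        std.predictions.p,
        p_new,
        y_val,
        threshold=config.nri_threshold,
        bootstrap_B=config.bootstrap_B,
        seed=config.seed,
    )
    d = nri_res.to_dict()
    d["delta_auc"] = compare_models_auc(std.predictions.p, p_new, y_val)
    _write_json(out / "nri.json", d)
    coef_table, p_int = interaction_test(lp, soldier, y_val)
    coef_table.to_csv(out / "interaction.csv")
    _write_json(out / "interaction.json", {"p_interaction": p_int})

    figures = _figures(out, stages, y_val, config.smoother_span) if config.figures else []

    try:
        pkg_version = _pkg_version("depval")
    except PackageNotFoundError:
        pkg_version = "unknown"
    _write_json(
        out / "run_log.json",
        {
            "version": pkg_version,
            "config_hash": _config_hash(config),
            "seeds": {"dev": config.dev.seed, "val": config.val.seed, "metrics": config.seed},
            "n_dev_analysis": int(len(dev)),
            "n_val_analysis": int(len(val)),
            "lambda_dev": lam,
            "stages": [st.label for st in stages],
            "figures": figures,
        },
    )
    return out
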