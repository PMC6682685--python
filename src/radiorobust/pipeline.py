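"""End-to-end orchestration: cohort -> preprocess -> features -> perturb ->
robustness filter -> models (pre- and post-filter) -> kTSP.

A :class:`RunConfig` plus the code version fully determine a run's outputs;
the single master seed is propagated to every stochastic stage.  Each run
writes its config, per-stage CSV/JSON artifacts and a SHA-256 manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .ktsp import ktsp_experiment
from .models import (
    LR_GRID_SMALL,
    RF_GRID_SMALL,
    patient_splits,
    run_factorial,
)
from .perturb import DEFAULT_GRID, perturbation_suite
from .preprocess import bias_correct, normalize_iqr, patches_from_volume, resample_isotropic
from .robustness import (
    family_summary,
    feature_columns,
    icc_table,
    robust_filter,
    threshold_sweep,
)
from .synthetic import make_cohort
from .tda import extract_tda
from .texture import extract_texture
from .types import CohortConfig

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    out_dir: str = "results"
    seed: int = 0
    data_dir: Optional[str] = None  # read NIfTI cohort instead of synth
    n_pos: int = 4
    n_neg: int = 8
    effect: str = "none"
    effect_magnitude: float = 1.0
    grid_shape: tuple = (96, 96, 64)
    tumor_radius: float = 14.0
    bias_field: bool = False
    perturb_grid: Dict[str, list] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_GRID.items()}
    )
    icc_cutoff: float = 0.75
    n_splits: int = 10
    test_frac: float = 0.2
    rfe_folds: int = 10
    cv_folds: int = 5
    small_grids: bool = True
    ktsp_n_rep: int = 100
    ktsp_split: float = 0.7
    ktsp_k_min: int = 3
    ktsp_k_max: int = 15

    def to_yaml(self, path: Path) -> None:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


def _stage(name: str, t0: float) -> float:
    t1 = time.time()
    log.info("stage %-12s %6.1fs", name, t1 - t0)
    return t1


def run_all(cfg: RunConfig) -> Dict:
    """Execute the full pipeline; returns the result bundle and writes all
    artifacts under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    t0 = time.time()

    if cfg.data_dir:
        cohort, label_table = rio.load_cohort(cfg.data_dir)
    else:
        cc = CohortConfig(
            n_pos=cfg.n_pos,
            n_neg=cfg.n_neg,
            shape=tuple(cfg.grid_shape),
            tumor_radius=cfg.tumor_radius,
            bias_field=cfg.bias_field,
            effect=cfg.effect,
            effect_magnitude=cfg.effect_magnitude,
            seed=cfg.seed,
        )
        cohort, label_table = make_cohort(cc)
    t0 = _stage("cohort", t0)

    patches = []
    for vs in cohort:
        vs = resample_isotropic(vs)
        if cfg.bias_field:
            vs = bias_correct(vs)
        vs = normalize_iqr(vs)
        patches.extend(patches_from_volume(vs))
    t0 = _stage("preprocess", t0)

    tex = rio.feature_table(patches, extract_texture)
    tda = rio.feature_table(patches, extract_tda)
    t0 = _stage("features", t0)

    pert_rows_tex: List[pd.DataFrame] = []
    pert_rows_tda: List[pd.DataFrame] = []
    for sp in patches:
        suite = perturbation_suite(sp, grid=cfg.perturb_grid, seed=cfg.seed)
        for spec, psp in suite:
            pert_rows_tex.append(
                rio.feature_table([psp], extract_texture, spec.perturbation_id)
            )
            pert_rows_tda.append(
                rio.feature_table([psp], extract_tda, spec.perturbation_id)
            )
    tex_pert = pd.concat(pert_rows_tex, ignore_index=True)
    tda_pert = pd.concat(pert_rows_tda, ignore_index=True)
    t0 = _stage("perturb", t0)

    bundle: Dict = {"patches": len(patches)}
    icc_all = {}
    survivors = {}
    for name, orig, pert in (
        ("texture", tex, tex_pert),
        ("tda", tda, tda_pert),
    ):
        t = icc_table(orig, pert)
        icc_all[name] = t
        survivors[name] = robust_filter(t, cfg.icc_cutoff)
        t.to_csv(out / f"icc_{name}.csv")
        family_summary(t).to_csv(out / f"icc_{name}_by_family.csv")
        threshold_sweep(t).to_csv(out / f"icc_{name}_sweep.csv")
        (out / f"survivors_{name}.txt").write_text(
            "\n".join(survivors[name]) + "\n"
        )
    t0 = _stage("robustness", t0)

    plan = patient_splits(
        label_table.set_index("patient_id")["label"],
        n_rep=cfg.n_splits,
        test_frac=cfg.test_frac,
        seed=cfg.seed,
    )
    grids = (
        {"rf": RF_GRID_SMALL, "lr": LR_GRID_SMALL} if cfg.small_grids else None
    )
    results_pre = run_factorial(
        {"Texture only": tex, "TDA only": tda},
        plan,
        label_table=label_table,
        param_grids=grids,
        seed=cfg.seed,
        rfe_folds=cfg.rfe_folds,
        cv_folds=cfg.cv_folds,
    )
    results_pre.to_csv(out / "results_prefilter.csv", index=False)

    meta = ["patient_id", "slice_index", "label"]
    tex_f = tex[meta + survivors["texture"]] if survivors["texture"] else None
    tda_f = tda[meta + survivors["tda"]] if survivors["tda"] else None
    post_sets = {}
    if tex_f is not None and len(feature_columns(tex_f)) >= 2:
        post_sets["Texture only"] = tex_f
    if tda_f is not None and len(feature_columns(tda_f)) >= 2:
        post_sets["TDA only"] = tda_f
    if post_sets:
        results_post = run_factorial(
            post_sets, plan, param_grids=grids, seed=cfg.seed,
            rfe_folds=cfg.rfe_folds, cv_folds=cfg.cv_folds,
        )
        results_post.to_csv(out / "results_postfilter.csv", index=False)
        bundle["results_postfilter"] = results_post
    t0 = _stage("models", t0)

    ktsp_report = {}
    for name, table in (("texture", tex), ("tda", tda)):
        res = ktsp_experiment(
            table,
            n_rep=cfg.ktsp_n_rep,
            split=cfg.ktsp_split,
            k_min=cfg.ktsp_k_min,
            k_max=cfg.ktsp_k_max,
            seed=cfg.seed,
        )
        ktsp_report[name] = {
            "train_auc_hpd": list(res.get("train_auc_hpd", (None, None))),
            "test_auc_hpd": list(res.get("test_auc_hpd", (None, None))),
            "test_auc_mean": float(res["test_aucs"].mean()),
            "chosen_k_histogram": {
                int(k): int(c)
                for k, c in zip(*np.unique(res["chosen_k"],
                                           return_counts=True))
            },
        }
    (out / "ktsp_report.json").write_text(json.dumps(ktsp_report, indent=2))
    t0 = _stage("ktsp", t0)

    tex.to_csv(out / "features_texture.csv", index=False)
    tda.to_csv(out / "features_tda.csv", index=False)
    tex_pert.to_csv(out / "features_texture_perturbed.csv", index=False)
    tda_pert.to_csv(out / "features_tda_perturbed.csv", index=False)
    label_table.to_csv(out / "labels.csv", index=False)
    rio.write_manifest(sorted(out.glob("*.csv")) + sorted(out.glob("*.json")),
                       out / "manifest.json")

    bundle.update(
        {
            "icc": icc_all,
            "survivors": survivors,
            "results_prefilter": results_pre,
            "ktsp": ktsp_report,
            "out_dir": str(out),
        }
    )
    return bundle
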