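"""End-to-end recovery benchmark on the planted-signal synthetic cohort.

This is the package's integration experiment: simulate a 300-subject,
30-ROI multi-site cohort whose severity score is driven by 15 planted
edges (64% of score variance, prediction ceiling r = 0.8), residualize
site/age/sex from the edges, run nested 5-fold cross-validation of the
sparse hierarchical graph model, and check that (a) pooled held-out
predictions correlate with the truth, (b) the model beats the
predict-the-mean baseline, and (c) out-of-fold gradient saliency
concentrates on the planted edges.

The scaled-down problem size (d = 8 feature maps, 200 epochs, lr0 = 1e-3)
is chosen for a 30-ROI cohort; see docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from .connectome import residualize_covariates
from .interpret import group_saliency, saliency_map
from .model import ModelConfig
from .synth import recovery_config, simulate_cohort
from .trainer import TrainConfig, cross_validate

__all__ = ["run_recovery_experiment", "saliency_precision"]


def saliency_precision(group_map: np.ndarray, support: list[tuple[int, int]],
                       ) -> float:
    """Precision@|support|: fraction of the top-|S| edges by |mean PD|
    that are planted edges."""
    n = group_map.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mags = np.abs(group_map[iu, ju])
    top = np.argsort(-mags, kind="stable")[:len(support)]
    support_set = set(support)
    hits = sum((int(iu[k]), int(ju[k])) in support_set for k in top)
    return hits / len(support)


def run_recovery_experiment(seed: int = 7, epochs: int = 200,
                            n_subjects: int = 300, d: int = 8,
                            lr0: float = 1e-3, restarts: int = 3) -> dict:
    """Simulate -> residualize -> cross-validate -> saliency; return metrics."""
    cfg = recovery_config(seed)
    if n_subjects != cfg.n_subjects:
        from dataclasses import replace
        cfg = replace(cfg, n_subjects=n_subjects)
    ds, truth = simulate_cohort(cfg)
    ds = residualize_covariates(ds, ("site", "age", "sex"))

    model_cfg = ModelConfig(n=cfg.n_rois, d=d, adjacency_mode="identity")
    train_cfg = TrainConfig(lr0=lr0, epochs=epochs, seed=seed,
                            restarts=restarts)
    result = cross_validate(ds, model_cfg, train_cfg, keep_fold_params=True)

    y = ds.targets
    baseline_mae = float(np.mean(np.abs(y - y.mean())))

    # out-of-fold saliency: each subject attributed with the model that
    # never saw it during training
    maps = []
    lookup = {sid: i for i, sid in enumerate(ds.subject_ids)}
    for split, params in zip(result.fold_splits, result.fold_params):
        for sid in split.test_ids:
            maps.append(saliency_map(ds.matrices[lookup[sid]], params, model_cfg))
    group, _ = group_saliency(maps, keep_fraction=0.10)
    precision = saliency_precision(group.values, truth.support)
    n_pairs = cfg.n_rois * (cfg.n_rois - 1) // 2
    chance = cfg.support_size / n_pairs

    return {
        "n_subjects": ds.n_subjects,
        "n_rois": ds.n_nodes,
        "pearson_r": result.pearson_r,
        "p_value": result.p_value,
        "mae": result.mae,
        "baseline_mae": baseline_mae,
        "saliency_precision": precision,
        "chance_precision": chance,
        "precision_ratio": precision / chance,
        "theoretical_ceiling_r": float(np.sqrt(cfg.signal_fraction)),
        "result": result,
        "truth": truth,
        "dataset": ds,
        "model_config": model_cfg,
    }
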