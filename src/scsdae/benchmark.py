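"""End-to-end downsampling benchmark: generate -> thin -> impute -> score.

Reproduces the bulk-downsampling evaluation design at configurable scale:
bulk-like profiles are thinned to each target zero rate, imputed with each
requested variant, and scored by CMD against the true sample-sample
correlation matrix and by mean per-sample Pearson correlation with truth.
"""

from __future__ import annotations

import numpy as np

from .metrics import cmd, correlation_matrix, pairwise_pearson_truth, EvalReport
from .model import NetworkSpec, SCSDAE, TrainConfig
from .preprocess import CountMatrix, normalize
from .simulate import logistic_downsample, make_bulklike_profiles

DEFAULT_CONFIG = {
    "n_samples": 206,
    "n_genes": 2000,
    "trajectory_smoothness": 0.15,
    "zero_rates": [0.5, 0.6, 0.7, 0.8, 0.9],
    "replicates": 10,
    "variants": ["scsdae"],
    "alpha": 0.001,  # bulk-downsampling preset
    "hidden_widths": [64, 16],
    "corruption_rate": 0.2,
    "pretrain_iters": 200,
    "finetune_iters": 400,
    "batch_size": 128,
    "slope": 1.0,
    "seed": 0,
}


def align_filter(observed: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop cells/genes with no observed expression from both matrices, so
    truth and observed stay column- and row-aligned after filtering."""
    rows = observed.sum(axis=1) > 0
    cols = observed[rows].sum(axis=0) > 0
    return observed[np.ix_(rows, cols)], truth[np.ix_(rows, cols)]


def run_benchmark(config: dict | None = None) -> dict:
    """Run the downsampling benchmark and return per-run and summary records.

    Returns ``{"config": ..., "runs": [...], "summary": [...]}`` where the
    summary holds mean and sd of each metric per (variant, zero rate),
    mirroring a methods x zero-rates results table.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    rng = np.random.default_rng(cfg["seed"])
    runs: list[dict] = []
    for rep in range(int(cfg["replicates"])):
        bulk = make_bulklike_profiles(cfg["n_samples"], cfg["n_genes"],
                                      cfg["trajectory_smoothness"], rng)
        for zero_rate in cfg["zero_rates"]:
            sim = logistic_downsample(bulk, zero_rate, cfg["slope"], rng)
            obs, truth = align_filter(sim.observed, sim.truth)
            truth_norm = normalize(CountMatrix(truth)).values
            R_truth = correlation_matrix(truth_norm, axis="samples")
            obs_norm = normalize(CountMatrix(obs)).values
            base = {
                "replicate": rep,
                "zero_rate": zero_rate,
                "realized_zero_rate": float((sim.observed == 0).mean()),
                "cmd_observed": cmd(R_truth, correlation_matrix(obs_norm)),
                "pearson_observed": float(pairwise_pearson_truth(obs_norm, truth_norm).mean()),
            }
            for variant in cfg["variants"]:
                seed = int(rng.integers(2 ** 31))
                widths = (obs.shape[1], *cfg["hidden_widths"])
                model = SCSDAE(
                    CountMatrix(obs),
                    spec=NetworkSpec(widths),
                    config=TrainConfig(
                        variant=variant, alpha=cfg["alpha"],
                        corruption_rate=cfg["corruption_rate"],
                        pretrain_iters=cfg["pretrain_iters"],
                        finetune_iters=cfg["finetune_iters"],
                        batch_size=cfg["batch_size"], seed=seed))
                res = model.fit()
                rec = dict(base)
                rec["variant"] = variant
                rec["cmd_imputed"] = cmd(R_truth, correlation_matrix(res.imputed))
                rec["pearson_imputed"] = float(
                    pairwise_pearson_truth(res.imputed, truth_norm).mean())
                runs.append(rec)
    summary = []
    for variant in cfg["variants"]:
        for zero_rate in cfg["zero_rates"]:
            sel = [r for r in runs if r["variant"] == variant and r["zero_rate"] == zero_rate]
            row = {"variant": variant, "zero_rate": zero_rate, "n": len(sel)}
            for key in ("cmd_observed", "cmd_imputed", "pearson_observed", "pearson_imputed"):
                vals = np.array([r[key] for r in sel])
                row[f"{key}_mean"] = float(vals.mean())
                row[f"{key}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            summary.append(row)
    return {"config": cfg, "runs": runs, "summary": summary}


def evaluate_matrices(truth: np.ndarray, observed: np.ndarray | None = None,
                      imputed: np.ndarray | None = None, groups=None,
                      de_flags=None, spiked_columns=None,
                      labels_pred=None) -> EvalReport:
    """Compute every applicable metric for a (truth, imputed) matrix pair."""
    from . import metrics as m

    report = EvalReport()
    target = imputed if imputed is not None else observed
    if target is None:
        raise ValueError("need an observed or imputed matrix")
    report.cmd = cmd(correlation_matrix(truth), correlation_matrix(target))
    report.mean_pairwise_pearson = float(m.pairwise_pearson_truth(target, truth).mean())
    if de_flags is not None:
        detected = m.gene_gene_significance(target)
        report.fdr, report.tpr = m.fdr_tpr(detected, de_flags)
        if groups is not None:
            report.sensitivity, report.specificity = m.kw_de_eval(target, groups, de_flags)
    if spiked_columns is not None and groups is not None:
        report.mae_total, report.mae_group_a, report.mae_group_b = m.group_mae(
            target, truth, spiked_columns, groups)
    if labels_pred is not None and groups is not None:
        report.ari = m.ari(groups, labels_pred)
    return report
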