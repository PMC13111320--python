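"""End-to-end desk-scale workflow: simulate -> preprocess -> tune -> train ->
predict -> alert -> evaluate.

The default problem sizes are deliberately desk-scale (a few hundred sites, a
reduced-width trunk, a narrowed epoch range and a small tuning budget) so the
whole chain runs on one CPU core in minutes; every component scales up by
passing larger settings. Hyperparameter fitness during tuning is the
validation loss of a short fixed-step proxy training run, so tuning cost is
flat across candidate batch sizes; the decoded epoch count is honoured by the
final fit only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from vitiphen import ado, classifier, evaluation, preprocessing, risk_alerts
from vitiphen.stages import N_INTERVALS, STAGES
from vitiphen.synthetic_data import SimulationParams, SiteSeries, simulate_dataset

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    n_sites: int = 400
    zone_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)
    clean: bool = True  # no contamination/gaps (the calibrated study condition)
    seed: int = 1
    # tuning budget
    tune_pop: int = 10
    tune_iters: int = 20
    proxy_steps: int = 8  # gradient steps per candidate evaluation
    proxy_train: int = 320  # samples in the proxy training subset
    proxy_val: int = 160
    epochs_range: tuple[int, int] = (6, 16)  # narrowed for the scaled run
    # model scale
    width_multiplier: float = 0.25
    expansion: int = 2
    final_feature_width: int = 32
    val_site_fraction: float = 0.2


@dataclass
class PipelineResult:
    theta: dict
    tune_history: list[float]
    train_history: list[dict]
    interval_accuracy_pct: float
    macro_f1: float
    median_onset_error_days: float
    onset_mae_days: float
    rain_alert_metrics: dict
    pest_alert_metrics: dict
    n_train_samples: int
    n_test_sites: int
    extras: dict = field(default_factory=dict)


def _network_spec(cfg: PipelineConfig) -> classifier.NetworkSpec:
    return classifier.NetworkSpec(
        width_multiplier=cfg.width_multiplier,
        expansion=cfg.expansion,
        final_feature_width=cfg.final_feature_width,
    )


def _proxy_objective(cfg, spec, x_tr, y_tr, x_va, y_va, space, seed):
    onehot_val = np.eye(4)[y_va]
    plain = classifier.LossConfig(mode="plain_ce", adaptive=False)

    def objective(position: np.ndarray) -> float:
        theta = ado.decode_position(position, space)
        model = classifier.build_network(
            spec, dropout=float(theta["dropout"]), kernel_size=int(theta["kernel_size"]), seed=seed
        )
        from vitiphen import nn as _nn

        opt = _nn.Adam(model.params(), lr=float(theta["learning_rate"]))
        rng = np.random.default_rng(seed + 7)
        batch = int(theta["batch_size"])
        n = x_tr.shape[0]
        for _ in range(cfg.proxy_steps):
            idx = rng.integers(0, n, batch)
            onehot = np.eye(4)[y_tr[idx]]
            logits = model.forward(x_tr[idx], train=True)
            _, grad = classifier._loss_grad_logits(logits, onehot, plain)
            model.backward(grad)
            opt.step()
        probs = model.predict_proba(x_va)
        return classifier.compute_loss(probs, onehot_val, plain)

    return objective


def run_pipeline(cfg: PipelineConfig | None = None) -> PipelineResult:
    cfg = cfg or PipelineConfig()
    seed = int(cfg.seed) % (2**31 - 1)
    params = SimulationParams.clean() if cfg.clean else SimulationParams()

    # 1. simulate + QC + imputation
    collection = simulate_dataset(cfg.n_sites, cfg.zone_mix, params, seed)
    kept, _dropped = preprocessing.qc_partition(collection)
    physical = [preprocessing.impute_series(s) for s in kept]

    # 2. grouped, zone-stratified split; carve validation sites out of train
    split = evaluation.make_splits(physical, evaluation.SplitPlan(seed=seed))
    rng = np.random.default_rng(seed + 1)
    train_ids = list(split.train_sites)
    rng.shuffle(train_ids)
    n_val = max(1, int(round(cfg.val_site_fraction * len(train_ids))))
    val_ids = set(train_ids[:n_val])
    fit_ids = set(train_ids[n_val:])
    by_id = {s.site_id: s for s in physical}
    fit_sites = [by_id[i] for i in sorted(fit_ids)]
    val_sites = [by_id[i] for i in sorted(val_ids)]
    test_sites = [by_id[i] for i in split.test_sites]

    # 3. normalization fitted on the training portion only
    fit_norm, norm = preprocessing.normalize_minmax(fit_sites, "fit")
    val_norm, _ = preprocessing.normalize_minmax(val_sites, norm)
    test_norm, _ = preprocessing.normalize_minmax(test_sites, norm)

    x_tr, y_tr, _ = classifier.make_samples(fit_norm)
    x_va, y_va, _ = classifier.make_samples(val_norm)

    # 4. hyperparameter search (ADO) on the fixed-step proxy objective
    spec = _network_spec(cfg)
    space = ado.hyperparameter_space(epochs_range=cfg.epochs_range)
    sub_tr = np.random.default_rng(seed + 2).choice(
        x_tr.shape[0], size=min(cfg.proxy_train, x_tr.shape[0]), replace=False
    )
    sub_va = np.random.default_rng(seed + 3).choice(
        x_va.shape[0], size=min(cfg.proxy_val, x_va.shape[0]), replace=False
    )
    objective = _proxy_objective(
        cfg, spec, x_tr[sub_tr], y_tr[sub_tr], x_va[sub_va], y_va[sub_va], space, seed
    )
    ado_cfg = ado.AdoConfig(N=cfg.tune_pop, Tmax=cfg.tune_iters, seed=seed)
    best_pos, _best_fit, tune_history = ado.optimize(objective, space, ado_cfg)
    theta = ado.decode_position(best_pos, space)

    # 5. final fit with the tuned configuration and adaptive class weights
    loss_cfg = classifier.LossConfig(mode="weighted_ce", weight_mapping="exp", adaptive=True)
    model, history = classifier.train_model(
        x_tr, y_tr, x_va, y_va, theta, loss_cfg, seed=seed, spec=spec
    )

    # 6. per-interval prediction on held-out sites
    y_pred_all: list[str] = []
    y_true_all: list[str] = []
    pred_onsets: dict[tuple[str, str], int] = {}
    true_onsets: dict[tuple[str, str], int] = {}
    stage_preds: dict[str, list[str]] = {}
    for s_norm, s_phys in zip(test_norm, test_sites):
        stages, _probs = classifier.predict_stages(model, s_norm)
        stage_preds[s_phys.site_id] = stages
        for t in range(N_INTERVALS):
            truth = s_phys.timeline.stage_per_interval[t]
            if truth == "pre_season":
                continue
            y_true_all.append(truth)
            y_pred_all.append(stages[t])
        for st, day in classifier.transitions_from_stages(stages).items():
            pred_onsets[(s_phys.site_id, st)] = day
        for st, day in s_phys.timeline.onset_day.items():
            true_onsets[(s_phys.site_id, st)] = day

    report = evaluation.stage_metrics(y_pred_all, y_true_all)
    keys = sorted(set(pred_onsets) & set(true_onsets))
    onset_errors = np.array([abs(pred_onsets[k] - true_onsets[k]) for k in keys], dtype=float)
    mae, _, _ = evaluation.timing_mae(pred_onsets, true_onsets)

    # 7. risk alerts on the held-out sites, scored against truth-derived events
    rule_cfg = risk_alerts.RiskRuleConfig()
    threshold = risk_alerts.rain_threshold(test_sites, rule_cfg)
    alerts: list[risk_alerts.AlertRecord] = []
    for s_phys in test_sites:
        stages = stage_preds[s_phys.site_id]
        alerts += risk_alerts.detect_rain_risk(stages, s_phys, threshold, rule_cfg)
        ver = classifier.transitions_from_stages(stages).get("veraison")
        alerts += risk_alerts.detect_pest_risk(ver, s_phys, rule_cfg)
    events = risk_alerts.events_from_truth(test_sites, threshold, rule_cfg, seed=seed + 4)
    counts = risk_alerts.match_events(alerts, events)
    rain_m = risk_alerts.alert_metrics(counts["rain"].tp, counts["rain"].fn, counts["rain"].fp)
    pest_m = risk_alerts.alert_metrics(counts["pest"].tp, counts["pest"].fn, counts["pest"].fp)

    return PipelineResult(
        theta=dict(theta),
        tune_history=tune_history,
        train_history=history,
        interval_accuracy_pct=report.accuracy_pct,
        macro_f1=report.macro_f1,
        median_onset_error_days=float(np.median(onset_errors)) if onset_errors.size else float("nan"),
        onset_mae_days=mae,
        rain_alert_metrics=rain_m,
        pest_alert_metrics=pest_m,
        n_train_samples=int(x_tr.shape[0]),
        n_test_sites=len(test_sites),
        extras={"confusion": report.confusion.tolist(), "norm_params": vars(norm)},
    )
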