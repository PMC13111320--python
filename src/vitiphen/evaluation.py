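"""Splits, metrics, uncertainty and ablation harness.

Splitting is group-aware (all samples of a site stay together) and stratified
by agroecological zone: a 70/30 train/test split plus 5 cross-validation folds
partitioning the training portion, with the test set held out throughout.
Metrics cover interval-stage classification (accuracy, macro-F1, confusion),
onset-timing MAE in days, percentile-bootstrap confidence intervals, paired
t-tests between fold-level metrics, permutation feature importance on the
pseudo-image columns, and a 2x2x2 ablation grid (tuned vs default
hyperparameters, biweekly vs monthly rows, with vs without rainfall).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import confusion_matrix, f1_score

from vitiphen.stages import STAGES
from vitiphen.synthetic_data import SiteSeries

__all__ = [
    "SplitPlan",
    "FoldAssignment",
    "MetricsReport",
    "make_splits",
    "stage_metrics",
    "timing_mae",
    "bootstrap_ci",
    "compare_models_ttest",
    "permutation_importance",
    "pool_rows_monthly",
    "run_ablation",
]


@dataclass(frozen=True)
class SplitPlan:
    train_fraction: float = 0.70
    n_folds: int = 5
    seed: int = 0


@dataclass
class FoldAssignment:
    train_sites: list[str]
    test_sites: list[str]
    folds: dict[str, int]  # site_id -> fold index (training sites only)


@dataclass
class MetricsReport:
    accuracy_pct: float
    macro_f1: float
    per_class_f1: dict[str, float]
    confusion: np.ndarray  # counts, rows = true
    n_samples: int
    extras: dict = field(default_factory=dict)


def make_splits(
    collection: Sequence[SiteSeries] | Sequence[tuple[str, str]],
    plan: SplitPlan | None = None,
) -> FoldAssignment:
    """Zone-stratified, site-grouped 70/30 split plus 5 folds of the training
    sites. Accepts full series or lightweight ``(site_id, zone)`` pairs.
    Deterministic under the plan's seed; errors if a zone has fewer sites than
    folds."""
    plan = plan or SplitPlan()
    pairs = [
        (s.site_id, s.zone) if isinstance(s, SiteSeries) else (s[0], s[1])
        for s in collection
    ]
    rng = np.random.default_rng(plan.seed)
    by_zone: dict[str, list[str]] = {}
    for sid, zone in pairs:
        by_zone.setdefault(zone, []).append(sid)

    train_sites: list[str] = []
    test_sites: list[str] = []
    folds: dict[str, int] = {}
    for zone in sorted(by_zone):
        sites = sorted(by_zone[zone])
        if len(sites) < plan.n_folds:
            raise ValueError(f"zone {zone!r} has fewer sites ({len(sites)}) than folds")
        order = rng.permutation(len(sites))
        n_train = int(round(plan.train_fraction * len(sites)))
        z_train = [sites[i] for i in order[:n_train]]
        test_sites += [sites[i] for i in order[n_train:]]
        train_sites += z_train
        for k, sid in enumerate(z_train):
            folds[sid] = k % plan.n_folds
    return FoldAssignment(train_sites=sorted(train_sites), test_sites=sorted(test_sites), folds=folds)


def stage_metrics(y_pred: Sequence[str], y_true: Sequence[str]) -> MetricsReport:
    """Classification metrics over the four stages."""
    for lab in list(y_pred) + list(y_true):
        if lab not in STAGES:
            raise ValueError(f"label {lab!r} outside the 4 stage classes")
    conf = confusion_matrix(y_true, y_pred, labels=list(STAGES))
    acc = 100.0 * np.trace(conf) / conf.sum()
    per_class = f1_score(y_true, y_pred, labels=list(STAGES), average=None, zero_division=0)
    return MetricsReport(
        accuracy_pct=float(acc),
        macro_f1=float(per_class.mean()),
        per_class_f1=dict(zip(STAGES, per_class.astype(float))),
        confusion=conf,
        n_samples=len(y_true),
    )


def timing_mae(
    pred_onsets: Mapping[tuple[str, str], int],
    true_onsets: Mapping[tuple[str, str], int],
) -> tuple[float, int, int]:
    """Mean absolute onset error in days over matched (site, stage) pairs.

    Returns ``(mae_days, n_matched, n_unmatched)``; unmatched pairs (an onset
    present on one side only) are excluded from the mean but counted.
    """
    keys = set(pred_onsets) & set(true_onsets)
    n_unmatched = len(set(pred_onsets) ^ set(true_onsets))
    if not keys:
        raise ValueError("no matched (site, stage) onset pairs")
    errs = [abs(pred_onsets[k] - true_onsets[k]) for k in keys]
    return float(np.mean(errs)), len(keys), n_unmatched


def bootstrap_ci(
    contributions: np.ndarray,
    b: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    statistic: Callable[[np.ndarray], float] = np.mean,
) -> tuple[float, float]:
    """Percentile bootstrap CI of a statistic of per-sample contributions."""
    x = np.asarray(contributions, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to bootstrap")
    if b < 100:
        raise ValueError("use at least 100 bootstrap resamples")
    rng = np.random.default_rng(seed)
    stats_ = np.array([statistic(x[rng.integers(0, x.size, x.size)]) for _ in range(b)])
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(stats_, alpha)), float(np.quantile(stats_, 1.0 - alpha))


def compare_models_ttest(
    fold_metrics_a: Sequence[float],
    fold_metrics_b: Sequence[float],
    alpha: float = 0.01,
) -> dict:
    """Classical paired two-tailed t-test over fold-level metrics.

    Degenerate cases: all differences zero reports p = 1 (not significant);
    constant nonzero differences report p = 0 with a ``degenerate`` flag.
    """
    a = np.asarray(fold_metrics_a, dtype=float)
    b = np.asarray(fold_metrics_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need equal-length paired fold vectors of length >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return {"t": 0.0, "p": 1.0, "significant": False, "degenerate": True}
        return {"t": np.inf if d.mean() > 0 else -np.inf, "p": 0.0, "significant": True, "degenerate": True}
    t, p = sps.ttest_rel(a, b)
    return {"t": float(t), "p": float(p), "significant": bool(p < alpha), "degenerate": False}


def permutation_importance(
    predict: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    y: np.ndarray,
    feature_col: int,
    seed: int = 0,
    n_repeats: int = 5,
) -> float:
    """Accuracy drop when one pseudo-image feature column is shuffled.

    ``predict`` maps an image batch (n, 1, rows, cols) to class indices;
    the column is permuted across samples (whole column profiles swapped
    between sites), preserving its marginal distribution.
    """
    base = float((predict(x) == y).mean())
    rng = np.random.default_rng(seed)
    drops = []
    for _ in range(n_repeats):
        perm = rng.permutation(x.shape[0])
        xs = x.copy()
        xs[:, :, :, feature_col] = x[perm][:, :, :, feature_col]
        drops.append(base - float((predict(xs) == y).mean()))
    return float(np.mean(drops))


def pool_rows_monthly(x: np.ndarray) -> np.ndarray:
    """Pairwise-mean pool the 26 rows of an image batch down to 13 rows."""
    if x.shape[2] % 2 != 0:
        raise ValueError("row count must be even to pool pairwise")
    return 0.5 * (x[:, :, 0::2, :] + x[:, :, 1::2, :])


def run_ablation(
    train_eval: Callable[[dict], MetricsReport],
    tuned_theta: Mapping,
    default_theta: Mapping,
) -> list[dict]:
    """Run the 2x2x2 ablation grid.

    ``train_eval`` receives a variant description ``{"theta", "monthly",
    "drop_rain"}`` and returns a MetricsReport; this harness only enumerates
    the grid and collects rows, so any model plugin can be ablated.
    """
    rows = []
    for theta_name, theta in (("tuned", tuned_theta), ("default", default_theta)):
        for monthly in (False, True):
            for drop_rain in (False, True):
                report = train_eval(
                    {"theta": dict(theta), "monthly": monthly, "drop_rain": drop_rain}
                )
                rows.append(
                    {
                        "optimizer": theta_name,
                        "resolution": "13x3" if monthly else "26x3",
                        "features": "ndvi+evi" if drop_rain else "ndvi+evi+rain",
                        "accuracy_pct": report.accuracy_pct,
                        "macro_f1": report.macro_f1,
                        **report.extras,
                    }
                )
    return rows
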