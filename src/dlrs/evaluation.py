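"""Diagnostic evaluation of DLRS outputs.

AUC is the Mann-Whitney concordance probability (ties credited 0.5); its 95%
confidence interval comes from a stratified percentile bootstrap. The
operating threshold maximizes Youden's J = sensitivity + specificity - 1 over
the observed scores, predicting positive when score >= threshold (the same
orientation as the published DLRS-high cutoff). Calibration uses equal-width
probability bins; decision-curve analysis reports net benefit
TP/n - FP/n * t/(1-t) against treat-all and treat-none references.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.stats import rankdata

from .exceptions import ConfigError, SingleClassError

__all__ = [
    "roc_auc",
    "auc_ci",
    "youden_cutoff",
    "classification_report",
    "calibration_curve",
    "decision_curve",
    "evaluate_scores",
    "CutoffResult",
    "ClassificationMetrics",
    "CalibrationCurve",
    "DecisionCurve",
    "EvalReport",
]


def _check_two_classes(labels: np.ndarray) -> None:
    if np.unique(labels).size < 2:
        raise SingleClassError("both classes must be present")


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=np.float64).ravel()
    y = np.asarray(labels).ravel().astype(int)
    if s.shape != y.shape:
        raise ConfigError(f"scores ({s.shape}) and labels ({y.shape}) differ in length")
    if not np.all(np.isin(np.unique(y), (0, 1))):
        raise ConfigError("labels must be binary 0/1")
    return s, y


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    s, y = _as_arrays(scores, labels)
    _check_two_classes(y)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = rankdata(s)  # average ranks = midrank tie credit
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auc_ci(scores, labels, n_boot: int = 2000, seed: int = 0,
           level: float = 0.95) -> tuple[float, float]:
    """Stratified percentile-bootstrap CI for the AUC."""
    s, y = _as_arrays(scores, labels)
    _check_two_classes(y)
    if n_boot < 100:
        raise ConfigError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    pos_idx, neg_idx = np.nonzero(y == 1)[0], np.nonzero(y == 0)[0]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        pi = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        ni = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        idx = np.concatenate([pi, ni])
        aucs[b] = roc_auc(s[idx], y[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(aucs, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


@dataclass(frozen=True)
class CutoffResult:
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float


def youden_cutoff(scores, labels) -> CutoffResult:
    """Max-J threshold over all distinct observed scores; ties broken low."""
    s, y = _as_arrays(scores, labels)
    _check_two_classes(y)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    best = None
    for t in np.unique(s):  # ascending, so ties resolve to the lowest threshold
        pred = s >= t
        sens = float((pred & (y == 1)).sum() / n_pos)
        spec = float((~pred & (y == 0)).sum() / n_neg)
        j = sens + spec - 1.0
        if best is None or j > best.youden_j + 1e-12:
            best = CutoffResult(float(t), sens, spec, float(j))
    return best


@dataclass(frozen=True)
class ClassificationMetrics:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float


def classification_report(scores, labels, threshold: float) -> ClassificationMetrics:
    """Confusion matrix and derived rates at ``score >= threshold``."""
    s, y = _as_arrays(scores, labels)
    if not np.isfinite(threshold):
        raise ConfigError("threshold must be finite")
    pred = s >= threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    tn = int((~pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    n = len(y)
    n_pos, n_neg = tp + fn, tn + fp
    return ClassificationMetrics(
        threshold=float(threshold), tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / n,
        sensitivity=tp / n_pos if n_pos else float("nan"),
        specificity=tn / n_neg if n_neg else float("nan"),
    )


@dataclass
class CalibrationCurve:
    bin_midpoints: np.ndarray
    mean_predicted: np.ndarray
    observed_fraction: np.ndarray
    counts: np.ndarray


def calibration_curve(scores, labels, n_bins: int = 10) -> CalibrationCurve:
    """Equal-width probability bins on [0, 1]; empty bins are omitted."""
    s, y = _as_arrays(scores, labels)
    if len(s) < n_bins:
        raise ConfigError(f"need n >= n_bins ({n_bins}), got {len(s)}")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(s, edges[1:-1]), 0, n_bins - 1)
    mids, preds, obs, counts = [], [], [], []
    for b in range(n_bins):
        in_bin = idx == b
        c = int(in_bin.sum())
        if c == 0:
            continue
        mids.append((edges[b] + edges[b + 1]) / 2.0)
        preds.append(float(s[in_bin].mean()))
        obs.append(float(y[in_bin].mean()))
        counts.append(c)
    return CalibrationCurve(
        bin_midpoints=np.array(mids), mean_predicted=np.array(preds),
        observed_fraction=np.array(obs), counts=np.array(counts),
    )


@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray


def decision_curve(scores, labels, thresholds=None) -> DecisionCurve:
    """Net benefit across threshold probabilities, with reference curves."""
    s, y = _as_arrays(scores, labels)
    if thresholds is None:
        thresholds = np.linspace(0.01, 0.99, 99)
    t = np.asarray(thresholds, dtype=np.float64)
    if np.any(t <= 0) or np.any(t >= 1):
        raise ConfigError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    prev = y.mean()
    odds = t / (1.0 - t)
    nb = np.empty_like(t)
    for i, ti in enumerate(t):
        pred = s >= ti
        tp = (pred & (y == 1)).sum() / n
        fp = (pred & (y == 0)).sum() / n
        nb[i] = tp - fp * odds[i]
    treat_all = prev - (1.0 - prev) * odds
    return DecisionCurve(
        thresholds=t, net_benefit=nb, treat_all=treat_all,
        treat_none=np.zeros_like(t),
    )


@dataclass
class EvalReport:
    """Full diagnostic report for one cohort at a fixed operating threshold."""

    auc: float
    auc_ci: tuple[float, float]
    cutoff: CutoffResult
    metrics: ClassificationMetrics
    calibration: CalibrationCurve
    decision: DecisionCurve
    n: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "cutoff": asdict(self.cutoff),
            "metrics": asdict(self.metrics),
            "calibration": {
                "bin_midpoints": self.calibration.bin_midpoints.tolist(),
                "mean_predicted": self.calibration.mean_predicted.tolist(),
                "observed_fraction": self.calibration.observed_fraction.tolist(),
                "counts": self.calibration.counts.tolist(),
            },
            "decision_curve": {
                "thresholds": self.decision.thresholds.tolist(),
                "net_benefit": self.decision.net_benefit.tolist(),
                "treat_all": self.decision.treat_all.tolist(),
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def evaluate_scores(scores, labels, threshold: float | None = None,
                    n_boot: int = 2000, seed: int = 0,
                    n_calibration_bins: int = 10) -> EvalReport:
    """Assemble the full report.

    If ``threshold`` is None the Youden cutoff is derived from these scores;
    pass the training-cohort cutoff to evaluate a validation cohort at a
    pre-registered operating point.
    """
    s, y = _as_arrays(scores, labels)
    cut = youden_cutoff(s, y)
    op = cut.threshold if threshold is None else float(threshold)
    return EvalReport(
        auc=roc_auc(s, y),
        auc_ci=auc_ci(s, y, n_boot=n_boot, seed=seed),
        cutoff=cut,
        metrics=classification_report(s, y, op),
        calibration=calibration_curve(s, y, n_bins=min(n_calibration_bins, len(s))),
        decision=decision_curve(s, y),
        n=len(y),
    )
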