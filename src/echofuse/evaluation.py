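"""ROC/threshold metrics, bootstrap CIs, DeLong AUC comparison.

The evaluation protocol: AUC as the Mann-Whitney concordance
probability (ties counted 1/2); operating thresholds chosen on the
development set by maximal geometric mean of sensitivity/specificity or
maximal F1, or on the test set by fixing sensitivity/specificity at
0.800; 5th/95th-percentile confidence intervals from 1,000 bootstrap
resamples of the test set; paired AUC differences tested with DeLong's
test, Bonferroni-adjusted across comparisons while keeping the 0.05
significance threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_auc_score, roc_curve

THRESHOLD_RULES = ("gmean", "f1_dev", "fixed_sens_0.8", "fixed_spec_0.8")


@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass
class MetricReport:
    auc: float
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    f1: float | None
    threshold: float
    threshold_rule: str | None
    n: int
    ci: dict = field(default_factory=dict)   # metric -> (5th, 95th)

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in
               ("auc", "sensitivity", "specificity", "ppv", "npv", "f1",
                "threshold", "threshold_rule", "n")}
        out["ci"] = {k: list(v) for k, v in self.ci.items()}
        return out


@dataclass
class ComparisonResult:
    auc_a: float
    auc_b: float
    p_raw: float
    p_adjusted: float
    n_comparisons: int


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return scores, labels


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve and AUC (Mann-Whitney concordance, ties counted 1/2)."""
    scores, labels = _validate(scores, labels)
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return RocCurve(thresholds=thresholds, sensitivity=tpr,
                    specificity=1.0 - fpr,
                    auc=float(roc_auc_score(labels, scores)))


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def _sens_spec_at(scores, labels, thresholds):
    """Vectorized sensitivity/specificity for prediction = score > t."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    sens = (pos[None, :] > thresholds[:, None]).mean(axis=1)
    spec = (neg[None, :] <= thresholds[:, None]).mean(axis=1)
    return sens, spec


def pick_threshold(dev_scores, dev_labels, rule: str = "gmean") -> float:
    """Operating threshold from the stated rule.

    Candidates are midpoints between adjacent sorted unique scores plus
    +/- infinity sentinels; ties break toward the larger threshold.
    """
    if rule not in THRESHOLD_RULES:
        raise ValueError(f"unknown threshold rule {rule!r}")
    scores, labels = _validate(dev_scores, dev_labels)
    cand = _candidate_thresholds(scores)
    if rule.startswith("fixed"):
        # the degenerate all-positive / all-negative operating points are
        # not meaningful "fixed sensitivity/specificity" thresholds
        cand = cand[np.isfinite(cand)]
        if cand.size == 0:
            raise ValueError(f"{rule} unattainable: scores are all tied")
    sens, spec = _sens_spec_at(scores, labels, cand)
    if rule == "gmean":
        objective = np.sqrt(sens * spec)
    elif rule == "f1_dev":
        tp = sens * (labels == 1).sum()
        pred_pos = (scores[None, :] > cand[:, None]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ppv = np.where(pred_pos > 0, tp / pred_pos, np.nan)
            objective = np.where(np.isnan(ppv) | ((ppv + sens) == 0), -np.inf,
                                 2 * ppv * sens / (ppv + sens))
    elif rule == "fixed_sens_0.8":
        ok = sens >= 0.800
        if not ok.any():
            raise ValueError(
                f"sensitivity 0.800 unattainable; max is {sens.max():.3f}")
        return float(cand[np.flatnonzero(ok)[-1]])
    else:  # fixed_spec_0.8
        ok = spec >= 0.800
        if not ok.any():
            raise ValueError(
                f"specificity 0.800 unattainable; max is {spec.max():.3f}")
        return float(cand[np.flatnonzero(ok)[0]])
    best = objective.max()
    return float(cand[np.flatnonzero(objective == best)[-1]])


def classification_metrics(scores, labels, threshold: float,
                           threshold_rule: str | None = None) -> MetricReport:
    """Point estimates from the 2x2 table at ``score > threshold``."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    pred = scores > threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else None       # undefined, not zero
    npv = tn / (tn + fn) if tn + fn else None
    f1 = (2 * ppv * sens / (ppv + sens)
          if ppv is not None and (ppv + sens) > 0 else None)
    try:
        auc = float(roc_auc_score(labels, scores))
    except ValueError:
        auc = float("nan")
    return MetricReport(auc=auc, sensitivity=sens, specificity=spec, ppv=ppv,
                        npv=npv, f1=f1, threshold=float(threshold),
                        threshold_rule=threshold_rule, n=labels.size)


def bootstrap_ci(metric_fn, scores, labels, n_boot: int = 1000,
                 seed: int = 0) -> tuple[float, float]:
    """5th/95th percentile interval from joint (score, label) resampling.

    Resamples that end up single-class are redrawn; the call errors if
    the metric is undefined (NaN) in more than half the resamples.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    n = scores.size
    if n < 10:
        raise ValueError("bootstrap needs at least 10 samples")
    rng = np.random.default_rng(seed)
    values = np.empty(n_boot)
    n_undefined = 0
    for b in range(n_boot):
        for _ in range(1000):
            idx = rng.integers(0, n, size=n)
            if labels[idx].min() != labels[idx].max():
                break
        else:
            raise ValueError("could not draw a two-class resample")
        try:
            v = metric_fn(scores[idx], labels[idx])
        except ValueError:
            v = float("nan")
        if v is None or not np.isfinite(v):
            n_undefined += 1
            values[b] = np.nan
        else:
            values[b] = v
    if n_undefined > n_boot / 2:
        raise ValueError(
            f"metric undefined in {n_undefined}/{n_boot} bootstrap resamples")
    lo, hi = np.nanpercentile(values, [5.0, 95.0])
    return float(lo), float(hi)


def _delong_placements(scores, labels):
    """Mid-rank placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    allr = rankdata(np.concatenate([pos, neg]))
    rp = rankdata(pos)
    rn = rankdata(neg)
    auc = (allr[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (allr[:m] - rp) / n
    v01 = 1.0 - (allr[m:] - rn) / m
    return auc, v10, v01


def delong_test(scores_a, scores_b, labels) -> ComparisonResult:
    """Paired two-sided DeLong test for a difference in AUCs."""
    scores_a = np.asarray(scores_a, dtype=np.float64).ravel()
    scores_b = np.asarray(scores_b, dtype=np.float64).ravel()
    _, labels = _validate(scores_a, labels)
    if scores_b.shape != labels.shape:
        raise ValueError("paired test needs aligned score vectors")
    auc_a, v10_a, v01_a = _delong_placements(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_placements(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    # 2x2 covariance of (auc_a, auc_b) from placement values; a class
    # with a single member contributes zero estimated variance
    s10 = np.cov(np.vstack([v10_a, v10_b])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b])) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc_a - auc_b
    if not np.isfinite(var) or var <= 0:
        p = 1.0 if delta == 0 else 0.0
    else:
        z = delta / np.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
    return ComparisonResult(auc_a=float(auc_a), auc_b=float(auc_b),
                            p_raw=p, p_adjusted=p, n_comparisons=1)


def bonferroni_adjust(p_values) -> list[float]:
    """p_i <- min(1, p_i * m); the significance threshold stays at 0.05."""
    p = np.asarray(p_values, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return [float(min(1.0, v * p.size)) for v in p]


def compare_models(named_scores: dict[str, np.ndarray], reference: str,
                   labels) -> dict[str, ComparisonResult]:
    """DeLong-compare every model against ``reference``, Bonferroni over
    the family of comparisons actually made."""
    others = [k for k in named_scores if k != reference]
    results = {}
    raw = []
    for name in others:
        res = delong_test(named_scores[reference], named_scores[name], labels)
        results[name] = res
        raw.append(res.p_raw)
    adjusted = bonferroni_adjust(raw)
    for name, p_adj in zip(others, adjusted):
        results[name].p_adjusted = p_adj
        results[name].n_comparisons = len(others)
    return results


def metric_report(test_scores, test_labels, threshold: float,
                  threshold_rule: str | None = None, n_boot: int = 1000,
                  seed: int = 0, with_ci: bool = True) -> MetricReport:
    """Point estimates plus bootstrap CIs for every reported metric."""
    report = classification_metrics(test_scores, test_labels, threshold,
                                    threshold_rule)
    if not with_ci:
        return report

    def metric(name):
        def fn(s, l):
            rep = classification_metrics(s, l, threshold)
            v = getattr(rep, name)
            return np.nan if v is None else v
        return fn

    for name in ("auc", "sensitivity", "specificity", "ppv", "npv", "f1"):
        try:
            report.ci[name] = bootstrap_ci(metric(name), test_scores,
                                           test_labels, n_boot=n_boot, seed=seed)
        except ValueError:
            pass
    return report


def stratified_report(scores, labels, strata_labels, threshold: float,
                      **kwargs) -> dict[str, MetricReport]:
    """Per-stratum reports at the single global threshold (thresholds are
    not re-fit per stratum); single-class strata are skipped with a
    warning."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    strata = np.asarray(strata_labels).ravel()
    out = {}
    for name in np.unique(strata):
        sel = strata == name
        if labels[sel].min() == labels[sel].max():
            warnings.warn(f"stratum {name!r} has a single class; skipped")
            continue
        out[str(name)] = metric_report(scores[sel], labels[sel], threshold,
                                       **kwargs)
    return out
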