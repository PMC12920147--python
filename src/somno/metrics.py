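"""Evaluation: Harrell's C-index, horizon AUROC, bootstrap CIs, Bonferroni,
confusion matrices and macro F1.

Rank metrics credit score ties 0.5. The horizon AUROC treats patients with
an event inside the horizon as positives, patients followed beyond the
horizon as negatives, and excludes patients censored before the horizon.
Confidence intervals are patient-level bootstrap percentile intervals;
p-values against a null value use a normal approximation on the bootstrap
standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

DAYS_PER_YEAR = 365.25


@dataclass
class EvalResult:
    metric_name: str
    value: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_boot: int = 0
    p_value: float = np.nan
    significant_after_correction: bool | None = None
    extra: dict = field(default_factory=dict)


def harrell_c_index(scores, event, time) -> float:
    """Fraction of correctly ranked comparable pairs.

    A pair (i, j) is comparable when t_i < t_j and patient i had the event;
    it is concordant when score_i > score_j, and score ties earn 0.5.
    Returns NaN (with a warning) when no pair is comparable.
    """
    scores = np.asarray(scores, dtype=float)
    event = np.asarray(event).astype(bool)
    time = np.asarray(time, dtype=float)
    if scores.ndim != 1 or len({len(scores), len(event), len(time)}) != 1:
        raise ValueError("scores, event and time must be equal-length vectors")
    comparable = (time[:, None] < time[None, :]) & event[:, None]
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        warnings.warn("C-index undefined: no comparable pairs")
        return float("nan")
    diff = scores[:, None] - scores[None, :]
    credit = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    return float((credit * comparable).sum() / n_pairs)


def horizon_auroc(scores, event, time, horizon_years: float = 6.0,
                  days_per_year: float = DAYS_PER_YEAR) -> float:
    """AUROC for events within a fixed horizon after the sleep study.

    Positives: event within the horizon. Negatives: followed (event or
    censoring) beyond the horizon. Censored-before-horizon patients are
    excluded. Ties in score receive half credit via the rank statistic.
    """
    if horizon_years <= 0:
        raise ValueError("horizon must be positive")
    scores = np.asarray(scores, dtype=float)
    event = np.asarray(event).astype(bool)
    time = np.asarray(time, dtype=float)
    h = horizon_years * days_per_year
    pos = event & (time <= h)
    neg = time > h
    if not pos.any() or not neg.any():
        warnings.warn("horizon AUROC undefined: a class is empty")
        return float("nan")
    keep = pos | neg
    y = pos[keep].astype(int)
    s = scores[keep]
    # Mann-Whitney rank statistic with midranks for ties
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s))
    sorted_s = s[order]
    r = np.arange(1, len(s) + 1, dtype=float)
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i : j + 1]] = r[i : j + 1].mean()
        i = j + 1
    n1 = int(y.sum())
    n0 = len(y) - n1
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class BootstrapResult:
    value: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_degenerate: int
    samples: np.ndarray

    def p_value_vs(self, null: float) -> float:
        """Two-sided p-value against ``null`` via the bootstrap SE."""
        from scipy.stats import norm

        se = float(self.samples.std(ddof=1))
        if se == 0:
            return 0.0 if self.value != null else 1.0
        zstat = (self.value - null) / se
        return float(2 * norm.sf(abs(zstat)))


def bootstrap_ci(metric_fn, data: tuple, n_boot: int = 1000,
                 seed: int = 0, alpha: float = 0.05) -> BootstrapResult:
    """Patient-level bootstrap percentile CI for ``metric_fn(*data)``.

    ``data`` holds equal-length per-patient arrays that are resampled with
    replacement together. Resamples on which the metric is undefined (NaN)
    are skipped and counted; more than 50% degenerate resamples aborts.
    """
    arrays = [np.asarray(a) for a in data]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("all data arrays must have equal length")
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        point = float(metric_fn(*arrays))
        vals = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            vals[b] = metric_fn(*[a[idx] for a in arrays])
    ok = np.isfinite(vals)
    n_bad = int((~ok).sum())
    if n_bad > n_boot // 2:
        raise ValueError(
            f"bootstrap degenerate: metric undefined on {n_bad}/{n_boot} resamples")
    good = vals[ok]
    lo, hi = np.percentile(good, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapResult(point, float(lo), float(hi), n_boot, n_bad, good)


def bonferroni(p_values, alpha: float = 0.01) -> np.ndarray:
    """Family-wise significance flags: p_i < alpha / m."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a nonempty vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return p < alpha / len(p)


def classification_report(y_true, y_pred, classes: list[str]) -> dict:
    """Confusion matrix (row-normalized %), per-class P/R/F1, macro F1.

    Classes absent from the truth get an undefined F1 and are excluded
    from the macro average with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("predictions and truth must align")
    labels = np.arange(len(classes))
    cm = _sk_confusion(y_true, y_pred, labels=labels).astype(float)
    row_sums = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cm_pct = 100.0 * cm / row_sums
    per_class = {}
    f1s = []
    for k, name in enumerate(classes):
        tp = cm[k, k]
        fn = cm[k].sum() - tp
        fp = cm[:, k].sum() - tp
        support = int(cm[k].sum())
        prec = tp / (tp + fp) if tp + fp else np.nan
        rec = tp / (tp + fn) if tp + fn else np.nan
        f1 = (2 * prec * rec / (prec + rec)
              if np.isfinite(prec) and np.isfinite(rec) and (prec + rec) > 0
              else (0.0 if support else np.nan))
        per_class[name] = {"precision": prec, "recall": rec, "f1": f1,
                           "support": support}
        if support:
            f1s.append(f1)
        else:
            warnings.warn(f"class {name!r} absent from truth; excluded from macro F1")
    return {
        "confusion_pct": cm_pct,
        "confusion_counts": cm.astype(int),
        "per_class": per_class,
        "macro_f1": float(np.mean(f1s)) if f1s else float("nan"),
        "accuracy": float((y_true == y_pred).mean()),
    }
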