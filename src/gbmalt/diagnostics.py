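"""Group comparison, ROC, leave-one-out cross-validation, and agreement.

The diagnostic question is binary: tumor recurrence (positive class)
versus post-treatment effect. Single imaging features are evaluated with a
pooled-variance t-test (Bonferroni-corrected per-test alpha 0.025 for the
two feature comparisons), empirical ROC analysis with a Youden-optimal
operating point, and leave-one-out cross-validation in which the feature
direction and cutoff (or a two-feature logistic score) are re-learned on
every training fold and only held-out predictions are pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import DomainError, InputError

BONFERRONI_ALPHA = 0.025   # two feature comparisons at family alpha 0.05


# ---------------------------------------------------------------------------
# elementary statistics

def students_t(group_a: Sequence[float], group_b: Sequence[float]
               ) -> Tuple[float, float]:
    """Two-sided pooled-variance two-sample t-test; returns (t, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 observations")
    pooled = a.var(ddof=1) * (a.size - 1) + b.var(ddof=1) * (b.size - 1)
    if pooled == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return sign * np.inf, np.finfo(float).tiny
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def binormal_auc(mu_pos: float, sd_pos: float, mu_neg: float, sd_neg: float
                 ) -> float:
    """Closed-form AUC of two Gaussian classes: Φ(Δμ/√(σ₊²+σ₋²))."""
    if sd_pos <= 0 or sd_neg <= 0:
        raise DomainError("class standard deviations must be positive")
    return float(stats.norm.cdf((mu_pos - mu_neg)
                                / np.hypot(sd_pos, sd_neg)))


# ---------------------------------------------------------------------------
# ROC

@dataclass(frozen=True)
class RocResult:
    auc: float
    sensitivity: float
    specificity: float
    cutoff: float              # in oriented-score space (predict + if ≥)
    direction: int
    fpr: np.ndarray = field(repr=False, default=None)
    tpr: np.ndarray = field(repr=False, default=None)


def roc(scores: Sequence[float], labels: Sequence[int],
        positive_direction: int = 1) -> RocResult:
    """Empirical ROC with Mann-Whitney AUC (ties ½) and Youden optimum.

    ``positive_direction`` +1 means higher scores indicate the positive
    class; −1 flips the orientation (e.g. low ADC10 suggests recurrence).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise InputError("ROC needs both classes present")
    if positive_direction not in (1, -1):
        raise InputError("positive_direction must be +1 or -1")
    oriented = positive_direction * scores
    fpr, tpr, thr = roc_curve(y.astype(int), oriented)
    j = int(np.argmax(tpr - fpr))
    return RocResult(auc=float(roc_auc_score(y.astype(int), oriented)),
                     sensitivity=float(tpr[j]), specificity=float(1 - fpr[j]),
                     cutoff=float(thr[j]), direction=positive_direction,
                     fpr=fpr, tpr=tpr)


def _youden_cutoff(scores: np.ndarray, y: np.ndarray) -> float:
    """Cutoff maximizing sensitivity + specificity − 1 for the rule
    "positive when score ≥ cutoff" (ties grouped)."""
    order = np.argsort(-scores, kind="stable")
    ys = y[order].astype(float)
    ss = scores[order]
    tp = np.cumsum(ys)
    fp = np.cumsum(1.0 - ys)
    n_pos = tp[-1]
    n_neg = fp[-1]
    distinct = np.r_[np.diff(ss) != 0, True]
    j = tp[distinct] / n_pos - fp[distinct] / n_neg
    best = int(np.argmax(j))
    if j[best] <= 0:
        return np.inf              # no cutoff beats predicting all-negative
    return float(ss[distinct][best])


# ---------------------------------------------------------------------------
# leave-one-out cross-validation

@dataclass(frozen=True)
class LoocvResult:
    cv_auc: float
    cv_accuracy: float
    heldout_scores: np.ndarray = field(repr=False, default=None)
    heldout_predictions: np.ndarray = field(repr=False, default=None)


def loocv(features: np.ndarray, labels: Sequence[int],
          model: str = "univariate", threshold: str = "youden"
          ) -> LoocvResult:
    """Leave-one-out CV of a univariate cutoff rule or a logistic combiner.

    Every subject is held out once; the classifier — feature direction plus
    Youden cutoff for ``univariate``, an additive two-feature logistic
    score for ``logistic_combined`` — is learned on the remaining subjects
    and applied to the held-out one. ``cv_auc`` pools the sign-aligned
    held-out scores; ``cv_accuracy`` counts held-out subjects classified
    correctly at the training-fold cutoff (``threshold='posterior'`` uses
    the 0.5-posterior rule for the logistic model instead).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).astype(bool)
    n = y.size
    if X.shape[0] != n:
        raise InputError("features and labels disagree in length")
    if y.sum() < 3 or (~y).sum() < 3:
        raise InputError("need at least 3 subjects per class")
    if model not in ("univariate", "logistic_combined"):
        raise InputError(f"unknown model {model!r}")
    if model == "univariate" and X.shape[1] != 1:
        raise InputError("univariate model expects exactly one feature")
    if threshold not in ("youden", "posterior"):
        raise InputError(f"unknown threshold rule {threshold!r}")

    scores = np.empty(n)
    preds = np.empty(n, dtype=bool)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        ytr = y[tr]
        if ytr.all() or not ytr.any():
            raise InputError("degenerate training fold with a single class")
        if model == "univariate":
            x = X[tr, 0]
            direction = 1.0 if x[ytr].mean() >= x[~ytr].mean() else -1.0
            cutoff = _youden_cutoff(direction * x, ytr)
            s = direction * X[i, 0]
        else:
            clf = LogisticRegression(max_iter=10_000)
            clf.fit(X[tr], ytr.astype(int))
            train_scores = clf.decision_function(X[tr])
            cutoff = (0.0 if threshold == "posterior"
                      else _youden_cutoff(train_scores, ytr))
            s = float(clf.decision_function(X[i:i + 1])[0])
            preds[i] = s >= cutoff
            # decision scores live on fold-specific scales (intercept and
            # coefficients are refit each fold), so pooled AUC uses each
            # held-out score's rank within its own training distribution
            scores[i] = ((train_scores < s).sum()
                         + 0.5 * (train_scores == s).sum()) / train_scores.size
            continue
        scores[i] = s
        preds[i] = s >= cutoff
    return LoocvResult(cv_auc=float(roc_auc_score(y.astype(int), scores)),
                       cv_accuracy=float(np.mean(preds == y)),
                       heldout_scores=scores, heldout_predictions=preds)


def gaussian_loocv_auc(mu_pos: float, sd_pos: float, n_pos: int,
                       mu_neg: float, sd_neg: float, n_neg: int,
                       n_reps: int, seed: int,
                       model: str = "univariate") -> np.ndarray:
    """Cross-validated AUCs of seeded Gaussian surrogate cohorts.

    Each replicate draws ``n_pos`` positive and ``n_neg`` negative feature
    values from the two class Gaussians and runs the LOOCV procedure; the
    array of per-replicate cv_auc values is returned.
    """
    rng = np.random.default_rng(seed)
    y = np.r_[np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)]
    out = np.empty(n_reps)
    for r in range(n_reps):
        x = np.r_[rng.normal(mu_pos, sd_pos, n_pos),
                  rng.normal(mu_neg, sd_neg, n_neg)]
        out[r] = loocv(x, y, model=model).cv_auc
    return out


# ---------------------------------------------------------------------------
# inter-reader agreement

def icc(reader1: Sequence[float], reader2: Sequence[float]) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure."""
    r1 = np.asarray(reader1, dtype=float)
    r2 = np.asarray(reader2, dtype=float)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise InputError("readers must supply equal-length 1-D measurements")
    n = r1.size
    if n < 3:
        raise InputError("ICC needs at least 3 subjects")
    x = np.column_stack([r1, r2])
    k = 2
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    if np.allclose(row_means.var(), 0.0):
        raise DomainError("zero between-subject variance: ICC undefined")
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    mse = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2
           ).sum() / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    return float((msr - mse) / denom)


# ---------------------------------------------------------------------------
# cohort-level report

@dataclass
class DiagnosticReport:
    """Group statistics, ROC and cross-validated performance per reader,
    plus inter-reader agreement."""

    alpha: float
    per_reader: Dict[str, dict]
    icc_adc10: Optional[float] = None
    icc_iauc90: Optional[float] = None

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "per_reader": self.per_reader,
                "icc_adc10": self.icc_adc10, "icc_iauc90": self.icc_iauc90}

    def to_text(self) -> str:
        lines = ["Diagnostic performance: tumor recurrence vs "
                 "post-treatment effect",
                 f"(per-test alpha {self.alpha} after Bonferroni correction)",
                 ""]
        for reader, block in self.per_reader.items():
            lines.append(f"Reader {reader}")
            for feat in ("adc10", "iauc90"):
                st = block[feat]
                lines.append(
                    f"  {feat:7s} recurrence {st['mean_pos']:.2f} ± "
                    f"{st['sd_pos']:.2f} | post-treatment {st['mean_neg']:.2f}"
                    f" ± {st['sd_neg']:.2f} | P = {st['p_value']:.3g}"
                    f"{' *' if st['significant'] else ''}")
                lines.append(
                    f"          sens {100 * st['sensitivity']:.1f}% spec "
                    f"{100 * st['specificity']:.1f}% AUC {st['auc']:.2f}")
            lines.append("  cross-validated (leave-one-out):")
            for name, key in (("DWI (ADC10)", "adc10"),
                              ("DCE (IAUC90)", "iauc90"),
                              ("DWI + DCE", "combined")):
                cv = block["cv"][key]
                lines.append(f"    {name:13s} AUC {cv['cv_auc']:.2f}  "
                             f"accuracy {100 * cv['cv_accuracy']:.1f}%")
            lines.append("")
        if self.icc_adc10 is not None:
            lines.append(f"Inter-reader ICC: ADC10 {self.icc_adc10:.2f}, "
                         f"IAUC90 {self.icc_iauc90:.2f}")
        return "\n".join(lines)


def evaluate_cohort(features: pd.DataFrame, alpha: float = BONFERRONI_ALPHA,
                    threshold: str = "youden") -> DiagnosticReport:
    """Full diagnostic evaluation of a feature table.

    ``features`` needs columns patient, reader, label, adc10, iauc90. The
    positive class is recurrence; feature direction is learned from the
    data (full-sample for the descriptive ROC, per training fold inside the
    cross-validation).
    """
    required = {"patient", "reader", "label", "adc10", "iauc90"}
    if not required.issubset(features.columns):
        raise InputError(f"feature table needs columns {sorted(required)}")
    per_reader: Dict[str, dict] = {}
    for reader, sub in features.groupby("reader", sort=True):
        y = (sub["label"] == "recurrence").to_numpy()
        block: dict = {"n": int(len(sub)), "cv": {}}
        for feat in ("adc10", "iauc90"):
            v = sub[feat].to_numpy(dtype=float)
            pos, neg = v[y], v[~y]
            t, p = students_t(pos, neg)
            direction = 1 if pos.mean() >= neg.mean() else -1
            rr = roc(v, y, positive_direction=direction)
            lo = loocv(v, y, model="univariate")
            block[feat] = {
                "mean_pos": float(pos.mean()), "sd_pos": float(pos.std(ddof=1)),
                "mean_neg": float(neg.mean()), "sd_neg": float(neg.std(ddof=1)),
                "t": t, "p_value": p, "significant": bool(p < alpha),
                "direction": direction, "auc": rr.auc,
                "sensitivity": rr.sensitivity, "specificity": rr.specificity,
            }
            block["cv"][feat] = {"cv_auc": lo.cv_auc,
                                 "cv_accuracy": lo.cv_accuracy}
        combined = loocv(sub[["adc10", "iauc90"]].to_numpy(dtype=float), y,
                         model="logistic_combined", threshold=threshold)
        block["cv"]["combined"] = {"cv_auc": combined.cv_auc,
                                   "cv_accuracy": combined.cv_accuracy}
        per_reader[str(reader)] = block

    icc_adc = icc_iauc = None
    readers = sorted(features["reader"].unique())
    if len(readers) == 2:
        wide = features.pivot(index="patient", columns="reader",
                              values=["adc10", "iauc90"]).dropna()
        icc_adc = icc(wide[("adc10", readers[0])], wide[("adc10", readers[1])])
        icc_iauc = icc(wide[("iauc90", readers[0])],
                       wide[("iauc90", readers[1])])
    return DiagnosticReport(alpha=alpha, per_reader=per_reader,
                            icc_adc10=icc_adc, icc_iauc90=icc_iauc)
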