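"""ROC analysis: AUC (Mann-Whitney), DeLong variance, sensitivity at a
fixed specificity, and the DeLong/Jackknife test for paired AUCs.

The AUC is the Mann-Whitney U statistic with ties counted 1/2.  Variances
and covariances of (paired) AUCs use DeLong's structural components — the
per-case placement values ``V10`` (for diseased cases) and ``V01`` (for
healthy cases) — which is asymptotically equivalent to the leave-one-out
jackknife.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    variance: float  # DeLong


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values (V10 per positive, V01 per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
    v01 = np.array([np.mean((n < pos) + 0.5 * (n == pos)) for n in neg])
    return v10, v01


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC curve and AUC; higher scores indicate the positive class."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    m = int((labels == 1).sum())
    n = int((labels == 0).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")

    thr = np.unique(scores)[::-1]
    thresholds = np.concatenate([[np.inf], thr])
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    for i, t in enumerate(thresholds):
        sens[i] = np.mean(pos >= t)
        spec[i] = np.mean(neg < t)

    ranks = sps.rankdata(scores)
    auc = (ranks[labels == 1].sum() - m * (m + 1) / 2.0) / (m * n)
    v10, v01 = _placements(scores, labels)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        variance=float(var),
    )


def sensitivity_at_specificity(roc: RocResult, spec_target: float = 0.85) -> float:
    """Max sensitivity among operating points with specificity >= target."""
    ok = roc.specificity >= spec_target
    if not ok.any():
        return 0.0
    return float(roc.sensitivity[ok].max())


@dataclass
class AucComparison:
    auc_a: float
    auc_b: float
    difference: float
    se: float
    ci95: tuple[float, float]
    z: float
    p_value: float


def auc_compare(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> AucComparison:
    """DeLong test for two correlated AUCs measured on the same subjects."""
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels).astype(int)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("paired scores must share the subject list")
    m = int((labels == 1).sum())
    n = int((labels == 0).sum())
    if m < 2 or n < 2:
        raise ValueError("need >= 2 cases per class")
    va10, va01 = _placements(scores_a, labels)
    vb10, vb01 = _placements(scores_b, labels)
    auc_a = float(va10.mean())
    auc_b = float(vb10.mean())
    s10 = np.cov(np.stack([va10, vb10]), ddof=1)
    s01 = np.cov(np.stack([va01, vb01]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    se = float(np.sqrt(max(var_diff, 0.0)))
    if se == 0.0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / se
        p = 2.0 * sps.norm.sf(abs(z))
    return AucComparison(
        auc_a=auc_a,
        auc_b=auc_b,
        difference=float(diff),
        se=se,
        ci95=(float(diff - 1.96 * se), float(diff + 1.96 * se)),
        z=float(z),
        p_value=float(p),
    )


def select_one_eye_per_subject(
    subject_ids: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Seeded subject-level sampler: index mask keeping one eye each."""
    subject_ids = np.asarray(subject_ids)
    keep = np.zeros(len(subject_ids), bool)
    for s in np.unique(subject_ids):
        idx = np.flatnonzero(subject_ids == s)
        keep[rng.choice(idx)] = True
    return keep
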