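"""Response labelling and ROC statistics.

Responder status follows the Miller-Payne convention: grades 4-5 are
responders, grades 1-3 non-responders. Discrimination of a scalar parameter
is summarized by the ROC area computed through the Mann-Whitney identity
(ties counted 1/2), with a DeLong variance for the 95% CI and for the
p-value against AUC = 0.5, and an optimal cutoff maximizing Youden's J
(sensitivity + specificity - 1). Scores may indicate response in either
direction (metabolic decline: low ΔSUV; diffusion rise: high ΔADC); the
orientation is chosen so the reported AUC is >= 0.5 and is recorded.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ResponseLabel:
    patient_id: str
    grade: int
    responder: bool


def classify_response(grade: int, patient_id: str = "") -> ResponseLabel:
    """Map a Miller-Payne grade to a responder label (grade >= 4)."""
    if grade not in (1, 2, 3, 4, 5):
        raise ValueError(f"Miller-Payne grade must be in 1..5, got {grade}")
    return ResponseLabel(patient_id=patient_id, grade=int(grade), responder=grade >= 4)


@dataclass
class ROCResult:
    """ROC summary for one scalar parameter.

    ``direction`` records the score orientation: ``responder_high`` means
    responders score high (predict responder when score >= cutoff),
    ``responder_low`` the reverse (predict responder when score <= cutoff).
    ``cutoff`` is on the original score scale. With perfect separation the
    DeLong variance degenerates to 0; the CI then collapses onto the AUC and
    the p-value is reported as 0.
    """

    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    cutoff: float
    sensitivity: float  # percent
    specificity: float  # percent
    direction: str
    n_pos: int
    n_neg: int


def _auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC = P(pos > neg) + P(pos == neg)/2 via midranks."""
    scores = np.concatenate([pos, neg])
    ranks = sps.rankdata(scores)
    r_pos = ranks[: len(pos)].sum()
    n1, n0 = len(pos), len(neg)
    return (r_pos - n1 * (n1 + 1) / 2) / (n1 * n0)


def _delong_variance(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    """DeLong variance of the AUC from placement values."""
    # V10[i] = P(neg < pos_i) + ties/2 ; V01[j] symmetric
    v10 = np.array([(np.sum(neg < x) + 0.5 * np.sum(neg == x)) / len(neg) for x in pos])
    v01 = np.array([(np.sum(pos > y) + 0.5 * np.sum(pos == y)) / len(pos) for y in neg])
    s10 = v10.var(ddof=1) if len(pos) > 1 else 0.0
    s01 = v01.var(ddof=1) if len(neg) > 1 else 0.0
    return s10 / len(pos) + s01 / len(neg)


def roc_analysis(scores, labels) -> ROCResult:
    """Full ROC analysis of one scalar score against binary responder labels.

    Missing scores (None/NaN) are dropped together with their labels. The
    cutoff is reported as the midpoint between adjacent distinct observed
    values; among cutoffs of equal Youden J, the one with higher sensitivity
    wins, then the more extreme threshold.
    """
    scores = np.array([np.nan if s is None else float(s) for s in scores])
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    keep = np.isfinite(scores)
    scores, labels = scores[keep], labels[keep]
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("ROC analysis needs at least one responder and one non-responder")

    auc_high = _auc_mann_whitney(pos, neg)
    if auc_high >= 0.5:
        direction, sign = "responder_high", 1.0
        auc = auc_high
    else:
        direction, sign = "responder_low", -1.0
        auc = 1.0 - auc_high
    opos, oneg = sign * pos, sign * neg

    var = _delong_variance(opos, oneg, auc)
    se = math.sqrt(var)
    if se > 0:
        ci_low = max(0.0, auc - 1.959963984540054 * se)
        ci_high = min(1.0, auc + 1.959963984540054 * se)
        p = 2.0 * sps.norm.sf(abs(auc - 0.5) / se)
    else:
        ci_low = ci_high = auc
        p = 0.0 if auc != 0.5 else 1.0

    cutoff, sens, spec = _youden_cutoff(opos, oneg)
    return ROCResult(
        auc=float(auc), ci_low=float(ci_low), ci_high=float(ci_high),
        p_value=float(p), cutoff=float(sign * cutoff),
        sensitivity=100.0 * sens, specificity=100.0 * spec,
        direction=direction, n_pos=len(pos), n_neg=len(neg),
    )


def _youden_cutoff(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float, float]:
    """J-optimal threshold on oriented scores (responder when score >= t).

    Candidate thresholds are midpoints between adjacent distinct observed
    values plus one sentinel below the minimum and one above the maximum.
    """
    values = np.unique(np.concatenate([pos, neg]))
    if len(values) == 1:
        mids = np.array([values[0] - 1.0, values[0] + 1.0])
    else:
        inner = (values[:-1] + values[1:]) / 2.0
        mids = np.concatenate([[values[0] - 1.0], inner, [values[-1] + 1.0]])
    center = np.median(values)
    best = None
    for t in mids:
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        j = sens + spec - 1.0
        key = (round(j, 12), round(sens, 12), round(abs(t - center), 12), t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    return best[1], best[2], best[3]


def subgroup_filter(records: pd.DataFrame, subtype_spec: str) -> pd.DataFrame:
    """Restrict a cohort table to a molecular-subtype subgroup.

    ``HER2_negative`` keeps HER2-negative patients; ``triple_negative`` keeps
    ER-, PR- and HER2-negative patients; ``all`` is the identity. Rows with a
    missing flag are dropped (for non-``all`` specs).
    """
    if subtype_spec == "all":
        return records
    if subtype_spec == "HER2_negative":
        needed = ["HER2"]
    elif subtype_spec == "triple_negative":
        needed = ["ER", "PR", "HER2"]
    else:
        raise ValueError(f"unknown subtype spec {subtype_spec!r}")
    sub = records.dropna(subset=needed)
    keep = np.ones(len(sub), dtype=bool)
    for flag in needed:
        keep &= ~sub[flag].astype(bool).to_numpy()
    return sub[keep]


def rank_compare(values_pre, values_post) -> float:
    """Two-sided Mann-Whitney U p-value comparing two independent samples.

    Exact by enumeration of all label assignments (on midranks, so ties are
    handled) when both samples have at most 8 values; the tie-corrected
    normal approximation otherwise.
    """
    x = np.asarray(list(values_pre), dtype=float)
    y = np.asarray(list(values_post), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("rank_compare needs two non-empty samples")
    if max(len(x), len(y)) <= 8:
        return _exact_mwu(x, y)
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)


def _exact_mwu(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p by enumerating every assignment of the pooled ranks."""
    n1, n = len(x), len(x) + len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * (n - n1) / 2
    dev_obs = abs(u_obs - mu)
    count = total = 0
    for idx in itertools.combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= dev_obs - 1e-12:
            count += 1
    return count / total
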