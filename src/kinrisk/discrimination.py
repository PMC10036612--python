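"""Discrimination and reclassification statistics.

ROC/AUC with Youden-J "best threshold" selection, the continuous net
reclassification improvement (NRI) and integrated discrimination
improvement (IDI) for nested risk-model comparison, and Spearman rank
correlation (used for the FamRS-PGS relationship).

Continuous NRI: a person moves "up" iff the new model's predicted risk
strictly exceeds the old one's, "down" iff strictly lower; exact ties
move neither way.  NRI_events = P(up|event) - P(down|event),
NRI_non-events = P(down|non-event) - P(up|non-event), and the overall
NRI is their sum (range [-2, 2]).  IDI is the change in discrimination
slope: [mean p_new(events) - mean p_new(non-events)] minus the same for
the old model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ROCResult:
    auc: float
    best_threshold: float
    sensitivity: float
    specificity: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass(frozen=True)
class ReclassResult:
    nri_events: float
    nri_nonevents: float
    nri_overall: float
    prop_up_events: float
    prop_down_events: float
    prop_up_nonevents: float
    prop_down_nonevents: float
    z_nri: float
    p_nri: float
    idi: float | None = None
    z_idi: float | None = None
    p_idi: float | None = None


@dataclass(frozen=True)
class CorrelationResult:
    spearman_rho: float
    rho_squared: float
    p_value: float


def _check_labels(labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("need both events and non-events")
    return labels


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve, AUC and the Youden-optimal operating point.

    AUC is the Mann-Whitney concordance probability, computed from
    mid-ranks so ties contribute 1/2.  The best threshold maximises
    Youden J = sensitivity + specificity - 1; ties in J are broken
    toward higher specificity.
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    n1 = labels.sum()
    n0 = len(labels) - n1
    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    fpr, tpr, thr = roc_curve(labels, scores)
    j = tpr - fpr
    # among maximal J pick lowest fpr (= highest specificity)
    best = min(np.flatnonzero(j == j.max()), key=lambda i: fpr[i])
    return ROCResult(
        auc=float(auc),
        best_threshold=float(thr[best]),
        sensitivity=float(tpr[best]),
        specificity=float(1 - fpr[best]),
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
    )


def _moves(p_old, p_new, labels):
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    if p_old.shape != p_new.shape or len(p_old) != len(labels):
        raise ValueError("p_old, p_new and labels must have equal length")
    for p in (p_old, p_new):
        if ((p < 0) | (p > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")
    up = p_new > p_old
    down = p_new < p_old
    return up, down


def continuous_nri(p_old, p_new, labels) -> ReclassResult:
    """Continuous NRI of adding predictors (see module docstring).

    The z statistic uses the standard per-class binomial-difference
    variance, var = (p_up + p_down - (p_up - p_down)^2) / n_class,
    summed over classes.
    """
    labels = _check_labels(labels)
    up, down = _moves(p_old, p_new, labels)
    ev, ne = labels, ~labels
    n_e, n_ne = ev.sum(), ne.sum()
    pu_e, pd_e = up[ev].mean(), down[ev].mean()
    pu_ne, pd_ne = up[ne].mean(), down[ne].mean()
    nri_e = pu_e - pd_e
    nri_ne = pd_ne - pu_ne
    overall = nri_e + nri_ne
    var = (pu_e + pd_e - nri_e**2) / n_e + (pu_ne + pd_ne - nri_ne**2) / n_ne
    if var > 0:
        z = overall / math.sqrt(var)
    else:
        z = 0.0 if overall == 0 else math.copysign(math.inf, overall)
    p = 2 * stats.norm.sf(abs(z)) if math.isfinite(z) else 0.0
    return ReclassResult(
        nri_events=float(nri_e),
        nri_nonevents=float(nri_ne),
        nri_overall=float(overall),
        prop_up_events=float(pu_e),
        prop_down_events=float(pd_e),
        prop_up_nonevents=float(pu_ne),
        prop_down_nonevents=float(pd_ne),
        z_nri=float(z),
        p_nri=float(p),
    )


def idi(p_old, p_new, labels) -> tuple[float, float, float]:
    """IDI with z and p from per-class paired-difference standard errors."""
    labels = _check_labels(labels)
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    _moves(p_old, p_new, labels)  # validation
    d = p_new - p_old
    d_e, d_ne = d[labels], d[~labels]
    value = d_e.mean() - d_ne.mean()
    if len(d_e) > 1 and len(d_ne) > 1:
        se = math.sqrt(d_e.var(ddof=1) / len(d_e) + d_ne.var(ddof=1) / len(d_ne))
    else:
        se = math.nan
    if se > 0 and math.isfinite(se):
        z = value / se
        p = 2 * stats.norm.sf(abs(z))
    else:
        z, p = (math.inf * np.sign(value), 0.0) if value != 0 else (0.0, 1.0)
    return float(value), float(z), float(p)


def reclassification(p_old, p_new, labels) -> ReclassResult:
    """Continuous NRI and IDI of the new vs old risk model, combined."""
    nri = continuous_nri(p_old, p_new, labels)
    idi_val, z_idi, p_idi = idi(p_old, p_new, labels)
    return ReclassResult(
        **{k: getattr(nri, k) for k in (
            "nri_events", "nri_nonevents", "nri_overall",
            "prop_up_events", "prop_down_events",
            "prop_up_nonevents", "prop_down_nonevents",
            "z_nri", "p_nri",
        )},
        idi=idi_val,
        z_idi=z_idi,
        p_idi=p_idi,
    )


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation (Pearson on mid-ranks, t-approximate p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(float(rho), float(rho**2), float(p))
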