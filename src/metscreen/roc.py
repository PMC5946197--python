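"""Empirical ROC analysis with Youden-index cutpoint selection.

Candidate thresholds are the midpoints between consecutive sorted unique
score values plus -inf/+inf sentinels, with the decision rule
``score >= threshold => predicted positive``.  The trapezoid AUC over this
grid equals the Mann-Whitney concordance probability (ties counted half).
Confidence intervals and the test of AUC = 0.5 use the DeLong
structural-component variance by default, with a stratified bootstrap
alternative.  The optimal screening cutoff maximizes Youden's
J = sensitivity + specificity - 1; ties prefer higher sensitivity, then
the smaller cutoff (screening favours sensitivity).  The cutoff report
also carries the diagnostic likelihood ratios LR+ = sens/(1 - spec) and
LR- = (1 - sens)/spec.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateLabelsError, InsufficientDataError


@dataclass(frozen=True)
class RocCurve:
    """Full empirical ROC: per-threshold sensitivity and specificity.

    ``thresholds`` ascend from -inf (sens 1, spec 0) to +inf (sens 0,
    spec 1); sensitivity is non-increasing in the threshold.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int
    n_neg: int
    higher_is_positive: bool = True


@dataclass(frozen=True)
class CutoffReport:
    """Youden-selected screening threshold with diagnostic summary.

    ``sensitivity`` and ``specificity`` are percentages at full precision;
    presentation rounding (whole percent, 2-dp LRs) happens only at export.
    """

    auc: float
    auc_ci: tuple[float, float]
    p_value: float
    youden_j: float
    cutoff: float
    sensitivity: float
    specificity: float
    lr_pos: float
    lr_neg: float
    n_pos: int
    n_neg: int
    degenerate: bool = False


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise DegenerateLabelsError("scores and labels must be equal-length 1-d")
    if not np.all(np.isfinite(s)):
        raise DegenerateLabelsError("scores must be finite")
    if y.all() or (~y).all():
        raise DegenerateLabelsError(
            "need at least one positive and one negative label"
        )
    return s, y


def build_roc(scores, labels) -> RocCurve:
    """Exact-count empirical ROC over the midpoint threshold grid."""
    s, y = _as_arrays(scores, labels)
    uniq = np.unique(s)
    thr = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    pos = np.sort(s[y])
    neg = np.sort(s[~y])
    sens = 1.0 - np.searchsorted(pos, thr, side="left") / len(pos)
    spec = np.searchsorted(neg, thr, side="left") / len(neg)
    return RocCurve(
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        n_pos=len(pos),
        n_neg=len(neg),
    )


def auc_trapezoid(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC in (1 - specificity, sensitivity)."""
    fpr = 1.0 - curve.specificity
    tpr = curve.sensitivity
    # lexicographic order so vertical runs (tied fpr) ascend in tpr and
    # contribute zero area; diagonal tie segments contribute half
    order = np.lexsort((tpr, fpr))
    return float(np.trapezoid(tpr[order], fpr[order]))


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def delong_auc_variance(scores, labels) -> tuple[float, float]:
    """AUC and its DeLong variance from structural components."""
    s, y = _as_arrays(scores, labels)
    pos = s[y]
    neg = s[~y]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n          # per-positive placement
    v10 = 1.0 - (tz[m:] - ty) / m    # per-negative placement
    var = np.var(v01, ddof=1) / m + np.var(v10, ddof=1) / n
    return float(auc), float(var)


def auc_ci_delong(
    scores, labels, level: float = 0.95
) -> tuple[float, float, float]:
    """DeLong normal-approximation CI (truncated to [0, 1]) and the
    two-sided p-value for AUC = 0.5."""
    s, y = _as_arrays(scores, labels)
    if y.sum() < 2 or (~y).sum() < 2:
        raise InsufficientDataError(
            "DeLong interval needs >= 2 positives and >= 2 negatives"
        )
    auc, var = delong_auc_variance(s, y)
    se = np.sqrt(var)
    z = stats.norm.ppf(0.5 + level / 2.0)
    if se == 0.0:
        p = 1.0 if auc == 0.5 else 0.0
        return auc, auc, p
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    p = float(2.0 * stats.norm.sf(abs(auc - 0.5) / se))
    return lo, hi, p


def auc_ci_bootstrap(
    scores,
    labels,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Stratified-bootstrap percentile CI for the AUC.

    The p-value reported is the DeLong one (the bootstrap interval does not
    test AUC = 0.5 directly).
    """
    s, y = _as_arrays(scores, labels)
    if y.sum() < 2 or (~y).sum() < 2:
        raise InsufficientDataError(
            "bootstrap interval needs >= 2 positives and >= 2 negatives"
        )
    rng = np.random.default_rng(seed)
    pos = s[y]
    neg = s[~y]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ps = rng.choice(pos, size=len(pos), replace=True)
        ns = rng.choice(neg, size=len(neg), replace=True)
        # Mann-Whitney concordance via midranks, ties counted half
        tz = _midrank(np.concatenate([ps, ns]))
        aucs[b] = (tz[: len(ps)].sum() - len(ps) * (len(ps) + 1) / 2.0) / (
            len(ps) * len(ns)
        )
    alpha = 1.0 - level
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    _, _, p = auc_ci_delong(s, y, level)
    return float(lo), float(hi), p


def _likelihood_ratios(sens: float, spec: float) -> tuple[float, float]:
    lr_pos = sens / (1.0 - spec) if spec < 1.0 else np.inf
    lr_neg = (1.0 - sens) / spec if spec > 0.0 else np.inf
    return lr_pos, lr_neg


def youden_optimal_cutoff(
    curve: RocCurve, scores: Sequence[float] | None = None
) -> tuple[float, float, float, float, bool]:
    """Select the threshold maximizing J = sens + spec - 1.

    Returns ``(cutoff, sensitivity, specificity, j, degenerate)`` with
    sens/spec as fractions.  Ties in J are broken by the higher
    sensitivity, then the smaller cutoff; since sensitivity is
    non-increasing along the ascending threshold grid, both rules select
    the first maximizing grid point.  A curve whose best J is 0 (an
    uninformative score) is flagged degenerate and reports the median
    score (or the median finite threshold) as the cutoff.
    """
    j = curve.sensitivity + curve.specificity - 1.0
    jmax = float(j.max())
    if jmax <= 1e-12:
        if scores is not None:
            cut = float(np.median(np.asarray(scores, dtype=float)))
        else:
            finite = curve.thresholds[np.isfinite(curve.thresholds)]
            cut = float(np.median(finite)) if len(finite) else 0.0
        return cut, 1.0, 0.0, 0.0, True
    idx = int(np.argmax(j >= jmax - 1e-12))
    return (
        float(curve.thresholds[idx]),
        float(curve.sensitivity[idx]),
        float(curve.specificity[idx]),
        float(j[idx]),
        False,
    )


def cutoff_report(
    scores,
    labels,
    level: float = 0.95,
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int | None = None,
) -> CutoffReport:
    """Full screening summary: AUC, CI, p, Youden cutoff, sens/spec, LRs."""
    s, y = _as_arrays(scores, labels)
    curve = build_roc(s, y)
    auc = auc_trapezoid(curve)
    if ci_method == "delong":
        lo, hi, p = auc_ci_delong(s, y, level)
    elif ci_method == "bootstrap":
        lo, hi, p = auc_ci_bootstrap(s, y, level, n_boot=n_boot, seed=seed)
    else:
        raise InsufficientDataError(f"unknown ci_method {ci_method!r}")
    cutoff, sens, spec, jval, degen = youden_optimal_cutoff(curve, scores=s)
    lr_pos, lr_neg = _likelihood_ratios(sens, spec)
    return CutoffReport(
        auc=auc,
        auc_ci=(lo, hi),
        p_value=p,
        youden_j=jval,
        cutoff=cutoff,
        sensitivity=100.0 * sens,
        specificity=100.0 * spec,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        n_pos=curve.n_pos,
        n_neg=curve.n_neg,
        degenerate=degen,
    )


#: column order of the stratified cutoff table export
CUTOFF_TABLE_COLUMNS = (
    "stratum",
    "index",
    "auc",
    "ci_low",
    "ci_high",
    "p_value",
    "j",
    "cutoff",
    "sensitivity_pct",
    "specificity_pct",
    "lr_pos",
    "lr_neg",
    "n_pos",
    "n_neg",
)


def derive_cutoffs_stratified(
    df: pd.DataFrame,
    index_cols: Sequence[str] = ("tmi", "fmi"),
    label_col: str = "mets",
    strata_cols: Sequence[str] = ("sex", "age_group"),
    level: float = 0.95,
    ci_method: str = "delong",
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One cutoff report per stratum per index.

    Strata failing ROC preconditions (e.g. no MetS cases) are listed in the
    returned ``skipped`` table with a reason rather than aborting the run.
    """
    rows: list[dict] = []
    skipped: list[dict] = []
    for key, grp in df.groupby(list(strata_cols), sort=True):
        stratum = "/".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
        for index in index_cols:
            try:
                rep = cutoff_report(
                    grp[index].to_numpy(dtype=float),
                    grp[label_col].to_numpy(dtype=bool),
                    level=level,
                    ci_method=ci_method,
                    seed=seed,
                )
            except (DegenerateLabelsError, InsufficientDataError) as exc:
                skipped.append(
                    {"stratum": stratum, "index": index, "reason": str(exc)}
                )
                continue
            rows.append(
                {
                    "stratum": stratum,
                    "index": index,
                    "auc": rep.auc,
                    "ci_low": rep.auc_ci[0],
                    "ci_high": rep.auc_ci[1],
                    "p_value": rep.p_value,
                    "j": rep.youden_j,
                    "cutoff": rep.cutoff,
                    "sensitivity_pct": rep.sensitivity,
                    "specificity_pct": rep.specificity,
                    "lr_pos": rep.lr_pos,
                    "lr_neg": rep.lr_neg,
                    "n_pos": rep.n_pos,
                    "n_neg": rep.n_neg,
                }
            )
    return (
        pd.DataFrame(rows, columns=list(CUTOFF_TABLE_COLUMNS)),
        pd.DataFrame(skipped, columns=["stratum", "index", "reason"]),
    )


def format_cutoff_table(table: pd.DataFrame) -> pd.DataFrame:
    """Presentation rounding: whole-percent sens/spec, 2-dp LRs/J/cutoff,
    3-dp AUC/CI.  Internal values stay full precision."""
    out = table.copy()
    for c in ("auc", "ci_low", "ci_high"):
        out[c] = out[c].round(3)
    for c in ("j", "cutoff", "lr_pos", "lr_neg"):
        out[c] = out[c].round(2)
    for c in ("sensitivity_pct", "specificity_pct"):
        out[c] = out[c].round(0).astype(int)
    return out
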