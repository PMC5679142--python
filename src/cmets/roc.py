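"""ROC analysis and optimal cutoffs for the cMetS score.

Positivity rule: a subject is called positive when ``score >= threshold``
(inclusive at the threshold).  The curve is evaluated at every unique
observed score plus a ``+inf`` sentinel, so its endpoints are
(sensitivity, specificity) = (1, 0) and (0, 1).  AUC is computed as the
Mann–Whitney probability — (concordant pairs + half the ties) over
n_pos · n_neg — which coincides with trapezoidal integration of the
curve.  The optimal cutoff maximizes sensitivity + specificity (Youden's
J + 1); ties are broken toward the smallest threshold.

Confidence intervals: Wald normal approximation for sensitivity and
specificity, the DeLong structural-components variance for AUC, and a
seeded percentile bootstrap over the whole cutoff-selection procedure
for the cutoff itself.  None of these is claimed to be the method behind
any previously printed interval; all are recorded in run metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from cmets.synthetic import AGE_BANDS, age_band_of

logger = logging.getLogger(__name__)

__all__ = [
    "ROCCurve",
    "CutoffResult",
    "roc_curve",
    "auc",
    "optimal_cutoff",
    "delong_auc_ci",
    "wald_ci",
    "bootstrap_cutoff_ci",
    "confidence_intervals",
    "stratified_validation",
    "YoudenCutpoint",
]

DEFAULT_BOOTSTRAP_B = 1000
DEFAULT_BOOTSTRAP_SEED = 20150101
_Z95 = 1.959963984540054  # standard normal 97.5% quantile


def _validate(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.ndim != 1 or y.shape != s.shape:
        raise ValueError("scores and labels must be 1-d and aligned")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one positive and one negative label")
    return s, y


@dataclass
class ROCCurve:
    """Operating points of 'positive if score >= threshold'.

    ``thresholds`` are the sorted unique scores plus a +inf sentinel;
    sensitivity is non-increasing and specificity non-decreasing along
    them.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int
    n_neg: int

    def trapezoid_auc(self) -> float:
        """Area by trapezoidal integration in (1 − specificity, sensitivity)."""
        fpr = 1.0 - self.specificity  # descending from 1 to 0
        return float(abs(np.trapezoid(self.sensitivity, fpr)))


def roc_curve(scores, labels) -> ROCCurve:
    """Sensitivity/specificity at every unique score and the +inf sentinel."""
    s, y = _validate(scores, labels)
    pos = np.sort(s[y == 1])
    neg = np.sort(s[y == 0])
    thr = np.append(np.unique(s), np.inf)
    sens = (len(pos) - np.searchsorted(pos, thr, side="left")) / len(pos)
    spec = np.searchsorted(neg, thr, side="left") / len(neg)
    return ROCCurve(thr, sens, spec, int(len(pos)), int(len(neg)))


def auc(scores, labels) -> float:
    """Mann–Whitney AUC: P(score_pos > score_neg) + ½ P(tie)."""
    s, y = _validate(scores, labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = rankdata(s)  # midranks handle ties
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _optimal_cutoff_curve(curve: ROCCurve) -> float:
    finite = np.isfinite(curve.thresholds)
    if finite.sum() <= 1:
        raise ValueError("degenerate ROC curve: all scores tied")
    j = curve.sensitivity[finite] + curve.specificity[finite]
    # ties broken toward the smallest threshold; the tolerance absorbs float
    # noise while staying below 1/(n_pos*n_neg), the smallest genuine J gap
    best = np.flatnonzero(j >= j.max() - 1e-9)[0]
    return float(curve.thresholds[finite][best])


def optimal_cutoff(curve_or_scores, labels=None) -> float:
    """Threshold maximizing sensitivity + specificity (smallest on ties)."""
    if isinstance(curve_or_scores, ROCCurve):
        return _optimal_cutoff_curve(curve_or_scores)
    return _optimal_cutoff_curve(roc_curve(curve_or_scores, labels))


def wald_ci(p: float, n: int) -> tuple[float, float]:
    """Wald 95% interval p ± 1.96·√(p(1−p)/n), clipped to [0, 1]."""
    if n <= 0:
        raise ValueError("n must be positive")
    half = _Z95 * np.sqrt(p * (1.0 - p) / n)
    return (float(max(0.0, p - half)), float(min(1.0, p + half)))


def delong_auc_ci(scores, labels) -> tuple[float, tuple[float, float], float]:
    """AUC with its DeLong 95% CI and variance.

    Uses the structural components (placement values): for each positive
    the fraction of negatives it beats (ties half), and vice versa; the
    variance is the sum of the two between-subject sample variances over
    their group sizes.
    """
    s, y = _validate(scores, labels)
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    v10 = (all_ranks[:m] - rankdata(pos)) / n          # placements of positives
    v01 = 1.0 - (all_ranks[m:] - rankdata(neg)) / m    # placements of negatives
    a = float(v10.mean())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    half = _Z95 * np.sqrt(var)
    return a, (float(max(0.0, a - half)), float(min(1.0, a + half))), float(var)


def bootstrap_cutoff_ci(
    scores,
    labels,
    B: int = DEFAULT_BOOTSTRAP_B,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
) -> tuple[float, float]:
    """Seeded percentile bootstrap (2.5/97.5%) of the optimal-cutoff procedure."""
    if B < 200:
        raise ValueError("B must be at least 200 for a percentile interval")
    s, y = _validate(scores, labels)
    rng = np.random.default_rng(seed)
    n = len(s)
    cuts = np.empty(B)
    for b in range(B):
        while True:  # resample must contain both classes
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if 0 < yb.sum() < n:
                break
        sb = s[idx]
        if np.all(sb == sb[0]):
            cuts[b] = sb[0]
            continue
        cuts[b] = _optimal_cutoff_curve(roc_curve(sb, yb))
    lo, hi = np.quantile(cuts, [0.025, 0.975], method="linear")
    return (float(lo), float(hi))


@dataclass
class CutoffResult:
    """Optimal threshold with accuracy measures and 95% CIs for one stratum."""

    stratum: str
    n_pos: int
    n_neg: int
    cutoff: float
    cutoff_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    auc: float
    auc_ci: tuple[float, float]
    flags: list = field(default_factory=list)

    def as_row(self) -> dict:
        d = asdict(self)
        for k in ("cutoff_ci", "sensitivity_ci", "specificity_ci", "auc_ci"):
            lo, hi = d.pop(k)
            d[k.replace("_ci", "_ci_low")] = lo
            d[k.replace("_ci", "_ci_high")] = hi
        d["flags"] = ";".join(self.flags)
        return d


def confidence_intervals(
    scores,
    labels,
    cutoff: float | None = None,
    B: int = DEFAULT_BOOTSTRAP_B,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
    stratum: str = "",
) -> CutoffResult:
    """Full accuracy summary at a cutoff (optimal one when not given).

    Sensitivity/specificity use the 'score >= cutoff' rule with Wald
    intervals (flagged when on the 0/1 boundary), AUC the DeLong
    interval, and the cutoff a percentile bootstrap over the whole
    selection procedure (flagged unstable when positives < 10).
    """
    s, y = _validate(scores, labels)
    if cutoff is None:
        cutoff = _optimal_cutoff_curve(roc_curve(s, y))
    flags = []
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    sens = float((s[y == 1] >= cutoff).mean())
    spec = float((s[y == 0] < cutoff).mean())
    sens_ci = wald_ci(sens, n_pos)
    spec_ci = wald_ci(spec, n_neg)
    if sens in (0.0, 1.0) or spec in (0.0, 1.0):
        flags.append("boundary")
    a, a_ci, _ = delong_auc_ci(s, y)
    if n_pos < 10:
        flags.append("unstable")
    cut_ci = bootstrap_cutoff_ci(s, y, B=B, seed=seed)
    return CutoffResult(
        stratum=stratum, n_pos=n_pos, n_neg=n_neg,
        cutoff=float(cutoff), cutoff_ci=cut_ci,
        sensitivity=sens, sensitivity_ci=sens_ci,
        specificity=spec, specificity_ci=spec_ci,
        auc=a, auc_ci=a_ci, flags=flags,
    )


def stratified_validation(
    scored: pd.DataFrame,
    B: int = DEFAULT_BOOTSTRAP_B,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
    score_col: str = "cmets",
    label_col: str = "mets",
) -> list[CutoffResult]:
    """Cutoff results for every sex × age-band stratum plus overall rows.

    Twelve rows: each of the three age bands × (boys, girls, total),
    then boys, girls and total over the full 7–18 range.  A stratum with
    a single class yields a row of NaN estimates and a logged warning.
    Bootstrap seeds are derived per stratum from ``seed`` so rows are
    independent yet reproducible.
    """
    df = scored.dropna(subset=[score_col, label_col])
    band = age_band_of(df["age"].to_numpy())
    sexes = df["sex"].to_numpy()
    results = []
    strata = [(b, g) for b in AGE_BANDS for g in ("male", "female", "total")]
    strata += [("7-18", g) for g in ("male", "female", "total")]
    for k, (b, g) in enumerate(strata):
        sel = np.ones(len(df), dtype=bool) if b == "7-18" else band == b
        if g != "total":
            sel &= sexes == g
        name = f"{b}/{g}"
        sub_s = df.loc[sel, score_col].to_numpy(dtype=float)
        sub_y = df.loc[sel, label_col].to_numpy().astype(int)
        if len(sub_y) == 0 or sub_y.sum() in (0, len(sub_y)):
            logger.warning("stratum %s has a single class; estimates omitted", name)
            results.append(
                CutoffResult(
                    stratum=name, n_pos=int(sub_y.sum()), n_neg=int(len(sub_y) - sub_y.sum()),
                    cutoff=np.nan, cutoff_ci=(np.nan, np.nan),
                    sensitivity=np.nan, sensitivity_ci=(np.nan, np.nan),
                    specificity=np.nan, specificity_ci=(np.nan, np.nan),
                    auc=np.nan, auc_ci=(np.nan, np.nan), flags=["single_class"],
                )
            )
            continue
        results.append(
            confidence_intervals(sub_s, sub_y, B=B, seed=seed + k, stratum=name)
        )
    return results


class YoudenCutpoint(BaseEstimator):
    """Estimator wrapper: learn the max-(sens+spec) cutoff from scores.

    ``fit(scores, labels)`` derives the ROC-optimal threshold with CIs;
    ``predict(scores)`` applies the 'score >= cutoff' rule.  Composes
    with scikit-learn model selection on a 1-d score feature.
    """

    def __init__(self, B: int = DEFAULT_BOOTSTRAP_B, seed: int = DEFAULT_BOOTSTRAP_SEED,
                 compute_ci: bool = True):
        self.B = B
        self.seed = seed
        self.compute_ci = compute_ci

    @staticmethod
    def _scores_1d(X):
        s = np.asarray(X, dtype=float)
        if s.ndim == 2:
            if s.shape[1] != 1:
                raise ValueError("expected a single score column")
            s = s[:, 0]
        return s

    def fit(self, X, y):
        s = self._scores_1d(X)
        s, y = _validate(s, y)
        curve = roc_curve(s, y)
        self.cutoff_ = _optimal_cutoff_curve(curve)
        self.auc_ = auc(s, y)
        self.sensitivity_ = float((s[y == 1] >= self.cutoff_).mean())
        self.specificity_ = float((s[y == 0] < self.cutoff_).mean())
        self.curve_ = curve
        self.result_ = (
            confidence_intervals(s, y, self.cutoff_, B=self.B, seed=self.seed)
            if self.compute_ci
            else None
        )
        return self

    def predict(self, X):
        if not hasattr(self, "cutoff_"):
            raise RuntimeError("YoudenCutpoint is not fitted")
        return (self._scores_1d(X) >= self.cutoff_).astype(int)

    def score(self, X, y):
        """Balanced accuracy (mean of sens and spec) of the fitted rule."""
        y = np.asarray(y).astype(int)
        pred = self.predict(X)
        sens = (pred[y == 1] == 1).mean()
        spec = (pred[y == 0] == 0).mean()
        return float(0.5 * (sens + spec))
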