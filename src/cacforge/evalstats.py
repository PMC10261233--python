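"""Interscan agreement and reproducibility statistics.

Implements the evaluation toolkit for comparing calcium scores between a
thick-slice CTAC-like scan and the thin-slice CSCT reference:

* average absolute relative difference, Delta_R = |a - b| / ((a + b)/2),
  reported in percent over all pairs and over concordant pairs (both
  scans positive);
* Bland-Altman limits of agreement with a heteroscedastic, half-normal
  regression form: the absolute residuals |d_i - b| are regressed through
  the origin on sqrt(mean_i), and the fitted slope is inflated by
  1.96 * sqrt(pi/2) because |N(0, s^2)| is half-normal with mean
  s * sqrt(2/pi);
* patient-level detection metrics (sensitivity, specificity, F1);
* Cohen's linearly weighted kappa on the five risk categories, with an
  asymptotic (delta-method) 95% confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

HALF_NORMAL_FACTOR = math.sqrt(math.pi / 2.0)


@dataclass(frozen=True)
class ScorePair:
    patient_id: str
    ctac_score: float
    csct_score: float
    condition: str = "rest"

    def __post_init__(self):
        if self.ctac_score < 0 or self.csct_score < 0:
            raise ValueError("scores must be nonnegative")


@dataclass(frozen=True)
class BlandAltmanFit:
    b: float  # mean difference (bias)
    a: float  # slope of |d - b| on sqrt(mean), fitted through the origin

    def limits(self, mean):
        """(lower, upper) 95% limit curves evaluated at ``mean``."""
        mean = np.asarray(mean, dtype=float)
        spread = 1.96 * HALF_NORMAL_FACTOR * self.a * np.sqrt(mean)
        return self.b - spread, self.b + spread


@dataclass
class AgreementReport:
    delta_r_all: float
    delta_r_concordant: float | None
    ba: BlandAltmanFit
    sensitivity: float | None
    specificity: float | None
    f1: float | None
    kappa_lw: float | None
    kappa_ci: tuple[float, float] | None
    n_pairs: int
    condition: str = "rest"

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "n_pairs": self.n_pairs,
            "delta_r_all_pct": self.delta_r_all,
            "delta_r_concordant_pct": self.delta_r_concordant,
            "bland_altman_b": self.ba.b,
            "bland_altman_a": self.ba.a,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "kappa_lw": self.kappa_lw,
            "kappa_ci_low": None if self.kappa_ci is None else self.kappa_ci[0],
            "kappa_ci_high": None if self.kappa_ci is None else self.kappa_ci[1],
        }


# ---------------------------------------------------------------------------
# Delta_R
# ---------------------------------------------------------------------------

def pair_delta_r(a: float, b: float) -> float:
    """|a - b| / ((a + b)/2) in percent; 0/0 is defined as 0 (agreement on absence)."""
    if a < 0 or b < 0:
        raise ValueError("scores must be nonnegative")
    if a == 0 and b == 0:
        return 0.0
    # clamp: the metric's mathematical range is [0, 200] but floating-point
    # division can overshoot by an ulp when one score is zero
    return min(200.0, 200.0 * abs(a - b) / (a + b))


def delta_r(pairs, include_double_zero: bool = True):
    """Average Delta_R in percent: (all pairs, concordant pairs).

    Concordant pairs are those where calcium was detected in both scans
    (both scores > 0); with no concordant pair that average is None.
    ``include_double_zero=False`` drops both-zero pairs from the all-pairs
    average instead of counting them as 0%.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("delta_r requires at least one score pair")
    values = []
    concordant = []
    for p in pairs:
        v = pair_delta_r(p.ctac_score, p.csct_score)
        if p.ctac_score == 0 and p.csct_score == 0 and not include_double_zero:
            pass
        else:
            values.append(v)
        if p.ctac_score > 0 and p.csct_score > 0:
            concordant.append(v)
    all_avg = float(np.mean(values)) if values else 0.0
    conc_avg = float(np.mean(concordant)) if concordant else None
    return all_avg, conc_avg


# ---------------------------------------------------------------------------
# Bland-Altman with half-normal regression limits
# ---------------------------------------------------------------------------

def bland_altman(pairs) -> BlandAltmanFit:
    """Fit heteroscedastic limits of agreement to CTAC-vs-CSCT score pairs.

    The bias ``b`` is the plain mean difference; the spread coefficient
    ``a`` is the zero-intercept least-squares slope of |d_i - b| on
    sqrt(mean_i). Limit curves are ``b +/- 1.96*sqrt(pi/2)*a*sqrt(mean)``.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ValueError("bland_altman requires at least 3 pairs")
    d = np.array([p.ctac_score - p.csct_score for p in pairs], dtype=float)
    m = np.array([(p.ctac_score + p.csct_score) / 2.0 for p in pairs], dtype=float)
    if np.all(m == 0):
        raise ValueError("all pair means are zero; no agreement structure to fit")
    b = float(d.mean())
    s = np.sqrt(m)
    r = np.abs(d - b)
    denom = float(s @ s)
    a = float(s @ r) / denom if denom > 0 else 0.0
    return BlandAltmanFit(b=b, a=a)


def ba_coverage(pairs, fit: BlandAltmanFit) -> float:
    """Fraction of pairs whose difference falls inside the limit curves."""
    d = np.array([p.ctac_score - p.csct_score for p in pairs], dtype=float)
    m = np.array([(p.ctac_score + p.csct_score) / 2.0 for p in pairs], dtype=float)
    lo, hi = fit.limits(m)
    return float(np.mean((d >= lo) & (d <= hi)))


# ---------------------------------------------------------------------------
# Detection metrics
# ---------------------------------------------------------------------------

def detection_metrics(pred_positive, ref_positive):
    """Patient-level (sensitivity, specificity, f1); undefined ones are None.

    'Positive' means any calcium detected in the scan. Sensitivity is
    None (not 0) when the reference has no positives, specificity None
    when it has no negatives, and F1 None when there are neither true
    positives nor any predicted/actual positives.
    """
    pred = np.asarray(pred_positive, dtype=bool)
    ref = np.asarray(ref_positive, dtype=bool)
    if pred.shape != ref.shape:
        raise ValueError("prediction and reference lists differ in length")
    tp = int(np.sum(pred & ref))
    tn = int(np.sum(~pred & ~ref))
    fp = int(np.sum(pred & ~ref))
    fn = int(np.sum(~pred & ref))
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else None
    return sens, spec, f1


# ---------------------------------------------------------------------------
# Linearly weighted kappa
# ---------------------------------------------------------------------------

def weighted_kappa(cats_a, cats_b, n_categories: int = 5):
    """Cohen's linearly weighted kappa with an asymptotic 95% CI.

    Agreement weights are ``w_ij = 1 - |i - j| / (k - 1)``. Returns
    ``(kappa, ci_low, ci_high)``; all three are None when kappa is
    undefined (both raters constant and identical, so chance-corrected
    agreement has no scale).
    """
    a = np.asarray(cats_a, dtype=int)
    b = np.asarray(cats_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("category lists must be equal-length 1-D")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 rated items")
    k = n_categories
    if np.any((a < 1) | (a > k) | (b < 1) | (b > k)):
        raise ValueError(f"categories must be integers in 1..{k}")

    p = np.zeros((k, k))
    for i, j in zip(a - 1, b - 1):
        p[i, j] += 1.0
    p /= n
    idx = np.arange(k)
    w = 1.0 - np.abs(idx[:, None] - idx[None, :]) / (k - 1)
    pa = p.sum(axis=1)  # rater A marginal
    pb = p.sum(axis=0)  # rater B marginal
    po = float((w * p).sum())
    pe = float((w * np.outer(pa, pb)).sum())
    if 1.0 - pe < 1e-15:
        return None, None, None
    kappa = (po - pe) / (1.0 - pe)

    # delta-method SE for weighted kappa (Fleiss, Cohen & Everitt form)
    wbar_row = w @ pb  # E_j[w_ij] under B's marginal, per i
    wbar_col = pa @ w  # E_i[w_ij] under A's marginal, per j
    term = w - (wbar_row[:, None] + wbar_col[None, :]) * (1.0 - kappa)
    var = (float((p * term**2).sum()) - (kappa - pe * (1.0 - kappa)) ** 2) / (
        n * (1.0 - pe) ** 2
    )
    se = math.sqrt(max(var, 0.0))
    return kappa, kappa - 1.96 * se, kappa + 1.96 * se


# ---------------------------------------------------------------------------
# Composite report
# ---------------------------------------------------------------------------

def agreement_report(
    pairs,
    cats_ctac=None,
    cats_csct=None,
    condition: str = "rest",
) -> AgreementReport:
    """Assemble the full agreement report for one scan condition."""
    pairs = list(pairs)
    dr_all, dr_conc = delta_r(pairs)
    ba = bland_altman(pairs)
    sens, spec, f1 = detection_metrics(
        [p.ctac_score > 0 for p in pairs], [p.csct_score > 0 for p in pairs]
    )
    if cats_ctac is not None and cats_csct is not None:
        kappa, lo, hi = weighted_kappa(cats_ctac, cats_csct)
        ci = None if kappa is None else (lo, hi)
    else:
        kappa, ci = None, None
    return AgreementReport(
        delta_r_all=dr_all,
        delta_r_concordant=dr_conc,
        ba=ba,
        sensitivity=sens,
        specificity=spec,
        f1=f1,
        kappa_lw=kappa,
        kappa_ci=ci,
        n_pairs=len(pairs),
        condition=condition,
    )
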