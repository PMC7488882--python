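"""Statistical evaluation of stroke-timing classifiers.

Covers the full comparison suite for intensity-ratio classifiers of the
4.5-hour treatment window: correlations with onset time, ROC/AUC with
binomial-exact confidence intervals and DeLong paired comparisons, Youden-J
optimal cutoffs with diagnostic metrics, logistic regression with model
chi-square and AICc, precision-recall-gain curves with AUPRG for imbalanced
subcohorts, F1 scores, Randolph's free-marginal multirater kappa, and
majority adjudication of visual DWI/FLAIR mismatch ratings.

Classification direction is always explicit: T2, T2w, DWI and FLAIR ratios
grow with time, so "within window" means ratio at or below the cutoff
(direction "below"); ADC drops and stays low, so its within-window side is
"above".  Proportions on counts are carried as exact rationals and
converted to floats only for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "DIRECTIONS",
    "ConfusionTable",
    "MetricEstimate",
    "RocResult",
    "CutoffResult",
    "LogisticModel",
    "PrgResult",
    "KappaResult",
    "ConvergenceError",
    "correlate",
    "roc_auc",
    "compare_aucs",
    "youden_cutoff",
    "diagnostic_metrics",
    "f1_score",
    "fit_logistic",
    "predict_probability",
    "prg_curve",
    "free_marginal_kappa",
    "kappa_from_agreement",
    "majority_adjudicate",
    "evaluate_cohort",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile

#: side of the cutoff that means "within the treatment window", per ratio
DIRECTIONS: dict[str, str] = {
    "adc": "above",
    "dwi": "below",
    "t2w": "below",
    "t2": "below",
    "flair": "below",
}


class ConvergenceError(Exception):
    """Raised when a model fit fails, e.g. under perfect separation."""


# --------------------------------------------------------------------------
# basic containers


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, labels: Sequence[int],
                         predicted: Sequence[int]) -> "ConfusionTable":
        y = np.asarray(labels, dtype=bool)
        p = np.asarray(predicted, dtype=bool)
        if y.shape != p.shape:
            raise ValueError("labels and predictions must align")
        return cls(tp=int((y & p).sum()), fp=int((~y & p).sum()),
                   fn=int((y & ~p).sum()), tn=int((~y & ~p).sum()))


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion-type metric with its 95% CI (p +/- 1.96 SE)."""

    value: float
    ci: tuple[float, float]
    defined: bool = True
    fraction: Fraction | None = None

    @property
    def percent(self) -> float:
        return 100.0 * self.value


def _proportion(num: int, den: int) -> MetricEstimate:
    if den == 0:
        return MetricEstimate(value=float("nan"), ci=(float("nan"), float("nan")),
                              defined=False, fraction=None)
    frac = Fraction(num, den)
    p = float(frac)
    se = float(np.sqrt(p * (1.0 - p) / den))
    return MetricEstimate(value=p, ci=(max(0.0, p - Z95 * se), min(1.0, p + Z95 * se)),
                          fraction=frac)


@dataclass
class DiagnosticMetrics:
    accuracy: MetricEstimate
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate

    def as_dict(self) -> dict[str, MetricEstimate]:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "ppv": self.ppv, "npv": self.npv}


def diagnostic_metrics(ct: ConfusionTable) -> DiagnosticMetrics:
    """Accuracy, sensitivity, specificity, PPV and NPV with 95% CIs.

    Each metric is an exact rational on the counts; the CI is the normal
    approximation p +/- 1.96 sqrt(p(1-p)/n) on its own denominator.  A zero
    denominator flags the metric undefined rather than raising.
    """
    return DiagnosticMetrics(
        accuracy=_proportion(ct.tp + ct.tn, ct.total),
        sensitivity=_proportion(ct.tp, ct.tp + ct.fn),
        specificity=_proportion(ct.tn, ct.tn + ct.fp),
        ppv=_proportion(ct.tp, ct.tp + ct.fp),
        npv=_proportion(ct.tn, ct.tn + ct.fn),
    )


def f1_score(ct: ConfusionTable, ci_method: str = "proportion") -> MetricEstimate:
    """F1 = 2 TP / (2 TP + FP + FN) with a 95% normal-approximation CI.

    ``ci_method``:
      * "proportion" (default): SE = sqrt(F1 (1-F1) / n) over the n scored
        items, the convention that reproduces published F1 intervals for
        this analysis;
      * "delta": multinomial delta-method SE on (TP, FP, FN).
    """
    den = 2 * ct.tp + ct.fp + ct.fn
    if den == 0:
        return MetricEstimate(float("nan"), (float("nan"), float("nan")), defined=False)
    frac = Fraction(2 * ct.tp, den)
    f1 = float(frac)
    n = ct.total
    if ci_method == "proportion":
        se = float(np.sqrt(f1 * (1.0 - f1) / n))
    elif ci_method == "delta":
        p1, p2, p3 = ct.tp / n, ct.fp / n, ct.fn / n
        d = 2 * p1 + p2 + p3
        g = np.array([2 * (p2 + p3), -2 * p1, -2 * p1]) / d**2
        p = np.array([p1, p2, p3])
        var = (np.sum(g**2 * p) - np.sum(g * p) ** 2) / n
        se = float(np.sqrt(max(var, 0.0)))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return MetricEstimate(value=f1, ci=(max(0.0, f1 - Z95 * se), min(1.0, f1 + Z95 * se)),
                          fraction=frac)


# --------------------------------------------------------------------------
# correlation


def correlate(x: Sequence[float], y: Sequence[float],
              method: str = "pearson") -> tuple[float, float]:
    """Correlation of a ratio with onset time: (coefficient, two-tailed p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D and aligned")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.any(np.isnan(x)) or np.any(np.isnan(y)):
        raise ValueError("missing values are not allowed")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no defined correlation")
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    elif method == "kendall":
        r = stats.kendalltau(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r.statistic), float(r.pvalue)


# --------------------------------------------------------------------------
# ROC / AUC


def _oriented(scores: np.ndarray, direction: str) -> np.ndarray:
    """Orient scores so that larger means more likely positive."""
    if direction == "below":
        return -scores
    if direction == "above":
        return scores
    raise ValueError(f"direction must be 'above' or 'below', got {direction!r}")


def _check_two_classes(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return n_pos, n_neg


def _mann_whitney_auc(oriented: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney probability, ties counted one half."""
    ranks = stats.rankdata(oriented)
    n_pos, n_neg = _check_two_classes(labels)
    r_pos = ranks[labels.astype(bool)].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class RocResult:
    auc: float
    ci: tuple[float, float]
    p_value: float  # H0: AUC = 0.5 (Mann-Whitney)
    direction: str
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # in oriented-score units
    n_pos: int
    n_neg: int


def roc_auc(scores: Sequence[float], labels: Sequence[int],
            direction: str = "below") -> RocResult:
    """ROC curve and AUC of a ratio classifier.

    The AUC equals the Mann-Whitney probability that a random positive
    scores more extreme in the stated direction than a random negative,
    ties counted one half.  The 95% CI is binomial-exact (Clopper-Pearson)
    on the concordant pair count out of n_pos * n_neg pairs; the p-value
    against AUC = 0.5 is the two-sided Mann-Whitney test.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    s = _oriented(scores, direction)
    n_pos, n_neg = _check_two_classes(labels)
    auc = _mann_whitney_auc(s, labels)
    fpr, tpr, thr = _sk_roc_curve(labels, s)
    n_pairs = n_pos * n_neg
    x = auc * n_pairs
    lo = float(stats.beta.ppf(0.025, x, n_pairs - x + 1)) if x > 0 else 0.0
    hi = float(stats.beta.ppf(0.975, x + 1, n_pairs - x)) if x < n_pairs else 1.0
    p = float(stats.mannwhitneyu(s[labels == 1], s[labels == 0],
                                 alternative="two-sided").pvalue)
    return RocResult(auc=auc, ci=(lo, hi), p_value=p, direction=direction,
                     fpr=fpr, tpr=tpr, thresholds=thr, n_pos=n_pos, n_neg=n_neg)


def _delong_components(oriented: np.ndarray, labels: np.ndarray):
    """DeLong structural components V01 (per positive) and V10 (per negative)."""
    pos = oriented[labels.astype(bool)]
    neg = oriented[~labels.astype(bool)]
    m, n = len(pos), len(neg)
    tz = stats.rankdata(np.concatenate([pos, neg]))
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    return float(v01.mean()), v01, v10


def compare_aucs(score_sets: Mapping[str, Sequence[float]],
                 labels: Sequence[int],
                 directions: Mapping[str, str] | None = None,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise DeLong tests of AUC differences on paired scores.

    All classifiers must score the same patients.  Returns one row per pair
    with the AUCs, the DeLong z and p, and the Bonferroni-adjusted p
    (multiplied by the number of pairs, capped at 1).
    """
    labels = np.asarray(labels, dtype=int)
    names = list(score_sets)
    if len(names) < 2:
        raise ValueError("need at least two classifiers to compare")
    _check_two_classes(labels)
    comps = {}
    for name in names:
        s = np.asarray(score_sets[name], dtype=float)
        if s.shape != labels.shape:
            raise ValueError(f"scores for {name!r} are not paired with the labels")
        d = (directions or {}).get(name, DIRECTIONS.get(name, "above"))
        comps[name] = _delong_components(_oriented(s, d), labels)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    rows = []
    for a, b in pairs:
        auc_a, v01a, v10a = comps[a]
        auc_b, v01b, v10b = comps[b]
        m, n = len(v01a), len(v10a)
        var = 0.0
        if m > 1:
            var += float(np.var(v01a - v01b, ddof=1)) / m
        if n > 1:
            var += float(np.var(v10a - v10b, ddof=1)) / n
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (auc_a - auc_b) / np.sqrt(var)
            p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append({"a": a, "b": b, "auc_a": auc_a, "auc_b": auc_b,
                     "z": float(z), "p": p,
                     "p_adjusted": min(1.0, p * len(pairs)),
                     "alpha_adjusted": alpha / len(pairs)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Youden cutoff


@dataclass
class CutoffResult:
    cutoff: float
    j: float  # Youden index = sens + spec - 1
    direction: str
    confusion: ConfusionTable
    metrics: DiagnosticMetrics


def _predict(scores: np.ndarray, cutoff: float, direction: str) -> np.ndarray:
    return scores <= cutoff if direction == "below" else scores >= cutoff


def youden_cutoff(scores: Sequence[float], labels: Sequence[int],
                  direction: str = "below") -> CutoffResult:
    """Operating cutoff maximizing the Youden J index.

    Candidates are the midpoints of adjacent sorted unique scores plus one
    sentinel beyond each extreme.  Ties in J are broken toward the cutoff
    that classifies more patients as beyond the window (fewer predicted
    positives), which favors specificity and hence treatment safety.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if direction not in ("above", "below"):
        raise ValueError(f"direction must be 'above' or 'below', got {direction!r}")
    _check_two_classes(labels)
    u = np.unique(scores)
    pad = (u[-1] - u[0]) / 2.0 if len(u) > 1 else max(abs(u[0]) * 0.5, 1.0)
    candidates = np.concatenate([[u[0] - pad], (u[:-1] + u[1:]) / 2.0, [u[-1] + pad]])
    best = None
    for c in candidates:
        pred = _predict(scores, c, direction)
        ct = ConfusionTable.from_predictions(labels, pred)
        sens = Fraction(ct.tp, ct.tp + ct.fn)
        spec = Fraction(ct.tn, ct.tn + ct.fp)
        j = sens + spec - 1
        n_pred_pos = int(pred.sum())
        if best is None or j > best[0] or (j == best[0] and n_pred_pos < best[1]):
            best = (j, n_pred_pos, float(c), ct)
    j, _, cutoff, ct = best
    return CutoffResult(cutoff=cutoff, j=float(j), direction=direction,
                        confusion=ct, metrics=diagnostic_metrics(ct))


# --------------------------------------------------------------------------
# logistic regression


@dataclass
class LogisticModel:
    predictors: tuple[str, ...]
    params: dict[str, float]  # includes "intercept"
    se: dict[str, float]
    tstat: dict[str, float]
    pvalues: dict[str, float]
    chi2: float  # 2 (lnL_model - lnL_null)
    chi2_df: int
    chi2_p: float
    aicc: float
    llf: float
    llnull: float
    n: int
    fitted: np.ndarray


def fit_logistic(table: pd.DataFrame, predictors: Sequence[str],
                 response: str = "label") -> LogisticModel:
    """Maximum-likelihood logistic regression of the within-window label.

    Reports coefficients with SEs, t = beta/SE with two-sided normal
    p-values, the model chi-square against the intercept-only null with
    df = number of predictors, and AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1)
    with k parameters including the intercept.

    Raises
    ------
    ConvergenceError
        On perfect separation or non-convergence.
    """
    predictors = tuple(predictors)
    data = table[list(predictors) + [response]] if predictors else table[[response]]
    if data.isna().any().any():
        raise ValueError("missing predictor or response values")
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    k = len(predictors) + 1
    if n <= k + 1:
        raise ValueError("need more observations than parameters (AICc needs n > k + 1)")
    X = np.column_stack([np.ones(n)] + [data[p].to_numpy(dtype=float)
                                        for p in predictors])
    import warnings
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except PerfectSeparationWarning as exc:  # noqa: F841
            raise ConvergenceError("perfect separation: coefficients diverge") from None
        except Exception as exc:
            raise ConvergenceError(str(exc)) from exc
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError("logistic fit did not converge")
    names = ("intercept",) + predictors
    params = dict(zip(names, map(float, res.params)))
    se = dict(zip(names, map(float, res.bse)))
    tstat = {k_: params[k_] / se[k_] for k_ in names}
    pvalues = dict(zip(names, map(float, res.pvalues)))
    chi2 = float(2.0 * (res.llf - res.llnull)) if predictors else 0.0
    chi2_df = len(predictors)
    chi2_p = float(stats.chi2.sf(chi2, chi2_df)) if chi2_df else 1.0
    aicc = float(-2.0 * res.llf + 2 * k + 2 * k * (k + 1) / (n - k - 1))
    return LogisticModel(predictors=predictors, params=params, se=se,
                         tstat=tstat, pvalues=pvalues, chi2=chi2,
                         chi2_df=chi2_df, chi2_p=chi2_p, aicc=aicc,
                         llf=float(res.llf), llnull=float(res.llnull),
                         n=n, fitted=np.asarray(res.predict()))


def predict_probability(model: LogisticModel,
                        values: Mapping[str, float]) -> float:
    """Probability of being within the window: P = e^Y / (1 + e^Y)."""
    y = model.params["intercept"]
    for name in model.predictors:
        y += model.params[name] * values[name]
    return float(1.0 / (1.0 + np.exp(-y)))


# --------------------------------------------------------------------------
# precision-recall-gain


@dataclass
class PrgResult:
    prevalence: float
    points: np.ndarray  # (k, 2) columns: recall-gain, precision-gain
    auprg: float


def prg_curve(scores: Sequence[float], labels: Sequence[int],
              direction: str = "below") -> PrgResult:
    """Precision-recall-gain curve and its area (AUPRG).

    Gains are precision and recall linearly rescaled so that the
    always-positive baseline sits at 0 and the perfect classifier at 1:
    gain(v) = (v - pi) / ((1 - pi) v) with prevalence pi.  The AUPRG
    integrates precision-gain over recall-gain in [0, 1]; the crossing into
    nonnegative recall-gain is interpolated in count space, and the curve
    always ends at the all-positive point (1, 0).  0 marks a trivial
    classifier; negative areas mark worse-than-trivial ranking.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    s = _oriented(scores, direction)
    n_pos, n_neg = _check_two_classes(labels)
    n = n_pos + n_neg
    pi = n_pos / n
    if not 0.0 < pi < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    c = pi / (1.0 - pi)

    order = np.argsort(-s, kind="stable")
    y = labels[order]
    s_sorted = s[order]
    # operating points at each distinct threshold (ties grouped), plus (0, 0)
    boundaries = np.flatnonzero(np.diff(s_sorted)) + 1
    ks = np.concatenate([[0], boundaries, [n]])
    tp = np.concatenate([[0], np.cumsum(y)])[ks]
    fp = ks - tp

    # interpolate the recall-gain = 0 crossing (TP = pi * n_pos) in counts
    tp_star = pi * n_pos
    pts_tp, pts_fp = [], []
    for (tp0, fp0), (tp1, fp1) in zip(zip(tp[:-1], fp[:-1]), zip(tp[1:], fp[1:])):
        if tp0 < tp_star <= tp1 and tp1 > tp0:
            alpha = (tp_star - tp0) / (tp1 - tp0)
            pts_tp.append(tp_star)
            pts_fp.append(fp0 + alpha * (fp1 - fp0))
        if tp1 >= tp_star:
            pts_tp.append(tp1)
            pts_fp.append(fp1)
    pts_tp = np.asarray(pts_tp, dtype=float)
    pts_fp = np.asarray(pts_fp, dtype=float)
    with np.errstate(divide="ignore"):
        rg = 1.0 - c * (n_pos - pts_tp) / pts_tp
        pg = 1.0 - c * pts_fp / pts_tp
    area = 0.0
    for i in range(len(rg) - 1):
        if rg[i + 1] <= 0:
            continue
        x0, x1 = max(rg[i], 0.0), rg[i + 1]
        if x1 > x0:
            area += (x1 - x0) * (pg[i] + pg[i + 1]) / 2.0
        elif rg[i + 1] == rg[i]:
            continue
    keep = rg >= 0
    points = np.column_stack([rg[keep], pg[keep]])
    return PrgResult(prevalence=pi, points=points, auprg=float(area))


# --------------------------------------------------------------------------
# inter-rater agreement


@dataclass
class KappaResult:
    po: float  # overall observed agreement
    k: int  # number of rating categories
    kappa: float
    ci: tuple[float, float]
    n_items: int


def kappa_from_agreement(po: float, k: int) -> float:
    """Free-marginal kappa from an overall agreement: (Po - 1/k) / (1 - 1/k)."""
    if k < 2:
        raise ValueError("need at least 2 categories")
    if not 0.0 <= po <= 1.0:
        raise ValueError("Po must be in [0, 1]")
    return (po - 1.0 / k) / (1.0 - 1.0 / k)


def free_marginal_kappa(ratings, k: int | None = None) -> KappaResult:
    """Randolph's free-marginal multirater kappa.

    ``ratings`` is an items x raters table of category labels (any hashable
    values; a "no response" marker counts as its own category).  Observed
    agreement Po is the mean over items of the pairwise rater agreement;
    kappa = (Po - 1/k) / (1 - 1/k).  The 95% CI is a normal approximation
    from the between-item variance of per-item agreement.
    """
    arr = np.asarray(pd.DataFrame(ratings))
    n_items, n_raters = arr.shape
    if n_items < 1 or n_raters < 2:
        raise ValueError("need at least 1 item and 2 raters")
    categories = pd.unique(arr.ravel())
    if k is None:
        k = len(categories)
    if k < 2:
        raise ValueError("need at least 2 categories")
    po_items = np.empty(n_items)
    for i in range(n_items):
        _, counts = np.unique(arr[i], return_counts=True)
        po_items[i] = (counts * (counts - 1)).sum() / (n_raters * (n_raters - 1))
    po = float(po_items.mean())
    kappa = kappa_from_agreement(po, k)
    if n_items > 1:
        se = float(np.std(po_items, ddof=1) / np.sqrt(n_items) / (1.0 - 1.0 / k))
    else:
        se = float("nan")
    return KappaResult(po=po, k=k, kappa=kappa,
                       ci=(kappa - Z95 * se, kappa + Z95 * se), n_items=n_items)


def majority_adjudicate(ratings: pd.DataFrame,
                        rater_columns: Sequence[str] | None = None,
                        arbitrator_column: str = "arbitrator",
                        abstain_values: Iterable = ("uncertain", "", None),
                        ) -> pd.Series:
    """Final match/mismatch labels from multirater votes.

    The majority of non-abstaining raters decides each item; exact ties
    (including 2-2 splits and all-abstain items) go to the arbitrator.

    Raises
    ------
    ValueError
        If a tie occurs and the arbitrator value is missing or abstaining.
    """
    if rater_columns is None:
        rater_columns = [c for c in ratings.columns if c != arbitrator_column]
    abstain = set(abstain_values)
    out = []
    for idx, row in ratings.iterrows():
        votes = [row[c] for c in rater_columns
                 if row[c] not in abstain and not pd.isna(row[c])]
        counts = pd.Series(votes).value_counts() if votes else pd.Series(dtype=int)
        if len(counts) == 1 or (len(counts) > 1 and counts.iloc[0] > counts.iloc[1]):
            out.append(counts.index[0])
            continue
        arb = row.get(arbitrator_column)
        if arb in abstain or pd.isna(arb):
            raise ValueError(f"item {idx!r}: tied votes with no arbitrator decision")
        out.append(arb)
    return pd.Series(out, index=ratings.index, name="final")


# --------------------------------------------------------------------------
# cohort-level summary


def evaluate_cohort(table: pd.DataFrame,
                    map_types: Sequence[str] = ("adc", "dwi", "t2w", "t2", "flair"),
                    window_min: float = 270.0,
                    subcohort_metrics: bool = False) -> dict:
    """Full per-ratio evaluation of a cohort table.

    For every available ratio column: Pearson/Spearman/Kendall correlation
    with onset time, ROC/AUC with CI and p, the Youden-optimal cutoff with
    diagnostic metrics, and a single-predictor logistic model.  Pairwise
    DeLong AUC comparisons cover all complete classifiers.  With
    ``subcohort_metrics`` PRG/AUPRG and F1 at the Youden cutoff are added
    (the class-imbalance-robust view used for FLAIR subcohorts).
    """
    results: dict = {"n": int(len(table)), "window_min": window_min,
                     "prevalence": float(table["label"].mean()), "ratios": {}}
    labels = table["label"].to_numpy(dtype=int)
    onsets = table["onset_min"].to_numpy(dtype=float)
    complete_scores: dict[str, np.ndarray] = {}
    for name in map_types:
        col = f"ratio_{name}"
        if col not in table.columns or table[col].isna().all():
            continue
        mask = ~table[col].isna().to_numpy()
        scores = table.loc[mask, col].to_numpy(dtype=float)
        sub_labels = labels[mask]
        sub_onsets = onsets[mask]
        direction = DIRECTIONS.get(name, "above")
        entry: dict = {"direction": direction, "n": int(mask.sum())}
        for method in ("pearson", "spearman", "kendall"):
            try:
                coef, p = correlate(scores, sub_onsets, method)
                entry[method] = {"coefficient": coef, "p": p}
            except ValueError:
                entry[method] = None
        roc = roc_auc(scores, sub_labels, direction)
        entry["auc"] = roc.auc
        entry["auc_ci"] = list(roc.ci)
        entry["auc_p"] = roc.p_value
        cut = youden_cutoff(scores, sub_labels, direction)
        entry["cutoff"] = cut.cutoff
        entry["youden_j"] = cut.j
        entry["confusion"] = {"tp": cut.confusion.tp, "fp": cut.confusion.fp,
                              "fn": cut.confusion.fn, "tn": cut.confusion.tn}
        entry["metrics"] = {
            mname: {"value": m.value, "ci": list(m.ci), "defined": m.defined}
            for mname, m in cut.metrics.as_dict().items()}
        try:
            lm = fit_logistic(table.loc[mask], [col])
            entry["logistic"] = {"params": lm.params, "se": lm.se,
                                 "tstat": lm.tstat, "p": lm.pvalues,
                                 "chi2": lm.chi2, "chi2_df": lm.chi2_df,
                                 "chi2_p": lm.chi2_p, "aicc": lm.aicc}
        except (ConvergenceError, ValueError) as exc:
            entry["logistic"] = {"error": str(exc)}
        if subcohort_metrics:
            prg = prg_curve(scores, sub_labels, direction)
            entry["auprg"] = prg.auprg
            f1 = f1_score(cut.confusion)
            entry["f1"] = {"value": f1.value, "ci": list(f1.ci)}
        results["ratios"][name] = entry
        if mask.all():
            complete_scores[name] = scores
    if len(complete_scores) >= 2:
        results["auc_comparisons"] = compare_aucs(
            complete_scores, labels).to_dict(orient="records")
    return results
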