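"""Patient-level and group-level evaluation of a prediction-score model.

Patient level: the ROC curve of the score against observed responder status,
its AUC (the probability that a random responder outscores a random
non-responder) with a 95% confidence interval, and the confusion statistics
(sensitivity, specificity, PPV, NPV, accuracy) at a cutpoint chosen on the
derivation set only.

Group level: a Friedman rank test over the two paired conditions (run-in vs
active treatment) within the predicted responders and predicted
non-responders separately, with Kendall's coefficient of concordance W as the
effect size.  With two conditions the Friedman statistic reduces to the
sign-count form (n_plus - n_minus)^2 / (n_plus + n_minus) on tie-free data;
tied pairs enter through the standard tie correction.  scipy's Friedman test
requires at least three conditions, so the two-condition statistic is
computed here directly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import DegenerateLabelsError, SizeError

RESPONDER_LABEL = 2


def _as_binary(labels) -> np.ndarray:
    """Normalise responder labels ({1,2} or {0,1}/bool) to a bool array."""
    arr = np.asarray(labels)
    uniq = set(np.unique(arr).tolist())
    if uniq <= {1, 2}:
        return arr == RESPONDER_LABEL
    return arr.astype(bool)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    curve: list = field(repr=False, default_factory=list)  # ordered (FPR, TPR)


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def _delong_se(scores: np.ndarray, y: np.ndarray) -> float:
    """DeLong (1988) standard error of the AUC via placement values."""
    pos = scores[y]
    neg = scores[~y]
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s10 / m + s01 / n))


def roc_auc_ci(scores, labels, ci_method: str = "hanley") -> RocResult:
    """ROC curve and AUC with a 95% confidence interval.

    Ties count one half (the Mann-Whitney convention).  The CI uses the
    Hanley-McNeil standard error with z = 1.96 by default ("delong"
    selects the DeLong estimator); bounds are clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if scores.shape != y.shape:
        raise SizeError("scores and labels differ in length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("both responder classes must be present")
    auc = float(roc_auc_score(y, scores))
    if ci_method == "delong":
        se = _delong_se(scores, y)
    else:
        se = _hanley_mcneil_se(auc, n_pos, n_neg)
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    return RocResult(
        auc=auc,
        ci_low=float(max(0.0, auc - 1.96 * se)),
        ci_high=float(min(1.0, auc + 1.96 * se)),
        n_pos=n_pos,
        n_neg=n_neg,
        curve=[(float(a), float(b)) for a, b in zip(fpr, tpr)],
    )


def auc_from_dprime(dprime: float) -> float:
    """AUC of the equal-variance binormal model: Phi(d' / sqrt(2)).

    d' = 0.8 ('large' effect) corresponds to AUC ~ 0.714.
    """
    if not np.isfinite(dprime):
        raise ValueError("d-prime must be finite")
    return float(norm.cdf(dprime / np.sqrt(2.0)))


# ---------------------------------------------------------------------------
# cutpoint and confusion statistics
# ---------------------------------------------------------------------------


def choose_cutpoint(scores, labels, method: str = "youden") -> float:
    """Responder threshold maximising Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are the midpoints of adjacent distinct scores;
    a subject is predicted responder when score >= threshold.  Ties in J go
    to the lowest threshold.  With all scores equal the classifier is
    degenerate: the common value is returned with a warning.
    """
    if method != "youden":
        raise ValueError(f"unknown cutpoint method {method!r}")
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if not y.any() or y.all():
        raise DegenerateLabelsError("both responder classes must be present")
    distinct = np.unique(scores)
    if distinct.size == 1:
        warnings.warn("all scores identical; cutpoint is degenerate", stacklevel=2)
        return float(distinct[0])
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best_t, best_j = None, None
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    for t in candidates:
        pred = scores >= t
        # J = tp/n_pos + tn/n_neg - 1, compared exactly via cross-multiplication
        j = int((pred & y).sum()) * n_neg + int((~pred & ~y).sum()) * n_pos
        if best_j is None or j > best_j:
            best_t, best_j = t, j
    return float(best_t)


@dataclass(frozen=True)
class ConfusionStats:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float


def classification_stats(predicted, actual) -> ConfusionStats:
    """Confusion statistics; ratios with a zero denominator are NaN."""
    pred = _as_binary(predicted)
    act = _as_binary(actual)
    if pred.shape != act.shape:
        raise SizeError("predicted and actual differ in length")

    tp = int((pred & act).sum())
    fp = int((pred & ~act).sum())
    tn = int((~pred & ~act).sum())
    fn = int((~pred & act).sum())

    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return ConfusionStats(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        accuracy=ratio(tp + tn, tp + tn + fp + fn),
    )


# ---------------------------------------------------------------------------
# group-level: Friedman (k = 2) and Kendall's W
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupLevelResult:
    chi2: float
    df: int
    p: float
    w: float
    n: int
    k: int


def kendalls_w_from_friedman(chi2: float, n: int, k: int) -> float:
    """Kendall's coefficient of concordance: W = chi2 / (n (k - 1)), in [0,1]."""
    if n < 1 or k < 2 or chi2 < 0:
        raise ValueError("need n >= 1, k >= 2, chi2 >= 0")
    return float(min(1.0, max(0.0, chi2 / (n * (k - 1)))))


def friedman_two_conditions(pre, post) -> GroupLevelResult:
    """Friedman rank test for two paired conditions, with tie correction.

    Within-subject ranks (average ranks for ties) give the chi-square on
    df = 1; the standard tie correction divides by 1 - sum(t^3 - t) /
    (n k (k^2 - 1)).  When every pair is tied the statistic is 0 (warning).
    Kendall's W is attached via :func:`kendalls_w_from_friedman`.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise SizeError("pre and post differ in length")
    n = pre.size
    if n < 2:
        raise SizeError(f"Friedman test needs at least 2 pairs, got {n}")
    k = 2

    diff = post - pre
    r_pre = np.where(diff > 0, 1.0, np.where(diff < 0, 2.0, 1.5))
    r_post = 3.0 - r_pre
    rank_sums = np.array([r_pre.sum(), r_post.sum()])
    chi2_unc = 12.0 / (n * k * (k + 1)) * float((rank_sums**2).sum()) - 3.0 * n * (k + 1)

    n_tied = int((diff == 0).sum())
    correction = 1.0 - (n_tied * (2**3 - 2)) / (n * k * (k**2 - 1))
    if correction <= 0.0:
        warnings.warn("all pairs tied; Friedman statistic is 0", stacklevel=2)
        chi2_val, p, w = 0.0, 1.0, 0.0
    else:
        chi2_val = max(chi2_unc, 0.0) / correction
        p = float(chi2_dist.sf(chi2_val, df=k - 1))
        w = kendalls_w_from_friedman(chi2_val, n, k)
    return GroupLevelResult(chi2=float(chi2_val), df=k - 1, p=p, w=w, n=n, k=k)


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

SET_NAMES = ("derivation", "validation", "full")


@dataclass
class EvaluationReport:
    """ROC + confusion statistics per analysis set, group-level concordance.

    The cutpoint is chosen on the derivation set only and reused verbatim on
    the validation and full sets, so held-out statistics never see held-out
    labels during threshold choice.
    """

    cutpoint: float
    roc: dict
    confusion: dict
    group_level: dict
    scores: pd.Series = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "cutpoint": self.cutpoint,
            "roc": {
                name: {k: v for k, v in asdict(r).items()}
                for name, r in self.roc.items()
            },
            "confusion": {name: asdict(c) for name, c in self.confusion.items()},
            "group_level": {
                name: (None if g is None else asdict(g))
                for name, g in self.group_level.items()
            },
        }

    def to_json(self) -> str:
        def _clean(obj):
            if isinstance(obj, float) and np.isnan(obj):
                return None
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj

        return json.dumps(_clean(self.to_dict()), sort_keys=True, indent=1)

    def to_table(self) -> str:
        """Human-readable classification table (rows = statistics, columns = sets)."""
        rows = ("sensitivity", "specificity", "ppv", "npv", "accuracy")
        header = f"{'statistic':<12}" + "".join(f"{s:>12}" for s in SET_NAMES)
        lines = [header]
        for row in rows:
            cells = []
            for s in SET_NAMES:
                v = getattr(self.confusion[s], row)
                cells.append(f"{'NA':>12}" if np.isnan(v) else f"{v:>12.3f}")
            lines.append(f"{row:<12}" + "".join(cells))
        lines.append("")
        for s in SET_NAMES:
            r = self.roc[s]
            lines.append(
                f"AUC {s}: {r.auc:.3f} (95% CI {r.ci_low:.3f}-{r.ci_high:.3f}, "
                f"n+={r.n_pos}, n-={r.n_neg})"
            )
        for name, g in self.group_level.items():
            if g is None:
                lines.append(f"group-level {name}: not estimable")
            else:
                lines.append(
                    f"group-level {name}: chi2(N={g.n}, df={g.df}) = {g.chi2:.2f}, "
                    f"p = {g.p:.2g}, W = {g.w:.2f}"
                )
        return "\n".join(lines)


def evaluate_model(model, g, outcome, split, config=None) -> EvaluationReport:
    """Score a cohort and evaluate the model on derivation/validation/full sets.

    Group-level Friedman tests are run on the full set within the *predicted*
    responders and non-responders (pre = run-in counts, post = active counts;
    when only ΔSSE is available the paired test uses 0 vs ΔSSE, which has the
    identical rank structure).  A predicted group with fewer than 2 members
    or a single class yields a ``None`` block.
    """
    from .config import RunConfig
    from .pps_core import score_subjects

    config = config or RunConfig()
    scores = score_subjects(model, g)
    outcome = outcome.align_to(g)
    labels = outcome.delta_sse_d

    sets = {
        "derivation": list(split.derivation_ids),
        "validation": list(split.validation_ids),
        "full": list(scores.index),
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cutpoint = choose_cutpoint(
            scores.loc[sets["derivation"]],
            labels.loc[sets["derivation"]],
            method=config.cutpoint_method,
        )

    roc, confusion = {}, {}
    for name, ids in sets.items():
        s = scores.loc[ids].to_numpy()
        y = labels.loc[ids].to_numpy()
        roc[name] = roc_auc_ci(s, y, ci_method=config.ci_method)
        confusion[name] = classification_stats(s >= cutpoint, y)

    if outcome.sse_pri is not None and outcome.sse_active is not None:
        pre_all, post_all = outcome.sse_pri, outcome.sse_active
    else:
        pre_all = pd.Series(0, index=scores.index)
        post_all = outcome.delta_sse

    group_level = {}
    predicted_responder = scores >= cutpoint
    for name, sel in (
        ("predicted_responders", predicted_responder),
        ("predicted_non_responders", ~predicted_responder),
    ):
        ids = scores.index[sel]
        if len(ids) < 2:
            group_level[name] = None
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            group_level[name] = friedman_two_conditions(
                pre_all.loc[ids].to_numpy(), post_all.loc[ids].to_numpy()
            )

    return EvaluationReport(
        cutpoint=cutpoint, roc=roc, confusion=confusion,
        group_level=group_level, scores=scores,
    )
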