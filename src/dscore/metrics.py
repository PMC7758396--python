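"""Diagnostic test evaluation: confusion metrics, Wald CIs, ROC/AUC, t-tests.

Conventions follow the clinical-reporting style the package reproduces:

* sensitivity/specificity/PPV/NPV are percentages with symmetric Wald
  intervals ``100 * (p ± 1.96 sqrt(p(1-p)/n))`` that are deliberately NOT
  clipped to [0, 100] — near-perfect metrics on small denominators
  legitimately print upper bounds above 100%;
* ROC curves sweep the unique score values (higher score = more positive),
  AUC is the trapezoidal area, identical to the Mann-Whitney concordance
  probability with half credit for ties;
* AUC confidence intervals use the Hanley-McNeil standard error;
* per-gene differential expression uses two-sample t-tests (Welch by
  default) on the x1000 CtS scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "wald_interval",
    "ConfusionSummary",
    "confusion",
    "performance_table",
    "RocResult",
    "roc",
    "auc_interval",
    "GeneTestResult",
    "gene_ttest",
    "gene_ttest_table",
]

Z95 = 1.96


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (printed tables use half-up, not banker's)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def wald_interval(k: int, n: int, z: float = Z95) -> tuple[float, float, float]:
    """Unclipped Wald interval for a binomial proportion, on the % scale.

    Returns ``(point, lower, upper)`` as percentages; bounds may fall
    outside [0, 100] by construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    p = k / n
    hw = z * np.sqrt(p * (1.0 - p) / n)
    return (100.0 * p, 100.0 * (p - hw), 100.0 * (p + hw))


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 counts with the four clinical metrics and their Wald intervals."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> tuple[float, float, float]:
        return wald_interval(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> tuple[float, float, float]:
        return wald_interval(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> tuple[float, float, float]:
        return wald_interval(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> tuple[float, float, float]:
        return wald_interval(self.tn, self.tn + self.fn)

    def metric(self, name: str) -> tuple[float, float, float]:
        return getattr(self, name)


def confusion(calls, truth, positive_class, unknown_labels=("unknown",)) -> ConfusionSummary:
    """Tabulate predicted vs true binary labels into a ConfusionSummary.

    Samples whose true label is in ``unknown_labels`` (or NaN) are dropped
    with a logged count. The remaining truth must contain at least one
    positive sample (sensitivity is undefined otherwise).
    """
    calls = pd.Series(list(calls))
    truth = pd.Series(list(truth))
    if len(calls) != len(truth):
        raise ValueError("calls and truth differ in length")
    known = truth.notna() & ~truth.isin(unknown_labels)
    dropped = int((~known).sum())
    if dropped:
        logger.info("dropping %d samples with unknown truth label", dropped)
    calls, truth = calls[known], truth[known]
    if not (truth == positive_class).any():
        raise ValueError(
            f"no samples of positive class {positive_class!r} in truth; "
            "sensitivity undefined"
        )
    pos_call = calls == positive_class
    pos_true = truth == positive_class
    return ConfusionSummary(
        tp=int((pos_call & pos_true).sum()),
        fp=int((pos_call & ~pos_true).sum()),
        fn=int((~pos_call & pos_true).sum()),
        tn=int((~pos_call & ~pos_true).sum()),
    )


def _fmt(triple: tuple[float, float, float]) -> str:
    # printed order is "point (upper-lower)%"
    pt, lo, hi = (round_half_up(v) for v in triple)
    return f"{pt:.2f} ({hi:.2f}–{lo:.2f})%"


def performance_table(summaries: dict[str, ConfusionSummary]) -> pd.DataFrame:
    """Render named confusion summaries as a report table.

    One column per summary; rows give the 2x2 counts and the four metrics
    formatted "xx.xx (upper-lower)%" with percentages rounded half-up to
    two decimals at rendering only.
    """
    if not summaries:
        raise ValueError("at least one summary required")
    rows = {}
    for name, s in summaries.items():
        rows[name] = {
            "TP": s.tp,
            "FN": s.fn,
            "FP": s.fp,
            "TN": s.tn,
            "Total": s.n,
            "Sensitivity (95% CI)": _fmt(s.sensitivity),
            "Specificity (95% CI)": _fmt(s.specificity),
            "PPV (95% CI)": _fmt(s.ppv),
            "NPV (95% CI)": _fmt(s.npv),
        }
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RocResult:
    """A swept ROC curve with trapezoidal AUC and Hanley-McNeil CI."""

    points: np.ndarray  # (m, 2) array of (fpr, tpr), (0,0) .. (1,1)
    auc: float
    auc_ci: tuple[float, float]
    n_pos: int
    n_neg: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["fpr", "tpr"])


def roc(scores, truth, positive_class) -> RocResult:
    """ROC curve by threshold sweep over the unique score values.

    Higher scores indicate the positive class. Tied scores move as one
    block, which gives tied positive-negative pairs half credit in the
    trapezoidal area — the Mann-Whitney convention.
    """
    scores = np.asarray(list(scores), dtype=float)
    truth = pd.Series(list(truth))
    if len(scores) != len(truth):
        raise ValueError("scores and truth differ in length")
    pos = (truth == positive_class).to_numpy()
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative sample")

    order = np.argsort(-scores, kind="stable")
    s_sorted, pos_sorted = scores[order], pos[order]
    # threshold only at distinct score values
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tps = np.cumsum(pos_sorted)[distinct]
    fps = np.cumsum(~pos_sorted)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(
        points=points,
        auc=auc,
        auc_ci=auc_interval(auc, n_pos, n_neg),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def auc_interval(
    auc: float, n_pos: int, n_neg: int, z: float = Z95
) -> tuple[float, float]:
    """Hanley-McNeil 95% interval for an AUC, clipped to [0, 1]."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both class counts must be >= 1")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    return (max(0.0, float(auc) - z * se), min(1.0, float(auc) + z * se))


@dataclass(frozen=True)
class GeneTestResult:
    """Two-group differential expression of one gene (x1000 CtS scale)."""

    gene: str
    mean_a: float
    mean_b: float
    difference: float  # mean_a - mean_b
    t_statistic: float
    p_value: float
    significant: bool  # at alpha = 0.05


def gene_ttest(
    profiles: pd.DataFrame,
    gene: str,
    group_split: tuple[str, str],
    equal_var: bool = False,
    alpha: float = 0.05,
) -> GeneTestResult:
    """Two-sample t-test for one gene between two labelled groups.

    ``group_split`` is (group A label, group B label); the reported
    difference is mean(A) - mean(B). Welch's unequal-variance test is the
    default; set ``equal_var=True`` for the pooled variant.
    """
    if gene not in profiles.columns:
        raise ValueError(f"gene {gene!r} not in profiles")
    label_a, label_b = group_split
    a = profiles.loc[profiles["label"] == label_a, gene].to_numpy(dtype=float)
    b = profiles.loc[profiles["label"] == label_b, gene].to_numpy(dtype=float)
    for vals, label in ((a, label_a), (b, label_b)):
        if len(vals) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 samples")
        if np.var(vals, ddof=1) == 0:
            raise ValueError(f"group {label!r} has zero variance for {gene}")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GeneTestResult(
        gene=gene,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        difference=float(a.mean() - b.mean()),
        t_statistic=float(t),
        p_value=float(p),
        significant=bool(p < alpha),
    )


def gene_ttest_table(
    profiles: pd.DataFrame,
    genes,
    group_split: tuple[str, str],
    equal_var: bool = False,
) -> pd.DataFrame:
    """Run ``gene_ttest`` over a panel; one row per gene, panel order."""
    rows = [gene_ttest(profiles, g, group_split, equal_var) for g in genes]
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("gene")
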